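"""Synthetic multimodal, multi-site cohort generation.

Generates two-group cohorts with known ground-truth effects: regional
additive shifts in structural maps, within-region temporal coherence and
band-limited amplitude changes in BOLD-like series, inter-regional latent
correlation shifts, age/sex confound slopes and per-site offset/gain
nuisances.  Every downstream stage of the package is testable against the
recorded truth without downloading any data.

The BOLD model is a per-region latent signal model: each region owns a
band-limited (0.01-0.08 Hz) latent time course, latents are correlated
across regions through a user-controlled correlation matrix, and each
member voxel mixes its region's latent with private broadband noise.  The
shared-variance fraction (coherence) controls ReHo, the series gain
controls ALFF, and the latent correlations control functional
connectivity -- three independent handles.

Units: translations in mm, rotations in **radians**, TR in seconds.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy import signal
from scipy.ndimage import gaussian_filter, label as cc_label

from neurofuse.functional import BoldSeries
from neurofuse.structural import VoxelVolume

__all__ = [
    "Atlas",
    "SubjectMeta",
    "SiteEffect",
    "EffectSpec",
    "NoiseSpec",
    "Demographics",
    "Cohort",
    "generate_atlas",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "effects_from_yaml",
]

MIN_REGION_VOXELS = 8


@dataclass
class Atlas:
    """Integer-labelled parcellation sharing the cohort grid.

    ``labels`` uses 0 for background and contiguous codes ``1..R``.
    """

    labels: np.ndarray
    region_names: list[str]
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)

    @property
    def R(self) -> int:
        return len(self.region_names)

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        codes = set(np.unique(self.labels).tolist())
        if not codes.issuperset(range(1, self.R + 1)) or not codes.issubset(
            range(0, self.R + 1)
        ):
            raise ValueError(
                f"atlas labels must be contiguous 1..{self.R} "
                f"(0 = background), got {sorted(codes)}"
            )
        counts = np.bincount(self.labels.ravel())
        too_small = [c for c in range(1, self.R + 1) if counts[c] < MIN_REGION_VOXELS]
        if too_small:
            raise ValueError(
                f"regions {too_small} have fewer than {MIN_REGION_VOXELS} voxels"
            )

    def region_voxels(self, code: int) -> np.ndarray:
        return self.labels == code


@dataclass
class SubjectMeta:
    id: str
    group: str  # "patient" | "control"
    age: float
    sex: str  # "M" | "F"
    site: str

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError(f"group must be patient/control, got {self.group!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M/F, got {self.sex!r}")


@dataclass
class SiteEffect:
    """Additive/multiplicative per-site nuisances."""

    struct_offset: float = 0.0
    struct_gain: float = 1.0
    bold_gain: float = 1.0
    bold_noise_gain: float = 1.0


@dataclass
class EffectSpec:
    """Ground-truth group effects injected into a synthetic cohort.

    ``struct_effect_d`` is a standardized mean shift (Cohen's d on region
    mean) added to patients in ``struct_regions``.  ``coherence_shift``
    raises the shared-variance fraction of voxels in ``reho_regions`` for
    patients.  ``amplitude_shift`` multiplies patient voxel series in
    ``alff_regions`` (1.0 = no effect).  ``fc_shift`` is added to the
    latent correlation of ``fc_edges`` for patients.
    """

    struct_effect_d: float = 0.0
    coherence_shift: float = 0.0
    amplitude_shift: float = 1.0
    fc_shift: float = 0.0
    struct_regions: tuple[int, ...] = ()
    reho_regions: tuple[int, ...] = ()
    alff_regions: tuple[int, ...] = ()
    fc_edges: tuple[tuple[int, int], ...] = ()
    age_slope: float = 0.0
    sex_effect: float = 0.0
    site_effects: dict[str, SiteEffect] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.amplitude_shift <= 0:
            raise ValueError("amplitude_shift must be > 0")
        self.struct_regions = tuple(int(r) for r in self.struct_regions)
        self.reho_regions = tuple(int(r) for r in self.reho_regions)
        self.alff_regions = tuple(int(r) for r in self.alff_regions)
        self.fc_edges = tuple((int(i), int(j)) for i, j in self.fc_edges)
        self.site_effects = {
            k: (v if isinstance(v, SiteEffect) else SiteEffect(**v))
            for k, v in self.site_effects.items()
        }


@dataclass
class NoiseSpec:
    """Scales of the generative noise model."""

    voxel_sigma: float = 0.05       # iid voxel noise in structural maps
    region_sigma: float = 0.05      # per-subject, per-region structural level
    subject_sigma: float = 0.03     # per-subject global structural level
    base_coherence: float = 0.35    # shared-variance fraction of region latent
    base_corr: float = 0.10         # latent correlation between all regions
    motion_step_trans: float = 0.02  # mm per volume (random walk)
    motion_step_rot: float = 2e-4    # rad per volume
    struct_smooth_sigma: float = 1.5  # voxels, cohort template smoothness


@dataclass
class Demographics:
    age_mean_control: float = 32.0
    age_mean_patient: float = 32.0
    age_sd: float = 9.0
    age_range: tuple[float, float] = (18.0, 65.0)
    male_fraction: float = 0.6


@dataclass
class Cohort:
    meta: list[SubjectMeta]
    gm: list[VoxelVolume]
    wm: list[VoxelVolume]
    bold: list[BoldSeries]
    motion: list[np.ndarray]  # T x 6: trans x/y/z (mm), rot x/y/z (rad)
    atlas: Atlas
    effects: EffectSpec
    noise: NoiseSpec
    tr: float
    seed: int

    @property
    def n_subjects(self) -> int:
        return len(self.meta)


def generate_atlas(
    shape: tuple[int, int, int],
    R: int,
    seed: int,
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0),
) -> Atlas:
    """Partition an ellipsoidal brain mask into R contiguous regions.

    Seeds are placed by farthest-point sampling and voxels take the label
    of the nearest seed, which yields compact connected blobs.  Raises if
    the grid cannot host R regions of >= 8 voxels.
    """
    if R < 2:
        raise ValueError("R must be >= 2")
    shape = tuple(int(s) for s in shape)
    grid = np.indices(shape).reshape(3, -1).T.astype(float)
    center = (np.asarray(shape, float) - 1.0) / 2.0
    semi = np.maximum(np.asarray(shape, float) * 0.45, 1.0)
    inside = (((grid - center) / semi) ** 2).sum(axis=1) <= 1.0
    mask_idx = np.where(inside)[0]
    if mask_idx.size < MIN_REGION_VOXELS * R:
        raise ValueError(
            f"shape {shape} holds {mask_idx.size} brain voxels; cannot fit "
            f"{R} regions of >= {MIN_REGION_VOXELS} voxels"
        )
    rng = np.random.default_rng(seed)
    coords = grid[mask_idx]

    for _ in range(25):
        # farthest-point seed placement from a random start
        seeds = [coords[rng.integers(coords.shape[0])]]
        d = np.linalg.norm(coords - seeds[0], axis=1)
        for _ in range(R - 1):
            nxt = coords[int(np.argmax(d))]
            seeds.append(nxt)
            d = np.minimum(d, np.linalg.norm(coords - nxt, axis=1))
        seeds_arr = np.asarray(seeds)
        dists = np.linalg.norm(coords[:, None, :] - seeds_arr[None, :, :], axis=2)
        assign = np.argmin(dists, axis=1) + 1

        labels = np.zeros(shape, dtype=np.int16)
        labels.reshape(-1)[mask_idx] = assign
        counts = np.bincount(assign, minlength=R + 1)
        if counts[1:].min() < MIN_REGION_VOXELS:
            continue
        if all(cc_label(labels == c)[1] == 1 for c in range(1, R + 1)):
            names = [f"region_{c:03d}" for c in range(1, R + 1)]
            return Atlas(labels=labels, region_names=names, voxel_size=voxel_size)
    raise ValueError(f"could not place {R} valid regions on shape {shape}")


def _draw_meta(
    n_per_group: int,
    sites: Sequence[str],
    demo: Demographics,
    rng: np.random.Generator,
) -> list[SubjectMeta]:
    meta: list[SubjectMeta] = []
    idx = 0
    for group, age_mean in (
        ("patient", demo.age_mean_patient),
        ("control", demo.age_mean_control),
    ):
        for k in range(n_per_group):
            age = float(
                np.clip(rng.normal(age_mean, demo.age_sd), *demo.age_range)
            )
            sex = "M" if rng.random() < demo.male_fraction else "F"
            site = sites[k % len(sites)]  # balanced within group
            meta.append(
                SubjectMeta(
                    id=f"sub-{idx:04d}", group=group, age=age, sex=sex, site=site
                )
            )
            idx += 1
    return meta


def _latent_correlation(
    R: int, effects: EffectSpec, noise: NoiseSpec, patient: bool
) -> np.ndarray:
    C = np.full((R, R), noise.base_corr)
    np.fill_diagonal(C, 1.0)
    if patient:
        for i, j in effects.fc_edges:
            rho = noise.base_corr + effects.fc_shift
            C[i - 1, j - 1] = C[j - 1, i - 1] = rho
    if np.any(np.abs(C[~np.eye(R, dtype=bool)]) >= 1.0):
        raise ValueError("fc_shift implies a correlation outside (-1, 1)")
    if np.linalg.eigvalsh(C).min() <= 1e-10:
        raise ValueError("latent correlation matrix is not positive definite")
    return C


def _bandlimited_latents(
    T: int, R: int, tr: float, C: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """T x R correlated, unit-variance, band-limited latent signals."""
    white = rng.standard_normal((T, R))
    nyq = 0.5 / tr
    sos = signal.butter(4, [0.01 / nyq, 0.08 / nyq], btype="band", output="sos")
    band = signal.sosfiltfilt(sos, white, axis=0)
    band = band - band.mean(axis=0)
    band = band / band.std(axis=0, ddof=0)
    L = np.linalg.cholesky(C)
    z = band @ L.T
    # re-standardize so coherence fractions are exact mixing weights
    return z / z.std(axis=0, ddof=0)


def generate_cohort(
    n_per_group: int,
    atlas: Atlas,
    effects: EffectSpec | None = None,
    noise: NoiseSpec | None = None,
    T: int = 120,
    tr: float = 2.0,
    seed: int = 0,
    sites: Sequence[str] = ("site1",),
    demographics: Demographics | None = None,
) -> Cohort:
    """Generate a two-group multimodal cohort on ``atlas``'s grid.

    Structural maps are a smooth cohort template plus per-subject global,
    per-region and voxel-level noise, group/confound/site terms.  BOLD
    series follow the latent-signal model described in the module
    docstring.  Motion traces are small random walks.  Deterministic for a
    fixed argument set.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if T < 40:
        raise ValueError("T must be >= 40")
    effects = effects or EffectSpec()
    noise = noise or NoiseSpec()
    demo = demographics or Demographics()
    rng = np.random.default_rng(seed)

    R = atlas.R
    shape = atlas.labels.shape
    mask = atlas.mask
    labels_flat = atlas.labels.ravel()
    region_sizes = np.bincount(labels_flat, minlength=R + 1)[1:]

    for r in (*effects.struct_regions, *effects.reho_regions, *effects.alff_regions):
        if not 1 <= r <= R:
            raise ValueError(f"affected region {r} outside 1..{R}")
    for i, j in effects.fc_edges:
        if not (1 <= i <= R and 1 <= j <= R) or i == j:
            raise ValueError(f"invalid fc edge ({i}, {j})")

    meta = _draw_meta(n_per_group, sites, demo, rng)
    mean_age = float(np.mean([m.age for m in meta]))

    # cohort-level smooth anatomical templates
    gm_template = 0.5 + 0.1 * gaussian_filter(
        rng.standard_normal(shape), noise.struct_smooth_sigma
    )
    wm_template = 0.4 + 0.1 * gaussian_filter(
        rng.standard_normal(shape), noise.struct_smooth_sigma
    )

    # standardized shift scale: between-subject SD of a region's mean value
    sigma_between = np.sqrt(
        noise.subject_sigma**2
        + noise.region_sigma**2
        + noise.voxel_sigma**2 / region_sizes
    )

    C_pat = _latent_correlation(R, effects, noise, patient=True)
    C_con = _latent_correlation(R, effects, noise, patient=False)

    gm_list: list[VoxelVolume] = []
    wm_list: list[VoxelVolume] = []
    bold_list: list[BoldSeries] = []
    motion_list: list[np.ndarray] = []

    for m in meta:
        is_pat = m.group == "patient"
        site_fx = effects.site_effects.get(m.site, SiteEffect())

        # --- structural maps -------------------------------------------------
        subj_level = rng.normal(0.0, noise.subject_sigma)
        region_level = rng.normal(0.0, noise.region_sigma, size=R)
        shift = np.zeros(R)
        if is_pat and effects.struct_effect_d != 0.0:
            for r in effects.struct_regions:
                shift[r - 1] = effects.struct_effect_d * sigma_between[r - 1]
        per_region = region_level + shift
        region_map = np.zeros(shape)
        region_map.reshape(-1)[labels_flat > 0] = per_region[
            labels_flat[labels_flat > 0] - 1
        ]
        confound = effects.age_slope * (m.age - mean_age) + effects.sex_effect * (
            m.sex == "M"
        )

        for template, out in ((gm_template, gm_list), (wm_template, wm_list)):
            data = (
                template
                + subj_level
                + region_map
                + confound
                + rng.normal(0.0, noise.voxel_sigma, size=shape)
            )
            data = np.where(
                mask, site_fx.struct_gain * data + site_fx.struct_offset, data
            )
            out.append(
                VoxelVolume(data=data, mask=mask.copy(), voxel_size=atlas.voxel_size)
            )

        # --- BOLD series -----------------------------------------------------
        C = C_pat if is_pat else C_con
        z = _bandlimited_latents(T, R, tr, C, rng)  # T x R
        coherence = np.full(R, noise.base_coherence)
        if is_pat:
            for r in effects.reho_regions:
                coherence[r - 1] += effects.coherence_shift
        coherence = np.clip(coherence, 1e-3, 0.95)
        gain = np.ones(R)
        if is_pat:
            for r in effects.alff_regions:
                gain[r - 1] = effects.amplitude_shift

        bold = np.zeros(shape + (T,))
        flat = bold.reshape(-1, T)
        eta = rng.standard_normal((int(mask.sum()), T)) * site_fx.bold_noise_gain
        in_mask_idx = np.where(labels_flat > 0)[0]
        codes = labels_flat[in_mask_idx] - 1
        w = np.sqrt(coherence[codes])
        series = (
            w[:, None] * z[:, codes].T
            + np.sqrt(1.0 - coherence[codes])[:, None] * eta
        )
        series = gain[codes][:, None] * series * site_fx.bold_gain
        drift = rng.normal(0.0, 0.002) * np.arange(T)
        flat[in_mask_idx] = 100.0 + series + drift
        bold_list.append(
            BoldSeries(
                data=bold,
                tr=tr,
                mask=mask.copy(),
                censor=np.ones(T, dtype=bool),
            )
        )

        # --- motion ----------------------------------------------------------
        steps = np.concatenate(
            [
                rng.normal(0.0, noise.motion_step_trans, size=(T, 3)),
                rng.normal(0.0, noise.motion_step_rot, size=(T, 3)),
            ],
            axis=1,
        )
        motion_list.append(np.cumsum(steps, axis=0))

    return Cohort(
        meta=meta,
        gm=gm_list,
        wm=wm_list,
        bold=bold_list,
        motion=motion_list,
        atlas=atlas,
        effects=effects,
        noise=noise,
        tr=tr,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def _nifti(data: np.ndarray, voxel_size: Sequence[float]) -> nib.Nifti1Image:
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img.header.set_data_dtype(np.float64)
    return img


def write_cohort(cohort: Cohort, directory: str | os.PathLike, overwrite: bool = False) -> Path:
    """Write a cohort as NIfTI volumes + TSV tables under ``directory``."""
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{directory} exists and is not empty; pass overwrite=True"
        )
    directory.mkdir(parents=True, exist_ok=True)

    atlas_img = nib.Nifti1Image(
        cohort.atlas.labels.astype(np.int16), np.diag(list(cohort.atlas.voxel_size) + [1.0])
    )
    atlas_img.header.set_data_dtype(np.int16)
    nib.save(atlas_img, directory / "atlas.nii")

    rows = []
    for m, gm, wm, bold, motion in zip(
        cohort.meta, cohort.gm, cohort.wm, cohort.bold, cohort.motion
    ):
        rows.append(
            {
                "participant_id": m.id,
                "group": m.group,
                "age": m.age,
                "sex": m.sex,
                "site": m.site,
            }
        )
        nib.save(_nifti(gm.data, gm.voxel_size), directory / f"{m.id}_gm.nii")
        nib.save(_nifti(wm.data, wm.voxel_size), directory / f"{m.id}_wm.nii")
        nib.save(
            _nifti(bold.data, cohort.atlas.voxel_size), directory / f"{m.id}_bold.nii"
        )
        pd.DataFrame(motion, columns=MOTION_COLUMNS).to_csv(
            directory / f"{m.id}_motion.tsv", sep="\t", index=False
        )
    pd.DataFrame(rows).to_csv(directory / "participants.tsv", sep="\t", index=False)

    info = {
        "tr": cohort.tr,
        "seed": cohort.seed,
        "region_names": cohort.atlas.region_names,
        "effects": dataclasses.asdict(cohort.effects),
        "noise": dataclasses.asdict(cohort.noise),
    }
    (directory / "cohort.json").write_text(json.dumps(info, indent=2))
    return directory


def read_cohort(directory: str | os.PathLike) -> Cohort:
    """Read a cohort written by :func:`write_cohort` (bitwise round trip)."""
    directory = Path(directory)
    info = json.loads((directory / "cohort.json").read_text())
    atlas_img = nib.load(directory / "atlas.nii")
    voxel_size = tuple(float(z) for z in atlas_img.header.get_zooms()[:3])
    atlas = Atlas(
        labels=np.asarray(atlas_img.dataobj, dtype=np.int16),
        region_names=list(info["region_names"]),
        voxel_size=voxel_size,
    )
    participants = pd.read_csv(
        directory / "participants.tsv", sep="\t", float_precision="round_trip"
    )

    meta, gm, wm, bold, motion = [], [], [], [], []
    for _, row in participants.iterrows():
        m = SubjectMeta(
            id=str(row["participant_id"]),
            group=str(row["group"]),
            age=float(row["age"]),
            sex=str(row["sex"]),
            site=str(row["site"]),
        )
        meta.append(m)
        gm_data = np.asarray(nib.load(directory / f"{m.id}_gm.nii").dataobj)
        wm_data = np.asarray(nib.load(directory / f"{m.id}_wm.nii").dataobj)
        bold_data = np.asarray(nib.load(directory / f"{m.id}_bold.nii").dataobj)
        gm.append(VoxelVolume(data=gm_data, mask=atlas.mask.copy(), voxel_size=voxel_size))
        wm.append(VoxelVolume(data=wm_data, mask=atlas.mask.copy(), voxel_size=voxel_size))
        bold.append(
            BoldSeries(
                data=bold_data,
                tr=float(info["tr"]),
                mask=atlas.mask.copy(),
                censor=np.ones(bold_data.shape[3], dtype=bool),
            )
        )
        motion.append(
            pd.read_csv(
                directory / f"{m.id}_motion.tsv", sep="\t",
                float_precision="round_trip",
            )[MOTION_COLUMNS].to_numpy()
        )

    eff = dict(info["effects"])
    eff["struct_regions"] = tuple(eff["struct_regions"])
    eff["reho_regions"] = tuple(eff["reho_regions"])
    eff["alff_regions"] = tuple(eff["alff_regions"])
    eff["fc_edges"] = tuple(tuple(e) for e in eff["fc_edges"])
    return Cohort(
        meta=meta,
        gm=gm,
        wm=wm,
        bold=bold,
        motion=motion,
        atlas=atlas,
        effects=EffectSpec(**eff),
        noise=NoiseSpec(**info["noise"]),
        tr=float(info["tr"]),
        seed=int(info["seed"]),
    )


def effects_from_yaml(path: str | os.PathLike) -> tuple[EffectSpec, NoiseSpec]:
    """Load an (EffectSpec, NoiseSpec) pair from a YAML config file.

    Recognized top-level keys: ``effects`` and ``noise``; both optional.
    """
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    eff = cfg.get("effects", {}) or {}
    if "fc_edges" in eff:
        eff["fc_edges"] = tuple(tuple(e) for e in eff["fc_edges"])
    for key in ("struct_regions", "reho_regions", "alff_regions"):
        if key in eff:
            eff[key] = tuple(eff[key])
    effects = EffectSpec(**eff)
    noise = NoiseSpec(**(cfg.get("noise", {}) or {}))
    return effects, noise
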