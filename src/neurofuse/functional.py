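"""Functional pathway: motion metrics, series cleaning, ReHo, ALFF, FC.

Cleaning contract: discard the first ``n_discard`` volumes, flag volumes
with framewise displacement above threshold (flagged volumes are kept in
the array but marked in ``censor`` and excluded from all downstream
statistics), linearly detrend, zero-phase Butterworth band-pass
(0.01-0.08 Hz, order 4), then regress out nuisance signals (global / WM /
CSF means plus the Friston-24 motion expansion, each detrended and
filtered identically) by least squares fitted on the kept volumes.

Units: translations mm, rotations **radians** (framewise displacement
converts rotations to arc length on a 50 mm sphere -- passing degrees
cannot be detected and will silently inflate FD).

ReHo is Kendall's coefficient of concordance of each voxel's series with
its 26 in-mask neighbours (fewer at mask borders, K adjusted); no tie
correction is applied, since ties have measure zero for continuous data.
ALFF is the mean square-root spectral power across 0.01-0.08 Hz; by
default it is computed on the series as given (i.e. after band-pass
filtering when fed cleaned data).  Both maps are standardized by their
in-mask mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.stats import rankdata

__all__ = [
    "BoldSeries",
    "CleaningConfig",
    "framewise_displacement",
    "friston24",
    "clean_bold",
    "reho_map",
    "alff_map",
    "fc_matrix",
]

MIN_VOLUMES = 40


@dataclass
class BoldSeries:
    """4D (x, y, z, t) series with repetition time and per-volume keep mask."""

    data: np.ndarray
    tr: float
    mask: np.ndarray
    censor: np.ndarray | None = None  # True = keep

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, t)")
        if self.data.shape[:3] != self.mask.shape:
            raise ValueError("mask shape does not match data grid")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.censor is None:
            self.censor = np.ones(self.data.shape[3], dtype=bool)
        self.censor = np.asarray(self.censor, dtype=bool)
        if self.censor.shape != (self.data.shape[3],):
            raise ValueError("censor length must equal the number of volumes")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class CleaningConfig:
    n_discard: int = 10
    band: tuple[float, float] = (0.01, 0.08)
    fd_thresh: float = 0.5           # mm
    max_translation_mm: float = 1.5  # subject exclusion rule
    max_rotation_deg: float = 1.5
    head_radius_mm: float = 50.0
    filter_order: int = 4
    nuisance: tuple[str, ...] = ("global", "wm", "csf", "friston24")

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError("band must satisfy 0 < low < high")


def framewise_displacement(motion: np.ndarray, head_radius_mm: float = 50.0) -> np.ndarray:
    """Per-volume FD: sum of absolute translation deltas (mm) plus
    ``head_radius * sum of absolute rotation deltas`` (radians).  FD of the
    first volume is 0."""
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be T x 6")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    if not np.all(np.isfinite(motion)):
        raise ValueError("non-finite motion parameters")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def friston24(motion: np.ndarray) -> np.ndarray:
    """Friston-24 expansion: 6 parameters, their one-volume lags, and the
    squares of both (T x 24)."""
    motion = np.asarray(motion, dtype=float)
    lag = np.vstack([np.zeros((1, 6)), motion[:-1]])
    return np.hstack([motion, lag, motion**2, lag**2])


def _bandpass_sos(band: tuple[float, float], tr: float, order: int):
    nyq = 0.5 / tr
    lo, hi = band
    if hi >= nyq:
        raise ValueError(f"band high {hi} Hz must be below Nyquist {nyq} Hz")
    return signal.butter(order, [lo / nyq, hi / nyq], btype="band", output="sos")


def clean_bold(
    b: BoldSeries,
    motion: np.ndarray,
    cfg: CleaningConfig | None = None,
    nuisance_masks: dict[str, np.ndarray] | None = None,
) -> tuple[BoldSeries, bool]:
    """Apply the cleaning contract; returns (cleaned series, excluded flag).

    ``nuisance_masks`` maps names in ``cfg.nuisance`` ("global", "wm",
    "csf") to 3D boolean masks whose mean series are regressed out; absent
    entries are skipped.  The excluded flag marks subjects whose raw
    motion exceeds the max translation/rotation rule (the series is still
    cleaned and returned).
    """
    cfg = cfg or CleaningConfig()
    motion = np.asarray(motion, dtype=float)
    if motion.shape[0] != b.n_volumes:
        raise ValueError("motion row count must equal number of volumes")

    excluded = bool(
        np.any(np.abs(motion[:, :3]) > cfg.max_translation_mm)
        or np.any(np.abs(motion[:, 3:]) > np.deg2rad(cfg.max_rotation_deg))
    )

    data = b.data[..., cfg.n_discard:]
    motion = motion[cfg.n_discard:]
    t = data.shape[3]
    if t < MIN_VOLUMES:
        raise ValueError(f"insufficient volumes: {t} after discard (< {MIN_VOLUMES})")

    fd = framewise_displacement(motion, cfg.head_radius_mm)
    censor = fd <= cfg.fd_thresh
    if censor.sum() < MIN_VOLUMES:
        raise ValueError(
            f"insufficient volumes: {int(censor.sum())} survive FD censoring"
        )

    sos = _bandpass_sos(cfg.band, b.tr, cfg.filter_order)

    def detrend_filter(x: np.ndarray) -> np.ndarray:
        x = signal.detrend(x, axis=-1, type="linear")
        return signal.sosfiltfilt(sos, x, axis=-1)

    # reshape always copies here if `data` is not C-contiguous (e.g. loaded
    # from NIfTI), so build the output from the flat working array below
    flat = np.ascontiguousarray(data.reshape(-1, t))
    in_mask = b.mask.reshape(-1)
    cleaned = np.zeros_like(flat)
    cleaned[in_mask] = detrend_filter(flat[in_mask])

    regressors = []
    nuisance_masks = nuisance_masks or {}
    for name in ("global", "wm", "csf"):
        if name in cfg.nuisance and name in nuisance_masks:
            m = np.asarray(nuisance_masks[name], dtype=bool).reshape(-1)
            regressors.append(cleaned[m].mean(axis=0))
    if "friston24" in cfg.nuisance:
        regressors.extend(detrend_filter(friston24(motion).T))
    if regressors:
        design = np.column_stack([np.ones(t)] + [np.asarray(r) for r in regressors])
        beta, *_ = np.linalg.lstsq(design[censor], cleaned[in_mask][:, censor].T, rcond=None)
        cleaned[in_mask] -= (design @ beta).T

    out = cleaned.reshape(data.shape)
    return BoldSeries(data=out, tr=b.tr, mask=b.mask.copy(), censor=censor), excluded


def _kendall_w(ranks_sum: np.ndarray, k: np.ndarray, n: int) -> np.ndarray:
    """Kendall's W from summed ranks (voxels x time) with per-voxel K."""
    expected = k[:, None] * (n + 1) / 2.0
    s = ((ranks_sum - expected) ** 2).sum(axis=1)
    return 12.0 * s / (k**2 * (n**3 - n))


def reho_map(b: BoldSeries, normalize: bool = True) -> "VoxelVolume":
    """Kendall's W of each voxel with its (up to) 26 in-mask neighbours.

    Uses only uncensored volumes.  With ``normalize=True`` the map is
    divided by its in-mask mean (post-division mean exactly 1).
    """
    from neurofuse.structural import VoxelVolume

    data = b.data[..., b.censor]
    n = data.shape[3]
    if n < 2:
        raise ValueError("need at least 2 timepoints for ReHo")

    shape = b.mask.shape
    ranks = np.zeros(shape + (n,))
    ranks[b.mask] = rankdata(data[b.mask], axis=-1)

    # zero-padded 27-neighbourhood accumulation of ranks and mask counts
    pr = np.pad(ranks, ((1, 1), (1, 1), (1, 1), (0, 0)))
    pm = np.pad(b.mask.astype(np.int64), 1)
    rank_sum = np.zeros(shape + (n,))
    k = np.zeros(shape, dtype=np.int64)
    for dx in (0, 1, 2):
        for dy in (0, 1, 2):
            for dz in (0, 1, 2):
                rank_sum += pr[dx:dx + shape[0], dy:dy + shape[1], dz:dz + shape[2]]
                k += pm[dx:dx + shape[0], dy:dy + shape[1], dz:dz + shape[2]]

    w = np.zeros(shape)
    m = b.mask
    w[m] = _kendall_w(rank_sum[m], k[m].astype(float), n)
    if normalize:
        w[m] /= w[m].mean()
    return VoxelVolume(data=w, mask=b.mask.copy())


def alff_map(b: BoldSeries, normalize: bool = True) -> "VoxelVolume":
    """Mean square-root spectral power over 0.01-0.08 Hz per voxel.

    Computed on the full (uncensored) series -- the FFT needs uniform
    sampling.  With ``normalize=True`` the map is divided by its in-mask
    mean.
    """
    from neurofuse.structural import VoxelVolume

    n = b.n_volumes
    freqs = np.fft.rfftfreq(n, d=b.tr)
    band = (freqs >= 0.01) & (freqs <= 0.08)
    if not band.any():
        min_n = int(np.ceil(1.0 / (0.08 * b.tr)))
        raise ValueError(
            f"no frequency bins in 0.01-0.08 Hz for n={n}, tr={b.tr}; "
            f"need at least ~{min_n} volumes"
        )
    series = b.data[b.mask]
    amp = 2.0 * np.abs(np.fft.rfft(series, axis=-1)) / n
    alff = amp[:, band].mean(axis=1)
    out = np.zeros(b.mask.shape)
    out[b.mask] = alff / alff.mean() if normalize else alff
    return VoxelVolume(data=out, mask=b.mask.copy())


def fc_matrix(b: BoldSeries, atlas: "Atlas") -> "ConnMatrix":
    """Pearson correlations of region-mean series over uncensored volumes."""
    from neurofuse.structural import ConnMatrix

    if atlas.labels.shape != b.mask.shape:
        raise ValueError("atlas grid does not match series grid")
    data = b.data[..., b.censor]
    means = []
    for code in range(1, atlas.R + 1):
        sel = (atlas.labels == code) & b.mask
        if not sel.any():
            raise ValueError(f"region {code} has no in-mask voxels")
        series = data[sel].mean(axis=0)
        if np.std(series) == 0:
            raise ValueError(f"region {code} has a zero-variance mean series")
        means.append(series)
    mat = np.corrcoef(np.asarray(means))
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 1.0)
    return ConnMatrix(values=mat, kind="functional", region_names=list(atlas.region_names))
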