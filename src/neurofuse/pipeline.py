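"""End-to-end measure extraction: Cohort -> per-measure feature tables.

Measure names follow the reporting layout: GM, WM (smoothed voxel-wise
maps), StructM (morphological similarity network edges), ReHo, ALFF
(normalized voxel-wise maps from cleaned series) and FuncM (functional
connectome edges).  Matrix measures are vectorized as the upper triangle
excluding the diagonal.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from neurofuse.confounds import MeasureFeatures
from neurofuse.functional import CleaningConfig, alff_map, clean_bold, fc_matrix, reho_map
from neurofuse.structural import (
    morphological_network,
    smooth_volume,
    upper_triangle,
    voxel_features,
)
from neurofuse.synthetic import Cohort

__all__ = ["ALL_MEASURES", "STRUCTURAL_MEASURES", "FUNCTIONAL_MEASURES", "extract_measures"]

STRUCTURAL_MEASURES = ("StructM", "GM", "WM")
FUNCTIONAL_MEASURES = ("FuncM", "ReHo", "ALFF")
ALL_MEASURES = STRUCTURAL_MEASURES + FUNCTIONAL_MEASURES


def extract_measures(
    cohort: Cohort,
    measures: Sequence[str] = ALL_MEASURES,
    fwhm_mm: float = 6.0,
    kde_grid: int = 512,
    cleaning: CleaningConfig | None = None,
    drop_excluded: bool = True,
) -> tuple[dict[str, MeasureFeatures], list[str]]:
    """Extract the requested measures for every subject.

    Subjects whose motion trips the exclusion rule are dropped from every
    table when ``drop_excluded`` is set; their ids are returned alongside
    the feature dict.  Structural maps are smoothed before vectorization
    and before the similarity network.  Functional voxel maps are
    globally normalized (in-mask mean 1).
    """
    unknown = set(measures) - set(ALL_MEASURES)
    if unknown:
        raise ValueError(f"unknown measures: {sorted(unknown)}")
    cleaning = cleaning or CleaningConfig()
    atlas = cohort.atlas
    need_functional = any(m in FUNCTIONAL_MEASURES for m in measures)

    columns: dict[str, list[np.ndarray]] = {m: [] for m in measures}
    kept_ids: list[str] = []
    excluded: list[str] = []

    for i, meta in enumerate(cohort.meta):
        subj_excluded = False
        row: dict[str, np.ndarray] = {}

        if need_functional:
            cleaned, subj_excluded = clean_bold(
                cohort.bold[i],
                cohort.motion[i],
                cleaning,
                nuisance_masks={"global": cohort.bold[i].mask},
            )
            if subj_excluded and drop_excluded:
                excluded.append(meta.id)
                continue
            if "ReHo" in measures:
                row["ReHo"] = voxel_features(reho_map(cleaned))
            if "ALFF" in measures:
                row["ALFF"] = voxel_features(alff_map(cleaned))
            if "FuncM" in measures:
                row["FuncM"] = upper_triangle(fc_matrix(cleaned, atlas).values)

        if "GM" in measures or "StructM" in measures:
            gm_s = smooth_volume(cohort.gm[i], fwhm_mm)
            if "GM" in measures:
                row["GM"] = voxel_features(gm_s)
            if "StructM" in measures:
                row["StructM"] = upper_triangle(
                    morphological_network(gm_s, atlas, grid_size=kde_grid).values
                )
        if "WM" in measures:
            row["WM"] = voxel_features(smooth_volume(cohort.wm[i], fwhm_mm))

        kept_ids.append(meta.id)
        for m in measures:
            columns[m].append(row[m])

    tables = {
        m: MeasureFeatures(
            matrix=np.vstack(columns[m]), measure=m, subject_ids=list(kept_ids)
        )
        for m in measures
    }
    return tables, excluded
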