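"""Region attribution from linear weights and summary-table arithmetic.

Aggregation conventions: dataset "Average" rows are unweighted arithmetic
means over datasets, modality-level means are unweighted means of the
three single-measure averages within a modality, and rounding is half
away from zero at two decimals (done in decimal arithmetic so printed
two-decimal inputs aggregate exactly).
"""

from __future__ import annotations

import warnings
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

__all__ = [
    "round2",
    "decimal_mean",
    "bac_from_sen_spec",
    "region_weights_matrix_measure",
    "region_weights_voxel_measure",
    "top_regions",
    "aggregate_summary",
    "modality_mean",
]


def round2(x) -> float:
    """Round to 2 decimals, ties away from zero, in decimal arithmetic."""
    return float(Decimal(str(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def decimal_mean(values: Iterable) -> float:
    """Unweighted mean computed exactly in decimal, rounded via round2."""
    decs = [Decimal(str(v)) for v in values]
    if not decs:
        raise ValueError("cannot average an empty collection")
    return float(
        (sum(decs) / Decimal(len(decs))).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def bac_from_sen_spec(sen: float, spec: float) -> float:
    """Balanced accuracy identity (sen + spec) / 2, rounded to 2 dp."""
    return decimal_mean([sen, spec])


def region_weights_matrix_measure(weight_vector: np.ndarray, R: int) -> np.ndarray:
    """Per-region attribution for a connectivity-matrix measure.

    ``weight_vector`` is the upper-triangle (row-major, diagonal excluded)
    weight layout of length R(R-1)/2.  The absolute weights are folded
    back into a symmetric matrix and each region scores the mean of its
    R-1 off-diagonal entries.
    """
    w = np.asarray(weight_vector, dtype=float)
    expected = R * (R - 1) // 2
    if w.shape != (expected,):
        raise ValueError(f"expected {expected} weights for R={R}, got {w.shape}")
    mat = squareform(np.abs(w))
    return mat.sum(axis=1) / (R - 1)


def region_weights_voxel_measure(weight_map, atlas) -> np.ndarray:
    """Mean absolute weight over each region's in-mask voxels.

    Regions with no in-mask voxel get NaN (flagged missing, not zero).
    """
    if weight_map.data.shape != atlas.labels.shape:
        raise ValueError("weight map grid does not match atlas")
    absw = np.abs(weight_map.data)
    out = np.full(atlas.R, np.nan)
    for code in range(1, atlas.R + 1):
        sel = (atlas.labels == code) & weight_map.mask
        if sel.any():
            out[code - 1] = absw[sel].mean()
    return out


def top_regions(
    table: pd.DataFrame, k: int = 10, region_names: Sequence[str] | None = None
) -> pd.DataFrame:
    """Rank regions by attribution averaged over folds, then datasets.

    ``table`` is long-form with columns region, dataset, fold, value.
    Returns the top-k regions with one column per dataset plus the
    cross-dataset mean; ties break on region index.
    """
    required = {"region", "dataset", "fold", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    per_ds = (
        table.groupby(["region", "dataset"])["value"].mean().unstack("dataset")
    )
    per_ds["mean"] = per_ds.mean(axis=1)
    R = per_ds.shape[0]
    if k > R:
        warnings.warn(f"k={k} exceeds {R} regions; returning all")
        k = R
    # ties break on region index: stable sort after ordering the index
    per_ds = per_ds.sort_index().sort_values("mean", ascending=False, kind="stable")
    out = per_ds.head(k).reset_index()
    if region_names is not None:
        out.insert(1, "region_name", [region_names[r - 1] for r in out["region"]])
    return out


def aggregate_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Append an unweighted per-measure "Average" row over datasets.

    ``results`` is long-form with columns measure, dataset and any of
    bac/sen/spec (percent).  Averages use decimal arithmetic rounded to
    2 dp; missing dataset cells are averaged over the available ones and
    flagged in ``n_datasets``.
    """
    if not {"measure", "dataset"}.issubset(results.columns):
        raise ValueError("results must have measure and dataset columns")
    metric_cols = [c for c in ("bac", "sen", "spec") if c in results.columns]
    if not metric_cols:
        raise ValueError("no metric columns (bac/sen/spec) found")
    rows = []
    for measure, grp in results.groupby("measure", sort=False):
        row: dict = {"measure": measure, "dataset": "Average"}
        for c in metric_cols:
            vals = grp[c].dropna()
            row[c] = decimal_mean(vals)
        row["n_datasets"] = int(grp[metric_cols[0]].notna().sum())
        rows.append(row)
    avg = pd.DataFrame(rows)
    out = pd.concat([results.copy(), avg], ignore_index=True)
    return out


def modality_mean(single_measure_averages: Sequence[float]) -> float:
    """Modality-level mean: unweighted mean of the (rounded) per-measure
    dataset averages within one modality, 2 dp."""
    return decimal_mean(single_measure_averages)
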