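import numpy as np
import pytest

from neurofuse.synthetic import (
    Atlas,
    Demographics,
    EffectSpec,
    NoiseSpec,
    generate_atlas,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_atlas() -> Atlas:
    return generate_atlas((10, 10, 10), R=4, seed=11)


@pytest.fixture(scope="session")
def atlas12() -> Atlas:
    return generate_atlas((10, 10, 10), R=12, seed=5)


@pytest.fixture(scope="session")
def null_cohort(small_atlas):
    """Small cohort with no group effects."""
    return generate_cohort(6, small_atlas, EffectSpec(), NoiseSpec(), T=60, seed=21)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def tiny_feature_cohort(
    n_per_group: int,
    n_features: int,
    effect: float,
    seed: int,
    n_measures: int = 1,
    age_group_gap: float = 0.0,
    age_slope: float = 0.0,
):
    """Direct Gaussian feature tables + metadata, bypassing image synthesis.

    Cheap scaffolding for classifier-level tests: ``effect`` shifts the
    patient mean of the first half of the features of each measure.
    """
    from neurofuse.confounds import MeasureFeatures
    from neurofuse.synthetic import SubjectMeta

    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    groups = ["patient"] * n_per_group + ["control"] * n_per_group
    ages = np.clip(
        rng.normal(35, 8, size=n)
        + np.where(np.array(groups) == "patient", age_group_gap, 0.0),
        18,
        70,
    )
    meta = [
        SubjectMeta(
            id=f"sub-{i:03d}",
            group=groups[i],
            age=float(ages[i]),
            sex="M" if rng.random() < 0.5 else "F",
            site="site1",
        )
        for i in range(n)
    ]
    measures = []
    for m in range(n_measures):
        X = rng.normal(size=(n, n_features))
        X[: n_per_group, : n_features // 2] += effect
        X += age_slope * (ages[:, None] - 35.0)
        measures.append(
            MeasureFeatures(
                matrix=X,
                measure=f"m{m}",
                subject_ids=[s.id for s in meta],
            )
        )
    return measures, meta
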