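"""Age/sex confound removal fitted on control subjects only.

A Gaussian-process regression (linear + squared-exponential + white-noise
kernel on standardized age and binary sex) models how each feature varies
with the confounds; residuals are used as classifier features.

Cost model: for narrow tables every feature gets its own
marginal-likelihood-optimized GP.  For wide (e.g. voxel-wise) tables the
kernel hyperparameters are optimized on a seeded subsample of features
and shared, after which each feature still receives an independent
posterior solve -- one Cholesky factorization serves the whole table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    RBF,
    ConstantKernel,
    DotProduct,
    WhiteKernel,
)

from neurofuse.synthetic import SubjectMeta

__all__ = ["MeasureFeatures", "ConfoundModel", "fit_confound_model", "residualize"]

PER_FEATURE_MAX = 30  # widest table that still gets per-feature hyperparameters


@dataclass
class MeasureFeatures:
    """Subjects x features table for one measure."""

    matrix: np.ndarray
    measure: str
    subject_ids: list[str]
    feature_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite entries")
        if len(self.subject_ids) != self.matrix.shape[0]:
            raise ValueError("subject_ids length must match row count")
        if not self.feature_labels:
            self.feature_labels = [
                f"{self.measure}_{i}" for i in range(self.matrix.shape[1])
            ]
        if len(self.feature_labels) != self.matrix.shape[1]:
            raise ValueError("feature_labels length must match column count")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def select(self, rows: np.ndarray) -> "MeasureFeatures":
        ids = [self.subject_ids[i] for i in np.atleast_1d(rows)]
        return MeasureFeatures(
            matrix=self.matrix[rows],
            measure=self.measure,
            subject_ids=ids,
            feature_labels=list(self.feature_labels),
        )


def _design(meta: Sequence[SubjectMeta], age_mean: float, age_sd: float, use_sex: bool) -> np.ndarray:
    age = np.array([(m.age - age_mean) / age_sd for m in meta])
    if not use_sex:
        return age[:, None]
    sex = np.array([1.0 if m.sex == "M" else 0.0 for m in meta])
    return np.column_stack([age, sex])


def _base_kernel():
    # conservative bounds: RBF length scale >= 0.5 on standardized inputs
    # and a white term starting at the full variance keep pure-noise
    # features from being chased by the smooth components
    return (
        ConstantKernel(0.1, (1e-4, 1e2))
        * DotProduct(sigma_0=1.0, sigma_0_bounds=(1e-2, 1e2))
        + ConstantKernel(0.1, (1e-4, 1e2)) * RBF(1.0, (1.0, 1e2))
        + WhiteKernel(1.0, (1e-6, 1e2))
    )


@dataclass
class ConfoundModel:
    """Fitted per-feature predictor of a measure from (age, sex)."""

    measure: str
    feature_labels: list[str]
    training_ids: list[str]
    age_mean: float
    age_sd: float
    use_sex: bool
    kernel_description: str
    # per-feature path
    _gprs: list[GaussianProcessRegressor] | None = None
    # shared-hyperparameter path
    _kernel: object | None = None
    _X_train: np.ndarray | None = None
    _cho: tuple | None = None
    _alphas: np.ndarray | None = None
    _y_means: np.ndarray | None = None

    def predict(self, meta: Sequence[SubjectMeta]) -> np.ndarray:
        X = _design(meta, self.age_mean, self.age_sd, self.use_sex)
        if self._gprs is not None:
            return np.column_stack([g.predict(X) for g in self._gprs])
        k_cross = self._cross_kernel(X, self._X_train)
        return k_cross @ self._alphas + self._y_means

    def _cross_kernel(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        # WhiteKernel contributes only on the training diagonal
        k = self._kernel.clone_with_theta(self._kernel.theta)
        k.k2.noise_level = 0.0
        return k(X, Y)


def fit_confound_model(
    X: MeasureFeatures,
    meta: Sequence[SubjectMeta],
    control_only: bool = True,
    seed: int = 0,
    per_feature: str = "auto",
    max_hyperopt_features: int = 3,
    n_restarts: int = 1,
) -> ConfoundModel:
    """Fit the GP confound model on (by default) control rows only.

    ``per_feature`` is "auto" (own hyperparameters when the table has at
    most 30 features, shared otherwise), "always" or "never".
    """
    if len(meta) != X.matrix.shape[0]:
        raise ValueError("meta length must match feature rows")
    rows = np.array(
        [i for i, m in enumerate(meta) if (not control_only) or m.group == "control"]
    )
    if rows.size < 10:
        raise ValueError(f"need >= 10 training rows, got {rows.size}")
    train_meta = [meta[i] for i in rows]
    ages = np.array([m.age for m in train_meta])
    if np.std(ages) == 0:
        raise ValueError("age variance is zero in the training rows")

    sexes = {m.sex for m in train_meta}
    use_sex = len(sexes) > 1
    if not use_sex:
        warnings.warn("all training subjects share one sex; dropping sex term")

    age_mean, age_sd = float(ages.mean()), float(ages.std(ddof=0))
    Xd = _design(train_meta, age_mean, age_sd, use_sex)
    Y = X.matrix[rows]
    p = Y.shape[1]

    if per_feature not in ("auto", "always", "never"):
        raise ValueError("per_feature must be auto/always/never")
    own = per_feature == "always" or (per_feature == "auto" and p <= PER_FEATURE_MAX)

    model = ConfoundModel(
        measure=X.measure,
        feature_labels=list(X.feature_labels),
        training_ids=[m.id for m in train_meta],
        age_mean=age_mean,
        age_sd=age_sd,
        use_sex=use_sex,
        kernel_description="const*linear + const*rbf + white",
    )

    if own:
        gprs = []
        for j in range(p):
            g = GaussianProcessRegressor(
                kernel=_base_kernel(),
                normalize_y=True,
                n_restarts_optimizer=n_restarts,
                random_state=seed,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                g.fit(Xd, Y[:, j])
            gprs.append(g)
        model._gprs = gprs
        return model

    # shared hyperparameters: optimize on a seeded feature subsample
    rng = np.random.default_rng(seed)
    sample = rng.choice(p, size=min(max_hyperopt_features, p), replace=False)
    thetas = []
    for j in sample:
        g = GaussianProcessRegressor(
            kernel=_base_kernel(),
            normalize_y=True,
            n_restarts_optimizer=0,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g.fit(Xd, Y[:, j])
        thetas.append(g.kernel_.theta)
    kernel = _base_kernel()
    kernel.theta = np.mean(thetas, axis=0)  # log-space mean

    noise_free = kernel.clone_with_theta(kernel.theta)
    noise_free.k2.noise_level = 0.0
    K = noise_free(Xd) + np.exp(kernel.k2.theta[0]) * np.eye(Xd.shape[0])
    K[np.diag_indices_from(K)] += 1e-10
    cho = cho_factor(K, lower=True)
    y_means = Y.mean(axis=0)
    model._kernel = kernel
    model._X_train = Xd
    model._cho = cho
    model._alphas = cho_solve(cho, Y - y_means)
    model._y_means = y_means
    return model


def residualize(
    X: MeasureFeatures, model: ConfoundModel, meta: Sequence[SubjectMeta]
) -> MeasureFeatures:
    """Subtract the model's (age, sex) predictions from every row."""
    if list(X.feature_labels) != list(model.feature_labels):
        raise ValueError("feature labels do not match the fitted model")
    if len(meta) != X.matrix.shape[0]:
        raise ValueError("meta length must match feature rows")
    return MeasureFeatures(
        matrix=X.matrix - model.predict(meta),
        measure=X.measure,
        subject_ids=list(X.subject_ids),
        feature_labels=list(X.feature_labels),
    )
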