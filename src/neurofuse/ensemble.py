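"""Calibrated linear-SVM soft-voting ensemble with nested cross-validation.

Outer evaluation is a seeded 10-fold stratified cross-validation.  Inside
every training fold: an optional confound model is fitted on that fold's
controls, each measure's soft-margin parameter C is selected by an inner
stratified grid search on mean balanced accuracy, integer soft-voting
coefficients (1..10) are selected on cached inner out-of-fold
probabilities, and the final per-measure models are refitted on the whole
training fold.  Permutation inference reruns the entire procedure on
label-shuffled data.

Tie-breaking rules (all deliberate): smaller C wins, lexicographically
smallest coefficient vector wins, and the patient class wins exact
fused-score ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

_SEED_MOD = 2**32

from neurofuse.confounds import (
    MeasureFeatures,
    fit_confound_model,
    residualize,
)
from neurofuse.synthetic import SubjectMeta

__all__ = [
    "ClassifierConfig",
    "EnsembleResult",
    "balanced_metrics",
    "train_calibrated_svm",
    "select_C",
    "soft_vote",
    "select_coefficients",
    "run_cv",
    "permutation_test",
    "evaluate_pooled_and_stratified",
    "cross_site",
]

DEFAULT_C_GRID = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3, 1e4)

# libsvm iteration cap: far above what any converging fit needs at these
# sample sizes; C-grid entries whose inner fits still hit it (degenerate
# high-C fits on inseparable data) are disqualified from selection
SVM_MAX_ITER = 30_000


@dataclass
class ClassifierConfig:
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    outer_folds: int = 10
    inner_folds: int = 10
    coeff_range: tuple[int, int] = (1, 10)
    n_permutations: int = 1000
    seed: int = 0
    coeff_search: str = "greedy"  # "full_grid" | "greedy"
    confound_policy: str = "in_fold"  # "in_fold" | "whole_sample" | "none"
    conservative_p: bool = False
    gp_per_feature: str = "auto"

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        lo, hi = self.coeff_range
        if lo < 1 or hi < lo or (lo, hi) != (int(lo), int(hi)):
            raise ValueError("coeff_range must be integers with 1 <= lo <= hi")
        if self.coeff_search not in ("full_grid", "greedy"):
            raise ValueError("coeff_search must be full_grid or greedy")
        if self.confound_policy not in ("in_fold", "whole_sample", "none"):
            raise ValueError("unknown confound_policy")


@dataclass
class EnsembleResult:
    measures: list[str]
    fold_bac: np.ndarray
    fold_sen: np.ndarray
    fold_spec: np.ndarray
    selected_C: np.ndarray        # folds x measures
    coefficients: np.ndarray      # folds x measures (ints)
    weights: list[dict[str, np.ndarray]]  # per fold: measure -> weight vector
    fold_test_ids: list[list[str]] = field(default_factory=list)
    permutation_p: float | None = None

    @property
    def mean_bac(self) -> float:
        return float(self.fold_bac.mean())

    @property
    def mean_sen(self) -> float:
        return float(self.fold_sen.mean())

    @property
    def mean_spec(self) -> float:
        return float(self.fold_spec.mean())


def _as_patient_bool(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        return arr == "patient"
    return arr.astype(bool)


def balanced_metrics(y_true: Sequence, y_pred: Sequence) -> tuple[float, float, float]:
    """(BAC, sensitivity, specificity) in percent; patient is positive."""
    yt, yp = _as_patient_bool(y_true), _as_patient_bool(y_pred)
    if yt.all() or not yt.any():
        raise ValueError("both classes must be present in the true labels")
    sen = 100.0 * (yp & yt).sum() / yt.sum()
    spec = 100.0 * (~yp & ~yt).sum() / (~yt).sum()
    return (sen + spec) / 2.0, sen, spec


def _platt_scaling(decisions: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit Platt's sigmoid P(patient) = 1 / (1 + exp(A f + B)) by
    regularized maximum likelihood on training decision values."""
    from scipy.optimize import minimize

    n_pos, n_neg = int(y.sum()), int((~y).sum())
    t = np.where(y, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def objective(ab):
        z = ab[0] * decisions + ab[1]
        L = np.logaddexp(0.0, z)
        s = np.exp(z - L)  # sigmoid(z) = 1 - p
        nll = np.sum(L - (1.0 - t) * z)
        grad = np.array([np.sum((s - (1.0 - t)) * decisions), np.sum(s - (1.0 - t))])
        return nll, grad

    x0 = np.array([0.0, np.log((n_neg + 1.0) / (n_pos + 1.0))])
    res = minimize(objective, x0, jac=True, method="L-BFGS-B")
    return float(res.x[0]), float(res.x[1])


class CalibratedLinearSVM:
    """Linear soft-margin SVM with sigmoid (Platt) probability calibration.

    A libsvm linear SVM fitted once, followed by a monotone sigmoid of
    the decision value fitted on the training decision values; exposes
    the linear weight vector and patient-class probabilities.  Predicted
    labels come from the calibrated probabilities so that single-measure
    predictions coincide with a one-measure soft vote.
    """

    def __init__(self, C: float, seed: int = 0):
        self.C = C
        self.seed = seed  # kept for interface stability; fitting is deterministic
        self._svc = SVC(kernel="linear", C=C, max_iter=SVM_MAX_ITER)
        self._A = 0.0
        self._B = 0.0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CalibratedLinearSVM":
        y = _as_patient_bool(y)
        if y.all() or not y.any():
            raise ValueError("both classes required to train the SVM")
        self._svc.fit(X, y.astype(int))
        self._A, self._B = _platt_scaling(self._svc.decision_function(X), y)
        return self

    @property
    def coef_(self) -> np.ndarray:
        return self._svc.coef_.ravel()

    def predict_proba_patient(self, X: np.ndarray) -> np.ndarray:
        z = self._A * self._svc.decision_function(X) + self._B
        return 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba_patient(X) >= 0.5


def train_calibrated_svm(
    X: np.ndarray, y: Sequence, C: float, seed: int = 0
) -> CalibratedLinearSVM:
    return CalibratedLinearSVM(C=C, seed=seed).fit(np.asarray(X), y)


def _inner_splitter(y: np.ndarray, n_folds: int, seed: int) -> StratifiedKFold:
    min_class = int(min(y.sum(), (~y).sum()))
    if min_class < 2:
        raise ValueError("a class has fewer than 2 members; cannot stratify")
    if min_class < n_folds:
        warnings.warn(
            f"reducing inner folds from {n_folds} to {min_class} "
            "(smallest class size)"
        )
        n_folds = min_class
    return StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)


try:  # low-level binding: skips per-fit validation overhead in grid loops
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)

    def _linear_svm_decision(
        X_tr: np.ndarray, y_tr: np.ndarray, X_te: np.ndarray, C: float
    ) -> tuple[np.ndarray, bool]:
        """Decision values of a linear SVC, identical to SVC(kernel='linear')
        (verified to 1e-13 in the test suite); positive = patient.  Also
        reports whether the solver converged within the iteration cap."""
        out = _libsvm.fit(
            X_tr,
            y_tr.astype(np.float64),
            svm_type=0,
            kernel="linear",
            C=C,
            tol=1e-3,
            max_iter=SVM_MAX_ITER,
        )
        sv, sv_coef, intercept, n_iter = out[1], out[3], out[4], out[-1]
        converged = bool(np.max(n_iter) < SVM_MAX_ITER)
        # sklearn negates libsvm's binary decision values
        return -(X_te @ (sv_coef @ sv).ravel() + intercept[0]), converged

except ImportError:  # pragma: no cover - fallback for other sklearn builds

    def _linear_svm_decision(X_tr, y_tr, X_te, C):
        svc = SVC(kernel="linear", C=C, max_iter=SVM_MAX_ITER)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            svc.fit(X_tr, y_tr.astype(int))
        converged = bool(np.max(svc.n_iter_) < SVM_MAX_ITER)
        return svc.decision_function(X_te), converged


def select_C(
    X: np.ndarray, y: Sequence, cfg: ClassifierConfig, seed: int | None = None
) -> float:
    """Grid-search C on mean inner-fold balanced accuracy; smaller C wins ties."""
    y = _as_patient_bool(y)
    seed = cfg.seed if seed is None else seed
    skf = _inner_splitter(y, cfg.inner_folds, seed)
    X = np.ascontiguousarray(X, dtype=np.float64)
    splits = list(skf.split(X, y))
    best_C, best_score = None, -np.inf
    for C in cfg.c_grid:
        scores, ok = [], True
        for tr, te in splits:
            decision, converged = _linear_svm_decision(X[tr], y[tr], X[te], C)
            if not converged:  # degenerate fit: this C is disqualified
                ok = False
                break
            bac, _, _ = balanced_metrics(y[te], decision > 0)
            scores.append(bac)
        if not ok:
            continue
        score = float(np.mean(scores))
        if score > best_score:  # strict: first (smallest) C wins ties
            best_C, best_score = C, score
    if best_C is None:  # every grid entry failed: most-regularized entry
        best_C = min(cfg.c_grid)
    return best_C


def soft_vote(
    probs: np.ndarray, coeffs: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted-average fusion of per-measure patient probabilities.

    ``probs`` is subjects x measures.  Returns (labels, fused patient
    scores); the patient class wins exact ties.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.ndim != 1 or coeffs.size != probs.shape[1]:
        raise ValueError("coefficient count must match measure count")
    if np.any(coeffs <= 0):
        raise ValueError("coefficients must be positive")
    fused = probs @ coeffs / coeffs.sum()
    return fused >= 0.5, fused


def _fold_rate_matrices(
    y: np.ndarray, fold_ids: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalized patient/control fold indicators.

    With these, mean per-fold BAC (in %) of a candidate label matrix L
    (subjects x K) is ``50 * (P @ L + C @ (1 - L)).mean(axis=0)``; folds
    lacking a class are dropped, matching the loop-based evaluation.
    """
    rows_p, rows_c = [], []
    for f in np.unique(fold_ids):
        sel = fold_ids == f
        pat, con = sel & y, sel & ~y
        if not pat.any() or not con.any():
            continue
        rows_p.append(pat / pat.sum())
        rows_c.append(con / con.sum())
    if not rows_p:
        raise ValueError("no inner fold contains both classes")
    return np.asarray(rows_p, dtype=float), np.asarray(rows_c, dtype=float)


def _fused_fold_bac(
    probs: np.ndarray, coeffs: np.ndarray, y: np.ndarray, fold_ids: np.ndarray
) -> float:
    labels, _ = soft_vote(probs, coeffs)
    P, C = _fold_rate_matrices(_as_patient_bool(y), fold_ids)
    return float(50.0 * (P @ labels + C @ (1.0 - labels)).mean())


def select_coefficients(
    probs: np.ndarray,
    y: Sequence,
    fold_ids: np.ndarray,
    cfg: ClassifierConfig,
) -> tuple[int, ...]:
    """Integer soft-voting coefficients maximizing mean inner-fold BAC.

    ``probs`` holds cached out-of-fold patient probabilities (subjects x
    measures) so no model is refitted during the search.  ``full_grid``
    enumerates the whole grid in lexicographic order (refused above 6
    measures); ``greedy`` is coordinate ascent from all-ones, two sweeps.
    Ties resolve to the lexicographically smallest vector.
    """
    y = _as_patient_bool(y)
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    M = probs.shape[1]
    lo, hi = cfg.coeff_range
    values = np.arange(lo, hi + 1)
    P, C = _fold_rate_matrices(y, fold_ids)

    def scores_of(label_matrix: np.ndarray) -> np.ndarray:
        return 50.0 * (P @ label_matrix + C @ (1.0 - label_matrix)).mean(axis=0)

    if cfg.coeff_search == "full_grid":
        if M > 6:
            raise ValueError(
                f"full_grid with {M} measures is {values.size**M} "
                "combinations; use coeff_search='greedy'"
            )
        combos = np.array(list(product(values, repeat=M)))  # lexicographic
        best, best_score = None, -np.inf
        for start in range(0, combos.shape[0], 20000):
            chunk = combos[start:start + 20000].astype(float)
            fused = probs @ chunk.T / chunk.sum(axis=1)
            sc = scores_of(fused >= 0.5)
            k = int(np.argmax(sc))  # first max = lexicographically smallest
            if sc[k] > best_score:
                best, best_score = tuple(int(v) for v in combos[start + k]), float(sc[k])
        return best

    coeffs = np.full(M, lo, dtype=int)
    for _ in range(2):
        for m in range(M):
            without = probs @ coeffs - coeffs[m] * probs[:, m]
            fused = (without[:, None] + values[None, :] * probs[:, m][:, None]) / (
                coeffs.sum() - coeffs[m] + values
            )[None, :]
            sc = scores_of(fused >= 0.5)
            coeffs[m] = int(values[np.argmax(sc)])  # first max = smallest value
    return tuple(int(c) for c in coeffs)


def _inner_oof_probs(
    X: np.ndarray, y: np.ndarray, C: float, splits: list, seed: int
) -> np.ndarray:
    """Out-of-fold patient probabilities over the training set."""
    oof = np.zeros(len(y))
    for tr, te in splits:
        model = train_calibrated_svm(X[tr], y[tr], C, seed=seed)
        oof[te] = model.predict_proba_patient(X[te])
    return oof


def _check_alignment(measures: Sequence[MeasureFeatures]) -> None:
    if not measures:
        raise ValueError("need at least one measure")
    ids = measures[0].subject_ids
    for m in measures[1:]:
        if m.subject_ids != ids:
            raise ValueError(f"measure {m.measure} rows are not aligned")


def _residualize_fold(
    measures: Sequence[MeasureFeatures],
    meta: Sequence[SubjectMeta],
    train_idx: np.ndarray,
    cfg: ClassifierConfig,
    seed: int,
) -> list[MeasureFeatures]:
    """Fit confound models on the training controls and residualize all rows."""
    out = []
    train_meta = [meta[i] for i in train_idx]
    for X in measures:
        model = fit_confound_model(
            X.select(train_idx),
            train_meta,
            control_only=True,
            seed=seed,
            per_feature=cfg.gp_per_feature,
        )
        out.append(residualize(X, model, meta))
    return out


def run_cv(
    measures: Sequence[MeasureFeatures],
    meta: Sequence[SubjectMeta],
    cfg: ClassifierConfig | None = None,
    mode: str = "combined",
    folds: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> EnsembleResult:
    """Outer stratified cross-validation of the (fused) classifier.

    ``mode`` is "combined" (soft voting across measures, with coefficient
    selection when there is more than one) or "single_measure" (exactly
    one measure, no fusion search).  ``folds`` overrides the outer splits
    (used for site-stratified evaluation).
    """
    cfg = cfg or ClassifierConfig()
    if mode not in ("combined", "single_measure"):
        raise ValueError("mode must be combined or single_measure")
    _check_alignment(measures)
    if mode == "single_measure" and len(measures) != 1:
        raise ValueError("single_measure mode takes exactly one measure")
    y = np.array([m.group == "patient" for m in meta])
    if len(y) != measures[0].matrix.shape[0]:
        raise ValueError("meta length must match feature rows")

    if folds is None:
        min_class = int(min(y.sum(), (~y).sum()))
        if min_class < cfg.outer_folds:
            raise ValueError(
                f"smallest class has {min_class} members; "
                f"use at most {min_class} outer folds"
            )
        skf = StratifiedKFold(
            n_splits=cfg.outer_folds, shuffle=True, random_state=cfg.seed
        )
        folds = list(skf.split(np.zeros(len(y)), y))

    if cfg.confound_policy == "whole_sample":
        measures = _residualize_fold(
            measures, meta, np.arange(len(y)), cfg, seed=cfg.seed
        )

    M = len(measures)
    fold_bac, fold_sen, fold_spec = [], [], []
    sel_C = np.zeros((len(folds), M))
    sel_coef = np.ones((len(folds), M), dtype=int)
    weights: list[dict[str, np.ndarray]] = []
    fold_test_ids: list[list[str]] = []

    for f, (tr, te) in enumerate(folds):
        fold_seed = (cfg.seed * 100003 + f) % _SEED_MOD
        if not (y[te].any() and (~y[te]).any()):
            raise ValueError(
                "an outer test fold lacks one class; use fewer folds"
            )
        fold_measures = measures
        if cfg.confound_policy == "in_fold":
            fold_measures = _residualize_fold(measures, meta, tr, cfg, seed=fold_seed)

        Xs = [m.matrix for m in fold_measures]
        y_tr = y[tr]
        skf_inner = _inner_splitter(y_tr, cfg.inner_folds, fold_seed)
        inner_splits = list(skf_inner.split(np.zeros(len(y_tr)), y_tr))
        inner_fold_ids = np.zeros(len(y_tr), dtype=int)
        for k, (_, inner_te) in enumerate(inner_splits):
            inner_fold_ids[inner_te] = k

        Cs = [
            select_C(Xm[tr], y_tr, cfg, seed=fold_seed) for Xm in Xs
        ]
        sel_C[f] = Cs

        if mode == "combined" and M > 1:
            oof = np.column_stack(
                [
                    _inner_oof_probs(Xm[tr], y_tr, C, inner_splits, fold_seed)
                    for Xm, C in zip(Xs, Cs)
                ]
            )
            coeffs = select_coefficients(oof, y_tr, inner_fold_ids, cfg)
        else:
            coeffs = tuple([1] * M)
        sel_coef[f] = coeffs

        models = [
            train_calibrated_svm(Xm[tr], y_tr, C, seed=fold_seed)
            for Xm, C in zip(Xs, Cs)
        ]
        probs = np.column_stack(
            [mod.predict_proba_patient(Xm[te]) for mod, Xm in zip(models, Xs)]
        )
        labels, _ = soft_vote(probs, coeffs)
        bac, sen, spec = balanced_metrics(y[te], labels)
        fold_bac.append(bac)
        fold_sen.append(sen)
        fold_spec.append(spec)
        weights.append(
            {m.measure: mod.coef_ for m, mod in zip(fold_measures, models)}
        )
        fold_test_ids.append([measures[0].subject_ids[i] for i in te])

    return EnsembleResult(
        measures=[m.measure for m in measures],
        fold_bac=np.asarray(fold_bac),
        fold_sen=np.asarray(fold_sen),
        fold_spec=np.asarray(fold_spec),
        selected_C=sel_C,
        coefficients=sel_coef,
        weights=weights,
        fold_test_ids=fold_test_ids,
    )


def permutation_test(
    measures: Sequence[MeasureFeatures],
    meta: Sequence[SubjectMeta],
    cfg: ClassifierConfig | None = None,
    mode: str = "combined",
    observed: EnsembleResult | None = None,
) -> tuple[float, EnsembleResult, np.ndarray]:
    """Permutation p-value for the cross-validated mean balanced accuracy.

    The whole training process (folds re-seeded per replicate) is re-run
    on label-shuffled data; ``p = #(permuted BAC > observed BAC) / n``
    (strict inequality).  With ``conservative_p`` the unbiased
    ``(b + 1) / (n + 1)`` estimate is returned instead.
    """
    cfg = cfg or ClassifierConfig()
    if cfg.n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if observed is None:
        observed = run_cv(measures, meta, cfg, mode=mode)
    rng = np.random.default_rng(cfg.seed)
    groups = [m.group for m in meta]
    perm_bacs = np.zeros(cfg.n_permutations)
    for i in range(cfg.n_permutations):
        shuffled = list(groups)
        rng.shuffle(shuffled)
        perm_meta = [replace(m, group=g) for m, g in zip(meta, shuffled)]
        perm_cfg = replace(cfg, seed=(cfg.seed * 7919 + i + 1) % _SEED_MOD)
        perm_bacs[i] = run_cv(measures, perm_meta, perm_cfg, mode=mode).mean_bac
    b = int((perm_bacs > observed.mean_bac).sum())
    if cfg.conservative_p:
        p = (b + 1) / (cfg.n_permutations + 1)
    else:
        p = b / cfg.n_permutations
    observed.permutation_p = p
    return p, observed, perm_bacs


def _site_group_folds(
    meta: Sequence[SubjectMeta], n_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Folds stratified jointly on site x group."""
    combo = np.array([f"{m.site}|{m.group}" for m in meta])
    _, counts = np.unique(combo, return_counts=True)
    if counts.min() < n_folds:
        warnings.warn(
            "some site x group cell is smaller than the fold count; "
            "folds will not all contain every site"
        )
        n_folds = max(2, int(counts.min()))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(combo)), combo))


def evaluate_pooled_and_stratified(
    measures: Sequence[MeasureFeatures],
    meta: Sequence[SubjectMeta],
    cfg: ClassifierConfig | None = None,
    mode: str = "combined",
) -> dict[str, EnsembleResult]:
    """Pooled (plain stratified CV on the concatenated sample) and
    site-stratified (folds stratified on site x group) evaluations."""
    cfg = cfg or ClassifierConfig()
    sites = {m.site for m in meta}
    results = {"pooled": run_cv(measures, meta, cfg, mode=mode)}
    if len(sites) < 2:
        results["stratified"] = results["pooled"]
        return results
    folds = _site_group_folds(meta, cfg.outer_folds, cfg.seed)
    results["stratified"] = run_cv(measures, meta, cfg, mode=mode, folds=folds)
    return results


def cross_site(
    train_measures: Sequence[MeasureFeatures],
    train_meta: Sequence[SubjectMeta],
    test_measures: Sequence[MeasureFeatures],
    test_meta: Sequence[SubjectMeta],
    cfg: ClassifierConfig | None = None,
    mode: str = "combined",
) -> dict:
    """Tune entirely within the training site, evaluate once on the test site.

    Confound model, C values and soft-voting coefficients all come from
    nested CV inside the training site; the test site is touched exactly
    once.  Returns a dict with bac/sen/spec (percent) and the tuned
    hyperparameters.
    """
    cfg = cfg or ClassifierConfig()
    _check_alignment(train_measures)
    _check_alignment(test_measures)
    if [m.measure for m in train_measures] != [m.measure for m in test_measures]:
        raise ValueError("train/test measure sets differ")
    for a, b in zip(train_measures, test_measures):
        if a.n_features != b.n_features:
            raise ValueError(
                f"feature dimension mismatch for {a.measure}: "
                f"{a.n_features} vs {b.n_features}"
            )
    y_tr = np.array([m.group == "patient" for m in train_meta])
    y_te = np.array([m.group == "patient" for m in test_meta])

    if cfg.confound_policy != "none":
        fitted = []
        for Xtr, Xte in zip(train_measures, test_measures):
            model = fit_confound_model(
                Xtr, train_meta, control_only=True, seed=cfg.seed,
                per_feature=cfg.gp_per_feature,
            )
            fitted.append(
                (residualize(Xtr, model, train_meta), residualize(Xte, model, test_meta))
            )
        train_measures = [f[0] for f in fitted]
        test_measures = [f[1] for f in fitted]

    Cs = [select_C(X.matrix, y_tr, cfg) for X in train_measures]
    if mode == "combined" and len(train_measures) > 1:
        skf = _inner_splitter(y_tr, cfg.inner_folds, cfg.seed)
        splits = list(skf.split(np.zeros(len(y_tr)), y_tr))
        fold_ids = np.zeros(len(y_tr), dtype=int)
        for k, (_, te) in enumerate(splits):
            fold_ids[te] = k
        oof = np.column_stack(
            [
                _inner_oof_probs(X.matrix, y_tr, C, splits, cfg.seed)
                for X, C in zip(train_measures, Cs)
            ]
        )
        coeffs = select_coefficients(oof, y_tr, fold_ids, cfg)
    else:
        coeffs = tuple([1] * len(train_measures))

    models = [
        train_calibrated_svm(X.matrix, y_tr, C, seed=cfg.seed)
        for X, C in zip(train_measures, Cs)
    ]
    probs = np.column_stack(
        [m.predict_proba_patient(X.matrix) for m, X in zip(models, test_measures)]
    )
    labels, _ = soft_vote(probs, coeffs)
    bac, sen, spec = balanced_metrics(y_te, labels)
    return {
        "bac": bac,
        "sen": sen,
        "spec": spec,
        "C": list(Cs),
        "coefficients": list(coeffs),
        "measures": [m.measure for m in train_measures],
    }
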