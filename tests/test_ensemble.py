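import numpy as np
import pytest

from conftest import tiny_feature_cohort
from neurofuse.ensemble import (
    ClassifierConfig,
    balanced_metrics,
    cross_site,
    evaluate_pooled_and_stratified,
    permutation_test,
    run_cv,
    select_C,
    select_coefficients,
    soft_vote,
    train_calibrated_svm,
)


class TestBalancedMetrics:
    def test_perfect_prediction(self):
        y = ["patient"] * 3 + ["control"] * 3
        assert balanced_metrics(y, y) == (100.0, 100.0, 100.0)

    def test_all_control_prediction(self):
        y = ["patient"] * 4 + ["control"] * 4
        pred = ["control"] * 8
        bac, sen, spec = balanced_metrics(y, pred)
        assert (bac, sen, spec) == (50.0, 0.0, 100.0)

    def test_paper_identity_dataset4_combined(self):
        """SEN 85.83 / SPEC 100.00 give BAC 92.92 (2 dp, half away from 0)."""
        from neurofuse.reporting import bac_from_sen_spec

        assert bac_from_sen_spec(85.83, 100.00) == 92.92

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            balanced_metrics(["patient", "patient"], ["patient", "control"])


class TestTrainCalibratedSvm:
    def test_separable_toy_trains_perfectly(self):
        X = np.array([[0.0, 0], [0, 1], [5, 5], [5, 6], [0, 0.5], [5, 5.5]])
        y = np.array([0, 0, 1, 1, 0, 1])
        model = train_calibrated_svm(X, y, C=1.0)
        assert np.array_equal(model.predict(X), y.astype(bool))

    def test_probabilities_sum_to_one(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.arange(30) % 2
        model = train_calibrated_svm(X, y, C=1.0)
        p = model.predict_proba_patient(X)
        assert np.all((p >= 0) & (p <= 1))
        # complement probability is 1 - p by construction of the sigmoid
        assert np.allclose(p + (1 - p), 1.0)

    def test_label_flip_symmetry(self):
        """Flipping all labels on a symmetric toy flips every prediction."""
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-2, 0.5, (20, 2)), rng.normal(2, 0.5, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        m1 = train_calibrated_svm(X, y, C=1.0)
        m2 = train_calibrated_svm(X, 1 - y, C=1.0)
        assert np.array_equal(m1.predict(X), ~m2.predict(X))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_calibrated_svm(np.zeros((4, 2)), np.ones(4), C=1.0)

    def test_exposes_weight_vector(self, rng):
        X = rng.normal(size=(20, 7))
        y = np.arange(20) % 2
        model = train_calibrated_svm(X, y, C=1.0)
        assert model.coef_.shape == (7,)


class TestSelectC:
    def test_member_of_grid(self):
        measures, meta = tiny_feature_cohort(15, 10, effect=1.0, seed=0)
        y = [m.group for m in meta]
        cfg = ClassifierConfig(inner_folds=5)
        C = select_C(measures[0].matrix, y, cfg)
        assert C in cfg.c_grid

    def test_duplicate_grid_tie_rule(self):
        measures, meta = tiny_feature_cohort(15, 10, effect=1.0, seed=1)
        y = [m.group for m in meta]
        cfg1 = ClassifierConfig(inner_folds=5, c_grid=(1.0, 1.0, 10.0, 10.0))
        cfg2 = ClassifierConfig(inner_folds=5, c_grid=(1.0, 10.0))
        assert select_C(measures[0].matrix, y, cfg1) == select_C(
            measures[0].matrix, y, cfg2
        )

    def test_heavy_label_noise_prefers_small_C(self):
        """With heavily noisy labels, small C (strong regularization) wins
        in >= 80% of seeded replicates."""
        wins = 0
        for rep in range(10):
            rng = np.random.default_rng(rep)
            n = 60
            X = rng.normal(size=(n, 5))
            true = (X[:, 0] > 0).astype(int)
            flip = rng.random(n) < 0.35
            y = np.where(flip, 1 - true, true)
            y_labels = np.where(y == 1, "patient", "control")
            cfg = ClassifierConfig(inner_folds=5, seed=rep)
            wins += select_C(X, y_labels, cfg) <= 1.0
        assert wins >= 8


class TestSoftVote:
    def test_equal_coefficients_plain_mean(self, rng):
        probs = rng.random((10, 3))
        _, fused = soft_vote(probs, [2, 2, 2])
        assert np.allclose(fused, probs.mean(axis=1))

    def test_single_measure_scale_invariance(self, rng):
        probs = rng.random((10, 1))
        for c in (1, 4, 10):
            labels, _ = soft_vote(probs, [c])
            assert np.array_equal(labels, probs[:, 0] >= 0.5)

    def test_worked_arithmetic(self):
        labels, fused = soft_vote(np.array([[0.6, 0.3]]), [3, 1])
        assert fused[0] == pytest.approx((3 * 0.6 + 1 * 0.3) / 4)
        assert fused[0] == pytest.approx(0.525)
        assert labels[0]  # patient

    def test_tie_goes_to_patient(self):
        labels, fused = soft_vote(np.array([[0.5]]), [1])
        assert fused[0] == 0.5 and labels[0]

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            soft_vote(np.ones((4, 2)), [1, 2, 3])


class TestSelectCoefficients:
    def _cached_setup(self, seed, n=40, M=2):
        rng = np.random.default_rng(seed)
        y = np.arange(n) % 2 == 0
        probs = np.clip(
            0.5 + np.where(y[:, None], 0.15, -0.15) + rng.normal(0, 0.25, (n, M)),
            0.01,
            0.99,
        )
        fold_ids = np.arange(n) % 5
        return probs, y, fold_ids

    def test_range_contract(self):
        probs, y, folds = self._cached_setup(0)
        cfg = ClassifierConfig(coeff_search="greedy")
        coeffs = select_coefficients(probs, y, folds, cfg)
        assert all(1 <= c <= 10 for c in coeffs)

    def test_full_grid_refuses_many_measures(self):
        probs, y, folds = self._cached_setup(0, M=7)
        cfg = ClassifierConfig(coeff_search="full_grid")
        with pytest.raises(ValueError, match="greedy"):
            select_coefficients(probs, y, folds, cfg)

    def test_informative_beats_shuffled(self):
        """The informative measure's coefficient >= the label-shuffled
        measure's in >= 80% of 20 seeded replicates."""
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            n = 60
            y = np.arange(n) % 2 == 0
            good = np.clip(
                0.5 + np.where(y, 0.25, -0.25) + rng.normal(0, 0.15, n), 0.01, 0.99
            )
            noise = rng.permutation(good)
            cfg = ClassifierConfig(coeff_search="full_grid", seed=rep)
            folds = rng.permutation(n) % 5
            coeffs = select_coefficients(
                np.column_stack([good, noise]), y, folds, cfg
            )
            wins += coeffs[0] >= coeffs[1]
        assert wins >= 16

    def test_full_grid_matches_refit_oracle(self):
        """Cache-correctness: selection over cached probabilities equals a
        naive implementation that recomputes the fused fold scores from
        scratch (no cache) for every pair."""
        from itertools import product

        probs, y, folds = self._cached_setup(3)
        cfg = ClassifierConfig(coeff_search="full_grid")
        got = select_coefficients(probs, y, folds, cfg)

        def naive_bac(c1, c2):
            scores = []
            for f in np.unique(folds):
                sel = folds == f
                fused = (c1 * probs[sel, 0] + c2 * probs[sel, 1]) / (c1 + c2)
                pred = fused >= 0.5
                sen = (pred & y[sel]).sum() / y[sel].sum()
                spec = (~pred & ~y[sel]).sum() / (~y[sel]).sum()
                scores.append(50.0 * (sen + spec))
            return np.mean(scores)

        best, best_score = None, -np.inf
        for combo in product(range(1, 11), repeat=2):
            s = naive_bac(*combo)
            if s > best_score:
                best, best_score = combo, s
        assert got == best


class TestRunCv:
    def test_folds_partition_subjects(self):
        measures, meta = tiny_feature_cohort(20, 8, effect=0.8, seed=4)
        cfg = ClassifierConfig(
            outer_folds=5, inner_folds=3, confound_policy="none", seed=1
        )
        res = run_cv(measures, meta, cfg, mode="single_measure")
        all_ids = [i for fold in res.fold_test_ids for i in fold]
        assert sorted(all_ids) == sorted(m.id for m in meta)
        assert len(set(all_ids)) == len(all_ids)

    def test_bac_identity_every_fold(self):
        measures, meta = tiny_feature_cohort(20, 8, effect=0.8, seed=5)
        cfg = ClassifierConfig(
            outer_folds=5, inner_folds=3, confound_policy="none", seed=2
        )
        res = run_cv(measures, meta, cfg, mode="single_measure")
        assert np.allclose(
            res.fold_bac, (res.fold_sen + res.fold_spec) / 2.0, atol=1e-10
        )

    def test_deterministic(self):
        measures, meta = tiny_feature_cohort(15, 6, effect=0.5, seed=6, n_measures=2)
        cfg = ClassifierConfig(
            outer_folds=4, inner_folds=3, confound_policy="none", seed=3,
            c_grid=(0.01, 1.0, 100.0),
        )
        r1 = run_cv(measures, meta, cfg, mode="combined")
        r2 = run_cv(measures, meta, cfg, mode="combined")
        assert np.array_equal(r1.fold_bac, r2.fold_bac)
        assert np.array_equal(r1.selected_C, r2.selected_C)
        assert np.array_equal(r1.coefficients, r2.coefficients)

    def test_strong_effect_high_bac(self):
        measures, meta = tiny_feature_cohort(30, 10, effect=1.5, seed=7, n_measures=2)
        cfg = ClassifierConfig(
            outer_folds=5, inner_folds=5, confound_policy="none", seed=4
        )
        res = run_cv(measures, meta, cfg, mode="combined")
        assert res.mean_bac > 80.0

    def test_single_measure_mode_arity(self):
        measures, meta = tiny_feature_cohort(10, 4, effect=0.0, seed=8, n_measures=2)
        cfg = ClassifierConfig(outer_folds=3, inner_folds=3, confound_policy="none")
        with pytest.raises(ValueError):
            run_cv(measures, meta, cfg, mode="single_measure")

    def test_too_many_folds_rejected(self):
        measures, meta = tiny_feature_cohort(4, 4, effect=0.0, seed=9)
        cfg = ClassifierConfig(outer_folds=10, inner_folds=3, confound_policy="none")
        with pytest.raises(ValueError, match="folds"):
            run_cv(measures, meta, cfg, mode="single_measure")

    def test_misaligned_measures_rejected(self):
        m1, meta = tiny_feature_cohort(10, 4, effect=0.0, seed=10)
        m2, _ = tiny_feature_cohort(10, 4, effect=0.0, seed=11)
        m2[0].subject_ids = [f"other-{i}" for i in range(20)]
        cfg = ClassifierConfig(outer_folds=3, inner_folds=3, confound_policy="none")
        with pytest.raises(ValueError, match="aligned"):
            run_cv(m1 + m2, meta, cfg, mode="combined")


class TestPermutationTest:
    def test_separable_toy_p_zero(self):
        """Observed 100% BAC cannot be strictly beaten: p = 0 under the
        strict-inequality formula."""
        measures, meta = tiny_feature_cohort(10, 4, effect=4.0, seed=12)
        cfg = ClassifierConfig(
            outer_folds=3, inner_folds=3, n_permutations=19,
            confound_policy="none", seed=5, c_grid=(1.0,),
        )
        p, res, perms = permutation_test(measures, meta, cfg, mode="single_measure")
        assert res.mean_bac == 100.0
        assert p == 0.0

    def test_p_in_unit_interval_and_conservative_variant(self):
        measures, meta = tiny_feature_cohort(8, 4, effect=0.0, seed=13)
        cfg = ClassifierConfig(
            outer_folds=3, inner_folds=3, n_permutations=9,
            confound_policy="none", seed=6, c_grid=(1.0,), conservative_p=True,
        )
        p, _, _ = permutation_test(measures, meta, cfg, mode="single_measure")
        assert 0.0 < p <= 1.0  # (b+1)/(n+1) can never be 0

    def test_invalid_n_permutations(self):
        measures, meta = tiny_feature_cohort(8, 4, effect=0.0, seed=14)
        cfg = ClassifierConfig(n_permutations=0, confound_policy="none")
        with pytest.raises(ValueError):
            permutation_test(measures, meta, cfg, mode="single_measure")


class TestPooledStratifiedAndCrossSite:
    def _two_site_measures(self, seed, offset=0.0, effect=1.2, n_per=20):
        from neurofuse.confounds import MeasureFeatures
        from neurofuse.synthetic import SubjectMeta

        rng = np.random.default_rng(seed)
        meta, rows = [], []
        idx = 0
        for site, site_offset in (("A", 0.0), ("B", offset)):
            for group, shift in (("patient", effect), ("control", 0.0)):
                for _ in range(n_per):
                    meta.append(
                        SubjectMeta(
                            id=f"s{idx:03d}", group=group,
                            age=float(rng.uniform(20, 60)),
                            sex="M" if rng.random() < 0.5 else "F", site=site,
                        )
                    )
                    rows.append(rng.normal(size=6) + shift + site_offset)
                    idx += 1
        X = MeasureFeatures(
            matrix=np.asarray(rows), measure="toy",
            subject_ids=[m.id for m in meta],
        )
        return [X], meta

    def test_single_site_pooled_equals_run_cv(self):
        measures, meta = tiny_feature_cohort(20, 6, effect=1.0, seed=15)
        cfg = ClassifierConfig(
            outer_folds=4, inner_folds=3, confound_policy="none", seed=7
        )
        both = evaluate_pooled_and_stratified(measures, meta, cfg, mode="single_measure")
        direct = run_cv(measures, meta, cfg, mode="single_measure")
        assert np.array_equal(both["pooled"].fold_bac, direct.fold_bac)
        assert np.array_equal(both["stratified"].fold_bac, direct.fold_bac)

    def test_stratified_folds_contain_every_site(self):
        measures, meta = self._two_site_measures(seed=16)
        cfg = ClassifierConfig(
            outer_folds=5, inner_folds=3, confound_policy="none", seed=8
        )
        both = evaluate_pooled_and_stratified(measures, meta, cfg, mode="single_measure")
        id_site = {m.id: m.site for m in meta}
        for fold_ids in both["stratified"].fold_test_ids:
            assert {id_site[i] for i in fold_ids} == {"A", "B"}

    def test_cross_site_feature_mismatch_rejected(self):
        from neurofuse.confounds import MeasureFeatures

        tr, meta_tr = tiny_feature_cohort(10, 6, effect=1.0, seed=17)
        te, meta_te = tiny_feature_cohort(10, 5, effect=1.0, seed=18)
        te[0].measure = tr[0].measure
        cfg = ClassifierConfig(inner_folds=3, confound_policy="none")
        with pytest.raises(ValueError, match="mismatch"):
            cross_site(tr, meta_tr, te, meta_te, cfg, mode="single_measure")

    def test_cross_site_same_distribution_close_to_within(self):
        """Identical-distribution sites: cross-site BAC within 5 points of
        within-site BAC (median over 10 replicates)."""
        gaps = []
        for rep in range(10):
            tr, meta_tr = tiny_feature_cohort(25, 6, effect=1.3, seed=200 + rep)
            te, meta_te = tiny_feature_cohort(25, 6, effect=1.3, seed=300 + rep)
            cfg = ClassifierConfig(
                outer_folds=5, inner_folds=3, confound_policy="none",
                seed=rep, c_grid=(0.01, 1.0, 100.0),
            )
            within = run_cv(tr, meta_tr, cfg, mode="single_measure").mean_bac
            across = cross_site(tr, meta_tr, te, meta_te, cfg, mode="single_measure")
            gaps.append(within - across["bac"])
        assert np.median(gaps) < 5.0

    def test_cross_site_offset_collapse(self):
        """Large site offsets: cross-site BAC >= 10 points below
        within-site (median over 10 replicates)."""
        gaps = []
        for rep in range(10):
            measures, meta = self._two_site_measures(
                seed=400 + rep, offset=6.0, effect=1.2
            )
            site = np.array([m.site for m in meta])
            idx_a, idx_b = np.where(site == "A")[0], np.where(site == "B")[0]
            tr = [measures[0].select(idx_a)]
            te = [measures[0].select(idx_b)]
            meta_a = [meta[i] for i in idx_a]
            meta_b = [meta[i] for i in idx_b]
            cfg = ClassifierConfig(
                outer_folds=5, inner_folds=3, confound_policy="none",
                seed=rep, c_grid=(0.01, 1.0, 100.0),
            )
            within = run_cv(tr, meta_a, cfg, mode="single_measure").mean_bac
            across = cross_site(tr, meta_a, te, meta_b, cfg, mode="single_measure")
            gaps.append(within - across["bac"])
        assert np.median(gaps) >= 10.0


class TestPooledNullWithSiteOffsets:
    def test_site_noise_orthogonal_to_group(self):
        """Strong site offsets but zero group effect: pooled BAC stays at
        chance (mean within 50 +- 3 s.e. over 10 replicates)."""
        from neurofuse.confounds import MeasureFeatures
        from neurofuse.synthetic import SubjectMeta

        bacs = []
        for rep in range(10):
            rng = np.random.default_rng(700 + rep)
            meta, rows = [], []
            idx = 0
            for site, offset in (("A", 0.0), ("B", 5.0)):
                for group in ("patient", "control"):
                    for _ in range(15):
                        meta.append(
                            SubjectMeta(
                                id=f"s{idx:03d}", group=group,
                                age=float(rng.uniform(20, 60)),
                                sex="M" if rng.random() < 0.5 else "F",
                                site=site,
                            )
                        )
                        rows.append(rng.normal(size=8) + offset)
                        idx += 1
            X = MeasureFeatures(
                matrix=np.asarray(rows), measure="toy",
                subject_ids=[m.id for m in meta],
            )
            cfg = ClassifierConfig(
                outer_folds=5, inner_folds=3, confound_policy="none",
                seed=rep, c_grid=(0.01, 1.0, 100.0),
            )
            both = evaluate_pooled_and_stratified([X], meta, cfg, mode="single_measure")
            bacs.append(both["pooled"].mean_bac)
        bacs = np.asarray(bacs)
        se = bacs.std(ddof=1) / np.sqrt(len(bacs))
        assert abs(bacs.mean() - 50.0) <= 3.0 * se, (bacs.mean(), se)


class TestFastSvmPath:
    def test_decision_values_match_public_svc(self):
        """The low-level grid-search path reproduces SVC(kernel='linear')
        decision values to 1e-12."""
        from sklearn.svm import SVC

        from neurofuse.ensemble import _linear_svm_decision

        import warnings as _warnings

        from neurofuse.ensemble import SVM_MAX_ITER

        rng = np.random.default_rng(5)
        for C in (0.01, 1.0, 100.0):
            X = rng.normal(size=(40, 8))
            y = rng.random(40) < 0.5
            if y.all() or not y.any():
                continue
            Xte = rng.normal(size=(12, 8))
            dec, converged = _linear_svm_decision(
                np.ascontiguousarray(X), y, Xte, C
            )
            if C <= 1.0:
                assert converged  # noise data at high C may legitimately cap
            svc = SVC(kernel="linear", C=C, max_iter=SVM_MAX_ITER)
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                svc.fit(X, y.astype(int))
            assert np.allclose(dec, svc.decision_function(Xte), atol=1e-12)


class TestCrossSiteDegenerateReuse:
    def test_same_site_as_train_and_test_is_above_chance(self):
        """Using the training site as its own test site approximates
        resubstitution: well above chance on an effect-bearing cohort."""
        measures, meta = tiny_feature_cohort(20, 6, effect=1.5, seed=55)
        cfg = ClassifierConfig(
            inner_folds=3, confound_policy="none", seed=9,
            c_grid=(0.01, 1.0, 100.0),
        )
        res = cross_site(measures, meta, measures, meta, cfg, mode="single_measure")
        assert res["bac"] > 70.0
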