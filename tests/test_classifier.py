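"""L1-logistic risk model: solver, two-step training, evaluation, score."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

import vmptb as v
from vmptb.classifier import (
    DEFAULT_C_GRID,
    TrainingSet,
    _metrics,
    clinical_training_set,
    minmax_normalize,
)

SMALL_GRID = (0.01, 0.1, 1.0, 10.0)


def toy_data(seed=0, n=40, p=6, informative=2):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    logits = X[:, :informative].sum(axis=1) * 1.5
    y = np.where(rng.random(n) < 1 / (1 + np.exp(-logits)), 1, -1)
    if len(np.unique(y)) < 2:
        y[0] = -y[0]
    return TrainingSet(x=X, y=y, feature_names=[f"f{j}" for j in range(p)])


def pair_count_auroc(scores, labels):
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        assert v.auroc([0.9, 0.8, 0.1, 0.2], [1, 1, -1, -1]) == 1.0

    def test_ties_count_half(self):
        assert v.auroc([0.5, 0.5], [1, -1]) == 0.5

    def test_matches_pair_counting(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(4, 31))
            labels = rng.choice([1, -1], size=n)
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            assert v.auroc(scores, labels) == pytest.approx(
                pair_count_auroc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            v.auroc([0.1, 0.2], [1, 1])


class TestFitL1Logistic:
    def test_huge_penalty_zeroes_weights(self):
        data = toy_data(seed=1)
        w, b = v.fit_l1_logistic(data, C=1e6)
        assert np.all(w == 0)
        n_pos = (data.y == 1).sum()
        n_neg = (data.y == -1).sum()
        assert b == pytest.approx(np.log(n_pos / n_neg), abs=1e-3)

    def test_separable_no_penalty_hits_iteration_cap(self, caplog):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([-1, -1, 1, 1])
        data = TrainingSet(x=X, y=y, feature_names=["f"])
        with caplog.at_level("WARNING"):
            w, b = v.fit_l1_logistic(data, C=0.0, max_iter=50)
        assert w[0] > 1.0  # diverging toward the separating direction

    def test_gradient_stationarity_finite_differences(self):
        """At the optimum the smooth-part gradient balances the penalty."""
        for seed in range(3):
            data = toy_data(seed=seed, n=30, p=4)
            C = 0.5
            w, b = v.fit_l1_logistic(data, C)

            def smooth(wvec, bval):
                m = data.y * (data.x @ wvec + bval)
                return np.logaddexp(0, -m).sum()

            eps = 1e-6
            for j in range(4):
                e = np.zeros(4)
                e[j] = eps
                g = (smooth(w + e, b) - smooth(w - e, b)) / (2 * eps)
                if w[j] > 0:
                    assert g == pytest.approx(-C, abs=1e-3)
                elif w[j] < 0:
                    assert g == pytest.approx(C, abs=1e-3)
                else:
                    assert abs(g) <= C + 1e-3
            gb = (smooth(w, b + eps) - smooth(w, b - eps)) / (2 * eps)
            assert gb == pytest.approx(0.0, abs=1e-3)

    def test_l1_norm_monotone_along_penalty_path(self):
        data = toy_data(seed=2)
        norms = [np.abs(v.fit_l1_logistic(data, C)[0]).sum()
                 for C in (0.01, 0.1, 1.0, 10.0, 100.0)]
        for lo, hi in zip(norms[1:], norms):
            assert lo <= hi + 1e-6

    def test_agrees_with_sklearn(self):
        """Independent solver cross-check (note the reciprocal C convention).

        saga leaves the intercept unpenalized, matching this package's
        convention; weights are compared loosely and the shared objective
        exactly: the direct solution must never be worse.
        """
        from sklearn.linear_model import LogisticRegression

        data = toy_data(seed=3)

        def objective(w, b, C):
            m = data.y * (data.x @ w + b)
            return np.logaddexp(0, -m).sum() + C * np.abs(w).sum()

        for C in (0.5, 2.0):
            w, b = v.fit_l1_logistic(data, C)
            clf = LogisticRegression(penalty="l1", C=1.0 / C, solver="saga",
                                     tol=1e-10, max_iter=100000)
            clf.fit(data.x, data.y)
            np.testing.assert_allclose(w, clf.coef_[0], atol=0.05)
            assert b == pytest.approx(clf.intercept_[0], abs=0.05)
            assert objective(w, b, C) <= objective(clf.coef_[0],
                                                   clf.intercept_[0], C) + 1e-6

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            v.fit_l1_logistic(toy_data(), C=-1.0)


class TestTwoStepTrain:
    def test_informative_features_pass_filter_and_model_is_sparse(self):
        data = toy_data(seed=3, n=80, p=8, informative=3)
        model = v.two_step_train(data, c_grid=SMALL_GRID, n_splits=3)
        assert {"f0", "f1", "f2"} <= set(model.training_meta["univariate_kept"])
        assert model.selected_features  # the lasso keeps a non-empty subset
        assert set(model.selected_features) <= set(model.training_meta["univariate_kept"])

    def test_p_cut_zero_gives_flagged_intercept_model(self):
        data = toy_data(seed=6)
        model = v.two_step_train(data, p_cut=0.0, c_grid=SMALL_GRID)
        assert model.intercept_only
        assert model.training_meta["flag"] == "intercept-only"
        n_pos, n_neg = (data.y == 1).sum(), (data.y == -1).sum()
        assert model.intercept == pytest.approx(np.log(n_pos / n_neg))

    def test_null_selection_rate_matches_filter_level(self):
        """With permuted labels the univariate filter keeps ~5% of features."""
        rng = np.random.default_rng(7)
        counts = []
        for _ in range(60):
            X = rng.normal(size=(40, 20))
            y = np.array([1] * 20 + [-1] * 20)
            model = v.two_step_train(
                TrainingSet(x=X, y=y, feature_names=[f"f{j}" for j in range(20)]),
                c_grid=[1.0])
            counts.append(len(model.training_meta.get("univariate_kept", [])))
        assert np.mean(counts) == pytest.approx(0.05 * 20, abs=0.6)


class TestLooEvaluate:
    def test_no_leakage_from_held_out_features(self):
        """A fold's model depends only on the remaining subjects.

        The held-out score of subject 0 must equal the decision value of a
        model retrained from scratch without subject 0 — so no statistic of
        the held-out sample (filter p-values, grid search, normalization)
        can leak into its own fold.
        """
        data = toy_data(seed=8, n=24, p=5)
        subjects = [f"u{i}" for i in range(24)]
        result = v.loo_evaluate(data, subjects, c_grid=SMALL_GRID, n_splits=3,
                                seed=0)
        rest = TrainingSet(x=data.x[1:], y=data.y[1:],
                           feature_names=data.feature_names)
        model = v.two_step_train(rest, c_grid=SMALL_GRID, n_splits=3, seed=0)
        expected = model.decision_values(data.x[:1], data.feature_names)[0]
        assert result.loo_scores.iloc[0] == pytest.approx(expected, abs=1e-10)

    def test_strong_signal_reaches_high_auroc(self):
        cfg = v.SyntheticConfig(seed=9, n_cases=20, n_controls_pool=150,
                                ptb_effect={
                                    "Lachnospiraceae_BVAB1": 2.5,
                                    "Sneathia_amnii": 2.5,
                                    "Prevotella_cluster2": 2.0,
                                    "TM7_H1": 2.0,
                                    "Lactobacillus_crispatus_cluster": -2.0,
                                })
        cohort = v.simulate_cohort(cfg)
        table = v.filter_min_reads(cohort.table)
        rec = cohort.records[cohort.records["sample_id"].isin(table.sample_ids)]
        chosen = v.earliest_sample_in_window(rec, (42, 167))
        frame = table.to_frame().loc[chosen["sample_id"]]
        outcomes = pd.Series(chosen["outcome"].to_numpy(), index=chosen["sample_id"])
        data = v.microbiome_training_set(frame, outcomes,
                                         taxa=v.filter_low_abundance(frame))
        res = v.loo_evaluate(data, list(chosen["subject_id"]),
                             c_grid=SMALL_GRID, n_splits=3)
        assert res.auroc >= 0.95

    def test_single_class_fold_rejected(self):
        X = np.array([[0.0], [1.0], [2.0]])
        data = TrainingSet(x=X, y=np.array([1, -1, -1]), feature_names=["f"])
        with pytest.raises(ValueError, match="one class"):
            v.loo_evaluate(data, ["a", "b", "c"], c_grid=(1.0,))


class TestPermutationTest:
    def test_add_one_convention(self):
        data = toy_data(seed=10, n=24, p=4, informative=3)
        p, null, observed = v.permutation_test(
            data, n_perm=19, seed=0, c_grid=(1.0,), n_splits=3)
        assert p == (1 + np.sum(null >= observed)) / 20
        assert 0 < p <= 1

    def test_strong_signal_gets_minimal_p(self):
        rng = np.random.default_rng(11)
        X = np.vstack([rng.normal(3, 0.3, size=(12, 2)),
                       rng.normal(-3, 0.3, size=(12, 2))])
        y = np.array([1] * 12 + [-1] * 12)
        data = TrainingSet(x=X, y=y, feature_names=["a", "b"])
        p, null, observed = v.permutation_test(
            data, n_perm=49, seed=1, c_grid=(0.1,), n_splits=3)
        assert observed == 1.0
        assert p <= 3 / 50  # at most a couple of perfect null refits


class TestPtbScore:
    def test_all_below_threshold_scores_zero(self):
        assert v.ptb_score({"Samn": 0.001, "BVAB1": 0.0005, "TM7": 0.0,
                            "Pcl2": 0.001}) == 0.0

    def test_single_taxon_at_one(self):
        assert v.ptb_score({"Samn": 1.0, "BVAB1": 0.0, "TM7": 0.0,
                            "Pcl2": 0.0}) == pytest.approx(0.775 * 3)

    def test_missing_taxon_named_in_error(self):
        with pytest.raises(KeyError, match="TM7_H1"):
            v.ptb_score({"Samn": 0.1, "BVAB1": 0.1, "Pcl2": 0.1})

    def test_monotone_in_each_input(self):
        base = {"Samn": 0.1, "BVAB1": 0.2, "TM7": 0.05, "Pcl2": 0.3}
        s0 = v.ptb_score(base)
        for key in base:
            bumped = dict(base)
            bumped[key] = min(1.0, base[key] * 2)
            assert v.ptb_score(bumped) >= s0


class TestClinicalModel:
    def test_feature_construction(self):
        rec = pd.DataFrame({
            "sample_id": ["a", "b"], "subject_id": ["u1", "u2"],
            "gestational_age": [100, 100], "outcome": ["PTB", "TB"],
            "short_cervix": [1, 0], "cerclage": [0, 0],
            "vaginal_ph": [5.0, 4.2], "bmi": [30.0, 25.0],
            "progesterone": [1, 0], "gravidity": [3.0, 2.0],
            "parity": [1.0, 1.0], "history_miscarriage_stillbirth": [0, 0],
            "history_ptb": [1, 0], "antibiotics_6mo": [0, 1],
        })
        data, subjects = clinical_training_set(rec)
        gmp = data.x[:, data.feature_names.index("gravidity_minus_parity")]
        np.testing.assert_allclose(gmp, [2.0, 1.0])
        flags = data.x[:, data.feature_names.index("short_cervix")]
        assert set(flags) <= {0.0, 1.0}

    def test_constant_feature_normalized_to_zero(self, caplog):
        X = np.array([[1.0, 5.0], [1.0, 7.0]])
        with caplog.at_level("WARNING"):
            out = minmax_normalize(X, X)
        np.testing.assert_allclose(out[:, 0], [0.0, 0.0])
        np.testing.assert_allclose(out[:, 1], [0.0, 1.0])

    def test_clinical_pipeline_discriminates(self, default_cohort):
        model, result = v.clinical_model(default_cohort.records)
        assert 0.6 <= result.auroc <= 0.95
        assert "history_ptb" in model.selected_features


def test_metrics_threshold_zero():
    scores = np.array([0.5, -0.2, 0.1, -0.4])
    y = np.array([1, 1, -1, -1])
    sens, spec, auc = _metrics(scores, y)
    assert sens == 0.5 and spec == 0.5


def test_whole_cohort_filter_mode_runs_and_differs_in_selection():
    """The comparison mode filters once up front; folds then skip step 1."""
    data = toy_data(seed=12, n=24, p=6, informative=2)
    subjects = [f"u{i}" for i in range(24)]
    in_fold = v.loo_evaluate(data, subjects, c_grid=(1.0,), n_splits=3)
    once = v.loo_evaluate(data, subjects, c_grid=(1.0,), n_splits=3,
                          whole_cohort_filter=True)
    assert 0 <= once.auroc <= 1
    assert len(once.loo_scores) == len(in_fold.loo_scores)
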