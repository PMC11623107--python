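"""Classifier training, grid search, metrics and importance extraction."""

import numpy as np
import pandas as pd
import pytest

from paretognome.io import additive_design, impute_missing, one_hot_encode
from paretognome.models import (
    DegenerateFoldError,
    EncodedDesign,
    TrainingConfig,
    cv_report,
    entropy_information_gain,
    extract_importance,
    grid_search_cv,
    stratified_folds,
    train_model,
)


@pytest.fixture(scope="module")
def recovery_design(small_dataset):
    gm, _, phen, truth = small_dataset
    return additive_design(gm), phen.labels, truth


class TestEntropyInformationGain:
    def test_uniform_two_class_entropy_is_one_bit(self):
        # H(50,50) = 1 bit; a no-op split keeps it: IG = 0
        assert entropy_information_gain([50, 50], [25, 25], [25, 25]) == pytest.approx(0.0)

    def test_perfect_split_gains_one_bit(self):
        assert entropy_information_gain([50, 50], [50, 0], [0, 50]) == pytest.approx(1.0, abs=1e-12)

    def test_mixed_split_matches_direct_formula(self):
        """parent (60,40), children (30,10) and (30,30), evaluated by hand."""

        def h(counts):
            p = np.array(counts, dtype=float)
            p = p[p > 0] / p.sum()
            return -(p * np.log2(p)).sum()

        expected = h([60, 40]) - 0.4 * h([30, 10]) - 0.6 * h([30, 30])
        got = entropy_information_gain([60, 40], [30, 10], [30, 30])
        assert got == pytest.approx(expected, abs=1e-12)

    def test_invalid_splits_rejected(self):
        with pytest.raises(ValueError):
            entropy_information_gain([10, 10], [5, 5], [6, 5])
        with pytest.raises(ValueError):
            entropy_information_gain([0, 0], [0, 0], [0, 0])


class TestFoldsAndReport:
    def test_stratified_folds_deterministic_and_both_classes(self):
        y = np.array([0] * 20 + [1] * 80)
        a = stratified_folds(y, 5, seed=3)
        b = stratified_folds(y, 5, seed=3)
        for (tra, tea), (trb, teb) in zip(a, b):
            assert np.array_equal(tra, trb) and np.array_equal(tea, teb)
            assert set(y[tea]) == {0, 1}

    def test_degenerate_fold_named(self):
        y = np.array([0, 1, 1, 1, 1, 1, 1, 1, 1, 1])
        with pytest.raises((DegenerateFoldError, ValueError)):
            stratified_folds(y, 5, seed=0)

    def test_perfect_classifier_scores_ones(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        X = np.column_stack([y * 2.0, rng.standard_normal(200)])
        report = cv_report(X, y, "logreg", {"C": 10.0}, folds=5, seed=0)
        for metric in ("accuracy", "control_f1", "case_f1"):
            mean, sd = getattr(report, metric)
            assert mean == pytest.approx(1.0)
            assert sd == pytest.approx(0.0)

    def test_constant_case_predictor_metrics_forced(self):
        """A label-independent design at 90% cases: accuracy ~0.9 and
        control recall 0."""
        rng = np.random.default_rng(1)
        n = 400
        y = (rng.random(n) < 0.9).astype(int)
        X = rng.standard_normal((n, 3))  # no signal; model predicts majority
        report = cv_report(X, y, "logreg", {"C": 0.01}, folds=5, seed=0)
        assert report.accuracy[0] == pytest.approx(y.mean(), abs=0.03)
        assert report.control_recall[0] == pytest.approx(0.0, abs=0.02)

    def test_report_frame_layout(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 100)
        X = rng.standard_normal((100, 4))
        frame = cv_report(X, y, "logreg", {}, folds=3, seed=0).to_frame()
        assert list(frame.columns) == [
            "accuracy",
            "control_precision", "control_recall", "control_f1",
            "case_precision", "case_recall", "case_f1",
        ]


class TestGridSearch:
    def test_single_point_grid_is_identity(self, recovery_design):
        design, y, _ = recovery_design
        tc = TrainingConfig("logreg", grid={"C": [0.5]}, folds=3, seed=1)
        params, report, results = grid_search_cv(design.matrix, y, tc)
        assert params == {"C": 0.5}
        direct = cv_report(design.matrix, y, "logreg", {"C": 0.5}, folds=3, seed=1)
        assert report.control_f1 == direct.control_f1

    def test_identical_points_first_wins(self, recovery_design):
        design, y, _ = recovery_design
        tc = TrainingConfig("logreg", grid={"C": [1.0, 1.0]}, folds=3, seed=1)
        params, _, results = grid_search_cv(design.matrix, y, tc)
        assert params == {"C": 1.0}
        assert len(results) == 2

    def test_winner_beats_majority_baseline_on_recovery(self, recovery_design):
        """The tuned model's control-F1 exceeds the always-control baseline
        computed on the same folds (design reduced to an informative subset,
        as after the greedy-selection stage)."""
        design, y, truth = recovery_design
        cols = np.unique(np.concatenate([truth.causal_indices, np.arange(40)]))
        X = design.matrix[:, cols]
        tc = TrainingConfig("logreg", grid={"C": [0.1, 1.0]}, folds=5, seed=1)
        _, report, _ = grid_search_cv(X, y, tc)
        from sklearn.metrics import f1_score

        baseline = np.mean(
            [
                f1_score(y[te], np.zeros_like(y[te]), pos_label=0)
                for _, te in stratified_folds(y, 5, seed=1)
            ]
        )
        assert report.control_f1[0] > baseline


class TestLogreg:
    def test_no_signal_coefficients_shrink(self):
        rng = np.random.default_rng(3)
        y = np.tile([0, 1], 100)
        X = rng.standard_normal((200, 10))
        model = train_model(X, y, "logreg", {"C": 0.001}, seed=0)
        assert np.abs(model.coef_).max() <= 5e-2
        probs = model.predict_proba(X)[:, 1]
        assert probs.min() >= 0 and probs.max() <= 1
        assert probs.mean() == pytest.approx(y.mean(), abs=0.05)

    def test_duplicated_column_leaves_predictions_unchanged(self, recovery_design):
        """The weight of a duplicated feature splits evenly between the two
        copies, leaving predicted probabilities invariant.  Exact only as
        the L2 penalty vanishes (a duplicate halves the effective penalty on
        that feature), so the check runs in the weak-penalty regime with a
        tight solver."""
        design, y, _ = recovery_design
        X = design.matrix[:, :50].astype(np.float64)
        params = {"C": 1000.0, "solver": "lbfgs", "tol": 1e-14, "max_iter": 20000}
        model_a = train_model(X, y, "logreg", params, seed=0)
        X_dup = np.column_stack([X, X[:, 0]])
        model_b = train_model(X_dup, y, "logreg", params, seed=0)
        halves = model_b.coef_[0, 0], model_b.coef_[0, -1]
        assert halves[0] == pytest.approx(halves[1], rel=1e-6)
        pa = model_a.predict_proba(X)[:, 1]
        pb = model_b.predict_proba(X_dup)[:, 1]
        assert np.allclose(pa, pb, atol=1e-6)

    def test_importance_is_absolute_coefficient(self):
        y = np.tile([0, 1], 50)
        X = np.column_stack([y * 1.0, -2.0 * y])
        design = EncodedDesign(X, np.array([0, 1]), np.array(["m1", "m2"], dtype=object), "additive")
        model = train_model(X, y, "logreg", {"C": 1.0}, seed=0)
        imp = extract_importance(model, design, "logreg")
        assert np.allclose(imp, np.abs(model.coef_.ravel()))
        assert (imp >= 0).all()


class TestGbdt:
    def test_single_stump_credits_the_separating_feature(self):
        y = np.tile([0, 1], 50)
        X = np.column_stack([y * 1.0, np.zeros(100)])
        design = EncodedDesign(X, np.array([0, 1]), np.array(["m1", "m2"], dtype=object), "additive")
        model = train_model(X, y, "gbdt", {"n_estimators": 1, "max_depth": 1}, seed=0)
        imp = extract_importance(model, design, "gbdt")
        assert imp[0] > 0
        assert imp[1] == 0  # unused feature

    def test_seeded_importance_reproducible(self, recovery_design):
        design, y, _ = recovery_design
        params = {"n_estimators": 30, "max_depth": 3}
        a = extract_importance(train_model(design.matrix, y, "gbdt", params, seed=7), design, "gbdt")
        b = extract_importance(train_model(design.matrix, y, "gbdt", params, seed=7), design, "gbdt")
        assert np.array_equal(a, b)
        assert (a >= 0).all()

    def test_label_permutation_destroys_importance(self, recovery_design):
        design, y, _ = recovery_design
        params = {"n_estimators": 30, "max_depth": 3}
        real = extract_importance(train_model(design.matrix, y, "gbdt", params, seed=7), design, "gbdt")
        rng = np.random.default_rng(7)
        perm = extract_importance(
            train_model(design.matrix, rng.permutation(y), "gbdt", params, seed=7), design, "gbdt"
        )
        assert real.max() > perm.max()

    def test_stump_gain_consistent_with_information_gain_ordering(self):
        """A clean split must register strictly more gain than a weak one."""
        rng = np.random.default_rng(5)
        y = np.tile([0, 1], 100)
        clean = y * 1.0
        noisy = y * 1.0
        flip = rng.random(200) < 0.4
        noisy[flip] = 1 - noisy[flip]
        X = np.column_stack([clean, noisy])
        design = EncodedDesign(X, np.array([0, 1]), np.array(["m1", "m2"], dtype=object), "additive")
        model = train_model(X, y, "gbdt", {"n_estimators": 1, "max_depth": 2}, seed=0)
        imp = extract_importance(model, design, "gbdt")
        assert imp[0] > imp[1]


class TestOneHotAggregation:
    def test_max_over_marker_triple(self, small_dataset):
        gm, _, phen, _ = small_dataset
        design = one_hot_encode(impute_missing(gm))
        sub = design.restrict_markers(np.arange(30))
        model = train_model(sub.matrix, phen.labels, "logreg", {"C": 1.0}, seed=0)
        imp = extract_importance(model, sub, "logreg", aggregate="max")
        coefs = np.abs(model.coef_.ravel())
        for j in range(30):
            cols = np.flatnonzero(sub.column_to_marker == j)
            assert imp[j] == pytest.approx(coefs[cols].max())
        imp_sum = extract_importance(model, sub, "logreg", aggregate="sum")
        assert (imp_sum >= imp - 1e-12).all()


class TestSignalDetection:
    @pytest.mark.parametrize("kind,params", [
        ("logreg", {"C": 1.0}),
        ("gbdt", {"n_estimators": 50, "max_depth": 3}),
        ("tabnet", {"max_epochs": 15}),
    ])
    def test_causal_mean_importance_exceeds_null(self, recovery_design, kind, params):
        design, y, truth = recovery_design
        model = train_model(design.matrix, y, kind, params, seed=0)
        imp = extract_importance(model, design, kind)
        causal = np.zeros(design.n_markers, bool)
        causal[truth.causal_indices] = True
        assert imp[causal].mean() > imp[~causal].mean()
        assert np.isfinite(imp).all() and (imp >= 0).all()
        assert len(imp) == design.n_markers
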