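"""Spline basis, ridge/MLP/stacked fits, internal validation, AE screening."""

import numpy as np
import pytest

from petrushka.absolute import (
    ModelSpec,
    ScreenConfig,
    ValidationReport,
    calibration_slope,
    cross_validate,
    fit_meta_learner,
    fit_mlp,
    fit_model,
    fit_ridge,
    minimum_sample_size,
    screen_adverse_events,
)
from petrushka.errors import (
    DegenerateInputError,
    DegenerateOutcomeError,
    InvalidArgumentError,
)
from petrushka.splines import build_spline_basis


class TestSplineBasis:
    def test_four_knots_give_two_nonlinear_columns(self):
        rng = np.random.default_rng(0)
        basis = build_spline_basis(rng.uniform(0, 1, 500), n_knots=4)
        assert basis.n_nonlinear == 2
        assert basis.transform(rng.uniform(0, 1, 50)).shape == (50, 2)

    def test_linear_truth_has_zero_nonlinear_coefficients(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-2, 5, 400)
        y = 3.0 * x + 1.0
        basis = build_spline_basis(x, 4)
        X = np.column_stack([np.ones_like(x), basis.design(x)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)  # least-squares oracle
        assert coef[0] == pytest.approx(1.0, abs=1e-8)
        assert coef[1] == pytest.approx(3.0, abs=1e-8)
        assert np.all(np.abs(coef[2:]) < 1e-8)

    def test_linear_beyond_boundary_knots(self):
        rng = np.random.default_rng(2)
        basis = build_spline_basis(rng.uniform(0, 1, 300), 4)
        for grid in (np.linspace(1.5, 3.0, 40),      # above upper knot
                     np.linspace(-3.0, -0.5, 40)):   # below lower knot
            second_diff = np.diff(basis.transform(grid), n=2, axis=0)
            assert np.all(np.abs(second_diff) < 1e-9)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(DegenerateInputError):
            build_spline_basis(np.array([1.0, 1.0, 2.0, 2.0] * 10), 4)


def _linear_data(n=800, p=5, noise=1.0, seed=0, binary=False):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.linspace(0.5, -0.5, p)
    lp = X @ beta
    if binary:
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
    else:
        y = 1.5 + lp + rng.normal(0, noise, n)
    return X, y, beta


class TestRidge:
    def test_lambda_zero_equals_ols(self):
        X, y, _ = _linear_data(seed=3)
        m = fit_ridge(X, y, lam=0.0)
        Xc = np.column_stack([np.ones(len(y)), X])
        ols, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        inter, coef = m.coefficients_original()
        assert inter == pytest.approx(ols[0], abs=1e-6)
        assert np.allclose(coef, ols[1:], atol=1e-6)

    def test_infinite_lambda_shrinks_to_outcome_mean(self):
        X, y, _ = _linear_data(seed=4)
        m = fit_ridge(X, y, lam=1e12)
        assert np.allclose(m.predict(X), y.mean(), atol=1e-3)

    def test_logistic_coefficient_recovery(self):
        X, y, beta = _linear_data(n=100_000, seed=5, binary=True)
        m = fit_ridge(X, y, family="binary", lam=1e-4)
        _, coef = m.coefficients_original()
        assert np.max(np.abs(coef - beta)) < 0.05

    def test_constant_binary_outcome_rejected(self):
        X, _, _ = _linear_data(n=50, seed=6)
        with pytest.raises(DegenerateOutcomeError):
            fit_ridge(X, np.ones(50), family="binary", lam=1.0)

    def test_probabilities_clipped_into_open_interval(self):
        X, y, _ = _linear_data(n=500, seed=7, binary=True)
        p = fit_ridge(X, y, family="binary", lam=1.0).predict(X)
        assert np.all((p > 0) & (p < 1))


class TestMLPAndStack:
    def test_mlp_deterministic_and_competitive_with_ridge(self):
        X, y, _ = _linear_data(n=3000, noise=1.0, seed=8)
        tr, te = slice(0, 2400), slice(2400, None)
        mlp = fit_mlp(X[tr], y[tr], seed=1, hidden=(64, 64), max_iter=200)
        assert np.allclose(mlp.predict(X[te]),
                           fit_mlp(X[tr], y[tr], seed=1, hidden=(64, 64),
                                   max_iter=200).predict(X[te]))
        ridge = fit_ridge(X[tr], y[tr], lam=0.0)
        mae = lambda m: np.mean(np.abs(y[te] - m.predict(X[te])))
        assert mae(mlp) <= 1.2 * mae(ridge)  # linear truth: near the ridge oracle

    def test_constant_outcome_predicts_constant(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(300, 3))
        m = fit_mlp(X, np.full(300, 7.0), seed=0, hidden=(16,), max_iter=100)
        pred = m.predict(X)
        assert pred.mean() == pytest.approx(7.0, abs=0.2)
        assert pred.std() < 0.5  # residual spread is init-scale noise only

    def test_redundant_stack_tracks_base_predictions(self):
        X, y, _ = _linear_data(n=1500, noise=0.5, seed=10)
        base = [ModelSpec("ridge", "continuous", {"lam": 0.0}),
                ModelSpec("ridge", "continuous", {"lam": 0.0})]
        stack = fit_meta_learner(base, X, y, seed=2)
        base_pred = fit_ridge(X, y, lam=0.0).predict(X)
        assert np.mean(np.abs(stack.predict(X) - base_pred)) < 0.25

    def test_stack_not_catastrophically_worse_than_best_base(self):
        # nonlinear truth: the two base learners genuinely differ
        rng = np.random.default_rng(11)
        X = rng.normal(size=(2500, 4))
        y = X[:, 0] ** 2 + X[:, 1] - 0.5 * X[:, 2] + rng.normal(0, 0.5, 2500)
        tr, te = slice(0, 2000), slice(2000, None)
        base = [ModelSpec("ridge", "continuous", {"lam": 1.0}),
                ModelSpec("mlp", "continuous", {"hidden": (64, 64), "seed": 3})]
        stack = fit_meta_learner(base, X[tr], y[tr], seed=3)
        maes = [np.mean(np.abs(y[te] - fit_model(s, X[tr], y[tr], seed=3).predict(X[te])))
                for s in base]
        stack_mae = np.mean(np.abs(y[te] - stack.predict(X[te])))
        assert stack_mae <= 1.10 * min(maes)

    def test_mismatched_families_rejected(self):
        X, y, _ = _linear_data(n=100, seed=12)
        with pytest.raises(InvalidArgumentError):
            fit_meta_learner([ModelSpec("ridge", "continuous"),
                              ModelSpec("ridge", "binary")], X, y)


class TestSerialization:
    def test_ridge_model_json_round_trip_fields(self, tmp_path):
        X, y, _ = _linear_data(n=200, seed=30)
        m = fit_ridge(X, y, lam=0.5, feature_names=[f"x{i}" for i in range(5)])
        import json

        payload = json.loads(m.to_json(tmp_path / "m.json"))
        assert payload["format_version"] == 1
        assert payload["lambda"] == 0.5
        assert len(payload["coef"]) == 5

    def test_mlp_model_serializes_weights(self):
        X, y, _ = _linear_data(n=200, seed=31)
        m = fit_mlp(X, y, seed=0, hidden=(8,), max_iter=50)
        import json

        payload = json.loads(m.to_json())
        assert len(payload["weights"]) == 2  # input->hidden, hidden->output


class TestCrossValidation:
    def test_noiseless_correct_spec_has_negligible_mae(self):
        X, y, _ = _linear_data(n=500, noise=0.0, seed=13)
        rep = cross_validate(ModelSpec("ridge", "continuous", {"lam": 0.0}), X, y, k=10)
        assert rep.mae < 1e-6

    def test_random_predictor_auc_near_half(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(10_000, 3))
        y = (rng.random(10_000) < 0.3).astype(float)  # independent of X
        rep = cross_validate(ModelSpec("ridge", "binary", {"lam": 1.0}), X, y,
                             k=10, seed=1)
        assert rep.auc == pytest.approx(0.5, abs=0.03)

    def test_well_specified_model_calibration_slope_near_one(self):
        X, y, _ = _linear_data(n=20_000, seed=15, binary=True)
        rep = cross_validate(ModelSpec("ridge", "binary", {"lam": 1e-4}), X, y,
                             k=10, seed=2)
        assert rep.calibration_slope == pytest.approx(1.0, abs=0.1)
        assert rep.auc > 0.6

    def test_auc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(16)
        y = (rng.random(2000) < 0.4).astype(float)
        score = rng.normal(size=2000) + y
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(y, score) == pytest.approx(
            roc_auc_score(y, np.exp(2 * score)), abs=1e-12)

    def test_invalid_k_rejected(self):
        X, y, _ = _linear_data(n=20, seed=17)
        with pytest.raises(InvalidArgumentError):
            cross_validate(ModelSpec("ridge", "continuous"), X, y, k=21)


class TestScreening:
    CONFIG = ScreenConfig(n_params=10, epp=10.0, r2_cs=0.05)

    def _screen(self, auc, n):
        val = {"nausea": ValidationReport(k=5, family="binary", auc=auc)}
        return screen_adverse_events(None, val, n_available={"nausea": n},
                                     prevalence={"nausea": 0.2}, config=self.CONFIG)

    def test_auc_just_below_threshold_excluded(self):
        assert self._screen(0.54, 10_000).included == []

    def test_auc_at_threshold_included(self):
        assert self._screen(0.55, 10_000).included == ["nausea"]

    def test_small_sample_excluded_regardless_of_auc(self):
        min_n = minimum_sample_size(0.2, self.CONFIG)
        assert self._screen(0.99, int(min_n) - 1).included == []
        assert self._screen(0.99, int(np.ceil(min_n))).included == ["nausea"]

    def test_unknown_event_name_rejected(self):
        with pytest.raises(InvalidArgumentError):
            screen_adverse_events(None, {"spontaneous_combustion": 0.9},
                                  n_available={"spontaneous_combustion": 10_000})

    def test_counts_taken_from_reference_arm(self, ipd_small):
        val = {"anxiety": 0.60}
        res = screen_adverse_events(ipd_small, val, config=self.CONFIG)
        n_parox = (ipd_small["treatment"] == "paroxetine").sum()
        assert res.table.loc[0, "n_available"] == n_parox
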