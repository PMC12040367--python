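"""Logistic fitting (IRLS), reference-oracle agreement, backward AIC."""

import numpy as np
import pytest

from lungrisk.logistic import (
    FeatureBlock,
    Scaler,
    SchemaError,
    SeparationError,
    backward_aic,
    fit_logistic,
    model_aic,
    predict_risk,
)


def identity_block(X, names):
    block = FeatureBlock(X, tuple(names))
    block.scaler = Scaler(tuple(names), np.zeros(X.shape[1]),
                          np.ones(X.shape[1]))
    return block


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 25 + [0] * 75)
        block = FeatureBlock(np.empty((100, 0)), ())
        model = fit_logistic(block, y)
        assert model.intercept == pytest.approx(np.log(0.25 / 0.75), abs=1e-9)
        # round-trip: predictions equal the training prevalence
        probs = predict_risk(model, FeatureBlock(np.empty((4, 0)), ()))
        np.testing.assert_allclose(probs, 0.25, atol=1e-9)

    def test_recovers_known_coefficients(self):
        rng = np.random.default_rng(42)
        n = 50_000
        X = rng.normal(size=(n, 2))
        beta = np.array([1.5, -2.0])
        p = 1 / (1 + np.exp(-(-0.5 + X @ beta)))
        y = (rng.random(n) < p).astype(int)
        model = fit_logistic(identity_block(X, ["x1", "x2"]), y)
        assert model.converged
        np.testing.assert_allclose(model.coefficients, beta, atol=0.1)
        assert model.intercept == pytest.approx(-0.5, abs=0.1)

    def test_agrees_with_independent_mle_oracle(self):
        # statsmodels Newton MLE on the same 200-row fixture
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 3))
        y = (rng.random(200) <
             1 / (1 + np.exp(-(0.3 + X @ [1.0, -0.7, 0.2])))).astype(int)
        ours = fit_logistic(identity_block(X, ["a", "b", "c"]), y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0, tol=1e-12)
        np.testing.assert_allclose(
            np.r_[ours.intercept, ours.coefficients], ref.params, atol=1e-6
        )
        assert ours.log_likelihood == pytest.approx(ref.llf, abs=1e-8)

    def test_separation_raises_advising_ridge(self):
        X = np.r_[np.full((20, 1), -1.0), np.full((20, 1), 1.0)]
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        with pytest.raises(SeparationError, match="ridge"):
            fit_logistic(identity_block(X, ["x"]), y, penalty=0.0)
        # same data fits fine with ridge
        model = fit_logistic(identity_block(X, ["x"]), y, penalty=1.0)
        assert model.converged and np.isfinite(model.coefficients).all()

    def test_single_class_labels_raise(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(identity_block(np.zeros((5, 1)), ["x"]),
                         np.ones(5, dtype=int))

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(500, 4))
        y = (rng.random(500) < 0.3).astype(int)
        m1 = fit_logistic(FeatureBlock(X, ("a", "b", "c", "d")), y)
        perm = rng.permutation(500)
        m2 = fit_logistic(FeatureBlock(X[perm], ("a", "b", "c", "d")), y[perm])
        np.testing.assert_allclose(m1.coefficients, m2.coefficients,
                                   atol=1e-8)

    def test_nested_model_likelihood_ordering(self):
        # adding columns can only improve the unpenalised training fit
        rng = np.random.default_rng(2)
        X = rng.normal(size=(400, 5))
        y = (rng.random(400) <
             1 / (1 + np.exp(-X[:, 0]))).astype(int)
        small = fit_logistic(FeatureBlock(X[:, :2], ("a", "b")), y)
        big = fit_logistic(FeatureBlock(X, ("a", "b", "c", "d", "e")), y)
        assert big.log_likelihood >= small.log_likelihood - 1e-9


class TestPredictRisk:
    def test_zero_model_gives_half(self):
        block = FeatureBlock(np.random.default_rng(0).normal(size=(10, 2)),
                             ("a", "b"))
        model = fit_logistic(block, np.array([0, 1] * 5))
        model.intercept = 0.0
        model.coefficients = np.zeros(2)
        np.testing.assert_allclose(predict_risk(model, block), 0.5)

    def test_monotone_in_positive_coefficient(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 2))
        y = (X[:, 0] + rng.normal(size=100) > 0).astype(int)
        model = fit_logistic(FeatureBlock(X, ("a", "b")), y, penalty=0.5)
        assert model.coefficients[0] > 0
        grid = np.linspace(-2, 2, 9)
        probe = FeatureBlock(
            np.c_[grid, np.zeros(9)], ("a", "b")
        )
        probs = predict_risk(model, probe)
        assert np.all(np.diff(probs) > 0)

    def test_column_mismatch_raises_schema_error(self):
        block = FeatureBlock(np.zeros((8, 2)) + [[0.0, 1.0]], ("a", "b"))
        model = fit_logistic(block, np.array([0, 1] * 4), penalty=1.0)
        with pytest.raises(SchemaError, match="missing"):
            predict_risk(model, FeatureBlock(np.zeros((3, 1)), ("a",)))


class TestBackwardAic:
    def test_empty_candidates(self):
        assert backward_aic([], np.empty((10, 0)),
                            np.array([0, 1] * 5)) == []

    def test_planted_predictor_retained_noise_dropped(self):
        retained, dropped_enough = 0, 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 20_000
            counts = rng.poisson(0.5, size=(n, 5))
            eta = -3.5 + 1.2 * counts[:, 0]  # only code 0 is informative
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
            names = ["C00", "N01", "N02", "N03", "N04"]
            selected = backward_aic(names, counts, y)
            retained += "C00" in selected
            dropped_enough += sum(c in selected for c in names[1:]) <= 1
        assert retained >= 9
        assert dropped_enough >= 9

    def test_final_aic_beats_full_and_removal_neighbours(self):
        rng = np.random.default_rng(9)
        n = 3000
        counts = rng.poisson(0.4, size=(n, 4))
        eta = -2.0 + 0.8 * counts[:, 0] - 0.5 * counts[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        names = ["A", "B", "C", "D"]
        selected = backward_aic(names, counts, y)

        def aic_of(subset):
            cols = [names.index(c) for c in subset]
            block = FeatureBlock(counts[:, cols],
                                 tuple(subset)) if cols else FeatureBlock(
                np.empty((n, 0)), ())
            return model_aic(fit_logistic(block, y))

        final = aic_of(selected)
        assert final <= aic_of(names) + 1e-9
        for drop in selected:  # exhaustive one-removal neighbour scan
            assert final <= aic_of([c for c in selected if c != drop]) + 1e-9

    def test_tie_break_removes_alphabetically_last(self):
        # two exactly duplicated informative columns: dropping either one
        # gives byte-identical AIC, so the tie-break must drop "B"
        rng = np.random.default_rng(4)
        n = 4000
        x = rng.poisson(0.5, size=n)
        counts = np.c_[x, x]
        eta = -2.0 + 1.0 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        selected = backward_aic(["A", "B"], counts, y)
        assert selected == ["A"]
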