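import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from commchange import (
    BaselineModel,
    InputVarianceTriple,
    communication_change,
    fit_baseline_model,
    partial_correlation,
    pearson_fc,
    predict_delta_fc,
    shared_input_variance,
    unshared_input_variance,
)


class TestPearsonFC:
    def test_perfect_and_anti_correlation(self, rng):
        x = rng.standard_normal(50)
        assert pearson_fc(x, x) == pytest.approx(1.0)
        assert pearson_fc(x, -x) == pytest.approx(-1.0)
        assert pearson_fc(np.arange(1.0, 5.0), 2 * np.arange(1.0, 5.0)) == pytest.approx(1.0)

    def test_textbook_formula_value(self):
        # x=(1,2,3,4), y=(1,3,2,4): cov*n = 4, var*n = 5 each -> r = 0.8
        assert pearson_fc([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_shift_scale_invariance_and_symmetry(self, rng):
        x, y = rng.standard_normal((2, 80))
        r = pearson_fc(x, y)
        assert pearson_fc(3 * x + 2, y) == pytest.approx(r, abs=1e-12)
        assert pearson_fc(y, x) == pytest.approx(r, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_fc(np.ones(10), np.arange(10.0))


class TestPartialCorrelation:
    def test_empty_covariates_equals_pearson(self, rng):
        x, y = rng.standard_normal((2, 60))
        assert partial_correlation(x, y, []) == pytest.approx(
            pearson_fc(x, y), abs=1e-12
        )

    def test_matches_precision_matrix_oracle(self, rng):
        """Residualization route equals -Omega_xy/sqrt(Omega_xx*Omega_yy)
        from the inverse covariance, on 100 random instances."""
        for _ in range(100):
            n_series = int(rng.integers(3, 9))
            mixing = rng.standard_normal((n_series, n_series))
            X = rng.standard_normal((200, n_series)) @ mixing
            pc = partial_correlation(X[:, 0], X[:, 1], list(X[:, 2:].T))
            omega = np.linalg.inv(np.cov(X.T))
            oracle = -omega[0, 1] / np.sqrt(omega[0, 0] * omega[1, 1])
            assert pc == pytest.approx(oracle, abs=1e-10)

    def test_covariate_equal_to_y_is_degenerate(self, rng):
        x, y = rng.standard_normal((2, 50))
        with pytest.raises(ValueError):
            partial_correlation(x, y, [y])

    def test_rank_deficient_covariates_rejected_by_default(self, rng):
        x, y, c = rng.standard_normal((3, 50))
        with pytest.raises(np.linalg.LinAlgError):
            partial_correlation(x, y, [c, 2 * c])


class TestInputVariances:
    def test_shared_is_sum_of_variances(self, rng):
        a = rng.standard_normal(500)
        b = rng.standard_normal(500)
        a = a / a.std(ddof=1)  # variance exactly 1
        b = b / b.std(ddof=1) * np.sqrt(2.0)  # variance exactly 2
        assert shared_input_variance([a, b]) == pytest.approx(3.0, abs=1e-10)
        assert shared_input_variance([]) == 0.0

    def test_shared_matches_covariance_trace(self, rng):
        sigs = list(rng.standard_normal((3, 120)))
        trace = np.trace(np.cov(np.array(sigs)))
        assert shared_input_variance(sigs) == pytest.approx(trace, abs=1e-12)

    def test_shared_additive_over_disjoint_sets(self, rng):
        s1 = list(rng.standard_normal((2, 90)))
        s2 = list(rng.standard_normal((3, 90)))
        assert shared_input_variance(s1 + s2) == pytest.approx(
            shared_input_variance(s1) + shared_input_variance(s2), abs=1e-12
        )

    def test_unshared_zero_when_fully_explained(self, rng):
        s = rng.standard_normal(100)
        assert unshared_input_variance([2 * s + 1], [s]) == pytest.approx(0.0, abs=1e-12)

    def test_unshared_with_no_shared_set_is_total_variance(self, rng):
        sigs = list(rng.standard_normal((2, 150)))
        assert unshared_input_variance(sigs, []) == pytest.approx(
            shared_input_variance(sigs), abs=1e-12
        )

    def test_residual_variance_bounded_by_total(self, rng):
        for _ in range(20):
            n1 = list(rng.standard_normal((2, 80)))
            ns = list(rng.standard_normal((3, 80)))
            assert unshared_input_variance(n1, ns) <= shared_input_variance(n1) + 1e-12

    def test_independent_sets_keep_most_variance(self, rng):
        """Residualizing against independent signals barely reduces variance
        as T grows."""
        kept = []
        for T in (200, 2000):
            n1 = [rng.standard_normal(T)]
            ns = list(rng.standard_normal((2, T)))
            kept.append(unshared_input_variance(n1, ns) / shared_input_variance(n1))
        assert kept[1] > kept[0] > 0.9

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            shared_input_variance([rng.standard_normal(10), rng.standard_normal(11)])


class TestBaselineModel:
    def _make_sessions(self, rng, n, betas, intercept, noise_sd):
        X = rng.uniform(0.5, 2.0, size=(n, 3))
        fc = X @ betas + intercept + noise_sd * rng.standard_normal(n)
        triples = [InputVarianceTriple(*row) for row in X]
        return fc, triples

    def test_exact_recovery_without_noise(self, rng):
        betas = np.array([0.4, -0.25, -0.15])
        fc, triples = self._make_sessions(rng, 12, betas, 0.3, 0.0)
        model = fit_baseline_model(fc, triples)
        np.testing.assert_allclose(model.betas(), betas, atol=1e-8)
        assert model.intercept == pytest.approx(0.3, abs=1e-8)
        assert model.adj_r2 == pytest.approx(1.0, abs=1e-8)

    def test_unbiased_recovery_with_noise(self, rng):
        """Across 200 replicates the mean estimates center on the truth."""
        betas = np.array([0.4, -0.25, -0.15])
        estimates = np.array(
            [
                fit_baseline_model(*self._make_sessions(rng, 30, betas, 0.1, 0.05)).betas()
                for _ in range(200)
            ]
        )
        se = estimates.std(axis=0) / np.sqrt(200)
        np.testing.assert_array_less(np.abs(estimates.mean(axis=0) - betas), 4 * se + 1e-3)

    def test_constant_fc_handled(self, rng):
        _, triples = self._make_sessions(rng, 10, np.zeros(3), 0.0, 0.0)
        model = fit_baseline_model(np.full(10, 0.3), triples)
        assert model.defined
        np.testing.assert_allclose(model.betas(), 0.0, atol=1e-10)
        assert model.adj_r2 <= 0.0 or model.adj_r2 == pytest.approx(0.0)

    def test_degenerate_regressor_flagged_undefined(self, rng):
        triples = [InputVarianceTriple(1.0, float(u), float(v)) for u, v in
                   rng.uniform(0.5, 1.5, size=(8, 2))]
        model = fit_baseline_model(rng.standard_normal(8), triples)
        assert not model.defined
        with pytest.raises(ValueError):
            predict_delta_fc(model, (0.1, 0.0, 0.0))

    def test_too_few_sessions_rejected(self, rng):
        fc, triples = self._make_sessions(rng, 4, np.zeros(3), 0.0, 0.1)
        with pytest.raises(ValueError):
            fit_baseline_model(fc, triples)


class TestCommunicationChange:
    model = BaselineModel(0.5, -0.3, -0.2, 0.1, 0.9)

    def test_zero_deltas_predict_zero(self):
        assert predict_delta_fc(self.model, (0.0, 0.0, 0.0)) == 0.0
        assert communication_change(0.07, self.model, (0.0, 0.0, 0.0)) == pytest.approx(0.07)

    def test_direct_arithmetic(self):
        # 0.5*0.1 - 0.3*0.1 - 0.2*0.1 = 0
        assert predict_delta_fc(self.model, (0.1, 0.1, 0.1)) == pytest.approx(0.0)

    @settings(deadline=None, derandomize=True)
    @given(
        st.floats(-1, 1),
        st.tuples(*[st.floats(-0.5, 0.5)] * 3),
        st.floats(0.1, 3),
    )
    def test_identity_and_linearity(self, dfc, delta, scale):
        """dComm + predicted dFC == dFC exactly, and the prediction is linear."""
        pred = predict_delta_fc(self.model, delta)
        comm = communication_change(dfc, self.model, delta)
        assert comm + pred == pytest.approx(dfc, abs=1e-12)
        scaled = tuple(scale * d for d in delta)
        assert predict_delta_fc(self.model, scaled) == pytest.approx(scale * pred, rel=1e-9, abs=1e-12)

    def test_no_coupling_change_gives_zero_comm(self, rng):
        """Sessions generated exactly from the baseline linear model keep
        dComm at zero no matter how input variances move."""
        betas = np.array([0.4, -0.25, -0.15])
        X = rng.uniform(0.5, 2.0, size=(10, 3))
        fc = X @ betas + 0.2
        triples = [InputVarianceTriple(*row) for row in X]
        model = fit_baseline_model(fc, triples)
        base_fc, base_triple = fc[0], triples[0]
        for s in range(1, 10):
            comm = communication_change(
                fc[s] - base_fc, model, triples[s] - base_triple
            )
            assert comm == pytest.approx(0.0, abs=1e-8)
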