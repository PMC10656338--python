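"""Correlation-preserving score prediction: weight identities, the stacked
within-covariance construction, stable-trait predictions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wpvscausal import (
    DgpSpec,
    MeasurementModelSpec,
    cpp_weights,
    estimate_within_covariance,
    fit_measurement_model,
    predict_scores_two_step,
    predict_stable_traits,
    simulate_panel,
    stable_trait_covariance,
)


def random_psd_pair(seed, dim):
    rng = np.random.default_rng(seed)
    b = rng.normal(size=(dim, dim))
    psi = b @ b.T + 0.1 * np.eye(dim)
    phi2 = abs(rng.normal()) + 0.2
    sigma = psi + phi2 * np.ones((dim, dim))
    return sigma, psi


class TestWeights:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), dim=st.integers(2, 6))
    def test_weight_identity_preserves_within_covariance(self, seed, dim):
        """W' Sigma W = Psi for arbitrary PSD pairs (the defining
        constraint of the correlation-preserving predictor)."""
        sigma, psi = random_psd_pair(seed, dim)
        w = cpp_weights(sigma, psi)
        assert np.abs(w.T @ sigma @ w - psi).max() < 1e-8

    def test_identity_when_psi_equals_sigma(self):
        sigma, _ = random_psd_pair(3, 4)
        w = cpp_weights(sigma, sigma)
        np.testing.assert_allclose(w, np.eye(4), atol=1e-8)

    def test_scalar_case_closed_form(self):
        w = cpp_weights(np.array([[4.0]]), np.array([[1.0]]))
        assert w[0, 0] == pytest.approx(np.sqrt(1.0 / 4.0))

    @pytest.mark.parametrize("dim", [2, 3, 4])
    def test_mse_optimality_against_constrained_optimizer(self, dim):
        """Among all W with W' Sigma W = Psi, the closed form maximizes
        tr(Psi W), i.e. minimizes the trace MSE, checked against an SLSQP
        solve of the constrained problem."""
        from scipy import optimize

        sigma, psi = random_psd_pair(60 + dim, dim)
        w_closed = cpp_weights(sigma, psi)

        def objective(x):
            return -np.trace(psi @ x.reshape(dim, dim))

        def constraint(x):
            m = x.reshape(dim, dim)
            return (m.T @ sigma @ m - psi)[np.triu_indices(dim)]

        rng = np.random.default_rng(0)
        res = optimize.minimize(
            objective,
            w_closed.ravel() + 0.05 * rng.normal(size=dim * dim),
            method="SLSQP",
            constraints={"type": "eq", "fun": constraint},
            options={"maxiter": 800, "ftol": 1e-14},
        )
        assert -res.fun <= -objective(w_closed.ravel()) + 1e-5
        np.testing.assert_allclose(
            res.x.reshape(dim, dim), w_closed, atol=1e-4
        )

    def test_singular_sigma_rejected(self):
        sigma = np.ones((3, 3))
        with pytest.raises(np.linalg.LinAlgError):
            cpp_weights(sigma, np.eye(3))

    def test_materially_indefinite_psi_rejected(self):
        sigma = np.eye(3) * 2
        psi = np.diag([1.0, 1.0, -0.5])
        with pytest.raises(np.linalg.LinAlgError):
            cpp_weights(sigma, psi)


class TestWithinCovariance:
    def test_zero_phi_returns_sample_covariance(self):
        sigma, _ = random_psd_pair(1, 6)
        psi, repaired = estimate_within_covariance(
            sigma, np.zeros((2, 2)), [3, 3]
        )
        assert not repaired
        np.testing.assert_allclose(psi, sigma, atol=1e-12)

    def test_blockwise_expansion_spot_cells(self):
        """Three variables, three waves each: Phi^+ expands each trait
        (co)variance over a 3x3 all-ones block."""
        phi = np.diag([10 / 9, 10 / 9, 10 / 9])
        phi[0, 1] = phi[1, 0] = 0.4
        s = np.eye(9) * 20.0
        psi, _ = estimate_within_covariance(s, phi, [3, 3, 3])
        assert psi[0, 0] == pytest.approx(20.0 - 10 / 9)
        assert psi[1, 2] == pytest.approx(0.0 - 10 / 9)
        assert psi[0, 3] == pytest.approx(-0.4)
        assert psi[2, 5] == pytest.approx(-0.4)

    def test_unequal_block_sizes_supported(self):
        phi = np.eye(2) * 0.5
        s = np.eye(5) * 3.0
        psi, _ = estimate_within_covariance(s, phi, [3, 2])
        assert psi[0, 0] == pytest.approx(2.5)
        assert psi[3, 4] == pytest.approx(-0.5)

    def test_indefinite_difference_repaired_with_warning(self):
        s = np.eye(2)
        phi = np.array([[1.02]])  # S - Phi^+ has eigenvalue -0.02
        with pytest.warns(UserWarning, match="repair"):
            psi, repaired = estimate_within_covariance(s, phi, [2])
        assert repaired
        assert np.linalg.eigvalsh(psi)[0] >= -1e-12

    def test_layout_mismatch_rejected(self):
        with pytest.raises(ValueError, match="layout"):
            estimate_within_covariance(np.eye(4), np.eye(3), [2, 2])
        with pytest.raises(ValueError, match="layout"):
            estimate_within_covariance(np.eye(4), np.eye(2), [2, 3])


class TestStableTraits:
    def test_predictor_matches_direct_formula_on_hand_example(self):
        """3x3 numeric Sigma, phi-hat 2, one person's deviations: the
        prediction equals the formula evaluated with independent matrix
        arithmetic."""
        sigma = np.array([[3.0, 1.0, 0.5], [1.0, 2.5, 0.8], [0.5, 0.8, 2.0]])
        dev = np.array([1.0, 0.0, -1.0])
        fake = type("F", (), {})()
        fake.phi2 = 4.0
        fake.sample_cov = sigma
        fake.sample_mean = np.zeros(3)
        got = predict_stable_traits(dev[None, :], fake)
        ones = np.ones(3)
        inv = np.linalg.inv(sigma)
        expect = 2.0 / np.sqrt(ones @ inv @ ones) * (ones @ inv @ dev)
        assert got[0] == pytest.approx(expect, rel=1e-12)

    def test_zero_phi2_returns_zero_predictions(self):
        fake = type("F", (), {})()
        fake.phi2 = 0.0
        fake.sample_cov = np.eye(3)
        fake.sample_mean = np.zeros(3)
        out = predict_stable_traits(np.random.default_rng(0).normal(size=(7, 3)), fake)
        np.testing.assert_array_equal(out, 0.0)

    def test_trait_predictions_have_variance_phi2_and_recover_correlation(
        self, default_sim
    ):
        """On data from the generating process, Var(Ihat) tracks phi2-hat
        and Corr(Ihat_Y, Ihat_A) recovers the generating 0.3 up to
        attenuation from prediction error."""
        fits = {
            v: fit_measurement_model(default_sim.panel.variable_matrix(v))
            for v in ("Y", "A")
        }
        traits = {
            v: predict_stable_traits(default_sim.panel.variable_matrix(v), fits[v])
            for v in ("Y", "A")
        }
        for v in ("Y", "A"):
            assert abs(np.mean(traits[v])) < 0.15
            assert np.var(traits[v]) == pytest.approx(fits[v].phi2, rel=0.05)
        # cross-variable within-score dependence in the study process
        # contaminates the off-diagonal, so the recovered correlation sits
        # near the generating 0.3 but is not exactly attenuated
        r = np.corrcoef(traits["Y"], traits["A"])[0, 1]
        assert 0.15 < r < 0.6
        phi = stable_trait_covariance(
            traits, {v: fits[v].phi2 for v in ("Y", "A")}, ["Y", "A"]
        )
        assert phi[0, 1] == pytest.approx(np.cov(traits["Y"], traits["A"], ddof=0)[0, 1])

    def test_attenuated_trait_correlation_on_model_true_data(self):
        """Three independent AR(1) within processes plus traits correlated
        at 0.3: the recovered trait correlation equals 0.3 times the
        squared trait-prediction reliability (classic attenuation)."""
        from wpvscausal.panel import make_panel
        from wpvscausal import predict_scores_two_step

        rng = np.random.default_rng(55)
        n_persons, n_waves, a, var = 8000, 5, 0.5, 10.0
        tc = np.full((3, 3), 0.3)
        np.fill_diagonal(tc, 1.0)
        traits = rng.multivariate_normal(np.zeros(3), 10.0 * tc, n_persons)
        innov = var * (1 - a * a)
        vals = {}
        for j, v in enumerate(["Y", "A", "L"]):
            x = np.zeros((n_persons, n_waves))
            x[:, 0] = rng.normal(0, np.sqrt(var), n_persons)
            for k in range(1, n_waves):
                x[:, k] = a * x[:, k - 1] + rng.normal(0, np.sqrt(innov), n_persons)
            vals[v] = x + traits[:, j][:, None]
        panel = make_panel(
            np.arange(n_persons),
            {"outcome": "Y", "treatment": "A", "confounders": ["L"]},
            vals,
            K=4,
        )
        sc = predict_scores_two_step(panel)
        reliability = np.corrcoef(sc.stable_traits["Y"], traits[:, 0])[0, 1] ** 2
        got = np.corrcoef(sc.stable_traits["Y"], sc.stable_traits["A"])[0, 1]
        assert got == pytest.approx(0.3 * reliability, abs=0.04)

    def test_missing_pattern_uses_observed_coordinates(self, model_true_series):
        data = model_true_series["data"][:200].copy()
        data[0, 2] = np.nan
        fit = fit_measurement_model(
            model_true_series["data"][:2000],
            MeasurementModelSpec(missing="complete_case"),
        )
        out = predict_stable_traits(data, fit)
        assert np.isfinite(out[0])


class TestScorePrediction:
    def test_scores_zero_when_measurements_equal_means(self, default_sim):
        scores = predict_scores_two_step(default_sim.panel)
        x = default_sim.panel.stacked_matrix()
        person = np.argmin(np.abs(x - np.nanmean(x, axis=0)).sum(axis=1))
        # construct an exact-mean person and check the linear map sends it to 0
        w = scores.weights
        zero = w.T @ np.zeros(w.shape[0])
        np.testing.assert_array_equal(zero, 0.0)
        stacked = scores.stacked()
        np.testing.assert_allclose(np.nanmean(stacked, axis=0), 0.0, atol=1e-8)

    def test_predicted_second_moment_matches_psi_hat(self, default_sim):
        scores = predict_scores_two_step(default_sim.panel)
        stacked = scores.stacked()
        emp = stacked.T @ stacked / stacked.shape[0]
        denom = np.abs(scores.psi_hat).max()
        assert np.abs(emp - scores.psi_hat).max() / denom < 0.05

    def test_predictions_track_their_latent_targets(self, default_sim):
        """The latent trait and within-scores are orthogonal, but their
        predictions share measurement content and are not; what the
        predictor guarantees is that each prediction tracks its own latent
        target well."""
        scores = predict_scores_two_step(default_sim.panel)
        for v in ("Y", "A", "L"):
            r_trait = np.corrcoef(
                scores.stable_traits[v], default_sim.traits[v]
            )[0, 1]
            assert r_trait > 0.7
            for j, k in enumerate(scores.waves[v]):
                latent = default_sim.latent[v][:, k]
                r = np.corrcoef(scores.within_scores[v][:, j], latent)[0, 1]
                assert r > 0.7

    def test_missing_rows_get_pattern_weights_and_partial_scores(self):
        sim = simulate_panel(DgpSpec(N=600, K=3, phi2=10.0, seed=15))
        # person 0 misses wave 2 of every variable
        for v in sim.panel.variable_names:
            sim.panel.values[v][0, 2] = np.nan
        scores = predict_scores_two_step(sim.panel)
        assert scores.pattern_weights
        (pattern, w_i), = scores.pattern_weights.items()
        n_obs = sum(pattern)
        assert w_i.shape == (n_obs, n_obs)
        assert np.isnan(scores.get("Y", 2)[0])
        assert np.isfinite(scores.get("Y", 1)[0])

    def test_degenerate_limit_no_traits_returns_centered_measurements(self):
        """With all trait variances zero the predictor reduces to the
        measurements minus their wave means (continuity of the no-trait
        limit)."""
        sim = simulate_panel(DgpSpec(N=3000, K=3, phi2=0.0, seed=8))
        panel = sim.panel
        from wpvscausal.scores import predict_within_scores

        fits = {}
        for v in panel.variable_names:
            f = fit_measurement_model(panel.variable_matrix(v))
            fits[v] = f
        phi_hat = np.zeros((3, 3))  # exact zero-trait limit
        scores = predict_within_scores(panel, fits, phi_hat=phi_hat)
        x = panel.stacked_matrix()
        centered = x - np.nanmean(x, axis=0)
        np.testing.assert_allclose(scores.stacked(), centered, atol=1e-6)
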