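"""Structured-covariance measurement model: Psi structures, ML/FIML
estimation, boundary flags, and fit indices."""

import numpy as np
import pytest

from wpvscausal import (
    MeasurementModelSpec,
    fit_indices,
    fit_measurement_model,
    implied_covariance,
)
from wpvscausal.measurement import psi_matrix


class TestImpliedCovariance:
    def test_zero_trait_zero_ar_gives_diagonal(self):
        theta = {
            "innovation_variances": np.array([2.0, 3.0, 4.0]),
            "ar_coefficients": np.array([0.0, 0.0]),
        }
        sigma = implied_covariance(0.0, theta, MeasurementModelSpec(), 3)
        np.testing.assert_allclose(sigma, np.diag([2.0, 3.0, 4.0]), atol=1e-12)

    def test_three_wave_time_varying_recursion_by_hand(self):
        """Cov(V*_k, V*_k') from hand-applied recursion: with v=(4,2,1) and
        a=(0.5, 0.25): psi_11 = .25*4+2 = 3, psi_22 = .0625*3+1, and the
        off-diagonals chain through the products of the coefficients."""
        theta = {
            "innovation_variances": np.array([4.0, 2.0, 1.0]),
            "ar_coefficients": np.array([0.5, 0.25]),
        }
        psi = psi_matrix(theta, "ar1_timevarying", 3)
        hand = np.array(
            [
                [4.0, 0.5 * 4, 0.25 * 0.5 * 4],
                [0.5 * 4, 3.0, 0.25 * 3.0],
                [0.25 * 0.5 * 4, 0.25 * 3.0, 0.25**2 * 3.0 + 1.0],
            ]
        )
        np.testing.assert_allclose(psi, hand, atol=1e-12)
        sigma = implied_covariance(2.5, theta, MeasurementModelSpec(), 3)
        np.testing.assert_allclose(sigma, hand + 2.5, atol=1e-12)

    @pytest.mark.parametrize(
        "structure,theta",
        [
            (
                "ar1_stationary",
                {"innovation_variance": 3.0, "ar_coefficient": 0.6},
            ),
            ("compound_symmetry", {"variance": 2.0, "correlation": 0.4}),
            (
                "toeplitz",
                {"variance": 2.0, "lag_correlations": np.array([0.5, 0.2, 0.1])},
            ),
        ],
    )
    def test_symmetry_for_every_structure(self, structure, theta):
        psi = psi_matrix(theta, structure, 4)
        np.testing.assert_array_equal(psi, psi.T)

    def test_stationary_structure_has_constant_variance(self):
        theta = {"innovation_variance": 7.5, "ar_coefficient": 0.5}
        psi = psi_matrix(theta, "ar1_stationary", 4)
        np.testing.assert_allclose(np.diag(psi), 10.0)
        assert psi[0, 1] == pytest.approx(5.0)

    def test_negative_phi2_rejected(self):
        theta = {"innovation_variance": 1.0, "ar_coefficient": 0.0}
        with pytest.raises(ValueError):
            implied_covariance(
                -1.0, theta, MeasurementModelSpec(psi_structure="ar1_stationary"), 3
            )


class TestFitting:
    def test_parameter_recovery_on_model_true_data(self, model_true_series):
        """All parameters of the generating measurement model are recovered
        within sampling error at N=5000."""
        fit = fit_measurement_model(model_true_series["data"])
        assert fit.converged and not fit.improper
        assert fit.phi2 == pytest.approx(10.0, abs=0.8)
        np.testing.assert_allclose(
            fit.theta["ar_coefficients"], model_true_series["a"], atol=0.06
        )
        assert fit.theta["innovation_variances"][0] == pytest.approx(10.0, abs=0.8)
        np.testing.assert_allclose(
            fit.theta["innovation_variances"][1:],
            model_true_series["innov"],
            atol=0.8,
        )
        np.testing.assert_allclose(fit.mu, 0.0, atol=0.25)
        # sigma decomposition identity
        ones = np.ones((5, 5))
        np.testing.assert_allclose(
            fit.sigma, fit.phi2 * ones + fit.psi, atol=1e-10
        )

    def test_trait_variance_proportion_is_half_at_phi2_ten(self, model_true_series):
        fit = fit_measurement_model(model_true_series["data"])
        prop = fit.phi2 / (fit.phi2 + fit.psi[0, 0])
        assert prop == pytest.approx(0.5, abs=0.04)

    def test_zero_trait_variance_hits_boundary(self, model_true_series):
        """Pure within-person AR data: the trait variance estimate collapses
        toward the boundary and is flagged improper when it reaches it."""
        fit = fit_measurement_model(model_true_series["within"])
        assert fit.phi2 <= 0.05
        assert fit.improper

    def test_loglik_at_fit_beats_generating_parameters(self, model_true_series):
        from wpvscausal.measurement import _ml_discrepancy

        data = model_true_series["data"]
        fit = fit_measurement_model(data)
        n = data.shape[1]
        xbar = data.mean(axis=0)
        c = data - xbar
        s_ml = c.T @ c / data.shape[0]
        true_packed = np.concatenate(
            [
                [np.log(10.0)],
                np.log([10.0] + [model_true_series["innov"]] * (n - 1)),
                [model_true_series["a"]] * (n - 1),
            ]
        )
        f_true = _ml_discrepancy(true_packed, s_ml, "ar1_timevarying", n)
        f_fit = _ml_discrepancy(
            np.concatenate(
                [
                    [np.log(fit.phi2)],
                    np.log(fit.theta["innovation_variances"]),
                    fit.theta["ar_coefficients"],
                ]
            ),
            s_ml,
            "ar1_timevarying",
            n,
        )
        assert f_fit <= f_true + 1e-6

    def test_complete_case_and_fiml_agree_on_complete_data(self, model_true_series):
        data = model_true_series["data"][:800]
        a = fit_measurement_model(data, MeasurementModelSpec(missing="fiml"))
        b = fit_measurement_model(data, MeasurementModelSpec(missing="complete_case"))
        assert a.phi2 == pytest.approx(b.phi2, abs=1e-6)
        np.testing.assert_allclose(a.psi, b.psi, atol=1e-6)

    def test_fiml_recovers_parameters_under_mcar_deletion(self, model_true_series):
        rng = np.random.default_rng(99)
        data = model_true_series["data"][:3000].copy()
        mask = rng.random(data.shape) < 0.2
        mask[mask.all(axis=1)] = False
        data[mask] = np.nan
        fit = fit_measurement_model(data, MeasurementModelSpec(missing="fiml"))
        assert fit.phi2 == pytest.approx(10.0, abs=1.2)
        np.testing.assert_allclose(
            fit.theta["ar_coefficients"], model_true_series["a"], atol=0.08
        )

    def test_gls_estimator_close_to_ml_on_model_true_data(self, model_true_series):
        data = model_true_series["data"][:2000]
        ml = fit_measurement_model(data, MeasurementModelSpec(estimator="ml"))
        gls = fit_measurement_model(data, MeasurementModelSpec(estimator="gls"))
        assert gls.phi2 == pytest.approx(ml.phi2, abs=1.0)

    def test_too_few_waves_rejected(self):
        with pytest.raises(ValueError, match="3 time points"):
            fit_measurement_model(np.random.default_rng(0).normal(size=(50, 2)))

    def test_unidentified_structure_rejected(self):
        # 3 waves give 9 moments; ar1_timevarying uses exactly 9 -> fine,
        # but toeplitz on 3 waves with... construct an artificial failure
        # via a tiny wave count is not possible for the provided
        # structures, so check the guard directly
        from wpvscausal.measurement import _n_theta

        assert _n_theta("ar1_timevarying", 3) == 5


class TestFitIndices:
    def test_perfect_fit_when_model_reproduces_sample(self, model_true_series):
        fit = fit_measurement_model(model_true_series["data"][:1000])
        s = fit.sigma.copy()  # pretend the sample moments equal the model's
        idx = fit_indices(fit, s, fit.mu, 1000)
        assert idx["cfi"] == pytest.approx(1.0)
        assert idx["rmsea"] == pytest.approx(0.0, abs=1e-8)
        assert idx["srmr"] == pytest.approx(0.0, abs=1e-8)

    def test_srmr_matches_hand_computed_standardized_residual(self):
        """3x3 sample vs implied differing in one covariance cell."""
        import dataclasses

        s = np.array([[4.0, 1.0, 0.5], [1.0, 4.0, 1.0], [0.5, 1.0, 4.0]])
        sigma = s.copy()
        sigma[0, 1] = sigma[1, 0] = 1.8
        fake = type("F", (), {})()
        fake.sigma = sigma
        fake.n_free_parameters = 3
        idx = fit_indices(fake, s, np.zeros(3), 500)
        hand = np.sqrt(((1.0 - 1.8) / 4.0) ** 2 / 6.0)
        assert idx["srmr"] == pytest.approx(hand, rel=1e-10)

    def test_baseline_model_scores_cfi_zero(self, model_true_series):
        """Evaluating the independence model against itself leaves no
        improvement over the baseline, so CFI is 0 by convention."""
        data = model_true_series["data"][:1000]
        xbar = data.mean(axis=0)
        c = data - xbar
        s = c.T @ c / len(data)
        base = type("F", (), {})()
        base.sigma = np.diag(np.diag(s))
        base.n_free_parameters = 2 * s.shape[0]
        idx = fit_indices(base, s, xbar, 1000)
        assert idx["cfi"] == pytest.approx(0.0, abs=1e-10)

    def test_singular_sample_covariance_rejected(self):
        fake = type("F", (), {})()
        fake.sigma = np.eye(3)
        fake.n_free_parameters = 3
        s = np.ones((3, 3))
        with pytest.raises(ValueError, match="singular"):
            fit_indices(fake, s, np.zeros(3), 10)

    def test_fit_indices_acceptable_on_simulation_dgp(self, default_sim):
        """The time-varying AR(1) approximation fits the study's outcome
        variable acceptably (the basis for using it in step 1)."""
        fit = fit_measurement_model(default_sim.panel.variable_matrix("Y"))
        assert fit.fit_indices["cfi"] > 0.95
        assert fit.fit_indices["srmr"] < 0.06
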