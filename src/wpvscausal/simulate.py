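"""Synthetic panel generator for the simulation study.

The generator draws a stable-trait triple I = (I_Y, I_A, I_L) from a
multivariate normal with common variance phi2 and correlation 0.3, an
initial within-person score triple with variances 10 and covariances 3, and
then rolls the within-person process forward with the first-order linear
equations

    Y*_k = 0.40 Y*_{k-1} + 0.40 A*_{k-1} + 0.10 L*_{k-1} + d_Y
    L*_k = 0.20 Y*_{k-1} + 0.20 A*_{k-1} + 0.50 L*_{k-1} + d_L
    A*_k = 0.20 Y*_k     + 0.40 A*_{k-1} + 0.30 L*_k     + d_A

with independent normal residuals of variance 5.  Observations are the sum
of trait and within-person score (temporal means zero).  The treatment is
measured at waves 0..K-1; outcome and confounders at waves 0..K.

Note the printed process is not exactly stationary: started from the
(10, 3) covariance it drifts slowly upward (the exact wave covariances and
the limiting solution of the discrete Lyapunov equation are exposed by
:func:`implied_wave_covariances` and :func:`implied_stationary_covariance`
so simulated moments can be checked against what the recursion actually
implies).

Misspecification scenarios:

``measurement_error``
    adds independent normal errors with variance equal to a stated fraction
    (0.10 or 0.20) of the initial measurement variance 10 + phi2;
``accumulating_loadings``
    replaces the outcome's measurement equation by
    Y_k = (1 + 0.5 k / K) I_Y + 0.3 I_A + 0.3 I_L + Y*_k, i.e. the
    time-invariant factor no longer acts as a stable trait;
``quadratic_treatment``
    adds 0.08 Y*_k^2 to the treatment-assignment equation, so any linear
    treatment model is misspecified (the causal coefficients on intervened
    treatments are unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .oracle import LinearDynamics
from .panel import PanelData, make_panel

__all__ = [
    "DgpSpec",
    "SimulatedPanel",
    "simulate_panel",
    "apply_centering",
    "implied_stationary_covariance",
    "implied_wave_covariances",
]

CENTERING_METHODS = ("true_score", "proposed", "observed_mean", "none", "ihat")


@dataclass(frozen=True)
class DgpSpec:
    """Generating conditions of the simulation study."""

    N: int = 1000
    K: int = 4
    seed: int = 0
    dynamics: LinearDynamics = field(default_factory=LinearDynamics)
    residual_variance: float = 5.0
    initial_variance: float = 10.0
    initial_covariance: float = 3.0
    phi2: float = 10.0
    trait_correlation: float = 0.3
    n_confounders: int = 1
    scenario: str = "none"  # none | measurement_error | accumulating_loadings
    #                         | quadratic_treatment
    error_fraction: float = 0.10  # for measurement_error
    quadratic_coef: float = 0.08  # for quadratic_treatment
    intervention_window: tuple[int, int] | None = None  # default: full history
    mar_dropout: float = 0.0  # logit-on-previous-outcome dropout, off by default
    treatment_final_wave: bool | None = None  # measure A at wave K too; None
    #   resolves to (K == 2), where 3 waves are needed for identification

    def __post_init__(self):
        if self.residual_variance <= 0 or self.phi2 < 0:
            raise ValueError("variances must be positive")
        if abs(self.trait_correlation) >= 1:
            raise ValueError("|trait correlation| must be < 1")
        if self.scenario not in (
            "none",
            "measurement_error",
            "accumulating_loadings",
            "quadratic_treatment",
        ):
            raise ValueError(f"unknown scenario {self.scenario!r}")

    @property
    def measure_treatment_final(self) -> bool:
        if self.treatment_final_wave is None:
            return self.K == 2
        return self.treatment_final_wave

    @property
    def window(self) -> tuple[int, int]:
        if self.intervention_window is not None:
            return self.intervention_window
        return (0, self.K - 1)

    @property
    def confounder_names(self) -> list[str]:
        if self.n_confounders == 1:
            return ["L"]
        return [f"L{j + 1}" for j in range(self.n_confounders)]


@dataclass
class SimulatedPanel:
    """A generated panel together with its latent truth."""

    panel: PanelData
    traits: dict[str, np.ndarray]  # variable -> (N,)
    latent: dict[str, np.ndarray]  # variable -> (N, K+1), NaN at unmeasured waves
    spec: DgpSpec


def _initial_cov(spec: DgpSpec, dim: int) -> np.ndarray:
    cov = np.full((dim, dim), spec.initial_covariance)
    np.fill_diagonal(cov, spec.initial_variance)
    return cov


def simulate_panel(spec: DgpSpec, rng: np.random.Generator | None = None) -> SimulatedPanel:
    """Seeded, reproducible draw of a panel plus its latent truth."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    N, K = spec.N, spec.K
    dyn = spec.dynamics
    confs = spec.confounder_names
    names = ["Y", "A", *confs]
    p = len(names)

    cov0 = _initial_cov(spec, p)
    if np.linalg.eigvalsh(cov0)[0] <= 0:
        raise ValueError("initial within covariance is not positive definite")
    init = rng.multivariate_normal(np.zeros(p), cov0, size=N)

    sd = np.sqrt(spec.residual_variance)
    latent = {name: np.full((N, K + 1), np.nan) for name in names}
    latent["Y"][:, 0] = init[:, 0]
    latent["A"][:, 0] = init[:, 1]
    for j, c in enumerate(confs):
        latent[c][:, 0] = init[:, 2 + j]

    # confounder coefficients are split evenly when several confounders are
    # generated (shape-level extension; the study itself uses one)
    share = 1.0 / len(confs)
    for k in range(1, K + 1):
        y_prev = latent["Y"][:, k - 1]
        a_prev = latent["A"][:, k - 1]
        l_prev = {c: latent[c][:, k - 1] for c in confs}
        lsum_prev = sum(l_prev.values()) * share
        y_k = (
            dyn.at("alpha_Y", k) * y_prev
            + dyn.at("beta_Y", k) * a_prev
            + dyn.at("gamma_Y", k) * lsum_prev
            + rng.normal(0.0, sd, N)
        )
        latent["Y"][:, k] = y_k
        for c in confs:
            latent[c][:, k] = (
                dyn.at("alpha_L", k) * y_prev
                + dyn.at("beta_L", k) * a_prev
                + dyn.at("gamma_L", k) * l_prev[c]
                + rng.normal(0.0, sd, N)
            )
        if k <= K - 1 or spec.measure_treatment_final:
            lsum_now = sum(latent[c][:, k] for c in confs) * share
            a_k = (
                dyn.at("alpha_A", k) * y_k
                + dyn.at("beta_A", k) * a_prev
                + dyn.at("gamma_A", k) * lsum_now
                + rng.normal(0.0, sd, N)
            )
            if spec.scenario == "quadratic_treatment":
                a_k = a_k + spec.quadratic_coef * y_k**2
            latent["A"][:, k] = a_k

    trait_corr = np.full((p, p), spec.trait_correlation)
    np.fill_diagonal(trait_corr, 1.0)
    traits_mat = rng.multivariate_normal(
        np.zeros(p), spec.phi2 * trait_corr, size=N
    )
    traits = {name: traits_mat[:, j] for j, name in enumerate(names)}

    waves = {name: list(range(K + 1)) for name in names}
    if not spec.measure_treatment_final:
        waves["A"] = list(range(K))
    values = {}
    for name in names:
        obs = latent[name] + traits[name][:, None]
        if spec.scenario == "accumulating_loadings" and name == "Y":
            loadings = 1.0 + 0.5 * np.arange(K + 1) / K
            obs = (
                latent["Y"]
                + traits["Y"][:, None] * loadings[None, :]
                + 0.3 * traits["A"][:, None]
                + 0.3 * sum(traits[c] for c in confs)[:, None]
            )
        if spec.scenario == "measurement_error":
            err_var = spec.error_fraction * (spec.initial_variance + spec.phi2)
            obs = obs + rng.normal(0.0, np.sqrt(err_var), obs.shape)
        obs = obs.copy()
        obs[:, [k for k in range(K + 1) if k not in waves[name]]] = np.nan
        values[name] = obs

    if spec.mar_dropout > 0:
        _apply_mar_dropout(values, waves, spec, rng)

    panel = make_panel(
        person_ids=np.arange(N),
        roles={"outcome": "Y", "treatment": "A", "confounders": confs},
        values=values,
        K=K,
        waves=waves,
    )
    return SimulatedPanel(panel=panel, traits=traits, latent=latent, spec=spec)


def _apply_mar_dropout(values, waves, spec: DgpSpec, rng) -> None:
    """Monotone dropout whose logit depends on the previous outcome (MAR)."""
    N = values["Y"].shape[0]
    scale = np.sqrt(spec.initial_variance + spec.phi2)
    base = np.log(spec.mar_dropout / (1 - spec.mar_dropout))
    dropped = np.zeros(N, dtype=bool)
    for k in range(1, spec.K + 1):
        logit = base + 0.5 * values["Y"][:, k - 1] / scale
        logit = np.where(np.isfinite(logit), logit, base)
        new_drop = rng.random(N) < 1.0 / (1.0 + np.exp(-logit))
        dropped |= new_drop
        for name, mat in values.items():
            if k in waves[name]:
                mat[dropped, k] = np.nan


# -- implied moments -------------------------------------------------------

def _reduced_form(spec: DgpSpec) -> tuple[np.ndarray, np.ndarray]:
    """Reduced-form transition and innovation covariance of (Y*, A*, L*).

    Only defined for the single-confounder, time-constant-coefficient
    process (the study's default)."""
    if spec.n_confounders != 1:
        raise ValueError("implied moments are defined for one confounder")
    d = spec.dynamics
    b0 = np.array(
        [
            [0.0, 0.0, 0.0],
            [d.at("alpha_A", 1), 0.0, d.at("gamma_A", 1)],
            [0.0, 0.0, 0.0],
        ]
    )
    b1 = np.array(
        [
            [d.at("alpha_Y", 1), d.at("beta_Y", 1), d.at("gamma_Y", 1)],
            [0.0, d.at("beta_A", 1), 0.0],
            [d.at("alpha_L", 1), d.at("beta_L", 1), d.at("gamma_L", 1)],
        ]
    )
    t = np.linalg.inv(np.eye(3) - b0)
    trans = t @ b1
    innov = t @ (spec.residual_variance * np.eye(3)) @ t.T
    return trans, innov


def implied_stationary_covariance(spec: DgpSpec) -> np.ndarray:
    """Limiting (Lyapunov) covariance of the within-person (Y*, A*, L*)."""
    trans, innov = _reduced_form(spec)
    return solve_discrete_lyapunov(trans, innov)


def implied_wave_covariances(spec: DgpSpec) -> list[np.ndarray]:
    """Exact concurrent covariance of (Y*, A*, L*) at each wave 0..K,
    propagated from the stated initial covariance."""
    trans, innov = _reduced_form(spec)
    cov = _initial_cov(spec, 3)
    out = [cov]
    for _ in range(spec.K):
        cov = trans @ cov @ trans.T + innov
        out.append(cov)
    return out


# -- centering comparators -------------------------------------------------

def apply_centering(
    sim: SimulatedPanel,
    method: str,
    measurement_spec=None,
):
    """Produce a ScoreSet by one of the study's centering comparators.

    ``true_score`` returns the latent within-person scores exactly;
    ``proposed`` runs the two-step correlation-preserving predictor;
    ``observed_mean`` subtracts each person's across-wave mean;
    ``none`` subtracts only the per-wave grand means;
    ``ihat`` subtracts the linear correlation-preserving stable-trait
    prediction from wave-mean-centered measurements.
    """
    from .scores import ScoreSet, predict_scores_two_step, predict_stable_traits
    from .measurement import MeasurementModelSpec, fit_measurement_model

    panel = sim.panel
    if method not in CENTERING_METHODS:
        raise ValueError(f"unknown centering method {method!r}")

    if method == "proposed":
        if measurement_spec is None:
            measurement_spec = MeasurementModelSpec()
        return predict_scores_two_step(panel, measurement_spec)

    names = panel.variable_names
    waves = {v: list(panel.waves[v]) for v in names}
    within = {}
    traits = {}
    improper = False

    if method == "true_score":
        for v in names:
            within[v] = sim.latent[v][:, waves[v]]
            traits[v] = sim.traits[v]
    elif method == "observed_mean":
        for v in names:
            mat = panel.variable_matrix(v)
            person_mean = np.nanmean(mat, axis=1, keepdims=True)
            within[v] = mat - person_mean
            traits[v] = person_mean[:, 0] - np.nanmean(mat)
    elif method == "none":
        for v in names:
            mat = panel.variable_matrix(v)
            within[v] = mat - np.nanmean(mat, axis=0, keepdims=True)
            traits[v] = np.zeros(panel.n_persons)
    elif method == "ihat":
        if measurement_spec is None:
            measurement_spec = MeasurementModelSpec()
        for v in names:
            fit = fit_measurement_model(panel.variable_matrix(v), measurement_spec)
            improper = improper or fit.improper
            ihat = predict_stable_traits(panel.variable_matrix(v), fit)
            mat = panel.variable_matrix(v)
            centered = mat - np.nanmean(mat, axis=0, keepdims=True)
            within[v] = centered - ihat[:, None]
            traits[v] = ihat

    return ScoreSet(
        person_ids=panel.person_ids,
        roles=panel.roles,
        waves=waves,
        within_scores=within,
        stable_traits=traits,
        method=method,
        improper=improper,
    )


def scenario_spec(base: DgpSpec, scenario: str, **kwargs) -> DgpSpec:
    """Convenience: derive a misspecification-scenario spec from a base."""
    return replace(base, scenario=scenario, **kwargs)
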