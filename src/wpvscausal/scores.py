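"""Correlation-preserving prediction of within-person variability scores.

Given per-variable measurement-model fits, the stacked measurement vector
X_i (all waves of the outcome, then of the treatment, then of each
confounder) is mapped to predicted within-person scores

    Xhat*_i = W' (X_i - mu),

where W is the best linear predictor that preserves the within-person
covariance structure, W' Sigma W = Psi, while minimizing the trace mean
squared error.  The closed form is

    W' = Psi^{1/2} (Psi^{3/2} Sigma^{-1} Psi^{3/2})^{-1/2} Psi^{3/2} Sigma^{-1}.

Sigma is estimated by the sample covariance S and mu by sample means; the
stacked within covariance is Psi_hat = S - Phi_hat^+, where Phi_hat^+
expands the stable-trait covariance matrix Phi_hat over all-ones blocks of
the corresponding time ranges.  Stable-trait scores themselves are
predicted by the linear correlation-preserving predictor

    Ihat_i = phi_hat / sqrt(1' Sigma^{-1} 1) * 1' Sigma^{-1} (X_i - xbar)

per variable, and the off-diagonal entries of Phi_hat are the sample
covariances of those predictions.  Persons with missing cells receive
pattern-specific weights built from the rows/columns of S and Psi_hat
restricted to their observed coordinates (valid under MAR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._linalg import nearest_psd, sym_power
from .measurement import MeasurementModelFit, MeasurementModelSpec, fit_measurement_model
from .panel import PanelData

__all__ = [
    "ScoreSet",
    "estimate_within_covariance",
    "cpp_weights",
    "predict_stable_traits",
    "stable_trait_covariance",
    "predict_within_scores",
    "predict_scores_two_step",
]


@dataclass
class ScoreSet:
    """Predicted within-person scores and stable-trait predictions."""

    person_ids: np.ndarray
    roles: dict
    waves: dict[str, list[int]]
    within_scores: dict[str, np.ndarray]  # var -> (N, len(waves[var])), NaN missing
    stable_traits: dict[str, np.ndarray]  # var -> (N,)
    method: str = "proposed"
    weights: np.ndarray | None = None  # global W (stacked dim x stacked dim)
    pattern_weights: dict | None = None  # missing-pattern -> W_i
    psi_hat: np.ndarray | None = None
    phi_hat: np.ndarray | None = None
    means: np.ndarray | None = None
    fits: dict[str, MeasurementModelFit] | None = None
    improper: bool = False
    notes: list = field(default_factory=list)

    @property
    def variable_names(self) -> list[str]:
        return [
            self.roles["outcome"],
            self.roles["treatment"],
            *self.roles.get("confounders", []),
        ]

    def get(self, variable: str, wave: int) -> np.ndarray:
        """Score column for one variable at one wave (NaN where absent)."""
        idx = self.waves[variable].index(wave)
        return self.within_scores[variable][:, idx]

    def stacked(self) -> np.ndarray:
        cols = [
            self.within_scores[v][:, j]
            for v in self.variable_names
            for j in range(len(self.waves[v]))
        ]
        return np.column_stack(cols)

    def subset(self, indices: np.ndarray) -> "ScoreSet":
        """Row-subset (e.g. a bootstrap resample) of the score set."""
        return ScoreSet(
            person_ids=np.arange(len(indices)),
            roles=self.roles,
            waves={v: list(w) for v, w in self.waves.items()},
            within_scores={v: m[indices] for v, m in self.within_scores.items()},
            stable_traits={v: t[indices] for v, t in self.stable_traits.items()},
            method=self.method,
            improper=self.improper,
        )


# -- stacked within covariance ---------------------------------------------

def estimate_within_covariance(
    S: np.ndarray,
    phi_hat: np.ndarray,
    block_sizes: list[int],
) -> tuple[np.ndarray, bool]:
    """Psi_hat = S - Phi_hat^+ with blockwise all-ones expansion.

    ``block_sizes`` gives the number of waves per variable in stacked
    order; block (v, w) of Phi_hat^+ is phi_hat[v, w] times an all-ones
    matrix of that block's shape (the Kronecker expansion when all blocks
    share one size).  The difference is eigenvalue-repaired to PSD when
    sampling error pushes it slightly indefinite; the repair is reported.
    """
    S = np.asarray(S, dtype=float)
    phi_hat = np.asarray(phi_hat, dtype=float)
    if len(block_sizes) != phi_hat.shape[0]:
        raise ValueError(
            f"layout mismatch: {len(block_sizes)} variable blocks but "
            f"phi_hat is {phi_hat.shape}"
        )
    if sum(block_sizes) != S.shape[0]:
        raise ValueError(
            f"layout mismatch: blocks sum to {sum(block_sizes)} but S is "
            f"{S.shape}"
        )
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")

    edges = np.concatenate([[0], np.cumsum(block_sizes)])
    phi_plus = np.zeros_like(S)
    for v in range(len(block_sizes)):
        for w in range(len(block_sizes)):
            phi_plus[edges[v] : edges[v + 1], edges[w] : edges[w + 1]] = phi_hat[v, w]
    psi_hat, repaired = nearest_psd(S - phi_plus, floor=0.0)
    if repaired:
        warnings.warn(
            "Psi_hat = S - Phi_hat^+ had negative eigenvalues; "
            "eigenvalue-repaired to PSD",
            stacklevel=2,
        )
    return psi_hat, repaired


# -- weight matrix ---------------------------------------------------------

def cpp_weights(sigma: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Correlation-preserving weight matrix W (returns W, not W')."""
    sigma = np.asarray(sigma, dtype=float)
    psi = np.asarray(psi, dtype=float)
    eig_sigma = np.linalg.eigvalsh(sigma)
    if eig_sigma[0] <= 1e-10 * max(eig_sigma[-1], 1.0):
        raise np.linalg.LinAlgError("Sigma is singular; cannot form weights")
    if np.linalg.eigvalsh(psi)[0] < -1e-6:
        raise np.linalg.LinAlgError("Psi has a materially negative eigenvalue")

    psi_half = sym_power(psi, 0.5)
    psi_3half = sym_power(psi, 1.5)
    sigma_inv = np.linalg.inv(sigma)
    core = sym_power(psi_3half @ sigma_inv @ psi_3half, -0.5)
    w_t = psi_half @ core @ psi_3half @ sigma_inv
    return w_t.T


# -- stable traits ---------------------------------------------------------

def predict_stable_traits(
    series: np.ndarray,
    fit: MeasurementModelFit,
    use_model_sigma: bool = False,
) -> np.ndarray:
    """Linear correlation-preserving stable-trait predictions Ihat.

    Rows with missing cells use the predictor restricted to their observed
    coordinates.  When phi2 is estimated as (numerically) zero the
    prediction is identically zero.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[1]
    if fit.phi2 <= 0:
        return np.zeros(series.shape[0])
    sigma = fit.sigma if use_model_sigma else fit.sample_cov
    xbar = fit.sample_mean
    phi = np.sqrt(fit.phi2)

    out = np.full(series.shape[0], np.nan)
    mask = np.isfinite(series)
    for row_mask in {tuple(m) for m in mask}:
        obs = np.flatnonzero(row_mask)
        rows = np.flatnonzero((mask == np.array(row_mask)).all(axis=1))
        if obs.size == 0:
            continue
        sub = sigma[np.ix_(obs, obs)]
        ones = np.ones(obs.size)
        try:
            w = np.linalg.solve(sub, ones)
        except np.linalg.LinAlgError:
            continue
        scale = phi / np.sqrt(ones @ w)
        dev = series[np.ix_(rows, obs)] - xbar[obs]
        out[rows] = scale * (dev @ w)
    return out


def stable_trait_covariance(
    traits: dict[str, np.ndarray], phi2: dict[str, float], order: list[str]
) -> np.ndarray:
    """Phi_hat: estimated phi2 on the diagonal, covariances of the
    stable-trait predictions off the diagonal."""
    p = len(order)
    phi = np.zeros((p, p))
    for i, v in enumerate(order):
        phi[i, i] = phi2[v]
        for j in range(i + 1, p):
            w = order[j]
            both = np.isfinite(traits[v]) & np.isfinite(traits[w])
            if both.sum() > 1:
                cov = np.cov(traits[v][both], traits[w][both], ddof=0)[0, 1]
            else:
                cov = 0.0
            phi[i, j] = phi[j, i] = cov
    return phi


# -- score prediction ------------------------------------------------------

def _stacked_moments(panel: PanelData) -> tuple[np.ndarray, np.ndarray]:
    """Sample means and (pairwise-complete, ML-scaled) covariance of the
    stacked measurement vector."""
    x = panel.stacked_matrix()
    mu = np.nanmean(x, axis=0)
    centered = x - mu
    d = x.shape[1]
    S = np.empty((d, d))
    finite = np.isfinite(centered)
    for i in range(d):
        for j in range(i, d):
            both = finite[:, i] & finite[:, j]
            S[i, j] = S[j, i] = (
                np.mean(centered[both, i] * centered[both, j]) if both.any() else 0.0
            )
    return mu, S


def predict_within_scores(
    panel: PanelData,
    fits: dict[str, MeasurementModelFit],
    W: np.ndarray | None = None,
    S: np.ndarray | None = None,
    mu: np.ndarray | None = None,
    psi_hat: np.ndarray | None = None,
    phi_hat: np.ndarray | None = None,
) -> ScoreSet:
    """Predict within-person scores for every person in the panel.

    Complete rows use the global W; rows with missing cells get a
    pattern-specific W_i built from S and Psi_hat restricted to observed
    coordinates.  Scores at unobserved cells are NaN, never zero.
    """
    names = panel.variable_names
    layout = panel.stacked_layout()
    block_sizes = [len(panel.waves[v]) for v in names]
    if S is None or mu is None:
        mu, S = _stacked_moments(panel)
    if phi_hat is None:
        traits = {v: predict_stable_traits(panel.variable_matrix(v), fits[v]) for v in names}
        phi_hat = stable_trait_covariance(
            traits, {v: fits[v].phi2 for v in names}, names
        )
    else:
        traits = {v: predict_stable_traits(panel.variable_matrix(v), fits[v]) for v in names}
    if psi_hat is None:
        psi_hat, _ = estimate_within_covariance(S, phi_hat, block_sizes)
    if W is None:
        W = cpp_weights(S, psi_hat)

    x = panel.stacked_matrix()
    dev = x - mu
    scores = np.full_like(x, np.nan)
    mask = np.isfinite(x)
    pattern_weights: dict[tuple, np.ndarray] = {}
    n_skipped = 0
    for row_mask in {tuple(m) for m in mask}:
        obs = np.flatnonzero(row_mask)
        rows = np.flatnonzero((mask == np.array(row_mask)).all(axis=1))
        if obs.size < 2:
            n_skipped += len(rows)
            continue
        if obs.size == x.shape[1]:
            w_i = W
        else:
            sub_s, _ = nearest_psd(S[np.ix_(obs, obs)], floor=1e-10)
            sub_psi, _ = nearest_psd(psi_hat[np.ix_(obs, obs)], floor=0.0)
            w_i = cpp_weights(sub_s, sub_psi)
            pattern_weights[row_mask] = w_i
        scores[np.ix_(rows, obs)] = dev[np.ix_(rows, obs)] @ w_i

    notes = []
    if n_skipped:
        notes.append(f"{n_skipped} person(s) with < 2 observed values: no scores")

    within = {}
    col = 0
    for v in names:
        nv = len(panel.waves[v])
        within[v] = scores[:, col : col + nv]
        col += nv

    return ScoreSet(
        person_ids=panel.person_ids,
        roles=panel.roles,
        waves={v: list(panel.waves[v]) for v in names},
        within_scores=within,
        stable_traits=traits,
        method="proposed",
        weights=W,
        pattern_weights=pattern_weights or None,
        psi_hat=psi_hat,
        phi_hat=phi_hat,
        means=mu,
        fits=fits,
        improper=any(fits[v].improper for v in names),
        notes=notes,
    )


def predict_scores_two_step(
    panel: PanelData, spec: MeasurementModelSpec | None = None
) -> ScoreSet:
    """Full step-1 pipeline: per-variable measurement fits, stable-trait
    predictions, stacked Psi_hat, weight matrix, and score prediction."""
    if spec is None:
        spec = MeasurementModelSpec()
    fits = {
        v: fit_measurement_model(panel.variable_matrix(v), spec)
        for v in panel.variable_names
    }
    return predict_within_scores(panel, fits)
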