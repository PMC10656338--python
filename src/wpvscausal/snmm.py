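"""Linear structural nested mean model with G-estimation.

The blip function at treatment wave t for the outcome at wave m is

    h_{t,m} = (beta_{mt} + sum_j gamma_{mtj} L*_{jt}) A*_t,

the effect of the observed treatment increment at t on the mean outcome at
m, holding later treatments at the person's reference level 0.  The
U-transform removes accumulated blips,

    U*_{t,m}(tau) = Y*_m - sum_{s=t}^{m-1} h_{s,m},

so that E[U | history through t, A*_t] does not depend on A*_t at the true
tau (the G-estimation identity).  Estimation solves the conditional-
covariance moment conditions: for each intervened treatment wave t and
later outcome wave m,

    sum_i (A*_t - E[A*_t | H_t]) (U*_{t,m} - E[U*_{t,m} | H_t]) = 0

(and, when treatment-by-confounder moderation is modelled, the same
moments with instrument L*_{jt} (A*_t - E[A*_t|H_t])), where H_t is the
first-order history (concurrent outcome and confounder scores plus the
previous treatment score).  E[A*_t|H_t] comes from the treatment nuisance
model (model A, linear-normal; optionally with a quadratic outcome term),
E[U|H_t] from a linear projection (model B).  The estimator is doubly
robust: either nuisance model being correct suffices for consistency.

With the identity link the estimating function is affine in tau, so the
Newton step solves the system exactly; the solver builds that linear
system directly and verifies the residual norm of the moment conditions at
the solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scores import ScoreSet

__all__ = ["BlipSpec", "SnmmFit", "transform_U", "fit_nuisance_models", "g_estimate", "joint_effect"]


@dataclass(frozen=True)
class BlipSpec:
    """Which blip parameters the SNMM carries.

    ``window`` is the inclusive range of intervened treatment waves (None:
    all measured treatment waves).  ``interactions`` adds a moderation term
    gamma_{mtj} L*_{jt} A*_t for every confounder j.
    """

    window: tuple[int, int] | None = None
    interactions: bool = False
    horizons: tuple[int, ...] | None = None  # outcome waves; None = all after window start

    def parameters(self, scores: ScoreSet) -> list[tuple]:
        """Ordered parameter keys: ('beta', m, t) / ('gamma', m, t, conf)."""
        y_waves = scores.waves[scores.roles["outcome"]]
        occ = self.occasions(scores)
        lo = occ[0]
        horizons = (
            self.horizons
            if self.horizons is not None
            else tuple(k for k in y_waves if k > lo)
        )
        confs = scores.roles.get("confounders", [])
        keys = []
        for m in sorted(horizons):
            for t in occ:
                if t >= m:
                    continue
                keys.append(("beta", m, t))
                if self.interactions:
                    keys.extend(("gamma", m, t, c) for c in confs)
        return keys

    def occasions(self, scores: ScoreSet) -> list[int]:
        a_waves = sorted(scores.waves[scores.roles["treatment"]])
        last_horizon = max(scores.waves[scores.roles["outcome"]])
        if self.window is not None:
            lo, hi = self.window
        else:
            lo, hi = a_waves[0], min(a_waves[-1], last_horizon - 1)
        return [t for t in a_waves if lo <= t <= hi]


def _blip_columns(scores: ScoreSet, key: tuple) -> np.ndarray:
    """Regressor column multiplying one blip parameter inside U."""
    a_name = scores.roles["treatment"]
    if key[0] == "beta":
        _, _m, t = key
        return scores.get(a_name, t)
    _, _m, t, conf = key
    return scores.get(conf, t) * scores.get(a_name, t)


def transform_U(
    tau: dict, scores: ScoreSet, blip: BlipSpec
) -> dict[tuple[int, int], np.ndarray]:
    """U*_{t,m}(tau) for every intervened wave t and outcome wave m > t.

    Keys are (t, m); values are per-person vectors with NaN where a needed
    score is missing.
    """
    y_name = scores.roles["outcome"]
    keys = blip.parameters(scores)
    occ = blip.occasions(scores)
    horizons = sorted({k[1] for k in keys})
    out = {}
    for t in occ:
        for m in horizons:
            if m <= t:
                continue
            u = scores.get(y_name, m).astype(float).copy()
            for key in keys:
                if key[1] != m:
                    continue
                s = key[2]
                if not (t <= s < m):
                    continue
                u = u - tau.get(key, 0.0) * _blip_columns(scores, key)
            out[(t, m)] = u
    return out


def _history_design(scores: ScoreSet, t: int) -> np.ndarray:
    """First-order history basis H_t: intercept, Y*_t, L*_t, A*_{t-1}."""
    y_name = scores.roles["outcome"]
    a_name = scores.roles["treatment"]
    confs = scores.roles.get("confounders", [])
    n = len(scores.person_ids)
    cols = [np.ones(n), scores.get(y_name, t)]
    cols += [scores.get(c, t) for c in confs]
    if (t - 1) in scores.waves[a_name]:
        cols.append(scores.get(a_name, t - 1))
    return np.column_stack(cols)


def _project(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Least-squares fitted values of y on x over complete rows (NaN kept
    elsewhere)."""
    ok = np.isfinite(y) & np.isfinite(x).all(axis=1)
    out = np.full_like(y, np.nan, dtype=float)
    if ok.sum() <= x.shape[1]:
        return out
    coef, *_ = np.linalg.lstsq(x[ok], y[ok], rcond=None)
    out[ok] = x[ok] @ coef
    return out


@dataclass
class NuisanceModels:
    """Fitted treatment model (A) and U-mean projection design (B)."""

    a_fitted: dict[int, np.ndarray]  # t -> E[A*_t | H_t]
    a_coef: dict[int, np.ndarray]
    a_columns: dict[int, list[str]]
    b_design: dict[int, np.ndarray]  # t -> basis used for model B
    model_b: str = "linear"


def fit_nuisance_models(
    scores: ScoreSet,
    blip: BlipSpec | None = None,
    quadratic_A: bool = False,
    model_B: str = "linear",
) -> NuisanceModels:
    """Fit model A per intervened occasion and prepare model-B bases.

    model A regresses A*_t on the first-order history (optionally adding a
    quadratic concurrent-outcome term, the correct specification under the
    quadratic-assignment scenario); model B is the projection basis used
    for conditional means of U ("linear" = same history basis,
    "intercept" = intercept only, a deliberately misspecified choice for
    robustness checks).
    """
    if blip is None:
        blip = BlipSpec()
    if model_B not in ("linear", "intercept"):
        raise ValueError(f"unknown model_B {model_B!r}")
    a_name = scores.roles["treatment"]
    y_name = scores.roles["outcome"]
    n = len(scores.person_ids)
    a_fitted, a_coef, a_columns, b_design = {}, {}, {}, {}
    for t in blip.occasions(scores):
        h = _history_design(scores, t)
        labels = ["1", f"{y_name}*_{t}"]
        labels += [f"{c}*_{t}" for c in scores.roles.get("confounders", [])]
        if h.shape[1] == len(labels) + 1:
            labels.append(f"{a_name}*_{t - 1}")
        xa = h
        if quadratic_A:
            xa = np.column_stack([h, scores.get(y_name, t) ** 2])
            labels = labels + [f"{y_name}*_{t}^2"]
        a = scores.get(a_name, t)
        ok = np.isfinite(a) & np.isfinite(xa).all(axis=1)
        if ok.sum() <= xa.shape[1]:
            raise ValueError(f"too few observations for treatment model at t={t}")
        if np.linalg.matrix_rank(xa[ok]) < xa.shape[1]:
            raise ValueError(f"collinear treatment-model design at t={t}")
        coef, *_ = np.linalg.lstsq(xa[ok], a[ok], rcond=None)
        fitted = np.full(n, np.nan)
        fitted[ok] = xa[ok] @ coef
        a_fitted[t] = fitted
        a_coef[t] = coef
        a_columns[t] = labels
        b_design[t] = h if model_B == "linear" else np.ones((n, 1))
    return NuisanceModels(a_fitted, a_coef, a_columns, b_design, model_B)


@dataclass
class SnmmFit:
    tau: dict
    blip: BlipSpec
    U_values: dict
    nuisance: NuisanceModels
    V: dict
    converged: bool
    iterations: int
    residual_norm: float
    condition_number: float
    keys: list = field(default_factory=list)
    se: dict | None = None

    def tau_vector(self) -> np.ndarray:
        return np.array([self.tau[k] for k in self.blip_keys])

    @property
    def blip_keys(self) -> list[tuple]:
        return self.keys

    def tau_labels(self) -> list[str]:
        out = []
        for key in self.keys:
            if key[0] == "beta":
                out.append(f"beta_{key[1]}{key[2]}")
            else:
                out.append(f"gamma_{key[1]}{key[2]}{key[3]}")
        return out


def g_estimate(
    scores: ScoreSet,
    blip: BlipSpec | None = None,
    quadratic_A: bool = False,
    model_B: str = "linear",
    tol: float = 1e-8,
) -> SnmmFit:
    """Solve the G-estimation moment conditions for the linear blip.

    Builds the affine system in tau exactly (one moment per parameter) and
    solves it; raises on a singular Jacobian, reporting its condition
    number.  The residual norm of the scaled moment conditions at the
    solution is verified against ``tol``.
    """
    if blip is None:
        blip = BlipSpec()
    keys = blip.parameters(scores)
    if not keys:
        raise ValueError("blip specification yields no parameters")
    nuis = fit_nuisance_models(scores, blip, quadratic_A=quadratic_A, model_B=model_B)
    a_name = scores.roles["treatment"]
    confs = scores.roles.get("confounders", [])
    horizons = sorted({k[1] for k in keys})
    y_name = scores.roles["outcome"]

    rows = []  # (t, m, instrument column)
    for t in blip.occasions(scores):
        resid_a = scores.get(a_name, t) - nuis.a_fitted[t]
        for m in horizons:
            if m <= t:
                continue
            rows.append(((t, m), resid_a))
            if blip.interactions:
                for c in confs:
                    rows.append(((t, m), scores.get(c, t) * resid_a))

    if len(rows) != len(keys):
        raise ValueError(
            f"moment system is not square: {len(rows)} moments for "
            f"{len(keys)} parameters"
        )

    # residualize (w.r.t. model B) the outcome and every blip column, per t
    proj_cache: dict[tuple, np.ndarray] = {}

    def residualized(col: np.ndarray, t: int, tag) -> np.ndarray:
        key = (t, tag)
        if key not in proj_cache:
            proj_cache[key] = col - _project(col, nuis.b_design[t])
        return proj_cache[key]

    n_par = len(keys)
    mat = np.zeros((n_par, n_par))
    rhs = np.zeros(n_par)
    counts = np.zeros(n_par)
    for r, ((t, m), instrument) in enumerate(rows):
        y_res = residualized(scores.get(y_name, m), t, ("y", m))
        valid = np.isfinite(instrument) & np.isfinite(y_res)
        cols = {}
        for c, key in enumerate(keys):
            if key[1] != m or not (t <= key[2] < m):
                continue
            col_res = residualized(_blip_columns(scores, key), t, ("c",) + key)
            cols[c] = col_res
            valid &= np.isfinite(col_res)
        if valid.sum() == 0:
            raise ValueError(f"no usable observations for moment (t={t}, m={m})")
        nv = valid.sum()
        rhs[r] = float(np.sum(instrument[valid] * y_res[valid])) / nv
        for c, col_res in cols.items():
            mat[r, c] = float(np.sum(instrument[valid] * col_res[valid])) / nv
        counts[r] = nv

    cond = float(np.linalg.cond(mat))
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"singular G-estimation Jacobian (condition number {cond:.3g})"
        )
    tau_vec = np.linalg.solve(mat, rhs)
    residual = mat @ tau_vec - rhs
    scale = max(1.0, float(np.abs(rhs).max()))
    res_norm = float(np.linalg.norm(residual) / scale)
    tau = {key: float(tau_vec[c]) for c, key in enumerate(keys)}

    u_vals = transform_U(tau, scores, blip)
    v = {}
    for (t, m), u in u_vals.items():
        u_res = u - _project(u, nuis.b_design[t])
        ok = np.isfinite(u_res)
        v[(t, m)] = 1.0 / float(np.var(u_res[ok])) if ok.any() else np.nan

    fit = SnmmFit(
        tau=tau,
        blip=blip,
        U_values=u_vals,
        nuisance=nuis,
        V=v,
        converged=res_norm < tol,
        iterations=1,
        residual_norm=res_norm,
        condition_number=cond,
        keys=keys,
    )
    return fit


def joint_effect(
    fit: SnmmFit,
    horizon: int,
    confounder_values: dict | None = None,
) -> float:
    """Joint effect at one horizon of a unit increment of every intervened
    treatment before it, at given confounder values.

    ``confounder_values`` maps (confounder, wave) -> value; defaults to 0,
    in which case the effect is the plain sum of the beta coefficients.
    """
    keys = [k for k in fit.blip_keys if k[1] == horizon]
    if not keys:
        raise ValueError(f"horizon {horizon} not in fitted blip")
    confounder_values = confounder_values or {}
    total = 0.0
    for key in keys:
        if key[0] == "beta":
            total += fit.tau[key]
        else:
            _, _m, t, conf = key
            total += fit.tau[key] * confounder_values.get((conf, t), 0.0)
    return float(total)
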