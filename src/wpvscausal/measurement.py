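"""Single-stable-trait measurement model, fitted per variable.

Each observed variable V measured at waves t_0..t_K is modelled as

    V_i = mu + I_i 1 + V*_i,   Var(I_i) = phi2,  Cov(V*_i) = Psi(theta),

so the implied covariance is Sigma = phi2 * 11' + Psi(theta).  Psi carries
the serial dependence of the within-person scores and must be given a
structure for identification; the default is a first-order autoregression
with time-varying coefficients and innovation variances.  Parameters are
estimated by (full-information) maximum likelihood under multivariate
normality; a generalized-least-squares discrepancy is available as an
alternative estimator.  Variances are optimized on the log scale, which
keeps them positive; estimates driven to the lower boundary are flagged as
improper solutions (the analogue of negative-variance estimates in
unconstrained covariance-structure software) and are never silently
repaired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "MeasurementModelSpec",
    "MeasurementModelFit",
    "fit_measurement_model",
    "implied_covariance",
    "psi_matrix",
    "fit_indices",
]

_LOGV_MIN, _LOGV_MAX = np.log(1e-8), np.log(1e8)
_BOUNDARY_FRACTION = 1e-3  # variance below this fraction of scale = improper


@dataclass(frozen=True)
class MeasurementModelSpec:
    psi_structure: str = "ar1_timevarying"
    estimator: str = "ml"  # ml | gls
    missing: str = "fiml"  # fiml | complete_case
    max_restarts: int = 3
    tol: float = 1e-8

    def __post_init__(self):
        if self.psi_structure not in (
            "ar1_timevarying",
            "ar1_stationary",
            "compound_symmetry",
            "toeplitz",
        ):
            raise ValueError(f"unknown psi structure {self.psi_structure!r}")
        if self.estimator not in ("ml", "gls"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.missing not in ("fiml", "complete_case"):
            raise ValueError(f"unknown missing-data handling {self.missing!r}")


@dataclass
class MeasurementModelFit:
    mu: np.ndarray
    phi2: float
    psi: np.ndarray
    sigma: np.ndarray
    theta: dict
    loglik: float
    fit_indices: dict
    converged: bool
    improper: bool
    n_obs: int
    n_free_parameters: int
    spec: MeasurementModelSpec
    sample_mean: np.ndarray | None = None
    sample_cov: np.ndarray | None = None
    messages: list = field(default_factory=list)


# -- Psi structures --------------------------------------------------------

def _n_theta(structure: str, n: int) -> int:
    return {
        "ar1_timevarying": 2 * n - 1,
        "ar1_stationary": 2,
        "compound_symmetry": 2,
        "toeplitz": n,
    }[structure]


def _psi_from_packed(packed: np.ndarray, structure: str, n: int) -> np.ndarray:
    if structure == "ar1_timevarying":
        v = np.exp(packed[:n])
        a = packed[n:]
        psi = np.empty((n, n))
        psi[0, 0] = v[0]
        for k in range(1, n):
            psi[k, :k] = a[k - 1] * psi[k - 1, :k]
            psi[:k, k] = psi[k, :k]
            psi[k, k] = a[k - 1] ** 2 * psi[k - 1, k - 1] + v[k]
        return psi
    if structure == "ar1_stationary":
        v = np.exp(packed[0])
        a = np.tanh(packed[1])
        var0 = v / (1.0 - a**2)
        lags = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        return var0 * a**lags
    if structure == "compound_symmetry":
        s2 = np.exp(packed[0])
        rho = np.tanh(packed[1])
        return s2 * ((1.0 - rho) * np.eye(n) + rho * np.ones((n, n)))
    if structure == "toeplitz":
        v = np.exp(packed[0])
        r = np.concatenate([[1.0], packed[1:]])
        lags = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        return v * r[lags]
    raise ValueError(structure)


def _theta_dict(packed: np.ndarray, structure: str, n: int) -> dict:
    if structure == "ar1_timevarying":
        return {
            "innovation_variances": np.exp(packed[:n]),
            "ar_coefficients": packed[n:].copy(),
        }
    if structure == "ar1_stationary":
        return {
            "innovation_variance": float(np.exp(packed[0])),
            "ar_coefficient": float(np.tanh(packed[1])),
        }
    if structure == "compound_symmetry":
        return {
            "variance": float(np.exp(packed[0])),
            "correlation": float(np.tanh(packed[1])),
        }
    return {
        "variance": float(np.exp(packed[0])),
        "lag_correlations": packed[1:].copy(),
    }


def psi_matrix(theta: dict, structure: str, n_waves: int) -> np.ndarray:
    """Within-person covariance from structural parameters.

    ``theta`` uses the natural-scale keys returned in
    ``MeasurementModelFit.theta``.
    """
    if structure == "ar1_timevarying":
        packed = np.concatenate(
            [np.log(theta["innovation_variances"]), theta["ar_coefficients"]]
        )
    elif structure == "ar1_stationary":
        packed = np.array(
            [np.log(theta["innovation_variance"]), np.arctanh(theta["ar_coefficient"])]
        )
    elif structure == "compound_symmetry":
        packed = np.array(
            [np.log(theta["variance"]), np.arctanh(theta["correlation"])]
        )
    elif structure == "toeplitz":
        packed = np.concatenate(
            [[np.log(theta["variance"])], theta["lag_correlations"]]
        )
    else:
        raise ValueError(structure)
    return _psi_from_packed(packed, structure, n_waves)


def implied_covariance(
    phi2: float, theta: dict, spec: MeasurementModelSpec, n_waves: int
) -> np.ndarray:
    """Sigma = phi2 * 11' + Psi(theta); symmetric PSD by construction."""
    if phi2 < 0:
        raise ValueError("phi2 must be >= 0")
    psi = psi_matrix(theta, spec.psi_structure, n_waves)
    if np.linalg.eigvalsh(psi)[0] < -1e-8:
        raise ValueError("Psi(theta) is not positive semidefinite")
    return phi2 * np.ones((n_waves, n_waves)) + psi


# -- discrepancy functions -------------------------------------------------

def _sigma_from_params(params, structure, n):
    phi2 = np.exp(params[0])
    psi = _psi_from_packed(params[1:], structure, n)
    return phi2 * np.ones((n, n)) + psi


def _ml_discrepancy(params, s_ml, structure, n):
    sigma = _sigma_from_params(params, structure, n)
    if not np.isfinite(sigma).all():
        return 1e10
    try:
        chol = np.linalg.cholesky(sigma)
        inv = np.linalg.inv(sigma)
    except np.linalg.LinAlgError:
        return 1e10
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    value = logdet + float(np.sum(inv * s_ml))
    return value if np.isfinite(value) else 1e10


def _gls_discrepancy(params, s_ml, structure, n):
    sigma = _sigma_from_params(params, structure, n)
    if not np.isfinite(sigma).all():
        return 1e10
    s_inv = np.linalg.inv(s_ml)
    resid = (s_ml - sigma) @ s_inv
    value = 0.5 * float(np.trace(resid @ resid))
    return value if np.isfinite(value) else 1e10


def _fiml_neg2ll(params, patterns, structure, n):
    """-2 loglik over missingness patterns; params = [mu, log phi2, theta]."""
    mu = params[:n]
    sigma = _sigma_from_params(params[n:], structure, n)
    if not np.isfinite(sigma).all():
        return 1e10
    total = 0.0
    for obs_idx, count, pat_mean, pat_scatter in patterns:
        sub = sigma[np.ix_(obs_idx, obs_idx)]
        try:
            chol = np.linalg.cholesky(sub)
            inv = np.linalg.inv(sub)
        except np.linalg.LinAlgError:
            return 1e10
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        diff = pat_mean - mu[obs_idx]
        quad = float(np.sum(inv * pat_scatter)) + count * float(diff @ inv @ diff)
        total += count * (len(obs_idx) * np.log(2 * np.pi) + logdet) + quad
    return total if np.isfinite(total) else 1e10


def _patterns(series: np.ndarray):
    """Group rows by missingness pattern; per pattern keep sufficient stats
    (observed indices, count, mean, centered scatter)."""
    mask = np.isfinite(series)
    keys = {}
    for i, row_mask in enumerate(map(tuple, mask)):
        keys.setdefault(row_mask, []).append(i)
    out = []
    for row_mask, rows in keys.items():
        obs_idx = np.flatnonzero(row_mask)
        if obs_idx.size == 0:
            continue
        block = series[np.ix_(rows, obs_idx)]
        mean = block.mean(axis=0)
        centered = block - mean
        out.append((obs_idx, len(rows), mean, centered.T @ centered))
    return out


# -- starting values -------------------------------------------------------

def _start_values(s_ml: np.ndarray, structure: str, n: int) -> list[np.ndarray]:
    off = s_ml[~np.eye(n, dtype=bool)]
    phi2_0 = max(float(np.mean(off)), 0.05 * float(np.mean(np.diag(s_ml))))
    starts = []
    for phi2 in (phi2_0, 0.5 * phi2_0, 0.05 * float(np.mean(np.diag(s_ml)))):
        psi0 = s_ml - phi2 * np.ones((n, n))
        diag = np.clip(np.diag(psi0), 1e-3 * np.mean(np.diag(s_ml)), None)
        if structure == "ar1_timevarying":
            a = np.zeros(n - 1)
            v = diag.copy()
            for k in range(1, n):
                a[k - 1] = np.clip(psi0[k, k - 1] / diag[k - 1], -0.95, 0.95)
                v[k] = max(diag[k] - a[k - 1] ** 2 * diag[k - 1], 0.05 * diag[k])
            theta = np.concatenate([np.log(v), a])
        elif structure == "ar1_stationary":
            a = np.clip(np.mean(np.diag(psi0, 1)) / np.mean(diag), -0.9, 0.9)
            theta = np.array([np.log(np.mean(diag) * (1 - a**2)), np.arctanh(a)])
        elif structure == "compound_symmetry":
            rho = np.clip(
                np.mean(np.diag(psi0, 1)) / np.mean(diag), -0.5, 0.9
            )
            theta = np.array([np.log(np.mean(diag)), np.arctanh(rho)])
        else:  # toeplitz
            v = float(np.mean(diag))
            r = [
                np.clip(np.mean(np.diag(psi0, lag)) / v, -0.9, 0.9)
                for lag in range(1, n)
            ]
            theta = np.concatenate([[np.log(v)], r])
        starts.append(np.concatenate([[np.log(phi2)], theta]))
    return starts


# -- fitting ---------------------------------------------------------------

def fit_measurement_model(
    series: np.ndarray, spec: MeasurementModelSpec | None = None
) -> MeasurementModelFit:
    """Fit the stable-trait + structured-Psi model to one variable.

    ``series`` is a persons x waves matrix with NaN for missing cells.
    """
    if spec is None:
        spec = MeasurementModelSpec()
    series = np.asarray(series, dtype=float)
    n = series.shape[1]
    if n < 3:
        raise ValueError("measurement model needs >= 3 time points (K >= 2)")
    obs_per_person = np.isfinite(series).sum(axis=1)
    if (obs_per_person >= 2).sum() < 2:
        raise ValueError("need >= 2 persons with >= 2 observed waves")

    has_missing = bool(np.isnan(series).any())
    complete = series[np.isfinite(series).all(axis=1)]
    use_fiml = has_missing and spec.missing == "fiml"
    if has_missing and spec.missing == "complete_case" and complete.shape[0] < 2:
        raise ValueError("complete-case requested but < 2 complete rows")

    if use_fiml:
        # moment start from available data
        frame_mean = np.nanmean(series, axis=0)
        centered = series - frame_mean
        s_start = np.full((n, n), np.nan)
        for i in range(n):
            for j in range(i, n):
                both = np.isfinite(centered[:, i]) & np.isfinite(centered[:, j])
                s_start[i, j] = s_start[j, i] = (
                    np.mean(centered[both, i] * centered[both, j])
                    if both.any()
                    else 0.0
                )
        s_for_start, x_bar, n_eff = s_start, frame_mean, series.shape[0]
    else:
        data = complete
        n_eff = data.shape[0]
        x_bar = data.mean(axis=0)
        c = data - x_bar
        s_for_start = (c.T @ c) / n_eff
    scale = float(np.mean(np.diag(s_for_start)))

    structure = spec.psi_structure
    n_theta = _n_theta(structure, n)
    n_moments = n * (n + 3) // 2
    n_free = n + 1 + n_theta  # means + phi2 + theta
    if n_free > n_moments:
        raise ValueError(
            f"model not identified: {n_free} free parameters for "
            f"{n_moments} first- and second-order moments"
        )

    bounds = [( _LOGV_MIN, _LOGV_MAX )]
    if structure == "ar1_timevarying":
        bounds += [(_LOGV_MIN, _LOGV_MAX)] * n + [(-5.0, 5.0)] * (n - 1)
    elif structure in ("ar1_stationary", "compound_symmetry"):
        bounds += [(_LOGV_MIN, _LOGV_MAX), (-5.0, 5.0)]
    else:
        bounds += [(_LOGV_MIN, _LOGV_MAX)] + [(-0.999, 0.999)] * (n - 1)

    if use_fiml:
        patterns = _patterns(series)
        objective = lambda p: _fiml_neg2ll(p, patterns, structure, n)
        pack = lambda cov_params: np.concatenate([x_bar, cov_params])
        full_bounds = [(None, None)] * n + bounds
    else:
        if spec.estimator == "gls":
            objective = lambda p: _gls_discrepancy(p, s_for_start, structure, n)
        else:
            objective = lambda p: _ml_discrepancy(p, s_for_start, structure, n)
        pack = lambda cov_params: cov_params
        full_bounds = bounds

    best = None
    messages = []
    starts = _start_values(s_for_start, structure, n)[: max(spec.max_restarts, 1)]
    for start in starts:
        res = optimize.minimize(
            objective,
            pack(start),
            method="L-BFGS-B",
            bounds=full_bounds,
            options={"maxiter": 1000, "ftol": spec.tol, "gtol": spec.tol},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("measurement model optimization failed entirely")
    converged = bool(best.success) or best.fun < 1e9
    if not best.success:
        messages.append(f"optimizer: {best.message}")

    params = best.x
    if use_fiml:
        mu = params[:n]
        cov_params = params[n:]
        neg2ll = best.fun
        loglik = -0.5 * neg2ll
    else:
        mu = x_bar
        cov_params = params
        f_ml = _ml_discrepancy(cov_params, s_for_start, structure, n)
        loglik = -0.5 * n_eff * (n * np.log(2 * np.pi) + f_ml)

    phi2 = float(np.exp(cov_params[0]))
    psi = _psi_from_packed(cov_params[1:], structure, n)
    sigma = phi2 * np.ones((n, n)) + psi

    # boundary / improper detection
    improper = phi2 < _BOUNDARY_FRACTION * scale
    if structure == "ar1_timevarying":
        improper = improper or bool(
            (np.exp(cov_params[1 : 1 + n]) < _BOUNDARY_FRACTION * scale).any()
        )
    elif structure in ("ar1_stationary", "toeplitz", "compound_symmetry"):
        improper = improper or float(np.exp(cov_params[1])) < _BOUNDARY_FRACTION * scale
    eig_min = float(np.linalg.eigvalsh(psi)[0])
    if eig_min < -1e-8:
        improper = True
        messages.append(f"Psi has negative eigenvalue {eig_min:.3g}")

    fit = MeasurementModelFit(
        mu=np.asarray(mu, dtype=float),
        phi2=phi2,
        psi=psi,
        sigma=sigma,
        theta=_theta_dict(cov_params[1:], structure, n),
        loglik=float(loglik),
        fit_indices={},
        converged=converged,
        improper=bool(improper),
        n_obs=int(n_eff),
        n_free_parameters=n_free,
        spec=spec,
        sample_mean=np.asarray(x_bar, dtype=float),
        sample_cov=np.asarray(s_for_start, dtype=float),
        messages=messages,
    )
    if not use_fiml:
        try:
            fit.fit_indices = fit_indices(fit, s_for_start, x_bar, n_eff)
        except ValueError as exc:  # e.g. singular sample covariance
            messages.append(str(exc))
    if not converged:
        warnings.warn("measurement model did not converge cleanly", stacklevel=2)
    return fit


# -- fit indices -----------------------------------------------------------

def fit_indices(
    fit: MeasurementModelFit,
    sample_cov: np.ndarray,
    sample_mean: np.ndarray,
    n: int,
) -> dict:
    """CFI, RMSEA and SRMR of a fitted model against the sample moments.

    The baseline for the CFI is the independence model with free means and
    variances.  Complete-data formulas; ``n`` is the number of persons.
    """
    s = np.asarray(sample_cov, dtype=float)
    p = s.shape[0]
    sign, logdet_s = np.linalg.slogdet(s)
    if sign <= 0:
        raise ValueError("sample covariance is singular; n too small for df")
    n_moments = p * (p + 3) // 2

    def discrepancy(sigma):
        sign_m, logdet_m = np.linalg.slogdet(sigma)
        if sign_m <= 0:
            raise ValueError("implied covariance is singular")
        return logdet_m + float(np.sum(np.linalg.inv(sigma) * s)) - logdet_s - p

    t_model = n * discrepancy(fit.sigma)
    df_model = n_moments - fit.n_free_parameters
    t_base = n * discrepancy(np.diag(np.diag(s)))
    df_base = n_moments - 2 * p

    num = max(t_model - df_model, 0.0)
    den = max(t_base - df_base, t_model - df_model, 0.0)
    cfi = 1.0 - num / den if den > 0 else 1.0
    rmsea = np.sqrt(num / (df_model * n)) if df_model > 0 else 0.0

    d = np.sqrt(np.diag(s))
    std_resid = (s - fit.sigma) / np.outer(d, d)
    tri = std_resid[np.tril_indices(p)]
    srmr = float(np.sqrt(np.mean(tri**2)))
    return {"cfi": float(cfi), "rmsea": float(rmsea), "srmr": srmr}
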