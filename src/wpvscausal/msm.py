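"""Marginal structural model for joint effects of continuous treatments.

The target is the marginal mean of potential within-person outcome scores
under a joint intervention on the treatment scores,

    E(Y*_k ^ abar_{k-1}) = sum_t beta_{k(t-1)} A*_{t-1},

estimated by weighted least squares with stabilized inverse-probability
weights.  Treatment-score densities are normal linear: the numerator
conditions on the previous treatment score only, the denominator
additionally on the concurrent outcome and confounder scores (the outcome
acts as a time-varying confounder of later treatment).

The stabilized weight for person i at horizon k multiplies the
numerator/denominator density ratios over the intervened treatment
occasions before k.  The first intervened occasion is included by default
(its numerator is the marginal treatment density, its denominator
conditions on the concurrent covariates): the initial treatment score is
correlated with the initial outcome/confounder scores, so leaving it
unweighted would leave that confounding uncontrolled.  Set
``include_first_occasion=False`` for the strict product starting at the
second occasion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scores import ScoreSet

__all__ = [
    "TreatmentModels",
    "MsmFit",
    "fit_treatment_models",
    "stabilized_weights",
    "fit_msm",
]


@dataclass
class _NormalLinear:
    """A fitted normal linear conditional density."""

    columns: list  # regressor labels, "" = intercept
    coef: np.ndarray
    sigma2: float

    def mean(self, design: np.ndarray) -> np.ndarray:
        return design @ self.coef

    def logpdf(self, y: np.ndarray, design: np.ndarray) -> np.ndarray:
        resid = y - self.mean(design)
        return -0.5 * (np.log(2 * np.pi * self.sigma2) + resid**2 / self.sigma2)


@dataclass
class TreatmentModels:
    occasions: list[int]
    numerator: dict[int, _NormalLinear]
    denominator: dict[int, _NormalLinear]
    quadratic: bool = False


def _design(scores: ScoreSet, t: int, columns: list) -> np.ndarray:
    cols = []
    for label in columns:
        if label == "":
            cols.append(np.ones(len(scores.person_ids)))
        else:
            var, wave, *power = label
            col = scores.get(var, wave)
            cols.append(col ** power[0] if power else col)
    return np.column_stack(cols)


def _ols(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, float]:
    ok = np.isfinite(y) & np.isfinite(x).all(axis=1)
    if ok.sum() <= x.shape[1]:
        raise ValueError("too few complete observations for treatment model")
    xo, yo = x[ok], y[ok]
    rank = np.linalg.matrix_rank(xo)
    if rank < xo.shape[1]:
        raise ValueError("degenerate (collinear) regressors in treatment model")
    coef, *_ = np.linalg.lstsq(xo, yo, rcond=None)
    resid = yo - xo @ coef
    return coef, float(np.mean(resid**2))


def _num_den_columns(scores: ScoreSet, t: int, quadratic: bool):
    a_name = scores.roles["treatment"]
    y_name = scores.roles["outcome"]
    confs = scores.roles.get("confounders", [])
    a_waves = scores.waves[a_name]
    num_cols = [""]
    if (t - 1) in a_waves:
        num_cols.append((a_name, t - 1))
    den_cols = list(num_cols)
    den_cols.append((y_name, t))
    den_cols.extend((c, t) for c in confs)
    if quadratic:
        den_cols.append((y_name, t, 2))
    return num_cols, den_cols


def fit_treatment_models(
    scores: ScoreSet,
    occasions: list[int] | None = None,
    quadratic: bool = False,
) -> TreatmentModels:
    """Per-occasion normal linear models for the treatment score.

    Numerator: f(A*_t | A*_{t-1}); denominator: f(A*_t | A*_{t-1}, Y*_t,
    L*_t[, Y*_t^2]).  ``occasions`` defaults to all measured treatment
    waves.
    """
    a_name = scores.roles["treatment"]
    if occasions is None:
        occasions = list(scores.waves[a_name])
    if len(occasions) < 1:
        raise ValueError("no treatment occasions")
    numerator, denominator = {}, {}
    for t in occasions:
        y = scores.get(a_name, t)
        num_cols, den_cols = _num_den_columns(scores, t, quadratic)
        coef_n, s2_n = _ols(y, _design(scores, t, num_cols))
        coef_d, s2_d = _ols(y, _design(scores, t, den_cols))
        numerator[t] = _NormalLinear(num_cols, coef_n, s2_n)
        denominator[t] = _NormalLinear(den_cols, coef_d, s2_d)
    return TreatmentModels(
        occasions=list(occasions),
        numerator=numerator,
        denominator=denominator,
        quadratic=quadratic,
    )


def stabilized_weights(
    models: TreatmentModels,
    scores: ScoreSet,
    horizons: list[int],
    include_first_occasion: bool = True,
    truncate: tuple[float, float] | None = None,
) -> dict[int, np.ndarray]:
    """Stabilized weights per horizon k: product over intervened occasions
    t < k of f(A*_t|A*_{t-1}) / f(A*_t|A*_{t-1}, Y*_t, L*_t).

    ``truncate`` optionally clips weights at (lower, upper) percentiles;
    off by default.
    """
    a_name = scores.roles["treatment"]
    n = len(scores.person_ids)
    occasions = sorted(models.occasions)
    used = occasions if include_first_occasion else occasions[1:]

    log_ratio = {}
    for t in used:
        y = scores.get(a_name, t)
        num = models.numerator[t]
        den = models.denominator[t]
        xn = _design(scores, t, num.columns)
        xd = _design(scores, t, den.columns)
        lr = num.logpdf(y, xn) - den.logpdf(y, xd)
        if not np.isfinite(lr[np.isfinite(y) & np.isfinite(xd).all(axis=1)]).all():
            bad = int(np.flatnonzero(~np.isfinite(lr))[0])
            raise FloatingPointError(
                f"density underflow for person index {bad} at occasion {t}"
            )
        log_ratio[t] = lr

    weights = {}
    for k in horizons:
        acc = np.zeros(n)
        for t in used:
            if t < k:
                acc = acc + log_ratio[t]
        w = np.exp(acc)
        if truncate is not None:
            finite = w[np.isfinite(w)]
            lo, hi = np.percentile(finite, truncate)
            w = np.clip(w, lo, hi)
        weights[k] = w
    return weights


@dataclass
class MsmFit:
    tau: dict  # (horizon, treatment wave) -> coefficient (NaN if unavailable)
    horizons: list[int]
    window: tuple[int, int]
    weights: dict
    models: TreatmentModels | None
    rank_deficient: list[int] = field(default_factory=list)
    joint_effects: dict = field(default_factory=dict)
    se: dict | None = None
    intercepts: dict = field(default_factory=dict)

    def tau_vector(self) -> np.ndarray:
        keys = sorted(self.tau)
        return np.array([self.tau[key] for key in keys])

    def tau_labels(self) -> list[str]:
        return [f"beta_{k}{t}" for k, t in sorted(self.tau)]


def fit_msm(
    scores: ScoreSet,
    weights: dict[int, np.ndarray] | None = None,
    horizons: list[int] | None = None,
    window: tuple[int, int] | None = None,
    models: TreatmentModels | None = None,
    intercept: bool = True,
    quadratic: bool = False,
    include_first_occasion: bool = True,
) -> MsmFit:
    """Weighted least squares of outcome scores on intervened treatment
    histories, one regression per horizon.

    ``window`` is the inclusive range of intervened treatment waves
    (default: all measured treatment waves); earlier treatment waves are
    controlled for as covariates.  Horizons default to every outcome wave
    after the first intervened treatment.  When the design matrix for a
    horizon is rank deficient the horizon's treatment coefficients are
    reported as unavailable (NaN) and the horizon is flagged.
    """
    y_name = scores.roles["outcome"]
    a_name = scores.roles["treatment"]
    a_waves = sorted(scores.waves[a_name])
    last_horizon = max(scores.waves[y_name])
    if window is None:
        window = (a_waves[0], min(a_waves[-1], last_horizon - 1))
    lo, hi = window
    intervened = [t for t in a_waves if lo <= t <= hi]
    controlled = [t for t in a_waves if t < lo]
    if horizons is None:
        horizons = [k for k in scores.waves[y_name] if k > lo]
    if not set(horizons) <= set(scores.waves[y_name]):
        raise ValueError("horizon outside measured outcome waves")

    if weights is None:
        if models is None:
            models = fit_treatment_models(scores, occasions=intervened, quadratic=quadratic)
        weights = stabilized_weights(
            models, scores, horizons, include_first_occasion=include_first_occasion
        )

    tau: dict = {}
    rank_deficient = []
    joint = {}
    intercepts = {}
    for k in horizons:
        treat_waves = [t for t in intervened if t < k]
        if not treat_waves:
            continue
        cols = [scores.get(a_name, t) for t in treat_waves]
        extra = [scores.get(a_name, t) for t in controlled]
        design_cols = cols + extra
        if intercept:
            design_cols.append(np.ones(len(scores.person_ids)))
        x = np.column_stack(design_cols)
        y = scores.get(y_name, k)
        w = weights[k]
        ok = np.isfinite(y) & np.isfinite(x).all(axis=1) & np.isfinite(w)
        if not ok.any():
            raise ValueError(f"no usable observations at horizon {k}")
        xo, yo, wo = x[ok], y[ok], w[ok]
        if np.linalg.matrix_rank(xo) < xo.shape[1]:
            rank_deficient.append(k)
            for t in treat_waves:
                tau[(k, t)] = np.nan
            continue
        sw = np.sqrt(wo)
        coef, *_ = np.linalg.lstsq(xo * sw[:, None], yo * sw, rcond=None)
        for j, t in enumerate(treat_waves):
            tau[(k, t)] = float(coef[j])
        if intercept:
            intercepts[k] = float(coef[-1])
        joint[k] = float(np.sum(coef[: len(treat_waves)]))

    return MsmFit(
        tau=tau,
        horizons=list(horizons),
        window=window,
        weights=weights,
        models=models,
        rank_deficient=rank_deficient,
        joint_effects=joint,
        intercepts=intercepts,
    )
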