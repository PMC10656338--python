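"""Nonparametric person-level bootstrap for second-step estimators.

Persons are resampled with replacement and the estimator is refit on each
resample; reported standard errors are the standard deviations of the
resampled estimates and confidence intervals are percentile intervals.
Resamples on which the estimator fails (e.g. a rank-deficient design) are
dropped and counted.
"""

from __future__ import annotations

import numpy as np

from .scores import ScoreSet

__all__ = ["bootstrap_se"]


def bootstrap_se(
    scores: ScoreSet,
    fit_fn,
    B: int = 500,
    seed: int = 0,
    ci_level: float = 0.95,
) -> dict:
    """Bootstrap a second-step fit.

    ``fit_fn`` maps a ScoreSet to a fitted object exposing ``tau`` (a
    mapping parameter-key -> estimate).  Returns a dict with per-parameter
    ``se`` and percentile ``ci``, plus the number of failed resamples.
    """
    point = fit_fn(scores)
    keys = list(point.tau)
    rng = np.random.default_rng(seed)
    n = len(scores.person_ids)
    draws = {k: [] for k in keys}
    failures = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            fit = fit_fn(scores.subset(idx))
        except Exception:
            failures += 1
            continue
        for k in keys:
            draws[k].append(fit.tau.get(k, np.nan))
    alpha = (1.0 - ci_level) / 2.0
    out = {"se": {}, "ci": {}, "failures": failures, "B": B}
    for k in keys:
        vals = np.asarray(draws[k], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            out["se"][k] = np.nan
            out["ci"][k] = (np.nan, np.nan)
            continue
        out["se"][k] = float(np.std(vals, ddof=1))
        out["ci"][k] = tuple(
            float(q) for q in np.quantile(vals, [alpha, 1.0 - alpha])
        )
    return out
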