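"""Analytic joint-effect coefficients for a linear first-order process.

For a within-person process in which the outcome score Y* and confounder
score L* evolve by first-order linear equations

    Y*_k = alpha_Y[k] Y*_{k-1} + beta_Y[k] A*_{k-1} + gamma_Y[k] L*_{k-1} + d_k
    L*_k = alpha_L[k] Y*_{k-1} + beta_L[k] A*_{k-1} + gamma_L[k] L*_{k-1} + e_k

a joint intervention that sets the treatment scores in a window severs the
treatment's own generating equation (modularity).  The coefficient on a
unit increment of a*_t in E(Y*_k under the intervention) is then obtained by
path tracing: the impulse enters the (Y*, L*) subsystem one step later
through (beta_Y, beta_L) and is propagated by the transition matrix built
from (alpha_Y, gamma_Y; alpha_L, gamma_L).

With the simulation coefficients (0.40/0.40/0.10 for Y*, 0.20/0.20/0.50 for
L*) this recursion yields, at K=4, coefficients (0.0486, 0.09, 0.18, 0.40)
on (a*_0, ..., a*_3) for the outcome at the final wave.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LinearDynamics", "JointEffects", "true_joint_effects"]


@dataclass(frozen=True)
class LinearDynamics:
    """First-order coefficients of the (Y*, A*, L*) process.

    Each coefficient may be a scalar (time-constant) or a mapping from the
    transition index k (the equation generating wave k) to a value.  The
    treatment-equation coefficients (``alpha_A`` on concurrent Y*, ``beta_A``
    on lagged A*, ``gamma_A`` on concurrent L*) do not enter the oracle —
    they are severed under intervention — but are carried so a single object
    describes the whole generating process.
    """

    alpha_Y: float = 0.40
    beta_Y: float = 0.40
    gamma_Y: float = 0.10
    alpha_A: float = 0.20
    beta_A: float = 0.40
    gamma_A: float = 0.30
    alpha_L: float = 0.20
    beta_L: float = 0.20
    gamma_L: float = 0.50

    def at(self, name: str, k: int) -> float:
        value = getattr(self, name)
        if isinstance(value, dict):
            return float(value[k])
        return float(value)


@dataclass
class JointEffects:
    """Per-horizon coefficients beta_{k t} on each intervened treatment."""

    K: int
    window: tuple[int, ...]
    coefficients: dict[int, dict[int, float]] = field(default_factory=dict)

    def coefficient(self, horizon: int, t: int) -> float:
        return self.coefficients[horizon][t]

    def joint_sum(self, horizon: int) -> float:
        """Joint effect of a one-unit increment of every intervened
        treatment observed before ``horizon``."""
        return float(sum(self.coefficients[horizon].values()))

    def tau_vector(self) -> np.ndarray:
        """Flatten to the study's parameter ordering: horizons ascending,
        treatment times ascending within horizon."""
        out = []
        for k in sorted(self.coefficients):
            for t in sorted(self.coefficients[k]):
                out.append(self.coefficients[k][t])
        return np.asarray(out)

    def labels(self) -> list[str]:
        out = []
        for k in sorted(self.coefficients):
            for t in sorted(self.coefficients[k]):
                out.append(f"beta_{k}{t}")
        return out


def true_joint_effects(
    dynamics: LinearDynamics,
    K: int,
    intervention_window: tuple[int, int] | None = None,
) -> JointEffects:
    """Path-tracing coefficients of intervened treatments on later outcomes.

    Parameters
    ----------
    dynamics
        First-order coefficients of the generating process.
    K
        Last wave index; treatments occur at waves 0..K-1.
    intervention_window
        Inclusive (first, last) treatment wave that is intervened.  Defaults
        to the full history (0, K-1).  Treatment waves outside the window are
        held at their observed values and contribute no impulse.

    Returns coefficients beta_{k t} for every horizon k that follows at
    least one intervened treatment.
    """
    if intervention_window is None:
        intervention_window = (0, K - 1)
    lo, hi = intervention_window
    if not (0 <= lo <= hi <= K - 1):
        raise ValueError(
            f"intervention window {intervention_window} outside 0..{K - 1}"
        )

    effects = JointEffects(K=K, window=tuple(range(lo, hi + 1)))
    for k in range(lo + 1, K + 1):
        per_t: dict[int, float] = {}
        for t in range(lo, min(hi, k - 1) + 1):
            # impulse enters (Y*, L*) at wave t+1
            state = np.array(
                [dynamics.at("beta_Y", t + 1), dynamics.at("beta_L", t + 1)]
            )
            for j in range(t + 2, k + 1):
                trans = np.array(
                    [
                        [dynamics.at("alpha_Y", j), dynamics.at("gamma_Y", j)],
                        [dynamics.at("alpha_L", j), dynamics.at("gamma_L", j)],
                    ]
                )
                state = trans @ state
            per_t[t] = float(state[0])
        effects.coefficients[k] = per_t
    return effects
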