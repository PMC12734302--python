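"""Distribution and conditional moments of the extinction time T.

Writing q_t = Pr(Z_t = 0) for a lineage founded by one individual, the
iterates satisfy q_0 = 0 and q_{t+1} = G(q_t), increasing monotonically to
the extinction probability Q.  The extinction time T (the generation at
which the lineage first hits size 0) then has Pr(T = t) = q_t - q_{t-1},
and, conditional on extinction,

    E(T | extinct)  = sum_t t  (q_t - q_{t-1}) / Q
    E(T^2| extinct) = sum_t t^2 (q_t - q_{t-1}) / Q

In the subcritical regime Q = 1 and the equivalent tail-sum forms
E(T) = sum_t (1 - q_t) and E(T^2) = sum_{t>=0} (2t+1)(1 - q_t) hold; both
routes are computed there and must agree, which guards the truncation.

At criticality (mu = 1 with positive variance) q_t -> 1 but the mean
extinction time diverges; the distribution is returned with a divergence
flag and no moments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .extinction import extinction_probability
from .laws import OffspringLaw, classify_regime

__all__ = [
    "ExtinctionTimeDist",
    "iterate_q",
    "extinction_time_distribution",
    "mean_extinction_time",
    "var_extinction_time",
    "extinction_time_quantile",
]


@dataclass(frozen=True)
class ExtinctionTimeDist:
    """Extinction-by-generation iterates and the law of the extinction time.

    Attributes
    ----------
    q : np.ndarray
        Cumulative extinction probabilities q_0 = 0, q_1, ..., q_tmax.
    pmf : np.ndarray
        pmf[t-1] = Pr(T = t) = q_t - q_{t-1}, for t = 1..tmax.
    Q_ref : float
        Limiting extinction probability from the extinction solver.
    T_mean, T_var : float | None
        Conditional mean and variance of T given extinction (generations
        and generations squared); None when divergent (critical regime).
    truncated_at : int
        Last generation computed.
    tail_mass : float
        Q_ref - q_tmax, the extinction mass beyond the computed horizon.
    divergent : bool
        True for critical laws, whose conditional mean is infinite.
    """

    q: np.ndarray
    pmf: np.ndarray
    Q_ref: float
    T_mean: float | None
    T_var: float | None
    truncated_at: int
    tail_mass: float
    divergent: bool = False


def iterate_q(
    law: OffspringLaw,
    t_max: int = 100_000,
    tol: float = 1e-12,
    Q: float | None = None,
) -> np.ndarray:
    """Iterates q_0 = 0, q_{t+1} = G(q_t) of the extinction-by-t probability.

    Stops early once the increment falls below ``tol * max(Q, 1e-3)`` or at
    ``t_max`` generations, whichever comes first.
    """
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    if Q is None:
        Q = extinction_probability(law).Q
    stop = tol * max(Q, 1e-3)
    q = [0.0]
    for _ in range(t_max):
        q_next = law.pgf(q[-1])
        q.append(q_next)
        if q_next - q[-2] < stop:
            break
    return np.asarray(q)


def _moments_with_tail(
    q: np.ndarray, law: OffspringLaw, Q: float
) -> tuple[float, float, float]:
    """Raw sums sum t^m Pr(T=t) for m = 1, 2 plus a geometric tail bound.

    Beyond the computed horizon the increments Q - q_t contract by roughly
    c = G'(Q) each generation, so the remaining mass m = Q - q_T is spread
    geometrically over t = T+1, T+2, ...  with ratio c.  Using
    sum_j c^{j-1}(1-c) (T+j)   = T + 1/(1-c)
    sum_j c^{j-1}(1-c) (T+j)^2 = T^2 + 2T/(1-c) + (1+c)/(1-c)^2
    the tail's contribution to both raw moments is added analytically.
    """
    T = q.size - 1
    t = np.arange(1, q.size)
    pmf = np.diff(q)
    s1 = float(np.dot(t, pmf))
    s2 = float(np.dot(t * t, pmf))
    mass = max(Q - q[-1], 0.0)
    if mass > 0.0:
        c = law.pgf_derivative(Q, 1)
        c = min(max(c, 0.0), 1.0 - 1e-12)
        r = 1.0 / (1.0 - c)
        s1 += mass * (T + r)
        s2 += mass * (T * T + 2.0 * T * r + (1.0 + c) * r * r)
    return s1, s2, mass


def extinction_time_distribution(
    law: OffspringLaw, tol: float = 1e-12, t_max: int = 100_000
) -> ExtinctionTimeDist:
    """Full extinction-time analysis: iterates, PMF, conditional moments."""
    regime = classify_regime(law)
    res = extinction_probability(law)
    Q = res.Q
    q = iterate_q(law, t_max=t_max, tol=tol, Q=Q)
    pmf = np.diff(q)

    if Q == 0.0:
        # extinction impossible (p_0 = 0): T has no mass to condition on
        return ExtinctionTimeDist(q, pmf, Q, None, None, q.size - 1, 0.0)

    if regime == "critical" and law.variance > 0:
        # q_t -> 1 but E(T) diverges: flagged, no moments reported.
        return ExtinctionTimeDist(
            q, pmf, Q, None, None, q.size - 1, max(Q - q[-1], 0.0), divergent=True
        )

    s1, s2, tail = _moments_with_tail(q, law, Q)
    mean = s1 / Q
    var = s2 / Q - mean * mean

    if regime == "subcritical":
        # independent tail-sum route, Q = 1: E(T) = sum (1 - q_t),
        # E(T^2) = sum_{t>=0} (2t+1)(1 - q_t); must agree with the PMF route.
        one_minus = 1.0 - q
        alt_mean = float(one_minus.sum())
        tvec = np.arange(q.size)
        alt_s2 = float(np.dot(2.0 * tvec + 1.0, one_minus))
        if abs(alt_mean - mean) > 1e-6 * max(abs(mean), 1.0) or abs(
            alt_s2 - s2
        ) > 1e-6 * max(abs(s2), 1.0):  # pragma: no cover - truncation guard
            raise RuntimeError(
                "subcritical moment cross-check failed: "
                f"{mean} vs {alt_mean}, {s2} vs {alt_s2}"
            )

    return ExtinctionTimeDist(q, pmf, Q, mean, var, q.size - 1, tail)


def mean_extinction_time(law: OffspringLaw, tol: float = 1e-12) -> float:
    """Conditional expected extinction time E(T | extinction), generations."""
    dist = extinction_time_distribution(law, tol=tol)
    if dist.divergent:
        raise ValueError("mean extinction time diverges at criticality")
    return dist.T_mean


def var_extinction_time(law: OffspringLaw, tol: float = 1e-12) -> float:
    """Conditional variance Var(T | extinction), generations squared."""
    dist = extinction_time_distribution(law, tol=tol)
    if dist.divergent:
        raise ValueError("extinction-time variance diverges at criticality")
    return dist.T_var


def extinction_time_quantile(dist: ExtinctionTimeDist, p: float) -> int:
    """Smallest t with Pr(T <= t | extinction) >= p, from the exact PMF."""
    if not 0.0 < p < 1.0:
        raise ValueError("quantile level must be in (0, 1)")
    cond = dist.q[1:] / dist.Q_ref
    idx = int(np.searchsorted(cond, p, side="left"))
    if idx >= cond.size:
        raise ValueError(
            f"quantile {p} lies beyond the computed horizon "
            f"(tail mass {dist.tail_mass:.3g})"
        )
    return idx + 1
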