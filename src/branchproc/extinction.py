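"""Extinction probability Q of a Galton-Watson process.

Q is the smallest non-negative root of the fixed-point equation Q = G(Q).
Monotone iteration q <- G(q) started at q = 0 converges to that smallest
root from below for every valid offspring law, which is the primary
algorithm here; Poisson laws additionally admit the Lambert-W closed form
Q = -W0(-lambda e^{-lambda}) / lambda and geometric laws Q = min(1, 1/R).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .laws import GeometricLaw, OffspringLaw, PoissonLaw, classify_regime

__all__ = [
    "ExtinctionResult",
    "extinction_probability",
    "extinction_probability_poisson",
    "extinction_probability_geometric",
    "group_extinction",
    "lambert_w0",
    "smallest_quadratic_root",
]


@dataclass(frozen=True)
class ExtinctionResult:
    """Extinction probability with solver diagnostics.

    Attributes
    ----------
    Q : float
        Smallest non-negative root of Q = G(Q).
    regime : str
        ``subcritical`` / ``critical`` / ``supercritical``.
    method : str
        ``fixed_point``, ``lambert_w``, ``geometric_closed_form`` or
        ``analytic_quadratic``.
    iterations : int
        Fixed-point iterations performed (0 for closed forms).
    residual : float
        |Q - G(Q)| at the reported solution.
    """

    Q: float
    regime: str
    method: str
    iterations: int
    residual: float


def lambert_w0(z: float) -> float:
    """Principal branch W0 of the Lambert W function (real, z >= -1/e).

    Returns w >= -1 with w e^w = z.
    """
    z = float(z)
    if z < -1.0 / np.e - 1e-15:
        raise ValueError(f"lambert_w0 requires z >= -1/e; got {z}")
    z = max(z, -1.0 / np.e)
    if z <= -1.0 / np.e + 1e-16:
        return -1.0  # branch point; lambertw returns nan exactly there
    w = special.lambertw(z, k=0)
    if abs(w.imag) > 1e-12:  # pragma: no cover - unreachable on valid domain
        raise ValueError(f"lambert_w0({z}) is not real")
    return float(w.real)


def extinction_probability_poisson(lam: float) -> float:
    """Closed-form Q for a Poisson(lambda) offspring law.

    Q = -W0(-lambda e^{-lambda}) / lambda, which equals 1 for lambda <= 1.
    """
    if not lam > 0:
        raise ValueError("lambda must be > 0")
    if lam <= 1.0:
        return 1.0
    return -lambert_w0(-lam * np.exp(-lam)) / lam


def extinction_probability_geometric(R: float) -> float:
    """Closed-form Q for a geometric offspring law of mean R: min(1, 1/R)."""
    if not R > 0:
        raise ValueError("R must be > 0")
    return min(1.0, 1.0 / R)


def group_extinction(Q: float, n_founders: int) -> float:
    """Probability that all of ``n_founders`` independent lineages die out.

    Lineages reproduce independently, so the answer is simply Q**n.
    """
    if not 0.0 <= Q <= 1.0:
        raise ValueError("Q must be a probability")
    if n_founders < 1:
        raise ValueError("n_founders must be >= 1")
    return Q**n_founders


def smallest_quadratic_root(probs) -> float:
    """Smallest non-negative root of Q = f0 + f1 Q + f2 Q^2 (cross-check).

    Solves f2 Q^2 + (f1 - 1) Q + f0 = 0 by the quadratic formula; used as
    an independent check of the fixed-point solver on three-point laws.
    """
    f0, f1, f2 = (float(x) for x in probs)
    if f2 == 0.0:
        return f0 / (1.0 - f1)
    disc = (f1 - 1.0) ** 2 - 4.0 * f2 * f0
    roots = [
        ((1.0 - f1) - np.sqrt(disc)) / (2.0 * f2),
        ((1.0 - f1) + np.sqrt(disc)) / (2.0 * f2),
    ]
    return min(r for r in roots if r >= -1e-12)


def extinction_probability(
    law: OffspringLaw,
    tol: float = 1e-14,
    max_iter: int = 10**6,
    method: str = "auto",
) -> ExtinctionResult:
    """Extinction probability of a lineage founded by one individual.

    Parameters
    ----------
    law : OffspringLaw
        Reproduction law.
    tol : float
        Stop the fixed-point iteration when successive iterates differ by
        less than ``tol``.
    max_iter : int
        Iteration cap; exceeded only for pathological inputs.
    method : str
        ``auto`` dispatches to the Lambert-W closed form for Poisson laws
        and to 1/R for geometric laws; ``fixed_point`` forces iteration.

    Notes
    -----
    Subcritical and critical laws have Q = 1.  Critical laws short-circuit
    (iteration at criticality converges only sublinearly); subcritical laws
    iterate normally and converge geometrically at rate G'(1) = mu < 1.
    """
    regime = classify_regime(law)
    if regime == "critical":
        return ExtinctionResult(1.0, regime, "fixed_point", 0, abs(1.0 - law.pgf(1.0)))

    if method == "auto":
        if isinstance(law, PoissonLaw):
            Q = extinction_probability_poisson(law.lam)
            return ExtinctionResult(Q, regime, "lambert_w", 0, abs(Q - law.pgf(Q)))
        if isinstance(law, GeometricLaw):
            Q = extinction_probability_geometric(law.R)
            return ExtinctionResult(
                Q, regime, "geometric_closed_form", 0, abs(Q - law.pgf(Q))
            )
    elif method != "fixed_point":
        raise ValueError(f"unknown method {method!r}")

    q = 0.0
    for it in range(1, max_iter + 1):
        q_next = law.pgf(q)
        if q_next - q < tol:
            q = q_next
            return ExtinctionResult(q, regime, "fixed_point", it, abs(q - law.pgf(q)))
        q = q_next
    raise RuntimeError(
        f"fixed-point iteration did not converge within {max_iter} iterations"
    )
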