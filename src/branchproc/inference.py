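"""Parameter estimation for branching processes from observed data.

* ``estimate_lambda_mle`` — the Lotka/Harris ratio estimator of the
  offspring mean from a census trajectory: the summed later censuses over
  the summed earlier ones, which is the Poisson maximum-likelihood
  estimate given the observed generation sizes.
* ``estimate_generations_since_founding`` — inverts expected supercritical
  growth, corrected for survivorship (the population is observed, hence
  conditioned on non-extinction): N = ln((1-Q) Z + Q) / ln(lambda).
* ``fit_poisson_binned`` — maximum-likelihood Poisson fit to a family-size
  table whose last category is top-coded ("K+"), treated as right
  censoring; a least-squares-on-bin-probabilities alternative is kept
  behind a flag.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats

from .extinction import extinction_probability_poisson

__all__ = [
    "estimate_lambda_mle",
    "estimate_generations_since_founding",
    "generations_since_founding_from_trajectory",
    "fit_poisson_binned",
]


def estimate_lambda_mle(sizes) -> float:
    """Offspring-mean MLE from consecutive census sizes.

    lambda_hat = sum_{i=1..n} Z_i / sum_{i=0..n-1} Z_i.  Scale-invariant:
    multiplying all censuses by a constant leaves the estimate unchanged.
    """
    z = np.asarray(sizes, dtype=float)
    if z.ndim != 1 or z.size < 2:
        raise ValueError("need at least two consecutive census sizes")
    if np.any(z < 0):
        raise ValueError("census sizes must be >= 0")
    denom = z[:-1].sum()
    if denom <= 0:
        raise ValueError("all earlier censuses are zero; lambda is undefined")
    return float(z[1:].sum() / denom)


def estimate_generations_since_founding(
    Z_final: float, lambda_hat: float, Q: float
) -> float:
    """Generations since a single founder, from the final census size.

    N_hat = ln((1-Q) Z_final + Q) / ln(lambda_hat).  The (1-Q)Z + Q
    correction accounts for observing a surviving population; with Q = 0
    it reduces to plain log_lambda(Z).  Returned unrounded.
    """
    if lambda_hat <= 1.0:
        raise ValueError("lambda_hat must exceed 1 (no growth to invert)")
    if not 0.0 <= Q < 1.0:
        raise ValueError("Q must lie in [0, 1)")
    if Z_final < 1:
        raise ValueError("Z_final must be >= 1")
    return float(np.log((1.0 - Q) * Z_final + Q) / np.log(lambda_hat))


def generations_since_founding_from_trajectory(sizes) -> tuple[float, float, float]:
    """Convenience pipeline: (lambda_hat, Q, N_hat) from a census trajectory.

    Estimates lambda by the ratio MLE, derives the Poisson extinction
    probability Q(lambda_hat) via Lambert W, and inverts growth from the
    last census.
    """
    lam = estimate_lambda_mle(sizes)
    Q = extinction_probability_poisson(lam)
    n_hat = estimate_generations_since_founding(float(sizes[-1]), lam, Q)
    return lam, Q, n_hat


def fit_poisson_binned(
    fractions, method: str = "mle", lam_max: float = 50.0
) -> tuple[float, float]:
    """Fit a Poisson mean to a top-coded family-size table.

    Parameters
    ----------
    fractions : sequence
        Proportions (or percentages; rescaled to sum 1) of families with
        0, 1, ..., K-1 children and, as the final entry, K or more.
    method : str
        ``mle`` maximises the multinomial likelihood with the final bin
        right-censored: P(K+) = 1 - CDF(K-1).  ``lsq`` minimises the sum
        of squared differences between table and Poisson bin masses.
    lam_max : float
        Upper bracket for the one-dimensional optimisation.

    Returns
    -------
    (lam_hat, objective) : the estimate and the achieved log-likelihood
    (``mle``) or negative squared error (``lsq``).
    """
    w = np.asarray(fractions, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("need at least two bins (0 and the top-coded one)")
    if np.any(w < 0):
        raise ValueError("bin fractions must be >= 0")
    total = w.sum()
    if total <= 0:
        raise ValueError("bin fractions sum to zero")
    # published tables are rounded per-cell: tolerate up to 0.5% total drift
    if abs(total - 1.0) > 5e-3 and abs(total - 100.0) > 0.5:
        raise ValueError(
            f"bin fractions sum to {total!r}; expected proportions (sum 1) "
            "or percentages (sum 100)"
        )
    w = w / total
    K = w.size - 1  # top bin aggregates counts >= K
    if w[0] == 1.0:
        return 0.0, 0.0

    ks = np.arange(K)

    def bin_masses(lam: float) -> np.ndarray:
        body = stats.poisson.pmf(ks, lam)
        return np.append(body, max(1.0 - body.sum(), 1e-300))

    if method == "mle":
        def neg(obj_lam: float) -> float:
            m = np.clip(bin_masses(obj_lam), 1e-300, None)
            return -float(np.dot(w, np.log(m)))
    elif method == "lsq":
        def neg(obj_lam: float) -> float:
            return float(np.sum((bin_masses(obj_lam) - w) ** 2))
    else:
        raise ValueError(f"unknown method {method!r}")

    res = optimize.minimize_scalar(
        neg, bounds=(1e-9, lam_max), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x), float(-res.fun)
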