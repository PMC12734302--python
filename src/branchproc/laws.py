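"""Offspring (reproduction) laws and their probability generating functions.

An offspring law is the PMF of the number of offspring an individual leaves
in one generation.  Everything downstream of it — extinction probability,
extinction-time moments, population-size distributions — is driven by the
probability generating function G(s) = sum_k f_k s^k evaluated on [0, 1],
so each law exposes ``pgf``, its first two derivatives, and the moments
E(X) = G'(1) and Var(X) = G''(1) + G'(1) - G'(1)^2.

Four families are supported:

* ``EmpiricalLaw`` — a finite table (f_0, ..., f_kmax), e.g. counts of
  daughter queens observed for invasive hornet foundresses;
* ``PoissonLaw`` — mean lambda, the classical choice of Fisher and Haldane,
  with closed-form PGF e^{lambda (s-1)};
* ``GeometricLaw`` — support starting at 0, parameterised by its mean R
  (success parameter p = 1/(1+R)); variance exceeds the mean, which suits
  strongly skewed reproductive success;
* ``NegativeBinomialLaw`` — shape r and success p; no closed-form
  extinction probability exists, so it participates numerically only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "OffspringLaw",
    "EmpiricalLaw",
    "PoissonLaw",
    "GeometricLaw",
    "NegativeBinomialLaw",
    "classify_regime",
    "law_from_spec",
]

#: tolerance below which an empirical PMF's deviation from unit mass is
#: considered exact; deviations up to _RENORM_TOL are renormalised with a
#: warning (published tables are often rounded), larger ones are errors.
_EXACT_TOL = 1e-12
_RENORM_TOL = 1e-9

#: equality tolerance on the offspring mean for criticality classification
_CRITICAL_TOL = 1e-12


def _check_s(s: float) -> float:
    s = float(s)
    if not (0.0 - 1e-15 <= s <= 1.0 + 1e-15):
        raise ValueError(f"PGF argument s={s} outside [0, 1]")
    return min(max(s, 0.0), 1.0)


class OffspringLaw:
    """Abstract base for reproduction laws.

    Subclasses implement ``pmf``, ``pgf`` and ``pgf_derivative``; the
    moment and classification helpers are shared.
    """

    family: str = "abstract"

    def pmf(self, k: int) -> float:
        raise NotImplementedError

    def pgf(self, s: float) -> float:
        raise NotImplementedError

    def pgf_derivative(self, s: float, order: int = 1) -> float:
        raise NotImplementedError

    @property
    def mean(self) -> float:
        return self.pgf_derivative(1.0, 1)

    @property
    def variance(self) -> float:
        m = self.pgf_derivative(1.0, 1)
        return self.pgf_derivative(1.0, 2) + m - m * m

    def pmf_vector(self, k_max: int) -> np.ndarray:
        """PMF values on 0..k_max as an array (tail beyond k_max dropped)."""
        return np.array([self.pmf(k) for k in range(k_max + 1)], dtype=float)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<{type(self).__name__} mean={self.mean:.6g}>"


@dataclass(frozen=True)
class EmpiricalLaw(OffspringLaw):
    """Finite offspring PMF given as probabilities indexed by count 0..k_max."""

    probs: np.ndarray
    family: str = field(default="empirical", init=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("empirical PMF must be a non-empty 1-d vector")
        if np.any(p < 0):
            raise ValueError("empirical PMF has negative probabilities")
        total = p.sum()
        dev = abs(total - 1.0)
        if dev > _RENORM_TOL:
            raise ValueError(
                f"empirical PMF sums to {total!r}, deviating from 1 by "
                f"{dev:.3g} (> {_RENORM_TOL:g}); not a valid PMF"
            )
        if dev > _EXACT_TOL:
            warnings.warn(
                f"empirical PMF sums to {total!r}; renormalising",
                UserWarning,
                stacklevel=2,
            )
            p = p / total
        p = p.copy()
        p.setflags(write=False)
        object.__setattr__(self, "probs", p)

    @property
    def k_max(self) -> int:
        return self.probs.size - 1

    def pmf(self, k: int) -> float:
        if k < 0:
            raise ValueError("offspring count k must be >= 0")
        return float(self.probs[k]) if k <= self.k_max else 0.0

    def pgf(self, s: float) -> float:
        s = _check_s(s)
        # Horner evaluation of sum_k f_k s^k
        acc = 0.0
        for c in self.probs[::-1]:
            acc = acc * s + c
        return float(acc)

    def pgf_derivative(self, s: float, order: int = 1) -> float:
        s = _check_s(s)
        if order not in (1, 2):
            raise ValueError("derivative order must be 1 or 2")
        k = np.arange(self.probs.size, dtype=float)
        if order == 1:
            coef = self.probs * k
            shift = 1
        else:
            coef = self.probs * k * (k - 1)
            shift = 2
        acc = 0.0
        for c in coef[:shift - 1:-1]:
            acc = acc * s + c
        return float(acc)


@dataclass(frozen=True)
class PoissonLaw(OffspringLaw):
    """Poisson offspring law with mean ``lam``; G(s) = e^{lam (s-1)}."""

    lam: float
    family: str = field(default="poisson", init=False)

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError("Poisson mean lambda must be > 0")

    def pmf(self, k: int) -> float:
        if k < 0:
            raise ValueError("offspring count k must be >= 0")
        return float(stats.poisson.pmf(k, self.lam))

    def pgf(self, s: float) -> float:
        s = _check_s(s)
        return float(np.exp(self.lam * (s - 1.0)))

    def pgf_derivative(self, s: float, order: int = 1) -> float:
        s = _check_s(s)
        if order not in (1, 2):
            raise ValueError("derivative order must be 1 or 2")
        return float(self.lam ** order * np.exp(self.lam * (s - 1.0)))

    @property
    def mean(self) -> float:
        return self.lam

    @property
    def variance(self) -> float:
        return self.lam


@dataclass(frozen=True)
class GeometricLaw(OffspringLaw):
    """Geometric offspring law on {0, 1, 2, ...} with mean R.

    The success parameter is p = 1/(1+R), equivalently R = (1-p)/p, and
    G(s) = p / (1 - (1-p) s).  Construct from either the mean ``R`` or the
    success parameter ``p``.
    """

    R: float
    family: str = field(default="geometric", init=False)

    def __post_init__(self) -> None:
        if not self.R > 0:
            raise ValueError("geometric mean R must be > 0")

    @classmethod
    def from_success_probability(cls, p: float) -> "GeometricLaw":
        if not 0 < p < 1:
            raise ValueError("success parameter p must be in (0, 1)")
        return cls(R=(1.0 - p) / p)

    @property
    def p(self) -> float:
        return 1.0 / (1.0 + self.R)

    def pmf(self, k: int) -> float:
        if k < 0:
            raise ValueError("offspring count k must be >= 0")
        p = self.p
        return float(p * (1.0 - p) ** k)

    def pgf(self, s: float) -> float:
        s = _check_s(s)
        p = self.p
        return float(p / (1.0 - (1.0 - p) * s))

    def pgf_derivative(self, s: float, order: int = 1) -> float:
        s = _check_s(s)
        if order not in (1, 2):
            raise ValueError("derivative order must be 1 or 2")
        p = self.p
        q = 1.0 - p
        u = 1.0 - q * s
        if order == 1:
            return float(p * q / u**2)
        return float(2.0 * p * q * q / u**3)

    @property
    def mean(self) -> float:
        return self.R


@dataclass(frozen=True)
class NegativeBinomialLaw(OffspringLaw):
    """Negative binomial offspring law (r failures-shape, success p).

    G(s) = (p / (1 - (1-p) s))^r with mean r(1-p)/p.  There is no closed
    form for its extinction probability; it enters the fixed-point solver
    purely through PGF evaluation.
    """

    r: float
    p: float
    family: str = field(default="negbinomial", init=False)

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError("negative binomial shape r must be > 0")
        if not 0 < self.p < 1:
            raise ValueError("negative binomial success p must be in (0, 1)")

    def pmf(self, k: int) -> float:
        if k < 0:
            raise ValueError("offspring count k must be >= 0")
        return float(stats.nbinom.pmf(k, self.r, self.p))

    def pgf(self, s: float) -> float:
        s = _check_s(s)
        q = 1.0 - self.p
        return float((self.p / (1.0 - q * s)) ** self.r)

    def pgf_derivative(self, s: float, order: int = 1) -> float:
        s = _check_s(s)
        if order not in (1, 2):
            raise ValueError("derivative order must be 1 or 2")
        q = 1.0 - self.p
        u = 1.0 - q * s
        base = self.p**self.r
        if order == 1:
            return float(self.r * q * base * u ** (-self.r - 1.0))
        return float(self.r * (self.r + 1.0) * q * q * base * u ** (-self.r - 2.0))

    @property
    def mean(self) -> float:
        return self.r * (1.0 - self.p) / self.p


def classify_regime(law: OffspringLaw, tol: float = _CRITICAL_TOL) -> str:
    """Classify a law as ``subcritical``, ``critical`` or ``supercritical``.

    The classification is by the offspring mean mu = G'(1): extinction is
    certain (Q = 1) iff mu <= 1, with equality judged at tolerance ``tol``.
    """
    mu = law.mean
    if abs(mu - 1.0) <= tol:
        return "critical"
    return "subcritical" if mu < 1.0 else "supercritical"


def law_from_spec(
    family: str,
    probs=None,
    lam: float | None = None,
    R: float | None = None,
    r: float | None = None,
    p: float | None = None,
) -> OffspringLaw:
    """Build a law from plain parameters (the CLI/config entry point)."""
    family = family.lower()
    if family == "empirical":
        if probs is None:
            raise ValueError("empirical law requires probs")
        return EmpiricalLaw(np.asarray(probs, dtype=float))
    if family == "poisson":
        if lam is None:
            raise ValueError("poisson law requires lambda")
        return PoissonLaw(lam)
    if family == "geometric":
        if R is not None:
            return GeometricLaw(R)
        if p is not None:
            return GeometricLaw.from_success_probability(p)
        raise ValueError("geometric law requires R (mean) or p")
    if family == "negbinomial":
        if r is None or p is None:
            raise ValueError("negative binomial law requires r and p")
        return NegativeBinomialLaw(r, p)
    raise ValueError(f"unknown offspring-law family {family!r}")
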