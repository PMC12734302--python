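"""Population-size distribution after t generations (Galton's second question).

The generating function of Z_t is the t-fold composite G_t = G o G_{t-1},
so the vector of probabilities Pr(Z_t = m) is the coefficient vector of the
composed power series.  For a finite law of maximal offspring count k_max
the composite is a polynomial of degree k_max^t and composition is carried
out exactly by dense convolution: given the coefficient vector g of
G_{t-1}, the powers g^k are built by repeated convolution and combined
weighted by the offspring probabilities f_k.

For parametric laws (infinite support) a truncation size must be stated;
the dropped mass is tracked in ``tail_mass`` and the reported coefficients
are then lower bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .laws import EmpiricalLaw, OffspringLaw

__all__ = [
    "SizeDistribution",
    "compose_size_distribution",
    "expected_name_counts",
    "tail_probability",
]

#: coefficients may round to tiny negatives during convolution; values
#: above this floor are clamped to 0, anything below is a real error.
_NEG_FLOOR = -1e-15


@dataclass(frozen=True)
class SizeDistribution:
    """Distribution of the population size Z_t founded by one individual.

    ``probs[m]`` is Pr(Z_t = m) for m = 0..truncation_M; ``tail_mass`` is
    the probability assigned to sizes beyond truncation_M (zero for finite
    laws tracked at full support).
    """

    generation: int
    probs: np.ndarray
    truncation_M: int
    tail_mass: float

    @property
    def mean(self) -> float:
        return float(np.dot(np.arange(self.probs.size), self.probs))


def _clamp(vec: np.ndarray) -> np.ndarray:
    if vec.min(initial=0.0) < _NEG_FLOOR:
        raise RuntimeError(
            f"composition produced coefficient {vec.min():.3g} below the "
            "negativity floor; law coefficients are inconsistent"
        )
    return np.maximum(vec, 0.0)


def _compose_once(f: np.ndarray, g: np.ndarray, max_size: int | None) -> np.ndarray:
    """Coefficients of sum_k f_k g(s)^k, optionally truncated to max_size+1."""
    out = np.zeros(1)
    out[0] = f[0]
    power = np.array([1.0])
    for k in range(1, f.size):
        power = np.convolve(power, g)
        if max_size is not None and power.size > max_size + 1:
            power = power[: max_size + 1]
        if out.size < power.size:
            out = np.pad(out, (0, power.size - out.size))
        out[: power.size] += f[k] * power
    return _clamp(out)


def compose_size_distribution(
    law: OffspringLaw, t: int, max_size: int | None = None
) -> SizeDistribution:
    """Distribution of Z_t by iterated PGF composition.

    Parameters
    ----------
    law : OffspringLaw
        Finite (empirical) laws are composed exactly over their full
        support k_max**t unless ``max_size`` caps it; parametric laws
        require an explicit ``max_size`` truncation directive.
    t : int
        Number of generations (>= 1).
    max_size : int, optional
        Largest population size tracked.  With truncation, coefficients
        are lower bounds and the deficit is reported as ``tail_mass``.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if isinstance(law, EmpiricalLaw):
        f = np.asarray(law.probs, dtype=float)
    else:
        if max_size is None:
            raise ValueError(
                "parametric laws have infinite support: pass max_size to "
                "state the truncation"
            )
        f = law.pmf_vector(max_size)

    g = f.copy()
    if max_size is not None and g.size > max_size + 1:
        g = g[: max_size + 1]
    for _ in range(t - 1):
        g = _compose_once(f, g, max_size)

    tail = max(1.0 - g.sum(), 0.0)
    return SizeDistribution(t, g, g.size - 1, tail)


def expected_name_counts(dist: SizeDistribution, n_founders: int) -> np.ndarray:
    """Expected number of founder lineages (surnames) with each size.

    With N independent founders the expected count of lineages at size m
    after t generations is N * Pr(Z_t = m).
    """
    if n_founders < 1:
        raise ValueError("n_founders must be >= 1")
    return n_founders * dist.probs


def tail_probability(dist: SizeDistribution, m_min: int) -> float:
    """Pr(Z_t >= m_min), including any truncated tail mass."""
    if m_min < 0:
        raise ValueError("m_min must be >= 0")
    if m_min > dist.truncation_M:
        raise ValueError(
            f"m_min={m_min} exceeds the tracked support (truncation_M="
            f"{dist.truncation_M})"
        )
    return float(dist.probs[m_min:].sum()) + dist.tail_mass
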