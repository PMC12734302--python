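"""Allele fate in small diploid populations.

Three complementary treatments of a new allele B arising in a population of
AA homozygotes:

* the exact Wright-Fisher Markov chain on the 2N+1 allele-count states,
  with absorption probabilities and extinction/fixation times conditioned
  on the absorbing outcome (Doob h-transform on the transient block);
* the Kimura-Ohta diffusion approximations for the neutral conditional
  mean times to loss and fixation, accurate already for N around 16;
* the single selfing-individual model: a population of exactly one
  individual reproducing by selfing, where selection can act only in the
  haploid (gamete) phase, giving the closed form Q = P_AA / (1 - P_AB);
* the large-population heterozygote limit, where every B copy resides in
  an independently reproducing heterozygote and B's extinction probability
  reduces to the standard Galton-Watson fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .extinction import extinction_probability
from .laws import OffspringLaw

__all__ = [
    "WrightFisherChain",
    "AbsorptionSummary",
    "SelfingModel",
    "build_wf_chain",
    "fixation_probability",
    "absorption_summary",
    "finite_horizon_absorption_times",
    "kimura_ohta_times",
    "gamete_selection_delta_p",
    "selfing_model_from_selection",
    "selfing_extinction_probability",
    "heterozygote_extinction",
]


@dataclass(frozen=True)
class WrightFisherChain:
    """Neutral Wright-Fisher chain on allele-count states 0..2N.

    Each generation the 2N gene copies of the offspring are drawn
    binomially from the current allele frequency i/(2N); states 0 (loss)
    and 2N (fixation) are absorbing.
    """

    N: int
    transition: np.ndarray

    @property
    def n_states(self) -> int:
        return 2 * self.N + 1


@dataclass(frozen=True)
class AbsorptionSummary:
    """Absorption outcome of the chain started from i0 copies.

    ``t_loss`` and ``t_fix`` are conditional mean absorption times in
    generations, given loss and fixation respectively.
    """

    p_fix: float
    p_loss: float
    t_loss: float
    t_fix: float


@dataclass(frozen=True)
class SelfingModel:
    """Single selfing AB parent producing exactly one offspring.

    ``P_AA``/``P_AB``/``P_BB`` are the offspring genotype probabilities;
    an AA offspring means the B allele is lost, a BB offspring means it is
    fixed, and an AB offspring renews the parental situation, whence
    Q = P_AA + P_AB * Q.  ``s`` records the haploid-phase selection
    coefficient used to build the model (0 for neutral Mendelian ratios).
    """

    P_AA: float
    P_AB: float
    P_BB: float
    s: float = 0.0

    def __post_init__(self) -> None:
        p = np.array([self.P_AA, self.P_AB, self.P_BB])
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("genotype probabilities must be >= 0 and sum to 1")
        if self.s <= -1.0:
            raise ValueError("selection coefficient must exceed -1")


def build_wf_chain(N: int) -> WrightFisherChain:
    """Neutral binomial-sampling transition matrix for a diploid population."""
    if N < 1:
        raise ValueError("N must be >= 1")
    n = 2 * N
    i = np.arange(n + 1)
    P = stats.binom.pmf(i[None, :], n, (i / n)[:, None])
    return WrightFisherChain(N, P)


def _transient_blocks(chain: WrightFisherChain):
    n = 2 * chain.N
    B = chain.transition[1:n, 1:n]
    to_fix = chain.transition[1:n, n]
    return B, to_fix


def fixation_probability(chain: WrightFisherChain, i0: int) -> float:
    """P(absorption at 2N | start at i0), by the linear system (I-B)h = r.

    For the neutral chain this equals the initial frequency i0/(2N); the
    general solve is kept so selection variants slot in unchanged.
    """
    n = 2 * chain.N
    if not 0 <= i0 <= n:
        raise ValueError("i0 must lie in 0..2N")
    if i0 in (0, n):
        return float(i0 == n)
    B, to_fix = _transient_blocks(chain)
    h = np.linalg.solve(np.eye(B.shape[0]) - B, to_fix)
    return float(h[i0 - 1])


def absorption_summary(chain: WrightFisherChain, i0: int) -> AbsorptionSummary:
    """Exact conditional absorption analysis from i0 copies.

    The conditional mean times are computed on the outcome-conditioned
    chain (Doob h-transform): with h_i = P(fix | i), the fix-conditioned
    transient block is B~_ij = B_ij h_j / h_i and the expected steps solve
    (I - B~) t = 1; symmetrically with 1 - h for loss.
    """
    n = 2 * chain.N
    if not 0 < i0 < n:
        raise ValueError("i0 must be a transient state (0 < i0 < 2N)")
    B, to_fix = _transient_blocks(chain)
    m = B.shape[0]
    I = np.eye(m)
    h = np.linalg.solve(I - B, to_fix)
    ones = np.ones(m)

    B_fix = B * (h[None, :] / h[:, None])
    t_fix = np.linalg.solve(I - B_fix, ones)

    g = 1.0 - h
    B_loss = B * (g[None, :] / g[:, None])
    t_loss = np.linalg.solve(I - B_loss, ones)

    p_fix = float(h[i0 - 1])
    return AbsorptionSummary(
        p_fix=p_fix,
        p_loss=1.0 - p_fix,
        t_loss=float(t_loss[i0 - 1]),
        t_fix=float(t_fix[i0 - 1]),
    )


def finite_horizon_absorption_times(
    chain: WrightFisherChain, i0: int, horizon: int
) -> tuple[float, float]:
    """Conditional mean absorption times truncated at a finite horizon.

    Propagates the state distribution for ``horizon`` generations and
    averages the absorption generation over the mass absorbed within the
    window (normalised by that mass).  Converges to the exact conditional
    times as the horizon grows; at short horizons it understates them.
    Returns ``(t_loss, t_fix)``.
    """
    n = 2 * chain.N
    if not 0 < i0 < n:
        raise ValueError("i0 must be a transient state (0 < i0 < 2N)")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    v = np.zeros(n + 1)
    v[i0] = 1.0
    prev_loss = prev_fix = 0.0
    mass_l = mass_f = sum_l = sum_f = 0.0
    for t in range(1, horizon + 1):
        v = v @ chain.transition
        f_loss = v[0] - prev_loss
        f_fix = v[n] - prev_fix
        mass_l += f_loss
        mass_f += f_fix
        sum_l += t * f_loss
        sum_f += t * f_fix
        prev_loss, prev_fix = v[0], v[n]
    return sum_l / mass_l, sum_f / mass_f


def kimura_ohta_times(N: int, p: float) -> tuple[float, float]:
    """Kimura-Ohta diffusion approximations for a neutral allele.

    Conditional mean times, in generations, for an allele at frequency p in
    a diploid population of size N:

        t_fix(p)  = -(4N / p) (1 - p) ln(1 - p)
        t_loss(p) = -4N (p / (1 - p)) ln(p)

    Returns ``(t_loss, t_fix)``.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly between 0 and 1")
    t_fix = -(4.0 * N / p) * (1.0 - p) * np.log1p(-p)
    t_loss = -4.0 * N * (p / (1.0 - p)) * np.log(p)
    return float(t_loss), float(t_fix)


def gamete_selection_delta_p(p: float, s: float) -> float:
    """Haploid-phase selection change in the frequency p of allele A.

    With fitness 1 for A and 1+s for B during the gamete stage,

        delta_p = -s p (1 - p) / (1 + s (1 - p)).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be a frequency")
    if s <= -1.0:
        raise ValueError("s must exceed -1")
    return -s * p * (1.0 - p) / (1.0 + s * (1.0 - p))


def selfing_model_from_selection(s: float, p: float = 0.5) -> SelfingModel:
    """Selfing-offspring genotype probabilities under gametic selection.

    Both gametes of the selfing AB parent are drawn independently from the
    post-selection gamete pool, where the A frequency is p' = p + delta_p:
    P_AA = p'^2, P_AB = 2 p'(1-p'), P_BB = (1-p')^2.
    """
    pp = p + gamete_selection_delta_p(p, s)
    return SelfingModel(pp * pp, 2.0 * pp * (1.0 - pp), (1.0 - pp) ** 2, s=s)


def selfing_extinction_probability(model: SelfingModel) -> float:
    """Extinction probability of the B allele: Q = P_AA / (1 - P_AB).

    AA offspring lose B outright, BB offspring fix it (extinction
    probability 0), AB offspring restart the process.
    """
    if model.P_AB >= 1.0:
        raise ValueError("degenerate model: P_AB = 1 never resolves")
    return model.P_AA / (1.0 - model.P_AB)


def heterozygote_extinction(law: OffspringLaw) -> float:
    """Extinction probability of a new allele carried only by heterozygotes.

    In a large population every copy of the B allele sits in an AB
    heterozygote reproducing independently under ``law``, so B's fate is a
    standard branching process and Q solves Q = G(Q).
    """
    return extinction_probability(law).Q
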