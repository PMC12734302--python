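"""Monte-Carlo Galton-Watson simulator.

Serves as fixture generator and as an independent stochastic oracle for the
analytic modules: extinction fractions check Q, per-generation extinct
fractions check the iterates q_t, and replicate histograms check the
composed size distributions.

Each individual in generation t draws an independent offspring count from
the law and the draws sum to Z_{t+1}.  For Poisson laws the generation
total is drawn directly as Poisson(lambda * Z_t), which is exact by
superposition; finite laws draw a multinomial split of Z_t over offspring
counts.  Trajectories that exceed the size cap are frozen and flagged
(supercritical runs are about extinction-or-escape, so capping does not
bias extinction statistics at long horizons).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .laws import EmpiricalLaw, OffspringLaw, PoissonLaw

__all__ = ["SimConfig", "TrajectorySet", "simulate_gw", "empirical_extinction_curve"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings: law, founders, horizon, replicates, seed."""

    law: OffspringLaw
    z0: int = 1
    t_max: int = 100
    reps: int = 1000
    seed: int = 0
    size_cap: int = 10**7

    def __post_init__(self) -> None:
        if self.z0 < 1:
            raise ValueError("z0 must be >= 1")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


@dataclass(frozen=True)
class TrajectorySet:
    """Replicate trajectories Z[rep, t] for t = 0..t_max.

    ``extinct`` marks replicates that hit 0 within the horizon;
    ``extinction_gen`` holds the first generation at 0 (-1 if never);
    ``capped`` marks replicates frozen at the size cap.
    """

    Z: np.ndarray
    extinct: np.ndarray
    extinction_gen: np.ndarray
    capped: np.ndarray
    config: SimConfig = field(repr=False)

    @property
    def extinct_fraction(self) -> float:
        return float(self.extinct.mean())


def _step(law: OffspringLaw, z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One generation: vector of next sizes given current sizes z (> 0)."""
    if isinstance(law, PoissonLaw):
        return rng.poisson(law.lam * z)
    if isinstance(law, EmpiricalLaw):
        probs = law.probs
        ks = np.arange(probs.size)
        out = np.empty_like(z)
        for i, n in enumerate(z):
            out[i] = int(rng.multinomial(n, probs) @ ks)
        return out
    # generic integer law: draw per-individual counts (small populations only)
    out = np.empty_like(z)
    for i, n in enumerate(z):
        u = rng.random(int(n))
        # inverse-CDF draws truncated where the CDF reaches ~1
        k, cdf, total = 0, [], 0.0
        while total < 1.0 - 1e-12 and k < 10_000:
            total += law.pmf(k)
            cdf.append(total)
            k += 1
        out[i] = int(np.searchsorted(np.asarray(cdf), u).sum())
    return out


def simulate_gw(config: SimConfig) -> TrajectorySet:
    """Simulate replicate Galton-Watson trajectories.

    Determinism: a fixed ``config.seed`` yields byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    reps, t_max = config.reps, config.t_max
    Z = np.zeros((reps, t_max + 1), dtype=np.int64)
    Z[:, 0] = config.z0
    capped = np.zeros(reps, dtype=bool)

    for t in range(t_max):
        cur = Z[:, t]
        active = (cur > 0) & ~capped
        nxt = cur.copy()
        if active.any():
            nxt[active] = _step(config.law, cur[active], rng)
        over = nxt > config.size_cap
        if over.any():
            capped |= over
            nxt[over] = np.minimum(nxt[over], config.size_cap)
        Z[:, t + 1] = nxt

    extinct = (Z == 0).any(axis=1)
    extinction_gen = np.where(extinct, np.argmax(Z == 0, axis=1), -1)
    return TrajectorySet(Z, extinct, extinction_gen, capped, config)


def empirical_extinction_curve(ts: TrajectorySet) -> np.ndarray:
    """Fraction of replicates extinct by each generation t = 0..t_max.

    The Monte-Carlo counterpart of the iterates q_t; nondecreasing in t.
    """
    return np.maximum.accumulate(ts.Z == 0, axis=1).mean(axis=0)
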