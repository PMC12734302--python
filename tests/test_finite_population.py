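"""Wright-Fisher absorption analysis, diffusion approximations, selfing model."""

import numpy as np
import pytest

from branchproc import (
    PoissonLaw,
    SelfingModel,
    absorption_summary,
    build_wf_chain,
    finite_horizon_absorption_times,
    gamete_selection_delta_p,
    heterozygote_extinction,
    kimura_ohta_times,
    selfing_extinction_probability,
    selfing_model_from_selection,
)
from branchproc.finite_population import fixation_probability

# Converged conditional absorption times, frozen from an independent
# long-horizon propagation of the absorption-time distribution (horizon
# 5000 generations, increments < 1e-12).  The N=4 and N=16 values differ
# from shorter-horizon tabulations in the 3rd decimal.
EXACT_TIMES = {
    1: (2.0, 2.0),
    2: (2.993103448, 5.779310345),
    4: (4.078920296, 13.566288313),
    16: (6.502759179, 61.118240556),
}


class TestChain:
    def test_single_individual_transition(self):
        chain = build_wf_chain(1)
        assert chain.transition[1] == pytest.approx([0.25, 0.5, 0.25])

    def test_absorbing_rows(self):
        chain = build_wf_chain(5)
        assert chain.transition[0, 0] == 1.0
        assert chain.transition[10, 10] == 1.0

    def test_rows_are_stochastic(self):
        chain = build_wf_chain(8)
        assert chain.transition.sum(axis=1) == pytest.approx(
            np.ones(17), abs=1e-12
        )

    def test_two_individual_loss_mass(self):
        chain = build_wf_chain(2)
        assert chain.transition[1, 0] == pytest.approx((3 / 4) ** 4)

    def test_invalid_size(self):
        with pytest.raises(ValueError):
            build_wf_chain(0)


class TestNeutralFixation:
    @pytest.mark.parametrize("N", [1, 2, 4, 8, 16])
    def test_fixation_probability_is_initial_frequency(self, N):
        chain = build_wf_chain(N)
        for i0 in range(2 * N + 1):
            assert fixation_probability(chain, i0) == pytest.approx(
                i0 / (2 * N), abs=1e-10
            )


class TestConditionalTimes:
    @pytest.mark.parametrize("N", [1, 2, 4, 16])
    def test_exact_conditional_times(self, N):
        summ = absorption_summary(build_wf_chain(N), 1)
        t_loss, t_fix = EXACT_TIMES[N]
        assert summ.t_loss == pytest.approx(t_loss, abs=5e-9)
        assert summ.t_fix == pytest.approx(t_fix, abs=5e-9)
        assert summ.p_fix == pytest.approx(1 / (2 * N), abs=1e-10)

    @pytest.mark.parametrize("N", [1, 2])
    def test_small_N_match_published_table(self, N):
        # for N <= 2 the tabulated values are fully converged
        published = {1: (2.0, 2.0), 2: (2.9931, 5.7793)}
        summ = absorption_summary(build_wf_chain(N), 1)
        assert summ.t_loss == pytest.approx(published[N][0], abs=5e-5)
        assert summ.t_fix == pytest.approx(published[N][1], abs=5e-5)

    @pytest.mark.parametrize(
        "N,horizon,t_loss,t_fix",
        [(4, 70, 4.0768, 13.5534), (16, 300, 6.5006, 61.0634)],
    )
    def test_finite_horizon_tabulations(self, N, horizon, t_loss, t_fix):
        """Published N=4/16 times correspond to horizon-truncated means."""
        tl, tf = finite_horizon_absorption_times(build_wf_chain(N), 1, horizon)
        assert tl == pytest.approx(t_loss, abs=5e-5)
        assert tf == pytest.approx(t_fix, abs=5e-5)

    def test_finite_horizon_converges_to_exact(self):
        chain = build_wf_chain(4)
        tl, tf = finite_horizon_absorption_times(chain, 1, 2000)
        summ = absorption_summary(chain, 1)
        assert tl == pytest.approx(summ.t_loss, abs=1e-9)
        assert tf == pytest.approx(summ.t_fix, abs=1e-9)

    def test_boundary_state_rejected(self):
        with pytest.raises(ValueError):
            absorption_summary(build_wf_chain(2), 0)

    def test_monte_carlo_cross_check(self):
        """Direct chain simulation reproduces the conditioned times (N=2)."""
        rng = np.random.default_rng(5)
        N, reps = 2, 50_000
        n = 2 * N
        state = np.ones(reps, dtype=np.int64)
        absorbed_at = np.zeros(reps, dtype=np.int64)
        for t in range(1, 2000):
            active = (state > 0) & (state < n)
            if not active.any():
                break
            state[active] = rng.binomial(n, state[active] / n)
            just = active & ((state == 0) | (state == n))
            absorbed_at[just] = t
        summ = absorption_summary(build_wf_chain(N), 1)
        for target, t_exp in ((0, summ.t_loss), (n, summ.t_fix)):
            times = absorbed_at[state == target]
            se = times.std(ddof=1) / np.sqrt(times.size)
            assert abs(times.mean() - t_exp) <= 3.0 * se


class TestKimuraOhta:
    @pytest.mark.parametrize(
        "N,p,t_loss,t_fix",
        [
            (1, 0.5, 2.7726, 2.7726),
            (4, 1 / 8, 4.7530, 14.9555),
            (16, 1 / 32, 7.1551, 62.9894),
        ],
    )
    def test_published_approximations(self, N, p, t_loss, t_fix):
        tl, tf = kimura_ohta_times(N, p)
        assert tl == pytest.approx(t_loss, abs=5e-5)
        assert tf == pytest.approx(t_fix, abs=5e-5)

    def test_single_copy_fixation_is_4N_ln2_at_half(self):
        _, tf = kimura_ohta_times(1, 0.5)
        assert tf == pytest.approx(4 * np.log(2), rel=1e-12)

    def test_diffusion_gap_shrinks_with_N(self):
        """The chain-vs-diffusion relative gap at N=16 is below that at N=1."""
        gaps = {}
        for N in (1, 16):
            summ = absorption_summary(build_wf_chain(N), 1)
            tl, tf = kimura_ohta_times(N, 1 / (2 * N))
            gaps[N] = (
                abs(summ.t_loss - tl) / tl,
                abs(summ.t_fix - tf) / tf,
            )
        assert gaps[16][0] < gaps[1][0]
        assert gaps[16][1] < gaps[1][1]

    def test_boundary_frequency_rejected(self):
        with pytest.raises(ValueError):
            kimura_ohta_times(4, 0.0)


class TestSelfingModel:
    def test_neutral_mendelian_half(self):
        model = SelfingModel(0.25, 0.5, 0.25)
        assert selfing_extinction_probability(model) == 0.25 / (1 - 0.5)

    def test_gametic_selection_shifts_Q(self):
        model = selfing_model_from_selection(0.01)
        assert model.P_AA == pytest.approx(0.247519, abs=5e-7)
        assert selfing_extinction_probability(model) == pytest.approx(
            0.495025, abs=5e-7
        )

    def test_direct_ratio_without_heterozygotes(self):
        assert selfing_extinction_probability(SelfingModel(0.5, 0.0, 0.5)) == 0.5

    def test_degenerate_model_rejected(self):
        with pytest.raises(ValueError):
            selfing_extinction_probability(SelfingModel(0.0, 1.0, 0.0))

    def test_delta_p_values(self):
        assert 0.5 + gamete_selection_delta_p(0.5, 0.01) == pytest.approx(
            0.497512, abs=5e-7
        )
        assert gamete_selection_delta_p(0.5, 0.0) == 0.0

    def test_neutral_selection_recovers_mendelian(self):
        model = selfing_model_from_selection(0.0)
        assert model.P_AA == pytest.approx(0.25)
        assert model.P_AB == pytest.approx(0.5)


class TestHeterozygoteLimit:
    @pytest.mark.parametrize(
        "lam,Q", [(1.1, 0.82391), (2.0, 0.20319), (1.0, 1.0)]
    )
    def test_reduces_to_branching_fixed_point(self, lam, Q):
        tol = 5e-5 if lam == 1.1 else 1e-5
        assert heterozygote_extinction(PoissonLaw(lam)) == pytest.approx(
            Q, abs=tol
        )
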