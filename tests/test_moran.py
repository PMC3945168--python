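"""Constant-size Moran stem model: kernels, events, fixation statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dediffsim import (
    MoranParams,
    MoranState,
    moran_chain_exact,
    moran_event,
    mutation_matrix,
    quasi_steady_chi,
    replacement_probabilities,
    simulate_fixation,
    simulate_two_type_absorption,
)
from dediffsim._rng import replicate_seed


class TestMutationMatrix:
    def test_forced_values(self):
        assert np.allclose(mutation_matrix(0.0), np.eye(3))
        M = mutation_matrix(0.1)
        assert np.allclose(M[0], [0.9, 0.1, 0.0])
        assert np.allclose(M[1], [0.0, 0.9, 0.1])
        assert np.allclose(M[2], [0.0, 0.0, 1.0])

    @given(u=st.floats(0.0, 1.0))
    def test_rows_sum_to_one_and_no_back_mutation(self, u):
        M = mutation_matrix(u)
        assert np.allclose(M.sum(axis=1), 1.0)
        assert np.allclose(np.tril(M, -1), 0.0)

    def test_rejects_invalid_rate(self):
        with pytest.raises(ValueError):
            mutation_matrix(1.5)


class TestReplacementKernel:
    def test_pure_resident_state_is_absorbing_without_mutation(self):
        params = MoranParams(N=5, stem_mutation_rate=0.0)
        P = replacement_probabilities(
            MoranState(counts=[5, 0, 0]), 0.0, params
        )
        assert P[0, 0] == pytest.approx(1.0)

    def test_full_dediff_forces_class2_birth(self):
        params = MoranParams(N=4, dediff_weight=1.0)
        P = replacement_probabilities(MoranState(counts=[2, 1, 1]), 1.0, params)
        assert P[:, 2].sum() == pytest.approx(1.0)

    def test_toy_kernel_matches_hand_enumeration(self):
        """N = 3, x = (1,1,1), u = 0.1, d = 0.2, chi = 0.5: enumerate the
        (death, birth) outcome distribution by hand."""
        params = MoranParams(N=3, stem_mutation_rate=0.1, dediff_weight=0.2)
        P = replacement_probabilities(MoranState(counts=[1, 1, 1]), 0.5, params)
        # birth: with prob 0.2*0.5 = 0.1 a class-2 entrant; otherwise a
        # uniform parent (1/3 each) pushed through the cascade
        p_copy = np.array([1 / 3 * 0.9, 1 / 3 * 0.1 + 1 / 3 * 0.9, 1 / 3 * 0.1 + 1 / 3])
        birth = 0.9 * p_copy + np.array([0.0, 0.0, 0.1])
        expected = np.outer(np.full(3, 1 / 3), birth)
        assert np.allclose(P, expected)

    def test_selection_weights_class2_parent(self):
        params = MoranParams(N=4, selection=1.0)
        P = replacement_probabilities(MoranState(counts=[2, 0, 2]), 0.0, params)
        # parent draw weights 2 : 0 : 4
        assert P[:, 2].sum() == pytest.approx(4 / 6)

    @given(
        x0=st.integers(0, 5), x1=st.integers(0, 5), x2=st.integers(0, 5),
        u=st.floats(0, 1), d=st.floats(0, 1), chi=st.floats(0, 1),
        s=st.floats(0, 2),
    )
    def test_kernel_normalizes(self, x0, x1, x2, u, d, chi, s):
        N = x0 + x1 + x2
        if N == 0:
            return
        params = MoranParams(
            N=N, stem_mutation_rate=u, dediff_weight=d, selection=s
        )
        P = replacement_probabilities(MoranState(counts=[x0, x1, x2]), chi, params)
        assert P.sum() == pytest.approx(1.0)
        assert P.min() >= 0.0


class TestMoranEvent:
    def test_conserves_population(self):
        params = MoranParams(N=7, stem_mutation_rate=0.2, dediff_weight=0.3)
        rng = np.random.default_rng(0)
        state = MoranState(counts=[3, 2, 2])
        for _ in range(200):
            state = moran_event(state, 0.4, params, rng)
            assert state.N == 7
            assert state.counts.min() >= 0

    def test_absorbing_state_unchanged(self):
        params = MoranParams(N=5, stem_mutation_rate=0.1)
        rng = np.random.default_rng(1)
        state = MoranState(counts=[0, 0, 5], t=3.0)
        new = moran_event(state, 0.0, params, rng)
        assert np.array_equal(new.counts, [0, 0, 5])
        assert new.t == pytest.approx(3.0 + params.event_interval)

    def test_event_matches_kernel_frequencies(self):
        params = MoranParams(N=3, stem_mutation_rate=0.1, dediff_weight=0.2)
        state = MoranState(counts=[1, 1, 1])
        P = replacement_probabilities(state, 0.5, params)
        rng = np.random.default_rng(7)
        counts = np.zeros((3, 3))
        for _ in range(4000):
            new = moran_event(state, 0.5, params, rng)
            diff = new.counts - state.counts
            if np.all(diff == 0):  # death class == birth class
                # attribute to the diagonal in proportion to the kernel
                continue
            i = int(np.nonzero(diff == -1)[0][0])
            j = int(np.nonzero(diff == 1)[0][0])
            counts[i, j] += 1
        off = ~np.eye(3, dtype=bool)
        freq = counts[off] / counts.sum()
        expect = P[off] / P[off].sum()
        assert np.allclose(freq, expect, atol=0.03)


class TestNeutralOracles:
    def test_single_mutant_fixes_with_probability_one_over_N(self):
        N = 20
        n_rep = 4000
        fixed = sum(
            simulate_two_type_absorption(N, seed=replicate_seed(901, i))[0]
            for i in range(n_rep)
        )
        phat = fixed / n_rep
        se = np.sqrt((1 / N) * (1 - 1 / N) / n_rep)
        assert abs(phat - 1 / N) < 3.5 * se

    def test_selective_chain_oracle(self):
        """Empirical absorption statistics match the exact tridiagonal chain."""
        N, s = 12, 0.15
        n_rep = 3000
        fixed, cond = 0, []
        for i in range(n_rep):
            fx, t = simulate_two_type_absorption(N, s=s, seed=replicate_seed(902, i))
            if fx:
                fixed += 1
                cond.append(t)
        chain = moran_chain_exact(N, s)
        rho = chain["fixation_prob"][1]
        se = np.sqrt(rho * (1 - rho) / n_rep)
        assert abs(fixed / n_rep - rho) < 3.5 * se
        t_exact = chain["mean_conditional_fixation_time"][1]
        assert np.mean(cond) == pytest.approx(
            t_exact, rel=4 * np.std(cond) / np.sqrt(len(cond)) / t_exact
        )

    def test_chain_neutral_values(self):
        chain = moran_chain_exact(20, 0.0)
        assert chain["fixation_prob"][1] == pytest.approx(1 / 20)
        # neutral Moran: conditional fixation of a single mutant takes
        # N - 1 generations
        assert chain["mean_conditional_fixation_time"][1] == pytest.approx(19.0)


class TestSimulateFixation:
    def test_never_fixes_without_mutation_sets_truncation(self):
        params = MoranParams(N=10, stem_mutation_rate=0.0)
        rec = simulate_fixation(params, seed=1, t_max=500.0)
        assert rec.truncated
        assert np.isnan(rec.t_fix)

    def test_certain_mutation_fixes_fast(self):
        params = MoranParams(N=10, stem_mutation_rate=1.0)
        rec = simulate_fixation(params, seed=2)
        assert not rec.truncated
        assert rec.t_fix < 30 * params.stem_cycle
        assert rec.fixed_class == 2
        assert rec.t_emergence <= rec.t_fix

    def test_reproducible_for_fixed_seed(self):
        params = MoranParams(N=30, stem_mutation_rate=0.02)
        a = simulate_fixation(params, seed=replicate_seed(5, 0))
        b = simulate_fixation(params, seed=replicate_seed(5, 0))
        assert a.t_fix == b.t_fix and a.t_emergence == b.t_emergence

    def test_dediff_bias_raises_fixation_probability_proxy(self):
        """With a constant dedifferentiation supply, class 2 fixes sooner
        than in the neutral model."""
        base = MoranParams(N=30, stem_mutation_rate=0.02)
        fast = MoranParams(N=30, stem_mutation_rate=0.02, dediff_weight=0.5)
        t_base = np.median(
            [
                simulate_fixation(base, seed=replicate_seed(6, i)).t_fix
                for i in range(40)
            ]
        )
        t_fast = np.median(
            [
                simulate_fixation(
                    fast, chi_provider=0.3, seed=replicate_seed(6, i)
                ).t_fix
                for i in range(40)
            ]
        )
        assert t_fast < t_base

    def test_exponential_interval_option(self):
        params = MoranParams(N=10, stem_mutation_rate=1.0, exponential_intervals=True)
        rec = simulate_fixation(params, seed=3)
        # times no longer multiples of tau/N
        assert rec.t_fix % params.event_interval != pytest.approx(0.0, abs=1e-12)


def test_quasi_steady_chi_mirrors_stem_composition():
    chi = quasi_steady_chi()
    assert chi(0.0, 99, 0, 1) == pytest.approx(0.01)
    assert chi(0.0, 0, 0, 50) == pytest.approx(1.0)
    assert chi(0.0, 0, 0, 0) == 0.0
    amplified = quasi_steady_chi((1.0, 1.0, 10.0))
    assert amplified(0.0, 90, 0, 10) == pytest.approx(100 / 190)
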