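"""Boltzmann tables, state extraction, divergences and the Glauber oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lifsampler import (
    BoltzmannTarget,
    ProbabilityTable,
    SpikeTrain,
    conditional_joint,
    dkl,
    empirical_joint,
    extract_states,
    glauber_sample,
    random_target,
    state_moments,
    target_joint,
)
from lifsampler.sampling_theory import StateSequence, all_states


def uniform_target(n):
    return BoltzmannTarget(np.zeros((n, n)), np.zeros(n))


class TestTargetJoint:
    def test_uniform_for_zero_parameters(self):
        table = target_joint(uniform_target(2))
        np.testing.assert_allclose(table.p, 0.25)

    def test_single_unit_sigmoid(self):
        """n=1 with b = ln 3 gives p(z=1) = 3/4."""
        t = BoltzmannTarget(np.zeros((1, 1)), np.array([math.log(3.0)]))
        table = target_joint(t)
        assert table.p[1] == pytest.approx(0.75, abs=1e-12)

    def test_two_units_coupled(self):
        """W_12 = 1, b = 0: p(1,1) = e/(3+e) by enumeration of 4 states."""
        t = BoltzmannTarget(np.array([[0.0, 1.0], [1.0, 0.0]]), np.zeros(2))
        table = target_joint(t)
        assert table.p[3] == pytest.approx(math.e / (3 + math.e), rel=1e-12)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            BoltzmannTarget(np.array([[0.0, 1.0], [0.5, 0.0]]), np.zeros(2))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError):
            BoltzmannTarget(np.eye(2), np.zeros(2))


class TestConditional:
    def test_empty_clamp_is_identity(self):
        t = random_target(4, seed=1)
        np.testing.assert_allclose(conditional_joint(t, {}).p,
                                   target_joint(t).p, atol=1e-14)

    def test_independent_units_unaffected_by_clamping(self):
        b = np.array([0.3, -0.7, 1.2])
        t = BoltzmannTarget(np.zeros((3, 3)), b)
        cond = conditional_joint(t, {0: 1})
        # free units keep p(z=1) = sigmoid(b)
        marg = cond.marginals()
        expected = 1 / (1 + np.exp(-b[1:]))
        np.testing.assert_allclose(marg, expected, rtol=1e-12)

    def test_matches_bruteforce_renormalization(self):
        """Clamping (z1, z2) = (0, 1) equals slicing the 32-state table."""
        t = random_target(5, seed=7)
        cond = conditional_joint(t, {0: 0, 1: 1})
        full = target_joint(t).p
        states = all_states(5)
        mask = (states[:, 0] == 0) & (states[:, 1] == 1)
        brute = full[mask] / full[mask].sum()
        np.testing.assert_allclose(cond.p, brute, rtol=1e-12)

    def test_clamping_everything_rejected(self):
        with pytest.raises(ValueError):
            conditional_joint(uniform_target(2), {0: 0, 1: 1})


class TestExtractStates:
    def test_single_refractory_interval_half_open(self):
        """A spike at 10 ms with tau_ref = 4 ms gives z=1 on [10, 14)."""
        spikes = SpikeTrain.from_times([10.0], source=0)
        seq = extract_states(spikes, 4.0, (0.0, 20.0), n_neurons=1)
        emp = empirical_joint(seq)
        assert emp.p[1] == pytest.approx(4.0 / 20.0, rel=1e-12)
        # state is exactly zero at t = 14
        idx = np.searchsorted(seq.breakpoints, 14.0, side="right") - 1
        assert seq.states[idx, 0] == 0

    def test_no_spikes_all_zero(self):
        seq = extract_states(SpikeTrain.empty(), 4.0, (0.0, 10.0), n_neurons=2)
        assert np.all(seq.states == 0)

    def test_overlapping_intervals_merge(self):
        """Spikes at 10 and 12 ms with tau_ref = 4 ms give z=1 on [10, 16)."""
        spikes = SpikeTrain.from_times([10.0, 12.0], source=0)
        seq = extract_states(spikes, 4.0, (0.0, 20.0), n_neurons=1)
        on_time = seq.durations[seq.states[:, 0] == 1].sum()
        assert on_time == pytest.approx(6.0, rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0.0, 90.0), min_size=0, max_size=15),
           st.floats(0.5, 10.0))
    def test_union_of_intervals_matches_grid_oracle(self, times, tau):
        """Piecewise-constant extraction agrees with a dense-grid oracle."""
        spikes = SpikeTrain.from_times(np.array(times))
        seq = extract_states(spikes, tau, (0.0, 100.0), n_neurons=1)
        grid = np.arange(0.005, 100.0, 0.01)
        oracle = np.zeros(grid.size, dtype=bool)
        for t_sp in times:
            oracle |= (grid >= t_sp) & (grid < t_sp + tau)
        idx = np.searchsorted(seq.breakpoints, grid, side="right") - 1
        idx = np.clip(idx, 0, seq.states.shape[0] - 1)
        assert np.array_equal(seq.states[idx, 0].astype(bool), oracle)


class TestEmpiricalJoint:
    def test_constant_state_is_point_mass(self):
        seq = StateSequence(np.array([0.0, 5.0]), np.array([[1, 0]]))
        emp = empirical_joint(seq)
        assert emp.p[1] == 1.0

    def test_half_half_occupancy(self):
        seq = StateSequence(np.array([0.0, 5.0, 10.0]),
                            np.array([[0], [1]]))
        np.testing.assert_allclose(empirical_joint(seq).p, [0.5, 0.5])

    def test_zero_length_window_rejected(self):
        seq = StateSequence(np.array([3.0, 3.0]), np.array([[0]]))
        with pytest.raises(ValueError):
            empirical_joint(seq)

    def test_occupancy_identity_isolated_neuron(self):
        """Non-overlapping refractory periods: p(z=1) = rate x tau_ref."""
        times = np.arange(10.0, 10000.0, 25.0)  # 40 Hz, tau_ref = 4 ms
        seq = extract_states(SpikeTrain.from_times(times), 4.0,
                             (0.0, 10000.0), n_neurons=1)
        emp = empirical_joint(seq)
        assert emp.p[1] == pytest.approx(40.0 * 4.0 / 1000.0, rel=0.01)

    def test_moments_match_table(self):
        rng = np.random.default_rng(3)
        bp = np.sort(np.concatenate([[0.0, 100.0], rng.uniform(0, 100, 20)]))
        states = rng.integers(0, 2, size=(bp.size - 1, 3)).astype(np.uint8)
        seq = StateSequence(bp, states)
        mean, second = state_moments(seq)
        table = empirical_joint(seq)
        np.testing.assert_allclose(mean, table.marginals(), atol=1e-12)
        assert np.allclose(second, second.T)
        np.testing.assert_allclose(np.diag(second), mean, atol=1e-12)


class TestDkl:
    def test_identical_tables_zero(self):
        t = target_joint(random_target(4, seed=2))
        assert dkl(t, t) == pytest.approx(0.0, abs=1e-14)

    def test_point_mass_vs_uniform_ln2(self):
        p = ProbabilityTable(1, np.array([1.0, 0.0]))
        q = ProbabilityTable(1, np.array([0.5, 0.5]))
        assert dkl(p, q) == pytest.approx(math.log(2.0), rel=1e-12)

    def test_matches_per_state_summation_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.random(32)
        b = rng.random(32)
        p = ProbabilityTable(5, a / a.sum())
        q = ProbabilityTable(5, b / b.sum())
        oracle = sum(pi * math.log(pi / qi) for pi, qi in zip(p.p, q.p) if pi > 0)
        assert dkl(p, q) == pytest.approx(oracle, abs=1e-12)

    def test_zero_q_on_support_rejected(self):
        p = ProbabilityTable(1, np.array([0.5, 0.5]))
        q = ProbabilityTable(1, np.array([1.0, 0.0]))
        with pytest.raises(ValueError):
            dkl(p, q)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_non_negative_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random(8) + 1e-9
        b = rng.random(8) + 1e-9
        p = ProbabilityTable(3, a / a.sum())
        q = ProbabilityTable(3, b / b.sum())
        assert dkl(p, q) >= 0.0


class TestRandomTarget:
    def test_bounds_symmetry_and_zero_diagonal(self):
        t = random_target(6, seed=9)
        assert np.all(np.abs(t.b) <= 1.0) and np.all(np.abs(t.W) <= 1.0)
        assert np.allclose(t.W, t.W.T) and np.all(np.diag(t.W) == 0)

    def test_beta_scheme_statistics(self):
        """Mean ~ 0 with the arcsine law's U-shaped density at +-1."""
        draws = np.concatenate([random_target(8, seed=s).b for s in range(1250)])
        assert abs(draws.mean()) < 0.02
        # U-shape: tails more likely than the middle
        tails = np.mean(np.abs(draws) > 0.8)
        middle = np.mean(np.abs(draws) < 0.2)
        assert tails > middle


class TestGlauberOracle:
    def test_converges_to_target_joint(self):
        """10^6 sweeps on a 5-unit target: DKL below 1e-3 (independent of
        the LIF path)."""
        t = random_target(5, seed=11)
        table = glauber_sample(t, 10 ** 6, seed=4)
        assert dkl(table, target_joint(t)) < 1e-3

    def test_matches_independent_sigmoids_without_couplings(self):
        b = np.array([0.5, -1.0])
        t = BoltzmannTarget(np.zeros((2, 2)), b)
        table = glauber_sample(t, 200_000, seed=6)
        np.testing.assert_allclose(table.marginals(),
                                   1 / (1 + np.exp(-b)), atol=0.01)
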