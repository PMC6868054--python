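"""Wake-sleep updates, analytic wake statistics, clamping and training."""

import numpy as np
import pytest

from lifsampler import (
    BoltzmannTarget,
    MomentState,
    PoissonSource,
    TrainingConfig,
    analytic_wake_stats,
    build_hierarchical_network,
    build_sampling_network,
    clamp_inputs,
    empirical_joint,
    extract_states,
    glauber_sample,
    pretrain_rbm,
    random_target,
    target_joint,
    train_to_target,
    wake_sleep_step,
)
from lifsampler.sampling_theory import all_states


def sigmoid(x):
    return 1 / (1 + np.exp(-np.asarray(x, dtype=float)))


class TestWakeSleepStep:
    def cfg(self, eta=1.0, momentum=0.0):
        return TrainingConfig(eta=eta, momentum=momentum, iterations=1)

    def test_fixed_point_gives_zero_updates(self):
        mean = np.array([0.4, 0.6])
        sec = np.outer(mean, mean)
        db, dW, _ = wake_sleep_step((mean, sec), (mean, sec), self.cfg(),
                                    MomentState.zeros(2))
        assert np.all(db == 0) and np.all(dW == 0)

    def test_bias_update_is_eta_times_gap(self):
        mean_d, mean_m = np.array([0.8]), np.array([0.3])
        db, _, _ = wake_sleep_step((mean_d, np.zeros((1, 1))),
                                   (mean_m, np.zeros((1, 1))),
                                   self.cfg(eta=1.0), MomentState.zeros(1))
        assert db[0] == pytest.approx(0.5)

    def test_momentum_recursion(self):
        """eta=1, gradient 0.5, momentum 0.6, previous update 1.0 -> 1.1."""
        prev = MomentState(np.array([1.0]), np.zeros((1, 1)))
        db, _, new = wake_sleep_step(
            (np.array([0.5]), np.zeros((1, 1))),
            (np.array([0.0]), np.zeros((1, 1))),
            self.cfg(eta=1.0, momentum=0.6), prev)
        assert db[0] == pytest.approx(1.1)
        assert new.db[0] == pytest.approx(1.1)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            wake_sleep_step((np.zeros(2), np.zeros((2, 2))),
                            (np.zeros(3), np.zeros((3, 3))),
                            self.cfg(), MomentState.zeros(2))

    def test_out_of_range_statistics_rejected(self):
        with pytest.raises(ValueError):
            wake_sleep_step((np.array([1.5]), np.zeros((1, 1))),
                            (np.array([0.5]), np.zeros((1, 1))),
                            self.cfg(), MomentState.zeros(1))


class TestAnalyticWakeStats:
    def test_independent_units_factorize(self):
        b = np.array([0.7, -0.2, 1.1])
        t = BoltzmannTarget(np.zeros((3, 3)), b)
        mean, second = analytic_wake_stats(t)
        np.testing.assert_allclose(mean, sigmoid(b), rtol=1e-12)
        for i in range(3):
            for j in range(3):
                if i != j:
                    assert second[i, j] == pytest.approx(
                        sigmoid(b[i]) * sigmoid(b[j]), rel=1e-12)

    def test_uniform_target_moments(self):
        t = BoltzmannTarget(np.zeros((2, 2)), np.zeros(2))
        mean, second = analytic_wake_stats(t)
        np.testing.assert_allclose(mean, 0.5)
        assert second[0, 1] == pytest.approx(0.25)

    def test_matches_glauber_oracle_within_monte_carlo_error(self):
        """Exact moments agree with a long Glauber run to ~3 sigma."""
        t = random_target(5, seed=13)
        mean, second = analytic_wake_stats(t)
        table = glauber_sample(t, 400_000, seed=2)
        z = all_states(5).astype(float)
        mc_mean = z.T @ table.p
        sigma = np.sqrt(mean * (1 - mean) / 4e5) * 40  # correlated sweeps
        assert np.all(np.abs(mc_mean - mean) < 3 * sigma + 3e-3)


class TestClampInputs:
    def test_zero_duration_empty_trains(self):
        out = clamp_inputs({0: 1, 1: 0}, duration=0.0)
        assert all(t.n_events == 0 for t in out.values())

    def test_ports_route_by_value(self):
        out = clamp_inputs({0: 1, 3: 0}, duration=100.0)
        assert set(out) == {"clamp_exc_0", "clamp_inh_3"}
        # 5 multapse members at 100 Hz over 100 ms -> 50 spikes
        assert out["clamp_exc_0"].n_events == 50

    def test_invalid_value_rejected(self):
        with pytest.raises(ValueError):
            clamp_inputs({0: 2}, duration=10.0)

    def test_clamping_efficacy_in_simulation(self):
        """Clamped-on occupancy > 0.9 and clamped-off occupancy < 0.1."""
        snet = build_sampling_network(2, noise=PoissonSource())
        clamps = clamp_inputs({0: 1, 1: 0}, duration=5e3)
        res = snet.run(5e3, seed=3, extra_inputs=clamps)
        seq = extract_states(res.spikes, snet.tau_ref, (100.0, 5e3),
                             neuron_ids=snet.sampling_ids)
        occ = (seq.states.astype(float) * seq.durations[:, None]).sum(0)
        occ /= seq.durations.sum()
        assert occ[0] > 0.9
        assert occ[1] < 0.1


class TestTrainToTarget:
    def test_learning_reduces_dkl_and_returns_argmin(self):
        """Short runs on random 5-unit targets: the final DKL beats the
        initial one (median over seeds) and the reported best iteration is
        the argmin of the recorded history."""
        finals, initials = [], []
        for k in range(3):
            t = random_target(5, seed=40 + k)
            cfg = TrainingConfig(eta=1.0, momentum=0.6, iterations=25,
                                 sampling_ms=4e3, seed=50 + k)
            res = train_to_target(t, cfg, noise=PoissonSource())
            assert res.best_iteration == int(np.argmin(res.dkl_history))
            initials.append(res.dkl_history[0])
            finals.append(res.dkl_history[-1])
        assert np.median(finals) < np.median(initials)

    def test_gradient_sign_single_bias(self):
        """With the sampled mean too low, the bias weight increases."""
        t = BoltzmannTarget(np.zeros((1, 1)), np.array([2.0]))
        cfg = TrainingConfig(eta=1.0, momentum=0.0, iterations=4,
                             sampling_ms=3e3, seed=1, init_scale=1e-9)
        res = train_to_target(t, cfg, noise=PoissonSource())
        # target occupancy sigma(2) ~ 0.88; starts near 0.5 -> bias grows
        assert res.b_dig[0] > 0

    def test_shadow_weights_stay_within_half_step_of_digital(self):
        """Discretized weights track the continuous shadow to <= 0.5."""
        t = random_target(3, seed=3)
        cfg = TrainingConfig(eta=0.5, momentum=0.3, iterations=10,
                             sampling_ms=2e3, seed=2)
        res = train_to_target(t, cfg, noise=PoissonSource())
        # the returned digital weights are the rounding of a clipped shadow
        assert np.all(np.abs(res.w_dig) <= 15)
        assert np.all(res.w_dig == np.round(res.w_dig))


class TestPretrainAndHierarchy:
    def test_rbm_blocks_and_symmetry(self):
        rng = np.random.default_rng(0)
        imgs = rng.integers(0, 2, size=(40, 144)).astype(np.uint8)
        labels = rng.integers(0, 3, size=40)
        W, b = pretrain_rbm(imgs, labels, n_hidden=10, n_label=3, epochs=2,
                            seed=1)
        n = 144 + 10 + 3
        assert W.shape == (n, n) and b.shape == (n,)
        np.testing.assert_allclose(W, W.T)
        # no direct visible-label or intra-layer couplings
        assert np.all(W[:144, :144] == 0)
        assert np.all(W[:144, 154:] == 0)
        assert np.all(np.diag(W) == 0)

    def test_hierarchical_network_layout(self):
        snet = build_hierarchical_network(16, 4, 2, noise=PoissonSource(),
                                          label_multapse=3)
        roles = [snet.net.roles[u.sampling_id] for u in snet.units]
        assert roles == ["visible"] * 16 + ["hidden"] * 4 + ["label"] * 2
        # single shared bias neuron
        assert len({u.bias_id for u in snet.units}) == 1
        # hidden-label connections carry the multapse range
        w_max = snet.w_max
        assert w_max[16, 20] == 45.0  # hidden unit 16 <-> label unit 20
        assert w_max[0, 16] == 15.0

    def test_wake_phase_visible_activity_ignores_hidden(self):
        """With the top-down synapses from the hidden layer disabled,
        visible and label spiking is unaffected by the hidden layer: wildly
        different hidden biases leave it bit-identical."""
        snet = build_hierarchical_network(6, 3, 2, noise=PoissonSource())
        n = 11
        rng = np.random.default_rng(1)
        w = np.zeros((n, n))
        for (i, j) in snet.connections:
            w[i, j] = w[j, i] = float(rng.integers(-10, 11))
        b = rng.integers(-5, 6, size=n).astype(float)
        hid = [6, 7, 8]
        clamps = clamp_inputs({k: 1 for k in list(range(3)) + [9]}, 500.0)
        vis_lab_ids = [snet.units[k].sampling_id
                       for k in list(range(6)) + [9, 10]]

        def visible_spikes(hidden_bias: float):
            b2 = b.copy()
            b2[hid] = hidden_bias
            snet.set_weights(w, b2)
            snet.zero_directed(hid)
            res = snet.run(500.0, seed=7, extra_inputs=clamps)
            keep = np.isin(res.spikes.sources, vis_lab_ids)
            return res.spikes.times[keep], res.spikes.sources[keep]

        t1, s1 = visible_spikes(-15.0)
        t2, s2 = visible_spikes(15.0)
        assert np.array_equal(t1, t2)
        assert np.array_equal(s1, s2)
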