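"""Experiment protocols: sampling, inference, classification, completion,
guided dreaming."""

import numpy as np
import pytest

from lifsampler import (
    PoissonSource,
    build_hierarchical_network,
    build_sampling_network,
    classify,
    dkl,
    empirical_joint,
    extract_states,
    guided_dream,
    inference_experiment,
    pattern_complete,
    random_target,
    sampling_experiment,
    target_joint,
)
from lifsampler.synthetic_data import make_synthetic_dataset


@pytest.fixture(scope="module")
def small_translated_net():
    """A 5-unit Poisson network with moderate random digital weights."""
    rng = np.random.default_rng(8)
    snet = build_sampling_network(5, noise=PoissonSource())
    w = np.zeros((5, 5))
    iu = np.triu_indices(5, 1)
    w[iu] = rng.integers(-6, 7, size=len(iu[0]))
    w = w + w.T
    snet.set_weights(w, rng.integers(-4, 5, size=5).astype(float))
    return snet


class TestSamplingExperiment:
    def test_final_value_matches_manual_composition(self, small_translated_net):
        """The trace's final point equals extract_states + empirical_joint +
        dkl composed by hand on an identical run."""
        target = random_target(5, seed=3)
        exp = sampling_experiment(small_translated_net, target,
                                  duration=2e4, seed=11)
        res = small_translated_net.run(2e4, seed=11)
        seq = extract_states(res.spikes, small_translated_net.tau_ref,
                             (0.0, 2e4),
                             neuron_ids=small_translated_net.sampling_ids)
        manual = dkl(empirical_joint(seq), target_joint(target))
        assert exp.final == pytest.approx(manual, rel=1e-12)

    def test_bit_for_bit_reproducibility(self, small_translated_net):
        target = random_target(5, seed=3)
        a = sampling_experiment(small_translated_net, target, duration=5e3,
                                seed=2)
        b = sampling_experiment(small_translated_net, target, duration=5e3,
                                seed=2)
        assert np.array_equal(a.metric, b.metric)


class TestInferenceExperiment:
    def test_free_subspace_has_eight_states(self, small_translated_net):
        target = random_target(5, seed=3)
        exp = inference_experiment(small_translated_net, target,
                                   clamp={0: 0, 1: 1}, duration=5e3, seed=4)
        cond_table_size = 2 ** 3
        assert exp.config["clamp"] == {0: 0, 1: 1}
        # the conditional it compares against covers the 3 free units
        from lifsampler import conditional_joint
        assert conditional_joint(target, {0: 0, 1: 1}).p.size == cond_table_size

    def test_clamped_units_follow_their_values(self, small_translated_net):
        target = random_target(5, seed=3)
        exp = inference_experiment(small_translated_net, target,
                                   clamp={0: 0, 1: 1}, duration=1e4, seed=5)
        occ = exp.extra["clamp_occupancy"]
        assert occ[0] < 0.1
        assert occ[1] > 0.9

    def test_clamping_all_units_rejected(self, small_translated_net):
        target = random_target(5, seed=3)
        with pytest.raises(ValueError):
            inference_experiment(small_translated_net, target,
                                 clamp={k: 0 for k in range(5)},
                                 duration=1e3)


class TestClassify:
    def test_silent_label_layer_flagged_as_error(self):
        """All-zero weights and zero-rate noise leave every neuron silent:
        predictions are -1, flagged, and counted as errors."""
        snet = build_hierarchical_network(4, 2, 2,
                                          noise=PoissonSource(rate=0.0))
        imgs = np.zeros((2, 4), dtype=np.uint8)

        # image clamp keeps visible busy but labels receive nothing
        def tiny_classify():
            from lifsampler.experiments import _layer_ids
            return classify(snet, imgs, labels=np.array([0, 1]),
                            present_ms=200.0, seed=1)

        exp = tiny_classify()
        assert list(exp.extra["predictions"]) == [-1, -1]
        assert exp.extra["silent"] == [0, 1]
        assert exp.final == 1.0

    def test_tie_breaks_to_lowest_label_and_is_logged(self):
        """Two label units with identical strong biases and no noise fire
        identically: the tie resolves to label 0 and is logged."""
        snet = build_hierarchical_network(4, 2, 2,
                                          noise=PoissonSource(rate=0.0))
        n = 8
        b = np.zeros(n)
        b[6] = b[7] = 12.0  # both label units strongly driven
        snet.set_weights(np.zeros((n, n)), b)
        imgs = np.zeros((1, 4), dtype=np.uint8)
        exp = classify(snet, imgs, labels=np.array([1]), present_ms=200.0,
                       seed=1)
        assert list(exp.extra["predictions"]) == [0]
        assert exp.extra["ties"] == [0]
        assert exp.final == 1.0

    def test_zero_presentation_window_rejected(self, small_translated_net):
        with pytest.raises(ValueError):
            classify(small_translated_net, np.zeros((1, 5)), present_ms=0.0)


class TestPatternComplete:
    def test_quarter_occlusion_masks_36_pixels(self):
        snet = build_hierarchical_network(144, 4, 2, noise=PoissonSource())
        data = make_synthetic_dataset(2, 2, 0.0, seed=1)
        exp = pattern_complete(snet, data.images[:2], scheme="salt&pepper",
                               fraction=0.25, present_ms=50.0, seed=2)
        for mask in exp.extra["masks"]:
            assert mask.mask.sum() == 36

    def test_perfect_reconstruction_gives_zero_mse(self):
        """A silent network reconstructs all-zero occluded pixels of an
        all-zero image exactly: MSE = 0 at every evaluation time."""
        snet = build_hierarchical_network(144, 2, 2,
                                          noise=PoissonSource(rate=0.0))
        # pin every unit firmly off so the occluded pixels reproduce the
        # all-zero image exactly
        snet.set_weights(np.zeros((148, 148)), np.full(148, -15.0))
        img = np.zeros((1, 144), dtype=np.uint8)
        exp = pattern_complete(snet, img, present_ms=100.0, seed=3)
        # after the pre-image scramble transient has left the trailing
        # filter window, reconstruction is exact
        settled = exp.times >= 25.0
        np.testing.assert_allclose(exp.metric[settled], 0.0)

    def test_untrained_network_sits_at_chance_level(self):
        """Random digital weights on balanced images: long-run MSE of the
        instantaneous states ~ 0.5, the Bernoulli(1/2) chance level."""
        data = make_synthetic_dataset(3, 10, 0.05, seed=5)
        snet = build_hierarchical_network(144, 60, 3)
        rng = np.random.default_rng(2)
        n = 207
        w = np.zeros((n, n))
        for (i, j) in snet.connections:
            w[i, j] = w[j, i] = float(rng.integers(-15, 16))
        snet.set_weights(w, rng.integers(-15, 16, size=n).astype(float))
        exp = pattern_complete(snet, data.images[:8], filter_ms=0.0,
                               present_ms=400.0, seed=3)
        long_run = exp.metric[exp.metric.size // 2:].mean()
        assert long_run == pytest.approx(0.5, abs=0.05)

    def test_invalid_fraction_rejected(self, small_translated_net):
        with pytest.raises(ValueError):
            pattern_complete(small_translated_net, np.zeros((1, 5)),
                             fraction=1.5)


def steerable_two_mode_network():
    """Hand-constructed 8-4-2 network whose label layer deterministically
    selects one of two complementary visible patterns."""
    snet = build_hierarchical_network(8, 4, 2, noise=PoissonSource(),
                                      label_multapse=3)
    n = 14
    w = np.zeros((n, n))
    vis, hid, lab = range(8), range(8, 12), range(12, 14)
    for h in hid:
        group = 0 if h < 10 else 1
        for v in vis:
            in_first_half = v < 4
            w[v, h] = w[h, v] = 2.0 if (in_first_half == (group == 0)) else -2.0
        for l in lab:
            w[h, l] = w[l, h] = 10.0 if (l - 12) == group else -10.0
    b = np.concatenate([np.full(8, -1.0), np.full(4, -1.0), np.zeros(2)])
    snet.set_weights(w, b)
    return snet


class TestGuidedDream:
    def test_snapshot_count_and_one_hot_clamp(self):
        snet = steerable_two_mode_network()
        exp = guided_dream(snet, [0, 1, 0], per_label_ms=300.0,
                           snapshots_per_segment=4, seed=5)
        assert exp.extra["snapshots"].shape == (3, 4, 8)
        # exactly one label unit occupied per segment
        occ = exp.extra["label_occupancy"]
        assert np.all(occ.max(axis=1) > 0.9)
        assert np.all(np.sort(occ, axis=1)[:, 0] < 0.1)

    def test_label_steers_generated_pattern(self):
        """Class-conditional generation: the two label clamps produce
        complementary visible patterns (large Hamming distance between the
        thresholded per-class means)."""
        snet = steerable_two_mode_network()
        exp = guided_dream(snet, [0, 1, 0, 1], per_label_ms=400.0, seed=6)
        snaps = exp.extra["snapshots"]
        mean0 = snaps[[0, 2]].reshape(-1, 8).mean(axis=0) > 0.5
        mean1 = snaps[[1, 3]].reshape(-1, 8).mean(axis=0) > 0.5
        assert np.sum(mean0 != mean1) >= 5  # near-complementary patterns

    def test_non_one_hot_schedule_rejected(self):
        snet = steerable_two_mode_network()
        with pytest.raises(ValueError):
            guided_dream(snet, [2], per_label_ms=100.0)
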