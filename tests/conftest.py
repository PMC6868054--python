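"""Shared fixtures: small networks, and session-scoped trained ensembles.

The expensive wake-sleep training runs are session fixtures so the
target-distribution, convergence, inference and discretization checks share
one ensemble instead of retraining.
"""

from __future__ import annotations

import numpy as np
import pytest

from lifsampler import (
    PoissonSource,
    TrainingConfig,
    VariabilityModel,
    build_sampling_network,
    random_target,
    train_to_target,
)

N_ENSEMBLE = 5
TRAIN_ITERATIONS = 300
SAMPLING_MS = 2e4
TEST_RUN_MS = 1e5


@pytest.fixture(scope="session")
def trained_poisson_ensemble():
    """Five 5-unit networks trained on random Beta-scheme targets.

    Scaled protocol: 300 iterations of 2e4 ms sleep sampling, learning rate
    1.0, momentum 0.6, 4-bit weights, default substrate variability,
    private 300 Hz Poisson noise.
    """
    out = []
    for k in range(N_ENSEMBLE):
        target = random_target(5, seed=100 + k)
        cfg = TrainingConfig(eta=1.0, momentum=0.6,
                             iterations=TRAIN_ITERATIONS,
                             sampling_ms=SAMPLING_MS, seed=200 + k,
                             keep_snapshots=True)
        res = train_to_target(target, cfg, noise=PoissonSource(),
                              substrate=VariabilityModel(),
                              substrate_seed=300 + k)
        out.append((target, res))
    return out


@pytest.fixture(scope="session")
def single_unit_network():
    """One Poisson-driven sampling unit, no variability."""
    return build_sampling_network(1, noise=PoissonSource())
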