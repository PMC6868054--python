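"""Stochasticity backends for the sampling network.

Two interchangeable sources drive the sampling neurons into their stochastic
high-conductance regime: ideal private Poisson spike trains (the benchmark,
generated off-network) and a sparse recurrent random network (RN) of
inhibitory neurons with a suprathreshold leak potential, which produces
deterministic, weakly correlated background activity on the same substrate.
Sampling neurons receive a fixed number of excitatory and inhibitory
projections drawn from the RN population; the synapse type is assigned per
connection, independently of the RN neurons' internal inhibitory role.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lif_core import (
    INH,
    EXC,
    NetworkDefinition,
    PortProjection,
    RANDOM_NETWORK_NEURON,
    SpikeTrain,
    SynapseSpec,
)

__all__ = [
    "PoissonSource",
    "RandomNetworkSpec",
    "poisson_train",
    "build_random_network",
    "noise_statistics",
]


@dataclass
class PoissonSource:
    """Private Poisson noise, one excitatory and one inhibitory train per neuron."""

    rate: float = 300.0  # Hz per synapse type
    weight_exc: float = 20.0  # nS
    weight_inh: float = 20.0  # nS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be non-negative")


@dataclass
class RandomNetworkSpec:
    """Sparse recurrent inhibitory random network used as a noise source.

    ``w_rn`` is the RN-internal synaptic weight in digital (4-bit) units;
    projections onto sampling neurons default to the same digital value.
    """

    n_r: int = 200
    k_rn: int = 20  # within-population in-degree
    k_noise: int = 15  # per-type in-degree onto each sampling neuron
    w_rn: float = 10.0  # digital units
    w_noise: float | None = None  # digital units, defaults to w_rn
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.k_rn < self.n_r:
            raise ValueError("require 0 < k_rn < n_r")
        if self.k_noise > self.n_r:
            raise ValueError("k_noise cannot exceed n_r")


def poisson_train(rate: float, duration: float, seed: int,
                  source: int = 0) -> SpikeTrain:
    """Homogeneous Poisson spike train on [0, duration) ms."""
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * duration / 1e3)
    times = np.sort(rng.uniform(0.0, duration, n))
    return SpikeTrain(times, np.full(n, source, dtype=np.int64))


def build_random_network(spec: RandomNetworkSpec, sampling_ids: list[int],
                         net: NetworkDefinition, weight_scale: float,
                         seed: int | None = None) -> list[int]:
    """Append an RN and its projections onto ``sampling_ids`` to ``net``.

    Each RN neuron receives exactly ``k_rn`` inhibitory inputs from distinct
    other RN neurons (no self-connections); each sampling neuron receives
    exactly ``k_noise`` excitatory and ``k_noise`` inhibitory projections from
    randomly chosen RN neurons (without replacement per target and type).
    ``weight_scale`` converts digital weights to nS.  Returns the RN neuron
    ids.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rn_ids = [net.add_neuron(RANDOM_NETWORK_NEURON, role="random")
              for _ in range(spec.n_r)]
    j_rn = spec.w_rn * weight_scale
    for post in rn_ids:
        others = [i for i in rn_ids if i != post]
        pres = rng.choice(others, size=spec.k_rn, replace=False)
        for pre in pres:
            net.synapses.append(
                SynapseSpec(pre=int(pre), post=post, weight=j_rn, kind=INH)
            )
    w_noise = spec.w_noise if spec.w_noise is not None else spec.w_rn
    j_noise = w_noise * weight_scale
    for post in sampling_ids:
        for kind in (EXC, INH):
            pres = rng.choice(rn_ids, size=spec.k_noise, replace=False)
            for pre in pres:
                net.synapses.append(
                    SynapseSpec(pre=int(pre), post=post, weight=j_noise, kind=kind)
                )
    return rn_ids


def noise_statistics(trains: list[SpikeTrain], duration: float,
                     bin_ms: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-train firing rates (Hz) and pairwise Pearson correlations.

    Correlations are computed between spike counts in ``bin_ms`` bins.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_bins = int(duration / bin_ms)
    if n_bins < 1:
        raise ValueError("window shorter than one bin")
    counts = np.stack([
        np.histogram(t.times, bins=n_bins, range=(0.0, n_bins * bin_ms))[0]
        for t in trains
    ]).astype(float)
    rates = counts.sum(axis=1) / (n_bins * bin_ms / 1e3)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(counts)
    return rates, corr
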