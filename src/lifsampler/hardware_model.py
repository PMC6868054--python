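"""Emulation of analog-substrate constraints.

Three effects of the analog platform are modeled by their statistics rather
than their electronics: (i) synaptic weights are stored with 4-bit
resolution in paired excitatory/inhibitory synapses, so continuous weights
are deterministically rounded and clipped to integers in [0, 15]; (ii)
fixed-pattern variability — persistent neuron-to-neuron and
synapse-to-synapse parameter spread — multiplies conductances and synaptic
time constants by lognormal factors drawn once per substrate seed; (iii)
trial-to-trial variability of the analog parameter storage adds a fresh,
smaller lognormal perturbation on top of the fixed pattern at every
experiment run, leaving digital weights untouched.

The paper-level coefficients of variation of the substrate are not public;
the defaults here are configuration, not measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .lif_core import NetworkDefinition

__all__ = [
    "DigitalWeight",
    "VariabilityModel",
    "discretize_weight",
    "discretize_array",
    "apply_fixed_pattern",
    "trial_rewrite",
    "DIGITAL_MAX",
]

DIGITAL_MAX = 15


@dataclass(frozen=True)
class DigitalWeight:
    """A 4-bit paired synapse value; at most one member nonzero."""

    exc: int
    inh: int

    def __post_init__(self) -> None:
        if not (0 <= self.exc <= DIGITAL_MAX and 0 <= self.inh <= DIGITAL_MAX):
            raise ValueError("digital weights must lie in [0, 15]")
        if self.exc and self.inh:
            raise ValueError("at most one of exc/inh may be nonzero")

    @property
    def signed(self) -> int:
        return self.exc - self.inh


@dataclass
class VariabilityModel:
    """Relative spreads (coefficients of variation) of the analog substrate.

    ``cv_psp`` scales synaptic conductances (PSP heights), ``cv_tau_syn`` the
    synaptic time constants — both persistent per substrate seed.
    ``cv_trial`` is the much smaller run-to-run spread from rewriting the
    analog parameter storage; its default is calibrated so that the
    trial-to-trial standard deviation of a sampling unit's activation
    function is on the order of 0.1 Hz, the value reported for the physical
    substrate.
    """

    cv_psp: float = 0.2
    cv_tau_syn: float = 0.1
    cv_trial: float = 5e-4

    def __post_init__(self) -> None:
        if min(self.cv_psp, self.cv_tau_syn, self.cv_trial) < 0:
            raise ValueError("coefficients of variation must be >= 0")


def discretize_weight(w: float, unit_scale: float = 1.0) -> DigitalWeight:
    """Deterministic 4-bit discretization of a signed continuous weight.

    The magnitude (in units of ``unit_scale``) is rounded half-away-from-zero
    to the nearest integer and clipped to [0, 15]; the sign routes the value
    to the excitatory or inhibitory slot.
    """
    if unit_scale <= 0:
        raise ValueError("unit scale must be positive")
    if not math.isfinite(w):
        raise ValueError("weight must be finite")
    mag = min(int(math.floor(abs(w) / unit_scale + 0.5)), DIGITAL_MAX)
    if w >= 0:
        return DigitalWeight(exc=mag, inh=0)
    return DigitalWeight(exc=0, inh=mag)


def discretize_array(w, unit_scale: float = 1.0) -> np.ndarray:
    """Vectorized signed 4-bit discretization (half-away-from-zero, clipped)."""
    if unit_scale <= 0:
        raise ValueError("unit scale must be positive")
    w = np.asarray(w, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")
    mag = np.minimum(np.floor(np.abs(w) / unit_scale + 0.5), DIGITAL_MAX)
    return np.sign(w) * mag


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean lognormal multipliers with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def apply_fixed_pattern(net: NetworkDefinition, model: VariabilityModel,
                        seed: int) -> NetworkDefinition:
    """Imprint the persistent substrate identity onto a network.

    Multiplies synaptic conductances (including external-port projections,
    which pass through physical synapse circuits) by lognormal factors with
    CV ``cv_psp`` and per-neuron synaptic time constants by factors with CV
    ``cv_tau_syn``; the same seed reproduces the identical perturbed
    network.
    """
    out = net.copy()
    rng = np.random.default_rng(seed)
    m = len(out.synapses)
    n = out.n_neurons
    out.syn_gain = out.syn_gain * _lognormal_factors(rng, model.cv_psp, m)
    port_gain = {} if out.port_gain is None else dict(out.port_gain)
    for name in out.ports:
        base = port_gain.get(name, np.ones(len(out.ports[name])))
        port_gain[name] = base * _lognormal_factors(
            rng, model.cv_psp, len(out.ports[name]))
    out.port_gain = port_gain
    out.tau_syn_exc_gain = out.tau_syn_exc_gain * _lognormal_factors(
        rng, model.cv_tau_syn, n)
    out.tau_syn_inh_gain = out.tau_syn_inh_gain * _lognormal_factors(
        rng, model.cv_tau_syn, n)
    return out


def trial_rewrite(net: NetworkDefinition, model: VariabilityModel,
                  trial_seed: int) -> NetworkDefinition:
    """Fresh per-run analog-rewrite noise on top of the fixed pattern.

    Rewriting the analog parameter storage perturbs the per-neuron analog
    parameters — synaptic and membrane time constants get fresh lognormal
    factors with CV ``cv_trial``.  Digital SRAM weights (the ``weight``
    fields) and the synapse-circuit gains are untouched: digital weights are
    rewritten precisely, which is why biases are implemented via synaptic
    weights in the first place.  Apply to the fixed-pattern network each run
    so trial noise does not accumulate.
    """
    out = net.copy()
    rng = np.random.default_rng(trial_seed)
    n = out.n_neurons
    out.tau_syn_exc_gain = out.tau_syn_exc_gain * _lognormal_factors(
        rng, model.cv_trial, n)
    out.tau_syn_inh_gain = out.tau_syn_inh_gain * _lognormal_factors(
        rng, model.cv_trial, n)
    out.tau_mem_gain = out.tau_mem_gain * _lognormal_factors(
        rng, model.cv_trial, n)
    return out
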