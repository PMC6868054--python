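"""Time-stepped simulation of leaky integrate-and-fire neurons.

The neuron model is the conductance-based LIF with exponential synaptic
kernels:

    C_m du/dt = -g_l (u - E_leak) - g_exc(t) (u - E_exc) - g_inh(t) (u - E_inh)

outside refractory windows; after a threshold crossing at ``t_sp`` the
membrane is clamped to ``V_reset`` on ``[t_sp, t_sp + tau_ref)``.  Each
presynaptic spike at ``t_sp`` contributes a conductance kernel

    g_syn(t) = J * exp(-(t - t_sp - d) / tau_syn) * theta(t - t_sp - d)

and kernels of successive spikes superpose linearly.  Integration uses
exponential Euler for the membrane and exact exponential decay for the
conductance state variables; spike times are recorded on the post-step
boundary (the bias of this convention vanishes as dt -> 0 and is covered by
a convergence test).

All times are in biological-time milliseconds, potentials in mV,
capacitances in nF and conductances in nS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "NeuronParameters",
    "SynapseSpec",
    "PortProjection",
    "NetworkDefinition",
    "SpikeTrain",
    "MembraneTrace",
    "SimulationResult",
    "simulate",
    "conductance_at",
    "suprathreshold_isi",
    "psp_peak",
    "SAMPLING_NEURON",
    "BIAS_NEURON",
    "RANDOM_NETWORK_NEURON",
]

EXC = "exc"
INH = "inh"


@dataclass(frozen=True)
class NeuronParameters:
    """Per-neuron parameters of the conductance-based LIF model.

    The leak conductance is derived as ``g_l = C_mem / tau_mem``.
    """

    V_reset: float  # mV
    E_leak: float  # mV
    V_thresh: float  # mV
    E_inh: float  # mV
    E_exc: float  # mV
    tau_ref: float  # ms
    tau_mem: float  # ms
    C_mem: float  # nF
    tau_syn_exc: float  # ms
    tau_syn_inh: float  # ms

    def __post_init__(self) -> None:
        if not (self.tau_ref > 0 and self.tau_mem > 0 and self.C_mem > 0):
            raise ValueError("tau_ref, tau_mem and C_mem must be positive")
        if not (self.tau_syn_exc > 0 and self.tau_syn_inh > 0):
            raise ValueError("synaptic time constants must be positive")
        if not (self.E_inh < self.V_thresh < self.E_exc):
            raise ValueError("require E_inh < V_thresh < E_exc")
        for name in ("tau_ref", "tau_mem", "tau_syn_exc", "tau_syn_inh"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def g_leak(self) -> float:
        """Leak conductance in nS."""
        return 1e3 * self.C_mem / self.tau_mem  # nF/ms -> nS


# Working points used throughout: sampling neurons rest at threshold and are
# driven stochastic by background input; bias and random-network neurons have
# a suprathreshold leak potential and fire regularly on their own.
SAMPLING_NEURON = NeuronParameters(
    V_reset=-35.0, E_leak=-20.0, V_thresh=-20.0, E_inh=-100.0, E_exc=60.0,
    tau_ref=4.0, tau_mem=7.0, C_mem=0.2, tau_syn_exc=8.0, tau_syn_inh=8.0,
)
BIAS_NEURON = NeuronParameters(
    V_reset=-30.0, E_leak=60.0, V_thresh=-20.0, E_inh=-100.0, E_exc=60.0,
    tau_ref=1.5, tau_mem=7.0, C_mem=0.2, tau_syn_exc=5.0, tau_syn_inh=5.0,
)
RANDOM_NETWORK_NEURON = NeuronParameters(
    V_reset=-60.0, E_leak=-10.0, V_thresh=-20.0, E_inh=-100.0, E_exc=60.0,
    tau_ref=4.0, tau_mem=7.0, C_mem=0.2, tau_syn_exc=8.0, tau_syn_inh=8.0,
)


@dataclass
class SynapseSpec:
    """A single synapse.

    ``kind`` selects the reversal potential (``"exc"`` -> E_exc, ``"inh"`` ->
    E_inh) and ``tau_syn`` defaults to the postsynaptic neuron's matching
    synaptic time constant.  ``multapse_group`` marks intentional duplicate
    (pre, post, kind) entries.
    """

    pre: int
    post: int
    weight: float  # nS, >= 0
    kind: str = EXC
    delay: float = 1.0  # ms
    tau_syn: float | None = None
    multapse_group: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in (EXC, INH):
            raise ValueError(f"kind must be 'exc' or 'inh', got {self.kind!r}")
        if self.weight < 0:
            raise ValueError("synaptic weight must be non-negative")
        if self.delay < 0:
            raise ValueError("synaptic delay must be non-negative")


@dataclass
class PortProjection:
    """Projection of a named external spike port onto one neuron."""

    post: int
    weight: float  # nS
    kind: str = EXC
    delay: float = 1.0  # ms


@dataclass
class SpikeTrain:
    """Timestamped spike events ``(time_ms, source_id)``, non-decreasing in time."""

    times: np.ndarray
    sources: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.sources = np.asarray(self.sources, dtype=np.int64)
        if self.times.shape != self.sources.shape:
            raise ValueError("times and sources must have the same length")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be non-decreasing")
        if self.times.size and self.times[0] < 0:
            raise ValueError("spike times must be non-negative")

    @classmethod
    def from_times(cls, times, source: int = 0) -> "SpikeTrain":
        times = np.sort(np.asarray(times, dtype=float))
        return cls(times, np.full(times.shape, source, dtype=np.int64))

    @classmethod
    def empty(cls) -> "SpikeTrain":
        return cls(np.empty(0), np.empty(0, dtype=np.int64))

    @classmethod
    def merge(cls, trains: list["SpikeTrain"]) -> "SpikeTrain":
        if not trains:
            return cls.empty()
        times = np.concatenate([t.times for t in trains])
        sources = np.concatenate([t.sources for t in trains])
        order = np.argsort(times, kind="stable")
        return cls(times[order], sources[order])

    def of(self, source: int) -> np.ndarray:
        """Spike times of one source."""
        return self.times[self.sources == source]

    @property
    def n_events(self) -> int:
        return int(self.times.size)

    def counts(self, n_sources: int) -> np.ndarray:
        return np.bincount(self.sources, minlength=n_sources)


@dataclass
class MembraneTrace:
    """Membrane potential of one neuron sampled on the integration grid."""

    neuron: int
    times: np.ndarray  # ms
    u: np.ndarray  # mV


@dataclass
class SimulationResult:
    spikes: SpikeTrain
    traces: list[MembraneTrace] = field(default_factory=list)
    duration: float = 0.0
    dt: float = 0.0


@dataclass
class NetworkDefinition:
    """Neurons, synapses and external input ports of one network.

    ``roles`` tags each neuron (sampling | bias | random | visible | hidden |
    label).  ``syn_gain`` and the per-neuron ``tau_syn_*_gain`` arrays carry
    the multiplicative analog perturbations of the substrate model; the
    effective conductance of synapse ``k`` is ``weight_k * syn_gain[k]``.
    """

    neurons: list[NeuronParameters] = field(default_factory=list)
    roles: list[str] = field(default_factory=list)
    synapses: list[SynapseSpec] = field(default_factory=list)
    ports: dict[str, list[PortProjection]] = field(default_factory=dict)
    syn_gain: np.ndarray | None = None
    port_gain: dict[str, np.ndarray] | None = None
    tau_syn_exc_gain: np.ndarray | None = None
    tau_syn_inh_gain: np.ndarray | None = None
    tau_mem_gain: np.ndarray | None = None

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    def add_neuron(self, params: NeuronParameters, role: str = "sampling") -> int:
        self.neurons.append(params)
        self.roles.append(role)
        return len(self.neurons) - 1

    def neurons_with_role(self, role: str) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == role]

    def ensure_gains(self) -> None:
        m = len(self.synapses)
        n = self.n_neurons
        if self.syn_gain is None or len(self.syn_gain) != m:
            self.syn_gain = np.ones(m)
        if self.tau_syn_exc_gain is None or len(self.tau_syn_exc_gain) != n:
            self.tau_syn_exc_gain = np.ones(n)
        if self.tau_syn_inh_gain is None or len(self.tau_syn_inh_gain) != n:
            self.tau_syn_inh_gain = np.ones(n)
        if self.tau_mem_gain is None or len(self.tau_mem_gain) != n:
            self.tau_mem_gain = np.ones(n)

    def validate(self) -> None:
        n = self.n_neurons
        if len(self.roles) != n:
            raise ValueError("one role per neuron required")
        seen: set[tuple[int, int, str]] = set()
        for s in self.synapses:
            if not (0 <= s.pre < n and 0 <= s.post < n):
                raise ValueError(f"synapse references missing neuron: {s}")
            key = (s.pre, s.post, s.kind)
            if key in seen and s.multapse_group is None:
                raise ValueError(
                    f"duplicate synapse {key} without multapse_group tag"
                )
            seen.add(key)
        for name, projs in self.ports.items():
            for p in projs:
                if not 0 <= p.post < n:
                    raise ValueError(f"port {name!r} targets missing neuron {p.post}")

    def copy(self) -> "NetworkDefinition":
        self.ensure_gains()
        return NetworkDefinition(
            neurons=list(self.neurons),
            roles=list(self.roles),
            synapses=[replace(s) for s in self.synapses],
            ports={k: [replace(p) for p in v] for k, v in self.ports.items()},
            syn_gain=self.syn_gain.copy(),
            port_gain=None if self.port_gain is None
            else {k: v.copy() for k, v in self.port_gain.items()},
            tau_syn_exc_gain=self.tau_syn_exc_gain.copy(),
            tau_syn_inh_gain=self.tau_syn_inh_gain.copy(),
            tau_mem_gain=self.tau_mem_gain.copy(),
        )


def conductance_at(t, spikes: SpikeTrain, J: float, tau_syn: float,
                   d: float = 0.0) -> np.ndarray | float:
    """Exponential-kernel conductance at time(s) ``t`` from a spike train.

    g(t) = sum_sp J * exp(-(t - t_sp - d)/tau_syn) * theta(t - t_sp - d)
    """
    if tau_syn <= 0:
        raise ValueError("tau_syn must be positive")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    dt_all = t_arr[:, None] - spikes.times[None, :] - d
    g = np.where(dt_all >= 0, J * np.exp(-np.maximum(dt_all, 0.0) / tau_syn), 0.0)
    out = g.sum(axis=1)
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def suprathreshold_isi(p: NeuronParameters) -> float:
    """Closed-form inter-spike interval of a suprathreshold-leak LIF neuron.

    ISI = tau_ref + tau_mem * ln[(E_leak - V_reset)/(E_leak - V_thresh)];
    requires E_leak > V_thresh.
    """
    if p.E_leak <= p.V_thresh:
        raise ValueError("neuron is not suprathreshold (E_leak <= V_thresh)")
    return p.tau_ref + p.tau_mem * math.log(
        (p.E_leak - p.V_reset) / (p.E_leak - p.V_thresh)
    )


def psp_peak(p: NeuronParameters, J: float = 1.0, kind: str = EXC) -> float:
    """Small-signal PSP peak height (mV) of a single spike at rest.

    Passive response of the membrane at E_leak to one exponential conductance
    kernel of weight ``J`` (nS); used to anchor the digital-weight ->
    conductance scale.
    """
    tau_s = p.tau_syn_exc if kind == EXC else p.tau_syn_inh
    e_rev = p.E_exc if kind == EXC else p.E_inh
    tau_m = p.tau_mem
    drive = (e_rev - p.E_leak) * J / (1e3 * p.C_mem)  # mV/ms per (nS·...) step
    if abs(tau_s - tau_m) < 1e-9:
        t_peak = tau_m
        h = drive * t_peak * math.exp(-t_peak / tau_m)
    else:
        a = tau_s * tau_m / (tau_s - tau_m)
        t_peak = a * math.log(tau_s / tau_m)
        h = drive * a * (math.exp(-t_peak / tau_s) - math.exp(-t_peak / tau_m))
    return abs(h)


# ---------------------------------------------------------------------------
# integration kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _lif_kernel(nsteps, dt, n,
                vreset, eleak, vth, einh, eexc, gl, cm, tref_steps,
                dec_e, dec_i,
                out_ptr, out_post, out_q, out_kind, out_dstep,
                ev_step, ev_post, ev_q, ev_kind, init_u,
                rec_idx, traces,
                sp_time, sp_src, cap):
    D = 2
    for k in range(out_dstep.size):
        if out_dstep[k] + 2 > D:
            D = out_dstep[k] + 2
    ring_e = np.zeros((D, n))
    ring_i = np.zeros((D, n))
    ge = np.zeros(n)
    gi = np.zeros(n)
    u = init_u.copy()
    refrac = np.zeros(n, dtype=np.int64)
    nspikes = 0
    ev_p = 0
    nrec = rec_idx.size
    for r in range(nrec):
        traces[r, 0] = u[rec_idx[r]]
    for t in range(nsteps):
        slot = t % D
        for i in range(n):
            ge[i] += ring_e[slot, i]
            gi[i] += ring_i[slot, i]
            ring_e[slot, i] = 0.0
            ring_i[slot, i] = 0.0
        while ev_p < ev_step.size and ev_step[ev_p] == t:
            if ev_kind[ev_p] == 0:
                ge[ev_post[ev_p]] += ev_q[ev_p]
            else:
                gi[ev_post[ev_p]] += ev_q[ev_p]
            ev_p += 1
        for i in range(n):
            if refrac[i] > 0:
                refrac[i] -= 1
                u[i] = vreset[i]
            else:
                gtot = gl[i] + ge[i] + gi[i]
                uinf = (gl[i] * eleak[i] + ge[i] * eexc[i] + gi[i] * einh[i]) / gtot
                u[i] = uinf + (u[i] - uinf) * math.exp(-dt * gtot / cm[i])
                if u[i] > vth[i]:
                    if nspikes < cap:
                        sp_time[nspikes] = (t + 1) * dt
                        sp_src[nspikes] = i
                        nspikes += 1
                    refrac[i] = tref_steps[i]
                    u[i] = vreset[i]
                    for k in range(out_ptr[i], out_ptr[i + 1]):
                        tgt = (t + 1 + out_dstep[k]) % D
                        if out_kind[k] == 0:
                            ring_e[tgt, out_post[k]] += out_q[k]
                        else:
                            ring_i[tgt, out_post[k]] += out_q[k]
        for i in range(n):
            ge[i] *= dec_e[i]
            gi[i] *= dec_i[i]
        for r in range(nrec):
            traces[r, t + 1] = u[rec_idx[r]]
    return nspikes


def _compile_arrays(net: NetworkDefinition, dt: float):
    net.ensure_gains()
    n = net.n_neurons
    vreset = np.array([p.V_reset for p in net.neurons])
    eleak = np.array([p.E_leak for p in net.neurons])
    vth = np.array([p.V_thresh for p in net.neurons])
    einh = np.array([p.E_inh for p in net.neurons])
    eexc = np.array([p.E_exc for p in net.neurons])
    cm = np.array([p.C_mem for p in net.neurons]) * 1e3  # nF -> nS*ms
    gl = np.array([p.g_leak for p in net.neurons]) / net.tau_mem_gain
    tref_steps = np.array(
        [int(round(p.tau_ref / dt)) for p in net.neurons], dtype=np.int64
    )
    tse = np.array([p.tau_syn_exc for p in net.neurons]) * net.tau_syn_exc_gain
    tsi = np.array([p.tau_syn_inh for p in net.neurons]) * net.tau_syn_inh_gain
    dec_e = np.exp(-dt / tse)
    dec_i = np.exp(-dt / tsi)

    m = len(net.synapses)
    pre = np.array([s.pre for s in net.synapses], dtype=np.int64).reshape(m)
    order = np.argsort(pre, kind="stable") if m else np.empty(0, dtype=np.int64)
    out_post = np.array(
        [net.synapses[k].post for k in order], dtype=np.int64
    )
    out_q = np.array(
        [net.synapses[k].weight * net.syn_gain[k] for k in order]
    )
    out_kind = np.array(
        [0 if net.synapses[k].kind == EXC else 1 for k in order], dtype=np.int64
    )
    out_dstep = np.array(
        [int(round(net.synapses[k].delay / dt)) for k in order], dtype=np.int64
    )
    out_ptr = np.zeros(n + 1, dtype=np.int64)
    if m:
        np.add.at(out_ptr[1:], pre[order], 1)
    out_ptr = np.cumsum(out_ptr)
    return (vreset, eleak, vth, einh, eexc, gl, cm, tref_steps,
            dec_e, dec_i, out_ptr, out_post, out_q, out_kind, out_dstep)


def _compile_events(net: NetworkDefinition, inputs: dict[str, SpikeTrain],
                    dt: float, nsteps: int):
    steps, posts, qs, kinds = [], [], [], []
    for name, train in inputs.items():
        if name not in net.ports:
            raise ValueError(f"unknown input port {name!r}")
        gains = None
        if net.port_gain is not None and name in net.port_gain:
            gains = net.port_gain[name]
        for j, proj in enumerate(net.ports[name]):
            arr = np.round((train.times + proj.delay) / dt).astype(np.int64)
            keep = arr < nsteps
            arr = arr[keep]
            g = gains[j] if gains is not None else 1.0
            steps.append(arr)
            posts.append(np.full(arr.size, proj.post, dtype=np.int64))
            qs.append(np.full(arr.size, proj.weight * g))
            kinds.append(
                np.full(arr.size, 0 if proj.kind == EXC else 1, dtype=np.int64)
            )
    if steps:
        ev_step = np.concatenate(steps)
        ev_post = np.concatenate(posts)
        ev_q = np.concatenate(qs)
        ev_kind = np.concatenate(kinds)
        order = np.argsort(ev_step, kind="stable")
        return ev_step[order], ev_post[order], ev_q[order], ev_kind[order]
    return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64),
            np.empty(0), np.empty(0, dtype=np.int64))


def simulate(net: NetworkDefinition, inputs: dict[str, SpikeTrain] | None = None,
             duration: float = 1000.0, dt: float = 0.1, seed: int = 0,
             record: list[int] | None = None,
             init_u: np.ndarray | None = None) -> SimulationResult:
    """Integrate the network for ``duration`` ms and return emitted spikes.

    The dynamics are deterministic given the inputs; ``seed`` is accepted for
    interface uniformity with stochastic components and does not alter the
    result.  ``record`` lists neuron ids whose membrane traces are sampled on
    the integration grid.  ``init_u`` overrides the initial membrane
    potentials (default: every neuron starts at its leak potential).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    net.validate()
    inputs = inputs or {}
    tmin = min(
        min(p.tau_syn_exc, p.tau_syn_inh, p.tau_mem, p.tau_ref)
        for p in net.neurons
    )
    if dt > tmin / 4 + 1e-12:
        raise ValueError(
            f"dt={dt} ms too coarse: must satisfy dt <= min(tau)/4 = "
            f"{tmin / 4:.4g} ms for the smallest time constant in the network"
        )
    nsteps = int(round(duration / dt))
    arrays = _compile_arrays(net, dt)
    ev = _compile_events(net, inputs, dt, nsteps)
    tref_steps = arrays[7]
    cap = int(np.sum(nsteps / np.maximum(tref_steps, 1)) + 2 * net.n_neurons)
    sp_time = np.empty(cap)
    sp_src = np.empty(cap, dtype=np.int64)
    rec_idx = np.array(record if record else [], dtype=np.int64)
    traces_arr = np.empty((rec_idx.size, nsteps + 1))
    if init_u is None:
        init_u = arrays[1].copy()  # leak potentials
    else:
        init_u = np.asarray(init_u, dtype=float).copy()
        if init_u.shape != (net.n_neurons,):
            raise ValueError("init_u must have one entry per neuron")
    nspikes = _lif_kernel(nsteps, dt, net.n_neurons, *arrays, *ev, init_u,
                          rec_idx, traces_arr, sp_time, sp_src, cap)
    spikes = SpikeTrain(sp_time[:nspikes].copy(), sp_src[:nspikes].copy())
    traces = [
        MembraneTrace(int(i), np.arange(nsteps + 1) * dt, traces_arr[r])
        for r, i in enumerate(rec_idx)
    ]
    return SimulationResult(spikes=spikes, traces=traces,
                            duration=duration, dt=dt)
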