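"""Sampling-unit assembly, activation-function calibration and translation.

A sampling unit is a pair of neurons: a sampling neuron encoding the binary
random variable and a bias neuron with a suprathreshold leak potential whose
regular firing drives the sampling neuron through a paired
excitatory/inhibitory synapse.  The signed digital bias weight ``w_b``
selects which member of the pair is active.  Driven by a noise backend, the
mean firing rate of the sampling neuron as a function of ``w_b`` is
approximately logistic,

    <nu>(w_b) = nu0 / (1 + exp(-(w_b - wb0)/s)),

and fitting this form per unit yields the translation between the
dimensionless Boltzmann parameters (W, b) and digital synaptic weights:
``w_b = wb0 + s * b`` for biases and ``w_ij = W_ij sqrt(s_i s_j) kappa`` for
couplings, with a single global coupling factor ``kappa`` derived from
mean-conductance equivalence between the bias drive and a presynaptic
on-state (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .lif_core import (
    BIAS_NEURON,
    EXC,
    INH,
    NetworkDefinition,
    PortProjection,
    SAMPLING_NEURON,
    SpikeTrain,
    SynapseSpec,
    psp_peak,
    simulate,
    suprathreshold_isi,
)
from .noise_sources import (
    PoissonSource,
    RandomNetworkSpec,
    build_random_network,
    poisson_train,
)

__all__ = [
    "ActivationFit",
    "SamplingUnit",
    "SamplingNetwork",
    "build_sampling_network",
    "measure_activation",
    "fit_activation",
    "translate_parameters",
    "logistic_rate",
    "default_weight_scale",
    "coupling_kappa",
    "DIGITAL_MAX",
    "CLAMP_RATE_HZ",
    "CLAMP_MULTAPSE",
]

DIGITAL_MAX = 15  # 4-bit single-synapse weight ceiling
CLAMP_RATE_HZ = 100.0  # per multapse member
CLAMP_MULTAPSE = 5
PSP_TARGET_MV = 3.0  # working point: PSP height of a unit digital weight


def default_weight_scale() -> float:
    """Conductance per digital weight unit (nS), anchored to a 3 mV PSP."""
    return PSP_TARGET_MV / psp_peak(SAMPLING_NEURON, 1.0, kind=EXC)


def coupling_kappa() -> float:
    """Digital coupling weight per (digital bias weight x unit abstract weight).

    Equates the mean conductance contributed per digital unit by the
    regularly firing bias neuron (rate nu_b, kernel time constant tau_syn)
    with the mean conductance contributed during a presynaptic on-state by a
    single spike (one spike per refractory period tau_ref).
    """
    nu_b = 1.0 / suprathreshold_isi(BIAS_NEURON)  # 1/ms
    tau_s = SAMPLING_NEURON.tau_syn_exc
    tau_r = SAMPLING_NEURON.tau_ref
    per_bias_unit = nu_b * tau_s
    per_coupling_unit = (tau_s / tau_r) * (1.0 - math.exp(-tau_r / tau_s))
    return per_bias_unit / per_coupling_unit


@dataclass
class ActivationFit:
    """Logistic activation parameters of one sampling unit."""

    nu0: float  # Hz, saturation rate
    wb0: float  # digital bias-weight units, midpoint
    s: float  # digital bias-weight units, width

    def __post_init__(self) -> None:
        if self.nu0 <= 0 or self.s <= 0:
            raise ValueError("nu0 and s must be positive")


@dataclass
class SamplingUnit:
    sampling_id: int
    bias_id: int
    bias_syn_exc: int  # synapse index in the network definition
    bias_syn_inh: int
    fit: ActivationFit | None = None


@dataclass
class SamplingNetwork:
    """A network of sampling units plus noise wiring and weight bookkeeping.

    Digital weights are signed floats; ``set_weights`` routes sign to the
    excitatory or inhibitory member of each synapse pair and applies the
    digital->conductance scale.  ``connections`` lists the unit pairs (i < j)
    realized as reciprocal synapse pairs.
    """

    net: NetworkDefinition
    units: list[SamplingUnit]
    connections: list[tuple[int, int]]
    # ordered (i,j) -> (excitatory synapse ids, inhibitory synapse ids);
    # lists longer than one form a multapse extending the 4-bit weight range
    coupling_syn: dict[tuple[int, int], tuple[list[int], list[int]]]
    weight_scale: float
    noise: PoissonSource | RandomNetworkSpec
    rn_ids: list[int] = field(default_factory=list)
    w_dig: np.ndarray | None = None
    b_dig: np.ndarray | None = None
    _net_fp: NetworkDefinition | None = None  # fixed-pattern substrate identity

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def sampling_ids(self) -> list[int]:
        return [u.sampling_id for u in self.units]

    @property
    def tau_ref(self) -> np.ndarray:
        return np.array(
            [self.net.neurons[u.sampling_id].tau_ref for u in self.units]
        )

    @property
    def w_max(self) -> np.ndarray:
        """Per-connection digital weight ceiling (15 x multapse size)."""
        n = self.n_units
        out = np.zeros((n, n))
        for (i, j), (exc, _) in self.coupling_syn.items():
            out[i, j] = DIGITAL_MAX * len(exc)
        return out

    def set_weights(self, w_dig: np.ndarray, b_dig: np.ndarray) -> None:
        """Install signed digital weights (couplings w_dig, biases b_dig).

        Multapse connections split the magnitude as evenly as possible over
        their member synapses (each still bounded by the 4-bit ceiling).
        """
        n = self.n_units
        w_dig = np.asarray(w_dig, dtype=float)
        b_dig = np.asarray(b_dig, dtype=float)
        if w_dig.shape != (n, n) or b_dig.shape != (n,):
            raise ValueError("weight shapes do not match the network")
        c = self.weight_scale
        syn = self.net.synapses
        for k, u in enumerate(self.units):
            syn[u.bias_syn_exc].weight = c * max(b_dig[k], 0.0)
            syn[u.bias_syn_inh].weight = c * max(-b_dig[k], 0.0)
        for (i, j), (exc_ids, inh_ids) in self.coupling_syn.items():
            w = w_dig[i, j]
            on_ids, off_ids = (exc_ids, inh_ids) if w >= 0 else (inh_ids, exc_ids)
            m = len(on_ids)
            mag = abs(w)
            if float(mag).is_integer():
                base, extra = int(mag) // m, int(mag) % m
                parts = [base + 1] * extra + [base] * (m - extra)
            else:
                parts = [mag / m] * m
            for kk, part in zip(on_ids, parts):
                syn[kk].weight = c * part
            for kk in off_ids:
                syn[kk].weight = 0.0
        self.w_dig = w_dig.copy()
        self.b_dig = b_dig.copy()

    def apply_substrate(self, model, substrate_seed: int) -> None:
        """Imprint a persistent fixed-pattern identity on the network."""
        from .hardware_model import apply_fixed_pattern

        self._net_fp = apply_fixed_pattern(self.net, model, substrate_seed)
        self.net = self._net_fp.copy()
        self.set_weights(self.w_dig, self.b_dig)

    def begin_trial(self, model, trial_seed: int) -> None:
        """Rewrite analog parameters for one run (fresh trial noise on top of
        the fixed pattern; digital weights untouched)."""
        from .hardware_model import trial_rewrite

        base = self._net_fp if self._net_fp is not None else self.net
        self.net = trial_rewrite(base, model, trial_seed)
        self.set_weights(self.w_dig, self.b_dig)

    def zero_directed(self, from_units) -> None:
        """Temporarily zero all coupling synapses whose source unit is in
        ``from_units`` (restore with ``set_weights``)."""
        from_units = set(from_units)
        for (a, b), (exc_ids, inh_ids) in self.coupling_syn.items():
            if a in from_units:
                for kk in exc_ids + inh_ids:
                    self.net.synapses[kk].weight = 0.0

    def noise_inputs(self, duration: float, seed: int) -> dict[str, SpikeTrain]:
        """Fresh external noise trains for one run (empty for the RN backend)."""
        if isinstance(self.noise, RandomNetworkSpec):
            return {}
        out: dict[str, SpikeTrain] = {}
        children = np.random.SeedSequence(seed).spawn(2 * self.n_units)
        for k in range(self.n_units):
            out[f"noise_exc_{k}"] = poisson_train(
                self.noise.rate, duration,
                int(children[2 * k].generate_state(1)[0] % (2 ** 31)))
            out[f"noise_inh_{k}"] = poisson_train(
                self.noise.rate, duration,
                int(children[2 * k + 1].generate_state(1)[0] % (2 ** 31)))
        return out

    def run(self, duration: float, seed: int, dt: float = 0.1,
            extra_inputs: dict[str, SpikeTrain] | None = None,
            record: list[int] | None = None):
        inputs = self.noise_inputs(duration, seed)
        if extra_inputs:
            inputs.update(extra_inputs)
        init_u = None
        if self.rn_ids:
            # desynchronize the deterministic random network: seeded random
            # initial potentials between reset and threshold
            rng = np.random.default_rng(np.random.SeedSequence([seed, 0x524E]))
            init_u = np.array([p.E_leak for p in self.net.neurons])
            for i in self.rn_ids:
                p = self.net.neurons[i]
                init_u[i] = rng.uniform(p.V_reset, p.V_thresh)
        return simulate(self.net, inputs, duration=duration, dt=dt,
                        seed=seed, record=record, init_u=init_u)


def build_sampling_network(
    n_units: int,
    noise: PoissonSource | RandomNetworkSpec | None = None,
    connections: list[tuple[int, int]] | None = None,
    shared_bias: bool = False,
    weight_scale: float | None = None,
    roles: list[str] | None = None,
    multapse: dict[tuple[int, int], int] | None = None,
    seed: int = 0,
) -> SamplingNetwork:
    """Assemble a sampling network with bias units, noise wiring and clamp ports.

    ``connections`` lists unit pairs (i, j), i < j, each realized by two
    directed excitatory/inhibitory synapse pairs; defaults to all-to-all.
    ``multapse`` maps a pair to a number of parallel synapses, extending its
    digital weight range beyond the single-synapse 4-bit ceiling.
    ``roles`` optionally tags the sampling neurons (visible/hidden/label).
    Every sampling neuron gets clamp ports ``clamp_exc_k``/``clamp_inh_k``
    whose projection weight is the single-synapse digital ceiling; the
    multapse structure of clamping lives in the injected spike trains.
    """
    if noise is None:
        noise = PoissonSource()
    c = default_weight_scale() if weight_scale is None else weight_scale
    net = NetworkDefinition()
    units: list[SamplingUnit] = []
    bias_shared = net.add_neuron(BIAS_NEURON, role="bias") if shared_bias else None
    for k in range(n_units):
        role = roles[k] if roles is not None else "sampling"
        sid = net.add_neuron(SAMPLING_NEURON, role=role)
        bid = bias_shared if shared_bias else net.add_neuron(BIAS_NEURON, role="bias")
        net.synapses.append(SynapseSpec(pre=bid, post=sid, weight=0.0, kind=EXC))
        k_exc = len(net.synapses) - 1
        net.synapses.append(SynapseSpec(pre=bid, post=sid, weight=0.0, kind=INH))
        k_inh = len(net.synapses) - 1
        units.append(SamplingUnit(sid, bid, k_exc, k_inh))
        net.ports[f"clamp_exc_{k}"] = [
            PortProjection(post=sid, weight=DIGITAL_MAX * c, kind=EXC)
        ]
        net.ports[f"clamp_inh_{k}"] = [
            PortProjection(post=sid, weight=DIGITAL_MAX * c, kind=INH)
        ]
    if connections is None:
        connections = [(i, j) for i in range(n_units) for j in range(i + 1, n_units)]
    multapse = multapse or {}
    coupling_syn: dict[tuple[int, int], tuple[list[int], list[int]]] = {}
    group_counter = 0
    for (i, j) in connections:
        if not (0 <= i < j < n_units):
            raise ValueError(f"connection ({i},{j}) must satisfy 0 <= i < j < n")
        m = int(multapse.get((i, j), 1))
        for a, b in ((i, j), (j, i)):
            exc_ids, inh_ids = [], []
            group = group_counter if m > 1 else None
            group_counter += 1
            for _ in range(m):
                net.synapses.append(SynapseSpec(
                    pre=units[a].sampling_id, post=units[b].sampling_id,
                    weight=0.0, kind=EXC, multapse_group=group))
                exc_ids.append(len(net.synapses) - 1)
                net.synapses.append(SynapseSpec(
                    pre=units[a].sampling_id, post=units[b].sampling_id,
                    weight=0.0, kind=INH, multapse_group=group))
                inh_ids.append(len(net.synapses) - 1)
            coupling_syn[(a, b)] = (exc_ids, inh_ids)
    rn_ids: list[int] = []
    if isinstance(noise, PoissonSource):
        for k, u in enumerate(units):
            net.ports[f"noise_exc_{k}"] = [
                PortProjection(post=u.sampling_id, weight=noise.weight_exc, kind=EXC)
            ]
            net.ports[f"noise_inh_{k}"] = [
                PortProjection(post=u.sampling_id, weight=noise.weight_inh, kind=INH)
            ]
    else:
        rn_ids = build_random_network(
            noise, [u.sampling_id for u in units], net, c, seed=seed
        )
    net.ensure_gains()
    net.validate()
    snet = SamplingNetwork(
        net=net, units=units, connections=list(connections),
        coupling_syn=coupling_syn, weight_scale=c, noise=noise, rn_ids=rn_ids,
    )
    snet.set_weights(np.zeros((n_units, n_units)), np.zeros(n_units))
    return snet


def logistic_rate(wb, nu0, wb0, s):
    return nu0 / (1.0 + np.exp(-(np.asarray(wb, dtype=float) - wb0) / s))


def measure_activation(snet: SamplingNetwork, wb_grid,
                       duration: float = 2e4, seed: int = 0,
                       dt: float = 0.1) -> np.ndarray:
    """Mean firing rate of every sampling unit at each bias weight.

    Couplings and all other bias inputs are zeroed, so all units are
    independent and measured simultaneously: one simulation per grid point,
    rate = spike count / duration.  Returns an array of shape
    (len(wb_grid), n_units) in Hz.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    wb_grid = np.asarray(wb_grid, dtype=float)
    if wb_grid.size == 0:
        raise ValueError("bias-weight grid must be non-empty")
    n = snet.n_units
    saved = (snet.w_dig.copy(), snet.b_dig.copy())
    rates = np.empty((wb_grid.size, n))
    try:
        for g, wb in enumerate(wb_grid):
            snet.set_weights(np.zeros((n, n)), np.full(n, wb))
            res = snet.run(duration, seed=seed + g, dt=dt)
            counts = res.spikes.counts(snet.net.n_neurons)
            rates[g] = counts[snet.sampling_ids] / (duration / 1e3)
    finally:
        snet.set_weights(*saved)
    return rates


def fit_activation(points) -> ActivationFit:
    """Least-squares logistic fit nu0/(1+exp(-(w_b-wb0)/s)) to (w_b, rate) pairs."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise ValueError("need >= 4 (w_b, rate) points")
    wb, nu = pts[:, 0], pts[:, 1]
    if np.ptp(nu) <= 0:
        raise ValueError("degenerate activation data: all rates equal")
    nu0_0 = max(nu.max(), 1e-6)
    wb0_0 = float(wb[np.argmin(np.abs(nu - nu0_0 / 2))])
    s_0 = max(np.ptp(wb) / 8.0, 1e-3)
    popt, _ = curve_fit(
        logistic_rate, wb, nu, p0=(nu0_0, wb0_0, s_0),
        bounds=([1e-9, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    return ActivationFit(nu0=float(popt[0]), wb0=float(popt[1]), s=float(popt[2]))


def translate_parameters(target, fits: list[ActivationFit],
                         kappa: float | None = None,
                         occupancy_matched: bool = True
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Map dimensionless (W, b) to continuous digital synaptic weights.

    Biases map through the fitted logistic so that the unit's on-state
    occupancy equals sigma(b): the refractory-limited saturation occupancy
    ``p_max = nu0 tau_ref`` is slightly below one, so the bias weight is
    ``w_b = wb0 + s logit(sigma(b)/p_max)`` (with ``occupancy_matched=False``
    the plain linear rule ``wb0 + s b`` is used, which leaves a systematic
    occupancy shortfall of the factor p_max).  Couplings:
    ``w_ij = W_ij sqrt(s_i s_j) kappa`` with the geometric mean treating
    both members of the reciprocal pair symmetrically.  Returns continuous
    values; discretization to the 4-bit grid is a separate, explicit step.
    """
    n = target.n
    if len(fits) != n:
        raise ValueError("need one activation fit per sampling unit")
    if kappa is None:
        kappa = coupling_kappa()
    s = np.array([f.s for f in fits])
    wb0 = np.array([f.wb0 for f in fits])
    if occupancy_matched:
        tau = SAMPLING_NEURON.tau_ref
        p_max = np.array([min(f.nu0 * tau / 1e3, 1.0) for f in fits])
        frac = np.clip(_sigmoid(target.b) / p_max, 1e-6, 1 - 1e-6)
        b_dig = wb0 + s * np.log(frac / (1 - frac))
    else:
        b_dig = wb0 + s * target.b
    w_dig = target.W * np.sqrt(np.outer(s, s)) * kappa
    np.fill_diagonal(w_dig, 0.0)
    return w_dig, b_dig


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))
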