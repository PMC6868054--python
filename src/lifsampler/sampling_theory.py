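"""Boltzmann targets, refractory state extraction and divergence metrics.

A spiking sampling network represents a vector of binary random variables:
neuron ``k`` is in the on-state ``z_k = 1`` exactly while it is refractory.
The target distribution over ``z`` in {0,1}^n is the Boltzmann distribution

    p*(z) = 1/Z exp(1/2 z^T W z + z^T b)

with ``W`` symmetric and zero-diagonal.  This module provides exact
enumeration of such targets (n <= 20), extraction of the piecewise-constant
network state from spike trains, time-weighted empirical distributions, the
Kullback-Leibler divergence DKL(p||p*) = sum_z p(z) ln(p(z)/p*(z)) used as
the benchmark metric, and an abstract Glauber-dynamics sampler that serves
as an oracle independent of the LIF path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .lif_core import SpikeTrain

__all__ = [
    "BoltzmannTarget",
    "ProbabilityTable",
    "StateSequence",
    "target_joint",
    "conditional_joint",
    "extract_states",
    "empirical_joint",
    "state_moments",
    "states_on_grid",
    "dkl",
    "random_target",
    "glauber_sample",
    "all_states",
]

_MAX_ENUM = 20


@dataclass
class BoltzmannTarget:
    """Dimensionless weights ``W`` (symmetric, zero diagonal) and biases ``b``."""

    W: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        n = self.b.size
        if n < 1:
            raise ValueError("need at least one random variable")
        if self.W.shape != (n, n):
            raise ValueError("W must be n x n with n = len(b)")
        if not np.allclose(self.W, self.W.T, atol=1e-12):
            raise ValueError("W must be symmetric")
        if not np.allclose(np.diag(self.W), 0.0, atol=1e-12):
            raise ValueError("W must have a zero diagonal")

    @property
    def n(self) -> int:
        return int(self.b.size)


@dataclass
class ProbabilityTable:
    """Probabilities over all 2^n binary states, indexed by sum_k z_k 2^k."""

    n: int
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.size != 2 ** self.n:
            raise ValueError("table must have 2^n entries")
        if np.any(self.p < -1e-15):
            raise ValueError("probabilities must be non-negative")
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1 within 1e-12")

    def marginals(self) -> np.ndarray:
        """p(z_k = 1) for each unit."""
        states = all_states(self.n)
        return states.T @ self.p


@dataclass
class StateSequence:
    """Piecewise-constant binary state vector z(t).

    ``breakpoints`` has length m+1 and tiles the observation window;
    ``states`` is an (m, n) 0/1 array, constant on each interval.
    """

    breakpoints: np.ndarray
    states: np.ndarray

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.states = np.asarray(self.states, dtype=np.uint8)
        if self.states.shape[0] != self.breakpoints.size - 1:
            raise ValueError("need one state vector per interval")
        if np.any(np.diff(self.breakpoints) < 0):
            raise ValueError("breakpoints must be non-decreasing")

    @property
    def n(self) -> int:
        return int(self.states.shape[1])

    @property
    def durations(self) -> np.ndarray:
        return np.diff(self.breakpoints)


def all_states(n: int) -> np.ndarray:
    """All 2^n binary state vectors; row index equals sum_k z_k 2^k."""
    idx = np.arange(2 ** n)
    return ((idx[:, None] >> np.arange(n)[None, :]) & 1).astype(np.uint8)


def target_joint(target: BoltzmannTarget) -> ProbabilityTable:
    """Exact Boltzmann distribution by enumeration (n <= 20)."""
    n = target.n
    if n > _MAX_ENUM:
        raise ValueError(f"explicit enumeration limited to n <= {_MAX_ENUM}")
    z = all_states(n).astype(float)
    energy = 0.5 * np.einsum("si,ij,sj->s", z, target.W, z) + z @ target.b
    energy -= energy.max()
    p = np.exp(energy)
    return ProbabilityTable(n, p / p.sum())


def conditional_joint(target: BoltzmannTarget,
                      clamp: dict[int, int]) -> ProbabilityTable:
    """Renormalized slice of the target over the free units.

    ``clamp`` maps unit index -> fixed value.  The returned table is over the
    free units in ascending index order.
    """
    n = target.n
    idx = sorted(clamp)
    if len(set(idx)) != len(clamp):
        raise ValueError("clamped indices must be distinct")
    for i in idx:
        if not 0 <= i < n:
            raise ValueError(f"clamp index {i} out of range")
        if clamp[i] not in (0, 1):
            raise ValueError("clamp values must be 0 or 1")
    free = [i for i in range(n) if i not in clamp]
    if not free:
        raise ValueError("at least one unit must remain free")
    joint = target_joint(target)
    z = all_states(n)
    mask = np.ones(2 ** n, dtype=bool)
    for i in idx:
        mask &= z[:, i] == clamp[i]
    sub = joint.p[mask]
    # order within the slice follows the free units' bit order, low to high
    order = np.argsort(
        (z[mask][:, free] * (1 << np.arange(len(free)))).sum(axis=1)
    )
    sub = sub[order]
    return ProbabilityTable(len(free), sub / sub.sum())


def extract_states(spikes: SpikeTrain, tau_ref, window,
                   n_neurons: int | None = None,
                   neuron_ids=None) -> StateSequence:
    """Piecewise-constant state z(t) on a window from spikes and tau_ref.

    ``z_k(t) = 1`` iff ``t`` lies in the union of half-open refractory
    intervals ``[t_sp, t_sp + tau_ref_k)`` of neuron ``k``'s spikes.
    ``neuron_ids`` selects and orders the neurons read out (defaults to
    0..n_neurons-1); ``tau_ref`` is a scalar or per-neuron array.
    """
    t0, t1 = float(window[0]), float(window[1])
    if t1 <= t0:
        raise ValueError("window must have positive length")
    if neuron_ids is None:
        if n_neurons is None:
            n_neurons = int(spikes.sources.max()) + 1 if spikes.n_events else 1
        neuron_ids = list(range(n_neurons))
    n = len(neuron_ids)
    tau = np.broadcast_to(np.asarray(tau_ref, dtype=float), (n,))
    if np.any(tau <= 0):
        raise ValueError("tau_ref must be positive")
    if spikes.n_events and (t0 < 0):
        raise ValueError("window outside simulated range")
    edges = [np.array([t0, t1])]
    intervals = []
    for k, nid in enumerate(neuron_ids):
        t_sp = spikes.of(nid)
        on = t_sp
        off = t_sp + tau[k]
        # merge overlapping refractory intervals
        if on.size:
            keep_on = [on[0]]
            keep_off = [off[0]]
            for a, b in zip(on[1:], off[1:]):
                if a <= keep_off[-1]:
                    keep_off[-1] = max(keep_off[-1], b)
                else:
                    keep_on.append(a)
                    keep_off.append(b)
            on = np.array(keep_on)
            off = np.array(keep_off)
        intervals.append((on, off))
        edges.append(on)
        edges.append(off)
    bp = np.unique(np.concatenate(edges))
    bp = bp[(bp >= t0) & (bp <= t1)]
    if bp[0] > t0:
        bp = np.concatenate([[t0], bp])
    if bp[-1] < t1:
        bp = np.concatenate([bp, [t1]])
    mid = 0.5 * (bp[:-1] + bp[1:])
    states = np.zeros((mid.size, n), dtype=np.uint8)
    for k, (on, off) in enumerate(intervals):
        if on.size:
            j = np.searchsorted(on, mid, side="right") - 1
            valid = j >= 0
            states[valid, k] = (mid[valid] < off[j[valid]]).astype(np.uint8)
    return StateSequence(bp, states)


def states_on_grid(spikes: SpikeTrain, tau_ref, grid, neuron_ids) -> np.ndarray:
    """Binary state matrix (len(grid), n) sampled at fixed times."""
    grid = np.asarray(grid, dtype=float)
    n = len(neuron_ids)
    tau = np.broadcast_to(np.asarray(tau_ref, dtype=float), (n,))
    out = np.zeros((grid.size, n), dtype=np.uint8)
    for k, nid in enumerate(neuron_ids):
        t_sp = spikes.of(nid)
        if not t_sp.size:
            continue
        j = np.searchsorted(t_sp, grid, side="right") - 1
        valid = j >= 0
        out[valid, k] = (grid[valid] < t_sp[j[valid]] + tau[k]).astype(np.uint8)
    return out


def empirical_joint(states: StateSequence) -> ProbabilityTable:
    """Time-weighted histogram of the sampled states."""
    total = states.breakpoints[-1] - states.breakpoints[0]
    if total <= 0:
        raise ValueError("zero-length observation window")
    n = states.n
    if n > _MAX_ENUM:
        raise ValueError(f"state table limited to n <= {_MAX_ENUM}")
    idx = (states.states.astype(np.int64) @ (1 << np.arange(n))).astype(np.int64)
    p = np.zeros(2 ** n)
    np.add.at(p, idx, states.durations)
    p /= p.sum()
    return ProbabilityTable(n, p)


def state_moments(states: StateSequence) -> tuple[np.ndarray, np.ndarray]:
    """Time-weighted first and second moments (<z>, <z z^T>)."""
    w = states.durations
    total = w.sum()
    if total <= 0:
        raise ValueError("zero-length observation window")
    z = states.states.astype(float)
    zw = z * (w / total)[:, None]
    mean = zw.sum(axis=0)
    second = zw.T @ z
    return mean, second


def dkl(p: ProbabilityTable, q: ProbabilityTable) -> float:
    """Kullback-Leibler divergence sum_z p(z) ln(p(z)/q(z)) in nats.

    Requires q > 0 wherever p > 0 (always true for Boltzmann targets);
    0 ln 0 is taken as 0.
    """
    if p.n != q.n:
        raise ValueError("tables must be over the same number of units")
    support = p.p > 0
    if np.any(q.p[support] <= 0):
        raise ValueError("q must be strictly positive on the support of p")
    return float(np.sum(p.p[support] * np.log(p.p[support] / q.p[support])))


def random_target(n: int, seed: int) -> BoltzmannTarget:
    """Random target with b_i, W_ij ~ 2[Beta(0.5, 0.5) - 0.5], in [-1, 1].

    Only the upper triangle of W is drawn; the matrix is symmetrized and the
    diagonal left zero.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    b = 2.0 * (rng.beta(0.5, 0.5, size=n) - 0.5)
    W = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    W[iu] = 2.0 * (rng.beta(0.5, 0.5, size=len(iu[0])) - 0.5)
    W = W + W.T
    return BoltzmannTarget(W, b)


@njit(cache=True)
def _glauber_kernel(W, b, n_sweeps, burn_in, z0, uniforms):
    n = b.size
    z = z0.copy()
    counts = np.zeros(2 ** n)
    u_idx = 0
    for sweep in range(n_sweeps + burn_in):
        for i in range(n):
            h = b[i]
            for j in range(n):
                h += W[i, j] * z[j]
            p_on = 1.0 / (1.0 + np.exp(-h))
            z[i] = 1 if uniforms[u_idx] < p_on else 0
            u_idx += 1
        if sweep >= burn_in:
            idx = 0
            for i in range(n):
                idx += z[i] << i
            counts[idx] += 1.0
    return counts


def glauber_sample(target: BoltzmannTarget, n_sweeps: int, seed: int,
                   burn_in: int = 100) -> ProbabilityTable:
    """Sequential Glauber-dynamics sampler over the target's state space.

    One sweep updates every unit once with p(z_i=1) = sigma(b_i + sum_j W_ij
    z_j).  Serves as the abstract MCMC oracle against which the LIF sampling
    path is compared; independent of the neuron simulator.
    """
    n = target.n
    if n > _MAX_ENUM:
        raise ValueError(f"state counting limited to n <= {_MAX_ENUM}")
    rng = np.random.default_rng(seed)
    z0 = rng.integers(0, 2, size=n).astype(np.int64)
    uniforms = rng.random((n_sweeps + burn_in) * n)
    counts = _glauber_kernel(target.W, target.b, n_sweeps, burn_in, z0, uniforms)
    return ProbabilityTable(n, counts / counts.sum())
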