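"""In-the-loop wake-sleep training of sampling networks.

Weight updates follow the wake-sleep rule

    db_i   = eta (<z_i>*     - <z_i>),
    dW_ij  = eta (<z_i z_j>* - <z_i z_j>),

where starred averages come from the target (data / wake phase) and
unstarred ones from the free-running network (model / sleep phase), each
augmented by a classical heavy-ball momentum term.  Updates are applied to
double-precision shadow weights which are deterministically discretized to
the 4-bit digital grid before every emulation run, mirroring in-the-loop
training on an analog substrate whose analog parameters are rewritten (with
trial noise) between runs.

For fully specified low-dimensional targets the wake term is computed
analytically by enumeration; for image data it is sampled with the visible
and label layers clamped and the top-down synapses from the hidden layer
disabled.  Pre-training of the hierarchical networks uses a standard
persistent-contrastive-divergence RBM, whose parameters are translated to
digital weights via the calibrated activation functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import (
    ActivationFit,
    SamplingNetwork,
    build_sampling_network,
    fit_activation,
    measure_activation,
    translate_parameters,
)
from .hardware_model import DIGITAL_MAX, VariabilityModel, discretize_array
from .lif_core import SpikeTrain
from .noise_sources import PoissonSource, RandomNetworkSpec
from .sampling_theory import (
    BoltzmannTarget,
    all_states,
    dkl,
    empirical_joint,
    extract_states,
    state_moments,
    states_on_grid,
    target_joint,
)
from .synthetic_data import ImageDataset, N_PIXELS

__all__ = [
    "TrainingConfig",
    "MomentState",
    "TrainingResult",
    "wake_sleep_step",
    "analytic_wake_stats",
    "moments_from_samples",
    "clamp_inputs",
    "train_to_target",
    "pretrain_rbm",
    "build_hierarchical_network",
    "train_on_dataset",
    "HierarchicalTrainingResult",
    "calibrate_average_fit",
    "image_clamp_pattern",
    "plateau_entry_iteration",
]


@dataclass
class TrainingConfig:
    """Wake-sleep hyperparameters.

    ``sampling_ms`` is the sleep-phase emulation time per iteration;
    ``burn_in_factor`` discards an initial transient of that many synaptic
    time constants before moments are measured.  ``discretize=False``
    bypasses the 4-bit constraint (continuous weights), used to attribute
    the trained-DKL plateau to weight resolution.
    """

    eta: float = 1.0
    momentum: float = 0.6
    minibatch: int | None = None  # images per class, data-driven runs only
    iterations: int = 200
    sampling_ms: float = 2e4
    seed: int = 0
    burn_in_factor: float = 10.0
    dt: float = 0.1
    discretize: bool = True
    init_scale: float = 15.0  # initial digital weights ~ U(-init_scale, +init_scale)
    wake_present_ms: float = 200.0  # per-image wake sampling time (data runs)
    moment_grid_ms: float = 1.0  # state-sampling grid for large networks
    keep_snapshots: bool = False  # record (w, b) at every iteration

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("learning rate must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")
        if self.iterations < 1:
            raise ValueError("need at least one iteration")


@dataclass
class MomentState:
    """Previous update per parameter, for the heavy-ball momentum term."""

    db: np.ndarray
    dW: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "MomentState":
        return cls(np.zeros(n), np.zeros((n, n)))


@dataclass
class TrainingResult:
    snet: SamplingNetwork
    w_dig: np.ndarray
    b_dig: np.ndarray
    dkl_history: np.ndarray
    best_iteration: int
    moment_gap_history: np.ndarray | None = None
    snapshots: list[tuple[np.ndarray, np.ndarray]] | None = None


def wake_sleep_step(data_stats, model_stats, cfg: TrainingConfig,
                    mom: MomentState) -> tuple[np.ndarray, np.ndarray, MomentState]:
    """One wake-sleep update with momentum.

    ``data_stats`` and ``model_stats`` are (mean, second-moment matrix)
    pairs; returns (db, dW, new momentum state) where
    ``delta_t = eta * gradient + momentum * delta_{t-1}``.
    """
    mean_d, sec_d = (np.asarray(a, dtype=float) for a in data_stats)
    mean_m, sec_m = (np.asarray(a, dtype=float) for a in model_stats)
    if mean_d.shape != mean_m.shape or sec_d.shape != sec_m.shape:
        raise ValueError("wake and sleep statistics shapes do not match")
    for arr in (mean_d, mean_m):
        if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
            raise ValueError("statistics must lie in [0, 1]")
    db = cfg.eta * (mean_d - mean_m) + cfg.momentum * mom.db
    dW = cfg.eta * (sec_d - sec_m) + cfg.momentum * mom.dW
    np.fill_diagonal(dW, 0.0)
    return db, dW, MomentState(db.copy(), dW.copy())


def analytic_wake_stats(target: BoltzmannTarget) -> tuple[np.ndarray, np.ndarray]:
    """Exact moments <z_i>* and <z_i z_j>* by enumeration of the target."""
    table = target_joint(target)
    z = all_states(target.n).astype(float)
    mean = z.T @ table.p
    second = (z * table.p[:, None]).T @ z
    return mean, second


def moments_from_samples(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical first and second moments of binary sample rows."""
    z = np.asarray(samples, dtype=float)
    return z.mean(axis=0), z.T @ z / z.shape[0]


def clamp_inputs(pattern: dict[int, int], duration: float,
                 rate: float = 100.0, multapse: int = 5,
                 period_offset: bool = True) -> dict[str, SpikeTrain]:
    """Regular multapse spike trains forcing units into given states.

    For each (unit, value) a bundle of ``multapse`` regular trains at
    ``rate`` Hz is injected — excitatory for value 1, inhibitory for value 0
    — through the unit's maximum-weight clamp port.  The member trains are
    phase-offset by period/multapse to avoid synchronous super-spikes; the
    returned train per unit is their superposition.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    period = 1e3 / rate
    out: dict[str, SpikeTrain] = {}
    for unit, value in pattern.items():
        if value not in (0, 1):
            raise ValueError("clamp values must be 0 or 1")
        times = []
        for m in range(multapse):
            offset = m * period / multapse if period_offset else 0.0
            times.append(np.arange(offset, duration, period))
        merged = np.sort(np.concatenate(times)) if times else np.empty(0)
        port = f"clamp_exc_{unit}" if value == 1 else f"clamp_inh_{unit}"
        out[port] = SpikeTrain.from_times(merged)
    return out


def plateau_entry_iteration(history: np.ndarray, frac: float = 0.2,
                            tail_fraction: float = 0.25,
                            smooth_window: int = 15) -> int:
    """First iteration from which a DKL trajectory stays within ``frac`` of
    its final plateau value.

    Weight discretization makes late-stage trajectories oscillate between
    neighboring digital configurations, so the trajectory is first smoothed
    with a centered running median of ``smooth_window`` iterations.  The
    plateau value is the median of the smoothed trajectory's last
    ``tail_fraction``; the entry point is the first index after which every
    smoothed value stays below ``plateau * (1 + frac)``.
    """
    history = np.asarray(history, dtype=float)
    if smooth_window > 1 and history.size > smooth_window:
        half = smooth_window // 2
        padded = np.pad(history, half, mode="edge")
        smoothed = np.array([
            np.median(padded[i:i + smooth_window])
            for i in range(history.size)
        ])
    else:
        smoothed = history
    tail = smoothed[int(len(smoothed) * (1 - tail_fraction)):]
    plateau = float(np.median(tail))
    below = smoothed <= plateau * (1.0 + frac)
    stays = np.flip(np.logical_and.accumulate(np.flip(below)))
    idx = np.flatnonzero(stays)
    return int(idx[0]) if idx.size else len(smoothed) - 1


def _seed_stream(seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]


def _sleep_moments(snet: SamplingNetwork, cfg: TrainingConfig, run_seed: int):
    """Free-running (sleep-phase) time-weighted moments and empirical table."""
    res = snet.run(cfg.sampling_ms, seed=run_seed, dt=cfg.dt)
    burn = cfg.burn_in_factor * max(
        snet.net.neurons[snet.sampling_ids[0]].tau_syn_exc, 1.0
    )
    seq = extract_states(res.spikes, snet.tau_ref, (burn, cfg.sampling_ms),
                         neuron_ids=snet.sampling_ids)
    mean, second = state_moments(seq)
    return mean, second, seq


def train_to_target(target: BoltzmannTarget,
                    cfg: TrainingConfig | None = None,
                    noise: PoissonSource | RandomNetworkSpec | None = None,
                    substrate: VariabilityModel | None = None,
                    substrate_seed: int = 0,
                    wake_stats=None,
                    snet: SamplingNetwork | None = None) -> TrainingResult:
    """Wake-sleep training of a sampling network toward a Boltzmann target.

    Per iteration: rewrite the substrate's analog parameters (trial noise),
    install the discretized weights, emulate the sleep phase, measure
    time-weighted moments, update the continuous shadow weights against the
    (analytic or supplied) wake statistics, and record DKL(empirical ||
    target).  The returned configuration is the one with the lowest recorded
    DKL, which — due to discretization-induced oscillations — is not
    necessarily the final one.
    """
    cfg = cfg or TrainingConfig()
    n = target.n
    if snet is None:
        snet = build_sampling_network(n, noise=noise)
    if snet.n_units != n:
        raise ValueError("network size does not match the target")
    rng = np.random.default_rng(cfg.seed)
    b_c = rng.uniform(-cfg.init_scale, cfg.init_scale, size=n)
    w_c = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    w_c[iu] = rng.uniform(-cfg.init_scale, cfg.init_scale, size=len(iu[0]))
    w_c = w_c + w_c.T
    if substrate is not None:
        snet.apply_substrate(substrate, substrate_seed)
    if wake_stats is None:
        wake_stats = analytic_wake_stats(target)
    tgt_table = target_joint(target)
    mom = MomentState.zeros(n)
    run_seeds = _seed_stream(cfg.seed + 1, cfg.iterations)
    trial_seeds = _seed_stream(cfg.seed + 2, cfg.iterations)
    history = np.empty(cfg.iterations)
    gap_history = np.empty(cfg.iterations)
    snapshots: list[tuple[np.ndarray, np.ndarray]] | None = (
        [] if cfg.keep_snapshots else None)
    best = (np.inf, None, None, -1)
    for it in range(cfg.iterations):
        if substrate is not None and substrate.cv_trial > 0:
            snet.begin_trial(substrate, trial_seeds[it])
        if cfg.discretize:
            w_d, b_d = discretize_array(w_c), discretize_array(b_c)
        else:
            w_d, b_d = w_c.copy(), b_c.copy()
        snet.set_weights(w_d, b_d)
        if snapshots is not None:
            snapshots.append((w_d.copy(), b_d.copy()))
        mean, second, seq = _sleep_moments(snet, cfg, run_seeds[it])
        d = dkl(empirical_joint(seq), tgt_table)
        history[it] = d
        gap_history[it] = float(np.abs(wake_stats[0] - mean).max())
        if d < best[0]:
            best = (d, w_d.copy(), b_d.copy(), it)
        db, dW, mom = wake_sleep_step(wake_stats, (mean, second), cfg, mom)
        b_c = np.clip(b_c + db, -DIGITAL_MAX, DIGITAL_MAX)
        w_c = np.clip(w_c + dW, -DIGITAL_MAX, DIGITAL_MAX)
        np.fill_diagonal(w_c, 0.0)
    _, w_best, b_best, best_it = best
    snet.set_weights(w_best, b_best)
    return TrainingResult(snet=snet, w_dig=w_best, b_dig=b_best,
                          dkl_history=history, best_iteration=best_it,
                          moment_gap_history=gap_history,
                          snapshots=snapshots)


# ---------------------------------------------------------------------------
# hierarchical (data-driven) networks
# ---------------------------------------------------------------------------

@dataclass
class HierarchicalTrainingResult:
    snet: SamplingNetwork
    w_dig: np.ndarray
    b_dig: np.ndarray
    log: list[dict] = field(default_factory=list)
    fits: list[ActivationFit] | None = None


def build_hierarchical_network(
    n_visible: int = N_PIXELS, n_hidden: int = 60, n_label: int = 3,
    noise: PoissonSource | RandomNetworkSpec | None = None,
    shared_bias: bool = True, label_multapse: int = 7, seed: int = 0,
) -> SamplingNetwork:
    """Three-layer sampling network: visible <-> hidden <-> label.

    Units are ordered visible (0..n_v-1), hidden, label; connections exist
    between consecutive layers only.  A single shared bias neuron serves all
    units by default, as on the substrate.  Hidden-label connections are
    realized as ``label_multapse``-fold multapses: the label layer is tiny
    compared to the visible layer, so its couplings must exceed the
    single-synapse 4-bit ceiling to steer the network during inference and
    guided dreaming.
    """
    n = n_visible + n_hidden + n_label
    vis = range(n_visible)
    hid = range(n_visible, n_visible + n_hidden)
    lab = range(n_visible + n_hidden, n)
    connections = [(v, h) for v in vis for h in hid] + \
                  [(h, l) for h in hid for l in lab]
    multapse = {(h, l): label_multapse for h in hid for l in lab}
    roles = (["visible"] * n_visible + ["hidden"] * n_hidden
             + ["label"] * n_label)
    return build_sampling_network(
        n, noise=noise, connections=connections, shared_bias=shared_bias,
        roles=roles, multapse=multapse, seed=seed,
    )


def pretrain_rbm(images: np.ndarray, labels: np.ndarray, n_hidden: int,
                 n_label: int, epochs: int = 40, lr: float = 0.05,
                 minibatch: int = 20, n_chains: int = 50,
                 momentum: float = 0.5, label_scale: int = 1,
                 seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Persistent-contrastive-divergence pre-training of a classification RBM.

    The RBM's visible layer is the image concatenated with the one-hot
    label; its hidden layer becomes the sampling network's hidden layer.
    The label units are replicated ``label_scale`` times during training
    (their summed weights map onto the single label units afterwards), so
    the label's energy contribution can compete with the much larger pixel
    block — without this a clamped label is too weak to steer generation.
    Returns the full symmetric coupling matrix and bias vector over
    (visible, hidden, label) in the network's unit order, in the Boltzmann
    convention p(z) ~ exp(z^T W z / 2 + b^T z).
    """
    rng = np.random.default_rng(seed)
    images = np.asarray(images, dtype=float)
    n_img, n_pix = images.shape
    onehot = np.zeros((n_img, n_label))
    onehot[np.arange(n_img), labels] = 1.0
    v_data = np.hstack([images] + [onehot] * label_scale)
    n_vis = n_pix + n_label * label_scale
    W = rng.normal(0.0, 0.01, size=(n_vis, n_hidden))
    bv = np.zeros(n_vis)
    bh = np.zeros(n_hidden)
    # visible biases at the data log-odds, the usual initialization
    p = np.clip(v_data.mean(axis=0), 1e-3, 1 - 1e-3)
    bv = np.log(p / (1 - p))
    chains = (rng.random((n_chains, n_vis)) < 0.5).astype(float)
    vel_W = np.zeros_like(W)
    vel_bv = np.zeros_like(bv)
    vel_bh = np.zeros_like(bh)

    def sigmoid(x):
        return 1.0 / (1.0 + np.exp(-x))

    for _epoch in range(epochs):
        order = rng.permutation(n_img)
        for start in range(0, n_img, minibatch):
            batch = v_data[order[start:start + minibatch]]
            ph_data = sigmoid(batch @ W + bh)
            # one Gibbs step on the persistent chains
            ph = sigmoid(chains @ W + bh)
            h = (rng.random(ph.shape) < ph).astype(float)
            pv = sigmoid(h @ W.T + bv)
            chains = (rng.random(pv.shape) < pv).astype(float)
            ph_model = sigmoid(chains @ W + bh)
            g_W = batch.T @ ph_data / len(batch) - chains.T @ ph_model / n_chains
            g_bv = batch.mean(axis=0) - chains.mean(axis=0)
            g_bh = ph_data.mean(axis=0) - ph_model.mean(axis=0)
            vel_W = momentum * vel_W + lr * g_W
            vel_bv = momentum * vel_bv + lr * g_bv
            vel_bh = momentum * vel_bh + lr * g_bh
            W += vel_W
            bv += vel_bv
            bh += vel_bh
    W_lab = sum(W[n_pix + i * n_label:n_pix + (i + 1) * n_label]
                for i in range(label_scale))
    b_lab = sum(bv[n_pix + i * n_label:n_pix + (i + 1) * n_label]
                for i in range(label_scale))
    n = n_pix + n_hidden + n_label
    W_full = np.zeros((n, n))
    b_full = np.zeros(n)
    vis = slice(0, n_pix)
    hid = slice(n_pix, n_pix + n_hidden)
    lab = slice(n_pix + n_hidden, n)
    W_full[vis, hid] = W[:n_pix]
    W_full[hid, vis] = W[:n_pix].T
    W_full[lab, hid] = W_lab
    W_full[hid, lab] = W_lab.T
    b_full[vis] = bv[:n_pix]
    b_full[lab] = b_lab
    b_full[hid] = bh
    return W_full, b_full


def image_clamp_pattern(image: np.ndarray, label: int | None,
                        n_visible: int, n_hidden: int, n_label: int,
                        mask: np.ndarray | None = None) -> dict[int, int]:
    """Clamp dictionary for one image (black pixel -> 1) and optional label.

    ``mask`` marks occluded pixels that receive no input.
    """
    pattern: dict[int, int] = {}
    for k in range(n_visible):
        if mask is not None and mask[k]:
            continue
        pattern[k] = int(image[k])
    if label is not None:
        for l in range(n_label):
            pattern[n_visible + n_hidden + l] = 1 if l == label else 0
    return pattern


def _grid_moments(snet: SamplingNetwork, spikes, t0: float, t1: float,
                  grid_ms: float):
    grid = np.arange(t0, t1, grid_ms)
    z = states_on_grid(spikes, snet.tau_ref, grid, snet.sampling_ids)
    zf = z.astype(float)
    return zf.mean(axis=0), zf.T @ zf / zf.shape[0]


def calibrate_average_fit(snet: SamplingNetwork, wb_grid=None,
                          duration: float = 5e3, seed: int = 0
                          ) -> list[ActivationFit]:
    """Per-unit logistic fits from simultaneous activation measurements.

    Units whose fit fails (e.g. degenerate rates under strong variability)
    fall back to the population-average fit, mirroring translation via an
    average activation function.
    """
    if wb_grid is None:
        wb_grid = np.linspace(-15, 15, 7)
    rates = measure_activation(snet, wb_grid, duration=duration, seed=seed)
    fits: list[ActivationFit | None] = []
    for k in range(snet.n_units):
        try:
            fits.append(fit_activation(np.column_stack([wb_grid, rates[:, k]])))
        except Exception:
            fits.append(None)
    good = [f for f in fits if f is not None]
    if not good:
        raise RuntimeError("activation calibration failed for every unit")
    avg = ActivationFit(
        nu0=float(np.median([f.nu0 for f in good])),
        wb0=float(np.median([f.wb0 for f in good])),
        s=float(np.median([f.s for f in good])),
    )
    return [f if f is not None else avg for f in fits]


def train_on_dataset(data: ImageDataset,
                     arch: tuple[int, int, int] = (N_PIXELS, 60, 3),
                     cfg: TrainingConfig | None = None,
                     substrate: VariabilityModel | None = None,
                     noise: PoissonSource | RandomNetworkSpec | None = None,
                     substrate_seed: int = 0,
                     pretrain_epochs: int = 40,
                     snet: SamplingNetwork | None = None,
                     fits: list[ActivationFit] | None = None
                     ) -> HierarchicalTrainingResult:
    """Data-driven training of a hierarchical sampling network.

    Pre-trains a classification RBM with persistent contrastive divergence,
    translates its parameters to digital weights through the calibrated
    activation functions, then fine-tunes with the substrate in the loop:
    wake statistics are sampled with visible and label layers clamped and
    top-down synapses from the hidden layer disabled; sleep statistics come
    from the free-running network; updates use minibatches with momentum and
    4-bit discretization per step.
    """
    n_vis, n_hid, n_lab = arch
    if data.images.shape[1] != n_vis:
        raise ValueError("image size does not match the visible layer")
    if data.labels.max() >= n_lab:
        raise ValueError("more label values than label units")
    cfg = cfg or TrainingConfig(eta=0.4, momentum=0.6, minibatch=7,
                                iterations=20, sampling_ms=2e3)
    n = n_vis + n_hid + n_lab
    hid_units = list(range(n_vis, n_vis + n_hid))
    if snet is None:
        snet = build_hierarchical_network(n_vis, n_hid, n_lab, noise=noise)
    if substrate is not None:
        snet.apply_substrate(substrate, substrate_seed)
    if fits is None:
        fits = calibrate_average_fit(snet, seed=cfg.seed)
    train_imgs, train_labels = data.subset("train")
    W_abs, b_abs = pretrain_rbm(train_imgs, train_labels, n_hid, n_lab,
                                epochs=pretrain_epochs, seed=cfg.seed)
    w_c, b_c = translate_parameters(BoltzmannTarget(W_abs, b_abs), fits)
    w_max = snet.w_max
    w_c = np.clip(w_c, -w_max, w_max)
    b_c = np.clip(b_c, -DIGITAL_MAX, DIGITAL_MAX)
    conn_mask = np.zeros((n, n), dtype=bool)
    for (i, j) in snet.connections:
        conn_mask[i, j] = conn_mask[j, i] = True
    w_c[~conn_mask] = 0.0
    mom = MomentState.zeros(n)
    rng = np.random.default_rng(cfg.seed + 17)
    run_seeds = _seed_stream(cfg.seed + 1, 2 * cfg.iterations * max(1, len(train_imgs)))
    trial_seeds = _seed_stream(cfg.seed + 2, cfg.iterations)
    log: list[dict] = []
    seed_ptr = 0
    per_class = cfg.minibatch or 7
    for it in range(cfg.iterations):
        if substrate is not None and substrate.cv_trial > 0:
            snet.begin_trial(substrate, trial_seeds[it])
        if cfg.discretize:
            w_d, b_d = discretize_array(w_c), discretize_array(b_c)
        else:
            w_d, b_d = w_c.copy(), b_c.copy()
        # --- wake phase: clamp visible + label, top-down synapses off
        batch_idx = []
        for c in range(n_lab):
            cls = np.flatnonzero(train_labels == c)
            if cls.size:
                batch_idx.extend(rng.choice(cls, size=min(per_class, cls.size),
                                            replace=False))
        wake_mean = np.zeros(n)
        wake_sec = np.zeros((n, n))
        for bi in batch_idx:
            snet.set_weights(w_d, b_d)
            snet.zero_directed(hid_units)
            pattern = image_clamp_pattern(train_imgs[bi], int(train_labels[bi]),
                                          n_vis, n_hid, n_lab)
            clamps = clamp_inputs(pattern, cfg.wake_present_ms)
            res = snet.run(cfg.wake_present_ms, seed=run_seeds[seed_ptr],
                           dt=cfg.dt, extra_inputs=clamps)
            seed_ptr += 1
            m, s2 = _grid_moments(snet, res.spikes, 20.0, cfg.wake_present_ms,
                                  cfg.moment_grid_ms)
            wake_mean += m
            wake_sec += s2
        wake_mean /= len(batch_idx)
        wake_sec /= len(batch_idx)
        # --- sleep phase: free-running network
        snet.set_weights(w_d, b_d)
        res = snet.run(cfg.sampling_ms, seed=run_seeds[seed_ptr], dt=cfg.dt)
        seed_ptr += 1
        burn = cfg.burn_in_factor * snet.net.neurons[snet.sampling_ids[0]].tau_syn_exc
        sleep_mean, sleep_sec = _grid_moments(snet, res.spikes, burn,
                                              cfg.sampling_ms, cfg.moment_grid_ms)
        db, dW, mom = wake_sleep_step((wake_mean, wake_sec),
                                      (sleep_mean, sleep_sec), cfg, mom)
        dW[~conn_mask] = 0.0
        b_c = np.clip(b_c + db, -DIGITAL_MAX, DIGITAL_MAX)
        w_c = np.clip(w_c + dW, -w_max, w_max)
        log.append({
            "iteration": it,
            "moment_gap": float(np.abs(wake_mean - sleep_mean).mean()),
            "w_norm": float(np.abs(w_c[conn_mask]).mean()),
        })
    if cfg.discretize:
        w_d, b_d = discretize_array(w_c), discretize_array(b_c)
    else:
        w_d, b_d = w_c.copy(), b_c.copy()
    snet.set_weights(w_d, b_d)
    return HierarchicalTrainingResult(snet=snet, w_dig=w_d, b_dig=b_d,
                                      log=log, fits=fits)
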