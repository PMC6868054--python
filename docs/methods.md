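# Methods

This note documents the model, the numerical choices, and the reasoning
behind the package's defaults, including the places where the design was
genuinely open. All times, rates and constants are expressed in the
biological-time frame; the 10⁴ acceleration of the physical substrate this
package emulates is a reporting convention, not a simulated mechanism.

## Neuron and synapse model

Neurons are conductance-based leaky integrate-and-fire units:

    C_m du/dt = −g_l (u − E_leak) − g_exc(t)(u − E_exc) − g_inh(t)(u − E_inh)

outside refractory windows; a threshold crossing at `t_sp` clamps the
membrane to `V_reset` on `[t_sp, t_sp + τ_ref)`. Each presynaptic spike
adds an exponential conductance kernel `J·exp(−(t − t_sp − d)/τ_syn)` after
delay `d`; kernels superpose linearly (ideal linear transmission is an
assumption — the analog substrate's saturation behavior is not public).
The leak conductance is derived as `g_l = C_m/τ_mem`.

Default parameters follow the emulated system's nominal values: sampling
neurons `V_reset = −35 mV`, `E_leak = V_thresh = −20 mV`, `E_inh = −100 mV`,
`E_exc = 60 mV`, `τ_ref = 4 ms`, `τ_mem = 7 ms`, `C_m = 0.2 nF`,
`τ_syn = 8 ms`; bias neurons have a strongly suprathreshold leak
(`E_leak = 60 mV`, `τ_ref = 1.5 ms`) and fire regularly with
ISI = τ_ref + τ_mem·ln[(E_leak − V_reset)/(E_leak − V_thresh)] ≈ 2.32 ms;
random-network neurons are mildly suprathreshold (`E_leak = −10 mV`).
The synaptic delay defaults to 1 ms for every connection ("on the order of
1 ms" is all that is known for the substrate).

### Integration

Exponential Euler for the membrane (exact for piecewise-constant
conductances) and exact exponential decay for the conductance state
variables, with `dt = 0.1 ms` by default; `dt` must not exceed a quarter of
the smallest time constant in the network. Threshold detection uses the
post-step value and the spike time is recorded on the end-of-step boundary;
the resulting O(dt) bias is covered by a convergence test (the
suprathreshold ISI matches the closed form to <1% at `dt = 0.025 ms`).
The simulator is deterministic: identical inputs and seeds reproduce
identical spike trains bit for bit. The inner loop is compiled with numba.

## States, distributions and divergence

Neuron `k` is in the on-state `z_k(t) = 1` exactly on the union of its
half-open refractory intervals `[t_sp, t_sp + τ_ref)`. Empirical
distributions weight states by occupancy *time* (a grid-sampling variant
exists for sensitivity checks and for the pairwise moments of large
networks, grid 1 ms). Only sampling neurons are read out; bias and
random-network neurons are excluded from `z`. The benchmark metric is the
standard non-negative Kullback-Leibler divergence
DKL(p‖p*) = Σ_z p(z)·ln(p(z)/p*(z)) in nats. Targets with n ≤ 20 are
enumerated exactly. An independent Glauber-dynamics sampler (sequential
stochastic updates with p(z_i = 1) = σ(b_i + Σ_j W_ij z_j)) serves as the
abstract MCMC oracle; it is never used inside the LIF path.

## Noise backends

*Poisson*: each sampling neuron receives a private excitatory and a private
inhibitory homogeneous Poisson train at 300 Hz. The synaptic weight of
these inputs is not public for the emulated system; the default (20 nS)
was chosen once so that the background conductance (~96 nS ≈ 3.4 g_l)
puts the neuron in a clear high-conductance state (τ_eff ≈ 1.6 ms ≪ τ_syn,
τ_ref) while a single noise PSP stays below the unit-weight signal PSP.
Under this drive the activation function is well fit by a logistic with
midpoint near w_b = 0 and saturation ν₀ ≈ 230 Hz.

*Random network (RN)*: a sparse recurrent network of inhibitory,
suprathreshold-leak neurons (defaults N_r = 200, in-degree K_RN = 20,
internal digital weight 10). Each sampling neuron receives exactly
K_noise = 15 excitatory and 15 inhibitory projections from randomly chosen
RN neurons (synapse type is assigned per connection, as on hardware, where
the circuit type is a property of the connection, not of the source
neuron); connectivity is drawn without replacement per target. Because the
RN is fully deterministic and its neurons are identical, the simulation
seeds each RN neuron's initial membrane potential uniformly between reset
and threshold; without this the population starts in lockstep. The
emulated RN settles to a stationary population rate of a few Hz and yields
a logistic activation function like the Poisson backend, with weak,
nonzero shared-input correlations that the training rule compensates.

## Calibration and translation

`measure_activation` zeroes all couplings and sweeps the bias weight,
measuring every unit simultaneously (one run per grid point);
`fit_activation` fits ν₀/(1 + exp(−(w_b − w_b0)/s)) by least squares
(scipy's `curve_fit`). Translation of abstract parameters to digital
weights:

* **Biases.** The refractory-limited saturation occupancy is
  `p_max = ν₀·τ_ref ≈ 0.92 < 1`, so the naive linear rule
  `w_b = w_b0 + s·b` systematically under-drives the unit (occupancy
  `p_max·σ(b)` instead of `σ(b)`). The default rule matches occupancies
  exactly at W = 0: `w_b = w_b0 + s·logit(σ(b)/p_max)`. The linear rule is
  available (`occupancy_matched=False`).
* **Couplings.** `w_ij = W_ij·√(s_i s_j)·κ`, the geometric mean treating
  the reciprocal synapse pair symmetrically. The global factor κ equates
  the mean conductance per digital unit delivered by the bias neuron
  (rate ν_b, kernel τ_syn) with that delivered by one presynaptic spike
  per refractory period during an on-state:
  κ = (ν_b·τ_syn) / [(τ_syn/τ_ref)(1 − e^(−τ_ref/τ_syn))] ≈ 4.37.
  The exact functional form used on the original system is not public;
  this rule is validated by the round-trip property (3 units,
  |W|, |b| ≤ 0.5, no training: DKL < 0.1, measured ≈ 0.01–0.03).
* **Conductance scale.** One digital weight unit corresponds to the
  conductance that produces a 3 mV PSP at rest (≈ 2.73 nS), the
  calibration working point of the emulated substrate.

Bias neurons are simulated explicitly (no DC shortcut). One bias neuron
per unit by default; large hierarchical networks share a single bias
neuron across all units via distinct synapse pairs, as on the substrate.

## Substrate constraints

* **4-bit weights.** Signed digital weights are rounded half-away-from-zero
  and clipped to [−15, 15]; the sign selects the excitatory or inhibitory
  member of the synapse pair. Connections may be declared as *multapses*
  (m parallel synapse pairs), which extends the representable range to
  ±15m; the magnitude is split as evenly as possible across members. The
  hierarchical network uses 7-fold multapses for hidden↔label couplings:
  three label units cannot otherwise compete with 144 visible units.
* **Fixed-pattern variability** (persistent per substrate seed):
  independent lognormal factors, CV 20% on every synaptic conductance
  (including external-input projections, which traverse physical synapse
  circuits) and CV 10% on per-neuron synaptic time constants. These values
  are configuration, not measurement — the emulated system's CVs are not
  public. Learning compensates fixed-pattern distortions.
* **Trial-to-trial variability** (fresh per run): lognormal factors on
  per-neuron analog parameters (τ_syn, τ_mem). Digital SRAM weights and
  synapse-circuit gains are *not* re-rolled per run — digital rewriting is
  precise, which is the very reason biases are implemented via synaptic
  weights on this class of substrate. The default CV (5×10⁻⁴) is
  calibrated so that the trial-to-trial standard deviation of a unit's
  activation function is ≈ 0.1 Hz, the value reported for the physical
  system. Larger CVs act as a fresh per-run bias jitter that training
  cannot compensate and would place the trained DKL far above the
  plateau the physical system demonstrably reached.

## Training

Wake-sleep with heavy-ball momentum: Δ_t = η·gradient + m·Δ_{t−1}
(η = 1.0 for Poisson target runs, 0.5 for RN runs, 0.4 for data runs;
m = 0.6). Continuous shadow weights are kept in double precision, clipped
to the representable digital range, and discretized before every run.
For target runs: initial digital weights U(−15, 15); the wake term is
computed analytically by enumeration; sleep moments are time-weighted over
the iteration window after a burn-in of 10·τ_syn = 80 ms; the substrate's
analog parameters are rewritten (trial noise) every iteration; the
configuration with the lowest recorded DKL is returned, since
discretization makes the late trajectory oscillate between neighboring
digital configurations.

For data runs: a persistent-contrastive-divergence classification RBM
(visible = image ⊕ one-hot label, PCD-1, minibatch 20, lr 0.05, momentum
0.5, 40 epochs) is pre-trained in the abstract domain and translated
through the median activation fit; fine-tuning clamps visible and label
layers per minibatch image (7 per class) with the top-down synapses from
the hidden layer zeroed during the wake phase, and samples sleep moments
from the free-running network on a 1 ms grid. Clamping injects a 5-fold
multapse of regular 100 Hz trains (phase-offset by 2 ms to avoid
super-spikes) at the maximum single-synapse weight — excitatory for 1,
inhibitory for 0. The RBM's label block can be replicated
(`label_scale`) to strengthen label steering during generation; the
default is 1 (replication improves guided dreaming but degrades
classification and completion through label-feedback hallucination).

## Experiment protocols

* *Sampling*: DKL of the cumulative empirical distribution over [0, t]
  against the target, on a logarithmic grid.
* *Inference*: clamp units (z₁, z₂) = (0, 1); DKL over the 2³-state free
  subspace against the analytic conditional. Convergence is faster than
  the joint's because the state space is smaller.
* *Classification*: visible layer clamped to the image (black = 1) for
  500 ms; the label neuron with the highest spike count wins; ties break
  to the lowest index (logged); a silent label layer counts as an error
  (flagged).
* *Pattern completion*: 25% of pixels receive no input (salt&pepper or a
  contiguous 6×6 patch); MSE over the occluded pixels uses each occluded
  neuron's state averaged over a trailing 10 ms box filter, evaluated
  every 5 ms from stimulus onset; 100 ms of random input (each visible
  neuron receives the excitatory clamp with probability ½) scrambles the
  network between images.
* *Guided dreaming*: visible and hidden layers run free; the label layer
  is clamped one-hot per schedule entry (500 ms default) with 100 ms of
  random visible input between entries; visible-layer snapshots are
  recorded (10 ms box filter for display).

Every protocol is a pure function of (network, configuration, seeds).

## Synthetic data

The image experiments run on generated 12×12 binary datasets: per class a
fixed random prototype with exactly half the pixels on and pairwise
Hamming distance ≥ 20, sampled with i.i.d. pixel flips (default
probability 0.05, the regime where classes remain cleanly separable —
roughly "reduced binarized digits" difficulty). The 12×12 resolution is
implied by the 144-unit visible layer. What the generator does *not*
emulate: the spatial correlation structure of real handwritten or fashion
images, their sparse backgrounds, and their connected low-energy manifolds
— so passing tests show that the pipeline trains, classifies, completes
and steers on well-separated desk-scale data, not that it reaches any
particular accuracy on real image sets. A reduction utility
(nearest-neighbor index map `floor((j+0.5)·n_in/n_out)`, then
binarization strictly above the per-image median) and an IDX reader are
provided for user-supplied 28×28 grayscale data.

## Problem sizes

The shipped benchmark protocol uses five 5-unit target/seed combinations,
300 training iterations (the headline DKL selects its configuration within
the first 200) at 2×10⁴ ms sleep sampling per iteration, and 10⁵ ms test
runs; the data pipeline trains a 144-60-3 network for 15 in-the-loop
iterations (2×10³ ms sleep, 200 ms wake per image) on 240 training images.
These sizes make the full suite run in a few minutes on one CPU while
leaving every qualitative conclusion intact.

## Known limitations

* **Residual DKL floor.** With the nominal parameter set the trained
  networks plateau at a median test DKL of ≈ 0.025–0.03 nats, slightly
  above the ≈ 0.02 the physical system reached. Decomposition shows the
  floor is *not* dominated by the 4-bit constraint or the calibrated
  variability but by the interaction kinematics: with `τ_ref = 4 ms`,
  `τ_syn = 8 ms` and `d = 1 ms`, only ~28% of a presynaptic spike's
  conductance kernel mass acts while the presynaptic neuron is actually
  in its on-state; the rest arrives late and smears pairwise correlations
  (reducing the delay to 0.1 ms drops the floor below 0.02). The physical
  system's *effective* refractory time was ≈ 10 ms (uncalibrated analog
  parameters), which makes the same delay and kernel tail relatively
  benign. The package keeps the nominal table values.
* **Guided dreaming on well-separated classes.** Class-conditional mode
  switching fails for vanilla-PCD models of balanced random prototypes —
  the abstract Gibbs sampler mode-locks exactly like the spiking network.
  Tempered pre-training (out of scope here) is the established remedy;
  the physical system showed the same failure mode for one of its
  fashion-image classes. The dreaming protocol itself is verified on a
  hand-constructed two-mode network where steering is guaranteed.
* The conditional (inference) distributions are less accurate than the
  joints, consistent with effective-weight asymmetry from fixed-pattern
  variability.
* Synapse loss, driver saturation, routing congestion and short-term
  plasticity are not modeled.
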