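# lifsampler

Spiking sampling networks (SSNs) in software: networks of leaky
integrate-and-fire (LIF) neurons that sample from Boltzmann distributions,
trained in the loop by a wake-sleep rule under the constraints of an
accelerated analog neuromorphic substrate — 4-bit paired
excitatory/inhibitory synaptic weights, fixed-pattern parameter
variability, trial-to-trial analog write noise, and background noise from a
deterministic recurrent inhibitory network instead of ideal Poisson input.

The package is aimed at computational neuroscientists and neuromorphic
engineers who want to study how sampling-based probabilistic inference
behaves under hardware-like distortions without access to the hardware
itself.

## The model

Each sampling neuron represents a binary random variable: it is in the
on-state `z_k = 1` exactly while refractory after a spike. With symmetric
couplings and suitable background noise the network's state vector samples
approximately from the Boltzmann distribution

    p*(z) = 1/Z · exp(½ zᵀW z + zᵀb),   z ∈ {0,1}ⁿ,

with `W` symmetric and zero-diagonal. Biases are implemented by a regularly
firing *bias neuron* per sampling unit, connected through a paired
excitatory/inhibitory synapse whose signed digital weight `w_b` controls
the unit's mean activity; the measured activation function is logistic,
`⟨ν⟩ = ν₀ / (1 + exp(−(w_b − w_b0)/s))`, and its fitted parameters
translate dimensionless `(W, b)` into digital synaptic weights.

Training uses the wake-sleep rule

    Δb_i  = η (⟨z_i⟩*   − ⟨z_i⟩),
    ΔW_ij = η (⟨z_i z_j⟩* − ⟨z_i z_j⟩),

with momentum, where starred moments come from the target (computed
analytically for small targets, or sampled with clamped visible/label
layers for image data) and unstarred moments from the free-running
network. Continuous shadow weights are rounded to the 4-bit digital grid
before every emulation run. Accuracy is measured by the Kullback-Leibler
divergence DKL(p‖p*) in nats; image tasks use the classification error
ratio and the mean squared error over reconstructed pixels.

## Worked example

Train a 5-unit SSN with private 300 Hz Poisson noise toward a random target
whose weights and biases are drawn from `2·[Beta(½, ½) − ½]`, under 4-bit
weights and default substrate variability:

```python
from lifsampler import (PoissonSource, TrainingConfig, VariabilityModel,
                        random_target, train_to_target, sampling_experiment)

target = random_target(5, seed=7)
cfg = TrainingConfig(eta=1.0, momentum=0.6, iterations=100,
                     sampling_ms=1e4, seed=3)
result = train_to_target(target, cfg, noise=PoissonSource(),
                         substrate=VariabilityModel(), substrate_seed=11)
print(f"initial DKL : {result.dkl_history[0]:.3f} nats")
print(f"after 20 it : {result.dkl_history[20]:.3f} nats")
print(f"best        : {result.dkl_history.min():.4f} nats "
      f"(iteration {result.best_iteration})")
exp = sampling_experiment(result.snet, target, duration=1e5, seed=12)
print(f"test-run DKL: {exp.final:.4f} nats")
```

prints

```
initial DKL : 4.202 nats
after 20 it : 0.039 nats
best        : 0.0274 nats (iteration 95)
test-run DKL: 0.0305 nats
```

The divergence collapses within the first ~20 iterations and then
oscillates between neighboring 4-bit configurations; the best configuration
seen during training is kept and re-tested on a longer sampling run.

The same machinery drives the higher-level pipelines: `train_on_dataset`
pre-trains a classification RBM on 12×12 binary images, translates it to a
144-60-3 hierarchical SSN and fine-tunes it in the loop; `classify`,
`pattern_complete` and `guided_dream` run the discriminative and generative
protocols. A `lifsampler` command-line tool exposes each pipeline
(`lifsampler train-target --help`, `lifsampler make-data …`, …).

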