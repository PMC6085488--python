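# Methods

This note records the model as implemented, the defaults and why they were
chosen, what the synthetic generator does and does not emulate, and the
numerical conventions that matter for reproducing results.

## Neuron model and discretization

Neurons are leaky integrate-and-fire units, `τ_m dV/dt = −V + I(t)`,
simulated on a fixed grid (default dt = 1 ms). Each step applies, in
order: exponential decay by the exact factor `exp(−dt/τ_m)` (not the
forward-Euler `1 − dt/τ_m`; the exact factor is stable for any dt),
integration of the instantaneous input current, threshold comparison, and
reset-to-zero of spiking units. Consequences of these conventions:

- at most one spike per unit per step (binary rasters);
- no refractory period;
- current is injected *after* the decay within a step, so a unit driven by
  constant subthreshold current c converges to the geometric fixed point
  `c / (1 − exp(−dt/τ_m))`;
- reset is to zero, not reset-by-subtraction.

τ_m defaults to 10 ms.

## Encoding

Pixel intensities in [0, 1] are rate-coded as independent Bernoulli draws
per pixel per step with probability `intensity × max_rate × dt` — the
standard discrete-time approximation of a Poisson process. Draw order is
documented (one uniform array of shape (H, W, T) per image) so rasters are
bit-reproducible across platforms for a given seeded generator. Encoding
rejects rates implying a per-step probability above 1. Input spikes are
regenerated at every presentation (fresh noise each epoch); a cached mode
is not provided because none of the shipped experiments need it.

Maximum rates follow the training schedule: 200 Hz during STDP
pre-training, 500 Hz during fine-tuning and inference.

## Topology machinery

Topology strings (`<H>x<W>-<N>C<k>-<w>P-…-<N>FC`, case-insensitive)
validate shape chaining at parse time; the two reference topologies
`28x28-36C5-2P-10FC` and `28x28-20C5-2P-50C5-2P-200FC-10FC` are golden
cases in the test suite. Convolution is valid-mode (no padding), stride 1,
cross-correlation convention, weights shared across positions. Pooling is
non-overlapping 2×2 with fixed weight 0.25 and firing threshold 0.8:
since spike counts are quantized in steps of 0.25, the strict comparison
`sum > 0.8` makes a pooled unit an AND gate over its window. Pooling units
are stateless comparators with no membrane. Before the first FC layer,
pooled maps are flattened row-major by (map, row, column).

Weight initialization: uniform in ±√(3/fan-in) (`lee` scheme, the
default) or ±√(6/(fan-in+fan-out)) (`glorot`). Thresholds are
`v_th = α √(3/fan-in)`, α = 5 for conv and 3 for FC layers, shared per
feature map in conv layers.

## STDP pre-training

The rule is weight-dependent positive STDP:
`Δw = η (trace − χ_offset)(w_max − w)(w − w_min)`, where the trace is kept
per pre-synaptic *unit* (not per synapse — consistent with weight sharing),
resets to exactly 1 on a pre-spike and decays by `exp(−dt/τ_pre)`,
τ_pre = 1.5 ms. Updates happen only at post-spike steps; when several
units of one output map spike in the same step, the per-location deltas
are averaged before being applied to the shared kernel, then clamped to
[w_min, w_max]. Depression for large timing differences arises entirely
from the `(trace − χ_offset)` sign; there is no separate negative-window
rule and no lateral inhibition (negative weights fill that role).

Several constants of this phase have no canonical published value; the
defaults, all exposed in `STDPConfig`/`HomeostasisConfig`, are:

| parameter | default | rationale |
|---|---|---|
| η_STDP | 0.002 | small relative to the weight range; tens of presentations shift kernels a few percent of the range |
| χ_offset | 0.4 | potentiation window ≈ 1.4 ms at τ_pre = 1.5 ms (trace > 0.4) |
| w_min, w_max | ±√(3/fan-in) | the initialization range, so STDP keeps weights on the init scale |
| θ₊ | 0.05 × v_th init | per-spike-step threshold increment, relative so it scales with layer fan-in |
| τ_θ | 100 ms | thresholds relax over a few presentations |

Thresholds relax toward the initialization value `α√(3/n)` (the floor),
not toward zero, so silent maps recover their initial excitability.

Greedy schedule: conv layers are pre-trained bottom-up; after a layer is
trained its kernels *and adapted thresholds* are frozen and its spiking
output (through pooling) feeds the next layer. FC weights and FC
thresholds are never modified during pre-training. The pipeline
pre-trains on a configurable fraction of the training set (default 10%),
and those samples are excluded from the first fine-tuning epoch. Membrane
state and traces reset between presentations; adapted thresholds persist.

## Spike-based backpropagation

Activations `a = Σ_k exp(−(T − t_k)/τ_p)` and pseudo-derivatives
`a′ = 1 + Σ_k (−1/τ_p) exp(−(T − t_k)/τ_p)` are evaluated once per
presentation at the final step T (the recursion needs one scalar per unit
per presentation; end-of-window is the documented choice). τ_p = 100 ms,
so a′ stays in (0, 1] for any raster up to a few hundred steps — the
surrogate never saturates. Silent units have a = 0, a′ = 1.

Max-normalization of activations (in the output error and in the weight
gradients) is per layer per sample, guarded with ε = 1e−9 for silent
layers; ties at the maximum all normalize to 1. The backward recursion
applies a′ at conv and FC outputs only; pooling contributes no derivative
factor and routes each pooled unit's gradient uniformly to its 2×2 source
window scaled by the fixed 0.25 weight (the transpose of the pooling
map — exact for contributing windows, and the all-or-nothing pooling rule
makes full routing equivalent in practice). Conv weight gradients are
*averaged* over the output positions sharing a kernel weight; mini-batch
gradients are averaged, not summed, so the learning rate is batch-size
robust. SGD is constant-rate with presets 0.4 (shallow topology) and
0.18 / 0.35 (deep topology); no momentum, decay, or dropout — the
unsupervised phase is positioned as the regularizer.

Thresholds are frozen during fine-tuning; only synaptic weights train.

## Inference and metrics

Prediction is the argmax of output-unit spike counts over a 200 ms window
at 500 Hz (rate-coding-consistent; an activation-argmax variant is
available via a flag), ties resolving to the lowest class index. The
negative-log-likelihood diagnostic normalizes output rates to a
probability simplex (sum-normalization, uniform fallback for all-silent
outputs, ε-clipping) and reports the conventional non-negative
cross-entropy `−Σ_i [x_i log p_i + (1−x_i) log(1−p_i)]`.

Training error is logged per mini-batch; "iterations to X% error" uses
the trailing five-batch mean to avoid crediting a single lucky batch.

## Synthetic data generator

`generate_patterns` emulates a small separable image-classification task:
each class is a fixed high-intensity template (horizontal/vertical bar,
diagonal and anti-diagonal bands, ring, block — pairwise different in at
least 25% of pixels on an 8×8 grid), plus i.i.d. uniform pixel noise of
configurable amplitude, clipped to [0, 1]. It does *not* emulate the
variability of handwritten digits: no deformation, translation, scale or
style variation, and classes are linearly separable. Passing tests on
this generator therefore demonstrate that the machinery (encoding,
dynamics, plasticity, gradients, orchestration) is correct and that the
optimization behaves sanely — not that the method reaches any particular
accuracy on real data.

## Toy-scale study conditions

The shipped experiments are deliberately small so the whole suite runs in
seconds on one CPU: 3 classes of 8×8 patterns at noise 0.1 (100 training
/ 20 test per class), topology `8x8-6C3-3FC`, mini-batches of 10
presented for 50 ms at 500 Hz, learning rate 0.4 (the shallow preset),
inference over 100 ms. The toy topology omits the pooling layer from the
learning path: with an 8×8 input the AND-gate pooling rule passes almost
no spikes through randomly initialized kernels, leaving the classifier
silent for most of training; pooling is instead exercised directly by its
exhaustive unit contract and inside the gradient-oracle networks. On this
task the supervised phase converges to under 5% training error in well
under ten mini-batch iterations, with or without pre-training — the task
is too easy for the pre-training speed-up seen at full scale to be
resolvable; the paired comparison machinery (identical initial weights,
independent seed streams for weights / encoding / data order) is provided
for full-scale studies.

## Known limitations

- The full-scale digit-recognition experiments (~150 epochs on 60k
  images) are supported by the code paths (IDX reader, deep topology,
  checkpointing, `compare` CLI) but are far outside the bundled test
  scale.
- Homeostasis constants and STDP rates are heuristics (table above), not
  canonical values; conclusions about pre-training strength at full scale
  will depend on them.
- No padding, strided or dilated convolution; no alternative pooling; no
  refractory dynamics; no event-camera input.
- Pooling layers after the first FC layer are unsupported (the parser
  rejects such topologies).
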