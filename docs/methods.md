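# Methods

This note records the modeling choices behind `cdbn-lesion`: the
probabilistic model and its inference rules, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical conventions.

## Model

### Energy functions and conditionals

The dense restricted Boltzmann machine (`crbm.DenseRBM`) is the standard
bipartite energy model over binary visible units v and hidden units h:

    E(v, h) = − b·v − c·h − vᵀ W h

Conditioned on one layer, the units of the other layer are independent
Bernoulli variables with probability σ(net input + own-layer bias), σ the
logistic function. The dense model is kept as an exactly enumerable
reference: every conditional and every gradient the convolutional code
computes can be cross-checked against brute-force enumeration of all
joint states on models with ≤ 14 units, and the test suite does exactly
that.

The convolutional RBM shares K r×r filters over all spatial positions of
an image-shaped visible layer:

    E(v, {h_k}) = − Σ_k Σ_ij h_k(i,j) [(w_k ∗ v)(i,j) + b_k] − c Σ_ij v(i,j)

with the "valid" convolution (w_k ∗ v)(i,j) = Σ_pq w_k(p,q) v(i+p, j+q).
Hidden conditionals are σ of the bottom-up filter response plus a per-map
bias; the visible conditional is σ of the adjoint (full, zero-padded)
convolution with the doubly flipped filters plus one scalar visible bias.
For multi-channel inputs the filters carry a channel axis and the
convolution sums over channels; the visible bias stays scalar.

Visible units hold normalized intensities in [0, 1] used directly as
mean-field values. This preserves the Gabor enhancement instead of
destroying it by thresholding; Bernoulli sampling of visibles remains
available for Gibbs chains.

### Probabilistic max pooling

Each non-overlapping 2×2 region of a feature map is summarized by a
pooled unit that is on with probability

    P(on) = Σ_P exp(a) / (1 + Σ_P exp(a)),

where a are the pre-sigmoid bottom-up activations in the region and the
1 in the denominator is the explicit "no unit fires" outcome. Pooling
*activations* rather than sampled binary states is essential: over {0, 1}
values the expression can only take a handful of values and the
competition degenerates. The literal binary variant is kept for
comparison (`prob_max_pool_binary`) but used nowhere.

Exponentials are computed with a max-shift that leaves the ratio exact,
and the float result is clipped into the open unit interval so the
strictly-inside-(0,1) property survives rounding at extreme activations.
Odd map dimensions are cropped by one row/column before pooling.

### Contrastive divergence

CD-k with batch averaging: positive statistics correlate the data-clamped
visibles with their hidden probabilities; the chain samples binary hidden
states and reconstructs visibles as mean-field probabilities; negative
statistics use the chain state after k steps. Biases update from the
corresponding marginal sums. Defaults: k = 1, no momentum, no weight
decay. On a dense RBM small enough to enumerate, the CD-1 update averaged
over 2000 chains points within a few degrees of the exact log-likelihood
gradient (cosine ≈ 0.99; the acceptance script recomputes this).

### Initialization

Filters start as zero-mean Gaussians with std 1/√(fan-in)
(fan-in = r²·channels) and hidden biases at −log(pool area) = −log 4.
Rationale: with a fixed tiny weight std the bottom-up activations of wide
layers collapse toward 0, every pooled probability sits at its
zero-activation value of area/(area+1) = 0.8, and binarization at any
mid-range threshold produces constant maps — the deeper layers then carry
no information at all. Fan-in scaling keeps activation spread O(1) at
every depth and the bias choice centers the pooled on-probability at 1/2,
which makes the binarized maps maximally informative for any threshold
near 1/2. Both can be overridden per layer (`CRBMLayer.initialize`).
A data-dependent bias calibration (median-centering each map's pooled
probabilities on the training batch) was evaluated and rejected: it
lowered downstream classification quality.

## Stack, features, classifier

Three CRBM layers (the printed search space carries three learning rates,
one per layer), default architecture on 32×32×3 input:

| layer | maps K | filter r | pool | output |
|-------|--------|----------|------|--------|
| 1     | 24     | 5        | 2    | 14×14  |
| 2     | 64     | 5        | 2    | 5×5    |
| 3     | 256    | 4        | 2    | 1×1    |

Training is greedy and unsupervised: layer 1 on the filtered patches,
each deeper layer on the previous layer's pooled probabilities binarized
at threshold p_l (value 1 iff probability ≥ p_l). The deterministic
mean-field forward pass mirrors this; the final layer's pooled
probabilities stay continuous, and the 256-d feature vector takes each
final map's spatial maximum (inert at 1×1, but defined for other
architectures). Config validation proves the dimension chain
(d → ⌊(d − r + 1)/s⌋ per layer) is realizable before any training.

The classification head is XGBoost with exactly 100 trees, single thread,
`tree_method="hist"`, all other hyperparameters at library defaults and
frozen by seed. Metrics: confusion matrix in fixed class order
(hard_exudate, microhemorrhage, healthy), accuracy = trace/total, and
macro-averaged precision/recall/F1 with the 0/0 → 0 convention.

## Hyperparameters and search

Eleven parameters with their search ranges:

| name | meaning | range |
|------|---------|-------|
| σ | Gabor envelope scale | [100, 200] |
| θ | orientation (rad) | [0, π] |
| λ | wavelength (px) | [8, 16] |
| ψ | phase (rad) | [0, 2π] |
| γ | aspect ratio | [0.5, 1] |
| k | kernel-side control | [45, 180] |
| p₁, p₂ | binarization thresholds | [0, 1] |
| α₁..α₃ | per-layer learning rates | [10⁻⁹, 10⁻⁵] |

The kernel side is round(k) forced odd. σ is interpreted literally
(unscaled pixel units), which makes the envelope nearly flat over the
kernel — the filter acts as a narrow oriented bandpass at wavelength λ.

`PipelineConfig` defaults to the published optimum of the search for the
six Gabor parameters. The thresholds default to p₁ = p₂ = 0.5 rather
than the published 0.4227/0.9839: under this implementation's activation
scales a 0.98 threshold binarizes virtually every pooled probability to
zero and empties the final layer's input, so the neutral mid-threshold is
the usable default; the published values remain loadable from config.

Optimizers (all operate internally in [0, 1]-normalized coordinates,
repair by clipping, use elitism of 1, and share one log schema):

* **RCGA** — binary tournament, SBX (η_c = 15) with the canonical
  equal-parent guard, polynomial mutation (η_m = 20, per-gene rate 1/11).
* **BUMDA** — selection at the population median; normal model per
  variable with weights g_i = f_i − f_worst_selected + 1, variance
  denominator 1 + Σg; variance floored at 10⁻¹².
* **UMDA** — top-50 % truncation, unweighted normal fit, same floor.

Fitness is the pipeline's macro F1 at a reduced budget (default 5 epochs,
≤ 600 patches, stratified 80/20) so a 20-generation, population-10 search
stays tractable on one CPU; the full budget is a config change. Fitness
evaluations that raise score 0 and are counted in the log.

## Synthetic data

The generator emulates the qualitative appearance of fundus patches:
warm orange-red background with smooth tonal texture (correlation length
≈ 16 px), dark vessel streaks across healthy tissue, clustered bright
yellowish blobs with irregular (Fourier-wobbled) boundaries for hard
exudates, and several small dark-red roundish spots for
microhemorrhages. Default dataset counts are 755/718/700 per class,
matching the reference cohort. Everything is a pure function of
(class, config, seed); datasets derive per-patch seeds from one master
seed and round-trip exactly through PNG + CSV manifest.

Two presets order the difficulty. `separable` has strong lesion contrast
and mild jitter: a 100-tree classifier on the three channel means alone
reaches ≥ 0.9 accuracy, and the full pipeline reaches macro F1 ≈ 0.83–0.88
on 200 patches per class. `realistic` widens tonal jitter and noise and
weakens the lesions until channel means are nearly uninformative
(accuracy ≈ 0.3). The lesion spatial scales in the separable preset were
chosen to straddle the Gabor passband (λ ∈ [8, 16] px): healthy texture
varies below the band, microhemorrhage spots sit in it, exudate blobs
above it.

What the generator does **not** emulate — and hence what passing tests do
not show about clinical data: real patches carry the class signal in
subtle texture against heavy noise, not in clean channel statistics. On
the synthetic separable preset the *raw* patches are linearly separable,
so the Gabor stage does not improve (and the no-Gabor ablation in the
acceptance output can exceed the filtered pipeline). On real fundus data
the filter's contribution is reported to be decisive; that property
cannot be reproduced from synthetic data and is out of scope here. The
synthetic results validate the machinery — exact inference, learning
dynamics, feature contracts, optimizer behavior — not clinical accuracy.

## Numerical conventions and degenerate inputs

- Convolution in the Gabor stage is true convolution (impulse response =
  kernel) with half-sample-symmetric ("reflect including edge") padding,
  same-size output; constant channels rescale to all-zeros.
- Problem sizes in tests and the acceptance script (200–600 patches,
  5–10 epochs, 1×–20× enumerable models) were chosen so the full suite
  runs in a few minutes on one CPU while every contract is exercised at
  full fidelity.
- Layer serialization stores arrays as base64 of raw little-endian bytes
  (exact float round-trip); model files are versioned JSON.
- Seeds: one master seed fans out to stage seeds via CRC-32 of the stage
  name XOR master, mod 2³¹, so stages can be rerun in isolation.
- Empty batches, single-class training sets, label values outside the
  class set, infeasible layer chains and non-finite parameters are all
  rejected with targeted errors; a non-finite CD update aborts with a
  diagnostic rather than propagating NaNs.

## Known limitations

- The paper-range learning rates (≤ 10⁻⁵) barely move the filters at desk
  scale; the pipeline's discriminative power on synthetic data comes
  mostly from the Gabor stage plus the randomly initialized hierarchy,
  with CD training reducing reconstruction error but not measurably
  improving class separation. Demonstrating a training benefit would
  require data whose generative structure aligns with class identity.
- Probabilistic max pooling is implemented in its mean-field role;
  stochastic pooled sampling through the stack is not exposed.
- No persistent CD, sparsity targets, or Gaussian-visible variants.
- Whole-image lesion localization and clinical deployment concerns are
  out of scope.
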