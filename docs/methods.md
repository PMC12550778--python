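# Methods

This note documents the models, the synthetic benchmark, the numerical
choices, and the limitations of `sharkfuse`. Nothing here states a result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Data model and preprocessing

Images are `H×W×C` real tensors with raw values in [0, 255]. All inputs
are standardized as `S' = (S − μ)/σ` where μ, σ are pooled over **every
pixel of the training split only** (per-dataset, not per-image); the
estimators fit these statistics inside `fit` and reuse them at predict
time, so validation/test data never leak into the normalization.
Degenerate (zero-variance) training data is rejected.

Augmentation draws, in a fixed order, a horizontal flip ~ Bernoulli(p),
a rotation angle ~ U(−θ_max, θ_max), a scale factor ~ U(lo, hi), a shear
angle ~ U(−s_max, s_max) and a translation ~ U(−t, t)·(H, W), and applies
flip first, then the remaining four as one composed affine warp about the
image center (bilinear interpolation, constant fill 0 = the dataset mean
in standardized space). Defaults: ±15°, scale [0.9, 1.1], flip 0.5,
translate ≤10%, shear ≤5°. Design points:

* The flip is an exact column reversal (`j → W−1−j`), not an interpolated
  warp, so flipping twice is bit-identical to the input.
* Identity parameters short-circuit to a copy, so an all-zero
  configuration is bit-exact.
* Augmentation is applied only to the training stream, per sample per
  epoch, from the training loop's seeded generator.

## The two branches

Both branches are numpy networks with hand-written backward passes
(verified against central finite differences in the test suite), trained
with categorical cross-entropy, an L2 penalty, global gradient-norm
clipping, and a seeded shuffled mini-batch loop. Optimizers: Adam
(default), SGD, RMSprop. Reference training hyperparameters: learning
rate 0.001, batch size 32, dropout 0.3, L2 5e-4, gradient clip 1.0.
Early stopping on validation loss is available but off by default.

**LVM branch.** Conv(3×3, same-padding, stride 1, ReLU) → max-pool(2),
repeated (default widths 8, 16), then either a flatten or — with
`use_attention=True` — a patch embedding (default 4×4 patches to a
32-dimensional space), additive sinusoidal positional encoding
`PE(pos, 2i) = sin(pos/10000^{2i/d})`, `PE(pos, 2i+1) = cos(·)`, and one
multi-head self-attention block `softmax(QKᵀ/√d_k)V` (4 heads); finally a
fully-connected head of exactly three weight layers (defaults 64, 32,
then the 3-class softmax) with dropout between. Attention defaults to
off: at the desk scale used here (64×64 inputs, 40 gradient steps) the
attention parameters cannot amortize, and the purely convolutional
variant is both faster and stronger; the flag preserves the
transformer-style variant for larger budgets.

**Inception branch.** Stem conv(8) → pool → inception blocks (default
branch widths (4, 8, 2, 2) and (6, 12, 4, 4); each block runs 1×1, 3×3,
5×5 and 3×3-maxpool→1×1 branches in parallel and concatenates channels)
→ one dynamic-convolution stage (16 filters): the effective kernel is
`W = Σₖ gₖ(S)·W_base[k]` over K = 4 base kernels, gated by
global-average-pool → dense(K) → softmax, so the kernel is an
input-conditioned convex mixture — the gate output is validated to lie on
the simplex. Then global average pooling (the feature embedding G(S)) and
a dense softmax head. The original design this surrogate stands in for
uses a large pretrained backbone; shipping pretrained weights is out of
scope, so the backbone here is trained from scratch and deliberately
small, and `feature_extractor=` accepts any callable mapping standardized
image batches to embeddings for users who have a real pretrained model
(only the dense head is trained in that case).

Layer widths throughout are sized for single-core CPU training of a
~300-image dataset in seconds, not for accuracy records.

## Shark Optimization Algorithm

A box-bounded maximizer over a population of P candidates. Positions
initialize uniformly, `S = S_min + r(S_max − S_min)`; velocities start at
zero. Per iteration, for each candidate:

```
V ← β V + c₁ r₁ (S* − S) + c₂ r₂ (S_best − S) + γ ξ,   ξ ~ N(0, I)
S ← clip(S + αₜ V, bounds)
```

where S* is the candidate's own best-found position (cognitive term),
S_best the swarm's (social term), r₁, r₂ ~ U(0,1) fresh per candidate per
iteration, and the control factor αₜ decays linearly from 1.0 to 0.1 over
the run, shifting exploration toward exploitation. The incumbent best is
elitist (the best-fitness history is monotone non-decreasing), boundary
handling is componentwise clipping, and the run stops early when the best
fitness improves by less than `tol` for `patience` consecutive
iterations. Defaults: P = 20, 100 iterations, c₁ = c₂ = 1.5, β = 0.7
(momentum in the conventional 0.5–0.9 band), γ = 0.1, tol = 1e-6,
patience = 15. Minimization is the negated objective.

Two published forms of the velocity rule exist — a cognitive+social form
and a momentum+noise "adaptive" form; this implementation merges them
into the single update above so both behaviors (memory attraction and
random exploration) are present. A literally printed position-as-velocity
variant is dimensionally inconsistent and was dropped.

## Ensemble fusion

`P_ensemble = ω₁ P₁ + ω₂ P₂` rowwise. Since both branch outputs are row
distributions and the argmax of a nonnegative combination depends only on
the ratio ω₁:ω₂, the search is restricted to the 1-D simplex
(ω₂ = 1 − ω₁) without loss. The objective — exact-match accuracy of the
fused argmax, ties broken toward the lowest class index — is evaluated on
the **validation** split; test data never influence the weight. The
fitness is a step function of ω₁ with at most N breakpoints, so the
`brute_force_weights` grid at step 0.001 is effectively exhaustive for
N ≤ 10⁴ and serves as the oracle the SOA search is tested against
(observed gap: 0).

## Metrics

One-vs-rest reduction of the K×K confusion matrix: TP = diagonal entry,
FN = rest of row, FP = rest of column, TN = remainder. Per class:
accuracy, precision, sensitivity, specificity, F1, and trapezoid AUC of
the ROC swept over descending distinct values of that class's probability
column. Headline values are unweighted (macro) means over classes —
except accuracy, which is the pooled fraction correct trace(C)/N (the
macro mean of one-vs-rest binary accuracies is a different, inflated
quantity and is reported only per class). Any 0/0 denominator yields 0
with a logged warning. The whole stack is tested to 1e-9 agreement
against scikit-learn and the AUC to 1e-12 against concordant-pair
(Mann–Whitney) counting; scikit-learn is used only as that oracle, never
as the implementation. Confidence intervals are seeded percentile
bootstraps over resampled mean accuracy (2000 resamples, 95% default);
the interval is clamped to contain the point estimate.

## Synthetic benchmark

The generator emulates the *structure* of a restricted clinical archive:
two modality profiles of 3 × n images. Background: a soft elliptical
body on a darker field plus smoothed correlated texture and white noise
(base noise sd 8). Classes: **normal** = background only; **benign** =
one smooth ellipse (soft rim, width 0.25·r₀) at intensity offset
`effect_size · contrast · 70`; **malignant** = a jagged-boundary blob
(4–6 random harmonics, amplitude 0.55, sharp rim) with internal speckle
(amplitude `effect_size · contrast · 45`) at the *same* mean offset as
benign — so intensity alone cannot separate the lesion classes and
benign-vs-malignant is the hardest pair, as in the clinical task.
Lesion radius ~ U(0.16, 0.24)·min(H, W), center jitter ±14%. Profiles:
CT = noise ×1.0 / contrast 1.0, MRI = noise ×1.8 / contrast 0.65, making
CT the easier modality by construction; the CT > MRI accuracy ordering is
therefore a *testable property of the pipeline*, not a finding about
imaging physics. `effect_size` scales every lesion-specific signal; at 0
the three classes are statistically identical and a probe classifier
tests at chance. Pixels are quantized to 8-bit levels so the PNG
writer/loader round-trip is pixel-exact.

What passing tests on this benchmark do **not** show: performance on real
scans. The generator has none of the anatomy, partial-volume effects,
scanner artifacts, protocol variability or label noise of clinical data;
it validates the machinery (training, fusion, optimization, metrics,
reproducibility) and the qualitative noise/contrast ordering, nothing
more.

## Protocol and problem sizes

The default experiment is the CT profile at 100 images/class, 64×64
grayscale, stratified 80/10/10 split (largest-remainder rounding per
class), 5 epochs per branch at batch 32 (40 gradient steps), SOA fusion
on the 30-sample validation split, evaluation on the 30-sample test
split — a deliberate scale-down, sized so a full run takes ~20 s on one
CPU core and the whole test suite stays in minutes. The reference
full-scale protocol (658 images/class, 50 epochs) is reachable through
the same configs.

Every stage derives its seed as `global_seed + offset (mod 2³¹)` with
fixed offsets (data 101, split 202, LVM 303, inception branch 404, SOA
505, bootstrap 606); one integer reproduces a run byte-for-byte, which
the acceptance suite asserts on the serialized metrics JSON.

## Known limitations

* The inception branch is a small from-scratch surrogate; with a real
  pretrained backbone its standalone accuracy (and the fused weights)
  would differ substantially.
* No auxiliary intermediate classifier head: the sequential container has
  no side branches, and such a head would be off by default at this scale
  anyway.
* The fusion search is two-model only by design; stacking or >2-branch
  fusion is out of scope.
* Validation splits of 30 samples make the fitted weight coarse
  (plateaus of the step-function fitness are wide); this is a property of
  the desk scale, not of the method.
* AUC variance estimation (DeLong) and tumor localization/staging are not
  implemented.
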