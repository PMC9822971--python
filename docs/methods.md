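# Methods

This note documents the models implemented in `rfdseg`, the assumptions
behind them, the parameters that matter, and the choices made where the
design was genuinely open.

## The discretization model

**Decision table.** Supervised discretization operates on a flattened
information decision table: per-pixel brightness (the single condition
attribute) and the gold-standard region category. Brightness is stored as
float64 and never rescaled, so inputs above 8 bits work unchanged; the
declared value range comes from the storage dtype (0–255 for 8-bit, the
dtype range for 16-bit, data-driven otherwise).

**Candidate breakpoints** are the sorted unique observed brightness values
themselves, not midpoints between adjacent values. This is what makes the
accounting exact: a full-dynamic-range 8-bit slice has 256 candidates, and
a 128-slice volume of such slices has 128 × 256 = 32 768 summed per-slice
candidates. For 3-D input the default scope is **per slice** (each 2-D
slice gets its own candidate set, GA run, and scheme); whole-volume mode is
available via a flag. Per-slice mode reflects how slice-wise acquisition
noise varies through a B-scan stack, and equivalence classes never cross
slices.

**Fuzzy c-means.** One-dimensional FCM with the fuzzifier fixed at m = 2
(the membership and center updates hard-code squared exponents).
Termination: max_ij |u_ij^{t+1} − u_ij^t| < ε with ε = 1e-5 and a cap of
300 iterations (both configurable; neither is externally prescribed, these
are ordinary FCM practice for 8-bit data). Center initialization is not
prescribed either; the default places centers at the (j + 0.5)/M quantiles
of the brightness distribution — deterministic and seed-free, so repeated
runs cannot drift. A seeded random init is retained for robustness
experiments. When a brightness value coincides with one or more centers,
membership 1 is split equally among the coincident centers (the standard
m = 2 singular limit; it keeps rows stochastic). Because memberships depend
only on brightness, the solver iterates over unique values weighted by
their pixel counts and broadcasts rows afterwards — algebraically identical
to the per-pixel iteration (the test suite bounds the floating-point
discrepancy below 1e-10 against a naive reference).

**Rough-fuzzy approximation.** Each category j is the fuzzy set
A_j(i) = u_ij. The equivalence relation is the partition induced by the
*evaluated scheme's* intervals: cuts are inclusive on the left, i.e.
intervals are (−∞, s₁], (s₁, s₂], …, (s_k, +∞), and a value's interval
index is the number of selected cuts strictly below it. Interpreting the
relation through the evaluated scheme (rather than raw brightness equality)
is what makes the fitness depend on the scheme at all; raw equality is
recovered as the all-selected limit, where η̄ = 1 exactly. Cardinality is
the sigma-count Σ_x F(x). Precision of a category with empty upper
approximation is defined as 1 (vacuously exact — avoids 0/0). Lower/upper
fields are computed per interval over unique values and broadcast, never by
the quadratic pairwise scan; the pairwise formulation is kept in the test
suite as the oracle.

**Data inconsistency** is reported as the fraction of pixels whose
equivalence class contains more than one gold label — a number in [0, 1]
that is 0 exactly when discretized brightness still determines the label.
(Other conventions — a boolean, a class count — exist; the fraction is the
most informative and reduces to the same zero.)

**Fitness and GA.** Fitness = α (N_CB − N_DS)/N_CB + β η̄ with α + β = 1;
default α = β = 0.5 (sensitivity to α is an experiment, not a constant).
GA defaults: population 50, generations 100, single-point crossover at 0.8,
per-bit mutation 1/n, tournament size 2, elitism 1, all logged per run.
The initial population contains the empty and all-selected chromosomes, so
the result is never worse than either limit, and the per-generation best is
monotone by elitism. Fitness values are memoized by chromosome. An optional
`fitness_target` stops the search early; no default target is set.

*Tie-breaking:* exact fitness ties occur systematically on degenerate
scopes — on a slice with only two brightness values, the empty scheme
(maximal parsimony, vacuous precision on absent classes) can score exactly
the same as the single separating cut. Ties are therefore broken
lexicographically toward higher η̄. This makes the optimizer prefer the
scheme that actually preserves category structure whenever parsimony cannot
distinguish, and it is what makes the end-to-end noiseless-phantom property
(η̄ = 1, inconsistency = 0) hold for every seed rather than most.

**Scheme application.** The network-facing encoding replaces each pixel by
the mean observed brightness of its interval in the fitting table, rescaled
to [0, 1] ("interval_mean"); `index` and `midpoint` encodings exist for
inspection. The mean-based representative preserves intensity semantics for
convolutions while removing within-interval variation, which is the point
of the pre-module.

## The network

A 3-D encoder–decoder processing blocks of configurable size (64³ at full
scale; the CPU test scale is 16³). Encoder stages are residual double-conv
blocks (two 3×3×3 convolutions, batch norm, ReLU, with an identity or 1×1×1
shortcut); channels double per 2× max-pooling from `base_channels` (16)
clamped at `max_channels` (128). The decoder mirrors with nearest
upsampling. Three optional mechanisms, individually toggleable so the
ablation variants (plain baseline, deep supervision only, dual attention
only, refinement only) are all expressible:

- **Dual attention** on skip features before fusion: a channel
  squeeze-and-gate (global average pool → two dense layers → sigmoid) times
  a spatial gate (1×1×1 conv → sigmoid). Wiring internals are not uniquely
  determined by the published description; this is the simplest pair of
  gates matching "spatial region and feature channel".
- **Deep supervision**: a 1×1×1 probability head on every decoder stage
  except the shallowest, upsampled to full resolution. These heads enter
  only the weighted cross-entropy term; multiple heads contribute their
  mean.
- **Attention refinement** before the classifier: parallel 3×3×3 and 5×5×5
  convolutions ("hybrid kernel") concatenated into
  `attention_feature_maps` (16) maps, then two 3×3×3 conv + BN + ReLU
  layers and a 1×1×1 classifier with channel softmax.

**Loss.** L_total = κ L_DSC + γ L_CE + λ L_max with κ, γ, λ = 1, 1, 0.5.
L_DSC is soft Dice with per-class *spatial* sums (the per-class published
form leaves the aggregation implicit; spatial aggregation is the standard
reading and makes empty classes contribute ε/ε ≈ 1, i.e. no penalty).
L_CE is unweighted voxel-mean cross entropy of the main head. L_max is the
class-weighted cross entropy of the supervision heads; class weights
default to inverse frequency in the training batch normalized to mean 1
(the published description asks for imbalance-alleviating weights without
a formula). Probabilities are floored at 1e-12 before logs.

**Optimizer.** Mini-batch SGD with momentum 0.9, L2 penalty 1e-4, global
gradient-norm clipping at the configured threshold (default 0.005 — the
published "gradient threshold" is read as norm clipping since no other
definition is given), initial learning rate 1e-3 with ×0.1 step drops at
the configured iterations. All sampling is seeded; two runs with the same
seed produce identical loss histories.

**Implementation.** No GPU framework is assumed: the network runs on a
purpose-built NumPy reverse-mode autodiff engine (`rfdseg.nn.autograd`)
with float64 arithmetic. Convolution is implemented as k³ channel-mixing
matmuls over shifted views (memory O(input), no im2col matrix). Every op's
backward pass is validated against central finite differences in the test
suite, and the graph-built training loss is asserted equal to the plain
NumPy loss formulas to 1e-12.

**Inference** tiles the volume with the model's patch size (tail windows
overlap), averages overlapping probabilities, renormalizes, and takes the
per-voxel argmax with ties broken toward the lower class index. Volumes
smaller than a patch are edge-padded and cropped back.

## Metrics

DSC is implemented as 2|P∩T|/(|P|+|T|). (The printed set-notation variant
dividing by |P∪T| evaluates to 2 for identical masks; the sum-denominator
form is the one consistent with a [0, 1] Dice and with reported ranges.)
HD95 ships in two modes because the name is used for two different
quantities: `paper` (default) is the literal 0.95 × max{d_XY, d_YX} scaling
of the symmetric Hausdorff maximum; `percentile` is the conventional 95th
percentile of pooled directed surface distances. Both are tested; on the
single-pair example they give 2.85 vs 3.0. ASD is the symmetric average
surface distance. Surfaces are foreground voxels with a face-connected
background neighbor (4-connectivity in 2-D, 6 in 3-D); image-border voxels
count as surface. Distances are Euclidean in voxel units; a physical
spacing vector multiplies coordinates when supplied. Sensitivity and
specificity are standard one-vs-rest confusion rates. Macro values are
unweighted means over classes present in the truth; classes absent from
both masks are skipped and reported; surface metrics of classes missing
from one side are NaN and excluded from the macro mean.

## The phantom generator

The phantom emulates the data regime the discretizer is designed for: per
slice, a retina band (REA) bounded by two smooth sinusoidal surfaces
occupying ≈ 61 % of the area, an ellipsoidal SRF blob strictly inside the
band (≈ 0.7 % of voxels), and a small PED bump seated on the lower band
boundary (≈ 0.03 % target; on small test volumes the realized fraction is
necessarily coarser, and infeasibly small classes are emitted empty with a
warning). Class base intensities (30, 110, 180, 240 by default — ordered,
well separated, inside 8 bits) are corrupted by multiplicative
gamma-distributed speckle with mean 1 and variance 1/looks, the canonical
coherent-imaging noise model, then quantized to 8 bits. `looks = inf`
disables noise, giving a piecewise-constant volume on which discretization
is provably exact — the end-to-end property tests use this limit.

What the phantom does *not* model: A-scan physics, depth-dependent signal
decay, vessel shadows, motion artifacts, annotator noise in the gold
standard. Passing tests on phantoms therefore demonstrate correctness of
the algorithms and the plumbing, not clinical-grade segmentation accuracy;
results on real OCT data depend on factors the phantom omits.

## Problem sizes and defaults used in tests

The test suite and the acceptance script run on one CPU: discretization
properties use a 16×64×64 phantom (per-slice GA over ≤ 256 candidates);
oracle equivalences use tables of N ≤ 500 pixels; GA-vs-exhaustive uses
≤ 12 candidates (2¹² enumerable schemes); the network capacity check
overfits a single noisy 16³ phantom with a depth-2, base-8-channel model
for 200 iterations (learning rate 0.05, clip 1.0 — an overfitting recipe,
distinct from the full-scale training defaults) and verifies training
macro-DSC ≥ 0.9. The full-scale configuration (64³ patches, depth 4,
16→128 channels, lr 1e-3 with drops) remains available through
`NetworkConfig`/`TrainConfig` but is not exercised by the default suite.

## Known limitations

- FCM is one-dimensional by design (brightness is the only condition
  attribute); no spatial regularization, kernelized or possibilistic
  variants.
- The rough-fuzzy model supports no variable-precision or tolerance
  generalizations.
- The GA is single-objective with fixed operator rates.
- 2-D network mode is out of scope; small 3-D patches stand in for
  desk-scale testing.
- The NumPy network is float64 and CPU-bound: suitable for method study
  and small volumes, not for full-resolution clinical training runs.
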