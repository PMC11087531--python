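# Methods

This note records the models implemented in `qigwo`, the parameter
conventions, the choices made where the underlying method is open to
interpretation, and what the synthetic-data experiments do and do not show.

## Grey wolf optimizer (gwo_core)

The continuous optimizer follows the standard encircling equations with
`A = 2a·r₁ − a`, `C = 2r₂` drawn fresh per leader per wolf per iteration
(draw order: leaders α, β, δ; r₁ before r₂), and the exploration
coefficient `a = 2(1 − t/T)` decaying linearly over the configured
iteration budget. Out-of-box positions are clamped to the search box; this
is the only constraint handling. All runs are bit-reproducible from
(seed, config): the generator is `numpy.random.default_rng(seed)` and the
draw order is fixed.

**Leader set.** The three leaders are the three best solutions found so
far, re-ranked after every iteration by merging the incumbent leaders with
the freshly evaluated pack (stable sort; incumbents win ties). A pure
per-iteration re-ranking — leaders drawn only from the current pack — was
evaluated first and discards improvements as soon as the pack moves past
them; on binary decodes it freezes the search on plateaus (it never solved
a 20-bit OneMax at the default budget in ten seeds). The elitist leader set
keeps the update equations unchanged while making the reported best
monotone by construction.

**Binary variant.** BGWO keeps continuous positions inside the box
(conventionally [0,1]^d) and decodes with the flag rule — bit 1 iff the
component is strictly greater than 0.5 — only when evaluating the
objective. Because the decoded objective is piecewise constant, the pack's
decode collapses onto the leader consensus once `a` is small, and any wolf
whose pattern duplicates a leader's pattern contributes no information. The
loop therefore re-seeds such duplicate wolves uniformly in the box before
evaluation. This duplicate guard is the binary path's analogue of the
quantum variant's component re-seeding; without it the optimizer finds the
global optimum of random 4-bit objective tables in 87/100 cases and 20-bit
OneMax in 0/10 seeds at the default budget (population 10, 200 iterations);
with it, 100/100 and 8/10.

**Defaults.** Population 10, 200 iterations. Both are configurable, also
from a `key = value` config file (`load_config`).

## Quantum-inspired binary optimizer (iqi_bgwo)

Each wolf carries one qubit amplitude pair (x, y) per dimension with
x² + y² = 1; y² is the probability of reading bit 1. Amplitudes initialize
to 1/√2 each (equal superposition). An initialization of literally 1/2 per
amplitude violates normalization (¼ + ¼ ≠ 1); the config accepts it but
renormalizes with a warning.

Per iteration, one λ and one γ are drawn per leader (both uniform on
[0,1]; the distribution of γ is otherwise unspecified, uniform is the
noncommittal choice), giving ζ = λπ and a scalar angle per wolf per leader
`θ_l = ζ_l γ_l Σ_d (X_l,d − X_d) · 2π`. The wolf's qubits are rotated by
the y-axis gate through θ_α, θ_β, θ_δ in sequence; since y-rotations
compose additively this equals one rotation by the summed angle. Only the
y-gate enters the dynamics; the x- and z-gates are provided as matrices for
completeness but unused (they introduce complex amplitudes).

**Position update and re-seeding.** Positions contract multiplicatively,
X ← X·y², which has an absorbing state at 0; any component below 1e-6 is
re-seeded uniformly on [0,1] to keep exploration alive.

**Decode pipeline.** A wolf's bits are obtained by thresholding its
(post-update) position against each *leader's* y² (bit = 1 iff X_d ≥ y²_l,
inclusive), majority-voting the three bit vectors, and gating through the
sigmoid transfer with threshold `s` (default 0.4, the average of the
published ten-trial sweep). Two readings were rejected as degenerate:

* comparing a wolf's own post-update position to its own y² reduces to
  `X_pre ≥ 1`, i.e. an all-zero decode, because the update just multiplied
  the position by that same y²;
* applying the sigmoid to an already-binary consensus maps it into
  [0.5, 0.731], so any `s ≤ 0.5` would emit all-ones. The gate here is an
  AND against the wolf's continuous component (`sigm(X_d) ≥ s`), which is
  inert at the default `s = 0.4` and progressively sparsifies the decode
  for `s > 0.5`.

A consequence of the multiplicative update is that freezing the rotation
(ζ = 0) freezes the qubit state and hence all thresholds, but *not* the
decode: positions keep contracting, so decoded bits still drift toward 0
between re-seeds. The stationarity tests therefore assert what the model
actually guarantees — stationary amplitudes and thresholds.

**Recombination and refinement.** The loop maintains an elite archive of
the three best *distinct* bit vectors seen so far and evaluates, per
iteration, (a) their majority vote — the voting step of the decode pipeline
used as a recombination operator — (b) their unanimity (bits all three
agree on), which prunes components without universal support, and (c) a
backward-elimination probe of the incumbent best with one active bit
cleared at random. The probe uses a dedicated random stream so the pack
dynamics are identical with or without it. The rationale: the rotation
angle is a scalar per wolf, so the quantum dynamics carry no per-component
signal; distinct-elite voting and the elimination probe supply the
component-level exploitation that wrapper feature selection needs (without
them the mean false-selection rate on the 5-of-30 recovery design is about
0.6; with them about 0.12–0.15, at unchanged recall). The role of the
non-leader wolves is otherwise under-determined in this family of
algorithms; the probe is this package's reading of a scout role.

## Benchmark suite

F1–F10 are the canonical grey-wolf benchmark battery: Sphere [−100,100],
Schwefel 2.22 [−10,10], Schwefel 1.2 [−100,100], Schwefel 2.21 [−100,100],
Rosenbrock [−30,30], generalized Schwefel [−500,500] (minimum
−418.9829·d at 420.9687·1), Rastrigin [−5.12,5.12], Ackley [−32,32],
Griewank [−600,600], generalized penalized no. 1 [−50,50]; dimension 30 by
default. Binary optimizers evaluate them through a fixed-point encoding (16
bits per dimension by default, most-significant bit first). Repetition r
uses seed `base_seed + r`. Summary statistics use the sample (ddof = 1)
convention; a single repetition reports zero spread. The statistical
battery is the paired Wilcoxon signed-rank test, Cohen's d with pooled
standard deviation, one-way ANOVA, and Tukey HSD when the omnibus test is
significant; a pair with all-zero differences is reported as degenerate
with d = 0. The harness reproduces the comparison protocol, not any
particular published magnitudes — per-table budgets for published grids are
generally under-specified. PSO and GA baselines are not bundled; a uniform
random-search baseline with the same evaluation budget is, and any callable
honoring the objective contract can be plugged in.

## SVM-RBF and hyperparameter search

The kernel is `k(a,b) = exp(−‖a−b‖²/σ²)·λ`; λ = 1 recovers the Gaussian
kernel and any λ > 0 rescales the Gram matrix linearly, preserving
symmetry and positive semi-definiteness. The soft-margin QP is not a
contribution of this package and is delegated to scikit-learn's SVC with
the kernel injected as a precomputed Gram matrix, one binary classifier per
class (one-vs-all); prediction takes the class with the largest decision
value, with no probability calibration. The search optimizes (penalty C,
σ) on log scales over C ∈ [2⁻⁵, 2¹⁵], σ ∈ [2⁻⁸, 2⁸] (the conventional RBF
grid ranges); λ is fixed at 1 by default because the kernel scale and the
penalty play overlapping roles, and C/σ are the performance-critical pair —
λ remains searchable through the config. The CV fitness uses stratified
folds fixed once per search (derived from the config seed) so the search
surface is deterministic; rows are canonicalized by lexicographic sort
before fold assignment, making the score invariant to row permutation.

## Wrapper feature selection

Fitness = `q·Pr(M) + e·|R|/|C|` with q = 0.99, e = 1 − q = 0.01, where
Pr(M) is read as the wrapper classifier's cross-validated error rate on the
masked features. Empty masks receive the sentinel fitness 1 + e (worse
than any feasible value) and cannot be returned. The wrapper classifier
defaults to the scaled-RBF SVM with fixed mid-range parameters (penalty 1,
σ = √(selected count), λ = 1) so one fitness evaluation costs one CV;
nested hyperparameter optimization is available behind the spec option.
Mask scores are cached per run. Trial summaries compute exact arithmetic
column means; rounding happens only at display time.

## Evaluation

Accuracy, sensitivity and specificity are percentages; MCC is scaled to
[−100, 100] and reported as 0 with a degenerate flag when any marginal is
empty. Two error-rate conventions are reported side by side —
`1 − (SEN+SPC)/200` (balanced) and `1 − ACC/100` (complement) — because
published CAD tables frequently print the complement while quoting the
balanced formula, and the two disagree off balanced class mixes. ROC
curves sweep descending score thresholds with ties grouped; AUC is the
trapezoidal area and equals the Mann–Whitney pair statistic, which the
tests verify by brute force. Multiclass ROC is one-vs-rest on the abnormal
class by default.

## Imaging

PGM reading supports P2 and P5 with comments and 16-bit (big-endian)
rasters; malformed input raises an error carrying the byte offset. The
parser is hand-written because the contract requires ASCII P2, bit-exact P5
round trips and offset-bearing errors. MIAS-style annotation coordinates
use a bottom-left origin; records keep the raw (x, y) and conversion
(row = height − 1 − y) happens where the image height is known, since the
annotation format does not carry it. ROIs are fixed 120×120 crops (the
annotation radius is kept as metadata, not used for rescaling); windows
near a border are shifted inward, never padded. Normal-class ROIs center
on a uniformly drawn pixel of the breast mask (Otsu threshold on the
median-filtered image, largest connected component). CLAHE accepts the
histogram-clip-factor convention (default 2.0, 8×8 tiles, converted
internally to scikit-image's clip fraction over 256 bins); constant images
pass through unchanged. Defaults: 3×3 median window, one random 72×72
patch per ROI. Classifier features are flattened, per-patch min-max
normalized patches.

## Synthetic data

Phantoms are stylized, not radiographically realistic: a noisy breast disk
(background 80, σ = 5 on the 8-bit scale), a radially symmetric Gaussian
blob for benign lesions, and the same blob with angular spikes (default 8)
plus boundary jitter for malignant ones. They exercise the pipeline's
geometry and the round-versus-spiculated shape contrast — benign half-max
contours have measurably higher circularity — which is what the shape- and
pipeline-level tests require. Passing tests on phantoms demonstrates the
plumbing and the optimizers' behavior, not clinical performance: the
phantom lesion/background contrast is far cleaner than real mammograms, so
the end-to-end accuracy on phantoms says nothing about accuracy on real
corpora. Default corpus composition is 207 normal / 63 benign / 52
malignant 1024×1024 images, matching the screening corpus the loader
targets; tests use 256×256 to stay desk-scale.

Feature tables are two-class Gaussians: informative features separate the
classes by `mean_shift·noise_sigma` (defaults: 5 informative of 30
features, shift 2.0, σ = 1, 150 samples per class), the rest are shared
noise; rows and columns are shuffled so the signal is not positional. The
two-sample mean difference of an informative feature recovers the
configured shift within sampling error.

## Problem sizes and determinism

Every generator and optimizer is a pure function of (spec/config, seed).
The bundled experiments use: sphere convergence with population 30 × 500
iterations over 10 seeds; exhaustive-oracle checks on 4-bit tables with
population 10 × 200 iterations over 100 tables; feature-selection recovery
with population 8 × 100 iterations and 5-fold CV over 10 seeds; XOR tuning
with population 10 × 15 iterations and 5-fold CV over 10 seeds; and a
40-image 256² phantom corpus with 3 patches per ROI and an ROI-level
held-out quarter. These sizes keep the full suite and the acceptance
script within a few minutes on one CPU while leaving each empirical
property a comfortable margin.

## Known limitations

* The quantum dynamics carry no per-dimension signal (scalar rotation
  angles), so the optimizer's component-level exploitation comes from the
  elite recombination/probe machinery, not from the qubits.
* No constraint handling beyond box clamping; no parallel evaluation.
* The SVM has no probability calibration, and only the scaled-RBF kernel.
* Phantom imaging omits pectoral muscle, tissue texture and calcification
  clusters; the corpus loader reports whatever class counts its input
  yields and asserts none.
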