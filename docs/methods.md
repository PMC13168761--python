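# Methods

This note records the models, the estimation choices, and the places where a
published procedure left a genuine design decision to the implementation.

## Classifier

The network is a 3D densely-connected CNN. A 3³ convolutional stem (stride
1) produces `init_filters` feature maps; each of four dense blocks holds one
dense layer — batch norm → ReLU → 1³ bottleneck convolution (4·growth
filters) → batch norm → ReLU → 3³ convolution (growth filters) — whose
output is channel-concatenated with its input, so the channel count entering
block *b* is `init_filters + growth·(b−1)`. The three transitions are batch
norm → ReLU → 1³ convolution (channel-preserving, no compression) → 2³
average pooling, stride 2. The head is global average pooling → dropout 0.5
→ fully connected → two-way softmax; `p(SVCI)` is the positive-class output.
Kernel sizes, the stem, and the absence of transition compression are this
package's choices (the reference recipe does not state them), which is why
the full-width parameter count (558,530 at two input channels, 64/32
filters) is reported as a diagnostic rather than matched to any printed
figure.

Reference training recipe (the `TrainConfig` defaults): batch 16, learning
rate 5e-5, 50 epochs, Adam with weight decay 1e-3, cosine-annealed learning
rate (exactly `lr·½(1+cos(πe/E))`, so the final epoch runs below 1e-7),
cross-entropy. Augmentation, applied on the fly to training batches only:
with p = 0.30 one of {additive intensity shift by `f−1`, `f ~ U(0.9, 1.1)`;
intensity scaling ×1.1}; with p = 0.20 one of {flip along the first spatial
axis; zoom by `U(0.9, 1.1)` resampled back}. "Shift from 0.9 to 1.1" is read
as an offset of `f−1 ∈ [−0.1, 0.1]`: on z-scored inputs an additive offset
near 1 would dominate the signal. Intensity normalization is a per-sample
z-score over in-mask voxels, so train and test statistics cannot mix by
construction. Ties at probability exactly 0.5 predict SIVD.

Desk scale. Every simulation-based test and the acceptance script run the
same architecture family at grid 16³ with `init_filters=24, growth=12`,
learning rate 1e-3, 15–25 epochs, and 24–60 subjects per group×site cell.
These sizes keep a full workflow run in minutes on one CPU core with the
numpy backend; the 1e-3 rate compensates for having tens rather than
hundreds of optimizer steps. Full-width structural properties (connectivity,
parameter count, determinism) are tested at the reference widths.

## Domain adaptation

DANN with the DenseNet trunk as shared feature extractor F, the classifier
head C, and a domain head D (pooled features → GRL → 256-wide rectified
hidden layer → two-way softmax; the hidden width is this package's choice).
λ follows the logistic schedule on linear training progress and multiplies
the reversed gradient; α = 0.1 weights the two domain losses in the total.
Each iteration draws one source and one target batch of equal size (default
4); iterations per epoch are `floor(min(n_src, n_tgt)/batch)`. The UDA
entry point takes no target labels at all. Adaptation warm-starts from the
source-trained checkpoint by default (cold start available) — the reference
procedure is silent here, and warm starting matches its stated purpose of
improving an already-trained model. Convergence is summarized as the rolling
standard deviation of the per-epoch source/target domain losses plus their
gap. Desk-scale UDA uses lr 1e-4 for the same step-count reason as above.

## Saliency

Guided backpropagation per the double-gating rule: at every rectifier the
backward signal is zeroed where the forward pre-activation was non-positive
or the incoming gradient is non-positive. The per-voxel map is the sum of
the **absolute** gated gradients over input channels. Summing signed values
would let channels with opposite pathological directions cancel: FA falls
while MD rises in damaged tissue, so their input-layer gradients for the
SVCI logit carry opposite signs, and the signed sum empirically erases the
lesion signal (tier/saliency rank correlation 0.32 signed vs 0.93 absolute
on planted cohorts). Maps are min-max normalized to [0, 1] within the
analysis mask.

Group inference: voxel-wise one-sample t (df = n−1), zero-variance voxels
excluded; t→z by tail matching; voxel-level GRF threshold from the expected
Euler characteristic with resel counts R₀..R₃ of a volume-matched box (side
lengths from the mask bounding box, divided by per-axis FWHM). Smoothness is
estimated from standardized residual maps via the derivative-variance
relation `FWHM = sqrt(4 ln 2 / var(∂u))`. Monte-Carlo calibration on smooth
nulls (FWHM 3 voxels, 200 fields): family-wise error 0.02 at α = 0.05, and
the threshold is within 3% of the empirical 95th percentile of the field
maximum. The EC polynomial is non-monotone below z ≈ 1.7, so the solver
searches a dense grid upward from the uncorrected threshold rather than
root-finding blindly.

## Mutual information and significance

MI is estimated per voxel from the joint histogram after equal-width
binning of each variable over its observed range, in bits; multi-channel
combinations average per-channel MI (a joint 3-variable histogram is not
estimable at n ≈ 44–60). The module default is 8 bins; the desk-scale
pipeline uses 3 bins, because the histogram-MI bias and its voxel-to-voxel
variance scale like (Bx−1)(By−1)/N and at N = 60 they would otherwise
swamp the spatial contrast of the maps.

Significance combines permutation and random-field control. Scores are
permuted across subjects (default 100 times); rank p-values use the add-one
formula and are floored at 1/(n_perm+1) ≈ 0.0099 — a floor that can never
cross a GRF-corrected threshold (z ≈ 4). The permutation stage therefore
also returns a null-calibrated z map, `z = (MI − mean_null)/sd_null`, and
that statistic is what the GRF threshold is applied to. The p→z route is
retained for uncorrected use.

Similarity metrics: Dice and Jaccard on the binarized (GRF-surviving) maps;
SSIM computed globally over in-mask voxels of min-max normalized maps with
C1 = (0.01 L)², C2 = (0.03 L)², L = 1; Jensen–Shannon divergence with base-2
logarithm (bounded by 1) on sum-normalized maps with 0·log 0 := 0.

## Risk profiling

Subject-level SSIM compares each patient's saliency map with each scale's
MI map. Both map families are Gaussian-smoothed by σ = 0.8 voxels first:
guided-backprop maps carry high-frequency gating noise that is irrelevant
to the regional alignment the score is meant to capture, and the light
smoothing roughly doubles the separation between planted severity tiers
without changing the ranking. K-means (k-means++ with 50 restarts, seeded)
clusters the per-scale SSIM values; clusters are relabeled low/moderate/high
by ascending mean, ties broken by descending size. The elbow rule picks K at
the largest curvature of **log** within-cluster dispersion — raw-scale
curvature always peaks at K = 2 for equally separated clumps, while the
log-scale rule recovers the true count. Kruskal–Wallis and Dunn's test
(with tie correction, Bonferroni over pairs) compare clusters. Testing SSIM
differences between clusters that were derived from the same SSIM values is
circular; the package reproduces it as a pipeline contract and the null
behavior of the tests is verified only with independently assigned labels.
The 80%-subsample sensitivity analysis rebuilds MI maps on a random subject
subset, recomputes all SSIMs, reclusters, and reports cluster-wise means,
the label change rate, and the full/subsample Spearman correlation.

## Harmonization

Parametric ComBat: per-feature location/scale model fitted by least squares
(site indicators plus optional covariates; diagnosis is excluded from the
covariates by default to avoid leakage), standardization by pooled residual
variance, then empirical-Bayes shrinkage of per-site location (normal prior
across features) and scale (moment-matched inverse-gamma prior) with the
standard fixed-point iteration. Parameters fit on training data only and
apply unchanged to held-out subjects; unseen sites are an error, constant
features are passed through with a warning. Features are a reduced
representation — per-atlas-region channel means — rather than full-resolution
voxels, which keeps the estimator well-conditioned at cohort sizes where
voxel-wise fitting would be noise.

## Evaluation

Confusion-matrix metrics are computed in exact rational arithmetic
(SVCI positive): accuracy, recall, specificity, and binary F1
`2TP/(2TP+FP+FN)`. Several published F1 values equal accuracy and are not
consistent with the binary formula given the implied confusion matrices; the
binary definition is the contract here, with a support-weighted average
available as a documented option. AUC is the trapezoidal area over all
thresholds with tied scores grouped (verified equal to Mann–Whitney
U/(n₊n₋)). Confidence intervals: Clopper–Pearson exact for proportion-type
metrics, percentile bootstrap (2000 resamples, seeded) for F1. DeLong's
structural-components test compares paired AUCs (z = 0, p = 1 for identical
scores). Decision curves report `NB(t) = TP/N − (FP/N)·t/(1−t)` on a
0.01–0.99 grid with treat-all/treat-none references; calibration uses ten
equal-width bins. Probability–score correlations choose Pearson vs Spearman
by Shapiro–Wilk normality of both variables at α = 0.05. The salient-region
relevance check trains a small 3-stage CNN regressor (8 filters per stage,
squared-error loss) on volumes zeroed outside a mask and reports test-set
correlation between estimated and true scores.

## Synthetic cohorts

Structure: 2 diagnosis groups × 2 sites × n subjects, four channels at
channel-typical baselines (FA 0.45; MD/AD/RD 0.80/1.20/0.60 ×10⁻³ mm²/s),
voxel noise SD 0.10 smoothed to FWHM 3 voxels (unit-variance after
smoothing, so downstream GRF assumptions hold). The atlas partitions a
central ellipsoid into nearest-seed parcels (convexity makes each parcel
contiguous). Lesions: per-region severity, Gamma(2, 0.5) by default
(nonnegative, right-skewed burden), or discrete tiers for stratification
ground truth — "extent" tiers spread lesions over progressively more regions
at fixed amplitude (burden spreads with severity, the default) and
"amplitude" tiers scale severity uniformly. The planted shift is
`effect_size · noise_sd · severity` with channel pattern FA −1, MD +1,
AD +0.5, RD +0.75 (radial more affected than axial), modulated within each
region by a subject-specific nonnegative smooth blob field (mean-preserving)
so lesions are focal like white-matter hyperintensities rather than uniform
region offsets — uniform offsets are nearly invisible to gradient-based
saliency, focal texture is not. Scores:
`intercept − sign·Σ(w·severity) + noise`, clamped to clinical ranges, with
sign +1 for MMSE/MoCA/Recalls and −1 for the timed TMT tests, and each
scale's weights concentrated on a different lesion region so the six MI maps
have distinct supports. Site effects: a global affine shift (offset 0.2,
scale 1.1) plus a fixed smooth multiplicative gain field (amplitude 0.25)
for the external site. The affine part is what ComBat removes; the gain
field survives per-sample z-normalization and is what makes the domain shift
visible to the classifier, motivating adaptation.

What the generator does not emulate: anatomy, partial-volume effects,
registration error, realistic lesion shapes, demographic covariates, or
score floors/ceilings beyond clamping. Passing tests therefore demonstrate
method correctness and recoverability of planted effects, not clinical
performance.

## Known limitations

- The tier-recovery clustering is the weakest link of the chain: the
  SSIM-vs-MI readout is strongly monotone in planted severity (Spearman
  ρ ≈ 0.8–0.93) but within-tier spread from subject-specific gating noise
  leaves cluster overlap, so adjusted Rand indices against planted tiers
  plateau around 0.5–0.7 at desk scale.
- Guided backpropagation is known to be only weakly class-sensitive; it is
  implemented as specified, and the group-level localization tests are the
  evidence it carries lesion information here.
- The GRF correction treats the mask as a volume-matched box; strongly
  non-convex masks would need exact resel counting.
- Histogram MI at n ≤ 60 is bias-dominated; bin counts are exposed in every
  API and recorded in outputs.
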