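# Methods

This note documents the models, conventions, and numerical choices behind
the package, and what the synthetic-data generators do and do not emulate.

## Activity scoring

Per-cell readouts follow the two reporter families. Kinase translocation
reporters (ERK, p38, JNK, PKA, AKT) export the fluorophore from the nucleus
upon pathway activation, so the readout is the cytoplasm-mean /
nucleus-mean intensity ratio; a zero nuclear mean drops the cell with a
logged count. Transcription-response-element reporters (p53, WNT, NFkB,
HIF, RAR, YAP/TAZ, plus the Geminin cell-cycle marker) accumulate the
fluorophore with pathway output, so the readout is the nuclear mean minus
the cell-specific background, clipped at zero and flagged when negative.

The activity score for a (drug, reporter, timepoint) group is the
two-sample Kolmogorov–Smirnov statistic against the pooled time-matched
vehicle-control cells of the same clone, signed by the direction of the
median shift. Pooling all control wells (rather than matching wells
one-to-one) maximizes the control sample size; this is the package's
convention where a choice had to be made. Sign tie-breaks: equal medians
fall back to the sign of the mean difference, then to zero. The magnitude
is exact — it is computed by an ECDF evaluation over the union of both
samples and is verified against a brute-force scan in the test suite.
Groups with fewer than 30 cells on either side are marked invalid rather
than scored.

Two properties of the sign are worth stating precisely. The median-decided
sign is invariant under strictly increasing monotone transforms of both
samples whenever the median is an order statistic (odd sample sizes); the
interpolated median of even-sized samples, and the mean-difference
tie-break, are not transform-invariant. The magnitude |D| is always
invariant.

**Threshold.** The significance threshold is the 99.5th percentile
(linear-interpolation quantile) of |score| over leave-one-well-out
control-vs-control scores — each control well scored against the pool of
the rest — requiring at least 20 such null scores. The phrase "0.5
percentile" in common usage is ambiguous between the 0.5th and 99.5th
percentile and between signed and absolute scores; the package reads it as
the extreme half-percent tail of |score|, which is the only reading
consistent with a symmetric ±0.2 band. The conventional fallback threshold
is 0.2. A drug is *active* if any valid |score| exceeds the threshold at
any post-treatment timepoint.

## State analysis

Drug × pathway score slices are clustered by agglomerative hierarchical
clustering with Euclidean distance and Ward linkage in the Ward.D2
convention (squared-distance update on raw Euclidean input, as implemented
by `scipy.cluster.hierarchy.linkage(method="ward")`). Pathways with any
missing score are dropped listwise before clustering or PCA, mirroring the
exclusion of a reporter that is not measured for every drug. Cluster
letters A, B, C are assigned by decreasing cluster size.

PCA is column-centered and unscaled (scores already share the [−1, 1]
scale), computed by SVD. The sign of each loading vector is fixed by
making its largest-magnitude entry positive; alternatively PC1 can be
oriented along a supplied axis (used when a fixed biological orientation of
the two states is wanted, e.g. for size–state correlations).

Per-drug metrics on the PC coordinates: conformity ψ = PC₁/√(ΣPCᵢ²);
adherence = |PC₁|/ΣPCᵢ² — implemented exactly as conventionally printed,
which makes it scale-dependent (it is not invariant to rescaling the effect
vector); a `normalized=True` variant divides by √(ΣPCᵢ²) instead. Strength
= √(ΣPCᵢ²), which equals the Euclidean norm of the centered effect vector
by rotation invariance.

**The φ metric.** φ = Πₙ σ²(projection onto reference axis n) / Πₚ σ²(
original pathway axis p), computed in log space. φ(identity reference) = 1
exactly, and φ(data's own eigenbasis) = det(Σ)/Πₚσ²ₚ ≤ 1 by Hadamard's
inequality, the minimum over all orthonormal references. Note that φ ≤ 1
does **not** hold for an arbitrary reference: for a strongly anisotropic
covariance that is already nearly diagonal on the original axes, a
scrambling rotation equalizes the projected variances and their product
exceeds the original-axes product (φ > 1). In the intended use — the
reference is a PCA basis fitted to related (pre-treatment) data — φ stays
in (0, 1] for all practical purposes, and low φ means the reference
explains the data's correlation structure well. Zero variance on any axis
makes φ undefined and raises.

## Deconvolution

The design has one 0/1 indicator column per annotated target and one
product column per unordered target pair co-annotated in at least one
compound; higher-order interactions are not generated. The loss
Σᵢ(yᵢ−Σⱼxᵢⱼβⱼ)² + λΣⱼvⱼβⱼ² is minimized in closed form via the normal
equations with diagonal penalty λvⱼ (vⱼ = 1 for individual targets, v for
interactions). By default columns and response are centered and the
intercept is recovered unpenalized; `center=False` solves the loss exactly
as written (no intercept), which is the form checked against a numerical
minimizer in the tests.

Cross-validation uses seeded folds stratified by response quantile. The λ
grid is 50 log-spaced values from λ_max = max|Xᶜᵀyᶜ|/n down to 10⁻⁴λ_max
(the standard data-driven ridge grid); v is searched over 2⁰…2³⁰. The
boundary rule: if the best CV error achievable at v = 2³⁰ (interactions
fully suppressed) lies within one standard error of the global CV minimum,
the search is deemed to have found no genuine interior optimum — the
curve is still decreasing or flat at the boundary — and the interaction
columns are dropped and the model refit over λ alone. The one-SE
comparison, rather than a literal argmin-at-boundary test, is needed
because the global minimum over a ~1500-point grid is biased low by
selection noise; with additive ground truth the CV curve in v is a noisy
plateau whose argmin lands anywhere. A finite-sample caveat: on designs
with strongly co-occurring target pairs, a *partially shrunk* interaction
column can act as legitimate extra regularization for the collinear
parents and genuinely lower CV error, so interaction-dropping on
interaction-free data is the typical, not the guaranteed, outcome.
Reported target effects are the individual (non-interaction) coefficients
only.

## Growth and division

The population model is exponential: N(t) = N₀·2^(t/τ) with division rate
α = ln2/τ, and mean per-cell mass m(t) = m₀·e^((γ−α)t), so bulk mass is
M(t) = N·m and balanced growth (γ = α) keeps m constant. Fits are
unweighted log-linear least squares pooling all replicate points: α from
ln N(t), and γ = d ln m/dt + α with m = M/N. Nonpositive points are
dropped with a warning; a flat count series yields α = 0, τ = ∞ with a
degenerate flag. Control normalization gives γ̃ = γ/γ_ctrl, α̃ = α/α_ctrl
and the imbalance log₂(γ̃/α̃); the noiseless generator→fit round trip is
exact to machine precision, and halving exactly one rate gives imbalance
∓1 by construction. Condition-level cell size from the screen is the
median segmented cell area per condition (configurable to nuclear area in
principle; area is what the generator plants).

## Barcode calling

Nuclei are segmented from the nuclear-marker channel by Gaussian smoothing
(σ = 2 px), Otsu thresholding, removal of sub-40-px objects, and a
distance-transform watershed that splits touching nuclei (peak separation
7 px). Cells are grown from the nuclear seeds by watershed over the
smoothed body channel; the cell label equals its seed nucleus label, so
every nucleus lies in exactly one cell. Tertiary compartments per cell:
cytoplasm (cell minus nucleus), a 3-px perinuclear ring, and a
cell-specific background annulus 2–5 px outside the cell excluding all
other cells.

The cytological profile holds, per channel and compartment, seven
intensity statistics (mean, median, SD, 25th/75th/90th percentiles,
integrated), per channel two local-variance summaries and four gray-level
co-occurrence properties (contrast, homogeneity, energy, correlation at
distance 1, two orientations averaged, 32 levels), a similarity-to-nucleus
feature (within-cell Pearson correlation with the nuclear marker — the
imaging-cytometry "similarity" feature), and eight shape descriptors —
over 200 features with a nuclear marker plus four fluorophores. Cells
under 10 px are dropped; empty compartments impute to 0. Feature
extraction is deterministic given an image.

The classifier is a gradient-boosted tree ensemble
(`HistGradientBoostingClassifier`) with a budget of 50 boosting stages —
the same additive-stages model class as the 50-rule boosting used
historically for this task; the contract is the stage budget and the
stratified 70/30 train/validation split, not the boosting variant.
Training requires ≥200 cells per class and is redone per experiment.
Evaluation: per predicted class the false detection rate FP/(FP+TP), per
true class the miss rate FN/(FN+TP), macro-averaged ignoring undefined
entries. Call confidence is the maximum class probability; calls below
the 5th percentile of validation confidences are flagged low-confidence
(e.g. clones absent at training).

**Barcode-space combinatorics.** Single-protein barcodes are the
fluorophore × localization product (4 × 5 = 20). Dual-protein barcodes are
unordered pairs of single barcodes with *distinct localizations*: each
protein must contribute an independent spatial pattern, while a shared
fluorophore is allowed (that channel then shows the union of two
patterns, still a unique readout). Each single barcode pairs with the 16
barcodes of a different localization, giving 20·16/2 = 160.

## The synthetic-data generators

The generators define the study conditions for every test and for the
acceptance harness; they emulate structure, not instrument physics.

**Screen.** Twelve reporters (5 translocation, 7 transcriptional) pooled
in every well; one well per drug plus 39 vehicle-control wells; timepoints
0–48 h at 12-h intervals; cell counts per clone per well per timepoint
Poisson with mean 656 (the sampling-depth regime of a 384-well screen at
10× magnification). Each cell draws a unit-variance normal latent around a
location μ = well jitter + well state·u + drug effect, transformed
monotonically into the readout: a logistic map onto (0, 4) for ratio
reporters, a lognormal map for intensity reporters (chosen for positivity
and heavy-enough tails; location shifts are therefore exactly what the
distribution-free score detects). Per-cell readout distributions of real
reporters are not publicly tabulated, so these families are stand-ins and
are not claimed to match any particular cell line's biology.

The planted state axis u is a unit vector with equal positive weights on
the growth-stress cluster (ERK, p38, JNK, PKA, AKT), equal negative
weights on the division-stress cluster (p53, WNT, NFkB, HIF, RAR,
YAP/TAZ), and zero on Geminin. A drug's effect is w_d(t) =
ramp_s(t)·s_d·u + ramp_e(t)·e_d with saturating ramps 1−e^(−t/τ): τ = 12 h
for the shared-state component and τ = 3 h for the idiosyncratic vector
e_d. The faster idiosyncratic ramp encodes that a compound's direct,
target-specific shock precedes the shared stress response — this is what
produces the observed homeostasis dynamics in which pre-treatment
correlations are scrambled in the first hour and then re-emerge and
deepen. The default three-group design plants |s_d| ∈ [3, 6] with opposite
signs for groups A and B (≈1–2 latent SDs per loaded pathway at full ramp,
comfortably above the stated recovery SNR ‖s·u‖ ≥ 3‖e‖ with conforming
e_sd = 0.35) and s = 0 with a large idiosyncratic component (e_sd = 1.2)
for group C.

Well-level nuisances: a scalar jitter (SD 0.05) shared by all clones of a
well, and a well-state coefficient along u (SD 0.2, constant over time).
The latter models the pre-treatment well-to-well variation in
growth/division balance: it is sized so that pairwise correlations at t=0
are modest (buried in the sampling noise of the score) while PCA across
wells still identifies the state axis before any drug is applied — the
regime in which multivariate analysis sees what pairwise analysis cannot.

Growth ground truth couples to the state: growth-stress drugs (s > 0)
inhibit mass synthesis more than division (imbalance < 0, smaller steady
cells), division-stress drugs the opposite, group C both rates mildly and
equally; planted mean cell area scales with γ̃/α̃ around a 600-px control
median. The control cycle is 24 h and balanced.

**Images.** Cells are random ellipses (area 300–1200 px, aspect
0.55–1), nuclei concentric ellipses at 30% area. Localization renderings:
whole-cell uniform; cytoplasmic = cell minus nucleus; nuclear = nucleus;
peroxisome = 5–20 puncta of radius 1–2 px in the cytoplasm; ER = a 3-px
perinuclear annulus. Every stack carries a nuclear-marker channel and a
phase-contrast-like body channel for segmentation. Noise: per-cell
lognormal brightness (CV 0.25), constant background offset (100 counts),
Poisson shot noise, and Gaussian read noise (SD 60) — defaults chosen so
the 12 classes are separable but not trivially so (validation error rates
land in the low percent range, comparable to real-image barcode calling).
Not modeled: point-spread optics, spectral bleed-through, cell motility,
lineage. Cells that cannot be placed without overlap after bounded retries
are skipped and counted. Pixel convention is 0-based (row, col); output is
16-bit unsigned TIFF, one page per channel.

**Growth timecourses** follow the exponential model above with
multiplicative lognormal noise of configurable CV, two replicates by
default. **Cohorts** are multivariate-normal draws with a supplied
reference correlation (validated symmetric, unit-diagonal, PSD — the
offending eigenvalue is named otherwise); the default marker panel is the
8-protein surrogate used for tumor reverse-phase protein array
comparisons.

All generators fan a single master seed out to independent child streams
and are bit-reproducible.

## Cohort similarity

Cohorts need strictly more than 30 samples (a 30-sample cohort is
skipped). Similarity to a reference correlation matrix is row-wise: the
diagonal is deleted and each protein's remaining p−1 correlations,
aligned by protein identity, are Pearson-correlated with the reference
row; the overall score is the mean over proteins. Missing entries are
handled pairwise-complete with a minimum of min(4, p−1) shared entries
per row, so complete small panels remain scoreable and the minimum binds
only when data are missing. The enrichment-strength scalar is
log₁₀(observed/expected), NaN-with-warning at observed = 0, an error at
expected ≤ 0.

## Problem sizes and determinism

The test suite and the acceptance harness run everything at desk scale:
the parameter-recovery screen uses 100 drugs × 12 pathways × 5 timepoints
at the default 656 cells per reporter per condition (≈5.5 M simulated
cells, scored in under a minute); barcode calling uses 220 cells per
clone across 12 clones (≈2 600 cells, ≈260 features); oracle-equivalence
checks use 1000 random KS sample pairs and 25 random ridge problems;
cohort convergence uses 10⁴ samples. Every stochastic step is seeded, and
the pipeline manifest records the seed and a config hash so identical
configurations produce byte-identical artifacts.

## Known limitations

- The synthetic generators plant location-shift effects only; shape or
  variance changes in reporter distributions (which the KS statistic would
  also detect) are not emulated.
- Cluster letters are assigned by size, not biology; orienting PC1 along a
  known state axis is the caller's choice.
- The adherence metric is scale-dependent as printed; use the normalized
  variant for cross-dataset comparisons.
- The barcode classifier is evaluated on the same synthetic image model it
  was trained on; passing its error bounds shows the pipeline wiring and
  the separability of the rendered classes, not performance on real
  microscopy.
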