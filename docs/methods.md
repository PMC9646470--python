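# Methods

## Scope

`revmark` analyses a paired (two-timepoint) bulk RNA-seq cohort with an
accompanying clinical outcome panel. The pipeline stages are: low-count
filtering → logCPM + precision weights → compound response scoring →
per-gene weighted random-intercept mixed models for three designs →
FDR-based set construction, intersection and reversal statistics →
validation against an external case/control cohort. Upstream read
processing (alignment, deduplication, counting) and downstream pathway
enrichment are out of scope; the package consumes a gene × sample integer
count matrix.

## Expression preparation

**Filter.** A gene is kept when its CPM reaches
`min_count / median(lib) × 1e6` (default `min_count = 50`) in at least
`n*` samples, where `n*` is the smallest group size `s`, softened to
`10 + (s − 10)·0.7` for `s > 10`, and when its total count reaches
`min_total_count` (default 15). Comparisons carry a relative slack of
1e−10 so exact boundary cases are kept. Groups default to the timepoint
labels. The filter is idempotent.

**logCPM.** `log2((count + 0.5) / (libsize + 1) × 1e6)` with raw column
totals as library sizes. No scale-factor (TMM-style) normalisation is
applied by default: for the within-patient contrasts that dominate these
designs, sample-specific scale factors are absorbed by the patient
intercept, and the composition shifts the generator produces are small.

**Precision weights.** Per gene, logCPM is regressed on an
intercept-plus-timepoint design by least squares; sqrt of the residual sd
is smoothed against average log2 count by lowess (span 0.5, 3 robustness
iterations). Each observation's sqrt-sd is predicted from its fitted log
count by piecewise-linear interpolation (constant beyond the trend's
ends, floored at 1e−6) and the weight is the prediction to the power −4.
Weights are therefore inverse variances up to a common scale.

## Compound response score

Per patient and instrument, the change is `orientation × (T10M − T0)`
with orientation −1 for instruments where lower is better, so positive
always means improvement. Each instrument's change column is divided by its uncentered root mean
square with an n−1 denominator; the compound score is the per-patient
mean of the scaled changes over non-missing instruments, with the number
used recorded. A flagged control instrument (resting activity) is always
excluded. Missing values propagate — no imputation — because averaging
over available instruments is the minimal assumption when the original
handling is unspecified.

## Mixed models

The model per gene is `y = Xβ + Zu + ε` with one random intercept per
patient, `u ~ N(0, τ²)`, and `ε_i ~ N(0, σ²/w_i)` with the precision
weights held fixed (they are known variance multipliers, not
re-estimated). Designs: therapy `[1, CBT]`; repeat length
`[1, CBT, CTG/100]` (the /100 scale makes coefficients "per 100
repeats"); response `[1, CBT, CR·1(T10M)]` with the response covariate
exactly zero at baseline. Rank-deficient designs (for instance all-zero
scores) raise immediately.

**Estimation.** REML with σ² profiled out leaves a one-dimensional
problem in θ = τ²/σ². Weights are normalised to mean one internally (σ²
is rescaled back), so θ lives on a natural scale; the search interval is
[0, 1e4]. Through the Woodbury identity on the block-diagonal marginal
covariance, every quantity — GLS normal equations, log-determinants,
quadratic forms — reduces to per-patient weighted segment sums, so all
genes are fitted simultaneously as array operations. The optimiser is a
33-point global grid (zero plus a geometric ladder) that brackets the
optimum, ~80 golden-section iterations, and finally bisection on the
*analytic* derivative of the profiled log-likelihood. The last step
matters: derivative-free searches stall at √machine-eps accuracy in θ,
which would cap the accuracy of downstream standard errors near 1e−7;
the score bisection reaches machine precision. Estimates at θ̂ = 0 are
flagged as boundary fits and coincide with weighted least squares.

**Inference.** For coefficient j, `t = β̂_j/se_j` and
`df = 2(se_j²)²/Var(se_j²)`, where `Var(se_j²) = g'J⁻¹g` with g the
gradient of se_j² in (τ², σ²) and J the observed REML information. Both
are evaluated in closed form (no finite differences) via the same
segment-sum algebra. At the τ² = 0 boundary the random intercept is
dropped from the delta method, which yields exactly the weighted
least-squares residual df `n − rank(X)`. If the information matrix is
not positive definite the σ²-only form is used, and failing that df
falls back to residual df with a flag. In the balanced equal-weight
paired design this machinery reproduces the paired t-test — estimate,
standard error, df = n_patients − 1 and p — to machine precision, and it
matches R's lmerTest to ~1e−9 on weighted unbalanced-covariate fixtures.

Two degenerate regimes are worth knowing about. First, data whose
between-patient variance exactly equals the within-pair residual share
sit precisely on the τ² = 0 boundary, where the paired-t correspondence
degenerates for any mixed-model implementation. Second, splitting an
observation into two half-weight copies leaves the GLS coefficient map
at any fixed variance ratio unchanged, but full REML re-estimation
shifts σ̂² by O(1/n), because the split adds a zero-valued residual
contrast; this is inherent to REML, not an implementation choice.

**Calibration.** On null cohorts from the generator (27 patients, no
planted effects) the empirical type-I error at nominal 0.05 is ~0.051
(therapy), ~0.047 (repeat length) and ~0.058 (response). The mild
liberality of the response design — a covariate active at one timepoint
only, with the variance ratio often small — is a property of
Satterthwaite inference itself at this sample size: per-gene p-values
agree with lmerTest to ~1e−9, including the inflated ones.

**Multiplicity.** Benjamini–Hochberg step-up over the genes with a
defined p-value; non-converged genes are excluded from the denominator
and counted. Significant sets use FDR < 0.05 (0.10 available in
configuration).

## Discovery statistics

The reversal report takes the repeat-length and response coefficient
vectors, computes Pearson r over all converged shared genes and over the
significant-in-both overlap, and the fraction of overlap genes whose two
coefficients have opposite signs. Per-overlap-gene Pearson correlations
between per-patient expression change (T10M − T0 logCPM) and the
compound score give nominal p-values via the t transform on n − 2 df. A
confounding check refits the response covariate on conditional residuals
of the repeat-length model (fixed effects and BLUPs removed, patient
random intercept re-estimated) and correlates the residualised
coefficients with the full-model ones. Per-patient change matrices are
clustered with complete linkage on Euclidean distances after per-gene
z-scaling; zero-variance genes are dropped with a warning, and leaf
order is deterministic for a fixed input order (scipy's tie-breaking by
original index).

## Cross-study validation

Per gene, cases and controls of an external normalized log-count matrix
are compared by a two-sided two-sample Wilcoxon rank-sum test — exact
enumeration when the combined sample is ≤ 12 without ties, otherwise the
normal approximation with continuity and tie corrections — and by the
case-minus-control mean difference. Concordance is Pearson r between the
internal per-100-repeat coefficients and the external mean differences
over shared genes (at least 3 required).

## Synthetic cohort generator

The generator emulates the trial: `n_patients = 27` patients × two
timepoints; `n_genes = 10,000` genes roughly matching the expressed
background after filtering. Per gene: baseline log2 mean ~ N(4, 2²); NB
dispersion log-uniform on [0.01, 0.2] (variance = mean + φ·mean²);
random-intercept sd uniform on [0.05, 0.3]. Effect sets: 500 therapy
genes (|log2FC| in [0.2, 1.2], covering the fold-change band reported in
blood), 600 repeat-length genes (|log2FC per 100 repeats| in [0.1, 0.4],
matching the published 0.76–1.23 per-100 fold-change band), 300
response genes (|log2FC per response unit| in [0.15, 0.6]), of which 100
are reversal genes: members of both the repeat-length and response sets
with response sign forced opposite to the repeat-length sign. Patients
draw repeat lengths log-uniform on [120, 900] and a latent response
uniform on [−1.5, 2.75], mirroring the reported compound-score display
range. Counts are Gamma-Poisson draws at a depth set by log-normal
library sizes (median 30 M × `libsize_scale`). The default
`libsize_scale = 0.1` (≈3 M reads) keeps runs desk-scale while leaving
~7,300 genes above the published filter — at 1/100 scale only ~1,500
genes survive, far from the expressed background the cohort should
emulate, and low-count skewness distorts null calibration.

The outcome panel has 10 informative instruments whose oriented change
is `loading × latent response + N(0, 0.5²)` with loadings uniform on
[0.5, 1.5], three instruments stored with inverted orientation (so the
scoring module must re-orient them), instrument-specific unit scales,
and one pure-noise control instrument that is always emitted and
flagged. The external cohort shares the gene-level truth: cases carry
the repeat-length shifts at freshly drawn repeat lengths, controls sit
at baseline; draws are independent of the paired cohort.

What the generator does *not* emulate: cell-type composition and its
changes, batch and seasonal effects, correlated gene modules
(co-expression), variant (interrupted) repeats beyond an exclusion flag,
and instrument-specific score distributions. Passing tests therefore
demonstrate correctness of the estimators and recovery under the
assumed generative model, not robustness to those real-data features.

The patient-sampling replay applies, in order: completeness and
variant-repeat exclusions, a per-variable window of one interquartile
range around the mean for each baseline variable, then seeded
site-stratified random selection capping candidates that share a
response delta at two, with an audit trail of counts per step.

## Numerical choices and reproducibility

Search interval θ ∈ [0, 1e4]; boundary threshold 1e−10; golden-section
bracket from a 33-point grid; 60 bisection steps on the analytic score.
RMS scaling refuses columns with fewer than two non-missing values or
zero RMS, naming the instrument. All tables are TSV with 'NA' for
missing and six significant digits; canonical files round-trip
byte-identically. One global seed fans out to per-stage child seeds
(stage name hashed), so stages are independently reproducible; identical
configuration and seed give identical outputs. The default test-suite
and acceptance problem sizes (10,000-gene cohorts, 20-replicate
Monte-Carlo loops, 5-cohort null calibration) were chosen to estimate
each property with useful precision on a single core in minutes.
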