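# Methods

`proteonet` re-implements, as a tested and reusable pipeline, the staged
analysis used for multi-batch isobaric-label (TMT) brain-proteome cohorts
in which disease groups lie on an ordered severity continuum (control,
four pathological stages, and an exaggerated-phenotype endpoint): pooled
reference-channel normalization, multi-pass empirical-Bayes batch
harmonization, bootstrap covariate regression, signed weighted
co-expression network construction with module statistics, differential
abundance, cross-network comparison, and marker-based cell-type analysis.
Everything operates on log2-scale abundance matrices (proteins x samples
on disk; estimators take the sklearn samples x features orientation).

## The synthetic cohort

The generator (`proteonet.simulate`) defines the study conditions the
test suite scores against. Per biological sample `s` and protein `p`:

    y[p,s] = baseline[p] + loading[p] * f[m(p), s]
             + batch_add[b(s), p] + platform_shift[p]*1[platform 2]
             + region_shift[p]*1[temporal]
             + b_age[p]*(age - mean) + b_pmi[p]*(pmi - mean)
             + batch_scale[b(s), p] * eps,   eps ~ N(0, noise_sd^2)

* **Cohort layout** — 10 labeling batches of 9 biological samples plus 2
  pooled-reference (GIS) channels flanking them, split across two
  instrument platforms and two brain regions; 90 biological samples in
  groups of 25/7/12/13/16/17 across the severity continuum. Samples are
  randomized to batches uniformly and the assignment recorded.
* **Planted modules** — five modules (sizes 60/50/45/40/30 of 1500
  proteins) each driven by a latent factor `f = trajectory(group) +
  N(0,1)` with loadings U(0.7, 1). Trajectory archetypes over severity
  0..5: decreasing, increasing, mid-stage peak, early plateau, flat; the
  2 SD default effect scales unit shape vectors. With noise_sd 0.5 this
  yields within-module correlations near 0.8. The unit factor jitter is
  what creates sample-level co-variation; its group means therefore
  carry sampling error ~1/sqrt(n_g), so recovery is always scored
  against the *realized* factor trajectory stored in `SyntheticTruth`,
  not the population shape.
* **Technical effects** — per-batch additive shifts N(0, 0.4^2) and
  multiplicative noise-scale factors LogNormal(0, 0.2^2) (the
  location/scale model the harmonization stage estimates), plus
  per-platform and per-region additive shifts. GIS channels carry the
  pooled mean of the clean biological signal plus the same technical
  terms and are noise-free by default, so they anchor harmonization
  exactly and GIS-anchored scoring is exact; `gis_noise_sd` can add
  reporter noise.
* **Missingness** — whole-batch: 12% of proteins are absent in every
  channel of one batch, matching a batch-level completeness filter.
* **Cell types** — five brain cell types with 20 disjoint markers each;
  signatures are log-normal baselines with markers 80x enriched in
  their own type; per-sample simplex fractions are Dirichlet with the
  astrocyte share doubled in the exaggerated group. Mixture samples for
  deconvolution tests are exact convex combinations of the signatures
  with multiplicative log-normal noise.

What the generator does **not** emulate: peptide/spectrum-level effects
(isotopic impurity, ratio compression), intensity-dependent missingness,
correlated module factors beyond what trajectories induce, or outlier
samples beyond what noise produces. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated generative
model, not robustness to every artifact of real reporter data.

## Preprocessing

GIS normalization subtracts, per protein and batch, the mean of that
batch's GIS channels; GIS channels are retained through the cross-batch
harmonization passes (they are technical replicates and strong anchors)
and dropped before the final pass. The completeness filter keeps exactly
the proteins with zero missing cells (batch-level missingness makes this
the "present in all batches" rule). Connectivity outlier removal
computes per-sample `k_i = sum_j (1 + cor(i,j))/2` over sample-sample
Pearson correlations, standardizes to Z.k within platform, and drops
|Z.k| > 2 in a single pass; a zero-spread stratum has no outliers. Z.k
is computed after GIS normalization by default (the alternative order is
runnable via the stage functions).

## Empirical-Bayes harmonization

`EmpiricalBayesBatchCorrector` implements the parametric location/scale
empirical-Bayes model: per protein, fit abundance = grand mean +
protected covariates + batch offsets; standardize residuals by the
pooled variance; estimate per-batch location/scale; shrink toward
moment-matched normal / inverse-gamma priors by the standard iterative
update (tolerance 1e-4); reconstruct with batch terms removed and
protected terms restored. A single batch returns the input unchanged;
zero-variance proteins collapse to their protected fit; degenerate
priors (zero between-protein spread, e.g. noiseless fixtures) fall back
to direct estimates. One test verifies agreement with the reference R
implementation (`sva::ComBat`) to ~1e-14 on a shared fixture.

The default plan mirrors the staged-cohort recipe: (1-2) within each
platform, remove labeling-batch effects protecting diagnosis and region;
(3) remove platform effects on the merged matrix with the same
protection; drop GIS channels; (4) remove region protecting sex. The
final pass deliberately does not protect diagnosis (mirroring the
recipe); with region randomized over samples the induced group
distortion is at the shrinkage-residue scale (retention slopes within
~3-7% of unity on the default cohort). Severity-age confounding is
mitigated only by protecting group in the regression stage — a
documented limitation.

### Variance partition

`variance_partition` decomposes each protein's variance by sequential
sums of squares in a stated factor order (shared variance credits the
earlier factor; fractions plus residual sum to 1). Two caveats drove
design choices. First, when every labeling batch runs on one platform,
platform is linearly dependent on batch; a fully aliased factor scores
0 by default instead of raising. Second, a k-df factor absorbs
~k/(n-1) of pure noise by chance, so raw sequential fractions have a
noise floor (~10% for batch at n=90); `method="excess"` subtracts each
factor's method-of-moments null expectation (df x residual mean square)
and clips at zero, which is the right instrument for asking whether any
*real* technical variance remains after harmonization. Post-plan excess
fractions on the default cohort: batch ~0.02%, platform ~0.15%, region
~0.09%.

## Bootstrap covariate regression

Per protein, `value = intercept + group + b_age*age + b_pmi*pmi` is
fitted on `n_boot` (default 1000) case-resampled datasets, resampling
within the protected group so diagnosis is represented in every fit;
nuisance slopes are aggregated by the mean and their centered
contributions subtracted. `n_boot=1` with `resample=False` reduces
exactly to least-squares removal. Planted slopes are removed exactly on
noiseless data; on null data the change is the coefficient's sampling
noise, E|delta| ~ 0.8*sqrt(2)*sigma/sqrt(n) (~0.11 SD at n=90) — an
irreducible property of any unshrunk estimator at this sample size.

## Network construction

Signed weighted co-expression analysis with the staged-cohort defaults:
biweight midcorrelation (Tukey weights `(1-u^2)^2`, `u = (x-med)/(9
mad)`; zero-mad vectors fall back to Pearson standardization), signed
adjacency `((1+cor)/2)^beta` with beta = 7, topological overlap with
mean denominator, average-linkage clustering of 1-TOM, minimum module
size 17, merge cut height 0.07, reassignment threshold 0.05, deep split
2, PAM stage on and respecting the dendrogram. All computation is a
single in-memory block. Soft-power selection reports the signed
scale-free fit R^2 (equal-width connectivity bins; equal-count bins
would make the log-frequency regression degenerate) and picks the
smallest adequate power nearest the target mean connectivity.

The adaptive (dynamic hybrid) cut is re-implemented from its published
description with a documented, deterministic branch-scoring rule: merge
heights are normalized between the 5th-percentile reference and 0.99 of
the top height; cluster cores are connected components below
`ref + maxCoreScatter * span` where the tightness threshold and the
minimum split gap come from the deep-split level (0.82 and 0.135 at the
default 2); inside a core a node splits when both children reach the
minimum size and the node's height clears the children's mean merge
height ("scatter") by the gap, with small stray side-branches unable to
block a deeper split; leftover proteins are unassigned ("grey") unless
the PAM stage places them — an unlabeled protein joins its nearest
module (mean dissimilarity) only when that distance is within the
module's 75th-percentile intra-module dissimilarity and, when the
dendrogram is respected, within its own static branch. Exact label
replication of the reference tool is not promised; planted-truth
recovery (ARI 1.0 on the default cohort, seeds 1-5) is the contract.

Eigenproteins are the first right-singular vectors of the z-scored
member matrix, scaled to unit variance and sign-aligned to correlate
positively with the mean standardized member profile. kME is the
Pearson correlation of each protein with each eigenprotein (Pearson by
convention even though network correlation is bicor). Modules whose
eigenproteins are closer than the merge cut (1 - cor < 0.07, average
linkage, iterated to a fixed point; the largest member keeps its label)
are merged; a single reassignment sweep then moves a protein to its
highest-kME module when Williams' test for dependent correlations is
significant at 0.05 (threshold 0 disables movement). Module labels are
size-ranked color names with numeric aliases (M1 = largest). Order of
operations: cut -> PAM -> merge -> reassign. The bicor outlier cap
(maxPOutliers analogue) is not applied — weights are the plain Tukey
biweights.

## Differential and module statistics

Per-protein one-way ANOVA with Tukey HSD post hoc, using Tukey-Kramer
standard errors for unbalanced groups; log2 differences are disease
minus control group means; no additional across-protein correction for
the significance counts (significance is defined at Tukey p < 0.05,
with an ANOVA-gated counting mode also available). For two groups the
Tukey p reduces exactly to the pooled t-test (q = t*sqrt(2)).

Module-trait significance fits `eigenprotein = group + age + sex + pmi`
and reports the type-II F test for the group term — the
covariate-adjusted construction the pipeline's module p-value denotes —
with a plain Kruskal-Wallis p as a secondary column (the two are
conflated in common usage; the F construction is what the linear-model
description operationally defines). Its type-I error is calibrated
(0.048 at nominal 0.05 over 500 null replicates).

## Cross-network comparison

Module overlap between two assignments is scored per module pair by
hypergeometric enrichment (P(X >= k)) and depletion (P(X <= k)) over the
shared universe (unassigned proteins excluded by default), with BH
correction across the full pair grid per direction; both raw and
adjusted values are exported, plus a signed -log10 display matrix.
Synthetic eigengene projection selects source-module members with
own-module kME at or above the 90th percentile (computed within each
module; a global mode is available), intersects with the target's
proteins, and computes their eigenprotein in the target samples when at
least 4 remain; exclusions are reported, not raised. Protein-level
cross-disease concordance is the Pearson correlation of two contrasts'
log2 differences over shared proteins.

## Cell-type analysis

Marker enrichment of modules uses one-sided Fisher exact tests with BH
correction over the module x cell-type grid; generic gene-set
over-representation uses the hypergeometric tail with BH FDR and a
normal-approximation Z, accepting sets at Z > 1.96 (the two tests agree
exactly on identical 2x2 configurations). Ortholog mapping is
file-based only (first mapping per foreign symbol wins).

Deconvolution runs on the linear scale (proportions mix linearly; log2
input is exponentiated). The default "LM" method follows the
digital-sorting reading: with type-exclusive markers a sample's mean
marker abundance for type t is proportional to its proportion, so
per-type scales are estimated by a nonnegative sum-to-one regression
and weights recovered as scaled marker means, then simplex-normalized
(or z-scored). An alternative "signature" method builds per-type
signature profiles from the most marker-extreme samples (or an explicit
signature table) and solves nonnegative least squares per sample; it is
more sensitive to signature estimation error on small cohorts. For
cross-cohort display, weights are z-scored per cell type within each
dataset before concatenation.

## Orchestration and determinism

`run_pipeline` executes simulate/load -> prep -> harmonize -> regress ->
network -> diffstats -> crossnet -> celltype from a YAML config, writes
every intermediate as TSV plus a manifest with content hashes, and is
byte-reproducible for a fixed config and seed. All randomness flows
from the config seed. The suite and the verification script use
desk-scale problem sizes — 90 samples, ~1500 proteins, 3-5 cohorts,
n_boot 100-200 — chosen so every stage's statistical behavior is
measurable while a complete run stays interactive (a full cohort takes
a few seconds on one CPU).

## Known limitations

* The empirical-Bayes corrector is parametric-prior only, transductive,
  and requires complete data (no nonparametric priors, reference-batch
  mode, or missing-tolerant adjustment).
* The dynamic cut reproduces planted structure, not the reference
  tool's exact labels; micro-decisions (branch scoring, PAM acceptance)
  are this package's documented choices.
* Covariate regression subtracts the mean bootstrap coefficient without
  significance gating; under the null this perturbs abundances at the
  coefficient-sampling-noise scale (~0.11 SD at n=90).
* Deconvolution assumes near-exclusive markers; heavily shared markers
  bias the marker-mean proportionality.
* No consensus/multi-set networks, module-preservation permutation
  statistics (Zsummary), block-wise approximation, or ontology-aware
  gene-set handling.
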