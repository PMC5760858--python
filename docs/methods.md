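# Methods

This note documents the models and procedures implemented in `wpcna`, the
defaults and why they were chosen, the numerical conventions, and the known
limitations. It is the authoritative description of what the code does;
every empirical statement here is computed by the test suite or the
acceptance script.

## The synthetic cohort generator

The generator exists so that every downstream stage has a known answer. It
is a module factor model on the log2 intensity scale:

    x_is = mu_i + lambda_i * e_{m(i)}(s) + eps_is,      eps_is ~ N(0, noise_sd^2)

* `mu_i ~ N(25, 2^2)` — per-protein baseline log2 LFQ intensity, matching
  the order of magnitude of MaxQuant LFQ values (2^20–2^30).
* `lambda_i ~ U(0.4, 1.0)` for members of a planted module, 0 for background
  proteins — a gradient of module membership so that hub structure (kME,
  intramodular connectivity) is non-trivial.
* The module factor combines fixed clinical-group shifts, covariate
  confounding, a C9orf72-carrier shift, and sample-level noise:

      e_m(s) = group_effects_m[g(s)] + covariate_loadings_m . z(c(s))
               + c9_effect_m * 1[carrier] + eta,   eta ~ N(0, factor_sd^2)

  with `factor_sd = 1.0` and `noise_sd = 1.0` by default, giving mean
  within-module correlations around 0.3–0.5 — the regime of real brain
  co-expression modules rather than an idealized block matrix.

The six default modules emulate the biology of a frontal-cortex ALS–FTD
cohort: two neuronal/synaptic modules that decrease with dementia, glial
modules (microglial RNA-binding, astrocytic inflammatory, oligodendrocyte)
that increase, a mitochondrial module, and a +0.6 log2 shift of the
inflammatory factor in C9orf72 carriers. Group-effect patterns across
modules are deliberately correlated (all dementia-responsive modules move
monotonically along control → ALS → ALS/FTD → FTD), which makes module
*separation* genuinely hard: module factors correlate at ~0.3, so recovery
tests exercise the cutter's ability to split correlated modules, not just
noise rejection.

Further conventions, each chosen once:

* **Covariates are matched across groups.** One multiset of age, sex and PMI
  values is drawn per cohort and assigned (shuffled) identically to every
  clinical group — the idealization of an age/sex-matched case–control
  autopsy series. Group contrasts are therefore exactly balanced on
  covariates, while per-module covariate loadings still confound expression,
  so covariate regression has real work to do.
* **Missingness is MNAR-like**: each cell is missing with probability
  `logistic(17 - 0.8 * mu_i)`, concentrating missingness in low-abundance
  proteins; the probability is capped at 0.04 for planted-module proteins so
  that ≥ 90 % of them survive the downstream 90 %-quantification filter.
* **Outlier samples** (2 by default) have their residuals redrawn at 5× the
  noise sd — gross technical failures, not subtle biological outliers.
* **pTDP score** is the quartile discretization (0–3) of the inflammatory
  module's factor; **TDP_LFQ** is the log2 abundance of a designated
  background protein that additionally tracks that factor with loading 0.7.
  Module–trait correlations against these traits therefore have known sign
  and approximate magnitude by construction.
* **Replication cohorts** (`generate_cohort(cfg, reuse_truth=...)`) keep all
  per-protein properties (ids, membership, lambda, mu) and redraw everything
  at the sample level. This matters for preservation: connectivity is only
  reproducible across cohorts because loadings are protein properties.

What the generator does **not** emulate: peptide-level quantification and
roll-up, batch/run-order drift, normalization artifacts, non-Gaussian heavy
tails of real LFQ noise, and biological correlation between background
proteins (background is pure noise). Passing recovery tests on this
generator shows the pipeline machinery is correct and well-calibrated; it
does not certify performance on any particular real cohort.

## Preprocessing

* **Missingness filter**: a protein is kept when its missing count is at
  most `floor(0.10 * n_samples)` — with 51 runs this is ≤ 5 missing values,
  i.e. quantified in at least 90 % of samples.
* **kNN imputation** (k = 10): a missing cell is the mean of the values, in
  that sample, of the k nearest proteins by Euclidean distance computed as
  the mean squared difference over commonly observed samples; a neighbor
  must itself be observed in the target sample. Cells with fewer than k
  eligible neighbors fall back to the protein's row mean with a warning.
  Distance ties break by protein order (stable sort).
* **Outlier removal**: sample connectivity `K_s` is the mean Pearson
  correlation of sample s with all other samples (computed across proteins);
  `Z.K` standardizes K (sd with one delta-df). The single lowest-Z.K sample
  is removed while it falls below −3, recomputing after each removal; ties
  break by lexicographic sample id, so the result is independent of column
  order. A guardrail aborts if more than 20 % of samples would be removed.
  On the default synthetic cohort this removes the two injected outliers
  and occasionally one or two samples with extreme module-factor draws —
  biologically atypical cases, which is precisely what the procedure flags
  in real cohorts too.
* **Bootstrap covariate regression**: per protein, `x ~ group indicators +
  centered covariates` is fitted on 100 stratified (within-group,
  with-replacement) bootstrap resamples; the covariate coefficients are
  averaged and their contribution subtracted. Group structure is retained by
  construction; `n_boot = 1` uses the identity resample and reduces exactly
  to OLS residualization of the covariates. Constant covariates are dropped
  with a warning. The seed is mandatory.
* **PC verification**: principal components of the samples × proteins matrix
  (proteins standardized) are Spearman-correlated with each covariate.

### The statistical floor of the Spearman check

After exact OLS residualization every protein — hence every principal
component — has *Pearson* correlation exactly 0 with each centered
covariate. The *Spearman* correlation does not vanish: rank transformation
re-introduces a residual spread of roughly 0.03 per PC–covariate pair at
n ≈ 46, so the maximum over 15 pairs concentrates around 0.05–0.14
(bootstrap Monte-Carlo noise in the averaged coefficients and the loss of
exact covariate balance after outlier removal contribute a comparable
amount). A post-regression maximum below 0.02 is therefore not an
achievable property of any per-protein linear adjustment at this sample
size; the meaningful guarantees are (i) the Pearson maximum is ~0 and
(ii) the Spearman maximum drops several-fold from its pre-regression value
(typically 0.3–0.5 → ~0.1 on the default cohort). The acceptance script
reports the honestly computed Spearman maximum.

The verification is run on the post-outlier-removal matrix, matching the
order of the analysis pipeline (regression operates on the retained cases);
with gross outlier samples still present the PC ranks are dominated by the
outliers and the check is uninterpretable.

## Differential expression

One-way fixed-effects ANOVA per protein with Tukey HSD post-hoc p-values
from the studentized range distribution, using the Tukey–Kramer standard
error `sqrt(MSE/2 * (1/n_a + 1/n_b))` so unbalanced groups are handled
exactly; with two groups the Tukey p equals the pooled two-sample t p.
Degenerate proteins (zero between- and within-group variance) report F = 0,
p = 1. The "information-rich" selection takes proteins with at least two of
the six pairwise p-values strictly below 0.01; the vs-control Venn uses
p ≤ threshold (the two rules are deliberately different — each mirrors the
convention of the analysis it feeds — and both are configurable). The
C9orf72 contrast is an equal-variance two-sample t-test by default (Welch by
flag) with log2FC = mean(carrier) − mean(non-carrier). Classical MDS is the
Torgerson double-centering eigendecomposition of Euclidean distances between
samples over z-scored selected proteins; dimensions are centered and
sign-fixed (first nonzero coordinate positive). The TDP-43 C/N-terminal
peptide ratio divides the C-terminal peptide XIC by the N-terminal peptide
XIC per sample, with a group ANOVA and Pearson r/r² against the pTDP score;
samples missing either peptide are excluded pairwise.

## Network construction

* **bicor**: observations are weighted by `(1 − u²)² 1[|u|<1]` with
  `u = (x − median)/(9 MAD)`. Vectors with MAD = 0 fall back to the Pearson
  (centered) normalization for the pairs that involve them; constant vectors
  correlate 0 with everything (warning) and 1 with themselves. No outlier
  cap parameter is applied.
* **Signed adjacency**: `((1 + cor)/2)^4.5` — anticorrelated proteins get
  adjacency near 0 rather than high adjacency, so modules are groups of
  positively co-regulated proteins.
* **TOM** uses the standard unsigned overlap formula on the signed
  adjacency (for a signed adjacency in [0, 1] the signed and unsigned
  overlap formulas coincide; the `signed_tom` flag is informational).
* **Clustering**: average linkage on 1 − TOM (scipy implementation).

### Dynamic Hybrid branch cutting

The cut height defaults to 99 % of the tallest merge. Static branches are
the maximal subtrees below the cut. Within each static branch a postorder
scan evaluates every branch against three criteria, with the deepSplit
level (0..4) mapped to `(maxCoreScatter, minGap)` =
(0.64, 0.09), (0.73, 0.0675), (0.82, 0.045), (0.91, 0.0225), (0.95, 0.0125),
made absolute via the 5th percentile q5 of merge heights:
`maxAbsCoreScatter = q5 + maxCoreScatter*(cut − q5)`,
`minAbsGap = minGap*(cut − q5)`.

* **Core scatter**: the branch core is its `min_size + round(sqrt(size −
  min_size))` leaves with the smallest mean dissimilarity to the branch (a
  deterministic proxy for the earliest-joining leaves); the scatter is the
  core's mean pairwise dissimilarity and must not exceed maxAbsCoreScatter.
* **Separation**: a branch may split from its sibling if it hangs below the
  parent merge by at least minAbsGap, **or** if its core is farther from the
  sibling's core than the larger of the two core scatters by the same
  margin. The second (dissimilarity-space) criterion is this
  implementation's own addition: average-linkage trees on
  compressed-contrast TOM attach correlated modules to each other through
  dense chains with no height gap, and the height criterion alone misses
  those splits.
* **Expansion and trimming**: a valid branch that does not contain two
  disjoint valid sub-branches is emitted whole, trimmed of leaves whose mean
  dissimilarity to the core exceeds the scatter threshold. This prevents
  both the "minimal-core" failure mode (emitting a 12-protein kernel and
  leaving the rest to PAM) and the "mixed superbranch" failure mode
  (accepting a branch whose tight core hides an incoherent bulk).
* **PAM stage**: each unassigned object joins the module with the smallest
  mean dissimilarity, restricted to modules on its own static branch when
  that branch carries any (`respect_dendro`), and capped at `max_pam_dist =
  cut height`. Assignments are refined iteratively against the full module
  memberships until stable (at most 5 sweeps) — the natural reading of
  "partitioning around medoids"; objects placed by the branch cut itself are
  never moved.

At deepSplit 4 the cutter is deliberately aggressive and will assign a
substantial fraction of pure-noise objects to (spurious) clusters; at
deepSplit 0–1 pure noise stays ≥ 90 % unassigned. Spurious modules on noise
are expected at the aggressive setting and are exactly what the permutation
preservation stage screens out.

### Eigenproteins, merging, kME, naming

The eigenprotein is the first right-singular vector of the standardized
member × sample submatrix (unit norm; centered by construction), sign-aligned
so the mean member correlation is positive; `varExplained = s1²/Σs²`.
Modules whose eigenproteins cluster below 0.07 on 1 − cor(E_i, E_j)
(average linkage) are merged, recomputing eigenproteins until stable. kME is
the Pearson correlation of each protein with each eigenprotein, with
two-sided Student t p-values on n − 2 df; an assigned protein moves to its
maximum-kME module only when its current module's kME is non-significant
(p ≥ 0.05) and the best module's is significant. Unassigned (M0) proteins
are never promoted by kME — the cut decides membership. Modules are renamed
M1..Mk by strictly decreasing size, ties broken by the lexicographically
smallest member id; the whole network build processes proteins in sorted id
order, so results are invariant to input row order.

Module–trait statistics are bicor with Student t p-values (constant traits
report 0/1 with a warning); a BH-adjusted column is emitted alongside the
raw p-values, which are the primary readout. Eigenprotein group differences
use tie-corrected Kruskal–Wallis for ≥ 3 groups and the equal-variance
Student t for 2.

## Enrichment

One-tailed enrichment is the upper hypergeometric tail P(X ≥ overlap) with
X ~ Hypergeom(N = background, K = set size, n = module size); odds ratios
come from the 2×2 table with Haldane 0.5 correction only when a cell is 0.
BH correction is applied within a family (cell-type markers, PPI lists, and
cross-network ORA are separate families, mirroring per-analysis
corrections). Annotation sets are uppercased, deduplicated and intersected
with the background before testing; the default background is all detected
proteins. The cross-network ORA uses the two-tailed Fisher exact test
(pmf-inclusion rule), signs each pair by observed-vs-expected overlap, and
reports a Woolf-interval 95 % CI on the log odds ratio. Heatmap exports cap
−log10(adjusted p) at 3 with stars at p < 0.05 and p < 0.005; the TSVs keep
full precision.

## Module preservation

For each reference module, six statistics are computed on the shared protein
universe: density — mean intramodular signed adjacency in the test data,
varExplained of the test eigenprotein, mean sign-aware kME
(`mean(sign(kME_ref) * kME_test)`); connectivity — Pearson correlations
between reference and test intramodular connectivity vectors (cor.kIM),
kME vectors (cor.kME), and vectorized intramodular correlation matrices
(cor.cor). The null permutes module labels among all shared proteins with
module sizes fixed (disjoint draws across modules within one permutation);
`Z = (obs − mean_null)/sd_null` per statistic (Z = 0 with a warning when
sd_null = 0 — e.g. all connectivity statistics under self-comparison, where
both sides are identical for any membership); `Zdensity` and
`Zconnectivity` are medians of their three Zs and `Zsummary` their mean.
Categories: Z < 0 none, 0 ≤ Z ≤ 2 weak, 2 < Z ≤ 10 moderate, Z > 10 high
(boundaries to the lower category). Modules with < 3 shared proteins are
skipped with a warning. This fixed 3 + 3 statistic set is a documented,
versioned subset of the many statistics the general permutation framework
admits; results are deterministic given the seed.

A caveat worth knowing: under a structured universe the permutation null is
itself structured (null draws contain planted-module proteins), so
connectivity Z-scores of a *homogeneous* module can be near or below zero
even when the module is real — the null draws get cross-cohort connectivity
correlation "for free" from their mixed membership. Density statistics are
robust to this; in realistic multi-module universes Zsummary behaves
monotonically in module coherence.

## Orchestration and determinism

`run_pipeline` executes simulate → preprocess → diffexpr → network → enrich
→ preserve from one config and one global seed; per-stage seeds are derived
as `(seed XOR crc32(stage_name)) mod 2^31`, so stages can be rerun in
isolation. The preservation stage builds a replication cohort
(`reuse_truth`) at a derived seed. All tables are TSV with header rows;
reports round to 6 significant digits, data files keep full precision; a
failed stage leaves a MANIFEST naming the stage and cause. Identical config
and seed give byte-identical outputs.

Problem sizes used by the shipped verification runs: the recovery and
covariate checks run the default 48 × 3,000 cohort (a single network build
takes a few seconds); preservation checks use 500 permutations on
~1,000-protein universes; type-I calibration uses 1,000 null replicates.

## Known limitations

* The Dynamic Hybrid implementation is an independent realization of the
  published branch-cutting criteria with its own separation/trimming rules
  (documented above); labelings can differ in detail from other
  implementations, particularly for marginal branches.
* Single-block construction only: the full correlation/TOM matrices are held
  in memory (~70 MB at 3,000 proteins; ~8 GB would be reached near 30,000).
* DE p-values are raw (threshold conventions follow the analysis design);
  no moderated-variance or permutation FDR machinery is included.
* The studentized-range survival function dominates runtime for large
  protein counts (~1 ms/value); ANOVA+Tukey on 3,000 proteins takes ~2 min.
* Preservation connectivity statistics have the structured-null caveat
  described above; interpret Zsummary jointly with Zdensity for homogeneous
  single-module designs.
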