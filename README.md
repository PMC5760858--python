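# wpcna — weighted protein co-expression network analysis

`wpcna` builds signed weighted co-expression networks from label-free
quantification (LFQ) proteomic cohorts and relates the resulting protein
modules to clinical and pathological traits. It is written for systems-level
analyses of postmortem brain proteomes across the ALS–FTD disease spectrum —
cohorts of a few dozen cases, a few thousand quantified protein groups,
ordinal clinical grading, TDP-43 pathology scores and C9orf72 genotype — but
every stage is generic over any (proteins × samples) abundance table plus a
sample trait table.

The pipeline, end to end:

1. **Preprocessing** — parse plain or MaxQuant `proteinGroups` tables
   (`LFQ intensity <sample>` columns; reverse/contaminant rows dropped;
   0 = not quantified), keep proteins quantified in ≥ 90 % of runs, log2
   transform, impute the remaining holes by k-nearest-neighbor proteins
   (k = 10), iteratively remove outlier samples by standardized sample
   connectivity (Z.K < −3), then remove age/sex/PMI covariation by
   bootstrap regression that explicitly protects the clinical group term,
   verified by Spearman correlation of the top principal components with
   the regressed covariates.
2. **Differential expression** — per-protein one-way ANOVA over the four
   clinical groups with Tukey HSD post-hoc tests (Tukey–Kramer for
   unbalanced groups), selection of "information-rich" proteins (≥ 2 of the
   6 pairwise contrasts with p < 0.01), classical (Torgerson) MDS of samples
   on those proteins, and a two-sample *t* volcano for C9orf72 carriers vs
   non-carriers.
3. **Network** — biweight midcorrelation (bicor) between all protein pairs;
   signed adjacency `a_ij = ((1 + cor_ij)/2)^β` with β = 4.5; topological
   overlap matrix `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)`;
   average-linkage clustering of 1 − TOM; Dynamic Hybrid branch cutting
   (deepSplit 4, minimum module size 12) with a PAM stage; module
   eigenproteins (first principal component of each module's standardized
   member × sample submatrix); merging of modules whose eigenproteins
   cluster below height 0.07; module membership kME (Pearson correlation of
   each protein with each eigenprotein) with p-value-driven reassignment at
   p < 0.05; modules named M1…Mk by decreasing size. Module–trait
   relationships use bicor with Student *t* p-values, and eigenprotein group
   differences use Kruskal–Wallis (Student *t* for two groups).
4. **Enrichment** — one-tailed hypergeometric enrichment of cell-type marker
   and TDP-43 protein–protein-interaction lists within modules on the
   detected-protein background, BH-corrected per family; two-tailed Fisher
   over-representation analysis between two networks' module assignments.
5. **Preservation** — permutation Z-summary: three density and three
   connectivity statistics of each reference module recomputed in a test
   cohort, standardized against 500 module-size-preserving label
   permutations, `Zsummary = (median Z_density + median Z_connectivity)/2`,
   categorized as none (< 0), weak (0–2), moderate (2–10), high (> 10).

A first-class **synthetic cohort generator** (`wpcna.simulate`) plants all of
this structure — module factor model `x_is = μ_i + λ_i e_m(s) + ε_is` with
group-dependent factors, covariate confounding, MNAR-like missingness,
outlier samples, marker/PPI gene sets and a full ground truth — so the whole
pipeline is testable without any external data.

## Worked example

```python
from wpcna import (SimConfig, generate_cohort, filter_missingness, knn_impute,
                   log2_transform, regress_covariates, remove_outliers,
                   build_network, eigenprotein_group_test, module_trait_cor)
from wpcna.io import numeric_traits

matrix, traits, truth = generate_cohort(SimConfig(seed=42))
imputed = knn_impute(log2_transform(filter_missingness(matrix)))
cleaned, report = remove_outliers(imputed)
traits_c = traits.aligned_to(cleaned.sample_ids)
regressed = regress_covariates(cleaned, traits_c, seed=1)
net = build_network(regressed)
```

Printing the key results of this run (`examples/04_build_network.py`):

```
module sizes: {'M1': 804, 'M2': 633, 'M3': 377, 'M4': 205, 'M5': 197, 'M6': 113}
adjusted Rand index vs planted membership (planted proteins only): 0.863
modules different across groups (Kruskal-Wallis p < 0.05): 5 of 6

strongest module-trait correlations (bicor, Student p):
module      trait  bicor        p    p_adj
    M2    TDP_LFQ  0.692 1.43e-07 2.57e-06
    M2 pTDP_score  0.658    9e-07  8.1e-06
    M1      group -0.514 0.000305  0.00183
```

Reading: six modules are detected; the planted module structure is recovered
almost exactly on the planted proteins (ARI 0.86 here, ≥ 0.9 at the default
acceptance seed); the module that carries the planted inflammatory factor
(M2) correlates strongly with TDP-43 pathology burden and TDP-43 LFQ levels,
while the large neuronal module (M1) falls along the control → FTD clinical
spectrum — the co-expression signature the pipeline is designed to expose.
The scripts in `examples/` walk through each capability (simulation,
preprocessing, differential expression, network, enrichment, preservation,
one-call orchestration) with a few lines of commentary each.

A thin CLI mirrors the library:

```bash
wpcna run --seed 7 --out-dir demo           # full synthetic pipeline + report
wpcna preprocess --abundance ab.tsv --traits traits.csv --seed 1
wpcna network --abundance regressed.tsv
wpcna preserve --ref ref.tsv --test rep.tsv --labels labels.tsv --n-perm 500 --seed 1
```

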