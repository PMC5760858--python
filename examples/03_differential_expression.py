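"""Differential abundance across the four clinical groups plus the C9orf72
genotype contrast, and the MDS view of the information-rich proteins."""
import pandas as pd

from wpcna import (SimConfig, generate_cohort, filter_missingness, knn_impute,
                   log2_transform, regress_covariates, remove_outliers,
                   anova_tukey, classical_mds, select_information_rich,
                   two_group_test, venn_vs_control)
from wpcna.containers import AbundanceMatrix

matrix, traits, _ = generate_cohort(SimConfig(seed=42, n_proteins=1500))
imputed = knn_impute(log2_transform(filter_missingness(matrix)))
cleaned, _ = remove_outliers(imputed)
traits_c = traits.aligned_to(cleaned.sample_ids)
regressed = regress_covariates(cleaned, traits_c, seed=1)

de = anova_tukey(regressed, traits_c.group_labels())
info = select_information_rich(de, p_thresh=0.01, min_sig_pairs=2)
venn = venn_vs_control(de, p_thresh=0.01)
print(f"proteins with ANOVA p <= 0.05: {(de.table['anova_p'] <= 0.05).sum()}")
print(f"information-rich proteins (>= 2 Tukey pairs with p < 0.01): {len(info)}")
print(f"unique proteins altered vs control (Tukey p <= 0.01): {venn['union']}")

coords = classical_mds(regressed, info, n_dims=2)
centroids = coords.groupby(traits_c.group_labels()).mean()
print("\nMDS group centroids (dimension 1 should order the clinical spectrum):")
print(centroids.round(2))

# C9Pos vs C9Neg within the ALS group only (no dementia)
als = traits_c.table.index[traits_c.table["group"] == 1]
sub = AbundanceMatrix(regressed.values[als], stage="regressed", scale="log2")
volcano = two_group_test(sub, traits_c.table.loc[als, "C9_status"])
print(f"\nC9Pos vs C9Neg ALS: {volcano.table['significant'].sum()} proteins "
      f"at p <= {volcano.alpha} "
      f"(max |log2FC| = {volcano.table['log2fc'].abs().max():.2f})")
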