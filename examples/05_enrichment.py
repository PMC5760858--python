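"""Cell-type marker and TDP43-PPI enrichment of detected modules.

One-tailed hypergeometric tests on the detected-protein background with
Benjamini-Hochberg correction per family (cell-type markers and PPI lists
are corrected separately).
"""
from wpcna import (SimConfig, generate_cohort, generate_gene_sets,
                   filter_missingness, knn_impute, log2_transform,
                   regress_covariates, remove_outliers, build_network,
                   filter_to_background, fisher_enrichment)
from wpcna.enrichment import gene_symbol

matrix, traits, truth = generate_cohort(SimConfig(seed=42, n_proteins=1500))
gene_sets = generate_gene_sets(truth, seed=42)

imputed = knn_impute(log2_transform(filter_missingness(matrix)))
cleaned, _ = remove_outliers(imputed)
regressed = regress_covariates(cleaned, traits.aligned_to(cleaned.sample_ids), seed=1)
net = build_network(regressed)

background = [gene_symbol(p) for p in regressed.protein_ids]
sets = filter_to_background(gene_sets, background)
modules = {mod: {gene_symbol(p) for p in net.labels.index[net.labels == mod]}
           for mod in net.module_sizes.index}
result = fisher_enrichment(modules, sets, background, tail="one")

sig = result[result["p_adj"] < 0.05].sort_values("p_adj")
print(f"{len(sig)} of {len(result)} (module, set) pairs enriched at BH p < 0.05:")
cols = ["module", "set", "overlap", "module_size", "set_size",
        "odds_ratio", "p_adj", "signed_neglog10_p_adj"]
print(sig[cols].to_string(index=False, float_format=lambda v: f"{v:.3g}"))
# Each planted cell-type module should light up for its own marker list, and
# the TDP43_PPI list for the module it was sampled from.
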