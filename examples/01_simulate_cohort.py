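"""Generate a synthetic LFQ cohort with planted co-expression modules.

The generator emulates a 4-group (control / ALS / ALS-FTD / FTD) frontal
cortex cohort: six planted modules tied to brain cell types, group-dependent
module activation, age/sex/PMI confounding, abundance-dependent missingness
and two injected outlier samples.
"""
from wpcna import SimConfig, generate_cohort

config = SimConfig(seed=42)
matrix, traits, truth = generate_cohort(config)

print(f"abundance matrix: {matrix.n_proteins} proteins x {matrix.n_samples} samples")
print(f"overall missing fraction: {matrix.values.isna().mean().mean():.3f}")
print(f"injected outlier samples: {truth.outlier_samples}")
print("\nplanted modules (name, cell type, size):")
for name, cell in truth.module_cell_type.items():
    print(f"  {name:16s} {cell:16s} {len(truth.members(name))}")
print("\ntrait table head:")
print(traits.table.head())
# The pTDP pathology score is a quartile discretization of the inflammatory
# module's latent factor, so module-trait correlations have a known answer.
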