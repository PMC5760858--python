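"""One-call orchestration: simulate -> preprocess -> differential expression
-> network -> enrichment -> preservation, with a JSON + markdown run report.

Equivalent shell command:  wpcna run --seed 7 --out-dir wpcna_demo
"""
from wpcna import RunConfig, SimConfig, run_pipeline
from wpcna.pipeline import stage_seed
from wpcna.simulate import default_modules

seed = 7
config = RunConfig(
    out_dir="wpcna_demo", seed=seed, n_perm=200,
    sim=SimConfig(seed=stage_seed(seed, "simulate"), n_proteins=1500,
                  modules=default_modules(1500)),
)
report = run_pipeline(config)

print("module sizes:", report["stages"]["network"]["module_sizes"])
print("significant modules (KW p<0.05):",
      report["stages"]["network"]["n_significant_modules_p05"])
print("enrichment hits:", report["stages"]["enrich"]["stars"])
print("preservation categories:", report["stages"]["preserve"]["categories"])
print("full report: wpcna_demo/report.md")
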