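"""End-to-end orchestration: simulate -> preprocess -> differential
expression -> network -> enrichment -> preservation, from a single declarative
config with one global seed.

Per-stage seeds are derived deterministically from the global seed by hashing
the stage name, so individual stages can be rerun in isolation and still
reproduce the full run. All tables are tab-separated with a header row;
reports round floats to 6 significant digits while data files keep full
precision.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr as dx
from . import io as wio
from .containers import AbundanceMatrix, SampleTraits
from .enrichment import fisher_enrichment, filter_to_background, cross_network_ora, \
    heatmap_bundle, gene_symbol
from .network import NetworkParams, build_network, module_trait_cor, \
    eigenprotein_group_test, NetworkResult
from .preprocess import filter_missingness, log2_transform, knn_impute, remove_outliers, \
    regress_covariates, pc_covariate_check
from .preservation import module_preservation
from .simulate import SimConfig, generate_cohort, generate_gene_sets

log = logging.getLogger("wpcna")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class RunConfig:
    out_dir: str = "wpcna_run"
    seed: int = 0
    sim: SimConfig | None = None
    abundance_path: str | None = None
    traits_path: str | None = None
    dialect: str = "plain"
    max_missing_frac: float = 0.10
    knn_k: int = 10
    zk_cut: float = -3.0
    covariates: tuple = ("age", "sex", "PMI")
    n_boot: int = 100
    de_p_thresh: float = 0.01
    network: NetworkParams = field(default_factory=NetworkParams)
    n_perm: int = 200
    stages: tuple = ("simulate", "preprocess", "diffexpr", "network", "enrich", "preserve")


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", **kw)


def _sig(x, digits: int = 6):
    if isinstance(x, float):
        return float(f"{x:.{digits}g}")
    return x


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the run report (also
    written to the output directory as JSON and markdown)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {},
                    "params": {"max_missing_frac": config.max_missing_frac,
                               "knn_k": config.knn_k, "zk_cut": config.zk_cut,
                               "n_boot": config.n_boot,
                               "network": dataclasses.asdict(config.network),
                               "n_perm": config.n_perm}}
    stage = "init"
    try:
        truth = None
        gene_sets = None
        if "simulate" in config.stages:
            stage = "simulate"
            sim = config.sim or SimConfig(seed=stage_seed(config.seed, "simulate"))
            matrix, traits, truth = generate_cohort(sim)
            gene_sets = generate_gene_sets(truth, seed=stage_seed(config.seed, "gene_sets"))
            wio.write_abundance(matrix, out / "abundance_raw.tsv")
            wio.write_traits(traits, out / "traits.csv")
            truth.to_json(out / "ground_truth.json")
            report["stages"]["simulate"] = {
                "n_proteins": matrix.n_proteins, "n_samples": matrix.n_samples,
                "planted_modules": {m: len(truth.members(m))
                                    for m in truth.module_cell_type},
                "outlier_samples": truth.outlier_samples,
            }
        else:
            stage = "load"
            matrix = wio.read_abundance(config.abundance_path, dialect=config.dialect)
            traits = wio.read_traits(config.traits_path)

        if "preprocess" in config.stages:
            stage = "preprocess"
            filtered = filter_missingness(matrix, config.max_missing_frac)
            imputed = knn_impute(log2_transform(filtered), k=config.knn_k)
            cleaned, outrep = remove_outliers(imputed, z_cut=config.zk_cut)
            traits_c = traits.aligned_to(cleaned.sample_ids)
            regressed = regress_covariates(cleaned, traits_c, covariates=config.covariates,
                                           n_boot=config.n_boot,
                                           seed=stage_seed(config.seed, "regress"))
            pc_check = pc_covariate_check(regressed, traits_c, covariates=config.covariates)
            _write(regressed.values, out / "abundance_regressed.tsv", index_label="Protein")
            _write(outrep.to_frame(), out / "outlier_report.tsv", index=False)
            _write(pc_check, out / "pc_covariate_check.tsv", index_label="PC")
            report["stages"]["preprocess"] = {
                "n_input_proteins": matrix.n_proteins,
                "n_filtered_proteins": filtered.n_proteins,
                "removed_samples": outrep.removed,
                "n_retained_samples": cleaned.n_samples,
                "max_abs_pc_covariate_rho": _sig(float(pc_check.abs().max().max())),
            }
        else:
            regressed = matrix
            traits_c = traits

        de = None
        if "diffexpr" in config.stages:
            stage = "diffexpr"
            groups = traits_c.group_labels()
            de = dx.anova_tukey(regressed, groups)
            info = dx.select_information_rich(de, p_thresh=config.de_p_thresh)
            venn = dx.venn_vs_control(de, p_thresh=config.de_p_thresh)
            _write(de.table, out / "de_table.tsv", index_label="Protein")
            with open(out / "venn.json", "w") as fh:
                json.dump({"regions": venn["regions"], "union": venn["union"]}, fh, indent=1)
            if info:
                mds = dx.classical_mds(regressed, info)
                _write(mds, out / "mds_coordinates.tsv", index_label="sample")
            report["stages"]["diffexpr"] = {
                "n_information_rich": len(info), "venn_union": venn["union"]}

        net: NetworkResult | None = None
        if "network" in config.stages:
            stage = "network"
            net = build_network(regressed, config.network)
            trait_cols = [c for c in ("group", "pTDP_score", "TDP_LFQ")
                          if c in traits_c.table.columns]
            tc = module_trait_cor(net.eigenproteins,
                                  traits_c.table[trait_cols].astype(float))
            gp = eigenprotein_group_test(net.eigenproteins, traits_c.group_labels())
            _write(net.labels.rename("module").to_frame(), out / "module_labels.tsv",
                   index_label="Protein")
            _write(net.eigenproteins, out / "eigenproteins.tsv", index_label="module")
            _write(net.kme, out / "kme.tsv", index_label="Protein")
            _write(tc, out / "module_trait_cor.tsv", index=False)
            _write(net.hubs(), out / "hubs.tsv", index=False)
            with open(out / "dendrogram.json", "w") as fh:
                json.dump({"merges": net.linkage[:, :2].astype(int).tolist(),
                           "heights": net.linkage[:, 2].tolist()}, fh)
            report["stages"]["network"] = {
                "module_sizes": {str(k): int(v) for k, v in net.module_sizes.items()},
                "n_unassigned": int((net.labels == "M0").sum()),
                "n_significant_modules_p05": int((gp < 0.05).sum()),
                "eigenprotein_group_p": {str(k): _sig(float(v)) for k, v in gp.items()},
                "module_trait": [
                    {k: _sig(v) for k, v in row.items()}
                    for row in tc.to_dict(orient="records")],
            }
            if de is not None:
                de_map = dx.map_de_to_modules(de, net.labels, p_thresh=config.de_p_thresh)
                _write(de_map, out / "de_to_modules.tsv", index=False)

        if "enrich" in config.stages and net is not None and gene_sets is not None:
            stage = "enrich"
            background = [gene_symbol(p) for p in regressed.protein_ids]
            sets = filter_to_background(gene_sets, background)
            modules = {mod: {gene_symbol(p) for p in net.labels.index[net.labels == mod]}
                       for mod in net.module_sizes.index}
            marker_names = [s for s in sets.names() if s.endswith("_markers")]
            fam_cell = fisher_enrichment(
                modules, _subset(sets, marker_names), background)
            fam_ppi = fisher_enrichment(
                modules, _subset(sets, [s for s in sets.names() if s not in marker_names]),
                background)
            enr = pd.concat([fam_cell.assign(family="cell_type"),
                             fam_ppi.assign(family="ppi")], ignore_index=True)
            _write(enr, out / "enrichment.tsv", index=False)
            with open(out / "enrichment_heatmap.json", "w") as fh:
                json.dump(heatmap_bundle(enr), fh)
            sig = enr[enr["p_adj"] < 0.05]
            report["stages"]["enrich"] = {
                "n_tests": len(enr), "n_significant": int(len(sig)),
                "stars": [f"{r.module}~{r.set}" for r in sig.itertuples()]}

        if "preserve" in config.stages and net is not None and truth is not None:
            stage = "preserve"
            sim2 = dataclasses.replace(config.sim or SimConfig(
                seed=stage_seed(config.seed, "simulate")),
                seed=stage_seed(config.seed, "simulate_test"))
            # replication cohort: same proteome (loadings/baselines), new samples
            matrix2, traits2, _ = generate_cohort(sim2, reuse_truth=truth)
            proc2 = knn_impute(log2_transform(
                filter_missingness(matrix2, config.max_missing_frac)), k=config.knn_k)
            pres = module_preservation(regressed, proc2, net.labels,
                                       n_perm=config.n_perm,
                                       seed=stage_seed(config.seed, "preserve"))
            _write(pres.table, out / "preservation.tsv")
            report["stages"]["preserve"] = {
                "categories": {str(k): str(v)
                               for k, v in pres.table["category"].items()},
                "Zsummary": {str(k): _sig(float(v))
                             for k, v in pres.table["Zsummary"].items()}}
    except Exception as exc:
        with open(out / "MANIFEST.txt", "w") as fh:
            fh.write(f"INCOMPLETE RUN\nfailed stage: {stage}\ncause: {exc!r}\n")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    with open(out / "report.md", "w") as fh:
        fh.write(_markdown_report(report))
    with open(out / "MANIFEST.txt", "w") as fh:
        fh.write("COMPLETE RUN\n" + "\n".join(sorted(p.name for p in out.iterdir())) + "\n")
    return report


def _subset(sets, names):
    from .enrichment import GeneSetCollection
    return GeneSetCollection(sets={n: sets[n] for n in names},
                             provenance={n: sets.provenance.get(n, "") for n in names})


def _markdown_report(report: dict) -> str:
    lines = ["# wpcna run report", "", f"seed: {report['seed']}", ""]
    for stage, info in report["stages"].items():
        lines.append(f"## {stage}")
        for k, v in info.items():
            lines.append(f"- **{k}**: {v}")
        lines.append("")
    lines.append("## effective parameters")
    lines.append("```json")
    lines.append(json.dumps(report["params"], indent=1, sort_keys=True))
    lines.append("```")
    return "\n".join(lines) + "\n"
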