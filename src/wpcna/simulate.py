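"""Synthetic LFQ cohort generator with planted co-expression structure.

The generative model is a module factor model on the log2 scale:

    x_is = mu_i + lambda_i * e_{m(i)}(s) + eps_is

where ``m(i)`` is the planted module of protein i (background proteins have
lambda = 0), and the per-sample module factor is

    e_m(s) = group_effects[g(s)] + covariate_loadings . z(c(s))
             + c9_effect * 1[C9 positive] + eta,   eta ~ N(0, factor_sd^2).

Covariates (age, sex, PMI) are drawn once per cohort as a single multiset and
assigned identically (shuffled) to every clinical group — the idealization of
an age/sex/PMI-matched case-control autopsy series — so group contrasts are
exactly balanced on covariates while per-module loadings still confound
expression. Missingness is abundance-dependent (MNAR-like): each cell is
dropped with probability logistic(intercept + slope * mu_i), capped for
planted-module proteins so the bulk of them survives the downstream 90%
quantification filter. A small number of outlier samples get their residuals
redrawn with an inflated standard deviation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, SampleTraits, ValidationError, GROUP_NAMES
from .enrichment import GeneSetCollection, gene_symbol

MIN_MODULE_SIZE = 12


@dataclass
class PlantedModule:
    """One planted co-expression module.

    ``group_effects`` are mean factor shifts (log2 units) for the four
    clinical groups (control, ALS, ALS/FTD, FTD); ``covariate_loadings`` act
    on standardized (age, sex, PMI); ``c9_effect`` shifts the factor in
    C9orf72 expansion carriers.
    """

    name: str
    size: int
    cell_type: str = "none"
    group_effects: tuple = (0.0, 0.0, 0.0, 0.0)
    covariate_loadings: tuple = (0.0, 0.0, 0.0)
    loading_range: tuple = (0.4, 1.0)
    c9_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.size < MIN_MODULE_SIZE:
            raise ValidationError(f"module {self.name!r}: size must be >= {MIN_MODULE_SIZE}")
        if self.cell_type not in ("neuron", "astrocyte", "microglia", "oligodendrocyte", "none"):
            raise ValidationError(f"module {self.name!r}: invalid cell_type {self.cell_type!r}")
        if len(self.group_effects) != 4 or not all(math.isfinite(v) for v in self.group_effects):
            raise ValidationError(f"module {self.name!r}: group_effects must be 4 finite values")
        if len(self.covariate_loadings) != 3:
            raise ValidationError(f"module {self.name!r}: covariate_loadings must have 3 entries")
        lo, hi = self.loading_range
        if not (0 < lo <= hi):
            raise ValidationError(f"module {self.name!r}: invalid loading_range")


def default_modules(n_proteins: int = 3000) -> list[PlantedModule]:
    """Six planted modules emulating the cell-type/disease patterns of a
    frontal-cortex ALS-FTD cohort: neuronal/synaptic modules fall with
    dementia, glial/inflammatory modules rise, with the inflammatory module
    additionally elevated in C9orf72 carriers. Sizes are stated for a
    3,000-protein cohort and scale proportionally (floor 12) for smaller
    ``n_proteins``."""
    scale = min(1.0, n_proteins / 3000.0)
    mods = [
        PlantedModule("synaptic", 300, "neuron", (0.0, -0.1, -0.8, -1.4), (0.25, 0.0, 0.1)),
        PlantedModule("rna_binding", 250, "microglia", (0.0, 0.2, 0.9, 1.5), (0.0, 0.15, 0.0)),
        PlantedModule("inflammatory", 200, "astrocyte", (0.0, 0.3, 1.1, 1.7), (0.2, 0.1, 0.0),
                      c9_effect=0.6),
        PlantedModule("oligodendrocyte", 150, "oligodendrocyte", (0.0, 0.3, 0.5, 0.8),
                      (0.0, 0.0, 0.2)),
        PlantedModule("mitochondrial", 120, "none", (0.0, 0.0, -0.5, -1.0), (0.15, 0.0, 0.0)),
        PlantedModule("neuronal_diff", 80, "neuron", (0.0, -0.1, -0.5, -1.0), (0.0, 0.1, 0.15)),
    ]
    if scale < 1.0:
        mods = [replace(m, size=max(MIN_MODULE_SIZE, int(round(m.size * scale))))
                for m in mods]
    return mods


@dataclass
class CovariateModel:
    age_mean: float = 65.0
    age_sd: float = 8.0
    pmi_mean: float = 12.0
    pmi_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.age_sd <= 0 or self.pmi_sd <= 0:
            raise ValidationError("covariate_model: sds must be > 0")


@dataclass
class SimConfig:
    """Cohort configuration; defaults give 4 x 12 samples and 3,000 proteins."""

    n_per_group: int = 12
    n_proteins: int = 3000
    modules: list = field(default_factory=default_modules)
    noise_sd: float = 1.0
    factor_sd: float = 1.0
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    missing_intercept: float = 17.0
    missing_slope: float = -0.8
    planted_missing_cap: float = 0.04
    n_outlier_samples: int = 2
    outlier_sd_multiplier: float = 5.0
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    c9_frac_per_group: tuple = (0.0, 0.4, 0.3, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ValidationError("n_per_group: must be >= 3")
        if self.noise_sd <= 0 and self.noise_sd != 0.0:
            raise ValidationError("noise_sd: must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd: must be >= 0")
        if self.factor_sd < 0:
            raise ValidationError("factor_sd: must be >= 0")
        if self.baseline_sd <= 0:
            raise ValidationError("baseline_sd: must be > 0")
        if self.outlier_sd_multiplier <= 1:
            raise ValidationError("outlier_sd_multiplier: must be > 1")
        total = sum(m.size for m in self.modules)
        if total > self.n_proteins:
            raise ValidationError(
                f"modules: planted sizes sum to {total} > n_proteins={self.n_proteins}")
        names = [m.name for m in self.modules]
        if len(set(names)) != len(names):
            raise ValidationError("modules: duplicate module names")

    @property
    def n_samples(self) -> int:
        return 4 * self.n_per_group


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort."""

    protein_module: dict[str, str]            # protein id -> module name or "background"
    module_cell_type: dict[str, str]
    factors: pd.DataFrame                     # module x sample latent values e_m(s)
    loadings: pd.Series                       # per-protein lambda_i
    baselines: pd.Series                      # per-protein mu_i
    outlier_samples: list[str]
    tdp_protein: str
    ptdp_source_module: str

    def members(self, module: str) -> list[str]:
        return [p for p, m in self.protein_module.items() if m == module]

    def planted_proteins(self) -> list[str]:
        return [p for p, m in self.protein_module.items() if m != "background"]

    def to_json(self, path) -> None:
        payload = {
            "protein_module": self.protein_module,
            "module_cell_type": self.module_cell_type,
            "factors": {m: self.factors.loc[m].tolist() for m in self.factors.index},
            "samples": list(self.factors.columns),
            "loadings": self.loadings.to_dict(),
            "baselines": self.baselines.to_dict(),
            "outlier_samples": self.outlier_samples,
            "tdp_protein": self.tdp_protein,
            "ptdp_source_module": self.ptdp_source_module,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


def _covariate_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Matched covariates: one multiset, shuffled independently per group."""
    n = config.n_per_group
    cm = config.covariate_model
    age_pool = np.round(rng.normal(cm.age_mean, cm.age_sd, size=n), 1)
    pmi_pool = np.round(np.clip(rng.normal(cm.pmi_mean, cm.pmi_sd, size=n), 2.0, None), 1)
    sex_pool = np.array([i % 2 for i in range(n)])
    cols = {"age": [], "sex": [], "PMI": []}
    for _g in range(4):
        for name, pool in (("age", age_pool), ("sex", sex_pool), ("PMI", pmi_pool)):
            cols[name].extend(pool[rng.permutation(n)])
    return pd.DataFrame(cols)


def generate_cohort(config: SimConfig, reuse_truth: GroundTruth | None = None
                    ) -> tuple[AbundanceMatrix, SampleTraits, GroundTruth]:
    """Simulate one cohort; deterministic given ``config`` (incl. seed).

    Returns the raw-scale abundance matrix (2^x intensities, NaN = missing),
    the trait table and the planted ground truth. Passing ``reuse_truth``
    generates a *replication cohort*: per-protein properties (ids, module
    membership, loadings lambda_i, baselines mu_i) are taken from the given
    ground truth while sample-level draws (factors, covariates, noise,
    missingness, outliers) are fresh — emulating the same proteome measured
    in an independent case series.
    """
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_samples
    n_prot = config.n_proteins
    groups = np.repeat(np.arange(4), config.n_per_group)
    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]

    covs = _covariate_table(config, rng)
    covs.index = sample_ids
    z_covs = (covs - covs.mean()) / covs.std(ddof=0).replace(0.0, 1.0)

    # C9orf72 status: first round(frac * n) samples of each group are carriers
    c9 = np.zeros(n_samples, dtype=int)
    for g in range(4):
        k = int(round(config.c9_frac_per_group[g] * config.n_per_group))
        idx = np.where(groups == g)[0]
        c9[rng.choice(idx, size=k, replace=False)] = 1

    # protein ids and module membership (planted modules first, then background)
    if reuse_truth is not None:
        protein_ids = list(reuse_truth.protein_module)
        if len(protein_ids) != n_prot:
            raise ValidationError(
                f"n_proteins: reuse_truth has {len(protein_ids)} proteins, "
                f"config expects {n_prot}")
        protein_module = dict(reuse_truth.protein_module)
        module_cell_type = dict(reuse_truth.module_cell_type)
        missing_mods = [m.name for m in config.modules if m.name not in module_cell_type]
        if missing_mods:
            raise ValidationError(f"modules: {missing_mods} absent from reuse_truth")
        background_ids = [p for p in protein_ids
                          if protein_module[p] == "background"
                          and p != reuse_truth.tdp_protein]
    else:
        protein_ids = []
        protein_module = {}
        module_cell_type = {}
        i = 0
        for mod in config.modules:
            module_cell_type[mod.name] = mod.cell_type
            for _ in range(mod.size):
                pid = f"G{i:05d}|P{i:05d}"
                protein_ids.append(pid)
                protein_module[pid] = mod.name
                i += 1
        background_ids = []
        for _ in range(n_prot - i):
            pid = f"G{i:05d}|P{i:05d}"
            protein_ids.append(pid)
            protein_module[pid] = "background"
            background_ids.append(pid)
            i += 1
    row_of = {p: r for r, p in enumerate(protein_ids)}

    # module factors
    factor_rows = {}
    for mod in config.modules:
        e = (np.asarray(mod.group_effects, dtype=float)[groups]
             + z_covs.to_numpy() @ np.asarray(mod.covariate_loadings, dtype=float)
             + mod.c9_effect * c9
             + rng.normal(0.0, config.factor_sd, size=n_samples))
        factor_rows[mod.name] = e
    factors = pd.DataFrame(factor_rows, index=sample_ids).T

    # per-protein loadings and baselines
    if reuse_truth is not None:
        lam = reuse_truth.loadings.reindex(protein_ids).to_numpy(dtype=float)
        mu = reuse_truth.baselines.reindex(protein_ids).to_numpy(dtype=float)
        tdp_protein = reuse_truth.tdp_protein
        ptdp_module = reuse_truth.ptdp_source_module
    else:
        lam = np.zeros(n_prot)
        for mod in config.modules:
            lo, hi = mod.loading_range
            rows = [row_of[p] for p, m in protein_module.items() if m == mod.name]
            lam[rows] = rng.uniform(lo, hi, size=len(rows))
        mu = rng.normal(config.baseline_mean, config.baseline_sd, size=n_prot)
        # TDP-43 stand-in: one designated background protein additionally
        # tracks the inflammatory-module factor (stays "background" in truth)
        ptdp_module = next((m.name for m in config.modules if "inflam" in m.name),
                           config.modules[0].name if config.modules else "background")
        tdp_protein = ""
        if background_ids and config.modules:
            tdp_protein = background_ids[0]
            lam[row_of[tdp_protein]] = 0.7

    # log2 abundances
    X = np.tile(mu[:, None], (1, n_samples)).astype(float)
    for mod_name in factors.index:
        rows = [row_of[p] for p, m in protein_module.items() if m == mod_name]
        X[rows] += np.outer(lam[rows], factors.loc[mod_name])
    if tdp_protein and ptdp_module in factors.index:
        j = row_of[tdp_protein]
        X[j] += lam[j] * factors.loc[ptdp_module].to_numpy()

    eps = rng.normal(0.0, config.noise_sd, size=(n_prot, n_samples)) if config.noise_sd > 0 \
        else np.zeros((n_prot, n_samples))

    # outlier samples: residuals redrawn with inflated sd
    outlier_idx = rng.choice(n_samples, size=config.n_outlier_samples, replace=False) \
        if config.n_outlier_samples > 0 else np.array([], dtype=int)
    sd_out = config.outlier_sd_multiplier * (config.noise_sd if config.noise_sd > 0 else 1.0)
    for s in outlier_idx:
        eps[:, s] = rng.normal(0.0, sd_out, size=n_prot)
    X = X + eps

    # pTDP score: quartile binning of the designated module's factor
    if config.modules:
        src = factors.loc[ptdp_module].to_numpy()
        qs = np.quantile(src, [0.25, 0.5, 0.75])
        ptdp = np.searchsorted(qs, src, side="right")
    else:
        ptdp = np.zeros(n_samples, dtype=int)

    tdp_lfq = X[row_of[tdp_protein]] if tdp_protein else np.full(n_samples, np.nan)

    # abundance-dependent missingness, capped for planted proteins
    p_miss = _logistic(config.missing_intercept + config.missing_slope * mu)
    planted = np.array([protein_module[p] != "background" for p in protein_ids])
    p_miss[planted] = np.minimum(p_miss[planted], config.planted_missing_cap)
    if tdp_protein:
        p_miss[row_of[tdp_protein]] = min(
            p_miss[row_of[tdp_protein]], config.planted_missing_cap)
    miss = rng.random((n_prot, n_samples)) < p_miss[:, None]

    intensity = np.power(2.0, X)
    intensity[miss] = np.nan
    values = pd.DataFrame(intensity, index=protein_ids, columns=sample_ids)
    matrix = AbundanceMatrix(values=values, stage="raw", scale="intensity")

    traits = SampleTraits(pd.DataFrame({
        "group": groups,
        "age": covs["age"].to_numpy(),
        "sex": covs["sex"].to_numpy().astype(int),
        "PMI": covs["PMI"].to_numpy(),
        "pTDP_score": ptdp,
        "TDP_LFQ": tdp_lfq,
        "C9_status": np.where(c9 == 1, "pos", "neg"),
    }, index=sample_ids))

    truth = GroundTruth(
        protein_module=protein_module,
        module_cell_type=module_cell_type,
        factors=factors,
        loadings=pd.Series(lam, index=protein_ids),
        baselines=pd.Series(mu, index=protein_ids),
        outlier_samples=[sample_ids[s] for s in sorted(outlier_idx)],
        tdp_protein=tdp_protein,
        ptdp_source_module=ptdp_module,
    )
    return matrix, traits, truth


def generate_gene_sets(truth: GroundTruth, *, marker_fraction: float = 1.0,
                       marker_decoys: int = 25, ppi_module: str | None = None,
                       ppi_overlap: int | None = None, ppi_size: int | None = None,
                       seed: int = 0) -> GeneSetCollection:
    """Marker lists per planted cell type plus a synthetic TDP43-PPI set.

    Each cell-type marker set takes ``marker_fraction`` of the member
    proteins of modules with that cell type plus ``marker_decoys`` background
    symbols; the PPI set takes ``ppi_overlap`` symbols from ``ppi_module``
    (default: the pTDP source module) topped up to ``ppi_size`` with
    background symbols.
    """
    rng = np.random.default_rng(seed)
    if not (0.0 <= marker_fraction <= 1.0):
        raise ValidationError("marker_fraction must lie in [0, 1]")
    background = sorted(truth.members("background"))
    sets: dict[str, set[str]] = {}
    prov: dict[str, str] = {}

    by_cell: dict[str, list[str]] = {}
    for mod, cell in truth.module_cell_type.items():
        if cell == "none":
            continue
        by_cell.setdefault(cell, []).extend(truth.members(mod))
    for cell, members in sorted(by_cell.items()):
        members = sorted(members)
        k = int(round(marker_fraction * len(members)))
        chosen = list(rng.choice(members, size=k, replace=False)) if k < len(members) else members
        decoys = list(rng.choice(background, size=min(marker_decoys, len(background)),
                                 replace=False)) if marker_decoys > 0 else []
        sets[f"{cell}_markers"] = {gene_symbol(p) for p in chosen + decoys}
        prov[f"{cell}_markers"] = "synthetic cell-type marker list"

    module = ppi_module or truth.ptdp_source_module
    members = sorted(truth.members(module))
    if ppi_overlap is None:
        ppi_overlap = min(30, max(1, len(members) // 2))
    if ppi_size is None:
        ppi_size = 2 * ppi_overlap
    if ppi_overlap > len(members):
        raise ValidationError(
            f"ppi_overlap={ppi_overlap} exceeds module {module!r} size {len(members)}")
    if ppi_overlap > ppi_size:
        raise ValidationError("ppi_overlap cannot exceed ppi_size")
    from_mod = list(rng.choice(members, size=ppi_overlap, replace=False))
    n_fill = ppi_size - ppi_overlap
    fill = list(rng.choice(background, size=min(n_fill, len(background)), replace=False)) \
        if n_fill > 0 else []
    sets["TDP43_PPI"] = {gene_symbol(p) for p in from_mod + fill}
    prov["TDP43_PPI"] = f"synthetic PPI list overlapping module {module}"
    return GeneSetCollection(sets=sets, provenance=prov)
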