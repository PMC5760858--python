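"""Differential abundance across clinical groups and the C9orf72 contrast.

One-way ANOVA with Tukey HSD post-hoc tests (Tukey-Kramer correction for
unbalanced groups) per protein, selection of "information-rich" proteins with
multiple highly significant pairwise contrasts, classical (Torgerson)
multidimensional scaling of samples on those proteins, a two-group t-test
volcano for C9 carriers vs non-carriers, mapping of differential proteins
onto co-expression modules, and the TDP-43 C/N-terminal peptide-ratio
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceMatrix, SampleTraits, ValidationError

#: the six unordered group pairs, in a fixed order
GROUP_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))

TDP43_C_PEPTIDE = "FGGNPGGFGNQGGFGNSR"
TDP43_N_PEPTIDE = "LVEGILHAPDAGWGNLVYVVNYPK"


@dataclass
class DEResult:
    """Per-protein ANOVA F/p, six Tukey pairwise p-values and log2 fold
    changes of each disease group versus control."""

    table: pd.DataFrame
    group_levels: tuple

    def tukey_columns(self) -> list[str]:
        return [f"tukey_p_{a}v{b}" for a, b in GROUP_PAIRS]


@dataclass
class VolcanoResult:
    table: pd.DataFrame
    alpha: float


def anova_tukey(m: AbundanceMatrix, groups: pd.Series) -> DEResult:
    """One-way fixed-effects ANOVA + Tukey HSD per protein.

    Tukey p-values come from the studentized range distribution with the
    Tukey-Kramer standard error for unbalanced group sizes.
    """
    groups = pd.Series(groups).loc[m.sample_ids].astype(int)
    levels = tuple(sorted(groups.unique()))
    if len(levels) < 2:
        raise ValidationError("need at least 2 groups")
    counts = groups.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValidationError(f"groups with fewer than 2 samples: {small}")

    V = m.values.to_numpy()                      # proteins x samples
    gidx = {g: np.where(groups.to_numpy() == g)[0] for g in levels}
    n_tot = V.shape[1]
    k = len(levels)
    means = {g: V[:, idx].mean(axis=1) for g, idx in gidx.items()}
    ns = {g: idx.size for g, idx in gidx.items()}
    grand = V.mean(axis=1)
    ssb = sum(ns[g] * (means[g] - grand) ** 2 for g in levels)
    ssw = sum(((V[:, gidx[g]] - means[g][:, None]) ** 2).sum(axis=1) for g in levels)
    df_b, df_w = k - 1, n_tot - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df_b) / (ssw / df_w)
    p = np.where(np.isfinite(F), stats.f.sf(np.where(np.isfinite(F), F, 0.0), df_b, df_w), 0.0)
    degenerate = (ssw <= 1e-300) & (ssb <= 1e-300)
    F = np.where(degenerate, 0.0, F)
    p = np.where(degenerate, 1.0, p)
    p = np.where(np.isinf(F), 0.0, p)

    mse = np.maximum(ssw / df_w, 0.0)
    out = pd.DataFrame({"F": F, "anova_p": p}, index=m.values.index)
    for a, b in GROUP_PAIRS:
        if a in ns and b in ns:
            se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            with np.errstate(divide="ignore", invalid="ignore"):
                q = np.abs(means[b] - means[a]) / se
            pq = np.ones_like(q)
            finite = np.isfinite(q) & (se > 0)
            pq[finite] = stats.studentized_range.sf(q[finite], k, df_w)
            pq[(se == 0) & (np.abs(means[b] - means[a]) > 0)] = 0.0
            out[f"tukey_p_{a}v{b}"] = np.clip(pq, 0.0, 1.0)
        else:
            out[f"tukey_p_{a}v{b}"] = np.nan
    for g in levels:
        if g != levels[0]:
            out[f"log2fc_{g}v{levels[0]}"] = means[g] - means[levels[0]]
    return DEResult(table=out, group_levels=levels)


def select_information_rich(de: DEResult, p_thresh: float = 0.01,
                            min_sig_pairs: int = 2) -> list[str]:
    """Proteins with at least ``min_sig_pairs`` Tukey pairwise p strictly
    below ``p_thresh`` among the six comparisons."""
    tk = de.table[de.tukey_columns()]
    n_sig = (tk < p_thresh).sum(axis=1)
    return list(de.table.index[n_sig >= min_sig_pairs])


def venn_vs_control(de: DEResult, p_thresh: float = 0.01) -> dict:
    """Three disease-vs-control significant sets (Tukey p <= threshold) with
    all seven Venn region counts and the union size."""
    sets = {}
    for g, name in ((1, "ALS"), (2, "ALSFTD"), (3, "FTD")):
        col = f"tukey_p_0v{g}"
        sets[name] = set(de.table.index[de.table[col] <= p_thresh]) \
            if col in de.table.columns else set()
    A, B, C = sets["ALS"], sets["ALSFTD"], sets["FTD"]
    regions = {
        "ALS_only": len(A - B - C), "ALSFTD_only": len(B - A - C), "FTD_only": len(C - A - B),
        "ALS_ALSFTD": len((A & B) - C), "ALS_FTD": len((A & C) - B),
        "ALSFTD_FTD": len((B & C) - A), "all_three": len(A & B & C),
    }
    return {"sets": sets, "regions": regions, "union": len(A | B | C)}


def two_group_test(m: AbundanceMatrix, labels: pd.Series, alpha: float = 0.05,
                   equal_var: bool = True) -> VolcanoResult:
    """Two-sample t-test volcano (log2FC = mean(pos) - mean(neg))."""
    labels = pd.Series(labels).loc[m.sample_ids]
    pos = m.values.loc[:, labels == "pos"].to_numpy()
    neg = m.values.loc[:, labels == "neg"].to_numpy()
    if pos.shape[1] < 2 or neg.shape[1] < 2:
        raise ValidationError("each label needs at least 2 samples")
    t, p = stats.ttest_ind(pos, neg, axis=1, equal_var=equal_var)
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)
    table = pd.DataFrame({
        "log2fc": pos.mean(axis=1) - neg.mean(axis=1),
        "t": t, "p": p, "significant": p <= alpha,
    }, index=m.values.index)
    return VolcanoResult(table=table, alpha=alpha)


def classical_mds(m: AbundanceMatrix, protein_set, n_dims: int = 2) -> pd.DataFrame:
    """Torgerson classical MDS of samples on z-scored selected proteins.

    Coordinates are centered; each dimension's sign is fixed so that its
    first nonzero coordinate is positive.
    """
    protein_set = list(protein_set)
    if not protein_set:
        raise ValidationError("protein set is empty")
    if n_dims >= m.n_samples:
        raise ValidationError("n_dims must be < n_samples")
    V = m.values.loc[protein_set].to_numpy()
    sd = V.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    Z = ((V - V.mean(axis=1, keepdims=True)) / sd[:, None]).T   # samples x proteins
    n = Z.shape[0]
    D2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    coords = np.zeros((n, n_dims))
    for d in range(n_dims):
        lam = evals[order[d]]
        if lam > 1e-12:
            coords[:, d] = evecs[:, order[d]] * np.sqrt(lam)
    coords -= coords.mean(axis=0)
    for d in range(n_dims):
        nz = np.nonzero(np.abs(coords[:, d]) > 1e-12)[0]
        if nz.size and coords[nz[0], d] < 0:
            coords[:, d] *= -1
    return pd.DataFrame(coords, index=m.values.columns,
                        columns=[f"Dim{d + 1}" for d in range(n_dims)])


def map_de_to_modules(result, labels: pd.Series, p_thresh: float = 0.05) -> pd.DataFrame:
    """Per module and comparison: proportion of significant members, with the
    mean log2FC of significant members and of all members (for coloring).

    ``result`` is a :class:`DEResult` (three disease-vs-control Tukey
    comparisons) or a :class:`VolcanoResult` (single comparison). M0 is
    included like any module.
    """
    labels = pd.Series(labels)
    comparisons: list[tuple[str, pd.Series, pd.Series]] = []
    if isinstance(result, DEResult):
        for g, name in ((1, "ALSvCTL"), (2, "ALSFTDvCTL"), (3, "FTDvCTL")):
            pcol, fcol = f"tukey_p_0v{g}", f"log2fc_{g}v0"
            if pcol in result.table.columns and fcol in result.table.columns:
                comparisons.append((name, result.table[pcol], result.table[fcol]))
    elif isinstance(result, VolcanoResult):
        comparisons.append(("posVneg", result.table["p"], result.table["log2fc"]))
        p_thresh = result.alpha
    else:
        raise TypeError("result must be DEResult or VolcanoResult")

    universe = comparisons[0][1].index
    if not set(universe).issubset(set(labels.index)):
        raise ValidationError("module labels do not cover the DE universe")
    rows = []
    for module, members in labels.loc[universe].groupby(labels.loc[universe]).groups.items():
        for name, pvals, fcs in comparisons:
            sig = pvals.loc[members] <= p_thresh
            n_sig = int(sig.sum())
            rows.append({
                "module": module, "comparison": name, "module_size": len(members),
                "n_significant": n_sig, "proportion": n_sig / len(members),
                "mean_log2fc_significant": float(fcs.loc[members][sig].mean()) if n_sig else np.nan,
                "mean_log2fc_all": float(fcs.loc[members].mean()),
            })
    return pd.DataFrame(rows)


def peptide_ratio(peptide_table: pd.DataFrame, traits: SampleTraits,
                  c_seq: str = TDP43_C_PEPTIDE, n_seq: str = TDP43_N_PEPTIDE) -> dict:
    """C/N-terminal peptide XIC ratio per sample, with a one-way group ANOVA
    and Pearson correlation against the pTDP pathology score.

    ``peptide_table`` needs columns ``sequence``, ``sample``, ``XIC``.
    Samples missing either peptide get a missing ratio and are excluded
    pairwise from the statistics.
    """
    for col in ("sequence", "sample", "XIC"):
        if col not in peptide_table.columns:
            raise ValidationError(f"peptide table missing column {col!r}")
    for seq in (c_seq, n_seq):
        if not (peptide_table["sequence"] == seq).any():
            raise ValidationError(f"peptide {seq!r} not present in table")
    xic = peptide_table.pivot_table(index="sample", columns="sequence", values="XIC",
                                    aggfunc="first")
    ratio = (xic[c_seq] / xic[n_seq]).reindex(traits.sample_ids)
    ratio.name = "CN_ratio"

    groups = traits.group_labels()
    ok = ratio.notna()
    by_group = [ratio[ok & (groups == g)].to_numpy() for g in sorted(groups.unique())]
    by_group = [v for v in by_group if v.size >= 2]
    if len(by_group) >= 2:
        with np.errstate(invalid="ignore", divide="ignore"):
            F, p = stats.f_oneway(*by_group)
        if not np.isfinite(F):     # degenerate: zero between- and within-group variance
            F, p = 0.0, 1.0
    else:
        F, p = np.nan, np.nan

    corr = {"r": np.nan, "r2": np.nan, "p": np.nan}
    if "pTDP_score" in traits.table.columns:
        score = traits.table["pTDP_score"].astype(float)
        both = ok & score.notna()
        if both.sum() >= 3 and ratio[both].std() > 0 and score[both].std() > 0:
            r, pr = stats.pearsonr(ratio[both], score[both])
            corr = {"r": float(r), "r2": float(r ** 2), "p": float(pr)}
    return {"ratio": ratio, "anova_F": float(F), "anova_p": float(p),
            "ptdp_correlation": corr}
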