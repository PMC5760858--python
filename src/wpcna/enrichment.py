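"""Gene-set overlap statistics for co-expression modules.

Implements the two enrichment flavors used for annotating modules:

* one-tailed hypergeometric (Fisher) enrichment of annotation sets
  (cell-type marker lists, TDP-43 protein-protein interaction lists) within
  modules, Benjamini-Hochberg corrected per family;
* two-tailed Fisher exact over-representation analysis (ORA) between two
  module assignments on a shared background, signed by whether the observed
  overlap exceeds its expectation under independence.

Gene symbols are uppercased and deduplicated; every test is conditioned on an
explicit background universe (the full list of quantified protein groups).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ValidationError


def gene_symbol(protein_id: str) -> str:
    """Gene symbol from a 'GENE|GROUPID' protein id (identity otherwise)."""
    return protein_id.split("|", 1)[0].upper()


@dataclass
class GeneSetCollection:
    """Named sets of (uppercased, deduplicated) gene symbols."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {name: {str(g).upper() for g in members}
                     for name, members in self.sets.items()}

    def names(self) -> list[str]:
        return list(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    prov: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g.upper() for g in parts[2:] if g}
            prov[parts[0]] = parts[1]
    return GeneSetCollection(sets=sets, provenance=prov)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.provenance.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def filter_to_background(collection: GeneSetCollection, background) -> GeneSetCollection:
    """Intersect every set with the background; drop emptied sets with a warning."""
    bg = {str(g).upper() for g in background}
    if not bg:
        raise ValidationError("background is empty")
    out: dict[str, set[str]] = {}
    for name, members in collection.sets.items():
        inter = members & bg
        if inter:
            out[name] = inter
        else:
            warnings.warn(f"gene set {name!r} has no overlap with background; dropped")
    return GeneSetCollection(sets=out, provenance=dict(collection.provenance))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    # Haldane 0.5 correction only when some cell is zero
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def fisher_enrichment(modules: dict[str, set[str]], sets: GeneSetCollection,
                      background, tail: str = "one") -> pd.DataFrame:
    """Per (module, set) overlap enrichment on a shared background.

    One-tailed p is the upper hypergeometric tail P(X >= overlap) with
    X ~ Hypergeom(N=|background|, K=|set|, n=|module|); ``tail="two"`` uses
    the two-sided Fisher exact pmf-inclusion rule. BH adjustment is applied
    across all pairs in the returned family.
    """
    bg = {str(g).upper() for g in background}
    if not bg:
        raise ValidationError("background is empty")
    N = len(bg)
    rows = []
    for mod_name, mod_members in modules.items():
        mod = {str(g).upper() for g in mod_members} & bg
        n = len(mod)
        for set_name in sets.names():
            s = sets[set_name] & bg
            K = len(s)
            k = len(mod & s)
            if k > min(K, n):
                raise ValidationError("overlap exceeds margin — inconsistent inputs")
            a, b, c, d = k, n - k, K - k, N - n - K + k
            if tail == "one":
                p = float(stats.hypergeom.sf(k - 1, N, K, n))
            elif tail == "two":
                _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
                p = float(p)
            else:
                raise ValueError(f"tail must be 'one' or 'two', got {tail!r}")
            rows.append({
                "module": mod_name, "set": set_name, "overlap": k,
                "module_size": n, "set_size": K, "background_size": N,
                "odds_ratio": _odds_ratio(a, b, c, d), "p": min(max(p, 0.0), 1.0),
            })
    result = pd.DataFrame(rows)
    if not result.empty:
        result["p_adj"] = bh_adjust(result["p"].to_numpy())
        expected = result["module_size"] * result["set_size"] / result["background_size"]
        sign = np.where(result["overlap"] >= expected, 1.0, -1.0)
        result["signed_neglog10_p_adj"] = sign * -np.log10(result["p_adj"].clip(lower=1e-300))
    return result


def cross_network_ora(labels_a: pd.Series, labels_b: pd.Series, background) -> pd.DataFrame:
    """Two-tailed Fisher exact ORA between two module assignments.

    Both labelings are restricted to the shared background; M0/unassigned
    labels participate like any other set so depletion is visible. Returns
    one row per module pair with the signed -log10 BH-adjusted p and a Woolf
    95% CI on the log odds ratio.
    """
    bg = {str(g).upper() for g in background}
    if not bg:
        raise ValidationError("background is empty")
    a_sets = {m: {gene_symbol(p) for p in idx} & bg
              for m, idx in labels_a.groupby(labels_a).groups.items()}
    b_sets = {m: {gene_symbol(p) for p in idx} & bg
              for m, idx in labels_b.groupby(labels_b).groups.items()}
    a_universe = set().union(*a_sets.values()) if a_sets else set()
    b_universe = set().union(*b_sets.values()) if b_sets else set()
    if not (a_universe & b_universe):
        raise ValidationError("labelings share no background proteins")
    N = len(bg)
    rows = []
    for ma, sa in sorted(a_sets.items()):
        for mb, sb in sorted(b_sets.items()):
            k = len(sa & sb)
            a = k
            b = len(sa) - k
            c = len(sb) - k
            d = N - len(sa) - len(sb) + k
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            expected = len(sa) * len(sb) / N
            ah, bh, ch, dh = (x + 0.5 if min(a, b, c, d) == 0 else x for x in (a, b, c, d))
            log_or = np.log((ah * dh) / (bh * ch))
            se = np.sqrt(1 / ah + 1 / bh + 1 / ch + 1 / dh)
            rows.append({
                "module_a": ma, "module_b": mb, "overlap": k,
                "size_a": len(sa), "size_b": len(sb), "expected": expected,
                "log_odds": log_or,
                "log_odds_ci_low": log_or - 1.959963984540054 * se,
                "log_odds_ci_high": log_or + 1.959963984540054 * se,
                "p": float(p),
            })
    result = pd.DataFrame(rows)
    result["p_adj"] = bh_adjust(result["p"].to_numpy())
    sign = np.where(result["overlap"] >= result["expected"], 1.0, -1.0)
    result["signed_neglog10_p_adj"] = sign * -np.log10(result["p_adj"].clip(lower=1e-300))
    return result


def heatmap_bundle(result: pd.DataFrame, cap: float = 3.0) -> dict:
    """JSON-serializable heatmap view: capped -log10 adjusted p with stars
    at p_adj < 0.05 (*) and < 0.005 (***); raw values remain in the TSV."""
    bundle = {"rows": [], "cap": cap}
    for _, r in result.iterrows():
        val = float(min(max(r["signed_neglog10_p_adj"], 0.0), cap))
        stars = "***" if r["p_adj"] < 0.005 else ("*" if r["p_adj"] < 0.05 else "")
        bundle["rows"].append({"module": str(r.get("module", r.get("module_a"))),
                               "set": str(r.get("set", r.get("module_b"))),
                               "value": val, "stars": stars})
    return bundle
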