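"""Permutation-based module preservation between two cohorts.

For every reference-defined module, six statistics are computed in the test
data: three density statistics (mean intramodular signed adjacency, variance
explained by the test eigenprotein, mean sign-aware kME) and three
connectivity statistics (correlation of intramodular connectivity, of kME
and of the vectorized intramodular correlation matrices between reference
and test). A permutation null redraws module membership among the shared
proteins (module sizes fixed); each statistic is standardized against its
null to a Z score, summarized as

    Zsummary = (median(density Z) + median(connectivity Z)) / 2

and classified with the conventional thresholds: Z < 0 none, 0-2 weak,
2-10 moderate, > 10 high preservation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, ValidationError
from .network import bicor, signed_adjacency, eigenvector_summary, _standardize_rows

DENSITY_STATS = ("mean_adjacency", "var_explained", "mean_signed_kme")
CONNECTIVITY_STATS = ("cor_kim", "cor_kme", "cor_cor")


@dataclass
class PreservationResult:
    table: pd.DataFrame      # per module: observed stats, null mean/sd, Zs, category
    n_perm: int
    seed: int


def classify_preservation(z_summary: float) -> str:
    """Preservation category from Zsummary (boundaries go to the lower
    category): < 0 none, 0-2 weak, 2-10 moderate, > 10 high."""
    if not np.isfinite(z_summary):
        raise ValidationError("Zsummary must be finite")
    if z_summary < 0:
        return "none"
    if z_summary <= 2:
        return "weak"
    if z_summary <= 10:
        return "moderate"
    return "high"


def _values(m) -> pd.DataFrame:
    if isinstance(m, AbundanceMatrix):
        return m.values
    return m


def _module_stats(idx: np.ndarray, cor_ref: np.ndarray, cor_test: np.ndarray,
                  adj_test: np.ndarray, data_ref: np.ndarray, data_test: np.ndarray
                  ) -> dict[str, float]:
    """The six preservation statistics for one membership set."""
    sub_ref = cor_ref[np.ix_(idx, idx)]
    sub_test = cor_test[np.ix_(idx, idx)]
    sub_adj = adj_test[np.ix_(idx, idx)]
    msize = idx.size

    # rows standardized to unit norm and the eigenvector is unit norm and
    # centered, so these dot products are exactly Pearson correlations
    e_ref, _ = eigenvector_summary(data_ref[idx])
    e_test, var_test = eigenvector_summary(data_test[idx])
    zr = _standardize_rows(data_ref[idx]) / np.sqrt(data_ref.shape[1])
    zt = _standardize_rows(data_test[idx]) / np.sqrt(data_test.shape[1])
    kme_ref = np.clip(zr @ e_ref, -1, 1)
    kme_test = np.clip(zt @ e_test, -1, 1)

    iu = np.triu_indices(msize, k=1)
    kim_ref = sub_ref.sum(axis=1) - 1.0
    kim_test = sub_test.sum(axis=1) - 1.0

    def _cor(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    return {
        "mean_adjacency": float(sub_adj[iu].mean()) if iu[0].size else 0.0,
        "var_explained": var_test,
        "mean_signed_kme": float(np.mean(np.sign(kme_ref) * kme_test)),
        "cor_kim": _cor(kim_ref, kim_test),
        "cor_kme": _cor(kme_ref, kme_test),
        "cor_cor": _cor(sub_ref[iu], sub_test[iu]) if iu[0].size else 0.0,
    }


def module_preservation(ref_matrix, test_matrix, ref_labels: pd.Series,
                        n_perm: int = 500, seed: int = 0, beta: float = 4.5,
                        skip_labels=("M0", 0)) -> PreservationResult:
    """Permutation Z-summary preservation of reference modules in test data."""
    ref_v = _values(ref_matrix)
    test_v = _values(test_matrix)
    shared = [p for p in ref_v.index if p in set(test_v.index)]
    lost = ref_v.shape[0] - len(shared)
    if lost:
        warnings.warn(f"{lost} reference proteins absent from test data; dropped")
    if len(shared) < 3:
        raise ValidationError("fewer than 3 shared proteins")
    ref = ref_v.loc[shared].to_numpy(dtype=float)
    test = test_v.loc[shared].to_numpy(dtype=float)
    labels = pd.Series(ref_labels).reindex(shared)

    cor_ref = bicor(ref)
    cor_test = bicor(test)
    adj_test = signed_adjacency(cor_test, beta=beta)

    pos = {p: i for i, p in enumerate(shared)}
    modules = {}
    for mod, members in labels.groupby(labels).groups.items():
        if mod in skip_labels:
            continue
        idx = np.array([pos[p] for p in members], dtype=np.int64)
        if idx.size < 3:
            warnings.warn(f"module {mod!r} has fewer than 3 shared proteins; skipped")
            continue
        modules[mod] = idx

    rng = np.random.default_rng(seed)
    n = len(shared)
    null = {mod: {s: [] for s in DENSITY_STATS + CONNECTIVITY_STATS} for mod in modules}
    for _ in range(n_perm):
        perm = rng.permutation(n)
        start = 0
        for mod, idx in modules.items():
            pidx = perm[start:start + idx.size]   # disjoint draws across modules
            start += idx.size
            s = _module_stats(np.sort(pidx), cor_ref, cor_test, adj_test, ref, test)
            for name, val in s.items():
                null[mod][name].append(val)

    rows = []
    for mod, idx in modules.items():
        obs = _module_stats(np.sort(idx), cor_ref, cor_test, adj_test, ref, test)
        row = {"module": mod, "size": idx.size}
        zs = {}
        for name in DENSITY_STATS + CONNECTIVITY_STATS:
            arr = np.asarray(null[mod][name])
            mu, sd = float(arr.mean()), float(arr.std(ddof=1))
            if sd == 0 or not np.isfinite(sd):
                warnings.warn(f"null sd is 0 for {name} of module {mod!r}; Z set to 0")
                z = 0.0
            else:
                z = (obs[name] - mu) / sd
            row[f"obs_{name}"] = obs[name]
            row[f"null_mean_{name}"] = mu
            row[f"null_sd_{name}"] = sd
            row[f"Z_{name}"] = z
            zs[name] = z
        z_density = float(np.median([zs[s] for s in DENSITY_STATS]))
        z_conn = float(np.median([zs[s] for s in CONNECTIVITY_STATS]))
        z_summary = (z_density + z_conn) / 2.0
        row.update({"Zdensity": z_density, "Zconnectivity": z_conn,
                    "Zsummary": z_summary,
                    "category": classify_preservation(z_summary)})
        rows.append(row)
    table = pd.DataFrame(rows).set_index("module") if rows else pd.DataFrame()
    return PreservationResult(table=table, n_perm=n_perm, seed=seed)
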