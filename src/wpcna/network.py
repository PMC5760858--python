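"""Signed weighted co-expression network construction and module statistics.

Pipeline: biweight midcorrelation (bicor) -> signed adjacency
a_ij = ((1 + cor_ij)/2)^beta -> topological overlap matrix (TOM) ->
average-linkage clustering of 1 - TOM -> Dynamic Hybrid branch cutting with a
PAM stage -> module eigenproteins (first principal component of each module's
standardized member x sample submatrix) -> merging of modules with highly
correlated eigenproteins -> kME (module membership) with p-value-driven
reassignment -> renaming M1..Mk by decreasing size -> module-trait bicor and
per-module eigenprotein group tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, fcluster
from scipy.spatial.distance import squareform

from .containers import AbundanceMatrix, SampleTraits, ValidationError
from .treecut import cutree_hybrid


@dataclass
class NetworkParams:
    """Network construction parameters (defaults follow the frontal-cortex
    LFQ analysis: beta=4.5, deepSplit=4, min size 12, merge height 0.07,
    PAM respecting the dendrogram, reassignment threshold P < 0.05)."""

    beta: float = 4.5
    deep_split: int = 4
    min_module_size: int = 12
    merge_cut_height: float = 0.07
    pam: bool = True
    reassign_p: float = 0.05
    signed_tom: bool = False

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValidationError("beta must be > 0")
        if not (0.0 < self.merge_cut_height < 1.0):
            raise ValidationError("merge_cut_height must lie in (0, 1)")
        if self.min_module_size < 3:
            raise ValidationError("min_module_size must be >= 3")
        if self.deep_split not in range(5):
            raise ValidationError("deep_split must be in 0..4")
        if not (0.0 < self.reassign_p < 1.0):
            raise ValidationError("reassign_p must lie in (0, 1)")


@dataclass
class NetworkResult:
    params: NetworkParams
    linkage: np.ndarray
    labels: pd.Series                  # protein -> "M0".."Mk"
    module_sizes: pd.Series            # "M1" (largest) .. "Mk"
    eigenproteins: pd.DataFrame        # module x sample
    var_explained: pd.Series
    kme: pd.DataFrame                  # protein x module
    kme_p: pd.DataFrame

    def hubs(self, n: int = 10) -> pd.DataFrame:
        """Top-n kME proteins per module."""
        rows = []
        for mod in self.module_sizes.index:
            members = self.labels.index[self.labels == mod]
            ranked = self.kme.loc[members, mod].sort_values(ascending=False).head(n)
            for rank, (pid, k) in enumerate(ranked.items(), 1):
                rows.append({"module": mod, "rank": rank, "protein": pid, "kME": k})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------- correlation

def _bicor_transform(X: np.ndarray) -> np.ndarray:
    """Row-wise biweight normalization; rows with MAD=0 fall back to the
    Pearson (centered) normalization; constant rows become zero vectors."""
    X = np.asarray(X, dtype=float)
    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    T = np.empty_like(X)
    robust = (mad[:, 0] > 0)
    if robust.any():
        xr = X[robust] - med[robust]
        u = xr / (9.0 * mad[robust])
        a = (1.0 - u ** 2) ** 2 * (np.abs(u) < 1.0)
        T[robust] = xr * a
    if (~robust).any():
        xc = X[~robust] - X[~robust].mean(axis=1, keepdims=True)
        T[~robust] = xc
    norm = np.sqrt((T ** 2).sum(axis=1, keepdims=True))
    zero = norm[:, 0] == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} constant vectors: bicor set to 0 for their pairs")
    norm[zero] = 1.0
    return T / norm


def bicor(X: np.ndarray) -> np.ndarray:
    """Biweight midcorrelation between the rows of ``X``."""
    T = _bicor_transform(X)
    C = np.clip(T @ T.T, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return C


def bicor_pair(x: np.ndarray, y: np.ndarray) -> float:
    return float(bicor(np.vstack([x, y]))[0, 1])


def bicor_matrix(m: AbundanceMatrix) -> pd.DataFrame:
    """Protein x protein bicor matrix of a regressed abundance matrix."""
    if m.stage != "regressed":
        raise ValidationError(f"bicor_matrix expects stage=regressed, got {m.stage}")
    if m.values.isna().any().any():
        raise ValidationError("bicor_matrix requires a complete matrix")
    C = bicor(m.values.to_numpy())
    return pd.DataFrame(C, index=m.values.index, columns=m.values.index)


def correlation_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided Student-t p-value for a correlation with n-2 df."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


# ------------------------------------------------------------- adjacency/TOM

def signed_adjacency(cor, beta: float = 4.5):
    """Signed adjacency a_ij = ((1 + cor_ij)/2)^beta, in [0, 1]."""
    arr = cor.to_numpy() if isinstance(cor, pd.DataFrame) else np.asarray(cor, dtype=float)
    if np.nanmax(np.abs(arr)) > 1.0 + 1e-9:
        raise ValidationError("correlations must lie in [-1, 1]")
    A = ((1.0 + arr) / 2.0) ** beta
    np.fill_diagonal(A, 1.0)
    if isinstance(cor, pd.DataFrame):
        return pd.DataFrame(A, index=cor.index, columns=cor.columns)
    return A


def tom_similarity(adjacency):
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij)
    with l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu."""
    A = adjacency.to_numpy() if isinstance(adjacency, pd.DataFrame) \
        else np.asarray(adjacency, dtype=float)
    L = A @ A - 2.0 * A          # removes the u=i and u=j terms (unit diagonal)
    k = A.sum(axis=1) - 1.0
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (L + A) / (kmin + 1.0 - A)
    T = np.clip(np.nan_to_num(T, nan=0.0), 0.0, 1.0)
    np.fill_diagonal(T, 1.0)
    T = (T + T.T) / 2.0
    if isinstance(adjacency, pd.DataFrame):
        return pd.DataFrame(T, index=adjacency.index, columns=adjacency.columns)
    return T


# ---------------------------------------------------------------- clustering

def cluster_and_cut(diss_tom, params: NetworkParams) -> tuple[np.ndarray, np.ndarray]:
    """Average-linkage clustering of a TOM dissimilarity followed by Dynamic
    Hybrid cutting. Returns (linkage matrix, labels with 0 = unassigned)."""
    D = diss_tom.to_numpy() if isinstance(diss_tom, pd.DataFrame) \
        else np.asarray(diss_tom, dtype=float)
    Z = linkage(squareform(D, checks=False), method="average")
    labels = cutree_hybrid(D, Z, min_module_size=params.min_module_size,
                           deep_split=params.deep_split, pam=params.pam)
    return Z, labels


# -------------------------------------------------------------- eigenproteins

def _standardize_rows(V: np.ndarray) -> np.ndarray:
    sd = V.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    return (V - V.mean(axis=1, keepdims=True)) / sd[:, None]


def eigenvector_summary(V: np.ndarray) -> tuple[np.ndarray, float]:
    """First right-singular vector (unit norm, sign-aligned to members) and
    the fraction of variance it explains, for a member x sample matrix."""
    Zs = _standardize_rows(np.asarray(V, dtype=float))
    if Zs.shape[0] == 1:
        e = Zs[0]
        norm = np.linalg.norm(e)
        return (e / norm if norm > 0 else e), 1.0
    _, s, vt = np.linalg.svd(Zs, full_matrices=False)
    e = vt[0]
    tot = (s ** 2).sum()
    var = float(s[0] ** 2 / tot) if tot > 0 else 0.0
    cors = Zs @ e
    if cors.mean() < 0:
        e = -e
    return e, var


def module_eigenprotein(m: AbundanceMatrix, labels: pd.Series,
                        include_unassigned: bool = False
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Module x sample eigenprotein matrix and per-module variance explained."""
    labels = pd.Series(labels).loc[m.values.index]
    eig = {}
    var = {}
    for mod, members in labels.groupby(labels).groups.items():
        if (mod == 0 or mod == "M0") and not include_unassigned:
            continue
        e, v = eigenvector_summary(m.values.loc[members].to_numpy())
        eig[mod] = e
        var[mod] = v
    eigens = pd.DataFrame(eig, index=m.values.columns).T
    return eigens, pd.Series(var, name="var_explained")


def merge_close_modules(m: AbundanceMatrix, labels: pd.Series,
                        cut_height: float = 0.07) -> pd.Series:
    """Iteratively merge modules whose eigenproteins cluster below
    ``cut_height`` on the 1 - cor(E_i, E_j) dissimilarity."""
    labels = pd.Series(labels).copy()
    while True:
        mods = [mod for mod in labels.unique() if mod != 0 and mod != "M0"]
        if len(mods) < 2:
            return labels
        eigens, _ = module_eigenprotein(m, labels)
        E = eigens.loc[mods].to_numpy()
        D = 1.0 - np.clip(np.corrcoef(E), -1.0, 1.0)
        np.fill_diagonal(D, 0.0)
        Z = linkage(squareform((D + D.T) / 2.0, checks=False), method="average")
        groups = fcluster(Z, t=cut_height, criterion="distance")
        if len(set(groups)) == len(mods):
            return labels
        for g in set(groups):
            merged = [mods[i] for i in range(len(mods)) if groups[i] == g]
            if len(merged) > 1:
                target = merged[0]
                labels[labels.isin(merged[1:])] = target


def kme_and_reassign(m: AbundanceMatrix, labels: pd.Series, eigens: pd.DataFrame,
                     reassign_p: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """kME (Pearson correlation of each protein with each eigenprotein) with
    Student-t p-values; proteins whose current-module kME is not significant
    but whose best module's is are moved there. Unassigned proteins stay
    unassigned — the branch cut decides membership."""
    labels = pd.Series(labels).loc[m.values.index].copy()
    Zp = _standardize_rows(m.values.to_numpy()) / np.sqrt(m.n_samples)
    Ze = _standardize_rows(eigens.to_numpy()) / np.sqrt(m.n_samples)
    K = np.clip(Zp @ Ze.T, -1.0, 1.0)
    P = correlation_p(K, m.n_samples)
    kme = pd.DataFrame(K, index=m.values.index, columns=eigens.index)
    kme_p = pd.DataFrame(P, index=m.values.index, columns=eigens.index)

    best = kme.idxmax(axis=1)
    for pid in labels.index:
        cur = labels[pid]
        if cur == 0 or cur == "M0" or cur not in kme.columns:
            continue
        b = best[pid]
        if b != cur and kme_p.loc[pid, cur] >= reassign_p and kme_p.loc[pid, b] < reassign_p:
            labels[pid] = b
    return kme, kme_p, labels


def name_and_rank(labels: pd.Series) -> tuple[pd.Series, dict]:
    """Rename modules M1..Mk by strictly decreasing size (ties broken by the
    lexicographically smallest member id); unassigned becomes M0."""
    labels = pd.Series(labels)
    sizes = []
    for mod, members in labels.groupby(labels).groups.items():
        if mod == 0 or mod == "M0":
            continue
        sizes.append((len(members), min(str(p) for p in members), mod))
    sizes.sort(key=lambda t: (-t[0], t[1]))
    mapping = {old: f"M{i + 1}" for i, (_, _, old) in enumerate(sizes)}
    mapping[0] = "M0"
    mapping["M0"] = "M0"
    renamed = labels.map(mapping)
    return renamed, mapping


# ------------------------------------------------------- module-trait tests

def module_trait_cor(eigens: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """bicor of each eigenprotein with each numeric trait, with Student-t
    p-values (n-2 df) and a BH-adjusted column."""
    from .enrichment import bh_adjust
    n = eigens.shape[1]
    rows = []
    for mod in eigens.index:
        for trait in traits.columns:
            tv = traits[trait].astype(float).to_numpy()
            if np.ptp(tv[~np.isnan(tv)]) == 0:
                warnings.warn(f"trait {trait!r} is constant; correlation set to 0")
                r, p = 0.0, 1.0
            else:
                ok = ~np.isnan(tv)
                r = bicor_pair(eigens.loc[mod].to_numpy()[ok], tv[ok])
                p = float(correlation_p(np.array([r]), int(ok.sum()))[0])
            rows.append({"module": mod, "trait": trait, "bicor": r, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def eigenprotein_group_test(eigens: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Kruskal-Wallis (>= 3 groups, tie-corrected) or Student t (2 groups)
    p-value per module eigenprotein."""
    groups = pd.Series(groups).loc[eigens.columns]
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValidationError("need at least 2 groups")
    counts = groups.value_counts()
    if (counts < 2).any():
        raise ValidationError("every group needs at least 2 samples")
    pvals = {}
    for mod in eigens.index:
        vals = [eigens.loc[mod, groups.index[groups == g]].to_numpy() for g in levels]
        if all(np.ptp(np.concatenate(vals)) == 0 for _ in [0]):
            pvals[mod] = 1.0
            continue
        if len(levels) == 2:
            _, p = stats.ttest_ind(vals[0], vals[1], equal_var=True)
        else:
            _, p = stats.kruskal(*vals)
        pvals[mod] = float(p)
    return pd.Series(pvals, name="group_p")


# ------------------------------------------------------------- orchestrator

def build_network(m: AbundanceMatrix, params: NetworkParams | None = None) -> NetworkResult:
    """Full network construction on a regressed matrix.

    Proteins are processed in lexicographic id order so the result is
    invariant to input row order.
    """
    params = params or NetworkParams()
    order = sorted(m.values.index)
    ms = m.with_values(m.values.loc[order])

    cor = bicor_matrix(ms)
    adj = signed_adjacency(cor, beta=params.beta)
    # with a signed adjacency (entries in [0, 1]) the signed and unsigned
    # overlap formulas coincide, so the signed_tom flag is informational
    tom = tom_similarity(adj)
    diss = 1.0 - tom.to_numpy()
    np.fill_diagonal(diss, 0.0)

    Z, raw_labels = cluster_and_cut(diss, params)
    labels = pd.Series(raw_labels, index=order)
    labels = merge_close_modules(ms, labels, cut_height=params.merge_cut_height)
    eigens, _ = module_eigenprotein(ms, labels)
    if len(eigens):
        _, _, labels = kme_and_reassign(ms, labels, eigens, reassign_p=params.reassign_p)
        labels = merge_close_modules(ms, labels, cut_height=params.merge_cut_height)
    named, mapping = name_and_rank(labels)
    eigens, var = module_eigenprotein(ms, named)
    mod_order = sorted(eigens.index, key=lambda s: int(s[1:]))
    eigens = eigens.loc[mod_order]
    kme, kme_p, _ = kme_and_reassign(ms, named, eigens, reassign_p=params.reassign_p)
    sizes = named[named != "M0"].value_counts().loc[mod_order]

    # restore caller's protein order
    named = named.loc[m.values.index]
    kme = kme.loc[m.values.index]
    kme_p = kme_p.loc[m.values.index]
    return NetworkResult(params=params, linkage=Z, labels=named, module_sizes=sizes,
                         eigenproteins=eigens, var_explained=var, kme=kme, kme_p=kme_p)
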