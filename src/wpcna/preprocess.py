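"""Raw LFQ table -> analysis-ready regressed log2 matrix.

Chain: missingness filter (proteins quantified in >= 90% of samples) ->
log2 transform -> k-nearest-neighbor imputation -> iterative
connectivity-based outlier-sample removal -> bootstrap covariate regression
(protecting clinical group) -> PCA/Spearman verification that the top
principal components no longer track the regressed covariates.
"""

from __future__ import annotations

import warnings
import math

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .containers import AbundanceMatrix, OutlierReport, SampleTraits, ValidationError

DEFAULT_COVARIATES = ("age", "sex", "PMI")


def filter_missingness(m: AbundanceMatrix, max_missing_frac: float = 0.10) -> AbundanceMatrix:
    """Keep proteins with at most floor(max_missing_frac * n_samples) missing values.

    The floor convention means that with 51 samples a protein may miss at
    most 5 quantifications (10% of runs).
    """
    if m.stage not in ("raw", "filtered"):
        raise ValidationError(f"filter_missingness expects stage raw/filtered, got {m.stage}")
    allowed = math.floor(max_missing_frac * m.n_samples)
    n_missing = m.values.isna().sum(axis=1)
    keep = n_missing <= allowed
    if not keep.any():
        raise ValidationError(
            f"no protein passes the missingness filter (<= {allowed} missing of "
            f"{m.n_samples}); consider raising max_missing_frac")
    return m.with_values(m.values.loc[keep], stage="filtered")


def log2_transform(m: AbundanceMatrix) -> AbundanceMatrix:
    """Elementwise log2 of present values; missing entries are preserved."""
    if m.scale == "log2":
        return m.copy()
    vals = m.values.to_numpy()
    bad = np.argwhere((vals <= 0) & ~np.isnan(vals))
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"nonpositive intensity at protein {m.values.index[i]!r}, "
            f"sample {m.values.columns[j]!r}")
    return m.with_values(np.log2(m.values), scale="log2")


def _pairwise_scaled_sq_distances(values: np.ndarray) -> np.ndarray:
    """Mean squared difference over commonly observed samples (NaN-aware)."""
    mask = (~np.isnan(values)).astype(float)
    Z = np.where(np.isnan(values), 0.0, values)
    cross = Z @ Z.T
    sq = (Z * Z) @ mask.T           # sum_i v_i^2 over common entries
    counts = mask @ mask.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = (sq + sq.T - 2.0 * cross) / counts
    d2[counts == 0] = np.inf
    np.fill_diagonal(d2, np.inf)    # a protein is never its own neighbor
    return np.maximum(d2, 0.0)


def knn_impute(m: AbundanceMatrix, k: int = 10) -> AbundanceMatrix:
    """Impute each missing cell from the k nearest proteins (Euclidean on
    commonly observed samples), using only neighbors observed in that sample.

    If a cell has fewer than ``k`` eligible neighbors, the protein's row mean
    is used instead (with a warning).
    """
    if m.stage != "filtered":
        raise ValidationError(f"knn_impute expects stage=filtered, got {m.stage}")
    values = m.values.to_numpy(dtype=float).copy()
    n_prot, n_samp = values.shape
    observed = ~np.isnan(values)
    holes = np.argwhere(~observed)
    if holes.size == 0:
        return m.with_values(m.values.copy(), stage="imputed")

    d2 = _pairwise_scaled_sq_distances(values)
    row_means = np.nanmean(values, axis=1)
    out = values.copy()
    fallbacks = 0
    order_cache: dict[int, np.ndarray] = {}
    for i, s in holes:
        if i not in order_cache:
            order_cache[i] = np.argsort(d2[i], kind="stable")
        neigh_vals = []
        for j in order_cache[i]:
            if not np.isfinite(d2[i, j]):
                break
            if observed[j, s]:
                neigh_vals.append(values[j, s])
                if len(neigh_vals) == k:
                    break
        if len(neigh_vals) < k:
            out[i, s] = row_means[i]
            fallbacks += 1
        else:
            out[i, s] = float(np.mean(neigh_vals))
    if fallbacks:
        warnings.warn(f"knn_impute: {fallbacks} cells had fewer than k={k} eligible "
                      "neighbors; used row mean")
    return m.with_values(pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
                         stage="imputed")


def sample_connectivity_z(m: AbundanceMatrix) -> pd.Series:
    """Standardized sample connectivity Z.K.

    K_s is the mean inter-sample Pearson correlation of sample s with every
    other sample; Z.K standardizes K across samples. All-equal K (zero sd)
    returns zeros by convention.
    """
    if m.stage not in ("imputed", "regressed"):
        raise ValidationError(f"sample_connectivity_z expects imputed data, got {m.stage}")
    if m.n_samples < 3:
        raise ValidationError("need at least 3 samples")
    cor = np.corrcoef(m.values.to_numpy().T)
    np.fill_diagonal(cor, np.nan)
    K = np.nanmean(cor, axis=1)
    sd = np.std(K, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        z = np.zeros_like(K)
    else:
        z = (K - K.mean()) / sd
    return pd.Series(z, index=m.values.columns, name="Z.K")


def remove_outliers(m: AbundanceMatrix, z_cut: float = -3.0,
                    iterative: bool = True) -> tuple[AbundanceMatrix, OutlierReport]:
    """Iteratively drop the single lowest-Z.K sample while it falls below
    ``z_cut``; refuses to remove more than 20% of samples."""
    report = OutlierReport()
    current = m
    max_removed = int(0.20 * m.n_samples)
    while True:
        z = sample_connectivity_z(current)
        worst_val = z.min()
        # deterministic tie-break: lexicographically smallest sample id
        worst = min(z.index[z == worst_val])
        tab = pd.DataFrame({"sample": z.index, "Z.K": z.to_numpy()})
        remove = bool(worst_val < z_cut)
        tab["removed"] = [remove and s == worst for s in z.index]
        report.iterations.append(tab)
        if not remove:
            break
        if len(report.removed) + 1 > max_removed:
            raise ValidationError(
                f"outlier removal would drop more than 20% of samples "
                f"({len(report.removed) + 1} of {m.n_samples}); aborting")
        report.removed.append(worst)
        current = current.with_values(current.values.drop(columns=[worst]))
        if not iterative:
            break
    report.retained = list(current.values.columns)
    return current, report


def regress_covariates(m: AbundanceMatrix, traits: SampleTraits,
                       covariates=DEFAULT_COVARIATES, preserve: str = "group",
                       n_boot: int = 100, seed: int = 0) -> AbundanceMatrix:
    """Remove covariate variation while retaining clinical-group structure.

    Per protein, a linear model x ~ group-indicators + covariates is fitted
    on ``n_boot`` stratified bootstrap resamples; the covariate coefficients
    are averaged across resamples and their contribution (on centered
    covariates) subtracted. ``n_boot=1`` uses the identity resample and
    reduces to ordinary least-squares residualization of the covariates.
    """
    if m.stage != "imputed":
        raise ValidationError(f"regress_covariates expects stage=imputed, got {m.stage}")
    traits = traits.aligned_to(m.sample_ids)
    covariates = list(covariates)
    if not covariates:
        return m.with_values(m.values.copy(), stage="regressed")

    kept = []
    for c in covariates:
        if c not in traits.table.columns:
            raise ValidationError(f"covariate {c!r} not in traits")
        if traits.table[c].astype(float).nunique() < 2:
            warnings.warn(f"covariate {c!r} is constant; dropped from regression")
        else:
            kept.append(c)
    if not kept:
        return m.with_values(m.values.copy(), stage="regressed")

    Y = m.values.to_numpy().T                               # samples x proteins
    n_samples = Y.shape[0]
    groups = traits.table[preserve].to_numpy()
    glevels = np.unique(groups)
    G = np.column_stack([(groups == g).astype(float) for g in glevels])
    C = traits.table[kept].to_numpy(dtype=float)
    C = C - C.mean(axis=0)
    X = np.column_stack([G, C])
    n_cov = C.shape[1]

    rng = np.random.default_rng(seed)
    beta_sum = np.zeros((n_cov, Y.shape[1]))
    group_idx = {g: np.where(groups == g)[0] for g in glevels}
    for b in range(n_boot):
        if n_boot == 1:
            idx = np.arange(n_samples)
        else:
            idx = np.concatenate([rng.choice(gi, size=gi.size, replace=True)
                                  for g, gi in group_idx.items()])
        coef, *_ = np.linalg.lstsq(X[idx], Y[idx], rcond=None)
        beta_sum += coef[G.shape[1]:, :]
    beta_cov = beta_sum / n_boot
    adjusted = Y - C @ beta_cov
    out = pd.DataFrame(adjusted.T, index=m.values.index, columns=m.values.columns)
    return m.with_values(out, stage="regressed")


def pc_covariate_check(m: AbundanceMatrix, traits: SampleTraits, n_pcs: int = 5,
                       covariates=DEFAULT_COVARIATES) -> pd.DataFrame:
    """Spearman correlation of the top principal components with covariates.

    PCs are computed on the samples x proteins matrix with proteins
    standardized; returns a (PC x covariate) table of Spearman rho.
    """
    if m.stage not in ("imputed", "regressed"):
        raise ValidationError(f"pc_covariate_check expects imputed/regressed, got {m.stage}")
    if n_pcs > m.n_samples - 1:
        raise ValidationError(f"n_pcs={n_pcs} exceeds n_samples-1={m.n_samples - 1}")
    traits = traits.aligned_to(m.sample_ids)
    V = m.values.to_numpy()
    sd = V.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    Z = ((V - V.mean(axis=1, keepdims=True)) / sd[:, None]).T   # samples x proteins
    scores = PCA(n_components=n_pcs, svd_solver="full").fit_transform(Z)
    rows = {}
    for k in range(n_pcs):
        rows[f"PC{k + 1}"] = {
            c: stats.spearmanr(scores[:, k], traits.table[c].astype(float)).statistic
            for c in covariates if c in traits.table.columns}
    return pd.DataFrame(rows).T
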