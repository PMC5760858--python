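"""Network construction: bicor and TOM against direct-formula oracles,
adjacency closed forms, Dynamic Hybrid cutting behavior, eigenproteins,
module merging, kME/reassignment, naming, module-trait statistics and the
eigenprotein group tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from wpcna.containers import ValidationError
from wpcna.network import (NetworkParams, bicor, bicor_pair, build_network,
                           cluster_and_cut, correlation_p,
                           eigenprotein_group_test, eigenvector_summary,
                           kme_and_reassign, merge_close_modules,
                           module_eigenprotein, module_trait_cor,
                           name_and_rank, signed_adjacency, tom_similarity)
from wpcna.treecut import cutree_hybrid

from conftest import make_matrix


# ---------------------------------------------------------------------- bicor

def bicor_oracle(x, y):
    """Direct evaluation of the biweight midcorrelation formula."""
    def weights(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9 * mad)
        a = (1 - u ** 2) ** 2 * (np.abs(u) < 1)
        return (v - med) * a
    wx, wy = weights(x), weights(y)
    return np.sum(wx * wy) / np.sqrt(np.sum(wx ** 2) * np.sum(wy ** 2))


def test_bicor_self_and_negation():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 30)
    assert bicor_pair(x, x) == pytest.approx(1.0)
    assert bicor_pair(x, -x) == pytest.approx(-1.0)


def test_bicor_matches_formula_with_gross_outlier():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 100.0])
    y = np.array([2.1, 2.9, 4.2, 5.1, 5.8, 7.2, -50.0])
    assert bicor_pair(x, y) == pytest.approx(bicor_oracle(x, y), abs=1e-10)


@pytest.mark.parametrize("seed", range(5))
def test_bicor_close_to_pearson_for_clean_gaussian(seed):
    rng = np.random.default_rng(seed)
    z = rng.normal(0, 1, 100)
    x = z + rng.normal(0, 1, 100)
    y = 0.5 * z + rng.normal(0, 1, 100)
    assert abs(bicor_pair(x, y) - np.corrcoef(x, y)[0, 1]) < 0.05


def test_bicor_mad_zero_falls_back_to_pearson():
    # >50% identical values force MAD = 0 while variance is nonzero; the
    # degenerate vector uses the Pearson (centered) normalization while its
    # partner keeps biweight weights — hybrid formula evaluated directly
    x = np.array([5.0] * 6 + [1.0, 2.0, 3.0, 4.0])
    y = np.arange(10.0)
    wx = x - x.mean()
    med, mad = np.median(y), np.median(np.abs(y - np.median(y)))
    u = (y - med) / (9 * mad)
    wy = (y - med) * (1 - u ** 2) ** 2 * (np.abs(u) < 1)
    expected = np.sum(wx * wy) / np.sqrt(np.sum(wx ** 2) * np.sum(wy ** 2))
    assert bicor_pair(x, y) == pytest.approx(expected, abs=1e-10)
    # both degenerate -> plain Pearson
    x2 = np.array([5.0] * 6 + [1.0, 2.0, 3.0, 4.0])
    y2 = np.array([2.0] * 6 + [5.0, 1.0, 9.0, 4.0])
    assert bicor_pair(x2, y2) == pytest.approx(np.corrcoef(x2, y2)[0, 1], abs=1e-10)


def test_bicor_constant_vector_gives_zero_with_warning():
    x = np.ones(10)
    y = np.arange(10.0)
    with pytest.warns(UserWarning, match="constant"):
        C = bicor(np.vstack([x, y]))
    assert C[0, 1] == 0.0
    assert C[0, 0] == 1.0


def test_bicor_matrix_symmetric_unit_diagonal():
    rng = np.random.default_rng(1)
    C = bicor(rng.normal(0, 1, (15, 20)))
    assert np.allclose(C, C.T)
    assert np.allclose(np.diag(C), 1.0)
    assert np.abs(C).max() <= 1.0


# ------------------------------------------------------------------ adjacency

def test_signed_adjacency_closed_forms():
    cor = np.array([[1.0, -1.0, 0.0], [-1.0, 1.0, 0.5], [0.0, 0.5, 1.0]])
    A = signed_adjacency(cor, beta=4.5)
    assert A[0, 1] == pytest.approx(0.0)
    assert A[0, 2] == pytest.approx(2.0 ** -4.5)    # ~0.04419
    assert A[1, 2] == pytest.approx(0.75 ** 4.5)
    assert np.all(np.diag(A) == 1.0)


def test_adjacency_monotone_in_correlation():
    cors = np.linspace(-1, 1, 21)
    vals = ((1 + cors) / 2) ** 4.5
    assert np.all(np.diff(vals) > 0)


def test_large_beta_approaches_perfect_correlation_indicator():
    grid = np.array([[1.0, 1.0, 0.5], [1.0, 1.0, 0.0], [0.5, 0.0, 1.0]])
    A = signed_adjacency(grid, beta=50.0)
    assert A[0, 1] == pytest.approx(1.0)
    assert A[0, 2] < 1e-6
    assert A[1, 2] < 1e-15


# ------------------------------------------------------------------------ TOM

def tom_oracle(A):
    n = A.shape[0]
    T = np.eye(n)
    k = A.sum(axis=1) - 1.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = (l + A[i, j]) / (min(k[i], k[j]) + 1.0 - A[i, j])
    return T


def test_tom_matches_brute_force_double_loop():
    rng = np.random.default_rng(2)
    C = bicor(rng.normal(0, 1, (6, 25)))
    A = signed_adjacency(C, beta=4.5)
    np.testing.assert_allclose(tom_similarity(A), tom_oracle(A), atol=1e-12)


def test_tom_fully_connected_is_one():
    A = np.ones((3, 3))
    assert np.allclose(tom_similarity(A), 1.0)


def test_tom_no_edge_no_shared_neighbors_is_zero():
    A = np.eye(4)
    A[0, 1] = A[1, 0] = 0.9   # isolated pair 0-1, isolated pair 2-3
    A[2, 3] = A[3, 2] = 0.8
    T = tom_similarity(A)
    assert T[0, 2] == pytest.approx(0.0)
    assert T[0, 3] == pytest.approx(0.0)


@pytest.mark.parametrize("seed", range(3))
def test_tom_bounds_and_symmetry_on_random_adjacency(seed):
    rng = np.random.default_rng(seed)
    M = rng.uniform(0, 1, (12, 12))
    A = (M + M.T) / 2
    np.fill_diagonal(A, 1.0)
    T = tom_similarity(A)
    assert np.all((T >= 0) & (T <= 1))
    assert np.allclose(T, T.T)
    assert np.allclose(np.diag(T), 1.0)


# ------------------------------------------------------------------- treecut

def block_dissimilarity(sizes, within, between, seed=0):
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    D = np.full((n, n), 0.0)
    start = 0
    blocks = []
    for s in sizes:
        blocks.append(np.arange(start, start + s))
        start += s
    for i in range(n):
        for j in range(i + 1, n):
            same = any(i in b and j in b for b in blocks)
            base = within if same else between
            D[i, j] = D[j, i] = np.clip(base + rng.normal(0, 0.02), 0.01, 0.999)
    return D


def test_two_planted_blocks_recovered_exactly():
    D = block_dissimilarity([20, 18], within=0.2, between=0.95, seed=1)
    Z = linkage(squareform(D, checks=False), "average")
    labels = cutree_hybrid(D, Z, min_module_size=12)
    assert len(set(labels)) == 2
    assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
    assert labels[0] != labels[-1]


def test_uniform_random_dissimilarity_mostly_unassigned_at_conservative_split():
    """Pure-noise dissimilarity yields no confident modules at conservative
    deep_split; the unassigned fraction shrinks monotonically as deep_split
    increases (aggressive splitting clusters noise by design)."""
    fracs = {ds: [] for ds in range(5)}
    for seed in range(6):
        rng = np.random.default_rng(seed)
        M = rng.uniform(0, 1, (30, 30))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        Z = linkage(squareform(D, checks=False), "average")
        for ds in range(5):
            lab = cutree_hybrid(D, Z, min_module_size=12, deep_split=ds, pam=False)
            fracs[ds].append((lab == 0).mean())
    means = [np.mean(fracs[ds]) for ds in range(5)]
    assert means[0] >= 0.9 and means[1] >= 0.75
    assert all(means[i] >= means[i + 1] - 1e-9 for i in range(4))


def test_identical_objects_form_single_module():
    D = np.zeros((30, 30))
    Z = linkage(squareform(D, checks=False), "average")
    labels = cutree_hybrid(D, Z, min_module_size=12)
    assert set(labels) == {1}


def test_small_input_warns_and_returns_single_module():
    D = block_dissimilarity([10], within=0.3, between=0.9)
    Z = linkage(squareform(D, checks=False), "average")
    with pytest.warns(UserWarning, match="single module"):
        labels = cutree_hybrid(D, Z, min_module_size=12)
    assert set(labels) == {1}


def test_cluster_and_cut_wrapper(small_cohort):
    D = block_dissimilarity([15, 15, 20], within=0.25, between=0.9, seed=3)
    Z, labels = cluster_and_cut(D, NetworkParams())
    assert Z.shape == (49, 4)
    assert len(set(labels) - {0}) == 3


# -------------------------------------------------------------- eigenproteins

def test_identical_member_profiles_give_var_explained_one():
    profile = np.random.default_rng(0).normal(0, 1, 10)
    X = np.tile(profile, (6, 1))
    m = make_matrix(X)
    labels = pd.Series(["M1"] * 6, index=m.values.index)
    eigens, var = module_eigenprotein(m, labels)
    assert var["M1"] == pytest.approx(1.0)
    r = np.corrcoef(eigens.loc["M1"], profile)[0, 1]
    assert abs(r) == pytest.approx(1.0)
    assert r > 0    # sign aligned to members


def test_sign_flip_of_members_flips_eigenprotein():
    rng = np.random.default_rng(1)
    X = np.outer(rng.uniform(0.5, 1, 8), rng.normal(0, 1, 12)) + rng.normal(0, .1, (8, 12))
    m1 = make_matrix(X)
    m2 = make_matrix(-X)
    labels = pd.Series(["M1"] * 8, index=m1.values.index)
    e1, _ = module_eigenprotein(m1, labels)
    e2, _ = module_eigenprotein(m2, labels)
    np.testing.assert_allclose(e1.loc["M1"], -e2.loc["M1"], atol=1e-8)
    # alignment contract: mean member correlation is positive in both
    for m, e in ((m1, e1), (m2, e2)):
        V = m.values.to_numpy()
        cors = [np.corrcoef(V[i], e.loc["M1"])[0, 1] for i in range(8)]
        assert np.mean(cors) > 0


def test_var_explained_matches_eigendecomposition_oracle():
    rng = np.random.default_rng(2)
    X = rng.normal(0, 1, (9, 14))
    m = make_matrix(X)
    labels = pd.Series(["M1"] * 9, index=m.values.index)
    _, var = module_eigenprotein(m, labels)
    Z = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=0, keepdims=True)
    evals = np.linalg.eigvalsh(Z @ Z.T)
    assert var["M1"] == pytest.approx(evals[-1] / evals.sum(), abs=1e-10)


def test_singleton_module_eigenprotein_is_standardized_profile():
    X = np.random.default_rng(3).normal(0, 1, (1, 8))
    m = make_matrix(X)
    eigens, var = module_eigenprotein(m, pd.Series(["M1"], index=m.values.index))
    assert var["M1"] == pytest.approx(1.0)
    assert np.corrcoef(eigens.loc["M1"], X[0])[0, 1] == pytest.approx(1.0)


def test_var_explained_at_least_mean_squared_kme():
    """First-PC optimality: varExplained >= mean squared kME of members."""
    rng = np.random.default_rng(4)
    X = np.outer(rng.uniform(0.4, 1, 20), rng.normal(0, 1, 16)) + rng.normal(0, 1, (20, 16))
    m = make_matrix(X)
    labels = pd.Series(["M1"] * 20, index=m.values.index)
    eigens, var = module_eigenprotein(m, labels)
    kme, _, _ = kme_and_reassign(m, labels, eigens)
    assert var["M1"] >= (kme["M1"] ** 2).mean() - 1e-8


# -------------------------------------------------------------------- merging

def _cohort_with_factor_modules(cors, sizes, seed=0, n_samples=20):
    """Modules whose eigenproteins have roughly the given correlations to a
    shared base factor."""
    rng = np.random.default_rng(seed)
    base = rng.normal(0, 1, n_samples)
    rows, labels = [], []
    for mi, (c, s) in enumerate(zip(cors, sizes)):
        f = c * base + np.sqrt(max(1 - c * c, 0)) * rng.normal(0, 1, n_samples)
        for _ in range(s):
            rows.append(rng.uniform(0.8, 1.2) * f + rng.normal(0, 0.05, n_samples))
            labels.append(f"M{mi + 1}")
    m = make_matrix(np.array(rows))
    return m, pd.Series(labels, index=m.values.index)


def test_highly_correlated_modules_merge():
    m, labels = _cohort_with_factor_modules([1.0, 0.999], [10, 10], seed=1)
    merged = merge_close_modules(m, labels, cut_height=0.07)
    assert merged.nunique() == 1


def test_distinct_modules_do_not_merge():
    m, labels = _cohort_with_factor_modules([1.0, 0.5], [10, 10], seed=2)
    merged = merge_close_modules(m, labels, cut_height=0.07)
    assert merged.nunique() == 2


def test_chain_of_close_modules_collapses_iteratively():
    m, labels = _cohort_with_factor_modules([1.0, 0.999, 0.998], [8, 8, 8], seed=3)
    merged = merge_close_modules(m, labels, cut_height=0.07)
    assert merged.nunique() == 1


# ----------------------------------------------------------- kME + reassigning

def test_hub_equal_to_eigenprotein_has_kme_one():
    rng = np.random.default_rng(5)
    f = rng.normal(0, 1, 15)
    X = np.vstack([f] + [f + rng.normal(0, 0.2, 15) for _ in range(7)])
    m = make_matrix(X)
    labels = pd.Series(["M1"] * 8, index=m.values.index)
    eigens, _ = module_eigenprotein(m, labels)
    kme, kme_p, _ = kme_and_reassign(m, labels, eigens)
    assert kme.loc["P000", "M1"] > 0.995
    assert kme_p.loc["P000", "M1"] < 1e-8


def test_kme_pvalue_matches_correlation_test_oracle():
    rng = np.random.default_rng(6)
    X = rng.normal(0, 1, (10, 18))
    m = make_matrix(X)
    labels = pd.Series(["M1"] * 5 + ["M2"] * 5, index=m.values.index)
    eigens, _ = module_eigenprotein(m, labels)
    kme, kme_p, _ = kme_and_reassign(m, labels, eigens)
    for pid in ("P000", "P007"):
        for mod in ("M1", "M2"):
            r, p = stats.pearsonr(X[int(pid[1:])], eigens.loc[mod])
            assert kme.loc[pid, mod] == pytest.approx(r, abs=1e-8)
            assert kme_p.loc[pid, mod] == pytest.approx(p, abs=1e-8)


def test_protein_matching_other_module_is_reassigned():
    rng = np.random.default_rng(7)
    f1, f2 = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
    rows = [f1 + rng.normal(0, 0.2, 20) for _ in range(6)]
    rows += [f2 + rng.normal(0, 0.2, 20) for _ in range(6)]
    rows.append(f2 + rng.normal(0, 0.2, 20))     # belongs to M2, labeled M1
    m = make_matrix(np.array(rows))
    labels = pd.Series(["M1"] * 6 + ["M2"] * 6 + ["M1"], index=m.values.index)
    eigens, _ = module_eigenprotein(m, labels)
    _, _, new_labels = kme_and_reassign(m, labels, eigens, reassign_p=0.05)
    assert new_labels.iloc[-1] == "M2"


def test_unassigned_proteins_stay_unassigned():
    rng = np.random.default_rng(8)
    f = rng.normal(0, 1, 20)
    rows = [f + rng.normal(0, 0.2, 20) for _ in range(6)]
    rows.append(f + rng.normal(0, 0.2, 20))      # would match M1, but is M0
    m = make_matrix(np.array(rows))
    labels = pd.Series(["M1"] * 6 + ["M0"], index=m.values.index)
    eigens, _ = module_eigenprotein(m, labels)
    _, _, new_labels = kme_and_reassign(m, labels, eigens)
    assert new_labels.iloc[-1] == "M0"


# --------------------------------------------------------------------- naming

def test_modules_renamed_by_decreasing_size():
    labels = pd.Series(["a"] * 21 + ["b"] * 548 + ["c"] * 100,
                       index=[f"P{i:04d}" for i in range(669)])
    named, mapping = name_and_rank(labels)
    assert mapping["b"] == "M1" and mapping["c"] == "M2" and mapping["a"] == "M3"
    assert (named.value_counts()["M1"], named.value_counts()["M3"]) == (548, 21)


def test_size_ties_broken_by_lexicographic_member_id():
    labels = pd.Series(["x"] * 5 + ["y"] * 5,
                       index=[f"B{i}" for i in range(5)] + [f"A{i}" for i in range(5)])
    named, mapping = name_and_rank(labels)
    assert mapping["y"] == "M1"   # contains A0 < B0
    assert mapping["x"] == "M2"


def test_unassigned_label_maps_to_m0():
    labels = pd.Series([0] * 3 + [1] * 15, index=[f"P{i}" for i in range(18)])
    named, _ = name_and_rank(labels)
    assert (named.iloc[:3] == "M0").all()


# -------------------------------------------------------------- module-trait

def test_eigenprotein_equal_to_trait_gives_bicor_one():
    rng = np.random.default_rng(9)
    trait = rng.normal(0, 1, 16)
    eigens = pd.DataFrame([trait], index=["M1"],
                          columns=[f"S{i}" for i in range(16)])
    out = module_trait_cor(eigens, pd.DataFrame({"t": trait},
                                                index=eigens.columns))
    assert out["bicor"].iloc[0] == pytest.approx(1.0)
    assert out["p"].iloc[0] < 1e-10


def test_constant_trait_warns_and_returns_zero():
    eigens = pd.DataFrame([np.arange(10.0)], index=["M1"],
                          columns=[f"S{i}" for i in range(10)])
    with pytest.warns(UserWarning, match="constant"):
        out = module_trait_cor(eigens, pd.DataFrame({"t": np.ones(10)},
                                                    index=eigens.columns))
    assert out["bicor"].iloc[0] == 0.0
    assert out["p"].iloc[0] == 1.0


def test_planted_inflammatory_module_correlates_with_ptdp(processed_small):
    regressed, traits, truth, _ = processed_small
    members = [p for p in truth.members("inflammatory")
               if p in set(regressed.values.index)]
    labels = pd.Series("M0", index=regressed.values.index)
    labels.loc[members] = "Minfl"
    eigens, _ = module_eigenprotein(regressed, labels)
    out = module_trait_cor(eigens, traits.table[["pTDP_score"]].astype(float))
    row = out[(out.module == "Minfl")].iloc[0]
    assert row["bicor"] > 0
    assert row["p"] < 0.05


# ----------------------------------------------------------------- group test

def test_kruskal_matches_formula_oracle():
    rng = np.random.default_rng(10)
    vals = rng.normal(0, 1, 24)
    groups = pd.Series(np.repeat([0, 1, 2, 3], 6),
                       index=[f"S{i}" for i in range(24)])
    eigens = pd.DataFrame([vals], index=["M1"], columns=groups.index)
    p = eigenprotein_group_test(eigens, groups)["M1"]
    # direct Kruskal-Wallis H computation (no ties in continuous data)
    ranks = stats.rankdata(vals)
    H = 12 / (24 * 25) * sum(
        6 * (ranks[groups.to_numpy() == g].mean() - 12.5) ** 2 for g in range(4))
    assert p == pytest.approx(stats.chi2.sf(H, 3), rel=1e-10)


def test_shifted_group_detected_with_high_power():
    rej = 0
    for seed in range(40):
        rng = np.random.default_rng(seed)
        vals = rng.normal(0, 1, 48)
        vals[36:] += 3.0
        groups = pd.Series(np.repeat([0, 1, 2, 3], 12),
                           index=[f"S{i}" for i in range(48)])
        eigens = pd.DataFrame([vals], index=["M1"], columns=groups.index)
        rej += eigenprotein_group_test(eigens, groups)["M1"] < 0.05
    assert rej / 40 >= 0.99


def test_two_groups_use_student_t():
    rng = np.random.default_rng(11)
    vals = rng.normal(0, 1, 20)
    groups = pd.Series([0] * 10 + [1] * 10, index=[f"S{i}" for i in range(20)])
    eigens = pd.DataFrame([vals], index=["M1"], columns=groups.index)
    p = eigenprotein_group_test(eigens, groups)["M1"]
    _, expected = stats.ttest_ind(vals[:10], vals[10:], equal_var=True)
    assert p == pytest.approx(expected, rel=1e-10)


def test_too_small_group_errors():
    groups = pd.Series([0, 0, 1], index=["S0", "S1", "S2"])
    eigens = pd.DataFrame([[1.0, 2.0, 3.0]], index=["M1"], columns=groups.index)
    with pytest.raises(ValidationError, match="at least 2"):
        eigenprotein_group_test(eigens, groups)


# ------------------------------------------------------------------ pipeline

def test_network_labels_invariant_to_protein_order(processed_small):
    regressed, *_ = processed_small
    sub = regressed.with_values(regressed.values.iloc[:250])
    shuffled = sub.with_values(
        sub.values.sample(frac=1.0, random_state=0))
    n1 = build_network(sub, NetworkParams())
    n2 = build_network(shuffled, NetworkParams())
    common = sub.values.index
    assert (n1.labels.loc[common] == n2.labels.loc[common]).all()


def test_build_network_recovers_planted_modules(processed_small):
    from sklearn.metrics import adjusted_rand_score
    regressed, traits, truth, _ = processed_small
    net = build_network(regressed)
    planted = [p for p in truth.planted_proteins() if p in set(net.labels.index)]
    ari = adjusted_rand_score([truth.protein_module[p] for p in planted],
                              net.labels.loc[planted])
    assert ari >= 0.85
    # naming contract: sizes strictly ordered M1 >= M2 >= ...
    sizes = net.module_sizes.to_numpy()
    assert np.all(np.diff(sizes) <= 0)
    # eigenprotein sign contract: mean member kME positive
    for mod in net.module_sizes.index:
        members = net.labels.index[net.labels == mod]
        assert net.kme.loc[members, mod].mean() > 0
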