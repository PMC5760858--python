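"""Dynamic Hybrid cutting of a hierarchical clustering dendrogram.

Branches of an average-linkage tree (built on topological-overlap
dissimilarity) are accepted as module cores when they (i) contain at least
``min_module_size`` objects, (ii) have a tight core (core scatter below a
threshold) and (iii) are separated from their sibling branch by a minimum
height gap. The ``deep_split`` level (0..4) tunes the splitting
aggressiveness through a documented constant table; thresholds are expressed
relative to the 5th percentile of merge heights and the cut height:

    maxAbsCoreScatter = q5 + maxCoreScatter * (cut_height - q5)
    minAbsGap         = minGap * (cut_height - q5)

Objects on no accepted branch are unassigned (label 0). The optional PAM
(partitioning around medoids) stage then assigns each unassigned object to
the module with the smallest average dissimilarity — restricted, when
``respect_dendro``, to modules on the object's static branch of the
dendrogram when that branch carries any, and to average dissimilarities no
larger than ``max_pam_dist`` — and refines those assignments iteratively
against the full module memberships until they stabilize. Objects placed on
a branch by the cut itself are never moved by PAM.
"""

from __future__ import annotations

import warnings

import numpy as np

#: deep_split level -> (maxCoreScatter, minGap)
DEEP_SPLIT_TABLE = {
    0: (0.64, 0.09),
    1: (0.73, 0.0675),
    2: (0.82, 0.045),
    3: (0.91, 0.0225),
    4: (0.95, 0.0125),
}


class _Tree:
    """Light wrapper over a scipy linkage matrix."""

    def __init__(self, Z: np.ndarray, n_leaves: int):
        self.Z = Z
        self.n = n_leaves
        self.heights = Z[:, 2]
        size = np.ones(2 * n_leaves - 1, dtype=np.int64)
        top = np.zeros(2 * n_leaves - 1)
        for i in range(Z.shape[0]):
            a, b = int(Z[i, 0]), int(Z[i, 1])
            size[n_leaves + i] = size[a] + size[b]
            top[n_leaves + i] = Z[i, 2]
        self.size = size
        self.top = top

    def children(self, node: int) -> tuple[int, int]:
        i = node - self.n
        return int(self.Z[i, 0]), int(self.Z[i, 1])

    def height(self, node: int) -> float:
        return 0.0 if node < self.n else float(self.Z[node - self.n, 2])

    def leaves(self, node: int) -> np.ndarray:
        out = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < self.n:
                out.append(v)
            else:
                stack.extend(self.children(v))
        return np.asarray(out, dtype=np.int64)


def branch_core(diss: np.ndarray, leaves, min_size: int) -> tuple[np.ndarray, float]:
    """Core leaves of a branch and their mean pairwise dissimilarity.

    The core is the ``min_size + round(sqrt(size - min_size))`` leaves with
    the smallest average dissimilarity to the rest of the branch — a
    deterministic proxy for the earliest-joining leaves.
    """
    idx = np.asarray(leaves, dtype=np.int64)
    m = idx.size
    if m < 2:
        return idx, 0.0
    sub = diss[np.ix_(idx, idx)]
    size = min(m, min_size + int(round(np.sqrt(max(m - min_size, 0)))))
    avg = sub.sum(axis=1) / (m - 1)
    core = np.argsort(avg, kind="stable")[:size]
    if core.size < 2:
        return idx[core], 0.0
    cs = sub[np.ix_(core, core)]
    return idx[core], float(cs.sum() / (core.size * (core.size - 1)))


def core_scatter(diss: np.ndarray, leaves, min_size: int) -> float:
    """Mean pairwise dissimilarity of the branch core (see branch_core)."""
    return branch_core(diss, leaves, min_size)[1]


def cutree_hybrid(diss: np.ndarray, Z: np.ndarray, *, min_module_size: int = 12,
                  deep_split: int = 4, cut_height: float | None = None,
                  pam: bool = True, respect_dendro: bool = True,
                  max_pam_dist: float | None = None,
                  pam_iterations: int = 5) -> np.ndarray:
    """Module labels (1..k; 0 = unassigned) for the leaves of ``Z``."""
    if deep_split not in DEEP_SPLIT_TABLE:
        raise ValueError(f"deep_split must be in 0..4, got {deep_split}")
    n = diss.shape[0]
    if n != diss.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    tree = _Tree(np.asarray(Z, dtype=float), n)
    heights = tree.heights

    if n < 2 * min_module_size:
        warnings.warn("fewer than 2*min_module_size objects: returning a single module")
        return np.ones(n, dtype=np.int64)
    hmax = float(heights.max()) if heights.size else 0.0
    if hmax <= 0.0:
        return np.ones(n, dtype=np.int64)   # all objects identical
    if cut_height is None:
        cut_height = 0.99 * hmax
    max_core_scatter, min_gap = DEEP_SPLIT_TABLE[deep_split]
    below = heights[heights <= cut_height]
    q5 = float(np.quantile(below, 0.05)) if below.size else 0.0
    span = max(cut_height - q5, 0.0)
    max_abs_scatter = q5 + max_core_scatter * span
    min_abs_gap = min_gap * span

    core_cache: dict[int, tuple[np.ndarray, float]] = {}

    def core(node: int) -> tuple[np.ndarray, float]:
        if node not in core_cache:
            core_cache[node] = branch_core(diss, tree.leaves(node), min_module_size)
        return core_cache[node]

    def scatter(node: int) -> float:
        return core(node)[1]

    def qualifies(node: int) -> bool:
        return tree.size[node] >= min_module_size and scatter(node) <= max_abs_scatter

    def separated(node: int, sibling: int, parent_height: float) -> bool:
        """A branch may split off if it hangs below its parent by the minimum
        height gap, or if its core is farther from the sibling's core than
        the core scatters by the same margin (dissimilarity-space gap)."""
        if parent_height - tree.top[node] >= min_abs_gap:
            return True
        ca, sa = core(node)
        cb, sb = core(sibling)
        cross = float(diss[np.ix_(ca, cb)].mean())
        return cross - max(sa, sb) >= min_abs_gap

    def valid(node: int, sibling: int, parent_height: float) -> bool:
        return qualifies(node) and separated(node, sibling, parent_height)

    def trimmed(node: int) -> np.ndarray:
        """Branch leaves that stay within the scatter threshold of the core
        (drops chained-on background while keeping genuine members)."""
        lv = tree.leaves(node)
        c, _ = core(node)
        keep = diss[np.ix_(lv, c)].mean(axis=1) <= max_abs_scatter
        core_set = np.isin(lv, c)
        return lv[keep | core_set]

    # static branches: maximal subtrees at or below the cut height
    root = 2 * n - 2
    static_roots = []
    stack = [root]
    while stack:
        v = stack.pop()
        if tree.height(v) <= cut_height:
            static_roots.append(v)
        else:
            stack.extend(tree.children(v))

    labels = np.zeros(n, dtype=np.int64)
    branch_of = np.full(n, -1, dtype=np.int64)
    next_label = 1
    module_leaves: dict[int, np.ndarray] = {}
    module_branch: dict[int, int] = {}

    for b_idx, sroot in enumerate(static_roots):
        branch_of[tree.leaves(sroot)] = b_idx
        if tree.size[sroot] < min_module_size:
            continue
        # postorder scan: clusters (leaf arrays) found strictly inside a node.
        # A valid branch that does not genuinely split (fewer than two inner
        # clusters) is emitted whole, trimmed of leaves far from its core.
        found: dict[int, list[np.ndarray]] = {}
        order: list[int] = []
        stack = [sroot]
        while stack:
            v = stack.pop()
            if v >= n:
                order.append(v)
                stack.extend(tree.children(v))
        for v in reversed(order):
            res: list[np.ndarray] = []
            h = tree.height(v)
            ca, cb = tree.children(v)
            for c, sib in ((ca, cb), (cb, ca)):
                sub = found.get(c, [])
                if valid(c, sib, h) and len(sub) < 2:
                    res.append(trimmed(c))
                else:
                    res.extend(sub)
            found[v] = res
        clusters = found.get(sroot, [])
        if not clusters and tree.size[sroot] >= min_module_size \
                and scatter(sroot) <= max_abs_scatter:
            clusters = [trimmed(sroot)]
        for lv in clusters:
            if lv.size < min_module_size:
                continue
            labels[lv] = next_label
            module_leaves[next_label] = lv
            module_branch[next_label] = b_idx
            next_label += 1

    if pam and module_leaves:
        if max_pam_dist is None:
            max_pam_dist = cut_height
        mods = sorted(module_leaves)
        branches_with_modules = set(module_branch.values())
        unassigned = np.where(labels == 0)[0]
        candidates: dict[int, list[int]] = {}
        for i in unassigned:
            # objects on a branch with no module fall back to all modules
            restrict = respect_dendro and branch_of[i] in branches_with_modules
            candidates[i] = [m for m in mods
                             if not restrict or module_branch[m] == branch_of[i]]
        # initial assignment against the cut cores, then iterative refinement
        # against full module memberships until stable
        for sweep in range(max(1, pam_iterations)):
            members = {m: np.where(labels == m)[0] for m in mods}
            changed = 0
            for i in unassigned:
                best, best_d = 0, np.inf
                for m in candidates[i]:
                    mem = members[m]
                    mem = mem[mem != i]
                    if mem.size == 0:
                        continue
                    d = float(diss[i, mem].mean())
                    if d < best_d:
                        best, best_d = m, d
                if best and best_d <= max_pam_dist and labels[i] != best:
                    labels[i] = best
                    changed += 1
            if changed == 0:
                break
    return labels
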