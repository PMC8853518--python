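"""Signed weighted coexpression networks and module detection.

The pipeline per tissue: signed similarity S_ij = (1 + cor(x_i, x_j)) / 2,
soft-thresholded adjacency a_ij = S_ij^beta with beta chosen for approximate
scale-free topology, the topological overlap measure (TOM) for pairwise
interconnectedness, average-linkage clustering of 1 - TOM, a dynamic
tree-cut to detect modules, module eigengenes (first principal component of
the standardized module expression), and merging of modules with highly
correlated eigengenes.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from bloodbrain.ingest import ExpressionMatrix

__all__ = [
    "NetworkParams",
    "ModuleAssignment",
    "signed_similarity",
    "adjacency",
    "pick_soft_threshold",
    "topological_overlap",
    "detect_modules",
    "module_eigengenes",
    "merge_similar_modules",
    "build_network",
]


@dataclasses.dataclass
class NetworkParams:
    """Network construction parameters.

    beta : soft-threshold power (if None it is picked by scale-free fit).
    candidate_betas : powers scanned when picking beta.
    scale_free_r2_target : minimum signed R^2 of the log-log degree fit.
    min_module_size : smallest branch that becomes a module (default 100).
    detect_cut_height : static cut on the 1 - TOM dendrogram (default 0.99).
    deep_split : split tall retained branches into large sub-branches.
    merge_cut_height : eigengene-dissimilarity cut below which modules merge.
    """

    beta: int | None = None
    candidate_betas: tuple[int, ...] = tuple(range(1, 21))
    scale_free_r2_target: float = 0.8
    min_module_size: int = 100
    detect_cut_height: float = 0.99
    deep_split: bool = True
    merge_cut_height: float = 0.25
    branch_gap: float = 0.05

    def __post_init__(self):
        if not 0 < self.detect_cut_height <= 1:
            raise ValueError("detect_cut_height must be in (0, 1]")
        if not 0 <= self.merge_cut_height <= 1:
            raise ValueError("merge_cut_height must be in [0, 1]")
        if self.min_module_size < 3:
            raise ValueError("min_module_size must be >= 3")


@dataclasses.dataclass
class ModuleAssignment:
    """Gene -> module labels (0 = unassigned) with module eigengenes."""

    labels: pd.Series  # index = gene ids, values = int labels
    eigengenes: pd.DataFrame | None = None  # samples x module labels

    def __post_init__(self):
        self.labels = self.labels.astype(int)

    def module_labels(self) -> list[int]:
        return sorted(set(self.labels.unique()) - {0})

    def genes(self) -> pd.Index:
        return self.labels.index

    def genes_in(self, module: int) -> list:
        return self.labels.index[self.labels == module].tolist()

    def sizes(self) -> dict[int, int]:
        return {m: int((self.labels == m).sum()) for m in self.module_labels()}

    @property
    def n_unassigned(self) -> int:
        return int((self.labels == 0).sum())


def _check_square(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square")
    return mat


def signed_similarity(expr: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Signed similarity S = (1 + Pearson correlation) / 2 between gene rows.

    Anti-correlated genes map to 0, uncorrelated to 0.5, co-regulated to 1.
    Zero-variance genes get uninformative similarity 0.5 and are returned in
    the flag vector (they are excluded from module seeding downstream).
    """
    if expr.n_samples < 3:
        raise ValueError("need >= 3 samples to estimate correlations")
    values = expr.values
    sd = values.std(axis=1)
    flat = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.nan_to_num(corr, nan=0.0)
    sim = (1.0 + corr) / 2.0
    sim[flat, :] = 0.5
    sim[:, flat] = 0.5
    np.fill_diagonal(sim, 1.0)
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return sim, flat


def adjacency(sim: np.ndarray, beta: int) -> np.ndarray:
    """Soft-thresholded adjacency a_ij = S_ij^beta (diagonal forced to 1)."""
    if beta < 1 or int(beta) != beta:
        raise ValueError("beta must be a positive integer")
    sim = _check_square(sim, "similarity")
    adj = sim**beta
    np.fill_diagonal(adj, 1.0)
    return adj


def scale_free_fit(adj: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free fit index of an adjacency matrix.

    Connectivities k_i are binned on a log10 scale; log10(frequency) is
    regressed on log10(mean k per bin).  Returns (signed R^2, slope); the
    index is negated when the slope is positive (heavy high-degree tail is
    the opposite of scale-free).
    """
    adj = _check_square(adj, "adjacency")
    k = adj.sum(axis=1) - np.diag(adj)
    k = k[k > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        raise ValueError("degenerate network: all connectivities equal")
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max() + 1e-9, n_bins + 1)
    which = np.digitize(logk, edges) - 1
    which = np.clip(which, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        raise ValueError("too few occupied bins for a scale-free fit")
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = ys - (slope * xs + intercept)
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
    signed = -r2 if slope > 0 else r2
    return float(signed), float(slope)


def pick_soft_threshold(
    sim: np.ndarray,
    candidate_betas=tuple(range(1, 21)),
    r2_target: float = 0.8,
) -> tuple[int, pd.DataFrame]:
    """Choose the smallest power whose network meets the scale-free target.

    Falls back to the power with maximal fit when none reaches the target.
    Returns (beta, fit table with columns beta, r2, slope, mean_k).
    """
    candidates = sorted(set(int(b) for b in candidate_betas))
    if len(candidates) < 2:
        raise ValueError("need >= 2 candidate powers")
    rows = []
    for beta in candidates:
        adj = adjacency(sim, beta)
        k = adj.sum(axis=1) - 1.0
        r2, slope = scale_free_fit(adj)
        rows.append({"beta": beta, "r2": r2, "slope": slope, "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    meeting = table[table["r2"] >= r2_target]
    if len(meeting):
        chosen = int(meeting.iloc[0]["beta"])
    else:
        chosen = int(table.loc[table["r2"].idxmax(), "beta"])
    return chosen, table


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Topological overlap measure.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j with
    l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu; TOM_ii = 1.
    Combines direct adjacency with shared-neighbour strength.
    """
    adj = _check_square(adj, "adjacency")
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a  # (A^2)_ij already excludes u=i and u=j terms once diag is 0
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - adj
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + adj) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _cut_tree_nodes(tree, height: float) -> list:
    """Maximal subtrees whose internal merges all lie below ``height``."""
    out = []
    stack = [tree]
    while stack:
        node = stack.pop()
        if node.is_leaf() or node.dist <= height:
            out.append(node)
        else:
            stack.append(node.get_left())
            stack.append(node.get_right())
    return out


def _join_heights(tree, min_size: int) -> dict[int, float]:
    """Height at which each node merges with a sibling branch of >= min_size.

    Lone outliers attaching one by one above a branch (a "straggler ladder")
    should not count as the branch ending, so the effective join height of a
    node skips past ancestors whose other child is small.  The tree root
    gets 1.0, the maximum possible TOM dissimilarity.
    """
    join: dict[int, float] = {tree.id: 1.0}
    stack = [tree]
    while stack:
        node = stack.pop()
        if node.is_leaf():
            continue
        left, right = node.get_left(), node.get_right()
        join[left.id] = node.dist if right.get_count() >= min_size else join[node.id]
        join[right.id] = node.dist if left.get_count() >= min_size else join[node.id]
        stack.append(left)
        stack.append(right)
    return join


def _harvest(node, join: dict[int, float], min_size: int, gap: float,
             deep: bool) -> list:
    """Collect distinct-branch module candidates from a subtree.

    A node is a distinct branch when it joins the nearest substantial
    sibling at least ``gap`` above its own internal completion height.
    With ``deep`` the finest nested distinct branches win (aggressive
    splitting); without it the outermost distinct branch is kept whole.
    """
    results: dict[int, list] = {}
    stack = [(node, False)]
    while stack:
        current, visited = stack.pop()
        if current.is_leaf() or current.get_count() < min_size:
            results[current.id] = []
            continue
        if not visited:
            stack.append((current, True))
            stack.append((current.get_left(), False))
            stack.append((current.get_right(), False))
            continue
        sub = results[current.get_left().id] + results[current.get_right().id]
        distinct = join[current.id] - current.dist >= gap
        if deep:
            results[current.id] = sub if sub else ([current] if distinct else [])
        else:
            results[current.id] = [current] if distinct else sub
    return results[node.id]


def detect_modules(
    tom: np.ndarray,
    genes: pd.Index,
    params: NetworkParams,
    exclude: np.ndarray | None = None,
) -> tuple[ModuleAssignment, np.ndarray]:
    """Average-linkage tree cut of the TOM dissimilarity into modules.

    Branches below ``detect_cut_height`` become module candidates; with
    ``deep_split`` a branch is further split at internal forks whose two
    sides are each large enough to stand alone.  A candidate becomes a
    module only if it has at least ``min_module_size`` members and is a
    distinct branch: it must attach to the rest of the tree at least
    ``branch_gap`` above its own internal completion height (a diffuse
    cloud of uncorrelated genes merges almost at the same height it joins
    everything else, and stays unassigned).  Remaining genes get label 0.
    ``exclude`` marks genes (e.g. zero-variance) that are never assigned.
    Labels are 1..K by decreasing module size.  Returns (assignment,
    linkage matrix).
    """
    tom = _check_square(tom, "TOM")
    n = tom.shape[0]
    genes = pd.Index(genes)
    if len(genes) != n:
        raise ValueError("gene ids must match the TOM dimension")
    if n < params.min_module_size:
        warnings.warn("fewer genes than min_module_size; all genes unassigned")
        labels = pd.Series(np.zeros(n, dtype=int), index=genes)
        return ModuleAssignment(labels), np.empty((0, 4))

    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    condensed = diss[np.triu_indices(n, k=1)]
    z = hierarchy.linkage(condensed, method="average")
    tree = hierarchy.to_tree(z)

    join = _join_heights(tree, params.min_module_size)
    cores = []
    for branch in _cut_tree_nodes(tree, params.detect_cut_height):
        cores.extend(
            _harvest(branch, join, params.min_module_size,
                     params.branch_gap, params.deep_split)
        )

    # expand each core back up through its straggler ladder: absorb sibling
    # branches too small to be modules themselves and attached closer to the
    # core than to its join point, stopping at any substantial branch
    parent: dict[int, object] = {}
    stack = [tree]
    while stack:
        node = stack.pop()
        if node.is_leaf():
            continue
        for child in (node.get_left(), node.get_right()):
            parent[child.id] = node
            stack.append(child)

    excluded = np.zeros(n, dtype=bool) if exclude is None else np.asarray(exclude, bool)
    modules = []
    for core in cores:
        current = core
        absorb_below = min(
            core.dist + 0.5 * (join[core.id] - core.dist), params.detect_cut_height
        )
        while current.id in parent:
            up = parent[current.id]
            sibling = up.get_right() if up.get_left().id == current.id else up.get_left()
            if sibling.get_count() >= params.min_module_size:
                break
            if up.dist > absorb_below:
                break
            current = up
        members = [i for i in current.pre_order(lambda leaf: leaf.id) if not excluded[i]]
        if len(members) >= params.min_module_size:
            modules.append(members)
    modules.sort(key=lambda m: (-len(m), min(m)))

    labels = np.zeros(n, dtype=int)
    for lab, members in enumerate(modules, start=1):
        labels[members] = lab
    return ModuleAssignment(pd.Series(labels, index=genes)), z


def module_eigengenes(expr: ExpressionMatrix, assignment: ModuleAssignment) -> pd.DataFrame:
    """First principal component of each module's standardized expression.

    Each eigengene is the first right singular vector of the gene-by-sample
    module submatrix after per-gene standardization, unit norm, sign-aligned
    so it correlates non-negatively with the module's mean standardized
    expression.  Returns samples x module labels.
    """
    frame = expr.to_frame()
    cols = {}
    for module in assignment.module_labels():
        members = assignment.genes_in(module)
        if len(members) < 3:
            raise ValueError(f"module {module} has fewer than 3 genes")
        sub = frame.loc[members].to_numpy()
        sd = sub.std(axis=1)
        sd[sd == 0] = 1.0
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        _u, _s, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(eig, mean_profile) < 0:
            eig = -eig
        cols[module] = eig
    return pd.DataFrame(cols, index=expr.samples)


def merge_similar_modules(
    expr: ExpressionMatrix,
    assignment: ModuleAssignment,
    merge_cut_height: float = 0.25,
    max_iter: int = 10,
) -> ModuleAssignment:
    """Merge modules whose eigengenes cluster below the merge cut height.

    Average-linkage clustering of eigengene dissimilarity 1 - cor(E_a, E_b);
    branches below ``merge_cut_height`` are unioned, eigengenes recomputed,
    and the procedure iterated until stable.
    """
    labels = assignment.labels.copy()
    for _ in range(max_iter):
        current = ModuleAssignment(labels)
        mods = current.module_labels()
        if len(mods) < 2 or merge_cut_height <= 0:
            break
        eig = module_eigengenes(expr, current)
        corr = np.corrcoef(eig.to_numpy().T)
        diss = 1.0 - corr
        np.fill_diagonal(diss, 0.0)
        condensed = np.clip(diss[np.triu_indices(len(mods), k=1)], 0.0, None)
        z = hierarchy.linkage(condensed, method="average")
        groups = hierarchy.fcluster(z, t=merge_cut_height, criterion="distance")
        if len(set(groups)) == len(mods):
            break
        remap = {}
        for group in sorted(set(groups)):
            members = [mods[i] for i in range(len(mods)) if groups[i] == group]
            target = min(members)
            for m in members:
                remap[m] = target
        labels = labels.map(lambda lab: remap.get(lab, lab))

    # relabel 1..K by decreasing size
    final = ModuleAssignment(labels)
    sizes = final.sizes()
    order = sorted(sizes, key=lambda m: (-sizes[m], m))
    relabel = {old: new for new, old in enumerate(order, start=1)}
    relabel[0] = 0
    labels = labels.map(relabel)
    merged = ModuleAssignment(labels)
    if merged.module_labels():
        merged.eigengenes = module_eigengenes(expr, merged)
    return merged


def build_network(expr: ExpressionMatrix, params: NetworkParams) -> dict:
    """End-to-end per-tissue network: similarity -> beta -> TOM -> modules.

    Returns a dict with keys beta, fit_table, assignment (post-merge, with
    eigengenes), linkage, flagged (zero-variance gene mask).
    """
    sim, flagged = signed_similarity(expr)
    if params.beta is not None:
        beta, fit_table = int(params.beta), None
    else:
        beta, fit_table = pick_soft_threshold(
            sim, params.candidate_betas, params.scale_free_r2_target
        )
    adj = adjacency(sim, beta)
    tom = topological_overlap(adj)
    assignment, z = detect_modules(tom, expr.genes, params, exclude=flagged)
    if assignment.module_labels():
        assignment.eigengenes = module_eigengenes(expr, assignment)
        assignment = merge_similar_modules(expr, assignment, params.merge_cut_height)
    return {
        "beta": beta,
        "fit_table": fit_table,
        "assignment": assignment,
        "linkage": z,
        "flagged": flagged,
    }


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string (for inspection)."""
    tree = hierarchy.to_tree(z)

    def render(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.get_left(), node.dist)
        right = render(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"
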