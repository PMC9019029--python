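"""Distance-based phylogeny: Fitch-Margoliash least squares, NJ, quartets.

The central operation is ``fitch_margoliash``: it fits an unrooted binary
tree to a distance matrix by minimizing the weighted least-squares criterion

    SSE = sum_{i<j} (d_ij - p_ij)^2 / d_ij^power      (power = 2 by default)

where p_ij is the path length between leaves i and j in the candidate tree
and branch lengths are constrained to be non-negative. The search uses
stepwise addition under randomized taxon orders ("jumbling"), followed by
nearest-neighbor-interchange sweeps and, optionally, global
subtree-pruning-and-regrafting sweeps; the best tree over all jumbles is
returned and the whole procedure is deterministic given the seed.

Neighbor joining (via scikit-bio) is provided as an independent
reference method, and ``quartet_distance`` counts the 4-leaf subsets on
which two trees disagree — the standard topology-comparison statistic for
trees of up to a few dozen leaves, computed here by direct enumeration.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .distance import DistanceMatrix

__all__ = [
    "SearchConfig",
    "fit_branch_lengths",
    "fitch_margoliash",
    "neighbor_joining",
    "root_with_outgroup",
    "quartet_distance",
    "is_monophyletic",
    "sibling_fraction",
    "parse_newick",
    "read_newick",
    "write_newick",
    "tree_to_newick",
]

_WEIGHT_FLOOR = 1e-9  # distance floor for 1/d^power weights (duplicates give d ~ 0)


@dataclass(frozen=True)
class SearchConfig:
    """Settings for the Fitch-Margoliash tree search."""

    jumbles: int = 5
    global_rearrangements: bool = True
    power: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jumbles < 1:
            raise ValueError("jumbles must be >= 1")
        if self.power < 0:
            raise ValueError("power must be >= 0")


# ---------------------------------------------------------------------------
# Internal adjacency-based tree representation for the FM search
# ---------------------------------------------------------------------------


def _copy_adj(adj: dict[int, set[int]]) -> dict[int, set[int]]:
    return {u: set(vs) for u, vs in adj.items()}


def _edge_list(adj: dict[int, set[int]]) -> list[tuple[int, int]]:
    return sorted(
        (u, v) for u, vs in adj.items() for v in vs if u < v
    )


class _Fitter:
    """Weighted least-squares branch-length fitting for a fixed leaf set."""

    def __init__(self, dvec: np.ndarray, weights: np.ndarray, n_leaves: int):
        self.n = n_leaves
        iu = np.triu_indices(n_leaves, k=1)
        self.dsq = np.zeros((n_leaves, n_leaves))
        self.dsq[iu] = dvec
        self.dsq += self.dsq.T
        self.wsq = np.zeros((n_leaves, n_leaves))
        self.wsq[iu] = weights
        self.wsq += self.wsq.T

    def incidence(self, adj: dict[int, set[int]], leaves: Sequence[int]):
        """Pair-edge incidence matrix for the leaves present in ``leaves``."""
        edges = _edge_list(adj)
        eidx = {e: i for i, e in enumerate(edges)}
        root = leaves[0]
        R = {root: np.zeros(len(edges))}
        stack = [root]
        seen = {root}
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    row = R[u].copy()
                    row[eidx[(min(u, v), max(u, v))]] = 1.0
                    R[v] = row
                    stack.append(v)
        L = np.stack([R[l] for l in leaves])
        k = len(leaves)
        ii, jj = np.triu_indices(k, k=1)
        A = np.abs(L[ii] - L[jj])  # edge on path iff in exactly one root-path
        return A, edges

    def fit(self, A: np.ndarray, dsub: np.ndarray, wsub: np.ndarray, exact: bool):
        """Return (lengths >= 0, weighted SSE)."""
        sw = np.sqrt(wsub)
        Aw = A * sw[:, None]
        dw = dsub * sw
        x, *_ = np.linalg.lstsq(Aw, dw, rcond=None)
        if x.min() < -1e-9 and exact:
            from scipy.optimize import nnls

            x, _ = nnls(Aw, dw)
        x = np.maximum(x, 0.0)
        resid = dsub - A @ x
        return x, float((wsub * resid * resid).sum())

    def evaluate(
        self, adj: dict[int, set[int]], leaves: Sequence[int], exact: bool = False
    ):
        A, edges = self.incidence(adj, leaves)
        k = len(leaves)
        ii, jj = np.triu_indices(k, k=1)
        la = np.asarray(leaves)
        dsub = self.dsq[la[ii], la[jj]]
        wsub = self.wsq[la[ii], la[jj]]
        x, sse = self.fit(A, dsub, wsub, exact)
        return sse, x, edges


def _stepwise_addition(
    fitter: _Fitter, order: np.ndarray
) -> dict[int, set[int]]:
    n = fitter.n
    next_node = [n]

    def new_node() -> int:
        next_node[0] += 1
        return next_node[0] - 1

    a, b, c = (int(x) for x in order[:3])
    center = new_node()
    adj: dict[int, set[int]] = {
        a: {center}, b: {center}, c: {center}, center: {a, b, c}
    }
    present = [a, b, c]
    for x in order[3:]:
        x = int(x)
        best = None
        for (u, v) in _edge_list(adj):
            cand = _copy_adj(adj)
            w = new_node()
            cand[u].discard(v)
            cand[v].discard(u)
            cand[u].add(w)
            cand[v].add(w)
            cand[w] = {u, v, x}
            cand[x] = {w}
            sse, _, _ = fitter.evaluate(cand, present + [x])
            if best is None or sse < best[0] - 1e-15:
                best = (sse, cand)
            next_node[0] -= 1  # reuse the id for the next candidate
        next_node[0] += 1  # commit one internal node
        adj = best[1]
        present.append(x)
    return adj


def _nni_sweeps(fitter: _Fitter, adj, leaves, sse, max_sweeps: int = 50):
    n_set = set(leaves)
    for _ in range(max_sweeps):
        improved = False
        for (u, v) in _edge_list(adj):
            if u in n_set or v in n_set:
                continue  # pendant edge
            a_nbrs = sorted(adj[u] - {v})
            b_nbrs = sorted(adj[v] - {u})
            for a2, b2 in ((a_nbrs[1], b_nbrs[0]), (a_nbrs[1], b_nbrs[1])):
                cand = _copy_adj(adj)
                cand[u].discard(a2); cand[a2].discard(u)
                cand[v].discard(b2); cand[b2].discard(v)
                cand[u].add(b2); cand[b2].add(u)
                cand[v].add(a2); cand[a2].add(v)
                cand_sse, _, _ = fitter.evaluate(cand, leaves)
                if cand_sse < sse - 1e-14:
                    adj, sse = cand, cand_sse
                    improved = True
                    break
            if improved:
                break  # adjacency changed; restart sweep on the fresh edge list
        if not improved:
            break
    return adj, sse


def _component(adj, start: int, blocked: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v != blocked and v not in seen:
                seen.add(v)
                stack.append(v)
    return seen


def _spr_sweeps(fitter: _Fitter, adj, leaves, sse, max_sweeps: int = 15):
    """Global rearrangements: prune every subtree, regraft on every edge."""
    node_ids = sorted(adj)
    next_id = max(node_ids) + 1
    for _ in range(max_sweeps):
        improved = False
        for (eu, ev) in _edge_list(adj):
            for (u, v) in ((eu, ev), (ev, eu)):
                # prune the component containing v (without crossing u)
                if len(adj[u]) == 1:
                    continue  # u is a leaf: pruning would detach everything else
                sub = _component(adj, v, blocked=u)
                base = _copy_adj(adj)
                base[u].discard(v)
                base[v].discard(u)
                # u had degree 3; suppress the degree-2 attachment point
                p, q = sorted(base[u])
                base[p].discard(u); base[q].discard(u)
                base[p].add(q); base[q].add(p)
                del base[u]
                restore_edge = (p, q)
                rem_edges = [
                    e for e in _edge_list(base)
                    if e[0] not in sub and e[1] not in sub
                ]
                for (x, y) in rem_edges:
                    if (x, y) == restore_edge:
                        continue  # regrafting on the merged edge recreates adj
                    cand = _copy_adj(base)
                    w = next_id
                    cand[x].discard(y); cand[y].discard(x)
                    cand[x].add(w); cand[y].add(w)
                    cand[w] = {x, y, v}
                    cand[v].add(w)
                    cand_sse, _, _ = fitter.evaluate(cand, leaves)
                    if cand_sse < sse - 1e-14:
                        adj, sse = cand, cand_sse
                        next_id += 1
                        improved = True
                        break
                if improved:
                    break
            if improved:
                break
        if not improved:
            break
    return adj, sse


def _adjacency_to_tree(
    adj: dict[int, set[int]],
    lengths: dict[tuple[int, int], float],
    labels: Sequence[str],
) -> dendropy.Tree:
    """Build an unrooted dendropy tree (root = an internal node, 3 children)."""
    n = len(labels)
    root = next(u for u in sorted(adj) if u >= n) if len(adj) > 2 else min(adj)

    def render(u: int, parent: int | None) -> str:
        children = [v for v in sorted(adj[u]) if v != parent]
        if not children and u < n:
            return _quote(labels[u])
        parts = []
        for v in children:
            e = (min(u, v), max(u, v))
            parts.append(f"{render(v, u)}:{lengths[e]:.8f}")
        return "(" + ",".join(parts) + ")"

    newick = render(root, None) + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = False
    return tree


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]:;,'\t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def fitch_margoliash(
    matrix: DistanceMatrix, config: SearchConfig | None = None
) -> dendropy.Tree:
    """Fit a least-squares (Fitch-Margoliash) tree to a distance matrix.

    Runs ``config.jumbles`` randomized-addition searches, each refined by
    NNI sweeps and (if ``global_rearrangements``) SPR sweeps, and returns
    the lowest-SSE tree. Jumbles stop early once a perfectly additive fit
    (SSE ~ 0) is found, since no rearrangement can improve on it.
    """
    config = config or SearchConfig()
    n = matrix.n
    if n < 3:
        raise ValueError("tree fitting requires at least 3 taxa")
    if (matrix.values < 0).any():
        raise ValueError("distances must be non-negative")
    iu = np.triu_indices(n, k=1)
    dvec = matrix.values[iu]
    wvec = 1.0 / np.maximum(dvec, _WEIGHT_FLOOR) ** config.power
    fitter = _Fitter(dvec, wvec, n)
    leaves = list(range(n))

    best: tuple[float, dict, dict] | None = None
    root_ss = np.random.SeedSequence(config.seed)
    for jumble, child_ss in enumerate(root_ss.spawn(config.jumbles)):
        rng = np.random.default_rng(child_ss)
        order = rng.permutation(n)
        adj = _stepwise_addition(fitter, order)
        sse, _, _ = fitter.evaluate(adj, leaves)
        if n > 3:
            adj, sse = _nni_sweeps(fitter, adj, leaves, sse)
            if config.global_rearrangements:
                while True:
                    adj, sse2 = _spr_sweeps(fitter, adj, leaves, sse)
                    adj, sse3 = _nni_sweeps(fitter, adj, leaves, sse2)
                    if sse3 >= sse - 1e-14:
                        sse = min(sse, sse3)
                        break
                    sse = sse3
        if best is None or sse < best[0] - 1e-14:
            sse_f, x, edges = fitter.evaluate(adj, leaves, exact=True)
            best = (sse_f, adj, dict(zip(edges, x)))
        if best[0] < 1e-12:
            break
    sse, adj, lengths = best
    return _adjacency_to_tree(adj, lengths, matrix.labels)


def fit_branch_lengths(
    matrix: DistanceMatrix, tree: dendropy.Tree, power: float = 2.0
) -> tuple[dendropy.Tree, float]:
    """Least-squares branch lengths for a fixed topology; returns (tree, SSE).

    Applies the same constrained (>= 0) weighted fit the tree search uses,
    so search results can be compared against alternative topologies.
    """
    labels = matrix.labels
    n = matrix.n
    idx = {lab: i for i, lab in enumerate(labels)}
    t = tree.clone(depth=1)
    t.deroot()
    node_id: dict[int, int] = {}
    next_id = n
    adj: dict[int, set[int]] = {}
    for node in t.preorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            if lab not in idx:
                raise ValueError(f"tree leaf {lab!r} absent from matrix")
            node_id[id(node)] = idx[lab]
        else:
            node_id[id(node)] = next_id
            next_id += 1
    for node in t.preorder_node_iter():
        u = node_id[id(node)]
        adj.setdefault(u, set())
        if node.parent_node is not None:
            v = node_id[id(node.parent_node)]
            adj[u].add(v)
            adj.setdefault(v, set()).add(u)
    iu = np.triu_indices(n, k=1)
    dvec = matrix.values[iu]
    wvec = 1.0 / np.maximum(dvec, _WEIGHT_FLOOR) ** power
    fitter = _Fitter(dvec, wvec, n)
    sse, x, edges = fitter.evaluate(adj, list(range(n)), exact=True)
    return _adjacency_to_tree(adj, dict(zip(edges, x)), labels), sse


def neighbor_joining(matrix: DistanceMatrix) -> dendropy.Tree:
    """Standard neighbor joining (scikit-bio), as an independent reference."""
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj

    sk_tree = nj(SkbioDM(matrix.values, ids=matrix.labels))
    buf = io.StringIO()
    sk_tree.write(buf, format="newick")
    tree = dendropy.Tree.get(data=buf.getvalue(), schema="newick", preserve_underscores=True)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Rooting, clades, quartets
# ---------------------------------------------------------------------------


def _leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def root_with_outgroup(
    tree: dendropy.Tree, outgroups: Iterable[str]
) -> dendropy.Tree:
    """Root on the edge separating the outgroup set, splitting it equally."""
    outgroups = set(outgroups)
    leaves = _leaf_labels(tree)
    missing = outgroups - leaves
    if missing:
        raise ValueError(f"outgroup labels absent from tree: {sorted(missing)}")
    t = tree.clone(depth=1)
    t.deroot()
    target = None
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if below == outgroups or below == leaves - outgroups:
            target = node
            break
    if target is None:
        raise ValueError("outgroup not monophyletic in unrooted tree")
    elen = target.edge.length or 0.0
    t.reroot_at_edge(target.edge, length1=elen / 2.0, length2=elen / 2.0)
    t.is_rooted = True
    return t


def is_monophyletic(
    tree: dendropy.Tree, labels: Iterable[str], outgroups: Iterable[str]
) -> bool:
    """True iff ``labels`` is exactly a clade after rooting with the outgroup."""
    labels = set(labels)
    outgroups = set(outgroups)
    if labels & outgroups:
        raise ValueError(
            f"labels overlap the outgroup set: {sorted(labels & outgroups)}"
        )
    leaves = _leaf_labels(tree)
    if not labels <= leaves:
        raise ValueError(f"labels absent from tree: {sorted(labels - leaves)}")
    rooted = root_with_outgroup(tree, outgroups)
    for node in rooted.preorder_node_iter():
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if below == labels:
            return True
    return False


def sibling_fraction(
    tree: dendropy.Tree, pairs: Sequence[tuple[str, str]]
) -> float:
    """Fraction of label pairs forming cherries in the unrooted tree."""
    t = tree.clone(depth=1)
    t.deroot()
    parent = {
        lf.taxon.label: id(lf.parent_node) for lf in t.leaf_node_iter()
    }
    missing = {l for p in pairs for l in p} - parent.keys()
    if missing:
        raise ValueError(f"labels absent from tree: {sorted(missing)}")
    if not pairs:
        raise ValueError("no pairs given")
    hits = sum(1 for a, b in pairs if parent[a] == parent[b])
    return hits / len(pairs)


def _topological_matrix(tree: dendropy.Tree, labels: Sequence[str]) -> np.ndarray:
    """Leaf-to-leaf path lengths in edge counts (unrooted topology)."""
    t = tree.clone(depth=1)
    t.deroot()
    adj: dict[int, list[int]] = {}
    leaf_node: dict[str, int] = {}
    for node in t.preorder_node_iter():
        adj.setdefault(id(node), [])
        if node.parent_node is not None:
            adj[id(node)].append(id(node.parent_node))
            adj.setdefault(id(node.parent_node), []).append(id(node))
        if node.is_leaf():
            leaf_node[node.taxon.label] = id(node)
    n = len(labels)
    D = np.zeros((n, n), dtype=np.int64)
    for i, lab in enumerate(labels):
        # BFS from each leaf
        dist = {leaf_node[lab]: 0}
        queue = [leaf_node[lab]]
        while queue:
            u = queue.pop(0)
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        for j, lab2 in enumerate(labels):
            D[i, j] = dist[leaf_node[lab2]]
    return D


def _quartet_codes(D: np.ndarray, combos: np.ndarray) -> np.ndarray:
    a, b, c, d = combos[:, 0], combos[:, 1], combos[:, 2], combos[:, 3]
    s = np.stack([D[a, b] + D[c, d], D[a, c] + D[b, d], D[a, d] + D[b, c]])
    return np.argmin(s, axis=0)


def quartet_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Number of 4-leaf subsets with differing induced quartet topologies.

    Computed by direct enumeration over all C(n, 4) subsets using the
    four-point condition on unit-branch-length path matrices; intended for
    n up to ~60.
    """
    l1, l2 = _leaf_labels(t1), _leaf_labels(t2)
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: {sorted(l1.symmetric_difference(l2))}"
        )
    labels = sorted(l1)
    n = len(labels)
    if n < 4:
        return 0
    D1 = _topological_matrix(t1, labels)
    D2 = _topological_matrix(t2, labels)
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), 4)),
        dtype=np.int64,
    ).reshape(-1, 4)
    return int((_quartet_codes(D1, combos) != _quartet_codes(D2, combos)).sum())


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"newick parse error: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise ValueError(f"duplicate leaf labels: {dupes}")
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True,
        preserve_spaces=True, real_value_format_specifier=".6f"
    ).strip()


def read_newick(path: str) -> dendropy.Tree:
    with open(path, "rt") as fh:
        return parse_newick(fh.read())


def write_newick(tree: dendropy.Tree, path: str) -> None:
    with open(path, "wt") as fh:
        fh.write(tree_to_newick(tree) + "\n")
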