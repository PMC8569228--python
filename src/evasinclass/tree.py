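"""Identity distances, neighbour joining, bootstrap and midpoint rooting.

Pairwise distances come from the alignment as ``sqrt(1 - fraction
identical)`` over mutually non-gap columns (the identity mode of the
classic ``dist.alignment`` distance).  Trees are built with the
Saitou–Nei neighbour-joining agglomeration, supported by bootstrap
resampling of alignment columns, and rooted at the midpoint of the
longest leaf-to-leaf path — the rooting used when no outgroup exists,
as is the case for evasins.

Trees are :class:`dendropy.Tree` objects throughout; bootstrap supports
are fractions in [0, 1] attached per internal edge (keyed by the leaf
bipartition the edge induces) and rendered as percentages in Newick
internal-node labels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "DistanceMatrix",
    "identity_distance",
    "neighbor_joining",
    "tree_bipartitions",
    "bootstrap_support",
    "midpoint_root",
    "write_newick",
    "read_newick",
]

GAP = "-"


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances over named sequences."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.ids) + "\n")
            for i, rid in enumerate(self.ids):
                fh.write(rid + "\t" + "\t".join(f"{x:.6f}" for x in self.values[i]) + "\n")


def _msa_arrays(msa) -> tuple[list[str], np.ndarray, np.ndarray]:
    ids = list(msa.ids)
    mat = np.array([list(r) for r in msa.rows], dtype="U1")
    nongap = mat != GAP
    return ids, mat, nongap


def identity_distance(msa, deletion: str = "pairwise") -> DistanceMatrix:
    """``sqrt(1 - matches/compared)`` for every row pair of the MSA.

    ``deletion="pairwise"`` compares only columns where both rows are
    non-gap (the default, matching the identity-mode alignment distance);
    ``"complete"`` restricts to columns with no gap in any row.  A pair
    with zero comparable columns gets distance 1 with a warning.
    """
    if msa.n_rows < 2:
        raise ValueError("distance needs an alignment with >=2 rows")
    ids, mat, nongap = _msa_arrays(msa)
    if deletion == "complete":
        keep = nongap.all(axis=0)
        mat = mat[:, keep]
        nongap = nongap[:, keep]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            compared = int(both.sum())
            if compared == 0:
                warnings.warn(
                    f"no comparable columns between {ids[i]} and {ids[j]}; "
                    "distance set to 1"
                )
                dij = 1.0
            else:
                matches = int((mat[i][both] == mat[j][both]).sum())
                dij = math.sqrt(max(0.0, 1.0 - matches / compared))
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(ids, d)


def _two_leaf_tree(ids, d, ns) -> dendropy.Tree:
    tree = dendropy.Tree(taxon_namespace=ns)
    for rid, half in zip(ids, (d / 2.0, d / 2.0)):
        child = tree.seed_node.new_child(edge_length=half)
        child.taxon = ns.get_taxon(rid)
    tree.is_rooted = False
    return tree


def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbour joining; returns an unrooted tree.

    At each step the pair minimizing
    ``Q(i,j) = (r-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)`` is joined,
    ties broken by the smallest (i, j) index pair in the current cluster
    ordering (the joined cluster takes the lower slot).  Negative branch
    length estimates are clamped to zero with the deficit moved to the
    sibling edge, preserving the pair's path length.  On additive inputs
    the tree's path lengths reproduce the matrix exactly.
    """
    n = len(D.ids)
    if n < 2:
        raise ValueError("neighbour joining needs >=2 taxa")
    ns = dendropy.TaxonNamespace(D.ids)
    if n == 2:
        return _two_leaf_tree(D.ids, float(D.values[0, 1]), ns)

    nodes: list[dendropy.Node] = []
    for rid in D.ids:
        node = dendropy.Node(taxon=ns.get_taxon(rid))
        nodes.append(node)
    d = D.values.copy()

    def clamp_pair(li: float, lj: float, total: float) -> tuple[float, float]:
        if li < 0:
            lj = total - 0.0
            li = 0.0
        elif lj < 0:
            li = total - 0.0
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        r = len(nodes)
        row_sums = d.sum(axis=1)
        q = (r - 2) * d - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest (i, j) pair on ties
        best = np.inf
        bi = bj = -1
        for i in range(r):
            for j in range(i + 1, r):
                if q[i, j] < best:
                    best, bi, bj = q[i, j], i, j
        dij = d[bi, bj]
        li = 0.5 * dij + (row_sums[bi] - row_sums[bj]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = clamp_pair(li, lj, dij)
        parent = dendropy.Node()
        parent.add_child(nodes[bi])
        nodes[bi].edge.length = li
        parent.add_child(nodes[bj])
        nodes[bj].edge.length = lj
        new_d = 0.5 * (d[bi] + d[bj] - dij)
        new_d = np.maximum(new_d, 0.0)
        keep = [k for k in range(r) if k not in (bi, bj)]
        d_next = np.empty((r - 1, r - 1))
        d_next[1:, 1:] = d[np.ix_(keep, keep)]
        d_next[0, 1:] = d_next[1:, 0] = new_d[keep]
        d_next[0, 0] = 0.0
        nodes = [parent] + [nodes[k] for k in keep]
        d = d_next

    center = dendropy.Node()
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = max(0.0, 0.5 * (dab + dac - dbc))
    lb = max(0.0, 0.5 * (dab + dbc - dac))
    lc = max(0.0, 0.5 * (dac + dbc - dab))
    for node, length in ((a, la), (b, lb), (c, lc)):
        center.add_child(node)
        node.edge.length = length
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=center)
    tree.is_rooted = False
    return tree


def _leafset(node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def _canonical(side: frozenset[str], all_leaves: frozenset[str]) -> frozenset[str]:
    """Orient a bipartition to the side not containing the smallest leaf."""
    anchor = min(all_leaves)
    return all_leaves - side if anchor in side else side


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions (canonical orientation) of a tree.

    Works identically for rooted and unrooted trees: trivial splits
    (single leaf, or all/zero leaves on one side) are excluded.
    """
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = _leafset(node)
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(_canonical(side, all_leaves))
    return out


def bootstrap_support(
    msa,
    n_reps: int = 100,
    seed: int = 0,
    tree: dendropy.Tree | None = None,
    deletion: str = "pairwise",
) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """Column-resampling bootstrap supports mapped onto the NJ tree.

    Each replicate draws alignment columns with replacement (same column
    count), recomputes identity distances and the NJ tree; the support of
    an internal edge is the fraction of replicates whose tree contains the
    same leaf bipartition.  Deterministic for a fixed seed.  With
    ``n_reps=0`` the tree is returned unchanged with an empty support map.
    """
    if tree is None:
        tree = neighbor_joining(identity_distance(msa, deletion))
    if n_reps == 0:
        return tree, {}
    if msa.n_rows < 4:
        raise ValueError("bootstrap needs an alignment with >=4 rows")
    from .align import MSA

    rng = np.random.default_rng(seed)
    ids, mat, _ = _msa_arrays(msa)
    L = mat.shape[1]
    ref_bips = tree_bipartitions(tree)
    counts = {bip: 0 for bip in ref_bips}
    for _ in range(n_reps):
        cols = rng.integers(0, L, L)
        sub = mat[:, cols]
        keep = ~(sub == GAP).all(axis=0)  # all-gap columns carry no signal
        sub = sub[:, keep]
        rep_msa = MSA(ids, ["".join(row) for row in sub])
        rep_tree = neighbor_joining(identity_distance(rep_msa, deletion))
        rep_bips = tree_bipartitions(rep_tree)
        for bip in ref_bips:
            if bip in rep_bips:
                counts[bip] += 1
    support = {bip: c / n_reps for bip, c in counts.items()}
    annotate_supports(tree, support)
    return tree, support


def annotate_supports(tree: dendropy.Tree, support: dict[frozenset[str], float]) -> None:
    """Write supports (×100, rounded) into internal node labels."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        bip = _canonical(_leafset(node), all_leaves)
        if bip in support:
            node.label = str(int(round(support[bip] * 100)))


def _adjacency(tree: dendropy.Tree):
    adj: dict = {}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            w = child.edge.length or 0.0
            adj.setdefault(node, []).append((child, w, child.edge))
            adj.setdefault(child, []).append((node, w, child.edge))
    return adj


def midpoint_root(
    tree: dendropy.Tree,
    support: dict[frozenset[str], float] | None = None,
) -> dendropy.Tree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    The returned tree (the input is not modified) has a degree-2 root
    whose position minimizes the maximum root-to-leaf distance; a midpoint
    falling exactly on a node yields a zero-length root edge.  Ties among
    equally long leaf paths are broken by the lexicographically smallest
    (leaf, leaf) label pair.  Raises if every branch length is zero.
    """
    tree = tree.clone(depth=1)
    leaves = sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs >=2 leaves")
    adj = _adjacency(tree)

    def distances_from(leaf):
        dist = {leaf: 0.0}
        prev = {leaf: None}
        stack = [leaf]
        while stack:
            u = stack.pop()
            for v, w, edge in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    prev[v] = (u, edge, w)
                    stack.append(v)
        return dist, prev

    best = None  # (-length handled via comparisons)
    for la in leaves:
        dist, prev = distances_from(la)
        for lb in leaves:
            if lb.taxon.label <= la.taxon.label:
                continue
            key = (-dist[lb], la.taxon.label, lb.taxon.label)
            if best is None or key < best[0]:
                best = (key, la, lb, dist[lb], prev)
    _, la, lb, total, prev = best
    if total <= 0:
        raise ValueError(
            "midpoint undefined: all branch lengths are zero "
            "(inspect the distance matrix)"
        )
    # walk from lb back to la accumulating half the path
    path = []
    node = lb
    while node is not la:
        u, edge, w = prev[node]
        path.append((u, node, edge, w))  # from u towards lb
        node = u
    path.reverse()  # now ordered la -> lb
    half = total / 2.0
    cum = 0.0
    for u, v, edge, w in path:
        if cum + w >= half:
            t = half - cum  # distance from u along this edge
            break
        cum += w
    else:  # numerical fallback: root on the last edge
        u, v, edge, w = path[-1]
        t = w
    # dendropy edge runs tail_node (parent) -> head_node (child)
    if edge.head_node is v:
        tail_side = t if edge.tail_node is u else w - t
    else:  # head is u
        tail_side = w - t if edge.tail_node is v else t
    head_side = w - tail_side
    tree.reroot_at_edge(edge, length1=tail_side, length2=head_side,
                        update_bipartitions=False)
    tree.is_rooted = True
    if support:
        annotate_supports(tree, support)
    return tree


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Serialize with branch lengths and support labels."""
    s = tree.as_string(schema="newick", suppress_rooting=False,
                       real_value_format_specifier=".10g")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def read_newick(source: str) -> dendropy.Tree:
    """Parse a Newick string or file path written by :func:`write_newick`."""
    import os

    if os.path.exists(str(source)):
        tree = dendropy.Tree.get(path=str(source), schema="newick")
    else:
        tree = dendropy.Tree.get(data=str(source), schema="newick")
    return tree
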