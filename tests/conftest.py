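"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_protein(rng, length, alphabet=AA20) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))


# ---------------------------------------------------------------- oracles

def sw_oracle_score(a: str, b: str, gap_open=11, gap_extend=1, matrix="BLOSUM62"):
    """Independent local-alignment score via Biopython's PairwiseAligner."""
    aligner = PairwiseAligner(
        mode="local",
        substitution_matrix=substitution_matrices.load(matrix),
        open_gap_score=-(gap_open + gap_extend),
        extend_gap_score=-gap_extend,
    )
    return max(0.0, float(aligner.score(a, b)))


def global_oracle_score(a: str, b: str, gap_open=11, gap_extend=1, matrix="BLOSUM62"):
    """Independent global affine-gap score (end gaps penalized)."""
    aligner = PairwiseAligner(
        mode="global",
        substitution_matrix=substitution_matrices.load(matrix),
        open_gap_score=-(gap_open + gap_extend),
        extend_gap_score=-gap_extend,
    )
    return float(aligner.score(a, b))


def motif_oracle_hits(sequence: str, motif) -> set[tuple[int, ...]]:
    """Exhaustive anchor-tuple enumeration over all candidate positions."""
    seq = sequence.upper()
    out = set()
    if len(set(motif.anchors)) == 1:
        # identical anchors: strictly increasing tuples are combinations
        positions = [i for i, c in enumerate(seq) if c == motif.anchors[0]]
        candidates = itertools.combinations(positions, motif.n_anchors)
    else:
        per_anchor = [
            [i for i, c in enumerate(seq) if c == res] for res in motif.anchors
        ]
        candidates = (
            combo for combo in itertools.product(*per_anchor)
            if all(b > a for a, b in zip(combo, combo[1:]))
        )
    for combo in candidates:
        ok = all(
            lo <= b - a - 1 <= hi
            for (a, b), (lo, hi) in zip(zip(combo, combo[1:]), motif.gaps)
        )
        if ok:
            out.add(tuple(p + 1 for p in combo))
    return out


def random_binary_tree(rng, n_leaves: int, min_len=0.1, max_len=1.0) -> dendropy.Tree:
    """A random unrooted binary tree with positive branch lengths."""
    ns = dendropy.TaxonNamespace([f"L{i:02d}" for i in range(n_leaves)])
    nodes = [dendropy.Node(taxon=t) for t in ns]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for k in (i, j):
            parent.add_child(nodes[k])
            nodes[k].edge.length = float(rng.uniform(min_len, max_len))
        nodes = [parent] + [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
    center = dendropy.Node()
    for node in nodes:
        center.add_child(node)
        node.edge.length = float(rng.uniform(min_len, max_len))
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=center)
    tree.is_rooted = False
    return tree


def leaf_distances(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """All pairwise leaf path lengths (independent of package code)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    out = {}
    for i, ta in enumerate(taxa):
        for tb in taxa[i + 1:]:
            out[(ta.label, tb.label)] = pdm.patristic_distance(ta, tb)
    return out
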