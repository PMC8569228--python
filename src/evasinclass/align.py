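"""Progressive multiple sequence alignment (ClustalW-style).

Pairwise global affine-gap alignments give normalized distances
(1 - fractional identity); a UPGMA guide tree orders profile-profile
merges; profiles are aligned with average-linkage column scores and
"once a gap, always a gap" semantics.  The default scoring matrix is
BLOSUM62 with Gonnet-250 (GONNET1992) selectable; identity-based
distances downstream are insensitive to the choice at this divergence
scale, so the matrix is a logged config knob rather than a result driver.

Progressive alignment is deterministic for a fixed input order but not
input-order independent: guide-tree tie-breaks and merge order follow the
lexicographic conventions documented on each function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .screen import load_matrix, _encode

__all__ = ["MSA", "pairwise_global_align", "guide_tree", "progressive_align"]

NEG_INF = float("-inf")
GAP = "-"


@dataclass
class MSA:
    """An alignment: equal-length rows over residues plus ``-``."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")
        for j in range(self.n_columns):
            if all(r[j] == GAP for r in self.rows):
                raise ValueError(f"all-gap column at position {j + 1}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rid, row in zip(self.ids, self.rows):
                fh.write(f">{rid}\n{row}\n")

    @classmethod
    def from_fasta(cls, path) -> "MSA":
        from Bio import SeqIO
        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(ids, rows)


def _affine_dp(score: np.ndarray, go: float, ge: float) -> tuple[float, list[str]]:
    """Global affine-gap DP over a precomputed (n x m) column-score array.

    Returns the optimal score and the operation list (``D`` diagonal,
    ``U`` consume row-side, ``L`` consume column-side).  Traceback
    tie-break: diagonal, then gap in the first (row-side) profile, then
    gap in the second.
    """
    n, m = score.shape
    M = np.full((n + 1, m + 1), NEG_INF)
    Ix = np.full((n + 1, m + 1), NEG_INF)  # gap in second (consume first)
    Iy = np.full((n + 1, m + 1), NEG_INF)  # gap in first (consume second)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -go - ge * (i - 1)
    for j in range(1, m + 1):
        Iy[0, j] = -go - ge * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i, j] = max(M[i - 1, j] - go, Ix[i - 1, j] - ge)
            Iy[i, j] = max(M[i, j - 1] - go, Iy[i, j - 1] - ge)
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) \
                + score[i - 1, j - 1]
    end = max(M[n, m], Ix[n, m], Iy[n, m])
    state = "M" if end == M[n, m] else ("Iy" if end == Iy[n, m] else "Ix")
    ops: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == "M":
            prev = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            ops.append("D")
            if prev == M[i - 1, j - 1]:
                state = "M"
            elif prev == Iy[i - 1, j - 1]:
                state = "Iy"
            else:
                state = "Ix"
            i, j = i - 1, j - 1
        elif state == "Iy":  # gap in first profile, consume second
            ops.append("L")
            if Iy[i, j] == M[i, j - 1] - go:
                state = "M"
            j -= 1
        else:  # Ix: gap in second profile, consume first
            ops.append("U")
            if Ix[i, j] == M[i - 1, j] - go:
                state = "M"
            i -= 1
    ops.reverse()
    return float(end), ops


def pairwise_global_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> tuple[str, str, float]:
    """Optimal global affine-gap alignment of two sequences.

    End gaps are penalized.  Gap costs follow the BLAST convention
    (length-k gap costs ``gap_open + k * gap_extend``).  Ties prefer
    match/mismatch over gaps, then a gap in the first sequence.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    alphabet, S = load_matrix(matrix)
    ca = _encode(a.upper(), alphabet, False)
    cb = _encode(b.upper(), alphabet, False)
    score = S[np.ix_(ca, cb)]
    total, ops = _affine_dp(score, gap_open + gap_extend, gap_extend)
    ra, rb = [], []
    i = j = 0
    for op in ops:
        if op == "D":
            ra.append(a[i]); rb.append(b[j]); i += 1; j += 1
        elif op == "U":
            ra.append(a[i]); rb.append(GAP); i += 1
        else:
            ra.append(GAP); rb.append(b[j]); j += 1
    return "".join(ra), "".join(rb), total


def _pair_distance(a: str, b: str, matrix: str, go: float, ge: float) -> float:
    ra, rb, _ = pairwise_global_align(a, b, matrix, go, ge)
    matches = sum(1 for x, y in zip(ra, rb) if x == y and x != GAP)
    return 1.0 - matches / len(ra)


def guide_tree(
    seqs: Mapping[str, str],
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
):
    """UPGMA merge order over 1-identity pairwise alignment distances.

    Returns a nested tuple structure; leaves are ids.  Ties (equal
    distances) merge the pair with the lexicographically smallest
    (cluster-id, cluster-id) pair, where a cluster is named by its
    smallest member id; the smaller-named cluster is placed first.
    """
    ids = list(seqs)
    if len(ids) < 2:
        raise ValueError("guide tree needs >=2 sequences")
    dist: dict[tuple[str, str], float] = {}
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            i, j = ids[x], ids[y]
            dist[(i, j)] = dist[(j, i)] = _pair_distance(
                seqs[i], seqs[j], matrix, gap_open, gap_extend)
    clusters: dict[str, tuple] = {i: i for i in ids}  # name -> subtree
    sizes: dict[str, int] = {i: 1 for i in ids}
    d = dict(dist)
    while len(clusters) > 1:
        names = sorted(clusters)
        best = None
        for x in range(len(names)):
            for y in range(x + 1, len(names)):
                key = (d[(names[x], names[y])], names[x], names[y])
                if best is None or key < best:
                    best = key
        _, ci, cj = best
        merged = (clusters[ci], clusters[cj])
        new_name = min(ci, cj)
        ni, nj = sizes[ci], sizes[cj]
        for other in names:
            if other in (ci, cj):
                continue
            val = (ni * d[(ci, other)] + nj * d[(cj, other)]) / (ni + nj)
            d[(new_name, other)] = d[(other, new_name)] = val
        del clusters[ci], clusters[cj]
        clusters[new_name] = merged
        sizes[new_name] = ni + nj
    return next(iter(clusters.values()))


def _profile_counts(rows: list[str], alphabet: str) -> np.ndarray:
    """Per-column residue count vectors; gaps contribute nothing."""
    idx = {c: i for i, c in enumerate(alphabet)}
    L = len(rows[0])
    counts = np.zeros((L, len(alphabet)))
    for row in rows:
        for j, c in enumerate(row):
            if c != GAP:
                counts[j, idx[c]] += 1
    return counts


def progressive_align(
    seqs: Mapping[str, str],
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> MSA:
    """Align sequences progressively along the UPGMA guide tree.

    Profile-profile column scores are the average substitution score over
    all residue pairs of the two columns (gap symbols score 0), and gap
    columns inserted at a merge are propagated to every member ("once a
    gap, always a gap").  Output rows are reordered to the input id order.
    """
    if len(seqs) < 2:
        raise ValueError("progressive alignment needs >=2 sequences")
    alphabet, S = load_matrix(matrix)
    tree = guide_tree(seqs, matrix, gap_open, gap_extend)
    go, ge = gap_open + gap_extend, gap_extend

    def merge(node) -> tuple[list[str], list[str]]:
        if isinstance(node, str):
            return [node], [seqs[node].upper()]
        (ids_a, rows_a), (ids_b, rows_b) = merge(node[0]), merge(node[1])
        ca = _profile_counts(rows_a, alphabet)
        cb = _profile_counts(rows_b, alphabet)
        score = (ca @ S @ cb.T) / (len(rows_a) * len(rows_b))
        _, ops = _affine_dp(score, go, ge)
        out_a = ["" for _ in rows_a]
        out_b = ["" for _ in rows_b]
        i = j = 0
        for op in ops:
            if op == "D":
                for k, r in enumerate(rows_a):
                    out_a[k] += r[i]
                for k, r in enumerate(rows_b):
                    out_b[k] += r[j]
                i += 1; j += 1
            elif op == "U":
                for k, r in enumerate(rows_a):
                    out_a[k] += r[i]
                for k in range(len(rows_b)):
                    out_b[k] += GAP
                i += 1
            else:
                for k in range(len(rows_a)):
                    out_a[k] += GAP
                for k, r in enumerate(rows_b):
                    out_b[k] += r[j]
                j += 1
        return ids_a + ids_b, out_a + out_b

    ids, rows = merge(tree)
    order = {rid: k for k, rid in enumerate(ids)}
    sorted_ids = [rid for rid in seqs]
    sorted_rows = [rows[order[rid]] for rid in sorted_ids]
    return MSA(sorted_ids, sorted_rows)
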