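"""Desk-scale homology screen: local alignment + E-value thresholding.

Candidates are compared against the set of biochemically characterized
query evasins by exact Smith–Waterman local alignment under affine gap
costs (Gotoh), and the raw score is converted to an expectation value with
the Karlin–Altschul form ``E = K * m * n * exp(-lambda * S)``.  Candidates
whose best E-value is strictly below the threshold are kept, then
byte-identical mature sequences are collapsed to a single representative
("distinct sequences").

The (K, lambda) defaults are values typical of gapped BLOSUM62 scoring;
they reproduce the keep/drop *decision* of a BLAST screen at a permissive
threshold, not BLAST's composition-adjusted statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import numpy as np
from Bio.Align import substitution_matrices

__all__ = [
    "ScreenConfig",
    "AlignmentHit",
    "load_matrix",
    "smith_waterman",
    "evalue",
    "screen",
    "deduplicate",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class ScreenConfig:
    """Scoring and statistics for the local-alignment screen.

    ``gap_open``/``gap_extend`` follow the BLAST convention: a gap of
    length k costs ``gap_open + k * gap_extend``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_k: float = 0.041
    karlin_lambda: float = 0.267
    evalue_threshold: float = 1e-4
    search_space_m: int | None = None
    search_space_n: int | None = None
    map_unknown_to_zero: bool = False

    def validate(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.karlin_k <= 0 or self.karlin_lambda <= 0:
            raise ValueError("Karlin-Altschul K and lambda must be positive")
        if self.evalue_threshold <= 0:
            raise ValueError("evalue threshold must be positive")


@dataclass(frozen=True)
class AlignmentHit:
    """Best local alignment of a candidate against one query."""

    query_id: str
    subject_id: str
    score: float
    evalue: float | None = None
    span_query: tuple[int, int] | None = None  # 1-based inclusive
    span_subject: tuple[int, int] | None = None


@lru_cache(maxsize=None)
def load_matrix(name: str) -> tuple[str, np.ndarray]:
    """Return (alphabet, square score array) for a named matrix."""
    m = substitution_matrices.load(name)
    alphabet = "".join(m.alphabet)
    return alphabet, np.array(m, dtype=float)


def _encode(seq: str, alphabet: str, allow_unknown: bool) -> np.ndarray:
    idx = {c: i for i, c in enumerate(alphabet)}
    codes = np.empty(len(seq), dtype=np.int64)
    for i, c in enumerate(seq):
        j = idx.get(c)
        if j is None:
            if allow_unknown:
                j = -1
            else:
                raise ValueError(f"unknown residue {c!r} (position {i + 1})")
        codes[i] = j
    return codes


def _score_matrix(a: str, b: str, config: ScreenConfig) -> np.ndarray:
    alphabet, S = load_matrix(config.matrix_name)
    ca = _encode(a.upper(), alphabet, config.map_unknown_to_zero)
    cb = _encode(b.upper(), alphabet, config.map_unknown_to_zero)
    out = np.zeros((len(a), len(b)))
    known_a = ca >= 0
    known_b = cb >= 0
    if known_a.all() and known_b.all():
        return S[np.ix_(ca, cb)]
    out[np.ix_(known_a, known_b)] = S[np.ix_(ca[known_a], cb[known_b])]
    return out


def smith_waterman(a: str, b: str, config: ScreenConfig | None = None,
                   query_id: str = "a", subject_id: str = "b") -> AlignmentHit:
    """Optimal local alignment score and one optimal span pair.

    Exact affine-gap DP (Gotoh).  Among equal-scoring cells the one with
    the smallest (end_a, end_b) coordinates is reported.  An all-negative
    comparison yields score 0 with empty spans.
    """
    config = config or ScreenConfig()
    config.validate()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    s = _score_matrix(a, b, config)
    go = config.gap_open + config.gap_extend  # cost of a length-1 gap
    ge = config.gap_extend
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Iy = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        Mi, Mi1 = M[i], M[i - 1]
        Ixi, Ixi1 = Ix[i], Ix[i - 1]
        Iyi = Iy[i]
        Iyi1 = Iy[i - 1]
        srow = s[i - 1]
        for j in range(1, m + 1):
            Ixi[j] = max(Mi1[j] - go, Ixi1[j] - ge)
            Iyi[j] = max(Mi[j - 1] - go, Iyi[j - 1] - ge)
            diag = max(0.0, Mi1[j - 1], Ixi1[j - 1], Iyi1[j - 1])
            Mi[j] = diag + srow[j - 1]
            if Mi[j] > best:  # strict: keeps smallest (i, j) on ties
                best, bi, bj = Mi[j], i, j
    if best <= 0:
        return AlignmentHit(query_id, subject_id, 0.0, None, None, None)
    # traceback from (bi, bj) in state M
    i, j, state = bi, bj, "M"
    start_i, start_j = bi, bj
    while True:
        if state == "M":
            start_i, start_j = i, j
            prev = max(0.0, M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            if prev == 0.0:
                break
            if prev == M[i - 1][j - 1]:
                state = "M"
            elif prev == Ix[i - 1][j - 1]:
                state = "Ix"
            else:
                state = "Iy"
            i, j = i - 1, j - 1
        elif state == "Ix":
            if Ix[i][j] == M[i - 1][j] - go:
                state = "M"
            i -= 1
        else:
            if Iy[i][j] == M[i][j - 1] - go:
                state = "M"
            j -= 1
    return AlignmentHit(query_id, subject_id, best, None,
                        (start_i, bi), (start_j, bj))


def evalue(score: float, config: ScreenConfig, m: int | None = None,
           n: int | None = None) -> float:
    """Karlin–Altschul expectation ``E = K * m * n * exp(-lambda * S)``.

    ``m``/``n`` default to the configured effective search-space lengths.
    """
    m = config.search_space_m if config.search_space_m is not None else m
    n = config.search_space_n if config.search_space_n is not None else n
    if m is None or n is None:
        raise ValueError("search space (m, n) not set")
    return config.karlin_k * m * n * math.exp(-config.karlin_lambda * score)


def screen(
    candidates: Mapping[str, str],
    queries: Mapping[str, str],
    config: ScreenConfig | None = None,
    query_classes: Mapping[str, str] | None = None,
) -> tuple[dict[str, str], list[dict]]:
    """Keep candidates with best E-value strictly below the threshold.

    Every candidate is aligned against every query; the effective database
    length ``n`` defaults to the summed candidate lengths and ``m`` to the
    query length (overridable via the config).  The best hit per candidate
    is recorded together with the class pre-label of its best query.

    Returns (kept id->sequence, best-hit rows).
    """
    config = config or ScreenConfig()
    config.validate()
    if not candidates or not queries:
        raise ValueError("candidate and query sets must be non-empty")
    db_len = sum(len(s) for s in candidates.values())
    kept: dict[str, str] = {}
    rows: list[dict] = []
    for cid in candidates:
        cseq = candidates[cid]
        best_hit: AlignmentHit | None = None
        best_e = math.inf
        for qid in sorted(queries):
            hit = smith_waterman(queries[qid], cseq, config, qid, cid)
            e = evalue(hit.score, config, m=len(queries[qid]), n=db_len)
            if e < best_e or (e == best_e and best_hit is None):
                best_e = e
                best_hit = AlignmentHit(hit.query_id, hit.subject_id, hit.score,
                                        e, hit.span_query, hit.span_subject)
        assert best_hit is not None
        pre_class = (query_classes or {}).get(best_hit.query_id, "")
        rows.append({
            "candidate": cid,
            "query": best_hit.query_id,
            "score": best_hit.score,
            "evalue": best_hit.evalue,
            "pre_class": pre_class,
            "kept": best_e < config.evalue_threshold,
        })
        if best_e < config.evalue_threshold:
            kept[cid] = cseq
    return kept, rows


def deduplicate(sequences: Mapping[str, str]) -> tuple[dict[str, str], dict[str, list[str]]]:
    """Collapse byte-identical sequences to one representative.

    The representative is the lexicographically smallest id of each
    identity group.  Returns (distinct id->sequence, representative ->
    sorted list of all ids it stands for).
    """
    groups: dict[str, list[str]] = {}
    for cid in sequences:
        groups.setdefault(sequences[cid], []).append(cid)
    distinct: dict[str, str] = {}
    collapse: dict[str, list[str]] = {}
    for seq, ids in groups.items():
        ids = sorted(ids)
        distinct[ids[0]] = seq
        collapse[ids[0]] = ids
    # deterministic ordering by representative id
    distinct = dict(sorted(distinct.items()))
    collapse = dict(sorted(collapse.items()))
    return distinct, collapse
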