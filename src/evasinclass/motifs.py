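"""PROSITE-style cysteine-spacing motif definitions, scanning and profiling.

Biochemically characterized evasins fall into two structural families whose
cysteine frameworks can be written as PROSITE-like spacing patterns: the
eight-cysteine framework typical of CC-chemokine-binding (class A1) evasins
and the six-cysteine "knottin" framework of CXC-chemokine-binding (class B)
evasins.  A pattern is an ordered list of anchor residues (here always ``C``)
separated by gap ranges ``x(n)`` / ``x(n,m)`` matching any residue.

The scanner enumerates *every* anchor placement compatible with the gap
ranges, so overlapping occurrences and alternative spacings of the same
start anchor are all reported.  Presence/absence plus the raw cysteine count
form the per-sequence profile used in the heatmap annotation tables.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CYS6_PATTERN",
    "CYS8_PATTERN",
    "MotifDefinition",
    "MotifHit",
    "SequenceProfile",
    "parse_prosite",
    "cys6_motif",
    "cys8_motif",
    "scan",
    "profile",
    "write_profiles",
]

#: Six-cysteine knottin spacing characteristic of class B evasins.
CYS6_PATTERN = "C-x(3)-C-x(6,10)-C-x(3,6)-C-x(1)-C-x(10,11)-C"

#: Eight-cysteine spacing characteristic of class A1 evasins.
CYS8_PATTERN = "C-x(14,17)-C-x(3)-C-x(11,16)-C-x(17,20)-C-x(4)-C-x(4,5)-C-x(8)-C"

_GAP_RE = re.compile(r"^x\((\d+)(?:,(\d+))?\)$")


@dataclass(frozen=True)
class MotifDefinition:
    """A compiled spacing pattern: anchors alternating with gap ranges.

    ``anchors[k]`` is the residue required at the k-th anchor position and
    ``gaps[k] = (lo, hi)`` bounds the number of arbitrary residues between
    anchors k and k+1.
    """

    name: str
    anchors: tuple[str, ...]
    gaps: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise ValueError(f"motif {self.name!r} needs >=2 anchors")
        if len(self.gaps) != len(self.anchors) - 1:
            raise ValueError(f"motif {self.name!r}: gap/anchor count mismatch")
        for lo, hi in self.gaps:
            if not (0 <= lo <= hi):
                raise ValueError(f"motif {self.name!r}: bad gap range ({lo},{hi})")

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def min_span(self) -> int:
        """Shortest sequence stretch a match can occupy."""
        return self.n_anchors + sum(lo for lo, _ in self.gaps)

    @property
    def max_span(self) -> int:
        """Longest sequence stretch a match can occupy."""
        return self.n_anchors + sum(hi for _, hi in self.gaps)

    def to_pattern(self) -> str:
        """Normalized PROSITE-style string (round-trips through parse_prosite)."""
        parts = [self.anchors[0]]
        for (lo, hi), res in zip(self.gaps, self.anchors[1:]):
            parts.append(f"x({lo})" if lo == hi else f"x({lo},{hi})")
            parts.append(res)
        return "-".join(parts)


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence: 1-based anchor positions, inclusive span."""

    seq_id: str
    motif: str
    anchors: tuple[int, ...]
    span: tuple[int, int]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.anchors, self.anchors[1:])):
            raise ValueError("anchor positions must be strictly increasing")


@dataclass(frozen=True)
class SequenceProfile:
    """Heatmap annotation row: cysteine count plus motif presence flags."""

    seq_id: str
    cys_count: int
    has_cys6: bool
    has_cys8: bool


def parse_prosite(pattern: str, name: str | None = None) -> MotifDefinition:
    """Compile a ``C-x(3)-C-x(6,10)-...`` pattern string.

    Tokens are joined by ``-``; stray whitespace around tokens is tolerated
    (published patterns are sometimes typeset with spaces).  Anchor tokens
    are single residue letters; gap tokens are ``x(n)`` or ``x(n,m)``.
    """
    tokens = [t.strip() for t in pattern.strip().split("-")]
    if not tokens or any(t == "" for t in tokens):
        raise ValueError(f"malformed pattern: {pattern!r}")
    anchors: list[str] = []
    gaps: list[tuple[int, int]] = []
    for i, tok in enumerate(tokens):
        if i % 2 == 0:  # anchor position
            if len(tok) != 1 or not tok.isalpha():
                raise ValueError(f"malformed anchor token {tok!r} in {pattern!r}")
            anchors.append(tok.upper())
        else:
            m = _GAP_RE.match(tok)
            if m is None:
                raise ValueError(f"malformed gap token {tok!r} in {pattern!r}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) is not None else lo
            if lo > hi:
                raise ValueError(f"inverted gap range in token {tok!r}")
            gaps.append((lo, hi))
    if len(tokens) % 2 == 0:
        raise ValueError(f"pattern must end on an anchor: {pattern!r}")
    return MotifDefinition(name=name or pattern, anchors=tuple(anchors), gaps=tuple(gaps))


def cys6_motif() -> MotifDefinition:
    return parse_prosite(CYS6_PATTERN, name="cys6")


def cys8_motif() -> MotifDefinition:
    return parse_prosite(CYS8_PATTERN, name="cys8")


def scan(sequence: str, motif: MotifDefinition, seq_id: str = "") -> list[MotifHit]:
    """Report every occurrence of ``motif`` in ``sequence``.

    All valid gap combinations are enumerated depth-first (leftmost start
    anchor first, shorter gaps before longer), so overlapping matches are
    all reported.  Gap positions may contain any residue, including the
    anchor letter itself (standard PROSITE ``x`` semantics); the pattern is
    unanchored within the sequence.
    """
    seq = sequence.upper()
    n = len(seq)
    hits: list[MotifHit] = []

    def extend(path: list[int], k: int) -> None:
        if k == motif.n_anchors:
            anchors = tuple(p + 1 for p in path)  # 1-based
            hits.append(
                MotifHit(seq_id=seq_id, motif=motif.name, anchors=anchors,
                         span=(anchors[0], anchors[-1]))
            )
            return
        lo, hi = motif.gaps[k - 1]
        prev = path[-1]
        for pos in range(prev + lo + 1, min(prev + hi + 1, n - 1) + 1):
            if seq[pos] == motif.anchors[k]:
                path.append(pos)
                extend(path, k + 1)
                path.pop()

    first = motif.anchors[0]
    for start in range(n - motif.min_span + 1):
        if seq[start] == first:
            extend([start], 1)
    return hits


def profile(
    sequences: Mapping[str, str] | Iterable[tuple[str, str]],
    motifs: Sequence[MotifDefinition] | None = None,
) -> list[SequenceProfile]:
    """Cysteine count + motif presence for each (id, mature sequence) pair.

    With the default motif set the flags are the Cys6/Cys8 columns of the
    tree heatmaps; a flag implies the corresponding cysteine-count lower
    bound (asserted).
    """
    if motifs is None:
        motifs = [cys6_motif(), cys8_motif()]
    by_name = {m.name: m for m in motifs}
    items = sequences.items() if isinstance(sequences, Mapping) else sequences
    out: list[SequenceProfile] = []
    for seq_id, seq in items:
        seq = seq.upper()
        cys = seq.count("C")
        flags = {name: bool(scan(seq, m, seq_id)) for name, m in by_name.items()}
        prof = SequenceProfile(
            seq_id=seq_id,
            cys_count=cys,
            has_cys6=flags.get("cys6", False),
            has_cys8=flags.get("cys8", False),
        )
        if prof.has_cys6:
            assert cys >= 6
        if prof.has_cys8:
            assert cys >= 8
        out.append(prof)
    return out


def write_profiles(profiles: Iterable[SequenceProfile], path) -> None:
    """Write the heatmap annotation TSV (id, cys_count, has_cys6, has_cys8)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "cys_count", "has_cys6", "has_cys8"])
        for p in profiles:
            w.writerow([p.seq_id, p.cys_count, int(p.has_cys6), int(p.has_cys8)])
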