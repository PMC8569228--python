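"""Synthetic precursor datasets with the structure the analysis assumes.

The generator emulates what the transcriptome screen sees: precursor
proteins (Met + hydrophobic signal peptide + mature body), mature bodies
carrying a planted cysteine-spacing motif, two diverged lineages so that a
neighbour-joining tree with midpoint rooting recovers the planted
partition, and decoy records that the ingest/screen filters must remove
(missing signal peptide, internal stop codon, no homology).

Evolution is substitution-only on non-anchor sites: planted cysteine
anchors are immutable (the real protein families conserve their cysteine
frameworks), and substitutions are drawn from the 19 non-cysteine letters
so that accidental motif gains are impossible by construction.  Every
record is described by one row of a ground-truth table.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .motifs import MotifDefinition, cys6_motif, cys8_motif

__all__ = [
    "SyntheticConfig",
    "TruthRow",
    "plant_motif",
    "evolve_lineages",
    "generate_dataset",
    "NON_CYS",
    "HYDROPHOBIC_LETTERS",
    "HYDROPHILIC_LETTERS",
]

#: 19-letter amino-acid alphabet excluding cysteine.
NON_CYS = "ADEFGHIKLMNPQRSTVWY"
HYDROPHOBIC_LETTERS = "AILVFMW"
#: Used for decoy "signal" regions and the first mature residue, so the
#: hydrophobic run of a true signal peptide ends exactly at the cleavage site.
HYDROPHILIC_LETTERS = "DEGHKNPQRSTY"

_MOTIFS = {"cys6": cys6_motif, "cys8": cys8_motif}

_LINEAGE_OF_GENUS = {
    "Ixodes": "Prostriate",
    "Amblyomma": "Metastriate",
    "Dermacentor": "Metastriate",
    "Hyalomma": "Metastriate",
    "Rhipicephalus": "Metastriate",
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate a class-A-like screen: one Metastriate lineage with a
    planted Cys8 framework against one Prostriate lineage without it,
    modest within-lineage divergence and strong between-lineage divergence
    (the regime in which the root bipartition is recoverable).
    """

    n_class1: int = 10
    n_class2: int = 10
    motif_class1: str = "cys8"
    motif_class2: str = "none"
    mature_length: int = 90
    signal_length: int = 20
    substitution_rate_within: float = 0.05
    substitution_rate_between: float = 0.40
    n_decoy_no_signal: int = 1
    n_decoy_stop: int = 1
    n_decoy_unrelated: int = 1
    seed: int = 0
    genus_class1: str = "Rhipicephalus"
    species_class1: str = "microplus"
    genus_class2: str = "Ixodes"
    species_class2: str = "ricinus"

    def motif_of(self, cls: int) -> MotifDefinition | None:
        name = self.motif_class1 if cls == 1 else self.motif_class2
        if name == "none":
            return None
        try:
            return _MOTIFS[name]()
        except KeyError:
            raise ValueError(f"unknown motif name {name!r}") from None

    def validate(self) -> None:
        counts = (self.n_class1, self.n_class2, self.n_decoy_no_signal,
                  self.n_decoy_stop, self.n_decoy_unrelated)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        for r in (self.substitution_rate_within, self.substitution_rate_between):
            if not (0.0 <= r <= 1.0):
                raise ValueError("substitution rates must lie in [0, 1]")
        if self.substitution_rate_within >= self.substitution_rate_between:
            raise ValueError(
                "within-lineage rate must be below the between-lineage rate "
                "(planted partition would not be recoverable)"
            )
        if self.signal_length < 10:
            raise ValueError("signal_length must be >= 10")
        for cls in (1, 2):
            motif = self.motif_of(cls)
            if motif is not None and self.mature_length < motif.min_span:
                raise ValueError(
                    f"mature_length {self.mature_length} below minimal span "
                    f"{motif.min_span} of motif {motif.name!r}"
                )


@dataclass
class TruthRow:
    """Ground truth for one generated FASTA record."""

    id: str
    lineage: str
    planted_class: str
    cleavage_pos: int | None
    motif: str
    anchor_positions: tuple[int, ...] = field(default_factory=tuple)
    decoy_type: str = ""


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _choice(rng: np.random.Generator, letters: str) -> str:
    return letters[int(rng.integers(len(letters)))]


def plant_motif(length: int, motif: MotifDefinition, seed=0) -> tuple[str, tuple[int, ...]]:
    """Build a mature body of ``length`` residues with exactly one motif hit.

    Gap widths are sampled uniformly within each stated range (shrunk
    toward the minima when the sampled span exceeds ``length``), the match
    is placed at a uniform offset, and all non-anchor positions are drawn
    from the 19-letter non-cysteine alphabet, so the planted anchors are
    the only cysteines and the only possible occurrence.

    Returns the sequence and the 1-based anchor positions.
    """
    rng = _rng(seed)
    if length < motif.min_span:
        raise ValueError(
            f"length {length} too short for motif {motif.name!r}: "
            f"minimum {motif.min_span} residues required"
        )
    gaps = [int(rng.integers(lo, hi + 1)) for lo, hi in motif.gaps]
    span = motif.n_anchors + sum(gaps)
    while span > length:  # shrink a shrinkable gap, largest slack first
        k = max(range(len(gaps)), key=lambda i: gaps[i] - motif.gaps[i][0])
        gaps[k] -= 1
        span -= 1
    start = int(rng.integers(0, length - span + 1))
    anchors = [start]
    for g in gaps:
        anchors.append(anchors[-1] + g + 1)
    anchor_set = set(anchors)
    seq = [
        motif.anchors[anchors.index(i)] if i in anchor_set else _choice(rng, NON_CYS)
        for i in range(length)
    ]
    return "".join(seq), tuple(a + 1 for a in anchors)


def _mutate(seq: list[str], rate: float, frozen: set[int],
            rng: np.random.Generator) -> list[str]:
    """Substitute each non-frozen site with probability ``rate``.

    Replacements come from the non-cysteine alphabet (position 0 stays
    hydrophilic so the signal-peptide boundary remains unambiguous).
    """
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        if int(i) in frozen:
            continue
        pool = HYDROPHILIC_LETTERS if i == 0 else NON_CYS
        repl = _choice(rng, pool)
        while repl == out[i]:
            repl = _choice(rng, pool)
        out[int(i)] = repl
    return out


def evolve_lineages(config: SyntheticConfig, rng=None) -> list[dict]:
    """Generate mature bodies for both lineages by two-clade divergence.

    A lineage-1 ancestor is built around its planted motif; the lineage-2
    ancestor is derived from it by substituting non-anchor sites at the
    between-lineage rate and re-planting lineage 2's motif (if any).  Each
    member is its ancestor substituted at the within-lineage rate.  Motif
    anchors are never mutated.

    Returns one dict per member: ``lineage`` (1/2), ``sequence``,
    ``motif`` name, ``anchors`` (1-based).
    """
    config.validate()
    rng = _rng(config.seed if rng is None else rng)
    L = config.mature_length

    def build_ancestor(cls: int, base: list[str] | None) -> tuple[list[str], tuple[int, ...]]:
        motif = config.motif_of(cls)
        if base is None:
            if motif is None:
                seq = [_choice(rng, NON_CYS) for _ in range(L)]
                anchors: tuple[int, ...] = ()
            else:
                s, anchors = plant_motif(L, motif, rng)
                seq = list(s)
        else:
            seq = [c if c != "C" else _choice(rng, NON_CYS) for c in base]
            seq = _mutate(seq, config.substitution_rate_between, set(), rng)
            anchors = ()
            if motif is not None:
                _, anchors = plant_motif(L, motif, rng)
                for pos, res in zip(anchors, motif.anchors):
                    seq[pos - 1] = res
        if seq[0] not in set(HYDROPHILIC_LETTERS) and (not anchors or anchors[0] != 1):
            seq[0] = _choice(rng, HYDROPHILIC_LETTERS)
        return seq, anchors

    anc1, anchors1 = build_ancestor(1, None)
    anc2, anchors2 = build_ancestor(2, anc1)

    members: list[dict] = []
    for cls, (anc, anchors, n) in (
        (1, (anc1, anchors1, config.n_class1)),
        (2, (anc2, anchors2, config.n_class2)),
    ):
        frozen = {a - 1 for a in anchors}
        motif = config.motif_of(cls)
        for _ in range(n):
            seq = _mutate(anc, config.substitution_rate_within, frozen, rng)
            members.append({
                "lineage": cls,
                "sequence": "".join(seq),
                "motif": motif.name if motif is not None else "none",
                "anchors": anchors,
                "ancestor": "".join(anc),
            })
    return members


def _signal_peptide(config: SyntheticConfig, rng: np.random.Generator) -> str:
    """Met + hydrophobic-biased stretch ending on a hydrophobic residue.

    At least 8 hydrophobic residues are guaranteed (and the final position
    is always hydrophobic), so the heuristic cleavage provider with its
    default window recovers the true cleavage site exactly.
    """
    n = config.signal_length - 1
    body = [
        _choice(rng, HYDROPHOBIC_LETTERS) if rng.random() < 0.85 else _choice(rng, "GSTP")
        for _ in range(n)
    ]
    body[-1] = _choice(rng, HYDROPHOBIC_LETTERS)
    hyd = [i for i, c in enumerate(body) if c in set(HYDROPHOBIC_LETTERS)]
    need = 8 - len(hyd)
    if need > 0:
        nonhyd = [i for i, c in enumerate(body) if c not in set(HYDROPHOBIC_LETTERS)]
        for i in nonhyd[:need]:
            body[i] = _choice(rng, HYDROPHOBIC_LETTERS)
    return "M" + "".join(body)


def generate_dataset(config: SyntheticConfig, out_prefix: str | Path) -> dict[str, Path]:
    """Write the synthetic FASTA + cleavage TSV + truth TSV + query FASTA.

    Layout per non-decoy record: ``M`` + signal peptide + mature body, so
    the mature protein starts at position ``signal_length + 1``.  Decoys:
    ``no_signal`` records get a hydrophilic N-terminal stretch (and are
    omitted from the cleavage table); ``stop`` records carry a ``*`` inside
    the mature region; ``unrelated`` records have an independent random
    mature body with no homology to the lineage ancestors.  The query FASTA
    holds the two lineage ancestors, standing in for biochemically
    characterized evasins.

    Deterministic: identical config+seed give byte-identical files.
    """
    config.validate()
    rng = _rng(config.seed)
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)

    members = evolve_lineages(config, rng)
    mature_start = config.signal_length + 1

    fasta_rows: list[tuple[str, str, str]] = []  # (id, header_rest, sequence)
    cleavage: list[tuple[str, int]] = []
    truth: list[TruthRow] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"SYN{counter:03d}"

    def taxonomy(cls: int) -> tuple[str, str, str]:
        genus = config.genus_class1 if cls == 1 else config.genus_class2
        species = config.species_class1 if cls == 1 else config.species_class2
        return genus, species, _LINEAGE_OF_GENUS.get(genus, "Metastriate")

    for m in members:
        rid = next_id()
        genus, species, lineage = taxonomy(m["lineage"])
        precursor = _signal_peptide(config, rng) + m["sequence"]
        fasta_rows.append((rid, f"genus={genus} species={species} lineage={lineage}", precursor))
        cleavage.append((rid, mature_start))
        truth.append(TruthRow(rid, lineage, f"class{m['lineage']}", mature_start,
                              m["motif"], m["anchors"], ""))

    base_members = [m for m in members if m["lineage"] == 1] or members

    for _ in range(config.n_decoy_no_signal):
        rid = next_id()
        genus, species, lineage = taxonomy(1)
        src = base_members[int(rng.integers(len(base_members)))]
        body = "".join(_mutate(list(src["sequence"]), config.substitution_rate_within,
                               {a - 1 for a in src["anchors"]}, rng))
        nterm = "M" + "".join(_choice(rng, HYDROPHILIC_LETTERS)
                              for _ in range(config.signal_length - 1))
        fasta_rows.append((rid, f"genus={genus} species={species} lineage={lineage}", nterm + body))
        truth.append(TruthRow(rid, lineage, "", None, src["motif"], src["anchors"], "no_signal"))

    for _ in range(config.n_decoy_stop):
        rid = next_id()
        genus, species, lineage = taxonomy(1)
        src = base_members[int(rng.integers(len(base_members)))]
        frozen = {a - 1 for a in src["anchors"]}
        body = list(src["sequence"])
        free = [i for i in range(1, len(body)) if i not in frozen]
        body[free[int(rng.integers(len(free)))]] = "*"
        fasta_rows.append((rid, f"genus={genus} species={species} lineage={lineage}",
                           _signal_peptide(config, rng) + "".join(body)))
        cleavage.append((rid, mature_start))
        truth.append(TruthRow(rid, lineage, "", mature_start, src["motif"],
                              src["anchors"], "stop"))

    for _ in range(config.n_decoy_unrelated):
        rid = next_id()
        genus, species, lineage = taxonomy(2)
        body = [_choice(rng, NON_CYS) for _ in range(config.mature_length)]
        body[0] = _choice(rng, HYDROPHILIC_LETTERS)
        fasta_rows.append((rid, f"genus={genus} species={species} lineage={lineage}",
                           _signal_peptide(config, rng) + "".join(body)))
        cleavage.append((rid, mature_start))
        truth.append(TruthRow(rid, lineage, "", mature_start, "none", (), "unrelated"))

    paths = {
        "fasta": out_prefix.with_suffix(".fasta"),
        "cleavage": Path(str(out_prefix) + ".cleavage.tsv"),
        "truth": Path(str(out_prefix) + ".truth.tsv"),
        "queries": Path(str(out_prefix) + ".queries.fasta"),
    }
    with open(paths["fasta"], "w") as fh:
        for rid, rest, seq in fasta_rows:
            fh.write(f">{rid} {rest}\n{seq}\n")
    with open(paths["cleavage"], "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "mature_start"])
        for rid, pos in cleavage:
            w.writerow([rid, pos])
    with open(paths["truth"], "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "lineage", "planted_class", "cleavage_pos", "motif",
                    "anchor_positions", "decoy_type"])
        for t in truth:
            w.writerow([t.id, t.lineage, t.planted_class,
                        "" if t.cleavage_pos is None else t.cleavage_pos,
                        t.motif, ",".join(map(str, t.anchor_positions)), t.decoy_type])
    with open(paths["queries"], "w") as fh:
        seen_anc: list[tuple[str, str]] = []
        for cls in (1, 2):
            anc = next((m["ancestor"] for m in members if m["lineage"] == cls), None)
            if anc is not None:
                seen_anc.append((f"ANC{cls}", anc))
        for qid, seq in seen_anc:
            fh.write(f">{qid} role=query\n{seq}\n")
    return paths
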