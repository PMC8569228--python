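"""Precursor ingest: FASTA reading, mature-protein derivation and filtering.

Evasin candidates enter as precursor protein sequences.  The protein start
is the first methionine; the secreted (mature) protein begins after the
signal peptide.  Signal-peptide prediction is delegated to a pluggable
:class:`CleavageProvider` — either a table of externally predicted cleavage
positions (e.g. compiled from a signal-peptide predictor's output) or a
lightweight hydrophobicity heuristic matched to the synthetic generator.

Records failing any of the gates (no methionine, no signal peptide, a stop
codon inside the predicted mature protein) are dropped with an explicit
reason, mirroring the selection criteria of the transcriptome screen.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol

from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinRecord",
    "CleavageProvider",
    "TableCleavageProvider",
    "HeuristicCleavageProvider",
    "HYDROPHOBIC",
    "read_fasta",
    "locate_protein_start",
    "derive_mature",
    "filter_records",
    "write_drop_report",
]

#: Residues treated as hydrophobic by the heuristic cleavage provider.
HYDROPHOBIC = frozenset("AILVFMW")

STATUS_OK = "ok"
STATUS_NO_MET = "no_met"
STATUS_NO_SIGNAL = "no_signal"
STATUS_INTERNAL_STOP = "internal_stop"


@dataclass
class ProteinRecord:
    """A precursor sequence with taxonomy metadata and processing status.

    Coordinates are 1-based and inclusive throughout.  ``mature_sequence``
    is ``raw_sequence[mature_start-1:]`` once a cleavage site is assigned.
    """

    id: str
    raw_sequence: str
    genus: str = ""
    species: str = ""
    description: str = ""
    meta: dict = field(default_factory=dict)
    protein_start: int | None = None
    mature_start: int | None = None
    mature_sequence: str | None = None
    status: str = STATUS_OK


class CleavageProvider(Protocol):
    """Maps a record to the 1-based raw-sequence position of the first
    mature residue, or ``None`` when no signal peptide is predicted."""

    def cleave(self, record: ProteinRecord) -> int | None: ...


class TableCleavageProvider:
    """Cleavage positions from a TSV (``id<TAB>mature_start``, 1-based).

    Stands in for an external signal-peptide predictor whose per-record
    cleavage positions were exported to a table; records absent from the
    table are treated as lacking a signal peptide.
    """

    def __init__(self, table: dict[str, int] | str | Path):
        if isinstance(table, (str, Path)):
            table = self._read_tsv(table)
        self.table = dict(table)

    @staticmethod
    def _read_tsv(path: str | Path) -> dict[str, int]:
        out: dict[str, int] = {}
        with open(path) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0] in ("id", "#id"):
                    continue
                out[row[0]] = int(row[1])
        return out

    def cleave(self, record: ProteinRecord) -> int | None:
        return self.table.get(record.id)


class HeuristicCleavageProvider:
    """Hydrophobicity-run heuristic for signal-peptide cleavage.

    Looking at positions 2..window of the Met-anchored sequence, a signal
    peptide is called when at least ``min_hydrophobic`` residues in that
    window are hydrophobic; the mature protein then starts right after the
    last hydrophobic residue of the window.  This is a deliberately simple
    stand-in matched to the synthetic generator's signal model — real data
    should use a table provider fed by a dedicated predictor.
    """

    def __init__(self, window: int = 20, min_hydrophobic: int = 8,
                 hydrophobic: frozenset[str] = HYDROPHOBIC):
        if window < 2:
            raise ValueError("window must cover at least position 2")
        self.window = window
        self.min_hydrophobic = min_hydrophobic
        self.hydrophobic = hydrophobic

    def cleave(self, record: ProteinRecord) -> int | None:
        if record.protein_start is None:
            raise ValueError(f"{record.id}: protein start not located")
        seq = record.raw_sequence[record.protein_start - 1:]
        w = min(self.window, len(seq))
        hyd = [i for i in range(2, w + 1) if seq[i - 1] in self.hydrophobic]
        if len(hyd) < self.min_hydrophobic:
            return None
        offset = hyd[-1] + 1  # first mature residue, Met-anchored coords
        if offset > len(seq):
            return None
        return record.protein_start - 1 + offset


def _parse_header_meta(description: str) -> dict[str, str]:
    meta = {}
    for tok in description.split()[1:]:
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k] = v
    return meta


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read precursor FASTA into records, in file order.

    Header tokens of the form ``key=value`` (``genus=``, ``species=``,
    ``lineage=`` ...) are parsed into metadata.  Sequences are upper-cased.
    Duplicate ids and files not starting with a header line are errors.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ValueError(f"{path}: malformed FASTA, line {lineno} is not a header")
            break
        else:
            logger.warning("%s: empty FASTA file", path)
            return []
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seen[rec.id] = seen.get(rec.id, 0) + 1
        meta = _parse_header_meta(rec.description)
        records.append(
            ProteinRecord(
                id=rec.id,
                raw_sequence=str(rec.seq).upper(),
                genus=meta.get("genus", ""),
                species=meta.get("species", ""),
                description=rec.description,
                meta=meta,
            )
        )
    dups = sorted(i for i, c in seen.items() if c > 1)
    if dups:
        raise ValueError(f"{path}: duplicate FASTA ids: {', '.join(dups)}")
    return records


def locate_protein_start(record: ProteinRecord) -> ProteinRecord:
    """Set ``protein_start`` to the first methionine (1-based).

    A record with no methionine cannot satisfy the first-Met rule and is
    flagged ``no_met`` rather than raising.
    """
    pos = record.raw_sequence.find("M")
    if pos < 0:
        record.status = STATUS_NO_MET
        record.protein_start = None
    else:
        record.protein_start = pos + 1
    return record


def derive_mature(record: ProteinRecord, provider: CleavageProvider) -> ProteinRecord:
    """Consult the cleavage provider and derive the mature sequence.

    ``None`` from the provider flags the record ``no_signal``.  A returned
    position outside ``(protein_start, len(raw_sequence)]`` is a provider
    bug and raises.
    """
    if record.status != STATUS_OK or record.protein_start is None:
        return record
    pos = provider.cleave(record)
    if pos is None:
        record.status = STATUS_NO_SIGNAL
        return record
    if not (record.protein_start < pos <= len(record.raw_sequence)):
        raise ValueError(
            f"{record.id}: cleavage position {pos} outside "
            f"({record.protein_start}, {len(record.raw_sequence)}]"
        )
    record.mature_start = pos
    record.mature_sequence = record.raw_sequence[pos - 1:]
    return record


def filter_records(
    records: Iterable[ProteinRecord],
) -> tuple[list[ProteinRecord], list[tuple[ProteinRecord, str]]]:
    """Apply the record gates; return (kept, dropped-with-reason).

    Dropped reasons are ``no_met``, ``no_signal`` and ``internal_stop``
    (a ``*`` anywhere in the predicted mature protein).  Stops upstream of
    the mature start do not drop a record.  Every record lands in exactly
    one of the two outputs.
    """
    kept: list[ProteinRecord] = []
    dropped: list[tuple[ProteinRecord, str]] = []
    for rec in records:
        if rec.status in (STATUS_NO_MET, STATUS_NO_SIGNAL):
            dropped.append((rec, rec.status))
            continue
        if rec.mature_sequence is None:
            dropped.append((rec, STATUS_NO_SIGNAL))
            continue
        if "*" in rec.mature_sequence:
            rec.status = STATUS_INTERNAL_STOP
            dropped.append((rec, STATUS_INTERNAL_STOP))
            continue
        kept.append(rec)
    logger.info("filter_records: kept %d, dropped %d", len(kept), len(dropped))
    return kept, dropped


def write_drop_report(dropped: list[tuple[ProteinRecord, str]], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "reason"])
        for rec, reason in dropped:
            w.writerow([rec.id, reason])
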