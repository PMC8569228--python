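"""Count tables and heatmap annotation files.

Turns class assignments, motif profiles and (optionally) a chemokine
binding annotation table into the summary artifacts of the analysis: the
per-species × per-class counts of distinct evasins/evasin-like proteins,
the distinct-chemokine binding summary per tick group, and the per-record
"information file" feeding the tree heatmaps (lineage, motif presence,
cysteine count, chemokines bound).
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .classify import LineageMap
from .motifs import SequenceProfile

__all__ = [
    "CHEMOKINE_CLASSES",
    "species_class_counts",
    "binding_summary",
    "heatmap_info",
]

CHEMOKINE_CLASSES = frozenset({"CC", "CXC", "CX3C", "XC"})

_ASSIGN_COLS = ["id", "genus", "species", "class"]


def _check_assignments(assignments: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _ASSIGN_COLS if c not in assignments.columns]
    if missing:
        raise ValueError(f"assignments table missing columns: {missing}")
    return assignments


def species_class_counts(
    assignments: pd.DataFrame,
    lineage_map: LineageMap | None = None,
) -> pd.DataFrame:
    """Distinct records per species per class, with lineage rollups.

    Returns a long table with columns ``level`` ("species" or "lineage"),
    ``name``, ``class`` and ``count``; species counts within a lineage sum
    to that lineage's row.
    """
    cols = ["level", "name", "class", "count"]
    if len(assignments) == 0:
        return pd.DataFrame(columns=cols)
    df = _check_assignments(assignments).copy()
    lmap = lineage_map or LineageMap()
    df["lineage"] = df["genus"].map(lmap.lineage_of)
    df["sp_name"] = df["genus"].str.cat(df["species"], sep=" ").str.strip()
    sp = (
        df.groupby(["sp_name", "class"], as_index=False)["id"].nunique()
        .rename(columns={"sp_name": "name", "id": "count"})
    )
    sp.insert(0, "level", "species")
    grp = (
        df.groupby(["lineage", "class"], as_index=False)["id"].nunique()
        .rename(columns={"lineage": "name", "id": "count"})
    )
    grp.insert(0, "level", "lineage")
    out = pd.concat([grp, sp], ignore_index=True)[cols]
    return out.sort_values(cols[:3], ignore_index=True)


def binding_summary(
    assignments: pd.DataFrame,
    annotations: pd.DataFrame,
    lineage_map: LineageMap | None = None,
) -> pd.DataFrame:
    """Distinct chemokines bound, per species and per lineage, by class.

    ``annotations`` has columns ``id`` (evasin), ``chemokine`` and
    ``chemokine_class`` (CC/CXC/CX3C/XC; anything else is an error).  A
    chemokine is counted once per species (and once per lineage) no
    matter how many evasins bind it; records without annotation
    contribute nothing.
    """
    cols = ["level", "name", "chemokine_class", "count"]
    for c in ("id", "chemokine", "chemokine_class"):
        if c not in annotations.columns:
            raise ValueError(f"annotation table missing column {c!r}")
    bad = sorted(set(annotations["chemokine_class"]) - CHEMOKINE_CLASSES)
    if bad:
        raise ValueError(f"unknown chemokine class tags: {bad}")
    if len(assignments) == 0 or len(annotations) == 0:
        return pd.DataFrame(columns=cols)
    df = _check_assignments(assignments).copy()
    lmap = lineage_map or LineageMap()
    df["lineage"] = df["genus"].map(lmap.lineage_of)
    df["sp_name"] = df["genus"].str.cat(df["species"], sep=" ").str.strip()
    merged = annotations.merge(df[["id", "sp_name", "lineage"]], on="id", how="inner")
    sp = (
        merged.groupby(["sp_name", "chemokine_class"], as_index=False)["chemokine"]
        .nunique().rename(columns={"sp_name": "name", "chemokine": "count"})
    )
    sp.insert(0, "level", "species")
    grp = (
        merged.groupby(["lineage", "chemokine_class"], as_index=False)["chemokine"]
        .nunique().rename(columns={"lineage": "name", "chemokine": "count"})
    )
    grp.insert(0, "level", "lineage")
    out = pd.concat([grp, sp], ignore_index=True)[cols]
    return out.sort_values(cols[:3], ignore_index=True)


def heatmap_info(
    assignments: pd.DataFrame,
    profiles: Iterable[SequenceProfile] | pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    lineage_map: LineageMap | None = None,
) -> pd.DataFrame:
    """One heatmap row per record: the four annotation circles.

    Columns: ``id``, ``class``, ``lineage``, ``has_cys6``, ``has_cys8``,
    ``cys_count``, ``n_chemokines`` (empty for records without binding
    annotation).  Assignment and profile ids must match exactly; orphans
    on either side are an error.
    """
    df = _check_assignments(assignments).copy()
    if isinstance(profiles, pd.DataFrame):
        prof = profiles.copy()
    else:
        prof = pd.DataFrame(
            [(p.seq_id, p.cys_count, p.has_cys6, p.has_cys8) for p in profiles],
            columns=["id", "cys_count", "has_cys6", "has_cys8"],
        )
    a_ids = set(df["id"])
    p_ids = set(prof["id"])
    orphans = sorted(a_ids ^ p_ids)
    if orphans:
        raise ValueError(f"assignment/profile id mismatch: {', '.join(orphans)}")
    lmap = lineage_map or LineageMap()
    df["lineage"] = df["genus"].map(lmap.lineage_of)
    out = df[["id", "class", "lineage"]].merge(prof, on="id")
    if annotations is not None and len(annotations) > 0:
        extra = sorted(set(annotations["id"]) - a_ids)
        if extra:
            raise ValueError(f"binding annotations for unknown ids: {', '.join(extra)}")
        nb = annotations.groupby("id")["chemokine"].nunique()
        out["n_chemokines"] = out["id"].map(nb)
        out["n_chemokines"] = out["n_chemokines"].astype("Int64")
    else:
        out["n_chemokines"] = pd.Series([pd.NA] * len(out), dtype="Int64")
    return out.sort_values("id", ignore_index=True)
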