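"""Root-adjacent clade classification of evasin trees.

The ancestral node of a midpoint-rooted tree has two descendant clades;
these define the top-level classes (A1/A2 for the CC-binding family,
B1/B2 for the CXC-binding family), and one further split below a clade
defines subclades (B1.1/B1.2).  Classes are named by tick-lineage
majority — the Metastriate-majority clade is "1" — because the published
class definitions anchor A1 to Metastriate and A2 to Prostriate ticks.
Purity (largest lineage fraction) is always reported; mixed clades are
allowed with a warning rather than rejected.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy

__all__ = [
    "PROSTRIATE",
    "METASTRIATE",
    "LineageMap",
    "UnknownGenusError",
    "CladePartition",
    "lineage_of",
    "root_partition",
    "assign_classes",
    "subclade_partition",
]

PROSTRIATE = "Prostriate"
METASTRIATE = "Metastriate"

_DEFAULT_LINEAGES = {
    "ixodes": PROSTRIATE,
    "amblyomma": METASTRIATE,
    "dermacentor": METASTRIATE,
    "hyalomma": METASTRIATE,
    "rhipicephalus": METASTRIATE,
}


class UnknownGenusError(KeyError):
    """A genus with no lineage assignment (e.g. an argasid tick)."""


class LineageMap:
    """Genus → tick lineage lookup, case-insensitive on genus.

    Ships the ixodid defaults (Ixodes → Prostriate; Amblyomma,
    Dermacentor, Hyalomma, Rhipicephalus → Metastriate) and can be
    extended from a TSV (``genus<TAB>lineage``).  Unknown genera raise —
    never a silent default.
    """

    def __init__(self, table: Mapping[str, str] | None = None):
        base = dict(_DEFAULT_LINEAGES)
        if table:
            for genus, lineage in table.items():
                if lineage not in (PROSTRIATE, METASTRIATE):
                    raise ValueError(f"unknown lineage label {lineage!r} for {genus!r}")
                base[genus.lower()] = lineage
        self._table = base

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LineageMap":
        extra: dict[str, str] = {}
        with open(path) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].lower() in ("genus", "#genus"):
                    continue
                extra[row[0]] = row[1]
        return cls(extra)

    def lineage_of(self, genus: str) -> str:
        try:
            return self._table[genus.strip().lower()]
        except KeyError:
            raise UnknownGenusError(
                f"genus {genus!r} has no lineage assignment; extend the "
                "lineage table to classify it"
            ) from None


def lineage_of(genus: str, lineage_map: LineageMap | None = None) -> str:
    """Lineage of a genus under the (default) lineage table."""
    return (lineage_map or LineageMap()).lineage_of(genus)


@dataclass
class CladePartition:
    """Class assignment of every leaf plus per-class composition."""

    scheme: str
    assignments: dict[str, str]
    class_info: dict[str, dict] = field(default_factory=dict)

    @property
    def class_sizes(self) -> dict[str, int]:
        return {label: info["n"] for label, info in self.class_info.items()}


def root_partition(tree: dendropy.Tree) -> tuple[frozenset[str], frozenset[str]]:
    """Leaf sets of the two clades descending from the root.

    Requires a rooted tree with a degree-2 root (i.e. midpoint-rooted).
    The larger set comes first; equal sizes are ordered by the
    lexicographically smallest contained leaf.
    """
    root = tree.seed_node
    children = root.child_nodes()
    if not tree.is_rooted or len(children) != 2:
        raise ValueError(
            "tree is not rooted with a binary root; apply midpoint_root first"
        )
    sides = [frozenset(lf.taxon.label for lf in ch.leaf_iter()) for ch in children]
    sides.sort(key=lambda s: (-len(s), min(s)))
    return sides[0], sides[1]


def _composition(leafset, genus_of, lineage_map) -> dict[str, int]:
    comp: dict[str, int] = {}
    missing = []
    for leaf in sorted(leafset):
        genus = genus_of.get(leaf)
        if genus is None:
            missing.append(leaf)
            continue
        lineage = lineage_map.lineage_of(genus)
        comp[lineage] = comp.get(lineage, 0) + 1
    if missing:
        raise ValueError(f"no genus metadata for leaves: {', '.join(missing)}")
    return comp


def _order_by_majority(sets, genus_of, lineage_map):
    """Metastriate-majority clade first; ties by size then smallest leaf."""
    decorated = []
    for s in sets:
        comp = _composition(s, genus_of, lineage_map)
        meta_frac = comp.get(METASTRIATE, 0) / len(s)
        decorated.append(((-meta_frac, -len(s), min(s)), s, comp))
    decorated.sort(key=lambda t: t[0])
    return [(s, comp) for _, s, comp in decorated]


def assign_classes(
    partition: tuple[frozenset[str], frozenset[str]],
    genus_of: Mapping[str, str],
    lineage_map: LineageMap | None = None,
    scheme: str = "A",
) -> CladePartition:
    """Name the two root clades by lineage majority.

    The clade with the larger Metastriate fraction becomes ``{scheme}1``
    and the other ``{scheme}2``.  Under scheme A a purity below 1.0
    triggers a warning, since the published class A tree separates the
    lineages perfectly; scheme B tolerates mixing silently (the published
    B1 clade is mixed).
    """
    if scheme not in ("A", "B"):
        raise ValueError("scheme must be 'A' or 'B'")
    lineage_map = lineage_map or LineageMap()
    ordered = _order_by_majority(partition, genus_of, lineage_map)
    assignments: dict[str, str] = {}
    class_info: dict[str, dict] = {}
    for k, (leafset, comp) in enumerate(ordered, start=1):
        label = f"{scheme}{k}"
        purity = max(comp.values()) / len(leafset)
        if scheme == "A" and purity < 1.0:
            warnings.warn(
                f"clade {label} is not lineage-pure (purity {purity:.2f}); "
                "the published class A partition separates lineages perfectly"
            )
        for leaf in leafset:
            assignments[leaf] = label
        class_info[label] = {
            "n": len(leafset),
            "composition": comp,
            "purity": purity,
        }
    return CladePartition(scheme=scheme, assignments=assignments, class_info=class_info)


def _find_clade_node(tree: dendropy.Tree, leafset: frozenset[str]):
    for node in tree.postorder_node_iter():
        if frozenset(lf.taxon.label for lf in node.leaf_iter()) == leafset:
            return node
    return None


def subclade_partition(
    tree: dendropy.Tree,
    clade_leafset: frozenset[str],
    genus_of: Mapping[str, str] | None = None,
    lineage_map: LineageMap | None = None,
    parent_label: str = "B1",
) -> dict[str, frozenset[str]]:
    """Split a clade at its defining node into labelled subclades.

    The clade must be exactly the leaf set of some subtree; its node's two
    children give the subclades, labelled ``<parent>.1``/``<parent>.2`` by
    the same Metastriate-majority (then size, then smallest-leaf)
    convention when genus metadata is given, otherwise by size.
    """
    clade_leafset = frozenset(clade_leafset)
    node = _find_clade_node(tree, clade_leafset)
    if node is None:
        raise ValueError("leaf set is not a clade of the tree")
    children = node.child_nodes()
    if len(children) < 2:
        raise ValueError("clade is a single leaf; no subclades exist")
    if len(children) != 2:
        raise ValueError("clade node is not binary; subclade split undefined")
    sides = [frozenset(lf.taxon.label for lf in ch.leaf_iter()) for ch in children]
    if genus_of is not None:
        ordered = [s for s, _ in _order_by_majority(
            sides, genus_of, lineage_map or LineageMap())]
    else:
        ordered = sorted(sides, key=lambda s: (-len(s), min(s)))
    return {f"{parent_label}.{k}": s for k, s in enumerate(ordered, start=1)}
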