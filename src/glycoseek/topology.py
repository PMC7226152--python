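"""Rooted glycan topologies with linkage positions and aglycone bookkeeping.

Topologies are written in a condensed text notation, non-reducing end on the
left, branches in square brackets, linkage as ``(anomer child-parent)``::

    Gal(b1-3)GalNAc                          core 1 (T antigen)
    Gal(b1-3)[Gal(b1-4)GlcNAc(b1-6)]GalNAc   core 2 tetrasaccharide
    NeuAc(a2-3)Gal(b1-3)[Fuc(a1-4)]GlcNAc    sialyl-Lewis A epitope

The root aglycone is carried separately: ``free_reducing`` (free anomeric
hydroxyl), ``benzyl`` (benzyl glycoside, the secreted reporter scaffold of
the cellular O-glycome amplification method) or ``serine_threonine`` (the
glycan sits on a peptide hydroxyl, contributing a delta mass only).

Permethylation-site counting walks every residue: free hydroxyls not consumed
by a glycosidic bond or the aglycone, one amide N-H per N-acetylated sugar,
and one carboxyl methyl ester per NeuAc.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

from .composition import GlycanComposition
from .residues import DEFAULT_RESIDUES, ResidueTable

__all__ = [
    "Linkage",
    "GlycanNode",
    "GlycanTopology",
    "parse_topology",
    "count_methylation_sites",
    "AGLYCONES",
]

AGLYCONES = ("free_reducing", "benzyl", "serine_threonine")

_NAME = re.compile(r"[A-Za-z][A-Za-z0-9]*")
_LINK = re.compile(r"\(([ab?])(\d+|\?)-(\d+|\?)\)")


@dataclass(frozen=True)
class Linkage:
    """Glycosidic linkage child(anomer child_pos -> parent_pos)parent."""

    anomer: str  # 'a', 'b' or '?'
    child_pos: int | None  # anomeric carbon of the child; None = unknown
    parent_pos: int | None  # ring position on the parent; None = unknown

    def __str__(self) -> str:
        c = "?" if self.child_pos is None else str(self.child_pos)
        p = "?" if self.parent_pos is None else str(self.parent_pos)
        return f"({self.anomer}{c}-{p})"


@dataclass(frozen=True)
class GlycanNode:
    name: str  # as written, e.g. 'Gal' or 'GlcNAc'
    children: tuple[tuple[Linkage, "GlycanNode"], ...] = ()

    def walk(self):
        """Yield nodes depth-first, root first."""
        yield self
        for _, child in self.children:
            yield from child.walk()


@dataclass(frozen=True)
class GlycanTopology:
    root: GlycanNode
    root_aglycone: str = "free_reducing"
    table: ResidueTable = field(default=DEFAULT_RESIDUES, compare=False)

    def __post_init__(self) -> None:
        if self.root_aglycone not in AGLYCONES:
            raise ValueError(
                f"unknown aglycone {self.root_aglycone!r}; expected one of {AGLYCONES}"
            )
        self._validate()

    def _validate(self) -> None:
        for node in self.root.walk():
            res = self.table[node.name]
            seen: set[int] = set()
            for link, child in node.children:
                cres = self.table[child.name]
                if link.parent_pos is not None:
                    if link.parent_pos not in res.hydroxyl_positions:
                        raise ValueError(
                            f"linkage position {link.parent_pos} outside the valence "
                            f"of {node.name} (free positions "
                            f"{res.hydroxyl_positions})"
                        )
                    if link.parent_pos in seen:
                        raise ValueError(
                            f"two children of {node.name} occupy position "
                            f"{link.parent_pos}"
                        )
                    seen.add(link.parent_pos)
                if link.child_pos is not None and link.child_pos != cres.anomeric_position:
                    raise ValueError(
                        f"{child.name} links through carbon {link.child_pos}, "
                        f"but its anomeric carbon is C{cres.anomeric_position}"
                    )

    def nodes(self) -> list[GlycanNode]:
        return list(self.root.walk())

    @property
    def residue_count(self) -> int:
        return len(self.nodes())

    def composition(self) -> GlycanComposition:
        counts: Counter = Counter()
        for node in self.root.walk():
            counts[self.table.canonical(node.name)] += 1
        return GlycanComposition.from_dict(counts, self.table)

    def to_string(self) -> str:
        return _unparse(self.root)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.to_string()


def _unparse(node: GlycanNode) -> str:
    parts = []
    for i, (link, child) in enumerate(node.children):
        text = _unparse(child) + str(link)
        parts.append(text if i == 0 else f"[{text}]")
    return "".join(parts) + node.name


def _read_link(text: str, i: int) -> tuple[Linkage, int]:
    m = _LINK.match(text, i)
    if not m:
        raise ValueError(f"expected linkage at {text[i:i + 12]!r} in {text!r}")
    child_pos = None if m.group(2) == "?" else int(m.group(2))
    parent_pos = None if m.group(3) == "?" else int(m.group(3))
    return Linkage(m.group(1), child_pos, parent_pos), m.end()


def _parse(text: str, i: int, bracketed: bool):
    kids: list[tuple[Linkage, GlycanNode]] = []
    while True:
        if i >= len(text):
            raise ValueError(f"unexpected end of topology string {text!r}")
        if text[i] == "[":
            link, node, i = _parse(text, i + 1, True)
            kids.append((link, node))
            continue
        m = _NAME.match(text, i)
        if not m:
            raise ValueError(f"expected residue name at {text[i:i + 12]!r} in {text!r}")
        name, i = m.group(0), m.end()
        if i < len(text) and text[i] == "(":
            link, i = _read_link(text, i)
            node = GlycanNode(name, tuple(kids))
            kids = []
            if bracketed:
                if i < len(text) and text[i] == "]":
                    return link, node, i + 1
                kids.append((link, node))
            else:
                kids.append((link, node))
        else:
            if bracketed:
                raise ValueError(
                    f"branch root {name!r} lacks a linkage in {text!r}"
                )
            return None, GlycanNode(name, tuple(kids)), i


def parse_topology(
    text: str,
    aglycone: str = "free_reducing",
    table: ResidueTable = DEFAULT_RESIDUES,
) -> GlycanTopology:
    """Parse the condensed branch notation into a :class:`GlycanTopology`."""
    text = text.strip().replace(" ", "")
    _, root, i = _parse(text, 0, False)
    if i != len(text):
        raise ValueError(f"trailing text {text[i:]!r} in topology {text!r}")
    return GlycanTopology(root, aglycone, table)


def count_methylation_sites(
    topo: GlycanTopology,
    free_hydroxyl_overrides: dict[str, int] | None = None,
) -> int:
    """Number of methyl groups added by exhaustive permethylation.

    Counts, residue by residue: free hydroxyls not consumed by a glycosidic
    bond or by the aglycone, plus one amide N-H per HexNAc/NeuAc, plus one
    carboxyl methyl-esterification per NeuAc.  A free reducing end adds its
    anomeric hydroxyl; a benzyl or Ser/Thr aglycone consumes the anomeric
    position.

    Nodes with children at unknown (``?``) parent positions need an entry in
    ``free_hydroxyl_overrides`` (keyed by residue name) stating how many free
    hydroxyls remain, since occupancy cannot be inferred.
    """
    overrides = free_hydroxyl_overrides or {}
    sites = 0
    for node in topo.root.walk():
        res = topo.table[node.name]
        occupied = [link.parent_pos for link, _ in node.children]
        if any(p is None for p in occupied):
            if node.name not in overrides:
                raise ValueError(
                    f"{node.name} has children at unknown positions; supply a "
                    f"free-hydroxyl override to count methylation sites"
                )
            free_oh = overrides[node.name]
        else:
            free_oh = len(set(res.hydroxyl_positions) - set(occupied))
        sites += free_oh + res.amide_nh_count + res.carboxyl_count
    if topo.root_aglycone == "free_reducing":
        sites += 1  # anomeric hydroxyl of the reducing end
    return sites
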