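"""Glycan compositions: residue-class multisets and their delta masses.

A composition such as ``HexNAc2Hex2Fuc1NeuAc1`` is the unit of MS1-level
mass arithmetic.  As a Ser/Thr variable modification the glycan replaces the
hydrogen of the side-chain hydroxyl, so the delta mass is the plain sum of
linked-residue masses with no water term — this is the convention behind
database-search deltas like +203.079 for a single HexNAc (Tn antigen).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

from .residues import DEFAULT_RESIDUES, ResidueTable, UnknownResidueError

__all__ = ["GlycanComposition", "composition_delta_mass"]

_TOKEN = re.compile(r"([A-Za-z][A-Za-z0-9]*?)(\d+)")


@dataclass(frozen=True)
class GlycanComposition:
    """Multiset of monosaccharide residue classes."""

    counts: tuple[tuple[str, int], ...]
    table: ResidueTable = field(default=DEFAULT_RESIDUES, compare=False)

    @classmethod
    def from_dict(
        cls, counts: dict[str, int], table: ResidueTable = DEFAULT_RESIDUES
    ) -> "GlycanComposition":
        merged: Counter = Counter()
        for name, n in counts.items():
            if n < 0:
                raise ValueError(f"negative residue count for {name!r}")
            merged[table.canonical(name)] += n
        items = tuple(sorted((k, v) for k, v in merged.items() if v > 0))
        return cls(items, table)

    @classmethod
    def parse(
        cls, text: str, table: ResidueTable = DEFAULT_RESIDUES
    ) -> "GlycanComposition":
        """Parse ``HexNAc2Hex2Fuc1NeuAc1``-style strings (order-insensitive).

        ``Fuc`` and ``dHex`` are synonyms; a count is required after every
        residue name.
        """
        text = text.strip()
        if not text:
            return cls.from_dict({}, table)
        pos = 0
        counts: Counter = Counter()
        for m in _TOKEN.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse composition {text!r} near {text[pos:]!r}")
            name, n = m.group(1), int(m.group(2))
            if name not in table:
                raise UnknownResidueError(
                    f"unknown residue class {name!r} in composition {text!r}"
                )
            counts[table.canonical(name)] += n
            pos = m.end()
        if pos != len(text):
            raise ValueError(f"cannot parse composition {text!r} near {text[pos:]!r}")
        return cls.from_dict(counts, table)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    @property
    def total_residues(self) -> int:
        return sum(n for _, n in self.counts)

    @property
    def mass(self) -> float:
        """Sum of linked-residue monoisotopic masses (no water)."""
        return sum(self.table[name].monoisotopic_mass * n for name, n in self.counts)

    def canonical_string(self) -> str:
        order = {"HexNAc": 0, "Hex": 1, "Fuc": 2, "NeuAc": 3}
        items = sorted(self.counts, key=lambda kv: (order.get(kv[0], 99), kv[0]))
        return "".join(f"{k}{v}" for k, v in items)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.canonical_string()


def composition_delta_mass(
    comp: GlycanComposition | str | dict,
    table: ResidueTable = DEFAULT_RESIDUES,
) -> float:
    """Ser/Thr O-glycosylation variable-modification delta mass in Da.

    The glycan substitutes the hydroxyl hydrogen of the residue, so the delta
    is the bare sum of linked-residue masses: HexNAc1 -> 203.079 (Tn),
    HexNAc1Hex1 -> 365.132 (T), ..., HexNAc2Hex2Fuc1NeuAc1 -> 1167.418
    (core 2 carrying a terminal sialyl-Lewis epitope).
    """
    if isinstance(comp, str):
        comp = GlycanComposition.parse(comp, table)
    elif isinstance(comp, dict):
        comp = GlycanComposition.from_dict(comp, table)
    return comp.mass
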