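"""Monosaccharide residue table and monoisotopic mass bookkeeping.

All masses are monoisotopic and refer to the *glycosidically linked* residue,
i.e. the free monosaccharide net of one water.  The four residue classes
(HexNAc, Hex, Fuc/dHex, NeuAc) cover the mucin-type O-glycans handled here:
cores 1 and 2 with fucose and N-acetyl-neuraminic acid extensions.

Each residue carries the structural counts needed for permethylation-site
bookkeeping: free hydroxyl positions, amide N-H protons (one for each
N-acetylated sugar) and carboxyl groups (one for NeuAc, methyl-esterified
under permethylation).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import yaml

__all__ = [
    "ATOMIC_MASS",
    "PROTON",
    "WATER",
    "CH2",
    "BENZYL_INCREMENT",
    "MonosaccharideResidue",
    "ResidueTable",
    "DEFAULT_RESIDUES",
    "UnknownResidueError",
    "formula_mass",
    "parse_formula",
]

# CODATA/IUPAC monoisotopic atomic masses (u), >=6 decimals.
ATOMIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "Na": 22.98976928,
}

PROTON = 1.007276  # mass of H+ (H atom minus electron)
WATER = ATOMIC_MASS["H"] * 2 + ATOMIC_MASS["O"]  # 18.010565
CH2 = ATOMIC_MASS["C"] + 2 * ATOMIC_MASS["H"]  # 14.015650, one methylation
# Benzyl glycoside relative to the free reducing sugar: the anomeric O-H
# hydrogen is replaced by a benzyl group, a net gain of C7H6.
BENZYL_INCREMENT = 7 * ATOMIC_MASS["C"] + 6 * ATOMIC_MASS["H"]  # 90.046950


class UnknownResidueError(KeyError):
    """Raised when a composition or topology names an unknown residue class."""


def parse_formula(formula: str) -> Counter:
    """Parse a Hill-style formula like ``C8H13NO5`` into an atom counter."""
    atoms: Counter = Counter()
    i = 0
    while i < len(formula):
        if not formula[i].isalpha():
            raise ValueError(f"bad formula {formula!r} at position {i}")
        j = i + 1
        while j < len(formula) and formula[j].islower():
            j += 1
        element = formula[i:j]
        k = j
        while k < len(formula) and formula[k].isdigit():
            k += 1
        count = int(formula[j:k]) if k > j else 1
        if element not in ATOMIC_MASS:
            raise ValueError(f"unknown element {element!r} in {formula!r}")
        atoms[element] += count
        i = k
    return atoms


def formula_mass(atoms: Counter | str) -> float:
    """Monoisotopic mass of an atom counter or formula string."""
    if isinstance(atoms, str):
        atoms = parse_formula(atoms)
    return sum(ATOMIC_MASS[el] * n for el, n in atoms.items())


@dataclass(frozen=True)
class MonosaccharideResidue:
    """One residue class as it occurs inside a glycan chain.

    ``hydroxyl_positions`` are the ring/tail positions carrying a free OH when
    the residue is terminal and linked only through its anomeric carbon; a
    glycosidic bond to a child consumes the corresponding position.
    """

    name: str
    elemental_formula: str
    hydroxyl_positions: tuple[int, ...]
    amide_nh_count: int = 0
    carboxyl_count: int = 0
    anomeric_position: int = 1
    aliases: tuple[str, ...] = ()
    _atoms: Counter = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_atoms", parse_formula(self.elemental_formula))

    @property
    def atoms(self) -> Counter:
        return Counter(self._atoms)

    @property
    def monoisotopic_mass(self) -> float:
        return formula_mass(self._atoms)

    @property
    def hydroxyl_count(self) -> int:
        return len(self.hydroxyl_positions)


_DEFAULT_LIST = [
    MonosaccharideResidue(
        name="HexNAc",
        elemental_formula="C8H13NO5",
        hydroxyl_positions=(3, 4, 6),
        amide_nh_count=1,
        aliases=("GalNAc", "GlcNAc"),
    ),
    MonosaccharideResidue(
        name="Hex",
        elemental_formula="C6H10O5",
        hydroxyl_positions=(2, 3, 4, 6),
        aliases=("Gal", "Glc", "Man"),
    ),
    MonosaccharideResidue(
        name="Fuc",
        elemental_formula="C6H10O4",
        hydroxyl_positions=(2, 3, 4),
        aliases=("dHex",),
    ),
    MonosaccharideResidue(
        name="NeuAc",
        elemental_formula="C11H17NO8",
        hydroxyl_positions=(4, 7, 8, 9),
        amide_nh_count=1,
        carboxyl_count=1,
        anomeric_position=2,
        aliases=("Neu5Ac", "NeuNAc"),
    ),
]


class ResidueTable:
    """Lookup of residue classes by canonical name or alias.

    Aliases keep the biological identity of a monosaccharide (Gal vs Glc,
    GalNAc vs GlcNAc) in topology strings while mass arithmetic works at the
    class level, which is all the mass spectrometer distinguishes.
    """

    def __init__(self, residues: list[MonosaccharideResidue] | None = None):
        self._by_name: dict[str, MonosaccharideResidue] = {}
        for res in residues if residues is not None else _DEFAULT_LIST:
            self.add(res)

    def add(self, residue: MonosaccharideResidue) -> None:
        self._by_name[residue.name] = residue
        for alias in residue.aliases:
            self._by_name[alias] = residue

    def __getitem__(self, name: str) -> MonosaccharideResidue:
        try:
            return self._by_name[name]
        except KeyError:
            raise UnknownResidueError(
                f"unknown residue class {name!r}; known: {sorted(self.classes)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def classes(self) -> set[str]:
        return {r.name for r in self._by_name.values()}

    def canonical(self, name: str) -> str:
        return self[name].name

    @classmethod
    def from_yaml(cls, path: str) -> "ResidueTable":
        """Build a table from a YAML override file.

        The file maps residue names to ``formula``, ``hydroxyl_positions`` and
        optional ``amide_nh``, ``carboxyl``, ``anomeric_position``, ``aliases``
        keys.  Entries replace or extend the built-in table.
        """
        with open(path) as fh:
            spec = yaml.safe_load(fh) or {}
        table = cls()
        for name, entry in spec.items():
            table.add(
                MonosaccharideResidue(
                    name=name,
                    elemental_formula=entry["formula"],
                    hydroxyl_positions=tuple(entry["hydroxyl_positions"]),
                    amide_nh_count=int(entry.get("amide_nh", 0)),
                    carboxyl_count=int(entry.get("carboxyl", 0)),
                    anomeric_position=int(entry.get("anomeric_position", 1)),
                    aliases=tuple(entry.get("aliases", ())),
                )
            )
        return table


DEFAULT_RESIDUES = ResidueTable()
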