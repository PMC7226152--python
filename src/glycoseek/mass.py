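"""Neutral masses, derivatization schemes, adducts and MS1 matching.

The mass model: a native glycan is the sum of its linked-residue masses plus
one water for a free or benzyl reducing end (the benzyl glycoside adds a
further +C7H6 relative to the free sugar).  Permethylation adds 14.01565 Da
per countable site (free OH, amide N-H, and the NeuAc carboxyl, which is
methyl-esterified).  Singly protonated ions use m/z = M + 1.007276.
"""

from __future__ import annotations

from dataclasses import dataclass

from .composition import GlycanComposition
from .residues import BENZYL_INCREMENT, CH2, PROTON, WATER, ATOMIC_MASS
from .topology import GlycanTopology, count_methylation_sites

__all__ = [
    "DerivatizationScheme",
    "NATIVE",
    "PERMETHYLATED",
    "AdductSpec",
    "PROTONATED",
    "neutral_mass",
    "mz",
    "display_mz",
    "match_composition",
    "CandidateMatch",
]

SODIUM_CATION = ATOMIC_MASS["Na"] - 0.000549  # Na+ (sodium minus one electron)


@dataclass(frozen=True)
class DerivatizationScheme:
    """Native or exhaustively permethylated glycan.

    Permethylation always methyl-esterifies sialic acid carboxyls, so
    ``sialic_acid_methyl_ester`` is forced true for the permethylated kind.
    """

    kind: str = "native"
    sialic_acid_methyl_ester: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("native", "permethylated"):
            raise ValueError(f"unknown derivatization kind {self.kind!r}")
        if self.kind == "permethylated":
            object.__setattr__(self, "sialic_acid_methyl_ester", True)


NATIVE = DerivatizationScheme("native")
PERMETHYLATED = DerivatizationScheme("permethylated")


@dataclass(frozen=True)
class AdductSpec:
    """Cationization: kind 'proton' or 'sodium', charge >= 1."""

    kind: str = "proton"
    charge: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("proton", "sodium"):
            raise ValueError(f"unknown adduct kind {self.kind!r}")
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")

    @property
    def adduct_mass(self) -> float:
        return PROTON if self.kind == "proton" else SODIUM_CATION


PROTONATED = AdductSpec("proton", 1)

_AGLYCONE_INCREMENT = {
    "free_reducing": WATER,
    "benzyl": WATER + BENZYL_INCREMENT,
    "serine_threonine": 0.0,  # delta-mass convention: glycan replaces the O-H hydrogen
}


def neutral_mass(topo: GlycanTopology, scheme: DerivatizationScheme = NATIVE) -> float:
    """Neutral monoisotopic mass of a (possibly derivatized) glycan topology."""
    mass = topo.composition().mass + _AGLYCONE_INCREMENT[topo.root_aglycone]
    if scheme.kind == "permethylated":
        mass += CH2 * count_methylation_sites(topo)
    return mass


def mz(neutral: float, adduct: AdductSpec = PROTONATED) -> float:
    """m/z of the adducted species: (M + z * adduct_mass) / z."""
    return (neutral + adduct.charge * adduct.adduct_mass) / adduct.charge


def display_mz(value: float) -> float:
    """One-decimal display m/z, the precision used in glycomics reports."""
    return round(value, 1)


@dataclass(frozen=True)
class CandidateMatch:
    topology: GlycanTopology
    scheme: DerivatizationScheme
    theoretical_mz: float
    ppm_error: float


def match_composition(
    observed_mz: float,
    candidates: list[tuple[GlycanTopology, DerivatizationScheme]],
    tolerance_ppm: float = 10.0,
    adduct: AdductSpec = PROTONATED,
) -> list[CandidateMatch]:
    """MS1-level assignment of an observed m/z to candidate glycans.

    Returns candidates whose computed adduct m/z lies within ``tolerance_ppm``,
    sorted by absolute ppm error with a deterministic tie-break on the
    canonical composition string.  An empty candidate list yields an empty
    result.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    matches = []
    for topo, scheme in candidates:
        theo = mz(neutral_mass(topo, scheme), adduct)
        ppm = (observed_mz - theo) / theo * 1e6
        if abs(ppm) <= tolerance_ppm:
            matches.append(CandidateMatch(topo, scheme, theo, ppm))
    matches.sort(
        key=lambda m: (abs(m.ppm_error), m.topology.composition().canonical_string())
    )
    return matches
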