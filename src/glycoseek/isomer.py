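"""Sialyl-Lewis A vs X discrimination by diagnostic fragment ions.

Both isomers are NeuAc + Gal + Fuc decorations of a GlcNAc, differing only in
the chain type: SLeA sits on a type-1 chain (Gal beta1-3, Fuc alpha1-4) and
SLeX on a type-2 chain (Gal beta1-4, Fuc alpha1-3).  At MS1 the two are
isobaric; MS/MS cross-ring cleavages through the GlcNAc-bearing arm split the
fragment sets, and masses present in only one theoretical set act as
diagnostics.  The classifier enumerates both candidate topologies on the
shared benzyl core, takes the tolerance-aware set difference of theoretical
m/z values, counts matched diagnostics per isomer and calls the winner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from .fragments import FragmentIon, enumerate_fragments
from .mass import DerivatizationScheme, PERMETHYLATED, match_composition
from .residues import ResidueTable, DEFAULT_RESIDUES
from .spectrum import PeakList
from .topology import GlycanTopology, parse_topology

__all__ = ["IsomerCall", "DiagnosticMatch", "sle_topology", "sle_diagnostics",
           "classify_sle_isomer", "SLE_COMPOSITION"]

SLE_COMPOSITION = "HexNAc2Hex2Fuc1NeuAc1"

_EPITOPE = {
    # chain type -> (Gal linkage to GlcNAc, Fuc linkage to GlcNAc)
    "SLeA": ("NeuAc(a2-3)Gal(b1-3)", "Fuc(a1-4)"),
    "SLeX": ("NeuAc(a2-3)Gal(b1-4)", "Fuc(a1-3)"),
}


def sle_topology(
    isomer: str,
    arm: str = "6",
    aglycone: str = "benzyl",
    table: ResidueTable = DEFAULT_RESIDUES,
) -> GlycanTopology:
    """Benzyl O-glycan carrying one sialyl-Lewis epitope, composition
    HexNAc2Hex2Fuc1NeuAc1.

    ``arm="6"`` (default): core 2, epitope on the GlcNAc(beta1-6) branch.
    ``arm="3"``: extended core 1, epitope on a GlcNAc(beta1-3) extension of
    the core galactose.  Composition is arm-invariant; topology is not.
    """
    if isomer not in _EPITOPE:
        raise ValueError(f"isomer must be 'SLeA' or 'SLeX', got {isomer!r}")
    gal, fuc = _EPITOPE[isomer]
    epitope = f"{gal}[{fuc}]GlcNAc"
    if arm == "6":
        text = f"Gal(b1-3)[{epitope}(b1-6)]GalNAc"
    elif arm == "3":
        text = f"{epitope}(b1-3)Gal(b1-3)GalNAc"
    else:
        raise ValueError(f"arm must be '6' or '3', got {arm!r}")
    return parse_topology(text, aglycone, table)


@dataclass(frozen=True)
class DiagnosticMatch:
    label: str
    theoretical_mz: float
    observed_mz: float
    error_da: float


@dataclass(frozen=True)
class IsomerCall:
    verdict: str  # 'SLeA', 'SLeX' or 'undetermined'
    matched_diagnostics: tuple[DiagnosticMatch, ...]  # winner's matches
    counts: dict = field(default_factory=dict)  # matched diagnostics per isomer


@lru_cache(maxsize=32)
def sle_diagnostics(
    scheme: DerivatizationScheme = PERMETHYLATED,
    tol_da: float = 0.5,
    arm: str = "6",
    max_cleavages: int = 2,
) -> dict[str, list[FragmentIon]]:
    """Theoretical fragments unique to each isomer at the given tolerance.

    A fragment is diagnostic when no fragment of the other isomer lies within
    ``tol_da`` of its m/z; duplicated m/z values within one isomer are
    collapsed to the lexicographically first label.
    """
    frags = {
        iso: enumerate_fragments(sle_topology(iso, arm), scheme, max_cleavages=max_cleavages)
        for iso in ("SLeA", "SLeX")
    }
    diag: dict[str, list[FragmentIon]] = {}
    for iso, other in (("SLeA", "SLeX"), ("SLeX", "SLeA")):
        other_mzs = sorted(f.mz for f in frags[other])
        unique: dict[float, FragmentIon] = {}
        for f in sorted(frags[iso], key=lambda f: (f.dc_label, f.site)):
            if any(abs(f.mz - om) <= tol_da for om in other_mzs):
                continue
            key = round(f.mz, 4)
            if key not in unique:
                unique[key] = f
        diag[iso] = sorted(unique.values(), key=lambda f: f.mz)
    return diag


def classify_sle_isomer(
    peaks: PeakList,
    scheme: DerivatizationScheme = PERMETHYLATED,
    tol_da: float = 0.5,
    min_diagnostics: int = 2,
    arm: str = "6",
    precursor_tolerance_ppm: float = 50.0,
) -> IsomerCall:
    """Call SLeA vs SLeX for one MS/MS spectrum of the m/z 1556.8 ion.

    The precursor must match the sialyl-Lewis composition
    HexNAc2Hex2Fuc1NeuAc1 as a permethylated (or native) benzyl glycan.  The
    verdict requires at least ``min_diagnostics`` matched diagnostics for the
    winner and strictly fewer for the loser; anything else is undetermined.
    """
    candidate = sle_topology("SLeA", arm)
    if not match_composition(
        peaks.precursor_mz, [(candidate, scheme)], precursor_tolerance_ppm
    ):
        raise ValueError(
            f"precursor m/z {peaks.precursor_mz:.3f} does not match the "
            f"sialyl-Lewis composition {SLE_COMPOSITION} "
            f"({scheme.kind}, benzyl) within {precursor_tolerance_ppm} ppm"
        )
    diagnostics = sle_diagnostics(scheme, tol_da, arm)
    matches: dict[str, list[DiagnosticMatch]] = {}
    for iso, diags in diagnostics.items():
        found: list[DiagnosticMatch] = []
        for frag in diags:
            best = None
            for obs, _ in peaks.peaks:
                err = obs - frag.mz
                if abs(err) <= tol_da and (best is None or abs(err) < abs(best)):
                    best = err
            if best is not None:
                found.append(
                    DiagnosticMatch(frag.dc_label, frag.mz, frag.mz + best, best)
                )
        matches[iso] = found
    n_a, n_x = len(matches["SLeA"]), len(matches["SLeX"])
    counts = {"SLeA": n_a, "SLeX": n_x}
    if n_a == n_x or max(n_a, n_x) < min_diagnostics:
        return IsomerCall("undetermined", (), counts)
    winner = "SLeA" if n_a > n_x else "SLeX"
    return IsomerCall(winner, tuple(matches[winner]), counts)
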