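"""Mass engine: residue table, composition deltas, derivatized neutral masses."""

import numpy as np
import pytest

from glycoseek.composition import GlycanComposition, composition_delta_mass
from glycoseek.mass import (
    AdductSpec,
    DerivatizationScheme,
    NATIVE,
    PERMETHYLATED,
    display_mz,
    match_composition,
    mz,
    neutral_mass,
)
from glycoseek.residues import CH2, DEFAULT_RESIDUES, UnknownResidueError, formula_mass
from glycoseek.topology import count_methylation_sites, parse_topology

from conftest import random_topology


class TestResidues:
    def test_residue_masses_match_their_formulas(self):
        """Residue masses derive from elemental formulas to <=1e-4 Da."""
        expected = {"HexNAc": 203.0794, "Hex": 162.0528, "Fuc": 146.0579,
                    "NeuAc": 291.0954}
        for name, ref in expected.items():
            res = DEFAULT_RESIDUES[name]
            assert res.monoisotopic_mass == pytest.approx(
                formula_mass(res.elemental_formula), abs=1e-10)
            assert res.monoisotopic_mass == pytest.approx(ref, abs=1e-4)

    def test_aliases_resolve_to_classes(self):
        assert DEFAULT_RESIDUES.canonical("GalNAc") == "HexNAc"
        assert DEFAULT_RESIDUES.canonical("dHex") == "Fuc"

    def test_unknown_residue_is_a_named_error(self):
        with pytest.raises(UnknownResidueError):
            DEFAULT_RESIDUES["Xyl"]

    def test_yaml_override_extends_the_table(self, tmp_path):
        cfg = tmp_path / "residues.yaml"
        cfg.write_text(
            "Pent:\n  formula: C5H8O4\n  hydroxyl_positions: [2, 3]\n"
            "  aliases: [Xyl]\n")
        from glycoseek.residues import ResidueTable

        table = ResidueTable.from_yaml(str(cfg))
        assert table["Xyl"].monoisotopic_mass == pytest.approx(132.0423, abs=1e-4)
        assert table.canonical("GalNAc") == "HexNAc"  # built-ins retained


class TestCompositionDelta:
    """The Ser/Thr variable-modification deltas used in glycopeptide searches."""

    @pytest.mark.parametrize(
        "composition, delta",
        [
            ("HexNAc1", 203.079),  # Tn antigen
            ("HexNAc1Hex1", 365.132),  # T antigen
            ("HexNAc1Hex1Fuc1", 511.190),  # fucosyl-T
            ("HexNAc1Hex1NeuAc1", 656.228),  # sialyl-T
            ("HexNAc1Hex1NeuAc2", 947.323),  # disialyl-T
            ("HexNAc2Hex2Fuc1NeuAc1", 1167.418),  # core 2 + sialyl-Lewis
        ],
    )
    def test_printed_deltas_to_three_decimals(self, composition, delta):
        assert round(composition_delta_mass(composition), 3) == delta

    def test_empty_composition_is_zero(self):
        assert composition_delta_mass("") == 0.0

    def test_parse_is_order_insensitive(self):
        a = GlycanComposition.parse("Fuc1HexNAc2NeuAc1Hex2")
        b = GlycanComposition.parse("HexNAc2Hex2Fuc1NeuAc1")
        assert a == b
        assert b.canonical_string() == "HexNAc2Hex2Fuc1NeuAc1"

    def test_unknown_residue_rejected(self):
        with pytest.raises(UnknownResidueError):
            composition_delta_mass("HexNAc1Pent1")

    def test_mass_is_additive_over_counts(self, rng):
        names = ["HexNAc", "Hex", "Fuc", "NeuAc"]
        for _ in range(20):
            counts = {n: int(rng.integers(0, 5)) for n in names}
            expected = sum(DEFAULT_RESIDUES[n].monoisotopic_mass * c
                           for n, c in counts.items())
            assert composition_delta_mass(counts) == pytest.approx(expected, abs=1e-9)


class TestMethylationSites:
    @pytest.mark.parametrize(
        "text, aglycone, sites",
        [
            ("GalNAc", "benzyl", 4),  # 3 OH + amide NH
            ("Gal(b1-3)GalNAc", "benzyl", 7),
            ("Hex", "free_reducing", 5),  # 4 OH + anomeric OH
            ("NeuAc(a2-6)GalNAc", "benzyl", 9),  # NeuAc: 4 OH + NH + COOH
        ],
    )
    def test_site_counts(self, text, aglycone, sites):
        assert count_methylation_sites(parse_topology(text, aglycone)) == sites

    def test_unknown_linkage_needs_override(self):
        topo = parse_topology("Gal(b1-?)GalNAc", "benzyl")
        with pytest.raises(ValueError, match="override"):
            count_methylation_sites(topo)
        assert count_methylation_sites(topo, {"GalNAc": 2}) == 7

    def test_invalid_linkage_position_rejected(self):
        with pytest.raises(ValueError, match="valence"):
            parse_topology("Gal(b1-5)GalNAc", "benzyl")


class TestNeutralMass:
    def test_permethylated_benzyl_core1(self):
        topo = parse_topology("Gal(b1-3)GalNAc", "benzyl")
        assert neutral_mass(topo, PERMETHYLATED) == pytest.approx(571.300, abs=1e-3)

    def test_permethylated_benzyl_sialyl_tn(self):
        topo = parse_topology("NeuAc(a2-6)GalNAc", "benzyl")
        assert neutral_mass(topo, PERMETHYLATED) == pytest.approx(728.373, abs=1e-3)

    def test_permethylation_adds_ch2_per_site(self, rng):
        """Permethylated minus native equals 14.01565 x site count, always."""
        for _ in range(30):
            topo = random_topology(rng)
            diff = neutral_mass(topo, PERMETHYLATED) - neutral_mass(topo, NATIVE)
            assert diff == pytest.approx(
                CH2 * count_methylation_sites(topo), abs=1e-9)

    def test_scheme_forces_sialic_methyl_ester(self):
        assert DerivatizationScheme("permethylated").sialic_acid_methyl_ester
        with pytest.raises(ValueError):
            DerivatizationScheme("acetylated")


# Topologies behind the printed one-decimal [M+H]+ values of the benzyl
# O-glycome: T, fucosyl-T, sialyl-T, sialyl-Tn, core 2 and SLe-core 2.
PRINTED_MZ = [
    ("Gal(b1-3)GalNAc", 572.3),
    ("Fuc(a1-2)Gal(b1-3)GalNAc", 746.4),
    ("NeuAc(a2-3)Gal(b1-3)GalNAc", 933.5),
    ("NeuAc(a2-6)GalNAc", 729.4),
    ("Gal(b1-3)[Gal(b1-4)GlcNAc(b1-6)]GalNAc", 1021.5),
    ("Gal(b1-3)[Gal(b1-4)[Fuc(a1-3)]GlcNAc(b1-6)]GalNAc", 1195.6),
    ("Gal(b1-3)[NeuAc(a2-3)Gal(b1-3)[Fuc(a1-4)]GlcNAc(b1-6)]GalNAc", 1556.8),
]


class TestMz:
    @pytest.mark.parametrize("text, printed", PRINTED_MZ)
    def test_printed_protonated_mz(self, text, printed):
        topo = parse_topology(text, "benzyl")
        assert display_mz(mz(neutral_mass(topo, PERMETHYLATED))) == printed

    def test_proton_only(self):
        assert mz(0.0) == pytest.approx(1.007276, abs=1e-6)

    def test_charge_zero_rejected(self):
        with pytest.raises(ValueError):
            AdductSpec("proton", 0)

    def test_sodium_option(self):
        assert mz(571.299, AdductSpec("sodium", 1)) == pytest.approx(594.288, abs=1e-3)


class TestMatchComposition:
    def setup_method(self):
        self.core2 = (parse_topology("Gal(b1-3)[Gal(b1-4)GlcNAc(b1-6)]GalNAc",
                                     "benzyl"), PERMETHYLATED)
        self.sle = (parse_topology(
            "Gal(b1-3)[NeuAc(a2-3)Gal(b1-3)[Fuc(a1-4)]GlcNAc(b1-6)]GalNAc",
            "benzyl"), PERMETHYLATED)
        self.h3f = (parse_topology(
            "Gal(b1-2)Gal(b1-3)[Gal(b1-4)[Fuc(a1-3)]GlcNAc(b1-6)]GalNAc",
            "benzyl"), PERMETHYLATED)  # HexNAc2Hex3Fuc1

    def test_core2_within_10ppm(self):
        matches = match_composition(1021.53, [self.core2], 10.0)
        assert len(matches) == 1

    def test_tolerance_respected(self):
        theo = mz(neutral_mass(*self.core2))
        assert match_composition(theo + 0.01, [self.core2], 0.1) == []

    def test_unique_match_among_near_isobars(self):
        # brute force: only the sialyl-Lewis composition lies near 1556.80
        matches = match_composition(1556.80, [self.sle, self.h3f], 30.0)
        assert [m.topology.composition().canonical_string() for m in matches] == [
            "HexNAc2Hex2Fuc1NeuAc1"]

    def test_empty_candidates_empty_result(self):
        assert match_composition(1000.0, [], 10.0) == []
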