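"""Identification-table IO and cross-line set algebra."""

import io
import itertools

import numpy as np
import pytest

from glycoseek.proteome import (
    ProteinRecord,
    common_core,
    load_id_table,
    strategy_overlap,
    write_id_table,
)

HEADER = "protein\tcell_line\tstrategy\thas_sle_glycopeptide\n"


def _records(design):
    """design: {line: {'ip': [...], 'pd': [...], 'sle': [...]}}"""
    recs = []
    for line, d in design.items():
        sle = set(d.get("sle", ()))
        for p in d.get("ip", ()):
            recs.append(ProteinRecord(p, line, "IP_SLeA", p in sle))
        for p in d.get("pd", ()):
            recs.append(ProteinRecord(p, line, "Eselectin_pulldown", p in sle))
    return recs


class TestLoadTable:
    def test_duplicates_merge(self):
        text = HEADER + "\n".join([
            "P1\tN87\tIP_SLeA\ttrue",
            "P1\tN87\tIP_SLeA\tfalse",  # duplicate, evidence ORed
            "P2\tN87\tIP_SLeA\tfalse",
            "P3\tN87\tEselectin_pulldown\ttrue",
            "P4\tOCUM1\tIP_SLeA\tfalse",
        ])
        records = load_id_table(io.StringIO(text))
        assert len(records) == 4
        p1 = [r for r in records if r.protein == "P1"][0]
        assert p1.has_sle_glycopeptide

    def test_unknown_strategy_skipped(self, caplog):
        text = HEADER + "P1\tN87\tIP_SLeA\ttrue\nP2\tN87\twestern_blot\ttrue\n"
        with caplog.at_level("WARNING"):
            records = load_id_table(io.StringIO(text))
        assert len(records) == 1
        assert "skipped 1" in caplog.text

    def test_missing_columns_named(self):
        with pytest.raises(ValueError, match="has_sle_glycopeptide"):
            load_id_table(io.StringIO("protein\tcell_line\tstrategy\nP1\tN87\tIP_SLeA\n"))

    def test_round_trip_byte_identical(self):
        # rows already in the loader's canonical (cell_line, strategy, key) order
        text = HEADER + "\n".join([
            "P2\tN87\tEselectin_pulldown\tfalse",
            "P1\tN87\tIP_SLeA\ttrue",
            "P3\tOCUM1\tIP_SLeA\ttrue",
        ]) + "\n"
        records = load_id_table(io.StringIO(text))
        buf = io.StringIO()
        write_id_table(records, buf)
        assert buf.getvalue() == text
        assert load_id_table(io.StringIO(buf.getvalue())) == records


class TestStrategyOverlap:
    def test_worked_example(self):
        recs = _records({"N87": {"ip": "ABC", "pd": "BCD"}})
        out = strategy_overlap(recs, "N87")
        assert (out["both"], out["ip_only"], out["pulldown_only"]) == (2, 1, 1)
        assert out["fraction_both_vs_ip"] == 0.667

    def test_identical_sets_fraction_one(self):
        recs = _records({"N87": {"ip": "ABC", "pd": "ABC"}})
        assert strategy_overlap(recs, "N87")["fraction_both_vs_ip"] == 1.0

    def test_missing_strategy_rejected(self):
        recs = _records({"N87": {"ip": "ABC"}})
        with pytest.raises(ValueError, match="Eselectin_pulldown"):
            strategy_overlap(recs, "N87")

    def test_random_sets_match_membership_oracle(self, rng):
        universe = [f"P{i}" for i in range(60)]
        for _ in range(100):
            ip = {p for p in universe if rng.random() < 0.5}
            pd_ = {p for p in universe if rng.random() < 0.5}
            if not ip or not pd_:
                continue
            recs = _records({"L": {"ip": ip, "pd": pd_}})
            out = strategy_overlap(recs, "L")
            both = sum(1 for p in universe if p in ip and p in pd_)
            assert out["both"] == both
            assert out["ip_only"] == len(ip) - both


class TestCommonCore:
    def test_planted_core_recovered(self, rng):
        core = [f"CORE{i}" for i in range(22)]
        design = {}
        for line in ("A", "B", "C"):
            extra = [f"{line}{i}" for i in range(50)]
            design[line] = {"ip": core + extra, "pd": core + extra[:25],
                            "sle": core}
        out = common_core(_records(design), ["A", "B", "C"],
                          require_sle_evidence=True, require_eselectin=True)
        assert list(out.common) == sorted(core)

    def test_evidence_filter_drops_unconfirmed_protein(self):
        design = {line: {"ip": ["P1", "P2"], "pd": ["P1", "P2"], "sle": ["P1"]}
                  for line in ("A", "B")}
        full = common_core(_records(design), ["A", "B"])
        filtered = common_core(_records(design), ["A", "B"],
                               require_sle_evidence=True)
        assert set(full.common) == {"P1", "P2"}
        assert set(filtered.common) == {"P1"}

    def test_single_line_rejected(self):
        with pytest.raises(ValueError):
            common_core(_records({"A": {"ip": "AB"}}), ["A"])
        with pytest.raises(ValueError):
            common_core([], [])

    def test_regions_match_inclusion_exclusion_oracle(self, rng):
        """Exclusive Venn regions equal brute-force enumeration over all
        subset patterns, for 100 random three-line designs."""
        lines = ("A", "B", "C")
        universe = [f"P{i}" for i in range(40)]
        for _ in range(100):
            membership = {ln: {p for p in universe if rng.random() < 0.5}
                          for ln in lines}
            recs = _records({ln: {"ip": membership[ln]} for ln in lines})
            out = common_core(recs, list(lines))
            # oracle: classify every protein by its exact membership pattern
            expected = {}
            for p in universe:
                pattern = frozenset(ln for ln in lines if p in membership[ln])
                if pattern:
                    expected[pattern] = expected.get(pattern, 0) + 1
            for r in range(1, 4):
                for subset in itertools.combinations(lines, r):
                    assert out.regions[frozenset(subset)] == expected.get(
                        frozenset(subset), 0)
            assert out.region_total == len(
                set().union(*membership.values()))

    def test_filters_never_increase_counts_and_intersection_monotone(self, rng):
        core = [f"C{i}" for i in range(5)]
        design = {}
        for line in ("A", "B", "C"):
            extra = [f"{line}{i}" for i in range(30)]
            design[line] = {"ip": core + extra, "pd": core + extra[:10],
                            "sle": core[:3]}
        recs = _records(design)
        plain = common_core(recs, ["A", "B", "C"])
        for sle, esel in ((True, False), (False, True), (True, True)):
            filt = common_core(recs, ["A", "B", "C"], sle, esel)
            assert len(filt.common) <= len(plain.common)
            assert filt.region_total <= plain.region_total
        two = common_core(recs, ["A", "B"])
        assert len(plain.common) <= len(two.common)
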