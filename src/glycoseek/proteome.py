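"""Set algebra over glycoprotein identification lists.

The experimental design behind these tables: plasma-membrane-enriched
extracts of several gastric cancer cell lines are processed by two parallel
isolation strategies — immunoprecipitation with an anti-sialyl-Lewis-A
antibody (``IP_SLeA``) and a pulldown with an E-selectin/Fc chimera
(``Eselectin_pulldown``) — and the isolated proteins identified by LC-MS/MS.
This module answers the set questions: which proteins are shared between
strategies within a cell line, and which survive intersection across cell
lines under evidence filters (confirmed SLeA O-glycopeptide in at least one
cell line; E-selectin affinity).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import pandas as pd

__all__ = ["ProteinRecord", "STRATEGIES", "load_id_table", "write_id_table",
           "strategy_overlap", "common_core", "VennSummary"]

log = logging.getLogger(__name__)

STRATEGIES = ("IP_SLeA", "Eselectin_pulldown")
_MANDATORY = ("protein", "cell_line", "strategy", "has_sle_glycopeptide")
_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f", ""}


@dataclass(frozen=True)
class ProteinRecord:
    """One identified protein in one cell line under one isolation strategy.

    ``protein`` is the identity key: accession when available, gene symbol as
    fallback, matched case-insensitively (identifications from different gel
    bands are collapsed onto this key).
    """

    protein: str
    cell_line: str
    strategy: str
    has_sle_glycopeptide: bool = False

    @property
    def key(self) -> str:
        return self.protein.strip().upper()


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean")


def load_id_table(path_or_buf, dialect: str = "tsv") -> list[ProteinRecord]:
    """Read a TSV/CSV identification table into validated, deduplicated records.

    Mandatory columns: ``protein`` (accession or gene symbol), ``cell_line``,
    ``strategy`` (one of IP_SLeA / Eselectin_pulldown) and
    ``has_sle_glycopeptide``.  An ``accession`` column, if present, takes
    precedence over ``protein``.  Malformed rows (unknown strategy,
    unparseable flag, empty protein) are logged and skipped; duplicated
    (protein, cell_line, strategy) rows are merged with OR over the evidence
    flag.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path_or_buf, sep=sep, dtype=str, keep_default_na=False)
    id_col = "accession" if "accession" in df.columns else "protein"
    missing = [c for c in _MANDATORY if c not in df.columns and c != "protein"]
    if id_col not in df.columns:
        missing.insert(0, "protein (or accession)")
    if missing:
        raise ValueError(f"identification table lacks mandatory columns: {missing}")
    records: dict[tuple[str, str, str], ProteinRecord] = {}
    skipped = 0
    for row in df.itertuples(index=False):
        d = row._asdict()
        protein = str(d[id_col]).strip()
        strategy = str(d["strategy"]).strip()
        try:
            if not protein:
                raise ValueError("empty protein id")
            if strategy not in STRATEGIES:
                raise ValueError(f"unknown strategy {strategy!r}")
            flag = _parse_bool(d["has_sle_glycopeptide"])
        except ValueError as exc:
            skipped += 1
            log.warning("skipping malformed row %r: %s", d, exc)
            continue
        rec = ProteinRecord(protein, str(d["cell_line"]).strip(), strategy, flag)
        k = (rec.key, rec.cell_line, rec.strategy)
        if k in records:
            if flag and not records[k].has_sle_glycopeptide:
                records[k] = rec
        else:
            records[k] = rec
    if skipped:
        log.warning("load_id_table: skipped %d malformed row(s)", skipped)
    return sorted(records.values(), key=lambda r: (r.cell_line, r.strategy, r.key))


def write_id_table(records: list[ProteinRecord], path_or_buf, dialect: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = pd.DataFrame(
        [
            {
                "protein": r.protein,
                "cell_line": r.cell_line,
                "strategy": r.strategy,
                "has_sle_glycopeptide": str(r.has_sle_glycopeptide).lower(),
            }
            for r in records
        ]
    )
    df.to_csv(path_or_buf, sep=sep, index=False)


def strategy_overlap(records: list[ProteinRecord], cell_line: str) -> dict:
    """IP-only / pulldown-only / shared counts for one cell line.

    The headline number is the fraction of IP-identified proteins also found
    by the E-selectin pulldown (``fraction_both_vs_ip``), reported to three
    decimals.
    """
    ip = {r.key for r in records if r.cell_line == cell_line and r.strategy == "IP_SLeA"}
    pd_ = {r.key for r in records
           if r.cell_line == cell_line and r.strategy == "Eselectin_pulldown"}
    if not ip or not pd_:
        raise ValueError(
            f"cell line {cell_line!r} lacks records for "
            f"{'IP_SLeA' if not ip else 'Eselectin_pulldown'}"
        )
    both = ip & pd_
    return {
        "cell_line": cell_line,
        "ip_total": len(ip),
        "pulldown_total": len(pd_),
        "both": len(both),
        "ip_only": len(ip - pd_),
        "pulldown_only": len(pd_ - ip),
        "fraction_both_vs_ip": round(len(both) / len(ip), 3),
        "fraction_both_vs_pulldown": round(len(both) / len(pd_), 3),
    }


@dataclass(frozen=True)
class VennSummary:
    cell_lines: tuple[str, ...]
    common: tuple[str, ...]  # proteins in every cell line, lexicographic
    regions: dict  # frozenset(cell line subset) -> exclusive region count

    @property
    def region_total(self) -> int:
        return sum(self.regions.values())


def _line_sets(
    records: list[ProteinRecord],
    cell_lines: list[str],
    require_sle_evidence: bool,
    require_eselectin: bool,
) -> dict[str, set[str]]:
    sle_anywhere = {r.key for r in records if r.has_sle_glycopeptide}
    sets: dict[str, set[str]] = {}
    for line in cell_lines:
        members = {r.key for r in records if r.cell_line == line}
        if require_eselectin:
            members &= {
                r.key for r in records
                if r.cell_line == line and r.strategy == "Eselectin_pulldown"
            }
        if require_sle_evidence:
            # "confirmed O-SLeA" means evidence in at least one cell line,
            # applied globally rather than per line.
            members &= sle_anywhere
        sets[line] = members
    return sets


def common_core(
    records: list[ProteinRecord],
    cell_lines: list[str],
    require_sle_evidence: bool = False,
    require_eselectin: bool = False,
) -> VennSummary:
    """Proteins common to all cell lines, plus all exclusive Venn regions.

    Filters: ``require_sle_evidence`` keeps proteins with a confirmed
    SLeA-terminated O-glycopeptide in at least one cell line;
    ``require_eselectin`` keeps proteins identified by the E-selectin
    pulldown in each cell line considered.  Region counts cover all 2^k - 1
    non-empty cell-line subsets (exclusive regions) and sum to the union's
    cardinality.
    """
    if not cell_lines:
        raise ValueError("cell_lines must be non-empty")
    if len(cell_lines) < 2:
        raise ValueError("common_core needs at least two cell lines")
    sets = _line_sets(records, list(cell_lines), require_sle_evidence, require_eselectin)
    union = set().union(*sets.values())
    regions: dict[frozenset, int] = {}
    for r in range(1, len(cell_lines) + 1):
        for subset in itertools.combinations(cell_lines, r):
            inside = set(union)
            for line in subset:
                inside &= sets[line]
            for line in cell_lines:
                if line not in subset:
                    inside -= sets[line]
            regions[frozenset(subset)] = len(inside)
    common = set(union)
    for line in cell_lines:
        common &= sets[line]
    return VennSummary(tuple(cell_lines), tuple(sorted(common)), regions)
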