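"""The nine-variable cancer-target prioritization score (0-15).

The score ranks candidate biomarkers by how cancer-restricted their
cell-surface expression is, rewarding membrane localization in tumors,
overexpression in gastric cancer and poor-prognosis association, while
penalizing expression in healthy tissues — in particular at the plasma
membrane, in lymphoid tissues and in gametes.  It is the procedure that
surfaced nucleolin, a canonically nuclear protein relocated to the cancer
cell membrane, as the top-ranked target.

Variables and point assignments:

=====  ============================================  ==========================
 var    meaning                                       points
=====  ============================================  ==========================
 i      location in healthy cells                     membrane 0 / other 1
 ii     location in cancer cells                      membrane 1 / other 0
 iii    healthy gastric epithelium, plasma membrane   neg 3 / low 2 / mod 1 / high 0
 iv     expression in gastric cancer                  neg 0 / low 1 / mod 2 / high 3
 v      high expression marks poor prognosis          yes 1 / no 0
 vi     brain expression                              exclusively brain 1 / else 0
 vii    lymphoid tissues, plasma membrane             not expressed 1 / expressed 0
 viii   gametes                                       not expressed 1 / expressed 0
 ix     healthy-tissue plasma-membrane index          none 3 / low 2 / mod 1 / high 0
=====  ============================================  ==========================

Variable (vi) is literal: only brain-exclusive expression scores the point;
proteins absent from the brain score 0 (configurable via ``brain_absent_point``).
Variable (ix) maps the maximum plasma-membrane expression level across
surveyed healthy tissues (excluding gastric epithelium, already variable iii).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

__all__ = ["AnnotationRecord", "ScoreBreakdown", "score_record",
           "rank_candidates", "VOCABULARY"]

_ORDINAL = ("negative", "low", "moderate", "high")
_INDEX = ("none", "low", "moderate", "high")

VOCABULARY = {
    "healthy_location": ("membrane", "other"),
    "cancer_location": ("membrane", "other"),
    "healthy_gastric_pm_expression": _ORDINAL,
    "gc_expression": _ORDINAL,
    "poor_prognosis": (False, True),
    "brain_pattern": ("exclusive", "shared", "absent"),
    "lymphoid_pm_expressed": (False, True),
    "gamete_expressed": (False, True),
    "healthy_pm_index_level": _INDEX,
}


@dataclass(frozen=True)
class AnnotationRecord:
    """Tissue/subcellular expression profile of one candidate protein.

    All fields are mandatory; there are no implicit defaults because a
    missing annotation is a data problem, not a zero.
    """

    protein: str
    healthy_location: str
    cancer_location: str
    healthy_gastric_pm_expression: str
    gc_expression: str
    poor_prognosis: bool
    brain_pattern: str
    lymphoid_pm_expressed: bool
    gamete_expressed: bool
    healthy_pm_index_level: str

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "protein":
                if not str(self.protein).strip():
                    raise ValueError("missing variable: protein")
                continue
            value = getattr(self, f.name)
            if value is None:
                raise ValueError(f"missing variable: {f.name}")
            allowed = VOCABULARY[f.name]
            if value not in allowed:
                raise ValueError(
                    f"{f.name}={value!r} outside vocabulary {allowed}"
                )


@dataclass(frozen=True)
class ScoreBreakdown:
    protein: str
    i: int
    ii: int
    iii: int
    iv: int
    v: int
    vi: int
    vii: int
    viii: int
    ix: int

    @property
    def total(self) -> int:
        return self.i + self.ii + self.iii + self.iv + self.v + self.vi + self.vii + self.viii + self.ix

    @property
    def healthy_sparing(self) -> int:
        """Tie-break key: points from healthy-tissue sparing (iii + ix)."""
        return self.iii + self.ix

    def as_dict(self) -> dict:
        return {
            "protein": self.protein,
            **{k: getattr(self, k) for k in
               ("i", "ii", "iii", "iv", "v", "vi", "vii", "viii", "ix")},
            "total": self.total,
        }


def score_record(rec: AnnotationRecord, brain_absent_point: int = 0) -> ScoreBreakdown:
    """Score one annotation record; total is the sum of the nine variables."""
    if brain_absent_point not in (0, 1):
        raise ValueError("brain_absent_point must be 0 or 1")
    ordinal = {v: k for k, v in enumerate(_ORDINAL)}  # negative..high -> 0..3
    index = {v: k for k, v in enumerate(_INDEX)}
    brain = {"exclusive": 1, "shared": 0, "absent": brain_absent_point}
    return ScoreBreakdown(
        protein=rec.protein,
        i=0 if rec.healthy_location == "membrane" else 1,
        ii=1 if rec.cancer_location == "membrane" else 0,
        iii=3 - ordinal[rec.healthy_gastric_pm_expression],
        iv=ordinal[rec.gc_expression],
        v=1 if rec.poor_prognosis else 0,
        vi=brain[rec.brain_pattern],
        vii=0 if rec.lymphoid_pm_expressed else 1,
        viii=0 if rec.gamete_expressed else 1,
        ix=3 - index[rec.healthy_pm_index_level],
    )


def rank_candidates(
    records: list[AnnotationRecord], brain_absent_point: int = 0
) -> list[ScoreBreakdown]:
    """Rank candidates by descending total score.

    Ties are broken by the larger healthy-sparing component (iii + ix), then
    lexicographic protein id; the result is stable and deterministic under
    input permutation.
    """
    if not records:
        raise ValueError("no records to rank")
    scored = [score_record(r, brain_absent_point) for r in records]
    scored.sort(key=lambda s: (-s.total, -s.healthy_sparing, s.protein))
    return scored
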