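"""Glycome-level quantification.

Glycans are expressed as relative abundance against the summed signal of the
whole glycome of a cell line; co-eluting sialyl-Lewis isomers sharing one m/z
are apportioned by the areas of their retention-time-resolved peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .isomer import IsomerCall

__all__ = ["GlycanObservation", "relative_abundance", "isomer_fraction",
           "xic_peak_area", "preprocess_for_clustering"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GlycanObservation:
    """One integrated glycan signal in one cell line."""

    glycan_id: str
    cell_line: str
    retention_time: float  # minutes
    area: float  # arbitrary units, >= 0

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("area must be non-negative")


def relative_abundance(observations: list[GlycanObservation]) -> pd.DataFrame:
    """Percent of the summed glycome signal per glycan, for one cell line.

    Multiple observations of the same glycan (e.g. isomer peaks at distinct
    retention times) are summed before normalization.  Output percentages sum
    to 100 within 1e-9.
    """
    if not observations:
        raise ValueError("no observations")
    lines = {o.cell_line for o in observations}
    if len(lines) != 1:
        raise ValueError(f"observations span several cell lines: {sorted(lines)}")
    totals: dict[str, float] = {}
    for o in observations:
        totals[o.glycan_id] = totals.get(o.glycan_id, 0.0) + o.area
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("all areas are zero; cannot normalize")
    df = pd.DataFrame(
        {
            "cell_line": sorted(lines)[0],
            "glycan": list(totals),
            "area": list(totals.values()),
        }
    ).sort_values("glycan", ignore_index=True)
    df["relative_abundance_pct"] = 100.0 * df["area"] / grand
    return df


def xic_peak_area(rt: np.ndarray, intensity: np.ndarray) -> float:
    """Trapezoidal area under an extracted-ion-chromatogram peak."""
    rt = np.asarray(rt, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if rt.ndim != 1 or rt.shape != intensity.shape or rt.size < 2:
        raise ValueError("rt and intensity must be matching 1-D arrays, n >= 2")
    return float(np.trapezoid(intensity, rt))


def isomer_fraction(
    peak_areas: list[float],
    calls: list[IsomerCall],
) -> dict[str, float]:
    """Apportion one shared m/z between SLeA and SLeX from per-peak calls.

    ``peak_areas[i]`` is the integrated area of the i-th retention-time peak
    and ``calls[i]`` its isomer call.  Undetermined peaks are excluded (the
    count is logged).  Returns ``{"SLeA": fA, "SLeX": 1 - fA, "n_excluded": k}``
    where fA = area(SLeA) / (area SLeA + area SLeX).
    """
    if len(peak_areas) != len(calls):
        raise ValueError("one isomer call is required per peak")
    areas = {"SLeA": 0.0, "SLeX": 0.0}
    excluded = 0
    for area, call in zip(peak_areas, calls):
        if area < 0:
            raise ValueError("peak areas must be non-negative")
        if call.verdict == "undetermined":
            excluded += 1
            continue
        areas[call.verdict] += area
    if excluded:
        log.info("isomer_fraction: excluded %d undetermined peak(s)", excluded)
    total = areas["SLeA"] + areas["SLeX"]
    if total <= 0:
        raise ValueError("no determined peaks with positive area")
    return {
        "SLeA": areas["SLeA"] / total,
        "SLeX": areas["SLeX"] / total,
        "n_excluded": excluded,
    }


def preprocess_for_clustering(
    abundance: pd.DataFrame,
    zero_replacement: str = "half_min_positive",
) -> tuple[pd.DataFrame, list[str]]:
    """Log-transform and autoscale a wide abundance matrix.

    Rows are samples (cell lines), columns glycans, values relative
    abundances (percent).  Zeros are replaced column-wise by half the
    smallest positive value in that column before the natural-log transform;
    each column is then centred and scaled to unit standard deviation
    (ddof=1).  Constant columns (including all-zero ones) cannot be scaled
    and are excluded; their names are returned alongside the matrix.
    Clustering itself is out of scope here.
    """
    if zero_replacement != "half_min_positive":
        raise ValueError(f"unknown zero replacement {zero_replacement!r}")
    if (abundance.values < 0).any():
        raise ValueError("abundances must be non-negative")
    out = {}
    excluded: list[str] = []
    for col in abundance.columns:
        x = abundance[col].to_numpy(dtype=float).copy()
        if (x == 0).any():
            positive = x[x > 0]
            if positive.size == 0:
                excluded.append(col)
                continue
            x[x == 0] = positive.min() / 2.0
        x = np.log(x)
        sd = x.std(ddof=1) if x.size > 1 else 0.0
        if sd == 0.0:
            excluded.append(col)
            continue
        out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=abundance.index), excluded
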