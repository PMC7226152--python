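"""Centroided peak lists, MGF/TSV round-tripping, and spectrum annotation.

Peak lists follow the ion-trap CID setting of the glycomics experiments:
matching is absolute-Da (default tolerance 0.5 Da, 0.8 Da maximal), not ppm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from pyteomics import mgf as _mgf

from .fragments import FragmentIon, enumerate_fragments
from .mass import DerivatizationScheme, PERMETHYLATED, mz as _mz, neutral_mass
from .topology import GlycanTopology

__all__ = ["PeakList", "AnnotatedPeak", "annotate_spectrum", "read_mgf",
           "write_mgf", "read_tsv", "write_tsv"]


@dataclass(frozen=True)
class PeakList:
    """One centroided MS/MS spectrum: precursor m/z plus (m/z, intensity) pairs."""

    precursor_mz: float
    peaks: tuple[tuple[float, float], ...]
    retention_time: float | None = None  # minutes
    source_id: str = ""

    def __post_init__(self) -> None:
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("peak intensities must be non-negative")

    @classmethod
    def from_arrays(cls, precursor_mz, mzs, intensities, retention_time=None,
                    source_id="") -> "PeakList":
        pairs = tuple(sorted(zip(map(float, mzs), map(float, intensities))))
        return cls(precursor_mz, pairs, retention_time, source_id)

    def canonicalized(self) -> "PeakList":
        """Strictly increasing m/z: duplicates merged by intensity sum."""
        merged: dict[float, float] = {}
        for m, i in self.peaks:
            merged[m] = merged.get(m, 0.0) + i
        return replace(self, peaks=tuple(sorted(merged.items())))

    @property
    def mzs(self):
        return [m for m, _ in self.peaks]

    @property
    def intensities(self):
        return [i for _, i in self.peaks]


@dataclass(frozen=True)
class AnnotatedPeak:
    observed_mz: float
    intensity: float
    fragment: FragmentIon
    error_da: float  # observed - theoretical


def annotate_spectrum(
    peaks: PeakList,
    topo: GlycanTopology,
    scheme: DerivatizationScheme = PERMETHYLATED,
    tol_da: float = 0.5,
    max_cleavages: int = 2,
    fragments: list[FragmentIon] | None = None,
) -> list[AnnotatedPeak]:
    """Match observed peaks to theoretical fragments of one topology.

    Greedy nearest-mass matching, at most one fragment per peak; ties are
    broken by fewer cleavage events, then lexicographic Domon-Costello label.
    Deterministic given inputs.  ``tol_da`` defaults to 0.5 Da for ion-trap
    spectra (0.8 Da is the maximal sensible value at unit resolution).
    """
    if tol_da <= 0:
        raise ValueError("tol_da must be positive")
    if fragments is None:
        fragments = enumerate_fragments(topo, scheme, max_cleavages=max_cleavages)
    out: list[AnnotatedPeak] = []
    for obs, inten in peaks.canonicalized().peaks:
        best: FragmentIon | None = None
        best_key = None
        for frag in fragments:
            err = abs(obs - frag.mz)
            if err > tol_da:
                continue
            key = (err, frag.cleavage_count, frag.dc_label, frag.site)
            if best_key is None or key < best_key:
                best, best_key = frag, key
        if best is not None:
            out.append(AnnotatedPeak(obs, inten, best, obs - best.mz))
    return out


# ---------------------------------------------------------------------------
# Peak-list IO: MGF (BEGIN IONS / PEPMASS / mz intensity rows) and 2-col TSV.

def write_mgf(peaklists: list[PeakList], path: str) -> None:
    spectra = []
    for idx, pl in enumerate(peaklists):
        params = {"title": pl.source_id or f"spectrum_{idx}",
                  "pepmass": pl.precursor_mz}
        if pl.retention_time is not None:
            params["rtinseconds"] = pl.retention_time * 60.0
        spectra.append({"params": params,
                        "m/z array": pl.mzs,
                        "intensity array": pl.intensities})
    with open(path, "w") as fh:
        _mgf.write(spectra, fh)


def read_mgf(path: str) -> list[PeakList]:
    out = []
    with _mgf.read(path) as reader:
        for spec in reader:
            params = spec.get("params", {})
            pep = params.get("pepmass", (0.0,))
            rt = params.get("rtinseconds")
            out.append(
                PeakList.from_arrays(
                    float(pep[0] if isinstance(pep, (tuple, list)) else pep),
                    spec["m/z array"],
                    spec["intensity array"],
                    retention_time=(float(rt) / 60.0) if rt is not None else None,
                    source_id=str(params.get("title", "")),
                )
            )
    return out


def write_tsv(peaklist: PeakList, path_or_buf) -> None:
    """Plain two-column m/z / intensity TSV (precursor in a # header)."""
    own = isinstance(path_or_buf, str)
    fh = open(path_or_buf, "w") if own else path_or_buf
    try:
        fh.write(f"# precursor_mz={peaklist.precursor_mz!r}\n")
        if peaklist.retention_time is not None:
            fh.write(f"# retention_time_min={peaklist.retention_time!r}\n")
        fh.write("mz\tintensity\n")
        for m, i in peaklist.peaks:
            fh.write(f"{m!r}\t{i!r}\n")
    finally:
        if own:
            fh.close()


def read_tsv(path_or_buf) -> PeakList:
    own = isinstance(path_or_buf, str)
    fh = open(path_or_buf) if own else path_or_buf
    try:
        precursor, rt = 0.0, None
        mzs, ints = [], []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                if key.strip() == "precursor_mz":
                    precursor = float(val)
                elif key.strip() == "retention_time_min":
                    rt = float(val)
                continue
            if line.startswith("mz\t"):
                continue
            m, i = line.split("\t")
            mzs.append(float(m))
            ints.append(float(i))
        return PeakList.from_arrays(precursor, mzs, ints, retention_time=rt)
    finally:
        if own:
            fh.close()
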