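"""Seeded generators for every input the analysis modules consume.

Three generators emulate the study's data-generating processes at their
reported scale, with no download:

* ion-trap CID spectra of known glycan topologies (theoretical fragments,
  Gaussian m/z jitter, log-normal intensities, uniform noise peaks);
* per-cell-line protein identification tables for two isolation strategies
  with a planted common core, controlled pairwise/triple overlaps and
  SLeA-glycopeptide evidence flags;
* annotation panels over the target-score vocabulary with one planted
  maximal, nucleolin-like profile (intracellular in health, membrane in
  cancer, absent from healthy tissues at the plasma membrane).

All randomness flows through ``numpy.random.Generator`` seeded with the
PCG64 algorithm from an explicit integer seed: identical parameters and seed
give identical outputs on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fragments import enumerate_fragments
from .mass import DerivatizationScheme, PERMETHYLATED, PROTONATED, mz, neutral_mass
from .proteome import ProteinRecord
from .score import AnnotationRecord, VOCABULARY
from .spectrum import PeakList
from .topology import GlycanTopology

__all__ = ["SpectrumParams", "IdTableParams", "AnnotationParams",
           "SimulationConfig", "simulate_spectrum", "simulate_id_tables",
           "simulate_annotations"]


# ---------------------------------------------------------------------------
# spectra

@dataclass(frozen=True)
class SpectrumParams:
    """Ion-trap CID spectrum model.

    ``jitter_sd`` is the 1-sigma m/z error applied to every theoretical
    fragment (Da; 0.2 emulates unit-resolution linear-ion-trap readings);
    ``n_noise_peaks`` uniform random peaks are added across the scan range.
    Signal intensities are log-normal around ~1e4 counts (ion-trap AGC
    target), noise an order of magnitude lower.
    """

    jitter_sd: float = 0.2
    n_noise_peaks: int = 20
    signal_log_mu: float = 9.2
    signal_log_sd: float = 0.6
    noise_log_mu: float = 6.9
    noise_log_sd: float = 0.8
    scan_min_mz: float = 150.0
    scan_margin: float = 50.0  # scan range extends this far beyond the precursor
    max_cleavages: int = 2

    def __post_init__(self) -> None:
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        if self.n_noise_peaks < 0:
            raise ValueError("n_noise_peaks must be non-negative")


def simulate_spectrum(
    topo: GlycanTopology,
    scheme: DerivatizationScheme = PERMETHYLATED,
    params: SpectrumParams = SpectrumParams(),
    seed: int = 0,
) -> PeakList:
    """Synthetic MS/MS spectrum of one topology: jittered theoretical
    fragments plus noise; the precursor is the exact theoretical [M+H]+."""
    rng = np.random.default_rng(seed)
    frags = enumerate_fragments(topo, scheme, max_cleavages=params.max_cleavages)
    precursor = mz(neutral_mass(topo, scheme), PROTONATED)
    theo = np.array(sorted({round(f.mz, 6) for f in frags}))
    theo = theo[(theo >= params.scan_min_mz) & (theo <= precursor + params.scan_margin)]
    mzs = theo + rng.normal(0.0, params.jitter_sd, theo.size) if params.jitter_sd else theo.astype(float)
    ints = rng.lognormal(params.signal_log_mu, params.signal_log_sd, theo.size)
    if params.n_noise_peaks:
        noise_mz = rng.uniform(params.scan_min_mz, precursor + params.scan_margin,
                               params.n_noise_peaks)
        noise_int = rng.lognormal(params.noise_log_mu, params.noise_log_sd,
                                  params.n_noise_peaks)
        mzs = np.concatenate([mzs, noise_mz])
        ints = np.concatenate([ints, noise_int])
    return PeakList.from_arrays(precursor, mzs, ints, source_id=f"sim:{topo}:{seed}")


# ---------------------------------------------------------------------------
# identification tables

@dataclass(frozen=True)
class IdTableParams:
    """Design of the three-line, two-strategy identification experiment.

    Defaults emulate the study scale: per-line identification totals near
    1000/500/800 distinct proteins, a planted 22-protein core present in all
    lines and both strategies with SLeA evidence, and strategy membership
    probabilities giving ~60% of IP identifications shared with the
    E-selectin pulldown.  The non-core overlap structure is explicit:
    ``pairwise_overlap_fraction`` of each line is drawn from dedicated
    two-line shared pools and ``triple_overlap_fraction`` from a three-line
    pool whose members never carry SLeA evidence — so the planted core is,
    by construction, the only fully shared evidence-positive set.
    """

    cell_lines: tuple[str, ...] = ("N87", "OCUM1", "KATOIII")
    line_sizes: tuple[int, ...] = (987, 467, 798)
    core_size: int = 22
    pairwise_overlap_fraction: float = 0.06
    triple_overlap_fraction: float = 0.05
    p_both: float = 0.54
    p_ip_only: float = 0.36
    p_pulldown_only: float = 0.10
    sle_evidence_fraction: float = 0.2

    def __post_init__(self) -> None:
        if len(self.cell_lines) != len(self.line_sizes):
            raise ValueError("one size per cell line is required")
        for frac in (self.pairwise_overlap_fraction, self.triple_overlap_fraction,
                     self.sle_evidence_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        probs = (self.p_both, self.p_ip_only, self.p_pulldown_only)
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("strategy probabilities must be >= 0 and sum to 1")
        shared = self.core_size + int(self.triple_overlap_fraction * min(self.line_sizes)) \
            + 2 * int(self.pairwise_overlap_fraction * min(self.line_sizes))
        if shared > min(self.line_sizes):
            raise ValueError(
                "inconsistent design: planted core plus shared pools exceed "
                "the smallest cell line"
            )


def simulate_id_tables(
    params: IdTableParams = IdTableParams(), seed: int = 0
) -> tuple[list[ProteinRecord], dict]:
    """Generate identification records plus the ground-truth design.

    Returns ``(records, truth)`` where ``truth`` holds the planted core ids
    and the exact per-region membership design.  Core proteins appear in
    every line under both strategies with SLeA evidence; triple-pool
    proteins appear in every line but never carry evidence; pairwise pools
    appear in exactly two lines; the remainder is line-private.  Strategy
    membership of non-core proteins is multinomial (both / IP-only /
    pulldown-only).
    """
    rng = np.random.default_rng(seed)
    lines = params.cell_lines
    n_min = min(params.line_sizes)
    counter = 0

    def take(n: int, prefix: str) -> list[str]:
        nonlocal counter
        ids = [f"{prefix}{i:05d}" for i in range(counter, counter + n)]
        counter += n
        return ids

    core = take(params.core_size, "C")
    triple = take(int(params.triple_overlap_fraction * n_min), "T")
    pair_pools: dict[frozenset, list[str]] = {}
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            n_pair = int(params.pairwise_overlap_fraction
                         * min(params.line_sizes[i], params.line_sizes[j]))
            pair_pools[frozenset((lines[i], lines[j]))] = take(n_pair, "S")

    membership: dict[str, list[str]] = {}
    for line, size in zip(lines, params.line_sizes):
        members = list(core) + list(triple)
        for pool_lines, pool in pair_pools.items():
            if line in pool_lines:
                members += pool
        members += take(size - len(members), "P")
        membership[line] = members

    probs = (params.p_both, params.p_ip_only, params.p_pulldown_only)
    records: list[ProteinRecord] = []
    for line in lines:
        for protein in membership[line]:
            if protein.startswith("C"):
                strategies = ("IP_SLeA", "Eselectin_pulldown")
                evidence = True
            else:
                choice = rng.choice(3, p=probs)
                strategies = (("IP_SLeA", "Eselectin_pulldown"),
                              ("IP_SLeA",), ("Eselectin_pulldown",))[choice]
                evidence = (not protein.startswith("T")) and bool(
                    rng.random() < params.sle_evidence_fraction
                )
            for strategy in strategies:
                records.append(ProteinRecord(protein, line, strategy, evidence))
    truth = {
        "core": core,
        "triple_pool": triple,
        "pair_pools": {tuple(sorted(k)): v for k, v in pair_pools.items()},
        "membership": membership,
    }
    return records, truth


# ---------------------------------------------------------------------------
# annotation panels

#: The planted profile: intracellular (nuclear) in health, plasma membrane in
#: cancer, invisible in healthy tissues — the maximal 15-point record.
NUCLEOLIN_LIKE = dict(
    healthy_location="other",
    cancer_location="membrane",
    healthy_gastric_pm_expression="negative",
    gc_expression="high",
    poor_prognosis=True,
    brain_pattern="exclusive",
    lymphoid_pm_expressed=False,
    gamete_expressed=False,
    healthy_pm_index_level="none",
)


@dataclass(frozen=True)
class AnnotationParams:
    """Annotation-panel generator: vocabulary frequencies reflecting that
    most proteins are broadly expressed in healthy tissues, plus one planted
    maximal profile.  Panel size defaults to the study's 22-candidate set."""

    panel_size: int = 22
    planted_protein: str = "NCL"
    frequencies: dict = field(default_factory=lambda: {
        "healthy_location": {"membrane": 0.4, "other": 0.6},
        "cancer_location": {"membrane": 0.5, "other": 0.5},
        "healthy_gastric_pm_expression": {
            "negative": 0.2, "low": 0.25, "moderate": 0.3, "high": 0.25},
        "gc_expression": {"negative": 0.2, "low": 0.25, "moderate": 0.3, "high": 0.25},
        "poor_prognosis": {False: 0.7, True: 0.3},
        "brain_pattern": {"exclusive": 0.05, "shared": 0.6, "absent": 0.35},
        "lymphoid_pm_expressed": {False: 0.4, True: 0.6},
        "gamete_expressed": {False: 0.5, True: 0.5},
        "healthy_pm_index_level": {
            "none": 0.15, "low": 0.25, "moderate": 0.3, "high": 0.3},
    })

    def __post_init__(self) -> None:
        if self.panel_size < 1:
            raise ValueError("panel_size must be >= 1")
        for name, freq in self.frequencies.items():
            allowed = VOCABULARY[name]
            if set(freq) != set(allowed) or abs(sum(freq.values()) - 1.0) > 1e-9:
                raise ValueError(f"frequencies for {name} must cover {allowed} and sum to 1")


def simulate_annotations(
    params: AnnotationParams = AnnotationParams(), seed: int = 0
) -> list[AnnotationRecord]:
    """Random annotation panel with the planted maximal profile included once.

    The planted record replaces one slot, so the panel has exactly
    ``panel_size`` records (a panel of size 1 is the planted record alone).
    """
    rng = np.random.default_rng(seed)
    records = [AnnotationRecord(protein=params.planted_protein, **NUCLEOLIN_LIKE)]
    for k in range(params.panel_size - 1):
        values = {}
        for name, freq in params.frequencies.items():
            choices = list(freq)
            idx = rng.choice(len(choices), p=[freq[c] for c in choices])
            values[name] = choices[int(idx)]
        records.append(AnnotationRecord(protein=f"P{k:04d}", **values))
    return records


# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Bundle of all generator parameters plus the master seed."""

    seed: int = 0
    spectrum: SpectrumParams = SpectrumParams()
    id_tables: IdTableParams = IdTableParams()
    annotations: AnnotationParams = AnnotationParams()

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)
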