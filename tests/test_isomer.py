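"""Spectrum annotation and sialyl-Lewis A/X discrimination."""

import numpy as np
import pytest

from glycoseek.fragments import enumerate_fragments
from glycoseek.isomer import classify_sle_isomer, sle_diagnostics, sle_topology
from glycoseek.mass import PERMETHYLATED, mz, neutral_mass
from glycoseek.simulate import SpectrumParams, simulate_spectrum
from glycoseek.spectrum import PeakList, annotate_spectrum


@pytest.fixture(scope="module")
def slea_topology():
    return sle_topology("SLeA")


@pytest.fixture(scope="module")
def slea_precursor(slea_topology):
    return mz(neutral_mass(slea_topology, PERMETHYLATED))


class TestAnnotate:
    def test_theoretical_spectrum_fully_self_annotates(self, slea_topology):
        clean = simulate_spectrum(
            slea_topology, PERMETHYLATED,
            SpectrumParams(jitter_sd=0.0, n_noise_peaks=0), seed=0)
        table = annotate_spectrum(clean, slea_topology, PERMETHYLATED, tol_da=0.01)
        assert len(table) == len(clean.peaks)
        assert all(abs(a.error_da) < 1e-5 for a in table)

    def test_empty_peak_list_empty_table(self, slea_topology, slea_precursor):
        empty = PeakList(slea_precursor, ())
        assert annotate_spectrum(empty, slea_topology) == []

    def test_printed_ion_trap_readings_match_cross_ring_ions(
            self, slea_topology, slea_precursor):
        """Unit-resolution readings from the SLeA product-ion spectrum
        (815.6, 1061.9; 707.7 with benzyl loss) match cross-ring-containing
        fragments within the 0.8-Da figure accuracy."""
        peaks = PeakList.from_arrays(slea_precursor,
                                     [707.7, 815.6, 1061.9], [1e4] * 3)
        table = annotate_spectrum(peaks, slea_topology, PERMETHYLATED, tol_da=0.8)
        assert len(table) == 3
        for ann in table:
            assert "X" in ann.fragment.dc_label
            assert abs(ann.error_da) <= 0.8

    def test_noise_spectrum_matched_fraction_below_coverage_bound(
            self, slea_topology, slea_precursor):
        """Uniform-noise peaks match at most at the rate set by the m/z axis
        coverage of the +-tol fragment intervals (binomial, 3 SE)."""
        tol, lo, hi = 0.5, 150.0, slea_precursor + 50.0
        frags = enumerate_fragments(slea_topology, PERMETHYLATED, max_cleavages=2)
        centers = sorted({f.mz for f in frags if lo <= f.mz <= hi})
        covered = 0.0
        cur_lo = cur_hi = None
        for c in centers:
            if cur_hi is None or c - tol > cur_hi:
                if cur_hi is not None:
                    covered += cur_hi - cur_lo
                cur_lo, cur_hi = c - tol, c + tol
            else:
                cur_hi = c + tol
        covered += cur_hi - cur_lo
        p = covered / (hi - lo)
        rng = np.random.default_rng(1234)
        n_rep, n_peaks, matched = 300, 30, 0
        for _ in range(n_rep):
            noise = PeakList.from_arrays(
                slea_precursor, rng.uniform(lo, hi, n_peaks), np.ones(n_peaks))
            matched += len(annotate_spectrum(noise, slea_topology,
                                             PERMETHYLATED, tol_da=tol,
                                             fragments=frags))
        n = n_rep * n_peaks
        assert matched / n <= p + 3 * np.sqrt(p * (1 - p) / n)

    def test_bad_tolerance_rejected(self, slea_topology, slea_precursor):
        with pytest.raises(ValueError):
            annotate_spectrum(PeakList(slea_precursor, ()), slea_topology,
                              tol_da=0.0)


class TestClassify:
    def test_theoretical_spectra_self_recover(self):
        for iso in ("SLeA", "SLeX"):
            clean = simulate_spectrum(
                sle_topology(iso), PERMETHYLATED,
                SpectrumParams(jitter_sd=0.0, n_noise_peaks=0), seed=0)
            assert classify_sle_isomer(clean).verdict == iso

    def test_peak_at_653_9_defines_slex(self, slea_precursor):
        """The 653.9 ion (Z/3,5X at the epitope GlcNAc) is absent from the
        SLeA fragment set and flips the verdict to SLeX at the 0.8-Da
        figure accuracy."""
        diag = sle_diagnostics(PERMETHYLATED, 0.8)
        assert any(abs(f.mz - 653.9) <= 0.8 for f in diag["SLeX"])
        assert all(abs(f.mz - 653.9) > 0.8 for f in diag["SLeA"])
        # common ions: shared between both isomer sets, diagnostic of neither
        slea = {round(f.mz, 4) for f in enumerate_fragments(
            sle_topology("SLeA"), PERMETHYLATED, max_cleavages=2)}
        slex = {round(f.mz, 4) for f in enumerate_fragments(
            sle_topology("SLeX"), PERMETHYLATED, max_cleavages=2)}
        common = sorted(slea & slex)[:10]
        second = next(f.mz for f in diag["SLeX"] if abs(f.mz - 653.9) > 2.0)
        peaks = PeakList.from_arrays(
            slea_precursor, common + [653.9, second],
            np.ones(len(common) + 2))
        call = classify_sle_isomer(peaks, PERMETHYLATED, tol_da=0.8)
        assert call.verdict == "SLeX"
        assert any(abs(m.observed_mz - 653.9) < 1e-6
                   for m in call.matched_diagnostics)

    def test_equal_diagnostic_counts_undetermined(self, slea_precursor):
        diag = sle_diagnostics(PERMETHYLATED, 0.5)
        peaks = PeakList.from_arrays(
            slea_precursor,
            [diag["SLeA"][0].mz, diag["SLeA"][1].mz,
             diag["SLeX"][0].mz, diag["SLeX"][1].mz],
            np.ones(4))
        assert classify_sle_isomer(peaks).verdict == "undetermined"

    def test_below_min_diagnostics_undetermined(self, slea_precursor):
        diag = sle_diagnostics(PERMETHYLATED, 0.5)
        peaks = PeakList.from_arrays(slea_precursor, [diag["SLeA"][0].mz], [1.0])
        assert classify_sle_isomer(peaks, min_diagnostics=2).verdict == "undetermined"

    def test_inconsistent_precursor_rejected(self):
        peaks = PeakList.from_arrays(933.5, [219.1], [1.0])  # sialyl-T precursor
        with pytest.raises(ValueError, match="does not match"):
            classify_sle_isomer(peaks)

    def test_recovery_on_jittered_spectra_smoke(self):
        """20 + 20 seeded spectra at the study noise level recover their
        generating isomer with no cross-calls (full panel in acceptance)."""
        cross = 0
        correct = 0
        for iso in ("SLeA", "SLeX"):
            topo = sle_topology(iso)
            for seed in range(20):
                call = classify_sle_isomer(simulate_spectrum(topo, seed=seed))
                if call.verdict == iso:
                    correct += 1
                elif call.verdict != "undetermined":
                    cross += 1
        assert cross == 0
        assert correct >= 38
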