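#!/usr/bin/env python
"""Sialyl-Lewis A/X discrimination on synthetic ion-trap spectra.

Enumerates the diagnostic fragments separating the type-1 (SLeA) from the
type-2 (SLeX) chain on the m/z 1556.8 benzyl core-2 glycan, measures
classifier recovery on 200 simulated spectra per isomer (0.2-Da jitter, 20
noise peaks), and turns retention-time-resolved isomer calls into SLeA:SLeX
abundance fractions for cell-line-like mixtures.  Writes diagnostics,
recovery and fraction tables to results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from glycoseek.isomer import classify_sle_isomer, sle_diagnostics, sle_topology
from glycoseek.mass import PERMETHYLATED
from glycoseek.quant import isomer_fraction, xic_peak_area
from glycoseek.simulate import simulate_spectrum

RESULTS = Path(__file__).resolve().parent.parent / "results"
N_PER_ISOMER = 200

# SLeA fraction designs emulating the spread seen across gastric cancer
# lines: one balanced line and three SLeA-dominant lines (<10% SLeX).
MIXTURES = {"balanced": 0.5, "dominant_90": 0.9, "dominant_95": 0.95}


def recovery_table() -> pd.DataFrame:
    rows = []
    for iso in ("SLeA", "SLeX"):
        topo = sle_topology(iso)
        counts = {"SLeA": 0, "SLeX": 0, "undetermined": 0}
        for seed in range(1, N_PER_ISOMER + 1):
            call = classify_sle_isomer(simulate_spectrum(topo, seed=seed))
            counts[call.verdict] += 1
        rows.append({"true_isomer": iso, **counts,
                     "recovery": counts[iso] / N_PER_ISOMER})
    return pd.DataFrame(rows)


def fraction_table() -> pd.DataFrame:
    rng = np.random.default_rng(2020)
    t = np.linspace(0, 8, 400)
    rows = []
    for name, truth in MIXTURES.items():
        # two chromatographic peaks sharing m/z 1556.8 at distinct RT
        h = np.array([truth, 1 - truth]) * (1 + 0.05 * rng.normal(size=2))
        xics = [h[0] * np.exp(-((t - 2.5) ** 2) / 0.1),
                h[1] * np.exp(-((t - 6.0) ** 2) / 0.1)]
        areas = [xic_peak_area(t, x) for x in xics]
        calls = [classify_sle_isomer(
                     simulate_spectrum(sle_topology(iso),
                                       seed=len(rows) * 2 + k + 1))
                 for k, iso in enumerate(("SLeA", "SLeX"))]
        out = isomer_fraction(areas, calls)
        rows.append({"mixture": name, "designed_slea_fraction": truth,
                     "recovered_slea_fraction": round(out["SLeA"], 4),
                     "excluded_peaks": out["n_excluded"]})
    return pd.DataFrame(rows)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    diag = sle_diagnostics(PERMETHYLATED, tol_da=0.5)
    table = pd.DataFrame(
        {"isomer": iso, "label": f.dc_label, "mz": round(f.mz, 3)}
        for iso in ("SLeA", "SLeX") for f in diag[iso]
    )
    table.to_csv(RESULTS / "sle_diagnostic_ions.tsv", sep="\t", index=False)
    print(f"{len(diag['SLeA'])} SLeA-only and {len(diag['SLeX'])} SLeX-only "
          "diagnostic fragments at 0.5-Da tolerance")
    key = [f for f in diag["SLeX"] if abs(f.mz - 653.9) <= 0.8]
    print("SLeX-defining ion near the printed 653.9 reading:",
          ", ".join(f"{f.dc_label} at {f.mz:.2f}" for f in key))

    rec = recovery_table()
    rec.to_csv(RESULTS / "isomer_recovery.tsv", sep="\t", index=False)
    print("\nClassifier recovery on synthetic spectra "
          f"({N_PER_ISOMER} per isomer, jitter 0.2 Da, 20 noise peaks):")
    print(rec.to_string(index=False))

    frac = fraction_table()
    frac.to_csv(RESULTS / "isomer_fractions.tsv", sep="\t", index=False)
    print("\nSLeA fraction recovered from RT-resolved two-peak chromatograms:")
    print(frac.to_string(index=False))


if __name__ == "__main__":
    main()
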