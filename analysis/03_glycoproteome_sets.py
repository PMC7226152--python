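#!/usr/bin/env python
"""Set algebra over the simulated three-line glycoproteome experiment.

Simulates identification tables for three cell lines under two isolation
strategies (anti-SLeA immunoprecipitation and E-selectin pulldown) at the
study's scale, then reports: per-line strategy overlap (the ~60% dual-
identification rate), Venn region counts across cell lines, and the common
core under the evidence filters (confirmed SLeA O-glycopeptide, E-selectin
affinity) — the set the target score ranks downstream.
"""

import json
from pathlib import Path

import pandas as pd

from glycoseek.proteome import common_core, strategy_overlap, write_id_table
from glycoseek.simulate import IdTableParams, simulate_id_tables

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 42


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    params = IdTableParams()
    records, truth = simulate_id_tables(params, seed=SEED)
    write_id_table(records, RESULTS / "identifications.tsv")

    overlap = pd.DataFrame(strategy_overlap(records, line)
                           for line in params.cell_lines)
    overlap.to_csv(RESULTS / "strategy_overlap.tsv", sep="\t", index=False)
    print("Per-line overlap between SLeA-IP and E-selectin pulldown:")
    print(overlap.to_string(index=False))
    print("(design: ~60% of IP identifications shared with the pulldown)")

    summary = common_core(records, list(params.cell_lines),
                          require_sle_evidence=True, require_eselectin=True)
    regions = {"+".join(sorted(k)): v for k, v in summary.regions.items()}
    payload = {
        "cell_lines": list(params.cell_lines),
        "filters": {"require_sle_evidence": True, "require_eselectin": True},
        "n_common": len(summary.common),
        "common": list(summary.common),
        "regions": regions,
        "planted_core_recovered": list(summary.common) == sorted(truth["core"]),
    }
    (RESULTS / "venn_summary.json").write_text(json.dumps(payload, indent=2) + "\n")
    print(f"\nproteins passing both filters in all three lines: "
          f"{len(summary.common)} (planted core recovered: "
          f"{payload['planted_core_recovered']})")
    print("exclusive Venn regions:", regions)
    print(f"wrote {RESULTS / 'venn_summary.json'}")


if __name__ == "__main__":
    main()
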