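#!/usr/bin/env python
"""Screen QC and hit calling from the quantified feature table.

Reads results/screen_features.csv (written by 01_simulate_screen.py),
normalizes ratios to the stimulated controls, computes per-set Z' and
replicate reproducibility, and calls hits at the 40% percent-effect cutoff.
Writes results/screen_hits.csv and results/screen_qc.json.
"""

import json
from pathlib import Path

from maldiscreen import io, screen

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    quants = io.read_feature_table(RESULTS / "screen_features.csv")
    res = screen.analyze_screen(quants, cutoff=40.0)

    hits = res.effects.sort_values(ascending=False).rename("mean_percent_effect")
    hits.to_frame().assign(hit=hits.index.isin(res.hits)).to_csv(
        RESULTS / "screen_hits.csv"
    )
    qc = {
        "zprime_mean": res.zprime,
        "zprime_per_set": {str(k): v for k, v in res.per_set_zprime.items()},
        "replicate_r2_mean": res.replicate_r2,
        "replicate_r2_pairs": {f"{a}-{b}": v for (a, b), v in res.r2_pairs.items()},
        "cutoff_percent": res.cutoff,
        "hits": res.hits,
    }
    (RESULTS / "screen_qc.json").write_text(json.dumps(qc, indent=2))

    print(f"Z' (across-set mean): {res.zprime:.2f}  "
          f"replicate R^2 (mean of pairs): {res.replicate_r2:.2f}")
    print(f"hits at {res.cutoff:.0f}% cutoff: {res.hits} "
          f"(effects: {[round(res.effects[h], 1) for h in res.hits]})")


if __name__ == "__main__":
    main()
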