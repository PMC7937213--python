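#!/usr/bin/env python
"""One-shot pipeline run plus the recall-bias sensitivity comparison.

Runs the full analysis bundle (every estimator, pooled, per-timepoint,
subgroups) on the default scenario, then re-runs the anchor diagnostics
on the recall-biased scenario — where patients rate their current state
rather than their change — to show the signature that pattern leaves:
GRC-post correlations overtaking GRC-change correlations.

Writes results/report/ (all bundle tables + run metadata) and
results/recall_bias_comparison.csv.
"""

from pathlib import Path

import pandas as pd

from clinthresh.anchor import validate_anchor
from clinthresh.report import run_full_analysis
from clinthresh.simulate import generate_trial, get_scenario

SEED = 2026
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    bundle = run_full_analysis(scenario="fimpact-like", n_boot=1000, seed=SEED)
    bundle.write(OUT / "report")
    print(bundle.summary(digits=2))

    rows = []
    for scen in ("fimpact-like", "recall-biased"):
        table, _ = generate_trial(get_scenario(scen), seed=SEED)
        for inst in table.instruments:
            rep = validate_anchor(table, inst, n_boot=200, seed=SEED)
            rows.append(
                {
                    "scenario": scen,
                    "instrument": inst,
                    "rho_post": round(rep.rho_post.rho, 2),
                    "rho_change": round(rep.rho_change.rho, 2),
                    "post_exceeds_change": abs(rep.rho_post.rho)
                    > abs(rep.rho_change.rho),
                }
            )
    cmp_df = pd.DataFrame(rows)
    cmp_df.to_csv(OUT / "recall_bias_comparison.csv", index=False)
    print("\nRecall-bias comparison (anchor driven by change vs current state):")
    print(cmp_df.to_string(index=False))
    print("\nWhen the anchor tracks the current state (recall-biased), the "
          "post-score correlation overtakes the change correlation for every "
          "instrument — the pattern that flags recall bias in real data.")


if __name__ == "__main__":
    main()
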