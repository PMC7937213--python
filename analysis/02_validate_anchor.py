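#!/usr/bin/env python
"""Is the global-rating-of-change question an adequate anchor?

A transition anchor supports MID estimation only if it tracks the change
score: its Spearman correlation with change should be sizeable, its
correlation with the baseline near zero, and — when patients truly recall
change rather than rating their current state — larger than its
correlation with the post score.  This script computes those correlations
per instrument with 1000-replicate bootstrap CIs, flags inadequate
anchors, and writes results/anchor_validation.csv.
"""

from pathlib import Path

import pandas as pd

from clinthresh.anchor import validate_anchor
from clinthresh.data_model import compute_changes, load_table

SEED = 2026
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = compute_changes(load_table(OUT / "cohort.csv"))
    rows = []
    for inst in table.instruments:
        rep = validate_anchor(table, inst, n_boot=1000, seed=SEED)
        rows.append(
            {
                "instrument": inst,
                "rho_baseline": round(rep.rho_baseline.rho, 3),
                "rho_post": round(rep.rho_post.rho, 3),
                "rho_post_ci": f"({rep.rho_post.ci.ci_low:.2f}, {rep.rho_post.ci.ci_high:.2f})",
                "rho_change": round(rep.rho_change.rho, 3),
                "rho_change_ci": f"({rep.rho_change.ci.ci_low:.2f}, {rep.rho_change.ci.ci_high:.2f})",
                "n_pairs": rep.rho_change.n,
                "adequate": rep.flags["adequate_change_correlation"],
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "anchor_validation.csv", index=False)
    print(df.to_string(index=False))
    bad = df.loc[~df["adequate"], "instrument"].tolist()
    if bad:
        print(f"\nInadequate anchors (|rho_change| < 0.3): {', '.join(bad)} — "
              "their MID estimates should not be trusted.")


if __name__ == "__main__":
    main()
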