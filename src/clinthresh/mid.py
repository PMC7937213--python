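"""Minimal-important-difference estimators for improvement.

Three anchor-based methods against the 5-level GRC:

* ROC — dichotomize the anchor to improved (GRC 1-3) vs no change (GRC 4),
  drop worseners (GRC 5), sweep improvement-magnitude cutoffs and take the
  one closest to the top-left ROC corner.  The MID is the selected cutoff.
* MDoC — mean difference of improvement between the "somewhat satisfied"
  (GRC 3) and "dissatisfied" (GRC 4) groups, with a percentile-bootstrap CI.
* MC — mean improvement within the GRC 3 group, with a bootstrap CI.

All methods operate on improvement magnitudes (positive = better), so pain
and function instruments share one code path and MIDs print as positive
numbers.  MIDs for deterioration are not estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bootstrap import BootstrapCI, percentile_ci
from .data_model import AnchoredOutcomeTable, compute_changes
from .roc import (
    AUCEstimate,
    DegenerateInputError,
    RocDirection,
    auc_delong_ci,
    build_roc,
    select_closest_to_corner,
)

IMPROVED = "improved"
NOT_IMPROVED = "not_improved"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class MIDEstimate:
    instrument: str
    method: str  # "ROC" | "MDoC" | "MC"
    mid: float
    ci: BootstrapCI | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    auc_estimate: AUCEstimate | None = None
    n_improved: int = 0
    n_not_improved: int = 0
    n_excluded_worse: int = 0


def dichotomize_grc_for_mid(grc: int) -> str:
    """GRC 1-3 -> improved, 4 -> not improved, 5 -> excluded (worse)."""
    if grc not in (1, 2, 3, 4, 5):
        raise ValueError(f"GRC must be in 1..5, got {grc!r}")
    if grc <= 3:
        return IMPROVED
    return NOT_IMPROVED if grc == 4 else EXCLUDED


def _mid_frame(table: AnchoredOutcomeTable, instrument: str) -> pd.DataFrame:
    """Complete (improvement, GRC) pairs for one instrument."""
    if not table.has_changes:
        table = compute_changes(table)
    d = table.for_instrument(instrument).data
    ok = d["grc"].notna() & d["improvement_magnitude"].notna()
    return d.loc[ok, ["patient_id", "improvement_magnitude", "grc"]].reset_index(drop=True)


def estimate_mid_roc(table: AnchoredOutcomeTable, instrument: str) -> MIDEstimate:
    """ROC-method MID: closest-to-corner cutoff on improvement magnitude."""
    d = _mid_frame(table, instrument)
    status = d["grc"].astype(int).map(dichotomize_grc_for_mid)
    n_excluded = int((status == EXCLUDED).sum())
    d = d.loc[status != EXCLUDED]
    labels = (status.loc[d.index] == IMPROVED).to_numpy()
    n_imp, n_not = int(labels.sum()), int((~labels).sum())
    if n_imp == 0 or n_not == 0:
        which = "improved" if n_imp == 0 else "not-improved"
        raise DegenerateInputError(
            f"{instrument}: the {which} class is empty after dichotomization"
        )
    scores = d["improvement_magnitude"].to_numpy()
    curve = build_roc(scores, labels, RocDirection.HIGHER_PREDICTS_POSITIVE)
    sel = select_closest_to_corner(curve)
    auc_est = auc_delong_ci(scores, labels, RocDirection.HIGHER_PREDICTS_POSITIVE)
    return MIDEstimate(
        instrument=instrument,
        method="ROC",
        mid=sel.cutoff,
        sensitivity=sel.sensitivity,
        specificity=sel.specificity,
        auc_estimate=auc_est,
        n_improved=n_imp,
        n_not_improved=n_not,
        n_excluded_worse=n_excluded,
    )


def _group_improvements(d: pd.DataFrame, grc_level: int) -> np.ndarray:
    return d.loc[d["grc"] == grc_level, "improvement_magnitude"].to_numpy()


def estimate_mid_mdoc(
    table: AnchoredOutcomeTable,
    instrument: str,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MIDEstimate:
    """Mean difference of change: mean(GRC 3) - mean(GRC 4) improvement."""
    d = _mid_frame(table, instrument)
    g3, g4 = _group_improvements(d, 3), _group_improvements(d, 4)
    if g3.size == 0 or g4.size == 0:
        raise DegenerateInputError(
            f"{instrument}: GRC group {'3' if g3.size == 0 else '4'} is empty"
        )

    sub = d.loc[d["grc"].isin([3, 4])].reset_index(drop=True)

    def stat(frame: pd.DataFrame) -> float:
        a = frame.loc[frame["grc"] == 3, "improvement_magnitude"]
        b = frame.loc[frame["grc"] == 4, "improvement_magnitude"]
        if a.empty or b.empty:
            return np.nan
        return float(a.mean() - b.mean())

    ci = percentile_ci(sub, stat, n_boot=n_boot, seed=seed)
    return MIDEstimate(
        instrument=instrument,
        method="MDoC",
        mid=ci.estimate,
        ci=ci,
        n_improved=int(g3.size),
        n_not_improved=int(g4.size),
    )


def estimate_mid_mc(
    table: AnchoredOutcomeTable,
    instrument: str,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MIDEstimate:
    """Mean change: mean improvement among the 'somewhat satisfied' (GRC 3)."""
    d = _mid_frame(table, instrument)
    g3 = _group_improvements(d, 3)
    if g3.size == 0:
        raise DegenerateInputError(f"{instrument}: GRC group 3 is empty")
    ci = percentile_ci(g3, lambda v: float(np.mean(v)), n_boot=n_boot, seed=seed)
    return MIDEstimate(
        instrument=instrument,
        method="MC",
        mid=ci.estimate,
        ci=ci,
        n_improved=int(g3.size),
    )
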