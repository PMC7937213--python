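"""Patient-acceptable-symptom-state (PASS) estimators.

PASS is a threshold on the follow-up (post) score, not the change: the
highest symptom level at which patients consider themselves well.  Two
anchor dichotomizations are supported — "satisfied" means GRC 1 only
(conservative: shoulder healed completely) or GRC 1-2 — and two methods:

* ROC — sweep post-score cutoffs (lower-predicts-satisfied for pain,
  higher for function instruments) and take the closest-to-corner point.
* percentile — the 75th percentile of satisfied patients' post scores for
  pain instruments, the 25th for function instruments; quantiles by linear
  interpolation between order statistics.

Worseners stay in the "rest" class; nobody is excluded for PASS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import AnchoredOutcomeTable
from .roc import (
    AUCEstimate,
    DegenerateInputError,
    RocDirection,
    auc_delong_ci,
    build_roc,
    select_closest_to_corner,
)


@dataclass(frozen=True)
class PassAnchorDef:
    """Which GRC responses count as 'satisfied': exactly {1} or {1, 2}."""

    satisfied_set: frozenset

    def __post_init__(self) -> None:
        s = frozenset(self.satisfied_set)
        if s not in (frozenset({1}), frozenset({1, 2})):
            raise ValueError(f"satisfied_set must be {{1}} or {{1,2}}, got {set(s)}")
        object.__setattr__(self, "satisfied_set", s)

    @property
    def label(self) -> str:
        return "GRC 1" if self.satisfied_set == frozenset({1}) else "GRC 1+2"


ANCHOR_GRC1 = PassAnchorDef(frozenset({1}))
ANCHOR_GRC12 = PassAnchorDef(frozenset({1, 2}))


@dataclass(frozen=True)
class PASSEstimate:
    instrument: str
    anchor: PassAnchorDef
    method: str  # "ROC" | "percentile"
    pass_threshold: float
    sensitivity: float | None = None
    specificity: float | None = None
    auc_estimate: AUCEstimate | None = None
    n_satisfied: int = 0
    n_rest: int = 0
    #: the "well" region: post <= threshold for pain, >= for function
    well_if_at_most: bool = True


def dichotomize_grc_for_pass(grc: int, anchor: PassAnchorDef) -> bool:
    """True when the response falls in the anchor's satisfied set."""
    if grc not in (1, 2, 3, 4, 5):
        raise ValueError(f"GRC must be in 1..5, got {grc!r}")
    return grc in anchor.satisfied_set


def _pass_frame(table: AnchoredOutcomeTable, instrument: str) -> pd.DataFrame:
    d = table.for_instrument(instrument).data
    ok = d["grc"].notna() & d["post_score"].notna()
    return d.loc[ok, ["patient_id", "post_score", "grc"]].reset_index(drop=True)


def estimate_pass_roc(
    table: AnchoredOutcomeTable, instrument: str, anchor: PassAnchorDef = ANCHOR_GRC1
) -> PASSEstimate:
    """ROC-method PASS on post scores with the closest-to-corner cutoff."""
    spec = table.instruments[instrument]
    d = _pass_frame(table, instrument)
    labels = d["grc"].astype(int).map(lambda g: dichotomize_grc_for_pass(g, anchor)).to_numpy()
    n_sat, n_rest = int(labels.sum()), int((~labels).sum())
    if n_sat == 0 or n_rest == 0:
        which = "satisfied" if n_sat == 0 else "rest"
        raise DegenerateInputError(f"{instrument}: the {which} class is empty")
    direction = (
        RocDirection.HIGHER_PREDICTS_POSITIVE
        if spec.increase_is_better
        else RocDirection.LOWER_PREDICTS_POSITIVE
    )
    scores = d["post_score"].to_numpy()
    curve = build_roc(scores, labels, direction)
    sel = select_closest_to_corner(curve)
    auc_est = auc_delong_ci(scores, labels, direction)
    return PASSEstimate(
        instrument=instrument,
        anchor=anchor,
        method="ROC",
        pass_threshold=sel.cutoff,
        sensitivity=sel.sensitivity,
        specificity=sel.specificity,
        auc_estimate=auc_est,
        n_satisfied=n_sat,
        n_rest=n_rest,
        well_if_at_most=not spec.increase_is_better,
    )


def estimate_pass_percentile(
    table: AnchoredOutcomeTable, instrument: str, anchor: PassAnchorDef = ANCHOR_GRC1
) -> PASSEstimate:
    """Percentile-method PASS: 75th (pain) / 25th (function) percentile of
    the satisfied group's post scores."""
    spec = table.instruments[instrument]
    d = _pass_frame(table, instrument)
    sat_mask = d["grc"].astype(int).map(lambda g: dichotomize_grc_for_pass(g, anchor))
    sat = d.loc[sat_mask, "post_score"].to_numpy()
    if sat.size == 0:
        raise DegenerateInputError(f"{instrument}: satisfied group is empty")
    q = 0.25 if spec.increase_is_better else 0.75
    threshold = float(np.quantile(sat, q))  # linear interpolation
    return PASSEstimate(
        instrument=instrument,
        anchor=anchor,
        method="percentile",
        pass_threshold=threshold,
        n_satisfied=int(sat.size),
        n_rest=int((~sat_mask).sum()),
        well_if_at_most=not spec.increase_is_better,
    )
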