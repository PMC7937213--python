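"""Anchor-adequacy diagnostics for the GRC transition question.

A usable transition anchor should correlate with the change score; its
correlation with the baseline should be near zero, and a larger
correlation with the post score than with the change is the signature of
recall bias (patients rating how they feel now, not how much they
changed).  This module computes Spearman correlations of the GRC with
baseline, post and change scores, with percentile-bootstrap CIs, and sets
qualitative adequacy flags.

Sign convention: the GRC is coded 1 = best ... 5 = worst, so we correlate
the reversed satisfaction score (6 - GRC, larger = more satisfied).  In
the default "aligned" mode outcome values are also oriented so that larger
= better (improvement magnitudes; post/baseline negated for pain), making
an informative anchor correlate positively everywhere.  The "paper-sign"
mode keeps raw signed scores, reproducing the sign pattern trial reports
print (negative correlations for pain instruments).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bootstrap import BootstrapCI, percentile_ci
from .data_model import AnchoredOutcomeTable, compute_changes


@dataclass(frozen=True)
class CorrelationEstimate:
    pair: str
    rho: float
    ci: BootstrapCI | None
    n: int


@dataclass
class AnchorValidationReport:
    instrument: str
    rho_baseline: CorrelationEstimate
    rho_post: CorrelationEstimate
    rho_change: CorrelationEstimate
    adequacy_threshold: float
    baseline_threshold: float
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.flags = {
            "near_zero_baseline": abs(self.rho_baseline.rho) < self.baseline_threshold
            if not np.isnan(self.rho_baseline.rho)
            else False,
            "change_exceeds_post": abs(self.rho_change.rho) > abs(self.rho_post.rho),
            "adequate_change_correlation": abs(self.rho_change.rho)
            >= self.adequacy_threshold,
        }

    @property
    def mid_reliable(self) -> bool:
        """False flags the pain-at-rest failure mode: MID untrustworthy."""
        return self.flags["adequate_change_correlation"]


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN when either vector is constant (undefined ranks spread).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def _corr_with_ci(
    frame: pd.DataFrame,
    value_col: str,
    pair: str,
    n_boot: int,
    seed: int | None,
) -> CorrelationEstimate:
    sub = frame.dropna(subset=["satisfaction", value_col])
    n = len(sub)
    if n < 3:
        return CorrelationEstimate(pair, float("nan"), None, n)
    ci = percentile_ci(
        sub[["satisfaction", value_col]],
        lambda f: spearman_rho(f["satisfaction"], f[value_col]),
        n_boot=n_boot,
        seed=seed,
    )
    return CorrelationEstimate(pair, ci.estimate, ci, n)


def validate_anchor(
    table: AnchoredOutcomeTable,
    instrument: str,
    adequacy_threshold: float = 0.3,
    baseline_threshold: float = 0.2,
    n_boot: int = 1000,
    seed: int | None = None,
    sign_mode: str = "aligned",
) -> AnchorValidationReport:
    """Correlate the anchor with baseline, post and change for one instrument.

    ``sign_mode='aligned'`` orients outcomes so larger = better;
    ``'paper'`` keeps raw signed scores (pain correlations come out
    negative).  ``adequacy_threshold`` applies to |rho_change|.
    """
    if sign_mode not in ("aligned", "paper"):
        raise ValueError("sign_mode must be 'aligned' or 'paper'")
    if not table.has_changes:
        table = compute_changes(table)
    spec = table.instruments[instrument]
    d = table.for_instrument(instrument).data.copy()
    d["satisfaction"] = 6 - d["grc"]

    if sign_mode == "aligned":
        flip = 1.0 if spec.increase_is_better else -1.0
        d["baseline_v"] = flip * d["baseline_score"]
        d["post_v"] = flip * d["post_score"]
        d["change_v"] = d["improvement_magnitude"]
    else:
        d["baseline_v"] = d["baseline_score"]
        d["post_v"] = d["post_score"]
        d["change_v"] = d["change_score"]

    # derive distinct bootstrap streams per correlation from one seed
    seeds = (
        [None] * 3
        if seed is None
        else list(np.random.SeedSequence(seed).generate_state(3) % (2**31 - 1))
    )
    rb = _corr_with_ci(d, "baseline_v", "grc_vs_baseline", n_boot, seeds[0])
    rp = _corr_with_ci(d, "post_v", "grc_vs_post", n_boot, seeds[1])
    rc = _corr_with_ci(d, "change_v", "grc_vs_change", n_boot, seeds[2])
    return AnchorValidationReport(
        instrument=instrument,
        rho_baseline=rb,
        rho_post=rp,
        rho_change=rc,
        adequacy_threshold=adequacy_threshold,
        baseline_threshold=baseline_threshold,
    )
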