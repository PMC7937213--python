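"""ROC engine: cutoff sweep, closest-to-corner selection, AUC, DeLong CI.

Candidate cutoffs are the midpoints between consecutive distinct observed
scores, plus one sentinel below the minimum and one above the maximum.
Midpoints are what produce non-observed thresholds such as 1.5 on an
integer-valued 0-12 instrument.  The AUC is the Mann-Whitney probability
that a random positive outscores a random negative (ties count 1/2); its
confidence interval uses DeLong's structural-components variance with a
Wald interval on the AUC scale, clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats


class RocDirection(str, Enum):
    HIGHER_PREDICTS_POSITIVE = "higher_score_predicts_positive"
    LOWER_PREDICTS_POSITIVE = "lower_score_predicts_positive"


class DegenerateInputError(ValueError):
    """Both classes must be represented (and large enough where stated)."""


@dataclass(frozen=True)
class ROCPoint:
    cutoff: float
    sensitivity: float
    specificity: float

    @property
    def distance_to_corner(self) -> float:
        return float(np.hypot(1.0 - self.sensitivity, 1.0 - self.specificity))


@dataclass
class ROCCurve:
    points: list[ROCPoint]
    n_positive: int
    n_negative: int
    direction: RocDirection


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float
    distance_to_corner: float


@dataclass(frozen=True)
class AUCEstimate:
    auc: float
    ci_low: float
    ci_high: float
    level: float
    variance: float


def _check_classes(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError(
            f"need both classes: n_positive={n_pos}, n_negative={n_neg}"
        )
    return n_pos, n_neg


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    return s, y


def candidate_cutoffs(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct scores plus two sentinels."""
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    lo, hi = u[0] - 1.0, u[-1] + 1.0
    return np.concatenate([[lo], mids, [hi]])


def build_roc(scores, labels, direction: RocDirection) -> ROCCurve:
    """Sweep candidate cutoffs and record (sensitivity, specificity).

    With ``HIGHER_PREDICTS_POSITIVE`` a subject is called positive when its
    score exceeds the cutoff; with ``LOWER_PREDICTS_POSITIVE`` when the
    score is below it.  No observed score ever equals a midpoint cutoff,
    so strict inequalities are unambiguous.
    """
    s, y = _as_arrays(scores, labels)
    n_pos, n_neg = _check_classes(y)
    direction = RocDirection(direction)

    cuts = candidate_cutoffs(s)
    pos, neg = np.sort(s[y]), np.sort(s[~y])
    if direction is RocDirection.HIGHER_PREDICTS_POSITIVE:
        tp = n_pos - np.searchsorted(pos, cuts, side="right")  # pos > c
        tn = np.searchsorted(neg, cuts, side="right")  # neg <= c
    else:
        tp = np.searchsorted(pos, cuts, side="left")  # pos < c
        tn = n_neg - np.searchsorted(neg, cuts, side="left")  # neg >= c
    points = [
        ROCPoint(float(c), t / n_pos, n / n_neg)
        for c, t, n in zip(cuts, tp, tn)
    ]
    return ROCCurve(points, n_pos, n_neg, direction)


def select_closest_to_corner(curve: ROCCurve) -> CutoffResult:
    """Cutoff minimizing Euclidean distance to the (1, 1) corner.

    Ties break toward higher sensitivity, then higher specificity, then
    the smaller cutoff value.
    """
    best = min(
        curve.points,
        key=lambda p: (p.distance_to_corner, -p.sensitivity, -p.specificity, p.cutoff),
    )
    return CutoffResult(
        best.cutoff, best.sensitivity, best.specificity, best.distance_to_corner
    )


def auc(scores, labels, direction: RocDirection = RocDirection.HIGHER_PREDICTS_POSITIVE) -> float:
    """Mann-Whitney AUC: fraction of correctly ordered (pos, neg) pairs."""
    s, y = _as_arrays(scores, labels)
    n_pos, n_neg = _check_classes(y)
    if RocDirection(direction) is RocDirection.LOWER_PREDICTS_POSITIVE:
        s = -s
    # midranks give the tie-corrected U statistic
    r = stats.rankdata(s)
    u = r[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _placement_values(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components for each observation.

    ``v10[i]`` is the fraction of negatives that positive i beats (ties
    1/2); ``v01[j]`` the fraction of positives beating negative j.
    Computed from midranks in O(n log n): the combined midrank of a
    positive minus its within-class midrank counts the negatives below it.
    """
    m, n = pos.size, neg.size
    both = np.concatenate([pos, neg])
    r_all = stats.rankdata(both)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return v10, v01


def auc_delong_ci(
    scores,
    labels,
    direction: RocDirection = RocDirection.HIGHER_PREDICTS_POSITIVE,
    level: float = 0.95,
) -> AUCEstimate:
    """DeLong variance and Wald interval for the nonparametric AUC."""
    s, y = _as_arrays(scores, labels)
    n_pos, n_neg = _check_classes(y)
    if n_pos < 2 or n_neg < 2:
        raise DegenerateInputError(
            "DeLong variance needs at least 2 observations per class"
        )
    if RocDirection(direction) is RocDirection.LOWER_PREDICTS_POSITIVE:
        s = -s
    v10, v01 = _placement_values(s[y], s[~y])
    theta = float(v10.mean())
    var = float(np.var(v10, ddof=1) / n_pos + np.var(v01, ddof=1) / n_neg)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return AUCEstimate(
        auc=theta,
        ci_low=float(np.clip(theta - half, 0.0, 1.0)),
        ci_high=float(np.clip(theta + half, 0.0, 1.0)),
        level=level,
        variance=var,
    )
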