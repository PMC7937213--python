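"""Percentile bootstrap confidence intervals for table statistics.

The default resampling unit is the row (a GRC-outcome pair), matching
pooled analyses where each patient contributes one pair per timepoint;
patient-level resampling is available as a sensitivity option.  Intervals
are empirical percentiles of the replicate distribution (linear
interpolation between order statistics, the same quantile rule used
throughout the package).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd


class BootstrapFailure(RuntimeError):
    """Statistic undefined on more than half of the replicates."""


@dataclass(frozen=True)
class BootstrapCI:
    estimate: float
    ci_low: float
    ci_high: float
    n_boot: int
    level: float
    seed: int | None
    resampling_unit: str
    n_dropped: int = 0  # replicates where the statistic was undefined


def _resample_rows(data, rng: np.random.Generator):
    n = len(data)
    idx = rng.integers(0, n, size=n)
    if isinstance(data, pd.DataFrame):
        return data.iloc[idx]
    return np.asarray(data)[idx]


def _resample_patients(data: pd.DataFrame, rng: np.random.Generator, patient_col: str):
    ids = data[patient_col].unique()
    take = rng.choice(ids, size=len(ids), replace=True)
    groups = {pid: g for pid, g in data.groupby(patient_col, sort=False)}
    return pd.concat([groups[pid] for pid in take], ignore_index=True)


def percentile_ci(
    data,
    statistic: Callable[[object], float],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    unit: str = "row",
    patient_col: str = "patient_id",
) -> BootstrapCI:
    """Percentile bootstrap CI for ``statistic(data)``.

    ``data`` may be a DataFrame or an array-like; ``unit`` is ``"row"`` or
    ``"patient"`` (DataFrame only).  Replicates where the statistic raises
    or returns NaN are dropped and counted; if more than half are dropped
    the interval is refused.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    point = float(statistic(data))
    rng = np.random.default_rng(seed)

    reps = np.empty(n_boot)
    dropped = 0
    for b in range(n_boot):
        if unit == "row":
            sample = _resample_rows(data, rng)
        elif unit == "patient":
            sample = _resample_patients(data, rng, patient_col)
        else:
            raise ValueError(f"unknown resampling unit {unit!r}")
        try:
            val = float(statistic(sample))
        except Exception:
            val = np.nan
        reps[b] = val
        if np.isnan(val):
            dropped += 1

    if dropped > n_boot / 2:
        raise BootstrapFailure(
            f"statistic undefined on {dropped}/{n_boot} bootstrap replicates"
        )
    good = reps[~np.isnan(reps)]
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(good, [alpha, 1.0 - alpha])
    return BootstrapCI(
        estimate=point,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        level=level,
        seed=seed,
        resampling_unit=unit,
        n_dropped=dropped,
    )
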