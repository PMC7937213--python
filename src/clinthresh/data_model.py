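"""Long-format data contract for anchored outcome analyses.

One row per patient x timepoint x instrument, carrying the baseline score,
the follow-up (post) score, and the 5-level global-rating-of-change (GRC)
anchor (1 = very satisfied / healed ... 5 = worse).  All estimators consume
this table after change-score computation and pairwise deletion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GRC_LEVELS = (1, 2, 3, 4, 5)

#: canonical column names of the long-format table
COLUMNS = (
    "patient_id",
    "group",
    "timepoint",
    "instrument",
    "baseline_score",
    "post_score",
    "grc",
)


class Direction(str, Enum):
    """Which way an instrument's scale points."""

    DECREASE_IS_BETTER = "decrease_is_better"  # pain VAS
    INCREASE_IS_BETTER = "increase_is_better"  # Constant-Murley, SST


@dataclass(frozen=True)
class InstrumentSpec:
    """Scale and orientation of one outcome instrument."""

    name: str
    scale_min: float
    scale_max: float
    direction: Direction
    integer_valued: bool = False

    def __post_init__(self) -> None:
        if not self.scale_min < self.scale_max:
            raise ValueError(
                f"{self.name}: scale_min must be < scale_max "
                f"({self.scale_min} >= {self.scale_max})"
            )

    @property
    def increase_is_better(self) -> bool:
        return self.direction is Direction.INCREASE_IS_BETTER

    def in_bounds(self, values: np.ndarray) -> np.ndarray:
        """Elementwise bound check; NaN counts as in-bounds (missing)."""
        v = np.asarray(values, dtype=float)
        ok = (v >= self.scale_min) & (v <= self.scale_max)
        return ok | np.isnan(v)


#: the four shoulder instruments of the subacromial-pain study design
DEFAULT_INSTRUMENTS: dict[str, InstrumentSpec] = {
    "pain_rest": InstrumentSpec("pain_rest", 0, 100, Direction.DECREASE_IS_BETTER),
    "pain_activity": InstrumentSpec("pain_activity", 0, 100, Direction.DECREASE_IS_BETTER),
    "cs": InstrumentSpec("cs", 0, 100, Direction.INCREASE_IS_BETTER),
    "sst": InstrumentSpec("sst", 0, 12, Direction.INCREASE_IS_BETTER, integer_valued=True),
}

INSTRUMENT_LABELS = {
    "pain_rest": "Pain at rest (VAS 0-100)",
    "pain_activity": "Pain on arm activity (VAS 0-100)",
    "cs": "Constant-Murley score (0-100)",
    "sst": "Simple Shoulder Test (0-12)",
}


class ValidationError(ValueError):
    """Raised when input rows violate the data contract.

    Carries ``rows``: the offending 0-based row indices of the source table.
    """

    def __init__(self, message: str, rows: Sequence[int] = ()):  # noqa: D107
        super().__init__(message)
        self.rows = list(rows)


class ConfigurationError(ValueError):
    """Raised for schema-level problems (missing mapped columns etc.)."""


@dataclass
class AnchoredOutcomeTable:
    """Validated long-format table plus its instrument specs.

    ``data`` always has the canonical :data:`COLUMNS`; after
    :func:`compute_changes` it additionally has ``change_score`` (post -
    baseline, signed) and ``improvement_magnitude`` (positive = improvement
    in the instrument's own direction).
    """

    data: pd.DataFrame
    instruments: Mapping[str, InstrumentSpec] = field(
        default_factory=lambda: dict(DEFAULT_INSTRUMENTS)
    )

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        _validate(self.data, self.instruments)

    # -- convenience ----------------------------------------------------
    @property
    def has_changes(self) -> bool:
        return "improvement_magnitude" in self.data.columns

    def subset(self, mask) -> "AnchoredOutcomeTable":
        return replace(self, data=self.data.loc[mask].reset_index(drop=True))

    def for_instrument(self, instrument: str) -> "AnchoredOutcomeTable":
        if instrument not in self.instruments:
            raise KeyError(f"unknown instrument {instrument!r}")
        return self.subset(self.data["instrument"] == instrument)

    def for_groups(self, groups: Iterable[str]) -> "AnchoredOutcomeTable":
        return self.subset(self.data["group"].isin(list(groups)))

    def timepoints(self) -> list:
        return sorted(self.data["timepoint"].unique().tolist())

    def pair_counts(self, score_col: str = "post_score") -> pd.DataFrame:
        """Analysis-ready pair counts per instrument x timepoint.

        A pair is a row where both the GRC and the required score are
        present (pairwise deletion).  Mirrors the unequal-N bookkeeping a
        trial report prints for each outcome and follow-up.
        """
        d = self.data
        ok = d["grc"].notna() & d[score_col].notna()
        if score_col != "baseline_score":
            ok &= d["baseline_score"].notna()
        counts = (
            d.loc[ok]
            .groupby(["instrument", "timepoint"], sort=True)
            .size()
            .unstack("timepoint", fill_value=0)
        )
        counts = counts.reindex(list(self.instruments), fill_value=0)
        counts["combined"] = counts.sum(axis=1)
        return counts


def _validate(df: pd.DataFrame, instruments: Mapping[str, InstrumentSpec]) -> None:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"table lacks required columns: {missing}")

    bad_rows: list[int] = []
    problems: list[str] = []

    grc = pd.to_numeric(df["grc"], errors="coerce")
    present = df["grc"].notna()
    bad_grc = present & (~grc.isin(GRC_LEVELS) | (grc != grc.round()))
    if bad_grc.any():
        idx = df.index[bad_grc].tolist()
        bad_rows += idx
        problems.append(f"GRC outside 1..5 at rows {idx}")

    for name, spec in instruments.items():
        sub = df[df["instrument"] == name]
        for col in ("baseline_score", "post_score"):
            vals = pd.to_numeric(sub[col], errors="coerce")
            # non-numeric strings become NaN; distinguish from truly missing
            coerced_bad = sub[col].notna() & vals.isna()
            out = ~spec.in_bounds(vals.to_numpy())
            bad = coerced_bad | pd.Series(out, index=sub.index)
            if bad.any():
                idx = sub.index[bad].tolist()
                bad_rows += idx
                problems.append(f"{name}.{col} out of [{spec.scale_min}, {spec.scale_max}] or non-numeric at rows {idx}")

    dup = df.duplicated(subset=["patient_id", "timepoint", "instrument"], keep=False)
    if dup.any():
        idx = df.index[dup].tolist()
        bad_rows += idx
        problems.append(f"duplicate (patient, timepoint, instrument) keys at rows {idx}")

    unknown = ~df["instrument"].isin(list(instruments))
    if unknown.any():
        idx = df.index[unknown].tolist()
        bad_rows += idx
        problems.append(f"unknown instruments at rows {idx}")

    if problems:
        raise ValidationError("; ".join(problems), rows=sorted(set(bad_rows)))


def load_table(
    path,
    schema: Mapping[str, str] | None = None,
    instruments: Mapping[str, InstrumentSpec] | None = None,
) -> AnchoredOutcomeTable:
    """Read a long-format CSV into a validated table.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    schema
        Optional mapping from canonical column name to the column name used
        in the file, e.g. ``{"patient_id": "id"}``.  Unmapped canonical
        names are assumed to appear verbatim.
    instruments
        Instrument specs keyed by the names used in the ``instrument``
        column; defaults to the four shoulder instruments.
    """
    raw = pd.read_csv(path)
    schema = dict(schema or {})
    rename = {schema.get(c, c): c for c in COLUMNS}
    missing = [src for src in rename if src not in raw.columns]
    if missing:
        raise ConfigurationError(f"mapped columns not found in file: {missing}")
    df = raw.rename(columns=rename)[list(COLUMNS)].copy()
    # coerce with diagnostics: flag rows whose raw cell was non-empty but not numeric
    src_cols = {c: schema.get(c, c) for c in COLUMNS}
    bad_rows = []
    for col in ("baseline_score", "post_score", "grc"):
        rawcol = raw[src_cols[col]]
        nonempty = rawcol.notna() & (rawcol.astype(str).str.strip() != "")
        numeric = pd.to_numeric(rawcol, errors="coerce")
        bad = nonempty & numeric.isna()
        if bad.any():
            bad_rows += raw.index[bad].tolist()
        df[col] = numeric
    if bad_rows:
        raise ValidationError(
            f"non-numeric values in score/GRC columns at rows {sorted(set(bad_rows))}",
            rows=sorted(set(bad_rows)),
        )
    return AnchoredOutcomeTable(df, dict(instruments or DEFAULT_INSTRUMENTS))


def compute_changes(table: AnchoredOutcomeTable) -> AnchoredOutcomeTable:
    """Attach change scores and improvement magnitudes.

    ``change_score = post - baseline`` (signed, instrument scale);
    ``improvement_magnitude`` flips the sign for decrease-is-better
    instruments so that positive always means the patient got better.
    Rows missing either score get a missing change.  Idempotent.
    """
    df = table.data.copy()
    df["change_score"] = df["post_score"] - df["baseline_score"]
    sign = df["instrument"].map(
        lambda n: 1.0 if table.instruments[n].increase_is_better else -1.0
    )
    df["improvement_magnitude"] = df["change_score"] * sign
    return replace(table, data=df)


def pool_timepoints(
    table: AnchoredOutcomeTable, timepoints: Sequence | None = None
) -> AnchoredOutcomeTable:
    """Restrict to (or keep all of) the requested follow-up timepoints.

    Pooling concatenates rows: a patient contributes one GRC-outcome pair
    per timepoint, and the pooled analyses treat those pairs as the unit of
    analysis (no clustering collapse).
    """
    if timepoints is None:
        return table
    timepoints = list(timepoints)
    if not timepoints:
        raise ValueError("timepoints must be nonempty")
    known = set(table.data["timepoint"].unique().tolist())
    unknown = [t for t in timepoints if t not in known]
    if unknown:
        raise ValueError(f"unknown timepoints {unknown}; table has {sorted(known)}")
    return table.subset(table.data["timepoint"].isin(timepoints))
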