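import numpy as np
import pandas as pd
import pytest

from clinthresh.data_model import (
    AnchoredOutcomeTable,
    ConfigurationError,
    ValidationError,
    compute_changes,
    load_table,
    pool_timepoints,
)
from conftest import make_table


def _write_csv(tmp_path, df, name="cohort.csv"):
    p = tmp_path / name
    df.to_csv(p, index=False)
    return p


def _rows(n=10, inst="pain_activity", tp=6):
    return pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "group": "ASD",
            "timepoint": tp,
            "instrument": inst,
            "baseline_score": 60.0,
            "post_score": 30.0,
            "grc": 2,
        }
    )


class TestLoadTable:
    def test_wellformed_csv_loads_identically(self, tmp_path):
        path = _write_csv(tmp_path, _rows(10))
        table = load_table(path)
        assert len(table.data) == 10
        assert table.data["post_score"].eq(30.0).all()

    def test_schema_mapping_renames_columns(self, tmp_path):
        df = _rows(5).rename(columns={"patient_id": "id", "grc": "anchor"})
        path = _write_csv(tmp_path, df)
        table = load_table(path, schema={"patient_id": "id", "grc": "anchor"})
        assert len(table.data) == 5

    def test_missing_mapped_column_is_configuration_error(self, tmp_path):
        path = _write_csv(tmp_path, _rows(3).drop(columns=["grc"]))
        with pytest.raises(ConfigurationError):
            load_table(path)

    def test_out_of_domain_grc_names_the_row(self, tmp_path):
        df = _rows(4)
        df.loc[2, "grc"] = 7
        with pytest.raises(ValidationError) as exc:
            load_table(_write_csv(tmp_path, df))
        assert 2 in exc.value.rows

    def test_score_beyond_scale_rejected(self, tmp_path):
        df = _rows(3)
        df.loc[1, "post_score"] = 130.0
        with pytest.raises(ValidationError) as exc:
            load_table(_write_csv(tmp_path, df))
        assert 1 in exc.value.rows

    def test_non_numeric_score_rejected_with_row(self, tmp_path):
        df = _rows(3).astype({"post_score": object})
        df.loc[1, "post_score"] = "forty"
        with pytest.raises(ValidationError) as exc:
            load_table(_write_csv(tmp_path, df))
        assert 1 in exc.value.rows

    def test_missing_post_score_is_accepted(self, tmp_path):
        df = _rows(3)
        df.loc[0, "post_score"] = np.nan
        table = load_table(_write_csv(tmp_path, df))
        assert len(table.data) == 3
        assert table.pair_counts().loc["pain_activity", "combined"] == 2

    def test_duplicate_key_rejected(self, tmp_path):
        df = pd.concat([_rows(2), _rows(2)], ignore_index=True)
        with pytest.raises(ValidationError):
            load_table(_write_csv(tmp_path, df))


class TestComputeChanges:
    @pytest.mark.parametrize(
        "inst,base,post,change,improvement",
        [
            ("pain_activity", 70, 40, -30, 30),  # pain: decrease is better
            ("sst", 5, 8, 3, 3),  # function: increase is better
            ("cs", 50, 45, -5, -5),  # deterioration on function
        ],
    )
    def test_signed_change_and_improvement(self, inst, base, post, change, improvement):
        t = make_table([("p1", "ASD", 6, inst, base, post, 3)])
        row = t.data.iloc[0]
        assert row["change_score"] == change
        assert row["improvement_magnitude"] == improvement

    def test_missing_post_propagates_to_change(self):
        t = make_table([("p1", "ASD", 6, "cs", 50, np.nan, 3)])
        assert np.isnan(t.data["change_score"].iloc[0])
        assert np.isnan(t.data["improvement_magnitude"].iloc[0])

    def test_idempotent(self, tiny_table):
        again = compute_changes(tiny_table)
        pd.testing.assert_frame_equal(again.data, tiny_table.data)

    def test_improvement_sign_matches_direction(self, fimpact_like):
        table, _ = fimpact_like
        d = table.data.dropna(subset=["change_score"])
        pain = d[d["instrument"].str.startswith("pain")]
        func = d[~d["instrument"].str.startswith("pain")]
        assert (pain["improvement_magnitude"] == -pain["change_score"]).all()
        assert (func["improvement_magnitude"] == func["change_score"]).all()


class TestPoolTimepoints:
    def test_pooled_count_is_sum_of_per_timepoint_counts(self, fimpact_like):
        table, _ = fimpact_like
        counts = table.pair_counts()
        per_tp = [
            pool_timepoints(table, [tp]).pair_counts()["combined"]
            for tp in table.timepoints()
        ]
        total = sum(per_tp)
        pd.testing.assert_series_equal(
            counts["combined"], total, check_names=False
        )

    def test_single_timepoint_is_identity_on_that_slice(self, tiny_table):
        sub = pool_timepoints(tiny_table, [6])
        pd.testing.assert_frame_equal(sub.data, tiny_table.data)

    def test_unknown_timepoint_raises(self, tiny_table):
        with pytest.raises(ValueError, match="unknown timepoints"):
            pool_timepoints(tiny_table, [99])

    def test_empty_timepoint_list_raises(self, tiny_table):
        with pytest.raises(ValueError):
            pool_timepoints(tiny_table, [])

    def test_pooling_commutes_with_instrument_filter(self, fimpact_like):
        table, _ = fimpact_like
        a = pool_timepoints(table, [6, 24]).for_instrument("cs")
        b = pool_timepoints(table.for_instrument("cs"), [6, 24])
        pd.testing.assert_frame_equal(a.data, b.data)


class TestPairCounts:
    def test_matches_brute_force_row_counting(self, fimpact_like):
        table, _ = fimpact_like
        counts = table.pair_counts()
        d = table.data
        for inst in table.instruments:
            for tp in table.timepoints():
                sub = d[(d["instrument"] == inst) & (d["timepoint"] == tp)]
                brute = int(
                    (
                        sub["grc"].notna()
                        & sub["post_score"].notna()
                        & sub["baseline_score"].notna()
                    ).sum()
                )
                assert counts.loc[inst, tp] == brute
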