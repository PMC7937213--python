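import numpy as np
import pandas as pd
import pytest

from clinthresh.data_model import AnchoredOutcomeTable, compute_changes
from clinthresh.simulate import generate_trial, get_scenario


def make_table(rows, instruments=None):
    """Build a small validated table from (pid, group, tp, inst, base, post, grc) tuples."""
    df = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "group",
            "timepoint",
            "instrument",
            "baseline_score",
            "post_score",
            "grc",
        ],
    )
    kwargs = {} if instruments is None else {"instruments": instruments}
    return compute_changes(AnchoredOutcomeTable(df, **kwargs))


@pytest.fixture
def tiny_table():
    """Four pain-on-activity patients spanning all GRC levels."""
    return make_table(
        [
            ("p1", "ASD", 6, "pain_activity", 70, 40, 1),
            ("p2", "DA", 6, "pain_activity", 60, 35, 2),
            ("p3", "ET", 6, "pain_activity", 65, 50, 3),
            ("p4", "ET", 6, "pain_activity", 55, 50, 4),
            ("p5", "ASD", 6, "pain_activity", 80, 85, 5),
        ]
    )


@pytest.fixture(scope="session")
def fimpact_like():
    table, truth = generate_trial(get_scenario("fimpact-like"), seed=11)
    return table, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
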