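"""Loading, exclusion rules, and Stage 1 descriptives."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazeddm.data import (
    TableAdapter,
    apply_exclusions,
    cueing_magnitudes,
    load_trial_table,
    standardized_mean_change,
)


def _table(rows):
    return pd.DataFrame(
        rows, columns=["participant", "condition", "response_side", "correct", "rt_ms"]
    )


@pytest.fixture
def trial_csv(tmp_path):
    path = tmp_path / "trials.csv"
    pd.DataFrame(
        {
            "subj": ["s1", "s1", "s2", "s2"],
            "validity": ["cued", "miscued", "cued", "miscued"],
            "resp": ["left", "right", "right", "left"],
            "acc": [1, 0, 1, 1],
            "rt": [350.0, 420.0, 390.0, 410.0],
        }
    ).to_csv(path, index=False)
    return path


def test_load_round_trip_with_column_map(trial_csv):
    table = load_trial_table(
        trial_csv,
        column_map={
            "participant": "subj",
            "condition": "validity",
            "response_side": "resp",
            "correct": "acc",
            "rt_ms": "rt",
        },
    )
    assert len(table) == 4
    assert table["correct"].dtype == bool
    assert list(table.columns) == [
        "participant", "condition", "response_side", "correct", "rt_ms",
    ]


def test_adapter_keeps_only_selected_cue_types(tmp_path):
    path = tmp_path / "mixed.csv"
    pd.DataFrame(
        {
            "participant": ["s1"] * 4,
            "condition": ["cued", "miscued", "cued", "miscued"],
            "response_side": ["left"] * 4,
            "correct": [1, 1, 1, 1],
            "rt_ms": [300.0, 310.0, 320.0, 330.0],
            "cue_type": ["gaze", "gaze", "arrow", "arrow"],
        }
    ).to_csv(path, index=False)
    table = load_trial_table(path, adapter=TableAdapter(keep_values={"cue_type": ["gaze"]}))
    assert len(table) == 2
    assert set(table["rt_ms"]) == {300.0, 310.0}


def test_missing_column_names_the_column(tmp_path):
    path = tmp_path / "broken.csv"
    pd.DataFrame({"participant": ["s1"], "condition": ["cued"],
                  "response_side": ["left"], "correct": [1]}).to_csv(path, index=False)
    with pytest.raises(KeyError, match="rt_ms"):
        load_trial_table(path)


def test_non_numeric_rt_reports_row_index(tmp_path):
    path = tmp_path / "badrt.csv"
    pd.DataFrame(
        {
            "participant": ["s1", "s1"],
            "condition": ["cued", "miscued"],
            "response_side": ["left", "right"],
            "correct": [1, 1],
            "rt_ms": [350.0, "oops"],
        }
    ).to_csv(path, index=False)
    with pytest.raises(ValueError, match="row indices \\[1\\]"):
        load_trial_table(path)


def test_rt_exclusion_boundaries_are_inclusive():
    """99 and 5001 go; exactly 100 and 5000 stay."""
    table = _table(
        [
            ("s1", "cued", "left", True, 99.0),
            ("s1", "cued", "left", True, 100.0),
            ("s1", "miscued", "left", True, 5000.0),
            ("s1", "miscued", "left", True, 5001.0),
        ]
    )
    out, report = apply_exclusions(table)
    assert sorted(out["rt_ms"]) == [100.0, 5000.0]
    assert report.n_trials_rt_excluded == 2
    assert report.n_trials_out == 2


def test_low_accuracy_participant_fully_removed():
    rows = [("bad", "cued", "left", i < 79, 300.0 + i) for i in range(100)]
    rows += [("good", "cued", "left", True, 400.0)] * 50
    out, report = apply_exclusions(_table(rows))
    assert report.participants_excluded_accuracy == ["bad"]
    assert set(out["participant"]) == {"good"}
    assert report.n_trials_accuracy_excluded == 100


def test_exclusions_are_idempotent_and_conserve_counts():
    rng = np.random.default_rng(5)
    n = 400
    table = _table(
        [
            (
                f"s{rng.integers(4)}",
                rng.choice(["cued", "miscued"]),
                "left",
                bool(rng.uniform() < 0.9),
                float(rng.choice([50.0, 300.0, 400.0, 6000.0])),
            )
            for _ in range(n)
        ]
    )
    once, report = apply_exclusions(table)
    twice, report2 = apply_exclusions(once)
    pd.testing.assert_frame_equal(once, twice)
    assert report2.n_trials_rt_excluded == 0
    assert (
        report.n_trials_out
        == report.n_trials_in - report.n_trials_rt_excluded - report.n_trials_accuracy_excluded
    )


def test_empty_table_rejected():
    with pytest.raises(ValueError):
        apply_exclusions(_table([]))


def test_cueing_magnitude_arithmetic():
    table = _table(
        [
            ("s1", "cued", "left", True, 300.0),
            ("s1", "cued", "left", True, 320.0),
            ("s1", "miscued", "left", True, 330.0),
            ("s1", "miscued", "left", True, 350.0),
        ]
    )
    summary = cueing_magnitudes(table)
    assert summary.per_participant_magnitude_ms["s1"] == pytest.approx(30.0)


def test_cohort_summary_mean_and_positive_count():
    rows = []
    for pid, mag in [("s1", 10.0), ("s2", -5.0), ("s3", 25.0)]:
        rows.append((pid, "cued", "left", True, 400.0))
        rows.append((pid, "miscued", "left", True, 400.0 + mag))
    summary = cueing_magnitudes(_table(rows))
    assert summary.mean_ms == pytest.approx(10.0)
    assert summary.n_positive == 2
    assert summary.n_participants == 3


def test_magnitudes_invariant_to_order_and_relabelling():
    rng = np.random.default_rng(0)
    rows = [
        (f"s{i % 5}", cond, "left", True, float(rng.normal(400, 40)))
        for i in range(200)
        for cond in ("cued", "miscued")
    ]
    table = _table(rows)
    shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
    a = cueing_magnitudes(table)
    b = cueing_magnitudes(shuffled)
    pd.testing.assert_series_equal(
        a.per_participant_magnitude_ms, b.per_participant_magnitude_ms
    )
    relabelled = table.assign(participant=table["participant"].map(lambda s: "x" + s))
    c = cueing_magnitudes(relabelled)
    np.testing.assert_allclose(
        np.sort(a.per_participant_magnitude_ms.to_numpy()),
        np.sort(c.per_participant_magnitude_ms.to_numpy()),
    )


def test_participant_missing_a_condition_is_flagged():
    rows = [
        ("s1", "cued", "left", True, 400.0),
        ("s1", "miscued", "left", True, 420.0),
        ("lonely", "cued", "left", True, 380.0),
    ]
    with pytest.warns(UserWarning, match="lonely"):
        summary = cueing_magnitudes(_table(rows))
    assert summary.n_participants == 1
    assert "lonely" in summary.participants_missing_condition


def test_smc_null_effect_is_zero():
    assert standardized_mean_change([0.0, 0.0, 0.0]).smc == 0.0


def test_smc_sign_matches_mean_change():
    pos = standardized_mean_change([5.0, 12.0, 3.0, 9.0])
    neg = standardized_mean_change([-5.0, -12.0, -3.0, -9.0])
    assert pos.smc > 0 > neg.smc


def test_smc_matches_hand_computed_bias_corrected_value():
    """5 change scores; d = J(4) * mean / SD = 0.8 * 10 / 10.700467."""
    res = standardized_mean_change([10.0, -5.0, 25.0, 8.0, 12.0])
    assert res.smc == pytest.approx(0.7476309016255964, abs=1e-9)
    assert res.variant == "change"
    assert res.bias_corrected


def test_smc_requires_two_participants_and_known_variant():
    with pytest.raises(ValueError):
        standardized_mean_change([3.0])
    with pytest.raises(ValueError):
        standardized_mean_change([1.0, 2.0], variant="mystery")


def test_smc_raw_variant_uses_supplied_sds():
    res = standardized_mean_change(
        [10.0, 20.0, 15.0], paired_sds=(50.0, 50.0), correlation=0.8, variant="raw"
    )
    j = 1 - 3 / (4 * 2 - 1)
    assert res.smc == pytest.approx(j * 15.0 / 50.0)
    assert res.variant == "raw"


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(
        st.floats(min_value=-200, max_value=200, allow_nan=False), min_size=3, max_size=30
    ).filter(lambda xs: np.std(xs, ddof=1) > 1e-9)
)
def test_smc_is_scale_invariant(mags):
    a = standardized_mean_change(mags).smc
    b = standardized_mean_change([2.5 * m for m in mags]).smc
    assert a == pytest.approx(b, rel=1e-9, abs=1e-12)
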