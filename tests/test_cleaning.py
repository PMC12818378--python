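"""Exclusion filters: thresholds, reason codes, conservation, bypass."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myelimetric import (
    CleaningThresholds,
    clean_measurements,
    compute_fiber_and_g,
    filter_physiological_g,
)


def _records(ax, my):
    return pd.DataFrame(
        {
            "sample_id": "S1",
            "group_label": "CTL",
            "axon_diameter": ax,
            "myelin_total": my,
            "source_row": range(1, len(ax) + 1),
        }
    )


@pytest.mark.parametrize(
    "ax,my,kept,reason",
    [
        (0.10, 0.05, False, "axon_below_min"),    # below the 0.15 um floor
        (0.15, 0.03, True, None),                  # boundary values retained
        (np.nan, 0.2, False, "missing"),
        (0.5, 0.02, False, "myelin_below_min"),
        (-0.5, 0.2, False, "nonfinite_or_nonpositive"),
        (np.inf, 0.2, False, "nonfinite_or_nonpositive"),
        (0.8, 0.2, True, None),
    ],
)
def test_threshold_rules_and_reasons(ax, my, kept, reason):
    retained, log = clean_measurements(_records([ax], [my]))
    assert (len(retained) == 1) == kept
    if reason:
        assert log.entries["reason"].tolist() == [reason]


def test_first_matching_reason_wins():
    # a row failing both thresholds is logged once, as the axon failure
    retained, log = clean_measurements(_records([0.10], [0.01]))
    assert len(retained) == 0
    assert log.counts() == {"axon_below_min": 1}


def test_cleaning_is_idempotent():
    rec = _records([0.10, 0.2, 0.8, np.nan], [0.05, 0.01, 0.3, 0.2])
    once, log1 = clean_measurements(rec)
    twice, log2 = clean_measurements(once)
    assert len(log2) == 0
    pd.testing.assert_frame_equal(once, twice)


def test_bypass_keeps_thresholds_off_but_not_missing_removal():
    rec = _records([0.10, np.nan, 0.8, -1.0], [0.01, 0.2, 0.3, 0.2])
    off = CleaningThresholds(enabled=False)
    retained, log = clean_measurements(rec, off)
    assert len(retained) == 2  # sub-threshold row kept, missing/invalid not
    assert set(log.entries["reason"]) == {"missing", "nonfinite_or_nonpositive"}


@pytest.mark.parametrize(
    "g,kept", [(0.45, False), (0.50, True), (0.70, True), (0.90, True), (0.95, False)]
)
def test_physiological_g_window(g, kept):
    # craft a record with exactly the wanted g: a = g*f, My = f - a
    f = 1.0
    rec = compute_fiber_and_g(_records([g * f], [f - g * f]))
    retained, log = filter_physiological_g(rec)
    assert (len(retained) == 1) == kept
    if not kept:
        assert log.entries["reason"].tolist() == ["g_out_of_range"]


def test_physiological_filter_noop_when_bypassed():
    rec = compute_fiber_and_g(_records([0.45], [0.55]))  # g = 0.45
    retained, log = filter_physiological_g(rec, CleaningThresholds(enabled=False))
    assert len(retained) == 1 and len(log) == 0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    ax=st.lists(
        st.one_of(
            st.floats(0.0, 3.0, allow_nan=False),
            st.just(float("nan")),
        ),
        min_size=1,
        max_size=40,
    ),
    my_seed=st.integers(0, 2**16),
)
def test_conservation_rows_in_equals_kept_plus_logged(ax, my_seed):
    rng = np.random.default_rng(my_seed)
    my = rng.uniform(-0.1, 0.6, len(ax))
    retained, log = clean_measurements(_records(ax, my))
    assert len(retained) + len(log) == len(ax)
    # every retained row satisfies the invariants
    assert (retained["axon_diameter"] >= 0.15).all()
    assert (retained["myelin_total"] >= 0.03).all()


def test_invalid_thresholds_rejected():
    with pytest.raises(ValueError):
        CleaningThresholds(g_low=0.9, g_high=0.5)
    with pytest.raises(ValueError):
        CleaningThresholds(axon_min=-1.0)
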