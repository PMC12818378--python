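"""Bin summaries, grand mean, ANOVA against a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import anova_bruteforce
from myelimetric import (
    BinScheme,
    EmptyCellError,
    grand_mean_g,
    summarize_bins,
    two_way_anova,
)

SCHEME = BinScheme((0.5, 0.7, 0.9, 1.1, 1.3, 1.5, 1.7), "fiber_diameter",
                   "CTL", "equal_width")


def _binned(g_by_bin: dict[int, list], group="CTL"):
    rows = []
    for b, gs in g_by_bin.items():
        for g in gs:
            rows.append({"group_label": group, "bin_index": b, "g_ratio": g})
    return pd.DataFrame(rows, columns=["group_label", "bin_index", "g_ratio"])


def test_bin_summary_descriptives():
    summ = summarize_bins(
        _binned({1: [0.7, 0.7, 0.7], 2: [0.6, 0.7, 0.8, 0.9], 3: [0.7, 0.8]}),
        SCHEME, n_boot=50,
    )
    assert len(summ) == 6
    b1 = summ[summ.bin_index == 1].iloc[0]
    assert b1["mean_g"] == pytest.approx(0.7)
    assert b1["sd_g"] == pytest.approx(0.0)
    b2 = summ[summ.bin_index == 2].iloc[0]
    assert b2["mean_g"] == pytest.approx(0.75)
    assert b2["median_g"] == pytest.approx(0.75)
    # hand value: sqrt(sum((x-0.75)^2)/3) for {0.6,0.7,0.8,0.9}
    assert b2["sd_g"] == pytest.approx(0.12909944487358058, rel=1e-12)
    # n-gating: shapiro needs 3, dip needs 4
    b3 = summ[summ.bin_index == 3].iloc[0]
    assert np.isnan(b3["shapiro_W"]) and np.isnan(b3["dip_stat"])
    assert not np.isnan(b2["dip_stat"])
    empty = summ[summ.bin_index == 5].iloc[0]
    assert empty["n"] == 0 and np.isnan(empty["mean_g"])


def test_grand_mean_constant_fit():
    summ = summarize_bins(
        _binned({b: [0.6] * 3 for b in (1, 2, 3)} | {b: [0.8] * 3 for b in (4, 5, 6)}),
        SCHEME, n_boot=50,
    )
    assert grand_mean_g(summ, "unweighted").value == pytest.approx(0.70)


def test_grand_mean_weighting():
    summ = summarize_bins(
        _binned({1: [0.6] * 10, 2: [0.8] * 30}), SCHEME, n_boot=50
    )
    assert grand_mean_g(summ, "n_weighted").value == pytest.approx(0.75)
    assert grand_mean_g(summ, "unweighted").value == pytest.approx(0.70)


def test_weighted_grand_mean_equals_pooled_mean():
    rng = np.random.default_rng(3)
    df = _binned({b: list(rng.normal(0.7, 0.03, rng.integers(2, 40)))
                  for b in range(1, 7)})
    summ = summarize_bins(df, SCHEME, n_boot=50)
    assert grand_mean_g(summ, "n_weighted").value == pytest.approx(
        df["g_ratio"].mean(), abs=1e-12
    )


def test_grand_mean_all_empty_raises():
    summ = summarize_bins(_binned({}), SCHEME, n_boot=50)
    with pytest.raises(ValueError):
        grand_mean_g(summ)


def test_anova_toy_matches_bruteforce_decomposition():
    """Balanced 2x2 with cells {(1,2),(3,4),(5,6),(7,8)}: the decomposition
    computed by the independent oracle is SS_group=32, SS_bin=8, SS_int=0,
    SS_res=2 with df 1,1,1,4."""
    df = pd.concat(
        [
            _binned({1: [1, 2], 2: [3, 4]}, group="G1"),
            _binned({1: [5, 6], 2: [7, 8]}, group="G2"),
        ],
        ignore_index=True,
    )
    oracle = anova_bruteforce(df)
    assert oracle["group"] == (pytest.approx(32.0), 1)
    assert oracle["bin"] == (pytest.approx(8.0), 1)
    assert oracle["group:bin"][0] == pytest.approx(0.0, abs=1e-12)
    assert oracle["residual"] == (pytest.approx(2.0), 4)
    tab = two_way_anova(df).set_index("term")
    for term in ("group", "bin", "group:bin", "residual"):
        assert tab.loc[term, "sum_sq"] == pytest.approx(oracle[term][0], abs=1e-9)
        assert tab.loc[term, "df"] == oracle[term][1]


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_anova_matches_bruteforce_on_random_balanced_designs(seed):
    rng = np.random.default_rng(seed)
    df = pd.concat(
        [
            _binned({b: list(rng.normal(0.7, 0.1, 4)) for b in (1, 2, 3)}, g)
            for g in ("G1", "G2")
        ],
        ignore_index=True,
    )
    oracle = anova_bruteforce(df)
    tab = two_way_anova(df).set_index("term")
    for term in ("group", "bin", "group:bin", "residual"):
        assert tab.loc[term, "sum_sq"] == pytest.approx(oracle[term][0], abs=1e-9)
        assert tab.loc[term, "df"] == oracle[term][1]
    # SS conservation for the balanced design
    assert tab["sum_sq"].sum() == pytest.approx(oracle["total"][0], abs=1e-9)
    assert tab["df"].sum() == oracle["total"][1]


def test_anova_no_mean_differences_gives_zero_f():
    df = pd.concat(
        [
            _binned({1: [9, 11], 2: [9, 11]}, "G1"),
            _binned({1: [9, 11], 2: [9, 11]}, "G2"),
        ],
        ignore_index=True,
    )
    tab = two_way_anova(df).set_index("term")
    for term in ("group", "bin", "group:bin"):
        assert tab.loc[term, "F"] == pytest.approx(0.0, abs=1e-10)


def test_anova_empty_cell_is_an_error():
    df = pd.concat(
        [_binned({1: [1, 2], 2: [3, 4]}, "G1"), _binned({1: [5, 6]}, "G2")],
        ignore_index=True,
    )
    with pytest.raises(EmptyCellError, match="G2"):
        two_way_anova(df)


def test_shapiro_rejects_at_nominal_rate_under_normality():
    rejections = 0
    reps = 1000
    for i in range(reps):
        rng = np.random.default_rng(20_000 + i)
        _, p = sps.shapiro(rng.normal(0.7, 0.03, 50))
        rejections += p < 0.05
    assert 0.03 <= rejections / reps <= 0.07
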