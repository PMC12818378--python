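"""Synthetic generator: structure, ground truth, determinism, sensitivity."""

import numpy as np
import pandas as pd
import pytest

from myelimetric import (
    SimConfig,
    SimulationInfeasibleError,
    append_extremes,
    clean_measurements,
    compute_fiber_and_g,
    load_measurements,
    scaled_config,
    sensitivity_delta,
    simulate_condition,
    simulation_to_workbook,
)


def test_baseline_structure_counts(ctl_records, sim_config):
    assert len(ctl_records) == sim_config.n_subgroups * 1000
    assert ctl_records["subgroup_id"].value_counts().eq(1000).all()
    assert set(ctl_records["sample_id"]) == {f"CTL{i}" for i in range(1, 6)}


def test_fiber_cap_and_g_bounds_hold(ctl_records, exp_records, sim_config):
    for rec in (ctl_records, exp_records):
        out = compute_fiber_and_g(rec)
        assert (out["fiber_diameter"] <= sim_config.fiber_cap).all()
        lo, hi = sim_config.g_bounds
        assert out["true_g"].between(lo, hi).all()
        assert (out["axon_diameter"] > 0).all()
        assert (out["myelin_total"] > 0).all()


def test_ground_truth_identity_is_exact(ctl_records, exp_records):
    for rec in (ctl_records, exp_records):
        out = compute_fiber_and_g(rec)
        assert np.abs(out["g_ratio"] - out["true_g"]).max() <= 1e-12


def test_single_row_algebra():
    # drawn g = 0.8 at a = 1.0 means m = 0.125, stored My = 0.25, f = 1.25
    a, g = 1.0, 0.8
    my = a * (1 / g - 1)
    assert my == pytest.approx(0.25)
    assert a + my == pytest.approx(1.25)


def test_same_seed_reproduces_bit_identical_tables(sim_config):
    a = simulate_condition(sim_config, "CTL")
    b = simulate_condition(sim_config, "CTL")
    pd.testing.assert_frame_equal(a, b)
    c = simulate_condition(SimConfig(seed=2), "CTL")
    assert not np.array_equal(a["axon_diameter"], c["axon_diameter"])


def test_condition_separation(ctl_records, exp_records):
    gap = (compute_fiber_and_g(exp_records)["g_ratio"].mean()
           - compute_fiber_and_g(ctl_records)["g_ratio"].mean())
    assert gap > 0.05


def test_subgroup_offsets_order_sample_means(ctl_records):
    means = (
        compute_fiber_and_g(ctl_records)
        .groupby("subgroup_id")["g_ratio"].mean()
    )
    assert means.is_monotonic_increasing  # offsets -0.02 .. +0.02


def test_extremes_structure_and_thresholds(ctl_with_extremes, sim_config):
    total = sim_config.n_subgroups * (1000 + 100)
    assert len(ctl_with_extremes) == total
    ext = ctl_with_extremes[ctl_with_extremes.is_extreme]
    assert len(ext) == 500
    assert (ext["axon_diameter"] < 0.15).all()
    assert (ext["myelin_total"] < 0.06).all()  # two-sided: 2 x 0.029 max
    out = compute_fiber_and_g(ext)
    assert np.abs(out["g_ratio"] - out["true_g"]).max() <= 1e-12
    assert (out["fiber_diameter"] <= sim_config.fiber_cap).all()


def test_cleaning_removes_exactly_the_extremes(ctl_with_extremes):
    retained, log = clean_measurements(ctl_with_extremes)
    assert len(log) == 500
    assert retained["is_extreme"].sum() == 0
    assert len(retained) == 5000  # no baseline row is removed


def test_sensitivity_delta_zero_without_extremes(ctl_records):
    assert sensitivity_delta(ctl_records).delta == 0.0


def test_sensitivity_delta_bounds(ctl_with_extremes, exp_with_extremes):
    assert sensitivity_delta(ctl_with_extremes).delta < 0.017
    assert sensitivity_delta(exp_with_extremes).delta < 0.014


def test_workbook_round_trip_conforms_to_input_contract(
    tmp_path, ctl_with_extremes
):
    path = tmp_path / "ctl.xlsx"
    simulation_to_workbook(ctl_with_extremes, path)
    rec = load_measurements(path, "CTL")
    assert len(rec) == len(ctl_with_extremes)
    for sid, sub in rec.groupby("sample_id"):
        orig = ctl_with_extremes[ctl_with_extremes.sample_id == sid]
        # XLSX stores 16 significant digits (Excel's numeric format)
        np.testing.assert_allclose(
            sub["axon_diameter"].to_numpy(), orig["axon_diameter"].to_numpy(),
            rtol=1e-14, atol=0,
        )
    truth = pd.read_excel(path, sheet_name="ground_truth")
    assert len(truth) == len(ctl_with_extremes)
    assert truth["is_extreme"].sum() == 500


def test_calibrated_iqr_preset_matches_quartiles():
    cfg = SimConfig.preset("calibrated_iqr", seed=3)
    # quartiles of the *uncapped* law are 0.3/1.2; the cap shifts them down,
    # so check the log-space parameters directly
    assert np.exp(cfg.axon_log_mu) == pytest.approx(0.6, rel=1e-6)
    assert cfg.axon_log_sigma == pytest.approx(1.0277, abs=1e-3)
    rec = simulate_condition(scaled_config(cfg, 200), "CTL")
    assert len(rec) == 1000
    assert (compute_fiber_and_g(rec)["fiber_diameter"] <= cfg.fiber_cap).all()


def test_infeasible_cap_aborts_with_diagnostic():
    cfg = SimConfig(seed=0, fiber_cap=0.0001, max_redraw_factor=2)
    with pytest.raises(SimulationInfeasibleError):
        simulate_condition(cfg, "CTL")


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(subgroup_offsets=(0.1, 0.1, 0.1, 0.1, 0.1))
    with pytest.raises(ValueError):
        SimConfig(extreme_axon_range=(0.05, 0.2))
    with pytest.raises(ValueError):
        SimConfig.preset("nope")
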