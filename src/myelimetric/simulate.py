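"""Ground-truth synthetic axon/myelin generator.

Each condition (CTL-like control, EXP/cuprizone-like demyelinated) holds
five subgroups ("animals") of 1000 baseline axons. Axon diameters a are
log-normal (``ln a ~ Normal(axon_log_mu, axon_log_sigma^2)``); each axon's
g-ratio is drawn from a truncated normal ``N(g_mean + delta_s, g_sd^2)`` on
``g_bounds``, where ``delta_s`` is the zero-mean subgroup offset. Myelin is
then solved from the identity ``g = a/(a + 2m)`` as ``m = a (1/g - 1) / 2``,
so every row carries a mathematically exact ground-truth g. Fibers larger
than the 2 um rodent-CNS cap are rejected and redrawn jointly in (a, g)
until the subgroup count is met.

Sensitivity rows ("extremes") model rare small-caliber, thin-myelin
artefacts: 100 rows per subgroup with ``a ~ U(0.05, 0.149)`` um and
one-sided ``m ~ U(0.005, 0.029)`` um, deliberately below both cleaning
thresholds; their g is recomputed from the identity and the fiber cap
reapplied.

Every stream is seeded per (seed, condition, subgroup), so subgroup output
is independent of generation order and runs are bit-reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._errors import SimulationInfeasibleError
from .cleaning import CleaningThresholds, clean_measurements
from .morphometry import compute_fiber_and_g

CONDITIONS = ("CTL", "EXP")


@dataclass(frozen=True)
class SimConfig:
    """All constants of the synthetic generator.

    Defaults are the reference study conditions. ``axon_log_mu`` /
    ``axon_log_sigma`` are the log-space parameters of the axon-diameter
    log-normal; the ``calibrated_iqr`` preset instead matches an empirical
    0.3-1.2 um interquartile range (the two published descriptions are
    mutually inconsistent; both are offered, the literal one is default).
    """

    n_subgroups: int = 5
    n_baseline_per_subgroup: int = 1000
    n_extreme_per_subgroup: int = 100
    g_mean_ctl: float = 0.70
    g_mean_exp: float = 0.80
    g_sd: float = 0.03
    g_bounds: tuple[float, float] = (0.65, 0.95)
    subgroup_offsets: tuple[float, ...] = (-0.02, -0.01, 0.0, 0.01, 0.02)
    axon_log_mu: float = 1.0
    axon_log_sigma: float = 0.5
    fiber_cap: float = 2.0
    extreme_axon_range: tuple[float, float] = (0.05, 0.149)
    extreme_myelin_range: tuple[float, float] = (0.005, 0.029)  # one-sided
    seed: int = 0
    max_redraw_factor: int = 1000

    def __post_init__(self) -> None:
        if len(self.subgroup_offsets) != self.n_subgroups:
            raise ValueError("need one subgroup offset per subgroup")
        if abs(sum(self.subgroup_offsets)) > 1e-12:
            raise ValueError("subgroup offsets must have zero mean")
        if not (0 < self.g_bounds[0] < self.g_bounds[1] < 1):
            raise ValueError("g_bounds must lie inside (0, 1)")
        if min(self.n_subgroups, self.n_baseline_per_subgroup,
               self.n_extreme_per_subgroup) <= 0:
            raise ValueError("all counts must be positive")
        if self.extreme_axon_range[1] >= 0.15:
            raise ValueError("extreme axon range must stay below 0.15 um")
        if self.extreme_myelin_range[1] >= 0.03:
            raise ValueError("extreme one-sided myelin must stay below 0.03 um")

    @classmethod
    def preset(cls, name: str = "printed", **overrides) -> "SimConfig":
        """Named parameter presets: ``printed`` (literal log-space mu=1.0,
        sigma=0.5) or ``calibrated_iqr`` (quartiles at 0.3 and 1.2 um)."""
        if name == "printed":
            return cls(**overrides)
        if name == "calibrated_iqr":
            q1, q3 = 0.3, 1.2
            z = sps.norm.ppf(0.75)
            mu = 0.5 * (np.log(q1) + np.log(q3))
            sigma = (np.log(q3) - np.log(q1)) / (2 * z)
            return cls(axon_log_mu=float(mu), axon_log_sigma=float(sigma),
                       **overrides)
        raise ValueError(f"unknown preset {name!r}")


def _g_mean(config: SimConfig, condition: str) -> float:
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    return config.g_mean_ctl if condition == "CTL" else config.g_mean_exp


def _subgroup_rng(config: SimConfig, condition: str, subgroup: int,
                  stream: int) -> np.random.Generator:
    return np.random.default_rng(
        [int(config.seed), CONDITIONS.index(condition), subgroup, stream]
    )


def _draw_subgroup(config: SimConfig, condition: str, subgroup: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample (a, g) pairs for one subgroup until the baseline
    count is met; returns accepted (a, g)."""
    rng = _subgroup_rng(config, condition, subgroup, stream=0)
    mean = _g_mean(config, condition) + config.subgroup_offsets[subgroup - 1]
    lo, hi = config.g_bounds
    alpha = (lo - mean) / config.g_sd
    beta = (hi - mean) / config.g_sd
    target = config.n_baseline_per_subgroup
    budget = config.max_redraw_factor * target

    a_acc: list[np.ndarray] = []
    g_acc: list[np.ndarray] = []
    got = drawn = 0
    while got < target:
        chunk = max(1000, 4 * (target - got))
        if drawn + chunk > budget:
            chunk = budget - drawn
            if chunk <= 0:
                raise SimulationInfeasibleError(
                    f"{condition} subgroup {subgroup}: fiber cap "
                    f"{config.fiber_cap} um accepted only {got}/{target} rows "
                    f"after {drawn} draws"
                )
        a = rng.lognormal(config.axon_log_mu, config.axon_log_sigma, chunk)
        g = sps.truncnorm.rvs(alpha, beta, loc=mean, scale=config.g_sd,
                              size=chunk, random_state=rng)
        my = a * (1.0 / g - 1.0)          # two-sided myelin 2m
        f = a + my
        ok = (f <= config.fiber_cap) & np.isfinite(f) & (a > 0) & (my > 0)
        a_acc.append(a[ok])
        g_acc.append(g[ok])
        got += int(ok.sum())
        drawn += chunk
    a = np.concatenate(a_acc)[:target]
    g = np.concatenate(g_acc)[:target]
    return a, g


def simulate_condition(config: SimConfig, condition: str) -> pd.DataFrame:
    """Baseline rows for one condition: n_subgroups x n_baseline axons.

    Returns a measurement table with ground-truth columns ``true_g``,
    ``subgroup_id`` and ``is_extreme`` alongside the standard measurement
    columns (``myelin_total`` is emitted two-sided, analysis-ready).
    """
    frames = []
    for s in range(1, config.n_subgroups + 1):
        a, g = _draw_subgroup(config, condition, s)
        my = a * (1.0 / g - 1.0)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": f"{condition}{s}",
                    "group_label": condition,
                    "axon_diameter": a,
                    "myelin_total": my,
                    "source_row": np.arange(1, len(a) + 1),
                    "true_g": g,
                    "subgroup_id": s,
                    "is_extreme": False,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def append_extremes(records: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Append the sensitivity rows (n_extreme per subgroup) to baseline
    records of a single condition and return the combined table."""
    conditions = records["group_label"].unique()
    if len(conditions) != 1:
        raise ValueError("append_extremes expects a single-condition table")
    condition = str(conditions[0])
    a_lo, a_hi = config.extreme_axon_range
    m_lo, m_hi = config.extreme_myelin_range
    frames = [records]
    for s in range(1, config.n_subgroups + 1):
        rng = _subgroup_rng(config, condition, s, stream=1)
        target = config.n_extreme_per_subgroup
        budget = config.max_redraw_factor * target
        a_acc: list[np.ndarray] = []
        m_acc: list[np.ndarray] = []
        got = drawn = 0
        while got < target:  # cap is vacuous here (max f ~ 0.207) but reapplied
            chunk = min(max(target - got, target), budget - drawn)
            if chunk <= 0:
                raise SimulationInfeasibleError(
                    f"{condition} subgroup {s}: extreme-row cap rejection "
                    f"exhausted its budget"
                )
            a = rng.uniform(a_lo, a_hi, chunk)
            m = rng.uniform(m_lo, m_hi, chunk)
            ok = (a + 2 * m) <= config.fiber_cap
            a_acc.append(a[ok])
            m_acc.append(m[ok])
            got += int(ok.sum())
            drawn += chunk
        a = np.concatenate(a_acc)[:target]
        m = np.concatenate(m_acc)[:target]
        my = 2.0 * m
        n0 = config.n_baseline_per_subgroup
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": f"{condition}{s}",
                    "group_label": condition,
                    "axon_diameter": a,
                    "myelin_total": my,
                    "source_row": np.arange(n0 + 1, n0 + target + 1),
                    "true_g": a / (a + my),
                    "subgroup_id": s,
                    "is_extreme": True,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["subgroup_id", "source_row"], ignore_index=True)


@dataclass(frozen=True)
class SensitivityResult:
    """Pooled-mean stability when extreme rows are kept vs cleaned away."""

    mean_with: float
    mean_without: float
    n_with: int
    n_without: int

    @property
    def delta(self) -> float:
        return abs(self.mean_with - self.mean_without)


def sensitivity_delta(
    records: pd.DataFrame,
    thresholds: CleaningThresholds | None = None,
) -> SensitivityResult:
    """|pooled mean g with all rows - pooled mean g after cleaning|.

    Both means use full-precision g computed from the measurement columns.
    """
    with_g = compute_fiber_and_g(records)
    cleaned, _log = clean_measurements(records, thresholds)
    without_g = compute_fiber_and_g(cleaned)
    return SensitivityResult(
        mean_with=float(with_g["g_ratio"].mean()),
        mean_without=float(without_g["g_ratio"].mean()),
        n_with=len(with_g),
        n_without=len(without_g),
    )


def simulation_to_workbook(records: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a simulated condition in the paired-column input layout
    (``<condition><s>_Ax`` / ``_My`` columns) plus a ground-truth sheet."""
    data = {}
    for sid, sub in records.groupby("sample_id", sort=False):
        data[f"{sid}_Ax"] = sub["axon_diameter"].to_numpy()
        data[f"{sid}_My"] = sub["myelin_total"].to_numpy()
    lengths = {len(v) for v in data.values()}
    if len(lengths) != 1:
        raise ValueError("subgroups of unequal length cannot share a sheet")
    truth = records[["sample_id", "source_row", "true_g", "subgroup_id",
                     "is_extreme"]]
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        pd.DataFrame(data).to_excel(writer, sheet_name="data", index=False)
        truth.to_excel(writer, sheet_name="ground_truth", index=False)


def scaled_config(config: SimConfig, n_baseline: int, n_extreme: int | None = None
                  ) -> SimConfig:
    """Same generator with smaller per-subgroup counts (for quick runs)."""
    return replace(
        config,
        n_baseline_per_subgroup=n_baseline,
        n_extreme_per_subgroup=n_extreme or config.n_extreme_per_subgroup,
    )
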