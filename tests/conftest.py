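"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own code paths: the dip
brute force solves the unimodal-band feasibility problem with linear
programming, the ANOVA brute force uses the classical balanced mean
decomposition, and the expected subgroup mean integrates the generator's
sampling density analytically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy import stats as sps
from scipy.optimize import linprog

from myelimetric import SimConfig, append_extremes, simulate_condition, \
    simulation_to_workbook


# ---------------------------------------------------------------- fixtures

TEST_SEED = 1


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=TEST_SEED)


@pytest.fixture(scope="session")
def ctl_records(sim_config) -> pd.DataFrame:
    return simulate_condition(sim_config, "CTL")


@pytest.fixture(scope="session")
def exp_records(sim_config) -> pd.DataFrame:
    return simulate_condition(sim_config, "EXP")


@pytest.fixture(scope="session")
def ctl_with_extremes(sim_config, ctl_records) -> pd.DataFrame:
    return append_extremes(ctl_records, sim_config)


@pytest.fixture(scope="session")
def exp_with_extremes(sim_config, exp_records) -> pd.DataFrame:
    return append_extremes(exp_records, sim_config)


@pytest.fixture(scope="session")
def sim_workbooks(tmp_path_factory, ctl_with_extremes, exp_with_extremes):
    """CTL and EXP condition workbooks (with sensitivity rows) on disk."""
    d = tmp_path_factory.mktemp("simulated")
    ctl_path = d / "ctl.xlsx"
    exp_path = d / "exp.xlsx"
    simulation_to_workbook(ctl_with_extremes, ctl_path)
    simulation_to_workbook(exp_with_extremes, exp_path)
    return {"CTL": str(ctl_path), "EXP": str(exp_path)}


def make_workbook(path, sheets: dict[str, dict[str, list]]) -> str:
    """Write a workbook from {sheet: {column: values}} (ragged columns are
    padded with blanks, mirroring hand-curated spreadsheets)."""
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        for sheet, cols in sheets.items():
            width = max((len(v) for v in cols.values()), default=0)
            padded = {
                k: list(v) + [None] * (width - len(v)) for k, v in cols.items()
            }
            pd.DataFrame(padded).to_excel(writer, sheet_name=sheet, index=False)
    return str(path)


# ------------------------------------------------------------- dip oracle


def dip_bruteforce(values, tol=1e-8) -> float:
    """Dip statistic by LP feasibility: minimal d such that a unimodal CDF
    (convex then concave, possibly with one atom at the mode) stays within
    sup-distance d of the ECDF."""
    x = np.sort(np.asarray(values, float))
    n = len(x)
    ux, first = np.unique(x, return_index=True)
    last = np.r_[first[1:], n] - 1
    m = len(ux)
    base_hi = first / n        # ECDF left limit at each unique point
    base_lo = (last + 1) / n   # ECDF value at each unique point
    dx = np.diff(ux)

    def lp_ok(nv, rows, bounds):
        if rows:
            a = np.array(rows)
            res = linprog(np.zeros(nv), A_ub=a, b_ub=np.zeros(len(rows)),
                          bounds=bounds, method="highs")
            return res.status == 0
        lo, hi = zip(*bounds)
        return all(l <= h + 1e-12 for l, h in zip(lo, hi))

    def convex_row(nv, j, idx=lambda i: i):
        # s_j <= s_{j+1} over unique-point values (0-based slopes)
        r = np.zeros(nv)
        r[idx(j)] += -1.0 / dx[j]
        r[idx(j + 1)] += 1.0 / dx[j] + 1.0 / dx[j + 1]
        r[idx(j + 2)] += -1.0 / dx[j + 1]
        return r

    def feasible(d):
        lo = np.maximum(base_lo - d, 0.0)
        hi = np.minimum(base_hi + d, 1.0)
        if m == 1:
            return lo[0] <= hi[0] + 1e-12
        if np.all(lo <= hi + 1e-12):
            mono = []
            for j in range(m - 1):
                r = np.zeros(m)
                r[j], r[j + 1] = 1.0, -1.0
                mono.append(r)
            # split c: slopes nondecreasing before, nonincreasing after,
            # with the two chains unlinked at the split
            for c in range(1, m + 1):
                rows = list(mono)
                rows += [convex_row(m, j) for j in range(0, c - 2)]
                rows += [-convex_row(m, j) for j in range(c - 1, m - 2)]
                if lp_ok(m, rows, list(zip(lo, hi))):
                    return True
        # atom at mode point k: left limit h (extra var) decoupled from g_k
        for k in range(m):
            h_bounds = (max(base_hi[k] - d, 0.0), min(base_hi[k] + d, 1.0))
            g_bounds = (max(base_lo[k] - d, 0.0), min(base_lo[k] + d, 1.0))
            if h_bounds[0] > h_bounds[1] + 1e-12 or g_bounds[0] > g_bounds[1] + 1e-12:
                continue
            lo_k, hi_k = lo.copy(), hi.copy()
            lo_k[k], hi_k[k] = g_bounds
            others = [j for j in range(m) if j != k]
            if any(lo_k[j] > hi_k[j] + 1e-12 for j in others):
                continue
            nv = m + 1          # vars g_0..g_{m-1}, h at index m
            idx = lambda j: m if j == k else j  # noqa: E731 (left side uses h)
            rows = []
            for j in range(m - 1):  # monotone; the step into k uses h
                r = np.zeros(nv)
                r[j] = 1.0
                r[m if j + 1 == k else j + 1] = -1.0
                rows.append(r)
            r = np.zeros(nv)
            r[m], r[k] = 1.0, -1.0          # h <= g_k (jump goes up)
            rows.append(r)
            rows += [convex_row(nv, j, idx) for j in range(0, k - 1)]
            rows += [-convex_row(nv, j) for j in range(k, m - 2)]
            bounds = [
                g_bounds if j == k else (lo_k[j], hi_k[j]) for j in range(m)
            ] + [h_bounds]
            if lp_ok(nv, rows, bounds):
                return True
        return False

    lo_d, hi_d = 0.0, 0.5
    while hi_d - lo_d > tol:
        mid = 0.5 * (lo_d + hi_d)
        if feasible(mid):
            hi_d = mid
        else:
            lo_d = mid
    return 0.5 * (lo_d + hi_d)


# ----------------------------------------------------------- ANOVA oracle


def anova_bruteforce(df: pd.DataFrame):
    """Balanced two-way SS decomposition from cell/marginal means."""
    y = df["g_ratio"].to_numpy(float)
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    ga = df.groupby("group_label")["g_ratio"].mean()
    gb = df.groupby("bin_index")["g_ratio"].mean()
    cells = df.groupby(["group_label", "bin_index"])["g_ratio"].agg(["mean", "count"])
    ss_a = sum(
        df[df.group_label == a].shape[0] * (ga[a] - grand) ** 2 for a in ga.index
    )
    ss_b = sum(
        df[df.bin_index == b].shape[0] * (gb[b] - grand) ** 2 for b in gb.index
    )
    ss_cells = sum(
        row["count"] * (row["mean"] - grand) ** 2 for _, row in cells.iterrows()
    )
    ss_int = ss_cells - ss_a - ss_b
    ss_res = ss_total - ss_cells
    df_a = len(ga) - 1
    df_b = len(gb) - 1
    df_int = df_a * df_b
    df_res = len(y) - len(ga) * len(gb)
    return {
        "group": (ss_a, df_a),
        "bin": (ss_b, df_b),
        "group:bin": (ss_int, df_int),
        "residual": (ss_res, df_res),
        "total": (ss_total, len(y) - 1),
    }


# ------------------------------------------- generator mean (semi-analytic)


def expected_subgroup_mean(g_mean: float, config: SimConfig) -> float:
    """E[g] of accepted draws: truncated normal tilted by the fiber-cap
    acceptance probability w(g) = P(a <= cap * g) under the log-normal."""
    lo, hi = config.g_bounds
    a_, b_ = (lo - g_mean) / config.g_sd, (hi - g_mean) / config.g_sd
    tn = sps.truncnorm(a_, b_, loc=g_mean, scale=config.g_sd)

    def w(g):
        return sps.norm.cdf(
            (np.log(config.fiber_cap * g) - config.axon_log_mu)
            / config.axon_log_sigma
        )

    num = integrate.quad(lambda g: g * w(g) * tn.pdf(g), lo, hi)[0]
    den = integrate.quad(lambda g: w(g) * tn.pdf(g), lo, hi)[0]
    return num / den
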