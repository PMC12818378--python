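"""Per-bin statistics, the constant-g grand mean, and group comparisons.

The grand mean implements the constant-g model of the axomyelin unit: a
single g fitted by least squares to the six bin means. The unweighted fit
treats each caliber cohort equally (the default); the n-weighted variant
equals the pooled mean over all fibers.

Group differences are tested with a fixed-effects two-way ANOVA of g on
group, diameter bin and their interaction (Type II sums of squares, since
per-bin n inevitably differs between groups). Distribution shape per bin is
profiled with Shapiro-Wilk normality and Hartigan's dip multimodality test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from ._errors import EmptyCellError
from .binning import N_BINS, BinScheme
from .dip import dip_test

SHAPIRO_MIN_N = 3
DIP_MIN_N = 4


def dip_multimodality(values, n_boot: int = 200) -> tuple[float, float]:
    """Hartigan's dip statistic and Monte-Carlo p-value; (nan, nan) when
    fewer than four observations are available."""
    v = np.asarray(values, dtype=float)
    if v.size < DIP_MIN_N:
        return float("nan"), float("nan")
    return dip_test(v, n_boot=n_boot)


def summarize_bins(
    records: pd.DataFrame,
    scheme: BinScheme,
    n_boot: int = 200,
) -> pd.DataFrame:
    """One row per bin (1..6): n, mean/median/sample-SD of full-precision g,
    Shapiro-Wilk (n >= 3) and dip test (n >= 4).

    Empty bins keep n=0 with NaN statistics. Requires ``bin_index`` and
    ``g_ratio`` columns; a ``group_label`` column is carried through.
    """
    groups = records["group_label"].unique()
    label = groups[0] if len(groups) == 1 else "pooled"
    rows = []
    for b in range(1, N_BINS + 1):
        g = records.loc[records["bin_index"] == b, "g_ratio"].to_numpy(float)
        n = g.size
        row = {
            "group_label": label,
            "bin_index": b,
            "n": n,
            "mean_g": float(np.mean(g)) if n else float("nan"),
            "median_g": float(np.median(g)) if n else float("nan"),
            "sd_g": float(np.std(g, ddof=1)) if n >= 2 else
                    (0.0 if n == 1 else float("nan")),
            "shapiro_W": float("nan"),
            "shapiro_p": float("nan"),
            "dip_stat": float("nan"),
            "dip_p": float("nan"),
        }
        if n >= SHAPIRO_MIN_N and np.ptp(g) > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # large-n p-value caveat
                w, p = sps.shapiro(g)
            row["shapiro_W"], row["shapiro_p"] = float(w), float(p)
        if n >= DIP_MIN_N:
            row["dip_stat"], row["dip_p"] = dip_multimodality(g, n_boot)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GrandG:
    """Constant-g grand mean fitted to the per-bin means."""

    value: float
    method: str  # "unweighted" | "n_weighted"
    bin_means_used: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"grand_g": self.value, "method": self.method,
              "n_bins_used": len(self.bin_means_used)}]
        )


def grand_mean_g(summaries: pd.DataFrame, method: str = "unweighted") -> GrandG:
    """Least-squares constant fit of g to the nonempty bin means.

    ``unweighted`` minimises sum_b (mean_b - g)^2, i.e. the arithmetic mean
    of the bin means; ``n_weighted`` weights each bin by its n, which equals
    the pooled mean over all records.
    """
    if method not in ("unweighted", "n_weighted"):
        raise ValueError("method must be 'unweighted' or 'n_weighted'")
    nonempty = summaries[summaries["n"] > 0]
    if nonempty.empty:
        raise ValueError("all bins are empty; no grand mean exists")
    means = nonempty["mean_g"].to_numpy(float)
    if method == "unweighted":
        value = float(np.mean(means))
    else:
        w = nonempty["n"].to_numpy(float)
        value = float(np.sum(w * means) / np.sum(w))
    return GrandG(value=value, method=method, bin_means_used=tuple(means))


def two_way_anova(records: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effects group x bin factorial ANOVA on full-precision g.

    Type II sums of squares (cells are unbalanced by construction). Returns
    the ANOVA table with rows group, bin, group:bin, residual and columns
    df, sum_sq, mean_sq, F, p. Raises :class:`EmptyCellError` when any
    group x bin cell is empty and on zero residual degrees of freedom.
    """
    df = records[["group_label", "bin_index", "g_ratio"]].copy()
    groups = df["group_label"].unique()
    bins_present = np.sort(df["bin_index"].unique())
    if len(groups) < 2:
        raise ValueError("two-way ANOVA needs at least 2 groups")
    if len(bins_present) < 2:
        raise ValueError("two-way ANOVA needs at least 2 nonempty bins")
    cells = df.groupby(["group_label", "bin_index"]).size()
    empty = [
        (g, b) for g in groups for b in bins_present if (g, b) not in cells.index
    ]
    if empty:
        raise EmptyCellError(f"empty group x bin cells: {empty}")
    n_cells = len(groups) * len(bins_present)
    if len(df) - n_cells <= 0:
        raise EmptyCellError("zero residual degrees of freedom")

    fit = smf.ols("g_ratio ~ C(group_label) * C(bin_index)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    rename = {
        "C(group_label)": "group",
        "C(bin_index)": "bin",
        "C(group_label):C(bin_index)": "group:bin",
        "Residual": "residual",
    }
    out = tab.rename(index=rename).reset_index(names="term")
    out["mean_sq"] = out["sum_sq"] / out["df"]
    out = out.rename(columns={"PR(>F)": "p"})
    return out[["term", "df", "sum_sq", "mean_sq", "F", "p"]]
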