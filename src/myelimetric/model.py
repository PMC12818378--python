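"""Model/Results interface over the g-ratio pipeline.

:class:`GRatioModel` wraps one group's measurements; ``fit()`` runs the
pipeline (clean -> fiber/g computation -> physiological-g filter -> bin
derivation or application -> per-bin statistics -> constant-g grand mean ->
plausibility diagnostics) and returns a :class:`GRatioResults` carrying
the retained records, bin summaries, grand g and exclusion accounting.

:class:`GRatioComparison` fits a control and an experimental model on the
control-derived bin scheme and adds the group x bin ANOVA.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

from .binning import BinScheme, assign_bins, derive_bins
from .cleaning import CleaningThresholds, clean_measurements, filter_physiological_g
from .io import ExclusionLog, load_measurements, write_outputs
from .morphometry import (
    CorrelationReport,
    compute_fiber_and_g,
    flag_g_vs_fiber_correlation,
)
from .stats import GrandG, grand_mean_g, summarize_bins, two_way_anova


class GRatioModel:
    """G-ratio morphometry model for a single measurement group.

    Parameters
    ----------
    data
        Measurement table (see :mod:`myelimetric.io`): one row per axon with
        ``axon_diameter`` and two-sided ``myelin_total`` in um.
    thresholds
        Cleaning configuration; defaults to the standard 0.15/0.03 um floors
        and 0.5-0.9 physiological g range.
    bin_variable, bin_method
        How the six diameter bins are derived when this model is the control
        (fiber or axon diameter; equal-width or quantile edges).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        thresholds: CleaningThresholds | None = None,
        bin_variable: str = "fiber_diameter",
        bin_method: str = "equal_width",
        corr_alpha: float = 0.05,
        corr_r_threshold: float = 0.3,
        dip_boot: int = 200,
    ) -> None:
        self.data = data.reset_index(drop=True)
        self.thresholds = thresholds or CleaningThresholds()
        self.bin_variable = bin_variable
        self.bin_method = bin_method
        self.corr_alpha = corr_alpha
        self.corr_r_threshold = corr_r_threshold
        self.dip_boot = dip_boot
        labels = self.data["group_label"].unique()
        self.group_label = str(labels[0]) if len(labels) == 1 else "mixed"

    @classmethod
    def from_workbook(
        cls,
        path: str | os.PathLike,
        group_label: str,
        myelin: str = "two-sided",
        **kwargs,
    ) -> "GRatioModel":
        """Build a model from a paired-column XLS/XLSX workbook."""
        return cls(load_measurements(path, group_label, myelin=myelin), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, group_label: str | None = None,
                       **kwargs) -> "GRatioModel":
        """Build a model from an in-memory measurement table."""
        df = df.copy()
        if group_label is not None:
            df["group_label"] = group_label
        if "source_row" not in df:
            df["source_row"] = range(1, len(df) + 1)
        if "sample_id" not in df:
            df["sample_id"] = group_label or "S1"
        return cls(df, **kwargs)

    def fit(self, scheme: BinScheme | None = None) -> "GRatioResults":
        """Run the pipeline; derive bins from this data unless a (control)
        scheme is supplied."""
        stage_counts: list[tuple[str, int, int]] = []
        log = ExclusionLog()

        n0 = len(self.data)
        cleaned, clean_log = clean_measurements(self.data, self.thresholds)
        log.extend(clean_log)
        stage_counts.append(("clean", n0, len(cleaned)))

        fibered = compute_fiber_and_g(cleaned)
        stage_counts.append(("fiber_and_g", len(cleaned), len(fibered)))

        kept, g_log = filter_physiological_g(fibered, self.thresholds)
        log.extend(g_log)
        stage_counts.append(("physiological_g", len(fibered), len(kept)))

        derived_here = scheme is None
        if scheme is None:
            scheme = derive_bins(kept, self.bin_variable, self.bin_method,
                                 source=self.group_label)
        binned, out_of_range = assign_bins(kept, scheme)
        stage_counts.append(("assign_bins", len(kept), len(binned)))

        summaries = summarize_bins(binned, scheme, n_boot=self.dip_boot)
        grand = grand_mean_g(summaries, "unweighted")
        grand_w = grand_mean_g(summaries, "n_weighted")
        corr = (
            flag_g_vs_fiber_correlation(binned, self.corr_alpha,
                                        self.corr_r_threshold)
            if len(binned) >= 3 else None
        )
        return GRatioResults(
            model=self,
            records=binned,
            scheme=scheme,
            scheme_derived_here=derived_here,
            summaries=summaries,
            grand_g=grand,
            grand_g_weighted=grand_w,
            exclusions=log,
            out_of_range=out_of_range,
            correlation=corr,
            stage_counts=stage_counts,
        )


@dataclass
class GRatioResults:
    """Fitted single-group results; see :meth:`summary`."""

    model: GRatioModel
    records: pd.DataFrame
    scheme: BinScheme
    scheme_derived_here: bool
    summaries: pd.DataFrame
    grand_g: GrandG
    grand_g_weighted: GrandG
    exclusions: ExclusionLog
    out_of_range: pd.DataFrame
    correlation: CorrelationReport | None
    stage_counts: list = field(default_factory=list)

    @property
    def pooled_mean_g(self) -> float:
        """Mean full-precision g over all retained fibers."""
        return float(self.records["g_ratio"].mean())

    def save(self, out_dir: str | os.PathLike) -> dict[str, str]:
        """Write the cleaned-data, bin-summary and exclusion workbooks."""
        extra = {"bin_scheme": self.scheme.to_frame(),
                 "grand_g": pd.concat(
                     [self.grand_g.to_frame(), self.grand_g_weighted.to_frame()],
                     ignore_index=True)}
        if self.correlation is not None:
            extra["g_fiber_correlation"] = self.correlation.to_frame()
        return write_outputs(self.records, self.summaries, self.exclusions,
                             out_dir, extra_sheets=extra)

    def summary(self) -> str:
        """Human-readable report of the fit."""
        lines = [
            f"G-ratio analysis: group {self.model.group_label}",
            "=" * 58,
            f"records in: {self.stage_counts[0][1]}   retained: "
            f"{len(self.records)}   excluded: {len(self.exclusions)}",
        ]
        counts = self.exclusions.counts()
        if counts:
            lines.append("exclusions: " + ", ".join(
                f"{k}={v}" for k, v in sorted(counts.items())))
        lines.append(
            f"bins ({self.scheme.method} on {self.scheme.variable}, "
            f"source {self.scheme.source}):"
        )
        lines.append(f"{'bin':>4} {'range (um)':>16} {'n':>6} {'mean g':>8} "
                     f"{'median':>8} {'sd':>8} {'W':>7} {'p(W)':>7}")
        for _, r in self.summaries.iterrows():
            lo = self.scheme.edges[int(r.bin_index) - 1]
            hi = self.scheme.edges[int(r.bin_index)]
            lines.append(
                f"{int(r.bin_index):>4} {lo:>7.3f}-{hi:<8.3f} {int(r.n):>6} "
                f"{r.mean_g:>8.4f} {r.median_g:>8.4f} {r.sd_g:>8.4f} "
                f"{r.shapiro_W:>7.3f} {r.shapiro_p:>7.3f}"
            )
        lines.append(
            f"grand mean g (constant-g fit to bin means): "
            f"{self.grand_g.value:.4f}   "
            f"(n-weighted/pooled: {self.grand_g_weighted.value:.4f})"
        )
        if self.correlation is not None:
            c = self.correlation
            state = "FLAGGED" if c.flagged else "ok"
            lines.append(
                f"fiber-g correlation: r={c.r:.3f}, p={c.p:.3g} [{state}]"
            )
        if len(self.out_of_range):
            lines.append(f"out-of-range fibers clamped: {len(self.out_of_range)}")
        return "\n".join(lines)


class GRatioComparison:
    """Control vs experimental comparison on control-derived bins."""

    def __init__(self, control: GRatioModel, experimental: GRatioModel) -> None:
        self.control = control
        self.experimental = experimental

    @classmethod
    def from_workbooks(
        cls,
        control_path: str | os.PathLike,
        experimental_path: str | os.PathLike,
        control_label: str = "CTL",
        experimental_label: str = "EXP",
        myelin: str = "two-sided",
        **kwargs,
    ) -> "GRatioComparison":
        return cls(
            GRatioModel.from_workbook(control_path, control_label,
                                      myelin=myelin, **kwargs),
            GRatioModel.from_workbook(experimental_path, experimental_label,
                                      myelin=myelin, **kwargs),
        )

    def fit(self) -> "ComparisonResults":
        ctl = self.control.fit()
        exp = self.experimental.fit(scheme=ctl.scheme)
        combined = pd.concat([ctl.records, exp.records], ignore_index=True)
        anova = two_way_anova(combined)
        paired = pd.concat([ctl.summaries, exp.summaries], ignore_index=True)
        return ComparisonResults(
            control=ctl, experimental=exp, anova_table=anova,
            paired_summaries=paired,
        )


@dataclass
class ComparisonResults:
    control: GRatioResults
    experimental: GRatioResults
    anova_table: pd.DataFrame
    paired_summaries: pd.DataFrame

    def summary(self) -> str:
        lines = [
            self.control.summary(),
            "",
            self.experimental.summary(),
            "",
            "Two-way ANOVA (g ~ group * bin, Type II SS)",
            "=" * 58,
        ]
        for _, r in self.anova_table.iterrows():
            f_txt = "" if pd.isna(r.F) else f" F={r.F:10.4f} p={r.p:.4g}"
            lines.append(
                f"{r.term:>10}: df={int(r.df):>5} SS={r.sum_sq:12.6f}{f_txt}"
            )
        return "\n".join(lines)
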