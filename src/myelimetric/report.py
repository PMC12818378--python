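"""Workflow orchestration: full analysis / comparison runs with a manifest.

Every run writes its outputs plus ``run_manifest.txt`` recording inputs,
configuration, per-stage row counts and output paths, so each processing
step is traceable and the conservation chain (rows out of one stage = rows
into the next) can be audited.
"""

from __future__ import annotations

import datetime as _dt
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from .cleaning import CleaningThresholds
from .model import ComparisonResults, GRatioComparison, GRatioModel, GRatioResults
from .plots import make_plots, plot_group_comparison

log = logging.getLogger("myelimetric")


@dataclass
class RunManifest:
    """Traceability record for one pipeline run."""

    inputs: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)  # (name, rows_in, rows_out)
    outputs: list = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def validate_chain(self) -> None:
        """Each stage must consume exactly what the previous one produced."""
        for (name_a, _in_a, out_a), (name_b, in_b, _out_b) in zip(
            self.stages, self.stages[1:]
        ):
            if out_a != in_b:
                raise ValueError(
                    f"row-count chain broken between {name_a} ({out_a} out) "
                    f"and {name_b} ({in_b} in)"
                )

    def write(self, path: str) -> str:
        self.validate_chain()
        lines = [
            "myelimetric run manifest",
            f"started:  {self.started}",
            f"finished: {self.finished}",
            "",
            "[inputs]",
            *(f"  {k} = {v}" for k, v in self.inputs.items()),
            "",
            "[config]",
            *(f"  {k} = {v}" for k, v in self.config.items()),
            "",
            "[stages]  (name: rows_in -> rows_out)",
            *(f"  {n}: {i} -> {o}" for n, i, o in self.stages),
            "",
            "[outputs]",
            *(f"  {p}" for p in self.outputs),
        ]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
        return path


def _setup_run_logging(out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(out_dir, "run.log"))
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)


def _manifest_for(result: GRatioResults, inputs: dict,
                  thresholds: CleaningThresholds) -> RunManifest:
    man = RunManifest(
        inputs=inputs,
        config={
            "thresholds": thresholds,
            "bin_edges": result.scheme.edges,
            "bin_variable": result.scheme.variable,
            "bin_method": result.scheme.method,
        },
        stages=list(result.stage_counts),
        started=_dt.datetime.now().isoformat(timespec="seconds"),
    )
    return man


def run_analysis(
    input_workbook: str,
    group_label: str,
    out_dir: str,
    thresholds: CleaningThresholds | None = None,
    myelin: str = "two-sided",
    bin_variable: str = "fiber_diameter",
    bin_method: str = "equal_width",
    scheme=None,
    write_plots: bool = True,
) -> GRatioResults:
    """Single-group workflow: load -> fit -> save outputs, plots, manifest."""
    _setup_run_logging(out_dir)
    thresholds = thresholds or CleaningThresholds()
    log.info("analysis start: %s (group %s)", input_workbook, group_label)
    model = GRatioModel.from_workbook(
        input_workbook, group_label, myelin=myelin, thresholds=thresholds,
        bin_variable=bin_variable, bin_method=bin_method,
    )
    result = model.fit(scheme=scheme)
    man = _manifest_for(
        result, {"workbook": input_workbook, "group": group_label}, thresholds
    )
    paths = result.save(out_dir)
    man.outputs.extend(paths.values())
    if write_plots:
        man.outputs.extend(make_plots(result.records, out_dir, prefix=group_label))
    man.finished = _dt.datetime.now().isoformat(timespec="seconds")
    man.write(os.path.join(out_dir, "run_manifest.txt"))
    log.info("analysis done: %d retained, %d excluded",
             len(result.records), len(result.exclusions))
    return result


def run_comparison(
    control_workbook: str,
    experimental_workbook: str,
    out_dir: str,
    thresholds: CleaningThresholds | None = None,
    myelin: str = "two-sided",
    bin_variable: str = "fiber_diameter",
    bin_method: str = "equal_width",
    write_plots: bool = True,
) -> ComparisonResults:
    """Two-group workflow: control-derived bins applied to both groups,
    paired summaries, two-way ANOVA, comparison plots, manifest."""
    _setup_run_logging(out_dir)
    thresholds = thresholds or CleaningThresholds()
    log.info("comparison start: %s vs %s", control_workbook, experimental_workbook)
    comp = GRatioComparison.from_workbooks(
        control_workbook, experimental_workbook, myelin=myelin,
        thresholds=thresholds, bin_variable=bin_variable, bin_method=bin_method,
    )
    res = comp.fit()
    ctl_dir = os.path.join(out_dir, "CTL")
    exp_dir = os.path.join(out_dir, "EXP")
    man = _manifest_for(
        res.control,
        {"control": control_workbook, "experimental": experimental_workbook},
        thresholds,
    )
    man.outputs.extend(res.control.save(ctl_dir).values())
    man.outputs.extend(res.experimental.save(exp_dir).values())
    res.anova_table.to_excel(
        os.path.join(out_dir, "anova.xlsx"), index=False
    )
    man.outputs.append(os.path.join(out_dir, "anova.xlsx"))
    if write_plots:
        man.outputs.extend(
            make_plots(res.control.records, out_dir, prefix="CTL"))
        man.outputs.extend(
            make_plots(res.experimental.records, out_dir, prefix="EXP"))
        combined = pd.concat(
            [res.control.records, res.experimental.records], ignore_index=True
        )
        p = plot_group_comparison(
            combined, os.path.join(out_dir, "group_comparison.png"))
        if p:
            man.outputs.append(p)
    man.finished = _dt.datetime.now().isoformat(timespec="seconds")
    man.write(os.path.join(out_dir, "run_manifest.txt"))
    log.info("comparison done")
    return res
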