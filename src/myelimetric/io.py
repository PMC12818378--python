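"""Workbook input/output.

Measurement workbooks pair columns by a shared sample prefix:
``<Sample>_Ax`` holds axon diameters and ``<Sample>_My`` holds myelin
thickness, both in micrometres. The myelin column is the *two-sided*
(diameter-contribution) value; one-sided radial measurements are doubled at
load when ``myelin="one-sided"`` is requested.

In memory a measurement table is a plain :class:`pandas.DataFrame` with the
columns in :data:`MEASUREMENT_COLUMNS`; downstream stages append
``fiber_diameter``, ``g_ratio`` and ``bin_index``. One row is one axon.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import EmptyWorkbookError, MissingCounterpartError

#: Core columns of a measurement table (one row per measured axon).
MEASUREMENT_COLUMNS = [
    "sample_id",
    "group_label",
    "axon_diameter",
    "myelin_total",
    "source_row",
]

#: Reason codes an excluded row may carry, in the order filters test them.
EXCLUSION_REASONS = [
    "missing",
    "nonfinite_or_nonpositive",
    "axon_below_min",
    "myelin_below_min",
    "g_out_of_range",
]

_AX_SUFFIX = "_Ax"
_MY_SUFFIX = "_My"


@dataclass
class ExclusionLog:
    """Ledger of every row removed anywhere in the pipeline.

    Each entry records the source row, sample, raw values and a single
    reason code, so ``rows_in == rows_out + len(log)`` holds at every stage.
    """

    entries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["source_row", "sample_id", "axon", "myelin", "reason"]
        )
    )

    def append(self, rows: pd.DataFrame, reason: str) -> None:
        if reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason: {reason!r}")
        if len(rows) == 0:
            return
        chunk = pd.DataFrame(
            {
                "source_row": rows["source_row"].to_numpy(),
                "sample_id": rows["sample_id"].to_numpy(),
                "axon": rows["axon_diameter"].to_numpy(),
                "myelin": rows["myelin_total"].to_numpy(),
                "reason": reason,
            }
        )
        if len(self.entries):
            self.entries = pd.concat([self.entries, chunk], ignore_index=True)
        else:
            self.entries = chunk

    def extend(self, other: "ExclusionLog") -> None:
        if len(other.entries):
            if len(self.entries):
                self.entries = pd.concat(
                    [self.entries, other.entries], ignore_index=True
                )
            else:
                self.entries = other.entries.copy()

    def counts(self) -> dict[str, int]:
        """Number of excluded rows per reason code."""
        return self.entries["reason"].value_counts().to_dict()

    def __len__(self) -> int:
        return len(self.entries)


def _paired_prefixes(columns: list[str]) -> list[str]:
    """Sample prefixes with both ``_Ax`` and ``_My`` columns; raises when a
    column lacks its counterpart. Suffix matching is case-sensitive."""
    ax = {c[: -len(_AX_SUFFIX)] for c in columns if c.endswith(_AX_SUFFIX)}
    my = {c[: -len(_MY_SUFFIX)] for c in columns if c.endswith(_MY_SUFFIX)}
    lone_ax = ax - my
    lone_my = my - ax
    if lone_ax or lone_my:
        missing = sorted(f"{p}{_MY_SUFFIX}" for p in lone_ax) + sorted(
            f"{p}{_AX_SUFFIX}" for p in lone_my
        )
        raise MissingCounterpartError(
            "paired column(s) missing: " + ", ".join(missing)
        )
    # preserve sheet order of the _Ax columns
    ordered = [
        c[: -len(_AX_SUFFIX)]
        for c in columns
        if c.endswith(_AX_SUFFIX) and c[: -len(_AX_SUFFIX)] in my
    ]
    return ordered


def load_measurements(
    workbook_path: str | os.PathLike,
    group_label: str,
    myelin: str = "two-sided",
) -> pd.DataFrame:
    """Read a measurement workbook into a measurement table.

    Parameters
    ----------
    workbook_path
        XLS/XLSX file; every sheet is scanned for ``<prefix>_Ax`` /
        ``<prefix>_My`` column pairs (strict, case-sensitive prefix match).
    group_label
        Label attached to every record (e.g. ``"CTL"``, ``"EXP"``).
    myelin
        ``"two-sided"`` stores the column as-is; ``"one-sided"`` doubles it
        so downstream always works with the diameter contribution 2m.

    Returns
    -------
    DataFrame with :data:`MEASUREMENT_COLUMNS`. Non-numeric or empty cells
    become NaN (flagged "missing" later by cleaning, not an error here).
    ``source_row`` is the 1-based data row within the source sheet.
    """
    if myelin not in ("two-sided", "one-sided"):
        raise ValueError("myelin must be 'two-sided' or 'one-sided'")
    sheets = pd.read_excel(workbook_path, sheet_name=None, engine="openpyxl")
    factor = 2.0 if myelin == "one-sided" else 1.0

    frames = []
    for _sheet_name, df in sheets.items():
        if df.empty and not len(df.columns):
            continue
        cols = [str(c) for c in df.columns]
        df.columns = cols
        prefixes = _paired_prefixes(cols)
        for prefix in prefixes:
            ax = pd.to_numeric(df[f"{prefix}{_AX_SUFFIX}"], errors="coerce")
            my = pd.to_numeric(df[f"{prefix}{_MY_SUFFIX}"], errors="coerce")
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": prefix,
                        "group_label": group_label,
                        "axon_diameter": ax.to_numpy(dtype=float),
                        "myelin_total": my.to_numpy(dtype=float) * factor,
                        "source_row": np.arange(1, len(df) + 1),
                    }
                )
            )
    if not frames:
        raise EmptyWorkbookError(f"no paired _Ax/_My columns in {workbook_path}")
    out = pd.concat(frames, ignore_index=True)
    if not len(out):
        raise EmptyWorkbookError(f"no data rows in {workbook_path}")
    return out


def measurements_to_workbook(records: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a measurement table back to the paired-column workbook layout
    (one sheet per sample, columns ``<sample>_Ax`` / ``<sample>_My``)."""
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        for sid, sub in records.groupby("sample_id", sort=False):
            sheet = pd.DataFrame(
                {
                    f"{sid}{_AX_SUFFIX}": sub["axon_diameter"].to_numpy(),
                    f"{sid}{_MY_SUFFIX}": sub["myelin_total"].to_numpy(),
                }
            )
            # extra columns use non-paired names so a re-load ignores them
            if "fiber_diameter" in sub:
                sheet[f"{sid}_Fiber"] = sub["fiber_diameter"].to_numpy()
            if "g_ratio_2dp" in sub:
                sheet[f"{sid}_g"] = sub["g_ratio_2dp"].to_numpy()
            sheet.to_excel(writer, sheet_name=str(sid)[:31], index=False)


def write_outputs(
    records: pd.DataFrame,
    summaries: pd.DataFrame,
    log: ExclusionLog,
    out_dir: str | os.PathLike,
    extra_sheets: dict[str, pd.DataFrame] | None = None,
) -> dict[str, str]:
    """Persist cleaned data, per-bin summaries and the exclusion log.

    Returns a mapping of logical name -> written path. ``extra_sheets`` adds
    sheets (bin scheme, grand g, ANOVA, diagnostics) to the summary workbook.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "cleaned_data": os.path.join(out_dir, "cleaned_data.xlsx"),
        "bin_summary": os.path.join(out_dir, "bin_summary.xlsx"),
        "exclusions": os.path.join(out_dir, "exclusions.xlsx"),
    }
    measurements_to_workbook(records, paths["cleaned_data"])
    with pd.ExcelWriter(paths["bin_summary"], engine="openpyxl") as writer:
        summaries.to_excel(writer, sheet_name="bin_summary", index=False)
        for name, frame in (extra_sheets or {}).items():
            frame.to_excel(writer, sheet_name=name[:31], index=False)
    with pd.ExcelWriter(paths["exclusions"], engine="openpyxl") as writer:
        log.entries.to_excel(writer, sheet_name="exclusions", index=False)
    return paths
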