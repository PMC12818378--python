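"""Biologically informed exclusion filters.

Axons thinner than 0.15 um are rare and of doubtful functional relevance,
and myelin sheaths under 0.03 um are too thin to insulate; measurements
below those floors are treated as segmentation/preparation artefacts and
removed. A separate plausibility filter drops fibers whose g-ratio falls
outside the physiological range (default 0.5-0.9). Both filters can be
bypassed as a block; removal of missing or structurally invalid rows
(non-finite, non-positive) cannot.

Comparisons are strict: a row exactly at a threshold is retained. Each
excluded row is logged once with its first matching reason in the fixed
order missing -> nonfinite_or_nonpositive -> axon_below_min ->
myelin_below_min, so per-reason counts always sum to rows_in - rows_out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExclusionLog


@dataclass(frozen=True)
class CleaningThresholds:
    """Exclusion thresholds, all in micrometres except the unitless g range.

    ``enabled=False`` bypasses the threshold and g-range filters; missing /
    non-finite removal still applies.
    """

    axon_min: float = 0.15
    myelin_min: float = 0.03
    g_low: float = 0.5
    g_high: float = 0.9
    enabled: bool = True

    def __post_init__(self) -> None:
        if not (self.axon_min > 0 and self.myelin_min > 0):
            raise ValueError("axon_min and myelin_min must be positive")
        if not (0 < self.g_low < self.g_high < 1):
            raise ValueError("need 0 < g_low < g_high < 1")


def clean_measurements(
    records: pd.DataFrame,
    thresholds: CleaningThresholds | None = None,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Remove missing/invalid rows and apply the size thresholds.

    Returns the retained rows (a copy, original order preserved) and an
    :class:`ExclusionLog` with one entry per removed row. Never raises on
    data content.
    """
    thresholds = thresholds or CleaningThresholds()
    log = ExclusionLog()
    ax = records["axon_diameter"].to_numpy(dtype=float)
    my = records["myelin_total"].to_numpy(dtype=float)

    missing = np.isnan(ax) | np.isnan(my)
    bad = (~missing) & (~np.isfinite(ax) | ~np.isfinite(my) | (ax <= 0) | (my <= 0))
    removed = missing | bad
    if thresholds.enabled:
        axon_low = (~removed) & (ax < thresholds.axon_min)
        removed |= axon_low
        myelin_low = (~removed) & (my < thresholds.myelin_min)
        removed |= myelin_low
    else:
        axon_low = myelin_low = np.zeros(len(records), dtype=bool)

    log.append(records[missing], "missing")
    log.append(records[bad], "nonfinite_or_nonpositive")
    log.append(records[axon_low], "axon_below_min")
    log.append(records[myelin_low], "myelin_below_min")
    return records[~removed].copy(), log


def filter_physiological_g(
    records: pd.DataFrame,
    thresholds: CleaningThresholds | None = None,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Drop fibers with g outside ``[g_low, g_high]`` (inclusive bounds).

    Requires a ``g_ratio`` column (full precision). No-op when cleaning is
    bypassed.
    """
    thresholds = thresholds or CleaningThresholds()
    log = ExclusionLog()
    if not thresholds.enabled:
        return records.copy(), log
    g = records["g_ratio"].to_numpy(dtype=float)
    out = (g < thresholds.g_low) | (g > thresholds.g_high)
    log.append(records[out], "g_out_of_range")
    return records[~out].copy(), log
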