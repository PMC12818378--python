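"""Control-derived diameter binning.

Six contiguous diameter intervals are derived from the *control* dataset
(the physiological reference frame) and then applied unchanged to every
group, so cross-group comparisons are made within the same caliber cohort.
Six bins balance caliber resolution against per-bin sample size.

Intervals are half-open ``[e_i, e_{i+1})`` except the last, which is closed
above. Experimental values outside the control range are clamped into the
first/last bin and counted, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import DegenerateControlError

N_BINS = 6

BIN_VARIABLES = ("fiber_diameter", "axon_diameter")
BIN_METHODS = ("equal_width", "quantile")


@dataclass(frozen=True)
class BinScheme:
    """Six diameter intervals defined by 7 strictly ascending edges (um).

    ``variable`` names the diameter the edges partition (fiber by default;
    axon selectable). ``source`` records which dataset the edges came from.
    """

    edges: tuple[float, ...]
    variable: str = "fiber_diameter"
    source: str = ""
    method: str = "equal_width"

    def __post_init__(self) -> None:
        if len(self.edges) != N_BINS + 1:
            raise ValueError(f"need {N_BINS + 1} edges, got {len(self.edges)}")
        if not np.all(np.diff(self.edges) > 0):
            raise ValueError("edges must be strictly ascending")
        if self.variable not in BIN_VARIABLES:
            raise ValueError(f"variable must be one of {BIN_VARIABLES}")
        if self.method not in BIN_METHODS:
            raise ValueError(f"method must be one of {BIN_METHODS}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_index": np.arange(1, N_BINS + 1),
                "lower": self.edges[:-1],
                "upper": self.edges[1:],
                "variable": self.variable,
                "method": self.method,
                "source": self.source,
            }
        )


def derive_bins(
    control: pd.DataFrame,
    variable: str = "fiber_diameter",
    method: str = "equal_width",
    source: str = "control",
) -> BinScheme:
    """Build the six-bin scheme from the control distribution.

    ``equal_width`` partitions [min, max] into six equal intervals;
    ``quantile`` places edges at the 0, 1/6, ..., 1 empirical quantiles
    (equalising per-bin n). Fewer than six records, a constant variable, or
    collapsing quantile edges raise :class:`DegenerateControlError`.
    """
    if variable not in BIN_VARIABLES:
        raise ValueError(f"variable must be one of {BIN_VARIABLES}")
    if method not in BIN_METHODS:
        raise ValueError(f"method must be one of {BIN_METHODS}")
    v = control[variable].to_numpy(dtype=float)
    if len(v) < N_BINS:
        raise DegenerateControlError(
            f"need at least {N_BINS} control records to derive bins, got {len(v)}"
        )
    lo, hi = float(np.min(v)), float(np.max(v))
    if lo == hi:
        raise DegenerateControlError(
            f"all control values of {variable} are equal ({lo}); cannot bin"
        )
    if method == "equal_width":
        edges = np.linspace(lo, hi, N_BINS + 1)
    else:
        edges = np.quantile(v, np.linspace(0.0, 1.0, N_BINS + 1))
        if not np.all(np.diff(edges) > 0):
            raise DegenerateControlError(
                f"quantile edges of {variable} collapse (ties dominate a bin)"
            )
    return BinScheme(tuple(float(e) for e in edges), variable, source, method)


def assign_bins(
    records: pd.DataFrame, scheme: BinScheme
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign every record a ``bin_index`` in 1..6 under ``scheme``.

    Values below the first or above the last edge (possible for
    experimental groups binned on control-derived edges) are clamped into
    bins 1 and 6; those rows are returned in the out-of-range log.
    """
    v = records[scheme.variable].to_numpy(dtype=float)
    edges = np.asarray(scheme.edges)
    # interior edges decide membership; [e_i, e_{i+1}) with last bin closed
    idx = np.searchsorted(edges[1:-1], v, side="right")
    below = v < edges[0]
    above = v > edges[-1]
    out = records.copy()
    out["bin_index"] = idx + 1
    oor = records[below | above].copy()
    oor["clamped_to"] = np.where(above[below | above], N_BINS, 1)
    return out, oor
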