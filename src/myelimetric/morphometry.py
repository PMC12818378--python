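"""Fiber diameter and g-ratio computation.

For an axon of diameter a with total (two-sided) myelin My, the fiber
diameter is f = a + My and the g-ratio g = a / f. With one-sided sheath
thickness m = My/2 this is the classical identity g = a / (a + 2m).

Full-precision g drives every statistic; the conventional 2-decimal
rendering is a presentation-layer column only (rounding before averaging
would bias means by up to 0.005).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._errors import InvariantViolationError


def round_half_away(x, decimals: int = 2):
    """Round half away from zero (0.005 -> 0.01), unlike numpy's
    banker's rounding."""
    x = np.asarray(x, dtype=float)
    scale = 10.0**decimals
    return np.sign(x) * np.floor(np.abs(x) * scale + 0.5) / scale


def compute_fiber_and_g(records: pd.DataFrame) -> pd.DataFrame:
    """Append ``fiber_diameter``, full-precision ``g_ratio`` and the
    2-decimal ``g_ratio_2dp`` columns.

    Inputs must already be cleaned: any non-finite or non-positive value is
    an invariant violation, not a data condition.
    """
    ax = records["axon_diameter"].to_numpy(dtype=float)
    my = records["myelin_total"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(ax)) and np.all(np.isfinite(my))):
        raise InvariantViolationError("non-finite measurement past cleaning")
    if np.any(ax <= 0) or np.any(my <= 0):
        raise InvariantViolationError("non-positive measurement past cleaning")
    out = records.copy()
    fiber = ax + my
    out["fiber_diameter"] = fiber
    out["g_ratio"] = ax / fiber
    out["g_ratio_2dp"] = round_half_away(ax / fiber, 2)
    return out


@dataclass(frozen=True)
class CorrelationReport:
    """Plausibility diagnostic: fiber diameter vs g-ratio association.

    Under the axomyelin-unit model g is roughly constant across fiber
    calibers, so a strong fiber-g correlation points at a methodological
    artefact (segmentation bias, resolution mismatch, sampling error)
    rather than biology. ``r`` is NaN for degenerate (zero-variance) input.
    """

    r: float
    p: float
    n: int
    r_threshold: float
    alpha: float
    flagged: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def flag_g_vs_fiber_correlation(
    records: pd.DataFrame,
    alpha: float = 0.05,
    r_threshold: float = 0.3,
) -> CorrelationReport:
    """Pearson correlation between fiber diameter and full-precision g.

    Flags when ``|r| >= r_threshold`` and ``p < alpha``. Purely diagnostic;
    never mutates or filters the data. Requires >= 3 records.
    """
    if len(records) < 3:
        raise ValueError("correlation diagnostic needs at least 3 records")
    f = records["fiber_diameter"].to_numpy(dtype=float)
    g = records["g_ratio"].to_numpy(dtype=float)
    if np.ptp(f) == 0 or np.ptp(g) == 0:
        return CorrelationReport(
            r=float("nan"), p=float("nan"), n=len(records),
            r_threshold=r_threshold, alpha=alpha, flagged=False,
        )
    res = sps.pearsonr(f, g)
    r, p = float(res.statistic), float(res.pvalue)
    return CorrelationReport(
        r=r, p=p, n=len(records), r_threshold=r_threshold, alpha=alpha,
        flagged=bool(abs(r) >= r_threshold and p < alpha),
    )
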