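"""Standard plots: per-sample axon-vs-fiber scatter with a linear fit,
per-sample g-ratio histograms in frequency-%, and two-group overlays."""

from __future__ import annotations

import logging
import os

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

log = logging.getLogger("myelimetric")

HIST_BINS = 20


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def plot_axon_fiber_scatter(records: pd.DataFrame, path: str) -> str | None:
    """Axon vs fiber diameter per sample, with an OLS line per sample.

    Under the axomyelin unit model the relation is linear with slope 1/g.
    Returns the written path, or None when there are too few points.
    """
    if len(records) < 2:
        log.warning("scatter skipped: fewer than 2 records")
        return None
    fig, ax = plt.subplots(figsize=(5, 4))
    for sid, sub in records.groupby("sample_id", sort=False):
        x = sub["axon_diameter"].to_numpy(float)
        y = sub["fiber_diameter"].to_numpy(float)
        pts = ax.plot(x, y, ".", ms=3, alpha=0.5, label=str(sid))[0]
        if len(sub) >= 2 and np.ptp(x) > 0:
            slope, intercept = _ols_line(x, y)
            xs = np.array([x.min(), x.max()])
            ax.plot(xs, slope * xs + intercept, "-", lw=1,
                    color=pts.get_color())
    ax.set_xlabel("axon diameter (µm)")
    ax.set_ylabel("fiber diameter (µm)")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_g_histograms(records: pd.DataFrame, path: str) -> str | None:
    """Per-sample g-ratio histograms normalised to frequency (%)."""
    if len(records) < 2:
        log.warning("histogram skipped: fewer than 2 records")
        return None
    samples = list(records.groupby("sample_id", sort=False))
    fig, axes = plt.subplots(
        1, len(samples), figsize=(2.6 * len(samples), 2.6),
        sharey=True, squeeze=False,
    )
    for ax, (sid, sub) in zip(axes[0], samples):
        g = sub["g_ratio"].to_numpy(float)
        ax.hist(g, bins=HIST_BINS, weights=np.full(g.size, 100.0 / g.size))
        ax.set_title(str(sid), fontsize=8)
        ax.set_xlabel("g-ratio")
    axes[0][0].set_ylabel("frequency (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_group_comparison(records: pd.DataFrame, path: str) -> str | None:
    """Overlayed g-ratio histograms (frequency-%) for two or more groups."""
    groups = list(records.groupby("group_label", sort=False))
    if len(groups) < 2:
        log.warning("comparison plot skipped: fewer than 2 groups")
        return None
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, sub in groups:
        g = sub["g_ratio"].to_numpy(float)
        ax.hist(g, bins=HIST_BINS, weights=np.full(g.size, 100.0 / g.size),
                alpha=0.5, label=str(label))
    ax.set_xlabel("g-ratio")
    ax.set_ylabel("frequency (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def make_plots(records: pd.DataFrame, out_dir: str, prefix: str = "") -> list[str]:
    """Write the standard plot set for one records table; returns the paths
    actually written (plots with too few points are skipped with a warning)."""
    os.makedirs(out_dir, exist_ok=True)
    tag = f"{prefix}_" if prefix else ""
    written = []
    for fn, name in (
        (plot_axon_fiber_scatter, "axon_fiber_scatter"),
        (plot_g_histograms, "g_histograms"),
        (plot_group_comparison, "group_comparison"),
    ):
        p = fn(records, os.path.join(out_dir, f"{tag}{name}.png"))
        if p:
            written.append(p)
    return written
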