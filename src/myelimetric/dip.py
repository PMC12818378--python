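"""Hartigan's dip statistic for unimodality.

The dip of an empirical CDF F_n is the largest deviation, over all x,
between F_n and the closest distribution function that is unimodal
(convex up to a mode, concave after it). Unimodal samples give dips near
the floor 1/(2n); well-separated mixtures give large dips.

The statistic is computed with the classical greatest-convex-minorant /
least-concave-majorant iteration over candidate modal intervals, jitted
with numba so that Monte-Carlo null calibration stays cheap. P-values are
calibrated against the uniform distribution — the asymptotically least
favourable unimodal null — by seeded simulation at the observed n; the
null tables are cached per sample size.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["dip_statistic", "dip_test"]


@njit(cache=True)
def _dip_kernel(xs: np.ndarray) -> float:
    """Dip of sorted sample ``xs`` (ascending, n >= 2).

    Works in count units throughout (deviations measured against i/n
    scaled by n) and divides by 2n at the end, so the minimum attainable
    value is 1/(2n).
    """
    n = xs.shape[0]
    dip = 1.0
    if xs[n - 1] == xs[0]:
        return dip / (2.0 * n)

    # 1-based arrays to keep the hull index bookkeeping readable
    x = np.empty(n + 1)
    x[1:] = xs
    mn = np.zeros(n + 1, dtype=np.int64)
    mj = np.zeros(n + 1, dtype=np.int64)
    gcm = np.zeros(n + 2, dtype=np.int64)
    lcm = np.zeros(n + 2, dtype=np.int64)
    low, high = 1, n

    # predecessor links for the greatest convex minorant over [1, j]
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or (
                (x[j] - x[mnj]) * (mnj - mnmnj)
                < (x[mnj] - x[mnmnj]) * (j - mnj)
            ):
                break
            mn[j] = mnmnj

    # successor links for the least concave majorant over [k, n]
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n or (
                (x[k] - x[mjk]) * (mjk - mjmjk)
                < (x[mjk] - x[mjmjk]) * (k - mjk)
            ):
                break
            mj[k] = mjmjk

    while True:
        # GCM change points on [low, high], stored high -> low
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        l_gcm = i
        ig = i
        ix = ig - 1

        # LCM change points on [low, high], stored low -> high
        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        l_lcm = i
        ih = i
        iv = 2

        # largest separation between the two hulls inside [low, high]
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (x[gcmix] - x[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (
                        x[lcmiv] - x[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0

        if d < dip:
            break

        # max deviation of F_n above the GCM on [low, gcm[ig]]
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb = gcm[j + 1]
            je = gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t

        # max deviation of F_n below the LCM on [lcm[ih], high]
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb = lcm[j]
            je = lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        if dip < max(dip_l, dip_u):
            dip = max(dip_l, dip_u)
        if low == gcm[ig] and high == lcm[ih]:
            break
        low = gcm[ig]
        high = lcm[ih]

    return dip / (2.0 * n)


def dip_statistic(values) -> float:
    """Dip statistic of a univariate sample (requires n >= 4)."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < 4:
        raise ValueError("dip statistic needs at least 4 observations")
    if not np.all(np.isfinite(v)):
        raise ValueError("dip statistic requires finite values")
    return float(_dip_kernel(v))


_NULL_SEED = 190_285  # year of Hartigan & Hartigan, fixed for reproducibility
_null_cache: dict[tuple[int, int], np.ndarray] = {}


def _null_dips(n: int, n_boot: int) -> np.ndarray:
    key = (n, n_boot)
    if key not in _null_cache:
        rng = np.random.default_rng([_NULL_SEED, n, n_boot])
        sims = np.empty(n_boot)
        for b in range(n_boot):
            sims[b] = _dip_kernel(np.sort(rng.random(n)))
        _null_cache[key] = np.sort(sims)
    return _null_cache[key]


def dip_test(values, n_boot: int = 200) -> tuple[float, float]:
    """Dip statistic and Monte-Carlo p-value against the uniform null.

    Returns ``(dip, p)``. The p-value is ``(1 + #{null >= dip}) /
    (n_boot + 1)`` over ``n_boot`` seeded uniform samples of the same size,
    so results are deterministic for a given (n, n_boot).
    """
    d = dip_statistic(values)
    null = _null_dips(len(np.asarray(values)), n_boot)
    p = (1.0 + np.count_nonzero(null >= d)) / (n_boot + 1.0)
    return d, float(p)
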