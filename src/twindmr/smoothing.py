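"""Within-region smoothing of per-probe statistics.

Bump hunting smooths the per-probe phenotype coefficients over genomic
position before thresholding, so isolated noisy probes do not seed
candidate regions.  Smoothing never crosses region boundaries.

Two smoothers are provided:

``loess``  (default) - tricube-weighted local linear fit over the k nearest
    probes within the region, k = max(3, ceil(span * n)).  Regions with
    fewer than 4 probes fall back to the running mean.
``runmean`` - centered running mean of odd ``window`` size, truncated at
    region edges.

The loess path runs inside every bootstrap iteration (thousands of calls),
so it is compiled with numba when available; the pure-python fallback is
numerically identical.
"""

from __future__ import annotations

import math

import numpy as np

try:  # numba is optional; the fallback is identical but slower
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap(args[0]) if args and callable(args[0]) else wrap


@njit(cache=True)
def _loess_region(y, x, span, out, start, stop):
    n = stop - start
    k = max(3, int(math.ceil(span * n)))
    if k > n:
        k = n
    for i in range(start, stop):
        # bandwidth = distance to the k-th nearest neighbour (in-region)
        dists = np.empty(n)
        for j in range(n):
            dists[j] = abs(x[start + j] - x[i])
        ds = np.sort(dists)
        h = ds[k - 1]
        if h <= 0.0:
            # all selected probes share a position: plain mean
            s = 0.0
            c = 0
            for j in range(n):
                if dists[j] <= 0.0:
                    s += y[start + j]
                    c += 1
            out[i] = s / c
            continue
        # tricube weights, weighted linear fit evaluated at x[i]
        sw = swx = swy = swxx = swxy = 0.0
        for j in range(n):
            d = dists[j] / h
            if d > 1.0:
                continue
            w = (1.0 - d * d * d) ** 3
            xj = x[start + j] - x[i]
            yj = y[start + j]
            sw += w
            swx += w * xj
            swy += w * yj
            swxx += w * xj * xj
            swxy += w * xj * yj
        denom = sw * swxx - swx * swx
        if abs(denom) < 1e-12 * max(sw * swxx, 1e-300):
            out[i] = swy / sw
        else:
            b = (sw * swxy - swx * swy) / denom
            a = (swy - b * swx) / sw
            out[i] = a  # fitted value at xj = 0, i.e. at x[i]


@njit(cache=True)
def _runmean_region(y, half, out, start, stop):
    for i in range(start, stop):
        lo = i - half
        if lo < start:
            lo = start
        hi = i + half + 1
        if hi > stop:
            hi = stop
        s = 0.0
        for j in range(lo, hi):
            s += y[j]
        out[i] = s / (hi - lo)


@njit(cache=True)
def _smooth_all(y, x, bounds, span, min_loess, window, out):
    half = window // 2
    for r in range(bounds.shape[0] - 1):
        start, stop = bounds[r], bounds[r + 1]
        if stop - start >= min_loess:
            _loess_region(y, x, span, out, start, stop)
        else:
            _runmean_region(y, half, out, start, stop)


def region_bounds(region_codes: np.ndarray) -> np.ndarray:
    """Start offsets of each contiguous region run, plus the total length.

    ``region_codes`` must be grouped (all probes of a region contiguous).
    """
    codes = np.asarray(region_codes)
    changes = np.flatnonzero(np.diff(codes) != 0) + 1
    return np.concatenate(([0], changes, [len(codes)])).astype(np.int64)


def smooth_within_regions(
    values: np.ndarray,
    positions: np.ndarray,
    region_codes: np.ndarray,
    span: float = 0.3,
    method: str = "loess",
    window: int = 3,
) -> np.ndarray:
    """Smooth ``values`` within each region; boundaries are never crossed.

    Parameters
    ----------
    values : per-probe statistic (e.g. phenotype coefficients)
    positions : genomic positions, strictly increasing within a region
    region_codes : grouped region codes aligned to ``values``
    span : loess span (fraction of in-region probes in each local fit)
    method : ``"loess"`` or ``"runmean"``
    window : running-mean window (odd), used by ``runmean`` and by the
        small-region (< 4 probes) fallback of ``loess``
    """
    y = np.ascontiguousarray(values, dtype=np.float64)
    x = np.ascontiguousarray(positions, dtype=np.float64)
    if y.shape != x.shape:
        raise ValueError("values and positions must align")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    bounds = region_bounds(region_codes)
    out = np.empty_like(y)
    if method == "loess":
        _smooth_all(y, x, bounds, span, 4, window, out)
    elif method == "runmean":
        _smooth_all(y, x, bounds, span, len(y) + 2, window, out)
    else:
        raise ValueError(f"unknown smoothing method {method!r}")
    return out
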