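"""Numba kernel for adaptive-partitioning mutual information.

The estimator works on rank-transformed data (average ranks scaled by two so
ties stay integral).  Starting from the full rank plane it recursively
quadrisects each cell at the marginal medians of the points it contains,
splitting only while a chi-square test rejects uniformity of the four
quadrant counts.  At the leaves the plug-in contribution is
p_cell * ln(p_cell / (p_row * p_col)), with the marginal cell probabilities
computed from the actual marginal rank counts (so tied data behave like the
discrete distribution they are).

Recursion depth is capped (default 4, i.e. at most a 16 x 16 marginal
resolution); this bounds the variance of the estimate and the value it can
report on deterministic dependence.  At co-expression sample sizes (a few
dozen) the cap never binds because cell counts stop the splits first.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["mi_from_scaled_ranks", "mi_pairs"]


@njit(cache=True)
def _bisect_left(a, x):
    lo, hi = 0, a.size
    while lo < hi:
        mid = (lo + hi) // 2
        if a[mid] < x:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True)
def mi_from_scaled_ranks(rx, ry, srx, sry, chi2_crit, min_split, max_depth):
    """MI in nats for one pair of scaled-rank vectors.

    ``rx``/``ry`` are 2x average ranks (int64, modified in place while
    partitioning); ``srx``/``sry`` are sorted copies used for marginal
    counts.
    """
    n = rx.size
    hi_bound = 2 * n + 2
    stack = np.empty((8 + 4 * (max_depth + 1), 7), np.int64)
    stack[0, 0] = 0
    stack[0, 1] = n
    stack[0, 2] = 0
    stack[0, 3] = hi_bound
    stack[0, 4] = 0
    stack[0, 5] = hi_bound
    stack[0, 6] = 0
    top = 1
    mi = 0.0
    tmpx = np.empty(n, np.int64)
    tmpy = np.empty(n, np.int64)
    while top > 0:
        top -= 1
        s = stack[top, 0]
        e = stack[top, 1]
        x0 = stack[top, 2]
        x1 = stack[top, 3]
        y0 = stack[top, 4]
        y1 = stack[top, 5]
        d = stack[top, 6]
        m = e - s
        if m == 0:
            continue
        if d < max_depth and m >= min_split:
            # marginal medians of the cell's own points
            for i in range(m):
                tmpx[i] = rx[s + i]
                tmpy[i] = ry[s + i]
            tx = np.sort(tmpx[:m])
            ty = np.sort(tmpy[:m])
            xm = tx[m // 2]
            ym = ty[m // 2]
            c0 = 0
            c1 = 0
            c2 = 0
            c3 = 0
            for i in range(s, e):
                if rx[i] < xm:
                    if ry[i] < ym:
                        c0 += 1
                    else:
                        c1 += 1
                else:
                    if ry[i] < ym:
                        c2 += 1
                    else:
                        c3 += 1
            exp = m / 4.0
            stat = (
                (c0 - exp) ** 2 + (c1 - exp) ** 2
                + (c2 - exp) ** 2 + (c3 - exp) ** 2
            ) / exp
            if stat > chi2_crit:
                o0 = 0
                o1 = c0
                o2 = c0 + c1
                o3 = c0 + c1 + c2
                for i in range(s, e):
                    if rx[i] < xm:
                        if ry[i] < ym:
                            tmpx[o0] = rx[i]
                            tmpy[o0] = ry[i]
                            o0 += 1
                        else:
                            tmpx[o1] = rx[i]
                            tmpy[o1] = ry[i]
                            o1 += 1
                    else:
                        if ry[i] < ym:
                            tmpx[o2] = rx[i]
                            tmpy[o2] = ry[i]
                            o2 += 1
                        else:
                            tmpx[o3] = rx[i]
                            tmpy[o3] = ry[i]
                            o3 += 1
                for i in range(m):
                    rx[s + i] = tmpx[i]
                    ry[s + i] = tmpy[i]
                b0 = s
                b1 = s + c0
                b2 = s + c0 + c1
                b3 = s + c0 + c1 + c2
                stack[top, 0] = b0
                stack[top, 1] = b1
                stack[top, 2] = x0
                stack[top, 3] = xm
                stack[top, 4] = y0
                stack[top, 5] = ym
                stack[top, 6] = d + 1
                top += 1
                stack[top, 0] = b1
                stack[top, 1] = b2
                stack[top, 2] = x0
                stack[top, 3] = xm
                stack[top, 4] = ym
                stack[top, 5] = y1
                stack[top, 6] = d + 1
                top += 1
                stack[top, 0] = b2
                stack[top, 1] = b3
                stack[top, 2] = xm
                stack[top, 3] = x1
                stack[top, 4] = y0
                stack[top, 5] = ym
                stack[top, 6] = d + 1
                top += 1
                stack[top, 0] = b3
                stack[top, 1] = e
                stack[top, 2] = xm
                stack[top, 3] = x1
                stack[top, 4] = ym
                stack[top, 5] = y1
                stack[top, 6] = d + 1
                top += 1
                continue
        # leaf: plug-in contribution with true marginal masses
        px = (_bisect_left(srx, x1) - _bisect_left(srx, x0)) / n
        py = (_bisect_left(sry, y1) - _bisect_left(sry, y0)) / n
        p = m / n
        if px > 0.0 and py > 0.0:
            mi += p * np.log(p / (px * py))
    if mi < 0.0:
        mi = 0.0
    return mi


@njit(cache=True)
def mi_pairs(R, S, pairs, chi2_crit, min_split, max_depth):
    """MI for many gene pairs; ``R`` is genes x samples scaled ranks and
    ``S`` its row-sorted counterpart."""
    n = R.shape[1]
    out = np.empty(pairs.shape[0])
    rx = np.empty(n, np.int64)
    ry = np.empty(n, np.int64)
    for k in range(pairs.shape[0]):
        i = pairs[k, 0]
        j = pairs[k, 1]
        for t in range(n):
            rx[t] = R[i, t]
            ry[t] = R[j, t]
        out[k] = mi_from_scaled_ranks(
            rx, ry, S[i], S[j], chi2_crit, min_split, max_depth
        )
    return out
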