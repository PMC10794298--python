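"""Brute-force reference implementations used as independent oracles.

Each function restates the defining rule of an operation as a direct,
unoptimized scan, so tests can check the package's implementations against
the definitions rather than against themselves.
"""

from __future__ import annotations

import math

import numpy as np


def brute_extrema(ys):
    """Strict interior extrema by direct neighbour comparison (tie-free input)."""
    out = []
    for i in range(1, len(ys) - 1):
        if ys[i] > ys[i - 1] and ys[i] > ys[i + 1]:
            out.append((i, "max"))
        elif ys[i] < ys[i - 1] and ys[i] < ys[i + 1]:
            out.append((i, "min"))
    return out


def brute_prominence(ys, index, kind):
    """Topographic prominence by literal left/right walks."""
    y = [-v for v in ys] if kind == "min" else list(ys)
    v = y[index]

    def walk(step):
        lowest = v
        j = index + step
        while 0 <= j < len(y) and y[j] <= v:
            lowest = min(lowest, y[j])
            j += step
        return lowest

    return v - max(walk(-1), walk(1))


def brute_match(cursor_extrema, target_extrema):
    """Exhaustive same-kind nearest-neighbour search (double-weighted x).

    Returns a list of (cursor, matched target) in cursor-index order; ties
    go to the earlier target sample.
    """
    res = []
    for c in sorted(cursor_extrema, key=lambda e: e.index):
        best, best_d = None, None
        for t in sorted(target_extrema, key=lambda e: e.index):
            if t.kind != c.kind:
                continue
            d = math.hypot(2.0 * (t.x - c.x), t.y - c.y)
            if best_d is None or d < best_d:
                best, best_d = t, d
        res.append((c, best, best_d))
    return res


def brute_assign(series, matches):
    """Exhaustive intended-sample search over every candidate window.

    Follows the defining rule sample by sample with plain loops: anchor the
    trial boundaries, take the inclusive [min, max] target span of the
    enclosing matched pair, minimize the plain Euclidean distance, earliest
    candidate on ties.  Returns (intended_index, distance) per sample.
    """
    n = series.n_samples
    cx, cy = series.cursor_x, series.cursor_y
    tx, ty = series.target_x, series.target_y
    cur = [m.cursor.index for m in matches]
    tgt = [m.target.index for m in matches]
    if not cur or cur[0] > 0:
        cur, tgt = [0] + cur, [0] + tgt
    if cur[-1] < n - 1:
        cur, tgt = cur + [n - 1], tgt + [n - 1]

    intended = [None] * n
    dist = [None] * n
    for k in range(len(cur) - 1):
        last = k == len(cur) - 2
        samples = range(cur[k], cur[k + 1] + (1 if last else 0))
        lo, hi = min(tgt[k], tgt[k + 1]), max(tgt[k], tgt[k + 1])
        for s in samples:
            best, best_d2 = None, None
            for j in range(lo, hi + 1):
                d2 = (tx[j] - cx[s]) ** 2 + (ty[j] - cy[s]) ** 2
                if best_d2 is None or d2 < best_d2:
                    best, best_d2 = j, d2
            intended[s] = best
            dist[s] = math.sqrt(best_d2)
    return np.array(intended), np.array(dist)
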