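"""Direction-change (local extremum) detection with a prominence criterion.

A direction change of the vertical coordinate is a strict local maximum or
minimum: a sample larger (max) or smaller (min) than both neighbours, i.e.
a reversal within 50 ms at 60 Hz.  Every direction change of the smooth
target trajectory is kept, whereas the cursor signal carries unintended
joystick fluctuation, so cursor extrema are filtered by topographic
prominence (default 20 px, about 2% of a 1080-px screen height).

Plateaus (runs of exactly equal neighbours, frequent in integer-pixel
joystick data) are collapsed to a single candidate at the plateau midpoint
before the strict neighbour comparison; returned extrema therefore strictly
alternate between maxima and minima, and the sequence endpoints are never
reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Extremum:
    """One direction change: sample index, kind, coordinates, prominence."""

    index: int
    kind: str  # 'max' | 'min'
    y: float
    x: float = float("nan")
    prominence: float = float("nan")


@dataclass
class DetectionConfig:
    """Prominence settings for cursor-extremum detection.

    ``cursor_min_prominence`` is the shipped default of 20 px for a 1080-px
    screen; ``screen_fraction`` derives a suggested value for other screens
    via :func:`default_prominence_for_screen`.
    """

    cursor_min_prominence: float = 20.0
    screen_fraction: float = 0.02

    def __post_init__(self) -> None:
        if self.cursor_min_prominence < 0:
            raise ValueError("cursor_min_prominence must be >= 0")


def default_prominence_for_screen(screen_height: float, fraction: float = 0.02) -> float:
    """Suggested prominence threshold: ``fraction`` of the screen height."""
    if screen_height <= 0:
        raise ValueError("screen_height must be positive")
    return fraction * screen_height


def compute_prominence(ys: np.ndarray, index: int, kind: str = "max") -> float:
    """Topographic prominence of the extremum at ``index``.

    For a maximum: walk left and right from the peak until a strictly
    higher sample or the sequence end is reached, recording the lowest value
    seen on each side; the prominence is the peak value minus the higher of
    the two bases.  Minima are handled on the negated sequence.  Using the
    sequence ends as bases means boundary-adjacent extrema (including an
    isolated global extremum) keep a finite, meaningful prominence.
    """
    y = np.asarray(ys, dtype=float)
    if kind == "min":
        y = -y
    v = y[index]
    bases = []
    for step in (-1, 1):
        lowest = v
        i = index + step
        while 0 <= i < len(y) and y[i] <= v:
            if y[i] < lowest:
                lowest = y[i]
            i += step
        bases.append(lowest)
    return float(v - max(bases))


def find_local_extrema(ys, xs=None) -> list[Extremum]:
    """All strict interior extrema of ``ys`` in index order, with prominence.

    Plateaus are collapsed to their midpoint sample before the comparison.
    If ``xs`` is given, each extremum carries its horizontal coordinate.
    """
    y = np.asarray(ys, dtype=float)
    if y.ndim != 1 or len(y) < 3:
        raise ValueError("need a one-dimensional sequence of at least 3 samples")
    boundary = np.flatnonzero(np.diff(y) != 0)
    starts = np.concatenate([[0], boundary + 1])  # run starts (plateau-collapsed)
    ends = np.concatenate([boundary, [len(y) - 1]])  # inclusive run ends
    vals = y[starts]
    out: list[Extremum] = []
    for r in range(1, len(vals) - 1):
        if vals[r] > vals[r - 1] and vals[r] > vals[r + 1]:
            kind = "max"
        elif vals[r] < vals[r - 1] and vals[r] < vals[r + 1]:
            kind = "min"
        else:
            continue
        idx = int((starts[r] + ends[r]) // 2)
        out.append(Extremum(index=idx, kind=kind, y=float(y[idx]),
                            x=float(xs[idx]) if xs is not None else float("nan"),
                            prominence=compute_prominence(y, idx, kind)))
    return out


def detect_target_extrema(series) -> list[Extremum]:
    """Every direction change of the target — no prominence filter.

    The trajectory is smooth by construction, so all of its extrema are
    genuine direction changes.
    """
    return find_local_extrema(series.target_y, series.target_x)


def detect_cursor_extrema(series, config: DetectionConfig | None = None) -> list[Extremum]:
    """Cursor direction changes with prominence >= the configured threshold."""
    cfg = config or DetectionConfig()
    ext = find_local_extrema(series.cursor_y, series.cursor_x)
    return [e for e in ext if e.prominence >= cfg.cursor_min_prominence]
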