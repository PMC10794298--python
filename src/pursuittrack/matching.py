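"""Direction-change matching and intended-sample assignment.

The spatial tracking error asks, for every cursor sample, which target
sample the participant was *aiming* at.  Two assumptions drive the
estimation: similarity (cursor maxima are matched only to target maxima,
minima only to minima) and proximity (the matched target direction change
minimizes a distance in which the horizontal — i.e. temporal — component is
weighted double).  Between two matched pairs of direction changes, the
intended sample for each enclosed cursor sample is the plain-Euclidean
nearest trajectory sample within the matched window.

Conventions fixed by this implementation (the underlying procedure leaves
them open):

* the weighted distance doubles the x difference inside the Euclidean form,
  ``sqrt((2*dx)**2 + dy**2)``;
* matching is independent same-kind nearest neighbour; many cursor extrema
  may share one target extremum, and order-crossing matches are flagged and
  span-repaired rather than re-optimized;
* samples before the first / after the last cursor extremum fall into
  windows anchored at the trial's first/last sample, matched to the
  trajectory's first/last sample, so every pursuit sample gets an
  assignment;
* candidate windows include both matched extremum samples; distance ties
  are broken toward the earliest candidate;
* the anticipation comparison uses time indices, so mirrored (leftward)
  trials need no special-casing once direction-normalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .extrema import Extremum
from .series import TrialTimeSeries

logger = logging.getLogger(__name__)


class MatchingError(ValueError):
    """No same-kind target extremum exists for a cursor extremum."""


@dataclass(frozen=True)
class ExtremumMatch:
    """A cursor direction change paired with its matched target counterpart."""

    cursor: Extremum
    target: Extremum
    weighted_distance: float
    direction_label: str  # 'anticipatory' | 'adaptive'
    crossed: bool = False


@dataclass
class IntendedAssignments:
    """Per-sample intended-trajectory assignments for one trial (arrays).

    ``distance`` is the spatial tracking error: the plain Euclidean distance
    between each pursuit sample and its intended trajectory sample.
    ``anticipated`` is True where the intended sample lies strictly later in
    time than the pursuit sample.  ``window_lo``/``window_hi`` record the
    inclusive candidate window used for each sample.
    """

    sample_index: np.ndarray
    intended_index: np.ndarray
    intended_x: np.ndarray
    intended_y: np.ndarray
    distance: np.ndarray
    anticipated: np.ndarray
    window_lo: np.ndarray
    window_hi: np.ndarray

    def __len__(self) -> int:
        return len(self.sample_index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample": self.sample_index,
            "intended_index": self.intended_index,
            "intended_x": self.intended_x,
            "intended_y": self.intended_y,
            "distance": self.distance,
            "anticipated": self.anticipated,
            "window_lo": self.window_lo,
            "window_hi": self.window_hi,
        })


def weighted_distance(p, q, x_weight: float = 2.0) -> float:
    """Similarity distance between two points with the x gap weighted double.

    ``sqrt((x_weight*dx)**2 + dy**2)`` — doubling the horizontal (temporal)
    axis distance favours target direction changes close in time.
    """
    dx = float(q[0]) - float(p[0])
    dy = float(q[1]) - float(p[1])
    if not (np.isfinite(dx) and np.isfinite(dy)):
        raise ValueError("coordinates must be finite")
    return float(np.hypot(x_weight * dx, dy))


def label_match_direction(match: ExtremumMatch) -> str:
    """'anticipatory' if the cursor reverses strictly before the target.

    Ties (same sample index) count as adaptive: anticipation requires the
    cursor event to genuinely precede the target event.
    """
    return "anticipatory" if match.cursor.index < match.target.index else "adaptive"


def match_extrema(cursor_extrema: list[Extremum], target_extrema: list[Extremum],
                  trial: str | None = None) -> list[ExtremumMatch]:
    """Match every cursor extremum to its nearest same-kind target extremum.

    Matching is many-to-one: each cursor extremum independently takes the
    target extremum of the same kind minimizing the double-x-weighted
    distance (ties toward the earlier target sample).  Matches are returned
    in cursor-index order; matches whose target order is inconsistent with
    the cursor order are flagged as crossed.
    """
    by_kind = {"max": [t for t in target_extrema if t.kind == "max"],
               "min": [t for t in target_extrema if t.kind == "min"]}
    matches: list[ExtremumMatch] = []
    for c in sorted(cursor_extrema, key=lambda e: e.index):
        candidates = by_kind[c.kind]
        if not candidates:
            where = f" in trial {trial}" if trial else ""
            raise MatchingError(
                f"no target {c.kind} available for cursor extremum at sample {c.index}{where}")
        dists = [weighted_distance((c.x, c.y), (t.x, t.y)) for t in candidates]
        best = int(np.argmin(dists))
        t = candidates[best]
        m = ExtremumMatch(cursor=c, target=t, weighted_distance=float(dists[best]),
                          direction_label="", crossed=False)
        matches.append(replace(m, direction_label=label_match_direction(m)))

    tgt_idx = [m.target.index for m in matches]
    flagged = []
    for j, m in enumerate(matches):
        crossed = (j > 0 and tgt_idx[j] < tgt_idx[j - 1]) or \
                  (j + 1 < len(matches) and tgt_idx[j + 1] < tgt_idx[j])
        flagged.append(replace(m, crossed=crossed) if crossed else m)
    n_crossed = sum(m.crossed for m in flagged)
    if n_crossed:
        logger.info("trial %s: %d crossed extremum matches (span-repaired)",
                    trial or "?", n_crossed)
    return flagged


def _anchor_indices(matches: list[ExtremumMatch], n: int) -> tuple[list[int], list[int]]:
    """Cursor/target anchor index lists, padded with virtual boundary anchors."""
    cur = [m.cursor.index for m in matches]
    tgt = [m.target.index for m in matches]
    if not cur or cur[0] > 0:
        cur.insert(0, 0)
        tgt.insert(0, 0)
    if cur[-1] < n - 1:
        cur.append(n - 1)
        tgt.append(n - 1)
    return cur, tgt


def assign_intended_samples(series: TrialTimeSeries,
                            matches: list[ExtremumMatch]) -> IntendedAssignments:
    """Estimate the intended trajectory sample for every pursuit sample.

    Consecutive matched cursor extrema (A, B) partition the trial into
    windows; a pursuit sample inside [A, B) takes as candidates the
    inclusive run of trajectory samples between the matched extrema A' and
    B' (the span's [min, max] if the match is crossed) and is assigned the
    candidate at minimal plain Euclidean distance, earliest index on ties.
    Virtual anchors at the trial boundaries guarantee that every pursuit
    sample receives exactly one assignment.
    """
    n = series.n_samples
    cx, cy = series.cursor_x, series.cursor_y
    tx, ty = series.target_x, series.target_y
    cur, tgt = _anchor_indices(matches, n)

    intended = np.empty(n, dtype=int)
    dist = np.empty(n, dtype=float)
    wlo = np.empty(n, dtype=int)
    whi = np.empty(n, dtype=int)
    for k in range(len(cur) - 1):
        s0, s1 = cur[k], cur[k + 1]
        sl = slice(s0, s1 + 1) if k == len(cur) - 2 else slice(s0, s1)
        lo, hi = min(tgt[k], tgt[k + 1]), max(tgt[k], tgt[k + 1])
        cand = np.arange(lo, hi + 1)
        assert cand.size > 0, "empty candidate window after span repair"
        d2 = (tx[cand][None, :] - cx[sl][:, None]) ** 2 \
            + (ty[cand][None, :] - cy[sl][:, None]) ** 2
        best = np.argmin(d2, axis=1)  # argmin takes the earliest on ties
        intended[sl] = cand[best]
        dist[sl] = np.sqrt(d2[np.arange(d2.shape[0]), best])
        wlo[sl], whi[sl] = lo, hi

    samples = np.arange(n)
    return IntendedAssignments(
        sample_index=samples, intended_index=intended,
        intended_x=tx[intended], intended_y=ty[intended], distance=dist,
        anticipated=intended > samples, window_lo=wlo, window_hi=whi)


def label_anticipation(assignments: IntendedAssignments) -> np.ndarray:
    """Anticipated iff the intended sample lies strictly later in time.

    On a direction-normalized (rightward) trial this is exactly the rule
    "intended x larger than pursuit x"; comparing time indices keeps it
    well defined for mirrored trials too.  Ties are not anticipated.
    """
    return assignments.intended_index > assignments.sample_index


def matches_to_frame(matches: list[ExtremumMatch]) -> pd.DataFrame:
    """One row per extremum match, for Fig.-style diagnostics and export."""
    return pd.DataFrame([{
        "cursor_index": m.cursor.index,
        "kind": m.cursor.kind,
        "cursor_x": m.cursor.x,
        "cursor_y": m.cursor.y,
        "cursor_prominence": m.cursor.prominence,
        "target_index": m.target.index,
        "target_x": m.target.x,
        "target_y": m.target.y,
        "weighted_distance": m.weighted_distance,
        "direction_label": m.direction_label,
        "crossed": m.crossed,
    } for m in matches])
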