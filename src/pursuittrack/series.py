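"""Synchronized target/cursor time series for one pursuit-tracking trial."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .trajectory import Condition


@dataclass
class TrialTimeSeries:
    """Target and cursor coordinates for one trial, sampled at the frame rate.

    In the standard joystick paradigm the cursor's horizontal position is
    locked to the target (``cursor_x == target_x``); both arrays are kept so
    that externally recorded two-dimensional data can be represented too.
    ``segment`` carries the trajectory segment label of each sample.
    """

    target_x: np.ndarray
    target_y: np.ndarray
    cursor_x: np.ndarray
    cursor_y: np.ndarray
    segment: np.ndarray
    condition: Condition
    participant_id: str = "sim"
    trial_index: int = 0
    frame_rate: float = 60.0
    screen_size: tuple[int, int] = (1920, 1080)
    clip_count: int = 0

    def __post_init__(self) -> None:
        self.target_x = np.asarray(self.target_x, dtype=float)
        self.target_y = np.asarray(self.target_y, dtype=float)
        self.cursor_x = np.asarray(self.cursor_x, dtype=float)
        self.cursor_y = np.asarray(self.cursor_y, dtype=float)
        self.segment = np.asarray(self.segment, dtype=object)
        n = len(self.target_x)
        for name in ("target_y", "cursor_x", "cursor_y", "segment"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from target_x")

    @property
    def n_samples(self) -> int:
        return len(self.target_x)

    def x_locked(self, atol: float = 1e-6) -> bool:
        """True if the cursor's horizontal position equals the target's."""
        return bool(np.all(np.abs(self.cursor_x - self.target_x) <= atol))

    def mirrored(self) -> "TrialTimeSeries":
        """Mirror about the vertical screen-centre axis (x -> -x)."""
        other = "left" if self.condition.side == "right" else "right"
        return replace(self, target_x=-self.target_x, cursor_x=-self.cursor_x,
                       condition=Condition(self.condition.velocity_level, other))


def normalize_direction(series: TrialTimeSeries) -> TrialTimeSeries:
    """Return a rightward-moving view of the trial.

    Leftward trials are mirrored so that x increases with time; rightward
    trials are returned unchanged.  All analysis runs on normalized trials,
    which makes results invariant under the left/right manipulation.
    """
    if series.condition.side == "left":
        return series.mirrored()
    return series
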