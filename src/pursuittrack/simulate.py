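"""Synthetic cursor pursuits with known ground truth.

The simulator turns a target trajectory into a plausible joystick pursuit
whose latent parameters (lag or lead, gain, offset, noise, sub-threshold
jitter, missed reversals) are known exactly, so every downstream stage —
extremum detection, matching, the error metrics and the QC rules — can be
validated against ground truth without human data.  The model is a pure
delay line, not a cognitively realistic controller:

    cursor_y(t) = gain * target_y(t - lag + jitter_t) + offset
                  + jitter oscillation + Gaussian noise,

with the reference held at the first/last target value beyond the trial
boundaries (a participant resting at the start position).  A negative lag is
a lead, i.e. anticipatory tracking.  Cursor x is always locked to target x.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .extrema import find_local_extrema
from .series import TrialTimeSeries
from .trajectory import TrialTrajectory

logger = logging.getLogger(__name__)


@dataclass
class PursuitModel:
    """Latent parameters of a simulated pursuit.

    lag
        Response latency in frames; negative values lead the target.
        The default of 9 frames is 150 ms at 60 Hz, a typical visuomotor
        delay for continuous manual tracking.
    lag_jitter_sd
        Frame-level Gaussian jitter of the lag (frames).
    gain, offset
        Multiplicative and additive distortion of the followed signal.
    noise_sd
        Gaussian motor/sensor noise per sample (px).
    jitter_amplitude, jitter_period
        A small superimposed oscillation (px, frames) emulating unintended
        joystick fluctuation below the prominence threshold.
    missed_reversal_prob
        Probability per target direction change that the pursuit tracks
        straight through it instead of reversing ("false tracking").
    """

    lag: float = 9.0
    lag_jitter_sd: float = 0.0
    gain: float = 1.0
    offset: float = 0.0
    noise_sd: float = 3.0
    jitter_amplitude: float = 0.0
    jitter_period: float = 10.0
    missed_reversal_prob: float = 0.0
    missed_reversal_halfwidth: int = 8
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.jitter_amplitude < 0 or self.lag_jitter_sd < 0:
            raise ValueError("noise and jitter magnitudes must be >= 0")
        if not 0.0 <= self.missed_reversal_prob <= 1.0:
            raise ValueError("missed_reversal_prob must be a probability")
        if self.jitter_period <= 0:
            raise ValueError("jitter_period must be positive")


def _skip_reversals(base: np.ndarray, ref: np.ndarray, target_y: np.ndarray,
                    prob: float, halfwidth: int, rng: np.random.Generator) -> np.ndarray:
    """Flatten the delayed reference across randomly skipped target extrema."""
    out = base.copy()
    for ext in find_local_extrema(target_y):
        if rng.random() >= prob:
            continue
        hit = np.flatnonzero(np.abs(ref - ext.index) <= halfwidth)
        if hit.size < 3:
            continue
        i0, i1 = hit[0], hit[-1]
        out[i0:i1 + 1] = np.linspace(out[i0], out[i1], i1 - i0 + 1)
    return out


def simulate_pursuit(traj: TrialTrajectory, model: PursuitModel,
                     participant_id: str = "sim",
                     rng: np.random.Generator | None = None) -> TrialTimeSeries:
    """Simulate one cursor pursuit of ``traj`` under ``model``.

    With an identity model (zero lag/offset/noise, unit gain) the cursor is
    an exact copy of the target; with a pure integer delay the cursor equals
    the target shifted by that many frames on all interior samples.
    Reproducible under ``model.seed`` (or an explicitly passed ``rng``).
    """
    n = traj.n_samples
    if abs(model.lag) >= n:
        raise ValueError("lag magnitude must be smaller than the trial length")
    if rng is None:
        rng = np.random.default_rng(model.seed)

    t = np.arange(n, dtype=float)
    ref = t - model.lag
    if model.lag_jitter_sd > 0:
        ref = ref + rng.normal(0.0, model.lag_jitter_sd, n)
    ref = np.clip(ref, 0.0, n - 1.0)  # hold first/last target value at the edges
    base = np.interp(ref, t, traj.y)
    if model.missed_reversal_prob > 0:
        base = _skip_reversals(base, ref, traj.y, model.missed_reversal_prob,
                               model.missed_reversal_halfwidth, rng)

    cursor = model.gain * base + model.offset
    if model.jitter_amplitude > 0:
        cursor = cursor + model.jitter_amplitude * np.sin(2.0 * np.pi * t / model.jitter_period)
    if model.noise_sd > 0:
        cursor = cursor + rng.normal(0.0, model.noise_sd, n)

    return TrialTimeSeries(target_x=traj.x, target_y=traj.y,
                           cursor_x=traj.x.copy(), cursor_y=cursor,
                           segment=traj.segment.copy(), condition=traj.condition,
                           participant_id=participant_id, trial_index=traj.trial_index,
                           frame_rate=traj.frame_rate, screen_size=traj.screen_size)


def clamp_to_screen(series: TrialTimeSeries,
                    screen_size: tuple[int, int] | None = None) -> TrialTimeSeries:
    """Clip the cursor to the vertical screen borders.

    Full joystick deflection maps to the screen border, so no recorded
    cursor sample can lie outside it.  Clipping events are counted on the
    returned series and logged.
    """
    size = screen_size or series.screen_size
    half = size[1] / 2.0
    clipped = np.clip(series.cursor_y, -half, half)
    count = int(np.count_nonzero(clipped != series.cursor_y))
    if count:
        logger.info("trial %s/%d: clipped %d cursor samples to the screen border",
                    series.participant_id, series.trial_index, count)
    return replace(series, cursor_y=clipped, clip_count=series.clip_count + count)


def inject_start_offset(series: TrialTimeSeries, offset: float,
                        decay_frames: int = 30) -> TrialTimeSeries:
    """Displace the trial start by ``offset`` px (joystick not relaxed).

    The first cursor sample is shifted by exactly ``offset`` pixels; the
    displacement decays linearly to zero over ``decay_frames`` frames, after
    which the original pursuit continues unchanged.  Used to exercise the
    100-px start-of-trial QC rule.
    """
    if offset == 0:
        return series
    t = np.arange(series.n_samples, dtype=float)
    ramp = np.clip(1.0 - t / max(decay_frames, 1), 0.0, 1.0)
    return replace(series, cursor_y=series.cursor_y + offset * ramp)


def simulate_random_walk(traj: TrialTrajectory, step_sd: float = 8.0,
                         participant_id: str = "sim",
                         rng: np.random.Generator | None = None) -> TrialTimeSeries:
    """A cursor performing an unrelated random walk (erroneous trial fixture)."""
    if rng is None:
        rng = np.random.default_rng()
    walk = np.cumsum(rng.normal(0.0, step_sd, traj.n_samples))
    series = TrialTimeSeries(target_x=traj.x, target_y=traj.y,
                             cursor_x=traj.x.copy(), cursor_y=walk,
                             segment=traj.segment.copy(), condition=traj.condition,
                             participant_id=participant_id, trial_index=traj.trial_index,
                             frame_rate=traj.frame_rate, screen_size=traj.screen_size)
    return clamp_to_screen(series)
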