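"""Tracking-error metrics, anticipation rates, QC flags and summaries.

Two error types are reported side by side for every trial and segment:

* the temporal tracking error — the per-sample vertical deviation between
  cursor and target compared at the same time point, whose classical trial
  reduction is the RMSE;
* the spatial tracking error — the per-sample Euclidean distance between a
  cursor sample and its estimated intended trajectory sample.

Both the arithmetic-mean and the root-mean-square reducers are always
computed: the field's terminology conflates "mean vertical deviation" with
"RMSE", so summary tables carry both and downstream consumers choose.

QC is deliberately advisory: the start-offset and outlier rules only *flag*
trials, and exclusion additionally requires a user-supplied visual
confirmation — flagging never removes data by itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import TrialAnalysis
from .series import TrialTimeSeries
from .trajectory import SEG_CONSTANT, SEG_GAP, SEG_RANDOM1, SEG_RANDOM2

logger = logging.getLogger(__name__)

#: Row order of the per-trial summary scopes.
SCOPES = (SEG_RANDOM1, SEG_CONSTANT, SEG_RANDOM2, "random_avg", "trial")


@dataclass
class QCConfig:
    """Thresholds of the two advisory QC rules."""

    start_offset_threshold: float = 100.0  # px from screen centre at trial start
    outlier_sd: float = 3.0                # SDs above the mean per-trial max error

    def __post_init__(self) -> None:
        if self.start_offset_threshold < 0 or self.outlier_sd < 0:
            raise ValueError("QC thresholds must be >= 0")


def temporal_error_series(series: TrialTimeSeries) -> np.ndarray:
    """Per-sample vertical deviation |cursor_y - target_y|, px."""
    return np.abs(series.cursor_y - series.target_y)


def spatial_error_series(assignments) -> np.ndarray:
    """Per-sample Euclidean distance to the intended trajectory sample, px."""
    return np.asarray(assignments.distance, dtype=float)


def trial_error_reduce(errors, reducer: str = "mean") -> float:
    """Reduce a per-sample error series to one value: 'mean' or 'rmse'."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("cannot reduce an empty error series")
    if reducer == "mean":
        return float(np.mean(e))
    if reducer == "rmse":
        return float(np.sqrt(np.mean(e ** 2)))
    raise ValueError(f"unknown reducer {reducer!r} (expected 'mean' or 'rmse')")


def anticipation_rate(anticipated, mask=None) -> float:
    """Fraction of (masked) samples whose intended sample lies later in time."""
    flags = np.asarray(anticipated, dtype=bool)
    if mask is not None:
        flags = flags[np.asarray(mask, dtype=bool)]
    if flags.size == 0:
        raise ValueError("no samples in scope")
    return float(np.mean(flags))


def effective_segments(labels) -> np.ndarray:
    """Fold spline-gap samples into the adjacent random segment.

    Gap samples before the repeated (constant) segment belong to random1,
    gaps after it to random2 — keeping the constant segment uncontaminated.
    """
    lab = np.asarray(labels, dtype=object)
    out = lab.copy()
    const = np.flatnonzero(lab == SEG_CONSTANT)
    first_const = const[0] if const.size else len(lab)
    is_gap = lab == SEG_GAP
    pos = np.arange(len(lab))
    out[is_gap & (pos < first_const)] = SEG_RANDOM1
    out[is_gap & (pos >= first_const)] = SEG_RANDOM2
    return out


def segment_summary(series: TrialTimeSeries, temporal: np.ndarray,
                    spatial: np.ndarray, anticipated: np.ndarray) -> pd.DataFrame:
    """Per-segment and whole-trial means of both errors and the anticipation rate.

    Rows: random1, constant, random2, random_avg (the unweighted mean of the
    two random segments, the standard control for intra-trial fatigue), and
    the whole trial.  Raises if segment labels are missing or unknown,
    pointing at the ``segment`` column.
    """
    labels = effective_segments(series.segment)
    known = {SEG_RANDOM1, SEG_CONSTANT, SEG_RANDOM2}
    seen = set(labels.tolist())
    if not seen or not seen.issubset(known):
        raise ValueError(
            f"segment column contains unknown or missing labels: {sorted(seen - known)}; "
            f"expected values from {sorted(known | {SEG_GAP})}")

    def row(scope: str, mask: np.ndarray) -> dict:
        return {
            "scope": scope,
            "n_samples": int(mask.sum()),
            "temporal_mean": trial_error_reduce(temporal[mask], "mean"),
            "temporal_rmse": trial_error_reduce(temporal[mask], "rmse"),
            "spatial_mean": trial_error_reduce(spatial[mask], "mean"),
            "spatial_rmse": trial_error_reduce(spatial[mask], "rmse"),
            "anticipation_rate": anticipation_rate(anticipated, mask),
        }

    rows = {}
    for scope in (SEG_RANDOM1, SEG_CONSTANT, SEG_RANDOM2):
        mask = labels == scope
        if mask.any():
            rows[scope] = row(scope, mask)
    if SEG_RANDOM1 in rows and SEG_RANDOM2 in rows:
        r1, r2 = rows[SEG_RANDOM1], rows[SEG_RANDOM2]
        rows["random_avg"] = {"scope": "random_avg",
                              "n_samples": r1["n_samples"] + r2["n_samples"]}
        for key in ("temporal_mean", "temporal_rmse", "spatial_mean",
                    "spatial_rmse", "anticipation_rate"):
            rows["random_avg"][key] = (r1[key] + r2[key]) / 2.0
    rows["trial"] = row("trial", np.ones(len(labels), dtype=bool))
    ordered = [rows[s] for s in SCOPES if s in rows]
    return pd.DataFrame(ordered)


def assign_blocks(n_trials: int, n_blocks: int = 3) -> np.ndarray:
    """Retrospective contiguous partition of a session into equal blocks.

    Block sizes differ by at most one, earlier blocks taking the remainder
    (7 trials in 3 blocks -> 3/2/2).  Returns 1-based block ids per trial in
    presentation order.
    """
    if n_blocks > n_trials:
        raise ValueError("n_blocks cannot exceed the number of trials")
    base, rem = divmod(n_trials, n_blocks)
    sizes = [base + (1 if b < rem else 0) for b in range(n_blocks)]
    return np.repeat(np.arange(1, n_blocks + 1), sizes)


def qc_flag_start_offset(series: TrialTimeSeries, threshold: float = 100.0,
                         center_y: float = 0.0) -> bool:
    """True if the cursor starts strictly more than ``threshold`` px off centre.

    A large deviation at trial start means the joystick was not relaxed and
    the trial opens with an artefactual error peak.
    """
    return bool(abs(series.cursor_y[0] - center_y) > threshold)


def qc_flag_outliers(max_errors, n_sd: float = 3.0) -> np.ndarray:
    """Flag trials whose peak temporal error is an outlier across the dataset.

    ``max_errors`` are per-trial maxima of the temporal error pooled over
    every participant and trial in the run; a trial is flagged when its
    maximum exceeds mean + ``n_sd`` * SD (sample SD, strict inequality, so
    identical trials are never flagged).  Flags are advisory: exclusion
    requires a separate, visually confirmed decision.
    """
    e = np.asarray(max_errors, dtype=float)
    if e.size < 3:
        raise ValueError("outlier flagging needs at least 3 trials (SD undefined)")
    return e > e.mean() + n_sd * e.std(ddof=1)


def errors_frame(analyses: list[TrialAnalysis]) -> pd.DataFrame:
    """Tidy per-sample error table: one row per pursuit sample."""
    parts = []
    for a in analyses:
        s = a.series
        parts.append(pd.DataFrame({
            "participant_id": s.participant_id,
            "trial": s.trial_index,
            "sample": np.arange(s.n_samples),
            "segment": s.segment,
            "temporal_error": a.temporal_error,
            "spatial_error": a.spatial_error,
            "intended_index": a.assignments.intended_index,
            "anticipated": a.assignments.anticipated,
        }))
    return pd.concat(parts, ignore_index=True)


def summarize_session(analyses: list[TrialAnalysis], n_blocks: int = 3,
                      qc: QCConfig | None = None,
                      reducer: str = "mean") -> pd.DataFrame:
    """Tidy per-trial x scope summary for a list of analyzed trials.

    Adds block ids (contiguous thirds per participant, in list order), both
    QC flags (outliers pooled over the whole input), extremum counts, and a
    ``temporal_error``/``spatial_error`` column pair filled with the chosen
    reducer for direct consumption by stats packages.
    """
    if not analyses:
        raise ValueError("no trials to summarize")
    qc = qc or QCConfig()
    trial_error_reduce(np.zeros(1), reducer)  # validate reducer early

    by_participant: dict[str, list[int]] = {}
    for i, a in enumerate(analyses):
        by_participant.setdefault(a.series.participant_id, []).append(i)
    blocks = np.empty(len(analyses), dtype=int)
    for idxs in by_participant.values():
        blocks[np.asarray(idxs)] = assign_blocks(len(idxs), n_blocks)

    max_errors = np.array([a.temporal_error.max() for a in analyses])
    if len(analyses) >= 3:
        outlier = qc_flag_outliers(max_errors, qc.outlier_sd)
    else:
        logger.warning("fewer than 3 trials: outlier QC rule skipped")
        outlier = np.zeros(len(analyses), dtype=bool)

    frames = []
    for i, a in enumerate(analyses):
        s = a.series
        seg = segment_summary(s, a.temporal_error, a.spatial_error, a.anticipated)
        seg.insert(0, "participant_id", s.participant_id)
        seg.insert(1, "trial", s.trial_index)
        seg.insert(2, "velocity_level", s.condition.velocity_level)
        seg.insert(3, "side", s.condition.side)
        seg.insert(4, "block", blocks[i])
        seg["temporal_error"] = seg[f"temporal_{reducer}"]
        seg["spatial_error"] = seg[f"spatial_{reducer}"]
        seg["n_cursor_extrema"] = len(a.cursor_extrema)
        seg["n_target_extrema"] = len(a.target_extrema)
        seg["qc_start_offset"] = qc_flag_start_offset(s, qc.start_offset_threshold)
        seg["qc_outlier"] = bool(outlier[i])
        frames.append(seg)
    out = pd.concat(frames, ignore_index=True)
    n_flagged = int((out.loc[out.scope == "trial", ["qc_start_offset", "qc_outlier"]]
                     .any(axis=1)).sum())
    logger.info("summarized %d trials (%d flagged for visual check)",
                len(analyses), n_flagged)
    return out
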