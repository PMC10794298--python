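"""CSV schemas, configuration files and run manifests.

CSV is the single interchange format: the simulator writes the same session
schema that externally recorded data are converted into, so simulated and
real sessions are interchangeable everywhere downstream.  All files are
UTF-8, '.' decimal, no index column, floats at 6 significant digits, fixed
column order — identical inputs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .extrema import DetectionConfig
from .metrics import QCConfig
from .series import TrialTimeSeries
from .simulate import PursuitModel
from .trajectory import Condition, GeneratorConfig, SegmentCoefficients, TrialTrajectory

logger = logging.getLogger(__name__)

SESSION_COLUMNS = ["participant_id", "trial", "velocity_level", "side", "sample",
                   "target_x", "target_y", "cursor_x", "cursor_y", "segment"]
TRAJECTORY_COLUMNS = ["trial", "velocity_level", "side", "sample",
                      "target_x", "target_y", "segment"]
FLOAT_FORMAT = "%.6g"


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")


def _check_samples_contiguous(df: pd.DataFrame, keys: list[str], path) -> None:
    for key, grp in df.groupby(keys, sort=False):
        samples = grp["sample"].to_numpy()
        if not np.array_equal(samples, np.arange(len(samples))):
            raise ValueError(f"{path}: trial {key} has non-contiguous or unsorted "
                             "sample indices (expected 0..n-1 in order)")


def read_session(path, frame_rate: float = 60.0,
                 screen_size: tuple[int, int] = (1920, 1080),
                 xlock_atol: float = 1e-4) -> list[TrialTimeSeries]:
    """Read and validate a session CSV into per-trial time series.

    Validation: all required columns present (the error names any missing
    one), numeric coordinate columns, contiguous sorted sample indices per
    trial.  A violated cursor/target x lock is downgraded to a warning —
    the analysis uses cursor x for pursuit points and target x for
    trajectory points, which handles genuinely two-dimensional data.
    """
    df = pd.read_csv(path)
    _check_columns(df, SESSION_COLUMNS, path)
    for col in ("sample", "target_x", "target_y", "cursor_x", "cursor_y"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"{path}: column {col!r} contains non-numeric values")
    if df.empty:
        raise ValueError(f"{path}: no rows")
    _check_samples_contiguous(df, ["participant_id", "trial"], path)
    if np.max(np.abs(df["cursor_x"].to_numpy() - df["target_x"].to_numpy())) > xlock_atol:
        logger.warning("%s: cursor_x deviates from target_x; treating cursor x as "
                       "authoritative for pursuit coordinates", path)
    trials = []
    for (pid, trial), grp in df.groupby(["participant_id", "trial"], sort=False):
        trials.append(TrialTimeSeries(
            target_x=grp["target_x"].to_numpy(), target_y=grp["target_y"].to_numpy(),
            cursor_x=grp["cursor_x"].to_numpy(), cursor_y=grp["cursor_y"].to_numpy(),
            segment=grp["segment"].to_numpy(),
            condition=Condition(str(grp["velocity_level"].iloc[0]),
                                str(grp["side"].iloc[0])),
            participant_id=str(pid), trial_index=int(trial),
            frame_rate=frame_rate, screen_size=screen_size))
    return trials


def trials_to_frame(trials: list[TrialTimeSeries]) -> pd.DataFrame:
    parts = []
    for t in trials:
        parts.append(pd.DataFrame({
            "participant_id": t.participant_id,
            "trial": t.trial_index,
            "velocity_level": t.condition.velocity_level,
            "side": t.condition.side,
            "sample": np.arange(t.n_samples),
            "target_x": t.target_x, "target_y": t.target_y,
            "cursor_x": t.cursor_x, "cursor_y": t.cursor_y,
            "segment": t.segment,
        }))
    return pd.concat(parts, ignore_index=True)[SESSION_COLUMNS]


def trajectories_to_frame(trajs: list[TrialTrajectory]) -> pd.DataFrame:
    parts = []
    for tr in trajs:
        parts.append(pd.DataFrame({
            "trial": tr.trial_index,
            "velocity_level": tr.condition.velocity_level,
            "side": tr.condition.side,
            "sample": np.arange(tr.n_samples),
            "target_x": tr.x, "target_y": tr.y,
            "segment": tr.segment,
        }))
    return pd.concat(parts, ignore_index=True)[TRAJECTORY_COLUMNS]


def read_trajectories(path, frame_rate: float = 60.0,
                      screen_size: tuple[int, int] = (1920, 1080)) -> list[TrialTrajectory]:
    """Read a trajectory CSV written by :func:`write_trajectories`."""
    df = pd.read_csv(path)
    _check_columns(df, TRAJECTORY_COLUMNS, path)
    _check_samples_contiguous(df, ["trial"], path)
    out = []
    for trial, grp in df.groupby("trial", sort=False):
        out.append(TrialTrajectory(
            x=grp["target_x"].to_numpy(), y=grp["target_y"].to_numpy(),
            segment=grp["segment"].to_numpy(),
            condition=Condition(str(grp["velocity_level"].iloc[0]),
                                str(grp["side"].iloc[0])),
            trial_index=int(trial), frame_rate=frame_rate, screen_size=screen_size))
    return out


def _write_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_session(path, trials_or_frame) -> None:
    df = trials_or_frame if isinstance(trials_or_frame, pd.DataFrame) \
        else trials_to_frame(trials_or_frame)
    _write_csv(df[SESSION_COLUMNS], path)


def write_trajectories(path, trajs_or_frame) -> None:
    df = trajs_or_frame if isinstance(trajs_or_frame, pd.DataFrame) \
        else trajectories_to_frame(trajs_or_frame)
    _write_csv(df[TRAJECTORY_COLUMNS], path)


def write_errors(path, errors: pd.DataFrame) -> None:
    _write_csv(errors, path)


def write_summary(path, summary: pd.DataFrame) -> None:
    _write_csv(summary, path)


# -- configuration ----------------------------------------------------------

def _build(cls, values: dict | None):
    values = dict(values or {})
    if cls is GeneratorConfig and "fixed_middle" in values:
        fm = values["fixed_middle"]
        values["fixed_middle"] = SegmentCoefficients(a=tuple(fm["a"]), b=tuple(fm["b"]))
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} option(s): {', '.join(sorted(unknown))}")
    for key in ("velocity_levels", "screen_size"):
        if key in values:
            values[key] = tuple(values[key])
    return cls(**values)


@dataclasses.dataclass
class RunConfig:
    """All pipeline parameters, grouped per stage, plus run-level settings."""

    generator: GeneratorConfig
    pursuit: PursuitModel
    detection: DetectionConfig
    qc: QCConfig
    n_blocks: int = 3
    reducer: str = "mean"
    seed: int = 0


def load_run_config(path) -> RunConfig:
    """Load a YAML or JSON config with flat keys per parameter group.

    Top-level groups: ``generator``, ``pursuit``, ``detection``, ``qc``;
    run-level keys: ``n_blocks``, ``reducer``, ``seed``.  All groups are
    optional and default to the package defaults.
    """
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    data = data or {}
    seed = int(data.get("seed", 0))
    gen = dict(data.get("generator") or {})
    gen.setdefault("seed", seed)
    return RunConfig(
        generator=_build(GeneratorConfig, gen),
        pursuit=_build(PursuitModel, data.get("pursuit")),
        detection=_build(DetectionConfig, data.get("detection")),
        qc=_build(QCConfig, data.get("qc")),
        n_blocks=int(data.get("n_blocks", 3)),
        reducer=str(data.get("reducer", "mean")),
        seed=seed)


def write_manifest(path, command: str, seed, params: dict, counts: dict) -> None:
    """Machine-readable run manifest: versions, seed, parameters, counts.

    Deliberately timestamp-free so identical runs produce byte-identical
    manifests.
    """
    manifest = {
        "tool": "pursuittrack",
        "version": __version__,
        "libraries": {"numpy": np.__version__, "pandas": pd.__version__},
        "command": command,
        "seed": seed,
        "parameters": params,
        "counts": counts,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")


def convert_session(in_path, out_path, mapping: dict) -> pd.DataFrame:
    """Convert an external CSV into the session schema via a column mapping.

    ``mapping`` has a ``columns`` dict (source name -> schema name) and an
    optional ``defaults`` dict filling schema columns absent from the
    source (e.g. participant id or segment labels).
    """
    df = pd.read_csv(in_path)
    df = df.rename(columns=dict(mapping.get("columns") or {}))
    for col, value in (mapping.get("defaults") or {}).items():
        if col not in df.columns:
            df[col] = value
    if "cursor_x" not in df.columns and "target_x" in df.columns:
        df["cursor_x"] = df["target_x"]  # x-locked paradigms often omit cursor x
    _check_columns(df, SESSION_COLUMNS, in_path)
    out = df[SESSION_COLUMNS]
    write_session(out_path, out)
    return out
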