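"""Target-trajectory generation for joystick pursuit-tracking experiments.

A target trajectory is a horizontally oriented waveform built from sums of
three sine and three cosine harmonics,

    f(x) = sum_{i=1..3} a_i * sin(i*x) + b_i * cos(i*x),

with the six coefficients drawn uniformly from ±40 px.  Each trial
concatenates three such segments: a random first segment, a *fixed* middle
segment that repeats identically in every trial (the substrate for implicit
sequence learning), and a random third segment.  Gaps of 30 samples between
adjacent segments are bridged with cubic splines so the assembled curve has
no jumps, and the curve is then resampled to constant speed along its arc
length — the three velocity conditions differ only in the spacing of the
resampled coordinates, not in the underlying shape.

Coordinate convention (fixed for all I/O in this package): origin at the
screen centre, x to the right, y up, units are pixels.  Trials are generated
rightward and mirrored about the vertical centre axis for leftward
conditions; every trial starts at the screen centre.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

VELOCITY_LEVELS = ("low", "medium", "high")
SIDES = ("right", "left")

SEG_RANDOM1 = "random1"
SEG_CONSTANT = "constant"
SEG_RANDOM2 = "random2"
SEG_GAP = "gap"


@dataclass(frozen=True)
class SegmentCoefficients:
    """Six waveform coefficients (three sine amplitudes, three cosine), px."""

    a: tuple[float, float, float]
    b: tuple[float, float, float]

    def amplitude_bound(self) -> float:
        """Upper bound on |f|: the sum of all coefficient magnitudes."""
        return float(sum(abs(v) for v in self.a) + sum(abs(v) for v in self.b))


#: Coefficients of the repeated middle segment, identical for every trial.
FIXED_MIDDLE = SegmentCoefficients(a=(37.0, -3.0, 26.0), b=(23.0, -15.0, -9.0))


@dataclass(frozen=True)
class Condition:
    """One cell of the 3 (velocity) x 2 (side) condition grid."""

    velocity_level: str
    side: str

    def __post_init__(self) -> None:
        if self.velocity_level not in VELOCITY_LEVELS:
            raise ValueError(f"velocity_level must be one of {VELOCITY_LEVELS}, "
                             f"got {self.velocity_level!r}")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")


@dataclass
class GeneratorConfig:
    """Parameters of the trajectory generator.

    The defaults reproduce the standard paradigm: coefficients in ±40 px,
    30-sample spline gaps, 60 Hz sampling on a 1920x1080 screen, speeds of
    (1.44, 2.16, 2.88) px/frame calibrated so the mean trial duration across
    the three velocity levels is 12 s, and 12 repeats of each of the six
    conditions (72 trials per session).
    ``trajectory_width`` is the horizontal extent of the dense curve before
    resampling.  Its default of 450 px is calibrated against the relative
    magnitude of the two error types under delayed tracking (temporal/spatial
    mean ratio just under three for a pure-delay pursuit), which fixes how
    steep the waveform is relative to the horizontal motion; the target stays
    well inside a 1920-px-wide screen.
    """

    coefficient_range: float = 40.0
    fixed_middle: SegmentCoefficients = FIXED_MIDDLE
    phase_start: float = 0.0
    phase_stop: float = 2.0 * np.pi
    samples_per_segment: int = 240
    gap_length: int = 30
    spline_flank: int = 10
    velocity_levels: tuple[float, float, float] = (1.44, 2.16, 2.88)
    frame_rate: float = 60.0
    screen_size: tuple[int, int] = (1920, 1080)
    trajectory_width: float = 450.0
    n_repeats_per_condition: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gap_length < 0:
            raise ValueError("gap_length must be >= 0")
        if self.phase_stop <= self.phase_start:
            raise ValueError("degenerate phase domain: phase_stop <= phase_start")
        if self.samples_per_segment < 3:
            raise ValueError("samples_per_segment must be >= 3")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.trajectory_width <= 0:
            raise ValueError("trajectory_width must be positive")
        speeds = tuple(float(v) for v in self.velocity_levels)
        if len(speeds) != 3 or len(set(speeds)) != 3 or min(speeds) <= 0:
            raise ValueError("velocity_levels must be three distinct positive speeds")
        if self.n_repeats_per_condition < 1:
            raise ValueError("n_repeats_per_condition must be >= 1")

    def speed_for(self, velocity_level: str) -> float:
        """Pixels-per-frame speed of a named velocity level."""
        return float(self.velocity_levels[VELOCITY_LEVELS.index(velocity_level)])

    def conditions(self) -> list[Condition]:
        return [Condition(v, s) for v in VELOCITY_LEVELS for s in SIDES]


@dataclass
class TrialTrajectory:
    """One target trajectory: ordered (x, y) coordinates plus metadata.

    ``segment`` labels each coordinate as random1 | constant | random2 | gap.
    ``speed`` is None for a dense (not yet resampled) trajectory and the
    pixels-per-frame spacing after :func:`resample_trial`.  ``region_breaks``
    are indices delimiting the resampling regions on a dense trajectory.
    """

    x: np.ndarray
    y: np.ndarray
    segment: np.ndarray
    condition: Condition
    trial_index: int = 0
    frame_rate: float = 60.0
    screen_size: tuple[int, int] = (1920, 1080)
    speed: float | None = None
    region_breaks: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.segment = np.asarray(self.segment, dtype=object)
        if not (len(self.x) == len(self.y) == len(self.segment)):
            raise ValueError("x, y and segment must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.x)

    @property
    def duration_s(self) -> float:
        """Trial duration at the configured frame rate (resampled trials)."""
        return self.n_samples / self.frame_rate


def eval_trig_segment(coeffs: SegmentCoefficients, phases) -> np.ndarray:
    """Evaluate f(x) = sum a_i sin(ix) + b_i cos(ix) elementwise, in pixels."""
    phases = np.asarray(phases, dtype=float)
    if phases.size and not np.all(np.isfinite(phases)):
        raise ValueError("phases must be finite")
    y = np.zeros_like(phases)
    for i, (a, b) in enumerate(zip(coeffs.a, coeffs.b), start=1):
        y += a * np.sin(i * phases) + b * np.cos(i * phases)
    return y


def sample_segment_coefficients(rng: np.random.Generator,
                                coefficient_range: float = 40.0) -> SegmentCoefficients:
    """Draw six independent coefficients uniformly from ±coefficient_range px."""
    if coefficient_range <= 0:
        raise ValueError("coefficient_range must be positive")
    draw = rng.uniform(-coefficient_range, coefficient_range, size=6)
    return SegmentCoefficients(a=tuple(draw[:3]), b=tuple(draw[3:]))


def _bridge_gap(x: np.ndarray, y: np.ndarray, gap: slice, flank: int) -> None:
    """Fill a gap in-place with a cubic spline fitted on flanking samples.

    The interpolant is fitted over ``flank`` known samples on each side of
    the gap (which include the adjacent segment endpoints) and evaluated on
    the gap's x positions.
    """
    left = np.arange(max(0, gap.start - flank), gap.start)
    right = np.arange(gap.stop, min(len(x), gap.stop + flank))
    known = np.concatenate([left, right])
    spline = CubicSpline(x[known], y[known])
    y[gap] = spline(x[gap])


def build_trial_trajectory(config: GeneratorConfig, condition: Condition,
                           rng: np.random.Generator,
                           trial_index: int = 0) -> TrialTrajectory:
    """Assemble the dense (pre-resampling) three-segment trajectory.

    Returns a rightward trajectory; direction is applied separately.  The
    first random segment is shifted vertically so the trial starts exactly at
    the screen centre.  ``region_breaks`` delimit the three resampling
    regions (random1+gap | constant | gap+random2) so that the repeated
    segment keeps bit-identical coordinates across trials after resampling.
    """
    n = config.samples_per_segment
    g = config.gap_length
    phases = np.linspace(config.phase_start, config.phase_stop, n)

    y1 = eval_trig_segment(sample_segment_coefficients(rng, config.coefficient_range), phases)
    y1 = y1 - y1[0]  # target starts at the screen centre
    y2 = eval_trig_segment(config.fixed_middle, phases)
    y3 = eval_trig_segment(sample_segment_coefficients(rng, config.coefficient_range), phases)

    total = 3 * n + 2 * g
    dx = config.trajectory_width / (total - 1)
    x = np.arange(total) * dx
    y = np.empty(total)
    segment = np.empty(total, dtype=object)

    s1 = slice(0, n)
    gap1 = slice(n, n + g)
    s2 = slice(n + g, 2 * n + g)
    gap2 = slice(2 * n + g, 2 * n + 2 * g)
    s3 = slice(2 * n + 2 * g, total)
    y[s1], y[s2], y[s3] = y1, y2, y3
    segment[s1], segment[s2], segment[s3] = SEG_RANDOM1, SEG_CONSTANT, SEG_RANDOM2
    segment[gap1] = segment[gap2] = SEG_GAP
    if g > 0:
        _bridge_gap(x, y, gap1, config.spline_flank)
        _bridge_gap(x, y, gap2, config.spline_flank)

    # region endpoints shared between neighbours: first and last constant sample
    breaks = (0, n + g, 2 * n + g - 1, total - 1)
    return TrialTrajectory(x=x, y=y, segment=segment, condition=condition,
                           trial_index=trial_index, frame_rate=config.frame_rate,
                           screen_size=config.screen_size, speed=None,
                           region_breaks=breaks)


def _chord_walk(pts: np.ndarray, cum: np.ndarray, chord: float, n_steps: int):
    """Place ``n_steps`` points after the start, each ``chord`` px from the last.

    Each step takes the first forward intersection of a circle of radius
    ``chord`` with the polyline (constant *screen displacement* per frame).
    Beyond the final vertex the last segment is extended, so the walk always
    completes; the overshoot past the path end is returned for the step-size
    solver.  Returns (points, arc positions, overshoot).
    """
    n_vert = len(pts)
    px = pts[:, 0].tolist()
    py = pts[:, 1].tolist()
    cums = cum.tolist()
    out = np.empty((n_steps + 1, 2))
    arcpos = np.empty(n_steps + 1)
    qx, qy = px[0], py[0]
    out[0] = qx, qy
    arcpos[0] = 0.0
    seg = 0  # current segment index: q lies on [pts[seg], pts[seg+1]]
    c2 = chord * chord
    for step in range(1, n_steps + 1):
        k = seg + 1
        while k < n_vert - 1 and (px[k] - qx) ** 2 + (py[k] - qy) ** 2 < c2:
            k += 1
        ax, ay = px[k - 1], py[k - 1]
        dx_, dy_ = px[k] - ax, py[k] - ay
        dd = dx_ * dx_ + dy_ * dy_
        rx, ry = ax - qx, ay - qy
        b = 2.0 * (dx_ * rx + dy_ * ry)
        c0 = rx * rx + ry * ry - c2
        disc = b * b - 4.0 * dd * c0
        t = (-b + (disc if disc > 0.0 else 0.0) ** 0.5) / (2.0 * dd)
        qx, qy = ax + t * dx_, ay + t * dy_
        seg = min(k - 1, n_vert - 2)
        arcpos[step] = cums[k - 1] + t * dd ** 0.5
        out[step] = qx, qy
    overshoot = arcpos[-1] - cum[-1]
    return out, arcpos, overshoot


def _constant_speed_core(points: np.ndarray, speed: float):
    """Equal-chord resampling; returns (points, nearest vertex indices).

    Solves for the chord length whose n-step walk ends exactly at the path
    end (the nominal arc step always undershoots; a secant iteration on the
    overshoot converges in a few walks).  Deterministic, so repeated
    segments resample to bit-identical coordinates.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("points must be an (n >= 2, 2) array")
    if speed <= 0:
        raise ValueError("speed must be positive")
    steps = np.hypot(np.diff(pts[:, 0]), np.diff(pts[:, 1]))
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    total = cum[-1]
    n_steps = int(round(total / speed))
    if n_steps == 0:
        logger.warning("resampling speed %.4g exceeds path length %.4g: "
                       "degenerate two-point output", speed, total)
        n_steps = 1

    c0 = total / n_steps
    over0 = _chord_walk(pts, cum, c0, n_steps)[2]
    if abs(over0) <= 1e-9:
        chord = c0
    else:
        c1 = c0 * (1.0 - over0 / total)  # overshoot is ~linear in the chord
        over1 = _chord_walk(pts, cum, c1, n_steps)[2]
        chord = c1
        for _ in range(20):
            if abs(over1) <= 1e-9 or over1 == over0:
                break
            c2 = c1 - over1 * (c1 - c0) / (over1 - over0)
            c0, over0 = c1, over1
            c1 = c2
            over1 = _chord_walk(pts, cum, c1, n_steps)[2]
            chord = c1
    out, arcpos, _ = _chord_walk(pts, cum, chord, n_steps)
    out[-1] = pts[-1]  # land exactly on the final vertex
    pos = np.clip(arcpos, 0.0, total)
    right = np.clip(np.searchsorted(cum, pos), 1, len(cum) - 1)
    nearer_left = (pos - cum[right - 1]) <= (cum[right] - pos)
    nearest = np.where(nearer_left, right - 1, right)
    return out, nearest


def resample_constant_speed(points: np.ndarray, speed: float, labels=None):
    """Resample a polyline to uniform Euclidean spacing (constant speed).

    Output points lie on the input polyline, with consecutive points
    separated by a constant Euclidean distance — the per-frame screen
    displacement of the target.  The step count is ``round(arc_length /
    speed)`` and the realised step is solved so the path ends exactly on the
    final input vertex; it deviates from ``speed`` by at most half a step
    over the whole path (under 0.5% for paths of 100+ steps).  If ``labels``
    is given, each output point inherits the label of the nearest input
    vertex by arc length and a ``(points, labels)`` tuple is returned.
    """
    out, nearest = _constant_speed_core(points, speed)
    if labels is None:
        return out
    return out, np.asarray(labels, dtype=object)[nearest]


def resample_trial(traj: TrialTrajectory, speed: float) -> TrialTrajectory:
    """Resample a dense trajectory to constant speed, region by region.

    Each region between ``region_breaks`` (random1+gap, constant,
    gap+random2) is resampled independently from its own start so the
    repeated middle segment produces identical coordinates in every trial of
    a velocity level.  Shared region endpoints are emitted once.
    """
    breaks = traj.region_breaks or (0, traj.n_samples - 1)
    n_regions = len(breaks) - 1
    xs, ys, labs = [], [], []
    for k in range(n_regions):
        lo, hi = breaks[k], breaks[k + 1]
        pts, nearest = _constant_speed_core(
            np.column_stack([traj.x[lo:hi + 1], traj.y[lo:hi + 1]]), speed)
        # interior points never borrow the shared boundary vertex's label,
        # so the repeated segment is exactly the middle region's point set
        # in every trial regardless of the random segments' geometry
        if k > 0:
            nearest = np.maximum(nearest, 1)
        if k < n_regions - 1:
            nearest[:-1] = np.minimum(nearest[:-1], hi - lo - 1)
            nearest[-1] = hi - lo
        lab = traj.segment[lo:hi + 1][nearest]
        if k > 0:  # region start coincides with previous region end
            pts, lab = pts[1:], lab[1:]
        xs.append(pts[:, 0])
        ys.append(pts[:, 1])
        labs.append(lab)
    return replace(traj, x=np.concatenate(xs), y=np.concatenate(ys),
                   segment=np.concatenate(labs), speed=float(speed),
                   region_breaks=None)


def apply_direction(traj: TrialTrajectory, side: str) -> TrialTrajectory:
    """Mirror a rightward trajectory for leftward trials (x -> -x).

    Mirroring is about the vertical screen-centre axis, so the start
    position at the centre is preserved; applying it twice is the identity.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    cond = Condition(traj.condition.velocity_level, side)
    if side == "right":
        return replace(traj, condition=cond)
    return replace(traj, x=-traj.x, condition=cond)


def generate_trial(config: GeneratorConfig, condition: Condition,
                   rng: np.random.Generator, trial_index: int = 0) -> TrialTrajectory:
    """Dense build + constant-speed resampling + direction, in one call."""
    dense = build_trial_trajectory(config, Condition(condition.velocity_level, "right"),
                                   rng, trial_index=trial_index)
    traj = resample_trial(dense, config.speed_for(condition.velocity_level))
    return apply_direction(traj, condition.side)


def trial_rng(seed: int, trial_index: int) -> np.random.Generator:
    """Deterministic per-trial substream so single trials are regenerable."""
    return np.random.default_rng([seed, 1 + trial_index])


def generate_session(config: GeneratorConfig) -> list[TrialTrajectory]:
    """Generate a full counterbalanced session.

    Every condition appears ``n_repeats_per_condition`` times (72 trials with
    the defaults); the presentation order is shuffled under the session seed
    and each trial draws its random coefficients from a deterministic
    per-trial substream.
    """
    cells = config.conditions() * config.n_repeats_per_condition
    order_rng = np.random.default_rng([config.seed, 0])
    order = order_rng.permutation(len(cells))
    trials = []
    for trial_index, cell_idx in enumerate(order):
        condition = cells[cell_idx]
        rng = trial_rng(config.seed, trial_index)
        trials.append(generate_trial(config, condition, rng, trial_index=trial_index))
    return trials
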