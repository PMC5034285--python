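"""State-level simulation of the two closed-loop virtual-reality tasks.

Two virtual environments are simulated offline at the camera frame rate:

* **Optomotor response (OMR)** — a whole-field grating drifts at a fixed
  speed; the larva's intended trajectory (tail deflection -> ARX
  kinematics -> integrated path, with a gain on axial speed) rotates and
  translates it relative to the grating.  The behavioral readout is the
  alignment angle theta between heading and grating direction.

* **Virtual prey capture** — a small spot sweeps along the azimuth at
  fixed angular speed until the first tail bout, then freezes in the
  world; afterwards its displayed azimuth and apparent size follow the
  larva's predicted trajectory.  A trial ends in capture (within 0.4 mm
  of the prey), failure (azimuth beyond +/-90 deg) or timeout.

Feedback modes: ``realtime`` updates the display every frame, ``delayed``
only while the predicted planar speed is below the end-of-bout threshold
(0.2 mm/s), ``open_loop`` never.  The world-frame state is always
complete — the modes differ only in the display snapshot the agent sees.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .arx import ARXModel, KinematicSeries, TARGETS, predict
from .config import OMRConfig, PreyConfig, logger
from .tracking import DeflectionSeries
from .trajectory import Path, Pose2D, integrate, wrap_angle

FEEDBACK_MODES = ("realtime", "delayed", "open_loop")


@dataclass(frozen=True)
class FeedbackMode:
    mode: str = "realtime"
    end_of_bout_speed_threshold_mm_s: float = 0.2

    def __post_init__(self):
        if self.mode not in FEEDBACK_MODES:
            raise ValueError(f"mode must be one of {FEEDBACK_MODES}")
        if self.end_of_bout_speed_threshold_mm_s <= 0:
            raise ValueError("speed threshold must be positive")


class KinematicsPipeline:
    """Deflection -> free-run ARX kinematics -> integrated trajectory."""

    def __init__(self, models: dict, sample_rate_hz: float | None = None):
        self.models = models
        self.sample_rate_hz = sample_rate_hz or models["axial_speed"].config.sample_rate_hz

    def kinematics(self, deflection) -> KinematicSeries:
        x = np.asarray(
            deflection.values if hasattr(deflection, "values") else deflection,
            dtype=float,
        )
        comps = {t: predict(self.models[t], x) for t in TARGETS}
        return KinematicSeries(
            comps["axial_speed"], comps["lateral_speed"], comps["yaw_speed"],
            self.sample_rate_hz,
        )

    def path(self, deflection, pose0: Pose2D = Pose2D(0.0, 0.0, 0.0)) -> Path:
        return integrate(self.kinematics(deflection), pose0)

    def heading_change(self, deflection) -> float:
        """Net heading change (rad, unwrapped) produced by one bout."""
        kin = self.kinematics(deflection)
        return float(np.sum(kin.yaw_speed) / self.sample_rate_hz)


@dataclass
class BoutRecord:
    start_frame: int
    end_frame: int
    theta_start_deg: float = float("nan")
    theta_end_deg: float = float("nan")


@dataclass
class TrialRecord:
    """Per-trial log: theta trace, bouts, outcome and the path in VR."""

    theta_deg: np.ndarray
    bouts: list
    outcome: str  # capture | failure | timeout | n/a
    latency_s: float
    path: Path
    mode: str = "realtime"
    initial_theta_deg: float = float("nan")
    prey_world_xy: tuple | None = None

    @property
    def has_bout(self) -> bool:
        return len(self.bouts) > 0

    def to_json(self) -> str:
        doc = {
            "theta_deg": np.asarray(self.theta_deg).tolist(),
            "bouts": [asdict(b) for b in self.bouts],
            "outcome": self.outcome,
            "latency_s": self.latency_s,
            "mode": self.mode,
            "initial_theta_deg": self.initial_theta_deg,
            "prey_world_xy": list(self.prey_world_xy) if self.prey_world_xy else None,
            "path": self.path.array.tolist(),
            "sample_rate_hz": self.path.sample_rate_hz,
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, line: str) -> "TrialRecord":
        doc = json.loads(line)
        return cls(
            theta_deg=np.array(doc["theta_deg"]),
            bouts=[BoutRecord(**b) for b in doc["bouts"]],
            outcome=doc["outcome"],
            latency_s=doc["latency_s"],
            path=Path(np.array(doc["path"]), doc["sample_rate_hz"]),
            mode=doc.get("mode", "realtime"),
            initial_theta_deg=doc.get("initial_theta_deg", float("nan")),
            prey_world_xy=tuple(doc["prey_world_xy"]) if doc.get("prey_world_xy") else None,
        )


def write_session(records, path) -> None:
    """One TrialRecord per line (JSON lines)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(r.to_json() + "\n")


def read_session(path) -> list:
    with open(path) as fh:
        return [TrialRecord.from_json(line) for line in fh if line.strip()]


# ------------------------------------------------------------------- OMR


@dataclass
class GratingState:
    """Whole-field grating: drift direction (world frame), phase along it."""

    direction: float  # rad
    phase: float = 0.0  # mm, modulo spatial_period
    speed: float = 10.0  # mm/s
    spatial_period: float = 10.0  # mm

    def __post_init__(self):
        if self.spatial_period <= 0:
            raise ValueError("spatial_period must be positive")
        self.phase = self.phase % self.spatial_period


def omr_step(state: GratingState, pose: Pose2D, larva_motion, gain: float, dt: float):
    """Advance the grating and apply one frame of larva motion.

    ``larva_motion`` is the per-frame body-frame pose delta
    (d_axial_mm, d_lateral_mm, d_heading_rad); the axial component is
    multiplied by ``gain`` before being applied.  Returns the new
    grating state, larva pose and theta = grating direction - heading.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    d_ax, d_lat, d_head = larva_motion
    state = GratingState(
        state.direction,
        state.phase + state.speed * dt,
        state.speed,
        state.spatial_period,
    )
    h = pose.heading
    x = pose.x + gain * d_ax * math.cos(h) - d_lat * math.sin(h)
    y = pose.y + gain * d_ax * math.sin(h) + d_lat * math.cos(h)
    pose = Pose2D(x, y, h + d_head)
    theta = wrap_angle(state.direction - pose.heading)
    return state, pose, theta


def run_omr_session(agent, pipeline: KinematicsPipeline, config: OMRConfig,
                    seed: int = 0, mode: str = "realtime") -> list:
    """Simulate an OMR session of ``config.n_trials`` stimulation periods.

    Each trial starts with the grating direction at a uniformly random
    angle to the larva's heading; the agent is queried when the larva is
    quiescent and may answer with a deflection bout, which the pipeline
    turns into kinematics applied frame by frame.  In ``open_loop`` mode
    the displayed theta is frozen at its initial value (the grating does
    not react), although the virtual trajectory is still recorded.
    """
    fmode = FeedbackMode(mode)
    rng = np.random.default_rng(seed)
    fs = config.sample_rate_hz
    dt = 1.0 / fs
    n_frames = int(round(config.trial_s * fs))
    records = []
    for _ in range(config.n_trials):
        theta0 = rng.uniform(-math.pi, math.pi)
        grating = GratingState(theta0, 0.0, config.grating_speed_mm_s,
                               config.spatial_period_mm)
        pose = Pose2D(0.0, 0.0, 0.0)
        if hasattr(agent, "reset"):
            agent.reset(rng)
        theta_trace = np.empty(n_frames)
        poses = np.empty((n_frames + 1, 3))
        poses[0] = (0.0, 0.0, 0.0)
        bout_list = []
        kin = None  # active bout kinematics
        kin_idx = 0
        displayed_theta = theta0
        quiet_speed = 0.0
        for k in range(n_frames):
            if kin is None:
                obs = {"theta_deg": math.degrees(displayed_theta), "t": k * dt}
                defl = agent.plan_bout(obs, k * dt)
                if defl is not None:
                    values = np.asarray(
                        defl.values if hasattr(defl, "values") else defl, dtype=float
                    )
                    kin = pipeline.kinematics(DeflectionSeries(values, fs))
                    kin_idx = 0
                    bout_list.append(
                        BoutRecord(k, k + len(values),
                                   theta_start_deg=math.degrees(
                                       wrap_angle(grating.direction - pose.heading)))
                    )
            if kin is not None:
                motion = (
                    kin.axial_speed[kin_idx] * dt,
                    kin.lateral_speed[kin_idx] * dt,
                    kin.yaw_speed[kin_idx] * dt,
                )
                quiet_speed = math.hypot(kin.axial_speed[kin_idx],
                                         kin.lateral_speed[kin_idx])
                kin_idx += 1
                if kin_idx >= len(kin):
                    kin = None
            else:
                motion = (0.0, 0.0, 0.0)
                quiet_speed = 0.0
            grating, pose, theta = omr_step(grating, pose, motion, config.gain, dt)
            if fmode.mode == "realtime":
                displayed_theta = theta
            elif fmode.mode == "delayed":
                if quiet_speed < fmode.end_of_bout_speed_threshold_mm_s:
                    displayed_theta = theta
            # open_loop: displayed_theta stays at theta0
            theta_trace[k] = math.degrees(theta)
            poses[k + 1] = (pose.x, pose.y, pose.heading)
            if kin is None and bout_list and bout_list[-1].end_frame == k + 1:
                bout_list[-1].theta_end_deg = theta_trace[k]
        for b in bout_list:
            if math.isnan(b.theta_end_deg):
                b.theta_end_deg = theta_trace[min(b.end_frame, n_frames) - 1]
        records.append(
            TrialRecord(
                theta_deg=theta_trace,
                bouts=bout_list,
                outcome="n/a",
                latency_s=bout_list[0].start_frame * dt if bout_list else float("nan"),
                path=Path(poses, fs),
                mode=fmode.mode,
                initial_theta_deg=math.degrees(theta0),
            )
        )
    return records


@dataclass
class AlignmentMetrics:
    aligned_fraction_vs_time: np.ndarray
    initial_aligned_fraction: float
    final_aligned_fraction: float
    mean_abs_theta_per_bout_deg: np.ndarray
    latency_bin_edges_deg: np.ndarray
    latency_mean_s_per_bin: np.ndarray
    n_trials: int


def alignment_metrics(records, aligned_threshold_deg: float = 30.0) -> AlignmentMetrics:
    """OMR alignment metrics over trials with at least one bout.

    A trial counts as aligned at time t when |theta(t)| is below the
    threshold (30 deg by default).  Also reports mean |theta| at the end
    of successive bouts and mean first-bout latency binned by initial
    theta.
    """
    eligible = [r for r in records if r.has_bout]
    if not eligible:
        raise ValueError("no trials with at least one bout")
    thetas = np.stack([r.theta_deg for r in eligible])
    aligned = np.abs(thetas) < aligned_threshold_deg
    frac = aligned.mean(axis=0)

    max_bouts = max(len(r.bouts) for r in eligible)
    per_bout = []
    for bi in range(max_bouts):
        vals = [abs(r.bouts[bi].theta_end_deg) for r in eligible if len(r.bouts) > bi]
        per_bout.append(float(np.mean(vals)))

    edges = np.linspace(-180.0, 180.0, 7)
    lat_means = np.full(len(edges) - 1, float("nan"))
    init = np.array([r.initial_theta_deg for r in eligible])
    lats = np.array([r.latency_s for r in eligible])
    for i in range(len(edges) - 1):
        sel = (init >= edges[i]) & (init < edges[i + 1])
        if sel.any():
            lat_means[i] = float(np.nanmean(lats[sel]))

    return AlignmentMetrics(
        aligned_fraction_vs_time=frac,
        initial_aligned_fraction=float(aligned[:, 0].mean()),
        final_aligned_fraction=float(aligned[:, -1].mean()),
        mean_abs_theta_per_bout_deg=np.array(per_bout),
        latency_bin_edges_deg=edges,
        latency_mean_s_per_bin=lat_means,
        n_trials=len(eligible),
    )


# ------------------------------------------------------------------ prey


def apparent_angle(radius_mm: float, distance_mm: float) -> float:
    """Apparent angular size 2*arctan(radius/distance), in degrees."""
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    if distance_mm <= radius_mm:
        raise ValueError("distance must exceed radius (prey reached/overlapping)")
    return math.degrees(2.0 * math.atan(radius_mm / distance_mm))


def true_azimuth_deg(pose: Pose2D, prey_xy) -> float:
    """Prey azimuth relative to heading, deg, wrapped to (-180, 180]."""
    dx, dy = prey_xy[0] - pose.x, prey_xy[1] - pose.y
    return math.degrees(wrap_angle(math.atan2(dy, dx) - pose.heading))


def true_distance_mm(pose: Pose2D, prey_xy) -> float:
    return math.hypot(prey_xy[0] - pose.x, prey_xy[1] - pose.y)


@dataclass
class PreyState:
    """World-frame prey + larva state plus the display snapshot shown."""

    prey_xy: tuple
    prey_radius_mm: float
    sweep_active: bool
    sweep_speed_deg_s: float
    larva: Pose2D
    display_azimuth_deg: float
    display_apparent_angle_deg: float

    def __post_init__(self):
        if self.prey_radius_mm <= 0:
            raise ValueError("prey_radius_mm must be positive")


def prey_step(state: PreyState, larva_motion, dt: float, mode: FeedbackMode) -> PreyState:
    """Advance the prey environment by one frame.

    Before the first bout (``sweep_active``) the prey moves toward
    azimuth 0 at the sweep speed at fixed range.  After the freeze the
    prey is fixed in the world, the larva pose integrates
    ``larva_motion`` = (d_axial_mm, d_lateral_mm, d_heading_rad), and
    the display snapshot is refreshed according to the feedback mode
    (every frame, only below the end-of-bout speed threshold, or never).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if state.sweep_active:
        az = state.display_azimuth_deg
        step = state.sweep_speed_deg_s * dt
        az_new = az - math.copysign(min(step, abs(az)), az) if az != 0.0 else 0.0
        dist = true_distance_mm(state.larva, state.prey_xy)
        ang = state.larva.heading + math.radians(az_new)
        prey_xy = (
            state.larva.x + dist * math.cos(ang),
            state.larva.y + dist * math.sin(ang),
        )
        return PreyState(
            prey_xy, state.prey_radius_mm, True, state.sweep_speed_deg_s,
            state.larva, az_new, apparent_angle(state.prey_radius_mm, dist),
        )

    d_ax, d_lat, d_head = larva_motion
    h = state.larva.heading
    pose = Pose2D(
        state.larva.x + d_ax * math.cos(h) - d_lat * math.sin(h),
        state.larva.y + d_ax * math.sin(h) + d_lat * math.cos(h),
        h + d_head,
    )
    speed = math.hypot(d_ax, d_lat) / dt
    az = state.display_azimuth_deg
    size = state.display_apparent_angle_deg
    refresh = (
        mode.mode == "realtime"
        or (mode.mode == "delayed" and speed < mode.end_of_bout_speed_threshold_mm_s)
    )
    if refresh:
        dist = true_distance_mm(pose, state.prey_xy)
        az = true_azimuth_deg(pose, state.prey_xy)
        size = apparent_angle(state.prey_radius_mm, max(dist, state.prey_radius_mm * 1.001))
    return PreyState(
        state.prey_xy, state.prey_radius_mm, False, state.sweep_speed_deg_s,
        pose, az, size,
    )


def run_prey_session(agent, pipeline: KinematicsPipeline, config: PreyConfig,
                     mode_schedule=None, seed: int = 0) -> list:
    """Simulate a virtual prey-capture session.

    The prey appears at +/-90 deg (random side) at ``appear_distance_mm``
    and sweeps toward 0 deg; the sweep freezes at the first bout onset.
    Capture: larva-prey distance <= capture threshold.  Failure: |true
    azimuth| beyond the failure threshold.  Timeout: the sweep completes
    with no bout (or the trial exceeds ``max_trial_s``).  Per-trial
    feedback mode comes from ``mode_schedule`` (a mode name, a sequence,
    or None for random draws with ``config.delayed_fraction`` delayed).
    """
    rng = np.random.default_rng(seed)
    fs = config.sample_rate_hz
    dt = 1.0 / fs
    max_frames = int(round(config.max_trial_s * fs))
    records = []
    for trial in range(config.n_trials):
        if mode_schedule is None:
            mode_name = "delayed" if rng.random() < config.delayed_fraction else "realtime"
        elif isinstance(mode_schedule, str):
            mode_name = mode_schedule
        else:
            mode_name = mode_schedule[trial % len(mode_schedule)]
        fmode = FeedbackMode(mode_name, config.end_of_bout_speed_threshold_mm_s)

        side = 90.0 if rng.random() < 0.5 else -90.0
        pose = Pose2D(0.0, 0.0, 0.0)
        ang = pose.heading + math.radians(side)
        prey_xy = (
            pose.x + config.appear_distance_mm * math.cos(ang),
            pose.y + config.appear_distance_mm * math.sin(ang),
        )
        state = PreyState(
            prey_xy, config.prey_radius_mm, True, config.sweep_speed_deg_s,
            pose, side, apparent_angle(config.prey_radius_mm, config.appear_distance_mm),
        )
        if hasattr(agent, "reset"):
            agent.reset(rng)

        theta_trace = []
        poses = [(0.0, 0.0, 0.0)]
        bout_list = []
        outcome = "timeout"
        kin = None
        kin_idx = 0
        for k in range(max_frames):
            t = k * dt
            obs = {
                "azimuth_deg": state.display_azimuth_deg,
                "apparent_angle_deg": state.display_apparent_angle_deg,
                "true_azimuth_deg": true_azimuth_deg(state.larva, state.prey_xy),
                "sweeping": state.sweep_active,
                "t": t,
            }
            if kin is None:
                defl = agent.plan_bout(obs, t)
                if defl is not None:
                    values = np.asarray(
                        defl.values if hasattr(defl, "values") else defl, dtype=float
                    )
                    kin = pipeline.kinematics(DeflectionSeries(values, fs))
                    kin_idx = 0
                    bout_list.append(
                        BoutRecord(k, k + len(values),
                                   theta_start_deg=obs["true_azimuth_deg"])
                    )
                    if state.sweep_active:
                        # first bout onset: prey frozen in the world
                        state = PreyState(
                            state.prey_xy, state.prey_radius_mm, False,
                            state.sweep_speed_deg_s, state.larva,
                            state.display_azimuth_deg,
                            state.display_apparent_angle_deg,
                        )
            if kin is not None:
                motion = (
                    kin.axial_speed[kin_idx] * dt,
                    kin.lateral_speed[kin_idx] * dt,
                    kin.yaw_speed[kin_idx] * dt,
                )
                kin_idx += 1
                if kin_idx >= len(kin):
                    kin = None
            else:
                motion = (0.0, 0.0, 0.0)
            if state.sweep_active and kin is None:
                state = prey_step(state, (0.0, 0.0, 0.0), dt, fmode)
                theta_trace.append(true_azimuth_deg(state.larva, state.prey_xy))
                poses.append((state.larva.x, state.larva.y, state.larva.heading))
                if state.display_azimuth_deg == 0.0:
                    outcome = "timeout"  # sweep completed with no bout
                    break
                continue
            state = prey_step(state, motion, dt, fmode)
            az = true_azimuth_deg(state.larva, state.prey_xy)
            dist = true_distance_mm(state.larva, state.prey_xy)
            theta_trace.append(az)
            poses.append((state.larva.x, state.larva.y, state.larva.heading))
            if kin is None and bout_list and bout_list[-1].end_frame <= k + 1:
                if math.isnan(bout_list[-1].theta_end_deg):
                    bout_list[-1].theta_end_deg = az
            if dist <= config.capture_distance_mm:
                outcome = "capture"
                break
            if abs(az) > config.failure_azimuth_deg:
                outcome = "failure"
                break
        for b in bout_list:
            if math.isnan(b.theta_end_deg):
                b.theta_end_deg = theta_trace[-1] if theta_trace else float("nan")
        records.append(
            TrialRecord(
                theta_deg=np.asarray(theta_trace),
                bouts=bout_list,
                outcome=outcome,
                latency_s=bout_list[0].start_frame * dt if bout_list else float("nan"),
                path=Path(np.asarray(poses), fs),
                mode=mode_name,
                initial_theta_deg=side,
                prey_world_xy=state.prey_xy,
            )
        )
    return records


def capture_fraction(records, mode: str | None = None) -> float:
    """Fraction of trials with >= 1 bout that ended in capture."""
    sel = [r for r in records if r.has_bout and (mode is None or r.mode == mode)]
    if not sel:
        return float("nan")
    return float(np.mean([r.outcome == "capture" for r in sel]))


def score_path_against_prey(path: Path, prey_xy, capture_distance_mm: float = 0.4,
                            failure_azimuth_deg: float = 90.0) -> bool:
    """Replay a realized path against a prey position: True if it reaches
    the capture distance before the azimuth exceeds the failure bound."""
    arr = path.array
    for x, y, h in arr:
        pose = Pose2D(x, y, h)
        if true_distance_mm(pose, prey_xy) <= capture_distance_mm:
            return True
        if abs(true_azimuth_deg(pose, prey_xy)) > failure_azimuth_deg:
            return False
    return False


def shuffle_control(records, n_shuffles: int = 100, seed: int = 0,
                    appear_distance_mm: float = 1.5,
                    capture_distance_mm: float = 0.4,
                    failure_azimuth_deg: float = 90.0) -> float:
    """Capture fraction of realized paths re-scored against random prey.

    Each path (trials with >= 1 bout) is re-scored against a prey placed
    at a uniformly random azimuth in [-90, 90] deg at the appearance
    distance from the path start; returns the mean capture fraction over
    shuffles.
    """
    paths = [r.path for r in records if r.has_bout and len(r.path) >= 1]
    if not paths:
        raise ValueError("no records with a path and at least one bout")
    rng = np.random.default_rng(seed)
    hits = 0
    total = 0
    for _ in range(n_shuffles):
        for p in paths:
            pose0 = p.pose(0)
            az = math.radians(rng.uniform(-90.0, 90.0))
            ang = pose0.heading + az
            prey = (
                pose0.x + appear_distance_mm * math.cos(ang),
                pose0.y + appear_distance_mm * math.sin(ang),
            )
            if len(p) == 1 or not np.any(np.diff(p.array[:, :2], axis=0)):
                total += 1  # zero-length path never captures
                continue
            hits += score_path_against_prey(
                p, prey, capture_distance_mm, failure_azimuth_deg
            )
            total += 1
    return hits / total


def normalized_bout_distance(path_segment: Path, prey_world_pos) -> float:
    """Distance to the prey at bout end divided by the distance at bout
    start (0.5 = the bout halved the distance)."""
    if len(path_segment) < 2:
        raise ValueError("path segment needs >= 2 poses")
    d0 = true_distance_mm(path_segment.pose(0), prey_world_pos)
    if d0 <= 0:
        raise ValueError("segment starts at the prey; ratio undefined")
    d1 = true_distance_mm(path_segment.pose(len(path_segment) - 1), prey_world_pos)
    return d1 / d0


def normalized_bout_distances(records, config: PreyConfig) -> dict:
    """Per-mode normalized distance-to-prey ratios over all bouts."""
    out = {}
    for r in records:
        if not r.has_bout or r.prey_world_xy is None:
            continue
        for b in r.bouts:
            lo = min(b.start_frame, len(r.path) - 1)
            hi = min(b.end_frame, len(r.path) - 1)
            if hi <= lo:
                continue
            seg = Path(r.path.array[lo:hi + 1], r.path.sample_rate_hz)
            try:
                ratio = normalized_bout_distance(seg, r.prey_world_xy)
            except ValueError:
                continue
            out.setdefault(r.mode, []).append(ratio)
    return {k: np.asarray(v) for k, v in out.items()}


# ---------------------------------------------------------------- agents


class InertAgent:
    """Never moves; yields no-bout trials."""

    def reset(self, rng):
        pass

    def plan_bout(self, obs, t):
        return None


class ReplayAgent:
    """Replays library deflections in order, ignoring the display."""

    def __init__(self, library, ibi_s: float = 0.5):
        self.library = library
        self.ibi_s = ibi_s
        self._i = 0
        self._next_t = 0.0

    def reset(self, rng):
        self._next_t = 0.0

    def plan_bout(self, obs, t):
        if t < self._next_t or self._i >= len(self.library.entries):
            return None
        entry = self.library.entries[self._i % len(self.library.entries)]
        self._i += 1
        self._next_t = t + len(entry.deflection) / self.library.sample_rate_hz + self.ibi_s
        return entry.deflection


class _TurnCalibratedAgent:
    """Base for scripted agents that aim using a calibrated turn template.

    The lateral/yaw models are linear in the signed deflection, so
    scaling the turn template by s turns the larva by s times the
    template's heading change; the scale for a desired turn is computed
    once from the pipeline.
    """

    def __init__(self, pipeline: KinematicsPipeline, max_scale: float = 4.0):
        from .synth import DEFAULT_TEMPLATES, simulate_deflection

        self.pipeline = pipeline
        turn = DEFAULT_TEMPLATES["routine_turn"]
        self._turn = simulate_deflection(
            type(turn)(**{**turn.__dict__, "seed": 7}), pipeline.sample_rate_hz
        ).values
        scoot = DEFAULT_TEMPLATES["scoot"]
        self._scoot = simulate_deflection(
            type(scoot)(**{**scoot.__dict__, "seed": 7}), pipeline.sample_rate_hz
        ).values
        self._unit_turn_rad = pipeline.heading_change(self._turn)
        if abs(self._unit_turn_rad) < 1e-9:
            raise ValueError("turn template produces no heading change under the pipeline")
        self.max_scale = max_scale

    def turn_bout(self, desired_rad: float) -> np.ndarray:
        scale = desired_rad / self._unit_turn_rad
        scale = float(np.clip(scale, -self.max_scale, self.max_scale))
        return scale * self._turn

    def scoot_bout(self) -> np.ndarray:
        return self._scoot


class PControllerAgent(_TurnCalibratedAgent):
    """OMR agent turning proportionally toward the grating direction.

    Each bout aims to change heading by ``gain_p * theta`` (theta =
    grating direction minus heading), which drives |theta| toward zero.
    """

    def __init__(self, pipeline, gain_p: float = 1.0, first_latency_s: float = 0.25,
                 ibi_s: float = 0.35, max_scale: float = 6.0):
        super().__init__(pipeline, max_scale)
        self.gain_p = gain_p
        self.first_latency_s = first_latency_s
        self.ibi_s = ibi_s
        self._next_t = first_latency_s

    def reset(self, rng):
        self._next_t = self.first_latency_s

    def plan_bout(self, obs, t):
        if t < self._next_t:
            return None
        values = self.turn_bout(self.gain_p * math.radians(obs["theta_deg"]))
        self._next_t = t + len(values) / self.pipeline.sample_rate_hz + self.ibi_s
        return values


class PreySeekerAgent(_TurnCalibratedAgent):
    """Prey-capture agent: strike when the prey enters the trigger window,
    then alternate aiming turns and forward scoots toward the displayed
    (or, with ``use_display=False``, the true) prey azimuth."""

    def __init__(self, pipeline, trigger_azimuth_deg: float = 30.0,
                 aim_tolerance_deg: float = 8.0, ibi_s: float = 0.6,
                 use_display: bool = True, max_scale: float = 4.0):
        super().__init__(pipeline, max_scale)
        self.trigger_azimuth_deg = trigger_azimuth_deg
        self.aim_tolerance_deg = aim_tolerance_deg
        self.ibi_s = ibi_s
        self.use_display = use_display
        self._next_t = 0.0
        self._engaged = False

    def reset(self, rng):
        self._next_t = 0.0
        self._engaged = False

    def plan_bout(self, obs, t):
        az = obs["azimuth_deg"] if self.use_display else obs["true_azimuth_deg"]
        if not self._engaged:
            if obs.get("sweeping", False) and abs(az) > self.trigger_azimuth_deg:
                return None
            self._engaged = True
        if t < self._next_t:
            return None
        if abs(az) > self.aim_tolerance_deg:
            values = self.turn_bout(math.radians(az))
        else:
            values = self.scoot_bout()
        self._next_t = t + len(values) / self.pipeline.sample_rate_hz + self.ibi_s
        return values
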