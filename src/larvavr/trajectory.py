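"""Dead-reckoning integration of body-frame kinematics into a 2D path.

The larva's planar displacement is fully described by three body-frame
speeds: axial (forward, mm/s), lateral (body-left, mm/s) and yaw
(counter-clockwise, rad/s).  Integrating them from an initial pose gives
the head trajectory; comparing an integrated prediction against an
observed path yields the per-bout error metrics used to validate the
tail-to-trajectory model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import logger


def wrap_angle(a):
    """Wrap an angle (rad) to (-pi, pi]."""
    w = np.asarray(a, dtype=float)
    out = -((-w + np.pi) % (2.0 * np.pi) - np.pi)
    return float(out) if np.isscalar(a) or out.ndim == 0 else out


@dataclass(frozen=True)
class Pose2D:
    """Planar pose: position in mm, heading in rad CCW from +x, wrapped."""

    x: float
    y: float
    heading: float

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y) and math.isfinite(self.heading)):
            raise ValueError("Pose2D fields must be finite")
        object.__setattr__(self, "heading", wrap_angle(self.heading))


class Path:
    """Time-stamped pose sequence.

    Stored as an (n, 3) float array of (x_mm, y_mm, heading_rad); headings
    are wrapped on access through :attr:`poses`.
    """

    def __init__(self, poses, sample_rate_hz: float):
        arr = np.atleast_2d(np.asarray(poses, dtype=float))
        if arr.shape[0] < 1 or arr.shape[1] != 3:
            raise ValueError("Path needs an (n, 3) array with n >= 1")
        if not np.all(np.isfinite(arr)):
            raise ValueError("Path poses must be finite")
        if sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        self.array = arr
        self.sample_rate_hz = float(sample_rate_hz)

    def __len__(self) -> int:
        return self.array.shape[0]

    @property
    def xy(self) -> np.ndarray:
        return self.array[:, :2]

    @property
    def headings(self) -> np.ndarray:
        return wrap_angle(self.array[:, 2])

    def pose(self, i: int) -> Pose2D:
        x, y, h = self.array[i]
        return Pose2D(x, y, h)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self)) / self.sample_rate_hz

    def to_csv(self, path, header: str | None = None) -> None:
        import pandas as pd

        df = pd.DataFrame(
            {
                "time_s": self.times_s,
                "x_mm": self.array[:, 0],
                "y_mm": self.array[:, 1],
                "heading_rad": self.headings,
            }
        )
        with open(path, "w") as fh:
            if header:
                fh.write(header.rstrip("\n") + "\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "Path":
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        dt = np.diff(df["time_s"].to_numpy())
        rate = 1.0 / float(np.median(dt)) if len(dt) else 1.0
        return cls(df[["x_mm", "y_mm", "heading_rad"]].to_numpy(), rate)


def integrate(kin, pose0: Pose2D, method: str = "euler") -> Path:
    """Integrate body-frame kinematics into a world-frame path.

    Forward Euler at the native frame rate: heading is advanced by
    ``yaw*dt`` and position by the body-frame velocity rotated into the
    world frame at the current (``euler``) or half-step (``midpoint``)
    heading.  The path has ``len(kin) + 1`` poses, starting at ``pose0``.
    """
    ax = np.asarray(kin.axial_speed, dtype=float)
    lat = np.asarray(kin.lateral_speed, dtype=float)
    yaw = np.asarray(kin.yaw_speed, dtype=float)
    if not (np.all(np.isfinite(ax)) and np.all(np.isfinite(lat)) and np.all(np.isfinite(yaw))):
        raise ValueError("kinematics must be finite")
    dt = 1.0 / kin.sample_rate_hz

    headings = np.empty(len(ax) + 1)
    headings[0] = pose0.heading
    headings[1:] = pose0.heading + np.cumsum(yaw) * dt

    if method == "euler":
        h = headings[:-1]
    elif method == "midpoint":
        h = headings[:-1] + 0.5 * yaw * dt
    else:
        raise ValueError(f"unknown integration method {method!r}")

    # body x-axis along heading, body y-axis = body-left (heading + 90 deg)
    dx = (ax * np.cos(h) - lat * np.sin(h)) * dt
    dy = (ax * np.sin(h) + lat * np.cos(h)) * dt

    arr = np.empty((len(ax) + 1, 3))
    arr[0] = (pose0.x, pose0.y, pose0.heading)
    arr[1:, 0] = pose0.x + np.cumsum(dx)
    arr[1:, 1] = pose0.y + np.cumsum(dy)
    arr[1:, 2] = headings[1:]
    return Path(arr, kin.sample_rate_hz)


@dataclass(frozen=True)
class BoutErrors:
    """Signed prediction-minus-observation errors for one bout."""

    heading_change_error_deg: float
    movement_direction_error_deg: float | None
    displacement_error_mm: float


def _bout_summary(path: Path):
    """(heading change rad, movement direction rad or None, displacement mm)."""
    p0, p1 = path.array[0], path.array[-1]
    dheading = wrap_angle(p1[2] - p0[2])
    d = p1[:2] - p0[:2]
    disp = float(np.hypot(d[0], d[1]))
    if disp == 0.0:
        return dheading, None, disp
    direction = wrap_angle(math.atan2(d[1], d[0]) - p0[2])
    return dheading, direction, disp


def bout_errors(pred: Path, obs: Path) -> BoutErrors:
    """Per-bout errors between a predicted and an observed path.

    Heading change = final minus initial heading; movement direction =
    angle of the net displacement relative to the initial heading;
    displacement = net distance travelled.  A bout whose observed
    displacement is zero has no defined movement direction and yields
    ``None`` for that component.
    """
    if len(pred) < 2 or len(obs) < 2:
        raise ValueError("both paths need at least 2 poses")
    hp, dp, sp = _bout_summary(pred)
    ho, do, so = _bout_summary(obs)
    if dp is None or do is None:
        dir_err = None
    else:
        dir_err = math.degrees(wrap_angle(dp - do))
    return BoutErrors(
        heading_change_error_deg=math.degrees(wrap_angle(hp - ho)),
        movement_direction_error_deg=dir_err,
        displacement_error_mm=sp - so,
    )


def aggregate_errors(pairs) -> dict:
    """Root-mean-square errors over (predicted, observed) path pairs.

    Bouts with zero observed displacement are excluded from the
    movement-direction component (their count is logged).
    """
    errs = [bout_errors(p, o) for p, o in pairs]
    if not errs:
        raise ValueError("no path pairs given")
    head = np.array([e.heading_change_error_deg for e in errs])
    disp = np.array([e.displacement_error_mm for e in errs])
    dirs = [e.movement_direction_error_deg for e in errs]
    n_excluded = sum(d is None for d in dirs)
    if n_excluded:
        logger.warning(
            "aggregate_errors: %d bout(s) with zero observed displacement "
            "excluded from movement-direction error", n_excluded
        )
    dir_arr = np.array([d for d in dirs if d is not None], dtype=float)
    return {
        "heading_change_rms_deg": float(np.sqrt(np.mean(head**2))),
        "movement_direction_rms_deg": (
            float(np.sqrt(np.mean(dir_arr**2))) if dir_arr.size else float("nan")
        ),
        "displacement_rms_mm": float(np.sqrt(np.mean(disp**2))),
        "n_bouts": len(errs),
        "n_direction_excluded": n_excluded,
    }
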