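"""Signed, dimensionless tail deflection from binarized larva images.

The deflection statistic summarises the tail bend in a single number per
frame.  A global ellipse is fitted to the fish silhouette (image-moment
equivalent ellipse); pixels are split in two groups along the major
axis (anterior vs posterior half); an ellipse is fitted to each group and the
center of curvature is the intersection of the two minor axes.  The
deflection is the body length at rest L0 divided by the mean distance R
of all fish pixels to that center, signed negative when the center lies
on the larva's left and positive on its right.  A straight fish (minor
axes parallel) has deflection 0.

All geometry is done in (x=col, y=row) pixel coordinates; "left of the
larva" is the +90 deg rotation of the head direction in that frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path as FilePath

import numpy as np

from .config import DEFAULT_SAMPLE_RATE_HZ, logger

#: minor axes within this angle of parallel are treated as a straight fish
PARALLEL_TOL_DEG = 1.0


@dataclass(frozen=True)
class EllipseFit:
    """Equivalent ellipse of a pixel set (image-moment convention)."""

    center: tuple  # (row, col) px
    major_axis_len: float  # px
    minor_axis_len: float  # px
    orientation: float  # rad, major-axis angle in the (x=col, y=row) frame

    def __post_init__(self):
        if not (self.major_axis_len >= self.minor_axis_len > 0):
            raise ValueError("need major_axis_len >= minor_axis_len > 0")


@dataclass
class DeflectionSeries:
    """Uniformly sampled signed tail deflection (dimensionless)."""

    values: np.ndarray
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    l0_mm: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("deflection values must be finite")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self)) / self.sample_rate_hz

    def to_csv(self, path, header: str | None = None) -> None:
        import pandas as pd

        df = pd.DataFrame(
            {
                "frame": np.arange(len(self)),
                "time_s": self.times_s,
                "deflection": self.values,
            }
        )
        with open(path, "w") as fh:
            if header:
                fh.write(header.rstrip("\n") + "\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path, l0_mm: float | None = None) -> "DeflectionSeries":
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        t = df["time_s"].to_numpy()
        rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else DEFAULT_SAMPLE_RATE_HZ
        return cls(df["deflection"].to_numpy(), rate, l0_mm)


def _pixel_xy(mask: np.ndarray) -> np.ndarray:
    rows, cols = np.nonzero(mask)
    return np.column_stack([cols, rows]).astype(float)


def _ellipse_from_points(pts: np.ndarray) -> EllipseFit:
    c = pts.mean(axis=0)
    d = pts - c
    mu20 = np.mean(d[:, 0] ** 2)
    mu02 = np.mean(d[:, 1] ** 2)
    mu11 = np.mean(d[:, 0] * d[:, 1])
    common = math.sqrt(max((mu20 - mu02) ** 2 + 4 * mu11**2, 0.0))
    lam1 = 0.5 * (mu20 + mu02 + common)
    lam2 = 0.5 * (mu20 + mu02 - common)
    orientation = 0.5 * math.atan2(2 * mu11, mu20 - mu02)
    major = 4.0 * math.sqrt(max(lam1, 0.0))
    minor = 4.0 * math.sqrt(max(lam2, 0.0))
    minor = max(minor, 1e-9)  # degenerate 1-px-thin sets
    major = max(major, minor)
    return EllipseFit(center=(c[1], c[0]), major_axis_len=major,
                      minor_axis_len=minor, orientation=orientation)


def ellipse_from_moments(mask: np.ndarray) -> EllipseFit:
    """Equivalent ellipse of a binary mask from second-order central moments."""
    mask = np.asarray(mask)
    pts = _pixel_xy(mask)
    if pts.shape[0] == 0:
        raise ValueError("no foreground")
    if pts.shape[0] < 5:
        raise ValueError(f"need >= 5 foreground pixels, got {pts.shape[0]}")
    return _ellipse_from_points(pts)


def _intersect_lines(p1, v1, p2, v2):
    """Intersection of p1 + t*v1 and p2 + s*v2 (all 2-vectors)."""
    a = np.array([[v1[0], -v2[0]], [v1[1], -v2[1]]])
    b = np.asarray(p2) - np.asarray(p1)
    t, _ = np.linalg.solve(a, b)
    return np.asarray(p1) + t * v1


def compute_deflection(
    mask: np.ndarray,
    l0_mm: float,
    px_per_mm: float,
    head_direction=None,
) -> float:
    """Signed dimensionless tail deflection of one binarized frame.

    ``head_direction`` (optional (dx, dy) in the x=col, y=row frame)
    overrides the built-in head heuristic, which takes the head half of
    the fish to be the pixel group with the rounder equivalent ellipse
    (larger minor/major ratio) — the head + yolk blob is rounder than the
    tail.  Sign: negative when the center of curvature lies on the
    larva's left (+90 deg from the head direction in this frame).
    """
    pts = _pixel_xy(np.asarray(mask))
    if pts.shape[0] == 0:
        raise ValueError("no foreground")
    if pts.shape[0] < 5:
        raise ValueError(f"need >= 5 foreground pixels, got {pts.shape[0]}")

    glob = _ellipse_from_points(pts)
    centroid = np.array([glob.center[1], glob.center[0]])  # (x, y)
    u = np.array([math.cos(glob.orientation), math.sin(glob.orientation)])

    # split along the major axis (anterior vs posterior half) by the sign
    # of the projection onto the major-axis direction: the two half
    # ellipses' minor axes are then chords' perpendiculars that meet at
    # the center of curvature
    rel = pts - centroid
    proj = rel @ u
    g1, g2 = pts[proj >= 0.0], pts[proj < 0.0]
    if g1.shape[0] < 5 or g2.shape[0] < 5:
        logger.warning("compute_deflection: empty/degenerate split group; returning 0")
        return 0.0

    e1 = _ellipse_from_points(g1)
    e2 = _ellipse_from_points(g2)

    # minor axes as infinite lines through the group centers
    v1 = np.array([-math.sin(e1.orientation), math.cos(e1.orientation)])
    v2 = np.array([-math.sin(e2.orientation), math.cos(e2.orientation)])
    cosang = abs(float(np.clip(np.dot(v1, v2), -1.0, 1.0)))
    if cosang >= math.cos(math.radians(PARALLEL_TOL_DEG)):
        return 0.0  # straight fish: R -> infinity

    c1 = np.array([e1.center[1], e1.center[0]])
    c2 = np.array([e2.center[1], e2.center[0]])
    center = _intersect_lines(c1, v1, c2, v2)

    r_mean_px = float(np.mean(np.linalg.norm(pts - center, axis=1)))
    if r_mean_px <= 0:
        return 0.0
    deflection = (l0_mm * px_per_mm) / r_mean_px

    if head_direction is None:
        # rounder group (larger minor/major ratio) marks the head half
        ratio1 = e1.minor_axis_len / e1.major_axis_len
        ratio2 = e2.minor_axis_len / e2.major_axis_len
        head_center = c1 if ratio1 >= ratio2 else c2
        proj = float(np.dot(head_center - centroid, u))
        head_dir = u if proj >= 0 else -u
    else:
        head_dir = np.asarray(head_direction, dtype=float)
        n = np.linalg.norm(head_dir)
        if n == 0:
            raise ValueError("head_direction must be nonzero")
        head_dir = head_dir / n

    left_dir = np.array([-head_dir[1], head_dir[0]])  # +90 deg from heading
    on_left = float(np.dot(center - centroid, left_dir)) > 0.0
    return -deflection if on_left else deflection


def binarize(frame: np.ndarray, threshold: float) -> np.ndarray:
    """Fixed-threshold binarization (foreground = bright pixels)."""
    return np.asarray(frame) > threshold


def deflection_series(
    stack,
    l0_mm: float,
    px_per_mm: float,
    threshold: float = 127.0,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    head_direction=None,
) -> DeflectionSeries:
    """Per-frame deflection of an image stack (array, iterable or TIFF path).

    Frames that are empty after thresholding contribute a 0 with a logged
    warning naming the frame index.
    """
    frames = _load_stack(stack)
    values = np.zeros(len(frames))
    for i, frame in enumerate(frames):
        mask = binarize(frame, threshold) if frame.dtype != bool else frame
        if not mask.any():
            logger.warning("deflection_series: frame %d empty after thresholding", i)
            continue
        try:
            values[i] = compute_deflection(mask, l0_mm, px_per_mm, head_direction)
        except ValueError:
            logger.warning("deflection_series: frame %d degenerate; value 0", i)
    return DeflectionSeries(values, sample_rate_hz, l0_mm)


def _load_stack(stack):
    """Accept an (n, r, c) array, a list of frames, a TIFF path or a
    directory of PNG/TIFF frames (sorted by name)."""
    if isinstance(stack, (str, FilePath)):
        p = FilePath(stack)
        if p.is_dir():
            import imageio.v3 as iio

            files = sorted(
                f for f in p.iterdir() if f.suffix.lower() in (".png", ".tif", ".tiff")
            )
            frames = [np.asarray(iio.imread(f)) for f in files]
        else:
            import tifffile

            arr = tifffile.imread(p)
            frames = [arr] if arr.ndim == 2 else list(arr)
    elif isinstance(stack, np.ndarray):
        frames = [stack] if stack.ndim == 2 else list(stack)
    else:
        frames = [np.asarray(f) for f in stack]
    if not frames:
        raise ValueError("empty image stack")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("frames must share a constant size")
    return frames
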