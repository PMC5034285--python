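"""Synthetic larvae: rendered images, bout deflections, ground-truth kinematics.

This module makes every downstream stage testable without animal data.
It renders a bent-larva silhouette as a constant-width band along a
circular arc (so the deflection geometry has an exact analytic
reference), synthesises category-typical tail-deflection bouts
(damped-envelope 20-30 Hz oscillations with category-specific amplitude
and left/right asymmetry), and produces paired ground-truth kinematics
by driving a known ARX system with the deflection — the independent
oracle for the identification code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .arx import ARXModel, KinematicSeries, TARGETS, apply_input_transform
from .config import ARXConfig, CATEGORIES, DEFAULT_SAMPLE_RATE_HZ, default_arx_configs
from .library import BoutEntry, BoutLibrary
from .tracking import DeflectionSeries
from .trajectory import Pose2D, integrate

# ---------------------------------------------------------------- rendering


@dataclass(frozen=True)
class LarvaRender:
    """Geometry of one rendered larva frame.

    The body midline is a circular arc of length ``body_length_mm`` and
    signed curvature ``curvature_per_mm`` (negative = left bend), starting
    at ``pose`` (head position, heading) and extending tailward.  All
    geometry uses the (x=col, y=row) pixel frame shared with the tracker.
    """

    body_length_mm: float = 4.0
    body_width_mm: float = 0.4
    curvature_per_mm: float = 0.0
    pose: Pose2D = Pose2D(0.0, 0.0, 0.0)
    px_per_mm: float = 20.0
    image_shape: tuple = (200, 200)
    taper: float = 1.0  # tail width as a fraction of head width (1 = constant)

    def __post_init__(self):
        if self.body_length_mm <= 0:
            raise ValueError("body_length_mm must be positive")
        if not (0 < self.body_width_mm < self.body_length_mm):
            raise ValueError("body_width_mm must be in (0, body_length_mm)")
        if abs(self.curvature_per_mm) * self.body_length_mm >= math.pi:
            raise ValueError("|curvature| * length must be < pi (self-intersection)")
        if not (0 < self.taper <= 1.0):
            raise ValueError("taper must be in (0, 1]")


def _midline(render: LarvaRender, s: np.ndarray) -> np.ndarray:
    """Midline points (mm) at arc lengths s from the head.

    Tangent angle tailward is phi(s) = heading + pi + kappa*s, so a
    negative kappa bends the tail toward the larva's left (heading+90deg).
    """
    k = render.curvature_per_mm
    h = render.pose.heading
    phi0 = h + math.pi
    if abs(k) < 1e-12:
        x = render.pose.x + s * math.cos(phi0)
        y = render.pose.y + s * math.sin(phi0)
    else:
        # exact integral of (cos(phi0 + k s), sin(phi0 + k s))
        x = render.pose.x + (np.sin(phi0 + k * s) - math.sin(phi0)) / k
        y = render.pose.y - (np.cos(phi0 + k * s) - math.cos(phi0)) / k
    return np.column_stack([x, y])


def arc_center(render: LarvaRender) -> tuple:
    """Analytic center of the midline arc in mm (requires kappa != 0)."""
    k = render.curvature_per_mm
    if abs(k) < 1e-12:
        raise ValueError("straight body has no arc center")
    phi0 = render.pose.heading + math.pi
    # center lies at signed radius 1/k along the +90deg normal of travel
    cx = render.pose.x + (1.0 / k) * (-math.sin(phi0))
    cy = render.pose.y + (1.0 / k) * (math.cos(phi0))
    return cx, cy


def _distance_to_arc(px, py, render: LarvaRender):
    """Distance (mm) from pixel coordinates to the midline arc."""
    k = render.curvature_per_mm
    if abs(k) < 1e-12:
        p0 = _midline(render, np.array([0.0]))[0]
        p1 = _midline(render, np.array([render.body_length_mm]))[0]
        d = p1 - p0
        t = ((px - p0[0]) * d[0] + (py - p0[1]) * d[1]) / float(d @ d)
        tc = np.clip(t, 0.0, 1.0)
        qx, qy = p0[0] + tc * d[0], p0[1] + tc * d[1]
        return np.hypot(px - qx, py - qy), t * render.body_length_mm
    cx, cy = arc_center(render)
    r = 1.0 / abs(k)
    beta = np.arctan2(py - cy, px - cx)
    p0 = _midline(render, np.array([0.0]))[0]
    alpha0 = math.atan2(p0[1] - cy, p0[0] - cx)
    # angle along the arc grows as k*s from alpha0
    rel = (beta - alpha0) * np.sign(k)
    rel = (rel + math.pi) % (2 * math.pi) - math.pi
    span = abs(k) * render.body_length_mm
    s = np.clip(rel, 0.0, span) / abs(k)
    on_arc = (rel >= 0.0) & (rel <= span)
    d_circle = np.abs(np.hypot(px - cx, py - cy) - r)
    ends = _midline(render, np.array([0.0, render.body_length_mm]))
    d_ends = np.minimum(
        np.hypot(px - ends[0, 0], py - ends[0, 1]),
        np.hypot(px - ends[1, 0], py - ends[1, 1]),
    )
    return np.where(on_arc, d_circle, d_ends), s


def render_larva(render: LarvaRender) -> np.ndarray:
    """Rasterize the larva: uint8 image, foreground 255.

    Foreground pixels are those within half the body width of the midline
    arc (distance-to-arc thresholding, giving an exact analytic reference
    band).  With ``taper < 1`` the half-width shrinks linearly from head
    to tail.  Raises if the body (including width) leaves the frame,
    naming the overflow direction.
    """
    rows, cols = render.image_shape
    s_dense = np.linspace(0.0, render.body_length_mm, 256)
    mid = _midline(render, s_dense)
    hw_head = render.body_width_mm / 2.0
    hw = hw_head * (1.0 - (1.0 - render.taper) * s_dense / render.body_length_mm)
    lo = mid.min(axis=0) - hw_head
    hi = mid.max(axis=0) + hw_head
    mm_w, mm_h = cols / render.px_per_mm, rows / render.px_per_mm
    overflow = []
    if lo[0] < 0:
        overflow.append("left")
    if lo[1] < 0:
        overflow.append("top")
    if hi[0] > mm_w:
        overflow.append("right")
    if hi[1] > mm_h:
        overflow.append("bottom")
    if overflow:
        raise ValueError(f"body exceeds frame on the {'/'.join(overflow)} side(s)")

    yy, xx = np.mgrid[0:rows, 0:cols]
    px = (xx + 0.5) / render.px_per_mm
    py = (yy + 0.5) / render.px_per_mm
    dist, s = _distance_to_arc(px.ravel(), py.ravel(), render)
    s_cl = np.clip(s, 0.0, render.body_length_mm)
    half_w = hw_head * (1.0 - (1.0 - render.taper) * s_cl / render.body_length_mm)
    mask = (dist <= half_w).reshape(rows, cols)
    return np.where(mask, np.uint8(255), np.uint8(0))


def render_stack(renders) -> np.ndarray:
    """Stack of rendered frames (n, rows, cols) uint8."""
    return np.stack([render_larva(r) for r in renders])


def write_tiff(stack: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint8),
                     photometric="minisblack")


# ----------------------------------------------------------- bout templates


@dataclass(frozen=True)
class BoutTemplate:
    """Parameters of one synthetic tail bout.

    ``asymmetry`` is the fraction of the oscillation envelope added as a
    constant bias toward one side (turns have a net one-sided bend).
    """

    category: str
    duration_s: float
    oscillation_hz: float
    peak_deflection: float
    asymmetry: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r}; valid: {CATEGORIES}"
            )
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not (15.0 <= self.oscillation_hz <= 40.0):
            raise ValueError("oscillation_hz must be in [15, 40]")
        if self.peak_deflection < 0:
            raise ValueError("peak_deflection must be >= 0")


#: per-category template defaults: amplitudes grow from fine forward scoots
#: to large escape bends; asymmetry encodes the net turn side.
DEFAULT_TEMPLATES = {
    "scoot": BoutTemplate("scoot", 0.30, 25.0, 0.55, 0.0),
    "asymmetric_scoot": BoutTemplate("asymmetric_scoot", 0.25, 26.0, 0.30, 0.45),
    "routine_turn": BoutTemplate("routine_turn", 0.30, 21.0, 0.85, 0.45),
    "c_bend": BoutTemplate("c_bend", 0.30, 28.0, 1.60, 0.15),
    "burst": BoutTemplate("burst", 0.55, 31.0, 1.25, 0.0),
}

PAD_S = 0.100  # quiet zero-padding on both sides of each bout


def simulate_deflection(
    template: BoutTemplate, sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
) -> DeflectionSeries:
    """Category-typical deflection bout, zero-padded 100 ms on both sides.

    The carrier is a sinusoid at the template frequency under a
    raised-cosine (Tukey) attack/decay envelope; asymmetry adds a
    same-envelope bias toward one side; a C-bend boosts its first
    half-cycle (the initial large body bend) relative to the
    counter-oscillation that follows.  Deterministic given the template
    (the seed drives small frequency/amplitude jitter only).
    """
    if sample_rate_hz < 2.0 * template.oscillation_hz:
        raise ValueError("sample_rate_hz must be >= 2 * oscillation_hz")
    rng = np.random.default_rng(template.seed)
    f = template.oscillation_hz * (1.0 + rng.uniform(-0.05, 0.05))
    peak = template.peak_deflection * (1.0 + rng.uniform(-0.08, 0.08))
    asym = template.asymmetry * (1.0 + rng.uniform(-0.10, 0.10))
    side = 1.0 if rng.random() < 0.5 else -1.0

    n = max(2, int(round(template.duration_s * sample_rate_hz)))
    t = np.arange(n) / sample_rate_hz
    carrier = np.sin(2.0 * math.pi * f * t)
    if template.category == "c_bend":
        # explosive onset: near-full amplitude within the first quarter
        # cycle (the initial C-shaped body bend), then a weaker
        # counter-oscillation decaying to rest
        t_attack = 0.25 / f
        dur = t[-1] if t[-1] > 0 else 1.0
        env = np.where(
            t < t_attack,
            np.sin(0.5 * math.pi * t / t_attack) ** 2,
            np.where(
                t < 0.4 * dur,
                1.0,
                0.5 * (1.0 + np.cos(math.pi * (t - 0.4 * dur) / (0.6 * dur))),
            ),
        )
        carrier = carrier * np.where(t < 0.5 / f, 1.0, 0.45)
    else:
        env = sps.windows.tukey(n, alpha=0.5)
    x = peak * env * (side * carrier + side * asym)

    pad = int(round(PAD_S * sample_rate_hz))
    values = np.concatenate([np.zeros(pad), x, np.zeros(pad)])
    return DeflectionSeries(values, sample_rate_hz)


def template_for(category: str, rng: np.random.Generator) -> BoutTemplate:
    """Jittered copy of the category default (±15% duration, ±10% peak)."""
    if category not in DEFAULT_TEMPLATES:
        raise ValueError(f"unknown category {category!r}; valid: {CATEGORIES}")
    base = DEFAULT_TEMPLATES[category]
    return BoutTemplate(
        category=category,
        duration_s=base.duration_s * (1.0 + rng.uniform(-0.15, 0.15)),
        oscillation_hz=float(
            np.clip(base.oscillation_hz + rng.uniform(-2.0, 2.0), 15.0, 40.0)
        ),
        peak_deflection=base.peak_deflection * (1.0 + rng.uniform(-0.10, 0.10)),
        asymmetry=base.asymmetry,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ------------------------------------------------------- ground-truth ARX


def _poly_from_poles(poles) -> np.ndarray:
    """A(z) coefficients a_1..a_N (a_0=1) from real pole locations."""
    coeffs = np.array([1.0])
    for p in poles:
        coeffs = np.convolve(coeffs, [1.0, -p])
    return coeffs[1:]


def default_true_models(sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ) -> dict:
    """Ground-truth ARX triple used by the generator.

    Stable, modestly damped dynamics scaled so that a default scoot
    advances the larva ~0.5 mm and a routine turn re-orients it by a few
    tens of degrees — the magnitudes of real bouts.
    """
    cfgs = default_arx_configs(sample_rate_hz)

    a_ax = np.zeros(cfgs["axial_speed"].n)
    a_ax[:2] = _poly_from_poles([0.55, 0.35])
    b_ax = 0.32 * np.array([1.0, 1.2, 1.3, 1.2, 1.0, 0.7, 0.4, 0.2])

    a_lat = np.zeros(cfgs["lateral_speed"].n)
    a_lat[:2] = _poly_from_poles([0.50, 0.20])
    b_lat = np.array([0.5, 0.35, 0.15, 0.0, -0.10, -0.10, -0.05, 0.0])

    a_yaw = np.zeros(cfgs["yaw_speed"].n)
    a_yaw[:2] = _poly_from_poles([0.60, 0.20])
    b_yaw = np.array([1.2, 1.0, 0.8, 0.6, 0.5, 0.4, 0.2, 0.1])

    return {
        "axial_speed": ARXModel(cfgs["axial_speed"], a_ax, b_ax, "axial_speed"),
        "lateral_speed": ARXModel(cfgs["lateral_speed"], a_lat, b_lat, "lateral_speed"),
        "yaw_speed": ARXModel(cfgs["yaw_speed"], a_yaw, b_yaw, "yaw_speed"),
    }


def random_stable_model(
    config: ARXConfig, rng: np.random.Generator, target: str = "axial_speed",
    pole_radius: float = 0.95,
) -> ARXModel:
    """Random ARX model with all poles inside ``pole_radius``.

    Coefficients are drawn directly at modest magnitude (rejection
    sampling on the root radius), matching the scale of identified
    tail-kinematics models and keeping the regression well conditioned.
    """
    while True:
        a = rng.normal(0.0, 0.25, config.n) / np.arange(1, config.n + 1) ** 0.5
        roots = np.roots(np.concatenate([[1.0], a]))
        if roots.size == 0 or np.max(np.abs(roots)) < pole_radius:
            b = rng.normal(0.0, 1.0, config.m + 1)
            return ARXModel(config, a, b, target)


def simulate_arx(
    models: dict,
    deflection: DeflectionSeries,
    noise_sd=0.0,
    seed: int = 0,
) -> KinematicSeries:
    """Run the ARX difference equation from rest with equation noise.

    Hand-rolled recurrence (independent of the filter-based predictor):
    y(k) = -sum a_i y(k-i) + sum b_j x'(k-j) + e(k), e ~ N(0, noise_sd),
    fed back through the autoregressive part (the textbook ARX error
    under which least squares is consistent).  ``noise_sd`` may be a
    scalar or a per-target dict.
    """
    rng = np.random.default_rng(seed)
    x = deflection.values
    out = {}
    for target in TARGETS:
        model = models[target]
        sd = noise_sd[target] if isinstance(noise_sd, dict) else noise_sd
        xp = apply_input_transform(x, model.config)
        n, m = model.config.n, model.config.m
        e = rng.normal(0.0, sd, size=len(x)) if sd > 0 else np.zeros(len(x))
        y = np.zeros(len(x))
        for k in range(len(x)):
            acc = e[k]
            for j in range(min(m, k) + 1):
                acc += model.b[j] * xp[k - j]
            for i in range(1, min(n, k) + 1):
                acc -= model.a[i - 1] * y[k - i]
            y[k] = acc
        out[target] = y
    return KinematicSeries(
        out["axial_speed"], out["lateral_speed"], out["yaw_speed"],
        deflection.sample_rate_hz,
    )


def noise_feedthrough_gain(model: ARXModel, n_taps: int = 4000) -> float:
    """sqrt(sum h^2) of the impulse response of 1/A(z).

    Equation noise of sd sigma_e reaches the output with stationary sd
    sigma_e * this gain; used to set a target output-noise variance.
    """
    imp = np.zeros(n_taps)
    imp[0] = 1.0
    h = sps.lfilter([1.0], np.concatenate([[1.0], model.a]), imp)
    return float(np.sqrt(np.sum(h**2)))


def noise_sd_for_output_ratio(models: dict, library: BoutLibrary, ratio: float) -> dict:
    """Equation-noise sd per target so that the stationary output-noise
    variance equals ``ratio`` times the pooled clean-signal variance."""
    out = {}
    for target in TARGETS:
        pooled = np.concatenate(
            [e.kinematics.component(target) for e in library.entries]
        )
        gain = noise_feedthrough_gain(models[target])
        out[target] = math.sqrt(ratio * float(np.var(pooled))) / gain
    return out


# --------------------------------------------------------------- library


def make_library(
    n_bouts: int,
    category_mix: dict | None = None,
    models: dict | None = None,
    noise_sd=0.0,
    seed: int = 0,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
) -> BoutLibrary:
    """Synthetic bout library with paired ground-truth kinematics and paths.

    Categories are drawn from ``category_mix`` (uniform over the five
    categories by default, probabilities summing to 1); kinematics come
    from the ground-truth ARX triple driven by each bout's deflection;
    paths are integrated from the kinematics.  Fully reproducible given
    the seed.
    """
    if n_bouts < 1:
        raise ValueError("n_bouts must be >= 1")
    if category_mix is None:
        category_mix = {c: 1.0 / len(CATEGORIES) for c in CATEGORIES}
    probs = np.array([category_mix.get(c, 0.0) for c in CATEGORIES])
    if not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("category_mix must sum to 1")
    if models is None:
        models = default_true_models(sample_rate_hz)

    rng = np.random.default_rng(seed)
    cats = rng.choice(len(CATEGORIES), size=n_bouts, p=probs)
    entries = []
    for ci in cats:
        category = CATEGORIES[ci]
        template = template_for(category, rng)
        defl = simulate_deflection(template, sample_rate_hz)
        kin = simulate_arx(models, defl, noise_sd, seed=int(rng.integers(0, 2**31 - 1)))
        path = integrate(kin, Pose2D(0.0, 0.0, 0.0))
        entries.append(BoutEntry(defl, kin, path, category))
    return BoutLibrary(entries, sample_rate_hz, ground_truth_models=models)
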