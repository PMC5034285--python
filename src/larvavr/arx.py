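"""ARX identification linking tail deflection to the three kinematic speeds.

The autoregressive model with external input predicts a kinematic
parameter y(k) (axial, lateral or yaw speed) from its own past and the
current/past tail deflection x(k):

    y(k) = -sum_{i=1..N} a_i y(k-i) + sum_{j=0..M} b_j x'(k-j) + e(k)

with a_0 fixed to 1 (causality) and x' the configured input transform
(identity, or |x| for the axial model).  The coefficient vector
Theta = (a_1..a_N, b_0..b_M) is identified by ordinary least squares on a
design matrix built from data observed from rest (all lags before the
series start are zero).  Evaluation uses free-run simulation: the model
is driven by the deflection alone, never by observed outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .config import ARXConfig, SIGN_CONVENTION, default_arx_configs, logger

TARGETS = ("axial_speed", "lateral_speed", "yaw_speed")


@dataclass
class KinematicSeries:
    """Per-frame body-frame speeds: axial (mm/s, forward +), lateral
    (mm/s, body-left +), yaw (rad/s, CCW +)."""

    axial_speed: np.ndarray
    lateral_speed: np.ndarray
    yaw_speed: np.ndarray
    sample_rate_hz: float

    def __post_init__(self):
        self.axial_speed = np.asarray(self.axial_speed, dtype=float)
        self.lateral_speed = np.asarray(self.lateral_speed, dtype=float)
        self.yaw_speed = np.asarray(self.yaw_speed, dtype=float)
        n = len(self.axial_speed)
        if len(self.lateral_speed) != n or len(self.yaw_speed) != n:
            raise ValueError("kinematic components must have equal length")
        for arr in (self.axial_speed, self.lateral_speed, self.yaw_speed):
            if not np.all(np.isfinite(arr)):
                raise ValueError("kinematics must be finite")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.axial_speed)

    def component(self, target: str) -> np.ndarray:
        if target not in TARGETS:
            raise KeyError(f"unknown target {target!r}; expected one of {TARGETS}")
        return getattr(self, target)

    def as_array(self) -> np.ndarray:
        """(3, T) array ordered axial, lateral, yaw."""
        return np.stack([self.axial_speed, self.lateral_speed, self.yaw_speed])

    @classmethod
    def from_array(cls, arr, sample_rate_hz: float) -> "KinematicSeries":
        arr = np.asarray(arr, dtype=float)
        return cls(arr[0], arr[1], arr[2], sample_rate_hz)


@dataclass
class ARXModel:
    """Identified coefficients for one kinematic target."""

    config: ARXConfig
    a: np.ndarray  # a_1..a_N (a_0 = 1 implicit)
    b: np.ndarray  # b_0..b_M
    target_name: str = "axial_speed"
    sign_convention: str = SIGN_CONVENTION

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if len(self.a) != self.config.n:
            raise ValueError(f"len(a)={len(self.a)} != N={self.config.n}")
        if len(self.b) != self.config.m + 1:
            raise ValueError(f"len(b)={len(self.b)} != M+1={self.config.m + 1}")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))):
            raise ValueError("coefficients must be finite")

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([self.a, self.b])

    def to_json(self, path=None) -> str:
        doc = {
            "target": self.target_name,
            "N": self.config.n,
            "M": self.config.m,
            "input_transform": self.config.input_transform,
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "sample_rate_hz": self.config.sample_rate_hz,
            "sign_convention": self.sign_convention,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ARXModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        cfg = ARXConfig(doc["N"], doc["M"], doc["input_transform"], doc["sample_rate_hz"])
        return cls(cfg, np.array(doc["a"]), np.array(doc["b"]),
                   doc["target"], doc.get("sign_convention", SIGN_CONVENTION))


def apply_input_transform(x, config: ARXConfig) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.abs(x) if config.input_transform == "absolute_value" else x


def _lagged(v: np.ndarray, lag: int) -> np.ndarray:
    """v shifted right by `lag`, zero-filled (rest pre-history)."""
    if lag == 0:
        return v
    out = np.zeros_like(v)
    out[lag:] = v[:-lag]
    return out


def build_design_matrix(y, x, config: ARXConfig):
    """Regression system (Phi, y) for the ARX least-squares problem.

    Row k regresses y(k) on [-y(k-1)..-y(k-N), x'(k), x'(k-1)..x'(k-M)];
    lags reaching before the series start are zero (system at rest).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) != len(x):
        raise ValueError("y and x must have equal length")
    if len(y) <= config.n + config.m:
        raise ValueError(
            f"series length {len(y)} must exceed N+M={config.n + config.m}"
        )
    xp = apply_input_transform(x, config)
    cols = [-_lagged(y, i) for i in range(1, config.n + 1)]
    cols += [_lagged(xp, j) for j in range(config.m + 1)]
    return np.column_stack(cols), y.copy()


def fit(y, x, config: ARXConfig, target_name: str = "axial_speed") -> ARXModel:
    """Least-squares ARX fit of one bout (see :func:`fit_bouts` to pool)."""
    return fit_bouts([(y, x)], config, target_name)


def fit_bouts(pairs, config: ARXConfig, target_name: str = "axial_speed") -> ARXModel:
    """Pooled least-squares fit over (y, x) bout pairs.

    Each bout contributes its own rest-initialized design matrix block, so
    lags never leak across bout boundaries.  Rank-deficient systems return
    the minimum-norm solution.
    """
    blocks = [build_design_matrix(y, x, config) for y, x in pairs]
    phi = np.vstack([b[0] for b in blocks])
    target = np.concatenate([b[1] for b in blocks])
    if not np.any(phi) and not np.any(target):
        logger.warning("fit: all-zero system; returning degenerate zero model")
    theta, *_ = np.linalg.lstsq(phi, target, rcond=None)
    return ARXModel(config, theta[: config.n], theta[config.n:], target_name)


OVERFLOW_GUARD = 1e12


def predict(model: ARXModel, x, y_history=None) -> np.ndarray:
    """Free-run simulation of the ARX recurrence driven by the input alone.

    Initialized at rest (zero history) unless ``y_history`` (most recent
    last) is given.  Raises on divergence past the overflow guard.
    """
    xp = apply_input_transform(x, model.config)
    a_full = np.concatenate([[1.0], model.a])
    if y_history is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            y = sps.lfilter(model.b, a_full, xp)
    else:
        y = _predict_with_history(model, xp, np.asarray(y_history, dtype=float))
    bad = ~np.isfinite(y) | (np.abs(y) > OVERFLOW_GUARD)
    if bad.any():
        k = int(np.argmax(bad))
        raise FloatingPointError(f"ARX recurrence diverged at frame {k}")
    return y


def _predict_with_history(model: ARXModel, xp, hist) -> np.ndarray:
    n, m = model.config.n, model.config.m
    ybuf = np.zeros(n)
    ybuf[: min(n, len(hist))] = hist[::-1][: n]  # ybuf[0] = y(k-1)
    xbuf = np.zeros(m + 1)
    out = np.empty(len(xp))
    for k in range(len(xp)):
        xbuf[1:] = xbuf[:-1]
        xbuf[0] = xp[k]
        yk = -float(model.a @ ybuf) + float(model.b @ xbuf)
        out[k] = yk
        if n:
            ybuf[1:] = ybuf[:-1]
            ybuf[0] = yk
    return out


def one_step_predict(model: ARXModel, y, x) -> np.ndarray:
    """One-step-ahead (teacher-forced) prediction from observed outputs."""
    phi, _ = build_design_matrix(y, x, model.config)
    return phi @ model.theta


def goodness_of_fit(y_true, y_pred) -> float:
    """Coefficient of determination R^2 = 1 - SS_res/SS_tot (may be < 0)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) != len(y_pred) or len(y_true) < 2:
        raise ValueError("need equal-length series of length >= 2")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("zero variance in y_true")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def _library_pairs(library, target: str):
    """[(y, x), ...] for one kinematic target across library bouts."""
    return [
        (entry.kinematics.component(target), entry.deflection.values)
        for entry in library.entries
    ]


def _pooled_free_run_r2(models: dict, library, indices) -> dict:
    out = {}
    for target in TARGETS:
        model = models[target]
        trues, preds = [], []
        for i in indices:
            entry = library.entries[i]
            trues.append(entry.kinematics.component(target))
            preds.append(predict(model, entry.deflection.values))
        out[target] = goodness_of_fit(np.concatenate(trues), np.concatenate(preds))
    return out


def fit_library(library, configs: dict | None = None) -> dict:
    """Fit all three kinematic targets on every bout of a library."""
    configs = configs or default_arx_configs(library.sample_rate_hz)
    models = {}
    for target in TARGETS:
        pairs = _library_pairs(library, target)
        models[target] = fit_bouts(pairs, configs[target], target)
    return models


def bootstrap_evaluate(
    library,
    configs: dict | None = None,
    n_iter: int = 100,
    train_frac: float = 0.8,
    seed: int = 0,
) -> dict:
    """Bout-level train/test bootstrap of free-run prediction quality.

    Each iteration splits the library at the bout level (train_frac of
    bouts to train, rest to test), fits each target on the pooled training
    bouts and free-runs each test bout from rest; frames of all test bouts
    are pooled into one R^2.  Returns per-target mean, sd and the raw
    per-iteration values.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if len(library.entries) < 5:
        raise ValueError("library must contain at least 5 bouts")
    configs = configs or default_arx_configs(library.sample_rate_hz)
    rng = np.random.default_rng(seed)
    n = len(library.entries)
    n_train = max(1, int(round(train_frac * n)))
    n_train = min(n_train, n - 1)
    scores = {t: [] for t in TARGETS}
    for _ in range(n_iter):
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        models = {
            t: fit_bouts(
                [(library.entries[i].kinematics.component(t),
                  library.entries[i].deflection.values) for i in train_idx],
                configs[t], t)
            for t in TARGETS
        }
        r2 = _pooled_free_run_r2(models, library, test_idx)
        for t in TARGETS:
            scores[t].append(r2[t])
    return {
        t: {
            "mean": float(np.mean(scores[t])),
            "sd": float(np.std(scores[t], ddof=1)) if n_iter > 1 else 0.0,
            "values": np.asarray(scores[t]),
        }
        for t in TARGETS
    }


def cross_amplitude_evaluate(library, configs: dict | None = None) -> dict:
    """Small/large-bout generalization table.

    Bouts are median-split on their maximum absolute deflection (stable
    sort; ties go to "small"); each half is fitted and evaluated free-run
    on the other, for all three targets.
    """
    if len(library.entries) < 4:
        raise ValueError("library must contain at least 4 bouts")
    configs = configs or default_arx_configs(library.sample_rate_hz)
    amp = np.array([e.max_abs_deflection for e in library.entries])
    order = np.argsort(amp, kind="stable")
    half = len(order) // 2
    small, large = order[:half + len(order) % 2], order[half + len(order) % 2:]
    out = {}
    for train_name, train_idx, test_idx in (
        ("train_small_test_large", small, large),
        ("train_large_test_small", large, small),
    ):
        models = {
            t: fit_bouts(
                [(library.entries[i].kinematics.component(t),
                  library.entries[i].deflection.values) for i in train_idx],
                configs[t], t)
            for t in TARGETS
        }
        out[train_name] = _pooled_free_run_r2(models, library, test_idx)
    return out
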