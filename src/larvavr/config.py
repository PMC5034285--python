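"""Run-level configuration, logging and reproducibility helpers.

All defaults mirror the experimental conditions the pipeline was designed
for: 200 Hz tail imaging, an OMR grating drifting at 10 mm/s with a 10 mm
spatial period (gain 3 on axial speed, 6 s stimulation / 20 s rest, 120
trials) and a virtual prey of 0.05 mm radius appearing 1.5 mm away,
sweeping at 20 deg/s, captured at 0.4 mm and lost beyond +/-90 deg.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path as FilePath

import yaml

logger = logging.getLogger("larvavr")
if not logger.handlers:
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

#: canonical order of the five swim-bout categories (also the tie-break order)
CATEGORIES = ("scoot", "asymmetric_scoot", "routine_turn", "c_bend", "burst")

DEFAULT_SAMPLE_RATE_HZ = 200.0

#: documented sign convention of the ARX recurrence, stored with every model
SIGN_CONVENTION = "y(k) = -sum_i a_i*y(k-i) + sum_j b_j*x'(k-j)"


@dataclass(frozen=True)
class ARXConfig:
    """Structure of one autoregressive-with-external-input model.

    ``n`` lagged outputs and ``m+1`` input taps (current sample plus ``m``
    lags).  ``input_transform`` is ``"identity"`` or ``"absolute_value"``;
    the axial-speed model uses the absolute deflection because forward
    thrust does not depend on the side of the tail beat.
    """

    n: int
    m: int
    input_transform: str = "identity"
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"output memory n must be >= 1, got {self.n}")
        if self.m < 0:
            raise ValueError(f"input memory m must be >= 0, got {self.m}")
        if self.input_transform not in ("identity", "absolute_value"):
            raise ValueError(
                f"unknown input_transform {self.input_transform!r}; "
                "expected 'identity' or 'absolute_value'"
            )


def default_arx_configs(sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ) -> dict:
    """Per-target model structures: axial uses |x| with a 100 ms output
    memory (N=20 at 200 Hz); lateral and yaw use the signed deflection with
    35 ms memories (N=7, M=7)."""
    return {
        "axial_speed": ARXConfig(20, 7, "absolute_value", sample_rate_hz),
        "lateral_speed": ARXConfig(7, 7, "identity", sample_rate_hz),
        "yaw_speed": ARXConfig(7, 7, "identity", sample_rate_hz),
    }


@dataclass
class OMRConfig:
    grating_speed_mm_s: float = 10.0
    spatial_period_mm: float = 10.0
    gain: float = 3.0
    trial_s: float = 6.0
    inter_trial_s: float = 20.0
    n_trials: int = 120
    aligned_threshold_deg: float = 30.0
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ


@dataclass
class PreyConfig:
    prey_radius_mm: float = 0.05
    appear_distance_mm: float = 1.5
    sweep_speed_deg_s: float = 20.0
    capture_distance_mm: float = 0.4
    failure_azimuth_deg: float = 90.0
    n_trials: int = 166
    delayed_fraction: float = 1.0 / 3.0
    end_of_bout_speed_threshold_mm_s: float = 0.2
    max_trial_s: float = 20.0
    feedback_latency_s: float = 0.0  # measured loop lag is ~70 ms; off by default
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ


@dataclass
class RunConfig:
    """Top-level configuration serialized losslessly to/from YAML."""

    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    l0_mm: float = 4.0
    px_per_mm: float = 20.0
    binarize_threshold: float = 127.0
    bout_on_threshold: float = 0.1
    bout_off_threshold: float = 0.05
    min_quiet_ms: float = 50.0
    min_bout_ms: float = 50.0
    seed: int = 0
    omr: OMRConfig = field(default_factory=OMRConfig)
    prey: PreyConfig = field(default_factory=PreyConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "omr" in d and isinstance(d["omr"], dict):
            d["omr"] = OMRConfig(**d["omr"])
        if "prey" in d and isinstance(d["prey"], dict):
            d["prey"] = PreyConfig(**d["prey"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        FilePath(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(FilePath(path).read_text()))

    def hash(self) -> str:
        """Short content hash embedded in every output file header."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(config: "RunConfig | None", seed: int | None) -> str:
    """One-line ``# key=value`` comment recording what produced a file."""
    parts = ["# larvavr"]
    if config is not None:
        parts.append(f"config_sha={config.hash()}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return " ".join(parts)
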