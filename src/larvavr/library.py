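"""Bout library container and its on-disk dialects (HDF5, CSV+manifest).

A bout library pairs tail-deflection series with the measured (or
ground-truth synthetic) kinematic series and 2D paths of individual swim
bouts, labeled by movement category.  It is the training corpus for the
ARX identification and the prototype source for bout classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path as FilePath

import h5py
import numpy as np

from .arx import ARXModel, KinematicSeries
from .config import CATEGORIES
from .tracking import DeflectionSeries
from .trajectory import Path


@dataclass
class BoutEntry:
    deflection: DeflectionSeries
    kinematics: KinematicSeries
    path: Path
    category: str
    max_abs_deflection: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r}; valid: {CATEGORIES}"
            )
        if len(self.deflection) != len(self.kinematics):
            raise ValueError("deflection and kinematics must have equal length")
        if self.max_abs_deflection is None:
            self.max_abs_deflection = float(np.max(np.abs(self.deflection.values)))


@dataclass
class BoutLibrary:
    entries: list
    sample_rate_hz: float
    ground_truth_models: dict | None = None  # target -> ARXModel, if synthetic

    def __post_init__(self):
        for e in self.entries:
            if e.deflection.sample_rate_hz != self.sample_rate_hz:
                raise ValueError("all entries must share the library sample rate")

    def __len__(self) -> int:
        return len(self.entries)

    def category_counts(self) -> dict:
        counts = {c: 0 for c in CATEGORIES}
        for e in self.entries:
            counts[e.category] += 1
        return counts

    # -- HDF5 dialect -------------------------------------------------
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["sample_rate_hz"] = self.sample_rate_hz
            if self.ground_truth_models:
                f.attrs["ground_truth_models"] = json.dumps(
                    {t: m.to_json() for t, m in self.ground_truth_models.items()}
                )
            for i, e in enumerate(self.entries):
                g = f.create_group(f"bout_{i:04d}")
                g.create_dataset("deflection", data=e.deflection.values)
                g.create_dataset("kinematics", data=e.kinematics.as_array())
                g.create_dataset("path", data=e.path.array.T)  # 3 x (T+1)
                g.attrs["category"] = e.category
                g.attrs["max_abs_deflection"] = e.max_abs_deflection

    @classmethod
    def from_hdf5(cls, path) -> "BoutLibrary":
        entries = []
        with h5py.File(path, "r") as f:
            rate = float(f.attrs["sample_rate_hz"])
            gt = None
            if "ground_truth_models" in f.attrs:
                gt = {
                    t: ARXModel.from_json(s)
                    for t, s in json.loads(f.attrs["ground_truth_models"]).items()
                }
            for name in sorted(k for k in f.keys() if k.startswith("bout_")):
                g = f[name]
                entries.append(
                    BoutEntry(
                        DeflectionSeries(g["deflection"][...], rate),
                        KinematicSeries.from_array(g["kinematics"][...], rate),
                        Path(np.asarray(g["path"][...]).T, rate),
                        str(g.attrs["category"]),
                        float(g.attrs["max_abs_deflection"]),
                    )
                )
        return cls(entries, rate, gt)

    # -- CSV-directory dialect ----------------------------------------
    def to_csv_dir(self, directory) -> None:
        d = FilePath(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {
            "sample_rate_hz": self.sample_rate_hz,
            "n_bouts": len(self.entries),
            "bouts": [],
        }
        if self.ground_truth_models:
            manifest["ground_truth_models"] = {
                t: json.loads(m.to_json()) for t, m in self.ground_truth_models.items()
            }
        for i, e in enumerate(self.entries):
            stem = f"bout_{i:04d}"
            arr = np.column_stack(
                [e.deflection.values, e.kinematics.as_array().T]
            )
            np.savetxt(
                d / f"{stem}_series.csv", arr, delimiter=",",
                header="deflection,axial_speed,lateral_speed,yaw_speed",
                comments="", fmt="%.17g",
            )
            np.savetxt(
                d / f"{stem}_path.csv", e.path.array, delimiter=",",
                header="x_mm,y_mm,heading_rad", comments="", fmt="%.17g",
            )
            manifest["bouts"].append(
                {"stem": stem, "category": e.category,
                 "max_abs_deflection": e.max_abs_deflection}
            )
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def from_csv_dir(cls, directory) -> "BoutLibrary":
        d = FilePath(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        rate = float(manifest["sample_rate_hz"])
        gt = None
        if "ground_truth_models" in manifest:
            gt = {
                t: ARXModel.from_json(json.dumps(doc))
                for t, doc in manifest["ground_truth_models"].items()
            }
        entries = []
        for rec in manifest["bouts"]:
            series = np.loadtxt(d / f"{rec['stem']}_series.csv",
                                delimiter=",", skiprows=1, ndmin=2)
            patharr = np.loadtxt(d / f"{rec['stem']}_path.csv",
                                 delimiter=",", skiprows=1, ndmin=2)
            entries.append(
                BoutEntry(
                    DeflectionSeries(series[:, 0], rate),
                    KinematicSeries(series[:, 1], series[:, 2], series[:, 3], rate),
                    Path(patharr, rate),
                    rec["category"],
                    float(rec["max_abs_deflection"]),
                )
            )
        return cls(entries, rate, gt)

    def save(self, path) -> None:
        """Dispatch on extension: ``.h5``/``.hdf5`` file or CSV directory."""
        p = FilePath(path)
        if p.suffix in (".h5", ".hdf5"):
            self.to_hdf5(p)
        else:
            self.to_csv_dir(p)

    @classmethod
    def load(cls, path) -> "BoutLibrary":
        p = FilePath(path)
        if p.is_dir():
            return cls.from_csv_dir(p)
        return cls.from_hdf5(p)
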