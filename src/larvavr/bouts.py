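"""Swim-bout detection, DTW fuzzy-KNN classification and category statistics.

Locomotion is a sequence of discrete bouts separated by quiescence.
Bouts are detected by hysteresis thresholding of the smoothed absolute
deflection, classified into the five canonical categories (scoot,
asymmetric scoot, routine turn, C bend, burst) by fuzzy K-nearest
neighbours under a dynamic-time-warping distance, and category
proportions across conditions are compared with per-category chi-squared
tests under a Bonferroni correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

from .config import CATEGORIES, logger


@dataclass
class Bout:
    """A detected movement episode over half-open frames [start, end)."""

    start_frame: int
    end_frame: int
    deflection_segment: np.ndarray
    category: str | None = None
    memberships: np.ndarray | None = None

    def __post_init__(self):
        if self.end_frame <= self.start_frame:
            raise ValueError("end_frame must exceed start_frame")
        self.deflection_segment = np.asarray(self.deflection_segment, dtype=float)
        if self.memberships is not None:
            self.memberships = np.asarray(self.memberships, dtype=float)
            if abs(float(self.memberships.sum()) - 1.0) > 1e-9:
                raise ValueError("memberships must sum to 1")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class PrototypeSet:
    """Labeled deflection segments serving as KNN references."""

    labels: list
    series: list

    def __post_init__(self):
        if len(self.labels) != len(self.series):
            raise ValueError("labels and series must align")
        present = set(self.labels)
        missing = [c for c in CATEGORIES if c not in present]
        if missing:
            raise ValueError(f"missing prototypes for categories: {missing}")
        self.series = [np.asarray(s, dtype=float) for s in self.series]

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_library(cls, library, max_per_category: int | None = None):
        labels, series = [], []
        counts = {c: 0 for c in CATEGORIES}
        for e in library.entries:
            if max_per_category is not None and counts[e.category] >= max_per_category:
                continue
            labels.append(e.category)
            series.append(e.deflection.values)
            counts[e.category] += 1
        return cls(labels, series)


SMOOTH_MS = 15.0  # moving-average window for the bout-detection envelope


def detect_bouts(
    deflection,
    on_threshold: float = 0.1,
    off_threshold: float = 0.05,
    min_quiet_ms: float = 50.0,
    min_bout_ms: float = 50.0,
) -> list:
    """Hysteresis bout detection on the smoothed absolute deflection.

    Onset: the 15 ms moving average of |deflection| crosses
    ``on_threshold`` upward (the start is then backtracked to where the
    envelope last rose through ``off_threshold``, so slow attacks do not
    delay the boundary).  Offset: the envelope stays below
    ``off_threshold`` for ``min_quiet_ms``; the bout ends where the
    sub-threshold run begins.  Bouts shorter than ``min_bout_ms`` are
    discarded.  Returns ordered, non-overlapping bouts (empty list for a
    quiet series).
    """
    if on_threshold <= 0 or off_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if on_threshold < off_threshold:
        raise ValueError("need on_threshold >= off_threshold (hysteresis)")
    values = np.asarray(
        deflection.values if hasattr(deflection, "values") else deflection,
        dtype=float,
    )
    fs = getattr(deflection, "sample_rate_hz", None) or 200.0
    win = max(1, int(round(SMOOTH_MS / 1000.0 * fs)))
    kernel = np.ones(win) / win
    env = np.convolve(np.abs(values), kernel, mode="same")

    min_quiet = max(1, int(round(min_quiet_ms / 1000.0 * fs)))
    min_bout = max(1, int(round(min_bout_ms / 1000.0 * fs)))

    bouts = []
    n = len(values)
    k = 0
    while k < n:
        if env[k] >= on_threshold:
            start = k
            floor = bouts[-1].end_frame if bouts else 0
            while start > floor and env[start - 1] >= off_threshold:
                start -= 1
            # walk forward until a quiet run of min_quiet frames (or the end)
            end = None
            j = k + 1
            quiet_start = None
            while j < n:
                if env[j] < off_threshold:
                    if quiet_start is None:
                        quiet_start = j
                    if j - quiet_start + 1 >= min_quiet:
                        end = quiet_start
                        break
                else:
                    quiet_start = None
                j += 1
            if end is None:
                end = quiet_start if quiet_start is not None else n
            if end - start >= min_bout:
                bouts.append(Bout(start, end, values[start:end]))
            k = max(end, j) + 1
        else:
            k += 1
    return bouts


def dtw_distance(s1, s2) -> float:
    """Normalized dynamic-time-warping distance between two series.

    Classic symmetric step pattern with absolute-difference local cost:
    diagonal steps (and the initial cell) weigh their cost twice,
    horizontal/vertical steps once, and the accumulated cost is divided
    by n+m.  For equal-length series this never exceeds the no-warp mean
    absolute difference, and a single-cell comparison returns |s1-s2|.
    """
    s1 = np.asarray(s1, dtype=float).ravel()
    s2 = np.asarray(s2, dtype=float).ravel()
    n, m = len(s1), len(s2)
    if n == 0 or m == 0:
        raise ValueError("series must be non-empty")
    c = np.abs(s1[:, None] - s2[None, :])

    inf = np.inf
    prev2 = np.full(n, inf)
    prev = np.full(n, inf)
    for d in range(n + m - 1):
        lo, hi = max(0, d - m + 1), min(n - 1, d)
        i = np.arange(lo, hi + 1)
        j = d - i
        cd = c[i, j]
        cur = np.full(n, inf)
        if d == 0:
            cur[0] = 2.0 * cd[0]
        else:
            im1 = np.maximum(i - 1, 0)
            from_left = np.where(j >= 1, prev[i], inf) + cd
            from_up = np.where(i >= 1, prev[im1], inf) + cd
            from_diag = np.where((i >= 1) & (j >= 1), prev2[im1], inf) + 2.0 * cd
            cur[i] = np.minimum(np.minimum(from_left, from_up), from_diag)
        prev2, prev = prev, cur
    return float(prev[n - 1]) / (n + m)


def classify(
    bout: Bout,
    prototypes: PrototypeSet,
    k: int = 5,
    fuzzifier: float = 2.0,
    mirror_invariant: bool = True,
) -> tuple:
    """Fuzzy K-nearest-neighbour classification under the DTW distance.

    Memberships weight the k nearest prototypes by d^(-2/(m-1)) and pool
    them per category; the label is the argmax.  An exact match
    (distance 0) gives membership 1 to that prototype's category.  Ties
    in the argmax resolve in the canonical category order with a logged
    flag.  With ``mirror_invariant`` (default) the distance to each
    prototype is the smaller of the DTW distances of the segment and its
    left/right mirror, since the five categories are chirality-free (a
    left and a right routine turn are the same category).  Returns
    ``(label, memberships)`` (5-vector in canonical order) and stores
    both on the bout.
    """
    if k < 1 or k > len(prototypes):
        raise ValueError("need 1 <= k <= number of prototypes")
    if fuzzifier <= 1.0:
        raise ValueError("fuzzifier must exceed 1")
    seg = bout.deflection_segment
    if mirror_invariant:
        d = np.array(
            [min(dtw_distance(seg, s), dtw_distance(-seg, s))
             for s in prototypes.series]
        )
    else:
        d = np.array([dtw_distance(seg, s) for s in prototypes.series])
    order = np.lexsort((np.arange(len(d)), d))[:k]

    memberships = np.zeros(len(CATEGORIES))
    zero_hits = [idx for idx in order if d[idx] == 0.0]
    if zero_hits:
        memberships[CATEGORIES.index(prototypes.labels[zero_hits[0]])] = 1.0
    else:
        w = d[order] ** (-2.0 / (fuzzifier - 1.0))
        for idx, wj in zip(order, w):
            memberships[CATEGORIES.index(prototypes.labels[idx])] += wj
        memberships /= memberships.sum()

    best = float(memberships.max())
    winners = np.nonzero(memberships == best)[0]
    if len(winners) > 1:
        logger.warning(
            "classify: membership tie between %s; using canonical order",
            [CATEGORIES[i] for i in winners],
        )
    label = CATEGORIES[int(winners[0])]
    bout.category = label
    bout.memberships = memberships
    return label, memberships


@dataclass
class BoutStatistics:
    durations_ms: np.ndarray
    inter_bout_intervals_s: np.ndarray
    counts: dict
    duration_mean_ms: float
    duration_sd_ms: float
    duration_sem_ms: float


def bout_statistics(bouts, sample_rate_hz: float) -> BoutStatistics:
    """Durations (ms), inter-bout intervals (s) and per-category counts."""
    durations = np.array([b.n_frames / sample_rate_hz * 1000.0 for b in bouts])
    if len(bouts) >= 2:
        ibi = np.array(
            [
                (b2.start_frame - b1.end_frame) / sample_rate_hz
                for b1, b2 in zip(bouts, bouts[1:])
            ]
        )
    else:
        ibi = np.array([])
    counts = {c: 0 for c in CATEGORIES}
    for b in bouts:
        if b.category is not None:
            counts[b.category] += 1
    n = len(durations)
    mean = float(durations.mean()) if n else float("nan")
    sd = float(durations.std(ddof=1)) if n > 1 else float("nan")
    return BoutStatistics(
        durations_ms=durations,
        inter_bout_intervals_s=ibi,
        counts=counts,
        duration_mean_ms=mean,
        duration_sd_ms=sd,
        duration_sem_ms=sd / math.sqrt(n) if n > 1 else float("nan"),
    )


def compare_category_proportions(counts_a, counts_b, alpha: float = 0.05) -> dict:
    """Per-category 2x2 chi-squared tests of proportions with Bonferroni.

    For each category the 2x2 table is (category vs rest) x (condition A
    vs B), tested without continuity correction; significance requires
    p < alpha / 5.  A category absent from both conditions yields p = 1.
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if len(counts_a) != len(CATEGORIES) or len(counts_b) != len(CATEGORIES):
        raise ValueError(f"need {len(CATEGORIES)} counts per condition")
    ta, tb = counts_a.sum(), counts_b.sum()
    if ta <= 0 or tb <= 0:
        raise ValueError("each condition needs a positive total")
    n_tests = len(CATEGORIES)
    out = {}
    for idx, cat in enumerate(CATEGORIES):
        a, b = counts_a[idx], ta - counts_a[idx]
        c, d = counts_b[idx], tb - counts_b[idx]
        n = a + b + c + d
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        if denom == 0:
            chi2, p = 0.0, 1.0
        else:
            chi2 = n * (a * d - b * c) ** 2 / denom
            p = float(spstats.chi2.sf(chi2, df=1))
        out[cat] = {
            "chi2": float(chi2),
            "p": p,
            "significant_after_bonferroni": p < alpha / n_tests,
        }
    return out


def bout_table(bouts, sample_rate_hz: float):
    """Bout table as a DataFrame (CSV layout: frames, duration, category,
    five membership columns)."""
    import pandas as pd

    rows = []
    for b in bouts:
        u = b.memberships if b.memberships is not None else [float("nan")] * 5
        rows.append(
            {
                "start_frame": b.start_frame,
                "end_frame": b.end_frame,
                "duration_ms": b.n_frames / sample_rate_hz * 1000.0,
                "category": b.category or "",
                "u_scoot": u[0],
                "u_asym": u[1],
                "u_routine": u[2],
                "u_cbend": u[3],
                "u_burst": u[4],
            }
        )
    return pd.DataFrame(rows)
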