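"""Amplitude-interval classification of leukemic cells.

Each of the four classes — benign (hematogones), malignant-early,
malignant-pre and malignant-pro (the three B-ALL stages) — occupies a
disjoint closed band of maximum phase-current amplitude on the 0-255 scale,
with amplitude decreasing as the disease progresses. Classification is
interval membership, equivalently an ordered-threshold decision tree over
the same bounds. Gap values (the printed bands do not cover [0, 255]) are
`unclassified` under the strict policy, or snapped to the nearest band under
the forced-choice `nearest` policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import yaml

from .errors import ConfigError, FitError, ParameterError
from .imaging import CLASS_LABELS, UNCLASSIFIED

#: Published per-class amplitude bands (0-255 scale), highest to lowest.
DEFAULT_BANDS: Dict[str, Tuple[float, float]] = {
    "benign": (211.0, 227.0),
    "malignant-early": (178.0, 186.0),
    "malignant-pre": (152.0, 165.0),
    "malignant-pro": (80.0, 89.0),
}


@dataclass
class AmplitudeRecord:
    """Per-image maximum phase-current amplitude with an optional true label."""

    image_id: str
    a_max: float
    true_label: Optional[str] = None

    def __post_init__(self):
        if self.a_max < 0:
            raise ParameterError("a_max must be >= 0")
        if self.true_label is not None and self.true_label not in CLASS_LABELS:
            raise ParameterError(f"unknown label {self.true_label!r}")


@dataclass
class ClassIntervals:
    """Disjoint closed amplitude interval per class label."""

    intervals: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS))

    def __post_init__(self):
        for label, (lo, hi) in self.intervals.items():
            if label not in CLASS_LABELS:
                raise ConfigError(f"unknown class label {label!r}")
            if lo > hi:
                raise ConfigError(f"interval for {label} has lo > hi: [{lo}, {hi}]")
        labels = list(self.intervals)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                lo_a, hi_a = self.intervals[a]
                lo_b, hi_b = self.intervals[b]
                if lo_a <= hi_b and lo_b <= hi_a:
                    raise ConfigError(f"intervals overlap: {a} and {b}")

    def to_yaml(self, path) -> None:
        data = {k: [float(lo), float(hi)] for k, (lo, hi) in self.intervals.items()}
        with open(path, "w") as fh:
            yaml.safe_dump({"intervals": data}, fh)

    @classmethod
    def from_yaml(cls, path) -> "ClassIntervals":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(intervals={k: (float(v[0]), float(v[1]))
                              for k, v in data["intervals"].items()})


@dataclass
class ClassStats:
    """Tukey box-plot statistics of per-image amplitudes, per class."""

    stats: Dict[str, Dict[str, float]]


def default_intervals() -> ClassIntervals:
    """The published per-class amplitude bands."""
    return ClassIntervals()


def classify_amplitude(a: float, intervals: Optional[ClassIntervals] = None,
                       policy: str = "strict") -> str:
    """Map an amplitude to a class label by closed-interval membership.

    strict: `unclassified` when no band contains a. nearest: the class whose
    band is closest (ties resolved to the higher-amplitude class).
    """
    if a < 0:
        raise ParameterError("amplitude must be >= 0")
    intervals = intervals or default_intervals()
    for label, (lo, hi) in intervals.intervals.items():
        if lo <= a <= hi:
            return label
    if policy == "strict":
        return UNCLASSIFIED
    if policy == "nearest":
        best_label, best_dist, best_lo = None, np.inf, -np.inf
        for label, (lo, hi) in intervals.intervals.items():
            dist = max(lo - a, a - hi, 0.0)
            if dist < best_dist or (dist == best_dist and lo > best_lo):
                best_label, best_dist, best_lo = label, dist, lo
        return best_label
    raise ParameterError(f"unknown policy {policy!r}")


def decision_tree_classify(a: float, intervals: Optional[ClassIntervals] = None) -> str:
    """Hierarchical threshold cascade over the interval bounds.

    Bands are tested from the highest downwards with nested comparisons —
    semantically identical to strict interval membership.
    """
    if a < 0:
        raise ParameterError("amplitude must be >= 0")
    intervals = intervals or default_intervals()
    ordered = sorted(intervals.intervals.items(), key=lambda kv: -kv[1][0])
    for label, (lo, hi) in ordered:
        if a >= lo:
            return label if a <= hi else UNCLASSIFIED
    return UNCLASSIFIED


def class_mean(records: Iterable[AmplitudeRecord], label: str) -> float:
    """Arithmetic mean of a_max over the records carrying the given label."""
    vals = [r.a_max for r in records if r.true_label == label]
    if not vals:
        raise ParameterError(f"no records labelled {label!r}")
    return float(np.mean(vals))


def fit_intervals(records: Iterable[AmplitudeRecord], method: str = "minmax",
                  q: float = 0.0) -> ClassIntervals:
    """Fit per-class amplitude bands from labelled records.

    minmax: [min, max] per class. quantile: the [q, 1-q] empirical quantiles.
    Overlapping fitted bands raise :class:`FitError` naming the class pair.
    """
    if method not in ("minmax", "quantile"):
        raise ParameterError(f"unknown fit method {method!r}")
    if not (0.0 <= q < 0.5):
        raise ParameterError("q must lie in [0, 0.5)")
    groups: Dict[str, List[float]] = {}
    for r in records:
        if r.true_label is None:
            continue
        groups.setdefault(r.true_label, []).append(r.a_max)
    for label, vals in groups.items():
        if len(vals) < 2:
            raise ParameterError(f"class {label!r} needs at least 2 records")
    bands = {}
    for label, vals in groups.items():
        arr = np.asarray(vals)
        if method == "minmax" or q == 0.0:
            bands[label] = (float(arr.min()), float(arr.max()))
        else:
            bands[label] = (float(np.quantile(arr, q)), float(np.quantile(arr, 1.0 - q)))
    labels = list(bands)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            lo_a, hi_a = bands[a]
            lo_b, hi_b = bands[b]
            if lo_a <= hi_b and lo_b <= hi_a:
                raise FitError(f"fitted intervals overlap for classes {a!r} and {b!r}")
    return ClassIntervals(intervals=bands)


def boxplot_stats(records: Iterable[AmplitudeRecord]) -> ClassStats:
    """Per-class Tukey five-number summary of a_max values.

    Quartiles use linear interpolation; whiskers reach the most extreme data
    points within 1.5 IQR of the quartiles.
    """
    groups: Dict[str, List[float]] = {}
    for r in records:
        if r.true_label is not None:
            groups.setdefault(r.true_label, []).append(r.a_max)
    if not groups:
        raise ParameterError("no labelled records")
    out = {}
    for label, vals in groups.items():
        arr = np.sort(np.asarray(vals))
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inliers = arr[(arr >= lo_fence) & (arr <= hi_fence)]
        out[label] = {
            "mean": float(arr.mean()), "median": float(med),
            "q1": float(q1), "q3": float(q3),
            "whisker_low": float(inliers.min()), "whisker_high": float(inliers.max()),
            "n": int(arr.size),
        }
    return ClassStats(stats=out)
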