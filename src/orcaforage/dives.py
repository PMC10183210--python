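"""Dive detection, phase partitioning, and per-phase kinematic features.

Dives are depth excursions deeper than 1 m bounded by surfacings shallower
than 0.5 m.  Each dive is split into descent, bottom (the contiguous span of
samples at >= 70% of the maximum dive depth) and ascent phases, and each
phase is summarized by the three kinematic variables known to discriminate
prey-capture maneuvers in resident killer whales:

* jerk peak -- the maximum of the jerk magnitude (the norm of the first
  difference of triaxial acceleration times the sampling rate) within the
  phase, divided by the deployment-wide median jerk magnitude.  The ratio
  form makes the statistic scale-free across tags and sampling rates.
* roll at jerk peak -- |roll| in degrees at the moment of the jerk peak;
  rolling onto the side is characteristic of a capture lunge.
* circular variance of heading -- 1 minus the mean resultant length of the
  phase's heading samples; erratic pursuit raises it toward 1.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .records import SensorSeries

__all__ = [
    "PhaseFeatures",
    "DiveRecord",
    "detect_dives",
    "partition_phases",
    "jerk_magnitude",
    "deployment_median_jerk",
    "circular_variance",
    "phase_features",
]

PHASES = ("descent", "bottom", "ascent")


@dataclass(frozen=True)
class PhaseFeatures:
    jerk_peak: float  # max jerk / deployment-median jerk, dimensionless
    roll_at_jerk_peak: float  # degrees, in [0, 180]
    heading_circular_variance: float  # in [0, 1]

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.jerk_peak, self.roll_at_jerk_peak, self.heading_circular_variance)


@dataclass(frozen=True)
class DiveRecord:
    """One detected dive.  Times are seconds from deployment start.

    ``descent_end``/``ascent_start`` and ``features`` are filled by
    :func:`partition_phases` and :func:`phase_features`; position and
    bathymetry by the track module; ``labels`` by the acoustic and capture
    classifiers.
    """

    dive_id: int
    start_time: float
    end_time: float
    max_depth: float
    descent_end: Optional[float] = None
    ascent_start: Optional[float] = None
    features: Optional[dict] = None  # phase -> PhaseFeatures
    start_latitude: Optional[float] = None
    start_longitude: Optional[float] = None
    bathymetry: Optional[float] = None
    labels: frozenset = frozenset()

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time

    def with_labels(self, *labels: str) -> "DiveRecord":
        return dataclasses.replace(self, labels=self.labels | frozenset(labels))


def detect_dives(
    series: SensorSeries,
    min_depth: float = 1.0,
    surface_depth: float = 0.5,
    min_duration: float = 4.0,
    exclusion_window: float = 300.0,
) -> list[DiveRecord]:
    """Parse a depth trace into dives.

    A dive is a maximal run of samples at or below ``surface_depth`` whose
    depth exceeds ``min_depth``, extended outward by one sample on each side
    to the bounding surface samples (the 0.5-m crossings).  Dives shorter
    than ``min_duration`` seconds are discarded (incomplete surfacings and
    pressure-sensor flutter), as are dives starting within the first
    ``exclusion_window`` seconds (short-term behavioral response to tagging).
    """
    fs = series.sampling_rate
    depth = series.depth
    n = depth.size
    if n / fs < exclusion_window:
        warnings.warn("series shorter than the post-tagging exclusion window; no dives")
        return []
    submerged = depth >= surface_depth
    # run boundaries of the submerged mask
    padded = np.diff(np.concatenate([[0], submerged.view(np.int8), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1) - 1  # inclusive
    dives: list[DiveRecord] = []
    for i0, i1 in zip(starts, ends):
        seg_max = depth[i0 : i1 + 1].max()
        if seg_max <= min_depth:
            continue
        j0 = max(i0 - 1, 0)  # last surface sample before descent
        j1 = min(i1 + 1, n - 1)  # first surface sample after ascent
        start_t = j0 / fs
        duration = (j1 - j0) / fs
        if duration < min_duration:
            continue
        if start_t < exclusion_window:
            continue
        dives.append(
            DiveRecord(
                dive_id=len(dives),
                start_time=start_t,
                end_time=j1 / fs,
                max_depth=float(seg_max),
            )
        )
    return dives


def partition_phases(
    dive: DiveRecord, series: SensorSeries, bottom_fraction: float = 0.70
) -> DiveRecord:
    """Fill descent/bottom/ascent boundaries on a detected dive.

    The bottom phase is the contiguous span from the first to the last
    sample at >= ``bottom_fraction`` of the maximum dive depth, so every
    dive has exactly three contiguous phases (a V-shaped dive has a
    single-sample bottom; an instant descent yields a one-interval descent).
    """
    fs = series.sampling_rate
    i0 = int(round(dive.start_time * fs))
    i1 = int(round(dive.end_time * fs))
    seg = series.depth[i0 : i1 + 1]
    thr = bottom_fraction * seg.max()
    at_bottom = np.flatnonzero(seg >= thr)
    first, last = at_bottom[0], at_bottom[-1]
    return dataclasses.replace(
        dive, descent_end=(i0 + first) / fs, ascent_start=(i0 + last) / fs
    )


def jerk_magnitude(series: SensorSeries) -> np.ndarray:
    """Norm of the first difference of triaxial acceleration times the rate.

    Returns m/s^3, length ``n - 1``, timestamped at the leading sample.
    """
    if len(series) < 2:
        raise ValueError("need at least two samples to differentiate")
    return np.linalg.norm(np.diff(series.accel, axis=0), axis=1) * series.sampling_rate


def deployment_median_jerk(series: SensorSeries) -> float:
    """Median jerk magnitude over the entire deployment (surface included)."""
    return float(np.median(jerk_magnitude(series)))


def circular_variance(headings_deg) -> float:
    """1 - mean resultant length of the headings viewed as unit vectors."""
    h = np.asarray(headings_deg, dtype=float)
    if h.size == 0:
        raise ValueError("circular variance of an empty sample is undefined")
    rad = np.deg2rad(h)
    rbar = np.abs(np.exp(1j * rad).mean())
    return float(1.0 - rbar)


def _phase_bounds_idx(dive: DiveRecord, fs: float) -> dict:
    i0 = int(round(dive.start_time * fs))
    i1 = int(round(dive.end_time * fs))
    ib0 = int(round(dive.descent_end * fs))
    ib1 = int(round(dive.ascent_start * fs))
    return {"descent": (i0, ib0), "bottom": (ib0, ib1), "ascent": (ib1, i1)}


def phase_features(
    dive: DiveRecord, series: SensorSeries, median_jerk: float
) -> DiveRecord:
    """Compute the three per-phase kinematic features for one dive.

    ``median_jerk`` is the deployment-level median of the jerk magnitude and
    must be positive (a constant-acceleration record is degenerate).  Phase
    boundaries must already be set by :func:`partition_phases`.
    """
    if dive.descent_end is None or dive.ascent_start is None:
        raise ValueError("partition_phases must run before phase_features")
    if median_jerk <= 0:
        raise ValueError("deployment median jerk must be positive")
    fs = series.sampling_rate
    jerk = jerk_magnitude(series)
    feats = {}
    for phase, (a, b) in _phase_bounds_idx(dive, fs).items():
        # jerk sample k spans accel samples [k, k+1]; a phase [a, b] in
        # sample indices contributes jerk indices [a, b-1]
        jb = max(b - 1, a)
        jseg = jerk[a : jb + 1]
        if jseg.size == 0:  # zero-length phase at the series edge
            jseg = jerk[a : a + 1]
        k = int(np.argmax(jseg))
        feats[phase] = PhaseFeatures(
            jerk_peak=float(jseg[k] / median_jerk),
            roll_at_jerk_peak=float(abs(series.roll[a + k])),
            heading_circular_variance=circular_variance(series.heading[a : b + 1]),
        )
    return dataclasses.replace(dive, features=feats)


def analyze_dives(
    series: SensorSeries,
    bottom_fraction: float = 0.70,
    **detect_kwargs,
) -> list[DiveRecord]:
    """Convenience pipeline: detect, partition and featurize all dives."""
    dives = detect_dives(series, **detect_kwargs)
    if not dives:
        return []
    med = deployment_median_jerk(series)
    out = []
    for d in dives:
        d = partition_phases(d, series, bottom_fraction)
        out.append(phase_features(d, series, med))
    return out
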