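"""Per-deployment foraging metrics and cohort group summaries.

The per-deployment metrics are the analysis' quantitative surface:

* capture rate -- prey-capture dives per hour of deployment;
* foraging efficiency -- prey-capture dives per hour of acoustic search
  time (dives with slow clicks only); missing when the audio could not be
  analyzed, undefined when searching time is zero;
* proportions of deployment time in capture dives and in travel/rest dives;
* maximum depth and bathymetry of each capture dive.

Group summaries are unweighted means over deployments (never pooled counts
over pooled hours -- the two disagree whenever durations vary), with the
standard error sd/sqrt(n).  Deployments of unknown sex are excluded from
sex-based groupings, deployments without analyzable audio from efficiency
and time-budget summaries, and zero-searching deployments from efficiency
means (the ratio is undefined there).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .acoustics import searching_time, travel_rest_time
from .dives import DiveRecord
from .records import DeploymentRecord

__all__ = [
    "DeploymentMetrics",
    "GroupSummary",
    "compute_metrics",
    "metrics_from_table",
    "group_means",
    "percent_difference",
]


@dataclass
class DeploymentMetrics:
    deployment_id: str
    n_capture_dives: int
    capture_rate: float  # captures / h of deployment
    efficiency: Optional[float]  # captures / h searching; None if unavailable
    searching_h: Optional[float]
    prop_time_capture: Optional[float]
    prop_time_travel_rest: Optional[float]
    capture_max_depths: Optional[list] = None
    capture_bathymetries: Optional[list] = None


@dataclass
class GroupSummary:
    key: tuple
    n: int
    mean: float
    se: Optional[float]  # None for single-deployment groups
    median: float


def compute_metrics(
    record: DeploymentRecord,
    dives: Sequence[DiveRecord],
    summaries: dict,
) -> DeploymentMetrics:
    """Metrics from fully processed dives (labels + acoustic summaries)."""
    if record.duration_h <= 0:
        raise ValueError("zero-duration deployment")
    cap = [d for d in dives if "capture" in d.labels]
    search_h = searching_time(dives, summaries)
    travel_h = travel_rest_time(dives, summaries)
    total_h = record.duration_h
    n_cap = len(cap)
    eff = n_cap / search_h if search_h > 0 else None
    return DeploymentMetrics(
        deployment_id=record.deployment_id,
        n_capture_dives=n_cap,
        capture_rate=n_cap / total_h,
        efficiency=eff,
        searching_h=search_h,
        prop_time_capture=sum(d.duration for d in cap) / (total_h * 3600.0),
        prop_time_travel_rest=travel_h / total_h,
        capture_max_depths=[d.max_depth for d in cap],
        capture_bathymetries=[d.bathymetry for d in cap if d.bathymetry is not None],
    )


def metrics_from_table(records: Sequence[DeploymentRecord]) -> list[DeploymentMetrics]:
    """Metrics straight from tabulated counts and durations.

    The bridge that lets the packaged deployment table drive cohort-level
    results without sensor-level reprocessing.  Records lacking a capture
    count are skipped.
    """
    out = []
    for r in records:
        if r.n_capture_dives is None:
            import warnings

            warnings.warn(f"{r.deployment_id}: no capture count; skipped")
            continue
        if r.searching_h is None:
            eff = None
        elif r.searching_h == 0:
            eff = None  # undefined ratio; excluded from efficiency summaries
        else:
            eff = r.n_capture_dives / r.searching_h
        out.append(
            DeploymentMetrics(
                deployment_id=r.deployment_id,
                n_capture_dives=r.n_capture_dives,
                capture_rate=r.n_capture_dives / r.duration_h,
                efficiency=eff,
                searching_h=r.searching_h,
                prop_time_capture=None,
                prop_time_travel_rest=None,
            )
        )
    return out


_GROUPINGS = ("population_sex", "population", "calf_status", "mother_status")


def _group_key(r: DeploymentRecord, grouping: str) -> Optional[tuple]:
    if grouping == "population_sex":
        if r.sex == "U":
            return None
        return (r.population, r.sex)
    if grouping == "population":
        return (r.population,)
    if grouping == "calf_status":
        if r.sex != "F" or not r.adult or r.has_calf is None:
            return None
        return (r.population, "calf" if r.has_calf else "no_calf")
    if grouping == "mother_status":
        if r.sex != "M" or not r.adult or r.mother_alive is None:
            return None
        return (r.population, "mother_alive" if r.mother_alive else "mother_dead")
    raise ValueError(f"unknown grouping {grouping!r}; choose from {_GROUPINGS}")


def group_means(
    metrics: Sequence[DeploymentMetrics],
    records: Sequence[DeploymentRecord],
    grouping: str = "population_sex",
    metric: str = "capture_rate",
) -> list[GroupSummary]:
    """Unweighted group means of a per-deployment metric.

    ``metric`` names a DeploymentMetrics field; deployments whose value is
    None (missing audio, undefined efficiency) are dropped.  Empty groups
    are omitted with a warning.
    """
    by_id = {m.deployment_id: m for m in metrics}
    groups: dict = {}
    for r in records:
        key = _group_key(r, grouping)
        m = by_id.get(r.deployment_id)
        if key is None or m is None:
            continue
        value = getattr(m, metric)
        if value is None:
            continue
        groups.setdefault(key, []).append(value)
    out = []
    for key in sorted(groups):
        vals = np.asarray(groups[key], dtype=float)
        out.append(
            GroupSummary(
                key=key,
                n=vals.size,
                mean=float(vals.mean()),
                se=float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else None,
                median=float(np.median(vals)),
            )
        )
    return out


def percent_difference(a: float, b: float) -> float:
    """How much larger ``a`` is than ``b``, in percent: (a/b - 1) * 100."""
    if b == 0:
        raise ZeroDivisionError("percent difference undefined for a zero baseline")
    return (a / b - 1.0) * 100.0
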