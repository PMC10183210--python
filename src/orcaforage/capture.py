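"""Prey-capture classification by calibrated kinematic thresholds.

Dives whose acoustic record contains both a terminal buzz and prey-handling
sounds are treated as acoustically confirmed captures.  Per population,
minimum thresholds for the three kinematic features are set to the
componentwise minima of the confirmed dives' best-phase feature triples --
the unique maximal thresholds that keep sensitivity at exactly 1.0 on the
confirmed set -- and the false-positive rate is then measured on the
remaining (negative) dives.  Calibration statistics are computed only on
dives at least 50 m deep, where acoustic confirmation is reliable; the
fitted thresholds are nevertheless applied to every dive.

The measured FPR is a property of the data, not a tuning target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .dives import DiveRecord, PHASES

__all__ = [
    "ThresholdSet",
    "confirmed_captures",
    "best_phase_features",
    "calibrate_thresholds",
    "calibrate_from_dives",
    "classify_dive",
    "evaluate_classifier",
]

CALIBRATION_DEPTH_CUTOFF = 50.0  # m


@dataclass(frozen=True)
class ThresholdSet:
    population: str
    jerk_min: float
    roll_min: float
    headvar_min: float
    tpr: float
    fpr: float
    depth_cutoff: float
    n_confirmed: int
    n_negatives: int


def confirmed_captures(
    dives: Sequence[DiveRecord],
    summaries: dict,
    require_handling: bool = True,
) -> set[int]:
    """Dive ids acoustically confirmed as captures (buzz + handling).

    Buzzes alone also occur in unsuccessful pursuits; handling sounds mark
    actual consumption, so both are required by default.
    """
    out = set()
    for d in dives:
        s = summaries[d.dive_id]
        if s.has_buzz and (s.has_handling or not require_handling):
            out.add(d.dive_id)
    return out


def best_phase_features(dive: DiveRecord) -> tuple[float, float, float]:
    """Feature triple of the phase with the largest jerk peak.

    The jerk transient is the most specific capture signature, so the phase
    that attains it is taken as the phase in which the capture occurred.
    """
    if not dive.features:
        raise ValueError("phase features missing; run phase_features first")
    best = max(PHASES, key=lambda p: dive.features[p].jerk_peak)
    return dive.features[best].as_tuple()


def calibrate_thresholds(
    confirmed: Iterable[tuple[float, float, float]],
    negatives: Iterable[tuple[float, float, float]],
    population: str,
    depth_cutoff: float = CALIBRATION_DEPTH_CUTOFF,
) -> ThresholdSet:
    """Componentwise-minimum thresholds over confirmed feature triples.

    ``confirmed`` and ``negatives`` are (jerk_peak, roll, heading-variance)
    triples of dives at or deeper than ``depth_cutoff``.  Sensitivity on the
    confirmed set is 1.0 by construction; the FPR is the fraction of
    negative triples passing all three thresholds.
    """
    conf = np.atleast_2d(np.asarray(list(confirmed), dtype=float))
    if conf.size == 0:
        raise ValueError("cannot calibrate without confirmed capture dives")
    neg = np.asarray(list(negatives), dtype=float).reshape(-1, 3)
    jerk_min, roll_min, headvar_min = conf.min(axis=0)
    if neg.size:
        fp = np.all(neg >= [jerk_min, roll_min, headvar_min], axis=1)
        fpr = float(fp.mean())
    else:
        fpr = 0.0
    return ThresholdSet(
        population=population,
        jerk_min=float(jerk_min),
        roll_min=float(roll_min),
        headvar_min=float(headvar_min),
        tpr=1.0,
        fpr=fpr,
        depth_cutoff=depth_cutoff,
        n_confirmed=conf.shape[0],
        n_negatives=neg.shape[0],
    )


def calibrate_from_dives(
    dives: Sequence[DiveRecord],
    confirmed_ids: set[int],
    population: str,
    depth_cutoff: float = CALIBRATION_DEPTH_CUTOFF,
) -> ThresholdSet:
    """Calibrate on deep dives, measuring FPR with the full dive classifier."""
    deep = [d for d in dives if d.max_depth >= depth_cutoff]
    conf = [best_phase_features(d) for d in deep if d.dive_id in confirmed_ids]
    if not conf:
        raise ValueError("no acoustically confirmed capture dives at calibration depth")
    neg_dives = [d for d in deep if d.dive_id not in confirmed_ids]
    ts = calibrate_thresholds(conf, [], population, depth_cutoff)
    fp = sum(classify_dive(d, ts) for d in neg_dives)
    fpr = fp / len(neg_dives) if neg_dives else 0.0
    return ThresholdSet(
        population=population,
        jerk_min=ts.jerk_min,
        roll_min=ts.roll_min,
        headvar_min=ts.headvar_min,
        tpr=1.0,
        fpr=float(fpr),
        depth_cutoff=depth_cutoff,
        n_confirmed=len(conf),
        n_negatives=len(neg_dives),
    )


def classify_dive(dive: DiveRecord, thresholds: ThresholdSet) -> bool:
    """Capture if any phase meets all three thresholds (inclusive)."""
    if not dive.features:
        raise ValueError("phase features missing; run phase_features first")
    for p in PHASES:
        f = dive.features[p]
        if (
            f.jerk_peak >= thresholds.jerk_min
            and f.roll_at_jerk_peak >= thresholds.roll_min
            and f.heading_circular_variance >= thresholds.headvar_min
        ):
            return True
    return False


def evaluate_classifier(
    predicted: Sequence[bool], truth: Sequence[bool]
) -> dict[str, float]:
    """Confusion-matrix true- and false-positive rates."""
    pred = np.asarray(predicted, dtype=bool)
    tru = np.asarray(truth, dtype=bool)
    if pred.shape != tru.shape:
        raise ValueError("prediction and truth lengths differ")
    n_pos = int(tru.sum())
    if n_pos == 0:
        raise ValueError("TPR undefined: no positives in truth")
    n_neg = tru.size - n_pos
    tpr = float((pred & tru).sum() / n_pos)
    fpr = float((pred & ~tru).sum() / n_neg) if n_neg else 0.0
    return {"tpr": tpr, "fpr": fpr}
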