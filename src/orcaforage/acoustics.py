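"""Inter-click-interval classification and acoustic time budgets.

Echolocation clicks are classed by the interval since the preceding click
in the same train: slow (> 100 ms, searching), fast (11-100 ms inclusive,
pursuit) and buzz (< 11 ms, terminal approach).  The first click of a train
inherits the class of its successor; a train breaks whenever the gap
exceeds ``train_break`` seconds, so pauses between click bouts are never
mistaken for slow clicking.

Dive-level time budgets follow from mapping events into dive intervals:
searching time is the summed duration of dives containing slow clicks and
nothing else; travel/rest time is the summed duration of silent dives
shallower than 30 m that were not classified as prey captures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .dives import DiveRecord
from .records import SoundEvent

__all__ = [
    "ClickTrainSummary",
    "classify_clicks",
    "summarize_dive_acoustics",
    "searching_time",
    "travel_rest_time",
]

BUZZ_MAX_ICI = 0.011  # s; buzz strictly below
FAST_MAX_ICI = 0.100  # s; fast band inclusive on both edges
TRAIN_BREAK = 2.0  # s; longer gaps split click trains


@dataclass
class ClickTrainSummary:
    dive_id: Optional[int]  # None == surface period (outside every dive)
    has_slow: bool = False
    has_fast: bool = False
    has_buzz: bool = False
    has_handling: bool = False
    n_slow: int = 0
    n_fast: int = 0
    n_buzz: int = 0
    n_handling: int = 0

    @property
    def any_click(self) -> bool:
        return self.has_slow or self.has_fast or self.has_buzz

    @property
    def slow_only(self) -> bool:
        return self.has_slow and not (self.has_fast or self.has_buzz or self.has_handling)


_EPS = 1e-9  # absolute slop so band edges survive float arithmetic


def _ici_class(ici: float) -> str:
    if ici < BUZZ_MAX_ICI - _EPS:
        return "buzz"
    if ici <= FAST_MAX_ICI + _EPS:
        return "fast"
    return "slow"


def classify_clicks(
    click_times: Sequence[float], train_break: float = TRAIN_BREAK
) -> list[SoundEvent]:
    """Class each click by its preceding inter-click interval.

    Input times must be sorted ascending.  Within a train the first click
    inherits its successor's class; an isolated click (a one-click train)
    is classed slow, since its neighbors are further than any slow ICI.
    """
    t = np.asarray(click_times, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("click times must be sorted ascending")
    classes: list[Optional[str]] = [None] * t.size
    train_start = 0
    for i in range(1, t.size + 1):
        if i == t.size or t[i] - t[i - 1] > train_break:
            # close train [train_start, i)
            if i - train_start == 1:
                classes[train_start] = "slow"
            else:
                for j in range(train_start + 1, i):
                    classes[j] = _ici_class(t[j] - t[j - 1])
                classes[train_start] = classes[train_start + 1]
            train_start = i
    return [SoundEvent(float(ti), "click", c) for ti, c in zip(t, classes)]


def summarize_dive_acoustics(
    dives: Sequence[DiveRecord], events: Sequence[SoundEvent]
) -> dict:
    """Assign each event to the dive containing it; return per-dive summaries.

    Events falling outside every dive interval are collected under the key
    ``None`` (surface periods) and excluded from all dive-level budgets.
    """
    summaries: dict = {d.dive_id: ClickTrainSummary(d.dive_id) for d in dives}
    summaries[None] = ClickTrainSummary(None)
    starts = np.array([d.start_time for d in dives])
    ends = np.array([d.end_time for d in dives])
    ids = [d.dive_id for d in dives]
    for ev in events:
        key = None
        if starts.size:
            hit = np.flatnonzero((starts <= ev.time) & (ev.time <= ends))
            if hit.size:
                key = ids[int(hit[0])]
        s = summaries[key]
        if ev.kind == "handling":
            s.has_handling = True
            s.n_handling += 1
        elif ev.click_class == "slow":
            s.has_slow, s.n_slow = True, s.n_slow + 1
        elif ev.click_class == "fast":
            s.has_fast, s.n_fast = True, s.n_fast + 1
        elif ev.click_class == "buzz":
            s.has_buzz, s.n_buzz = True, s.n_buzz + 1
        else:
            raise ValueError("clicks must be classified before dive mapping")
    return summaries


def searching_time(dives: Sequence[DiveRecord], summaries: dict) -> float:
    """Hours summed over dives in which only slow clicks were detected."""
    total_s = sum(
        d.duration for d in dives if summaries[d.dive_id].slow_only
    )
    return total_s / 3600.0


def travel_rest_time(
    dives: Sequence[DiveRecord], summaries: dict, depth_cutoff: float = 30.0
) -> float:
    """Hours summed over silent dives shallower than ``depth_cutoff`` m.

    A travel/rest dive produced no click of any class and no handling
    sound, and was not classified as a prey capture.
    """
    total_s = 0.0
    for d in dives:
        s = summaries[d.dive_id]
        if (
            d.max_depth < depth_cutoff
            and not s.any_click
            and not s.has_handling
            and "capture" not in d.labels
        ):
            total_s += d.duration
    return total_s / 3600.0
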