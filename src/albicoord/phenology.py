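"""Breeding-stage windows: fixed incubation start, detected hatch, brooding end.

Wandering albatrosses on Possession Island are remarkably consistent
phenologically: laying begins around 16 December, eggs hatch from
mid-March after a ~78-day incubation, and brooding ends around 11 April.
Individual hatch dates are not observed directly, but hatching produces
a sudden drop in foraging trip duration (incubation trips average ~5.6
days against ~2.7 days during brooding), so the hatch date of each
pair-season is detected as a change point in its trip-duration series.
Where no convincing drop exists, the population average hatch date of
15 March is used as a fallback.

A season is labeled by the year of its December: season 2010 spans
Dec 2010 - Apr 2011.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["StageWindows", "detect_hatch", "assign_stages", "build_windows"]

#: Default change-point acceptance: the post-split mean trip duration must be
#: below this fraction of the pre-split mean for the drop to count as hatching.
DEFAULT_RATIO_THRESHOLD = 0.6
DEFAULT_MIN_TRIPS = 4


@dataclass(frozen=True)
class StageWindows:
    """Breeding-stage boundaries for one pair-season."""

    season: int
    incubation_start: pd.Timestamp
    hatch_date: pd.Timestamp
    brooding_end: pd.Timestamp
    hatch_source: str  # "detected" | "fallback"

    def __post_init__(self):
        if not (self.incubation_start < self.hatch_date <= self.brooding_end):
            raise ValueError(
                "stage windows must satisfy incubation_start < hatch_date "
                f"<= brooding_end, got {self.incubation_start}, "
                f"{self.hatch_date}, {self.brooding_end}"
            )
        if self.hatch_source not in ("detected", "fallback"):
            raise ValueError(f"invalid hatch_source {self.hatch_source!r}")


def incubation_start_of(season: int) -> pd.Timestamp:
    return pd.Timestamp(year=season, month=12, day=16)


def fallback_hatch_of(season: int) -> pd.Timestamp:
    return pd.Timestamp(year=season + 1, month=3, day=15)


def brooding_end_of(season: int) -> pd.Timestamp:
    return pd.Timestamp(year=season + 1, month=4, day=11)


def detect_hatch(
    trips: pd.DataFrame,
    search_start: pd.Timestamp | None = None,
    search_end: pd.Timestamp | None = None,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    min_trips: int = DEFAULT_MIN_TRIPS,
) -> pd.Timestamp | None:
    """Detect a pair-season's hatch date from a drop in trip duration.

    A single change point is placed on the log trip durations inside the
    search window (default 1 Feb - 11 Apr) by least squares: the split
    index minimizing the pooled within-segment sum of squares over all
    split positions.  The split is accepted only if the mean post-split
    trip duration is below ``ratio_threshold`` times the mean pre-split
    duration — a "sudden drop" rather than drift.  The hatch date is the
    start of the first post-split trip.

    Returns ``None`` (fallback advised) when there are fewer than
    ``min_trips`` trips in the window or no split passes the ratio test.
    """
    trips = trips.sort_values("start")
    if search_start is not None:
        trips = trips[trips["start"] >= search_start]
    if search_end is not None:
        trips = trips[trips["start"] <= search_end]
    d = trips["duration_h"].to_numpy(dtype=float)
    if len(d) < min_trips:
        return None
    if np.any(d <= 0):
        raise ValueError("trip durations must be positive")
    logd = np.log(d)
    best_k, best_sse = None, np.inf
    for k in range(1, len(d)):
        sse = np.var(logd[:k]) * k + np.var(logd[k:]) * (len(d) - k)
        if sse < best_sse:
            best_k, best_sse = k, sse
    if np.mean(d[best_k:]) < ratio_threshold * np.mean(d[:best_k]):
        return trips["start"].iloc[best_k]
    return None


def build_windows(
    trips: pd.DataFrame,
    season: int,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    min_trips: int = DEFAULT_MIN_TRIPS,
) -> StageWindows:
    """Stage windows for one pair-season, detecting hatch where possible."""
    start = incubation_start_of(season)
    end = brooding_end_of(season)
    hatch = detect_hatch(
        trips,
        search_start=pd.Timestamp(year=season + 1, month=2, day=1),
        search_end=end,
        ratio_threshold=ratio_threshold,
        min_trips=min_trips,
    )
    if hatch is None:
        return StageWindows(season, start, fallback_hatch_of(season), end, "fallback")
    return StageWindows(season, start, hatch, end, "detected")


def assign_stages(trips: pd.DataFrame, windows: StageWindows) -> pd.DataFrame:
    """Label each trip with the breeding stage containing its start.

    Membership is by trip *start* time: starts in
    ``[incubation_start, hatch_date)`` are incubation, in
    ``[hatch_date, brooding_end]`` brooding, anything else unassigned
    (excluded downstream).
    """
    trips = trips.copy()
    start = trips["start"]
    stage = np.where(
        (start >= windows.incubation_start) & (start < windows.hatch_date),
        "incubation",
        np.where(
            (start >= windows.hatch_date) & (start <= windows.brooding_end),
            "brooding",
            "unassigned",
        ),
    )
    trips["stage"] = stage
    return trips


def hatch_source_tally(windows: list[StageWindows]) -> dict:
    """Counts of detected vs fallback hatch dates across pair-seasons."""
    tally = {"detected": 0, "fallback": 0}
    for w in windows:
        tally[w.hatch_source] += 1
    return tally
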