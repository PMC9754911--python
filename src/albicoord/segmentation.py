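"""Immersion-logger segmentation: bouts, foraging trips, nest shifts.

Leg-mounted saltwater immersion loggers record whether the sensor is in
seawater ("wet": the bird is sitting on the water) or in air ("dry": the
bird is flying or on land).  Two logger dialects exist:

* a *binned* dialect recording wet seconds per 10-minute bin, classified
  wet when strictly more than 45 s of the bin were wet, and
* a *state-change* dialect recording the timestamp of every wet/dry
  transition.

Because the maximum continuous flight time of a wandering albatross is
about 12 h, any dry spell strictly longer than ``max_flight_h`` (default
12 h) means the bird was on land (a nest shift).  A foraging trip runs
from the first wet bout after a shift to the start of the next shift.
Since bouts strictly alternate in state, the first bout after a shift is
always wet, so shifts and trips tile the record between the first and
last shift.

All timestamps are handled as timezone-naive UTC; bins are half-open
``[start, start + width)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BOUT_COLUMNS",
    "TRIP_COLUMNS",
    "SHIFT_COLUMNS",
    "AccuracySummary",
    "OverlapSummary",
    "parse_binned",
    "parse_state_change",
    "extract_trips_and_shifts",
    "infer_partner_trips",
    "inference_accuracy",
    "nest_overlap",
]

BOUT_COLUMNS = ["bird_id", "state", "start", "end", "duration_h"]
TRIP_COLUMNS = [
    "bird_id",
    "pair_id",
    "season",
    "index",
    "start",
    "end",
    "duration_h",
    "source",
    "stage",
]
SHIFT_COLUMNS = ["bird_id", "start", "end", "duration_h"]

_HOUR = pd.Timedelta(hours=1)


def _empty_bouts() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bird_id": pd.Series(dtype=object),
            "state": pd.Series(dtype=object),
            "start": pd.Series(dtype="datetime64[ns]"),
            "end": pd.Series(dtype="datetime64[ns]"),
            "duration_h": pd.Series(dtype=float),
        }
    )


def _runs_to_bouts(bird_id, states, starts, ends) -> pd.DataFrame:
    """Merge a labeled sequence of contiguous intervals into maximal bouts."""
    states = np.asarray(states)
    if len(states) == 0:
        return _empty_bouts()
    change = np.flatnonzero(states[1:] != states[:-1]) + 1
    first = np.concatenate(([0], change))
    last = np.concatenate((change - 1, [len(states) - 1]))
    start = np.asarray(starts)[first]
    end = np.asarray(ends)[last]
    out = pd.DataFrame(
        {
            "bird_id": bird_id,
            "state": states[first],
            "start": start,
            "end": end,
        }
    )
    out["duration_h"] = (out["end"] - out["start"]) / _HOUR
    return out


def parse_binned(
    stream: pd.DataFrame,
    wet_threshold_s: float = 45.0,
    bin_width_min: int = 10,
) -> pd.DataFrame:
    """Parse a binned-dialect stream into alternating wet/dry bouts.

    Parameters
    ----------
    stream
        Columns ``bird_id``, ``bin_start`` (datetime), ``wet_seconds``.
        Bins of one bird must be contiguous and non-overlapping.
    wet_threshold_s
        A bin is wet iff its wet seconds strictly exceed this (">45 s
        wet in 10 min").
    bin_width_min
        Bin width in minutes.

    Returns
    -------
    DataFrame with :data:`BOUT_COLUMNS`, one bird after another,
    strictly alternating in state within each bird.
    """
    stream = stream.rename(columns={"bin_start_iso8601_utc": "bin_start"})
    required = {"bird_id", "bin_start", "wet_seconds"}
    missing = required - set(stream.columns)
    if missing:
        raise ValueError(f"binned stream missing columns: {sorted(missing)}")
    if len(stream) == 0:
        return _empty_bouts()
    width = pd.Timedelta(minutes=bin_width_min)
    width_s = bin_width_min * 60.0
    pieces = []
    for bird, grp in stream.groupby("bird_id", sort=False):
        grp = grp.sort_values("bin_start")
        starts = pd.to_datetime(grp["bin_start"]).to_numpy()
        wet_s = grp["wet_seconds"].to_numpy(dtype=float)
        if np.any((wet_s < 0) | (wet_s > width_s)):
            bad = starts[np.argmax((wet_s < 0) | (wet_s > width_s))]
            raise ValueError(
                f"{bird}: wet_seconds outside [0, {width_s:g}] at bin {bad}"
            )
        if len(starts) > 1:
            gaps = np.diff(starts)
            bad = gaps != width.to_timedelta64()
            if np.any(bad):
                i = int(np.argmax(bad))
                what = "duplicate bin" if gaps[i] == np.timedelta64(0) else "gap"
                raise ValueError(f"{bird}: {what} at bin {starts[i + 1]}")
        states = np.where(wet_s > wet_threshold_s, "wet", "dry")
        pieces.append(_runs_to_bouts(bird, states, starts, starts + width.to_timedelta64()))
    return pd.concat(pieces, ignore_index=True)


def parse_state_change(
    stream: pd.DataFrame,
    start: pd.Timestamp | None = None,
    end: pd.Timestamp | None = None,
) -> pd.DataFrame:
    """Parse a state-change-dialect stream into bouts.

    ``stream`` has columns ``bird_id``, ``timestamp`` (strictly
    increasing per bird), ``new_state`` in {"wet", "dry"}.  A bout spans
    successive transitions.  Consecutive rows with identical state (a
    logger glitch, or the end-of-record marker the synthetic renderer
    emits) are merged with a warning.

    ``start``/``end`` optionally clip the record to the deployment
    window: a leading bout (opposite state of the first transition) is
    added from ``start``, and the final open bout is closed at ``end``.
    Without ``end``, the last row only marks the end of the record.
    """
    stream = stream.rename(columns={"timestamp_iso8601_utc": "timestamp"})
    required = {"bird_id", "timestamp", "new_state"}
    missing = required - set(stream.columns)
    if missing:
        raise ValueError(f"state-change stream missing columns: {sorted(missing)}")
    if len(stream) == 0:
        return _empty_bouts()
    bad_state = ~stream["new_state"].isin(["wet", "dry"])
    if bad_state.any():
        raise ValueError(
            f"invalid new_state values: {stream.loc[bad_state, 'new_state'].unique()}"
        )
    pieces = []
    for bird, grp in stream.groupby("bird_id", sort=False):
        grp = grp.sort_values("timestamp", kind="stable")
        times = pd.to_datetime(grp["timestamp"]).to_numpy()
        if np.any(np.diff(times) < np.timedelta64(0)):
            raise ValueError(f"{bird}: timestamps not increasing")
        states = grp["new_state"].to_numpy()
        if start is not None and times[0] > np.datetime64(start):
            lead = "dry" if states[0] == "wet" else "wet"
            times = np.concatenate(([np.datetime64(start)], times))
            states = np.concatenate(([lead], states))
        # a repeat in the final row is the end-of-record marker, not a glitch
        n_dup = int(np.sum(states[1:-1] == states[:-2])) if len(states) > 2 else 0
        if n_dup:
            warnings.warn(
                f"{bird}: merged {n_dup} repeated state record(s)", stacklevel=2
            )
        bout_start = times[:-1]
        bout_end = times[1:]
        bout_state = states[:-1]
        if end is not None:
            last = np.datetime64(end)
            if last > times[-1]:
                bout_start = np.concatenate((bout_start, times[-1:]))
                bout_end = np.concatenate((bout_end, [last]))
                bout_state = np.concatenate((bout_state, states[-1:]))
        bouts = _runs_to_bouts(bird, bout_state, bout_start, bout_end)
        bouts = bouts[bouts["duration_h"] > 0].reset_index(drop=True)
        pieces.append(bouts)
    return pd.concat(pieces, ignore_index=True)


def extract_trips_and_shifts(
    bouts: pd.DataFrame,
    max_flight_h: float = 12.0,
    pair_id: str | None = None,
    season: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a bout sequence into foraging trips and nest shifts.

    A nest shift is a dry bout *strictly* longer than ``max_flight_h``
    (a dry bout of exactly 12 h is flight).  Each trip spans from the
    first wet bout after a shift to the start of the next shift; dry
    bouts of at most ``max_flight_h`` inside a trip are flight.  Trips
    not bracketed by shifts on both sides (deployment edges) are
    dropped: their durations would be censored.
    """
    trips_rows = []
    shift_rows = []
    for bird, grp in bouts.groupby("bird_id", sort=False):
        grp = grp.sort_values("start").reset_index(drop=True)
        is_shift = (grp["state"] == "dry") & (grp["duration_h"] > max_flight_h)
        idx = np.flatnonzero(is_shift.to_numpy())
        if len(idx) == 0:
            warnings.warn(
                f"{bird}: no dry bout > {max_flight_h} h; no trips extracted",
                stacklevel=2,
            )
            continue
        for i in idx:
            shift_rows.append(
                (bird, grp.loc[i, "start"], grp.loc[i, "end"], grp.loc[i, "duration_h"])
            )
        for a, b in zip(idx[:-1], idx[1:]):
            between = grp.iloc[a + 1 : b]
            wet = between[between["state"] == "wet"]
            if len(wet) == 0:  # pragma: no cover - impossible with alternating bouts
                continue
            t0 = wet["start"].iloc[0]
            t1 = grp.loc[b, "start"]
            trips_rows.append((bird, t0, t1, (t1 - t0) / _HOUR))
    trips = pd.DataFrame(trips_rows, columns=["bird_id", "start", "end", "duration_h"])
    shifts = pd.DataFrame(shift_rows, columns=SHIFT_COLUMNS)
    trips["pair_id"] = pair_id
    trips["season"] = season
    trips["source"] = "observed"
    trips["stage"] = "unassigned"
    trips = trips.sort_values(["bird_id", "start"]).reset_index(drop=True)
    trips["index"] = trips.groupby("bird_id").cumcount()
    return trips[TRIP_COLUMNS], shifts


def infer_partner_trips(
    tagged_trips: pd.DataFrame, partner_id: str | None = None
) -> pd.DataFrame:
    """Infer the untagged partner's trips from the tagged bird's record.

    Because one parent is always on the nest, the tagged bird's time on
    land is its partner's time at sea: each gap between consecutive
    observed trips of the tagged bird is one inferred partner trip.
    ``n`` observed trips yield ``n - 1`` inferred trips.
    """
    if len(tagged_trips) == 0:
        return tagged_trips.copy()
    rows = []
    for bird, grp in tagged_trips.groupby("bird_id", sort=False):
        grp = grp.sort_values("start")
        pid = partner_id if partner_id is not None else f"partner_of_{bird}"
        for prev_end, next_start, pair, season in zip(
            grp["end"].iloc[:-1],
            grp["start"].iloc[1:],
            grp["pair_id"].iloc[1:],
            grp["season"].iloc[1:],
        ):
            rows.append(
                {
                    "bird_id": pid,
                    "pair_id": pair,
                    "season": season,
                    "start": prev_end,
                    "end": next_start,
                    "duration_h": (next_start - prev_end) / _HOUR,
                    "source": "inferred",
                    "stage": "unassigned",
                }
            )
    out = pd.DataFrame(rows, columns=[c for c in TRIP_COLUMNS if c != "index"])
    out = out.sort_values(["bird_id", "start"]).reset_index(drop=True)
    out["index"] = out.groupby("bird_id").cumcount()
    return out[TRIP_COLUMNS]


@dataclass(frozen=True)
class AccuracySummary:
    """Partner-trip inference accuracy against ground truth."""

    mean_pct: float
    sd_pct: float
    n_matched: int
    n_unmatched: int


def inference_accuracy(
    inferred: pd.DataFrame, truth: pd.DataFrame
) -> AccuracySummary:
    """Per-trip percent accuracy of inferred against true partner trips.

    Each inferred trip is matched to the true trip with which it shares
    the most time (within the same pair when both frames carry
    ``pair_id``); accuracy per matched trip is
    ``100 * (1 - |inferred - true| / true)`` floored at 0.  Unmatched
    inferred trips are excluded and counted.
    """
    if len(inferred) == 0:
        return AccuracySummary(float("nan"), float("nan"), 0, 0)
    by_pair = "pair_id" in inferred.columns and "pair_id" in truth.columns
    truth_groups = (
        {k: g for k, g in truth.groupby("pair_id")} if by_pair else {None: truth}
    )
    accs = []
    unmatched = 0
    for _, row in inferred.iterrows():
        grp = truth_groups.get(row["pair_id"] if by_pair else None)
        if grp is None or len(grp) == 0:
            unmatched += 1
            continue
        t_start = grp["start"].to_numpy()
        t_end = grp["end"].to_numpy()
        t_dur = grp["duration_h"].to_numpy(dtype=float)
        s = np.datetime64(row["start"])
        e = np.datetime64(row["end"])
        d = float(row["duration_h"])
        overlap = (np.minimum(e, t_end) - np.maximum(s, t_start)) / np.timedelta64(1, "h")
        if np.max(overlap) <= 0:
            unmatched += 1
            continue
        j = int(np.argmax(overlap))
        accs.append(max(0.0, 100.0 * (1.0 - abs(d - t_dur[j]) / t_dur[j])))
    accs = np.asarray(accs)
    if len(accs) == 0:
        return AccuracySummary(float("nan"), float("nan"), 0, unmatched)
    sd = float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0
    return AccuracySummary(float(np.mean(accs)), sd, len(accs), unmatched)


@dataclass(frozen=True)
class OverlapSummary:
    """Nest relief overlap on a dual-tagged pair."""

    mean_h: float
    n_events: int
    n_excluded: int  # change-overs separated by more than the gap bound
    pct_of_mean_trip: dict  # stage -> 100 * mean_h / stage-mean trip duration


def nest_overlap(
    tagged_trips: pd.DataFrame,
    partner_observed_trips: pd.DataFrame,
    max_gap_h: float = 24.0,
) -> OverlapSummary:
    """Mean nest-relief overlap for a pair with both members tagged.

    At each change-over, the overlap is the delay between the returning
    bird's arrival (end of its trip) and the nest-bound bird's next
    departure (start of its trip), floored at 0.  A gap larger than
    ``max_gap_h`` cannot be a relief delay — it means a trip is missing
    from one record (deployment edges, unresolvable short trips) — and
    is excluded with a count.
    """
    both = pd.concat([tagged_trips, partner_observed_trips], ignore_index=True)
    lags = []
    n_excluded = 0
    groups = (
        [g for _, g in both.groupby(["pair_id", "season"], dropna=False)]
        if "pair_id" in both.columns
        else [both]
    )
    for grp in groups:
        grp = grp.sort_values("start").reset_index(drop=True)
        for i in range(len(grp) - 1):
            if grp.loc[i, "bird_id"] != grp.loc[i + 1, "bird_id"]:
                lag = (grp.loc[i + 1, "start"] - grp.loc[i, "end"]) / _HOUR
                if lag > max_gap_h:
                    n_excluded += 1
                    continue
                lags.append(max(0.0, lag))
    mean_h = float(np.mean(lags)) if lags else float("nan")
    pct = {}
    if "stage" in both.columns:
        for stage, grp in both.groupby("stage"):
            if stage == "unassigned":
                continue
            m = float(grp["duration_h"].mean())
            if m > 0:
                pct[stage] = 100.0 * mean_h / m
    return OverlapSummary(mean_h, len(lags), n_excluded, pct)
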