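"""Build the stage-specific model tables from trips, traits, and boldness.

One model row is one focal foraging trip.  The response is the square
root of trip duration in hours (correcting the strong positive skew of
trip lengths).  The key covariate is the *partner's previous trip
deviation*: the duration of the partner trip immediately preceding the
focal trip minus the expanding mean of that partner's earlier trips in
the same breeding stage.  A focal bird that lengthens its trip when its
partner just made a longer-than-usual trip (positive slope on this
deviation) is coordinating care.

Continuous covariates are standardized with pooled means/SDs computed
across both breeding stages *before* the stages are split into separate
tables, so coefficients are comparable between stages.  Extreme age
categories are collapsed (separately per stage) until at least five
distinct birds occupy the boundary category, guarding the quadratic age
terms against leverage from sparse extremes; quadratic terms are the
squares of the collapsed-then-scaled linear terms.

Row filters applied (and itemized, so nothing is dropped silently):

* trips with no defined partner deviation (no earlier in-stage partner
  trip);
* the first brooding trip of each pair-season, whose "previous partner
  trip" lies in incubation;
* trips outside the stage windows ("unassigned");
* in the few pairs with both members tagged, the record of the bird
  tagged second.

Model rows are built from the *tagged* bird's observed trips only; the
partner's (inferred) trips supply covariate history but are not
responses.  Besides matching what the loggers actually measure, this is
a statistical guard: when both members' trips are rows, each bird's
residual feeds the other bird's future deviation covariate, and the
resulting cross-row correlation between design and errors biases the
coordination slope toward zero (a predetermined-regressor problem;
simulation shows ~0.1 sqrt-h attenuation at this study's trips-per-pair
count).  With one member's trips as rows, the covariate history shares
no residuals with the responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "expanding_deviation",
    "partner_prev_deviation",
    "collapse_ages",
    "build_model_table",
    "FeatureTables",
]

#: Continuous covariates standardized with pooled (cross-stage) moments.
SCALED_COLUMNS = [
    "focal_boldness",
    "partner_boldness",
    "focal_age",
    "partner_age",
    "date",
    "partner_prev_dev",
]

MODEL_COLUMNS = [
    "pair_id",
    "season",
    "bird_id",
    "stage",
    "source",
    "resp_sqrt_h",
    "duration_h",
    "sex_male",
    "new_partner",
    "focal_boldness",
    "partner_boldness",
    "focal_age",
    "focal_age2",
    "partner_age",
    "partner_age2",
    "date",
    "partner_prev_dev",
]


def expanding_deviation(durations) -> np.ndarray:
    """Deviation of each value from the mean of all *earlier* values.

    ``dev[i] = d[i] - mean(d[:i])``; the first element has no history
    and is NaN.  This is the within-stage "deviation from the partner's
    average previous trip duration".
    """
    d = np.asarray(durations, dtype=float)
    out = np.full(len(d), np.nan)
    if len(d) > 1:
        csum = np.cumsum(d)
        prev_mean = csum[:-1] / np.arange(1, len(d))
        out[1:] = d[1:] - prev_mean
    return out


def partner_prev_deviation(
    focal_trips: pd.DataFrame, partner_trips: pd.DataFrame
) -> pd.Series:
    """Partner's previous-trip deviation (hours) for each focal trip.

    Both inputs are single pair-season, single *stage* trip tables.  For
    each focal trip, the partner trip immediately preceding it (latest
    partner trip ending at or before the focal start) contributes
    ``duration - mean(durations of that partner's earlier in-stage
    trips)``; NaN when that partner trip has no earlier in-stage trip,
    or no partner trip precedes the focal trip at all.
    """
    partner = partner_trips.sort_values("start").reset_index(drop=True)
    devs = expanding_deviation(partner["duration_h"].to_numpy())
    p_end = partner["end"].to_numpy()
    out = np.full(len(focal_trips), np.nan)
    for i, t0 in enumerate(focal_trips["start"].to_numpy()):
        j = np.searchsorted(p_end, t0, side="right") - 1
        if j >= 0:
            out[i] = devs[j]
    return pd.Series(out, index=focal_trips.index, name="partner_prev_dev")


def collapse_ages(
    bird_ages: pd.DataFrame, min_count: int = 5
) -> tuple[pd.Series, tuple[float, float]]:
    """Collapse extreme ages until boundary categories hold >= min_count birds.

    ``bird_ages`` has columns ``bird_id`` and ``age`` (one row per bird
    per role; duplicates of the same bird are counted once).  Working
    inward from each end of the age distribution, extreme values merge
    into the adjacent category until the cumulative number of distinct
    birds at the boundary reaches ``min_count``.  Interior ages are
    untouched.  Returns the collapsed ages (aligned to ``bird_ages``)
    and the (lower, upper) boundary ages.
    """
    uniq = bird_ages.drop_duplicates("bird_id")
    counts = uniq.groupby("age")["bird_id"].nunique().sort_index()
    total = int(counts.sum())
    ages = counts.index.to_numpy(dtype=float)
    if total < min_count:
        warnings.warn(
            f"only {total} birds (< {min_count}); ages not collapsed", stacklevel=2
        )
        return bird_ages["age"].astype(float), (float(ages[0]), float(ages[-1]))
    cum_lo = np.cumsum(counts.to_numpy())
    lo = float(ages[int(np.argmax(cum_lo >= min_count))])
    cum_hi = np.cumsum(counts.to_numpy()[::-1])
    hi = float(ages[::-1][int(np.argmax(cum_hi >= min_count))])
    if lo > hi:
        warnings.warn(
            "collapsing boundaries crossed; too few birds for stable extremes",
            stacklevel=2,
        )
        lo, hi = hi, lo
    return bird_ages["age"].astype(float).clip(lo, hi), (lo, hi)


@dataclass
class FeatureTables:
    """Stage model tables plus the bookkeeping needed to reproduce them."""

    incubation: pd.DataFrame
    brooding: pd.DataFrame
    scaling: dict = field(default_factory=dict)  # column -> (mean, sd)
    age_boundaries: dict = field(default_factory=dict)  # (stage, role) -> (lo, hi)
    exclusions: dict = field(default_factory=dict)  # reason -> n rows

    def table(self, stage: str) -> pd.DataFrame:
        if stage not in ("incubation", "brooding"):
            raise KeyError(stage)
        return getattr(self, stage)


def _days_since(start: pd.Series, season: pd.Series) -> np.ndarray:
    ref = pd.to_datetime(
        {"year": season.astype(int), "month": 12, "day": 16}
    ).to_numpy()
    return (start.to_numpy() - ref) / np.timedelta64(1, "D")


def build_model_table(
    trips: pd.DataFrame,
    pairs: pd.DataFrame,
    traits: pd.DataFrame,
    boldness: pd.DataFrame,
    min_age_count: int = 5,
    drop_birds: list | None = None,
    row_sources: tuple = ("observed",),
) -> FeatureTables:
    """Assemble the incubation and brooding model tables.

    Parameters
    ----------
    trips
        Observed + inferred trips with stages assigned
        (:data:`~albicoord.segmentation.TRIP_COLUMNS`).
    pairs
        One row per pair-season: ``pair_id``, ``season``,
        ``bird_id_1``, ``bird_id_2``, ``new_partner``.
    traits
        One row per bird: ``bird_id``, ``sex`` ("F"/"M"), ``age``.
    boldness
        ``bird_id``, ``boldness_score`` (population mean-centered).
    drop_birds
        Records to exclude entirely (the second-tagged member of
        dual-tagged pairs).
    row_sources
        Trip sources that become model rows (default: the tagged bird's
        ``observed`` trips).  All trips, whatever their source, feed the
        partner-deviation covariate.
    """
    trips = trips.copy()
    exclusions: dict[str, int] = {}
    if drop_birds:
        mask = trips["bird_id"].isin(drop_birds)
        exclusions["second_tagged_bird"] = int(mask.sum())
        trips = trips[~mask]
    mask = trips["stage"].isin(["incubation", "brooding"])
    exclusions["outside_stage_windows"] = int((~mask).sum())
    trips = trips[mask].copy()

    # partner linkage
    partner_of = {}
    new_partner = {}
    for _, row in pairs.iterrows():
        key = (row["pair_id"], row["season"])
        partner_of[key + (row["bird_id_1"],)] = row["bird_id_2"]
        partner_of[key + (row["bird_id_2"],)] = row["bird_id_1"]
        new_partner[key] = bool(row["new_partner"])
    missing = [
        (p, s, b)
        for p, s, b in zip(trips["pair_id"], trips["season"], trips["bird_id"])
        if (p, s, b) not in partner_of
    ]
    if missing:
        raise ValueError(f"trips reference unknown pair members: {sorted(set(missing))[:5]}")

    trait_row = traits.set_index("bird_id")
    score = boldness.set_index("bird_id")["boldness_score"]
    unknown = set(trips["bird_id"]) - set(trait_row.index)
    if unknown:
        raise ValueError(f"no traits for birds: {sorted(unknown)}")

    # coordination covariate, per pair-season-stage and focal bird
    trips = trips.sort_values(["pair_id", "season", "start"]).reset_index(drop=True)
    trips["partner_prev_dev"] = np.nan
    for (pid, season, stage), grp in trips.groupby(["pair_id", "season", "stage"]):
        for bird in grp["bird_id"].unique():
            focal = grp[grp["bird_id"] == bird]
            partner = grp[grp["bird_id"] != bird]
            trips.loc[focal.index, "partner_prev_dev"] = partner_prev_deviation(
                focal, partner
            )

    is_row = trips["source"].isin(row_sources)
    exclusions["covariate_only_rows"] = int((~is_row).sum())

    out = pd.DataFrame(
        {
            "pair_id": trips["pair_id"],
            "season": trips["season"],
            "bird_id": trips["bird_id"],
            "stage": trips["stage"],
            "source": trips["source"],
            "start": trips["start"],
            "duration_h": trips["duration_h"],
            "resp_sqrt_h": np.sqrt(trips["duration_h"].to_numpy(dtype=float)),
            "partner_prev_dev": trips["partner_prev_dev"],
        }
    )
    out["partner_id"] = [
        partner_of[(p, s, b)]
        for p, s, b in zip(out["pair_id"], out["season"], out["bird_id"])
    ]
    out["new_partner"] = [
        int(new_partner[(p, s)]) for p, s in zip(out["pair_id"], out["season"])
    ]
    out["sex_male"] = (trait_row.loc[out["bird_id"], "sex"] == "M").astype(int).to_numpy()
    out["focal_boldness"] = score.reindex(out["bird_id"]).to_numpy()
    out["partner_boldness"] = score.reindex(out["partner_id"]).to_numpy()
    out["focal_age_raw"] = trait_row.loc[out["bird_id"], "age"].to_numpy(dtype=float)
    out["partner_age_raw"] = trait_row.loc[out["partner_id"], "age"].to_numpy(dtype=float)
    out["date"] = _days_since(out["start"], out["season"])
    out = out[is_row.to_numpy()]

    # per-stage age collapsing over the union of focal and partner roles
    age_boundaries = {}
    out["focal_age"] = np.nan
    out["partner_age"] = np.nan
    for stage, grp in out.groupby("stage"):
        bird_ages = pd.concat(
            [
                grp[["bird_id", "focal_age_raw"]].rename(
                    columns={"focal_age_raw": "age"}
                ),
                grp[["partner_id", "partner_age_raw"]].rename(
                    columns={"partner_id": "bird_id", "partner_age_raw": "age"}
                ),
            ],
            ignore_index=True,
        )
        _, (lo, hi) = collapse_ages(bird_ages, min_count=min_age_count)
        age_boundaries[stage] = (lo, hi)
        out.loc[grp.index, "focal_age"] = grp["focal_age_raw"].clip(lo, hi)
        out.loc[grp.index, "partner_age"] = grp["partner_age_raw"].clip(lo, hi)

    # pooled scaling across both stages, before any stage split;
    # NaN deviations (dropped below) do not contribute to the moments
    scaling = {}
    for col in SCALED_COLUMNS:
        x = out[col].to_numpy(dtype=float)
        mean = float(np.nanmean(x))
        sd = float(np.nanstd(x, ddof=1))
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"column {col} has zero variance; not scaled", stacklevel=2)
            sd = 1.0
        out[col] = (x - mean) / sd
        scaling[col] = (mean, sd)
    out["focal_age2"] = out["focal_age"] ** 2
    out["partner_age2"] = out["partner_age"] ** 2

    # row filters
    first_brood = (
        out[out["stage"] == "brooding"]
        .sort_values("start")
        .groupby(["pair_id", "season"])
        .head(1)
        .index
    )
    exclusions["first_brooding_trip"] = len(first_brood)
    out = out.drop(index=first_brood)
    undef = out["partner_prev_dev"].isna()
    exclusions["undefined_partner_deviation"] = int(undef.sum())
    out = out[~undef]

    out = out.sort_values(["pair_id", "season", "start"]).reset_index(drop=True)
    incubation = out[out["stage"] == "incubation"][MODEL_COLUMNS].reset_index(drop=True)
    brooding = out[out["stage"] == "brooding"][MODEL_COLUMNS].reset_index(drop=True)
    return FeatureTables(
        incubation=incubation,
        brooding=brooding,
        scaling=scaling,
        age_boundaries=age_boundaries,
        exclusions=exclusions,
    )
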