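"""Synthetic dual-forager schedules and raw immersion-logger streams.

The generator mirrors the analysis model so that every downstream stage
has ground truth.  A pair alternates foraging trips: exactly one bird is
at sea at any time, except during a short nest-relief overlap when both
are on land.  Each new trip's square-root duration is a linear predictor

    sqrt(dur) = stage intercept + sum(beta * covariate)
                + beta_coord * (partner's previous-trip deviation / coord_scale_h)
                + pair intercept + pair slope * (same deviation term)
                + year effect + residual

with the deviation computed exactly as the feature builder will compute
it (partner's last trip minus the expanding mean of that partner's
earlier trips in the same breeding stage; zero while undefined).  Trait
covariates enter standardized by the configured population moments, so
the betas are on the sqrt-hours-per-SD scale the fitted models report.

Durations are the squares of the linear predictor, floored at a small
positive value.  Residuals are truncated at +/-3 SD: unbounded Gaussian
tails occasionally produce trips shorter than the 12-h flight ceiling,
which no segmentation rule could recover (the same class of constraint
as keeping at-sea dry bouts under 12 h).

Rendering turns a schedule into raw logger streams: on-land intervals
are fully dry; at-sea intervals alternate wet bouts (sitting on the
water) with dry flight bouts truncated below the flight ceiling, and
begin and end wet so trip boundaries are observable.  Both logger
dialects are supported and round-trip through the segmentation module
up to bin-width quantization.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .features import expanding_deviation
from .segmentation import SHIFT_COLUMNS, TRIP_COLUMNS

__all__ = [
    "SimulationConfig",
    "PairTraits",
    "TrueSchedule",
    "simulate_traits",
    "simulate_pair_season",
    "simulate_study",
    "render_logger_stream",
    "write_truth_tables",
    "simulate_boldness_observations",
]

_HOUR = pd.Timedelta(hours=1)


def _default_beta() -> dict:
    # sqrt-hours per SD of the covariate (binary terms per level change);
    # magnitudes follow the averaged estimates of the field study
    return {
        "sex_male": -1.0,
        "focal_boldness": -0.2,
        "partner_boldness": -0.24,
        "focal_age": 0.0,
        "focal_age2": 0.0,
        "partner_age": 0.3,
        "partner_age2": -0.2,
        "new_partner": 0.4,
        "date": 0.5,
        "coordination": 0.2,
    }


@dataclass
class SimulationConfig:
    """All generative parameters; defaults emulate the field study."""

    n_pairs: int = 70
    n_years: int = 7
    first_season: int = 2008
    seed: int = 0

    # stage intercepts on the sqrt-hours scale: sqrt(5.6 d) and sqrt(2.7 d)
    intercept_incubation: float = 11.6
    intercept_brooding: float = 8.1
    beta: dict = field(default_factory=_default_beta)

    # variance components, sqrt-hours scale
    sigma_pair_intercept: float = 1.0
    sigma_pair_slope: float = 0.1
    sigma_year: float = 0.5
    sigma_resid: float = 2.2
    resid_truncate_sd: float = 3.0

    #: nominal SD (hours) of the partner deviation; the generative
    #: coordination covariate is deviation_h / coord_scale_h
    coord_scale_h: float = 50.0
    trip_floor_h: float = 2.0

    # schedule
    overlap_lag_mean_h: float = 1.9  # exponential; 0 = instantaneous relief
    initial_shift_min_h: float = 13.0
    initial_shift_mean_extra_h: float = 12.0
    hatch_mean_offset_d: float = 89.0  # days after 16 Dec -> 15 Mar
    hatch_sd_d: float = 6.0

    # within-trip wet/dry alternation
    wet_bout_mean_h: float = 1.5
    wet_bout_min_h: float = 0.05
    dry_bout_mean_h: float = 2.0
    max_dry_at_sea_h: float = 11.0

    # logger rendering; deployment starts partway through incubation
    # (loggers are fitted at a nest visit, not on the lay date), so a
    # season yields a few hundred, not a couple of thousand, model rows
    # across the study — the regime of the field data
    logger_dialect: str = "binned"
    bin_width_min: int = 10
    wet_threshold_s: float = 45.0
    deployment_offset_min_d: float = 30.0
    deployment_offset_max_d: float = 60.0

    # population traits
    n_dual_tagged: int = 3
    prop_repeat_pairs: float = 0.3
    prop_new_partner: float = 0.2
    age_mean: float = 21.14
    age_sd: float = 7.67
    age_min: int = 7
    age_max: int = 45
    boldness_sd: float = 1.0
    date_mean_d: float = 45.0
    date_sd_d: float = 30.0

    def __post_init__(self):
        for name in ("sigma_pair_intercept", "sigma_pair_slope", "sigma_year", "sigma_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.overlap_lag_mean_h < 0:
            raise ValueError("overlap_lag_mean_h must be >= 0")
        if self.max_dry_at_sea_h >= 12.0:
            raise ValueError(
                "max_dry_at_sea_h must stay below the 12-h flight ceiling, "
                "else segmentation is broken by construction"
            )
        if self.logger_dialect not in ("binned", "state_change"):
            raise ValueError(f"unknown logger dialect {self.logger_dialect!r}")
        if not 0 < self.hatch_mean_offset_d:
            raise ValueError("hatch_mean_offset_d must be positive")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass(frozen=True)
class PairTraits:
    """Known attributes of one pair in one season."""

    pair_id: str
    season: int
    bird_ids: tuple  # (female, male)
    sexes: dict  # bird_id -> "F" | "M"
    ages: dict  # bird_id -> int
    boldness: dict  # bird_id -> score (population-centered)
    new_partner: bool
    tagged_bird: str
    dual_tagged: bool = False


@dataclass
class TrueSchedule:
    """Ground-truth alternating schedule for one pair-season."""

    traits: PairTraits
    hatch_date: pd.Timestamp
    trips: pd.DataFrame  # TRIP_COLUMNS + dev_h, coord_x, sqrt_dur
    deployment_start: pd.Timestamp | None = None

    @property
    def season_start(self) -> pd.Timestamp:
        return pd.Timestamp(year=self.traits.season, month=12, day=16)

    @property
    def brooding_end(self) -> pd.Timestamp:
        return pd.Timestamp(year=self.traits.season + 1, month=4, day=11)


def simulate_traits(config: SimulationConfig, rng: np.random.Generator) -> list[PairTraits]:
    """Draw pair-season traits: sexes, ages, boldness, partnership status.

    Most pairs are observed in a single season; a configurable fraction
    re-appears in a second season (same partners, no longer new).  The
    first ``n_dual_tagged`` pairs carry loggers on both members.
    """
    out = []
    for p in range(config.n_pairs):
        pid = f"P{p:03d}"
        f_id, m_id = f"{pid}F", f"{pid}M"
        seasons = [int(config.first_season + rng.integers(config.n_years))]
        if config.n_years > 1 and rng.random() < config.prop_repeat_pairs:
            second = int(config.first_season + rng.integers(config.n_years))
            if second != seasons[0]:
                seasons.append(second)
        ages0 = {
            b: int(np.clip(round(rng.normal(config.age_mean, config.age_sd)),
                           config.age_min, config.age_max))
            for b in (f_id, m_id)
        }
        bold = {b: float(rng.normal(0.0, config.boldness_sd)) for b in (f_id, m_id)}
        new = rng.random() < config.prop_new_partner
        tagged = f_id if rng.random() < 0.5 else m_id
        for k, season in enumerate(sorted(seasons)):
            out.append(
                PairTraits(
                    pair_id=pid,
                    season=season,
                    bird_ids=(f_id, m_id),
                    sexes={f_id: "F", m_id: "M"},
                    ages={b: a + (season - sorted(seasons)[0]) for b, a in ages0.items()},
                    boldness=bold,
                    new_partner=new and k == 0,
                    tagged_bird=tagged,
                    dual_tagged=p < config.n_dual_tagged,
                )
            )
    return out


def _z(x, mean, sd):
    return (x - mean) / sd


def simulate_pair_season(
    config: SimulationConfig,
    traits: PairTraits,
    rng: np.random.Generator,
    pair_effects: tuple[float, float] | None = None,
    year_effect: float | None = None,
) -> TrueSchedule:
    """Generate one pair-season's alternating trip schedule.

    ``pair_effects`` (random intercept, random coordination slope) and
    ``year_effect`` may be supplied by :func:`simulate_study` so they are
    shared across seasons of a pair and across pairs within a year; when
    omitted they are drawn here.
    """
    for b in traits.bird_ids:
        if b not in traits.sexes or b not in traits.ages or b not in traits.boldness:
            raise ValueError(f"incomplete traits for bird {b}")
    if pair_effects is None:
        pair_effects = (
            rng.normal(0.0, config.sigma_pair_intercept),
            rng.normal(0.0, config.sigma_pair_slope),
        )
    if year_effect is None:
        year_effect = rng.normal(0.0, config.sigma_year)
    u_pair, b_pair = pair_effects

    t0 = pd.Timestamp(year=traits.season, month=12, day=16)
    brooding_end = pd.Timestamp(year=traits.season + 1, month=4, day=11)
    hatch = t0 + pd.Timedelta(
        days=float(np.clip(rng.normal(config.hatch_mean_offset_d, config.hatch_sd_d),
                           45.0, 110.0))
    )

    beta = config.beta
    zb = {b: traits.boldness[b] / max(config.boldness_sd, 1e-12) for b in traits.bird_ids}
    za = {
        b: _z(traits.ages[b], config.age_mean, config.age_sd) for b in traits.bird_ids
    }
    birds = list(traits.bird_ids)
    focal = birds[int(rng.integers(2))]
    t_dep = t0 + pd.Timedelta(
        hours=config.initial_shift_min_h
        + rng.exponential(config.initial_shift_mean_extra_h)
    )
    history: dict[str, dict[str, list]] = {
        b: {"incubation": [], "brooding": []} for b in birds
    }
    rows = []
    while t_dep <= brooding_end:
        stage = "incubation" if t_dep < hatch else "brooding"
        partner = birds[0] if focal == birds[1] else birds[1]
        prev = history[partner][stage]
        if len(prev) >= 2:
            dev_h = float(expanding_deviation(prev)[-1])
        else:
            dev_h = np.nan
        coord_x = 0.0 if np.isnan(dev_h) else dev_h / config.coord_scale_h
        date_z = _z(
            (t_dep - t0) / pd.Timedelta(days=1), config.date_mean_d, config.date_sd_d
        )
        intercept = (
            config.intercept_incubation
            if stage == "incubation"
            else config.intercept_brooding
        )
        eta = (
            intercept
            + beta["sex_male"] * (traits.sexes[focal] == "M")
            + beta["focal_boldness"] * zb[focal]
            + beta["partner_boldness"] * zb[partner]
            + beta["focal_age"] * za[focal]
            + beta["focal_age2"] * za[focal] ** 2
            + beta["partner_age"] * za[partner]
            + beta["partner_age2"] * za[partner] ** 2
            + beta["new_partner"] * traits.new_partner
            + beta["date"] * date_z
            + (beta["coordination"] + b_pair) * coord_x
            + u_pair
            + year_effect
        )
        if not np.isfinite(eta):
            terms = {k: beta[k] for k in beta}
            raise FloatingPointError(
                f"non-finite linear predictor for {focal} at {t_dep}; betas: {terms}"
            )
        resid = rng.normal(0.0, config.sigma_resid)
        if config.sigma_resid > 0:
            bound = config.resid_truncate_sd * config.sigma_resid
            while abs(resid) > bound:
                resid = rng.normal(0.0, config.sigma_resid)
        sqrt_dur = max(eta + resid, np.sqrt(config.trip_floor_h))
        dur_h = sqrt_dur**2
        t_ret = t_dep + pd.Timedelta(hours=dur_h)
        rows.append(
            {
                "bird_id": focal,
                "pair_id": traits.pair_id,
                "season": traits.season,
                "start": t_dep,
                "end": t_ret,
                "duration_h": dur_h,
                "source": "truth",
                "stage": stage,
                "dev_h": dev_h,
                "coord_x": coord_x,
                "sqrt_dur": sqrt_dur,
            }
        )
        history[focal][stage].append(dur_h)
        lag = (
            rng.exponential(config.overlap_lag_mean_h)
            if config.overlap_lag_mean_h > 0
            else 0.0
        )
        t_dep = t_ret + pd.Timedelta(hours=lag)
        focal = partner
    trips = pd.DataFrame(rows, columns=TRIP_COLUMNS + ["dev_h", "coord_x", "sqrt_dur"])
    if len(trips):
        trips = trips.sort_values(["bird_id", "start"]).reset_index(drop=True)
        trips["index"] = trips.groupby("bird_id").cumcount()
        trips = trips[TRIP_COLUMNS + ["dev_h", "coord_x", "sqrt_dur"]]
    offset = rng.uniform(config.deployment_offset_min_d, config.deployment_offset_max_d)
    return TrueSchedule(
        traits=traits,
        hatch_date=hatch,
        trips=trips,
        deployment_start=t0 + pd.Timedelta(days=float(offset)),
    )


@dataclass
class StudyData:
    """A full synthetic study: traits tables and per-pair-season schedules."""

    config: SimulationConfig
    schedules: list
    pairs: pd.DataFrame  # pair_id, season, bird_id_1, bird_id_2, new_partner, ...
    traits: pd.DataFrame  # bird_id, sex, age
    true_boldness: pd.DataFrame  # bird_id, boldness_score (generative truth)

    @property
    def truth_trips(self) -> pd.DataFrame:
        return pd.concat([s.trips for s in self.schedules], ignore_index=True)

    def analysis_trips(self, deployed: bool = True) -> pd.DataFrame:
        """Truth trips relabeled the way the logger pipeline sees them.

        The tagged bird's trips are marked ``observed`` and the
        partner's ``inferred`` (with true durations — no logger or
        relief-lag noise), optionally clipped to the deployment window.
        Lets the modeling layer be exercised against exact ground truth.
        """
        trips = self.deployed_trips if deployed else self.truth_trips
        trips = trips.copy()
        tagged = {
            (t.pair_id, t.season): t.tagged_bird
            for t in (s.traits for s in self.schedules)
        }
        is_tagged = [
            b == tagged[(p, s)]
            for p, s, b in zip(trips["pair_id"], trips["season"], trips["bird_id"])
        ]
        trips["source"] = np.where(is_tagged, "observed", "inferred")
        return trips

    @property
    def deployed_trips(self) -> pd.DataFrame:
        """Truth trips starting after each pair-season's logger deployment."""
        frames = []
        for s in self.schedules:
            if s.deployment_start is None:
                frames.append(s.trips)
            else:
                frames.append(s.trips[s.trips["start"] >= s.deployment_start])
        return pd.concat(frames, ignore_index=True)


def simulate_study(config: SimulationConfig, rng: np.random.Generator) -> StudyData:
    """Simulate every pair-season of a study with shared year effects."""
    all_traits = simulate_traits(config, rng)
    year_fx = {
        config.first_season + i: rng.normal(0.0, config.sigma_year)
        for i in range(config.n_years)
    }
    pair_fx = {}
    schedules = []
    for tr in all_traits:
        if tr.pair_id not in pair_fx:
            pair_fx[tr.pair_id] = (
                rng.normal(0.0, config.sigma_pair_intercept),
                rng.normal(0.0, config.sigma_pair_slope),
            )
        schedules.append(
            simulate_pair_season(
                config,
                tr,
                rng,
                pair_effects=pair_fx[tr.pair_id],
                year_effect=year_fx[tr.season],
            )
        )
    pairs = pd.DataFrame(
        {
            "pair_id": [t.pair_id for t in all_traits],
            "season": [t.season for t in all_traits],
            "bird_id_1": [t.bird_ids[0] for t in all_traits],
            "bird_id_2": [t.bird_ids[1] for t in all_traits],
            "new_partner": [t.new_partner for t in all_traits],
            "tagged_bird": [t.tagged_bird for t in all_traits],
            "dual_tagged": [t.dual_tagged for t in all_traits],
        }
    )
    bird_rows = {}
    bold_rows = {}
    for t in all_traits:
        for b in t.bird_ids:
            bird_rows[b] = {"bird_id": b, "sex": t.sexes[b], "age": t.ages[b]}
            bold_rows[b] = {"bird_id": b, "boldness_score": t.boldness[b]}
    traits_df = pd.DataFrame(sorted(bird_rows.values(), key=lambda r: r["bird_id"]))
    bold_df = pd.DataFrame(sorted(bold_rows.values(), key=lambda r: r["bird_id"]))
    return StudyData(
        config=config,
        schedules=schedules,
        pairs=pairs,
        traits=traits_df,
        true_boldness=bold_df,
    )


def _wet_dry_intervals(
    start_h: float, end_h: float, config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Wet intervals (hours from record start) of one at-sea interval.

    The interval opens and closes wet (the bird lands by the colony on
    departure and arrival), alternating wet bouts with flight bouts
    truncated below the at-sea dry ceiling.
    """
    wet = []
    t = start_h
    state = "wet"
    while t < end_h:
        if state == "wet":
            length = config.wet_bout_min_h + rng.exponential(config.wet_bout_mean_h)
        else:
            length = min(
                rng.exponential(config.dry_bout_mean_h), config.max_dry_at_sea_h
            )
        t_next = min(t + length, end_h)
        if state == "wet":
            wet.append((t, t_next))
        state = "dry" if state == "wet" else "wet"
        t = t_next
    # interval must end wet: extend the final wet bout over a trailing dry
    if wet and wet[-1][1] < end_h:
        wet[-1] = (wet[-1][0], end_h)
    elif not wet:
        wet.append((start_h, end_h))
    return wet


def render_logger_stream(
    schedule: TrueSchedule,
    tagged_bird: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    dialect: str | None = None,
) -> pd.DataFrame:
    """Render one bird's immersion-logger stream from the true schedule.

    Returns a binned-dialect frame (``bird_id``, ``bin_start``,
    ``wet_seconds``) or a state-change frame (``bird_id``, ``timestamp``,
    ``new_state``), covering deployment from the season start to 14 h
    after the bird's last return (so the final trip is bracketed by a
    land period longer than the flight ceiling).
    """
    dialect = dialect or config.logger_dialect
    if dialect not in ("binned", "state_change"):
        raise ValueError(f"unknown logger dialect {dialect!r}")
    own = schedule.trips[schedule.trips["bird_id"] == tagged_bird].sort_values("start")
    t0 = schedule.season_start
    rec0 = schedule.deployment_start if schedule.deployment_start is not None else t0
    ds = (rec0 - t0) / _HOUR
    starts = ((own["start"] - t0) / _HOUR).to_numpy(dtype=float)
    ends = ((own["end"] - t0) / _HOUR).to_numpy(dtype=float)
    if np.any(starts[1:] < ends[:-1]):
        raise ValueError(f"{tagged_bird}: overlapping trips in schedule")
    record_end = (ends[-1] + 14.0) if len(ends) else ds + 24.0
    wet_intervals = []
    for s, e in zip(starts, ends):
        if e <= ds:
            continue
        wet_intervals.extend(
            (max(ws, ds), we)
            for ws, we in _wet_dry_intervals(s, e, config, rng)
            if we > ds
        )

    if dialect == "state_change":
        rows = [(tagged_bird, rec0, "dry")]
        for ws, we in wet_intervals:
            rows.append((tagged_bird, t0 + pd.Timedelta(hours=ws), "wet"))
            rows.append((tagged_bird, t0 + pd.Timedelta(hours=we), "dry"))
        # end-of-record marker; repeats the current (dry) state
        rows.append((tagged_bird, t0 + pd.Timedelta(hours=record_end), "dry"))
        return pd.DataFrame(rows, columns=["bird_id", "timestamp", "new_state"])

    bin_h = config.bin_width_min / 60.0
    first_bin = int(np.floor(ds / bin_h))
    n_bins = int(np.ceil(record_end / bin_h)) - first_bin
    wet_s = np.zeros(n_bins)
    for ws, we in wet_intervals:
        first = int(ws // bin_h) - first_bin
        last = int(np.ceil(we / bin_h)) - first_bin
        for i in range(max(first, 0), min(last, n_bins)):
            lo = max(ws, (i + first_bin) * bin_h)
            hi = min(we, (i + first_bin + 1) * bin_h)
            if hi > lo:
                wet_s[i] += (hi - lo) * 3600.0
    bin_starts = t0 + pd.to_timedelta(
        (np.arange(n_bins, dtype=np.int64) + first_bin) * config.bin_width_min,
        unit="m",
    )
    return pd.DataFrame(
        {
            "bird_id": tagged_bird,
            "bin_start": bin_starts,
            "wet_seconds": np.round(wet_s, 6),
        }
    )


def write_truth_tables(
    schedules, trips_path=None, shifts_path=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ground-truth trip and nest-shift tables for both pair members.

    Shifts are each bird's on-land intervals between its own consecutive
    trips.  Tables use the same schema the segmentation module emits
    (plus the generative ``dev_h``/``coord_x``/``sqrt_dur`` columns on
    trips) and are optionally written to CSV.
    """
    if isinstance(schedules, TrueSchedule):
        schedules = [schedules]
    trip_frames = []
    shift_rows = []
    for sched in schedules:
        trip_frames.append(sched.trips)
        if len(sched.trips) == 0:
            continue
        for bird, grp in sched.trips.groupby("bird_id"):
            grp = grp.sort_values("start")
            bounds = (
                [sched.season_start]
                + list(grp["end"].iloc[:-1])
                + [grp["end"].iloc[-1] if len(grp) else sched.season_start]
            )
            nexts = list(grp["start"]) + [grp["end"].iloc[-1] + pd.Timedelta(hours=14)]
            for lo, hi in zip(bounds, nexts):
                if hi > lo:
                    shift_rows.append(
                        (bird, lo, hi, (hi - lo) / _HOUR)
                    )
    trips = (
        pd.concat(trip_frames, ignore_index=True)
        if trip_frames
        else pd.DataFrame(columns=TRIP_COLUMNS + ["dev_h", "coord_x", "sqrt_dur"])
    )
    shifts = pd.DataFrame(shift_rows, columns=SHIFT_COLUMNS)
    if trips_path is not None:
        trips.to_csv(trips_path, index=False)
    if shifts_path is not None:
        shifts.to_csv(shifts_path, index=False)
    return trips, shifts


def simulate_boldness_observations(
    true_scores: pd.DataFrame,
    rng: np.random.Generator,
    n_obs_per_bird: int = 10,
    n_observers: int = 5,
    observer_sd: float = 0.5,
    noise_sd: float = 0.8,
    habituation: float = -0.05,
) -> pd.DataFrame:
    """Ordinal human-approach responses consistent with known boldness.

    Latent response = 2.5 + true score + observer effect + habituation
    drift + noise, rounded and clipped to the 0-5 scale.  Used to
    exercise the scoring model against known bird effects.
    """
    observer_fx = rng.normal(0.0, observer_sd, size=n_observers)
    rows = []
    for _, r in true_scores.iterrows():
        for k in range(1, n_obs_per_bird + 1):
            o = int(rng.integers(n_observers))
            latent = (
                2.5
                + r["boldness_score"]
                + observer_fx[o]
                + habituation * k
                + rng.normal(0.0, noise_sd)
            )
            rows.append(
                {
                    "bird_id": r["bird_id"],
                    "observer_id": f"O{o}",
                    "observation_number": k,
                    "response": int(np.clip(round(latent), 0, 5)),
                }
            )
    return pd.DataFrame(rows)
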