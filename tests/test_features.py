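"""Coordination covariate, age collapsing, and the model-table assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from albicoord.features import (
    build_model_table,
    collapse_ages,
    expanding_deviation,
    partner_prev_deviation,
)
from albicoord.simulate import SimulationConfig, simulate_study
from conftest import T0, make_trips, low_noise_config


class TestExpandingDeviation:
    def test_running_mean_arithmetic(self):
        dev = expanding_deviation([100.0, 120.0, 140.0])
        assert np.isnan(dev[0])
        assert dev[1] == pytest.approx(20.0)
        assert dev[2] == pytest.approx(30.0)  # 140 - mean(100, 120)

    def test_constant_series_deviates_zero(self):
        dev = expanding_deviation([80.0] * 6)
        assert np.isnan(dev[0])
        assert np.allclose(dev[1:], 0.0)

    def test_single_value_undefined(self):
        assert np.all(np.isnan(expanding_deviation([50.0])))


class TestPartnerPrevDeviation:
    def test_alternating_schedule(self):
        partner = make_trips([100.0, 120.0, 140.0], bird_id="P", gap_h=50.0)
        # focal trips start right after each partner trip ends
        focal_starts = partner["end"] + pd.Timedelta(hours=1)
        focal = pd.concat(
            [make_trips([49.0], bird_id="F", start=s) for s in focal_starts],
            ignore_index=True,
        )
        dev = partner_prev_deviation(focal, partner)
        assert np.isnan(dev.iloc[0])
        assert dev.iloc[1] == pytest.approx(20.0)
        assert dev.iloc[2] == pytest.approx(30.0)

    def test_no_preceding_partner_trip_undefined(self):
        partner = make_trips([100.0], bird_id="P", start=T0 + pd.Timedelta(days=10))
        focal = make_trips([50.0], bird_id="F", start=T0)
        assert np.all(np.isnan(partner_prev_deviation(focal, partner)))

    def test_perfect_coordination_has_slope_one(self):
        # a partner averaging 200 h and swinging +/-100 h, matched exactly
        # by the focal bird, shows a regression slope of 1
        partner_durs = [200.0, 300.0, 100.0, 300.0, 100.0, 200.0, 300.0]
        partner = make_trips(partner_durs, bird_id="P", gap_h=60.0)
        focal_rows = []
        devs_expected = expanding_deviation(partner_durs)
        for i in range(1, len(partner_durs)):
            start = partner["end"].iloc[i] + pd.Timedelta(hours=1)
            focal_rows.append(
                make_trips([200.0 + devs_expected[i]], bird_id="F", start=start)
            )
        focal = pd.concat(focal_rows, ignore_index=True)
        dev = partner_prev_deviation(focal, partner).to_numpy()
        slope = np.polyfit(dev, focal["duration_h"].to_numpy(), 1)[0]
        assert slope == pytest.approx(1.0)


def bird_age_frame(counts):
    rows = []
    i = 0
    for age, n in counts.items():
        for _ in range(n):
            rows.append({"bird_id": f"b{i}", "age": age})
            i += 1
    return pd.DataFrame(rows)


def brute_force_boundaries(counts, min_count=5):
    ages = sorted(counts)
    cum = 0
    lo = ages[-1]
    for a in ages:
        cum += counts[a]
        if cum >= min_count:
            lo = a
            break
    cum = 0
    hi = ages[0]
    for a in reversed(ages):
        cum += counts[a]
        if cum >= min_count:
            hi = a
            break
    return lo, hi


class TestCollapseAges:
    def test_cumulative_count_from_each_end(self):
        counts = {7: 1, 8: 2, 9: 1, 10: 3, 11: 4, 12: 6, 20: 4, 25: 2, 30: 1}
        frame = bird_age_frame(counts)
        collapsed, (lo, hi) = collapse_ages(frame)
        assert (lo, hi) == brute_force_boundaries(counts)
        assert lo == 10
        assert (collapsed >= lo).all() and (collapsed <= hi).all()

    def test_identity_when_extremes_already_full(self):
        counts = {10: 5, 12: 3, 15: 6}
        frame = bird_age_frame(counts)
        collapsed, (lo, hi) = collapse_ages(frame)
        assert (collapsed == frame["age"]).all()
        assert (lo, hi) == (10, 15)

    def test_interior_birds_untouched(self):
        counts = {7: 2, 10: 4, 15: 8, 20: 4, 30: 2}
        frame = bird_age_frame(counts)
        collapsed, (lo, hi) = collapse_ages(frame)
        interior = frame["age"].between(lo, hi)
        assert (collapsed[interior] == frame.loc[interior, "age"]).all()

    def test_too_few_birds_warns(self):
        with pytest.warns(UserWarning, match="not collapsed"):
            collapse_ages(bird_age_frame({10: 1, 12: 2}))

    @given(
        st.dictionaries(
            st.integers(min_value=5, max_value=45),
            st.integers(min_value=1, max_value=6),
            min_size=3,
            max_size=12,
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_on_random_age_distributions(self, counts):
        frame = bird_age_frame(counts)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            collapsed, (lo, hi) = collapse_ages(frame)
        blo, bhi = brute_force_boundaries(counts)
        if blo <= bhi:  # implementation swaps crossed boundaries
            assert (lo, hi) == (blo, bhi)
        assert (collapsed == frame["age"].clip(lo, hi)).all()


@pytest.fixture(scope="module")
def built_tables():
    cfg = low_noise_config(n_pairs=12, n_years=2)
    study = simulate_study(cfg, np.random.default_rng(21))
    trips = study.analysis_trips()
    tables = build_model_table(trips, study.pairs, study.traits, study.true_boldness)
    return cfg, study, trips, tables


class TestBuildModelTable:
    def test_response_is_sqrt_duration(self, built_tables):
        *_, tables = built_tables
        for stage in ("incubation", "brooding"):
            tab = tables.table(stage)
            assert np.allclose(tab["resp_sqrt_h"] ** 2, tab["duration_h"])

    def test_deviation_matches_generator_truth(self, built_tables):
        cfg, study, trips, tables = built_tables
        mean, sd = tables.scaling["partner_prev_dev"]
        truth = study.truth_trips[["pair_id", "season", "bird_id", "duration_h", "dev_h"]]
        for stage in ("incubation", "brooding"):
            tab = tables.table(stage)
            merged = tab.merge(truth, on=["pair_id", "season", "bird_id", "duration_h"])
            assert len(merged) == len(tab)
            assert np.allclose(merged["partner_prev_dev"] * sd + mean, merged["dev_h"])

    def test_pooled_scaling_before_stage_split(self, built_tables):
        # scaled columns reconstruct from one shared (mean, sd) pair, and
        # those moments are the pooled pre-exclusion moments of the data
        cfg, study, trips, tables = built_tables
        mean, sd = tables.scaling["date"]
        pooled = []
        for stage in ("incubation", "brooding"):
            tab = tables.table(stage)
            raw = tab["date"] * sd + mean
            assert (raw >= 0).all() and (raw <= 130).all()
            pooled.append(tab["date"])
        # moments computed before the row exclusions, so the retained rows
        # need not be exactly mean 0 / sd 1 -- but must be close
        z = pd.concat(pooled)
        assert abs(z.mean()) < 0.2
        assert 0.8 < z.std() < 1.2

    def test_first_brooding_trip_excluded_per_pair_season(self):
        # a pair with 1 incubation and 4 brooding focal trips keeps 3
        # brooding rows (the partner history makes later devs defined)
        focal = make_trips([100.0, 60.0, 60.0, 60.0, 60.0], bird_id="F",
                           gap_h=60.0, source="observed")
        partner_starts = focal["end"] + pd.Timedelta(hours=1)
        partner = pd.concat(
            [make_trips([59.0], bird_id="M", start=s, source="inferred")
             for s in partner_starts[:-1]],
            ignore_index=True,
        )
        trips = pd.concat([focal, partner], ignore_index=True)
        # hatch falls between the focal's incubation trip and the partner's
        # first (inferred) trip, so all four partner trips are brooding
        hatch = focal["end"].iloc[0] + pd.Timedelta(minutes=30)
        trips["stage"] = np.where(trips["start"] < hatch, "incubation", "brooding")
        pairs = pd.DataFrame(
            [{"pair_id": "P0", "season": 2010, "bird_id_1": "F", "bird_id_2": "M",
              "new_partner": False}]
        )
        traits = pd.DataFrame(
            [{"bird_id": "F", "sex": "F", "age": 20},
             {"bird_id": "M", "sex": "M", "age": 22}]
        )
        bold = pd.DataFrame(
            [{"bird_id": "F", "boldness_score": 0.5},
             {"bird_id": "M", "boldness_score": -0.5}]
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny table: unscalable columns etc.
            tables = build_model_table(trips, pairs, traits, bold)
        assert len(tables.brooding) == 3
        assert tables.exclusions["first_brooding_trip"] == 1

    def test_row_accounting_no_silent_drops(self, built_tables):
        cfg, study, trips, tables = built_tables
        retained = len(tables.incubation) + len(tables.brooding)
        assert retained + sum(tables.exclusions.values()) == len(trips)

    def test_quadratic_age_is_square_of_scaled_linear(self, built_tables):
        *_, tables = built_tables
        for stage in ("incubation", "brooding"):
            tab = tables.table(stage)
            assert np.allclose(tab["focal_age2"], tab["focal_age"] ** 2)
            assert np.allclose(tab["partner_age2"], tab["partner_age"] ** 2)

    def test_unknown_bird_rejected(self, built_tables):
        cfg, study, trips, tables = built_tables
        bad = trips.copy()
        bad.loc[bad.index[0], "bird_id"] = "GHOST"
        with pytest.raises(ValueError, match="unknown pair members"):
            build_model_table(bad, study.pairs, study.traits, study.true_boldness)

    def test_drop_birds_excluded_entirely(self, built_tables):
        cfg, study, trips, tables = built_tables
        bird = tables.incubation["bird_id"].iloc[0]
        reduced = build_model_table(
            trips, study.pairs, study.traits, study.true_boldness, drop_birds=[bird]
        )
        assert bird not in set(reduced.incubation["bird_id"])
        assert reduced.exclusions["second_tagged_bird"] > 0
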