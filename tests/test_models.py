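"""AICc machinery, subset enumeration, nested exclusion, averaging, LMM fits."""

import itertools

import numpy as np
import pandas as pd
import pytest

from albicoord.features import build_model_table
from albicoord.models import (
    FitResult,
    ModelSpec,
    aicc,
    akaike_weights,
    best_set,
    enumerate_specs,
    exclude_nested,
    fit_lmm,
    model_average,
    r2_nakagawa,
    rank_all,
    required_terms,
)
from albicoord.simulate import SimulationConfig, simulate_study
from conftest import low_noise_config


class TestAicc:
    def test_closed_form(self):
        assert aicc(-5.0, 3, 10) == pytest.approx(20.0)

    def test_large_n_limit_is_aic(self):
        assert aicc(-5.0, 3, 10**9) == pytest.approx(-2 * -5.0 + 2 * 3, abs=1e-6)

    def test_smallest_valid_n_doubles_penalty(self):
        # n = k + 2 makes the correction 2k(k+1)/(n-k-1) = 2k(k+1)
        k = 4
        assert aicc(0.0, k, k + 2) == pytest.approx(2 * k + 2 * k * (k + 1))

    def test_undefined_below_minimum_n(self):
        with pytest.raises(ValueError, match="AICc undefined"):
            aicc(-5.0, 3, 4)


class TestEnumerateSpecs:
    def test_quadratic_requires_linear(self):
        specs = enumerate_specs(("focal_age", "focal_age2"))
        assert {s.terms for s in specs} == {
            (),
            ("focal_age",),
            ("focal_age", "focal_age2"),
        }

    def test_interaction_requires_both_mains(self):
        specs = enumerate_specs(("focal_boldness", "sex", "focal_boldness:sex"))
        assert len(specs) == 5  # of the 8 subsets, 3 violate marginality

    def test_matches_brute_force_filter(self):
        terms = (
            "partner_age",
            "partner_age2",
            "partner_boldness",
            "partner_boldness:partner_age",
            "partner_prev_dev",
        )
        specs = {s.terms for s in enumerate_specs(terms)}
        brute = set()
        for r in range(len(terms) + 1):
            for combo in itertools.combinations(terms, r):
                if all(required_terms(t) <= set(combo) for t in combo):
                    brute.add(tuple(sorted(combo)))
        assert specs == brute

    def test_no_spec_violates_marginality(self):
        for s in enumerate_specs(
            ("focal_age", "focal_age2", "partner_prev_dev", "focal_age2:partner_prev_dev")
        ):
            for t in s.terms:
                assert required_terms(t) <= set(s.terms)

    def test_invalid_spec_construction_rejected(self):
        with pytest.raises(ValueError, match="marginality"):
            ModelSpec(("focal_age2",))

    def test_limit_guards_explosions(self):
        with pytest.raises(ValueError, match="candidate models"):
            enumerate_specs([f"t{i}" for i in range(12)], limit=100)


def fake_fit(terms, aicc_value, estimates=None, ses=None):
    names = ["Intercept"] + sorted(terms)
    est = dict(estimates or {})
    se = dict(ses or {})
    return FitResult(
        spec=ModelSpec(tuple(terms)),
        params=pd.Series({t: est.get(t, 1.0) for t in names}),
        bse=pd.Series({t: se.get(t, 0.1) for t in names}),
        vcomp={"pair": 1.0, "pair_slope": 0.0, "year": 0.0},
        resid_var=1.0,
        llf=0.0,
        k=len(names) + 4,
        n=100,
        aicc=aicc_value,
        converged=True,
        singular=False,
        method="ml",
        var_fixed=2.0,
        mean_dev_sq=1.0,
    )


class TestBestSet:
    def test_delta_two_strict(self):
        fits = [fake_fit(["date"], a) for a in (100.0, 101.9, 102.1)]
        assert [f.aicc for f in best_set(fits)] == [100.0, 101.9]

    def test_single_model_is_its_own_set(self):
        fits = [fake_fit(["date"], 50.0)]
        assert best_set(fits) == fits

    def test_boundary_tie_excluded(self):
        fits = [fake_fit(["date"], 100.0), fake_fit(["sex"], 102.0)]
        assert len(best_set(fits)) == 1


class TestExcludeNested:
    def test_complex_version_of_better_simple_model_removed(self):
        a = fake_fit(["date"], 100.0)
        b = fake_fit(["date", "sex"], 101.0)
        assert exclude_nested([a, b]) == [a]

    def test_better_complex_model_keeps_both(self):
        a = fake_fit(["date"], 101.0)
        b = fake_fit(["date", "sex"], 100.0)
        assert set(id(f) for f in exclude_nested([a, b])) == {id(a), id(b)}

    def test_chain_collapses_to_simplest(self):
        chain = [
            fake_fit([], 100.0),
            fake_fit(["date"], 100.5),
            fake_fit(["date", "sex"], 101.0),
        ]
        kept = exclude_nested(chain)
        assert len(kept) == 1 and kept[0].spec.terms == ()

    def test_matches_pairwise_brute_force_on_random_sets(self):
        rng = np.random.default_rng(3)
        pool = ["date", "sex", "focal_boldness", "partner_boldness", "partner_prev_dev"]
        for _ in range(200):
            fits = []
            seen = set()
            for _ in range(rng.integers(2, 7)):
                terms = tuple(
                    sorted(rng.choice(pool, size=rng.integers(0, 4), replace=False))
                )
                if terms in seen:
                    continue
                seen.add(terms)
                fits.append(fake_fit(list(terms), float(rng.uniform(100, 104))))
            kept = exclude_nested(fits)
            brute = [
                f
                for f in fits
                if not any(
                    set(g.spec.terms) < set(f.spec.terms) and g.aicc < f.aicc
                    for g in fits
                )
            ]
            assert {id(f) for f in kept} == {id(f) for f in brute}


class TestModelAverage:
    def test_weights_for_delta_zero_two(self):
        w = akaike_weights([100.0, 102.0])
        assert w[0] == pytest.approx(0.731, abs=5e-4)
        assert w[1] == pytest.approx(0.269, abs=5e-4)

    def test_single_model_average_is_identity(self):
        f = fake_fit(["date", "sex"], 100.0, estimates={"date": 2.5, "sex": -1.4})
        avg = model_average([f])
        assert avg.weights[0] == pytest.approx(1.0)
        assert avg.estimate("date") == (pytest.approx(2.5), pytest.approx(0.1))

    def test_term_with_common_estimate_averages_to_it(self):
        fits = [
            fake_fit(["date"], 100.0, estimates={"date": 0.7}),
            fake_fit(["date", "sex"], 101.0, estimates={"date": 0.7}),
        ]
        avg = model_average(fits)
        est, se = avg.estimate("date")
        assert est == pytest.approx(0.7)

    def test_presence_weight_and_absent_term(self):
        fits = [fake_fit(["date"], 100.0), fake_fit(["sex"], 100.0)]
        avg = model_average(fits)
        row = avg.table[avg.table["term"] == "date"]
        assert row["presence_weight"].iloc[0] == pytest.approx(0.5)
        assert avg.estimate("partner_prev_dev") is None

    def test_interaction_terms_flagged_suppressed(self):
        fits = [fake_fit(["focal_boldness", "sex", "focal_boldness:sex"], 100.0)]
        avg = model_average(fits)
        flagged = set(avg.table.loc[avg.table["suppressed"], "term"])
        assert flagged == {"focal_boldness", "sex", "focal_boldness:sex"}

    def test_unconditional_se_combines_spread(self):
        # equal weights, estimates 1 and 3, within-model SEs 0.1:
        # sqrt(mean(se^2 + (b - 2)^2)) = sqrt(0.01 + 1)
        fits = [
            fake_fit(["date"], 100.0, estimates={"date": 1.0}),
            fake_fit(["date", "sex"], 100.0, estimates={"date": 3.0}),
        ]
        est, se = model_average(fits).estimate("date")
        assert est == pytest.approx(2.0)
        assert se == pytest.approx(np.sqrt(0.01 + 1.0))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            model_average([])


class TestR2Nakagawa:
    def test_closed_form(self):
        f = fake_fit(["date"], 100.0)  # var_fixed 2, pair 1, resid 1
        marginal, conditional = r2_nakagawa(f)
        assert (marginal, conditional) == (pytest.approx(0.5), pytest.approx(0.75))

    def test_zero_fixed_variance(self):
        f = fake_fit([], 100.0)
        f.var_fixed = 0.0
        assert r2_nakagawa(f)[0] == 0.0

    def test_bounds_on_real_fit(self, model_table):
        fit = fit_lmm(model_table, ("sex", "partner_prev_dev"))
        m, c = r2_nakagawa(fit)
        assert 0.0 <= m <= c <= 1.0


@pytest.fixture(scope="module")
def model_table():
    cfg = low_noise_config(n_pairs=25, n_years=3)
    study = simulate_study(cfg, np.random.default_rng(31))
    tables = build_model_table(
        study.analysis_trips(), study.pairs, study.traits, study.true_boldness
    )
    return tables.incubation


class TestFitLmm:
    def test_zero_random_variance_recovered(self):
        # data generated with no pair/year/slope variance: the residual
        # variance matches the generative sigma^2 and the components ~ 0
        beta = {k: 0.0 for k in SimulationConfig().beta}
        cfg = SimulationConfig(
            n_pairs=40, n_years=4, n_dual_tagged=0,
            sigma_pair_intercept=0.0, sigma_pair_slope=0.0, sigma_year=0.0,
            sigma_resid=1.0, resid_truncate_sd=30.0,
            deployment_offset_min_d=0.0, deployment_offset_max_d=0.0,
            beta=beta,
        )
        study = simulate_study(cfg, np.random.default_rng(41))
        tables = build_model_table(
            study.analysis_trips(), study.pairs, study.traits, study.true_boldness
        )
        fit = fit_lmm(tables.incubation, ())
        assert fit.resid_var == pytest.approx(1.0, rel=0.15)
        assert all(v < 0.05 for v in fit.vcomp.values())
        assert fit.singular  # zero variance components flagged

    def test_refit_is_deterministic(self, model_table):
        a = fit_lmm(model_table, ("sex", "date"))
        b = fit_lmm(model_table, ("sex", "date"))
        assert a.aicc == b.aicc
        pd.testing.assert_series_equal(a.params, b.params)

    def test_k_counts_fixed_plus_variance_components(self, model_table):
        fit = fit_lmm(model_table, ("sex", "date"))
        assert fit.k == 3 + 3 + 1  # fixed (incl intercept) + 3 VCs + residual

    def test_reml_and_ml_agree_on_strong_effects(self, model_table):
        ml = fit_lmm(model_table, ("sex",), method="ml")
        reml = fit_lmm(model_table, ("sex",), method="reml")
        assert ml.params["sex"] == pytest.approx(reml.params["sex"], abs=0.05)

    def test_invalid_method_rejected(self, model_table):
        with pytest.raises(ValueError, match="method"):
            fit_lmm(model_table, (), method="mcmc")


class TestRankAll:
    def test_ranked_table_sorted_and_weighted(self, model_table):
        ranked = rank_all(model_table, ("sex", "date"))
        assert ranked.n_candidates == 4
        assert (np.diff(ranked.table["aicc"]) >= 0).all()
        assert ranked.table["weight"].sum() == pytest.approx(1.0)
        assert ranked.table["delta"].iloc[0] == 0.0
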