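"""Design construction, model fitting, bootstrap and sensitivity analyses."""

import numpy as np
import pandas as pd
import pytest

import ppgr
from ppgr.centering import person_center
from ppgr.exposures import EXPOSURES
from ppgr.meals import build_meal_records, filter_participants, qualify_meals
from ppgr.models import (COVARIATE_TERMS, MEAL_TIME_TERMS, ModelSpec,
                         association_table, bootstrap_ci, build_design,
                         fit_random_intercept, interaction_test, stratified_fit)
from ppgr.pipeline import build_events, compute_meal_features, RunConfig


@pytest.fixture(scope="module")
def events():
    """Analysis table for a 50-participant cohort with default truth."""
    bundle = ppgr.generate_cohort(ppgr.SimConfig(n_participants=50, seed=31))
    meals, _ = build_meal_records(bundle.ema)
    qual = qualify_meals(meals, bundle.traces)
    retained = filter_participants(qual)
    am = meals[meals.meal_id.isin(qual.loc[qual.qualified, "meal_id"])
               & meals.participant_id.isin(retained)].reset_index(drop=True)
    feats = compute_meal_features(am, bundle.traces, bundle.epochs,
                                  bundle.sleep, RunConfig())
    ev = build_events(am, feats, bundle.participants)
    ev = ev.dropna(subset=["iauc_2h", "preprandial_mean_2h", "pp_lpa_h",
                           "sleep_h"]).reset_index(drop=True)
    return person_center(ev, EXPOSURES)


class TestBuildDesign:
    def test_full_spec_term_counting(self, events):
        d = build_design(events, ModelSpec(mode="full"))
        within = [c for c in d.X.columns if c.endswith("_within")]
        between = [c for c in d.X.columns if c.endswith("_between")]
        assert len(within) == 21 and len(between) == 21
        assert set(MEAL_TIME_TERMS) <= set(d.X.columns)
        assert "intercept" in d.X.columns

    def test_basic_spec_single_exposure_pair(self, events):
        d = build_design(events, ModelSpec(mode="basic",
                                           exposures=["refined_grains"]))
        within = [c for c in d.X.columns if c.endswith("_within")]
        between = [c for c in d.X.columns if c.endswith("_between")]
        assert within == ["refined_grains_within"]
        assert between == ["refined_grains_between"]
        assert set(COVARIATE_TERMS) - set(d.dropped_terms) <= set(d.X.columns)

    def test_basic_mode_requires_one_exposure(self):
        with pytest.raises(ValueError):
            ModelSpec(mode="basic", exposures=["eggs", "dairy"])

    def test_unknown_exposure_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(exposures=["pizza"])

    def test_rank_deficient_design_raises_with_names(self, events):
        ev = events.copy()
        ev["refined_grains_between"] = 2.0 * ev["whole_grains_between"]
        with pytest.raises(ValueError, match="collinear"):
            build_design(ev, ModelSpec(mode="full"))

    def test_complete_case_rows_counted(self, events):
        ev = events.copy()
        ev.loc[ev.index[:7], "sleep_h_within"] = np.nan
        d = build_design(ev, ModelSpec(mode="full"))
        assert d.n_dropped == 7


class TestFit:
    def test_engines_agree(self, events):
        d = build_design(events, ModelSpec(mode="basic",
                                           exposures=["refined_grains"]))
        fast = fit_random_intercept(d, engine="fast").set_index("term")
        sm = fit_random_intercept(d, engine="statsmodels").set_index("term")
        np.testing.assert_allclose(fast["beta"], sm.loc[fast.index, "beta"],
                                   rtol=1e-4, atol=1e-3)

    def test_row_permutation_invariance(self, events):
        spec = ModelSpec(mode="basic", exposures=["pp_mvpa_h"])
        d1 = build_design(events, spec)
        shuffled = events.sample(frac=1.0, random_state=1).reset_index(drop=True)
        d2 = build_design(shuffled, spec)
        f1 = fit_random_intercept(d1).set_index("term")["beta"]
        f2 = fit_random_intercept(d2).set_index("term")["beta"]
        np.testing.assert_allclose(f1, f2[f1.index], rtol=1e-6, atol=1e-6)

    def test_within_estimates_near_truth(self, events):
        d = build_design(events, ModelSpec(mode="full"))
        fit = fit_random_intercept(d).set_index("term")
        est = fit.loc["refined_grains_within"]
        assert est["beta"] == pytest.approx(46.2, abs=4 * est["se"] + 2)

    def test_level_labels(self, events):
        d = build_design(events, ModelSpec(mode="full"))
        fit = fit_random_intercept(d)
        lv = fit.set_index("term")["level"]
        assert lv["refined_grains_within"] == "within"
        assert lv["refined_grains_between"] == "between"
        assert lv["age"] == "context"


class TestBootstrap:
    def test_same_seed_reproduces_cis(self, events):
        spec = ModelSpec(mode="basic", exposures=["refined_grains"])
        d = build_design(events, spec)
        ci1 = bootstrap_ci(d, B=200, seed=5)
        ci2 = bootstrap_ci(d, B=200, seed=5)
        pd.testing.assert_frame_equal(ci1, ci2)

    def test_ci_contains_point_estimate_for_strong_effect(self, events):
        spec = ModelSpec(mode="basic", exposures=["refined_grains"])
        d = build_design(events, spec)
        beta = fit_random_intercept(d).set_index("term").loc[
            "refined_grains_within", "beta"]
        ci = bootstrap_ci(d, B=200, seed=6).set_index("term")
        lo, hi = ci.loc["refined_grains_within", ["ci_low", "ci_high"]]
        assert lo <= beta <= hi

    def test_width_shrinks_with_cohort_size(self):
        # pure random-intercept data, intercept-only model
        def width(G, seed):
            rng = np.random.default_rng(seed)
            g = np.repeat([f"P{i}" for i in range(G)], 6)
            df = pd.DataFrame({
                "participant_id": g,
                "iauc_2h": (rng.normal(0, 1, G))[
                    np.repeat(np.arange(G), 6)] + rng.normal(0, 2, 6 * G),
                "eggs": rng.integers(0, 2, 6 * G).astype(float),
                "preprandial_mean_2h": 5.4,
            })
            df = person_center(df, ["eggs"])
            spec = ModelSpec(mode="basic", exposures=["eggs"],
                             include_meal_time=False,
                             covariates=["preprandial_mean_2h"])
            d = build_design(df, spec)
            ci = bootstrap_ci(d, B=200, seed=seed).set_index("term")
            lo, hi = ci.loc["eggs_within", ["ci_low", "ci_high"]]
            return hi - lo
        w_small = np.mean([width(30, s) for s in (0, 1)])
        w_large = np.mean([width(120, s) for s in (2, 3)])
        assert w_large < 0.75 * w_small

    def test_too_few_replicates_rejected(self, events):
        d = build_design(events, ModelSpec(mode="basic", exposures=["eggs"]))
        with pytest.raises(ValueError):
            bootstrap_ci(d, B=50)


class TestInteractions:
    def test_interaction_terms_present_and_flagged(self, events):
        res = interaction_test(events, "sex")
        assert (res["term"].str.contains(":sex_male")).all()
        assert {"significant", "marginal"} <= set(res.columns)
        # between-person exposures are excluded from interaction models
        assert not res["term"].str.contains("_between").any()

    def test_constant_modifier_rejected(self, events):
        ev = events[events["sex"] == "female"]
        with pytest.raises(ValueError):
            interaction_test(ev, "sex")


class TestStratified:
    def test_bookkeeping_matches_rule_counts(self, events):
        strat = stratified_fit(events, "prediabetes")
        n_pred = events.loc[events["prediabetes"].astype(bool),
                            "participant_id"].nunique()
        if "prediabetes" in strat:
            assert strat["prediabetes"].attrs["n_groups"] == n_pred

    def test_stratifier_absent_from_covariates(self, events):
        strat = stratified_fit(events, "sex")
        for df in strat.values():
            assert not df["term"].str.contains("sex_male").any()
            assert not df["term"].str.contains("_between").any()

    def test_identical_truth_gives_overlapping_stratum_cis(self, events):
        strat = stratified_fit(events, "sex")
        z = 1.96
        rows = {}
        for name, df in strat.items():
            r = df.set_index("term").loc["refined_grains_within"]
            rows[name] = (r["beta"] - z * r["se"], r["beta"] + z * r["se"])
        (lo1, hi1), (lo2, hi2) = rows.values()
        assert max(lo1, lo2) <= min(hi1, hi2)

    def test_unknown_stratifier_rejected(self, events):
        with pytest.raises(ValueError):
            stratified_fit(events, "bmi")


def test_association_table_shape(events):
    tab = association_table(events, B=0, run_basic=True)
    terms = set(tab["term"])
    assert {f"{e}_within" for e in EXPOSURES} <= terms
    assert set(MEAL_TIME_TERMS) <= terms
    assert {"basic_beta", "full_beta", "full_ci_low", "full_ci_high",
            "full_p"} <= set(tab.columns)
    ok = tab["full_ci_low"] <= tab["full_beta"]
    assert ok.all() and (tab["full_beta"] <= tab["full_ci_high"]).all()
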