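"""The synthetic-cohort generator: determinism, calibration, closed loop."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

import ppgr
from ppgr.cgm import iauc_2h
from ppgr.cohort import (GroundTruth, SimConfig, default_ground_truth,
                         generate_cohort, intended_iauc, null_ground_truth)
from ppgr.exposures import EXPOSURES, TIME_CATEGORIES
from ppgr.meals import build_meal_records


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        cfg = SimConfig(n_participants=4, seed=17)
        b1, b2 = generate_cohort(cfg), generate_cohort(SimConfig(n_participants=4,
                                                                 seed=17))
        pd.testing.assert_frame_equal(b1.ema, b2.ema)
        pd.testing.assert_frame_equal(b1.meal_truth, b2.meal_truth)
        pd.testing.assert_frame_equal(b1.participants, b2.participants)
        for pid in b1.traces:
            np.testing.assert_array_equal(b1.traces[pid].values,
                                          b2.traces[pid].values)
            np.testing.assert_array_equal(b1.epochs[pid].enmo,
                                          b2.epochs[pid].enmo)

    def test_adding_participants_preserves_existing_ones(self):
        b_small = generate_cohort(SimConfig(n_participants=3, seed=23))
        b_large = generate_cohort(SimConfig(n_participants=6, seed=23))
        for pid in b_small.traces:
            np.testing.assert_array_equal(b_small.traces[pid].values,
                                          b_large.traces[pid].values)
        pd.testing.assert_frame_equal(
            b_small.ema, b_large.ema[b_large.ema.participant_id.isin(
                b_small.traces)].reset_index(drop=True))

    def test_different_seeds_differ(self):
        b1 = generate_cohort(SimConfig(n_participants=3, seed=1))
        b2 = generate_cohort(SimConfig(n_participants=3, seed=2))
        assert not b1.meal_truth["intended_iauc"].equals(
            b2.meal_truth["intended_iauc"])


class TestConfigValidation:
    def test_overlapping_ema_windows_rejected(self):
        cfg = SimConfig(ema_windows=((8.0, 10.0), (9.5, 11.0)))
        with pytest.raises(ValueError):
            cfg.validate()

    def test_window_outside_day_rejected(self):
        cfg = SimConfig(ema_windows=((5.0, 7.0),))
        with pytest.raises(ValueError):
            cfg.validate()

    def test_unknown_effect_name_rejected(self):
        with pytest.raises(ValueError):
            GroundTruth(within_effects={"pizza": 1.0})


class TestTraces:
    def test_trace_span_and_spacing(self, clean_cohort):
        cfg = clean_cohort.config
        for trace in clean_cohort.traces.values():
            lo, hi = trace.span
            assert hi - lo >= cfg.n_days * 86400.0
            steps = np.diff(trace.times)
            assert np.allclose(steps, 900.0)

    def test_participant_count_and_streams(self, small_cohort):
        assert len(small_cohort.participants) == 12
        assert set(small_cohort.traces) == set(small_cohort.epochs)
        assert small_cohort.sleep["participant_id"].nunique() == 12

    def test_prediabetes_rule_consistent(self, small_cohort):
        p = small_cohort.participants
        rule = (p["fpg"] >= 5.6) | (p["hba1c"] >= 5.7)
        assert (p["prediabetes"] == rule).all()
        assert p["age"].between(21, 69).all()


class TestIntendedIauc:
    def test_null_everything_gives_zero(self):
        truth = null_ground_truth()
        truth.iauc_intercept = 0.0
        expo = {e: 0.0 for e in EXPOSURES}
        assert intended_iauc(expo, truth) == 0.0

    def test_single_effect_passthrough(self):
        zeros = {e: 0.0 for e in EXPOSURES}
        truth = GroundTruth(within_effects={**zeros, "refined_grains": 46.2},
                            between_effects=dict(zeros),
                            time_of_day_effects={TIME_CATEGORIES[1]: 0.0,
                                                 TIME_CATEGORIES[2]: 0.0},
                            iauc_intercept=0.0, residual_sd=0.0)
        expo = {**zeros, "refined_grains": 1.0}
        assert intended_iauc(expo, truth) == pytest.approx(46.2)

    def test_negative_predictor_truncated_at_zero(self):
        truth = null_ground_truth()
        truth.iauc_intercept = -50.0
        assert intended_iauc({e: 0.0 for e in EXPOSURES}, truth) == 0.0

    def test_kernel_is_a_unit_area_bump(self):
        truth = default_ground_truth()
        area, _ = integrate.quad(lambda u: truth.kernel_pdf(u), 0, 120)
        assert area == pytest.approx(1.0, abs=1e-8)
        u = np.linspace(0, 120, 500)
        k = truth.kernel_pdf(u)
        assert (k >= 0).all()
        assert 30 <= u[np.argmax(k)] <= 60          # peak mid-window
        assert k[0] == 0.0 and k[-1] == pytest.approx(0.0, abs=1e-12)

    def test_recomputed_iauc_recovers_intended_value(self, clean_cohort):
        """Closed loop: trapezoid on the generated trace returns the target."""
        mt = clean_cohort.meal_truth
        daytime = mt[mt.time_category.notna()]
        for rec in daytime.itertuples():
            v = iauc_2h(clean_cohort.traces[rec.participant_id],
                        rec.meal_timestamp)
            if rec.intended_iauc >= 20.0:
                assert v == pytest.approx(rec.intended_iauc, rel=0.05)
            else:
                assert v == pytest.approx(rec.intended_iauc, abs=2.0)


class TestCalibration:
    def test_summary_levels_match_design_targets(self, small_cohort):
        mt = small_cohort.meal_truth
        day = mt[mt.time_category.notna()]
        assert day["intended_iauc"].mean() == pytest.approx(137.4, abs=25)
        assert day["sleep_h"].mean() == pytest.approx(5.5, abs=0.7)
        assert day["daily_lpa_h"].mean() == pytest.approx(2.8, abs=0.5)
        assert day["daily_mvpa_h"].mean() == pytest.approx(1.6, abs=0.4)
        shares = day["time_category"].value_counts(normalize=True)
        assert shares["afternoon_1200_1800"] == pytest.approx(0.36, abs=0.08)

    def test_ema_roundtrip_reconstructs_meal_timestamps(self, small_cohort):
        meals, errors = build_meal_records(small_cohort.ema)
        assert errors.empty
        logged = small_cohort.meal_truth.query("logged")
        merged = meals.merge(logged[["meal_id"]], on="meal_id", how="outer",
                             indicator=True)
        assert (merged["_merge"] == "both").all()

    def test_vigorous_fraction_of_mvpa(self, small_cohort):
        enmo = np.concatenate([s.enmo for s in small_cohort.epochs.values()])
        mvpa = enmo[enmo >= 100.0]
        frac = (mvpa >= 400.0).mean()
        assert frac == pytest.approx(0.03, abs=0.01)

    def test_within_share_monotone_in_configured_ratio(self):
        """More configured night-to-night sleep noise -> larger realized
        within-person variance fraction of the sleep exposure."""
        fracs = []
        for wsd in (0.3, 1.1, 2.2):
            cfg = SimConfig(n_participants=25, seed=77, sleep_within_sd=wsd)
            mt = generate_cohort(cfg).meal_truth
            day = mt[mt.time_category.notna()]
            dev = day["sleep_h"] - day.groupby("participant_id")[
                "sleep_h"].transform("mean")
            between = day.groupby("participant_id")["sleep_h"].mean().var()
            fracs.append(dev.var() / (dev.var() + between))
        assert fracs[0] < fracs[1] < fracs[2]


def test_bundle_write_roundtrip(tmp_path, clean_cohort):
    clean_cohort.write(tmp_path, include_epochs=False)
    for name in ("participants.csv", "ema_responses.csv", "cgm.csv",
                 "sleep_windows.csv", "ground_truth.json", "sim_config.yaml",
                 "meal_truth.csv"):
        assert (tmp_path / name).exists()
    cgm = pd.read_csv(tmp_path / "cgm.csv", parse_dates=["timestamp"])
    pid = clean_cohort.participants["participant_id"].iloc[0]
    back = ppgr.GlucoseTrace.from_frame(cgm, pid)
    np.testing.assert_allclose(back.values, clean_cohort.traces[pid].values)
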