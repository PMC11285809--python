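import numpy as np
import pandas as pd
import pytest

import boarsleep as bs
from boarsleep.synthetic import (
    BehaviourSchedule,
    ScheduleEntry,
    make_dhglm_design,
    schedule_to_labels,
)


class TestScheduleValidation:
    def test_overlap_rejected(self):
        t = pd.Timestamp("2020-06-01")
        entries = [
            ScheduleEntry(t, t + pd.Timedelta(minutes=10), "active"),
            ScheduleEntry(t + pd.Timedelta(minutes=5), t + pd.Timedelta(minutes=15), "active"),
        ]
        with pytest.raises(ValueError, match="overlap"):
            BehaviourSchedule(entries=entries)

    def test_gap_rejected(self):
        t = pd.Timestamp("2020-06-01")
        entries = [
            ScheduleEntry(t, t + pd.Timedelta(minutes=10), "active"),
            ScheduleEntry(t + pd.Timedelta(minutes=11), t + pd.Timedelta(minutes=20), "active"),
        ]
        with pytest.raises(ValueError, match="gap"):
            BehaviourSchedule(entries=entries)

    def test_zero_length_rejected(self):
        t = pd.Timestamp("2020-06-01")
        with pytest.raises(ValueError, match="zero"):
            BehaviourSchedule(entries=[ScheduleEntry(t, t, "active")])

    def test_unknown_behaviour_rejected(self):
        t = pd.Timestamp("2020-06-01")
        with pytest.raises(ValueError, match="unknown"):
            BehaviourSchedule(entries=[ScheduleEntry(t, t + pd.Timedelta(minutes=1), "flying")])

    def test_frame_round_trip(self, mixed_schedule):
        df = mixed_schedule.to_frame()
        back = BehaviourSchedule.from_frame(df)
        assert back.entries == mixed_schedule.entries


class TestTraceGeneration:
    def test_noiseless_still_magnitude_exactly_one(self, noiseless_cfg):
        sch = bs.make_schedule([("sternal_still", 60)])
        trace = bs.generate_trace(sch, noiseless_cfg)
        mags = np.linalg.norm(trace.acc, axis=1)
        assert np.allclose(mags, 1.0, atol=1e-12)

    def test_same_seed_byte_identical(self, mixed_schedule):
        cfg = bs.TraceGenConfig(seed=99)
        a = bs.generate_trace(mixed_schedule, cfg)
        b = bs.generate_trace(mixed_schedule, cfg)
        assert np.array_equal(a.acc, b.acc)
        assert np.array_equal(a.time, b.time)

    def test_different_seed_differs(self, mixed_schedule):
        a = bs.generate_trace(mixed_schedule, bs.TraceGenConfig(seed=1))
        b = bs.generate_trace(mixed_schedule, bs.TraceGenConfig(seed=2))
        assert not np.array_equal(a.acc, b.acc)

    def test_active_entries_exceed_stillness_threshold(self, noiseless_cfg):
        sch = bs.make_schedule([("active", 10)])
        trace = bs.generate_trace(sch, noiseless_cfg)
        kin = bs.compute_kinematics(trace)
        assert np.mean(kin.vedba_smoothed > 0.2) > 0.9

    def test_sternal_orientation_classified_sternal(self, mixed_kin):
        posture = bs.classify_posture(mixed_kin)
        # minute 15 sits mid-way through the first sternal entry
        i = 15 * 60 * 20
        assert posture[i] == bs.classify.STERNAL

    def test_sample_count_matches_schedule_span(self, mixed_schedule, noiseless_cfg):
        trace = bs.generate_trace(mixed_schedule, noiseless_cfg)
        start, end = mixed_schedule.span
        assert len(trace) == round((end - start).total_seconds() * 20)

    def test_entries_too_short_for_ramps_rejected(self):
        sch = bs.make_schedule([("active", 0.03), ("sternal_still", 0.03), ("active", 0.03)])
        with pytest.raises(ValueError, match="too short"):
            bs.generate_trace(sch, bs.TraceGenConfig(seed=0))


class TestTruthBouts:
    def test_trim_rules(self):
        sch = bs.make_schedule([("active", 10), ("sternal_still", 12), ("active", 10)])
        bouts = bs.schedule_to_truth_bouts(sch)
        assert len(bouts) == 1
        assert bouts[0].duration == pytest.approx(7 * 60)

    def test_short_period_dropped(self):
        sch = bs.make_schedule([("active", 10), ("sternal_still", 4), ("active", 10)])
        assert bs.schedule_to_truth_bouts(sch) == []

    def test_adjacent_recumbent_entries_merge(self):
        # 10 min sternal + 10 min lateral merge, then lose 5 min -> 15 min
        sch = bs.make_schedule(
            [("active", 5), ("sternal_still", 10), ("lateral_still", 10), ("active", 5)]
        )
        bouts = bs.schedule_to_truth_bouts(sch)
        assert len(bouts) == 1
        assert bouts[0].duration == pytest.approx(15 * 60)

    def test_idempotent_under_entry_resorting(self, mixed_schedule):
        shuffled = BehaviourSchedule(
            entries=list(reversed(mixed_schedule.entries)),
            animal_id=mixed_schedule.animal_id,
        )
        assert bs.schedule_to_truth_bouts(shuffled) == bs.schedule_to_truth_bouts(
            mixed_schedule
        )

    def test_labels_cover_schedule(self, mixed_schedule):
        labels = schedule_to_labels(mixed_schedule)
        assert len(labels) == len(mixed_schedule.entries)
        assert set(labels["truth_class"]) == {"recumbent", "other"}


class TestDhglmSimulation:
    def test_degenerate_hierarchy_is_homoscedastic(self):
        cfg = bs.DhglmSimConfig(
            n_individuals=50,
            days_per_individual=200,
            beta_mean={"intercept": 2.0},
            beta_sigma={"intercept": 0.0},
            sd_intercept_mean=0.0,
            sd_intercept_sigma=0.0,
            rho=0.0,
            seed=5,
        )
        data, truth = bs.simulate_dhglm_data(cfg)
        resid = data["y"] - 2.0
        assert resid.mean() == pytest.approx(0.0, abs=0.03)
        assert resid.std() == pytest.approx(1.0, abs=0.02)
        assert np.all(truth["a"] == 0) and np.all(truth["b"] == 0)

    def test_singular_covariance_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            bs.DhglmSimConfig(rho=1.0)

    def test_per_individual_sds_track_latent_b(self):
        cfg = bs.DhglmSimConfig(n_individuals=50, days_per_individual=100, seed=6)
        data, truth = bs.simulate_dhglm_data(cfg)
        # remove the fixed-effect SD structure, then compare per-individual
        # residual spread against the latent sigma intercepts
        Z = np.column_stack([np.ones(len(data)), data["temp"]])
        bs_vec = np.array(list(cfg.beta_sigma.values()))
        scaled = (data["y"] - data["y"].groupby(data["individual"]).transform("mean")) / np.exp(
            Z @ bs_vec
        )
        sds = scaled.groupby(data["individual"]).std()
        r = np.corrcoef(np.log(sds.to_numpy()), truth["b"])[0, 1]
        assert r > 0.8

    def test_deterministic_given_seed(self):
        cfg = bs.DhglmSimConfig(n_individuals=5, days_per_individual=10, seed=9)
        d1, _ = bs.simulate_dhglm_data(cfg)
        d2, _ = bs.simulate_dhglm_data(cfg)
        pd.testing.assert_frame_equal(d1, d2)

    def test_ar1_induces_autocorrelation(self):
        cfg = bs.DhglmSimConfig(
            n_individuals=4, days_per_individual=4000,
            beta_mean={"intercept": 0.0}, beta_sigma={"intercept": 0.0},
            sd_intercept_mean=0.0, sd_intercept_sigma=0.0, rho=0.0,
            ar1=0.6, seed=10,
        )
        data, _ = bs.simulate_dhglm_data(cfg)
        y = data[data["individual"] == "ind000"]["y"].to_numpy()
        r1 = np.corrcoef(y[:-1], y[1:])[0, 1]
        assert r1 == pytest.approx(0.6, abs=0.05)

    def test_design_has_one_row_per_individual_day(self):
        cfg = bs.DhglmSimConfig(n_individuals=7, days_per_individual=13)
        design = make_dhglm_design(cfg)
        assert len(design) == 7 * 13
        assert design.groupby("individual").size().nunique() == 1


def test_boar_schedule_is_valid_and_diurnal():
    sch = bs.boar_schedule(days=2, seed=1)
    truth = bs.schedule_to_truth_bouts(sch)
    assert truth  # a multi-day schedule always yields qualifying bouts
    # recumbent time should concentrate in the daylight window
    day_secs = sum(
        (e.end - e.start).total_seconds()
        for e in sch.entries
        if e.behaviour in ("sternal_still", "lateral_still") and 6 <= e.start.hour < 18
    )
    night_secs = sum(
        (e.end - e.start).total_seconds()
        for e in sch.entries
        if e.behaviour in ("sternal_still", "lateral_still") and not 6 <= e.start.hour < 18
    )
    assert day_secs > night_secs
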