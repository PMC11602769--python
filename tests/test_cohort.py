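"""Synthetic cohort generator: dynamics, emission, missingness, schedule."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from wardsense import (CohortConfig, WardProfile, apply_missingness,
                       emit_sensor_stream, generate_cohort, load_cohort,
                       save_cohort, schedule_assessments,
                       simulate_symptom_trajectory)
from wardsense.cohort import ConfigError
from wardsense.features import total_acceleration
from wardsense.scales import SCALE_NAMES


def _degenerate_config(**kw) -> CohortConfig:
    """All stochastic and diurnal structure switched off."""
    cfg = CohortConfig(n_participants=1, seed=0, **kw)
    cfg.noise_sd = 0.0
    cfg.jump_rate_per_day = 0.0
    cfg.drift_per_day = 0.0
    cfg.init_sd = {s: 0.0 for s in SCALE_NAMES}
    cfg.hr_noise_sd = 0.0
    cfg.circadian_hr_amp = 0.0
    cfg.circadian_act_amp = 0.0
    cfg.hr_activity_gain = 0.0
    cfg.sleep_hr_dip = 0.0
    cfg.p_nosignal = 0.0
    cfg.rater_noise_sd = 0.0
    cfg.coupling = {s: {k: 0.0 for k in ch} for s, ch in cfg.coupling.items()}
    cfg.demo_effects = {s: (0.0, 0.0) for s in SCALE_NAMES}
    return cfg


class TestTrajectory:
    def test_degenerate_dynamics_constant_paths(self):
        cfg = _degenerate_config()
        rng = np.random.default_rng(0)
        ward = cfg.wards[0]
        traj = simulate_symptom_trajectory("p0", cfg, ward, rng, stay_days=7)
        for s in SCALE_NAMES:
            assert np.allclose(traj.latent_severity[s], cfg.init_mean[s])

    def test_determinism(self):
        cfg = CohortConfig(n_participants=1, seed=5)
        ward = cfg.wards[0]
        t1 = simulate_symptom_trajectory("p0", cfg, ward,
                                         np.random.default_rng(42), stay_days=14)
        t2 = simulate_symptom_trajectory("p0", cfg, ward,
                                         np.random.default_rng(42), stay_days=14)
        for s in SCALE_NAMES:
            assert np.array_equal(t1.latent_severity[s], t2.latent_severity[s])

    def test_drift_closed_form(self):
        # drift -0.5/day over a 28-day stay with no noise integrates to -14
        cfg = _degenerate_config()
        cfg.drift_per_day = -0.5
        cfg.init_mean = {"BPRS": 30.0, "HAMA": 10.0, "MADRS": 20.0, "YMRS": 5.0}
        traj = simulate_symptom_trajectory("p0", cfg, cfg.wards[0],
                                           np.random.default_rng(0), stay_days=28)
        assert traj.latent_severity["BPRS"][-1] == pytest.approx(16.0)
        assert traj.latent_severity["MADRS"][-1] == pytest.approx(6.0)
        # YMRS would go to -9 but is clipped at the scale floor
        assert traj.latent_severity["YMRS"][-1] == pytest.approx(0.0)

    def test_nonpositive_stay_rejected(self):
        cfg = CohortConfig(n_participants=1)
        with pytest.raises(ConfigError):
            simulate_symptom_trajectory("p0", cfg, cfg.wards[0],
                                        np.random.default_rng(0), stay_days=0)


class TestEmission:
    def test_flat_config_constant_heart_rate(self):
        cfg = _degenerate_config()
        ward = dataclasses.replace(cfg.wards[0], hr_baseline=64.0)
        traj = simulate_symptom_trajectory("p0", cfg, ward,
                                           np.random.default_rng(0), stay_days=3)
        stream = emit_sensor_stream(traj, ward, np.random.default_rng(0), cfg)
        assert np.allclose(stream.data["heart_rate"], 64.0)

    def test_severity_raises_activity(self):
        # same seed, same config; only the planted mania severity differs
        cfg = _degenerate_config()
        cfg.coupling["YMRS"]["activity"] = 2.0
        ward = cfg.wards[0]
        lo = simulate_symptom_trajectory("p0", cfg, ward,
                                         np.random.default_rng(1), stay_days=5)
        cfg_hi = dataclasses.replace(cfg)  # same object semantics, new init
        cfg_hi.init_mean = dict(cfg.init_mean, YMRS=40.0)
        hi = simulate_symptom_trajectory("p0", cfg_hi, ward,
                                         np.random.default_rng(1), stay_days=5)
        em_lo = emit_sensor_stream(lo, ward, np.random.default_rng(9), cfg)
        em_hi = emit_sensor_stream(hi, ward, np.random.default_rng(9), cfg_hi)
        mag = lambda df: total_acceleration(df["accel_x"], df["accel_y"],
                                            df["accel_z"]).mean()
        assert mag(em_hi.data) > mag(em_lo.data)

    def test_zero_switch_rate_constant_zone(self):
        cfg = _degenerate_config()
        cfg.base_switch_per_hour = 0.0
        traj = simulate_symptom_trajectory("p0", cfg, cfg.wards[0],
                                           np.random.default_rng(0), stay_days=3)
        stream = emit_sensor_stream(traj, cfg.wards[0],
                                    np.random.default_rng(0), cfg)
        assert stream.data["zone"].nunique() == 1

    def test_timestamps_strictly_increasing(self, tiny_cohort):
        for stream in tiny_cohort.streams.values():
            ts = stream.data["timestamp"]
            assert ts.is_monotonic_increasing and not ts.duplicated().any()


class TestMissingness:
    def test_zero_rate_unchanged(self):
        cfg = _degenerate_config()
        ward = dataclasses.replace(cfg.wards[0], missingness_rate=0.0)
        traj = simulate_symptom_trajectory("p0", cfg, ward,
                                           np.random.default_rng(0), stay_days=3)
        stream = emit_sensor_stream(traj, ward, np.random.default_rng(0), cfg)
        out = apply_missingness(stream, ward, np.random.default_rng(0), cfg)
        assert out.missing_fraction == 0.0
        pd.testing.assert_frame_equal(out.data, stream.data)

    def test_realized_fraction_near_target(self):
        cfg = _degenerate_config()
        ward = dataclasses.replace(cfg.wards[0], missingness_rate=0.5)
        traj = simulate_symptom_trajectory("p0", cfg, ward,
                                           np.random.default_rng(0), stay_days=30)
        stream = emit_sensor_stream(traj, ward, np.random.default_rng(0), cfg)
        out = apply_missingness(stream, ward, np.random.default_rng(4), cfg)
        assert abs(out.missing_fraction - 0.5) < 0.05

    def test_same_seed_same_mask(self):
        cfg = _degenerate_config()
        ward = dataclasses.replace(cfg.wards[0], missingness_rate=0.3)
        traj = simulate_symptom_trajectory("p0", cfg, ward,
                                           np.random.default_rng(0), stay_days=5)
        stream = emit_sensor_stream(traj, ward, np.random.default_rng(0), cfg)
        a = apply_missingness(stream, ward, np.random.default_rng(8), cfg)
        b = apply_missingness(stream, ward, np.random.default_rng(8), cfg)
        assert np.array_equal(a.data["heart_rate"].isna(),
                              b.data["heart_rate"].isna())

    def test_invalid_rate_rejected(self):
        with pytest.raises(ConfigError):
            WardProfile("w", missingness_rate=1.0)


class TestSchedule:
    def test_weekly_rule_21_days(self):
        cfg = _degenerate_config()
        traj = simulate_symptom_trajectory("p0", cfg, cfg.wards[0],
                                           np.random.default_rng(0), stay_days=21)
        out = schedule_assessments(traj, cfg, np.random.default_rng(0))
        assert len(out) == 4
        days = [(a.time - traj.times[0]).days for a in out]
        assert days == [0, 7, 14, 21]

    def test_short_stay_baseline_only(self):
        cfg = _degenerate_config()
        traj = simulate_symptom_trajectory("p0", cfg, cfg.wards[0],
                                           np.random.default_rng(0), stay_days=3)
        out = schedule_assessments(traj, cfg, np.random.default_rng(0))
        assert len(out) == 1 and out[0].trigger == "weekly"

    def test_zero_rater_noise_scores_equal_latent(self):
        cfg = _degenerate_config()
        cfg.init_mean = {"BPRS": 23.4, "HAMA": 11.7, "MADRS": 18.2, "YMRS": 6.6}
        traj = simulate_symptom_trajectory("p0", cfg, cfg.wards[0],
                                           np.random.default_rng(0), stay_days=7)
        out = schedule_assessments(traj, cfg, np.random.default_rng(0))
        for a in out:
            for s in SCALE_NAMES:
                assert a.scores[s] == round(cfg.init_mean[s])

    def test_assessments_within_stay_and_weekly_spacing(self, tiny_cohort):
        for pid, grp in tiny_cohort.assessments.groupby("participant_id"):
            t = pd.to_datetime(grp["timestamp"]).sort_values()
            stream = tiny_cohort.streams[pid]
            assert t.iloc[0] >= stream.data["timestamp"].iloc[0]
            assert t.iloc[-1] <= stream.data["timestamp"].iloc[-1] \
                + pd.Timedelta(minutes=1)
            weekly = pd.to_datetime(
                grp.loc[grp["trigger"] == "weekly", "timestamp"]).sort_values()
            gaps = weekly.diff().dropna()
            assert (gaps == pd.Timedelta(days=7)).all()

    def test_scores_within_ranges(self, tiny_cohort, tiny_config):
        for s in SCALE_NAMES:
            lo, hi = tiny_config.scale_ranges[s]
            assert tiny_cohort.assessments[s].between(lo, hi).all()


class TestCohort:
    def test_counts(self, tiny_cohort):
        assert len(tiny_cohort.streams) == 6
        assert len(tiny_cohort.metadata) == 6
        assert len(tiny_cohort.assessments) >= 6

    def test_serialization_byte_identical(self, tmp_path):
        cfg = CohortConfig(n_participants=2, seed=9, stay_mean_days=5,
                           stay_sd_days=0, stay_min_days=5, stay_max_days=5)
        for d in ("a", "b"):
            save_cohort(generate_cohort(cfg), tmp_path / d)
        for f in sorted((tmp_path / "a").rglob("*")):
            if f.is_file():
                g = tmp_path / "b" / f.relative_to(tmp_path / "a")
                assert f.read_bytes() == g.read_bytes(), f.name

    def test_roundtrip_load(self, tiny_cohort, tmp_path):
        save_cohort(tiny_cohort, tmp_path)
        back = load_cohort(tmp_path)
        assert set(back.streams) == set(tiny_cohort.streams)
        pid = next(iter(back.streams))
        a = back.streams[pid].data["heart_rate"].to_numpy()
        b = tiny_cohort.streams[pid].data["heart_rate"].to_numpy()
        np.testing.assert_allclose(a, b, rtol=1e-5, equal_nan=True)

    def test_ward_baseline_separation(self):
        cfg = _degenerate_config()
        cfg.n_participants = 4
        cfg.wards = [dataclasses.replace(cfg.wards[0], ward_id="lo",
                                         hr_baseline=60.0),
                     dataclasses.replace(cfg.wards[0], ward_id="hi",
                                         hr_baseline=90.0)]
        bundle = generate_cohort(cfg)
        means = {}
        for pid, stream in bundle.streams.items():
            ward = bundle.metadata.set_index("participant_id").loc[pid, "ward"]
            means.setdefault(ward, []).append(stream.data["heart_rate"].mean())
        gap = np.mean(means["hi"]) - np.mean(means["lo"])
        assert gap == pytest.approx(30.0, abs=1.0)

    def test_empty_ward_list_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(n_participants=1, wards=[])

    def test_planted_coupling_monotone_in_correlation(self):
        # stronger severity->activity coupling must strengthen the
        # cohort-level score/acceleration association
        corrs = []
        for mult in (0.0, 1.5, 4.0):
            cfg = CohortConfig(n_participants=10, seed=17, stay_mean_days=7,
                               stay_sd_days=0, stay_min_days=7, stay_max_days=7)
            cfg.coupling = {s: {k: 0.0 for k in ch}
                            for s, ch in cfg.coupling.items()}
            cfg.coupling["YMRS"]["activity"] = mult
            cfg.wards = [dataclasses.replace(w, missingness_rate=0.0)
                         for w in cfg.wards]
            bundle = generate_cohort(cfg)
            rows = []
            for pid, stream in bundle.streams.items():
                acc = total_acceleration(stream.data["accel_x"],
                                         stream.data["accel_y"],
                                         stream.data["accel_z"]).mean()
                score = bundle.assessments.loc[
                    bundle.assessments["participant_id"] == pid, "YMRS"].mean()
                rows.append((score, acc))
            arr = np.array(rows)
            corrs.append(np.corrcoef(arr[:, 0], arr[:, 1])[0, 1])
        assert corrs[0] < corrs[1] < corrs[2]
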