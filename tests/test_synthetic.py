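"""Synthetic cohort generator: pressure, kinetics, forward optics, manifests."""

import dataclasses
import math

import numpy as np
import pytest

from neoperf.optics import process_trace
from neoperf.synthetic import (
    GroupPreset,
    SimConfig,
    forward_optics,
    generate_cohort,
    load_calibration_table,
    simulate_hemodynamics,
    simulate_pressure,
    simulate_trial,
)


def quiet_config(**kw):
    base = dict(
        timing_jitter_fraction=0.0,
        amplitude_jitter_fraction=0.0,
        pressure_noise_fraction=0.0,
        hbt_noise_sd=0.0,
        sto2_noise_sd=0.0,
    )
    base.update(kw)
    return SimConfig(**base)


def flat_preset(**kw):
    base = dict(
        group_id="I", n_subjects=1,
        hbt_baseline_mean=0.68, hbt_baseline_sd=0.0,
        hbt_press_drop_mean=0.0, hbt_press_drop_sd=0.0,
        hbt_recovery_deficit_mean=0.0, hbt_recovery_deficit_sd=0.0,
        hbt_recovery_rate_mean=0.0, hbt_recovery_rate_sd=0.0,
        sto2_baseline_mean=52.0, sto2_baseline_sd=0.0,
        sto2_press_drop_mean=0.0, sto2_press_drop_sd=0.0,
        sto2_recovery_deficit_mean=0.0, sto2_recovery_deficit_sd=0.0,
        sto2_recovery_rate_first_mean=0.0, sto2_recovery_rate_first_sd=0.0,
        sto2_recovery_rate_repeat_mean=0.0, sto2_recovery_rate_repeat_sd=0.0,
        hbt_noise_sd=0.0, sto2_noise_sd=0.0,
    )
    base.update(kw)
    return GroupPreset(**base)


class TestPressure:
    def test_zero_jitter_boundaries_at_nominal_times(self, rng):
        trace, timings = simulate_pressure(quiet_config(), rng)
        expected_on = [5.0, 20.0, 35.0]
        for t, on in zip(timings, expected_on):
            assert t.t_on == pytest.approx(on)
            assert t.t_off == pytest.approx(on + 5.0)

    def test_sample_count_arithmetic(self, rng):
        cfg = quiet_config()
        trace, _ = simulate_pressure(cfg, rng)
        expected = round((5.0 + 3 * 15.0 + 2.0) * 20.0)
        assert len(trace) == expected

    def test_timing_jitter_stays_within_ten_percent(self):
        cfg = quiet_config(timing_jitter_fraction=0.1)
        for seed in range(30):
            _, timings = simulate_pressure(cfg, np.random.default_rng(seed))
            for t in timings:
                assert 4.5 <= t.t_off - t.t_on <= 5.5


class TestHemodynamics:
    def test_flat_preset_gives_flat_trajectories(self, rng):
        cfg = quiet_config()
        _, timings = simulate_pressure(cfg, rng)
        time = np.arange(round(52 * 20)) / 20.0
        hemo = simulate_hemodynamics(flat_preset(), cfg, timings, time, rng)
        assert np.allclose(hemo["hbt"], 0.68)
        assert np.allclose(hemo["sto2"], 52.0)

    def test_press_plateau_matches_closed_form_limit(self, rng):
        """Noise-free pressed level follows the exponential approach formula."""
        cfg = quiet_config()
        preset = flat_preset(hbt_press_drop_mean=0.05)
        _, timings = simulate_pressure(cfg, rng)
        time = np.arange(round(52 * 20)) / 20.0
        hemo = simulate_hemodynamics(preset, cfg, timings, time, rng)
        t_off = timings[0].t_off
        i_off = int(round(t_off * 20)) - 1
        expected = (0.68 - 0.05) + 0.05 * math.exp(-(time[i_off] - timings[0].t_on) / cfg.press_tau_s)
        assert hemo["hbt"][i_off] == pytest.approx(expected, rel=1e-9)

    def test_release_ramp_has_configured_slope(self, rng):
        cfg = quiet_config()
        preset = flat_preset(hbt_recovery_rate_mean=0.9)
        _, timings = simulate_pressure(cfg, rng)
        time = np.arange(round(52 * 20)) / 20.0
        hemo = simulate_hemodynamics(preset, cfg, timings, time, rng)
        i0 = timings[0].offset_index
        i1 = i0 + int(2.0 * 20)
        slope = np.polyfit(time[i0:i1], hemo["hbt"][i0:i1], 1)[0]
        assert slope == pytest.approx(0.9, rel=1e-6)

    def test_chromophores_consistent_with_hbt_and_sto2(self, rng):
        cfg = quiet_config()
        _, timings = simulate_pressure(cfg, rng)
        time = np.arange(round(52 * 20)) / 20.0
        hemo = simulate_hemodynamics(flat_preset(), cfg, timings, time, rng)
        assert np.allclose(hemo["d_hbo2"] + hemo["d_hb"], hemo["hbt"])
        assert np.allclose(100 * hemo["d_hbo2"] / hemo["hbt"], hemo["sto2"])

    def test_non_physical_sto2_preset_rejected(self):
        with pytest.raises(ValueError, match="non-physical"):
            flat_preset(sto2_press_drop_mean=60.0)


class TestForwardOptics:
    def test_zero_concentrations_pass_incident_through(self, geometry):
        time = np.arange(40) / 20.0
        trace = forward_optics(np.zeros(40), np.zeros(40), time, geometry, 20.0,
                               incident=(0.8, 1.2))
        assert np.allclose(trace.intensity_out[:, 0], 0.8)
        assert np.allclose(trace.intensity_out[:, 1], 1.2)

    def test_doubling_distance_doubles_attenuation(self, geometry, rng):
        time = np.arange(30) / 20.0
        hbo2 = rng.uniform(0.2, 0.5, 30)
        hb = rng.uniform(0.1, 0.4, 30)
        geo2 = dataclasses.replace(geometry, source_detector_distance_cm=2.0)
        t1 = forward_optics(hbo2, hb, time, geometry, 20.0)
        t2 = forward_optics(hbo2, hb, time, geo2, 20.0)
        od1 = -np.log10(t1.intensity_out[:, 0])
        od2 = -np.log10(t2.intensity_out[:, 0])
        assert np.allclose(od2, 2 * od1)

    def test_round_trip_through_mbll_inversion(self, geometry, rng):
        """Forward optics followed by the processing pipeline is the identity."""
        time = np.arange(100) / 20.0
        hbo2 = rng.uniform(0.2, 0.5, 100)
        hb = rng.uniform(0.1, 0.4, 100)
        trace = forward_optics(hbo2, hb, time, geometry, 20.0)
        hemo = process_trace(trace, geometry)
        assert np.allclose(hemo.d_hbo2, hbo2, rtol=1e-8)
        assert np.allclose(hemo.d_hb, hb, rtol=1e-8)


class TestCohort:
    def test_same_seed_is_byte_identical(self, tmp_path, presets, geometry):
        cfg = SimConfig()
        small = {"I": dataclasses.replace(presets["I"], n_subjects=1)}
        m1 = generate_cohort(small, cfg, tmp_path / "a", seed=9, geometry=geometry,
                             groups=("I",))
        m2 = generate_cohort(small, cfg, tmp_path / "b", seed=9, geometry=geometry,
                             groups=("I",))
        assert (tmp_path / "a" / "manifest.json").read_text() == (
            tmp_path / "b" / "manifest.json").read_text()
        f = m1["trials"][0]["file"]
        assert (tmp_path / "a" / f).read_bytes() == (tmp_path / "b" / f).read_bytes()

    def test_manifest_parameter_means_near_preset(self, presets, geometry):
        """Ground-truth baselines across Group I subjects stay within 3 SE."""
        cfg = SimConfig()
        from neoperf.synthetic import simulate_cohort

        trials = simulate_cohort({"I": presets["I"]}, cfg, seed=5,
                                 geometry=geometry, groups=("I",))
        assert len(trials) == presets["I"].n_subjects * cfg.trials_per_subject
        b = np.array([t.ground_truth["hbt_baseline"] for t in trials])
        se = presets["I"].hbt_baseline_sd / math.sqrt(presets["I"].n_subjects)
        assert abs(b.mean() - presets["I"].hbt_baseline_mean) < 3 * se

    def test_trial_record_schema(self, presets, geometry, rng):
        cfg = SimConfig()
        tr = simulate_trial(presets["IV"], cfg, geometry, rng, "IV-001", 1)
        assert tr.group == "IV"
        assert len(tr.pressure) == len(tr.optical)
        assert len(tr.timings) == cfg.n_cycles
        assert "hbt_baseline" in tr.ground_truth


class TestCalibration:
    def test_table_covers_all_groups_and_quantities(self):
        table = load_calibration_table()
        assert set(table["group"]) == {"I", "II", "III", "IV"}
        assert set(table["basis"]) == {"reported", "assumed"}

    def test_presets_encode_reported_directionality(self, presets):
        # full-term baselines above premature ones
        assert presets["I"].hbt_baseline_mean > presets["III"].hbt_baseline_mean
        assert presets["II"].hbt_baseline_mean > presets["IV"].hbt_baseline_mean
        # premature reperfusion rates higher
        assert presets["IV"].hbt_recovery_rate_mean > presets["I"].hbt_recovery_rate_mean
        # first-cycle StO2 recovery advantage largest for Group I
        assert (presets["I"].sto2_recovery_rate_first_mean
                > presets["III"].sto2_recovery_rate_first_mean)

    def test_group_sizes(self, presets):
        assert [presets[g].n_subjects for g in ("I", "II", "III", "IV")] == [24, 14, 51, 13]
        assert sum(p.n_subjects for p in presets.values()) == 102

    def test_noise_free_pipeline_recovers_baseline_target(self, presets, geometry):
        """Single noise-free Group-I trial: pipeline Index I == preset mean <0.5%."""
        from neoperf.indexes import compute_indexes
        from neoperf.protocol import segment_protocol

        cfg = quiet_config()
        preset = dataclasses.replace(
            presets["I"],
            hbt_baseline_sd=0.0, hbt_press_drop_sd=0.0,
            hbt_recovery_deficit_sd=0.0, hbt_recovery_rate_sd=0.0,
            sto2_baseline_sd=0.0, sto2_press_drop_sd=0.0,
            sto2_recovery_deficit_sd=0.0, sto2_recovery_rate_first_sd=0.0,
            sto2_recovery_rate_repeat_sd=0.0, hbt_noise_sd=0.0, sto2_noise_sd=0.0,
        )
        tr = simulate_trial(preset, cfg, geometry, np.random.default_rng(0), "I-001", 1)
        seg = segment_protocol(tr.pressure)
        hemo = process_trace(tr.optical, geometry)
        idx = compute_indexes(hemo, seg, "HbT")
        assert idx.index_i == pytest.approx(preset.hbt_baseline_mean, rel=0.005)
        assert idx.index_ii == pytest.approx(0.6409, rel=0.005)
        assert idx.index_iii == pytest.approx(0.6680, rel=0.005)
        assert idx.index_vi == pytest.approx(preset.hbt_recovery_rate_mean, rel=0.02)
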