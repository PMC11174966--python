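"""Generator contracts: beat model, noise model, cohort assembly."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from neoecg.synth import (
    NEONATAL_TEMPLATE, BeatTemplateParams, CohortConfig, DegenerateMorphologyError,
    GroundTruth, GroupSpec, NoiseConfig, WaveParams, _default_groups, add_noise,
    beat_ground_truth, generate_beat, generate_cohort, synthesize_feature_table,
    synthesize_record,
)


def _template(**overrides) -> BeatTemplateParams:
    return replace(NEONATAL_TEMPLATE, **overrides)


def _silent_template() -> BeatTemplateParams:
    return BeatTemplateParams(
        p=WaveParams(0.0, -0.095, 0.016), q=WaveParams(0.0, -0.025, 0.010),
        r=WaveParams(0.0, 0.0, 0.012), s=WaveParams(0.0, 0.025, 0.010),
        t=WaveParams(0.0, 0.180, 0.030),
    )


class TestGenerateBeat:
    def test_all_zero_amplitudes_give_zero_waveform(self):
        wf, _ = generate_beat(_silent_template(), rr=0.5, fs=256)
        assert wf.shape == (128,)
        assert np.all(wf == 0.0)

    def test_single_r_bump_peaks_at_r_center(self):
        tpl = replace(_silent_template(), r=WaveParams(1.0, 0.0, 0.012))
        wf, _ = generate_beat(tpl, rr=0.5, fs=256)
        assert wf.shape == (128,)
        r_center = 0.3 * 0.5 * 256  # 38.4
        assert abs(np.argmax(wf) - r_center) <= 1
        # peak equals R amplitude up to one sample's interpolation error
        assert wf.max() == pytest.approx(1.0, abs=0.01)

    def test_t_wave_slope_matches_analytic_gaussian_derivative(self):
        a, w = 0.30, 0.035
        tpl = replace(_silent_template(), t=WaveParams(a, 0.180, w))
        wf, gt = generate_beat(tpl, rr=0.6, fs=1024)
        numeric = np.min(np.gradient(wf) * 1024)  # steepest descent, mV/s
        analytic = -a * np.exp(-0.5) / w
        assert numeric == pytest.approx(analytic, rel=0.01)
        assert gt["tslope_mv_per_s"] == pytest.approx(analytic, rel=1e-12)

    def test_t_peak_ground_truth_matches_sampled_peak(self):
        wf, gt = generate_beat(NEONATAL_TEMPLATE, rr=0.5, fs=256)
        t = np.arange(wf.size) / 256 - 0.15
        in_t = (t > 0.08) & (t < 0.3)
        assert wf[in_t].max() == pytest.approx(gt["t_amplitude_mv"], rel=0.01)

    def test_overlapping_t_wave_raises_degenerate_error(self):
        tpl = _template(t=WaveParams(0.25, 0.30, 0.040))
        with pytest.raises(DegenerateMorphologyError):
            generate_beat(tpl, rr=0.5, fs=256)

    @pytest.mark.parametrize("rr,fs", [(0.2, 256), (0.5, 100)])
    def test_preconditions(self, rr, fs):
        with pytest.raises(ValueError):
            generate_beat(NEONATAL_TEMPLATE, rr=rr, fs=fs)

    def test_wave_order_validation(self):
        with pytest.raises(ValueError):
            _template(s=WaveParams(-0.15, -0.01, 0.010))  # S before R


class TestSynthesizeRecord:
    def test_zero_jitter_gives_exact_rr(self):
        groups = _default_groups()
        groups["normal"] = GroupSpec(ph_range=(7.20, 7.45), mean_hr_bpm=120.0)
        cfg = CohortConfig(groups=groups, hr_sd_bpm=0.0, rr_jitter=0.0,
                           duration_s=20.0, noise=None)
        _, truth, _ = synthesize_record(cfg, "normal", 3)
        assert np.allclose(np.diff(truth.r_times_s), 0.5, atol=1e-12)

    def test_same_seed_is_bit_identical(self, clean_cohort_config):
        a, _, _ = synthesize_record(clean_cohort_config, "normal", 9)
        b, _, _ = synthesize_record(clean_cohort_config, "normal", 9)
        assert np.array_equal(a.data, b.data)

    @pytest.mark.parametrize("group,lo,hi", [
        ("acidosis", 6.5, 7.20), ("normal", 7.20, 7.45), ("alkalosis", 7.45, 8.0),
    ])
    def test_ph_drawn_inside_group_range(self, clean_cohort_config, group, lo, hi):
        for seed in range(5):
            _, truth, events = synthesize_record(clean_cohort_config, group, seed)
            if group == "acidosis":
                assert truth.ph < 7.20
            elif group == "alkalosis":
                assert truth.ph > 7.45
            else:
                assert lo <= truth.ph <= hi
            assert events["ph"].iloc[0] == truth.ph

    def test_event_placed_mid_record(self, clean_record):
        rec, _, events = clean_record
        assert events["time_s"].iloc[0] == pytest.approx(rec.duration / 2)

    def test_ground_truth_r_times_strictly_increasing(self, clean_record):
        _, truth, _ = clean_record
        assert np.all(np.diff(truth.r_times_s) > 0)

    def test_ground_truth_validates_monotonicity(self):
        with pytest.raises(ValueError):
            GroundTruth(r_times_s=np.array([0.5, 0.4]), qt_s=0.28,
                        t_amplitude_mv=0.25, tslope_mv_per_s=-5.0,
                        hr_bpm=120.0, ph=7.3, group="normal")


class TestAddNoise:
    def test_zero_noise_is_identity(self, clean_record):
        rec, _, _ = clean_record
        out = add_noise(rec, NoiseConfig(0.0, 0.25, 0.0, 50.0, 0.0, seed=1))
        assert np.array_equal(out.data, rec.data)

    def test_powerline_rms_is_amplitude_over_sqrt2(self):
        from neoecg.preprocess import ECGRecord

        silent = ECGRecord(data=np.zeros((256 * 60, 1)), fs=256.0)
        a = 0.07
        out = add_noise(silent, NoiseConfig(0.0, 0.25, a, 50.0, 0.0, seed=2))
        rms = np.sqrt(np.mean(out.data[:, 0] ** 2))
        assert rms == pytest.approx(a / np.sqrt(2), rel=0.01)

    def test_emg_sample_sd_matches_configured_sd(self):
        from neoecg.preprocess import ECGRecord

        silent = ECGRecord(data=np.zeros((256 * 120, 1)), fs=256.0)
        s = 0.03
        out = add_noise(silent, NoiseConfig(0.0, 0.25, 0.0, 50.0, s, seed=3))
        assert np.std(out.data[:, 0]) == pytest.approx(s, rel=0.05)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            NoiseConfig(baseline_amplitude_mv=-0.1)


class TestGenerateCohort:
    def test_default_group_sizes_give_108_records(self):
        cfg = CohortConfig(group_sizes=(9, 83, 16), duration_s=21.0, noise=None)
        cohort = generate_cohort(cfg)
        assert len(cohort) == 108
        labels = [truth.group for _, truth, _ in cohort]
        assert labels.count("acidosis") == 9
        assert labels.count("normal") == 83
        assert labels.count("alkalosis") == 16

    def test_single_group_cohort(self):
        cfg = CohortConfig(group_sizes=(0, 5, 0), duration_s=21.0, noise=None)
        cohort = generate_cohort(cfg)
        assert len(cohort) == 5
        assert all(truth.group == "normal" for _, truth, _ in cohort)

    def test_master_seed_reproducibility(self):
        cfg = CohortConfig(group_sizes=(1, 2, 1), duration_s=21.0)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for (ra, _, _), (rb, _, _) in zip(a, b):
            assert np.array_equal(ra.data, rb.data)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CohortConfig(group_sizes=(-1, 5, 0))
        with pytest.raises(ValueError):
            CohortConfig(fs_hz=150.0)
        with pytest.raises(ValueError):
            CohortConfig(groups={**_default_groups(),
                                 "acidosis": GroupSpec(ph_range=(7.0, 7.3))})


class TestFeatureTable:
    def test_null_table_groups_share_feature_distributions(self):
        cfg = CohortConfig(group_sizes=(60, 60, 60))
        table = synthesize_feature_table(cfg, seed=5)
        # same generative law in every group: medians agree loosely
        med = table.groupby("group")["t_amplitude"].median()
        assert med.max() / med.min() < 1.25

    def test_effect_multiplier_scales_group_feature(self):
        groups = _default_groups()
        groups["acidosis"] = GroupSpec(ph_range=(6.9, 7.199), t_amplitude_mult=0.5)
        table = synthesize_feature_table(
            CohortConfig(group_sizes=(40, 40, 0), groups=groups), seed=6)
        med = table.groupby("group")["t_amplitude"].median()
        assert med["acidosis"] / med["normal"] == pytest.approx(0.5, rel=0.2)
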