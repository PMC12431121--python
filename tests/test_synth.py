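"""Synthetic-recording generator: determinism, statistics, round trips."""

import json

import numpy as np
import pytest

from adlmotion.core import ParameterError, PhaseSchedule
from adlmotion.device_io import MUSCLE_ORDER
from adlmotion.imu import quat_to_euler
from adlmotion.synth import (
    AngleLobe,
    DRINKING_SCHEDULE,
    MuscleBurst,
    SynthConfig,
    expected_rectified_mean,
    lobe_attenuation,
    sample_protocol,
    simulate_dataset,
    synth_emg,
    synth_imu,
    write_dataset,
)


def zero_noise_config(**kwargs):
    defaults = dict(
        schedule=PhaseSchedule(
            "drinking", DRINKING_SCHEDULE.mean_durations, (0.0,) * 7
        ),
        cycle_sd_s=0.0,
        angle_jitter_deg=0.0,
        subject_time_jitter_pct=0.0,
        subject_amp_cv=0.0,
        carrier="deterministic",
        snap_to_frames=False,
    )
    defaults.update(kwargs)
    return SynthConfig(**defaults)


class TestSampleProtocol:
    def test_zero_sd_matches_template_exactly(self):
        rng = np.random.default_rng(0)
        trials = sample_protocol(zero_noise_config(), rng)
        for trial in trials:
            assert np.allclose(trial["durations_pct"], DRINKING_SCHEDULE.mean_durations)
            assert trial["cycle_s"] == pytest.approx(10.0)

    def test_same_seed_is_deterministic(self):
        a = sample_protocol(SynthConfig(), np.random.default_rng(5))
        b = sample_protocol(SynthConfig(), np.random.default_rng(5))
        assert json.dumps(a) == json.dumps(b)

    def test_draw_means_within_3_se_of_template(self):
        # 10 000 draws per phase: CLT check that the symmetric truncated
        # normal the durations are drawn from is an unbiased sampler of
        # the template means (renormalizing fractions to sum 100 then
        # adds only a second-order, sub-SE coupling between phases)
        from adlmotion.synth import _truncated_normal

        rng = np.random.default_rng(31)
        means = np.asarray(DRINKING_SCHEDULE.mean_durations)
        sds = np.asarray(DRINKING_SCHEDULE.sd_durations)
        half = np.minimum(2.5 * sds, np.maximum(means - 0.5, 0.0))
        n = 10_000
        draws = np.stack(
            [_truncated_normal(rng, means, sds, half) for _ in range(n)]
        )
        se = draws.std(axis=0, ddof=1) / np.sqrt(n)
        assert np.all(np.abs(draws.mean(axis=0) - means) <= 3 * se)

    def test_durations_stay_positive_and_sum_100(self):
        rng = np.random.default_rng(11)
        for trial in sample_protocol(SynthConfig(n_trials=50), rng):
            d = np.asarray(trial["durations_pct"])
            assert np.all(d > 0)
            assert d.sum() == pytest.approx(100.0)


class TestSynthEMG:
    def test_same_seed_bit_identical(self):
        config = SynthConfig(n_trials=2)
        bursts = config.task_bursts["dominant"]
        t1 = sample_protocol(config, np.random.default_rng(3))
        t2 = sample_protocol(config, np.random.default_rng(3))
        a = synth_emg(t1, bursts, "dominant", config, np.random.default_rng(4))
        b = synth_emg(t2, bursts, "dominant", config, np.random.default_rng(4))
        assert np.array_equal(a.counts, b.counts)

    def test_zero_amplitude_baseline_statistics(self, spec):
        # with no bursts, counts fluctuate around mid-scale and the
        # rectified mean matches the quantized half-normal expectation
        config = SynthConfig(n_trials=1)
        bursts = {
            m.value: MuscleBurst(peak_pct=50.0, amp_mv=0.0, baseline_mv=0.3)
            for m in MUSCLE_ORDER
        }
        rng = np.random.default_rng(8)
        trials = sample_protocol(config, rng)
        raw = synth_emg(trials, bursts, "dominant", config, rng)
        assert abs(raw.counts.mean() - spec.adc_midscale) < 0.05
        mv = (raw.counts - spec.adc_midscale) * spec.mv_per_count
        expected = expected_rectified_mean(np.array([0.3]), spec.mv_per_count)[0]
        assert np.abs(mv).mean() == pytest.approx(expected, rel=0.02)

    def test_deterministic_carrier_recovers_bump(self, spec):
        # noiseless limit: |carrier| is the modulation itself, so after
        # quantization the mid-cycle signal equals the injected bump
        config = zero_noise_config(n_trials=1)
        amp = 50.0  # large vs the 0.39 mV ADC step
        bursts = {
            m.value: MuscleBurst(peak_pct=40.0, amp_mv=amp, baseline_mv=0.0)
            for m in MUSCLE_ORDER
        }
        rng = np.random.default_rng(1)
        trials = sample_protocol(config, rng)
        raw = synth_emg(trials, bursts, "dominant", config, rng)
        mv = (raw.counts[:, 0] - spec.adc_midscale) * spec.mv_per_count
        b0, b7 = trials[0]["boundaries_s"][0], trials[0]["boundaries_s"][-1]
        pct = 100.0 * (raw.time - b0) / (b7 - b0)
        inside = (pct >= 0) & (pct <= 100)
        bump = amp * np.exp(-((pct[inside] - 40.0) ** 2) / (2 * 10.0**2))
        assert np.allclose(mv[inside], bump, atol=spec.mv_per_count)


class TestSynthIMU:
    def test_no_lobes_no_jitter_identity_quaternions(self):
        config = zero_noise_config(n_trials=1)
        rng = np.random.default_rng(2)
        trials = sample_protocol(config, rng)
        raw = synth_imu(trials, {"fe": [], "abad": [], "rot": []}, "dominant", config, rng)
        assert np.allclose(raw.quaternions, [1.0, 0.0, 0.0, 0.0], atol=1e-12)

    def test_yaw_lobe_round_trips_before_smoothing(self):
        config = zero_noise_config(n_trials=1)
        rng = np.random.default_rng(2)
        trials = sample_protocol(config, rng)
        lobe = AngleLobe(50.0, 40.0, 30.0)
        raw = synth_imu(trials, {"fe": [lobe], "abad": [], "rot": []}, "dominant", config, rng)
        euler, _ = quat_to_euler(raw.quaternions)
        b0, b7 = trials[0]["boundaries_s"][0], trials[0]["boundaries_s"][-1]
        pct = 100.0 * (raw.time - b0) / (b7 - b0)
        inside = (pct >= 0) & (pct <= 100)
        support = np.abs(pct - 50.0) <= 20.0
        expected = np.zeros_like(pct)
        expected[inside & support] = 15.0 * (
            1.0 + np.cos(2 * np.pi * (pct[inside & support] - 50.0) / 40.0)
        )
        assert np.allclose(euler[:, 0], expected, atol=1e-6)
        assert np.allclose(euler[:, 1:], 0.0, atol=1e-6)

    def test_gimbal_lock_request_rejected(self):
        with pytest.raises(ParameterError, match="gimbal"):
            SynthConfig(
                lobes={
                    "dominant": {"fe": [], "abad": [], "rot": [AngleLobe(50.0, 40.0, 95.0)]},
                    "non_dominant": {"fe": [], "abad": [], "rot": []},
                }
            )

    def test_same_seed_identical_stream(self):
        config = SynthConfig(n_trials=1)
        lobes = config.task_lobes["dominant"]
        t = sample_protocol(config, np.random.default_rng(6))
        a = synth_imu(t, lobes, "dominant", config, np.random.default_rng(7))
        b = synth_imu(t, lobes, "dominant", config, np.random.default_rng(7))
        assert np.array_equal(a.quaternions, b.quaternions)


class TestExpectedRectifiedMean:
    def test_continuous_limit_is_half_normal(self):
        sigma = np.array([0.5, 1.0, 2.0])
        assert np.allclose(expected_rectified_mean(sigma), sigma * np.sqrt(2 / np.pi))

    def test_quantized_expectation_matches_monte_carlo(self, rng):
        step = 0.39
        for sigma in (0.2, 0.5, 1.5):
            x = rng.normal(0.0, sigma, size=400_000)
            mc = np.abs(step * np.round(x / step)).mean()
            analytic = expected_rectified_mean(np.array([sigma]), step)[0]
            assert analytic == pytest.approx(mc, rel=0.01, abs=1e-4)

    def test_fine_quantization_approaches_continuous(self):
        sigma = np.array([0.5])
        fine = expected_rectified_mean(sigma, 1e-4)[0]
        assert fine == pytest.approx(0.5 * np.sqrt(2 / np.pi), rel=1e-3)


class TestLobeAttenuation:
    def test_wide_lobe_barely_attenuated(self, spec):
        # 9 s lobe vs 1 s window: closed form gives (1 + sinc(1/9))/2
        x = np.pi / 9.0
        assert lobe_attenuation(AngleLobe(50.0, 90.0, 10.0), spec, 10.0) == (
            pytest.approx(0.5 * (1.0 + np.sin(x) / x))
        )

    def test_matches_numerical_convolution(self, spec):
        lobe = AngleLobe(50.0, 45.0, 20.0)
        cycle_s = 10.0
        t = np.arange(0, cycle_s, 1.0 / spec.imu_rate)
        pct = 100.0 * t / cycle_s
        vals = np.where(
            np.abs(pct - 50.0) <= 22.5,
            10.0 * (1 + np.cos(2 * np.pi * (pct - 50.0) / 45.0)),
            0.0,
        )
        kernel = np.ones(spec.imu_window) / spec.imu_window
        smoothed = np.convolve(vals, kernel, mode="same")
        assert smoothed.max() / vals.max() == pytest.approx(
            lobe_attenuation(lobe, spec, cycle_s), rel=1e-3
        )


class TestWriteDataset:
    def test_round_trip_and_checksums(self, tmp_path, small_dataset):
        from adlmotion.report import load_dataset
        from adlmotion.synth import _sha256

        out = tmp_path / "ds"
        config = SynthConfig(n_subjects=3)
        manifest_path = write_dataset(small_dataset, out, config)
        manifest = json.loads(manifest_path.read_text())
        for rel, digest in manifest["files"].items():
            assert _sha256(out / rel) == digest
        loaded, _ = load_dataset(out)
        assert len(loaded) == 3
        orig = small_dataset[0].trial_set
        back = next(r.trial_set for r in loaded if r.trial_set.subject_id == orig.subject_id)
        assert np.array_equal(orig.emg["dominant"].counts, back.emg["dominant"].counts)
        assert np.allclose(
            orig.imu["dominant"].quaternions,
            back.imu["dominant"].quaternions,
            atol=5e-9,
        )
        for a, b in zip(orig.annotations, back.annotations):
            assert np.allclose(a.boundaries, b.boundaries)

    def test_refuses_non_empty_dir(self, tmp_path, small_dataset):
        out = tmp_path / "ds"
        out.mkdir()
        (out / "existing.txt").write_text("hello")
        with pytest.raises(FileExistsError):
            write_dataset(small_dataset, out)
        write_dataset(small_dataset, out, overwrite=True)  # flag permits it

    def test_dataset_bytes_deterministic_under_seed(self, tmp_path):
        config = SynthConfig(n_subjects=2, n_trials=2)
        m1 = write_dataset(simulate_dataset(config, 77), tmp_path / "a", config)
        m2 = write_dataset(simulate_dataset(config, 77), tmp_path / "b", config)
        f1 = json.loads(m1.read_text())["files"]
        f2 = json.loads(m2.read_text())["files"]
        assert f1 == f2  # sha256 of every file identical
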