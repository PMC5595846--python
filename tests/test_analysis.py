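"""Sinusoid extraction, sweep analysis, and aggregation."""

import math

import numpy as np
import pytest

import microdma as md
from microdma.analysis import FLAG_DISTORTION, extract_sinusoid

from conftest import relative_errors


def dft_projection(t, y, f):
    """Independent single-bin discrete Fourier estimate (the lock-in analog)."""
    a = 2.0 * np.mean(y * np.sin(2 * math.pi * f * t))
    b = 2.0 * np.mean(y * np.cos(2 * math.pi * f * t))
    return math.hypot(a, b), math.atan2(b, a)


class TestExtractSinusoid:
    def test_pure_sine_exact(self):
        t = np.arange(5000) / 1000.0
        for phase in (0.0, 0.7, -2.0):
            y = 2.5 * np.sin(2 * math.pi * 1.0 * t + phase)
            fit = extract_sinusoid(t, y, 1.0)
            assert fit.amplitude == pytest.approx(2.5, rel=1e-12)
            assert fit.phase == pytest.approx(phase, abs=1e-12)
            assert fit.residual_rms < 1e-12

    def test_matches_fourier_projection_on_integer_periods(self):
        """Estimator equivalence with the direct DFT bin at 1e-10 relative."""
        t = np.arange(5000) / 1000.0  # exactly 5 periods at 1 Hz
        y = 1.3 * np.sin(2 * math.pi * 1.0 * t + 0.4) + 0.2
        fit = extract_sinusoid(t, y, 1.0)
        amp, phase = dft_projection(t, y, 1.0)
        assert abs(fit.amplitude - amp) / amp < 1e-10
        assert abs(fit.phase - phase) < 1e-10

    def test_linear_drift_rejected(self):
        # drift worth 10 % of the segment leaves the amplitude within 0.5 %
        t = np.arange(5000) / 1000.0
        y = np.sin(2 * math.pi * 1.0 * t + 0.2) + 0.1 * t / t[-1]
        fit = extract_sinusoid(t, y, 1.0)
        assert fit.amplitude == pytest.approx(1.0, rel=5e-3)
        assert fit.drift_slope == pytest.approx(0.1 / t[-1], rel=1e-6)

    def test_noise_robustness_vs_dft(self):
        """At 30 dB SNR over 5 periods: amplitude within 2 %, phase within
        1 degree, and consistent with the DFT estimate within mutual error."""
        rng = np.random.default_rng(7)
        t = np.arange(5000) / 1000.0
        sigma = 1.0 / math.sqrt(2) / 10 ** (30 / 20)
        y = np.sin(2 * math.pi * 1.0 * t + 0.5) + rng.normal(0, sigma, t.size)
        fit = extract_sinusoid(t, y, 1.0)
        amp_dft, phase_dft = dft_projection(t, y, 1.0)
        assert fit.amplitude == pytest.approx(1.0, rel=0.02)
        assert abs(fit.phase - 0.5) < math.radians(1.0)
        mutual = 3 * sigma * math.sqrt(2.0 / t.size)
        assert abs(fit.amplitude - amp_dft) < mutual
        assert abs(fit.phase - phase_dft) < mutual

    def test_short_segment_rejected(self):
        t = np.arange(1500) / 1000.0
        with pytest.raises(md.InsufficientDataError):
            extract_sinusoid(t, np.sin(2 * math.pi * t), 1.0)


class TestAnalyzeSweep:
    def test_sls_noise_free_recovery_within_2pct(self, noise_free_full_band, sls_model):
        """Twin-generated SLS recording, noise-free: G', G'' within 2 % at
        every grid frequency."""
        result = md.analyze_sweep(noise_free_full_band)
        errs = relative_errors(result, sls_model)
        assert np.nanmax(np.abs(errs[:, 0])) < 0.02
        assert np.nanmax(np.abs(errs[:, 1])) < 0.02

    def test_time_shift_convention_safety(self, sls_recording):
        """Shifting both channels by a common delay leaves phi and G* unchanged."""
        base = md.analyze_sweep(sls_recording)
        shifted = md.Recording(
            sls_recording.time + 1.2345,
            sls_recording.piezo_position,
            sls_recording.deflection,
            sls_recording.load,
            sls_recording.segment_labels,
            sls_recording.metadata,
        )
        res = md.analyze_sweep(shifted)
        assert np.allclose(res.data["phase_rad"], base.data["phase_rad"], atol=1e-12)
        assert np.allclose(res.storage, base.storage)

    def test_missing_oscillation_segments_rejected(self, sls_recording):
        labels = np.array(["approach"] * len(sls_recording.time), dtype=object)
        broken = md.Recording(
            sls_recording.time,
            sls_recording.piezo_position,
            sls_recording.deflection,
            sls_recording.load,
            labels,
            sls_recording.metadata,
        )
        with pytest.raises(md.FormatError):
            md.analyze_sweep(broken)

    def test_stick_slip_corrupts_only_lowest_frequency(self, sls_model, probe, contact):
        """Needle-shaft friction: the lowest-frequency row is distortion-
        flagged while all faster rows stay clean and accurate."""
        settings = md.TwinSettings(friction=md.StickSlipConfig(enabled=True))
        rec = md.simulate_measurement(
            sls_model, probe, contact, md.SweepProtocol.np_mode(), seed=3, settings=settings
        )
        result = md.analyze_sweep(rec)
        assert FLAG_DISTORTION in result.flags(0)
        truth0 = md.complex_modulus(sls_model, float(result.frequencies[0]))
        assert abs(result.loss[0] - truth0.loss) / truth0.loss > 0.02
        errs = relative_errors(result, sls_model)
        for i in range(1, len(result.data)):
            assert FLAG_DISTORTION not in result.flags(i)
            assert abs(errs[i, 0]) < 0.02
            assert abs(errs[i, 1]) < 0.05

    def test_raw_intensity_recording_recovers_moduli(self, sls_model, probe, contact):
        """Full-fidelity path: fringe intensity -> demodulation -> moduli."""
        protocol = md.SweepProtocol.np_mode(
            f_min=2.0, n_frequencies=3, hold_time=2.0, sample_rate=25000.0
        )
        settings = md.TwinSettings(load_ramp_time=2.0)
        rec = md.simulate_measurement(
            sls_model,
            probe,
            contact,
            protocol,
            seed=1,
            settings=settings,
            fidelity="raw_intensity",
        )
        assert rec.metadata["channel_role"] == "intensity"
        assert np.all(np.isnan(rec.load))
        result = md.analyze_sweep(rec)
        errs = relative_errors(result, sls_model)
        assert np.nanmax(np.abs(errs[:, 0])) < 0.05
        assert np.nanmax(np.abs(errs[:, 1])) < 0.10


class TestAggregateSweeps:
    def test_identical_results_have_zero_dispersion(self, sls_recording):
        res = md.analyze_sweep(sls_recording)
        agg = md.aggregate_sweeps([res] * 5, exclude_flagged=False)
        assert np.allclose(agg.data["G_storage_sd_Pa"], 0.0)
        assert np.allclose(agg.data["G_storage_mean_Pa"], res.storage)
        assert agg.n_sweeps == 5

    def test_single_sweep_convention(self, sls_recording):
        res = md.analyze_sweep(sls_recording)
        agg = md.aggregate_sweeps([res], exclude_flagged=False)
        assert np.allclose(agg.data["G_storage_mean_Pa"], res.storage)
        assert np.allclose(agg.data["G_storage_sd_Pa"], 0.0)

    def test_mismatched_grids_rejected(self, sls_model, probe, contact, short_settings):
        p1 = md.SweepProtocol.np_mode(f_min=2.0, n_frequencies=3, hold_time=5.0)
        p2 = md.SweepProtocol.np_mode(f_min=1.0, n_frequencies=3, hold_time=5.0)
        r1 = md.analyze_sweep(
            md.simulate_measurement(sls_model, probe, contact, p1, 1, settings=short_settings)
        )
        r2 = md.analyze_sweep(
            md.simulate_measurement(sls_model, probe, contact, p2, 1, settings=short_settings)
        )
        with pytest.raises(md.IncompatibleGridsError):
            md.aggregate_sweeps([r1, r2])

    def test_multi_seed_mean_close_to_truth(self, sls_model, probe, contact, short_settings):
        """Monte-Carlo over seeds: the mean tracks ground truth."""
        protocol = md.SweepProtocol.np_mode(f_min=2.0, n_frequencies=3, hold_time=5.0)
        results = [
            md.analyze_sweep(
                md.simulate_measurement(
                    sls_model, probe, contact, protocol, seed, settings=short_settings
                )
            )
            for seed in range(1, 6)
        ]
        agg = md.aggregate_sweeps(results, exclude_flagged=False)
        for i, f in enumerate(agg.data["frequency_hz"]):
            truth = md.complex_modulus(sls_model, float(f))
            mean = agg.data["G_storage_mean_Pa"].iloc[i]
            assert abs(mean - truth.storage) / truth.storage < 0.02
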