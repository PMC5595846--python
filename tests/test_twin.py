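"""Instrument twin: protocol grid, closed-loop behavior, contact, calibration."""

import math

import numpy as np
import pytest

import microdma as md
from microdma.analysis import extract_sinusoid


class TestFrequencyGrid:
    def test_full_band_defaults(self):
        grid = md.generate_frequency_grid(md.SweepProtocol())
        assert len(grid) == 15
        assert grid[0] == pytest.approx(0.05)
        assert grid[-1] == pytest.approx(10.0)
        assert np.all(np.diff(grid) > 0)
        # log spacing: constant ratio
        ratios = grid[1:] / grid[:-1]
        assert np.allclose(ratios, ratios[0], rtol=1e-12)

    def test_np_mode_defaults(self):
        grid = md.generate_frequency_grid(md.SweepProtocol.np_mode())
        assert len(grid) == 5
        assert grid[0] == pytest.approx(0.5)
        assert grid[-1] == pytest.approx(10.0)

    def test_two_point_grid_is_endpoints(self):
        grid = md.generate_frequency_grid(md.SweepProtocol(n_frequencies=2))
        assert np.allclose(grid, [0.05, 10.0])

    def test_invalid_grid_rejected(self):
        with pytest.raises(md.ParameterError):
            md.SweepProtocol(n_frequencies=1)


class TestProtocolValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(f_min=2.0, f_max=1.0),
            dict(oscillation_amplitude=400e-6),
            dict(periods_per_frequency=0),
            dict(hold_time=-1.0),
            dict(mode="turbo"),
        ],
    )
    def test_bad_protocols_rejected(self, kwargs):
        with pytest.raises(md.ParameterError):
            md.SweepProtocol(**kwargs)

    def test_springpot_cannot_drive_twin(self, probe, contact, short_protocol):
        with pytest.raises(md.ParameterError):
            md.simulate_measurement(
                md.RheologyModel.springpot(100.0, 0.5),
                probe,
                contact,
                short_protocol,
                seed=1,
            )


class TestSimulateMeasurement:
    def test_determinism_bit_identical(self, sls_model, probe, contact, short_protocol, short_settings):
        a = md.simulate_measurement(sls_model, probe, contact, short_protocol, 5, settings=short_settings)
        b = md.simulate_measurement(sls_model, probe, contact, short_protocol, 5, settings=short_settings)
        for name in ("time", "piezo_position", "deflection", "load"):
            assert np.array_equal(getattr(a, name), getattr(b, name))
        assert list(a.segment_labels) == list(b.segment_labels)

    def test_segments_partition_time_axis(self, sls_recording, short_protocol):
        segments = sls_recording.segments()
        total = sum(sl.stop - sl.start for _, sl in segments)
        assert total == len(sls_recording.time)
        labels = [lab for lab, _ in segments]
        assert labels[0] == "approach"
        assert labels[-1] == "retract"

    def test_oscillation_segments_span_requested_periods(self, sls_recording, short_protocol):
        fs = short_protocol.sample_rate
        osc = sls_recording.oscillation_segments()
        assert len(osc) == short_protocol.n_frequencies
        for f, sl in osc:
            duration = (sl.stop - sl.start) / fs
            assert duration >= short_protocol.periods_per_frequency / f * (1 - 1e-9)

    def test_hold_mean_load_within_1pct(self, np_mode_recording):
        proto_load = float(np_mode_recording.metadata["protocol.static_load"])
        sl = np_mode_recording.segment_slice("hold")
        hold = np_mode_recording.load[sl]
        settled = hold[len(hold) // 2 :]
        assert abs(settled.mean() - proto_load) / proto_load < 0.01

    def test_oscillation_amplitude_tracked_within_2pct(self, np_mode_recording):
        amp = float(np_mode_recording.metadata["protocol.oscillation_amplitude"])
        for f, sl in np_mode_recording.oscillation_segments():
            n_skip = (sl.stop - sl.start) // 5
            window = slice(sl.start + n_skip, sl.stop)
            t = np_mode_recording.time[window]
            fit = extract_sinusoid(t - t[0], np_mode_recording.load[window], f)
            assert abs(fit.amplitude - amp) / amp < 0.02, f"at {f} Hz"

    def test_indentation_lags_load_for_passive_sample(self, np_mode_recording):
        """Causality: measured phase lag >= 0 at every sweep frequency."""
        z_c = md.detect_contact(np_mode_recording).z_contact
        h = (
            np_mode_recording.piezo_position
            - np_mode_recording.deflection
            - z_c
        )
        for f, sl in np_mode_recording.oscillation_segments():
            n_skip = (sl.stop - sl.start) // 5
            window = slice(sl.start + n_skip, sl.stop)
            t = np_mode_recording.time[window]
            phi = (
                extract_sinusoid(t - t[0], np_mode_recording.load[window], f).phase
                - extract_sinusoid(t - t[0], h[window], f).phase
            )
            phi = (phi + math.pi) % (2 * math.pi) - math.pi
            assert phi > -1e-3

    def test_true_indentation_never_negative(self, sls_recording):
        assert np.all(sls_recording.true_indentation >= 0.0)

    def test_elastic_sample_noise_free_zero_phase(self, quiet_probe, contact, short_protocol, short_settings):
        rec = md.simulate_measurement(
            md.RheologyModel.elastic(20000.0),
            quiet_probe,
            contact,
            short_protocol,
            seed=1,
            settings=short_settings,
        )
        res = md.analyze_sweep(rec)
        assert np.all(np.abs(res.data["phase_rad"]) < 2e-3)

    def test_rigid_sample_piezo_tracks_deflection(self, quiet_probe, contact, short_protocol, short_settings):
        """On glass, h ~ 0: piezo motion goes entirely into cantilever bending."""
        rec = md.simulate_measurement(
            None, quiet_probe, contact, short_protocol, seed=2, settings=short_settings
        )
        sl = rec.segment_slice("hold")
        dz = rec.piezo_position[sl][-1] - rec.piezo_position[sl][0]
        dd = rec.deflection[sl][-1] - rec.deflection[sl][0]
        assert dz == pytest.approx(dd, abs=5e-9)
        assert np.all(rec.true_indentation <= 1e-15)

    def test_unreachable_load_faults(self, sls_model, probe, contact, short_settings):
        protocol = md.SweepProtocol.np_mode(
            f_min=2.0, n_frequencies=3, hold_time=5.0, static_load=0.4
        )
        with pytest.raises((md.ProtocolFaultError, md.SimulationFaultError)):
            md.simulate_measurement(
                sls_model, probe, contact, protocol, seed=1, settings=short_settings
            )

    def test_no_contact_when_sample_out_of_reach(self, sls_model, quiet_probe, contact, short_protocol):
        # drift-free probe: with readout drift a long enough approach would
        # (realistically) fake a contact through the rising deflection offset
        settings = md.TwinSettings(
            approach_start_gap=600e-6, piezo_travel=500e-6, load_ramp_time=2.0
        )
        with pytest.raises(md.NoContactError):
            md.simulate_measurement(
                sls_model, quiet_probe, contact, short_protocol, seed=1, settings=settings
            )


class TestDetectContact:
    def _synthetic_recording(self, load, fs=1000.0, k=65.0):
        n = load.size
        meta = {
            "probe.spring_constant": k,
            "probe.deflection_noise_rms": 0.0,
            "protocol.sample_rate": fs,
            "seed": 0,
        }
        return md.Recording(
            time=np.arange(n) / fs,
            piezo_position=np.linspace(0, 20e-6, n),
            deflection=load / k,
            load=load,
            segment_labels=np.array(["approach"] * n, dtype=object),
            metadata=meta,
        )

    def test_detects_persistent_crossing_on_elastic_ramp(self, quiet_probe, contact, short_protocol, short_settings):
        rec = md.simulate_measurement(
            md.RheologyModel.elastic(20000.0),
            quiet_probe,
            contact,
            short_protocol,
            seed=1,
            settings=short_settings,
        )
        det = md.detect_contact(rec)
        true_z = float(rec.metadata["sim.true_contact_position"])
        assert det.z_contact == pytest.approx(true_z, abs=0.5e-6)

    def test_all_noise_recording_raises(self):
        rng = np.random.default_rng(0)
        rec = self._synthetic_recording(rng.normal(0, 1e-9, 2000))
        with pytest.raises(md.NoContactError):
            md.detect_contact(rec, threshold=1e-7)

    def test_single_sample_spike_rejected(self):
        load = np.zeros(3000)
        load[500] = 5e-6  # spurious pre-contact spike (lumen contamination)
        load[2000:] = np.linspace(0, 50e-6, 1000)  # true contact ramp
        rec = self._synthetic_recording(load)
        det = md.detect_contact(rec, threshold=1e-6, debounce_time=0.02)
        assert det.index > 2000


class TestCalibration:
    def test_ideal_probe_unity_scale_and_surface_offset(self, probe, contact, short_protocol, short_settings):
        rec = md.simulate_measurement(
            None, probe, contact, short_protocol, seed=2, settings=short_settings
        )
        cal = md.calibrate_on_glass(rec)
        assert cal.scale == pytest.approx(1.0, abs=5e-3)
        assert cal.offset == pytest.approx(
            float(rec.metadata["sim.true_contact_position"]), abs=0.2e-6
        )

    def test_recovers_injected_miscalibration(self, contact, short_protocol, short_settings):
        probe = md.ProbeConfig(deflection_sensitivity=1.03)
        rec = md.simulate_measurement(
            None, probe, contact, short_protocol, seed=2, settings=short_settings
        )
        cal = md.calibrate_on_glass(rec)
        assert cal.scale == pytest.approx(1.03, abs=5e-3)
        corrected = md.apply_calibration(rec, cal)
        cal2 = md.calibrate_on_glass(corrected)
        assert cal2.scale == pytest.approx(1.0, abs=5e-3)

    def test_badly_miscalibrated_probe_rejected(self, contact, short_protocol, short_settings):
        probe = md.ProbeConfig(deflection_sensitivity=0.7)
        rec = md.simulate_measurement(
            None, probe, contact, short_protocol, seed=2, settings=short_settings
        )
        with pytest.raises(md.ProbeRejectionError):
            md.calibrate_on_glass(rec)
        cal = md.calibrate_on_glass(rec, raise_on_reject=False)
        assert not cal.ok

    def test_soft_sample_recording_rejected_for_calibration(self, sls_recording):
        with pytest.raises(md.ParameterError):
            md.calibrate_on_glass(sls_recording)
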