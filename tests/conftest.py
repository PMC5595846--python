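"""Shared fixtures.

Expensive closed-loop simulations are session-scoped and reused across test
modules; short protocols (reduced hold, fewer frequencies) are used wherever
the property under test does not depend on the full study protocol.
"""

import numpy as np
import pytest

import microdma as md


@pytest.fixture(scope="session")
def probe():
    return md.ProbeConfig()


@pytest.fixture(scope="session")
def quiet_probe():
    """Noise- and drift-free probe for deterministic oracle checks."""
    return md.ProbeConfig(deflection_noise_rms=0.0, drift_rate=0.0)


@pytest.fixture(scope="session")
def contact(probe):
    return md.ContactConfig(bead_radius=probe.bead_radius)


@pytest.fixture(scope="session")
def sls_model():
    """Soft standard-linear-solid sample in the measured tissue range."""
    return md.RheologyModel.standard_linear_solid(2000.0, 4000.0, 0.3)


@pytest.fixture(scope="session")
def short_protocol():
    """Fast protocol for tests that only need a valid closed-loop recording."""
    return md.SweepProtocol.np_mode(f_min=2.0, n_frequencies=3, hold_time=5.0)


@pytest.fixture(scope="session")
def short_settings():
    return md.TwinSettings(load_ramp_time=2.0)


@pytest.fixture(scope="session")
def sls_recording(sls_model, probe, contact, short_protocol, short_settings):
    return md.simulate_measurement(
        sls_model, probe, contact, short_protocol, seed=11, settings=short_settings
    )


@pytest.fixture(scope="session")
def np_mode_recording(sls_model, probe, contact):
    """Full NP-mode protocol recording (default hold, 5 frequencies)."""
    return md.simulate_measurement(
        sls_model, probe, contact, md.SweepProtocol.np_mode(), seed=1
    )


@pytest.fixture(scope="session")
def noise_free_full_band(sls_model, quiet_probe, contact):
    """Noise-free full-band (15-frequency) recording of the soft SLS sample."""
    return md.simulate_measurement(
        sls_model, quiet_probe, contact, md.SweepProtocol(), seed=1
    )


def relative_errors(result, model):
    """Per-row relative recovery errors (storage, loss) against ground truth."""
    errs = []
    for i, f in enumerate(result.frequencies):
        truth = md.complex_modulus(model, float(f))
        errs.append(
            (
                (result.storage[i] - truth.storage) / truth.storage,
                (result.loss[i] - truth.loss) / truth.loss if truth.loss else np.nan,
            )
        )
    return np.array(errs)
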