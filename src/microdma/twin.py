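"""Digital twin of the needle-based ferrule-top indenter.

The twin couples, in closed loop and at a control rate an order of magnitude
above the recording rate:

* a quasi-static cantilever (``F = k d``; the sweep band tops out at 10 Hz,
  orders of magnitude below any cantilever resonance, so inertia is ignored);
* a piezo actuator driven either at constant velocity (approach / retract) or
  by a gain-scheduled PI controller on the load error (load-controlled hold
  and oscillation segments);
* a Hertzian spherical contact with a linear-viscoelastic half-space, via the
  hereditary form ``F(t) = c_geom * (G # d(h^{3/2}))`` (``#`` = Stieltjes
  convolution with the shear relaxation kernel), each Maxwell branch advanced
  by its exact exponential update;
* an interferometric deflection measurement with additive white noise, slow
  linear drift and an optional sensitivity miscalibration;
* an optional stick-slip transmission between piezo and probe emulating
  needle-shaft friction at very low speeds (off by default), which is the
  instrument's documented low-frequency failure mode.

The protocol state machine matches the measurement procedure: approach at
constant speed, debounced contact detection, ramp to the static load, hold
(>= 60 s by default, letting the tissue dissipate), one oscillation segment
per grid frequency in increasing order, retract.  ``simulate_measurement``
with identical configuration and seed returns a bit-identical Recording.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _engine
from .contact import ContactConfig
from .errors import (
    NoContactError,
    ParameterError,
    ProbeRejectionError,
    ProtocolFaultError,
    SimulationFaultError,
)
from .interferometer import CavityConfig, fringe_intensity
from .rheology import RheologyModel, branch_arrays

__all__ = [
    "ProbeConfig",
    "SweepProtocol",
    "StickSlipConfig",
    "TwinSettings",
    "Recording",
    "SegmentPlan",
    "ContactDetection",
    "CalibrationResult",
    "generate_frequency_grid",
    "plan_segments",
    "simulate_measurement",
    "detect_contact",
    "calibrate_on_glass",
    "apply_calibration",
]

#: Absolute floor for the contact-detection threshold (N), used when the
#: configured deflection noise is zero.
MIN_CONTACT_THRESHOLD = 1e-8

FORMAT_VERSION = "microdma-recording-1"


@dataclass(frozen=True)
class ProbeConfig:
    """Cantilever probe and measurement-noise description.

    Attributes
    ----------
    spring_constant : float
        k in N/m (fabricated probes fall in the 60-70 N/m band).
    bead_radius : float
        Sphere radius in m; must match the ContactConfig used downstream.
    deflection_noise_rms : float
        White measurement noise on the deflection channel, m RMS per sample.
    drift_rate : float
        Slow linear drift of the deflection readout, m/s.
    deflection_sensitivity : float
        Multiplicative readout miscalibration (ideal 1.0); recoverable by
        :func:`calibrate_on_glass`.
    """

    spring_constant: float = 65.0
    bead_radius: float = 150e-6
    deflection_noise_rms: float = 3e-10
    drift_rate: float = 1e-9
    deflection_sensitivity: float = 1.0

    def __post_init__(self) -> None:
        if not self.spring_constant > 0:
            raise ParameterError(f"spring_constant must be > 0, got {self.spring_constant}")
        if not self.bead_radius > 0:
            raise ParameterError(f"bead_radius must be > 0, got {self.bead_radius}")
        if self.deflection_noise_rms < 0 or self.drift_rate < 0:
            raise ParameterError("noise and drift must be >= 0")
        if not self.deflection_sensitivity > 0:
            raise ParameterError("deflection_sensitivity must be > 0")


@dataclass(frozen=True)
class SweepProtocol:
    """Load-controlled frequency-sweep protocol.

    Defaults follow the measurement procedure: 300 uN static load with 10 uN
    oscillation amplitude (the source protocol prints these numbers without
    units; the uN reading is consistent with a 60-70 N/m cantilever on
    kPa-scale samples and is recorded as an assumption), 15 log-spaced
    frequencies over 0.05-10 Hz in ``full_band`` mode or 5 over 0.5-10 Hz in
    ``np_mode``, 5 oscillation periods per frequency, at least 60 s of static
    hold, 100 um retraction, 1 kHz recording rate.
    """

    static_load: float = 300e-6
    oscillation_amplitude: float = 10e-6
    f_min: float = 0.05
    f_max: float = 10.0
    n_frequencies: int = 15
    periods_per_frequency: int = 5
    hold_time: float = 60.0
    retract_distance: float = 100e-6
    sample_rate: float = 1000.0
    mode: str = "full_band"

    def __post_init__(self) -> None:
        if self.mode not in ("full_band", "np_mode"):
            raise ParameterError(f"mode must be 'full_band' or 'np_mode', got {self.mode!r}")
        if not 0 < self.f_min < self.f_max:
            raise ParameterError("need 0 < f_min < f_max")
        if self.n_frequencies < 2:
            raise ParameterError(f"n_frequencies must be >= 2, got {self.n_frequencies}")
        if self.periods_per_frequency < 1:
            raise ParameterError("periods_per_frequency must be >= 1")
        if not 0 < self.oscillation_amplitude < self.static_load:
            raise ParameterError("need 0 < oscillation_amplitude < static_load")
        if self.hold_time < 0 or self.retract_distance < 0:
            raise ParameterError("hold_time and retract_distance must be >= 0")
        if not self.sample_rate > 0:
            raise ParameterError("sample_rate must be > 0")

    @classmethod
    def full_band(cls, **overrides) -> "SweepProtocol":
        """15 log-spaced frequencies, 0.05-10 Hz."""
        return cls(**overrides)

    @classmethod
    def np_mode(cls, **overrides) -> "SweepProtocol":
        """Shortened in-situ protocol: 5 log-spaced frequencies, 0.5-10 Hz."""
        defaults = dict(f_min=0.5, f_max=10.0, n_frequencies=5, mode="np_mode")
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class StickSlipConfig:
    """Needle-shaft friction artifact on the piezo-to-probe transmission.

    When enabled, the probe base only follows the commanded piezo position
    while the commanded speed exceeds ``v_stick``; below it the probe sticks
    until the accumulated position error exceeds ``breakaway``, then slips.
    At the lowest sweep frequencies the commanded velocity spends most of the
    cycle below ``v_stick``, turning the indentation waveform into a
    staircase and corrupting the fitted phase -- the documented origin of
    unreliable loss moduli at the low end of the band.
    """

    enabled: bool = False
    v_stick: float = 8e-6  # m/s
    breakaway: float = 0.5e-6  # m
    dwell_time: float = 0.4  # s below v_stick before the junction sets
    velocity_smoothing: float = 0.05  # s; EMA time constant of the speed gate


@dataclass(frozen=True)
class TwinSettings:
    """Simulation-side knobs that are not part of the measurement protocol."""

    approach_start_gap: float = 10e-6  # probe-sample gap at t = 0 [m]
    approach_speed: float = 20e-6  # [m/s]
    load_ramp_time: float = 5.0  # ramp from contact to static load [s]
    retract_speed: float = 50e-6  # [m/s]
    piezo_travel: float = 500e-6  # [m]
    max_piezo_speed: float = 1e-3  # slew limit [m/s]
    contact_threshold: Optional[float] = None  # [N]; None -> 5 x load noise RMS
    debounce_time: float = 0.02  # persistent-crossing window [s]
    control_oversample: int = 10  # control steps per recorded sample
    controller_alpha: float = 0.2  # fraction of load error corrected per step
    controller_ti: float = 0.02  # integral time [s]
    friction: StickSlipConfig = field(default_factory=StickSlipConfig)

    def resolve_threshold(self, probe: ProbeConfig) -> float:
        if self.contact_threshold is not None:
            return self.contact_threshold
        return max(
            5.0 * probe.spring_constant * probe.deflection_noise_rms,
            MIN_CONTACT_THRESHOLD,
        )


@dataclass
class Recording:
    """Uniformly sampled indentation recording with protocol annotations.

    ``deflection`` normally holds the calibrated cantilever deflection in m
    and ``load = k * deflection``; when ``metadata['channel_role']`` is
    ``'intensity'`` the same column holds raw interferometer intensity
    (arbitrary units) and ``load`` is NaN until demodulation.

    ``true_indentation`` is twin ground truth (not serialized): the actual
    indentation depth h(t), useful for validating the analysis chain.
    """

    time: np.ndarray
    piezo_position: np.ndarray
    deflection: np.ndarray
    load: np.ndarray
    segment_labels: np.ndarray
    metadata: dict
    true_indentation: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("piezo_position", "deflection", "load", "segment_labels"):
            if len(getattr(self, name)) != n:
                raise ParameterError(f"column {name} length mismatch")

    @property
    def sample_rate(self) -> float:
        return float(self.metadata["protocol.sample_rate"])

    def segments(self) -> list[tuple[str, slice]]:
        """Contiguous runs of identical segment labels, in time order."""
        labels = self.segment_labels
        out: list[tuple[str, slice]] = []
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                out.append((str(labels[start]), slice(start, i)))
                start = i
        return out

    def segment_slice(self, label: str) -> slice:
        for lab, sl in self.segments():
            if lab == label:
                return sl
        raise KeyError(f"no segment labeled {label!r}")

    def oscillation_segments(self) -> list[tuple[float, slice]]:
        """(frequency, slice) for each oscillation segment, increasing f."""
        out = []
        for lab, sl in self.segments():
            if lab.startswith("oscillation@"):
                out.append((float(lab.split("@", 1)[1]), sl))
        return out


@dataclass(frozen=True)
class SegmentPlan:
    """Planned length of one post-approach protocol segment."""

    kind: str  # ramp | hold | oscillation | retract
    label: str
    n_samples: int  # at the recording rate
    frequency: float = 0.0


@dataclass(frozen=True)
class ContactDetection:
    index: int
    z_contact: float


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the glass calibration: deflection sensitivity and offset."""

    scale: float
    offset: float
    ok: bool


def generate_frequency_grid(protocol: SweepProtocol) -> np.ndarray:
    """Log-spaced sweep frequencies, inclusive of both ends, increasing."""
    return np.geomspace(protocol.f_min, protocol.f_max, protocol.n_frequencies)


def frequency_label(frequency: float) -> str:
    return f"oscillation@{frequency!r}"


def plan_segments(protocol: SweepProtocol, settings: TwinSettings) -> list[SegmentPlan]:
    """Lengths of all post-approach segments at the recording rate.

    Shared by the twin and by the recording reader (reconstruction of
    missing segment labels), so both always agree on the rounding.
    """
    fs = protocol.sample_rate
    plans = [
        SegmentPlan("ramp", "hold", int(round(settings.load_ramp_time * fs))),
        SegmentPlan("hold", "hold", int(round(protocol.hold_time * fs))),
    ]
    for f in generate_frequency_grid(protocol):
        # ceil: each segment must span at least periods_per_frequency periods
        n = int(math.ceil(protocol.periods_per_frequency / f * fs - 1e-9))
        plans.append(SegmentPlan("oscillation", frequency_label(float(f)), n, float(f)))
    n_retract = int(round(protocol.retract_distance / settings.retract_speed * fs))
    plans.append(SegmentPlan("retract", "retract", n_retract))
    return plans


def _config_hash(meta: dict) -> str:
    """Short stable hash over all configuration metadata."""
    payload = "\n".join(
        f"{k}={meta[k]!r}" for k in sorted(meta) if not k.startswith("sim.")
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _model_metadata(model: Optional[RheologyModel]) -> dict:
    if model is None:
        return {"model.kind": "rigid"}
    meta = {"model.kind": model.kind}
    for key in sorted(model.parameters):
        meta[f"model.{key}"] = float(model.parameters[key])
    return meta


def build_metadata(
    model: Optional[RheologyModel],
    probe: ProbeConfig,
    contact: ContactConfig,
    protocol: SweepProtocol,
    settings: TwinSettings,
    seed: int,
    fidelity: str = "deflection",
    cavity: Optional[CavityConfig] = None,
) -> dict:
    meta = {
        "format": FORMAT_VERSION,
        "probe.spring_constant": probe.spring_constant,
        "probe.bead_radius": probe.bead_radius,
        "probe.deflection_noise_rms": probe.deflection_noise_rms,
        "probe.drift_rate": probe.drift_rate,
        "probe.deflection_sensitivity": probe.deflection_sensitivity,
        "contact.bead_radius": contact.bead_radius,
        "contact.poisson_ratio": contact.poisson_ratio,
        "protocol.static_load": protocol.static_load,
        "protocol.oscillation_amplitude": protocol.oscillation_amplitude,
        "protocol.f_min": protocol.f_min,
        "protocol.f_max": protocol.f_max,
        "protocol.n_frequencies": protocol.n_frequencies,
        "protocol.periods_per_frequency": protocol.periods_per_frequency,
        "protocol.hold_time": protocol.hold_time,
        "protocol.retract_distance": protocol.retract_distance,
        "protocol.sample_rate": protocol.sample_rate,
        "protocol.mode": protocol.mode,
        "settings.approach_start_gap": settings.approach_start_gap,
        "settings.approach_speed": settings.approach_speed,
        "settings.load_ramp_time": settings.load_ramp_time,
        "settings.retract_speed": settings.retract_speed,
        "settings.piezo_travel": settings.piezo_travel,
        "settings.contact_threshold": settings.resolve_threshold(probe),
        "settings.debounce_time": settings.debounce_time,
        "settings.control_oversample": settings.control_oversample,
        "settings.friction_enabled": settings.friction.enabled,
        "channel_role": "intensity" if fidelity == "raw_intensity" else "deflection",
        "seed": int(seed),
    }
    meta.update(_model_metadata(model))
    if fidelity == "raw_intensity":
        cav = cavity or CavityConfig()
        meta.update(
            {
                "cavity.wavelength": cav.wavelength,
                "cavity.rest_cavity_length": cav.rest_cavity_length,
                "cavity.fringe_visibility": cav.fringe_visibility,
                "cavity.mean_intensity": cav.mean_intensity,
                "cavity.wavelength_modulation_depth": cav.wavelength_modulation_depth,
                "cavity.modulation_frequency": cav.modulation_frequency,
            }
        )
    meta["config_hash"] = _config_hash(meta)
    return meta


def simulate_measurement(
    model: Optional[RheologyModel],
    probe: ProbeConfig,
    contact: ContactConfig,
    protocol: SweepProtocol,
    seed: int,
    settings: Optional[TwinSettings] = None,
    fidelity: str = "deflection",
    cavity: Optional[CavityConfig] = None,
) -> Recording:
    """Execute the full measurement protocol on a simulated sample.

    Parameters
    ----------
    model : RheologyModel or None
        Sample ground truth; ``None`` simulates a rigid (glass) substrate
        for the calibration procedure.
    probe, contact, protocol : configuration dataclasses.
    seed : int
        Seeds all measurement noise; identical inputs give a bit-identical
        Recording.
    settings : TwinSettings, optional
    fidelity : {'deflection', 'raw_intensity'}
        At ``raw_intensity`` the deflection channel is converted to the raw
        modulated interferometer intensity (requires ``sample_rate >= 10 x``
        the cavity modulation frequency).
    cavity : CavityConfig, optional
        Only used at raw_intensity fidelity.

    Raises
    ------
    NoContactError, ProtocolFaultError, SimulationFaultError, ParameterError
    """
    settings = settings or TwinSettings()
    if model is not None and not model.supports_time_domain:
        raise ParameterError(
            f"model kind {model.kind!r} is frequency-domain only and cannot drive the twin"
        )
    if not math.isclose(probe.bead_radius, contact.bead_radius, rel_tol=1e-9):
        raise ParameterError("probe.bead_radius and contact.bead_radius must agree")
    if fidelity not in ("deflection", "raw_intensity"):
        raise ParameterError(f"unknown fidelity {fidelity!r}")
    cav = cavity or CavityConfig()
    if fidelity == "raw_intensity" and protocol.sample_rate < 10.0 * cav.modulation_frequency:
        raise ParameterError(
            "raw_intensity fidelity needs sample_rate >= 10 x cavity modulation frequency"
        )

    fs = protocol.sample_rate
    ov = settings.control_oversample
    dtc = 1.0 / (fs * ov)

    rigid = model is None
    if rigid:
        g_e, g_b, tau_b, eta = 0.0, np.zeros(0), np.ones(0), 0.0
    else:
        g_e, g_b, tau_b, eta = branch_arrays(model)
    decay = np.exp(-dtc / tau_b) if g_b.size else np.zeros(0)
    gain = g_b * (tau_b / dtc) * (1.0 - decay) if g_b.size else np.zeros(0)
    b_sum = float(np.sum(gain)) + eta / dtc
    nu = contact.poisson_ratio
    c_geom = 8.0 * math.sqrt(contact.bead_radius) / (3.0 * (1.0 - nu))

    k = probe.spring_constant
    threshold = settings.resolve_threshold(probe)
    n_debounce = max(1, int(round(settings.debounce_time / dtc)))
    z_surface = settings.approach_start_gap
    rng = np.random.default_rng(seed)

    state = np.zeros(_engine.STATE_SIZE)
    sigma = np.zeros(g_b.size)
    gstep = 0
    chunks: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]] = []

    def run(mode, n_steps, *, setpoint=None, speed=0.0, detect=False, label=""):
        nonlocal gstep
        if n_steps <= 0:
            return 0, -1, _engine.FAULT_NONE
        if setpoint is None:
            setpoint = np.zeros(0)
        if probe.deflection_noise_rms > 0:
            noise = rng.normal(0.0, probe.deflection_noise_rms, n_steps)
        else:
            noise = np.zeros(n_steps)
        cap = n_steps // ov + 2
        rec_zp = np.empty(cap)
        rec_d = np.empty(cap)
        rec_h = np.empty(cap)
        n_rec, n_done, detect_step, fault = _engine.integrate_segment(
            mode,
            setpoint,
            speed,
            n_steps,
            dtc,
            k,
            probe.deflection_sensitivity,
            c_geom,
            rigid,
            g_e,
            decay,
            gain,
            sigma,
            b_sum,
            z_surface,
            settings.piezo_travel,
            settings.max_piezo_speed,
            settings.controller_alpha,
            settings.controller_ti,
            1e-3 * k,
            2e-3 * settings.controller_ti,
            int(round(0.5 / dtc)),
            noise,
            probe.drift_rate,
            gstep * dtc,
            settings.friction.enabled,
            settings.friction.v_stick,
            settings.friction.breakaway,
            max(1, int(round(settings.friction.dwell_time / dtc))),
            min(1.0, dtc / settings.friction.velocity_smoothing),
            detect,
            threshold,
            n_debounce,
            state,
            ov,
            gstep,
            rec_zp,
            rec_d,
            rec_h,
        )
        gstep += n_done
        if n_rec:
            chunks.append((label, rec_zp[:n_rec], rec_d[:n_rec], rec_h[:n_rec]))
        if fault == _engine.FAULT_RANGE:
            raise ProtocolFaultError("load setpoint unreachable within piezo travel")
        if fault == _engine.FAULT_DIVERGED:
            raise SimulationFaultError("cantilever deflection diverged; control loop unstable")
        return n_rec, detect_step, fault

    # -- approach ----------------------------------------------------------
    n_max = int(math.ceil(settings.piezo_travel / settings.approach_speed / dtc))
    _, detect_step, _ = run(
        _engine.MODE_POSITION,
        n_max,
        speed=settings.approach_speed,
        detect=True,
        label="approach",
    )
    if detect_step < 0:
        raise NoContactError("no persistent load-threshold crossing during approach")
    # pad to the next recording-sample boundary so all later segments align
    run(
        _engine.MODE_POSITION,
        (-gstep) % ov,
        speed=settings.approach_speed,
        label="approach",
    )

    # -- load-controlled phases --------------------------------------------
    f_start = state[_engine.IDX_FMEAS]
    for plan in plan_segments(protocol, settings):
        n_ctrl = plan.n_samples * ov
        t_local = np.arange(n_ctrl) * dtc
        if plan.kind == "ramp":
            frac = t_local / (plan.n_samples / fs)
            sp = f_start + (protocol.static_load - f_start) * frac
            run(_engine.MODE_LOAD, n_ctrl, setpoint=sp, label=plan.label)
        elif plan.kind == "hold":
            sp = np.full(n_ctrl, protocol.static_load)
            run(_engine.MODE_LOAD, n_ctrl, setpoint=sp, label=plan.label)
        elif plan.kind == "oscillation":
            sp = protocol.static_load + protocol.oscillation_amplitude * np.sin(
                2.0 * math.pi * plan.frequency * t_local
            )
            run(_engine.MODE_LOAD, n_ctrl, setpoint=sp, label=plan.label)
        else:  # retract
            run(
                _engine.MODE_POSITION,
                n_ctrl,
                speed=-settings.retract_speed,
                label=plan.label,
            )

    # -- assemble ----------------------------------------------------------
    labels = np.concatenate([np.full(len(c[1]), c[0], dtype=object) for c in chunks])
    z_p = np.concatenate([c[1] for c in chunks])
    d_meas = np.concatenate([c[2] for c in chunks])
    h_true = np.concatenate([c[3] for c in chunks])
    n = len(z_p)
    time = np.arange(n) / fs
    load = k * d_meas
    meta = build_metadata(model, probe, contact, protocol, settings, seed, fidelity, cav)
    meta["sim.true_contact_position"] = z_surface

    if fidelity == "raw_intensity":
        intensity = fringe_intensity(d_meas, cav, time)
        return Recording(
            time, z_p, intensity, np.full(n, np.nan), labels, meta, true_indentation=h_true
        )
    return Recording(time, z_p, d_meas, load, labels, meta, true_indentation=h_true)


def detect_contact(
    recording: Recording,
    threshold: Optional[float] = None,
    debounce_time: float = 0.02,
) -> ContactDetection:
    """Debounced contact detection on the approach segment of a recording.

    Returns the first sample of a run of at least ``debounce_time`` during
    which the load persistently exceeds ``threshold`` (shorter spurious
    spikes, e.g. from lumen contamination, are rejected), together with the
    contact position ``z_contact = z_p - threshold / k`` extrapolated back
    through the cantilever compliance.

    ``threshold`` defaults to five times the load noise RMS recorded in the
    metadata (with a 10 nN floor).
    """
    k = float(recording.metadata["probe.spring_constant"])
    if threshold is None:
        noise = float(recording.metadata.get("probe.deflection_noise_rms", 0.0))
        threshold = max(5.0 * k * noise, MIN_CONTACT_THRESHOLD)
    try:
        sl = recording.segment_slice("approach")
    except KeyError as exc:
        raise NoContactError("recording has no approach segment") from exc
    load = recording.load[sl]
    window = max(1, int(round(debounce_time * recording.sample_rate)))
    above = load > threshold
    if len(above) >= window:
        runsum = np.convolve(above.astype(int), np.ones(window, dtype=int), mode="valid")
        hits = np.flatnonzero(runsum == window)
    else:
        hits = np.array([], dtype=int)
    if hits.size == 0:
        raise NoContactError(
            f"no {window}-sample run above threshold {threshold:.3g} N in the approach"
        )
    idx = int(hits[0]) + sl.start
    z_contact = float(recording.piezo_position[idx] - threshold / k)
    return ContactDetection(index=idx, z_contact=z_contact)


def calibrate_on_glass(
    recording: Recording,
    slope_bound: float = 0.1,
    raise_on_reject: bool = True,
) -> CalibrationResult:
    """Deflection sensitivity and geometric offset from a rigid-substrate run.

    On glass the indentation depth is zero, so deflection tracks piezo
    position one-to-one: a linear fit of deflection vs piezo position over
    the loaded region gives the sensitivity scale (ideal 1.0) and the contact
    offset.  A slope deviating from 1 by more than ``slope_bound`` signals an
    unusable probe (discard and replace).
    """
    if recording.metadata.get("model.kind") not in (None, "rigid"):
        raise ParameterError("calibration requires a rigid-substrate recording")
    load = recording.load
    # fit over the loading ramp only: during the static hold the piezo is
    # essentially stationary, so readout drift there would bias the slope
    peak = float(np.max(load))
    sel = (load > 0.1 * peak) & (load < 0.9 * peak)
    if int(np.count_nonzero(sel)) < 10:
        raise ParameterError("not enough loaded samples for a calibration fit")
    slope, intercept = np.polyfit(
        recording.piezo_position[sel], recording.deflection[sel], 1
    )
    ok = abs(slope - 1.0) <= slope_bound
    result = CalibrationResult(scale=float(slope), offset=float(-intercept / slope), ok=ok)
    if raise_on_reject and not ok:
        raise ProbeRejectionError(
            f"calibration slope {slope:.3f} deviates from 1 by more than {slope_bound}"
        )
    return result


def apply_calibration(recording: Recording, calibration: CalibrationResult) -> Recording:
    """Rescale the deflection channel by the calibrated sensitivity."""
    k = float(recording.metadata["probe.spring_constant"])
    deflection = recording.deflection / calibration.scale
    meta = dict(recording.metadata)
    meta["calibration.scale"] = calibration.scale
    return Recording(
        recording.time,
        recording.piezo_position,
        deflection,
        k * deflection,
        recording.segment_labels,
        meta,
        true_indentation=recording.true_indentation,
    )
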