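"""Analysis pipeline: recording -> frequency-dependent G', G''.

Per oscillation segment the pipeline discards a configurable number of
transient periods, fits single-frequency sinusoids (with offset and linear
drift terms) to the load and indentation channels by least squares -- the
software equivalent of lock-in detection, exact at the known drive frequency
-- and inverts the amplitude ratio and phase lag through the linearized
Hertz contact to the complex shear modulus.

The phase lag is formed as the *difference* of the two fitted phases, so the
per-channel phase convention (and any common time shift) cancels.  Small
negative phase differences within the fit's own phase-noise bound are
clipped to zero and flagged rather than propagated as negative loss moduli
(passivity prior); larger violations and waveform distortion (large
non-sinusoidal fit residuals, the signature of stick-slip corrupted
low-frequency segments) are flagged as unreliable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .contact import (
    DEFAULT_GEOMETRY_BOUND,
    DEFAULT_LINEARITY_BOUND,
    ContactConfig,
    OscillationObservation,
    moduli_from_oscillation,
)
from .errors import FormatError, InsufficientDataError, ParameterError
from .interferometer import CavityConfig, demodulate
from .twin import Recording, detect_contact

__all__ = [
    "FLAG_LINEARITY",
    "FLAG_GEOMETRY",
    "FLAG_MAX_DEPTH",
    "FLAG_PHASE_CLIPPED",
    "FLAG_PHASE_RANGE",
    "FLAG_DISTORTION",
    "SinusoidFit",
    "AnalysisSettings",
    "SweepResult",
    "AggregateResult",
    "extract_sinusoid",
    "analyze_sweep",
    "aggregate_sweeps",
    "resolve_channels",
]

FLAG_LINEARITY = "linearity"
FLAG_GEOMETRY = "geometry"
FLAG_MAX_DEPTH = "max_depth"
FLAG_PHASE_CLIPPED = "phase_clipped"
FLAG_PHASE_RANGE = "phase_range"
FLAG_DISTORTION = "waveform_distortion"

RESULT_COLUMNS = [
    "frequency_hz",
    "F1_N",
    "h1_m",
    "phase_rad",
    "h0_m",
    "G_storage_Pa",
    "G_loss_Pa",
    "qc_flags",
]


@dataclass(frozen=True)
class SinusoidFit:
    """Least-squares fit of ``a sin + b cos + c + e t`` at a known frequency.

    ``phase`` follows the convention ``y = amplitude * sin(2 pi f t + phase)``
    with ``phase = atan2(b, a)``; identical for every channel, so phase
    differences between channels are convention-free.
    """

    amplitude: float
    phase: float
    offset: float
    drift_slope: float
    residual_rms: float
    n_samples: int

    @property
    def phase_sigma(self) -> float:
        """Phase standard error assuming white residuals."""
        if self.amplitude == 0:
            return math.inf
        return (self.residual_rms / self.amplitude) * math.sqrt(2.0 / self.n_samples)


@dataclass(frozen=True)
class AnalysisSettings:
    """Tunable bounds of the sweep analysis (all dimensionless or SI)."""

    discard_periods: float = 1.0  # transient periods dropped before fitting
    linearity_bound: float = DEFAULT_LINEARITY_BOUND  # max h1/h0
    geometry_bound: float = DEFAULT_GEOMETRY_BOUND  # max h0/R
    max_static_depth: float = 40e-6  # m
    distortion_bound: float = 0.1  # max residual RMS / amplitude
    phase_clip_sigmas: float = 4.0  # clip window for small negative phases
    min_phase_clip: float = 2e-4  # rad; floor of the clip window
    contact_threshold: Optional[float] = None  # N; None -> from metadata
    debounce_time: float = 0.02  # s
    z_contact: Optional[float] = None  # m; override contact detection


@dataclass
class SweepResult:
    """Per-frequency moduli and QC flags for one analyzed sweep."""

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def frequencies(self) -> np.ndarray:
        return self.data["frequency_hz"].to_numpy()

    @property
    def storage(self) -> np.ndarray:
        return self.data["G_storage_Pa"].to_numpy()

    @property
    def loss(self) -> np.ndarray:
        return self.data["G_loss_Pa"].to_numpy()

    def flags(self, row: int) -> frozenset[str]:
        raw = self.data["qc_flags"].iloc[row]
        return frozenset(raw.split("|")) if raw else frozenset()

    def unflagged(self, ignore: Sequence[str] = ()) -> np.ndarray:
        """Boolean mask of rows whose flags (minus ``ignore``) are empty."""
        ignore_set = set(ignore)
        return np.array(
            [not (self.flags(i) - ignore_set) for i in range(len(self.data))]
        )


@dataclass
class AggregateResult:
    """Per-frequency mean and dispersion over repeated sweeps."""

    data: pd.DataFrame
    n_sweeps: int
    metadata: dict = field(default_factory=dict)


def extract_sinusoid(time: np.ndarray, values: np.ndarray, frequency: float) -> SinusoidFit:
    """Fit ``a sin(2 pi f t) + b cos(2 pi f t) + c + e (t - tbar)``.

    Raises
    ------
    InsufficientDataError
        If the segment spans fewer than 2 periods of ``frequency``.
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    if time.size < 8:
        raise InsufficientDataError(f"segment has only {time.size} samples")
    dt = time[1] - time[0]
    duration = time[-1] - time[0] + dt
    if duration < 2.0 / frequency:
        raise InsufficientDataError(
            f"segment spans {duration * frequency:.2f} periods at {frequency} Hz; need >= 2"
        )
    theta = 2.0 * math.pi * frequency * time
    tc = time - time.mean()
    design = np.column_stack([np.sin(theta), np.cos(theta), np.ones_like(time), tc])
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    a, b, c, e = coef
    residual = values - design @ coef
    return SinusoidFit(
        amplitude=float(math.hypot(a, b)),
        phase=float(math.atan2(b, a)),
        offset=float(c),
        drift_slope=float(e),
        residual_rms=float(np.sqrt(np.mean(residual**2))),
        n_samples=int(time.size),
    )


def resolve_channels(recording: Recording) -> tuple[np.ndarray, np.ndarray]:
    """Deflection and load arrays, demodulating raw-intensity recordings.

    For raw-intensity recordings the deflection column holds interferometer
    intensity; it is demodulated with the cavity parameters embedded in the
    metadata and re-anchored so the pre-contact approach start reads zero.
    """
    meta = recording.metadata
    role = meta.get("channel_role", "deflection")
    k = float(meta["probe.spring_constant"])
    if role == "deflection":
        return recording.deflection, recording.load
    if role != "intensity":
        raise FormatError(f"unknown channel_role {role!r}")
    cavity = CavityConfig(
        wavelength=float(meta["cavity.wavelength"]),
        rest_cavity_length=float(meta["cavity.rest_cavity_length"]),
        fringe_visibility=float(meta["cavity.fringe_visibility"]),
        mean_intensity=float(meta["cavity.mean_intensity"]),
        wavelength_modulation_depth=float(meta["cavity.wavelength_modulation_depth"]),
        modulation_frequency=float(meta["cavity.modulation_frequency"]),
    )
    deflection = demodulate(recording.deflection, recording.sample_rate, cavity)
    n_anchor = max(8, int(round(0.2 * recording.sample_rate)))
    deflection = deflection - float(np.median(deflection[:n_anchor]))
    return deflection, k * deflection


def _wrap_phase(phi: float) -> float:
    return (phi + math.pi) % (2.0 * math.pi) - math.pi


def analyze_sweep(
    recording: Recording,
    contact: Optional[ContactConfig] = None,
    settings: Optional[AnalysisSettings] = None,
) -> SweepResult:
    """Extract per-frequency storage and loss moduli from one recording.

    Parameters
    ----------
    recording : Recording
        Must carry labeled oscillation segments.
    contact : ContactConfig, optional
        Defaults to the geometry embedded in the recording metadata.
    settings : AnalysisSettings, optional

    Returns
    -------
    SweepResult
        Rows sorted by increasing frequency; each row carries the raw
        observables (F1, h1, phase, h0), the inverted moduli and a
        ``|``-separated QC flag string (empty when clean).
    """
    settings = settings or AnalysisSettings()
    meta = recording.metadata
    if contact is None:
        contact = ContactConfig(
            bead_radius=float(meta["contact.bead_radius"]),
            poisson_ratio=float(meta["contact.poisson_ratio"]),
        )
    deflection, load = resolve_channels(recording)

    osc = recording.oscillation_segments()
    if not osc:
        raise FormatError("recording has no labeled oscillation segments")

    if settings.z_contact is not None:
        z_contact = settings.z_contact
    else:
        rec_for_detect = recording
        if meta.get("channel_role") == "intensity":
            rec_for_detect = Recording(
                recording.time,
                recording.piezo_position,
                deflection,
                load,
                recording.segment_labels,
                {**meta, "channel_role": "deflection"},
            )
        z_contact = detect_contact(
            rec_for_detect,
            threshold=settings.contact_threshold,
            debounce_time=settings.debounce_time,
        ).z_contact

    indentation = recording.piezo_position - deflection - z_contact
    fs = recording.sample_rate

    rows = []
    for f, sl in osc:
        n_skip = int(round(settings.discard_periods / f * fs))
        window = slice(sl.start + n_skip, sl.stop)
        t = recording.time[window] - recording.time[sl.start]
        fit_f = extract_sinusoid(t, load[window], f)
        fit_h = extract_sinusoid(t, indentation[window], f)
        f1 = fit_f.amplitude
        h1 = fit_h.amplitude
        h0 = fit_h.offset
        phi = _wrap_phase(fit_f.phase - fit_h.phase)

        flags: set[str] = set()
        phase_noise = max(
            settings.phase_clip_sigmas
            * math.hypot(fit_f.phase_sigma, fit_h.phase_sigma),
            settings.min_phase_clip,
        )
        if -phase_noise <= phi < 0.0:
            phi = 0.0
            flags.add(FLAG_PHASE_CLIPPED)
        elif not 0.0 <= phi < math.pi / 2:
            flags.add(FLAG_PHASE_RANGE)
        if h1 / h0 > settings.linearity_bound:
            flags.add(FLAG_LINEARITY)
        if h0 / contact.bead_radius > settings.geometry_bound:
            flags.add(FLAG_GEOMETRY)
        if h0 > settings.max_static_depth:
            flags.add(FLAG_MAX_DEPTH)
        distortion = max(fit_f.residual_rms / f1, fit_h.residual_rms / h1)
        if distortion > settings.distortion_bound:
            flags.add(FLAG_DISTORTION)

        if h0 > 0 and f1 > 0 and h1 > 0:
            obs = OscillationObservation(f, f1, h1, abs(phi), h0)
            moduli = moduli_from_oscillation(obs, contact, check=False)
            storage = moduli.storage
            loss = math.copysign(moduli.loss, phi) if phi != 0 else 0.0
        else:  # degenerate segment; report NaN, flag as unreliable
            storage = loss = math.nan
            flags.add(FLAG_PHASE_RANGE)
        rows.append(
            {
                "frequency_hz": f,
                "F1_N": f1,
                "h1_m": h1,
                "phase_rad": phi,
                "h0_m": h0,
                "G_storage_Pa": storage,
                "G_loss_Pa": loss,
                "qc_flags": "|".join(sorted(flags)),
            }
        )

    data = pd.DataFrame(rows, columns=RESULT_COLUMNS).sort_values("frequency_hz")
    data = data.reset_index(drop=True)
    if all(row["qc_flags"] for row in rows):
        warnings.warn("all rows carry QC flags; sweep result is unreliable", stacklevel=2)
    result_meta = {
        "source_config_hash": meta.get("config_hash", ""),
        "source_seed": meta.get("seed", ""),
        "contact.bead_radius": contact.bead_radius,
        "contact.poisson_ratio": contact.poisson_ratio,
        "analysis.discard_periods": settings.discard_periods,
        "analysis.z_contact": z_contact,
    }
    return SweepResult(data=data, metadata=result_meta)


def aggregate_sweeps(
    results: Sequence[SweepResult],
    exclude_flagged: bool = True,
) -> AggregateResult:
    """Per-frequency mean and standard deviation over repeated sweeps.

    All results must share one frequency grid.  With ``exclude_flagged``
    (default) QC-flagged rows do not enter the averages; ``n_used`` records
    how many sweeps contributed at each frequency.  Dispersion is the sample
    standard deviation, zero by convention when only one value contributes.
    """
    if not results:
        raise ParameterError("need at least one SweepResult")
    from .errors import IncompatibleGridsError

    grid = results[0].frequencies
    for r in results[1:]:
        if len(r.frequencies) != len(grid) or not np.allclose(
            r.frequencies, grid, rtol=1e-9, atol=0.0
        ):
            raise IncompatibleGridsError("sweep results use different frequency grids")

    rows = []
    for i, f in enumerate(grid):
        storage_vals, loss_vals = [], []
        for r in results:
            if exclude_flagged and r.flags(i):
                continue
            storage_vals.append(r.storage[i])
            loss_vals.append(r.loss[i])
        n_used = len(storage_vals)
        if n_used == 0:
            mean_s = mean_l = sd_s = sd_l = math.nan
        else:
            mean_s = float(np.mean(storage_vals))
            mean_l = float(np.mean(loss_vals))
            sd_s = float(np.std(storage_vals, ddof=1)) if n_used > 1 else 0.0
            sd_l = float(np.std(loss_vals, ddof=1)) if n_used > 1 else 0.0
        rows.append(
            {
                "frequency_hz": f,
                "G_storage_mean_Pa": mean_s,
                "G_storage_sd_Pa": sd_s,
                "G_loss_mean_Pa": mean_l,
                "G_loss_sd_Pa": sd_l,
                "n_used": n_used,
            }
        )
    data = pd.DataFrame(rows)
    return AggregateResult(data=data, n_sweeps=len(results), metadata={"n": len(results)})
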