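"""Fabry-Perot fringe model and quadrature demodulation.

The fiber facet and the cantilever form a low-finesse two-beam cavity of rest
length L0.  With cantilever deflection d (which shortens the cavity) the
detector intensity is

    I(t) = I0 [1 + V cos(4 pi (L0 - d) / lambda_t)],

periodic in d with period lambda/2.  A high-frequency wavelength modulation
``lambda_t = lambda0 + dlambda sin(2 pi f_m t)`` imprints a phase modulation
of index ``psi = 4 pi (L0 - d) dlambda / lambda0^2`` on the cavity phase
``phi_c = 4 pi (L0 - d) / lambda0``, so the intensity spectrum carries
Bessel-weighted harmonics of f_m:

    I/I0 = 1 + V cos(phi_c) [J0(psi) + 2 J2(psi) cos(2 Omega t) + ...]
             + V sin(phi_c) [2 J1(psi) sin(Omega t) + ...].

:func:`demodulate` recovers ``phi_c`` from the first two harmonics
(phase-generated-carrier arctangent scheme): lock-in mixing at f_m and 2 f_m
gives quadrature pair ``(I0 V J1 sin phi_c, I0 V J2 cos phi_c)``; dividing by
the known Bessel factors and taking atan2 yields ``phi_c`` independent of I0
and V (ratiometric), which is then unwrapped across fringes and converted
back to deflection.  The default modulation depth sets psi = 2.63 where
J1 = J2 (the classic operating point that balances both quadratures).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.special import jv

from .errors import ParameterError, ReadoutQualityError, SimulationFaultError

__all__ = ["CavityConfig", "fringe_intensity", "demodulate"]

#: Modulation index at which J1(psi) = J2(psi); used for the default depth.
BALANCED_MODULATION_INDEX = 2.63


@dataclass
class CavityConfig:
    """Fiber-cantilever cavity and wavelength-modulation parameters.

    Attributes
    ----------
    wavelength : float
        Center wavelength lambda0 in m (default 1550 nm, the operating
        wavelength of the single-mode telecom fiber used in these probes).
    rest_cavity_length : float
        L0 in m at zero deflection.
    fringe_visibility : float
        V in (0, 1].
    mean_intensity : float
        I0 in arbitrary detector units.
    wavelength_modulation_depth : float or None
        dlambda in m; ``None`` selects the depth giving the balanced
        modulation index psi = 2.63 for this cavity.
    modulation_frequency : float
        f_m in Hz; must be far above the mechanical signal band.
    """

    wavelength: float = 1.55e-6
    rest_cavity_length: float = 300e-6
    fringe_visibility: float = 0.6
    mean_intensity: float = 1.0
    wavelength_modulation_depth: float | None = None
    modulation_frequency: float = 2000.0

    def __post_init__(self) -> None:
        if not self.wavelength > 0:
            raise ParameterError(f"wavelength must be > 0, got {self.wavelength}")
        if not self.rest_cavity_length > 0:
            raise ParameterError(f"rest_cavity_length must be > 0, got {self.rest_cavity_length}")
        if not 0.0 < self.fringe_visibility <= 1.0:
            raise ParameterError(
                f"fringe_visibility must be in (0, 1], got {self.fringe_visibility}"
            )
        if not self.modulation_frequency > 0:
            raise ParameterError(
                f"modulation_frequency must be > 0, got {self.modulation_frequency}"
            )
        if self.wavelength_modulation_depth is None:
            self.wavelength_modulation_depth = (
                BALANCED_MODULATION_INDEX
                * self.wavelength**2
                / (4.0 * math.pi * self.rest_cavity_length)
            )

    @property
    def modulation_index(self) -> float:
        """psi at zero deflection."""
        return (
            4.0
            * math.pi
            * self.rest_cavity_length
            * self.wavelength_modulation_depth
            / self.wavelength**2
        )


def fringe_intensity(deflection, cavity: CavityConfig, t):
    """Detector intensity for deflection ``d(t)`` (scalar or array).

    Uses the exact instantaneous wavelength, so all harmonics of the
    modulation (including the second-order terms a first-order demodulator
    ignores) are present in the simulated signal.

    Raises
    ------
    SimulationFaultError
        If any deflection reaches the rest cavity length (cantilever would
        crash into the fiber facet).
    """
    d = np.asarray(deflection, dtype=float)
    if np.any(d >= cavity.rest_cavity_length):
        raise SimulationFaultError("deflection reached the fiber facet (d >= L0)")
    lam_t = cavity.wavelength + cavity.wavelength_modulation_depth * np.sin(
        2.0 * math.pi * cavity.modulation_frequency * np.asarray(t, dtype=float)
    )
    phase = 4.0 * math.pi * (cavity.rest_cavity_length - d) / lam_t
    out = cavity.mean_intensity * (1.0 + cavity.fringe_visibility * np.cos(phase))
    return out if out.ndim else float(out)


def _lowpass(x: np.ndarray, cutoff: float, fs: float) -> np.ndarray:
    b, a = butter(4, cutoff / (0.5 * fs))
    return filtfilt(b, a, x)


def demodulate(
    intensity: np.ndarray,
    sample_rate: float,
    cavity: CavityConfig,
    refine: bool = True,
    visibility_floor: float = 0.05,
    envelope_dip_floor: float = 0.78,
) -> np.ndarray:
    """Recover cantilever deflection from a modulated intensity record.

    Parameters
    ----------
    intensity : ndarray
        Detector intensity sampled uniformly at ``sample_rate``.
    sample_rate : float
        Must be at least 10x the modulation frequency.
    refine : bool
        Run a second pass in which the modulation index is re-evaluated
        per-sample from the first-pass deflection (the index depends on the
        instantaneous cavity length); removes the dominant systematic of the
        single-pass arctangent scheme for multi-fringe excursions.
    visibility_floor : float
        Minimum acceptable ratio of demodulated fringe envelope to mean
        intensity; below it the probe would be discarded in practice.

    Returns
    -------
    ndarray
        Deflection in m, up to an additive constant (the absolute fringe
        order is unobservable).  Zero-phase filtering is used throughout, so
        the output has no demodulation phase lag; the first and last few
        filter settling times (~10 ms at default settings) carry edge
        transients and should be trimmed by the caller.

    Raises
    ------
    ParameterError
        If the sampling rate is below 10x the modulation frequency.
    ReadoutQualityError
        If the fringe envelope is below ``visibility_floor`` or the phase
        advances by more than pi between consecutive samples (unwrap
        ambiguity: deflection slew too fast for the sampling rate).
    """
    intensity = np.asarray(intensity, dtype=float)
    if sample_rate < 10.0 * cavity.modulation_frequency:
        raise ParameterError(
            "intensity must be sampled at >= 10x the modulation frequency "
            f"({sample_rate:.3g} Hz < 10 x {cavity.modulation_frequency:.3g} Hz)"
        )
    n = intensity.size
    t = np.arange(n) / sample_rate
    omega_m = 2.0 * math.pi * cavity.modulation_frequency
    cutoff = cavity.modulation_frequency / 4.0

    # Lock-in quadratures at f_m and 2 f_m; lowpass keeps the baseband.
    p_raw = _lowpass(intensity * np.sin(omega_m * t), cutoff, sample_rate)
    q_raw = _lowpass(intensity * np.cos(2.0 * omega_m * t), cutoff, sample_rate)
    mean_i = float(np.mean(intensity))

    psi = cavity.modulation_index
    n_edge = int(round(0.02 * sample_rate))  # filter settling region

    def _phase(psi_val) -> np.ndarray:
        p = p_raw / jv(1, psi_val)
        q = q_raw / jv(2, psi_val)
        envelope = np.hypot(p, q)
        if mean_i <= 0 or float(np.median(envelope)) / mean_i < visibility_floor:
            raise ReadoutQualityError(
                "fringe envelope below visibility floor; probe would be discarded"
            )
        # A localized envelope collapse means the fringe pattern moved faster
        # than the demodulation band and was smeared by the lowpass: the
        # recovered phase there is not trustworthy (fringe-count ambiguity).
        interior = envelope[n_edge:-n_edge] if n > 2 * n_edge else envelope
        if float(interior.min()) < envelope_dip_floor * float(np.median(interior)):
            raise ReadoutQualityError(
                "fringe envelope collapsed locally; deflection slew too fast "
                "for reliable fringe tracking"
            )
        wrapped = np.arctan2(p, q)
        unwrapped = np.unwrap(wrapped)
        if np.any(np.abs(np.diff(unwrapped)) > 0.9 * math.pi):
            raise ReadoutQualityError(
                "phase advanced by more than ~pi between samples; deflection slew "
                "too fast for reliable fringe unwrapping"
            )
        return unwrapped

    half_fringe = cavity.wavelength / 2.0

    def _deflection(phi: np.ndarray) -> np.ndarray:
        # The absolute fringe order is unobservable: any d + m*lambda/2 fits.
        # Anchor to the branch nearest zero at the first sample (the probe
        # starts unloaded), which also keeps the refine pass physical.
        d = -phi * cavity.wavelength / (4.0 * math.pi)
        return d - round(d[0] / half_fringe) * half_fringe

    d = _deflection(_phase(psi))
    if refine:
        # psi scales with the instantaneous cavity length L0 - d.
        psi_t = psi * (cavity.rest_cavity_length - d) / cavity.rest_cavity_length
        d = _deflection(_phase(psi_t))
    return d
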