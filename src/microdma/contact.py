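"""Hertzian spherical contact mechanics.

Forward model (used by the instrument twin)
-------------------------------------------
A rigid sphere of radius R indenting an isotropic, homogeneous, linear
half-space to depth h carries the Hertz load

    F = (4/3) E_eff sqrt(R) h^(3/2),      E_eff = E / (1 - nu^2),

with E = 2 G (1 + nu) the compression (Young) modulus of a material with
shear modulus G and Poisson ratio nu.  For a viscoelastic half-space the same
geometry enters through the hereditary form: the load responds to the history
of h^(3/2) through the shear relaxation kernel (handled by the twin; this
module only supplies the geometric factors and the elastic backbone).

Inverse model (used by the analysis pipeline)
---------------------------------------------
A small load oscillation F1 e^(i 2 pi f t) about a static depth h0 produces an
indentation oscillation h1 with phase lag phi.  Linearizing Hertz about h0
gives the dynamic contact stiffness S = 2 E_eff sqrt(R h0), from which

    G'  = (1 - nu) F1 cos(phi) / (4 h1 sqrt(R h0))
    G'' = (1 - nu) F1 sin(phi) / (4 h1 sqrt(R h0))

i.e. the complex compression modulus E* = (1 - nu^2) (F1/h1) e^(i phi)
/ (2 sqrt(R h0)) converted to shear via G = E / (2 (1 + nu)).

No adhesion, no finite-thickness (bottom-effect) correction: plain Hertz
linearization, which is also exactly the model inside the twin, so the
forward-inverse loop closes up to the linearization error O(h1/h0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import LinearityError, ParameterError, PhaseRangeError
from .rheology import ComplexShearModulus

__all__ = [
    "ContactConfig",
    "OscillationObservation",
    "hertz_force",
    "dynamic_stiffness",
    "moduli_from_oscillation",
    "shear_from_compression",
    "effective_modulus",
]

#: Default bound on h1/h0 below which the Hertz linearization is trusted.
DEFAULT_LINEARITY_BOUND = 0.05

#: Default bound on h0/R implementing "indentation much smaller than bead radius".
DEFAULT_GEOMETRY_BOUND = 0.4


@dataclass(frozen=True)
class ContactConfig:
    """Spherical contact geometry and the sample's Poisson ratio.

    Attributes
    ----------
    bead_radius : float
        Sphere radius R in m, > 0.
    poisson_ratio : float
        nu in [0, 0.5]; 0.5 for roughly incompressible soft tissue.
    """

    bead_radius: float
    poisson_ratio: float = 0.5

    def __post_init__(self) -> None:
        if not (self.bead_radius > 0 and math.isfinite(self.bead_radius)):
            raise ParameterError(f"bead_radius must be > 0, got {self.bead_radius}")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ParameterError(f"poisson_ratio must be in [0, 0.5], got {self.poisson_ratio}")


@dataclass(frozen=True)
class OscillationObservation:
    """Amplitudes and phase of one steady load-controlled oscillation.

    Attributes
    ----------
    frequency : float
        Oscillation frequency in Hz.
    force_amplitude : float
        F1 in N, > 0.
    indentation_amplitude : float
        h1 in m, > 0.
    phase_lag : float
        phi in rad; indentation lags load by phi (>= 0 for a passive sample).
    static_depth : float
        h0 in m, > 0, the operating point of the linearization.
    """

    frequency: float
    force_amplitude: float
    indentation_amplitude: float
    phase_lag: float
    static_depth: float

    def __post_init__(self) -> None:
        if not self.frequency > 0:
            raise ParameterError(f"frequency must be > 0, got {self.frequency}")
        for name in ("force_amplitude", "indentation_amplitude", "static_depth"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")


def effective_modulus(shear_modulus: float, poisson_ratio: float) -> float:
    """Indentation modulus E_eff = E/(1-nu^2) = 2 G / (1 - nu)."""
    return 2.0 * shear_modulus / (1.0 - poisson_ratio)


def hertz_force(depth: float, contact: ContactConfig, shear_modulus: float) -> float:
    """Hertz load on a sphere at indentation ``depth``.

    ``F = (4/3) E_eff sqrt(R) h^(3/2)`` with ``E_eff = 2 G / (1 - nu)``.

    Raises
    ------
    ParameterError
        If depth is negative (no adhesion model) or G < 0.
    """
    if depth < 0:
        raise ParameterError(f"depth must be >= 0 (no adhesion model), got {depth}")
    if shear_modulus < 0:
        raise ParameterError(f"shear_modulus must be >= 0, got {shear_modulus}")
    e_eff = effective_modulus(shear_modulus, contact.poisson_ratio)
    return (4.0 / 3.0) * e_eff * math.sqrt(contact.bead_radius) * depth**1.5


def dynamic_stiffness(h0: float, contact: ContactConfig, e_eff: float) -> float:
    """Contact stiffness ``S = dF/dh = 2 E_eff sqrt(R h0)`` at static depth h0."""
    if not h0 > 0:
        raise ParameterError(f"static depth h0 must be > 0, got {h0}")
    return 2.0 * e_eff * math.sqrt(contact.bead_radius * h0)


def shear_from_compression(e: float, poisson_ratio: float) -> float:
    """Convert a compression (Young) modulus to shear: ``G = E / (2 (1 + nu))``."""
    if not -1.0 < poisson_ratio <= 0.5:
        raise ParameterError(f"poisson_ratio must be in (-1, 0.5], got {poisson_ratio}")
    if e < 0:
        raise ParameterError(f"compression modulus must be >= 0, got {e}")
    return e / (2.0 * (1.0 + poisson_ratio))


def moduli_from_oscillation(
    obs: OscillationObservation,
    contact: ContactConfig,
    linearity_bound: float = DEFAULT_LINEARITY_BOUND,
    check: bool = True,
) -> ComplexShearModulus:
    """Invert one oscillation observation to the complex shear modulus.

    Parameters
    ----------
    obs : OscillationObservation
    contact : ContactConfig
    linearity_bound : float
        Maximum accepted h1/h0 (linearization validity).
    check : bool
        When True (default), raise :class:`LinearityError` if h1/h0 exceeds
        the bound and :class:`PhaseRangeError` if phi is outside [0, pi/2).
        The analysis pipeline calls with ``check=False`` and records QC flags
        instead of aborting, so flagged rows still carry the (unreliable)
        computed values.

    Returns
    -------
    ComplexShearModulus
        G' and G'' at ``obs.frequency``.
    """
    ratio = obs.indentation_amplitude / obs.static_depth
    if check and ratio > linearity_bound:
        raise LinearityError(
            f"h1/h0 = {ratio:.3g} exceeds linearity bound {linearity_bound:.3g}"
        )
    if check and not 0.0 <= obs.phase_lag < math.pi / 2:
        raise PhaseRangeError(
            f"phase lag {obs.phase_lag:.4g} rad outside [0, pi/2) for a passive sample"
        )
    nu = contact.poisson_ratio
    scale = (1.0 - nu) * obs.force_amplitude / (
        4.0
        * obs.indentation_amplitude
        * math.sqrt(contact.bead_radius * obs.static_depth)
    )
    return ComplexShearModulus(
        obs.frequency,
        scale * math.cos(obs.phase_lag),
        scale * math.sin(obs.phase_lag),
    )
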