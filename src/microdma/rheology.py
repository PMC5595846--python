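"""Parametric linear-viscoelastic sample models.

A sample is described by its complex shear modulus ``G*(omega) = G' + i G''``.
This module provides both the frequency-domain evaluation (used as ground
truth and as the fit target for parameter-recovery tests) and an exact
time-domain update of the internal branch stresses (used by the instrument
twin to simulate indentation of the sample).

Supported model kinds
---------------------
``elastic``
    A single spring: ``G* = G_e``.
``kelvin_voigt``
    Spring and dashpot in parallel: ``G* = G_e + i omega eta``.
``standard_linear_solid``
    Equilibrium spring plus one Maxwell branch:
    ``G* = G_e + G_1 i omega tau_1 / (1 + i omega tau_1)``.
``generalized_maxwell``
    Equilibrium spring plus any number of Maxwell branches (Prony series).
    Zero branches degenerates to ``elastic``.
``springpot``
    Fractional element ``G* = c_alpha (i omega)^alpha`` with 0 < alpha < 1.
    Frequency-domain only: it has no finite-dimensional internal state, so the
    time-domain twin refuses it.

All moduli are SHEAR moduli in Pa.  Conversion to the indentation
(compression) modulus happens in :mod:`microdma.contact`, nowhere else.

Time-domain state
-----------------
The state vector is ``[strain, sigma_1, ..., sigma_n]`` where ``sigma_i`` is
the stress carried by Maxwell branch *i*.  Under piecewise-linear strain the
branch ODE ``d sigma/dt + sigma/tau = G d eps/dt`` has the exact per-step
solution

    ``sigma(t+dt) = sigma(t) exp(-dt/tau)
                    + G (d eps/dt) tau (1 - exp(-dt/tau))``

which is what :func:`memory_kernel_state_step` applies (unconditionally
stable for any dt).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ParameterError, TimeDomainUnsupportedError

__all__ = [
    "MODEL_KINDS",
    "TIME_DOMAIN_KINDS",
    "ComplexShearModulus",
    "RheologyModel",
    "complex_modulus",
    "init_state",
    "memory_kernel_state_step",
    "branch_arrays",
]

MODEL_KINDS = (
    "elastic",
    "kelvin_voigt",
    "standard_linear_solid",
    "generalized_maxwell",
    "springpot",
)

#: Kinds that support the exact finite-state time-domain update.
TIME_DOMAIN_KINDS = (
    "elastic",
    "kelvin_voigt",
    "standard_linear_solid",
    "generalized_maxwell",
)


@dataclass(frozen=True)
class ComplexShearModulus:
    """Complex shear modulus of a sample at one frequency.

    Attributes
    ----------
    frequency : float
        Frequency in Hz, > 0.
    storage : float
        Storage modulus G' in Pa (in-phase, elastic part).
    loss : float
        Loss modulus G'' in Pa (out-of-phase, viscous part).
    """

    frequency: float
    storage: float
    loss: float

    def __post_init__(self) -> None:
        if not (self.frequency > 0 and math.isfinite(self.frequency)):
            raise ParameterError(f"frequency must be finite and > 0, got {self.frequency}")
        if not (math.isfinite(self.storage) and math.isfinite(self.loss)):
            raise ParameterError("storage and loss moduli must be finite")

    @property
    def magnitude(self) -> float:
        """|G*| in Pa."""
        return math.hypot(self.storage, self.loss)

    @property
    def loss_tangent(self) -> float:
        """G''/G'."""
        return self.loss / self.storage

    @property
    def as_complex(self) -> complex:
        return complex(self.storage, self.loss)


def _require_positive(params: Mapping[str, float], keys: Sequence[str]) -> None:
    for key in keys:
        value = params.get(key)
        if value is None:
            raise ParameterError(f"missing parameter {key!r}")
        if not (value > 0 and math.isfinite(value)):
            raise ParameterError(f"parameter {key!r} must be finite and > 0, got {value}")


@dataclass(frozen=True)
class RheologyModel:
    """A parametric linear-viscoelastic sample model.

    ``parameters`` is a flat name->value mapping (SI units) so a model is
    serializable as one key-value config section.  Branch parameters of the
    generalized Maxwell model are named ``G_1, tau_1, G_2, tau_2, ...``.
    """

    kind: str
    parameters: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ParameterError(f"unknown model kind {self.kind!r}; expected one of {MODEL_KINDS}")
        object.__setattr__(self, "parameters", dict(self.parameters))
        p = self.parameters
        if self.kind == "elastic":
            _require_positive(p, ["G_e"])
        elif self.kind == "kelvin_voigt":
            _require_positive(p, ["G_e", "eta"])
        elif self.kind == "standard_linear_solid":
            _require_positive(p, ["G_e", "G_1", "tau_1"])
        elif self.kind == "generalized_maxwell":
            _require_positive(p, ["G_e"])
            for i in range(1, self.n_branches + 1):
                _require_positive(p, [f"G_{i}", f"tau_{i}"])
        elif self.kind == "springpot":
            _require_positive(p, ["c_alpha", "alpha"])
            if not 0.0 < p["alpha"] < 1.0:
                raise ParameterError(f"springpot exponent alpha must be in (0, 1), got {p['alpha']}")

    # -- constructors -----------------------------------------------------
    @classmethod
    def elastic(cls, G_e: float) -> "RheologyModel":
        return cls("elastic", {"G_e": G_e})

    @classmethod
    def kelvin_voigt(cls, G_e: float, eta: float) -> "RheologyModel":
        return cls("kelvin_voigt", {"G_e": G_e, "eta": eta})

    @classmethod
    def standard_linear_solid(cls, G_e: float, G_1: float, tau_1: float) -> "RheologyModel":
        return cls("standard_linear_solid", {"G_e": G_e, "G_1": G_1, "tau_1": tau_1})

    @classmethod
    def generalized_maxwell(
        cls, G_e: float, branches: Sequence[tuple[float, float]]
    ) -> "RheologyModel":
        params: dict[str, float] = {"G_e": G_e}
        for i, (g, tau) in enumerate(branches, start=1):
            params[f"G_{i}"] = g
            params[f"tau_{i}"] = tau
        return cls("generalized_maxwell", params)

    @classmethod
    def springpot(cls, c_alpha: float, alpha: float) -> "RheologyModel":
        return cls("springpot", {"c_alpha": c_alpha, "alpha": alpha})

    # -- introspection ----------------------------------------------------
    @property
    def n_branches(self) -> int:
        """Number of Maxwell branches carrying internal state."""
        if self.kind == "standard_linear_solid":
            return 1
        if self.kind == "generalized_maxwell":
            n = 0
            while f"G_{n + 1}" in self.parameters:
                n += 1
            return n
        return 0

    @property
    def supports_time_domain(self) -> bool:
        return self.kind in TIME_DOMAIN_KINDS


def branch_arrays(model: RheologyModel) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Decompose a time-domain model into ``(G_e, G_i[], tau_i[], eta)``.

    ``eta`` is the parallel dashpot viscosity (Kelvin-Voigt), zero otherwise.
    """
    if not model.supports_time_domain:
        raise TimeDomainUnsupportedError(
            f"model kind {model.kind!r} has no exact finite-state time-domain update"
        )
    p = model.parameters
    g_e = p["G_e"]
    eta = p.get("eta", 0.0) if model.kind == "kelvin_voigt" else 0.0
    n = model.n_branches
    g = np.array([p[f"G_{i}"] for i in range(1, n + 1)], dtype=float)
    tau = np.array([p[f"tau_{i}"] for i in range(1, n + 1)], dtype=float)
    return g_e, g, tau, eta


def complex_modulus(model: RheologyModel, frequency: float) -> ComplexShearModulus:
    """Evaluate ``G*(omega)`` at ``omega = 2 pi frequency``.

    Parameters
    ----------
    model : RheologyModel
    frequency : float
        Frequency in Hz, strictly positive.

    Returns
    -------
    ComplexShearModulus
    """
    if not (frequency > 0 and math.isfinite(frequency)):
        raise ParameterError(f"frequency must be finite and > 0, got {frequency}")
    omega = 2.0 * math.pi * frequency
    p = model.parameters
    if model.kind == "springpot":
        g_star = p["c_alpha"] * (1j * omega) ** p["alpha"]
    elif model.kind == "kelvin_voigt":
        g_star = complex(p["G_e"], omega * p["eta"])
    else:
        g_e, g, tau, _ = branch_arrays(model)
        i_omega_tau = 1j * omega * tau
        g_star = g_e + np.sum(g * i_omega_tau / (1.0 + i_omega_tau)) if g.size else complex(g_e)
    return ComplexShearModulus(frequency, float(np.real(g_star)), float(np.imag(g_star)))


def init_state(model: RheologyModel) -> np.ndarray:
    """Return the zero (fully relaxed) internal state ``[eps, sigma_1..n]``."""
    if not model.supports_time_domain:
        raise TimeDomainUnsupportedError(
            f"model kind {model.kind!r} has no exact finite-state time-domain update"
        )
    return np.zeros(1 + model.n_branches, dtype=float)


def memory_kernel_state_step(
    model: RheologyModel,
    state: np.ndarray,
    strain_increment: float,
    dt: float,
) -> tuple[np.ndarray, float]:
    """Advance the internal state by one step of piecewise-linear strain.

    The strain is assumed to ramp linearly by ``strain_increment`` over the
    interval ``dt``; each Maxwell branch is integrated exactly (exponential
    integrator), so the update is unconditionally stable and, at steady state
    under sinusoidal strain, reproduces :func:`complex_modulus` to rounding
    error of the piecewise-linear strain interpolation.

    Parameters
    ----------
    state : ndarray
        Current state ``[eps, sigma_1..n]``; not modified.
    strain_increment : float
        Dimensionless strain change over the step.
    dt : float
        Step duration in s, > 0.

    Returns
    -------
    (new_state, stress)
        Updated state and the total stress in Pa at the end of the step.
    """
    if not (dt > 0 and math.isfinite(dt)):
        raise ParameterError(f"dt must be finite and > 0, got {dt}")
    g_e, g, tau, eta = branch_arrays(model)
    expected = 1 + g.size
    if state.shape != (expected,):
        raise ParameterError(f"state must have shape ({expected},), got {state.shape}")
    new_state = np.empty_like(state)
    eps_new = state[0] + strain_increment
    new_state[0] = eps_new
    stress = g_e * eps_new + eta * strain_increment / dt
    if g.size:
        decay = np.exp(-dt / tau)
        new_state[1:] = state[1:] * decay + g * (strain_increment / dt) * tau * (1.0 - decay)
        stress += float(np.sum(new_state[1:]))
    return new_state, float(stress)
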