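"""Flat key-value run configuration (INI dialect).

A run config collects everything a simulation or analysis needs, in SI
units, under the sections ``[probe]``, ``[contact]``, ``[protocol]``,
``[model]``, ``[noise]``, ``[settings]`` and ``[run]``.  Example::

    [probe]
    spring_constant = 65.0
    bead_radius = 150e-6

    [contact]
    poisson_ratio = 0.5

    [protocol]
    mode = np_mode
    hold_time = 60

    [model]
    kind = standard_linear_solid
    G_e = 2000
    G_1 = 4000
    tau_1 = 0.3

    [noise]
    deflection_noise_rms = 3e-10
    drift_rate = 1e-9

    [run]
    seed = 1
    fidelity = deflection

Unlisted keys take the package defaults; ``model.kind = rigid`` selects the
rigid (glass) substrate used by the calibration procedure.
"""

from __future__ import annotations

import configparser
import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from .contact import ContactConfig
from .errors import ParameterError
from .interferometer import CavityConfig
from .rheology import RheologyModel
from .twin import ProbeConfig, StickSlipConfig, SweepProtocol, TwinSettings

__all__ = ["RunConfig", "load_config", "default_config"]

_INT_FIELDS = {"n_frequencies", "periods_per_frequency", "control_oversample", "seed"}
_STR_FIELDS = {"mode", "kind", "fidelity"}
_BOOL_FIELDS = {"enabled"}


@dataclass
class RunConfig:
    """Parsed run configuration."""

    probe: ProbeConfig
    contact: ContactConfig
    protocol: SweepProtocol
    model: Optional[RheologyModel]
    settings: TwinSettings
    cavity: CavityConfig
    seed: int = 1
    fidelity: str = "deflection"


def default_config() -> RunConfig:
    # default sample: a soft-silicone-like two-branch solid (~20-35 kPa G'),
    # stiff enough that the default protocol satisfies every geometric QC bound
    return RunConfig(
        probe=ProbeConfig(),
        contact=ContactConfig(bead_radius=ProbeConfig().bead_radius),
        protocol=SweepProtocol(),
        model=RheologyModel.generalized_maxwell(20000.0, [(8000.0, 1.0), (6000.0, 0.05)]),
        settings=TwinSettings(),
        cavity=CavityConfig(),
    )


def _coerce(key: str, raw: str):
    if key in _STR_FIELDS:
        return raw.strip()
    if key in _BOOL_FIELDS:
        return raw.strip().lower() in ("1", "true", "yes", "on")
    if key in _INT_FIELDS:
        return int(raw)
    try:
        return float(raw)
    except ValueError as exc:
        raise ParameterError(f"cannot parse config value {key} = {raw!r}") from exc


def _section(parser: configparser.ConfigParser, name: str) -> dict:
    if not parser.has_section(name):
        return {}
    return {key: _coerce(key, value) for key, value in parser.items(name)}


def _build(cls, defaults, overrides: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - valid
    if unknown:
        raise ParameterError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return dataclasses.replace(defaults, **overrides)


def load_config(path: Union[str, Path]) -> RunConfig:
    """Parse an INI run configuration, filling defaults for absent keys."""
    parser = configparser.ConfigParser()
    parser.optionxform = str  # model parameters like G_e are case-sensitive
    read = parser.read(Path(path))
    if not read:
        raise ParameterError(f"cannot read config file {path}")

    probe_kw = _section(parser, "probe")
    noise_kw = _section(parser, "noise")  # merged into the probe description
    probe = _build(ProbeConfig, ProbeConfig(), {**probe_kw, **noise_kw})

    contact_kw = _section(parser, "contact")
    contact_kw.setdefault("bead_radius", probe.bead_radius)
    contact = _build(ContactConfig, ContactConfig(bead_radius=probe.bead_radius), contact_kw)

    protocol_kw = _section(parser, "protocol")
    mode = protocol_kw.get("mode", "full_band")
    base = SweepProtocol.np_mode() if mode == "np_mode" else SweepProtocol()
    protocol_kw.pop("mode", None)
    protocol = dataclasses.replace(_build(SweepProtocol, base, protocol_kw), mode=mode)

    model_kw = _section(parser, "model")
    kind = model_kw.pop("kind", "standard_linear_solid")
    if kind == "rigid":
        model: Optional[RheologyModel] = None
    else:
        if not model_kw:
            model = default_config().model
        else:
            model = RheologyModel(kind, model_kw)

    settings_kw = _section(parser, "settings")
    friction_kw = _section(parser, "friction")
    friction = _build(StickSlipConfig, StickSlipConfig(), friction_kw)
    settings = _build(TwinSettings, TwinSettings(friction=friction), settings_kw)

    cavity_kw = _section(parser, "cavity")
    cavity = _build(CavityConfig, CavityConfig(), cavity_kw) if cavity_kw else CavityConfig()

    run_kw = _section(parser, "run")
    seed = int(run_kw.get("seed", 1))
    fidelity = run_kw.get("fidelity", "deflection")
    if fidelity not in ("deflection", "raw_intensity"):
        raise ParameterError(f"unknown fidelity {fidelity!r}")

    return RunConfig(
        probe=probe,
        contact=contact,
        protocol=protocol,
        model=model,
        settings=settings,
        cavity=cavity,
        seed=seed,
        fidelity=fidelity,
    )
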