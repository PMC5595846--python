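"""Delimited-text file formats for recordings and result tables.

All files share one dialect: ``#``-prefixed header lines carrying a format
tag and flat ``key = value`` metadata, then a tab-separated table whose
first row names the columns.  All stored quantities are SI; floats are
written with ``repr`` so that write -> read round-trips bit-exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .analysis import RESULT_COLUMNS, AggregateResult, SweepResult
from .errors import FormatError
from .twin import FORMAT_VERSION, Recording, SweepProtocol, TwinSettings, plan_segments

__all__ = [
    "read_recording",
    "write_recording",
    "read_sweep_result",
    "write_sweep_result",
    "read_aggregate",
    "write_aggregate",
]

SWEEP_FORMAT = "microdma-sweep-1"
AGGREGATE_FORMAT = "microdma-aggregate-1"

RECORDING_COLUMNS = ["time_s", "piezo_position_m", "deflection_m", "load_N", "segment_label"]
INTENSITY_COLUMN = "intensity_au"

MANDATORY_RECORDING_KEYS = ("probe.spring_constant", "protocol.sample_rate", "seed")

_EMPTY_FLAGS = "-"


def _format_value(value) -> str:
    return repr(value)


def _parse_value(text: str):
    text = text.strip()
    if text in ("True", "False"):
        return text == "True"
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    if text.startswith("'") and text.endswith("'"):
        return text[1:-1]
    return text


def _write_header(handle, format_tag: str, metadata: dict) -> None:
    handle.write(f"# {format_tag}\n")
    for key in sorted(metadata):
        handle.write(f"# {key} = {_format_value(metadata[key])}\n")


def _read_header(path: Path, expected_format: str) -> tuple[dict, int]:
    metadata: dict = {}
    n_header = 0
    with open(path, "r") as handle:
        first = handle.readline()
        n_header += 1
        if not first.startswith("#") or first[1:].strip() != expected_format:
            raise FormatError(
                f"{path}:1: expected format tag {expected_format!r}, got {first.strip()!r}"
            )
        for line in handle:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if "=" not in body:
                raise FormatError(f"{path}:{n_header}: malformed metadata line {body!r}")
            key, _, value = body.partition("=")
            metadata[key.strip()] = _parse_value(value)
    return metadata, n_header


def write_recording(recording: Recording, path: Union[str, Path]) -> None:
    """Write a Recording to a tab-separated text file with metadata header."""
    path = Path(path)
    role = recording.metadata.get("channel_role", "deflection")
    columns = list(RECORDING_COLUMNS)
    if role == "intensity":
        columns[2] = INTENSITY_COLUMN
    frame = pd.DataFrame(
        {
            columns[0]: recording.time,
            columns[1]: recording.piezo_position,
            columns[2]: recording.deflection,
            columns[3]: recording.load,
            columns[4]: recording.segment_labels.astype(str),
        }
    )
    with open(path, "w") as handle:
        _write_header(handle, FORMAT_VERSION, recording.metadata)
        frame.to_csv(handle, sep="\t", index=False, float_format="%.17g")


def _protocol_from_metadata(meta: dict) -> tuple[SweepProtocol, TwinSettings]:
    protocol = SweepProtocol(
        static_load=float(meta["protocol.static_load"]),
        oscillation_amplitude=float(meta["protocol.oscillation_amplitude"]),
        f_min=float(meta["protocol.f_min"]),
        f_max=float(meta["protocol.f_max"]),
        n_frequencies=int(meta["protocol.n_frequencies"]),
        periods_per_frequency=int(meta["protocol.periods_per_frequency"]),
        hold_time=float(meta["protocol.hold_time"]),
        retract_distance=float(meta["protocol.retract_distance"]),
        sample_rate=float(meta["protocol.sample_rate"]),
        mode=str(meta["protocol.mode"]),
    )
    settings = TwinSettings(
        approach_start_gap=float(meta["settings.approach_start_gap"]),
        approach_speed=float(meta["settings.approach_speed"]),
        load_ramp_time=float(meta["settings.load_ramp_time"]),
        retract_speed=float(meta["settings.retract_speed"]),
        piezo_travel=float(meta["settings.piezo_travel"]),
        contact_threshold=float(meta["settings.contact_threshold"]),
        debounce_time=float(meta["settings.debounce_time"]),
        control_oversample=int(meta["settings.control_oversample"]),
    )
    return protocol, settings


def _reconstruct_labels(n_total: int, meta: dict, path: Path) -> np.ndarray:
    """Rebuild segment labels for a legacy file from its protocol metadata."""
    try:
        protocol, settings = _protocol_from_metadata(meta)
    except KeyError as exc:
        raise FormatError(
            f"{path}: no segment_label column and incomplete protocol metadata ({exc})"
        ) from exc
    plans = plan_segments(protocol, settings)
    n_post = sum(p.n_samples for p in plans)
    n_approach = n_total - n_post
    if n_approach < 0:
        raise FormatError(f"{path}: sample count inconsistent with protocol metadata")
    labels = np.empty(n_total, dtype=object)
    labels[:n_approach] = "approach"
    pos = n_approach
    for plan in plans:
        labels[pos : pos + plan.n_samples] = plan.label
        pos += plan.n_samples
    return labels


def read_recording(path: Union[str, Path]) -> Recording:
    """Read a Recording, validating dialect, metadata and the time grid."""
    path = Path(path)
    metadata, n_header = _read_header(path, FORMAT_VERSION)
    for key in MANDATORY_RECORDING_KEYS:
        if key not in metadata:
            raise FormatError(f"{path}: missing mandatory metadata key {key!r}")
    frame = pd.read_csv(
        path, sep="\t", comment="#", keep_default_na=False, float_precision="round_trip"
    )
    role = metadata.get("channel_role", "deflection")
    deflection_col = INTENSITY_COLUMN if role == "intensity" else "deflection_m"
    for col in ("time_s", "piezo_position_m", deflection_col, "load_N"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    time = frame["time_s"].to_numpy(dtype=float)
    if time.size < 2:
        raise FormatError(f"{path}: recording needs at least 2 samples")
    dt = np.diff(time)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0))
        raise FormatError(
            f"{path}:{n_header + 2 + bad}: time axis not strictly increasing"
        )
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise FormatError(f"{path}: time grid is not uniform")
    load = pd.to_numeric(frame["load_N"], errors="coerce").to_numpy(dtype=float)
    if "segment_label" in frame.columns:
        labels = frame["segment_label"].to_numpy(dtype=object)
    else:
        labels = _reconstruct_labels(len(time), metadata, path)
    return Recording(
        time=time,
        piezo_position=frame["piezo_position_m"].to_numpy(dtype=float),
        deflection=frame[deflection_col].to_numpy(dtype=float),
        load=load,
        segment_labels=labels,
        metadata=metadata,
    )


def write_sweep_result(result: SweepResult, path: Union[str, Path]) -> None:
    path = Path(path)
    frame = result.data.copy()
    frame["qc_flags"] = frame["qc_flags"].replace("", _EMPTY_FLAGS)
    with open(path, "w") as handle:
        _write_header(handle, SWEEP_FORMAT, result.metadata)
        frame.to_csv(handle, sep="\t", index=False, float_format="%.17g")


def read_sweep_result(path: Union[str, Path]) -> SweepResult:
    path = Path(path)
    metadata, _ = _read_header(path, SWEEP_FORMAT)
    frame = pd.read_csv(
        path, sep="\t", comment="#", keep_default_na=False, float_precision="round_trip"
    )
    missing = [c for c in RESULT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in RESULT_COLUMNS[:-1]:
        frame[col] = pd.to_numeric(frame[col])
    frame["qc_flags"] = frame["qc_flags"].astype(str).replace(_EMPTY_FLAGS, "")
    return SweepResult(data=frame[RESULT_COLUMNS], metadata=metadata)


def write_aggregate(result: AggregateResult, path: Union[str, Path]) -> None:
    path = Path(path)
    meta = dict(result.metadata)
    meta["n_sweeps"] = result.n_sweeps
    with open(path, "w") as handle:
        _write_header(handle, AGGREGATE_FORMAT, meta)
        result.data.to_csv(handle, sep="\t", index=False, float_format="%.17g")


def read_aggregate(path: Union[str, Path]) -> AggregateResult:
    path = Path(path)
    metadata, _ = _read_header(path, AGGREGATE_FORMAT)
    frame = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    return AggregateResult(
        data=frame, n_sweeps=int(metadata.get("n_sweeps", 0)), metadata=metadata
    )
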