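"""Trace file format: a plain-text header block plus columnar CSV samples.

Header lines start with ``#`` and hold ``key = value`` pairs::

    # npsrheo-trace 1
    # sample_rate = 10000.0
    # channels = R_pore,R_1,R_2,R_3,R_4
    # units = ohm
    # device_id = simulated
    # applied_pressure_Pa = 13800.0

followed by a CSV table with a ``t`` column and one column per channel.
``units = ohm`` stores resistances directly; ``units = volt`` stores the
per-zone differential voltages plus a measured-current column ``I_m`` and
is converted to resistance on load (``R_i = V_i / I_m``).
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .device_model import DeviceGeometry
from .errors import ConfigError
from .signal_pipeline import RawTrace

__all__ = ["read_trace", "write_trace"]

FORMAT_NAME = "npsrheo-trace"
FORMAT_VERSION = 1


def write_trace(trace: RawTrace, path: str | Path) -> None:
    """Write a trace losslessly (full float precision) to ``path``."""
    path = Path(path)
    meta = dict(trace.metadata)
    units = meta.pop("units", "ohm")
    lines = [
        f"# {FORMAT_NAME} {FORMAT_VERSION}",
        f"# sample_rate = {trace.sample_rate!r}",
        f"# channels = {','.join(trace.channels)}",
        f"# units = {units}",
    ]
    for k, v in meta.items():
        lines.append(f"# {k} = {v}")
    df = pd.DataFrame({"t": trace.t, **trace.channels})
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def _parse_header(fh) -> tuple[dict, int]:
    header: dict = {}
    n_lines = 0
    first = fh.readline()
    n_lines += 1
    parts = first.strip().lstrip("# ").split()
    if len(parts) != 2 or parts[0] != FORMAT_NAME:
        raise ConfigError("not a trace file (missing format line)")
    if int(parts[1]) != FORMAT_VERSION:
        raise ConfigError(f"unsupported trace format version {parts[1]}")
    while True:
        pos_line = fh.readline()
        if not pos_line.startswith("#"):
            break
        n_lines += 1
        key, _, value = pos_line.lstrip("# ").partition("=")
        header[key.strip()] = value.strip()
    return header, n_lines


def read_trace(path: str | Path, geometry: DeviceGeometry | None = None) -> RawTrace:
    """Read a trace file; converts voltage-mode recordings to resistance.

    With ``geometry`` given, the channel count and order are validated
    against the device's channel names.
    """
    path = Path(path)
    with path.open() as fh:
        header, n_header = _parse_header(fh)
    required = ("sample_rate", "channels", "units")
    for k in required:
        if k not in header:
            raise ConfigError(f"trace header missing '{k}'")
    sample_rate = float(header["sample_rate"])
    channel_names = [c.strip() for c in header["channels"].split(",") if c.strip()]
    units = header["units"]
    df = pd.read_csv(path, skiprows=n_header, float_precision="round_trip")
    if "t" not in df.columns:
        raise ConfigError("trace table must have a 't' column")
    data_cols = [c for c in df.columns if c != "t"]
    if data_cols != channel_names:
        raise ConfigError("table columns do not match header channel list")
    t = df["t"].to_numpy(dtype=float)
    if len(t) > 2 and not np.allclose(np.diff(t), 1.0 / sample_rate, rtol=1e-6, atol=1e-12):
        raise ConfigError("non-uniform sampling or sample_rate mismatch")
    if units == "ohm":
        channels = {c: df[c].to_numpy(dtype=float) for c in channel_names}
    elif units == "volt":
        if "I_m" not in channel_names:
            raise ConfigError("voltage-mode trace needs an 'I_m' current channel")
        i_m = df["I_m"].to_numpy(dtype=float)
        if np.any(i_m <= 0):
            raise ConfigError("measured current must be positive")
        channels = {
            c.replace("V_", "R_"): df[c].to_numpy(dtype=float) / i_m
            for c in channel_names
            if c != "I_m"
        }
    else:
        raise ConfigError(f"unknown units '{units}' (expected 'ohm' or 'volt')")
    meta = {k: v for k, v in header.items() if k not in ("sample_rate", "channels")}
    if geometry is not None:
        expected = list(geometry.channel_names)
        if list(channels) != expected:
            raise ConfigError(
                f"trace channels {list(channels)} do not match geometry {expected}"
            )
    return RawTrace(t=t, channels=channels, sample_rate=sample_rate, metadata=meta)
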