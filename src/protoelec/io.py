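"""CSV readers/writers and pipeline configuration.

File formats are deliberately plain: comma-separated UTF-8 with a
required header row and ``.`` decimals, chosen for inspectability.

* Traces: ``time_s,<channel>_mV,...`` — the time base must be uniform
  to 1e-6 relative tolerance; the ``_mV`` suffix encodes the unit
  convention and is stripped into the channel name on read.
* Spectra: ``freq_hz,z_real_ohm,z_imag_ohm`` — frequencies are sorted
  ascending on read (stable for ties); negative frequencies are
  rejected.
* Environment logs: ``time_s,temperature_C,ph``.
* Pipeline configs: YAML mapping of stage sections; round-trips
  losslessly.

Format violations raise :class:`~protoelec.errors.FormatError` carrying
the offending line number where one exists.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import EnvSeries, ImpedanceSpectrum, MultichannelTrace
from .errors import FormatError

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_env_csv",
    "write_env_csv",
    "load_config",
    "save_config",
]


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed CSV ({exc})") from exc
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    return df


def read_trace_csv(path) -> MultichannelTrace:
    """Read a multichannel trace; header ``time_s,<channel>_mV,...``."""
    df = _read_csv(path)
    if df.columns[0] != "time_s":
        raise FormatError(f"{path}: first column must be 'time_s', got {df.columns[0]!r} (line 1)")
    channels = [c for c in df.columns[1:] if c.endswith("_mV")]
    if not channels:
        raise FormatError(f"{path}: no channel columns with the required '_mV' suffix (line 1)")
    bad = [c for c in df.columns[1:] if not c.endswith("_mV")]
    if bad:
        raise FormatError(f"{path}: columns without '_mV' unit suffix: {bad} (line 1)")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise FormatError(f"{path}: ragged or non-numeric row (line {row + 2})")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least 2 samples to establish the time step")
    steps = np.diff(t)
    dt = steps[0]
    if dt <= 0 or np.any(np.abs(steps - dt) > 1e-6 * max(abs(dt), 1e-30)):
        k = int(np.argmax(np.abs(steps - dt))) if dt > 0 else 0
        raise FormatError(f"{path}: non-uniform time base (line {k + 3})")
    return MultichannelTrace(
        dt_s=float(dt),
        channels={c[: -len("_mV")]: df[c].to_numpy(dtype=float) for c in channels},
        t0_s=float(t[0]),
    )


def write_trace_csv(trace: MultichannelTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False)


def read_spectrum_csv(path) -> ImpedanceSpectrum:
    """Read an impedance spectrum; header ``freq_hz,z_real_ohm,z_imag_ohm``."""
    df = _read_csv(path)
    required = ["freq_hz", "z_real_ohm", "z_imag_ohm"]
    if list(df.columns[:3]) != required:
        raise FormatError(f"{path}: header must start with {required} (line 1)")
    if df[required].isna().any().any():
        row = int(df[required].isna().any(axis=1).idxmax())
        raise FormatError(f"{path}: non-numeric or missing value (line {row + 2})")
    f = df["freq_hz"].to_numpy(dtype=float)
    if np.any(f <= 0):
        row = int(np.argmax(f <= 0))
        raise FormatError(f"{path}: non-positive frequency (line {row + 2})")
    order = np.argsort(f, kind="stable")
    f = f[order]
    if np.any(np.diff(f) == 0):
        row = int(np.argmax(np.diff(f) == 0))
        raise FormatError(f"{path}: duplicate frequency {f[row]} Hz")
    z = df["z_real_ohm"].to_numpy(dtype=float) + 1j * df["z_imag_ohm"].to_numpy(dtype=float)
    return ImpedanceSpectrum(f, z[order])


def write_spectrum_csv(spectrum: ImpedanceSpectrum, path) -> None:
    spectrum.to_frame().to_csv(path, index=False)


def read_env_csv(path) -> EnvSeries:
    """Read a temperature/pH log; header ``time_s,temperature_C,ph``."""
    df = _read_csv(path)
    required = ["time_s", "temperature_C", "ph"]
    if list(df.columns[:3]) != required:
        raise FormatError(f"{path}: header must start with {required} (line 1)")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    steps = np.diff(t)
    dt = steps[0]
    if dt <= 0 or np.any(np.abs(steps - dt) > 1e-6 * abs(dt)):
        raise FormatError(f"{path}: non-uniform time base")
    return EnvSeries(
        dt_s=float(dt),
        temperature_C=df["temperature_C"].to_numpy(dtype=float),
        ph=df["ph"].to_numpy(dtype=float),
    )


def write_env_csv(env: EnvSeries, path) -> None:
    pd.DataFrame(
        {
            "time_s": np.arange(env.n_samples) * env.dt_s,
            "temperature_C": env.temperature_C,
            "ph": env.ph,
        }
    ).to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a YAML pipeline config into a nested dict."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping of stage sections")
    return data


def save_config(config: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
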