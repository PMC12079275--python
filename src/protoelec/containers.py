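"""In-memory containers for the recording modalities.

Four lightweight dataclasses carry the data between generation, file I/O
and analysis stages:

``MultichannelTrace``
    Uniformly sampled membrane-potential recordings (mV) on a shared
    time base, one named channel per electrode.
``ImpedanceSpectrum``
    A frequency sweep of complex impedance (Ω), stored as strictly
    increasing frequencies in Hz with a complex impedance array.
``IVSweepSet``
    An ordered list of voltage-sweep cycles, each a (V, I) pair.
``EnvSeries``
    Paired temperature (°C) and pH logs on one time base.

All containers validate their invariants at construction and are plain
views over numpy arrays; analysis code never mutates them in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidSpecError

__all__ = ["MultichannelTrace", "ImpedanceSpectrum", "IVSweepSet", "EnvSeries"]


@dataclass
class MultichannelTrace:
    """Uniformly sampled per-channel membrane-potential series in mV."""

    dt_s: float
    channels: dict[str, np.ndarray]
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise InvalidSpecError(f"dt_s must be positive, got {self.dt_s}")
        if not self.channels:
            raise InvalidSpecError("trace needs at least one channel")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise InvalidSpecError(f"channels have unequal lengths: {sorted(lengths)}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def time_s(self) -> np.ndarray:
        return self.t0_s + self.dt_s * np.arange(self.n_samples)

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, channel: str) -> np.ndarray:
        if channel not in self.channels:
            raise KeyError(f"unknown channel {channel!r}; have {self.channel_names}")
        return self.channels[channel]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.time_s})
        for name, v in self.channels.items():
            df[f"{name}_mV"] = v
        return df


@dataclass
class ImpedanceSpectrum:
    """Complex impedance Z(f) = Z' + jZ'' over a frequency sweep."""

    frequencies_hz: np.ndarray
    z_ohm: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        self.z_ohm = np.asarray(self.z_ohm, dtype=complex)
        if self.frequencies_hz.ndim != 1 or len(self.frequencies_hz) != len(self.z_ohm):
            raise InvalidSpecError("frequencies and impedances must be 1-D and equal length")
        if np.any(self.frequencies_hz <= 0):
            raise InvalidSpecError("frequencies must be strictly positive")
        if np.any(np.diff(self.frequencies_hz) <= 0):
            raise InvalidSpecError("frequencies must be strictly increasing")

    @property
    def z_real(self) -> np.ndarray:
        return self.z_ohm.real

    @property
    def z_imag(self) -> np.ndarray:
        return self.z_ohm.imag

    def __len__(self) -> int:
        return len(self.frequencies_hz)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "freq_hz": self.frequencies_hz,
                "z_real_ohm": self.z_real,
                "z_imag_ohm": self.z_imag,
            }
        )


@dataclass
class IVSweepSet:
    """Ordered voltage-sweep cycles (V in volts, I in amperes)."""

    cycles: list[tuple[np.ndarray, np.ndarray]]
    scan_rate_V_s: float
    # generator ground truth (per-cycle resistance) when synthetic, else None
    true_resistances_ohm: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.cycles:
            raise InvalidSpecError("sweep set needs at least one cycle")
        if self.scan_rate_V_s <= 0:
            raise InvalidSpecError("scan rate must be positive")
        checked = []
        for v, i in self.cycles:
            v = np.asarray(v, dtype=float)
            i = np.asarray(i, dtype=float)
            if v.shape != i.shape:
                raise InvalidSpecError("V and I series of a cycle must have equal length")
            checked.append((v, i))
        self.cycles = checked

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)


@dataclass
class EnvSeries:
    """Synchronous temperature (°C) and pH logs."""

    dt_s: float
    temperature_C: np.ndarray
    ph: np.ndarray

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise InvalidSpecError("dt_s must be positive")
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        self.ph = np.asarray(self.ph, dtype=float)
        if self.temperature_C.shape != self.ph.shape:
            raise InvalidSpecError("temperature and pH series must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.ph)
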