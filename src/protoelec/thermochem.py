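"""Temperature-pH coupling analysis and Arrhenius protonation kinetics.

The coupled thermal/protochemical oscillations of proteinoid-actin
networks are characterized by four statistics:

* the dominant oscillation period of each log, read from the peak of a
  linearly detrended, Hann-windowed, 4x zero-padded periodogram with
  parabolic peak interpolation;
* the phase lag between temperature and pH (positive when pH lags),
  located at the maximum of the normalized cross-correlation of the
  detrended series, searched within plus/minus one dominant period;
* the coupling coefficient kappa, the magnitude-squared coherence of
  the two detrended series evaluated at their shared dominant
  frequency (kappa in [0, 1]);
* the normalized autocorrelation r(tau) at a requested lag.

Protonation kinetics follow the Arrhenius law
k(T) = k0 * exp(-Ea / (R * T)) with the gas constant
R = 8.314462618 J/(mol*K) and T in kelvin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import EnvSeries
from .errors import DomainError, InsufficientDataError, InvalidSpecError, NoPeakError

__all__ = [
    "ArrheniusParams",
    "dominant_period",
    "phase_lag",
    "coupling_coefficient",
    "autocorrelation",
    "arrhenius_rate",
]

R_GAS_J_MOL_K = 8.314462618
#: periodogram peak must exceed this multiple of the median spectral power
PEAK_CONFIDENCE_RATIO = 25.0


@dataclass(frozen=True)
class ArrheniusParams:
    """Arrhenius activation energy (kJ/mol) and prefactor (1/s)."""

    ea_kJ_mol: float
    k0_per_s: float

    def __post_init__(self) -> None:
        if self.ea_kJ_mol < 0:
            raise InvalidSpecError("activation energy must be non-negative")
        if self.k0_per_s <= 0:
            raise InvalidSpecError("prefactor must be positive")


def _detrended(x: np.ndarray) -> np.ndarray:
    return signal.detrend(np.asarray(x, dtype=float), type="linear")


def dominant_period(series, dt_s: float, min_confidence: float = PEAK_CONFIDENCE_RATIO) -> float:
    """Dominant oscillation period (s) of a series.

    The series is linearly detrended, Hann-windowed and zero-padded 4x;
    the periodogram peak is refined by parabolic interpolation in
    frequency. Raises :class:`NoPeakError` when the series is constant
    or the peak fails the confidence criterion (peak power below
    ``min_confidence`` times the median nonzero power — the signature of
    a flat, noise-dominated spectrum).
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 64:
        raise InsufficientDataError("need at least 64 samples for a period estimate")
    if dt_s <= 0:
        raise InvalidSpecError("dt_s must be positive")
    x = _detrended(x)
    if np.allclose(x, 0.0, atol=1e-15 * max(1.0, float(np.max(np.abs(series))))):
        raise NoPeakError("constant series has no oscillation period")
    n = len(x)
    nfft = 4 * n
    windowed = x * np.hanning(n)
    spec = np.abs(np.fft.rfft(windowed, nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=dt_s)
    spec[0] = 0.0
    k = int(np.argmax(spec))
    if k == 0 or freqs[k] <= 0:
        raise NoPeakError("no nonzero-frequency peak found")
    floor = float(np.median(spec[1:]))
    if floor > 0 and spec[k] < min_confidence * floor:
        raise NoPeakError(
            f"low-confidence peak: power ratio {spec[k] / floor:.1f} < {min_confidence}"
        )
    # parabolic interpolation around the peak bin
    if 1 <= k < len(spec) - 1:
        y0, y1, y2 = spec[k - 1], spec[k], spec[k + 1]
        denom = y0 - 2.0 * y1 + y2
        delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    f_peak = (k + delta) / (nfft * dt_s)
    return 1.0 / f_peak


def phase_lag(env: EnvSeries, max_lag_s: float | None = None) -> float:
    """Lag (s) of pH behind temperature; positive when pH lags.

    The lag maximizes the normalized cross-correlation of the detrended
    series, searched within plus/minus one dominant period of the
    temperature log (or ``max_lag_s`` when given).
    """
    t = _detrended(env.temperature_C)
    p = _detrended(env.ph)
    if np.allclose(t, 0) or np.allclose(p, 0):
        raise InvalidSpecError("phase lag undefined for constant series")
    if max_lag_s is None:
        try:
            max_lag_s = dominant_period(env.temperature_C, env.dt_s)
        except NoPeakError:
            max_lag_s = (len(t) - 1) * env.dt_s / 2.0
    max_shift = min(len(t) // 2, max(1, int(round(max_lag_s / env.dt_s))))
    lags = np.arange(-max_shift, max_shift + 1)
    r = _normalized_xcorr(p, t, lags)
    # periodic signals repeat their correlation peak one period away and
    # detrending perturbs the copies at the 1e-4 level, so the global
    # argmax can land on an alias: among separated local maxima that are
    # practically indistinguishable from the best, prefer the smallest |lag|
    local_max, _ = signal.find_peaks(r)
    peak = r.max()
    near = [k for k in local_max if r[k] >= peak - 1e-3 * max(abs(peak), 1.0)]
    if near:
        best = lags[min(near, key=lambda k: abs(lags[k]))]
    else:
        best = lags[int(np.argmax(r))]
    return float(best * env.dt_s)


def _normalized_xcorr(p: np.ndarray, t: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Zero-normalized cross-correlation of p against t at the given lags.

    Each lag's coefficient is computed over the overlapping window only,
    with that window's own means and variances (running sums), so the
    shrinking overlap of large lags does not bias the peak location.
    """
    n = len(p)
    raw = signal.correlate(p, t, mode="full", method="fft")
    raw_lags = signal.correlation_lags(n, n, mode="full")
    raw_at = dict(zip(raw_lags, raw))
    csum_p = np.concatenate([[0.0], np.cumsum(p)])
    csum_p2 = np.concatenate([[0.0], np.cumsum(p * p)])
    csum_t = np.concatenate([[0.0], np.cumsum(t)])
    csum_t2 = np.concatenate([[0.0], np.cumsum(t * t)])
    out = np.empty(len(lags))
    for j, k in enumerate(lags):
        m = n - abs(k)  # overlap length
        if k >= 0:  # p[k:] against t[:m]
            s_p, s_p2 = csum_p[n] - csum_p[k], csum_p2[n] - csum_p2[k]
            s_t, s_t2 = csum_t[m], csum_t2[m]
        else:  # p[:m] against t[-k:]
            s_p, s_p2 = csum_p[m], csum_p2[m]
            s_t, s_t2 = csum_t[n] - csum_t[-k], csum_t2[n] - csum_t2[-k]
        cov = raw_at[k] - s_p * s_t / m
        var_p = s_p2 - s_p**2 / m
        var_t = s_t2 - s_t**2 / m
        out[j] = cov / np.sqrt(var_p * var_t) if var_p > 0 and var_t > 0 else -np.inf
    return out


def coupling_coefficient(env: EnvSeries, nperseg: int | None = None) -> float:
    """Coupling coefficient kappa: magnitude-squared coherence of the
    detrended temperature and pH series at their shared dominant
    frequency. Always in [0, 1]."""
    t = _detrended(env.temperature_C)
    p = _detrended(env.ph)
    if np.allclose(t, 0) or np.allclose(p, 0):
        raise InvalidSpecError("coupling undefined for constant series")
    n = len(t)
    if nperseg is None:
        nperseg = max(64, n // 8)
    nperseg = min(nperseg, n)
    freqs, coh = signal.coherence(t, p, fs=1.0 / env.dt_s, nperseg=nperseg)
    try:
        period = dominant_period(env.temperature_C, env.dt_s)
        f0 = 1.0 / period
        k = int(np.argmin(np.abs(freqs - f0)))
        if k == 0 and len(freqs) > 1:
            k = 1
    except NoPeakError:
        # no shared oscillation: summarize by the band-average coherence
        # (the max bin would be biased upward under independence)
        return float(np.clip(np.mean(coh[1:]), 0.0, 1.0)) if len(coh) > 1 else 0.0
    return float(np.clip(coh[k], 0.0, 1.0))


def autocorrelation(series, lag_s: float, dt_s: float) -> float:
    """Normalized autocorrelation r(tau) at the requested lag.

    r(0) = 1 and |r(tau)| <= 1; the lag must be shorter than the series
    span.
    """
    x = np.asarray(series, dtype=float)
    if dt_s <= 0:
        raise InvalidSpecError("dt_s must be positive")
    k = int(round(lag_s / dt_s))
    if k < 0 or k >= len(x):
        raise DomainError(f"lag {lag_s} s out of range for a {len(x)}-sample series")
    d = x - x.mean()
    denom = float(np.sum(d * d))
    if denom == 0:
        return 1.0 if k == 0 else 0.0
    return float(np.sum(d[: len(d) - k] * d[k:]) / denom)


def arrhenius_rate(temperature_C, params: ArrheniusParams):
    """Protonation rate k = k0 * exp(-Ea / (R T)) at temperature(s) in Celsius."""
    t = np.asarray(temperature_C, dtype=float)
    if np.any(t <= -273.15):
        raise DomainError("temperature must exceed absolute zero")
    t_k = t + 273.15
    k = params.k0_per_s * np.exp(-params.ea_kJ_mol * 1e3 / (R_GAS_J_MOL_K * t_k))
    return float(k) if np.isscalar(temperature_C) else k
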