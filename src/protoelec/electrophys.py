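"""Spike detection, oscillation statistics, excitability classification,
stimulation-response characterization, and I-V cycling memory analysis.

Spike detection operates on the deviation of a channel from a rolling-
median baseline: candidate peaks are local maxima whose height above
baseline exceeds a prominence threshold, thinned so accepted peaks are
separated by at least a refractory interval (larger peaks win ties, the
same semantics as scipy's ``find_peaks`` distance filter). A spike's
amplitude is its peak value minus the median of the window immediately
preceding the peak, so the estimate is not contaminated by the spike's
own repolarization tail.

Excitability labels follow a fixed rule cascade:

1. ``regular_spiking`` — at least 5 spikes with interspike-interval
   CV < 0.5 (type I firing);
2. ``plateau_class2`` — a sustained (>10 % of the record) high state
   followed by a step to a lower state;
3. ``bistable`` — bimodal voltage histogram (Sarle bimodality
   coefficient > 0.555) with at least 2 transitions between the modes;
4. ``quiescent`` otherwise.

I-V cycling: per-cycle resistance is the mean of V/I over samples with
|V| above a dead-band (default 0.25 V), and the memory effect is the
Pearson correlation between cycle index and mean resistance, computed
from the raw summation formula (defined as 0 when either variance
vanishes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal, stats

from .containers import IVSweepSet, MultichannelTrace
from .errors import InsufficientDataError, InvalidSpecError

__all__ = [
    "SpikeTrain",
    "SpikeStats",
    "ChannelSpikeStats",
    "StimulationResponse",
    "detect_spikes",
    "spike_stats",
    "classify_dynamics",
    "stimulation_response",
    "iv_cycle_analysis",
    "pearson_r",
]

#: default detection thresholds for 2.5 Hz recordings with tens-of-mV spikes
DEFAULT_PROMINENCE_MV = 5.0
DEFAULT_REFRACTORY_S = 10.0
BASELINE_WINDOW_SAMPLES = 50


@dataclass
class SpikeTrain:
    """Detected spikes of one channel."""

    times_s: np.ndarray
    amplitudes_mV: np.ndarray
    indices: np.ndarray

    @property
    def n_spikes(self) -> int:
        return len(self.times_s)


@dataclass
class ChannelSpikeStats:
    n_spikes: int
    amp_median_mV: float
    amp_mean_mV: float
    amp_sd_mV: float
    amp_max_mV: float
    period_mean_s: float
    period_sd_s: float
    period_median_s: float
    period_periodogram_s: float  # spectral fallback estimate, NaN if unavailable


@dataclass
class SpikeStats:
    """Per-channel amplitude and period summaries."""

    per_channel: dict[str, ChannelSpikeStats]


def _rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    window = max(3, int(window))
    if window % 2 == 0:
        window += 1
    return ndimage.median_filter(x, size=window, mode="nearest")


def detect_spikes(
    trace: MultichannelTrace,
    channel: str,
    min_prominence_mV: float = DEFAULT_PROMINENCE_MV,
    refractory_s: float = DEFAULT_REFRACTORY_S,
    baseline_window: int = BASELINE_WINDOW_SAMPLES,
) -> SpikeTrain:
    """Detect spikes on one channel; see the module docstring for the rule.

    ``refractory_s`` must be at least one sample. Amplitudes are peak
    minus the median of the ``baseline_window`` samples preceding the
    peak (clipped at the trace start).
    """
    if refractory_s < trace.dt_s:
        raise InvalidSpecError("refractory interval must be at least one sample")
    v = trace[channel]
    baseline = _rolling_median(v, baseline_window)
    dev = v - baseline
    distance = max(1, int(round(refractory_s / trace.dt_s)))
    # height: exceed the rolling-median baseline by the threshold;
    # prominence: reject noise bumps riding on a repolarization tail,
    # whose topographic prominence is only the noise scale
    idx, _ = signal.find_peaks(
        dev, height=min_prominence_mV, prominence=min_prominence_mV, distance=distance
    )
    # amplitude baseline: median over one refractory interval preceding
    # the peak — long enough to average noise, short enough to stay clear
    # of the previous spike's repolarization tail
    amp_window = max(3, distance)
    amps = np.empty(len(idx))
    for k, i in enumerate(idx):
        lo = max(0, i - amp_window)
        local = np.median(v[lo:i]) if i > lo else v[i]
        amps[k] = v[i] - local
    return SpikeTrain(
        times_s=trace.t0_s + idx * trace.dt_s,
        amplitudes_mV=amps,
        indices=idx,
    )


def _periodogram_period(v: np.ndarray, dt_s: float) -> float:
    """Dominant oscillation period from a detrended periodogram (NaN if flat)."""
    x = signal.detrend(np.asarray(v, dtype=float))
    if np.allclose(x, 0) or len(x) < 16:
        return math.nan
    freqs, power = signal.periodogram(x, fs=1.0 / dt_s, window="hann")
    if len(power) < 3:
        return math.nan
    k = int(np.argmax(power[1:])) + 1
    if power[k] <= 0 or freqs[k] <= 0:
        return math.nan
    return 1.0 / freqs[k]


def spike_stats(
    trace: MultichannelTrace,
    min_prominence_mV: float = DEFAULT_PROMINENCE_MV,
    refractory_s: float = DEFAULT_REFRACTORY_S,
) -> SpikeStats:
    """Amplitude and period summaries for every channel of a trace.

    Periods are successive spike-time differences; sample (n−1) standard
    deviations throughout. Channels with fewer than 2 spikes report NaN
    period statistics, and a periodogram-based period estimate is
    attached for channels with fewer than 5 spikes (NaN when the channel
    has no spectral peak).
    """
    per: dict[str, ChannelSpikeStats] = {}
    for name in trace.channel_names:
        train = detect_spikes(trace, name, min_prominence_mV, refractory_s)
        amps = train.amplitudes_mV
        n = train.n_spikes
        if n >= 1:
            amp_median = float(np.median(amps))
            amp_mean = float(np.mean(amps))
            amp_sd = float(np.std(amps, ddof=1)) if n >= 2 else math.nan
            amp_max = float(np.max(amps))
        else:
            amp_median = amp_mean = amp_sd = amp_max = math.nan
        if n >= 2:
            periods = np.diff(train.times_s)
            p_mean = float(np.mean(periods))
            p_sd = float(np.std(periods, ddof=1)) if len(periods) >= 2 else math.nan
            p_median = float(np.median(periods))
        else:
            p_mean = p_sd = p_median = math.nan
        p_spec = _periodogram_period(trace[name], trace.dt_s) if n < 5 else math.nan
        per[name] = ChannelSpikeStats(
            n_spikes=n,
            amp_median_mV=amp_median,
            amp_mean_mV=amp_mean,
            amp_sd_mV=amp_sd,
            amp_max_mV=amp_max,
            period_mean_s=p_mean,
            period_sd_s=p_sd,
            period_median_s=p_median,
            period_periodogram_s=p_spec,
        )
    return SpikeStats(per_channel=per)


def bimodality_coefficient(x: np.ndarray) -> float:
    """Sarle's bimodality coefficient b = (g1² + 1) / (g2 + 3(n−1)²/((n−2)(n−3)))."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.std(x) == 0:
        return 0.0
    g1 = stats.skew(x, bias=False)
    g2 = stats.kurtosis(x, bias=False)  # excess kurtosis
    return float((g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


def _plateau_then_step(v: np.ndarray) -> bool:
    """True when a sustained high state (>10% of samples) is later left
    for a clearly lower level."""
    n = len(v)
    lo, hi = np.percentile(v, [2, 98])
    vrange = hi - lo
    if vrange <= 1e-12:
        return False
    high = v > lo + 0.75 * vrange
    labels, n_runs = ndimage.label(high)
    if n_runs == 0:
        return False
    run_sizes = ndimage.sum_labels(np.ones(n), labels, index=np.arange(1, n_runs + 1))
    best = int(np.argmax(run_sizes)) + 1
    if run_sizes[best - 1] < 0.10 * n:
        return False
    if run_sizes[best - 1] < 0.7 * run_sizes.sum():
        return False  # several comparable high epochs: bistable switching, not one plateau
    run_end = int(np.max(np.nonzero(labels == best)[0]))
    if run_end >= n - max(5, n // 50):
        return False  # plateau persists to the end: no step down observed
    after = v[run_end + 1 :]
    plateau_level = float(np.mean(v[labels == best]))
    return bool(np.mean(after) < plateau_level - 0.4 * vrange)


def _state_transitions(v: np.ndarray) -> int:
    """Count transitions across the mid-level with hysteresis bands."""
    lo, hi = np.percentile(v, [2, 98])
    mid = 0.5 * (lo + hi)
    band = 0.15 * (hi - lo)
    state = 0
    transitions = 0
    for value in v:
        if value > mid + band:
            if state == -1:
                transitions += 1
            state = 1
        elif value < mid - band:
            if state == 1:
                transitions += 1
            state = -1
    return transitions


def classify_dynamics(
    trace: MultichannelTrace,
    channel: str,
    min_prominence_mV: float = DEFAULT_PROMINENCE_MV,
    refractory_s: float = DEFAULT_REFRACTORY_S,
) -> str:
    """Label a channel's dynamics; see the module docstring for the rules."""
    v = trace[channel]
    if len(v) < 100:
        raise InsufficientDataError("need at least 100 samples to classify dynamics")
    train = detect_spikes(trace, channel, min_prominence_mV, refractory_s)
    if train.n_spikes >= 5:
        periods = np.diff(train.times_s)
        cv = np.std(periods, ddof=1) / np.mean(periods)
        if cv < 0.5:
            return "regular_spiking"
    if _plateau_then_step(v):
        return "plateau_class2"
    if bimodality_coefficient(v) > 0.555 and _state_transitions(v) >= 2:
        return "bistable"
    return "quiescent"


@dataclass
class StimulationResponse:
    """Per-channel response summary to square-wave stimulation."""

    baseline_mean_mV: float
    baseline_variance_mV2: float
    delta_v_mV: float  # mean input-output difference (attenuation)
    latency_ms: float
    recovery_ms: float


def _edges(gate: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.diff(gate.astype(int))
    return np.nonzero(d == 1)[0] + 1, np.nonzero(d == -1)[0] + 1


def stimulation_response(
    stimulus: MultichannelTrace,
    responses: MultichannelTrace,
    settle_s: float = 0.1,
) -> dict[str, StimulationResponse]:
    """Characterize per-channel responses to a square-wave stimulus.

    ``stimulus`` must hold a single channel. Baseline statistics are
    computed over off-phase samples excluding a ``settle_s`` window
    after every stimulus transition; the mean input-output difference is
    the stimulus amplitude minus the mean evoked displacement over
    (settled) on-phase samples. Latency is the median time from an on
    edge to the response first reaching 10 % of its evoked change;
    recovery is the median time from an off edge to the response
    re-entering 10 % of the evoked change around baseline, minus the
    channel's latency (the propagation delay applies to both edges).
    """
    if abs(stimulus.dt_s - responses.dt_s) > 1e-12 or stimulus.n_samples != responses.n_samples:
        raise InvalidSpecError("stimulus and responses must share one time base")
    stim = stimulus.channels[stimulus.channel_names[0]]
    lo, hi = float(np.min(stim)), float(np.max(stim))
    if hi - lo <= 1e-12:
        raise InvalidSpecError("stimulus has no transitions")
    gate = stim > 0.5 * (lo + hi)
    on_edges, off_edges = _edges(gate)
    if len(on_edges) == 0 or len(off_edges) == 0:
        raise InvalidSpecError("stimulus has no transitions")
    stim_amp = hi - lo
    dt = responses.dt_s
    settle = int(round(settle_s / dt))

    # settled masks: drop `settle` samples after every transition
    settled = np.ones(responses.n_samples, dtype=bool)
    for e in np.concatenate([on_edges, off_edges]):
        settled[e : e + settle] = False
    if gate[0]:
        # session starts mid-phase: the preceding transition is unobserved
        settled[:settle] = False
    off_mask = (~gate) & settled
    on_mask = gate & settled
    if not off_mask.any() or not on_mask.any():
        raise InsufficientDataError("no settled samples; shrink settle_s or lengthen phases")

    out: dict[str, StimulationResponse] = {}
    for name in responses.channel_names:
        v = responses[name]
        base_mean = float(np.mean(v[off_mask]))
        base_var = float(np.var(v[off_mask], ddof=1))
        evoked = float(np.mean(v[on_mask])) - base_mean
        delta_v = stim_amp - abs(evoked)
        thresh = 0.1 * abs(evoked)
        sgn = 1.0 if evoked >= 0 else -1.0

        latencies = []
        for e in on_edges:
            seg = sgn * (v[e:] - base_mean)
            hits = np.nonzero(seg >= thresh)[0]
            if len(hits):
                latencies.append(hits[0] * dt)
        latency_s = float(np.median(latencies)) if latencies else math.nan

        recoveries = []
        for e in off_edges:
            seg = sgn * (v[e:] - base_mean)
            hits = np.nonzero(seg <= thresh)[0]
            if len(hits):
                recoveries.append(hits[0] * dt)
        recovery_s = float(np.median(recoveries)) if recoveries else math.nan
        if not math.isnan(recovery_s) and not math.isnan(latency_s):
            recovery_s = max(0.0, recovery_s - latency_s)

        out[name] = StimulationResponse(
            baseline_mean_mV=base_mean,
            baseline_variance_mV2=base_var,
            delta_v_mV=delta_v,
            latency_ms=latency_s * 1e3,
            recovery_ms=recovery_s * 1e3,
        )
    return out


def pearson_r(x, y) -> float:
    """Pearson correlation by the raw summation formula.

    r = Σ(x−x̄)(y−ȳ) / sqrt(Σ(x−x̄)² Σ(y−ȳ)²), defined as 0 when either
    variance is 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidSpecError("x and y must be equal-length 1-D series")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(np.sum(dx * dx))
    syy = float(np.sum(dy * dy))
    if sxx == 0.0 or syy == 0.0:
        return 0.0
    # clip: rounding can push a perfect correlation a ulp past 1
    return float(np.clip(np.sum(dx * dy) / math.sqrt(sxx * syy), -1.0, 1.0))


def iv_cycle_analysis(
    sweeps: IVSweepSet,
    dead_band_V: float = 0.25,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-cycle mean resistance, its per-cycle sd, and the Pearson r of
    mean resistance against cycle number (the memory-effect statistic).

    Resistance samples are V/I over points with |V| ≥ ``dead_band_V``
    (the dead-band avoids the V/I blow-up near zero volts).
    """
    if sweeps.n_cycles < 2:
        raise InsufficientDataError("need at least 2 cycles")
    means = np.empty(sweeps.n_cycles)
    sds = np.empty(sweeps.n_cycles)
    for i, (v, cur) in enumerate(sweeps.cycles):
        mask = np.abs(v) >= dead_band_V
        mask &= cur != 0
        if not mask.any():
            raise InsufficientDataError(f"cycle {i}: all samples inside the dead-band")
        r = v[mask] / cur[mask]
        means[i] = np.mean(r)
        sds[i] = np.std(r, ddof=1) if mask.sum() >= 2 else math.nan
    cycle_idx = np.arange(1, sweeps.n_cycles + 1, dtype=float)
    return means, sds, pearson_r(cycle_idx, means)
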