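"""Synthetic generators for every recording modality.

The raw recordings behind the published results were never deposited,
so each analysis stage is exercised against phenomenological emulators
whose statistical structure matches the published summary statistics:
spike amplitude/interval distributions, multiphasic plateau and
bistable trajectories, square-wave stimulation sessions, circuit-model
impedance spectra, drifting hysteretic I-V sweep cycles, coupled
temperature/pH oscillation logs, and decaying capacitance series.

Every generator is a pure function of its spec including the seed
(bit-reproducible), and zero-noise settings produce outputs from which
the matching analysis stage recovers the configured parameters exactly.

Module-level spec constants encode the published study conditions:

``MICROSPHERE_SPIKING_SPEC``
    Regular-spiking microsphere recording: spikes of 25.3 ± 5.2 mV over
    a ~25 mV baseline, mean interspike interval 52.4 s, logged at
    2.5 Hz (Δt = 0.4 s).
``STIM_SESSION_SPEC``
    20 s square-wave stimulation session (1000 mV, 50 % duty) with the
    published per-channel baselines, input-output differences, and
    ms-scale latencies/recovery times, generated at 1 ms resolution.
``ENV_LOG_SPEC``
    1 Hz temperature/pH logs: ~90 min thermal oscillation cycles with a
    slow multi-hour drift, pH averaging 7.88 ± 0.05 and lagging
    temperature by 20 min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .circuits import CircuitModel
from .circuits import evaluate_impedance
from .containers import EnvSeries, ImpedanceSpectrum, IVSweepSet, MultichannelTrace
from .errors import DomainError, InvalidSpecError

__all__ = [
    "TraceSpec",
    "StimulationSpec",
    "EnvSpec",
    "MICROSPHERE_SPIKING_SPEC",
    "STIM_SESSION_SPEC",
    "ENV_LOG_SPEC",
    "MIXTURE_IV_CONDITION",
    "CAPACITANCE_CONDITIONS",
    "gen_spiking_trace",
    "gen_multiphasic_trace",
    "plateau_profile_phases",
    "bistable_profile_phases",
    "gen_stimulation_session",
    "gen_impedance_spectrum",
    "gen_iv_sweeps",
    "gen_env_series",
    "gen_capacitance_series",
]


# ---------------------------------------------------------------------------
# spiking traces


@dataclass(frozen=True)
class TraceSpec:
    """Parameters of a spontaneously spiking membrane-potential trace."""

    baseline_mV: float = 25.0
    spike_amp_mean_mV: float = 25.3
    spike_amp_sd_mV: float = 5.2
    isi_mean_s: float = 52.4
    isi_cv: float = 0.2
    noise_sd_mV: float = 1.0
    dt_s: float = 0.4
    duration_s: float = 20000.0
    seed: int = 0
    decay_tau_frac: float = 0.2  # repolarization time constant as fraction of mean ISI
    channel: str = "ChF"

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise InvalidSpecError("dt_s must be positive")
        if self.duration_s <= self.dt_s:
            raise InvalidSpecError("duration must exceed one sample")
        if self.isi_mean_s <= 0:
            raise InvalidSpecError("mean interspike interval must be positive")
        if self.isi_cv < 0 or self.noise_sd_mV < 0 or self.spike_amp_sd_mV < 0:
            raise InvalidSpecError("spreads must be non-negative")
        if self.decay_tau_frac <= 0:
            raise InvalidSpecError("decay_tau_frac must be positive")


#: published regular-spiking microsphere condition (2.5 Hz logging)
MICROSPHERE_SPIKING_SPEC = TraceSpec()


def _draw_isis(spec: TraceSpec, rng: np.random.Generator, horizon_s: float) -> np.ndarray:
    """Interspike intervals out to the horizon; gamma with given mean/CV."""
    n_expected = int(horizon_s / spec.isi_mean_s) + 10
    if spec.isi_cv == 0:
        return np.full(n_expected, spec.isi_mean_s)
    shape = 1.0 / spec.isi_cv**2
    scale = spec.isi_mean_s * spec.isi_cv**2
    return rng.gamma(shape, scale, size=n_expected)


def gen_spiking_trace(spec: TraceSpec) -> MultichannelTrace:
    """Spontaneous action-potential-like spiking trace.

    Spikes are placed at intervals drawn from a gamma distribution with
    the configured mean and CV (exactly periodic when CV = 0); each
    spike rises within one sample to an amplitude drawn from
    N(amp_mean, amp_sd) and decays exponentially with time constant
    ``decay_tau_frac * isi_mean_s``; Gaussian baseline noise is added.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(spec.duration_s / spec.dt_s)
    v = np.zeros(n)
    isis = _draw_isis(spec, rng, spec.duration_s)
    times = np.cumsum(isis)
    times = times[times < spec.duration_s]
    tau = spec.decay_tau_frac * spec.isi_mean_s
    decay_len = min(n, int(8 * tau / spec.dt_s) + 1)
    kernel = np.exp(-np.arange(decay_len) * spec.dt_s / tau)
    for t in times:
        i = int(round(t / spec.dt_s))
        if i >= n:
            continue
        amp = spec.spike_amp_mean_mV + spec.spike_amp_sd_mV * rng.standard_normal()
        stop = min(n, i + decay_len)
        v[i:stop] += amp * kernel[: stop - i]
    v += spec.baseline_mV
    if spec.noise_sd_mV > 0:
        v += spec.noise_sd_mV * rng.standard_normal(n)
    return MultichannelTrace(dt_s=spec.dt_s, channels={spec.channel: v})


# ---------------------------------------------------------------------------
# multiphasic / bistable traces


def gen_multiphasic_trace(
    phase_table: list[tuple[float, float, str]],
    noise_sd_mV: float = 0.0,
    dt_s: float = 0.4,
    seed: int = 0,
    channel: str = "ChB",
    start_mV: float = 0.0,
) -> MultichannelTrace:
    """Piecewise trajectory from a phase table of (duration_s, target_mV, shape).

    Shapes: ``constant`` (hold the target), ``step`` (jump to target,
    hold), ``linear`` (ramp from the previous level to the target), and
    ``exp`` (exponential approach with time constant duration/5).
    Supports both the class-2 plateau profile and bistable multiphasic
    trajectories.
    """
    if not phase_table:
        raise InvalidSpecError("phase table must contain at least one phase")
    segments = []
    level = start_mV
    for duration_s, target_mV, shape in phase_table:
        if duration_s <= 0:
            raise InvalidSpecError("phase durations must be positive")
        m = int(round(duration_s / dt_s))
        if m < 1:
            raise InvalidSpecError("phase shorter than one sample")
        if shape in ("constant", "step"):
            seg = np.full(m, target_mV)
        elif shape == "linear":
            seg = level + (target_mV - level) * (np.arange(1, m + 1) / m)
        elif shape == "exp":
            tau = duration_s / 5.0
            t = np.arange(1, m + 1) * dt_s
            seg = target_mV + (level - target_mV) * np.exp(-t / tau)
        else:
            raise InvalidSpecError(f"unknown ramp shape {shape!r}")
        segments.append(seg)
        level = float(seg[-1])
    v = np.concatenate(segments)
    if noise_sd_mV > 0:
        rng = np.random.default_rng(seed)
        v = v + noise_sd_mV * rng.standard_normal(len(v))
    return MultichannelTrace(dt_s=dt_s, channels={channel: v})


def plateau_profile_phases(
    ramp_rate_mV_min: float = 8.0,
    v_max_mV: float = 40.0,
    plateau_s: float = 5000.0,
    v_step_mV: float = -60.0,
    v_settle_mV: float = -20.0,
    settle_s: float = 5000.0,
) -> list[tuple[float, float, str]]:
    """Class-2 plateau study condition: depolarization ramp at
    8 mV/min to ~40 mV, a ~5000 s metastable plateau, a sharp step to a
    hyperpolarized state, and an exponential settle to steady state."""
    ramp_s = abs(v_max_mV) / ramp_rate_mV_min * 60.0
    return [
        (ramp_s, v_max_mV, "linear"),
        (plateau_s, v_max_mV, "constant"),
        (200.0, v_step_mV, "step"),
        (settle_s, v_settle_mV, "exp"),
    ]


def bistable_profile_phases(
    high_mV: float = 40.0,
    low_mV: float = -20.0,
    dwell_s: float = 2000.0,
    n_switches: int = 5,
) -> list[tuple[float, float, str]]:
    """Bistable study condition: repeated switching between two stable
    membrane-potential states (ΔV ≈ 60 mV)."""
    phases = []
    for k in range(n_switches):
        target = high_mV if k % 2 == 0 else low_mV
        phases.append((dwell_s, target, "step"))
    return phases


# ---------------------------------------------------------------------------
# stimulation sessions


@dataclass(frozen=True)
class StimulationSpec:
    """Square-wave stimulation session with per-channel responses."""

    stim_amplitude_mV: float = 1000.0
    duty_fraction: float = 0.5
    period_s: float = 2.0
    duration_s: float = 20.0
    channel_baselines_mV: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "ChC": (-6.22, 0.81),
            "ChD": (-66.78, 1.77),
            "ChE": (-66.73, 1.72),
            "ChF": (-82.74, 1.63),
        }
    )
    channel_attenuation_mV: dict[str, float] = field(
        default_factory=lambda: {"ChC": 205.63, "ChD": 231.14, "ChE": 256.64, "ChF": 282.15}
    )
    latency_ms: dict[str, float] = field(
        default_factory=lambda: {"ChC": 4.2, "ChD": 5.4, "ChE": 6.6, "ChF": 7.8}
    )
    recovery_ms: dict[str, float] = field(
        default_factory=lambda: {"ChC": 10.5, "ChD": 12.1, "ChE": 13.7, "ChF": 15.3}
    )
    dt_s: float = 0.001  # stimulation sessions are generated at 1 ms resolution
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.duty_fraction < 1.0:
            raise InvalidSpecError("duty fraction must lie in (0, 1)")
        if self.dt_s <= 0 or self.period_s <= 0 or self.duration_s <= 0:
            raise InvalidSpecError("dt, period and duration must be positive")
        channels = set(self.channel_baselines_mV)
        for name, mapping in (
            ("attenuation", self.channel_attenuation_mV),
            ("latency", self.latency_ms),
            ("recovery", self.recovery_ms),
        ):
            if set(mapping) != channels:
                raise InvalidSpecError(f"channel_{name} keys must match channel_baselines keys")
        min_latency_s = min(self.latency_ms.values()) * 1e-3
        if self.dt_s > min_latency_s / 4.0:
            raise InvalidSpecError(
                f"dt {self.dt_s}s too coarse to resolve the minimum latency "
                f"{min_latency_s * 1e3:.3g} ms (need dt <= latency/4)"
            )


#: published square-wave stimulation condition (channels C-F)
STIM_SESSION_SPEC = StimulationSpec()


def gen_stimulation_session(spec: StimulationSpec) -> tuple[MultichannelTrace, MultichannelTrace]:
    """Square-wave stimulus plus per-channel responses.

    Each channel's response is its baseline plus the stimulus minus its
    attenuation, gated by the stimulus with a pure propagation delay
    (latency), an instantaneous rise, and an exponential return to
    baseline after stimulus-off whose time constant is set so the
    response re-enters 10 % of the evoked change ``recovery_ms`` after
    the (delayed) off edge. Per-channel Gaussian noise uses the
    configured baseline sd.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(spec.duration_s / spec.dt_s)
    t = np.arange(n) * spec.dt_s
    phase = np.mod(t, spec.period_s) / spec.period_s
    gate = phase < spec.duty_fraction
    stimulus = MultichannelTrace(
        dt_s=spec.dt_s, channels={"stimulus": spec.stim_amplitude_mV * gate.astype(float)}
    )

    responses: dict[str, np.ndarray] = {}
    for ch, (base_mean, base_sd) in spec.channel_baselines_mV.items():
        delta = spec.stim_amplitude_mV - spec.channel_attenuation_mV[ch]
        lat_samples = int(round(spec.latency_ms[ch] * 1e-3 / spec.dt_s))
        delayed = np.zeros(n, dtype=bool)
        delayed[lat_samples:] = gate[: n - lat_samples]
        v = np.where(delayed, delta, 0.0)
        tau = spec.recovery_ms[ch] * 1e-3 / math.log(10.0)
        # exponential tails after every falling edge of the delayed gate
        falling = np.nonzero(np.diff(delayed.astype(int)) == -1)[0] + 1
        rising = np.nonzero(np.diff(delayed.astype(int)) == 1)[0] + 1
        for f_edge in falling:
            nxt = rising[rising > f_edge]
            stop = int(nxt[0]) if len(nxt) else n
            k = np.arange(stop - f_edge)
            v[f_edge:stop] = delta * np.exp(-k * spec.dt_s / tau)
        v += base_mean
        if base_sd > 0:
            v += base_sd * rng.standard_normal(n)
        responses[ch] = v
    return stimulus, MultichannelTrace(dt_s=spec.dt_s, channels=responses)


# ---------------------------------------------------------------------------
# impedance spectra


def gen_impedance_spectrum(
    model: CircuitModel,
    frequencies_hz,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> ImpedanceSpectrum:
    """Model spectrum with multiplicative complex Gaussian noise of
    relative standard deviation ``noise_frac``."""
    frequencies_hz = np.asarray(frequencies_hz, dtype=float)
    if np.any(frequencies_hz <= 0):
        raise DomainError("frequencies must be strictly positive")
    z = evaluate_impedance(model, frequencies_hz)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        z = z * (
            1.0
            + noise_frac * rng.standard_normal(len(z))
            + 1j * noise_frac * rng.standard_normal(len(z))
        )
    return ImpedanceSpectrum(frequencies_hz, z)


# ---------------------------------------------------------------------------
# I-V sweep cycles

#: drift/noise condition whose population cycle-resistance correlation is 0.35
MIXTURE_IV_CONDITION: dict[str, float] = {
    "r0_ohm": 2.0e5,
    "drift_per_cycle_ohm": 400.0,
    "resistance_noise_sd_ohm": 15452.0,
    "hysteresis_width": 0.1,
}


def gen_iv_sweeps(
    r0_ohm: float,
    drift_per_cycle_ohm: float = 0.0,
    hysteresis_width: float = 0.0,
    n_cycles: int = 50,
    v_range_V: float = 5.0,
    scan_rate_V_s: float = 0.1,
    resistance_noise_sd_ohm: float = 0.0,
    samples_per_cycle: int = 400,
    seed: int = 0,
) -> IVSweepSet:
    """Drifting, hysteretic voltage-sweep cycles.

    Each cycle ramps 0 → +v_range → −v_range → 0 at the scan rate; the
    cycle resistance drifts linearly (slope ``drift_per_cycle_ohm``)
    with additive Gaussian noise, and hysteresis splits the forward and
    backward branches by a fractional width (forward branch
    R·(1 − h/2), backward R·(1 + h/2)). The drawn per-cycle resistances
    are attached as ground truth for recovery tests.
    """
    if n_cycles < 1:
        raise InvalidSpecError("need at least one cycle")
    if scan_rate_V_s <= 0:
        raise InvalidSpecError("scan rate must be positive")
    if r0_ohm == 0:
        raise DomainError("zero resistance is not a valid sweep condition")
    rng = np.random.default_rng(seed)
    # triangular voltage profile over one cycle
    quarter = samples_per_cycle // 4
    up = np.linspace(0.0, v_range_V, quarter, endpoint=False)
    down = np.linspace(v_range_V, -v_range_V, 2 * quarter, endpoint=False)
    back = np.linspace(-v_range_V, 0.0, samples_per_cycle - 3 * quarter, endpoint=False)
    v_cycle = np.concatenate([up, down, back])
    dv = np.gradient(v_cycle)
    forward = dv >= 0

    cycles = []
    true_r = np.empty(n_cycles)
    for i in range(n_cycles):
        r_i = r0_ohm + drift_per_cycle_ohm * i
        if resistance_noise_sd_ohm > 0:
            r_i += resistance_noise_sd_ohm * rng.standard_normal()
        if r_i <= 0:
            raise DomainError(f"cycle {i}: drift/noise produced non-positive resistance {r_i:.3g}")
        true_r[i] = r_i
        r_branch = np.where(forward, r_i * (1.0 - hysteresis_width / 2.0),
                            r_i * (1.0 + hysteresis_width / 2.0))
        cycles.append((v_cycle.copy(), v_cycle / r_branch))
    return IVSweepSet(cycles=cycles, scan_rate_V_s=scan_rate_V_s, true_resistances_ohm=true_r)


# ---------------------------------------------------------------------------
# temperature / pH logs


@dataclass(frozen=True)
class EnvSpec:
    """Coupled temperature/pH oscillation logs.

    The temperature log is a primary sinusoid with one harmonic plus a
    slow quasi-periodic drift; the pH log is the temperature log's
    oscillatory component scaled to ``ph_amp`` and delayed by
    ``lag_min`` (pH lags temperature when positive). ``ph_period_min``
    is used only in uncoupled mode (``coupled=False``), where pH gets
    an independent oscillator.
    """

    temp_mean_C: float = 16.5
    temp_amp_C: float = 0.06
    temp_period_min: float = 90.0
    ph_mean: float = 7.88
    ph_amp: float = 0.05
    ph_period_min: float = 86.6
    lag_min: float = 20.0
    temp_noise_sd: float = 0.01
    ph_noise_sd: float = 0.005
    dt_s: float = 1.0
    duration_s: float = 250000.0
    seed: int = 0
    drift_amp_C: float = 0.4
    drift_period_min: float = 333.0
    harmonic_frac: float = 0.25
    coupled: bool = True

    def __post_init__(self) -> None:
        if self.temp_period_min <= 0 or self.ph_period_min <= 0 or self.drift_period_min <= 0:
            raise InvalidSpecError("periods must be positive")
        if not math.isfinite(self.lag_min):
            raise InvalidSpecError("lag must be finite")
        if self.dt_s <= 0 or self.duration_s <= self.dt_s:
            raise InvalidSpecError("dt and duration must be positive with duration > dt")
        if self.temp_amp_C <= 0 and self.coupled:
            raise InvalidSpecError("coupled mode needs a positive temperature amplitude")
        if self.temp_noise_sd < 0 or self.ph_noise_sd < 0:
            raise InvalidSpecError("noise sds must be non-negative")


#: published long-term logging condition (1 Hz, ~69 h)
ENV_LOG_SPEC = EnvSpec()


def _oscillation(spec: EnvSpec, t_s: np.ndarray) -> np.ndarray:
    """Temperature oscillatory component (primary + harmonic + slow drift)."""
    w = 2.0 * np.pi / (spec.temp_period_min * 60.0)
    wd = 2.0 * np.pi / (spec.drift_period_min * 60.0)
    return (
        spec.temp_amp_C * (np.sin(w * t_s) + spec.harmonic_frac * np.sin(2.0 * w * t_s))
        + spec.drift_amp_C * np.sin(wd * t_s)
    )


def gen_env_series(spec: EnvSpec) -> EnvSeries:
    """Generate paired temperature and pH logs; see :class:`EnvSpec`."""
    rng = np.random.default_rng(spec.seed)
    n = int(spec.duration_s / spec.dt_s)
    t_s = np.arange(n) * spec.dt_s
    osc = _oscillation(spec, t_s)
    temp = spec.temp_mean_C + osc
    if spec.temp_noise_sd > 0:
        temp = temp + spec.temp_noise_sd * rng.standard_normal(n)
    lag_s = spec.lag_min * 60.0
    if spec.coupled:
        scale = spec.ph_amp / spec.temp_amp_C
        ph = spec.ph_mean + scale * _oscillation(spec, t_s - lag_s)
    else:
        wp = 2.0 * np.pi / (spec.ph_period_min * 60.0)
        ph = spec.ph_mean + spec.ph_amp * np.sin(wp * (t_s - lag_s))
    if spec.ph_noise_sd > 0:
        ph = ph + spec.ph_noise_sd * rng.standard_normal(n)
    return EnvSeries(dt_s=spec.dt_s, temperature_C=temp, ph=ph)


# ---------------------------------------------------------------------------
# capacitance series

#: distinct capacitance decay profiles per compound (c0 in μF, rate in 1/s)
CAPACITANCE_CONDITIONS: dict[str, tuple[float, float]] = {
    "actin": (0.8, 1.0e-4),
    "proteinoid": (1.5, 2.0e-4),
    "mixture": (2.2, 5.0e-5),
}


def gen_capacitance_series(
    c0: float,
    decay_rate_per_s: float = 0.0,
    fluctuation_sd: float = 0.0,
    dt_s: float = 1.0,
    duration_s: float = 5000.0,
    seed: int = 0,
) -> np.ndarray:
    """Exponentially decaying capacitance with fluctuations, clipped
    positive: C(t) = c0·exp(−rate·t) + noise."""
    if c0 <= 0:
        raise InvalidSpecError("c0 must be positive")
    rng = np.random.default_rng(seed)
    n = int(duration_s / dt_s)
    t = np.arange(n) * dt_s
    c = c0 * np.exp(-decay_rate_per_s * t)
    if fluctuation_sd > 0:
        c = c + fluctuation_sd * rng.standard_normal(n)
    return np.maximum(c, 1e-12 * c0)
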