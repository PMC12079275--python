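"""Spike detection/statistics, excitability labels, stimulation responses,
and I-V cycle memory analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protoelec import electrophys, synthetic
from protoelec.containers import IVSweepSet, MultichannelTrace
from protoelec.errors import InsufficientDataError, InvalidSpecError


def make_trace(values, dt=0.4, channel="ChF"):
    return MultichannelTrace(dt_s=dt, channels={channel: np.asarray(values, dtype=float)})


# ---------------------------------------------------------------------------
# brute-force detection oracle


def oracle_rolling_median(x, window):
    window = max(3, int(window))
    if window % 2 == 0:
        window += 1
    half = window // 2
    padded = np.concatenate([np.full(half, x[0]), x, np.full(half, x[-1])])
    return np.array([np.median(padded[i : i + window]) for i in range(len(x))])


def oracle_detect(v, height, prom_thresh, distance, baseline_window=50):
    """From-scratch re-implementation of the detection rule: strict local
    maxima of the deviation from a rolling-median baseline, height filter,
    refractory thinning (larger peaks win), then topographic prominence."""
    dev = v - oracle_rolling_median(v, baseline_window)
    n = len(dev)
    candidates = [
        i for i in range(1, n - 1) if dev[i - 1] < dev[i] > dev[i + 1] and dev[i] >= height
    ]
    # refractory: accept in decreasing height order
    accepted = []
    for i in sorted(candidates, key=lambda i: dev[i], reverse=True):
        if all(abs(i - a) >= distance for a in accepted):
            accepted.append(i)
    # topographic prominence on the deviation signal
    keep = []
    for i in sorted(accepted):
        lmin = dev[i]
        j = i - 1
        while j >= 0 and dev[j] <= dev[i]:
            lmin = min(lmin, dev[j])
            j -= 1
        rmin = dev[i]
        j = i + 1
        while j < n and dev[j] <= dev[i]:
            rmin = min(rmin, dev[j])
            j += 1
        if dev[i] - max(lmin, rmin) >= prom_thresh:
            keep.append(i)
    return keep


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        trace = make_trace(np.zeros(500))
        assert electrophys.detect_spikes(trace, "ChF").n_spikes == 0

    def test_planted_train_fully_recovered(self):
        v = np.zeros(1000)
        planted = np.arange(50, 1000, 100)
        v[planted] = 30.0
        trace = make_trace(v)
        train = electrophys.detect_spikes(trace, "ChF")
        assert train.n_spikes == len(planted)
        assert np.array_equal(train.indices, planted)
        assert np.allclose(train.amplitudes_mV, 30.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle_on_random_traces(self, seed):
        rng = np.random.default_rng(seed)
        v = 3.0 * rng.standard_normal(1000)
        v[rng.integers(50, 950, size=8)] += rng.uniform(8, 30, size=8)
        trace = make_trace(v)
        got = electrophys.detect_spikes(trace, "ChF", 5.0, 10.0).indices
        want = oracle_detect(v, 5.0, 5.0, distance=round(10.0 / 0.4))
        assert list(got) == want

    def test_translation_invariant(self):
        rng = np.random.default_rng(3)
        v = 2.0 * rng.standard_normal(800)
        v[::97] += 25.0
        t1 = electrophys.detect_spikes(make_trace(v), "ChF")
        t2 = electrophys.detect_spikes(make_trace(v + 123.4), "ChF")
        assert np.array_equal(t1.indices, t2.indices)
        assert np.allclose(t1.amplitudes_mV, t2.amplitudes_mV)

    def test_unknown_channel_raises_key_error(self):
        with pytest.raises(KeyError):
            electrophys.detect_spikes(make_trace(np.zeros(100)), "ChZ")

    def test_refractory_below_one_sample_rejected(self):
        with pytest.raises(InvalidSpecError):
            electrophys.detect_spikes(make_trace(np.zeros(100)), "ChF", refractory_s=0.1)


class TestSpikeStats:
    def test_two_spikes_give_configured_period(self):
        v = np.zeros(400)
        v[100] = 30.0
        v[100 + round(52.4 / 0.4)] = 30.0
        stats = electrophys.spike_stats(make_trace(v)).per_channel["ChF"]
        assert stats.period_mean_s == pytest.approx(52.4)

    def test_amplitude_summary_of_known_values(self):
        v = np.zeros(400)
        for i, amp in zip((50, 150, 250), (10.0, 20.0, 30.0)):
            v[i] = amp
        stats = electrophys.spike_stats(make_trace(v)).per_channel["ChF"]
        assert stats.amp_median_mV == pytest.approx(20.0)
        assert stats.amp_mean_mV == pytest.approx(20.0)
        assert stats.amp_sd_mV == pytest.approx(10.0)  # sample sd
        assert stats.amp_max_mV == pytest.approx(30.0)

    def test_empty_channel_reports_zero_spikes(self):
        stats = electrophys.spike_stats(make_trace(np.zeros(300))).per_channel["ChF"]
        assert stats.n_spikes == 0
        assert math.isnan(stats.amp_mean_mV)

    def test_periods_invariant_to_amplitude_rescaling(self):
        spec = synthetic.TraceSpec(duration_s=3000.0, noise_sd_mV=0.0, seed=4)
        trace = synthetic.gen_spiking_trace(spec)
        v = trace["ChF"]
        doubled = make_trace(2.0 * v)
        s1 = electrophys.spike_stats(trace).per_channel["ChF"]
        s2 = electrophys.spike_stats(doubled).per_channel["ChF"]
        assert s1.period_mean_s == pytest.approx(s2.period_mean_s)

    def test_long_synthetic_trace_recovers_amplitude_mean(self):
        trace = synthetic.gen_spiking_trace(synthetic.TraceSpec(seed=42))
        stats = electrophys.spike_stats(trace).per_channel["ChF"]
        sem = stats.amp_sd_mV / math.sqrt(stats.n_spikes)
        assert abs(stats.amp_mean_mV - 25.3) < 2 * sem


class TestClassifyDynamics:
    def test_spiking_generator_labelled_regular(self):
        spec = synthetic.TraceSpec(duration_s=3000.0, seed=0)
        trace = synthetic.gen_spiking_trace(spec)
        assert electrophys.classify_dynamics(trace, "ChF") == "regular_spiking"

    def test_plateau_profile_labelled_class2(self):
        trace = synthetic.gen_multiphasic_trace(
            synthetic.plateau_profile_phases(), noise_sd_mV=0.5, dt_s=1.0, seed=1
        )
        assert electrophys.classify_dynamics(trace, "ChB") == "plateau_class2"

    def test_bistable_switching_labelled_bistable(self):
        trace = synthetic.gen_multiphasic_trace(
            synthetic.bistable_profile_phases(), noise_sd_mV=2.0, dt_s=1.0, seed=2
        )
        assert electrophys.classify_dynamics(trace, "ChB") == "bistable"

    def test_constant_trace_labelled_quiescent(self):
        assert electrophys.classify_dynamics(make_trace(np.full(500, -12.0)), "ChF") == "quiescent"

    def test_short_trace_rejected(self):
        with pytest.raises(InsufficientDataError):
            electrophys.classify_dynamics(make_trace(np.zeros(50)), "ChF")


class TestStimulationResponse:
    def test_response_equal_to_stimulus_has_zero_delta_v(self):
        n = 4000
        gate = (np.arange(n) % 2000) < 1000
        stim = MultichannelTrace(0.001, {"stimulus": 1000.0 * gate})
        resp = MultichannelTrace(0.001, {"ChX": 1000.0 * gate})
        out = electrophys.stimulation_response(stim, resp)["ChX"]
        assert out.delta_v_mV == pytest.approx(0.0, abs=1e-9)

    def test_full_attenuation_leaves_constant_baseline(self):
        spec = synthetic.StimulationSpec(
            channel_baselines_mV={"ChC": (-6.22, 0.0)},
            channel_attenuation_mV={"ChC": 1000.0},
            latency_ms={"ChC": 5.0},
            recovery_ms={"ChC": 10.0},
            seed=0,
        )
        _, resp = synthetic.gen_stimulation_session(spec)
        assert np.allclose(resp["ChC"], -6.22)

    def test_planted_latency_recovered_within_one_ms(self):
        spec = synthetic.StimulationSpec(
            channel_baselines_mV={"ChX": (0.0, 0.0)},
            channel_attenuation_mV={"ChX": 200.0},
            latency_ms={"ChX": 5.0},
            recovery_ms={"ChX": 12.0},
            seed=0,
        )
        stim, resp = synthetic.gen_stimulation_session(spec)
        out = electrophys.stimulation_response(stim, resp)["ChX"]
        assert out.latency_ms == pytest.approx(5.0, abs=1.0)
        assert out.recovery_ms == pytest.approx(12.0, abs=2.0)

    def test_published_channel_parameters_recovered(self):
        stim, resp = synthetic.gen_stimulation_session(
            synthetic.StimulationSpec(seed=7)
        )
        out = electrophys.stimulation_response(stim, resp)
        assert out["ChC"].baseline_mean_mV == pytest.approx(-6.22, abs=0.5)
        assert out["ChC"].delta_v_mV == pytest.approx(205.63, abs=1.0)
        assert out["ChF"].baseline_mean_mV == pytest.approx(-82.74, abs=1.0)

    def test_zero_noise_baseline_variance_is_zero(self):
        spec = synthetic.StimulationSpec(
            channel_baselines_mV={"ChX": (-10.0, 0.0)},
            channel_attenuation_mV={"ChX": 300.0},
            latency_ms={"ChX": 4.0},
            recovery_ms={"ChX": 11.0},
        )
        stim, resp = synthetic.gen_stimulation_session(spec)
        out = electrophys.stimulation_response(stim, resp)["ChX"]
        # residual decay tail past the settle window is < 1e-6 mV
        assert out.baseline_variance_mV2 == pytest.approx(0.0, abs=1e-10)

    def test_constant_stimulus_rejected(self):
        stim = MultichannelTrace(0.001, {"stimulus": np.zeros(1000)})
        resp = MultichannelTrace(0.001, {"ChX": np.zeros(1000)})
        with pytest.raises(InvalidSpecError):
            electrophys.stimulation_response(stim, resp)


def pearson_oracle(x, y):
    """Textbook summation formula, written out term by term."""
    n = len(x)
    xbar = sum(x) / n
    ybar = sum(y) / n
    num = sum((x[i] - xbar) * (y[i] - ybar) for i in range(n))
    den = math.sqrt(
        sum((x[i] - xbar) ** 2 for i in range(n)) * sum((y[i] - ybar) ** 2 for i in range(n))
    )
    return num / den


class TestPearson:
    def test_matches_summation_oracle(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2.0, 2.1, 1.9, 2.2]
        assert electrophys.pearson_r(x, y) == pytest.approx(pearson_oracle(x, y), abs=1e-12)

    def test_zero_variance_defined_as_zero(self):
        assert electrophys.pearson_r([1, 1, 1], [1, 2, 3]) == 0.0

    @settings(max_examples=100, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3)), min_size=3, max_size=40
        ),
        a=st.floats(0.1, 50.0),
        b=st.floats(-100.0, 100.0),
    )
    def test_bounded_and_affine_invariant(self, data, a, b):
        x = np.array([d[0] for d in data])
        y = np.array([d[1] for d in data])
        r = electrophys.pearson_r(x, y)
        assert -1.0 <= r <= 1.0
        r_affine = electrophys.pearson_r(a * x + b, y)
        if np.std(x) > 1e-6 and np.std(y) > 1e-6:
            assert r_affine == pytest.approx(r, abs=1e-6)


class TestIVCycleAnalysis:
    def test_monotone_resistance_gives_r_one(self):
        sweeps = synthetic.gen_iv_sweeps(1000.0, drift_per_cycle_ohm=50.0, n_cycles=10)
        _, _, r = electrophys.iv_cycle_analysis(sweeps)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_decreasing_resistance_gives_r_minus_one(self):
        sweeps = synthetic.gen_iv_sweeps(10000.0, drift_per_cycle_ohm=-50.0, n_cycles=10)
        _, _, r = electrophys.iv_cycle_analysis(sweeps)
        assert r == pytest.approx(-1.0, abs=1e-9)

    def test_constant_resistance_gives_r_zero(self):
        sweeps = synthetic.gen_iv_sweeps(1000.0, n_cycles=8)
        _, _, r = electrophys.iv_cycle_analysis(sweeps)
        assert r == 0.0

    def test_memory_condition_r_recovered_from_waveforms(self):
        # condition whose population cycle-resistance correlation is 0.35;
        # recovery is judged against the realized resistance series
        cond = synthetic.MIXTURE_IV_CONDITION
        sweeps = synthetic.gen_iv_sweeps(
            cond["r0_ohm"],
            cond["drift_per_cycle_ohm"],
            cond["hysteresis_width"],
            resistance_noise_sd_ohm=cond["resistance_noise_sd_ohm"],
            seed=7,
        )
        _, _, r = electrophys.iv_cycle_analysis(sweeps)
        r_true = electrophys.pearson_r(
            np.arange(1, sweeps.n_cycles + 1), sweeps.true_resistances_ohm
        )
        assert r == pytest.approx(r_true, abs=0.1)

    def test_mean_resistance_recovered_per_cycle(self):
        sweeps = synthetic.gen_iv_sweeps(5000.0, drift_per_cycle_ohm=100.0, n_cycles=5)
        means, sds, _ = electrophys.iv_cycle_analysis(sweeps)
        assert np.allclose(means, sweeps.true_resistances_ohm, rtol=1e-9)
        assert np.allclose(sds, 0.0, atol=1e-6)

    def test_all_samples_in_dead_band_rejected(self):
        v = np.full(100, 0.1)
        sweeps = IVSweepSet(cycles=[(v, v / 100.0), (v, v / 100.0)], scan_rate_V_s=0.1)
        with pytest.raises(InsufficientDataError):
            electrophys.iv_cycle_analysis(sweeps)

    def test_single_cycle_rejected(self):
        sweeps = synthetic.gen_iv_sweeps(1000.0, n_cycles=1)
        with pytest.raises(InsufficientDataError):
            electrophys.iv_cycle_analysis(sweeps)
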