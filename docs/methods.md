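# Methods

This note records the models implemented by `protoelec`, the numerical
choices behind them, what the synthetic generators do and do not
emulate, and the known limitations. Everything quantitative stated here
is computed by the test suite or `scripts/acceptance.py`.

## Equivalent-circuit impedance

Impedance elements use the standard EIS conventions, with ω = 2πf in
rad/s and the principal branch for complex powers:

| element | impedance | parameter units |
|---|---|---|
| resistor | R | Ω |
| capacitor | 1/(jωC) | F |
| inductor | jωL | H |
| CPE | 1/(Q(jω)ⁿ), n ∈ [0,1] | Q in S·sⁿ |
| Warburg (semi-infinite) | W(1−j)/√(2ω) ≡ W/√(jω) | W in Ω·s^−1/2 |
| O (finite-length, open) | coth(B√(jω))/(Y₀√(jω)) | Y₀ in S·s^1/2, B in s^1/2 |

The O element defaults to the coth (open/reflective boundary) branch,
the common "O" convention in EIS software; a tanh (short) variant is
selectable per element. The proteinoid cell's published O magnitude
9741 Ω·s^−1/2 maps to Y₀ = 1/9741 S·s^1/2 with B = 0.329 s^1/2; the
second printed characteristic parameter (1.000) is retained as the
ideality of the element and not separately fitted. A circuit is a
series list of nodes, each an element or a parallel group; parallel
groups combine by admittance sum. Series composition is verified
against an independent tree-walking evaluator.

### Fitting

`fit_circuit` minimizes the weighted residual stack over real and
imaginary parts. The default weighting is **modulus** (1/|Zᵢ| per
point): it is the statistically efficient whitening when the noise is
multiplicative (proportional to |Z|), which is also the noise model of
the synthetic spectra. Unit and proportional weightings are selectable.
The reported chi-squared is the weighted sum divided by the residual
degrees of freedom 2N − p.

Parameters are fitted as log10 values (all are positive and span up to
nine decades), bounds are honoured by the trust-region-reflective
least-squares solver, and the best of four starts (the supplied initial
plus three log-uniform jitters of ±0.3 decades, drawn with a fixed
internal seed) is returned — fitting is therefore deterministic.
Percent uncertainties derive from the covariance of the log-parameters:
a stderr s in log10 units maps to 100·(10^s − 1) %. Parameters landing
within numerical distance of a bound are listed in `at_bounds`;
non-convergence is reported in the result (`converged=False` with the
optimizer's message), never silently.

### Identifiability

Not every printed parameter is constrained by an in-band spectrum
(0.1 mHz – 100 kHz):

- **proteinoid C₁ = 10⁻¹² F** sits at the published lower fitting
  limit; its parallel reactance exceeds 10⁸ Ω everywhere in band, so
  R₂∥C₁ ≈ R₂ and consequently **R₁ and R₂ enter the model only through
  their sum**. Round-trip tests assert the sum, W₁, Y₀ and B.
- **mixture C₁ = 1 pF** likewise has |Z_C₁| ≥ 1.6 MΩ at 100 kHz against
  R₁ = 3.7 kΩ: excluded from recovery assertions.
- Under 1 % multiplicative noise a parameter can be recovered to <5 %
  with ~95 % reliability only if twice its 1σ uncertainty is below 5 %.
  For the actin circuit that admits R₂, n₁ and R₃ but not R₁ (~10.7 %),
  C₁ (~13.4 %) or Q₁ (3.8 % at 1σ, ~7.6 % at 2σ) — their Monte Carlo
  recovery dispersion matches those uncertainty levels. Noiseless round
  trips recover *all* actin parameters to machine precision.

## Conductivity and LCR derivations

σ = L/(|Z|·πr²) with the cell geometry as an explicit, overridable
object. The default radius r = 1 cm is the documented package default:
together with L = 10 cm it is the unique radius consistent with all
three cell conductivities derived from the corresponding impedance
magnitudes (10/(6797π) = 4.68×10⁻⁴, 10/(26630π) = 1.20×10⁻⁴,
10/(177000π) = 1.80×10⁻⁵ S/cm). Enhancement ratios cancel shared
geometry exactly and reduce to inverse impedance ratios.

`lcr_derive` reports θ as a magnitude in degrees with the sign of the
reactance carried separately (tabulated LCR data mix sign conventions),
and D = R/|X| with an infinity flag at X = 0. Reconstruction of series
capacitance/inductance from R/X is deliberately out of scope: typical
single-frequency LCR tables mix measurement modes, and the redundant
quantities are not mutually consistent — only θ is reliably
recomputable from an R/X pair.

## Spike detection and statistics

Detection operates on the deviation of a channel from a **centered
rolling-median baseline** (50 samples, ~20 s at the 2.5 Hz logging
rate). Candidates are local maxima at least `min_prominence_mV`
(default 5 mV) above baseline, must also have that much *topographic*
prominence — which rejects noise bumps riding on a repolarization tail,
whose prominence is only the noise scale — and are thinned to a minimum
separation of `refractory_s` (default 10 s), larger peaks winning.
Detection is translation-invariant and matches a from-scratch
all-maxima-then-filter oracle exactly.

A spike's **amplitude** is its peak minus the median of the window of
one refractory interval immediately *preceding* the peak. A centered
median window would straddle the spike's own decay and systematically
under-report amplitude by a third of the spike height; the trailing
window stays clear of the spike while remaining long enough to average
baseline noise. Periods are successive peak-time differences; standard
deviations are sample (n−1) throughout; channels with fewer than five
spikes additionally carry a periodogram-based period estimate.

**Excitability labels** apply a fixed rule cascade: `regular_spiking`
(≥5 spikes, ISI CV < 0.5), then `plateau_class2` (one dominant high
state occupying >10 % of the record and ≥70 % of all high-state
samples, later left for a level at least 0.4 of the voltage range
lower), then `bistable` (Sarle bimodality coefficient > 0.555 and ≥2
mid-level crossings with ±15 %-of-range hysteresis), else `quiescent`.
The 70 % dominant-run condition separates a single metastable plateau
from repeated bistable switching, which otherwise also presents a
"high state followed by a lower state".

## Stimulation responses

The stimulus gate is thresholded at mid-amplitude. Baseline mean and
variance use off-phase samples excluding a settle window (default
100 ms) after every transition — long enough that an exponential
recovery with the longest configured time constant decays below 10⁻⁴ of
the evoked step. The mean input–output difference is the stimulus
amplitude minus the evoked displacement (on-phase mean − baseline).
Latency is the median time from an on-edge to 10 % of the evoked
change; recovery is the median time from an off-edge back to within
10 %, minus the channel's latency (the propagation delay applies to
both edges). A session that starts mid-phase has its leading samples
excluded as an unobserved transition.

## I–V cycling

Per-cycle resistance is the mean of V/I over samples with |V| ≥ 0.25 V
(the dead-band avoids the V/I blow-up near 0 V). The memory statistic
is the Pearson correlation of mean resistance against cycle number,
computed by the raw summation formula, defined as 0 when either
variance vanishes, and clipped to [−1, 1] against last-ulp rounding.

## Temperature–pH coupling

All spectral estimates linearly detrend first (the logs carry slow
drift on top of oscillations). The dominant period comes from a
Hann-windowed, 4× zero-padded periodogram with parabolic interpolation
around the peak bin; a peak below 25× the median spectral power is
rejected as low-confidence (white noise produces max/median ratios
around 10 at these lengths; genuine oscillations produce ratios in the
hundreds).

Phase lag is the argmax of the **zero-normalized cross-correlation**,
each lag scored over its own overlap window with that window's means
and variances — plain full cross-correlation biases the peak toward
zero lag as the overlap shrinks. The search spans ± one dominant
period; periodic signals repeat their peak one period away (and
detrending perturbs the copies at the 10⁻⁴ level), so among separated
local maxima within 10⁻³ of the best the smallest |lag| wins. Positive
lag means pH lags temperature.

The coupling coefficient κ is the magnitude-squared coherence (Welch,
segments of n/8) evaluated at the dominant temperature frequency;
κ ∈ [0,1], equals 1 for noiseless linear filtering, and falls back to
the band-average coherence when no dominant frequency exists (the
maximum bin would be biased to ~0.3 under independence). Arrhenius
rates use R = 8.314462618 J/(mol·K) with temperatures in kelvin.

## Gray–Scott simulation

Explicit Euler, dt = 1 grid-time unit, unit spacing, 5-point Laplacian
with **periodic boundaries** (avoids edge artifacts in spot counts;
dt = 1 is stable for the diffusion coefficients used, all ≤ 0.16,
against the dx²/(4D) bound). The standard initial condition is A = 1
everywhere and B = 1 in a central 11×11 square (configurable
half-width), with optional seeded uniform noise to break symmetry. The
trivial steady state (A=1, B=0) is preserved exactly; a single step
equals a double-loop oracle to 10⁻¹²; the three compound parameter sets
produce nonuniform patterns (spatial sd(B) > 0.01) within 5000 steps on
a 100×100 grid with fields bounded in [0, 1.5].

Capacitance modulation is linear: p_t = p_base·(1 + β·(C_t − C̄)/C̄)
for D_A, D_B and F, the kill rate held fixed, with the capacitance
series linearly resampled to the step count and β = 0.5 by default (the
mapping gain is a free design choice; the linear form is the simplest
mapping that preserves the mean parameters and transfers the decay
profile's shape). Modulations that would push a parameter negative or
past the diffusion stability bound are rejected up front. Spot counts
use 4-connected components of B > mean + sd, cross-checked against a
flood-fill oracle.

## Synthetic generators

Every generator is a pure function of its spec including a single
64-bit seed; no global RNG state. The module-level spec constants
encode the study conditions; the notable defaults and the reasoning:

- **Spiking trace**: gamma-distributed ISIs with mean 52.4 s and
  CV 0.2 ("quasi-periodic": clearly rhythmic, visibly jittered);
  amplitudes N(25.3, 5.2²) mV over a 25 mV baseline; one-sample rise
  and exponential decay with τ = 0.2·mean ISI (≈10 s, matching the
  tens-of-seconds waveform); baseline noise sd 1 mV (small against the
  25 mV spikes, as in the recordings); 2.5 Hz sampling, 20,000 s.
- **Stimulation session**: 1000 mV square wave, 50 % duty, 2 s period,
  20 s, generated at dt = 1 ms — ms-scale latencies cannot be resolved
  at the 0.4 s logging interval, and the fast-acquisition rate of the
  original sessions is not recorded, so 1 ms is adopted as the
  generation resolution. Channels C–F carry the published baselines and
  the two published input–output endpoints (C 205.63, F 282.15 mV);
  D and E interpolate evenly between them, as do the latency
  (4.2–7.8 ms) and recovery (10.5–15.3 ms) endpoints. The response is
  baseline + (stimulus − attenuation) gated with a pure latency delay,
  instantaneous rise, and exponential return whose time constant is
  recovery/ln 10 (so the 10 % re-entry time equals the configured
  recovery).
- **Environment logs**: temperature = mean + primary sinusoid (90 min,
  amplitude 0.06 °C) + 0.25-weighted second harmonic + slow drift
  (0.4 °C, ~5.5 h), 1 Hz for 2.5×10⁵ s; pH is the temperature's
  oscillatory component scaled to amplitude 0.05 about mean 7.88 and
  delayed 20 min. The slow drift reproduces the hierarchical structure
  of the measured logs and is what keeps the pH autocorrelation above
  0.6 out to 10³ s; round-trip tests that probe the primary period set
  the drift to zero. An uncoupled mode gives pH an independent
  oscillator at its own period (86.6 min) for experiments that need it.
- **I–V sweeps**: triangular 0→+5→−5→0 V cycles at 100 mV/s; cycle
  resistance drifts linearly with Gaussian cycle noise; hysteresis
  splits forward/backward branches by a fractional width. The memory
  condition (r₀ = 200 kΩ, drift 400 Ω/cycle, noise sd 15.45 kΩ) is
  solved in closed form so the *population* correlation between cycle
  number and resistance is 0.35; at n = 50 a single session's sample r
  scatters around that with SE ≈ 0.13, so recovery is judged against
  the generator's drawn resistance series, which the waveform-level
  estimate reproduces essentially exactly.
- **Capacitance decays**: C(t) = C₀e^(−λt) + noise, clipped positive,
  with per-compound (C₀, λ) chosen to give visibly distinct microfarad-
  scale decay profiles.

What the generators do **not** emulate: spike-waveform diversity
(afterhyperpolarization, bursting), nonstationary baselines and
electrode drift, correlated multi-channel noise, non-gamma ISI
structure, distributed (non-lumped) stimulation responses, and any
chemistry of proteinoid assembly — they are phenomenological emulators
of the recordings' summary statistics. Passing recovery tests therefore
demonstrates that the analysis stages are unbiased and correctly scaled
under the stated statistical structure, not that they are robust to
every artifact of real recordings.

## Problem sizes

Default analyses run in seconds on one CPU: 91-point spectra (10 per
decade over 9 decades), 50,000-sample traces, 2.5×10⁵-sample
environment logs, 50×400-sample sweep sessions, and 100×100×5000-step
reaction–diffusion runs. The test suite uses these same sizes for the
headline checks and smaller grids for oracle comparisons.

## Known limitations

- Only the three published circuit topologies are constructible by
  name; there is no general netlist language or distributed-element
  model.
- No Kramers–Kronig validation or cross-topology model selection.
- The printed chi-squared values of the original fits (0.0002, 0.0053)
  are not reproducible without the raw spectra and their (unstated)
  weighting convention; the package's chi-squared is defined explicitly
  instead.
- The exact printed per-channel spike statistics of the original
  multi-channel tables are treated as generator settings, not
  recoverable outputs, since the raw recordings are unavailable.
- Excitability classification is rule-based and tuned to the four
  archetypes it names; it does not attempt spike sorting or
  model-based state inference.
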