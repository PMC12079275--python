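"""Temperature-pH coupling: dominant periods, phase lag, coherence and
Arrhenius kinetics.

Paired 1 Hz logs are generated with ~90 min thermal cycles, a slow
multi-hour drift, and a pH series that mirrors the temperature
oscillation (mean 7.88) delayed by 20 min. The analysis reads back the
oscillation period, the lag of pH behind temperature, their spectral
coherence at the shared frequency, and the pH autocorrelation; the
Arrhenius law converts the temperature swing into a protonation-rate
modulation.
"""

import dataclasses

from protoelec import synthetic, thermochem

spec = dataclasses.replace(synthetic.ENV_LOG_SPEC, seed=2, drift_amp_C=0.0,
                           duration_s=120000.0, dt_s=2.0)
env = synthetic.gen_env_series(spec)

period = thermochem.dominant_period(env.temperature_C, env.dt_s)
lag = thermochem.phase_lag(env)
kappa = thermochem.coupling_coefficient(env)
print(f"temperature period : {period / 60:.1f} min (configured {spec.temp_period_min})")
print(f"pH lags temperature: {lag / 60:.1f} min (configured {spec.lag_min})")
print(f"coupling kappa     : {kappa:.3f}  (1 = perfectly coherent at the shared frequency)")
print(f"pH mean            : {env.ph.mean():.3f} (configured {spec.ph_mean})")
for tau in (100.0, 500.0, 1000.0):
    r = thermochem.autocorrelation(env.ph, tau, env.dt_s)
    print(f"pH autocorrelation r({tau:.0f} s) = {r:.2f}")

params = thermochem.ArrheniusParams(ea_kJ_mol=29.3, k0_per_s=1.0)
ratio = thermochem.arrhenius_rate(25.0, params) / thermochem.arrhenius_rate(16.0, params)
print(f"\nArrhenius Ea = 29.3 kJ/mol: a 16->25 C swing speeds protonation {ratio:.2f}x,")
print("the mechanism by which thermal cycles drive the delayed pH cycles.")
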