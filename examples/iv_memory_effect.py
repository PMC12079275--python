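"""I-V cycling memory effect: does resistance drift with cycle number?

Sessions of 50 hysteretic +/-5 V sweep cycles (100 mV/s) are generated
with a slow upward resistance drift buried in cycle-to-cycle noise —
the condition whose population cycle-resistance correlation is 0.35.
The analysis computes per-cycle mean resistance from the sweep
waveforms and the Pearson correlation against cycle number: a positive
r is a memory effect (the material remembers its cycling history),
r near 0 means stable electrical properties. With only 50 cycles a
single session's r scatters widely around the population value, so the
example reports several replicate sessions.
"""

import numpy as np

from protoelec import electrophys, synthetic

cond = synthetic.MIXTURE_IV_CONDITION


def session_r(drift, seed):
    sweeps = synthetic.gen_iv_sweeps(
        r0_ohm=cond["r0_ohm"],
        drift_per_cycle_ohm=drift,
        hysteresis_width=cond["hysteresis_width"],
        resistance_noise_sd_ohm=cond["resistance_noise_sd_ohm"],
        seed=seed,
    )
    _, _, r = electrophys.iv_cycle_analysis(sweeps)
    r_truth = electrophys.pearson_r(
        np.arange(1, sweeps.n_cycles + 1), sweeps.true_resistances_ohm
    )
    return r, r_truth


seeds = range(10)
with_drift = np.array([session_r(cond["drift_per_cycle_ohm"], s) for s in seeds])
no_drift = np.array([session_r(0.0, s) for s in seeds])

print("10 replicate sessions of 50 cycles each:")
print(f"  drifting resistance : r = {with_drift[:, 0].mean():.2f} "
      f"+/- {with_drift[:, 0].std(ddof=1):.2f}  (population 0.35)")
print(f"  stable resistance   : r = {no_drift[:, 0].mean():.2f} "
      f"+/- {no_drift[:, 0].std(ddof=1):.2f}  (population 0)")
err = np.abs(with_drift[:, 0] - with_drift[:, 1]).max()
print(f"  worst |r_waveform - r_truth| across sessions: {err:.3f}")

print("\nThe waveform-level estimate reproduces the correlation of the")
print("underlying resistance series almost exactly; the spread across")
print("sessions is the sampling noise of r at n = 50 cycles.")
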