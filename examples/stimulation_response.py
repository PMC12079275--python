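"""Square-wave stimulation: per-channel input-output differences,
latencies and recovery times.

A 20 s session (1000 mV square wave, 50% duty) is generated at 1 ms
resolution with four response channels whose baselines, attenuations
and millisecond-scale latencies follow the published session. The
analysis recovers each channel's baseline, the mean input-output
difference (how much of the stimulus is lost crossing the network),
and the response timing.
"""

import dataclasses

from protoelec import electrophys, synthetic

spec = dataclasses.replace(synthetic.STIM_SESSION_SPEC, seed=0)
stimulus, responses = synthetic.gen_stimulation_session(spec)
result = electrophys.stimulation_response(stimulus, responses)

print(f"{'ch':>4} {'baseline mV':>12} {'var mV^2':>9} {'dV mV':>8} "
      f"{'latency ms':>11} {'recovery ms':>12}")
for ch, r in result.items():
    print(f"{ch:>4} {r.baseline_mean_mV:12.2f} {r.baseline_variance_mV2:9.2f} "
          f"{r.delta_v_mV:8.2f} {r.latency_ms:11.1f} {r.recovery_ms:12.1f}")

print("\ndV is the stimulus amplitude minus the evoked displacement: the")
print("voltage attenuation of each conduction path (configured 205.6-282.2 mV).")
print("Latency is time to 10% of the evoked change after a stimulus edge.")
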