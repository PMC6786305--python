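"""A short closed-loop reaching run at the published 16x16 / 8-motor scale.

One simulated minute: the event camera watches the ball, 23,040 plastic
synapses carry the visuomotor mapping, the population vector of 8 motor
neurons moves the ball, and the directional reward streams back to every
synapse.  Prints the timing bookkeeping and goal-reach count.
"""

from sporesim import ExperimentConfig, run_closed_loop
from sporesim.experiment import reach_rate, weak_weight_count

cfg = ExperimentConfig(task="reaching", duration=60.0, seed=1)
log = run_closed_loop(cfg)

print(f"simulated {cfg.duration:.0f} s: {log.reward.size} fast steps, "
      f"{log.n_slow_updates} parameter updates")
print(f"goal reached {len(log.reset_times)} times "
      f"(rate {reach_rate(log)[0]} per partial 250 s window)")
print(f"mean instantaneous reward {log.reward.mean():.3f}")
w = log.snapshots[-1]
print(f"weak weights (< 0.07): {weak_weight_count(w)} of {w.size}")
print("-> at beta = 1e-7 one minute barely moves the parameters; learning at")
print("   this scale takes simulated hours (see the reduced benchmark instead).")
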