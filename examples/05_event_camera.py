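"""The simulated event camera: only change is sensed.

A dynamic vision sensor emits ON/OFF address events where pixel intensity
changes beyond a threshold since the pixel's last event.  A moving ball
produces a sparse event stream at its edges; a static one produces silence —
which is why the reaching network needs an exploration neuron.
"""

import numpy as np

from sporesim import DVSSimulator, ReachingConfig, ReachingState, render_reaching
from sporesim.vision import encode_reaching_spikes

cfg = ReachingConfig()
dvs = DVSSimulator((cfg.pixels, cfg.pixels), threshold=0.1)

state = ReachingState(ball_pos=np.array([4.0, 4.0]))
dvs.step(render_reaching(state, cfg).pixels)  # primes the sensor

moving, static = 0, 0
for k in range(1000):  # 1 s at the 1 ms frame clock
    state.ball_pos += np.array([-2.0, -2.0]) * 0.001  # 2.8 m/s toward center
    moving += len(dvs.step(render_reaching(state, cfg).pixels))
for k in range(1000):
    static += len(dvs.step(render_reaching(state, cfg).pixels))

print(f"moving ball : {moving} events in 1 s")
print(f"static ball : {static} events in 1 s")
events = dvs.step(render_reaching(ReachingState(np.array([0.0, 0.0])), cfg).pixels)
spikes = encode_reaching_spikes(events, pixels=cfg.pixels)
print(f"a teleport to the center fires {len(events)} pixels -> "
      f"{spikes.sum()} input spikes (pixel + row + column each)")
print("-> motion codes the scene; silence is ambiguity, not emptiness.")
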