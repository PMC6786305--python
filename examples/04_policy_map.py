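"""Policy maps: what motion does an event at each pixel command?

For a reaching network, each pixel's contribution to the population-vector
command is the weight-weighted sum of the motor neurons' preferred
directions (including the pixel's row/column axis feature neurons).  The
angular correctness is the cosine between that vector and the direction
toward the plane center — +1 means the pixel pushes the ball straight home.
"""

import numpy as np

from sporesim import NeuronConfig, ReachingConfig, SporeConfig, build_reaching_network
from sporesim.experiment import policy_map

cfg = ReachingConfig(pixels=8, n_motor=4, multiplicity=2)
top = build_reaching_network(cfg, SporeConfig(), NeuronConfig(), rng_seed=0)

vectors, correctness = policy_map(top.plastic.w.ravel(), top)
finite = correctness[np.isfinite(correctness)]
print(f"policy map over {cfg.pixels}x{cfg.pixels} pixels")
print(f"mean vector magnitude  {np.linalg.norm(vectors, axis=2).mean():.2f}")
print(f"mean angular correctness {finite.mean():+.3f} (random init: ~0)")
print(f"pixels pointing goalward (cos > 0.5): {(finite > 0.5).mean() * 100:.0f}%")
print("-> a freshly initialized network pushes in random directions; after")
print("   learning, correctness rises as pixel vectors rotate toward the center.")
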