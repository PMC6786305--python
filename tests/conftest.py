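"""Shared fixtures; the desk-scale benchmark runs once per session."""

import numpy as np
import pytest

from sporesim.experiment import reduced_reaching_config, run_closed_loop

N_SEEDS = 5
BENCH_DURATION = 1800.0  # 30 simulated minutes per run


@pytest.fixture(scope="session")
def benchmark_runs():
    """Paired learning / frozen-weight reaching runs on the reduced task.

    Five seeds, 30 simulated minutes each, identical architecture and drive;
    the frozen runs (beta = 0) are the random-policy baseline.  Shared across
    the acceptance tests that evaluate learning uplift and sparsification.
    """
    learn, frozen = [], []
    for seed in range(N_SEEDS):
        learn.append(run_closed_loop(
            reduced_reaching_config(seed=seed, plastic=True, duration=BENCH_DURATION)))
        frozen.append(run_closed_loop(
            reduced_reaching_config(seed=seed, plastic=False, duration=BENCH_DURATION)))
    return {"learn": learn, "frozen": frozen}
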