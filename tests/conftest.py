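import os

# tiny linear-algebra calls dominate; multithreaded BLAS only contends
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS", "NUMEXPR_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

from mesocage.eventlog import Trial
from mesocage.mouse_sim import AgentParams, SyntheticMovieConfig, simulate_colony, simulate_movie


@pytest.fixture(scope="session")
def small_colony():
    """Two-day, four-mouse colony with default (study-condition) agents."""
    rng = np.random.default_rng(11)
    params = {f"tag{i:02d}": AgentParams() for i in range(4)}
    store, truth = simulate_colony(params, days=2, rng=rng)
    return store, truth


@pytest.fixture(scope="session")
def go_trials():
    """Alternating correct/early go trials spaced like real headfix trials."""
    return [
        Trial(
            cue_time=2.5 + i * 6.0,
            cue_kind="go",
            withhold_duration=2.0,
            delay=0.9,
            licks=[],
            outcome=2 if i % 2 == 0 else -4,
        )
        for i in range(12)
    ]


@pytest.fixture(scope="session")
def synthetic_movie(go_trials):
    """Default-condition synthetic movie + truth for the trials above."""
    rng = np.random.default_rng(7)
    stack, truth = simulate_movie(go_trials, SyntheticMovieConfig(), rng)
    return stack, truth
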