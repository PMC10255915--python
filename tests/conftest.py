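"""Shared fixtures.

The session-scoped benchmark fixture runs the full synthetic comparison
(default generator conditions, tiny backbones, 30 epochs, 3 seeds) once;
several acceptance-level tests then assert different phenomena on the
same runs.  It is by far the most expensive fixture, so it is built
lazily: only test sessions that request it pay for it.
"""

import pytest

BENCHMARK_SEEDS = (0, 1, 2)
BENCHMARK_EPOCHS = 30


@pytest.fixture(scope="session")
def benchmark_results():
    """Mutual vs single comparison on the default benchmark, 3 seeds."""
    from tsml import run_benchmark

    return [
        run_benchmark(seed, epochs=BENCHMARK_EPOCHS) for seed in BENCHMARK_SEEDS
    ]
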