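import numpy as np
import pytest

from neurorhythm import simulate, traces


def child_seeds(base: int, n: int) -> list[int]:
    """Deterministic per-run child seeds below 2**31."""
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(base).spawn(n)]


@pytest.fixture(scope="session")
def small_culture():
    """A small rhythmic culture plus its scored activity pattern."""
    cfg = simulate.CultureSimConfig(
        n_neurons=20, session_times_h=tuple(range(0, 36, 4)), seed=101
    )
    recordings, truth = simulate.simulate_culture(cfg)
    records = traces.score_recordings(recordings)
    pattern = traces.assemble_pattern(records)
    return cfg, recordings, truth, records, pattern


def make_pattern(scores, session_times=None):
    scores = np.asarray(scores, dtype=float)
    n, k = scores.shape
    if session_times is None:
        session_times = np.arange(k, dtype=float)
    return traces.ActivityPattern(
        neuron_ids=[f"n{i}" for i in range(n)],
        session_times_h=np.asarray(session_times, dtype=float),
        scores=scores,
    )
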