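import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import squigalign as sq
from squigalign.event_detection import Event

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def m2():
    """Toy 2-mer synthetic pore model (16 k-mers)."""
    return sq.synthetic_pore_model(2, seed=11)


@pytest.fixture(scope="session")
def m6():
    """Default 6-mer synthetic pore model (4096 k-mers)."""
    return sq.synthetic_pore_model(6)


def make_instance(seed: int, model, max_events: int = 30, max_kmers: int = 20):
    """Deterministic small alignment instance for oracle comparisons.

    Even seeds draw events from the simulator (realistic stays/skips);
    odd seeds use uniform random event means (adversarial scores).
    Returns (events, sequence, transitions).
    """
    rng = np.random.default_rng(seed)
    n_kmers = int(rng.integers(1, max_kmers + 1))
    seq = sq.random_sequence(n_kmers + model.k - 1, seed=1000 + seed)
    if seed % 2 == 0:
        events, _ = sq.simulate_events(
            seq,
            model,
            sq.ScalingParams(),
            sq.SimParams(stay_prob=0.25, skip_prob=0.05, noise_mult=1.0, seed=seed),
        )
        events = events[:max_events]
    else:
        n_events = int(rng.integers(1, max_events + 1))
        means = rng.uniform(60.0, 140.0, size=n_events)
        events = [Event(i * 10, 10, float(x), 0.0) for i, x in enumerate(means)]
    trans = sq.default_transitions(len(events), n_kmers)
    return events, seq, trans
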