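"""Synthetic squiggle generator with known ground-truth alignment.

Emulates the generative process the aligner assumes: walking the read's
k-mers left to right, each k-mer is occasionally *skipped* (no event),
otherwise emits a geometric number of events (*stays*) whose means are
Gaussian draws around the read-scaled pore-model level. Raw mode expands
each event into noisy current samples. Because the ground-truth
(event, k-mer) pairing and segment boundaries are recorded, simulator
output serves as the test substrate for event detection, calibration and
alignment recovery.

All randomness flows from a single integer seed through NumPy's PCG64
generator, so output is bit-reproducible across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .event_detection import Event
from .scoring import KmerModel, ScalingParams, seq_to_kmer_ranks

__all__ = [
    "SimParams",
    "SimTruth",
    "simulate_events",
    "simulate_raw",
    "events_per_base",
    "synthetic_pore_model",
    "random_sequence",
    "true_kmer_recovery",
]


@dataclass(frozen=True)
class SimParams:
    """Generative parameters of the synthetic squiggle.

    Defaults describe a typical DNA translocation regime: about two
    events per k-mer (stay_prob 0.5), rare skips, event-level noise at
    the pore-model stdv (noise_mult 1), ~15 samples per event at 1 pA
    sample noise.
    """

    stay_prob: float = 0.5
    skip_prob: float = 0.05
    noise_mult: float = 1.0
    samples_per_event_mean: int = 15
    sample_noise: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.stay_prob < 1.0:
            raise ValueError("stay_prob must be in [0, 1)")
        if not 0.0 <= self.skip_prob < 0.5:
            raise ValueError("skip_prob must be in [0, 0.5)")
        if self.stay_prob + self.skip_prob >= 1.0:
            raise ValueError("stay_prob + skip_prob must be < 1")
        if self.noise_mult < 0:
            raise ValueError("noise_mult must be >= 0")
        if self.samples_per_event_mean < 1:
            raise ValueError("samples_per_event_mean must be >= 1")
        if self.sample_noise < 0:
            raise ValueError("sample_noise must be >= 0")


@dataclass
class SimTruth:
    """Ground truth attached to a simulated read."""

    pairs: list[tuple[int, int]]
    boundaries: list[int] = field(default_factory=list)
    scaling: ScalingParams = field(default_factory=ScalingParams)


def _simulate_events(sequence, model, scaling, params, rng):
    ranks = seq_to_kmer_ranks(sequence, model.k)
    n_kmers = int(ranks.size)

    skip = np.zeros(n_kmers, dtype=bool)
    if params.skip_prob > 0:
        skip = rng.random(n_kmers) < params.skip_prob
        if skip.all():
            # tiny sequences can lose every k-mer; retry once without skips
            skip = np.zeros(n_kmers, dtype=bool)

    events: list[Event] = []
    pairs: list[tuple[int, int]] = []
    pos = 0
    for q in range(n_kmers):
        if skip[q]:
            continue
        r = int(ranks[q])
        n_stay = int(rng.geometric(1.0 - params.stay_prob)) if params.stay_prob > 0 else 1
        mu = scaling.scale * model.mean(r) + scaling.shift
        sd = params.noise_mult * scaling.var * model.stdv(r)
        for _ in range(n_stay):
            mean = float(mu + rng.normal(0.0, sd)) if sd > 0 else float(mu)
            pairs.append((len(events), q))
            events.append(
                Event(
                    start=pos,
                    length=params.samples_per_event_mean,
                    mean=mean,
                    stdv=float(sd),
                )
            )
            pos += params.samples_per_event_mean
    if not events:
        raise RuntimeError("simulation produced no events")
    return events, SimTruth(pairs=pairs, scaling=scaling)


def simulate_events(sequence, model: KmerModel, scaling: ScalingParams, params: SimParams):
    """Simulate the event table of one read.

    Walks the k-mers of ``sequence`` in order. Each k-mer is skipped with
    ``skip_prob`` (contributing no event and no truth pair); otherwise it
    emits ``G ~ 1 + Geometric(stay_prob)`` events whose means are drawn
    from ``N(scale * mu_k + shift, noise_mult * var * sigma_k)``. Event
    ``stdv`` is set to the generating noise scale.

    Returns
    -------
    (list of Event, SimTruth)
        Events in emission order, plus the true (event, k-mer) pairing
        and the scaling that was applied.
    """
    rng = np.random.default_rng(params.seed)
    return _simulate_events(sequence, model, scaling, params, rng)


def simulate_raw(sequence, model: KmerModel, scaling: ScalingParams, params: SimParams):
    """Simulate the raw current trace of one read.

    Runs :func:`simulate_events`, then expands each event into
    ``S ~ max(4, Poisson(samples_per_event_mean))`` samples drawn from
    ``N(event mean, sample_noise)``. The true segment boundaries are
    recorded in the returned truth, and each event's start/length are
    rewritten to its actual sample extent.

    Returns
    -------
    (numpy.ndarray, list of Event, SimTruth)
        The signal (pA per sample), the generating events, and ground
        truth with ``boundaries`` populated.
    """
    rng = np.random.default_rng(params.seed)
    events, truth = _simulate_events(sequence, model, scaling, params, rng)

    chunks = []
    boundaries = [0]
    placed: list[Event] = []
    pos = 0
    for ev in events:
        n = max(4, int(rng.poisson(params.samples_per_event_mean)))
        if params.sample_noise > 0:
            seg = rng.normal(ev.mean, params.sample_noise, size=n)
        else:
            seg = np.full(n, ev.mean)
        chunks.append(seg)
        placed.append(Event(start=pos, length=n, mean=ev.mean, stdv=ev.stdv))
        pos += n
        boundaries.append(pos)
    truth.boundaries = boundaries
    return np.concatenate(chunks), placed, truth


def events_per_base(events, sequence) -> float:
    """Average number of events per base of the read.

    This ratio is the heuristic used to pre-size alignment memory for a
    batch of reads (around 2 for typical DNA data).
    """
    if len(sequence) == 0:
        raise ValueError("empty sequence")
    if len(events) == 0:
        raise ValueError("no events")
    return len(events) / len(sequence)


def synthetic_pore_model(k: int = 6, seed: int = 2025) -> KmerModel:
    """A synthetic stand-in pore model (not a measured chemistry table).

    Assigns every k-mer an independent level mean uniform on [60, 130] pA
    and stdv uniform on [0.8, 1.4] pA — the span and per-k-mer spread of
    real DNA pore models, so an event-noise multiplier of 1 corresponds
    to roughly 1 pA of level noise — deterministically from ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = 4**k
    return KmerModel(
        k,
        rng.uniform(60.0, 130.0, size=n),
        rng.uniform(0.8, 1.4, size=n),
    )


def random_sequence(length: int, seed: int = 0) -> str:
    """Uniform random DNA sequence of the given length."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def true_kmer_recovery(alignment_pairs, truth_pairs) -> float:
    """Fraction of truth events whose true k-mer appears in the alignment.

    An event counts as recovered when the exact (event, k-mer) pair from
    the truth is present in the alignment's pair list.
    """
    truth = list(truth_pairs)
    if not truth:
        raise ValueError("empty truth")
    got = set(map(tuple, alignment_pairs))
    hit = sum(1 for p in truth if tuple(p) in got)
    return hit / len(truth)
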