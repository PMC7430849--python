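"""Exhaustive unbanded event alignment, used as ground truth.

Computes every cell of the full ``(n_events + 1) x (n_kmers + 1)`` table
(virtual origin row/column included) with the same recurrence, penalties
and tie-breaking as the banded aligner. The banded heuristic restricts
the search space, so its score can never exceed this oracle's; whenever
the band is wide enough to cover the whole table the two must agree
exactly. The inner loop here is deliberately written from scratch —
plain scalar Python, no shared code with the banded implementation — so
that agreement between the two is evidence of correctness rather than a
tautology.
"""

from __future__ import annotations

import math

import numpy as np

from .abea import (
    EventAlignment,
    Trace,
    TransitionParams,
    default_transitions,
)
from .scoring import KmerModel, ScalingParams, seq_to_kmer_ranks

__all__ = ["full_dp_align"]

_LOG_2PI = math.log(2.0 * math.pi)
_NEG_INF = float("-inf")


def full_dp_align(
    events,
    sequence: str,
    model: KmerModel,
    scaling: ScalingParams,
    trans: TransitionParams | None = None,
    max_cells: int = 10**6,
) -> EventAlignment:
    """Optimal event-to-k-mer alignment by full dynamic programming.

    Parameters
    ----------
    events, sequence, model, scaling, trans :
        As for :func:`squigalign.abea.abea_align`.
    max_cells : int
        Refuse tables larger than this many cells; the oracle is meant
        for verification at small scale, not production alignment.

    Returns
    -------
    EventAlignment
        Optimal score and trace-back pairs under the identical scoring
        contract (ties DIAG > UP > LEFT; trace-back starts at the
        event row maximising the last-column score, earliest row on
        ties).
    """
    n_events = len(events)
    if n_events < 1:
        raise ValueError("need at least one event")
    ranks = [int(r) for r in seq_to_kmer_ranks(sequence, model.k)]
    n_kmers = len(ranks)
    if n_events * n_kmers > max_cells:
        raise ValueError(
            f"table of {n_events} x {n_kmers} = {n_events * n_kmers} cells "
            f"exceeds the oracle guard of {max_cells}"
        )
    if trans is None:
        trans = default_transitions(n_events, n_kmers)

    mus = [scaling.scale * model.mean(r) + scaling.shift for r in ranks]
    sds = [scaling.var * model.stdv(r) for r in ranks]
    means = [ev.mean for ev in events]

    # padded table: S[e+1][q+1] is cell (e, q); S[0][0] the origin,
    # S[e+1][0] the trim column
    S = [[_NEG_INF] * (n_kmers + 1) for _ in range(n_events + 1)]
    T = [[int(Trace.NONE)] * (n_kmers + 1) for _ in range(n_events + 1)]
    S[0][0] = 0.0
    for e in range(n_events):
        S[e + 1][0] = (e + 1) * trans.lp_trim
        T[e + 1][0] = int(Trace.UP)

    for e in range(n_events):
        x = means[e]
        row = S[e + 1]
        above = S[e]
        for q in range(n_kmers):
            sd = sds[q]
            z = (x - mus[q]) / sd
            lp = -0.5 * _LOG_2PI - math.log(sd) - 0.5 * z * z
            d = above[q] + trans.lp_step + lp
            u = above[q + 1] + trans.lp_stay + lp
            l = row[q] + trans.lp_skip
            best = d
            tag = int(Trace.DIAG)
            if u > best:
                best = u
                tag = int(Trace.UP)
            if l > best:
                best = l
                tag = int(Trace.LEFT)
            if best == _NEG_INF:
                tag = int(Trace.NONE)
            row[q + 1] = best
            T[e + 1][q + 1] = tag

    best_score = _NEG_INF
    best_event = -1
    for e in range(n_events):
        s = S[e + 1][n_kmers]
        if s > best_score:
            best_score = s
            best_event = e

    alignment = EventAlignment(pairs=[], score=best_score, n_kmers=n_kmers)
    if best_event < 0:
        return alignment

    pairs: list[tuple[int, int]] = []
    moves: list[int] = []
    e, q = best_event, n_kmers - 1
    while e >= 0 and q >= 0:
        tag = T[e + 1][q + 1]
        pairs.append((e, q))
        moves.append(tag)
        if tag == int(Trace.DIAG):
            e -= 1
            q -= 1
        elif tag == int(Trace.UP):
            e -= 1
        elif tag == int(Trace.LEFT):
            q -= 1
        else:
            break
    pairs.reverse()
    moves.reverse()

    emissions = []
    for (pe, pq), mv in zip(pairs, moves):
        if mv in (int(Trace.DIAG), int(Trace.UP)):
            sd = sds[pq]
            z = (means[pe] - mus[pq]) / sd
            emissions.append(-0.5 * _LOG_2PI - math.log(sd) - 0.5 * z * z)
        else:
            emissions.append(float("nan"))

    alignment.pairs = pairs
    alignment.moves = moves
    alignment.emissions = emissions
    ems = [em for em, mv in zip(emissions, moves) if mv in (int(Trace.DIAG), int(Trace.UP))]
    avg = float(np.mean(ems)) if ems else _NEG_INF
    alignment.avg_log_emission = avg
    alignment.qc_pass = (
        bool(pairs)
        and avg >= trans.min_average_log_emission
        and pairs[0][1] == 0
        and pairs[-1][1] == n_kmers - 1
    )
    return alignment
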