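"""Adaptive Banded Event Alignment (ABEA).

Aligns a read's events (rows) to its k-mers (columns) with a banded
dynamic program. Instead of the full ``n_events x n_kmers`` table, only
anti-diagonal bands of width ``W`` (default 100) are computed; after each
band the next one shifts either DOWN (advance an event) or RIGHT (advance
a k-mer) following the Suzuki-Kasahara heuristic: the band moves toward
whichever of its two end cells currently scores higher, keeping the
optimal path inside the band at O((n_events + n_kmers) * W) cost.

Moves and their meaning in pore terms:

* DIAG (*step*): one event, next k-mer;
* UP (*stay*): an extra event emitted by the same k-mer (the strand
  paused in the pore);
* LEFT (*skip*): a k-mer that emitted no event (the strand moved too
  fast to sample).

A virtual origin cell (-1, -1) scores 0 and a virtual trim column
``(e, -1)`` scores ``(e + 1) * lp_trim``, letting the alignment discard
leading events at a fixed per-event penalty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .scoring import LOG_2PI, KmerModel, ScalingParams, scaled_levels, seq_to_kmer_ranks

__all__ = [
    "Trace",
    "Direction",
    "BandState",
    "TransitionParams",
    "EventAlignment",
    "count_bands",
    "default_transitions",
    "band_move",
    "fill_band",
    "abea_align",
    "qc_check",
]

NEG_INF = float("-inf")


class Trace(IntEnum):
    """Back-pointer tag of a DP cell."""

    NONE = 0
    DIAG = 1  # step: event+1, kmer+1
    UP = 2    # stay: event+1
    LEFT = 3  # skip: kmer+1


class Direction(IntEnum):
    """Band movement between consecutive anti-diagonals."""

    DOWN = 0   # lower-left event index + 1
    RIGHT = 1  # lower-left k-mer index + 1


@dataclass
class BandState:
    """One anti-diagonal band of the DP table.

    The cell at offset ``o`` (0 <= o < W) has coordinates
    ``(event_idx, kmer_idx) = (lower_left[0] - o, lower_left[1] + o)``,
    so ``event_idx + kmer_idx`` is constant within a band. Cells outside
    the table hold ``-inf`` / ``Trace.NONE``.
    """

    scores: np.ndarray
    trace: np.ndarray
    lower_left: tuple[int, int]

    @classmethod
    def blank(cls, W: int, lower_left: tuple[int, int]) -> "BandState":
        return cls(
            scores=np.full(W, NEG_INF, dtype=np.float64),
            trace=np.full(W, int(Trace.NONE), dtype=np.uint8),
            lower_left=(int(lower_left[0]), int(lower_left[1])),
        )

    @property
    def width(self) -> int:
        return self.scores.size


@dataclass(frozen=True)
class TransitionParams:
    """Log-probabilities of the three moves plus the trim penalty.

    ``exp(lp_step) + exp(lp_stay) + exp(lp_skip)`` must not exceed 1.
    ``min_average_log_emission`` is the QC floor on the mean per-event
    emission score of an accepted alignment.
    """

    lp_step: float
    lp_stay: float
    lp_skip: float
    lp_trim: float
    min_average_log_emission: float = -5.0

    def __post_init__(self) -> None:
        total = math.exp(self.lp_step) + math.exp(self.lp_stay) + math.exp(self.lp_skip)
        if total > 1.0 + 1e-6:
            raise ValueError(f"move probabilities sum to {total} > 1")
        for name in ("lp_step", "lp_stay", "lp_skip", "lp_trim"):
            if getattr(self, name) > 0:
                raise ValueError(f"{name} must be <= 0")


def count_bands(n_events: int, n_kmers: int) -> int:
    """Number of anti-diagonal bands covering the table proper.

    A table of ``n_events`` rows and ``n_kmers`` columns has
    ``n_events + n_kmers - 1`` anti-diagonals; e.g. 13 events against 6
    k-mers give 18 bands, the last one carrying zero-based index 17.
    """
    if n_events < 1 or n_kmers < 1:
        raise ValueError("n_events and n_kmers must be >= 1")
    return n_events + n_kmers - 1


def default_transitions(n_events: int, n_kmers: int) -> TransitionParams:
    """Heuristic move probabilities from the event/k-mer count ratio.

    With ``r = n_events / n_kmers`` events per k-mer, the stay
    probability is set to ``1 - 1 / (r + 1)`` so that the expected number
    of events emitted per k-mer matches ``r``; the skip mass is a fixed
    small ``1e-10``; stepping takes the rest. Trimming a leading event
    costs ``ln 0.01``.
    """
    if n_events < 1 or n_kmers < 1:
        raise ValueError("n_events and n_kmers must be >= 1")
    events_per_kmer = n_events / n_kmers
    p_stay = 1.0 - 1.0 / (events_per_kmer + 1.0)
    p_skip = 1e-10
    return TransitionParams(
        lp_step=math.log(1.0 - p_stay - p_skip),
        lp_stay=math.log(p_stay),
        lp_skip=math.log(p_skip),
        lp_trim=math.log(0.01),
    )


def band_move(prev: BandState, band_index: int, W: int | None = None) -> Direction:
    """Suzuki-Kasahara band-movement rule.

    Compares the previous band's two end cells: if the upper-right end
    (offset W-1) scores strictly higher than the lower-left end (offset
    0), the band moves RIGHT, otherwise DOWN (ties included). When both
    ends lie outside the table (both -inf), the band alternates by the
    parity of ``band_index`` (RIGHT on odd), staying near the main
    diagonal.
    """
    W = prev.width if W is None else W
    ll = prev.scores[0]
    ur = prev.scores[W - 1]
    if ll == NEG_INF and ur == NEG_INF:
        return Direction.RIGHT if band_index % 2 == 1 else Direction.DOWN
    return Direction.RIGHT if ll < ur else Direction.DOWN


def _gather(scores: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    W = scores.size
    valid = (offsets >= 0) & (offsets < W)
    return np.where(valid, scores[np.clip(offsets, 0, W - 1)], NEG_INF)


def fill_band(
    curr: BandState,
    prev: BandState,
    prev2: BandState,
    events,
    kmer_ranks,
    model: KmerModel,
    scaling: ScalingParams,
    trans: TransitionParams,
    *,
    _event_means: np.ndarray | None = None,
    _mu_s: np.ndarray | None = None,
    _sig_s: np.ndarray | None = None,
    _drift: np.ndarray | None = None,
) -> BandState:
    """Compute all cells of one band from the two preceding bands.

    For each in-table cell ``(e, q)`` of ``curr`` the recurrence is::

        diag = S(e-1, q-1) + lp_step + lp_emission(e, q)   # band n-2
        up   = S(e-1, q)   + lp_stay + lp_emission(e, q)   # band n-1
        left = S(e,   q-1) + lp_skip                       # band n-1

    with ties broken DIAG > UP > LEFT and all-(-inf) candidates tagged
    ``Trace.NONE``. The band's trim cell ``(e, -1)``, when present, is
    seeded directly with ``(e + 1) * lp_trim`` (reachable by UP). The
    keyword arrays are precomputed caches used by :func:`abea_align`;
    they are derived from the positional arguments when omitted.

    Only bands ``n-1`` and ``n-2`` are read, so all cells of a band are
    independent and computed vectorised.
    """
    W = curr.width
    n_events = len(events)
    kmer_ranks = np.asarray(kmer_ranks, dtype=np.int64)
    n_kmers = kmer_ranks.size
    ll_e, ll_k = curr.lower_left

    if _event_means is None:
        _event_means = np.array([e.mean for e in events], dtype=np.float64)
    if _mu_s is None or _sig_s is None:
        _mu_s, _sig_s = scaled_levels(model, kmer_ranks, scaling)

    # virtual trim column cell (e, -1): trimming the first e+1 events
    trim_off = -1 - ll_k
    if 0 <= trim_off < W:
        e = ll_e - trim_off
        if 0 <= e < n_events:
            curr.scores[trim_off] = (e + 1) * trans.lp_trim
            curr.trace[trim_off] = int(Trace.UP)

    lo = max(0 - ll_k, ll_e - (n_events - 1), 0)
    hi = min(n_kmers - ll_k, ll_e + 1, W)
    if lo >= hi:
        return curr

    o = np.arange(lo, hi)
    e_idx = ll_e - o
    q_idx = ll_k + o

    pe, pk = prev.lower_left
    p2e, p2k = prev2.lower_left
    up = _gather(prev.scores, pe - (e_idx - 1))
    left = _gather(prev.scores, (q_idx - 1) - pk)
    diag = _gather(prev2.scores, (q_idx - 1) - p2k)

    mu = _mu_s[q_idx]
    if _drift is not None:
        mu = mu + _drift[e_idx]
    sd = _sig_s[q_idx]
    z = (_event_means[e_idx] - mu) / sd
    lp = -0.5 * LOG_2PI - np.log(sd) - 0.5 * z * z

    score_d = diag + trans.lp_step + lp
    score_u = up + trans.lp_stay + lp
    score_l = left + trans.lp_skip

    best = score_d
    tag = np.full(o.size, int(Trace.DIAG), dtype=np.uint8)
    m = score_u > best
    best = np.where(m, score_u, best)
    tag[m] = int(Trace.UP)
    m = score_l > best
    best = np.where(m, score_l, best)
    tag[m] = int(Trace.LEFT)
    tag[~np.isfinite(best)] = int(Trace.NONE)

    curr.scores[o] = best
    curr.trace[o] = tag
    return curr


@dataclass
class EventAlignment:
    """Result of aligning events to k-mers.

    ``pairs`` is the ordered list of visited ``(event_idx, kmer_idx)``
    cells; consecutive pairs differ by (+1,+1) step, (+1,0) stay or
    (0,+1) skip. ``moves`` records the trace tag by which each pair's
    cell was reached and ``emissions`` the per-pair emission log density
    (NaN for skip cells, which carry no event observation).
    """

    pairs: list[tuple[int, int]]
    score: float
    qc_pass: bool = False
    avg_log_emission: float = NEG_INF
    moves: list[int] = field(default_factory=list)
    emissions: list[float] = field(default_factory=list)
    n_kmers: int = 0

    def __len__(self) -> int:
        return len(self.pairs)


def qc_check(alignment: EventAlignment, trans: TransitionParams) -> tuple[bool, float]:
    """Accept or reject an alignment.

    The mean emission log density over event-carrying pairs (those
    reached by DIAG or UP) must reach ``trans.min_average_log_emission``,
    and the alignment must span the full k-mer range (first pair at k-mer
    0, last at the final k-mer).
    """
    ems = [
        em
        for em, mv in zip(alignment.emissions, alignment.moves)
        if mv in (int(Trace.DIAG), int(Trace.UP))
    ]
    avg = float(np.mean(ems)) if ems else NEG_INF
    ok = (
        bool(alignment.pairs)
        and avg >= trans.min_average_log_emission
        and alignment.pairs[0][1] == 0
        and alignment.pairs[-1][1] == alignment.n_kmers - 1
    )
    return ok, avg


def abea_align(
    events,
    sequence: str,
    model: KmerModel,
    scaling: ScalingParams,
    W: int = 100,
    trans: TransitionParams | None = None,
    event_times=None,
    return_bands: bool = False,
):
    """Banded event-to-k-mer alignment of one read.

    Seeds two bands around the virtual origin (-1, -1), then repeats
    {move per :func:`band_move`; fill per :func:`fill_band`} until the
    band chain has passed the bottom-right cell (``n_events + n_kmers +
    2`` bands in total, of which :func:`count_bands` cover the table
    proper). Trace-back starts at the event row maximising the score in
    the last k-mer column over all bands containing that column.

    Parameters
    ----------
    events : list of Event
        Segmented events of the read, in time order.
    sequence : str
        Read nucleotide sequence (length >= model.k).
    model, scaling :
        Pore model and per-read calibration.
    W : int
        Band width in cells; 100 is the standard width for nanopore
        signals.
    trans : TransitionParams, optional
        Move penalties; defaults derive from the event/k-mer ratio.
    event_times : sequence of float, optional
        Per-event start times in seconds, used only when
        ``scaling.drift`` is non-zero.
    return_bands : bool
        Also return the computed band chain (for inspection/testing).

    Returns
    -------
    EventAlignment, or (EventAlignment, list of BandState)
        When no finite-score cell exists in the last k-mer column the
        alignment has empty ``pairs`` and ``qc_pass=False``.
    """
    n_events = len(events)
    if n_events < 1:
        raise ValueError("need at least one event")
    if W < 2:
        raise ValueError(f"band width must be >= 2, got {W}")
    kmer_ranks = seq_to_kmer_ranks(sequence, model.k)
    n_kmers = int(kmer_ranks.size)
    if trans is None:
        trans = default_transitions(n_events, n_kmers)

    event_means = np.array([e.mean for e in events], dtype=np.float64)
    mu_s, sig_s = scaled_levels(model, kmer_ranks, scaling)
    drift = None
    if scaling.drift != 0.0 and event_times is not None:
        drift = scaling.drift * np.asarray(event_times, dtype=np.float64)

    half = W // 2
    n_bands = n_events + n_kmers + 2
    bands: list[BandState] = []

    # band 0: virtual origin (-1, -1) scores 0
    b0 = BandState.blank(W, (half - 1, -1 - half))
    b0.scores[half] = 0.0
    bands.append(b0)
    # band 1: trim cell (0, -1)
    b1 = BandState.blank(W, (half, -1 - half))
    b1.scores[half] = trans.lp_trim
    b1.trace[half] = int(Trace.UP)
    bands.append(b1)

    for i in range(2, n_bands):
        prev = bands[i - 1]
        direction = band_move(prev, i, W)
        pe, pk = prev.lower_left
        ll = (pe + 1, pk) if direction == Direction.DOWN else (pe, pk + 1)
        curr = BandState.blank(W, ll)
        fill_band(
            curr,
            prev,
            bands[i - 2],
            events,
            kmer_ranks,
            model,
            scaling,
            trans,
            _event_means=event_means,
            _mu_s=mu_s,
            _sig_s=sig_s,
            _drift=drift,
        )
        bands.append(curr)

    # trace-back start: best-scoring event row in the last k-mer column
    q_last = n_kmers - 1
    best_score = NEG_INF
    best_event = -1
    for e in range(n_events):
        band_idx = e + q_last + 2
        ll_e, _ = bands[band_idx].lower_left
        off = ll_e - e
        if 0 <= off < W:
            s = bands[band_idx].scores[off]
            if s > best_score:
                best_score = float(s)
                best_event = e

    alignment = EventAlignment(pairs=[], score=best_score, n_kmers=n_kmers)
    if best_event < 0:
        if return_bands:
            return alignment, bands
        return alignment

    pairs: list[tuple[int, int]] = []
    moves: list[int] = []
    e, q = best_event, q_last
    while e >= 0 and q >= 0:
        band_idx = e + q + 2
        ll_e, _ = bands[band_idx].lower_left
        tag = int(bands[band_idx].trace[ll_e - e])
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
    for (pe_, pq_), mv in zip(pairs, moves):
        if mv in (int(Trace.DIAG), int(Trace.UP)):
            mu = mu_s[pq_] if drift is None else mu_s[pq_] + drift[pe_]
            sd = sig_s[pq_]
            z = (event_means[pe_] - mu) / sd
            emissions.append(float(-0.5 * LOG_2PI - np.log(sd) - 0.5 * z * z))
        else:
            emissions.append(float("nan"))

    alignment.pairs = pairs
    alignment.moves = moves
    alignment.emissions = emissions
    alignment.qc_pass, alignment.avg_log_emission = qc_check(alignment, trans)
    if return_bands:
        return alignment, bands
    return alignment
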