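"""Segmentation of a raw nanopore current trace into events.

A nanopore read is a time series of ionic current (pA). While a k-mer
resides in the pore the current fluctuates around a characteristic level;
translocation to the next k-mer produces an abrupt level change. Event
detection finds these change points with a two-sample sliding t-statistic
and cuts the trace into *events*, each summarised by its start sample,
length, mean and standard deviation. Downstream alignment operates on
events, not on raw samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Event",
    "DetectorParams",
    "sliding_tstat",
    "detect_events",
    "events_from_boundaries",
]

# floor applied to window variances so a perfectly flat window does not
# produce a division by zero
_VAR_FLOOR = 1e-9


@dataclass(frozen=True)
class Event:
    """One segmented signal unit.

    Attributes
    ----------
    start : int
        Sample index of the first sample of the event (0-based).
    length : int
        Number of samples in the event (>= 1).
    mean : float
        Mean current of the segment, pA.
    stdv : float
        Population standard deviation of the segment, pA (>= 0).
    """

    start: int
    length: int
    mean: float
    stdv: float

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"event length must be >= 1, got {self.length}")
        if self.stdv < 0:
            raise ValueError(f"event stdv must be >= 0, got {self.stdv}")


@dataclass(frozen=True)
class DetectorParams:
    """Parameters of the two-window change-point detector.

    Two detectors run in parallel: a short-window one sensitive to brief
    events and a long-window one that is more robust to noise. A boundary
    is accepted when either detector's t-statistic forms a local maximum
    above its threshold.
    """

    window_short: int = 3
    window_long: int = 6
    threshold_short: float = 1.4
    threshold_long: float = 9.0
    peak_min_distance: int = 3

    def __post_init__(self) -> None:
        if self.window_short < 2 or self.window_long < 2:
            raise ValueError("detector windows must be >= 2 samples")
        if self.window_short >= self.window_long:
            raise ValueError("window_short must be < window_long")
        if self.threshold_short <= 0 or self.threshold_long <= 0:
            raise ValueError("detector thresholds must be > 0")
        if self.peak_min_distance < 1:
            raise ValueError("peak_min_distance must be >= 1")


def sliding_tstat(signal, w: int):
    """Two-sample Welch t-statistic at every boundary position.

    For each interior position ``i`` with ``w <= i <= len(signal) - w`` the
    statistic compares the ``w`` samples to the left of ``i`` against the
    ``w`` samples to its right::

        t(i) = |m_L - m_R| / sqrt(v_L / w + v_R / w)

    with window means ``m`` and population variances ``v`` (floored at
    1e-9). Positions outside the valid range are set to 0.

    Parameters
    ----------
    signal : sequence of float
        Raw current samples, pA.
    w : int
        Window size in samples (>= 2).

    Returns
    -------
    numpy.ndarray
        Array of length ``len(signal)`` with ``t(i)`` at index ``i``;
        empty when the signal is shorter than ``2 * w``.
    """
    if w < 2:
        raise ValueError(f"window must be >= 2, got {w}")
    x = np.asarray(signal, dtype=np.float64)
    n = x.size
    if n < 2 * w:
        return np.zeros(0, dtype=np.float64)

    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    i = np.arange(w, n - w + 1)

    s_l = c1[i] - c1[i - w]
    q_l = c2[i] - c2[i - w]
    s_r = c1[i + w] - c1[i]
    q_r = c2[i + w] - c2[i]

    m_l = s_l / w
    m_r = s_r / w
    v_l = np.maximum(q_l / w - m_l * m_l, _VAR_FLOOR)
    v_r = np.maximum(q_r / w - m_r * m_r, _VAR_FLOOR)

    out = np.zeros(n, dtype=np.float64)
    out[i] = np.abs(m_l - m_r) / np.sqrt(v_l / w + v_r / w)
    return out


def _emit_peaks(t, threshold: float) -> list[int]:
    # a detector "arms" when t rises above its threshold, tracks the running
    # maximum, and emits that maximum's position once t falls below threshold
    peaks: list[int] = []
    armed = False
    best = -np.inf
    best_pos = -1
    for pos, val in enumerate(t):
        if not armed:
            if val > threshold:
                armed = True
                best = val
                best_pos = pos
        else:
            if val > best:
                best = val
                best_pos = pos
            if val < threshold:
                peaks.append(best_pos)
                armed = False
    if armed:
        peaks.append(best_pos)
    return peaks


def detect_events(signal, params: DetectorParams | None = None) -> list[Event]:
    """Segment a raw current trace into events.

    Boundaries are positions where either detector's t-statistic peaks
    above its threshold; accepted boundaries at least
    ``params.peak_min_distance`` samples apart, together with the two trace
    ends, partition the signal. Degenerate input (too short, or no peak)
    yields a single event spanning the whole trace.

    Parameters
    ----------
    signal : sequence of float
        Raw current samples, pA; must be non-empty.
    params : DetectorParams, optional
        Detector configuration; defaults are tuned for DNA at ~10-20
        samples per event.

    Returns
    -------
    list of Event
        Ordered, disjoint events whose lengths sum to ``len(signal)``.
    """
    p = params if params is not None else DetectorParams()
    x = np.asarray(signal, dtype=np.float64)
    n = x.size
    if n == 0:
        raise ValueError("cannot detect events in an empty signal")

    t_short = sliding_tstat(x, p.window_short)
    t_long = sliding_tstat(x, p.window_long)
    candidates = sorted(
        set(_emit_peaks(t_short, p.threshold_short))
        | set(_emit_peaks(t_long, p.threshold_long))
    )

    accepted: list[int] = []
    for pos in candidates:
        if pos <= 0 or pos >= n:
            continue
        if not accepted or pos - accepted[-1] >= p.peak_min_distance:
            accepted.append(pos)

    boundaries = [0] + accepted + [n]
    return events_from_boundaries(x, boundaries)


def events_from_boundaries(signal, boundaries) -> list[Event]:
    """Cut a signal at the given boundary positions.

    Parameters
    ----------
    signal : sequence of float
        Raw current samples.
    boundaries : sequence of int
        Strictly increasing positions within ``[0, len(signal)]``; one
        event is produced per consecutive pair.

    Returns
    -------
    list of Event
        Segment events with sample mean and population stdv.
    """
    x = np.asarray(signal, dtype=np.float64)
    b = list(boundaries)
    if len(b) < 2:
        raise ValueError("need at least two boundaries")
    for lo, hi in zip(b, b[1:]):
        if hi <= lo:
            raise ValueError(f"boundaries not strictly increasing: {lo} >= {hi}")
    if b[0] < 0 or b[-1] > x.size:
        raise ValueError(f"boundaries outside [0, {x.size}]")

    events = []
    for lo, hi in zip(b, b[1:]):
        seg = x[lo:hi]
        events.append(
            Event(
                start=int(lo),
                length=int(hi - lo),
                mean=float(seg.mean()),
                stdv=float(seg.std()),
            )
        )
    return events
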