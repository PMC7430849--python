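"""k-mer encoding, pore-model lookup, read calibration and emission scoring.

The pore model assigns each k-mer a Gaussian current distribution
``N(mu_k, sigma_k)`` (pA). Observed event levels are distorted per read by
an affine transform; :func:`estimate_scalings` recovers a shift/scale pair
by moment matching so that an event mean ``x`` attributed to k-mer ``K``
is scored with the log density ``ln N(x; scale * mu_K + shift,
var * sigma_K)``. This emission score is the per-cell data term of the
alignment dynamic program.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "KmerModel",
    "ScalingParams",
    "kmer_rank",
    "rank_to_kmer",
    "seq_to_kmer_ranks",
    "estimate_scalings",
    "log_prob_emission",
]

LOG_2PI = math.log(2.0 * math.pi)

_BASES = "ACGT"
_CODES = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _CODES[ord(_b)] = _i


def kmer_rank(kmer: str) -> int:
    """Encode a k-mer as a base-4 integer (A=0, C=1, G=2, T=3, big-endian).

    The encoding is a bijection between k-mers and ``[0, 4**k)`` and is the
    index used for pore-model lookup.
    """
    rank = 0
    for ch in kmer:
        code = _CODES[ord(ch)] if ord(ch) < 256 else -1
        if code < 0:
            raise ValueError(f"invalid base {ch!r} in k-mer {kmer!r}")
        rank = rank * 4 + int(code)
    return rank


def rank_to_kmer(rank: int, k: int) -> str:
    """Inverse of :func:`kmer_rank` for a given k."""
    if not 0 <= rank < 4**k:
        raise ValueError(f"rank {rank} out of range for k={k}")
    out = []
    for _ in range(k):
        out.append(_BASES[rank % 4])
        rank //= 4
    return "".join(reversed(out))


def seq_to_kmer_ranks(sequence: str, k: int) -> np.ndarray:
    """Ranks of all overlapping k-mers of a sequence, left to right.

    A sequence of length L yields ``L - k + 1`` ranks.
    """
    if len(sequence) < k:
        raise ValueError(
            f"sequence of length {len(sequence)} is shorter than k={k}"
        )
    codes = _CODES[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        pos = int(np.argmax(codes < 0))
        raise ValueError(f"invalid base {sequence[pos]!r} at position {pos}")
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    return (windows @ powers).astype(np.int64)


class KmerModel:
    """Pore model: per-k-mer expected current level and spread.

    Parameters
    ----------
    k : int
        k-mer length (the R9.4.1 chemistry reads 5-6 bases at a time;
        6 is the supported default).
    level_mean, level_stdv : numpy.ndarray
        Arrays of length ``4**k`` indexed by k-mer rank, pA. Entries for
        k-mers absent from the source table are NaN; looking one up is an
        error.
    """

    def __init__(self, k: int, level_mean, level_stdv):
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        level_mean = np.asarray(level_mean, dtype=np.float64)
        level_stdv = np.asarray(level_stdv, dtype=np.float64)
        if level_mean.shape != (4**k,) or level_stdv.shape != (4**k,):
            raise ValueError(f"model arrays must have length 4**{k}")
        defined = ~np.isnan(level_stdv)
        if np.any(level_stdv[defined] <= 0):
            raise ValueError("level_stdv must be > 0 for every k-mer")
        self.k = int(k)
        self.level_mean = level_mean
        self.level_stdv = level_stdv

    @classmethod
    def from_table(cls, kmers, means, stdvs) -> "KmerModel":
        """Build a model from parallel lists of k-mers, means and stdvs."""
        kmers = list(kmers)
        if not kmers:
            raise ValueError("empty pore model")
        k = len(kmers[0])
        mean = np.full(4**k, np.nan)
        stdv = np.full(4**k, np.nan)
        seen = set()
        for kmer, m, s in zip(kmers, means, stdvs):
            if len(kmer) != k:
                raise ValueError(
                    f"mixed k-mer lengths: {kmer!r} has length {len(kmer)}, "
                    f"expected {k}"
                )
            if kmer in seen:
                raise ValueError(f"duplicate k-mer {kmer!r} in pore model")
            seen.add(kmer)
            if s <= 0:
                raise ValueError(f"non-positive stdv {s} for k-mer {kmer!r}")
            r = kmer_rank(kmer)
            mean[r] = m
            stdv[r] = s
        return cls(k, mean, stdv)

    def n_defined(self) -> int:
        return int(np.sum(~np.isnan(self.level_mean)))

    def mean(self, rank: int) -> float:
        v = self.level_mean[rank]
        if np.isnan(v):
            raise KeyError(f"k-mer rank {rank} not present in the model")
        return float(v)

    def stdv(self, rank: int) -> float:
        v = self.level_stdv[rank]
        if np.isnan(v):
            raise KeyError(f"k-mer rank {rank} not present in the model")
        return float(v)

    def __repr__(self) -> str:  # pragma: no cover
        return f"KmerModel(k={self.k}, n_kmers={self.n_defined()})"


@dataclass(frozen=True)
class ScalingParams:
    """Per-read affine calibration from model space to observed current.

    ``shift`` (pA) and dimensionless ``scale`` map a model level ``mu`` to
    the expected observed level ``scale * mu + shift``. ``drift`` (pA/s)
    is carried for completeness but defaults to 0 and is never estimated;
    ``var`` multiplies the model stdv.
    """

    shift: float = 0.0
    scale: float = 1.0
    drift: float = 0.0
    var: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if self.var <= 0:
            raise ValueError(f"var must be > 0, got {self.var}")


def estimate_scalings(events, kmer_ranks, model: KmerModel) -> ScalingParams:
    """Method-of-moments shift/scale calibration of a read.

    Matches the mean and standard deviation of the observed event levels
    to those of the model levels along the read's k-mers::

        scale = sd(event means) / sd(model levels)
        shift = mean(event means) - scale * mean(model levels)

    Exact on noiselessly affinely transformed data; on noisy data the
    scale carries a small positive bias of order ``sigma_noise^2 /
    var(model levels)``.
    """
    kmer_ranks = np.asarray(kmer_ranks, dtype=np.int64)
    if len(events) < 2 or kmer_ranks.size < 2:
        raise ValueError("need at least 2 events and 2 k-mers to calibrate")
    x = np.array([e.mean for e in events], dtype=np.float64)
    mu = model.level_mean[kmer_ranks]
    if np.isnan(mu).any():
        raise KeyError("read contains k-mers absent from the pore model")
    sd_mu = float(mu.std())
    if sd_mu < 1e-12:
        raise ValueError("degenerate pore model: zero variance in levels")
    scale = float(x.std()) / sd_mu
    shift = float(x.mean()) - scale * float(mu.mean())
    return ScalingParams(shift=shift, scale=scale)


def log_prob_emission(
    event_mean: float,
    rank: int,
    model: KmerModel,
    scaling: ScalingParams,
    event_time: float = 0.0,
) -> float:
    """Natural-log Gaussian density of an event level under a k-mer.

    With ``mu_s = scale * mu_k + shift + drift * event_time`` and
    ``sigma_s = var * sigma_k``::

        ln N(event_mean; mu_s, sigma_s)

    Maximal at ``event_mean == mu_s``; finite for all finite inputs.
    ``event_time`` (seconds since read start) only matters when
    ``scaling.drift`` is non-zero.
    """
    mu = scaling.scale * model.mean(rank) + scaling.shift
    if scaling.drift != 0.0:
        mu += scaling.drift * event_time
    sd = scaling.var * model.stdv(rank)
    z = (event_mean - mu) / sd
    return -0.5 * LOG_2PI - math.log(sd) - 0.5 * z * z


def scaled_levels(model: KmerModel, kmer_ranks, scaling: ScalingParams):
    """Vectorised ``(mu_s, sigma_s)`` along a rank sequence.

    Internal helper shared by the aligner and the eventalign writer.
    """
    kmer_ranks = np.asarray(kmer_ranks, dtype=np.int64)
    mu = model.level_mean[kmer_ranks]
    sd = model.level_stdv[kmer_ranks]
    if np.isnan(mu).any():
        raise KeyError("read contains k-mers absent from the pore model")
    return scaling.scale * mu + scaling.shift, scaling.var * sd
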