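"""Readers and writers for the plain-text formats of the tool.

Formats handled: FASTA read sequences; tab-separated pore-model tables
(kmer / level_mean / level_stdv); event tables (start / length / mean /
stdv); one-column (or index + value) raw-signal listings; and the
eventalign-style per-pair alignment TSV. All coordinates are 0-based
with half-open intervals; floats are written with 6 significant digits.
Readers reject malformed input outright and name the offending line —
silent repair of data files is worse than failure.

Binary signal containers (FAST5/HDF5, SLOW5) are deliberately out of
scope: raw signal enters as plain text.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .abea import EventAlignment
from .event_detection import Event
from .scoring import KmerModel, ScalingParams, rank_to_kmer, seq_to_kmer_ranks

__all__ = [
    "ReadRecord",
    "FormatError",
    "read_fasta",
    "read_pore_model",
    "read_signal_tsv",
    "read_events_tsv",
    "write_events_tsv",
    "write_eventalign_tsv",
    "read_eventalign_tsv",
]

DEFAULT_SAMPLE_RATE = 4000.0

EVENTALIGN_COLUMNS = [
    "read_id",
    "kmer_idx",
    "kmer",
    "event_idx",
    "event_mean",
    "scaled_model_mean",
    "log_emission",
]


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class ReadRecord:
    """One read: id, sequence, and optionally its events or raw signal."""

    read_id: str
    sequence: str = ""
    events: list[Event] | None = None
    raw: "object | None" = None
    sample_rate: float | None = None


def _fmt(x: float) -> str:
    return format(float(x), ".6g")


def read_fasta(path) -> list[ReadRecord]:
    """Read all entries of a FASTA file (sequences only).

    Sequences are upper-cased and U is mapped to T. Raises
    :class:`FormatError` naming the line for data before the first
    header, empty headers, or entries with no sequence.
    """
    records: list[ReadRecord] = []
    header: str | None = None
    header_line = 0
    seq_parts: list[str] = []

    def flush():
        if header is None:
            return
        seq = "".join(seq_parts)
        if not seq:
            raise FormatError(f"{path}: entry {header!r} at line {header_line} has an empty sequence")
        records.append(ReadRecord(read_id=header, sequence=seq))

    with open(path) as fh:
        for lineno, raw_line in enumerate(fh, start=1):
            line = raw_line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                header_line = lineno
                seq_parts = []
            elif line.startswith(";"):
                continue
            else:
                if header is None:
                    raise FormatError(f"{path}: sequence data before any header at line {lineno}")
                seq_parts.append(line.upper().replace("U", "T"))
    flush()
    return records


def read_pore_model(path) -> KmerModel:
    """Read a tab-separated pore-model table.

    A header line naming at least ``kmer``, ``level_mean`` and
    ``level_stdv`` is permitted (extra columns ignored); without one the
    first three columns are taken in that order. k is inferred from the
    first k-mer; duplicates, mixed lengths and non-positive stdvs are
    errors.
    """
    kmers: list[str] = []
    means: list[float] = []
    stdvs: list[float] = []
    col_idx = (0, 1, 2)
    saw_header = False
    with open(path) as fh:
        for lineno, raw_line in enumerate(fh, start=1):
            line = raw_line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if not saw_header and not kmers:
                lowered = [f.strip().lower() for f in fields]
                if "kmer" in lowered:
                    try:
                        col_idx = (
                            lowered.index("kmer"),
                            lowered.index("level_mean"),
                            lowered.index("level_stdv"),
                        )
                    except ValueError as exc:
                        raise FormatError(
                            f"{path}: header at line {lineno} lacks "
                            "kmer/level_mean/level_stdv columns"
                        ) from exc
                    saw_header = True
                    continue
            if len(fields) <= max(col_idx):
                raise FormatError(f"{path}: too few columns at line {lineno}")
            try:
                kmers.append(fields[col_idx[0]].strip().upper())
                means.append(float(fields[col_idx[1]]))
                stdvs.append(float(fields[col_idx[2]]))
            except ValueError as exc:
                raise FormatError(f"{path}: unparseable number at line {lineno}") from exc
    if not kmers:
        raise FormatError(f"{path}: no pore-model rows found")
    try:
        return KmerModel.from_table(kmers, means, stdvs)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_signal_tsv(path) -> ReadRecord:
    """Read a raw current trace from plain text.

    One sample per line (pA), or two whitespace-separated columns
    ``sample_index  pA`` in which case the last column is used. An
    optional ``#sample_rate=<Hz>`` header is honoured (default 4000 Hz).
    Non-numeric lines raise :class:`FormatError` naming the line.
    """
    samples: list[float] = []
    sample_rate = DEFAULT_SAMPLE_RATE
    with open(path) as fh:
        for lineno, raw_line in enumerate(fh, start=1):
            line = raw_line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.lower().startswith("sample_rate="):
                    try:
                        sample_rate = float(body.split("=", 1)[1])
                    except ValueError as exc:
                        raise FormatError(
                            f"{path}: bad sample_rate header at line {lineno}"
                        ) from exc
                continue
            fields = line.split()
            if len(fields) > 2:
                raise FormatError(f"{path}: expected 1-2 columns at line {lineno}")
            try:
                samples.append(float(fields[-1]))
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric value at line {lineno}") from exc
    import numpy as np

    return ReadRecord(
        read_id="", raw=np.asarray(samples, dtype=float), sample_rate=sample_rate
    )


def read_events_tsv(path) -> list[Event]:
    """Read an event table (columns start, length, mean, stdv)."""
    try:
        df = pd.read_csv(path, sep="\t", comment=None)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse events TSV: {exc}") from exc
    for col in ("start", "length", "mean", "stdv"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing events column {col!r}")
    return [
        Event(start=int(r.start), length=int(r.length), mean=float(r.mean), stdv=float(r.stdv))
        for r in df.itertuples(index=False)
    ]


def write_events_tsv(events, path) -> None:
    """Write an event table (columns start, length, mean, stdv)."""
    with open(path, "w") as fh:
        fh.write("start\tlength\tmean\tstdv\n")
        for ev in events:
            fh.write(f"{ev.start}\t{ev.length}\t{_fmt(ev.mean)}\t{_fmt(ev.stdv)}\n")


def write_eventalign_tsv(
    alignment: EventAlignment,
    read: ReadRecord,
    model: KmerModel,
    scaling: ScalingParams,
    path,
) -> None:
    """Write one aligned (event, k-mer) pair per row, in alignment order.

    Columns: read_id, kmer_idx, kmer, event_idx, event_mean,
    scaled_model_mean, log_emission. The emission column holds the
    Gaussian log density of the event level under the scaled k-mer
    model (blank for skip pairs, which carry no event observation).
    """
    if read.events is None:
        raise ValueError("read record has no events")
    ranks = seq_to_kmer_ranks(read.sequence, model.k)
    n_events = len(read.events)
    n_kmers = int(ranks.size)
    with open(path, "w") as fh:
        fh.write("\t".join(EVENTALIGN_COLUMNS) + "\n")
        for i, (e, q) in enumerate(alignment.pairs):
            if not (0 <= e < n_events and 0 <= q < n_kmers):
                raise ValueError(
                    f"alignment pair ({e}, {q}) out of range for "
                    f"{n_events} events x {n_kmers} k-mers"
                )
            rank = int(ranks[q])
            mu_s = scaling.scale * model.mean(rank) + scaling.shift
            em = alignment.emissions[i] if i < len(alignment.emissions) else float("nan")
            em_txt = _fmt(em) if em == em else ""
            fh.write(
                f"{read.read_id}\t{q}\t{rank_to_kmer(rank, model.k)}\t{e}\t"
                f"{_fmt(read.events[e].mean)}\t{_fmt(mu_s)}\t{em_txt}\n"
            )


def read_eventalign_tsv(path) -> pd.DataFrame:
    """Parse an eventalign TSV back into a DataFrame (round-trip check)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENTALIGN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing eventalign columns {missing}")
    return df
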