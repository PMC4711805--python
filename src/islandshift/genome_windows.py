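"""FASTA input and fixed-length genome windows with nucleotide-count features.

A bacterial genome is partitioned into consecutive, non-overlapping windows
of a nominal length ``j``.  Each window is summarised by the counts of the
four nucleotides (A, T, C, G), giving the 4-dimensional feature vector that
the mean-shift clustering operates on.  Ambiguity codes are masked to N and
contribute to no count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

#: Component order of every 4-vector in the package.
NUCLEOTIDES = "ATCG"
_NUC_CODES = np.frombuffer(b"ATCG", dtype=np.uint8)

# uppercase + mask everything outside {A,C,G,T} to N
_NORMALIZE = bytes(
    b if b in b"ACGT" else ord("N")
    for b in (bytes([c]).upper()[0] for c in range(256))
)


class FastaFormatError(ValueError):
    """Raised for an empty or malformed FASTA record."""


class GenomeTooShortError(ValueError):
    """Raised when the genome is shorter than a single window."""


@dataclass(frozen=True)
class GenomeSequence:
    """A single genome record, upper-cased, alphabet {A,C,G,T,N}."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Window:
    """One genome slice [start, end) with its (A,T,C,G) count vector."""

    index: int
    start: int
    end: int
    counts: np.ndarray
    is_partial: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class WindowStats:
    """Per-nucleotide mean and population standard deviation of window sums."""

    mean: np.ndarray
    sd: np.ndarray
    n_windows: int


def normalize_sequence(seq: str) -> str:
    """Uppercase and map any character outside {A,C,G,T} to N."""
    return seq.encode("ascii", errors="replace").translate(_NORMALIZE).decode("ascii")


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read the first record of a FASTA file as a :class:`GenomeSequence`.

    Multi-record files emit a warning and only the first record is used
    (the method analyses one replicon at a time).

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    FastaFormatError
        If the file holds no record or the first record is empty.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaFormatError(f"no FASTA record found in {path}")
    if len(records) > 1:
        warnings.warn(
            f"{path} contains {len(records)} records; only the first "
            f"({records[0].id}) is analysed",
            stacklevel=2,
        )
    rec = records[0]
    seq = normalize_sequence(str(rec.seq))
    if not seq:
        raise FastaFormatError(f"record {rec.id!r} in {path} is empty")
    return GenomeSequence(id=rec.id, sequence=seq)


def count_nucleotides(seq: str) -> np.ndarray:
    """Counts of A, T, C, G (in that order) in *seq*; N counts nowhere."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return np.array([int(np.count_nonzero(arr == c)) for c in _NUC_CODES],
                    dtype=np.int64)


def partition_windows(genome: GenomeSequence, j: int) -> list[Window]:
    """Tile the genome with non-overlapping windows of nominal length *j*.

    Windows start at position 0; window ``k`` spans ``[k*j, min((k+1)*j, L))``.
    A trailing window shorter than *j* is retained and flagged ``is_partial``
    so that the genome end participates in clustering.
    """
    if j < 1:
        raise ValueError(f"window length must be positive, got {j}")
    L = genome.length
    if L < j:
        raise GenomeTooShortError(
            f"genome length {L} is shorter than one window of {j} bp"
        )
    arr = np.frombuffer(genome.sequence.encode("ascii"), dtype=np.uint8)
    # cumulative counts give O(1) per-window sums
    cums = [np.concatenate(([0], np.cumsum(arr == c, dtype=np.int64)))
            for c in _NUC_CODES]
    starts = np.arange(0, L, j)
    windows = []
    for i, s in enumerate(starts):
        e = min(int(s) + j, L)
        counts = np.array([c[e] - c[s] for c in cums], dtype=np.int64)
        windows.append(
            Window(index=i, start=int(s), end=e, counts=counts,
                   is_partial=(e - s < j))
        )
    return windows


def window_stats(windows: list[Window]) -> WindowStats:
    """Component-wise mean and population SD of count vectors.

    Partial trailing windows are excluded: their sums are not comparable to
    full-window sums.  At least two full windows are required.
    """
    full = [w for w in windows if not w.is_partial]
    if len(full) < 2:
        raise ValueError(
            f"need at least 2 full windows for statistics, got {len(full)}"
        )
    mat = np.array([w.counts for w in full], dtype=float)
    return WindowStats(
        mean=mat.mean(axis=0),
        sd=mat.std(axis=0),  # population SD (ddof=0)
        n_windows=len(full),
    )


def windows_to_tsv(windows: list[Window]) -> str:
    """Tab-separated window table: index, start, end, A, T, C, G."""
    lines = ["index\tstart\tend\tA\tT\tC\tG"]
    for w in windows:
        a, t, c, g = (int(x) for x in w.counts)
        lines.append(f"{w.index}\t{w.start}\t{w.end}\t{a}\t{t}\t{c}\t{g}")
    return "\n".join(lines) + "\n"
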