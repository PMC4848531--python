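"""Sequence I/O and core sequence types.

FASTQ is 4-line phred+33 (optionally gzip-compressed); the reference is a
single-record FASTA of a small circular sequence.  Internally coordinates are
0-based half-open; reports use 1-based inclusive positions.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._kernels import COMPLEMENT

VALID_READ_CHARS = frozenset("ACGTN")
VALID_REF_CHARS = frozenset("ACGTN")
PHRED_OFFSET = 33
MAX_PHRED = 93


def encode(bases: str) -> np.ndarray:
    """Base string -> uint8 ASCII array."""
    return np.frombuffer(bases.encode("ascii"), dtype=np.uint8).copy()


def decode(arr: np.ndarray) -> str:
    """uint8 ASCII array -> base string."""
    return arr.tobytes().decode("ascii")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (N -> N)."""
    bad = set(seq) - VALID_READ_CHARS
    if bad:
        raise ValueError(f"invalid base(s) {sorted(bad)} in sequence")
    return decode(reverse_complement_arr(encode(seq)))


def reverse_complement_arr(arr: np.ndarray) -> np.ndarray:
    return COMPLEMENT[arr[::-1]]


@dataclass
class FastqRecord:
    """One sequencing read: identifier, bases over {A,C,G,T,N}, phred qualities."""

    read_id: str
    bases: str
    quals: np.ndarray

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int64)
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"record {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} qualities"
            )
        bad = set(self.bases) - VALID_READ_CHARS
        if bad:
            raise ValueError(f"record {self.read_id!r}: invalid base(s) {sorted(bad)}")
        if len(self.quals) and (self.quals.min() < 0 or self.quals.max() > MAX_PHRED):
            raise ValueError(
                f"record {self.read_id!r}: quality outside [0, {MAX_PHRED}]"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class ReferenceSeq:
    """A single (usually circular) reference sequence.

    N bases are tolerated with a warning; their positions are recorded as
    unanalyzable and never count toward match/mismatch denominators.
    """

    name: str
    bases: str
    circular: bool = True
    n_positions: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        bad = set(self.bases) - VALID_REF_CHARS
        if bad:
            raise ValueError(f"reference {self.name!r}: invalid base(s) {sorted(bad)}")
        self.n_positions = frozenset(
            i for i, b in enumerate(self.bases) if b == "N"
        )

    @property
    def length(self) -> int:
        return len(self.bases)

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def array(self) -> np.ndarray:
        arr = getattr(self, "_array", None)
        if arr is None:
            arr = encode(self.bases)
            object.__setattr__(self, "_array", arr)
        return arr


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _fastq_records(path: str | Path) -> Iterator[FastqRecord]:
    with _open_text(path) as handle:
        it = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                item = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"{path}: malformed record {index}: {exc}") from exc
            title, seq, qual = item
            quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(
                np.int64
            ) - PHRED_OFFSET
            try:
                yield FastqRecord(title.split()[0] if title else "", seq.upper(), quals)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed record {index}: {exc}") from exc
            index += 1


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    """Stream records from a single FASTQ file (phred+33, optionally gzip)."""
    return _fastq_records(path)


def read_fastq_pairs(
    path1: str | Path, path2: str | Path
) -> Iterator[tuple[FastqRecord, FastqRecord]]:
    """Stream synchronized read pairs from two FASTQ files.

    Raises ValueError naming the shorter file if the record counts differ,
    or naming the file and record index on a malformed record.
    """
    it1 = _fastq_records(path1)
    it2 = _fastq_records(path2)
    sentinel = object()
    while True:
        r1 = next(it1, sentinel)
        r2 = next(it2, sentinel)
        if r1 is sentinel and r2 is sentinel:
            return
        if r1 is sentinel:
            raise ValueError(f"{path1} has fewer records than {path2}")
        if r2 is sentinel:
            raise ValueError(f"{path2} has fewer records than {path1}")
        yield r1, r2


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> None:
    """Write records as 4-line phred+33 FASTQ (gzip if the path ends in .gz)."""
    with _open_text(path, "wt") as out:
        for rec in records:
            qual = "".join(chr(int(q) + PHRED_OFFSET) for q in rec.quals)
            out.write(f"@{rec.read_id}\n{rec.bases}\n+\n{qual}\n")


def read_reference(path: str | Path, circular: bool = True) -> ReferenceSeq:
    """Load a single-record FASTA reference.

    Rejects multi-record FASTA, empty files and non-ACGTN characters; warns if
    the sequence contains N.
    """
    with _open_text(path) as handle:
        records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA record found")
    if len(records) > 1:
        raise ValueError(
            f"{path}: {len(records)} records found; one reference per run"
        )
    rec = records[0]
    bases = str(rec.seq).upper()
    if not bases:
        raise ValueError(f"{path}: empty reference sequence")
    bad = set(bases) - VALID_REF_CHARS
    if bad:
        raise ValueError(f"{path}: invalid character(s) {sorted(bad)} in reference")
    ref = ReferenceSeq(name=rec.id, bases=bases, circular=circular)
    if ref.n_positions:
        warnings.warn(
            f"{path}: reference contains {len(ref.n_positions)} N base(s); "
            "those positions are unanalyzable",
            stacklevel=2,
        )
    return ref


def write_reference(ref: ReferenceSeq, path: str | Path) -> None:
    with _open_text(path, "wt") as out:
        out.write(f">{ref.name}\n")
        for i in range(0, len(ref.bases), 70):
            out.write(ref.bases[i : i + 70] + "\n")
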