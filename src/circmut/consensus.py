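"""Tandem-repeat consensus building from paired-end reads.

A rolling-circle library turns each circularized single-strand fragment into
a read pair that contains the fragment's sequence several times in tandem.
This module merges a pair into one long read, detects the smallest tandem
period by self-alignment, and collapses the tandem copies into one consensus
read whose base qualities are the capped sums of the contributing copies.
Positions seen fewer than twice, or with disagreeing copies, are masked with
quality 0 so that downstream filters drop them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._kernels import N
from .seqio import FastqRecord, decode, encode, reverse_complement_arr

DEFAULT_MIN_OVERLAP = 10
DEFAULT_MAX_MISMATCH_RATE = 0.05
DEFAULT_MIN_PERIOD = 30
DEFAULT_MIN_EVIDENCE = 20
MAX_PHRED = 93


@dataclass
class MergedRead:
    """Read1 and reverse-complemented Read2 merged on their longest overlap."""

    bases: str
    quals: np.ndarray
    overlap_len: int
    source_pair_id: str

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError("merged bases and qualities differ in length")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class ConsensusRead:
    """Error-corrected smallest tandem unit of a merged read pair."""

    bases: str
    quals: np.ndarray
    copy_count: np.ndarray
    period: int
    source_pair_id: str

    def __post_init__(self) -> None:
        if not (
            len(self.bases) == self.period == len(self.quals) == len(self.copy_count)
        ):
            raise ValueError("consensus fields must all have length == period")
        if len(self.quals) and (self.quals.min() < 0 or self.quals.max() > MAX_PHRED):
            raise ValueError(f"consensus quality outside [0, {MAX_PHRED}]")
        if np.any(self.quals[self.copy_count < 2] != 0):
            raise ValueError("positions passed by fewer than two copies must be masked")

    def __len__(self) -> int:
        return self.period


def _prepare_pair_arrays(
    r1: FastqRecord, r2: FastqRecord
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Encode a pair as (read1, q1, rc(read2), q2 reversed); N bases get quality 0."""
    a = encode(r1.bases)
    qa = np.asarray(r1.quals, dtype=np.int64).copy()
    b = reverse_complement_arr(encode(r2.bases))
    qb = np.asarray(r2.quals, dtype=np.int64)[::-1].copy()
    qa[a == N] = 0
    qb[b == N] = 0
    return a, qa, b, qb


def _merge_arrays(
    a: np.ndarray,
    qa: np.ndarray,
    b: np.ndarray,
    qb: np.ndarray,
    min_overlap: int,
    max_mismatch_rate: float,
) -> tuple[np.ndarray, np.ndarray, int] | None:
    o = _kernels.best_overlap(a, b, min_overlap, max_mismatch_rate)
    if o == 0:
        return None
    bases, quals = _kernels.merge_kernel(a, qa, b, qb, o)
    return bases, quals, o


def merge_pair(
    r1: FastqRecord,
    r2: FastqRecord,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
) -> MergedRead | None:
    """Merge read1 with the reverse complement of read2 on their longest overlap.

    Among all suffix(read1)/prefix(rc(read2)) overlaps of length >= min_overlap
    whose mismatch fraction is <= max_mismatch_rate, the longest is chosen.  At
    overlapped positions the base of the higher-quality source wins (ties go to
    read1); agreeing positions get quality min(q1+q2, 93), disagreeing positions
    keep the chosen base's quality.  Returns None ("no-overlap") if no overlap
    qualifies.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not 0 <= max_mismatch_rate <= 1:
        raise ValueError("max_mismatch_rate must be in [0, 1]")
    a, qa, b, qb = _prepare_pair_arrays(r1, r2)
    merged = _merge_arrays(a, qa, b, qb, min_overlap, max_mismatch_rate)
    if merged is None:
        return None
    bases, quals, o = merged
    return MergedRead(decode(bases), quals, o, r1.read_id)


def find_tandem_period(
    m: MergedRead | str,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
    min_evidence: int = DEFAULT_MIN_EVIDENCE,
    min_period: int = DEFAULT_MIN_PERIOD,
) -> int | None:
    """Smallest tandem period of the merged read, by aligning it to itself.

    Returns the smallest p in [min_period, len(m) - min_evidence] such that
    m[0:len-p] vs m[p:len] has mismatch fraction <= max_mismatch_rate (N
    excluded from numerator and denominator), or None if no period qualifies
    or the read is too short.
    """
    if min_evidence < 1:
        raise ValueError("min_evidence must be >= 1")
    bases = m.bases if isinstance(m, MergedRead) else m
    arr = encode(bases)
    if len(arr) < min_period + min_evidence:
        return None
    p = _kernels.period_scan(arr, min_period, min_evidence, max_mismatch_rate)
    return p or None


def build_consensus(m: MergedRead, period: int) -> ConsensusRead:
    """Collapse the tandem copies of a merged read onto one consensus unit.

    Consensus position i collects m[i], m[i+period], ... (N excluded);
    the consensus base is the majority base (ties: larger quality sum, then
    alphabetical); quality is min(sum of collected qualities, 93) when all
    collected bases agree and the position was passed at least twice, else 0.
    """
    if period <= 0 or period >= len(m):
        raise ValueError(f"period {period} outside (0, {len(m)})")
    arr = encode(m.bases)
    quals = np.asarray(m.quals, dtype=np.int64)
    bases, cquals, copies = _kernels.consensus_scan(arr, quals, period)
    return ConsensusRead(decode(bases), cquals, copies, period, m.source_pair_id)


def pair_to_consensus(
    r1: FastqRecord,
    r2: FastqRecord,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
    min_period: int = DEFAULT_MIN_PERIOD,
    min_evidence: int = DEFAULT_MIN_EVIDENCE,
    period_max_mismatch_rate: float | None = None,
) -> ConsensusRead | None:
    """Merge a pair, detect its tandem period and build the consensus read.

    Returns None if the pair does not merge or no tandem period is found;
    such pairs count only toward the circularization-rate denominator.
    ``period_max_mismatch_rate`` defaults to the merge rate.
    """
    a, qa, b, qb = _prepare_pair_arrays(r1, r2)
    return consensus_from_arrays(
        a,
        qa,
        b,
        qb,
        min_overlap=min_overlap,
        max_mismatch_rate=max_mismatch_rate,
        min_period=min_period,
        min_evidence=min_evidence,
        period_max_mismatch_rate=period_max_mismatch_rate,
        source_pair_id=r1.read_id,
    )


def consensus_from_arrays(
    a: np.ndarray,
    qa: np.ndarray,
    b: np.ndarray,
    qb: np.ndarray,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
    min_period: int = DEFAULT_MIN_PERIOD,
    min_evidence: int = DEFAULT_MIN_EVIDENCE,
    period_max_mismatch_rate: float | None = None,
    source_pair_id: str = "",
) -> ConsensusRead | None:
    """Array-level merge + period detection + consensus (b already reverse-complemented)."""
    if period_max_mismatch_rate is None:
        period_max_mismatch_rate = max_mismatch_rate
    merged = _merge_arrays(a, qa, b, qb, min_overlap, max_mismatch_rate)
    if merged is None:
        return None
    bases, quals, _o = merged
    if len(bases) < min_period + min_evidence:
        return None
    period = _kernels.period_scan(bases, min_period, min_evidence, period_max_mismatch_rate)
    if period == 0:
        return None
    cb, cq, copies = _kernels.consensus_scan(bases, quals, period)
    cs = ConsensusRead(decode(cb), cq, copies, period, source_pair_id)
    cs._array = cb  # cached encoding for the mapper
    return cs


def circularization_rate(n_consensus: int, n_pairs: int) -> float:
    """Fraction of raw read pairs that yielded a consensus read (CR)."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if n_consensus > n_pairs:
        raise ValueError("n_consensus cannot exceed n_pairs")
    return n_consensus / n_pairs


def consensus_to_fastq_record(cs: ConsensusRead) -> FastqRecord:
    """Consensus read as a FASTQ record (qualities already capped at 93)."""
    return FastqRecord(cs.source_pair_id, cs.bases, cs.quals)
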