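"""Placement of consensus reads on a small circular reference.

A consensus read starts at an arbitrary junction of its circularized source
fragment, so some rotation of it is a contiguous (possibly origin-spanning)
substring of the circular reference.  Rotations are enumerated at a
configurable stride (default 5, i.e. one fifth of the mapping work) and each
is placed by an exact ungapped scan of both strands.  The scan is
seed-accelerated: any placement with at most ``max_mismatch`` mismatches
must contain an exact k-mer seed (pigeonhole), so candidate positions come
from a k-mer index of the reference and only candidates are verified.  Short
or N-containing reads fall back to the exhaustive scan.

With stride > 1 the sampled rotation can mis-phase the junction by up to
stride-1 bases; mismatching bases within stride-1 of either read end are
treated as junction placement artifacts: they do not count against the
mismatch budget and are masked out of the pileup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import _kernels
from ._kernels import N, TWOBIT
from .consensus import ConsensusRead
from .seqio import ReferenceSeq, decode, encode, reverse_complement_arr

DEFAULT_STRIDE = 5
DEFAULT_MAX_MISMATCH = 3
DEFAULT_SEED_K = 8


@dataclass
class AlignmentHit:
    """Ungapped placement of a consensus read on the circular reference.

    ``fwd_bases``/``fwd_quals`` give the read oriented along the reference
    forward strand (reverse-complemented for '-' hits), which is what the
    pileup consumes.  ``masked_fwd_positions`` are read positions (forward
    orientation) whose mismatches were attributed to junction mis-phasing;
    they are excluded from ``mismatches`` and from the pileup.
    """

    ref_pos: int
    strand: str
    rotation_offset: int
    n_mismatch: int
    mismatches: list
    aligned_len: int
    fwd_bases: np.ndarray
    fwd_quals: np.ndarray
    masked_fwd_positions: np.ndarray
    source_pair_id: str = ""

    def __post_init__(self) -> None:
        if self.n_mismatch != len(self.mismatches):
            raise ValueError("n_mismatch must equal len(mismatches)")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")


class ReferenceIndex:
    """k-mer index over the doubled (wrap-around) reference, both coordinates circular."""

    def __init__(self, ref: ReferenceSeq, k: int = DEFAULT_SEED_K):
        if len(ref) < k:
            raise ValueError("reference shorter than the seed length")
        self.ref = ref
        self.k = k
        self.L = len(ref)
        arr = ref.array
        self.doubled = np.concatenate([arr, arr])
        self.has_n = bool(ref.n_positions)
        self._weights = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
        ids, valid = self.window_codes(self.doubled)
        pos = np.arange(ids.shape[0])
        sel = (pos < self.L) & valid
        ids, pos = ids[sel], pos[sel]
        order = np.argsort(ids, kind="stable")
        self.sorted_ids = ids[order]
        self.sorted_pos = pos[order]

    def window_codes(self, arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(kmer id, validity) for every window start of an ASCII base array."""
        codes = TWOBIT[arr].astype(np.int64)
        win = sliding_window_view(codes, self.k)
        ids = win @ self._weights
        valid = (win != 255).all(axis=1)
        return ids, valid


def as_index(ref: ReferenceSeq | ReferenceIndex, k: int = DEFAULT_SEED_K) -> ReferenceIndex:
    if isinstance(ref, ReferenceIndex):
        return ref
    return ReferenceIndex(ref, k)


def enumerate_rotations(
    cs: ConsensusRead, stride: int = DEFAULT_STRIDE
) -> list[tuple[str, np.ndarray, np.ndarray, int]]:
    """Rotations of a consensus read at offsets 0, stride, 2*stride, ... < period.

    Qualities and copy counts rotate with the bases.  Returns a list of
    (bases, quals, copy_count, offset) tuples.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    out = []
    arr = encode(cs.bases)
    quals = np.asarray(cs.quals)
    copies = np.asarray(cs.copy_count)
    for off in range(0, cs.period, stride):
        out.append(
            (
                decode(np.concatenate([arr[off:], arr[:off]])),
                np.concatenate([quals[off:], quals[:off]]),
                np.concatenate([copies[off:], copies[:off]]),
                off,
            )
        )
    return out


def _seed_offsets(lq: int, k: int) -> list[int]:
    return list(range(0, lq - k + 1, k))


def _seeds_usable(qarr: np.ndarray, index: ReferenceIndex, budget: int, zone: int) -> bool:
    """True when the pigeonhole guarantee holds: at least budget+1 seeds lie
    strictly inside the un-zoned middle of the read and neither the read nor
    the reference contains N (N breaks a seed without consuming mismatch
    budget)."""
    if index.has_n or bool((qarr == N).any()):
        return False
    k = index.k
    middle = [
        u for u in _seed_offsets(len(qarr), k) if u >= zone and u + k <= len(qarr) - zone
    ]
    return len(middle) >= budget + 1


def _candidate_positions(qarr: np.ndarray, index: ReferenceIndex) -> set[int]:
    """Circular start positions sharing at least one exact seed with the read."""
    k = index.k
    ids, valid = index.window_codes(qarr)
    cands: set[int] = set()
    for u in _seed_offsets(len(qarr), k):
        if not valid[u]:
            continue
        lo = np.searchsorted(index.sorted_ids, ids[u], side="left")
        hi = np.searchsorted(index.sorted_ids, ids[u], side="right")
        for idx in range(lo, hi):
            cands.add((int(index.sorted_pos[idx]) - u) % index.L)
    return cands


def _placements(
    qarr: np.ndarray, index: ReferenceIndex, raw_limit: int, budget: int, zone: int
) -> dict[int, int]:
    """All circular placements with raw mismatch count <= raw_limit.

    Complete for every placement carrying at most ``budget`` mismatches
    outside the end zones; falls back to the exhaustive scan when the seed
    guarantee does not hold.
    """
    L = index.L
    if _seeds_usable(qarr, index, budget, zone):
        out = {}
        for t in _candidate_positions(qarr, index):
            c = int(_kernels.count_mismatches(qarr, index.doubled, t, raw_limit))
            if c <= raw_limit:
                out[t] = c
        return out
    counts = _kernels.brute_scan(qarr, index.doubled, L, raw_limit)
    ts = np.nonzero(counts <= raw_limit)[0]
    return {int(t): int(counts[t]) for t in ts}


def _mismatch_mask(qarr: np.ndarray, index: ReferenceIndex, t: int) -> np.ndarray:
    refseg = index.doubled[t : t + len(qarr)]
    return (qarr != refseg) & (qarr != N) & (refseg != N)


def align_one(
    seq: str | np.ndarray,
    ref: ReferenceSeq | ReferenceIndex,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    quals: np.ndarray | None = None,
) -> AlignmentHit | None:
    """Best ungapped placement of ``seq`` on both strands of the circular reference.

    Returns the hit with the fewest mismatches if that count is <= max_mismatch
    and the minimum is achieved at a single (position, strand) placement; None
    otherwise (no qualifying placement, or an ambiguous tie).  N in the read or
    reference never counts as a mismatch.
    """
    index = as_index(ref)
    qarr = encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.uint8)
    if len(qarr) >= index.L:
        raise ValueError(
            f"read length {len(qarr)} must be shorter than the reference ({index.L})"
        )
    if len(qarr) == 0:
        return None
    qrc = reverse_complement_arr(qarr)
    scored: list[tuple[int, str, int]] = []
    for strand, q in (("+", qarr), ("-", qrc)):
        for t, c in _placements(q, index, max_mismatch, max_mismatch, 0).items():
            scored.append((c, strand, t))
    if not scored:
        return None
    best_c = min(c for c, _, _ in scored)
    top = [(s, t) for c, s, t in scored if c == best_c]
    if len(top) > 1:
        return None  # ambiguous placement
    strand, t = top[0]
    fwd = qarr if strand == "+" else qrc
    if quals is None:
        fwd_quals = np.zeros(len(qarr), dtype=np.int64)
    else:
        quals = np.asarray(quals, dtype=np.int64)
        fwd_quals = quals if strand == "+" else quals[::-1]
    mm = _mismatch_mask(fwd, index, t)
    idx = np.nonzero(mm)[0]
    mismatches = [
        (
            int((t + i) % index.L),
            chr(index.doubled[t + i]),
            chr(fwd[i]),
            int(fwd_quals[i]),
        )
        for i in idx
    ]
    return AlignmentHit(
        ref_pos=int(t % index.L),
        strand=strand,
        rotation_offset=0,
        n_mismatch=len(mismatches),
        mismatches=mismatches,
        aligned_len=len(qarr),
        fwd_bases=fwd.copy(),
        fwd_quals=np.asarray(fwd_quals).copy(),
        masked_fwd_positions=np.empty(0, dtype=np.int64),
    )


def map_consensus(
    cs: ConsensusRead,
    ref: ReferenceSeq | ReferenceIndex,
    stride: int = DEFAULT_STRIDE,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> AlignmentHit | None:
    """Best placement of a consensus read across its sampled rotations.

    Every rotation at offsets 0, stride, 2*stride, ... is placed on both
    strands; the hit with the fewest non-junction mismatches wins, rotation
    ties broken by the smallest offset.  A rotation whose minimum is achieved
    at two distinct reference placements is ambiguous and discarded.  Returns
    None for unmapped reads (counted in the cycle-mapping-rate denominator
    only).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    index = as_index(ref)
    p = cs.period
    if p >= index.L:
        raise ValueError(f"read length {p} must be shorter than the reference ({index.L})")
    zone = stride - 1
    if 2 * zone >= p:
        zone = 0
    raw_limit = max_mismatch + 2 * zone
    arr = getattr(cs, "_array", None)
    if arr is None:
        arr = encode(cs.bases)
    quals = np.asarray(cs.quals, dtype=np.int64)
    d = np.concatenate([arr, arr])
    dq = np.concatenate([quals, quals])
    rcd = reverse_complement_arr(d)

    if _seeds_usable(arr, index, max_mismatch, zone):
        eff, off, s_code, t = _kernels.map_scan(
            d,
            dq,
            rcd,
            index.doubled,
            index.L,
            index.sorted_ids,
            index.sorted_pos,
            index.k,
            stride,
            max_mismatch,
            zone,
        )
        if eff < 0:
            return None
        strand = "+" if s_code == 0 else "-"
        q = d[off : off + p] if strand == "+" else rcd[p - off : 2 * p - off]
        mm = _mismatch_mask(q, index, int(t))
        best = (int(eff), int(off), strand, int(t), mm)
    else:
        best = None  # (eff, off, strand, t, mm)
        for off in range(0, p, stride):
            qf = d[off : off + p]
            qr = rcd[p - off : 2 * p - off]
            pairs = []
            for strand, q in (("+", qf), ("-", qr)):
                counts = _kernels.brute_scan(q, index.doubled, index.L, raw_limit)
                pairs.extend(
                    (strand, int(t)) for t in np.nonzero(counts <= raw_limit)[0]
                )
            results = []
            for strand, t in pairs:
                q = qf if strand == "+" else qr
                fq = dq[off : off + p] if strand == "+" else dq[off : off + p][::-1]
                mm = _mismatch_mask(q, index, t)
                scored = mm & (fq >= 1)
                eff = int(scored[zone : p - zone].sum()) if zone else int(scored.sum())
                if eff <= max_mismatch:
                    results.append((eff, strand, t, mm))
            if not results:
                continue
            min_eff = min(r[0] for r in results)
            top = [r for r in results if r[0] == min_eff]
            if len(top) > 1:
                continue  # ambiguous rotation: two tied reference placements
            eff, strand, t, mm = top[0]
            if best is None or eff < best[0]:
                best = (eff, off, strand, t, mm)
                if eff == 0:
                    break
        if best is None:
            return None
    eff, off, strand, t, mm = best
    fwd = (d[off : off + p] if strand == "+" else rcd[p - off : 2 * p - off]).copy()
    fwd_quals = (dq[off : off + p] if strand == "+" else dq[off : off + p][::-1]).copy()
    idx = np.nonzero(mm)[0]
    in_zone = (idx < zone) | (idx >= p - zone) if zone else np.zeros(len(idx), dtype=bool)
    masked = idx[in_zone]
    # quality-masked mismatches are dropped here too: they carry quality 0 and
    # never reach the pileup, so they are not reported as read mismatches
    kept = idx[~in_zone & (fwd_quals[idx] >= 1)]
    mismatches = [
        (
            int((t + i) % index.L),
            chr(index.doubled[t + i]),
            chr(fwd[i]),
            int(fwd_quals[i]),
        )
        for i in kept
    ]
    return AlignmentHit(
        ref_pos=int(t % index.L),
        strand=strand,
        rotation_offset=off,
        n_mismatch=len(mismatches),
        mismatches=mismatches,
        aligned_len=p,
        fwd_bases=fwd,
        fwd_quals=fwd_quals,
        masked_fwd_positions=masked.astype(np.int64),
        source_pair_id=cs.source_pair_id,
    )


def cycle_mapping_rate(n_mapped: int, n_consensus: int) -> float:
    """Fraction of consensus reads that mapped to the reference (CMR)."""
    if n_consensus < 1:
        raise ValueError("n_consensus must be >= 1")
    if n_mapped > n_consensus:
        raise ValueError("n_mapped cannot exceed n_consensus")
    return n_mapped / n_consensus


# ---------------------------------------------------------------------------
# SAM-style export/import of mapped consensus reads.  Positions are reported
# modulo the reference length (wrap-around reads simply run past the end);
# rotation offset and junction-masked positions travel in XO/XJ tags.

def write_sam(hits, ref: ReferenceSeq, path) -> None:
    with open(path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:unsorted\n")
        out.write(f"@SQ\tSN:{ref.name}\tLN:{len(ref)}\n")
        out.write(
            "@CO\tcircular reference: alignments may wrap; POS is the start "
            "modulo the reference length\n"
        )
        for i, h in enumerate(hits):
            flag = 16 if h.strand == "-" else 0
            qual = "".join(chr(min(int(q), 93) + 33) for q in h.fwd_quals)
            tags = [f"NM:i:{h.n_mismatch}", f"XO:i:{h.rotation_offset}"]
            if len(h.masked_fwd_positions):
                tags.append(
                    "XJ:B:i," + ",".join(str(int(x)) for x in h.masked_fwd_positions)
                )
            name = h.source_pair_id or f"cs{i}"
            out.write(
                f"{name}\t{flag}\t{ref.name}\t{h.ref_pos + 1}\t255\t"
                f"{h.aligned_len}M\t*\t0\t0\t{decode(h.fwd_bases)}\t{qual}\t"
                + "\t".join(tags)
                + "\n"
            )


def read_sam(path, ref: ReferenceSeq) -> list[AlignmentHit]:
    index = as_index(ref)
    hits = []
    with open(path) as handle:
        for line in handle:
            if line.startswith("@"):
                continue
            fields = line.rstrip("\n").split("\t")
            name, flag, _rname, pos, _mapq, _cigar = fields[:6]
            seq, qual = fields[9], fields[10]
            rotation = 0
            masked = np.empty(0, dtype=np.int64)
            for tag in fields[11:]:
                if tag.startswith("XO:i:"):
                    rotation = int(tag[5:])
                elif tag.startswith("XJ:B:i,"):
                    masked = np.array([int(x) for x in tag[7:].split(",")], dtype=np.int64)
            fwd = encode(seq)
            fwd_quals = np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int64) - 33
            t = int(pos) - 1
            mm = _mismatch_mask(fwd, index, t)
            idx = np.nonzero(mm)[0]
            kept = [i for i in idx if i not in set(masked.tolist())]
            mismatches = [
                (
                    int((t + i) % index.L),
                    chr(index.doubled[t + i]),
                    chr(fwd[i]),
                    int(fwd_quals[i]),
                )
                for i in kept
            ]
            hits.append(
                AlignmentHit(
                    ref_pos=t,
                    strand="-" if int(flag) & 16 else "+",
                    rotation_offset=rotation,
                    n_mismatch=len(mismatches),
                    mismatches=mismatches,
                    aligned_len=len(fwd),
                    fwd_bases=fwd,
                    fwd_quals=fwd_quals,
                    masked_fwd_positions=masked,
                    source_pair_id=name,
                )
            )
    return hits
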