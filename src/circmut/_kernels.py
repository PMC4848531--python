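"""Numba-compiled inner loops of the per-pair hot path.

All kernels operate on uint8 arrays of ASCII base codes (A/C/G/T/N).
``N`` never counts as a match or a mismatch: it is dropped from both the
numerator and the denominator of every mismatch fraction.
"""

from __future__ import annotations

import numpy as np
from numba import njit

A, C, G, T, N = 65, 67, 71, 84, 78

#: ASCII -> 2-bit code (A=0, C=1, G=2, T=3), 255 for anything else (incl. N).
TWOBIT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate((A, C, G, T)):
    TWOBIT[_b] = _i

#: 2-bit code -> ASCII letter.
LETTER = np.array([A, C, G, T], dtype=np.uint8)

#: ASCII -> complement ASCII (N -> N); identity elsewhere.
COMPLEMENT = np.arange(256, dtype=np.uint8)
for _x, _y in ((A, T), (T, A), (C, G), (G, C), (N, N)):
    COMPLEMENT[_x] = _y


@njit(cache=True)
def best_overlap(a, b, min_overlap, max_rate):
    """Longest suffix(a)/prefix(b) overlap with mismatch fraction <= max_rate.

    Returns the overlap length, or 0 if no overlap of length >= min_overlap
    qualifies.  Positions where either base is N are excluded from both the
    mismatch count and the denominator; an overlap whose denominator is empty
    does not qualify.
    """
    la = a.shape[0]
    lb = b.shape[0]
    for o in range(min(la, lb), min_overlap - 1, -1):
        lim = max_rate * o  # denom <= o, so mism > lim implies failure
        mism = 0
        denom = 0
        ok = True
        for i in range(o):
            x = a[la - o + i]
            y = b[i]
            if x == N or y == N:
                continue
            denom += 1
            if x != y:
                mism += 1
                if mism > lim:
                    ok = False
                    break
        if ok and denom > 0 and mism <= max_rate * denom:
            return o
    return 0


@njit(cache=True)
def period_scan(m, min_period, min_evidence, max_rate):
    """Smallest tandem period of ``m`` by self-overlap, or 0 if none.

    Compares m[0:L-p] with m[p:L] for p ascending from min_period while the
    comparison covers at least min_evidence positions.
    """
    L = m.shape[0]
    pmax = L - min_evidence
    for p in range(min_period, pmax + 1):
        n = L - p
        lim = max_rate * n
        mism = 0
        denom = 0
        ok = True
        for i in range(n):
            x = m[i]
            y = m[i + p]
            if x == N or y == N:
                continue
            denom += 1
            if x != y:
                mism += 1
                if mism > lim:
                    ok = False
                    break
        if ok and denom > 0 and mism <= max_rate * denom:
            return p
    return 0


@njit(cache=True)
def consensus_scan(m, q, period):
    """Collapse a merged tandem read onto its smallest unit.

    Position i of the consensus collects m[i], m[i+period], ... (N excluded).
    The consensus base is the majority base (ties: larger quality sum, then
    alphabetical).  Quality is the capped (93) sum of the collected qualities
    when all collected bases agree and at least two were collected; 0
    otherwise.
    """
    L = m.shape[0]
    bases = np.empty(period, dtype=np.uint8)
    quals = np.zeros(period, dtype=np.int64)
    copies = np.zeros(period, dtype=np.int64)
    for i in range(period):
        cnt0 = cnt1 = cnt2 = cnt3 = 0
        qs0 = qs1 = qs2 = qs3 = 0
        total = 0
        j = i
        while j < L:
            b = m[j]
            if b != N:
                code = TWOBIT[b]
                total += 1
                if code == 0:
                    cnt0 += 1
                    qs0 += q[j]
                elif code == 1:
                    cnt1 += 1
                    qs1 += q[j]
                elif code == 2:
                    cnt2 += 1
                    qs2 += q[j]
                else:
                    cnt3 += 1
                    qs3 += q[j]
            j += period
        copies[i] = total
        if total == 0:
            bases[i] = N
            quals[i] = 0
            continue
        cnts = (cnt0, cnt1, cnt2, cnt3)
        qsums = (qs0, qs1, qs2, qs3)
        best = 0
        for c in range(1, 4):
            if cnts[c] > cnts[best] or (cnts[c] == cnts[best] and qsums[c] > qsums[best]):
                best = c
        bases[i] = LETTER[best]
        if cnts[best] == total and total >= 2:
            s = qsums[best]
            quals[i] = 93 if s > 93 else s
        else:
            quals[i] = 0
    return bases, quals, copies


@njit(cache=True)
def count_mismatches(q, ref, start, limit):
    """Mismatches of q against ref[start:start+len(q)], early-exiting at limit+1."""
    mism = 0
    for i in range(q.shape[0]):
        x = q[i]
        y = ref[start + i]
        if x == N or y == N:
            continue
        if x != y:
            mism += 1
            if mism > limit:
                return mism
    return mism


@njit(cache=True)
def brute_scan(q, doubled, L, limit):
    """Mismatch count of q at every circular start 0..L-1 (capped at limit+1)."""
    out = np.empty(L, dtype=np.int64)
    for t in range(L):
        out[t] = count_mismatches(q, doubled, t, limit)
    return out


@njit(cache=True)
def merge_kernel(a, qa, b, qb, o):
    """Merged bases/qualities for a fixed overlap o (choice rules as merge_pair)."""
    la = a.shape[0]
    lb = b.shape[0]
    n = la + lb - o
    out = np.empty(n, dtype=np.uint8)
    q = np.empty(n, dtype=np.int64)
    for i in range(la - o):
        out[i] = a[i]
        q[i] = qa[i]
    for i in range(o):
        j = la - o + i
        x = a[j]
        y = b[i]
        qx = qa[j]
        qy = qb[i]
        if x == y:
            out[j] = x
            s = qx + qy
            q[j] = 93 if s > 93 else s
        elif qy > qx:
            out[j] = y
            q[j] = qy
        else:
            out[j] = x
            q[j] = qx
    for i in range(lb - o):
        out[la + i] = b[o + i]
        q[la + i] = qb[o + i]
    return out, q


@njit(cache=True)
def _window_ids(arr, k):
    nw = arr.shape[0] - k + 1
    ids = np.empty(nw, dtype=np.int64)
    valid = np.empty(nw, dtype=np.bool_)
    for pos in range(nw):
        v = 0
        ok = True
        for i in range(k):
            c = TWOBIT[arr[pos + i]]
            if c == 255:
                ok = False
                break
            v = (v << 2) | c
        ids[pos] = v
        valid[pos] = ok
    return ids, valid


@njit(cache=True)
def map_scan(d, dq, rcd, dref, L, sorted_ids, sorted_pos, k, stride, max_mm, zone):
    """Best rotation placement of a consensus read on a circular reference.

    ``d``/``dq``/``rcd`` are the doubled read bases/qualities and the
    reverse complement of the bases; ``dref`` the doubled reference with its
    sorted k-mer index.  Scans rotation offsets ascending; per rotation,
    seed candidates on both strands are verified ungapped.  A placement is
    scored by its effective mismatches: base mismatches at quality-passing
    consensus positions (quality >= 1) outside the ``zone`` bases at either
    read end — i.e. exactly the evidence the pileup will use; quality-masked
    positions and junction-zone mismatches (junction mis-phasing artifacts)
    are discounted.  A rotation whose minimum is tied between two placements
    is ambiguous and skipped.  Returns (eff, off, strand, t) of the first
    rotation reaching 0 effective mismatches, else the best rotation;
    eff = -1 when unmapped.  Caller guarantees the seed pigeonhole (no N,
    enough middle seeds).
    """
    p = d.shape[0] // 2
    raw_limit = max_mm + 2 * zone
    ids_f, valid_f = _window_ids(d, k)
    ids_r, valid_r = _window_ids(rcd, k)
    n_ref = sorted_ids.shape[0]
    n_seeds = (p - k) // k + 1
    cand_t = np.empty(128, dtype=np.int64)
    cand_s = np.empty(128, dtype=np.int64)
    best_eff = -1
    best_off = -1
    best_strand = 0
    best_t = -1
    for off in range(0, p, stride):
        ncand = 0
        for si in range(n_seeds):
            u = si * k
            for strand in range(2):
                pos = off + u if strand == 0 else (p - off) + u
                if strand == 0:
                    if not valid_f[pos]:
                        continue
                    code = ids_f[pos]
                else:
                    if not valid_r[pos]:
                        continue
                    code = ids_r[pos]
                lo = np.searchsorted(sorted_ids, code)
                while lo < n_ref and sorted_ids[lo] == code:
                    t = (sorted_pos[lo] - u) % L
                    lo += 1
                    dup = False
                    for ci in range(ncand):
                        if cand_t[ci] == t and cand_s[ci] == strand:
                            dup = True
                            break
                    if not dup and ncand < 128:
                        cand_t[ncand] = t
                        cand_s[ncand] = strand
                        ncand += 1
        r_min = 1 << 30
        r_count = 0
        r_t = -1
        r_s = 0
        for ci in range(ncand):
            t = cand_t[ci]
            s = cand_s[ci]
            mism = 0
            eff = 0
            bad = False
            for i in range(p):
                x = d[off + i] if s == 0 else rcd[p - off + i]
                y = dref[t + i]
                if x == N or y == N:
                    continue
                if x != y:
                    mism += 1
                    if mism > raw_limit:
                        bad = True
                        break
                    qual = dq[off + i] if s == 0 else dq[off + p - 1 - i]
                    if qual >= 1 and zone <= i < p - zone:
                        eff += 1
            if bad or eff > max_mm:
                continue
            if eff < r_min:
                r_min = eff
                r_count = 1
                r_t = t
                r_s = s
            elif eff == r_min:
                r_count += 1
        if r_count == 1:
            if best_eff < 0 or r_min < best_eff:
                best_eff = r_min
                best_off = off
                best_strand = r_s
                best_t = r_t
                if r_min == 0:
                    return best_eff, best_off, best_strand, best_t
    return best_eff, best_off, best_strand, best_t
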