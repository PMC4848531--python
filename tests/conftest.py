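"""Shared fixtures and independent oracles for the test suite.

The brute-force helpers here deliberately avoid the package's own alignment
and counting code paths: they are plain-Python re-derivations used as
oracles.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from circmut.mapping import AlignmentHit
from circmut.seqio import ReferenceSeq

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp_py(s: str) -> str:
    return s[::-1].translate(_RC)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def brute_placements(seq: str, ref_bases: str, limit: int):
    """All (mismatches, strand, pos) circular placements with count <= limit.

    Plain-Python exhaustive scan over both strands; N on either side is
    neither match nor mismatch.
    """
    L = len(ref_bases)
    out = []
    for strand in "+-":
        q = seq if strand == "+" else revcomp_py(seq)
        for t in range(L):
            mm = 0
            for i, b in enumerate(q):
                r = ref_bases[(t + i) % L]
                if b == "N" or r == "N":
                    continue
                if b != r:
                    mm += 1
            if mm <= limit:
                out.append((mm, strand, t))
    return out


def brute_best(seq: str, ref_bases: str, limit: int):
    """(best mismatch count, [(strand, pos) at the minimum]) or (None, [])."""
    placements = brute_placements(seq, ref_bases, limit)
    if not placements:
        return None, []
    best = min(mm for mm, _, _ in placements)
    return best, [(s, t) for mm, s, t in placements if mm == best]


def make_hit(
    ref: ReferenceSeq,
    pos: int,
    bases: str,
    quals=None,
    strand: str = "+",
    masked=(),
) -> AlignmentHit:
    """Hand-built alignment hit (bases already reference-forward oriented)."""
    arr = np.frombuffer(bases.encode(), dtype=np.uint8).copy()
    if quals is None:
        quals = np.full(len(bases), 60, dtype=np.int64)
    quals = np.asarray(quals, dtype=np.int64)
    L = len(ref)
    mismatches = []
    for i, b in enumerate(bases):
        r = ref.bases[(pos + i) % L]
        if b != "N" and r != "N" and b != r and i not in masked and quals[i] >= 1:
            mismatches.append(((pos + i) % L, r, b, int(quals[i])))
    return AlignmentHit(
        ref_pos=pos,
        strand=strand,
        rotation_offset=0,
        n_mismatch=len(mismatches),
        mismatches=mismatches,
        aligned_len=len(bases),
        fwd_bases=arr,
        fwd_quals=quals,
        masked_fwd_positions=np.array(sorted(masked), dtype=np.int64),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160428)


@pytest.fixture
def small_ref(rng) -> ReferenceSeq:
    return ReferenceSeq("toy", random_seq(rng, 300), circular=True)
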