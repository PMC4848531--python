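"""Mutation analytics over mapped consensus reads.

Everything downstream of mapping runs off a per-position pileup of
quality-passing consensus bases: the overall mutation frequency, the
12-type substitution spectrum, the minor-allele-frequency (MAF)
distribution, pyrimidine-context stratification of C->T events, 100-bp
window profiles, subsampling curves, fold changes and Student t-tests,
plus two closed-form calculators — the per-base conversion of a
region-level (supF-style) mutant fraction, and the expected allele
frequencies of a two-strain mixture.

Substitutions are counted as observed on the reference forward strand and
the 12 ordered types are kept separate.  Frequencies are fractions in
[0, 1]; reports print them in scientific notation with 3 significant
digits, but all arithmetic uses unrounded values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._kernels import TWOBIT
from .mapping import AlignmentHit
from .seqio import ReferenceSeq

BASES = "ACGT"
SUBSTITUTION_TYPES = [(a, b) for a in BASES for b in BASES if a != b]
DEFAULT_MAF_BINS = (0.0, 1e-5, 1e-4, 1e-3, 1.0)
DEFAULT_WINDOW = 100


class Pileup:
    """Per-reference-position A/C/G/T counts of quality-passing consensus bases."""

    def __init__(self, ref: ReferenceSeq):
        self.ref = ref
        self.counts = np.zeros((len(ref), 4), dtype=np.int64)
        self.ref_codes = TWOBIT[ref.array].astype(np.int64)  # 255 at N positions

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def add_hit(self, hit: AlignmentHit, min_quality: int = 1) -> None:
        """Count every aligned base with quality >= min_quality.

        Junction-masked positions and N bases contribute nothing; reference
        N positions are skipped as unanalyzable.
        """
        L = len(self.ref)
        lq = hit.aligned_len
        if not 0 <= hit.ref_pos < L:
            raise ValueError(f"hit position {hit.ref_pos} outside reference [0, {L})")
        positions = (hit.ref_pos + np.arange(lq)) % L
        codes = TWOBIT[hit.fwd_bases].astype(np.int64)
        keep = (hit.fwd_quals >= min_quality) & (codes != 255)
        keep &= self.ref_codes[positions] != 255
        if len(hit.masked_fwd_positions):
            keep[hit.masked_fwd_positions] = False
        np.add.at(self.counts, (positions[keep], codes[keep]), 1)

    def mismatch_matrix(self) -> np.ndarray:
        """Counts with the reference allele zeroed out (non-reference bases only)."""
        out = self.counts.copy()
        valid = self.ref_codes != 255
        out[np.arange(len(self.ref))[valid], self.ref_codes[valid]] = 0
        out[~valid] = 0
        return out

    def total_mismatches(self) -> int:
        return int(self.mismatch_matrix().sum())

    def to_frame(self) -> pd.DataFrame:
        """Per-site report (1-based positions)."""
        df = pd.DataFrame(self.counts, columns=list(BASES))
        df.insert(0, "pos", np.arange(1, len(self.ref) + 1))
        df.insert(1, "ref", list(self.ref.bases))
        df["coverage"] = self.coverage
        return df


def build_pileup(
    hits: Iterable[AlignmentHit], ref: ReferenceSeq, min_quality: int = 1
) -> Pileup:
    """Accumulate quality-filtered consensus bases into a pileup."""
    if min_quality < 1:
        raise ValueError("min_quality must be >= 1 (masked bases carry quality 0)")
    p = Pileup(ref)
    for hit in hits:
        p.add_hit(hit, min_quality)
    return p


def _normalize_types(types: Iterable) -> set[tuple[str, str]]:
    out = set()
    for t in types:
        if isinstance(t, str):
            frm, to = t[0], t[-1]
        else:
            frm, to = t
        if (frm, to) not in SUBSTITUTION_TYPES:
            raise ValueError(f"not a substitution type: {t!r}")
        out.add((frm, to))
    return out


def overall_mutation_frequency(
    p: Pileup, exclude_types: Iterable = ()
) -> float:
    """Fraction of quality-passing consensus bases that differ from the reference.

    ``exclude_types`` removes the counts of specific substitution events
    (e.g. the sonication-associated C->G and G->C) from the numerator only;
    the denominator stays the total covered bases.
    """
    total = int(p.coverage.sum())
    if total == 0:
        raise ValueError("pileup has zero coverage")
    excl = _normalize_types(exclude_types)
    mm = p.mismatch_matrix()
    numer = int(mm.sum())
    for frm, to in excl:
        sel = p.ref_codes == BASES.index(frm)
        numer -= int(mm[sel, BASES.index(to)].sum())
    return numer / total


def spectrum_by_type(p: Pileup) -> pd.DataFrame:
    """Counts and per-opportunity frequencies of the 12 ordered substitution types.

    The denominator of X->Y is the total coverage of positions whose reference
    base is X; a type with zero denominator has frequency NaN (undefined, not
    zero).
    """
    mm = p.mismatch_matrix()
    cov = p.coverage
    rows = []
    for frm, to in SUBSTITUTION_TYPES:
        sel = p.ref_codes == BASES.index(frm)
        count = int(mm[sel, BASES.index(to)].sum())
        denom = int(cov[sel].sum())
        rows.append(
            {
                "from": frm,
                "to": to,
                "count": count,
                "denominator": denom,
                "frequency": count / denom if denom else np.nan,
            }
        )
    return pd.DataFrame(rows)


def site_maf(p: Pileup) -> pd.DataFrame:
    """Per-site minor allele frequency at variant sites.

    A variant site has at least one quality-passing non-reference base; its
    MAF is the count of the most frequent non-reference allele over the
    site's coverage.
    """
    mm = p.mismatch_matrix()
    cov = p.coverage
    top = mm.max(axis=1)
    sel = top > 0
    alleles = np.array(list(BASES))[mm.argmax(axis=1)]
    return pd.DataFrame(
        {
            "pos": np.nonzero(sel)[0] + 1,
            "allele": alleles[sel],
            "count": top[sel],
            "coverage": cov[sel],
            "maf": top[sel] / cov[sel],
        }
    )


def maf_distribution(
    hits: Sequence[AlignmentHit],
    ref: ReferenceSeq,
    n_reads_sample: int = 1_000_000,
    bins: Sequence[float] = DEFAULT_MAF_BINS,
    seed: int | None = None,
    min_quality: int = 1,
) -> pd.DataFrame:
    """Proportion of variant sites per MAF bin after read subsampling.

    ``n_reads_sample`` mapped reads are drawn without replacement (seeded)
    before the pileup is built; bins are half-open [lo, hi).  Proportions are
    over variant sites and sum to 1 when any variant site exists.
    """
    bins = list(bins)
    if sorted(bins) != bins or len(bins) < 2:
        raise ValueError("bins must be an ascending boundary list")
    hits = list(hits)
    if n_reads_sample < len(hits):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(hits), size=n_reads_sample, replace=False)
        hits = [hits[i] for i in idx]
    elif n_reads_sample > len(hits):
        warnings.warn(
            f"requested {n_reads_sample} reads but only {len(hits)} available; using all",
            stacklevel=2,
        )
    pile = build_pileup(hits, ref, min_quality)
    mafs = site_maf(pile)["maf"].to_numpy()
    n_sites = len(mafs)
    rows = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        in_bin = int(((mafs >= lo) & (mafs < hi)).sum())
        rows.append(
            {
                "maf_lo": lo,
                "maf_hi": hi,
                "n_sites": in_bin,
                "proportion": in_bin / n_sites if n_sites else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_variant_sites"] = n_sites
    return df


def _circular_run_lengths(mask: np.ndarray) -> np.ndarray:
    """Length of the maximal circular run of True containing each position (0 if False)."""
    L = len(mask)
    if mask.all():
        return np.full(L, L)
    out = np.zeros(L, dtype=np.int64)
    # rotate so the sequence starts on a False, making runs non-wrapping
    start = int(np.nonzero(~mask)[0][0])
    rolled = np.roll(mask, -start)
    run_len = 0
    run_start = 0
    for i in range(L + 1):
        if i < L and rolled[i]:
            if run_len == 0:
                run_start = i
            run_len += 1
        elif run_len:
            for j in range(run_start, run_start + run_len):
                out[(j + start) % L] = run_len
            run_len = 0
    return out


def classify_pyrimidine_context(
    ref: ReferenceSeq, pos: int, strand: str = "+"
) -> str:
    """Classify a C position as mono-, di- or polypyrimidine context.

    The maximal run of pyrimidines (C/T on the strand carrying the C,
    neighbors taken circularly) containing the position determines the
    class: run length 1 -> 'mono', 2 -> 'di', >= 3 -> 'poly'.  On the '-'
    strand a reference G is examined as a C.
    """
    if strand not in "+-":
        raise ValueError(f"invalid strand {strand!r}")
    base = ref.bases[pos]
    if strand == "+":
        if base != "C":
            raise ValueError(f"position {pos} is {base}, not C, on '+'")
        mask = np.isin(ref.array, [ord("C"), ord("T")])
    else:
        if base != "G":
            raise ValueError(f"position {pos} is {base}, not C, on '-'")
        mask = np.isin(ref.array, [ord("G"), ord("A")])
    run = int(_circular_run_lengths(mask)[pos])
    return "mono" if run == 1 else "di" if run == 2 else "poly"


def ct_frequency_by_context(p: Pileup, ref: ReferenceSeq) -> pd.DataFrame:
    """C->T frequency at mono-, di- and polypyrimidine sites.

    Reference C positions contribute C->T events on '+'; reference G
    positions contribute G->A events, read as C->T on the '-' strand with
    the context classified on that strand.  Frequencies are events over the
    total coverage of the class's C positions; an empty class is NaN.
    """
    pyr_run = _circular_run_lengths(np.isin(ref.array, [ord("C"), ord("T")]))
    pur_run = _circular_run_lengths(np.isin(ref.array, [ord("G"), ord("A")]))
    cov = p.coverage
    events = np.zeros(len(ref), dtype=np.int64)
    runs = np.zeros(len(ref), dtype=np.int64)
    is_site = np.zeros(len(ref), dtype=bool)
    c_sel = p.ref_codes == BASES.index("C")
    g_sel = p.ref_codes == BASES.index("G")
    events[c_sel] = p.counts[c_sel, BASES.index("T")]
    events[g_sel] = p.counts[g_sel, BASES.index("A")]
    runs[c_sel] = pyr_run[c_sel]
    runs[g_sel] = pur_run[g_sel]
    is_site = c_sel | g_sel
    rows = []
    for name, lo, hi in (("mono", 1, 1), ("di", 2, 2), ("poly", 3, np.inf)):
        sel = is_site & (runs >= lo) & (runs <= hi)
        n_events = int(events[sel].sum())
        n_cov = int(cov[sel].sum())
        rows.append(
            {
                "context": name,
                "n_sites": int(sel.sum()),
                "events": n_events,
                "coverage": n_cov,
                "frequency": n_events / n_cov if n_cov else np.nan,
            }
        )
    return pd.DataFrame(rows)


def window_frequencies(p: Pileup, window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Mutation frequency in consecutive non-overlapping windows.

    The final window may be shorter than ``window`` and is flagged.  A window
    with zero coverage has NaN frequency.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    L = len(p.ref)
    mm = p.mismatch_matrix().sum(axis=1)
    cov = p.coverage
    rows = []
    for start in range(0, L, window):
        end = min(start + window, L)
        c = int(cov[start:end].sum())
        m = int(mm[start:end].sum())
        rows.append(
            {
                "start": start + 1,
                "end": end,
                "mismatches": m,
                "coverage": c,
                "frequency": m / c if c else np.nan,
                "short": end - start < window,
            }
        )
    return pd.DataFrame(rows)


def subsample_curve(
    pairs: Sequence,
    sizes: Sequence[int],
    frequency_fn: Callable[[Sequence], float],
    replicates: int = 3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean and sd of the overall mutation frequency at several raw-data sizes.

    For each target size (raw sequenced bases, read1+read2), whole pairs are
    sampled without replacement until the cumulative base count reaches the
    target, and ``frequency_fn`` (typically the full pipeline) is run on the
    sample.  Requesting more than the available data uses everything, with a
    warning.
    """
    pairs = list(pairs)
    pair_bases = np.array([len(r1) + len(r2) for r1, r2 in pairs], dtype=np.int64)
    total = int(pair_bases.sum())
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        freqs = []
        for _ in range(replicates):
            if size >= total:
                subset = pairs
                if size > total:
                    warnings.warn(
                        f"requested {size} bases but only {total} available; using all",
                        stacklevel=2,
                    )
            else:
                order = rng.permutation(len(pairs))
                cum = np.cumsum(pair_bases[order])
                n_take = int(np.searchsorted(cum, size) + 1)
                subset = [pairs[i] for i in order[:n_take]]
            freqs.append(frequency_fn(subset))
        freqs = np.array(freqs, dtype=float)
        rows.append(
            {
                "size": size,
                "mean": float(freqs.mean()),
                "sd": float(freqs.std(ddof=1)) if len(freqs) > 1 else 0.0,
                "replicates": replicates,
            }
        )
    return pd.DataFrame(rows)


def fold_change(freq: float, baseline: float) -> float:
    """Mutation frequency relative to a baseline condition."""
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    return freq / baseline


def t_test_two_sample(xs: Sequence[float], ys: Sequence[float]) -> tuple[float, float]:
    """Two-sample Student t-test (pooled variance), two-tailed p-value."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) < 2 or len(ys) < 2:
        raise ValueError("each group needs at least 2 values")
    t, pval = stats.ttest_ind(xs, ys, equal_var=True)
    return float(t), float(pval)


def tsma_per_base(e_L: float, L: int = 95) -> float:
    """Per-nucleotide mutation frequency from a region-level mutant fraction.

    Inverts e_L = 1 - (1 - alpha)^L, the probability that a polynucleotide of
    length L carries at least one change when each base mutates independently
    with frequency alpha (the supF marker has L = 95).
    """
    if not 0 <= e_L < 1:
        raise ValueError("e_L must be in [0, 1)")
    if L < 1:
        raise ValueError("L must be >= 1")
    return 1.0 - (1.0 - e_L) ** (1.0 / L)


def tsma_region(alpha: float, L: int = 95) -> float:
    """Region-level mutant fraction from a per-nucleotide frequency (inverse of tsma_per_base)."""
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    if L < 1:
        raise ValueError("L must be >= 1")
    return 1.0 - (1.0 - alpha) ** L


@dataclass
class MixtureSpec:
    """Per-site allele frequencies of two strains and their mixing ratio.

    ``strain_a``/``strain_b`` map a site position to {allele: frequency};
    frequencies at each site must sum to 1 within each strain.  ``ratio`` is
    the (a, b) mixing weights, e.g. (10000, 1).
    """

    strain_a: dict
    strain_b: dict
    ratio: tuple[float, float]

    def __post_init__(self) -> None:
        wa, wb = self.ratio
        if wa <= 0 or wb <= 0:
            raise ValueError("ratio parts must be positive")
        for name, strain in (("a", self.strain_a), ("b", self.strain_b)):
            for site, freqs in strain.items():
                s = sum(freqs.values())
                if abs(s - 1.0) > 1e-6:
                    raise ValueError(
                        f"strain {name} site {site}: allele frequencies sum to {s}, not 1"
                    )


def mixture_expected_af(spec: MixtureSpec, site: int) -> dict[str, float]:
    """Expected allele frequencies at a site of the mixed sample.

    The expectation is the mixing-ratio-weighted average of the per-strain
    frequencies: f(x) = (wa * fa(x) + wb * fb(x)) / (wa + wb).
    """
    if site not in spec.strain_a or site not in spec.strain_b:
        raise ValueError(f"site {site} absent from the mixture specification")
    wa, wb = spec.ratio
    fa = spec.strain_a[site]
    fb = spec.strain_b[site]
    alleles = sorted(set(fa) | set(fb))
    return {
        x: (wa * fa.get(x, 0.0) + wb * fb.get(x, 0.0)) / (wa + wb) for x in alleles
    }
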