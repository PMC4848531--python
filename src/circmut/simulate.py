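"""Synthetic rolling-circle (Cir-seq style) read-pair generator with ground truth.

Each simulated molecule is a 60-100 nt single-strand fragment drawn uniformly
from a circular reference, optionally carrying injected true mutations (per
site, at a stated frequency) and pre-amplification "damage" errors.  The
fragment is circularized, tandem-copied from a uniform rotation, and read as
a pair of fixed-length reads whose templates overlap; sequencing errors are
injected independently per read base.  Because damage happens to the single
molecule before amplification it is shared by all tandem copies — exactly the
class of error that consensus calling cannot remove — while sequencing errors
are independent per copy and are suppressed by the consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._kernels import LETTER, TWOBIT
from .seqio import (
    FastqRecord,
    ReferenceSeq,
    decode,
    reverse_complement_arr,
    write_fastq,
)

#: alternatives[c] lists the three 2-bit codes different from c
_ALTERNATIVES = np.array(
    [[b for b in range(4) if b != c] for c in range(4)], dtype=np.int64
)


@dataclass
class Mutation:
    """A true mutation: reference position, from/to base, per-molecule frequency."""

    position: int
    from_base: str
    to_base: str
    frequency: float


@dataclass
class SimConfig:
    """Study conditions of a simulated library.

    Defaults mirror a gel-selected 60-100 nt fragment library read as 100 nt
    pairs on a constant-Q30 instrument with a 1e-3 per-base sequencing error
    rate and no pre-amplification damage.
    """

    reference: ReferenceSeq | None = None
    ref_length: int = 5000
    mutations: list[Mutation] = field(default_factory=list)
    fragment_len_range: tuple[int, int] = (60, 100)
    read_length: int = 100
    n_pairs: int = 10_000
    seq_error_rate: float = 1e-3
    damage_rate: float = 0.0
    damage_model: str = "sonication"
    sonication_bias: float = 0.8
    quality: int = 30
    overlap_range: tuple[int, int] | None = None  # template overlap of the two reads
    min_overlap: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        fmin, fmax = self.fragment_len_range
        if fmin < 30:
            raise ValueError("fragment length minimum must be >= 30")
        if fmax < fmin:
            raise ValueError("fragment length range reversed")
        if self.read_length < fmin:
            raise ValueError("read length must be >= the fragment minimum")
        for m in self.mutations:
            if not 0 < m.frequency <= 1:
                raise ValueError(f"mutation frequency {m.frequency} outside (0, 1]")
        if self.damage_model not in ("sonication", "uniform"):
            raise ValueError(f"unknown damage model {self.damage_model!r}")
        if self.overlap_range is None:
            self.overlap_range = (self.min_overlap, self.read_length)
        omin, omax = self.overlap_range
        if not 1 <= omin <= omax <= self.read_length:
            raise ValueError("overlap range must satisfy 1 <= min <= max <= read length")


def draw_reference(cfg: SimConfig) -> ReferenceSeq:
    """The configured reference, or a random one drawn deterministically from the seed.

    The drawn reference depends only on ``seed`` and ``ref_length`` so that
    libraries of different depths share the same genome.
    """
    if cfg.reference is not None:
        return cfg.reference
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EF]))
    codes = rng.integers(0, 4, size=cfg.ref_length)
    return ReferenceSeq("sim_ref", decode(LETTER[codes]), circular=True)


def simulate_fragment(
    cfg: SimConfig,
    ref: ReferenceSeq,
    rng: np.random.Generator,
    _doubled: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """One single-strand fragment with mutations and damage applied.

    The fragment start, length and strand are uniform; each configured
    mutation covered by the fragment is applied independently with its
    frequency; damage is applied per base at the damage rate (biased toward
    C<->G transversions under the "sonication" model).  Returns the fragment
    as an ASCII array (already reverse-complemented for '-' strand molecules)
    and a provenance dict.
    """
    L = len(ref)
    doubled = (
        _doubled if _doubled is not None else np.concatenate([ref.array, ref.array])
    )
    start = int(rng.integers(0, L))
    fmin, fmax = cfg.fragment_len_range
    length = int(rng.integers(fmin, fmax + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    frag = doubled[start : start + length].copy()
    applied = []
    for m in cfg.mutations:
        offset = (m.position - start) % L
        if offset < length and rng.random() < m.frequency:
            frag[offset] = ord(m.to_base)
            applied.append(m)
    n_damage = 0
    if cfg.damage_rate > 0:
        dmg = np.nonzero(rng.random(length) < cfg.damage_rate)[0]
        for i in dmg:
            code = int(TWOBIT[frag[i]])
            base = chr(frag[i])
            if (
                cfg.damage_model == "sonication"
                and base in "CG"
                and rng.random() < cfg.sonication_bias
            ):
                frag[i] = ord("G") if base == "C" else ord("C")
            else:
                frag[i] = LETTER[_ALTERNATIVES[code][rng.integers(3)]]
        n_damage = len(dmg)
    if strand == "-":
        frag = reverse_complement_arr(frag)
    prov = {
        "start": start,
        "length": length,
        "strand": strand,
        "mutations": ";".join(
            f"{m.position}:{m.from_base}>{m.to_base}" for m in applied
        ),
        "n_damage": n_damage,
    }
    return frag, prov


def _sequencing_errors(
    read: np.ndarray, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    if rate <= 0:
        return read, 0
    hits = np.nonzero(rng.random(len(read)) < rate)[0]
    for i in hits:
        read[i] = LETTER[_ALTERNATIVES[int(TWOBIT[read[i]])][rng.integers(3)]]
    return read, len(hits)


def simulate_pair_arrays(
    frag: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read-pair base arrays from one circularized fragment.

    The fragment is tandem-tiled from a uniform rotation; read1 is the first
    read_length bases, read2 the reverse complement of a later window whose
    template overlap with read1 is uniform within the configured range.
    """
    RL = cfg.read_length
    f = len(frag)
    rot = int(rng.integers(0, f))
    rolled = np.concatenate([frag[rot:], frag[:rot]])
    template = rolled[np.arange(2 * RL) % f]
    omin, omax = cfg.overlap_range
    overlap = int(rng.integers(omin, omax + 1))
    s = RL - overlap
    r1 = template[:RL].copy()
    r2 = reverse_complement_arr(template[s : s + RL])
    r1, e1 = _sequencing_errors(r1, cfg.seq_error_rate, rng)
    r2, e2 = _sequencing_errors(r2, cfg.seq_error_rate, rng)
    prov = {"rotation": rot, "overlap": overlap, "n_seq_errors": e1 + e2}
    return r1, r2, prov


def simulate_pair(
    frag: np.ndarray, cfg: SimConfig, rng: np.random.Generator, pair_id: str = "pair0"
) -> tuple[FastqRecord, FastqRecord, dict]:
    """FASTQ record pair from one fragment (constant qualities)."""
    r1, r2, prov = simulate_pair_arrays(frag, cfg, rng)
    q = np.full(cfg.read_length, cfg.quality, dtype=np.int64)
    return (
        FastqRecord(pair_id, decode(r1), q),
        FastqRecord(pair_id, decode(r2), q.copy()),
        prov,
    )


def simulate_read_pairs(cfg: SimConfig, as_records: bool = True):
    """Yield (read1, read2, truth_row) for every pair, deterministically under the seed.

    With ``as_records=False`` the reads come as (bases, quals) array tuples
    instead of FastqRecord objects (same random stream; used by the in-memory
    pipeline at depths where object overhead matters).
    """
    ref = draw_reference(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    doubled = np.concatenate([ref.array, ref.array])
    qconst = np.full(cfg.read_length, cfg.quality, dtype=np.int64)
    for i in range(cfg.n_pairs):
        frag, fprov = simulate_fragment(cfg, ref, rng, _doubled=doubled)
        row = {"pair_id": f"pair{i}", **fprov}
        if as_records:
            r1, r2, pprov = simulate_pair(frag, cfg, rng, pair_id=f"pair{i}")
            row.update(pprov)
            yield r1, r2, row
        else:
            b1, b2, pprov = simulate_pair_arrays(frag, cfg, rng)
            row.update(pprov)
            yield (b1, qconst), (b2, qconst), row


def run_simulation(
    cfg: SimConfig, out_dir: str | Path, gzip_output: bool = False
) -> dict:
    """Write the simulated library: reads_1/2.fastq[.gz] and truth.tsv.

    The truth table records, per pair, the fragment start/length/strand, the
    applied true mutations, the damage and sequencing error counts, the
    tandem rotation and the template overlap.  Byte-identical under a fixed
    seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if gzip_output else ".fastq"
    path1 = out_dir / f"reads_1{suffix}"
    path2 = out_dir / f"reads_2{suffix}"
    rows = []
    r1s: list[FastqRecord] = []
    r2s: list[FastqRecord] = []
    for r1, r2, row in simulate_read_pairs(cfg):
        r1s.append(r1)
        r2s.append(r2)
        rows.append(row)
    write_fastq(r1s, path1)
    write_fastq(r2s, path2)
    truth = pd.DataFrame(
        rows,
        columns=[
            "pair_id",
            "start",
            "length",
            "strand",
            "mutations",
            "n_damage",
            "rotation",
            "overlap",
            "n_seq_errors",
        ],
    )
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return {
        "fastq1": path1,
        "fastq2": path2,
        "truth": truth_path,
        "reference": draw_reference(cfg),
        "n_pairs": cfg.n_pairs,
    }
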