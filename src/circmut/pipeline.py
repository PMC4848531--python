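"""One-shot composition: read pairs -> consensus -> mapping -> pileup -> analytics."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Iterable, Sequence


from . import __version__, analysis, consensus, mapping
from .consensus import ConsensusRead, pair_to_consensus
from .mapping import AlignmentHit, ReferenceIndex, as_index
from .seqio import FastqRecord, ReferenceSeq
from .simulate import SimConfig, simulate_read_pairs


@dataclass
class RunConfig:
    """Every knob of the pipeline, serialized verbatim into the run summary."""

    min_overlap: int = consensus.DEFAULT_MIN_OVERLAP
    merge_max_mismatch_rate: float = consensus.DEFAULT_MAX_MISMATCH_RATE
    period_max_mismatch_rate: float = consensus.DEFAULT_MAX_MISMATCH_RATE
    min_period: int = consensus.DEFAULT_MIN_PERIOD
    min_evidence: int = consensus.DEFAULT_MIN_EVIDENCE
    stride: int = mapping.DEFAULT_STRIDE
    max_mismatch: int = mapping.DEFAULT_MAX_MISMATCH
    min_quality: int = 1
    window: int = analysis.DEFAULT_WINDOW
    maf_bins: tuple = analysis.DEFAULT_MAF_BINS
    maf_reads: int = 1_000_000
    exclude_types: tuple = ()
    subsample_sizes: tuple = ()
    replicates: int = 3
    seed: int = 0

    def as_dict(self) -> dict:
        d = asdict(self)
        d["exclude_types"] = [f"{a}>{b}" for a, b in analysis._normalize_types(self.exclude_types)]
        return d


@dataclass
class PipelineResult:
    """Counts, rates and the pileup of one pipeline run."""

    n_pairs: int = 0
    n_consensus: int = 0
    n_mapped: int = 0
    pileup: analysis.Pileup | None = None
    consensus_reads: list = field(default_factory=list)
    hits: list = field(default_factory=list)

    @property
    def cr(self) -> float:
        return consensus.circularization_rate(self.n_consensus, self.n_pairs)

    @property
    def cmr(self) -> float:
        return mapping.cycle_mapping_rate(self.n_mapped, self.n_consensus)

    def overall_frequency(self, exclude_types: Iterable = ()) -> float:
        return analysis.overall_mutation_frequency(self.pileup, exclude_types)

    def summary(self, config: RunConfig | None = None) -> dict:
        out = {
            "version": __version__,
            "n_pairs": self.n_pairs,
            "n_consensus": self.n_consensus,
            "n_mapped": self.n_mapped,
            "cr": self.cr if self.n_pairs else None,
            "cmr": self.cmr if self.n_consensus else None,
        }
        if config is not None:
            out["config"] = config.as_dict()
            out["seed"] = config.seed
            if self.pileup is not None and self.pileup.coverage.sum() > 0:
                out["overall_frequency"] = self.overall_frequency(config.exclude_types)
                out["overall_frequency_all_types"] = self.overall_frequency()
        return out


def consensus_from_pairs(
    pairs: Iterable[tuple[FastqRecord, FastqRecord]], cfg: RunConfig | None = None
) -> tuple[list[ConsensusRead], int]:
    """Build consensus reads from raw pairs; returns (reads, n_pairs seen)."""
    cfg = cfg or RunConfig()
    out = []
    n_pairs = 0
    for r1, r2 in pairs:
        n_pairs += 1
        cs = pair_to_consensus(
            r1,
            r2,
            min_overlap=cfg.min_overlap,
            max_mismatch_rate=cfg.merge_max_mismatch_rate,
            min_period=cfg.min_period,
            min_evidence=cfg.min_evidence,
            period_max_mismatch_rate=cfg.period_max_mismatch_rate,
        )
        if cs is not None:
            out.append(cs)
    return out, n_pairs


def map_consensus_reads(
    reads: Iterable[ConsensusRead],
    ref: ReferenceSeq | ReferenceIndex,
    cfg: RunConfig | None = None,
) -> list[AlignmentHit]:
    cfg = cfg or RunConfig()
    index = as_index(ref)
    hits = []
    for cs in reads:
        hit = mapping.map_consensus(cs, index, stride=cfg.stride, max_mismatch=cfg.max_mismatch)
        if hit is not None:
            hits.append(hit)
    return hits


def run_pipeline(
    pairs: Iterable[tuple[FastqRecord, FastqRecord]],
    ref: ReferenceSeq | ReferenceIndex,
    cfg: RunConfig | None = None,
    keep_hits: bool = False,
    keep_consensus: bool = False,
) -> PipelineResult:
    """Run the full pipeline over raw read pairs, streaming into a pileup.

    ``keep_hits`` retains the AlignmentHit list (needed for MAF subsampling
    or SAM export); by default hits are folded into the pileup and dropped to
    keep memory flat at any depth.
    """
    cfg = cfg or RunConfig()
    index = as_index(ref)
    result = PipelineResult(pileup=analysis.Pileup(index.ref))
    for r1, r2 in pairs:
        result.n_pairs += 1
        cs = pair_to_consensus(
            r1,
            r2,
            min_overlap=cfg.min_overlap,
            max_mismatch_rate=cfg.merge_max_mismatch_rate,
            min_period=cfg.min_period,
            min_evidence=cfg.min_evidence,
            period_max_mismatch_rate=cfg.period_max_mismatch_rate,
        )
        if cs is None:
            continue
        result.n_consensus += 1
        if keep_consensus:
            result.consensus_reads.append(cs)
        hit = mapping.map_consensus(cs, index, stride=cfg.stride, max_mismatch=cfg.max_mismatch)
        if hit is None:
            continue
        result.n_mapped += 1
        result.pileup.add_hit(hit, cfg.min_quality)
        if keep_hits:
            result.hits.append(hit)
    return result


def run_simulated_pipeline(
    sim_cfg: SimConfig,
    cfg: RunConfig | None = None,
    keep_hits: bool = False,
    keep_consensus: bool = False,
) -> PipelineResult:
    """Simulate a library in memory and run the pipeline over it.

    Streams base arrays straight from the simulator into the consensus and
    mapping stages, so multi-million-pair runs keep flat memory and skip
    per-read object overhead; results are identical to writing FASTQ and
    running ``run_pipeline`` on it.
    """
    from .seqio import reverse_complement_arr
    from .simulate import draw_reference

    cfg = cfg or RunConfig()
    index = as_index(draw_reference(sim_cfg))
    result = PipelineResult(pileup=analysis.Pileup(index.ref))
    for (a, qa), (b2, qb2), _row in simulate_read_pairs(sim_cfg, as_records=False):
        result.n_pairs += 1
        cs = consensus.consensus_from_arrays(
            a,
            qa,
            reverse_complement_arr(b2),
            qb2[::-1],
            min_overlap=cfg.min_overlap,
            max_mismatch_rate=cfg.merge_max_mismatch_rate,
            min_period=cfg.min_period,
            min_evidence=cfg.min_evidence,
            period_max_mismatch_rate=cfg.period_max_mismatch_rate,
            source_pair_id=_row["pair_id"],
        )
        if cs is None:
            continue
        result.n_consensus += 1
        if keep_consensus:
            result.consensus_reads.append(cs)
        hit = mapping.map_consensus(cs, index, stride=cfg.stride, max_mismatch=cfg.max_mismatch)
        if hit is None:
            continue
        result.n_mapped += 1
        result.pileup.add_hit(hit, cfg.min_quality)
        if keep_hits:
            result.hits.append(hit)
    return result


def pairs_frequency_fn(ref: ReferenceSeq | ReferenceIndex, cfg: RunConfig | None = None):
    """Frequency function over a pair subset, for subsampling curves."""
    cfg = cfg or RunConfig()
    index = as_index(ref)

    def fn(pairs: Sequence) -> float:
        result = run_pipeline(pairs, index, cfg)
        return result.overall_frequency(cfg.exclude_types)

    return fn


def subsample_curve(
    pairs: Sequence[tuple[FastqRecord, FastqRecord]],
    ref: ReferenceSeq | ReferenceIndex,
    sizes: Sequence[int],
    cfg: RunConfig | None = None,
):
    """Subsampling curve of the overall frequency at several raw-base sizes."""
    cfg = cfg or RunConfig()
    return analysis.subsample_curve(
        pairs,
        sizes,
        pairs_frequency_fn(ref, cfg),
        replicates=cfg.replicates,
        seed=cfg.seed,
    )
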