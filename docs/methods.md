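# Methods

This note documents the model behind `circmut`, the numerical and design
choices that are not forced by the data formats, and what the synthetic
validation does and does not establish.

## Error model and why consensus works

A rolling-circle library presents each single-strand source molecule as
several tandem copies inside one read pair.  Three error classes behave
differently:

* **Sequencing/PCR-cycle errors** hit copies independently at rate *e* per
  base.  A consensus position passed by exactly two copies reports a wrong
  base only when both copies err identically: probability e²/3 (each errs
  with *e*; same alternative with 1/3).  With three copies the leading term
  is O(e³).  At e = 10⁻² the two-copy background is ≈ 3.3×10⁻⁵ — two to
  three orders below the raw error rate.
* **Pre-amplification damage** (e.g. sonication-induced modifications,
  biased toward C↔G transversions) alters the molecule before copying, so
  every copy agrees on the damaged base.  Consensus cannot remove it; it is
  indistinguishable from a true mutation.  The simulator models it
  separately precisely so tests can demonstrate this limit.
* **True mutations** likewise appear in all copies, with full summed
  quality.

## Consensus rules

Merging takes the *longest* suffix(read1)/prefix(rc(read2)) overlap with
mismatch fraction ≤ 0.05 (the `max_mismatch_rate` default; N bases count
neither way).  At overlapped positions the higher-quality base wins (ties →
read 1); agreeing positions get quality min(q1+q2, 93).  On perfectly
periodic templates an overlap extended by one period is equally exact, and
the longest-overlap rule then yields a shorter merged read; this costs
usable copies occasionally but never correctness (the lost positions fall
below the two-copy threshold and are masked).

Period detection compares the merged read with itself shifted by *p* and
returns the smallest p ∈ [`min_period`, len − `min_evidence`] whose mismatch
fraction is ≤ 0.05.  Defaults: `min_period` 30 (fragments are size-selected
to 60–100 nt; smaller periods are artifactual), `min_evidence` 20 (a ≥20-base
self-overlap must support the period).

Consensus position *i* collects bases at i, i+p, i+2p, … (N excluded).  The
base is the majority (ties: larger quality sum, then alphabetical); quality
is the capped sum when all copies agree and ≥2 were collected, else 0.  A
masked position therefore keeps a base (so the read still aligns) but never
enters any denominator downstream.

## Circular mapping

Rotations of the consensus read are sampled at offsets 0, s, 2s, …
(`stride` s = 5 by default, reproducing a 5× reduction of mapping work;
s = 1 is exhaustive).  Each rotation is placed on both strands of the
doubled reference by exact ungapped comparison.  Placement candidates come
from an 8-mer index: any placement with ≤ `max_mismatch` (default 3)
scoring mismatches must contain an exact seed in the read's middle region
(pigeonhole), so only candidate positions are verified; reads that are too
short for the guarantee, or contain N, fall back to scanning every
position.

**Junction mis-phasing.** With stride s > 1 the sampled rotation can miss
the true junction by up to s−1 bases, leaving up to s−1 junction-straddling
bases at each read end aligned past the fragment boundary.  Mismatches
within s−1 bases of either read end are therefore masked: excluded from the
placement score, from the reported mismatch list and from the pileup
(bounded by 2(s−1) bases per read).

**Scoring.** A placement is scored by its *effective* mismatches: base
mismatches at quality-passing (q ≥ 1) positions outside the junction zones —
exactly the evidence the pileup will use.  Scoring quality-masked
mismatches would let a mis-phased rotation tie the true phase (its junction
garbage being masked) and win on tie-break order, depositing junction bases
into the pileup as spurious high-quality mismatches; scoring on pileup
evidence eliminates this failure mode.  The minimum-score placement wins;
rotation ties break to the smallest offset, and a rotation whose minimum is
achieved at two distinct reference placements is discarded as ambiguous
(low-frequency calling cannot tolerate mis-placement).

Two consequences are accepted and quantified by simulation: (i) at stride 5
a true mutation falling in a junction zone of the chosen rotation is masked,
attenuating per-site counts by roughly 10–15%; this is well inside the
binomial confidence intervals at the depths used for validation, and
vanishes at stride 1.  (ii) A circular fragment whose boundary base repeats
in the reference (ref[start−1] = ref[start+p−1]) has two equally exact
placements one base apart; the scan returns one of them deterministically.
Both placements align every base to a correct reference position except the
single boundary base, so no spurious mismatches arise.

## Analytics conventions

* Substitutions are counted as observed on the reference forward strand; all
  12 ordered types are kept (no strand collapsing).
* Overall frequency = quality-passing mismatching bases / quality-passing
  bases.  Excluding event types (e.g. C→G and G→C, which sonication
  inflates) removes their counts from the numerator only.
* Per-type frequencies divide by the coverage of the source base
  (per-opportunity rates); zero-denominator types are reported as undefined,
  not zero.
* MAF at a variant site is the count of the most frequent non-reference
  allele over coverage; the distribution is reported over half-open bins
  [0, 10⁻⁵, 10⁻⁴, 10⁻³, 1) after seeded subsampling of mapped reads.
* C→T context analysis treats reference-G positions with G→A events as
  C→T on the minus strand, with the pyrimidine run classified on that
  strand; runs are taken on the circular sequence (mono = run length 1,
  di = 2, poly ≥ 3).
* Windows are consecutive, non-overlapping, 100 bp by default; a short final
  window is kept and flagged.
* Subsampling draws whole read pairs without replacement until the requested
  raw base count (read1+read2) is reached and reruns the full pipeline per
  replicate (3 by default).
* The t-test is the classical pooled-variance two-sample Student test,
  two-tailed.
* The supF conversion α = 1 − (1 − e_L)^(1/L) assumes independent,
  identically distributed per-base mutation; L defaults to the 95 nt supF
  marker.  Its inverse is exact to floating precision (round-trip tested to
  1e-12).
* All randomness (simulator, subsampling) flows from explicit seeds recorded
  in the run summary; reruns are bit-identical.

## Simulator: what it emulates, and what not

Fragments are uniform over the circular reference (start, length 60–100,
strand); listed mutations apply independently per covering molecule at their
stated frequency; damage applies per base at `damage_rate` before tandem
copying ("sonication" model: C/G sites flip to their partner with
probability `sonication_bias` = 0.8, else uniform; "uniform" model: any
alternative).  The tandem template starts at a uniform rotation; read 2's
template window overlaps read 1's by a uniform overlap ≥ 20; sequencing
errors are independent per read base; qualities are constant (Q30) for
determinism.

Not modeled: coverage bias (GC, amplification), chimeric RCA products,
indels (the pipeline is substitution-only by design), quality-score
miscalibration, adapter read-through.  CR/CMR in simulation (~0.94/~1.0)
are therefore upper bounds; the real-data rates reported for this kind of
library (~0.73/~0.35) reflect library artifacts the simulator deliberately
omits.  Passing the synthetic suite shows the *algorithms* are correct and
the statistical behaviour (error suppression, damage passthrough, unbiased
frequency recovery) is as derived; it does not certify performance on any
particular real library.

## Validation problem sizes

Chosen to make every check statistically informative on one CPU:

* Error suppression: 10⁵ pairs, e = 10⁻², fragment length pinned to 90 and
  template overlap to 20 so every consensus position is covered exactly
  twice; the measured background must fall within 3× of e²/3 and at least
  10× below e (~300 expected events).
* Parameter recovery: 5 kb reference, 45 sites at frequencies
  {10⁻³, 10⁻⁴, 10⁻⁵} (15 each), 2×10⁶ pairs ≈ 20,000× quality-passing
  consensus coverage, e = 10⁻³; at least 95% of sites must contain their
  true frequency in the exact (Clopper–Pearson) 99% interval of the observed
  count.  This depth makes the 10⁻⁵ decade informative (expected ~0.2
  mutant reads per site, where the exact interval still covers correctly)
  while keeping the whole suite within a practical runtime (~7 min).
* Mapper oracle: 100 random references of 70–200 bp, queries of 30–60 nt
  with up to 4 substitutions on either strand, compared against a
  plain-Python exhaustive scan for placement, mismatch count and ambiguity.
* Damage passthrough: d = 10⁻³, e = 0, stride 1 (no junction masking), the
  mismatch total must sit inside the 99.9% binomial band of d.

## Known limitations

* Substitution-only: any read requiring a gapped alignment is unmapped.
* Stride > 1 trades ~10–15% per-site sensitivity for a stride-fold mapping
  speed-up; use `--stride 1` when per-site counts matter more than time.
* One reference sequence per run; multi-chromosome input is out of scope.
* Phred offset is fixed at 33; offset-64 data must be converted upstream.
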