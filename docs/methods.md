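# Methods

## Scope

`provmap` locates provirus integration sites in a host genome from
paired-end whole-genome sequencing via split (chimeric) reads, summarises
sequencing depth, and quantifies deaminase-type hypermutation in cloned
amplicon sequences. A first-class synthetic-data generator produces inputs
with the statistical structure the analysis assumes, so every stage can be
validated against ground truth.

All internal coordinates are 0-based half-open; conversions to 1-based
happen only at I/O boundaries (SAM records, report TSVs).

## Synthetic world

The generator emulates a WGS experiment on a mouse line carrying a
single-copy GFP-tagged MLV-family provirus:

- **Genome.** Two placed chromosomes (495 kb each) and one unplaced 10 kb
  scaffold of i.i.d. uniform DNA, plus an 8 kb provirus contig whose
  terminal 600 bp are annotated as 5′/3′ UTRs. Uniform random sequence has
  no repeats, segmental duplications or endogenous retrovirus background —
  a green recovery test therefore establishes correctness of the pipeline
  logic, not robustness to repeat-rich mammalian genomes.
- **Insertions.** One heterozygous germline event and one somatic event at
  cell fraction 0.1, placed uniformly away from contig ends, each with a
  4 bp target-site duplication (typical magnitude for MLV-family
  integrases; the true value is not critical and is configurable).
  Orientation is `+` for the germline and `−` for the somatic event so both
  strands are exercised. Each event lives on its own genome copy sampled
  with probability equal to its dosage (0.5 het, 1.0 hom, cell fraction for
  somatic); events are treated as mutually exclusive within a copy, which
  is adequate at low cell fractions.
- **Reads.** Pair count = depth × host-genome length / (2 × read length),
  with fragment lengths Normal(400, 60) truncated below at the read length
  (a common short-insert PCR-free library scale). Mate 1 is the fragment
  head on a random strand, mate 2 the reverse complement of the tail.
  Substitution errors are applied i.i.d. at 1% per base, independent of the
  quality string — a simplification; real base errors correlate with
  quality. Qualities start at Phred 37 and decay linearly to a floor of 25
  with Gaussian jitter (SD 3), clipped to [2, 41]: enough 3′ degradation to
  make trimming non-trivial without modelling an instrument.
- **Clones.** Per-clone substitution counts are Poisson(rate × length) on a
  549-nt amplicon; a configurable fraction (default 0.8) of mutations is
  forced to plus-strand G→A at reference G positions, the rest are uniform
  substitutions. Defaults (5 mice, 4–8 clones each, λ = 7.3 per clone)
  match the restricted condition the generator emulates. No indels are
  simulated.
- **Randomness.** One seed fans out to named substreams (reference,
  events, reads, clones) via `SeedSequence` spawn keys, so regenerating one
  component never shifts another. Every output is byte-reproducible for a
  fixed seed.

## Trimming

The 3′ partial-sum rule with cutoff 20: S(i) = Σ_{j≥i}(q_j − 20), cut at
the minimising i (ties toward the smaller i, i.e. trim more, so the result
matches the exhaustive-search oracle deterministically), only when the
minimum is negative. Pairs with either mate shorter than 20 bp after
trimming are discarded. Adapter handling is reduced to exact-match
clipping (full occurrence, or a ≥3 bp terminal prefix of the adapter)
because the synthetic reads carry no adapters; error-tolerant adapter
alignment is out of scope.

## Split-read alignment

Design constraints: the simulated data contain substitutions only, so
segments are **ungapped** and every placement of a read is a single
(contig, strand, diagonal). This is the central simplification — it makes
scoring a vectorised array comparison and is a documented limitation for
data with indels.

- **Index.** Exact k-mer (k = 21) positions over the forward strand of the
  concatenated reference, contigs separated by padding that can never
  match (so placements cannot bridge contigs). Reverse-strand placements
  come from querying the read's reverse complement.
- **Seeding.** Two phases: first only the two terminal k-mers of each read
  (cheap; resolves ~96% of 1%-error reads), then a full strided sweep
  (every 5 bp plus the last offset) for the remainder — junction-spanning
  reads, high-error reads, and reads whose end seeds were corrupted.
  Seeds with more than 16 genomic hits are skipped as repetitive.
- **Scoring.** Match +1, mismatch −1. A placement whose mismatch rate is
  ≤ 0.05 over the whole read is accepted as a full alignment (the best
  such placement wins; ties resolved deterministically by strand then
  diagonal). Otherwise the best two-segment partition over all seeded
  placement pairs is searched: each segment ≥ 25 bp, each under the same
  mismatch-rate bound, total = prefix + suffix − 2 (the split penalty
  discourages spurious splits). If the best partition uses the same
  placement twice the read is degenerate (no genuine split) and goes
  unmapped.
- **Microhomology.** When several junction offsets are score-equal the
  largest is taken: ambiguous bases belong to the left segment. The
  standalone `resolve_microhomology` applies the same convention to
  externally produced splits and is idempotent on the aligner's output.
- **Uniqueness.** `unique` means the reported placement beats the best
  competing seeded placement by ≥ 5 score units. This is an explicit,
  testable surrogate for a read mapper's internal "uniquely mapped" flag;
  competitors are only visible if they share a seed with the read, which
  is exact for duplicated sequence and approximate for diverged repeats.
- **SAM.** Full alignments and split prefix segments are primary records;
  split suffix segments carry flag 0x800 with SA cross-reference tags.

## Integration calling

Unique splits with exactly one segment on the provirus contig are the
evidence unit. The host-side breakpoint is the reference coordinate of the
host base adjacent to the junction (last base of a prefix segment on `+`,
mirrored for suffix/`−`); with a TSD of length t the 5′- and 3′-junction
breakpoints differ by up to t, which single-linkage clustering (gap
≤ 300 bp ≈ 2 read lengths) merges into one call. Call breakpoint = lower
median of member breakpoints.

Discard rules, applied per call and kept in the output for audit:

1. `discarded_unplaced` — the host contig is an unplaced scaffold. The
   rule is applied to **all** calls, not only singletons (the stricter of
   the two possible readings; per-call status makes the alternative
   recoverable).
2. `discarded_no_utr` — a singleton whose provirus segment does not touch
   a terminal UTR; such "partial integrations" are read-through or
   recombination artefacts rather than true junctions.

"Strong evidence" is operationalised as `status == pass` with no extra
support threshold, so a genuine single junction read with UTR coverage
survives (as a somatic site must). Germline/somatic labels are *not*
assigned; the support/depth ratio is reported as an annotation and the
interpretation is left to the analyst. Support counts reads.

## Coverage

Depth at a base = number of aligned segments overlapping it (both mates,
both split segments; no deduplication, matching a PCR-free analysis).
Mean and breadth (fraction ≥ t×, default t = 4) are computed over host
contigs only — the provirus is a transgene, not part of the genome the
metric describes — with `include_provirus` available. All aligned segment
bases count, including the host side of split reads.

## Hypermutation

Clones are globally aligned to the amplicon reference by Needleman–Wunsch
(match +1, mismatch −1, gap open −4 for the first gap base, extend −1),
delegated to Biopython's `PairwiseAligner`; the tie-break among co-optimal
alignments is the library's deterministic first-ranked alignment. An
independent brute-force DP validates the scores in the tests. Substitution
columns fill a 4×4 spectrum; gap and N columns are excluded from the count
but gaps are reported separately, since chain-termination sequencing
artefacts should not inflate mutation counts. The plus-strand G→A fraction
and the base preceding each mutated G (dinucleotide context, the
APOBEC3-family preference signal) are reported per clone. Per-mouse
summaries are the mean and sample SD (n−1; 0 for a single clone) of
per-clone counts — the per-animal quantity such experiments plot.

## Numerical and degenerate-input choices

- Empty read → empty read; empty split input → empty call list; an empty
  genome or clone set raises.
- Alignment of reads at contig edges is clamped to the contig; overhang
  bases count as mismatches before clamping.
- Reads shorter than 2 × min_seg are never split; reads shorter than k go
  unmapped.
- Breakpoint median uses the lower of the two central values for even
  clusters (deterministic, biased at most 1 bp).
- The truth-recovery report matches each true site to the nearest passing
  call on the same contig.

## Limitations

- Ungapped segments: indels in real data would break both the aligner and
  the simulator's assumptions.
- Uniform random genomes understate multi-mapping; the uniqueness margin
  is exercised only by explicit duplication fixtures in the tests.
- At most two segments per split; multi-part chimeras are out of scope.
- The quality model is phenomenological (linear decay + jitter), not an
  instrument profile, and base errors are independent of quality.
- Discordant read-pair evidence is deliberately unused: calling is
  split-read only.
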