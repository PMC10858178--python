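# provmap

Split-read mapping of provirus integration sites from whole-genome
sequencing, with coverage summaries and APOBEC3 hypermutation profiling.

## The problem

When a retroviral transgene (here modelled on a GFP-tagged Moloney murine
leukemia virus provirus) is carried in a mouse line, two questions follow
directly from whole-genome sequencing of the carrier:

1. **Where is the provirus integrated?** Reads spanning an integration
   junction align as *chimeras*: the read prefix maps to a host chromosome
   and the suffix to the provirus (or vice versa). These *trans splits* are
   absent from the insertion-free genomic background, so clustered split
   evidence pinpoints both the inherited germline copy and additional
   somatic integrations (visible as low-support clusters relative to the
   sequencing depth).
2. **Is the virus being restricted by cytidine deaminases?** APOBEC3
   enzymes deaminate cytidine on the proviral minus strand, which appears
   as an excess of plus-strand G→A substitutions in cloned and sequenced
   amplicons of the provirus. Counting substitutions per clone and
   summarising per animal quantifies that restriction.

`provmap` implements the full desk-side pipeline for both analyses —
quality trimming, split-read alignment, the artefact discard rules,
breakpoint clustering, depth/breadth summaries, and clone mutation
spectra — plus a synthetic-data generator that emulates the sequencing
design, so every stage is testable against ground truth.

## Method sketch

- **Trimming.** Standard 3′ partial-sum rule: for cutoff *c* and suffix
  sums S(i) = Σ_{j≥i} (q_j − c), cut at the i\* minimising S(i) when
  S(i\*) < 0 (ties trim more). Pairs with a mate < 20 bp are discarded.
- **Split alignment.** Exact k-mer seeds (k = 21) grouped per
  (contig, strand, diagonal); segments are ungapped, so scoring a
  placement is a vectorised profile comparison. A read is *full* when one
  placement covers it with mismatch rate ≤ 0.05; otherwise the best
  prefix+suffix partition (segments ≥ 25 bp, match +1 / mismatch −1,
  split penalty −2) is reported as a split. Microhomology at the junction
  is absorbed by the left segment; a placement is *unique* when it beats
  the best competitor by ≥ 5 score units.
- **Integration calling.** Unique splits joining the provirus and a host
  contig are clustered per contig by single linkage on the host-side
  breakpoint (gap ≤ 300 bp). A call is discarded when it lies on an
  unplaced scaffold, or when it is a singleton whose provirus segment does
  not cover a terminal UTR (likely partial-integration artefact); all
  discards stay in the output with their status.
- **Coverage.** Per-base depth from every aligned segment; mean depth and
  breadth (fraction of host bases ≥ t×, default t = 4) over the host
  genome.
- **Hypermutation.** Each clone is globally aligned to the 549-nt amplicon
  reference (Needleman–Wunsch, +1/−1, gap open −4 / extend −1);
  substitutions fill a 4×4 spectrum with the G→A fraction and dinucleotide
  context reported, and per-mouse mean ± SD of per-clone counts.

## Worked example

`examples/01_simulate_and_call.py` simulates a 200 kb host genome carrying
one heterozygous germline insertion and one somatic insertion at 10% cell
fraction (30×, 2×150 bp, 1% base errors), then runs the full chain:

```
simulated 20000 read pairs from 3 haplotypes
trimming kept 20000/20000 pairs
26 unique trans splits (host x provirus chimeras)

calls (contig, breakpoint, support, status) vs simulated truth:
  chr1:61289  support=23  pass
  chr2:46024  support=3  pass
  truth: germline_het at chr1:61286 (cf=0.5)
  truth: somatic at chr2:46024 (cf=0.1)
```

The germline site is recovered within the 4-bp target-site duplication
with support ≈ half the depth (heterozygous); the somatic site shows the
low support expected at a 10% cell fraction. The other example scripts
demonstrate trimming, a single chimeric alignment, coverage summaries and
the clone mutation analysis, each printing what the numbers mean.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computation from scratch on the default
simulated world (1 Mb host genome incl. an unplaced scaffold, 8 kb
provirus, germline + somatic insertion, 30×): simulation, trimming,
split alignment, integration calling with truth comparison, coverage
summary, and the amplicon-clone hypermutation analysis, printing a short
summary and writing the results JSON to `--out`.

## Layout

- `src/provmap/simulate.py` — synthetic references, insertions (with TSD),
  paired-end reads, amplicon clones, truth tables
- `src/provmap/qc.py` — quality trimming and pair filtering
- `src/provmap/align.py` — k-mer index and split-read aligner, SAM output
- `src/provmap/calls.py` — trans-split extraction, clustering, discard rules
- `src/provmap/coverage.py` — depth and breadth summaries
- `src/provmap/hypermut.py` — clone alignment and mutation spectra
- `src/provmap/pipeline.py` — file-based stages and `run_all` with manifest
- `docs/methods.md` — model, parameters, and design notes
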