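"""Synthetic sequencing data with the structure assumed by the integration caller.

The generator emulates the design of a whole-genome study of a GFP-tagged
murine-leukemia-virus provirus carried in the mouse germline: a small
multi-contig host genome with placed chromosomes and at least one unplaced
scaffold, a single-copy heterozygous germline provirus insertion plus one
low-cell-fraction somatic insertion (each flanked by a target-site
duplication), ~30x 2x150 bp paired-end reads with base-call errors and
3'-decaying quality strings, and sets of 549-nt amplicon clones carrying
deaminase-type plus-strand G->A mutations.

All coordinates are 0-based half-open.  A single top-level seed fans out to
per-component substreams (reference, events, reads, clones) so that the
output of one component does not depend on whether another was generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from . import dna

_STREAMS = {"reference": 0, "events": 1, "reads": 2, "clones": 3}

MODES = ("germline_het", "germline_hom", "somatic")


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, order-insensitive RNG substream for one generator component."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[name],))
    )


# ---------------------------------------------------------------------------
# domain types


@dataclass(slots=True)
class Contig:
    name: str
    sequence: str
    placed: bool = True
    is_provirus: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("contig name must be non-empty")
        if not self.sequence:
            raise ValueError(f"contig {self.name!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, slots=True)
class ProvirusAnnotation:
    """Terminal UTR intervals of the provirus contig, 0-based half-open."""

    utr5: tuple[int, int]
    utr3: tuple[int, int]

    def validate(self, provirus_len: int) -> None:
        u5, u3 = self.utr5, self.utr3
        if u5[0] != 0:
            raise ValueError("utr5 must start at position 0")
        if u3[1] != provirus_len:
            raise ValueError("utr3 must end at the provirus length")
        if u5[1] - u5[0] < 1 or u3[1] - u3[0] < 1:
            raise ValueError("UTR intervals must each span at least 1 bp")
        if u5[1] > u3[0]:
            raise ValueError("UTR intervals must not overlap")

    def overlaps_utr(self, start: int, end: int) -> bool:
        """True if [start, end) overlaps either terminal UTR."""
        return (start < self.utr5[1] and end > self.utr5[0]) or (
            start < self.utr3[1] and end > self.utr3[0]
        )


@dataclass
class ReferenceSet:
    """Host contigs plus (optionally) one provirus contig with UTR annotation."""

    contigs: list[Contig]
    provirus_annotation: ProvirusAnnotation | None = None

    def __post_init__(self) -> None:
        names = [c.name for c in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("contig names must be unique")
        pro = [c for c in self.contigs if c.is_provirus]
        if len(pro) > 1:
            raise ValueError("at most one provirus contig allowed")
        if pro and self.provirus_annotation is not None:
            self.provirus_annotation.validate(len(pro[0]))

    @property
    def provirus(self) -> Contig | None:
        for c in self.contigs:
            if c.is_provirus:
                return c
        return None

    @property
    def host_contigs(self) -> list[Contig]:
        return [c for c in self.contigs if not c.is_provirus]

    @property
    def host_length(self) -> int:
        return sum(len(c) for c in self.host_contigs)

    def get(self, name: str) -> Contig:
        for c in self.contigs:
            if c.name == name:
                return c
        raise KeyError(name)

    def is_placed(self, name: str) -> bool:
        return self.get(name).placed


@dataclass(frozen=True, slots=True)
class InsertionEvent:
    """Ground-truth integration; insertion occurs before ``position``.

    ``cell_fraction`` is the effective haplotype dosage: 1.0 for a homozygous
    germline insertion, 0.5 for heterozygous, and the carrying cell fraction
    for a somatic event (the carrier haplotype is sampled with this
    probability when reads are drawn).
    """

    host_contig: str
    position: int
    orientation: str = "+"
    tsd_len: int = 4
    mode: str = "germline_het"
    cell_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown insertion mode {self.mode!r}")
        if self.orientation not in "+-":
            raise ValueError("orientation must be '+' or '-'")
        if self.tsd_len < 0:
            raise ValueError("tsd_len must be >= 0")
        if self.mode == "germline_hom" and self.cell_fraction != 1.0:
            raise ValueError("germline_hom requires cell_fraction 1.0")
        if self.mode == "germline_het" and self.cell_fraction != 0.5:
            raise ValueError("germline_het requires cell_fraction 0.5")
        if not (0 < self.cell_fraction <= 1):
            raise ValueError("cell_fraction must be in (0, 1]")


@dataclass(slots=True)
class ReadPair:
    id: str
    seq1: str
    seq2: str
    qual1: np.ndarray
    qual2: np.ndarray
    truth_origin: tuple | None = None

    def __post_init__(self) -> None:
        for seq, qual in ((self.seq1, self.qual1), (self.seq2, self.qual2)):
            if len(seq) != len(qual):
                raise ValueError("sequence and quality lengths differ")
            q = np.asarray(qual)
            if len(q) and (q.min() < 0 or q.max() > 41):
                raise ValueError("Phred scores must lie in [0, 41]")


@dataclass(frozen=True)
class CloneConfig:
    """Amplicon clone-set parameters.

    Defaults emulate the restricted (human-APOBEC3-carrying) condition of the
    study design: five mice, four to eight sequenced clones each, a 549-nt
    amplicon, and a per-base substitution rate whose per-clone expectation is
    7.3 -- the magnitude reported for that condition.  ``ga_signature`` is the
    fraction of mutations forced to plus-strand G->A.
    """

    n_mice: int = 5
    clones_per_mouse: tuple[int, int] | int = (4, 8)
    amplicon_len: int = 549
    rate: float = 7.3 / 549
    ga_signature: float = 0.8

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("mutation rate must be >= 0")
        if not (0 <= self.ga_signature <= 1):
            raise ValueError("ga_signature must be in [0, 1]")
        if self.amplicon_len < 1 or self.n_mice < 1:
            raise ValueError("amplicon_len and n_mice must be positive")


@dataclass
class SimulationConfig:
    """Stated world of the default simulation.

    One megabase of host sequence (two 495-kb placed chromosomes plus one
    10-kb unplaced scaffold), an 8-kb provirus with 600-bp terminal UTRs,
    2x150 bp pairs at 30x with 1% base errors, a 4-bp target-site
    duplication, and one heterozygous germline plus one 10%-cell-fraction
    somatic insertion.
    """

    seed: int = 0
    placed_lengths: tuple[int, ...] = (495_000, 495_000)
    unplaced_lengths: tuple[int, ...] = (10_000,)
    provirus_len: int = 8_000
    utr_len: int = 600
    provirus_name: str = "provirus"
    read_len: int = 150
    frag_mean: float = 400.0
    frag_sd: float = 60.0
    depth: float = 30.0
    base_error_rate: float = 0.01
    qual_start: int = 37
    qual_floor: int = 25
    qual_jitter_sd: float = 3.0
    tsd_len: int = 4
    somatic_cell_fraction: float = 0.1
    events: list[InsertionEvent] | None = None
    clones: CloneConfig = field(default_factory=CloneConfig)

    def __post_init__(self) -> None:
        lengths = (*self.placed_lengths, *self.unplaced_lengths, self.provirus_len)
        if any(n <= 0 for n in lengths):
            raise ValueError("all contig lengths must be positive")
        if self.utr_len < 1 or 2 * self.utr_len > self.provirus_len:
            raise ValueError("utr_len must be >= 1 and fit twice in the provirus")
        if self.read_len < 1:
            raise ValueError("read_len must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not (0 <= self.base_error_rate < 1):
            raise ValueError("base_error_rate must be in [0, 1)")
        if self.tsd_len < 0:
            raise ValueError("tsd_len must be >= 0")


@dataclass
class Haplotype:
    """One full genome copy (contig name -> sequence) with a sampling weight."""

    name: str
    sequences: dict[str, str]
    weight: float

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


# ---------------------------------------------------------------------------
# reference and haplotype construction


def build_reference(config: SimulationConfig) -> ReferenceSet:
    """Random host contigs + provirus contig, deterministic for a given seed."""
    rng = substream(config.seed, "reference")
    contigs: list[Contig] = []
    for i, n in enumerate(config.placed_lengths, start=1):
        contigs.append(Contig(f"chr{i}", dna.random_dna(rng, n), placed=True))
    for i, n in enumerate(config.unplaced_lengths, start=1):
        contigs.append(Contig(f"scaffold_un{i}", dna.random_dna(rng, n), placed=False))
    contigs.append(
        Contig(
            config.provirus_name,
            dna.random_dna(rng, config.provirus_len),
            placed=False,
            is_provirus=True,
        )
    )
    ann = ProvirusAnnotation(
        utr5=(0, config.utr_len),
        utr3=(config.provirus_len - config.utr_len, config.provirus_len),
    )
    return ReferenceSet(contigs, ann)


def default_events(config: SimulationConfig, refset: ReferenceSet) -> list[InsertionEvent]:
    """One heterozygous germline insertion and one somatic insertion.

    Positions are drawn (from the 'events' substream) uniformly on the first
    two placed chromosomes, keeping a margin from contig ends so every
    junction is reachable by whole fragments.
    """
    rng = substream(config.seed, "events")
    placed = [c for c in refset.host_contigs if c.placed]
    if not placed:
        raise ValueError("no placed contigs to insert into")
    margin = min(10_000, max(len(placed[0]) // 10, config.read_len))
    c1 = placed[0]
    c2 = placed[1] if len(placed) > 1 else placed[0]
    pos1 = int(rng.integers(margin, len(c1) - margin))
    pos2 = int(rng.integers(margin, len(c2) - margin))
    return [
        InsertionEvent(c1.name, pos1, "+", config.tsd_len, "germline_het", 0.5),
        InsertionEvent(
            c2.name, pos2, "-", config.tsd_len, "somatic", config.somatic_cell_fraction
        ),
    ]


def insert_provirus(host: Contig | str, provirus: Contig | str, event: InsertionEvent) -> str:
    """Carrier haplotype sequence for one insertion.

    The provirus (reverse-complemented for orientation '-') is placed before
    ``event.position`` with the host bases [position, position + tsd_len)
    duplicated on both sides, as retroviral integration leaves them.
    """
    h = host.sequence if isinstance(host, Contig) else host
    p = provirus.sequence if isinstance(provirus, Contig) else provirus
    pos, tsd = event.position, event.tsd_len
    if not (0 <= pos and pos + tsd <= len(h)):
        raise ValueError(f"insertion position {pos} (+{tsd} bp TSD) outside host contig")
    ins = p if event.orientation == "+" else dna.revcomp(p)
    return h[: pos + tsd] + ins + h[pos:]


def build_haplotypes(
    refset: ReferenceSet, events: Sequence[InsertionEvent]
) -> list[Haplotype]:
    """Reference haplotype plus one carrier haplotype per insertion event.

    Each event is represented on its own genome copy sampled with probability
    ``cell_fraction`` (0.5 for heterozygous germline, 1.0 for homozygous);
    the residual weight is the insertion-free reference genome.  Events are
    therefore treated as mutually exclusive within a genome copy, adequate
    for the low cell fractions simulated here.
    """
    pro = refset.provirus
    if pro is None:
        raise ValueError("reference set has no provirus contig")
    base = {c.name: c.sequence for c in refset.host_contigs}
    haps: list[Haplotype] = []
    total_w = 0.0
    for ev in events:
        if ev.host_contig not in base:
            raise KeyError(f"event contig {ev.host_contig!r} not in reference")
        seqs = dict(base)
        seqs[ev.host_contig] = insert_provirus(base[ev.host_contig], pro.sequence, ev)
        haps.append(
            Haplotype(f"hap_{ev.mode}_{ev.host_contig}_{ev.position}", seqs, ev.cell_fraction)
        )
        total_w += ev.cell_fraction
    if total_w > 1 + 1e-9:
        raise ValueError("event cell fractions sum to more than 1")
    if total_w < 1 - 1e-9:
        haps.insert(0, Haplotype("hap_reference", base, 1.0 - total_w))
    return haps


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class ReadBatch:
    """Column-wise store of read pairs (uint8 base codes, padded with 4)."""

    ids: list[str]
    seq1: np.ndarray
    qual1: np.ndarray
    len1: np.ndarray
    seq2: np.ndarray
    qual2: np.ndarray
    len2: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ids)

    def pairs(self) -> Iterator[ReadPair]:
        for i in range(self.n):
            l1, l2 = int(self.len1[i]), int(self.len2[i])
            yield ReadPair(
                self.ids[i],
                dna.decode(self.seq1[i, :l1]),
                dna.decode(self.seq2[i, :l2]),
                self.qual1[i, :l1].astype(np.int16),
                self.qual2[i, :l2].astype(np.int16),
            )

    @classmethod
    def from_pairs(cls, pairs: Sequence[ReadPair]) -> "ReadBatch":
        n = len(pairs)
        width = max((max(len(p.seq1), len(p.seq2)) for p in pairs), default=0)
        seq1 = np.full((n, width), dna.N, dtype=np.uint8)
        seq2 = np.full((n, width), dna.N, dtype=np.uint8)
        qual1 = np.zeros((n, width), dtype=np.uint8)
        qual2 = np.zeros((n, width), dtype=np.uint8)
        len1 = np.zeros(n, dtype=np.int64)
        len2 = np.zeros(n, dtype=np.int64)
        ids = []
        for i, p in enumerate(pairs):
            ids.append(p.id)
            len1[i], len2[i] = len(p.seq1), len(p.seq2)
            seq1[i, : len1[i]] = dna.encode(p.seq1)
            seq2[i, : len2[i]] = dna.encode(p.seq2)
            qual1[i, : len1[i]] = np.asarray(p.qual1, dtype=np.uint8)
            qual2[i, : len2[i]] = np.asarray(p.qual2, dtype=np.uint8)
        return cls(ids, seq1, qual1, len1, seq2, qual2, len2)


def _quality_matrix(
    rng: np.random.Generator, n: int, read_len: int, config: SimulationConfig
) -> np.ndarray:
    """Phred profile: linear decay from qual_start to qual_floor + jitter."""
    pos = np.arange(read_len)
    slope = (config.qual_start - config.qual_floor) / max(read_len - 1, 1)
    base = config.qual_start - slope * pos
    jitter = rng.normal(0.0, config.qual_jitter_sd, size=(n, read_len))
    return np.clip(np.rint(base[None, :] + jitter), 2, 41).astype(np.uint8)


def simulate_reads(
    haplotypes: Sequence[Haplotype],
    config: SimulationConfig,
    genome_length: int | None = None,
) -> tuple[ReadBatch, pd.DataFrame]:
    """Paired-end reads from a weighted haplotype mixture, plus a truth table.

    The expected pair count is depth * genome_length / (2 * read_len);
    fragment lengths are normal(frag_mean, frag_sd) truncated below at the
    read length, mate 2 is the reverse complement of the fragment tail, and
    substitution errors are applied uniformly at ``base_error_rate``.
    The truth table records, per read id, the source haplotype, contig,
    fragment interval (haplotype coordinates) and fragment strand.
    """
    if not haplotypes:
        raise ValueError("need at least one haplotype")
    weights = np.array([h.weight for h in haplotypes], dtype=float)
    if weights.min() < 0 or abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError("haplotype weights must be non-negative and sum to 1")
    if config.depth <= 0:
        raise ValueError("depth must be > 0")
    rng = substream(config.seed, "reads")
    R = config.read_len
    if genome_length is None:
        genome_length = int(round(sum(h.total_length * h.weight for h in haplotypes)))
    n_pairs = int(round(config.depth * genome_length / (2 * R)))

    hap_idx = rng.choice(len(haplotypes), size=n_pairs, p=weights)
    seq1 = np.empty((n_pairs, R), dtype=np.uint8)
    seq2 = np.empty((n_pairs, R), dtype=np.uint8)
    truth_hap = np.empty(n_pairs, dtype=object)
    truth_contig = np.empty(n_pairs, dtype=object)
    truth_start = np.zeros(n_pairs, dtype=np.int64)
    truth_end = np.zeros(n_pairs, dtype=np.int64)
    truth_strand = np.empty(n_pairs, dtype=object)
    ar = np.arange(R)

    for hi, hap in enumerate(haplotypes):
        sel = np.flatnonzero(hap_idx == hi)
        if sel.size == 0:
            continue
        names = list(hap.sequences)
        lens = np.array([len(hap.sequences[nm]) for nm in names], dtype=float)
        contig_idx = rng.choice(len(names), size=sel.size, p=lens / lens.sum())
        for ci, nm in enumerate(names):
            rows = sel[contig_idx == ci]
            if rows.size == 0:
                continue
            enc = dna.encode(hap.sequences[nm])
            clen = len(enc)
            flen = np.rint(rng.normal(config.frag_mean, config.frag_sd, rows.size))
            flen = np.clip(flen, R, clen).astype(np.int64)
            span = (clen - flen + 1).astype(np.float64)
            start = (rng.random(rows.size) * span).astype(np.int64)
            flip = rng.integers(0, 2, rows.size).astype(bool)
            left = enc[start[:, None] + ar]
            right = enc[(start + flen - R)[:, None] + ar]
            rc_right = 3 - right[:, ::-1]
            seq1[rows] = np.where(flip[:, None], rc_right, left)
            seq2[rows] = np.where(flip[:, None], left, rc_right)
            truth_hap[rows] = hap.name
            truth_contig[rows] = nm
            truth_start[rows] = start
            truth_end[rows] = start + flen
            truth_strand[rows] = np.where(flip, "-", "+")

    if config.base_error_rate > 0:
        for seq in (seq1, seq2):
            mask = rng.random(seq.shape) < config.base_error_rate
            shift = rng.integers(1, 4, size=seq.shape, dtype=np.uint8)
            seq[mask] = (seq[mask] + shift[mask]) % 4

    qual1 = _quality_matrix(rng, n_pairs, R, config)
    qual2 = _quality_matrix(rng, n_pairs, R, config)
    ids = [f"r{i:07d}" for i in range(n_pairs)]
    lens_full = np.full(n_pairs, R, dtype=np.int64)
    batch = ReadBatch(ids, seq1, qual1, lens_full, seq2, qual2, lens_full.copy())
    truth = pd.DataFrame(
        {
            "read_id": ids,
            "haplotype": truth_hap,
            "contig": truth_contig,
            "start": truth_start,
            "end": truth_end,
            "strand": truth_strand,
        }
    )
    return batch, truth


# ---------------------------------------------------------------------------
# amplicon clones


def random_amplicon(config: CloneConfig, rng: np.random.Generator) -> str:
    return dna.random_dna(rng, config.amplicon_len)


def simulate_clones(
    amplicon_ref: str,
    config: CloneConfig,
    rng: np.random.Generator,
) -> tuple[list[tuple[str, str]], dict[str, list[tuple[int, str, str]]]]:
    """Mutated amplicon clones per mouse, with per-clone truth mutation lists.

    Per-clone substitution counts are Poisson(rate * length); a fraction
    ``ga_signature`` of the mutations is forced to plus-strand G->A at
    reference G positions (the cytidine-deaminase footprint on the coding
    strand), the remainder are uniform substitutions at uniform positions.
    No indels are introduced.

    Returns ``(clones, truth)`` where clones are ``(clone_id, sequence)`` with
    ids of the form ``mouse<M>_clone<K>``, and truth maps clone id to sorted
    ``(position, ref_base, alt_base)`` triples.
    """
    if config.rate < 0:
        raise ValueError("mutation rate must be >= 0")
    if not amplicon_ref:
        raise ValueError("amplicon reference must be non-empty")
    L = len(amplicon_ref)
    ref = np.frombuffer(amplicon_ref.encode("ascii"), dtype="S1")
    g_positions = np.flatnonzero(ref == b"G")
    clones: list[tuple[str, str]] = []
    truth: dict[str, list[tuple[int, str, str]]] = {}
    others = "ACGT"
    for m in range(1, config.n_mice + 1):
        if isinstance(config.clones_per_mouse, int):
            n_clones = config.clones_per_mouse
        else:
            lo, hi = config.clones_per_mouse
            n_clones = int(rng.integers(lo, hi + 1))
        for k in range(1, n_clones + 1):
            clone_id = f"mouse{m}_clone{k}"
            n_mut = int(rng.poisson(config.rate * L))
            n_mut = min(n_mut, L)
            n_ga = int(rng.binomial(n_mut, config.ga_signature)) if n_mut else 0
            n_ga = min(n_ga, g_positions.size)
            muts: dict[int, tuple[str, str]] = {}
            if n_ga:
                for p in rng.choice(g_positions, size=n_ga, replace=False):
                    muts[int(p)] = ("G", "A")
            remaining = n_mut - n_ga
            while remaining > 0:
                p = int(rng.integers(0, L))
                if p in muts:
                    continue
                refb = amplicon_ref[p]
                alt = [b for b in others if b != refb][int(rng.integers(0, 3))]
                muts[p] = (refb, alt)
                remaining -= 1
            seq = list(amplicon_ref)
            for p, (_, alt) in muts.items():
                seq[p] = alt
            clones.append((clone_id, "".join(seq)))
            truth[clone_id] = sorted((p, r, a) for p, (r, a) in muts.items())
    return clones, truth
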