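"""Split-read aligner: k-mer index, full/split calls, oracle equivalence, SAM."""

import numpy as np
import pysam
import pytest

from provmap import dna
from provmap.align import (
    AlignParams,
    KmerIndex,
    SegmentAlignment,
    SplitAlignment,
    align_read,
    resolve_microhomology,
    write_sam,
)
from provmap.simulate import Contig, ProvirusAnnotation, ReferenceSet

PARAMS = AlignParams(seed_stride=1)  # exhaustive seeding for oracle tests


@pytest.fixture(scope="module")
def genome():
    """Two host contigs + provirus, 25 kb total: small enough for brute force."""
    r = np.random.default_rng(99)
    contigs = [
        Contig("chr1", dna.random_dna(r, 10_000)),
        Contig("chr2", dna.random_dna(r, 10_000)),
        Contig("provirus", dna.random_dna(r, 5_000), placed=False, is_provirus=True),
    ]
    return ReferenceSet(contigs, ProvirusAnnotation((0, 400), (4600, 5000)))


@pytest.fixture(scope="module")
def index(genome):
    return KmerIndex(genome, k=21)


from tests_oracles import oracle_best  # brute-force all-placement scan


class TestKmerIndex:
    def test_lookup_enumeration(self):
        refset = ReferenceSet([Contig("c", "ACGTACGT")])
        idx = KmerIndex(refset, k=4)
        assert idx.lookup("ACGT") == [("c", 0), ("c", 4)]
        assert idx.lookup("GTAC") == [("c", 2)]

    def test_absent_kmer_empty(self):
        idx = KmerIndex(ReferenceSet([Contig("c", "AAAAAAAA")]), k=4)
        assert idx.lookup("ACGT") == []

    def test_rebuild_identical(self, genome):
        a = KmerIndex(genome, k=15)
        b = KmerIndex(genome, k=15)
        for kmer in ("ACGTTGCAACGTTGC", genome.contigs[0].sequence[100:115]):
            assert a.lookup(kmer) == b.lookup(kmer)

    def test_k_longer_than_contig_errors(self):
        with pytest.raises(ValueError):
            KmerIndex(ReferenceSet([Contig("c", "ACGT")]), k=8)


class TestFullAlignment:
    def test_identity_read(self, genome, index):
        read = genome.contigs[0].sequence[4000:4150]
        res = align_read(read, index, PARAMS)
        assert res.kind == "full"
        assert (res.full.contig, res.full.ref_start, res.full.ref_end) == ("chr1", 4000, 4150)
        assert res.full.mismatches == 0 and res.full.strand == "+"
        assert res.unique and res.score == 150

    def test_reverse_strand_mirrored(self, genome, index):
        read = genome.contigs[1].sequence[2000:2150]
        fwd = align_read(read, index, PARAMS)
        rev = align_read(dna.revcomp(read), index, PARAMS)
        assert rev.kind == "full" and fwd.kind == "full"
        assert (rev.full.contig, rev.full.ref_start, rev.full.ref_end) == (
            fwd.full.contig,
            fwd.full.ref_start,
            fwd.full.ref_end,
        )
        assert {fwd.full.strand, rev.full.strand} == {"+", "-"}
        assert rev.score == fwd.score

    def test_random_read_unmapped(self, index):
        r = np.random.default_rng(5)
        res = align_read(dna.random_dna(r, 150), index, PARAMS)
        assert res.kind == "unmapped"

    def test_duplicated_region_not_unique(self):
        r = np.random.default_rng(17)
        block = dna.random_dna(r, 600)
        refset = ReferenceSet(
            [
                Contig("c1", dna.random_dna(r, 2000) + block + dna.random_dna(r, 2000)),
                Contig("c2", dna.random_dna(r, 2000) + block + dna.random_dna(r, 2000)),
            ]
        )
        idx = KmerIndex(refset, 21)
        res = align_read(block[200:350], idx, PARAMS)
        assert res.kind == "full"
        assert not res.unique
        assert res.secondary_score == res.score


class TestSplitAlignment:
    def test_constructed_chimera(self, genome, index):
        host = genome.contigs[0].sequence
        pro = genome.provirus.sequence
        # pick a provirus start with no junction microhomology so the
        # constructed junction is the unambiguous optimum
        q = next(q for q in range(2500, 2600) if pro[q] != host[3060])
        read = host[3000:3060] + pro[q : q + 90]
        res = align_read(read, index, PARAMS)
        assert res.kind == "split"
        sp = res.split
        assert sp.junction_offset == 60
        assert (sp.seg_a.contig, sp.seg_a.ref_start, sp.seg_a.ref_end) == ("chr1", 3000, 3060)
        assert (sp.seg_b.contig, sp.seg_b.ref_start, sp.seg_b.ref_end) == (
            "provirus",
            q,
            q + 90,
        )
        assert res.unique

    def test_chimera_with_minimum_flanks(self, genome, index):
        host = genome.contigs[1].sequence
        pro = genome.provirus.sequence
        read = host[5000:5025] + pro[100:225]  # 25 bp flank, the minimum
        res = align_read(read, index, PARAMS)
        assert res.kind == "split"
        assert res.split.seg_a.contig == "chr2"
        assert res.split.seg_b.contig == "provirus"

    def test_short_flank_not_split(self, genome, index):
        # a flank below min_seg cannot form a segment: a 4 bp flank is
        # absorbed as end mismatches of a full provirus alignment, while a
        # 20 bp flank pushes the mismatch rate over the gate and, with no
        # valid partition, the read goes unmapped
        host = genome.contigs[0].sequence
        pro = genome.provirus.sequence
        res4 = align_read(host[7000:7004] + pro[3000:3146], index, PARAMS)
        assert res4.kind == "full"
        assert res4.full.contig == "provirus"
        res20 = align_read(host[7000:7020] + pro[3000:3130], index, PARAMS)
        assert res20.kind == "unmapped"

    def test_score_matches_brute_force(self, genome, index):
        r = np.random.default_rng(31)
        params = PARAMS
        reads = []
        host1 = genome.contigs[0].sequence
        pro = genome.provirus.sequence
        for _ in range(12):  # error-free and lightly mutated full reads
            p = int(r.integers(0, len(host1) - 150))
            read = list(host1[p : p + 150])
            for _ in range(int(r.integers(0, 3))):
                q = int(r.integers(0, 150))
                read[q] = "ACGT"[int(r.integers(0, 4))]
            reads.append("".join(read))
        for _ in range(8):  # chimeras with both flanks >= min_seg
            j = int(r.integers(30, 120))
            p = int(r.integers(0, len(host1) - 150))
            q = int(r.integers(0, len(pro) - 150))
            reads.append(host1[p : p + j] + pro[q : q + 150 - j])
        for read in reads:
            res = align_read(read, index, params)
            best_full, best_split = oracle_best(genome, read, params)
            if res.kind == "full":
                assert best_full is not None
                assert res.score == best_full
            elif res.kind == "split":
                assert best_full is None  # no single placement passed the rate gate
                assert res.score == best_split

    def test_junction_exact_for_error_free_flanks(self, genome, index):
        # every error-free junction-spanning read with both flanks >= 25 bp
        # must give a trans split at the exact junction (sites chosen with no
        # microhomology so "exact" is well defined)
        host = genome.contigs[0].sequence
        pro = genome.provirus.sequence
        r = np.random.default_rng(77)
        tested = 0
        while tested < 15:
            j = int(r.integers(25, 126))
            p = int(r.integers(0, len(host) - 150))
            q = int(r.integers(0, len(pro) - 150))
            if host[p + j] == pro[q]:  # would create junction ambiguity
                continue
            read = host[p : p + j] + pro[q : q + 150 - j]
            res = align_read(read, index, PARAMS)
            assert res.kind == "split", f"flank {j} not split"
            assert res.split.junction_offset == j
            assert res.split.seg_a.ref_start == p
            assert res.split.seg_b.ref_start == q
            tested += 1


class TestMicrohomology:
    def test_overlap_absorbed_by_seg_a(self):
        # junction flanked by 3 bases ("TGA") identical at both loci; the
        # bases after the homology differ on each side so the ambiguity is
        # exactly 3 bp
        r = np.random.default_rng(3)
        host = dna.random_dna(r, 2997) + "TGA" + "GGG" + dna.random_dna(r, 500)
        pro = "TGA" + "CCT" + dna.random_dna(r, 3000)
        refset = ReferenceSet(
            [Contig("chr1", host), Contig("provirus", pro, placed=False, is_provirus=True)],
            ProvirusAnnotation((0, 300), (len(pro) - 300, len(pro))),
        )
        idx = KmerIndex(refset, 21)
        # 60 host bases (ending in the homology copy) + provirus after its copy
        read = host[2943:3003] + pro[3:93]
        res = align_read(read, idx, PARAMS)
        assert res.kind == "split"
        # junctions 57..60 are score-equal; the ambiguous bases go to seg_a
        assert res.split.junction_offset == 60
        assert res.split.seg_a.ref_end == 3003
        assert res.split.seg_b.ref_start == 3

    def test_resolver_no_overlap_unchanged(self, genome):
        host = genome.contigs[0].sequence
        pro = genome.provirus.sequence
        j, p = 60, 3000
        q = next(q for q in range(2500, 2600) if pro[q] != host[p + j])
        split = SplitAlignment(
            "r",
            SegmentAlignment("chr1", p, p + j, "+", 0, j, 0),
            SegmentAlignment("provirus", q, q + 90, "+", j, 150, 0),
            j,
            148,
            True,
        )
        read = host[p : p + j] + pro[q : q + 90]
        out = resolve_microhomology(split, read, genome)
        assert out.junction_offset == j

    def test_resolver_shifts_through_homology(self, genome):
        host = genome.contigs[0].sequence
        pro = genome.provirus.sequence
        # engineer: present the same split but with the junction reported 3
        # bases early even though read continues to match both loci
        p, q = 3000, 2500
        read = host[p : p + 60] + pro[q + 3 : q + 90]
        # pretend seg_a stopped at 57 and seg_b covers host-identical bases
        split = SplitAlignment(
            "r",
            SegmentAlignment("chr1", p, p + 57, "+", 0, 57, 0),
            SegmentAlignment("chr1", p + 57, p + 147, "+", 57, 147, 0),
            57,
            145,
            True,
        )
        out = resolve_microhomology(split, read[:147], genome)
        assert out.junction_offset >= 57  # advances only through matches


class TestSam:
    def test_full_and_split_records(self, genome, index, tmp_path):
        host = genome.contigs[0].sequence
        pro = genome.provirus.sequence
        full_read = host[1000:1150]
        q = next(q for q in range(2500, 2600) if pro[q] != host[3060])
        chim_read = host[3000:3060] + pro[q : q + 90]
        results = [
            align_read(full_read, index, PARAMS, read_id="full1"),
            align_read(chim_read, index, PARAMS, read_id="chim1"),
        ]
        path = tmp_path / "out.sam"
        write_sam(results, genome, path, reads={"full1": full_read, "chim1": chim_read})
        recs = list(pysam.AlignmentFile(str(path), "r"))
        assert len(recs) == 3
        flags = sorted(r.flag for r in recs)
        assert sum(1 for r in recs if r.flag & 2048) == 1
        full_rec = next(r for r in recs if r.query_name == "full1")
        assert full_rec.reference_start == 1000  # pysam returns 0-based
        assert not full_rec.flag & 2048
        chim = [r for r in recs if r.query_name == "chim1"]
        prim = next(r for r in chim if not r.flag & 2048)
        supp = next(r for r in chim if r.flag & 2048)
        assert prim.reference_name == "chr1" and prim.reference_start == 3000
        assert supp.reference_name == "provirus" and supp.reference_start == q
        assert prim.has_tag("SA") and supp.has_tag("SA")

    def test_roundtrip_coordinates(self, genome, index, tmp_path):
        read = genome.contigs[1].sequence[4000:4150]
        res = align_read(read, index, PARAMS, read_id="rt")
        path = tmp_path / "rt.sam"
        write_sam([res], genome, path, reads={"rt": read})
        rec = next(iter(pysam.AlignmentFile(str(path), "r")))
        assert rec.reference_name == res.full.contig
        assert rec.reference_start == res.full.ref_start
        assert rec.reference_end == res.full.ref_end


def test_align_params_validation():
    with pytest.raises(ValueError):
        AlignParams(k=5)
    with pytest.raises(ValueError):
        AlignParams(min_seg=10)
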