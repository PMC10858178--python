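"""Trans-split extraction, clustering, discard rules and reporting."""

import json

import numpy as np
import pytest

from provmap.align import AlignmentResult, SegmentAlignment, SplitAlignment
from provmap.calls import (
    STATUS_NO_UTR,
    STATUS_PASS,
    STATUS_UNPLACED,
    CallParams,
    TransSplit,
    cluster_splits,
    extract_trans_splits,
    filter_calls,
    report_calls,
)
from provmap.simulate import Contig, ProvirusAnnotation, ReferenceSet


@pytest.fixture()
def refset():
    return ReferenceSet(
        [
            Contig("chr19", "ACGT" * 500),
            Contig("chr13", "ACGT" * 500),
            Contig("scaffold_un1", "ACGT" * 250, placed=False),
            Contig("provirus", "ACGT" * 2000, placed=False, is_provirus=True),
        ],
        ProvirusAnnotation((0, 600), (7400, 8000)),
    )


def make_split(
    read_id,
    host_contig="chr19",
    host_pos=1000,
    pro_start=100,
    pro_end=200,
    host_is_prefix=True,
    host_strand="+",
    unique=True,
):
    """AlignmentResult with one host and one provirus segment."""
    host = SegmentAlignment(host_contig, host_pos, host_pos + 60, host_strand, 0, 60, 0)
    pro = SegmentAlignment("provirus", pro_start, pro_end, "+", 60, 150, 0)
    a, b = (host, pro) if host_is_prefix else (pro, host)
    if not host_is_prefix:
        a = SegmentAlignment("provirus", pro_start, pro_end, "+", 0, 90, 0)
        b = SegmentAlignment(host_contig, host_pos, host_pos + 60, host_strand, 90, 150, 0)
    split = SplitAlignment(read_id, a, b, a.read_end, 148, unique)
    return AlignmentResult(read_id, "split", None, split, 148, 0, unique)


class TestExtraction:
    def test_roles_and_annotations(self, refset):
        res = make_split("r1", host_pos=1000, pro_start=50, pro_end=150)
        (ts,) = extract_trans_splits([res], refset)
        assert ts.host_segment.contig == "chr19"
        assert ts.provirus_segment.contig == "provirus"
        assert ts.covers_utr  # [50, 150) overlaps utr5 [0, 600)
        assert ts.host_placed

    def test_internal_provirus_segment_no_utr(self, refset):
        res = make_split("r1", pro_start=3000, pro_end=3100)
        (ts,) = extract_trans_splits([res], refset)
        assert not ts.covers_utr

    def test_host_only_split_excluded(self, refset):
        host_a = SegmentAlignment("chr19", 100, 160, "+", 0, 60, 0)
        host_b = SegmentAlignment("chr13", 500, 590, "+", 60, 150, 0)
        sp = SplitAlignment("r", host_a, host_b, 60, 148, True)
        res = AlignmentResult("r", "split", None, sp, 148, 0, True)
        assert extract_trans_splits([res], refset) == []

    def test_non_unique_excluded_by_default(self, refset):
        res = make_split("r", unique=False)
        assert extract_trans_splits([res], refset) == []
        kept = extract_trans_splits(
            [res], refset, CallParams(require_unique=False)
        )
        assert len(kept) == 1

    def test_full_and_unmapped_ignored(self, refset):
        full = AlignmentResult(
            "f", "full", SegmentAlignment("chr19", 0, 150, "+", 0, 150, 0), None, 150, 0, True
        )
        un = AlignmentResult("u", "unmapped", None, None, 0, None, False)
        assert extract_trans_splits([full, un], refset) == []

    def test_missing_provirus_errors(self):
        refset = ReferenceSet([Contig("chr1", "ACGT" * 100)])
        with pytest.raises(ValueError):
            extract_trans_splits([], refset)

    def test_breakpoint_conventions(self, refset):
        # host prefix on '+': junction-adjacent base is the segment's last
        res = make_split("a", host_pos=1000, host_is_prefix=True, host_strand="+")
        (ts,) = extract_trans_splits([res], refset)
        assert ts.host_breakpoint == 1059
        # host suffix on '+': junction-adjacent base is the segment's first
        res = make_split("b", host_pos=1000, host_is_prefix=False, host_strand="+")
        (ts,) = extract_trans_splits([res], refset)
        assert ts.host_breakpoint == 1000
        # strand flips mirror the convention
        res = make_split("c", host_pos=1000, host_is_prefix=True, host_strand="-")
        (ts,) = extract_trans_splits([res], refset)
        assert ts.host_breakpoint == 1000


def ts(read_id, contig="chr19", bp=1000, covers_utr=True, placed=True):
    seg = SegmentAlignment(contig, bp - 59, bp + 1, "+", 0, 60, 0)
    pro = SegmentAlignment("provirus", 0, 90, "+", 60, 150, 0)
    return TransSplit(read_id, seg, pro, bp, covers_utr, placed)


class TestClustering:
    def test_empty_input(self):
        assert cluster_splits([]) == []

    def test_far_apart_become_two_singletons(self):
        calls = cluster_splits([ts("a", bp=1000), ts("b", bp=11_000)], CallParams(300))
        assert [c.support for c in calls] == [1, 1]
        assert all(c.singular for c in calls)

    def test_tight_window_one_call(self):
        # 19 splits within a 105 bp window collapse to one call of support 19
        rng = np.random.default_rng(0)
        bps = sorted(int(b) for b in rng.integers(4_666_860, 4_666_966, 19))
        seg = [ts(f"r{i}", contig="chr19", bp=b) for i, b in enumerate(bps)]
        calls = cluster_splits(seg, CallParams(300))
        assert len(calls) == 1
        call = calls[0]
        assert call.support == 19 and not call.singular
        assert call.span == (bps[0], bps[-1])
        assert call.breakpoint == bps[9]  # lower median of 19 members
        assert call.span[0] <= call.breakpoint <= call.span[1]

    def test_single_linkage_chains(self):
        # consecutive gaps of 250 chain into one cluster under window 300
        splits = [ts(f"r{i}", bp=1000 + 250 * i) for i in range(5)]
        calls = cluster_splits(splits, CallParams(300))
        assert len(calls) == 1 and calls[0].support == 5

    def test_conservation_of_support(self):
        rng = np.random.default_rng(42)
        splits = [
            ts(f"r{i}", contig=f"chr{int(rng.integers(1, 4))}", bp=int(rng.integers(0, 50_000)))
            for i in range(100)
        ]
        calls = cluster_splits(splits, CallParams(300))
        assert sum(c.support for c in calls) == len(splits)

    def test_even_cluster_lower_median(self):
        calls = cluster_splits([ts("a", bp=100), ts("b", bp=140)], CallParams(300))
        assert calls[0].breakpoint == 100


def oracle_status(call):
    """Independent rule-by-rule evaluation of the discard rules."""
    if not call.host_placed:
        return STATUS_UNPLACED
    if call.support == 1 and call.utr_supported == 0:
        return STATUS_NO_UTR
    return STATUS_PASS


class TestFilter:
    def test_singular_without_utr_discarded(self):
        calls = cluster_splits([ts("a", covers_utr=False)])
        (call,) = filter_calls(calls)
        assert call.status == STATUS_NO_UTR

    def test_singular_with_utr_passes(self):
        (call,) = filter_calls(cluster_splits([ts("a", covers_utr=True)]))
        assert call.status == STATUS_PASS

    def test_unplaced_discarded_even_with_support(self):
        splits = [
            ts(f"r{i}", contig="scaffold_un1", bp=1000 + i, placed=True) for i in range(5)
        ]
        for s in splits:
            s.host_placed = False
        (call,) = filter_calls(cluster_splits(splits))
        assert call.status == STATUS_UNPLACED

    def test_filter_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        splits = []
        for i in range(200):
            contig = ["chr19", "chr13", "scaffold_un1"][int(rng.integers(0, 3))]
            splits.append(
                ts(
                    f"r{i}",
                    contig=contig,
                    bp=int(rng.integers(0, 100_000)),
                    covers_utr=bool(rng.integers(0, 2)),
                    placed=contig != "scaffold_un1",
                )
            )
        calls = filter_calls(cluster_splits(splits, CallParams(300)))
        for call in calls:
            assert call.status == oracle_status(call)

    def test_twenty_of_thirtyone_survive(self):
        """31 trans splits, 11 discardable -> exactly 20 splits in passing calls."""
        splits = []
        # 19 clustered on chr19 within a 105 bp window (passes, support 19)
        for i in range(19):
            splits.append(ts(f"c{i}", contig="chr19", bp=4_666_860 % 2000 + 5 * i))
        # 1 singular with UTR coverage on chr13 (passes, support 1)
        splits.append(ts("s_utr", contig="chr13", bp=500, covers_utr=True))
        # 8 singular without UTR coverage, spread far apart on chr13
        for i in range(8):
            splits.append(
                ts(f"noutr{i}", contig="chr13", bp=10_000 + 5_000 * i, covers_utr=False)
            )
        # 3 on the unplaced scaffold (one cluster, discarded)
        for i in range(3):
            splits.append(
                ts(f"un{i}", contig="scaffold_un1", bp=200 + i, placed=False)
            )
        assert len(splits) == 31
        calls = filter_calls(cluster_splits(splits, CallParams(300)))
        passing = [c for c in calls if c.status == STATUS_PASS]
        assert sum(c.support for c in passing) == 20
        discarded = sum(c.support for c in calls if c.status != STATUS_PASS)
        assert discarded == 11


class TestReport:
    def test_report_files_and_truth_recovery(self, refset, tmp_path):
        splits = [ts(f"r{i}", contig="chr19", bp=1000 + i) for i in range(6)]
        calls = filter_calls(cluster_splits(splits))
        truth = __import__("pandas").DataFrame(
            {"contig": ["chr19"], "position": [1001]}
        )
        out = report_calls(calls, refset, tmp_path, truth=truth, depth_mean=30.0)
        assert out["bed"].exists() and out["tsv"].exists() and out["json"].exists()
        bed_lines = out["bed"].read_text().strip().split("\n")
        assert len(bed_lines) == 1
        contig, start, end = bed_lines[0].split("\t")[:3]
        assert contig == "chr19" and int(start) == 1000 and int(end) == 1006
        summary = json.loads(out["json"].read_text())
        (rec,) = summary["truth_recovery"]
        assert rec["error_bp"] <= 5 and rec["support"] == 6
        assert summary["splits_in_passing_calls"] == 6

    def test_zero_passing_calls(self, refset, tmp_path):
        calls = filter_calls(cluster_splits([ts("a", covers_utr=False)]))
        out = report_calls(calls, refset, tmp_path)
        assert out["bed"].read_text() == ""
        summary = json.loads(out["json"].read_text())
        assert summary["n_pass"] == 0 and summary["n_calls"] == 1

    def test_tsv_one_based(self, refset, tmp_path):
        import pandas as pd

        calls = filter_calls(cluster_splits([ts("a", bp=99)]))
        out = report_calls(calls, refset, tmp_path)
        frame = pd.read_csv(out["tsv"], sep="\t")
        assert frame.loc[0, "breakpoint"] == 100


def test_call_params_validation():
    with pytest.raises(ValueError):
        CallParams(cluster_window=0)
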