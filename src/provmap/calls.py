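"""Trans-split extraction, breakpoint clustering and the discard rules.

A *trans split* is a unique split alignment with exactly one segment on the
provirus contig and one on any other contig -- the direct evidence for a new
integration, since such chimeras are absent from the insertion-free genomic
background.  Splits are clustered per host contig by single linkage on the
host-side breakpoint (gap at most ``cluster_window``); each cluster becomes
one candidate call.  Calls are then annotated with the study's discard
rules: a singleton whose provirus segment does not cover a terminal UTR is a
likely partial-integration artefact, and any call on an unplaced scaffold is
treated as unreliable.  Discarded calls stay in the output with their status
so the filtering is auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .align import AlignmentResult, SegmentAlignment
from .simulate import ReferenceSet

STATUS_PASS = "pass"
STATUS_NO_UTR = "discarded_no_utr"
STATUS_UNPLACED = "discarded_unplaced"


@dataclass(frozen=True)
class CallParams:
    cluster_window: int = 300  # ~2x read length
    require_unique: bool = True

    def __post_init__(self) -> None:
        if self.cluster_window < 1:
            raise ValueError("cluster_window must be >= 1")


@dataclass(slots=True)
class TransSplit:
    read_id: str
    host_segment: SegmentAlignment
    provirus_segment: SegmentAlignment
    host_breakpoint: int
    covers_utr: bool
    host_placed: bool


@dataclass(slots=True)
class IntegrationCall:
    host_contig: str
    breakpoint: int  # lower median of member host breakpoints
    span: tuple[int, int]  # [min, max] member breakpoints
    support: int
    singular: bool
    utr_supported: int
    host_placed: bool
    status: str = STATUS_PASS
    members: tuple[str, ...] = ()


def _breakpoint(seg: SegmentAlignment, is_prefix: bool) -> int:
    """Host coordinate adjacent to the junction.

    For the read-prefix segment the junction sits at the segment's read-wise
    3' end; in reference coordinates that is the last base (ref_end - 1) on
    '+' and the first base (ref_start) on '-'.  The read-suffix segment is
    the mirror image.
    """
    if is_prefix == (seg.strand == "+"):
        return seg.ref_end - 1
    return seg.ref_start


def extract_trans_splits(
    results: Sequence[AlignmentResult],
    refset: ReferenceSet,
    params: CallParams | None = None,
    provirus_name: str | None = None,
) -> list[TransSplit]:
    """Unique splits joining the provirus contig with any host contig."""
    params = params or CallParams()
    if provirus_name is None:
        pro = refset.provirus
        if pro is None:
            raise ValueError("reference set has no provirus contig")
        provirus_name = pro.name
    elif provirus_name not in {c.name for c in refset.contigs}:
        raise ValueError(f"provirus contig {provirus_name!r} not in reference")
    ann = refset.provirus_annotation
    out: list[TransSplit] = []
    for res in results:
        if res.kind != "split":
            continue
        if params.require_unique and not res.unique:
            continue
        sp = res.split
        a_pro = sp.seg_a.contig == provirus_name
        b_pro = sp.seg_b.contig == provirus_name
        if a_pro == b_pro:  # both or neither on the provirus
            continue
        host, pro_seg = (sp.seg_b, sp.seg_a) if a_pro else (sp.seg_a, sp.seg_b)
        covers = (
            ann.overlaps_utr(pro_seg.ref_start, pro_seg.ref_end) if ann is not None else False
        )
        out.append(
            TransSplit(
                read_id=sp.read_id,
                host_segment=host,
                provirus_segment=pro_seg,
                host_breakpoint=_breakpoint(host, is_prefix=not a_pro),
                covers_utr=covers,
                host_placed=refset.is_placed(host.contig),
            )
        )
    return out


def cluster_splits(
    splits: Sequence[TransSplit], params: CallParams | None = None
) -> list[IntegrationCall]:
    """Single-linkage clustering of host breakpoints per contig."""
    params = params or CallParams()
    by_contig: dict[str, list[TransSplit]] = {}
    for s in splits:
        by_contig.setdefault(s.host_segment.contig, []).append(s)
    calls: list[IntegrationCall] = []
    for contig in sorted(by_contig):
        members = sorted(by_contig[contig], key=lambda s: (s.host_breakpoint, s.read_id))
        cluster: list[TransSplit] = []
        for s in members:
            if cluster and s.host_breakpoint - cluster[-1].host_breakpoint > params.cluster_window:
                calls.append(_make_call(contig, cluster))
                cluster = []
            cluster.append(s)
        if cluster:
            calls.append(_make_call(contig, cluster))
    return calls


def _make_call(contig: str, members: list[TransSplit]) -> IntegrationCall:
    bps = sorted(s.host_breakpoint for s in members)
    n = len(bps)
    return IntegrationCall(
        host_contig=contig,
        breakpoint=bps[(n - 1) // 2],  # lower median
        span=(bps[0], bps[-1]),
        support=n,
        singular=n == 1,
        utr_supported=sum(s.covers_utr for s in members),
        host_placed=members[0].host_placed,
        members=tuple(s.read_id for s in members),
    )


def filter_calls(calls: Sequence[IntegrationCall]) -> list[IntegrationCall]:
    """Annotate each call with its filter status (discarded calls retained).

    The unplaced-scaffold rule applies to every call (checked first); a
    placed singleton with no UTR-covering member is a likely
    partial-integration artefact.  Everything else passes.
    """
    out: list[IntegrationCall] = []
    for call in calls:
        if not call.host_placed:
            status = STATUS_UNPLACED
        elif call.singular and call.utr_supported == 0:
            status = STATUS_NO_UTR
        else:
            status = STATUS_PASS
        out.append(
            IntegrationCall(
                call.host_contig,
                call.breakpoint,
                call.span,
                call.support,
                call.singular,
                call.utr_supported,
                call.host_placed,
                status,
                call.members,
            )
        )
    return out


def calls_to_frame(calls: Sequence[IntegrationCall]) -> pd.DataFrame:
    """Tabular view; breakpoint and span are 1-based in the TSV convention."""
    return pd.DataFrame(
        {
            "contig": [c.host_contig for c in calls],
            "breakpoint": [c.breakpoint + 1 for c in calls],
            "span_start": [c.span[0] + 1 for c in calls],
            "span_end": [c.span[1] + 1 for c in calls],
            "support": [c.support for c in calls],
            "utr_supported": [c.utr_supported for c in calls],
            "status": [c.status for c in calls],
        }
    )


def report_calls(
    calls: Sequence[IntegrationCall],
    refset: ReferenceSet,
    out_dir,
    truth: pd.DataFrame | None = None,
    depth_mean: float | None = None,
) -> dict:
    """Write BED (0-based half-open spans), TSV (1-based) and a JSON summary.

    ``truth``, when given, is a frame with columns contig/position (0-based)
    of the simulated insertions; the summary then reports the breakpoint
    error of the nearest passing call per true event.  ``depth_mean`` adds a
    support/depth ratio annotation per passing call (germline vs somatic
    status itself is left to the caller's judgement).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bed_path = out_dir / "calls.bed"
    with open(bed_path, "w") as bed:
        for c in calls:
            if c.status != STATUS_PASS:
                continue
            bed.write(
                f"{c.host_contig}\t{c.span[0]}\t{c.span[1] + 1}\t"
                f"support={c.support}\t{c.support}\t.\n"
            )
    frame = calls_to_frame(calls)
    tsv_path = out_dir / "calls.tsv"
    frame.to_csv(tsv_path, sep="\t", index=False)

    status_counts = frame["status"].value_counts().to_dict() if len(frame) else {}
    passing = [c for c in calls if c.status == STATUS_PASS]
    summary = {
        "n_calls": len(calls),
        "n_pass": len(passing),
        "status_counts": {k: int(v) for k, v in sorted(status_counts.items())},
        "splits_total": int(sum(c.support for c in calls)),
        "splits_in_passing_calls": int(sum(c.support for c in passing)),
    }
    if depth_mean:
        summary["support_depth_ratio"] = {
            f"{c.host_contig}:{c.breakpoint + 1}": round(c.support / depth_mean, 4)
            for c in passing
        }
    if truth is not None and len(truth):
        recovery = []
        for _, row in truth.iterrows():
            same = [c for c in passing if c.host_contig == row["contig"]]
            if same:
                best = min(same, key=lambda c: abs(c.breakpoint - row["position"]))
                recovery.append(
                    {
                        "contig": row["contig"],
                        "true_position": int(row["position"]),
                        "called_breakpoint": int(best.breakpoint),
                        "error_bp": int(abs(best.breakpoint - row["position"])),
                        "support": best.support,
                    }
                )
            else:
                recovery.append(
                    {
                        "contig": row["contig"],
                        "true_position": int(row["position"]),
                        "called_breakpoint": None,
                        "error_bp": None,
                        "support": 0,
                    }
                )
        summary["truth_recovery"] = recovery
    json_path = out_dir / "calls_summary.json"
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"bed": bed_path, "tsv": tsv_path, "json": json_path, "summary": summary}
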