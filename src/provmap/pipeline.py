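"""Stage orchestration: simulate -> trim -> align -> call -> coverage (+ clones).

Each stage is an importable function that reads and writes plain-text
artifacts, and :func:`run_all` chains them, keeping the large intermediates
in memory and writing a single JSON manifest with the parameters and SHA-256
checksums of every artifact, so a run is reproducible and auditable from the
manifest alone.  Partial outputs are removed if a run fails.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import seqio
from .align import AlignParams, KmerIndex, align_pairs, write_sam
from .calls import (
    CallParams,
    TransSplit,
    cluster_splits,
    extract_trans_splits,
    filter_calls,
    report_calls,
)
from .coverage import depth_profile, iter_segments, summarize
from .hypermut import (
    profile_clone,
    profiles_to_frame,
    spectrum_to_dict,
    summaries_to_frame,
    summarize_mice,
)
from .qc import TrimConfig, trim_batch
from .align import SegmentAlignment
from .simulate import (
    SimulationConfig,
    build_haplotypes,
    build_reference,
    default_events,
    simulate_clones,
    simulate_reads,
    substream,
)


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    sim: SimulationConfig | None = None
    trim: TrimConfig = field(default_factory=TrimConfig)
    align: AlignParams = field(default_factory=AlignParams)
    call: CallParams = field(default_factory=CallParams)
    coverage_thresholds: tuple[int, ...] = (4,)
    write_sam: bool = False
    run_clones: bool = True

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.sim is None:
            self.sim = SimulationConfig(seed=self.seed)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def simulate_stage(config: PipelineConfig) -> dict:
    """Generate reference, haplotypes, reads and truth tables; write them all."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    refset = build_reference(sim)
    events = sim.events if sim.events is not None else default_events(sim, refset)
    haplotypes = build_haplotypes(refset, events)
    batch, truth = simulate_reads(haplotypes, sim, genome_length=refset.host_length)

    paths = {
        "reference_fasta": out / "reference.fasta",
        "reference_meta": out / "reference.json",
        "utr_bed": out / "provirus_utr.bed",
        "truth_insertions_bed": out / "truth_insertions.bed",
        "reads1": out / "reads_1.fastq",
        "reads2": out / "reads_2.fastq",
        "truth_reads": out / "truth_reads.tsv",
    }
    seqio.write_reference(refset, paths["reference_fasta"], paths["reference_meta"])
    seqio.write_utr_bed(refset, paths["utr_bed"])
    seqio.write_insertion_bed(events, paths["truth_insertions_bed"])
    seqio.write_fastq_pair(batch, paths["reads1"], paths["reads2"])
    seqio.write_truth_reads(truth, paths["truth_reads"])
    return {
        "paths": paths,
        "refset": refset,
        "events": events,
        "haplotypes": haplotypes,
        "batch": batch,
        "truth": truth,
    }


def trim_stage(reads1, reads2, out1, out2, stats_json, config: TrimConfig | None = None) -> dict:
    """File-based trimming: FASTQ pair in, trimmed FASTQ pair + stats JSON out."""
    config = config or TrimConfig()
    batch = seqio.read_fastq_pair(reads1, reads2)
    kept, stats = trim_batch(batch, config)
    seqio.write_fastq_pair(kept, out1, out2)
    with open(stats_json, "w") as fh:
        json.dump(stats.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"batch": kept, "stats": stats}


def align_stage(
    reference_fasta,
    reference_meta,
    reads1,
    reads2,
    out_dir,
    align_params: AlignParams | None = None,
    call_params: CallParams | None = None,
    sam: bool = False,
) -> dict:
    """File-based alignment: writes trans-split TSV, aligned-segment TSV, SAM (opt)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    refset = seqio.read_reference(reference_fasta, reference_meta)
    batch = seqio.read_fastq_pair(reads1, reads2)
    index = KmerIndex(refset, (align_params or AlignParams()).k)
    results = align_pairs(batch, index, align_params)
    splits = extract_trans_splits(results, refset, call_params)
    splits_path = out_dir / "splits.tsv"
    seqio.splits_to_frame(splits).to_csv(splits_path, sep="\t", index=False)
    segs = pd.DataFrame(
        list(iter_segments(results)), columns=["contig", "start", "end"]
    )
    segments_path = out_dir / "segments.tsv"
    segs.to_csv(segments_path, sep="\t", index=False)
    paths = {"splits": splits_path, "segments": segments_path}
    if sam:
        sam_path = out_dir / "alignments.sam"
        write_sam(results, refset, sam_path)
        paths["sam"] = sam_path
    return {"paths": paths, "results": results, "splits": splits, "refset": refset}


def trans_splits_from_frame(frame: pd.DataFrame) -> list[TransSplit]:
    """Rebuild TransSplit records from a splits TSV (for file-based calling)."""
    splits = []
    for row in frame.itertuples(index=False):
        host = SegmentAlignment(
            row.host_contig, int(row.host_start), int(row.host_end),
            row.host_strand, 0, int(row.host_end) - int(row.host_start), 0,
        )
        pro = SegmentAlignment(
            row.provirus_contig if hasattr(row, "provirus_contig") else "provirus",
            int(row.provirus_start), int(row.provirus_end),
            row.provirus_strand, 0, int(row.provirus_end) - int(row.provirus_start), 0,
        )
        splits.append(
            TransSplit(
                read_id=row.read_id,
                host_segment=host,
                provirus_segment=pro,
                host_breakpoint=int(row.host_breakpoint),
                covers_utr=bool(row.covers_utr),
                host_placed=bool(row.host_placed),
            )
        )
    return splits


def call_stage(
    splits_tsv,
    reference_fasta,
    reference_meta,
    out_dir,
    call_params: CallParams | None = None,
    truth: pd.DataFrame | None = None,
    depth_mean: float | None = None,
) -> dict:
    """File-based calling from a trans-split table."""
    refset = seqio.read_reference(reference_fasta, reference_meta)
    frame = pd.read_csv(splits_tsv, sep="\t")
    splits = trans_splits_from_frame(frame)
    calls = filter_calls(cluster_splits(splits, call_params))
    report = report_calls(calls, refset, out_dir, truth=truth, depth_mean=depth_mean)
    return {"calls": calls, "report": report}


def coverage_stage(
    segments_tsv, reference_fasta, reference_meta, out_dir, thresholds=(4,)
) -> dict:
    """File-based coverage summary from an aligned-segment table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    refset = seqio.read_reference(reference_fasta, reference_meta)
    segs = pd.read_csv(segments_tsv, sep="\t")
    profiles = depth_profile(
        ((r.contig, int(r.start), int(r.end)) for r in segs.itertuples(index=False)),
        refset,
    )
    summary = summarize(profiles, refset, thresholds)
    per_contig = pd.DataFrame(
        {"contig": list(summary.per_contig), "mean_depth": list(summary.per_contig.values())}
    )
    per_contig.to_csv(out_dir / "coverage_per_contig.tsv", sep="\t", index=False)
    with open(out_dir / "coverage.json", "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"summary": summary}


def mutations_stage(reference_fasta, clones_fasta, out_dir) -> dict:
    """Profile cloned amplicons against their reference; write TSVs + spectrum."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref = next(iter(seqio.read_fasta(reference_fasta).values()))
    clones = seqio.read_fasta(clones_fasta)
    profiles = [profile_clone(ref, seq, cid) for cid, seq in clones.items()]
    summaries = summarize_mice(profiles)
    profiles_to_frame(profiles).to_csv(out_dir / "clones.tsv", sep="\t", index=False)
    summaries_to_frame(summaries).to_csv(out_dir / "mice.tsv", sep="\t", index=False)
    with open(out_dir / "spectrum.json", "w") as fh:
        json.dump(spectrum_to_dict(profiles), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"profiles": profiles, "summaries": summaries}


def run_all(config: PipelineConfig) -> dict:
    """Full chain with one manifest; removes partial outputs on failure."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []

    def track(*paths) -> None:
        created.extend(Path(p) for p in paths)

    try:
        sim = simulate_stage(config)
        track(*sim["paths"].values())
        refset, batch = sim["refset"], sim["batch"]

        kept, stats = trim_batch(batch, config.trim)
        trimmed1, trimmed2 = out / "trimmed_1.fastq", out / "trimmed_2.fastq"
        seqio.write_fastq_pair(kept, trimmed1, trimmed2)
        stats_path = out / "trim_stats.json"
        with open(stats_path, "w") as fh:
            json.dump(stats.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        track(trimmed1, trimmed2, stats_path)

        index = KmerIndex(refset, config.align.k)
        results = align_pairs(kept, index, config.align)
        splits = extract_trans_splits(results, refset, config.call)
        splits_path = out / "splits.tsv"
        seqio.splits_to_frame(splits).to_csv(splits_path, sep="\t", index=False)
        track(splits_path)
        if config.write_sam:
            sam_path = out / "alignments.sam"
            write_sam(results, refset, sam_path)
            track(sam_path)

        profiles = depth_profile(iter_segments(results), refset)
        cov = summarize(profiles, refset, config.coverage_thresholds)
        cov_path = out / "coverage.json"
        with open(cov_path, "w") as fh:
            json.dump(cov.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        track(cov_path)

        truth_calls = pd.DataFrame(
            {
                "contig": [ev.host_contig for ev in sim["events"]],
                "position": [ev.position for ev in sim["events"]],
            }
        )
        calls = filter_calls(cluster_splits(splits, config.call))
        report = report_calls(
            calls, refset, out, truth=truth_calls, depth_mean=cov.mean_depth
        )
        track(report["bed"], report["tsv"], report["json"])

        clone_outputs = {}
        if config.run_clones:
            plen = len(refset.provirus.sequence)
            amp_len = config.sim.clones.amplicon_len
            start = (plen - amp_len) // 2
            amplicon = refset.provirus.sequence[start : start + amp_len]
            rng = substream(config.sim.seed, "clones")
            clones, truth_muts = simulate_clones(amplicon, config.sim.clones, rng)
            amp_path, clones_path = out / "amplicon.fasta", out / "clones.fasta"
            seqio.write_fasta([("amplicon", amplicon)], amp_path)
            seqio.write_fasta(clones, clones_path)
            truth_rows = [
                {"clone_id": cid, "position": p, "ref": r, "alt": a}
                for cid, muts in truth_muts.items()
                for p, r, a in muts
            ]
            truth_path = out / "truth_mutations.tsv"
            pd.DataFrame(
                truth_rows, columns=["clone_id", "position", "ref", "alt"]
            ).to_csv(truth_path, sep="\t", index=False)
            track(amp_path, clones_path, truth_path)
            mut = mutations_stage(amp_path, clones_path, out)
            track(out / "clones.tsv", out / "mice.tsv", out / "spectrum.json")
            clone_outputs = {
                "n_clones": len(clones),
                "grand_mean_subs": float(
                    np.mean([p.n_subs for p in mut["profiles"]])
                ),
            }

        manifest = {
            "config": _jsonable(config),
            "trim_stats": stats.to_dict(),
            "coverage": cov.to_dict(),
            "calls_summary": report["summary"],
            "clones": clone_outputs,
            "files": {
                str(p.relative_to(out)): seqio.sha256_of(p) for p in sorted(set(created))
            },
        }
        manifest_path = out / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest
    except Exception:
        for p in created:
            try:
                p.unlink(missing_ok=True)
            except OSError:
                pass
        raise
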