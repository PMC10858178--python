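"""File I/O: FASTA, FASTQ (Phred+33, gzip-transparent), BED and TSV tables.

Internal coordinates are 0-based half-open throughout the package;
conversions to 1-based happen only here and in the report writers.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import dna
from .simulate import (
    Contig,
    InsertionEvent,
    ProvirusAnnotation,
    ReadBatch,
    ReadPair,
    ReferenceSet,
)

FASTA_WIDTH = 60


def _open(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    """Write (name, sequence) records, 60-column wrapped."""
    with _open(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_WIDTH):
                fh.write(seq[i : i + FASTA_WIDTH] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> sequence mapping."""
    with _open(path, "rt") as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_reference(refset: ReferenceSet, fasta_path, meta_path=None) -> None:
    """Reference FASTA plus a JSON sidecar with placement/UTR metadata."""
    write_fasta(((c.name, c.sequence) for c in refset.contigs), fasta_path)
    if meta_path is not None:
        meta = {
            "contigs": [
                {
                    "name": c.name,
                    "length": len(c),
                    "placed": c.placed,
                    "is_provirus": c.is_provirus,
                }
                for c in refset.contigs
            ],
        }
        if refset.provirus_annotation is not None:
            meta["utr5"] = list(refset.provirus_annotation.utr5)
            meta["utr3"] = list(refset.provirus_annotation.utr3)
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_reference(fasta_path, meta_path) -> ReferenceSet:
    seqs = read_fasta(fasta_path)
    with open(meta_path) as fh:
        meta = json.load(fh)
    contigs = [
        Contig(m["name"], seqs[m["name"]], placed=m["placed"], is_provirus=m["is_provirus"])
        for m in meta["contigs"]
    ]
    ann = None
    if "utr5" in meta:
        ann = ProvirusAnnotation(tuple(meta["utr5"]), tuple(meta["utr3"]))
    return ReferenceSet(contigs, ann)


def write_fastq_pair(batch: ReadBatch, path1, path2) -> None:
    """Write both mates of a batch as FASTQ (Phred+33)."""
    for path, seqs, quals, lens, mate in (
        (path1, batch.seq1, batch.qual1, batch.len1, 1),
        (path2, batch.seq2, batch.qual2, batch.len2, 2),
    ):
        with _open(path, "wt") as fh:
            for i, rid in enumerate(batch.ids):
                n = int(lens[i])
                fh.write(
                    f"@{rid}/{mate}\n{dna.decode(seqs[i, :n])}\n+\n"
                    f"{dna.phred_to_ascii(quals[i, :n])}\n"
                )


def iter_fastq_pairs(path1, path2) -> Iterator[ReadPair]:
    """Stream read pairs from two FASTQ files; malformed records raise with index."""
    with _open(path1, "rt") as fh1, _open(path2, "rt") as fh2:
        it1, it2 = FastqGeneralIterator(fh1), FastqGeneralIterator(fh2)
        i = 0
        while True:
            try:
                rec1 = next(it1, None)
                rec2 = next(it2, None)
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record at index {i}: {exc}") from exc
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                raise ValueError("FASTQ mate files have different record counts")
            id1 = rec1[0].split()[0].removesuffix("/1")
            id2 = rec2[0].split()[0].removesuffix("/2")
            if id1 != id2:
                raise ValueError(f"mate ids disagree at record {i}: {id1!r} vs {id2!r}")
            yield ReadPair(
                id1, rec1[1], rec2[1], dna.ascii_to_phred(rec1[2]), dna.ascii_to_phred(rec2[2])
            )
            i += 1


def read_fastq_pair(path1, path2) -> ReadBatch:
    return ReadBatch.from_pairs(list(iter_fastq_pairs(path1, path2)))


def write_truth_reads(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_insertion_bed(events: Sequence[InsertionEvent], path) -> None:
    """Ground-truth insertions as BED: 0-based half-open TSD interval."""
    with _open(path, "wt") as fh:
        for ev in events:
            fh.write(
                f"{ev.host_contig}\t{ev.position}\t{ev.position + max(ev.tsd_len, 1)}\t"
                f"{ev.mode};orient={ev.orientation};cf={ev.cell_fraction}\n"
            )


def write_utr_bed(refset: ReferenceSet, path) -> None:
    pro = refset.provirus
    ann = refset.provirus_annotation
    if pro is None or ann is None:
        raise ValueError("reference set lacks a provirus annotation")
    with _open(path, "wt") as fh:
        fh.write(f"{pro.name}\t{ann.utr5[0]}\t{ann.utr5[1]}\tutr5\n")
        fh.write(f"{pro.name}\t{ann.utr3[0]}\t{ann.utr3[1]}\tutr3\n")


def splits_to_frame(splits) -> pd.DataFrame:
    """Trans splits as a flat table (0-based coordinates, documented columns)."""
    rows = []
    for s in splits:
        h, p = s.host_segment, s.provirus_segment
        rows.append(
            {
                "read_id": s.read_id,
                "host_contig": h.contig,
                "host_start": h.ref_start,
                "host_end": h.ref_end,
                "host_strand": h.strand,
                "provirus_start": p.ref_start,
                "provirus_end": p.ref_end,
                "provirus_strand": p.strand,
                "host_breakpoint": s.host_breakpoint,
                "covers_utr": s.covers_utr,
                "host_placed": s.host_placed,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "host_contig",
            "host_start",
            "host_end",
            "host_strand",
            "provirus_start",
            "provirus_end",
            "provirus_strand",
            "host_breakpoint",
            "covers_utr",
            "host_placed",
        ],
    )


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
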