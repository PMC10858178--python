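"""Deaminase (APOBEC3-type) hypermutation quantification of cloned amplicons.

Each sequenced clone of the 549-nt amplicon is globally aligned to the
reference, substitutions are counted into a 4x4 spectrum, and the
plus-strand G->A fraction -- the cytidine-deaminase footprint on the coding
strand -- is reported together with the dinucleotide context (base preceding
each mutated G).  Per-mouse summaries give the mean and sample standard
deviation of per-clone substitution counts, the quantity plotted per animal
in this kind of experiment.  Indels are excluded from the substitution count
and reported separately as a gap-column count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .dna import BASES

_IDX = {b: i for i, b in enumerate(BASES)}

# global (Needleman-Wunsch) scoring: match +1, mismatch -1, gap open -4
# (first gap base), gap extend -1
_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -4
_aligner.extend_gap_score = -1


class AlignedPair(NamedTuple):
    reference: str  # gapped reference row
    clone: str  # gapped clone row
    score: float


@dataclass
class CloneMutationProfile:
    clone_id: str
    n_subs: int
    spectrum: np.ndarray  # 4x4 counts, rows = reference base, cols = observed
    ga_fraction: float
    context_counts: dict[str, int]
    n_gap_columns: int = 0

    def validate(self) -> None:
        assert int(self.spectrum.sum()) == self.n_subs
        assert not self.spectrum.diagonal().any()


@dataclass(frozen=True)
class MouseSummary:
    mouse_id: str
    n_clones: int
    mean_subs: float
    sd_subs: float


def global_align(clone: str, reference: str) -> AlignedPair:
    """Global alignment of a clone against the amplicon reference.

    Deterministic: the top-ranked alignment of the pairwise aligner is used.
    """
    if not clone or not reference:
        raise ValueError("sequences must be non-empty")
    alns = _aligner.align(reference.upper(), clone.upper())
    best = alns[0]
    return AlignedPair(reference=str(best[0]), clone=str(best[1]), score=best.score)


def count_mutations(pair: AlignedPair, clone_id: str = "clone") -> CloneMutationProfile:
    """Substitution spectrum of one aligned clone.

    Gap columns and columns containing N are excluded from ``n_subs``; for
    every plus-strand G->A substitution the preceding reference base (the
    5' dinucleotide context) is recorded.
    """
    ref, obs = pair.reference, pair.clone
    if len(ref) != len(obs):
        raise ValueError("aligned rows differ in length")
    spectrum = np.zeros((4, 4), dtype=np.int64)
    context: dict[str, int] = {}
    n_gaps = 0
    prev_ref_base = ""
    for r, o in zip(ref, obs):
        if r == "-" or o == "-":
            n_gaps += 1
            if r != "-":
                prev_ref_base = r
            continue
        if r in _IDX and o in _IDX and r != o:
            spectrum[_IDX[r], _IDX[o]] += 1
            if r == "G" and o == "A":
                key = (prev_ref_base or ".") + "G"
                context[key] = context.get(key, 0) + 1
        prev_ref_base = r
    n_subs = int(spectrum.sum())
    ga = int(spectrum[_IDX["G"], _IDX["A"]])
    return CloneMutationProfile(
        clone_id=clone_id,
        n_subs=n_subs,
        spectrum=spectrum,
        ga_fraction=ga / n_subs if n_subs else 0.0,
        context_counts=context,
        n_gap_columns=n_gaps,
    )


def profile_clone(reference: str, clone: str, clone_id: str = "clone") -> CloneMutationProfile:
    """Align one clone to the reference and count its mutations."""
    return count_mutations(global_align(clone, reference), clone_id)


def mouse_of(clone_id: str) -> str:
    """Mouse id from a clone id of the form ``<mouse>_<clone>``."""
    if "_" not in clone_id:
        raise ValueError(f"clone id {clone_id!r} does not encode a mouse id")
    return clone_id.rsplit("_", 1)[0]


def summarize_mice(profiles: Sequence[CloneMutationProfile]) -> list[MouseSummary]:
    """Per-mouse mean and sample SD (n-1) of per-clone substitution counts."""
    if not profiles:
        raise ValueError("no clone profiles to summarise")
    groups: dict[str, list[int]] = {}
    for p in profiles:
        groups.setdefault(mouse_of(p.clone_id), []).append(p.n_subs)
    out = []
    for mouse in sorted(groups):
        counts = np.array(groups[mouse], dtype=float)
        sd = float(counts.std(ddof=1)) if counts.size > 1 else 0.0
        out.append(
            MouseSummary(
                mouse_id=mouse,
                n_clones=int(counts.size),
                mean_subs=float(counts.mean()),
                sd_subs=sd,
            )
        )
    return out


def profiles_to_frame(profiles: Sequence[CloneMutationProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            {
                "clone_id": p.clone_id,
                "mouse_id": mouse_of(p.clone_id),
                "n_subs": p.n_subs,
                "ga_count": int(p.spectrum[_IDX["G"], _IDX["A"]]),
                "ga_fraction": p.ga_fraction,
                "n_gap_columns": p.n_gap_columns,
            }
        )
    return pd.DataFrame(rows)


def summaries_to_frame(summaries: Sequence[MouseSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mouse_id": [s.mouse_id for s in summaries],
            "n_clones": [s.n_clones for s in summaries],
            "mean_subs": [s.mean_subs for s in summaries],
            "sd_subs": [s.sd_subs for s in summaries],
        }
    )


def spectrum_to_dict(profiles: Sequence[CloneMutationProfile]) -> dict:
    """Pooled substitution spectrum over all clones, keys like 'G>A'."""
    total = np.zeros((4, 4), dtype=np.int64)
    for p in profiles:
        total += p.spectrum
    return {
        f"{BASES[i]}>{BASES[j]}": int(total[i, j])
        for i in range(4)
        for j in range(4)
        if i != j
    }
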