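"""Paired-read merging and minimum-length filtering.

Read pairs are merged by scanning for the best overlap between R1 and the
reverse complement of R2; overlap disagreements are resolved toward the
higher-quality base. Merged sequences shorter than 300 nt are removed before
clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["MergedRead", "MergeStats", "merge_pairs", "length_filter"]


@dataclass(frozen=True)
class MergedRead:
    sample_id: str
    sequence: str
    read_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("merged read must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class MergeStats:
    """Per-stage read accounting emitted alongside the merged reads."""

    n_pairs_in: int = 0
    n_merged: int = 0
    n_unmerged: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "pairs_in": self.n_pairs_in,
            "merged": self.n_merged,
            "unmerged_discarded": self.n_unmerged,
        }


def _best_overlap(
    s1: str, s2: str, min_overlap: int, max_mismatch_frac: float
) -> tuple[int, int] | None:
    """Best (overlap_len, mismatches) of an R1-suffix / R2rc-prefix overlap.

    Scans all overlap lengths >= min_overlap, keeping the candidate with the
    lowest mismatch fraction (ties to the longer overlap); returns None when
    no candidate passes max_mismatch_frac.
    """
    best: tuple[int, int] | None = None
    best_frac = None
    max_len = min(len(s1), len(s2))
    a1 = np.frombuffer(s1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(s2.encode(), dtype=np.uint8)
    for olen in range(max_len, min_overlap - 1, -1):
        mism = int(np.count_nonzero(a1[len(s1) - olen :] != a2[:olen]))
        frac = mism / olen
        if frac <= max_mismatch_frac and (best_frac is None or frac < best_frac):
            best = (olen, mism)
            best_frac = frac
            if mism == 0:
                break
    return best


def merge_pairs(
    r1: Sequence[SeqRecord],
    r2: Sequence[SeqRecord],
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
    stats: MergeStats | None = None,
) -> list[MergedRead]:
    """Merge index-paired R1/R2 records into single amplicon sequences.

    A pair merges iff some R1-suffix/R2(revcomp)-prefix overlap of length
    >= min_overlap has mismatch fraction <= max_mismatch_frac; disagreeing
    overlap bases take the higher-quality call (R1 wins ties). Unmergeable
    pairs are discarded and counted. The sample id is taken from the read id
    prefix before the first ':'.
    """
    if len(r1) != len(r2):
        raise ValueError(f"unpaired inputs: {len(r1)} R1 vs {len(r2)} R2 records")
    merged: list[MergedRead] = []
    stats = stats if stats is not None else MergeStats()
    stats.n_pairs_in += len(r1)
    for rec1, rec2 in zip(r1, r2):
        if rec1.id != rec2.id:
            raise ValueError(f"read ids out of order: {rec1.id!r} vs {rec2.id!r}")
        s1 = str(rec1.seq)
        q1 = rec1.letter_annotations.get("phred_quality", [30] * len(s1))
        rc = rec2.reverse_complement()
        s2 = str(rc.seq)
        q2 = rc.letter_annotations.get("phred_quality", [30] * len(s2))
        hit = _best_overlap(s1, s2, min_overlap, max_mismatch_frac)
        if hit is None:
            stats.n_unmerged += 1
            continue
        olen, _ = hit
        left = s1[: len(s1) - olen]
        right = s2[olen:]
        overlap = []
        for k in range(olen):
            i1 = len(s1) - olen + k
            b1, b2 = s1[i1], s2[k]
            if b1 == b2 or q1[i1] >= q2[k]:
                overlap.append(b1)
            else:
                overlap.append(b2)
        seq = left + "".join(overlap) + right
        sample_id = rec1.id.split(":", 1)[0]
        merged.append(MergedRead(sample_id, seq, read_id=rec1.id))
        stats.n_merged += 1
    return merged


def length_filter(reads: Sequence[MergedRead], min_len: int = 300) -> list[MergedRead]:
    """Drop merged reads shorter than min_len (default 300 nt), keeping order."""
    return [r for r in reads if r.length >= min_len]
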