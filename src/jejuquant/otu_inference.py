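"""De novo OTU inference: greedy 99%-identity clustering, small-OTU rejection,
and two-parent chimera flagging.

Clustering is the classic greedy abundance-sorted centroid scheme: unique
sequences are visited in decreasing abundance (first occurrence breaks ties)
and each joins the first centroid it matches at or above the identity
threshold, otherwise founds a new OTU. Identity is end-gap-free global
identity (see `_alignment.identity`). Clustering is per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from ._alignment import identity, per_base_match_mask
from .read_processing import MergedRead

__all__ = [
    "OTU",
    "PipelineThresholds",
    "cluster_otus",
    "filter_small_otus",
    "detect_chimeras",
]


@dataclass(frozen=True)
class PipelineThresholds:
    """Pre-annotation filtering thresholds (study defaults)."""

    cluster_identity: float = 0.99
    min_otu_size: int = 50
    min_read_len: int = 300

    def __post_init__(self) -> None:
        if not 0 < self.cluster_identity <= 1:
            raise ValueError("cluster_identity must lie in (0, 1]")
        if self.min_otu_size < 1:
            raise ValueError("min_otu_size must be >= 1")


@dataclass
class OTU:
    otu_id: str
    centroid: str
    size: int
    sample_id: str
    member_read_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("an OTU has at least one member")


def cluster_otus(reads: Sequence[MergedRead], cluster_identity: float = 0.99) -> list[OTU]:
    """Greedily cluster one sample's merged reads into OTUs.

    The returned OTUs are sorted by decreasing size (founding order breaks
    ties); the sum of their sizes equals the number of input reads.
    """
    if not 0 < cluster_identity <= 1:
        raise ValueError("cluster_identity must lie in (0, 1]")
    if not reads:
        return []
    samples = {r.sample_id for r in reads}
    if len(samples) != 1:
        raise ValueError(f"cluster_otus expects reads from a single sample, got {sorted(samples)}")
    sample_id = reads[0].sample_id

    # dereplicate, remembering abundance and first-occurrence order
    order: dict[str, int] = {}
    members: dict[str, list[str]] = {}
    for i, r in enumerate(reads):
        if r.sequence not in order:
            order[r.sequence] = i
            members[r.sequence] = []
        members[r.sequence].append(r.read_id)
    uniq = sorted(order, key=lambda s: (-len(members[s]), order[s]))

    otus: list[OTU] = []
    for seq in uniq:
        placed = False
        for otu in otus:
            if identity(seq, otu.centroid) >= cluster_identity:
                otu.size += len(members[seq])
                otu.member_read_ids.extend(members[seq])
                placed = True
                break
        if not placed:
            otus.append(
                OTU(
                    otu_id=f"{sample_id}|OTU{len(otus) + 1:04d}",
                    centroid=seq,
                    size=len(members[seq]),
                    sample_id=sample_id,
                    member_read_ids=list(members[seq]),
                )
            )
    otus.sort(key=lambda o: (-o.size, o.otu_id))
    return otus


def filter_small_otus(otus: Sequence[OTU], min_size: int = 50) -> list[OTU]:
    """Reject OTUs with fewer than min_size member reads (default 50)."""
    return [o for o in otus if o.size >= min_size]


def detect_chimeras(
    otus: Sequence[OTU],
    parent_abundance_ratio: float = 2.0,
    min_mismatch_margin: int = 2,
    min_parent_contribution: float = 0.2,
    max_splice_divergence: float = 0.01,
) -> dict[str, bool]:
    """Flag chimeric OTUs within one sample by a two-parent splice test.

    For each OTU, candidate parents are same-sample OTUs at least
    parent_abundance_ratio times as abundant. The OTU is flagged when some
    left/right splice of two distinct parents (i) explains the centroid
    nearly perfectly — at most max_splice_divergence mismatches per centroid
    position — (ii) beats the best single parent by at least
    min_mismatch_margin mismatches, and (iii) draws at least
    min_parent_contribution of the centroid from each parent. Requirement
    (i) is what separates true PCR splices from merely divergent sequences:
    for an unrelated sequence the best splice of two arbitrary parents still
    leaves it largely unexplained. The most abundant OTU can never be
    flagged (no eligible parents).
    """
    flags: dict[str, bool] = {}
    for otu in otus:
        parents = [p for p in otus if p.otu_id != otu.otu_id and p.size >= parent_abundance_ratio * otu.size]
        flags[otu.otu_id] = False
        if len(parents) < 2:
            continue
        L = len(otu.centroid)
        masks = {p.otu_id: per_base_match_mask(otu.centroid, p.centroid) for p in parents}
        best_single = min(sum(not m for m in masks[p.otu_id]) for p in parents)
        lo = int(min_parent_contribution * L)
        hi = L - lo
        best_splice = None
        for pa in parents:
            ma = masks[pa.otu_id]
            prefix_mm = [0] * (L + 1)
            for i in range(L):
                prefix_mm[i + 1] = prefix_mm[i] + (not ma[i])
            for pb in parents:
                if pb.otu_id == pa.otu_id:
                    continue
                mb = masks[pb.otu_id]
                suffix_mm = [0] * (L + 1)
                for i in range(L - 1, -1, -1):
                    suffix_mm[i] = suffix_mm[i + 1] + (not mb[i])
                for cut in range(lo, hi + 1):
                    mm = prefix_mm[cut] + suffix_mm[cut]
                    if best_splice is None or mm < best_splice:
                        best_splice = mm
        if (
            best_splice is not None
            and best_splice <= max_splice_divergence * L
            and best_splice <= best_single - min_mismatch_margin
        ):
            flags[otu.otu_id] = True
    return flags
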