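"""Pairwise identity for amplicon sequences.

Identity is defined as matches / alignment columns, with terminal gaps
excluded from the column count ("end-gap-free"). V3-V4 amplicons from
different taxa are near-equal in length, so a global alignment whose
terminal indel runs are discounted is an adequate and fast convention.
Alignment itself is delegated to edlib.
"""

from __future__ import annotations

import re

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


def _cigar_ops(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def identity(a: str, b: str) -> float:
    """End-gap-free global identity between two DNA sequences in [0, 1].

    matches / (alignment columns - terminal indel columns). Empty input
    against anything yields 0.0.
    """
    if not a or not b:
        return 0.0
    if a == b:
        return 1.0
    # canonical argument order keeps the score exactly symmetric even when
    # co-optimal alignments trim different terminal gaps
    if (len(a), a) > (len(b), b):
        a, b = b, a
    res = edlib.align(a, b, mode="NW", task="path")
    ops = _cigar_ops(res["cigar"])
    cols = sum(n for n, _ in ops)
    matches = cols - res["editDistance"]
    # strip terminal indel runs from the column count
    trim = 0
    for n, op in ops:
        if op in "ID":
            trim += n
        else:
            break
    for n, op in reversed(ops):
        if op in "ID":
            trim += n
        else:
            break
    core = cols - trim
    if core <= 0:
        return 0.0
    return matches / core


def per_base_match_mask(centroid: str, parent: str) -> list[bool]:
    """For each centroid position, whether the aligned parent base matches.

    Centroid positions aligned to a parent gap (or outside the parent) are
    False. Used by the two-parent chimera test to score splice models in
    centroid coordinates.
    """
    if not centroid:
        return []
    if centroid == parent:
        return [True] * len(centroid)
    res = edlib.align(parent, centroid, mode="NW", task="path")
    mask: list[bool] = []
    for n, op in _cigar_ops(res["cigar"]):
        if op == "=":
            mask.extend([True] * n)
        elif op in ("X", "D"):
            # D: gap in the parent (query) consuming centroid bases
            mask.extend([False] * n)
        # op == "I": parent base not aligned to any centroid position
    assert len(mask) == len(centroid)
    return mask
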