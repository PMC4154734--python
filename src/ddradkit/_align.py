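"""Pairwise identity and center-star multiple alignment.

Identity between two sequences is defined as matching columns divided by
alignment columns, with end gaps free (terminal gap columns are excluded
from both counts). The alignment considered is the better, by identity, of
the ungapped alignment (equal lengths only) and the score-optimal global
alignment under unit match/mismatch with affine gaps and free end gaps.
This fixed definition makes clustering results reproducible.

Cluster alignments use the center-star construction: every member is
pairwise-aligned to the centroid and the pairwise alignments are merged
column-wise. For members that are >= 85% identical to the centroid this is
an adequate and fully deterministic replacement for a general-purpose
multiple aligner.
"""

from __future__ import annotations

from Bio import Align


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    # end gaps free on both sequences
    aligner.open_end_gap_score = 0
    aligner.extend_end_gap_score = 0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_align(a: str, b: str) -> tuple[str, str]:
    """Deterministic score-optimal global alignment (end gaps free) of two
    sequences, returned as equal-length gapped strings."""
    alignment = _ALIGNER.align(a, b)[0]
    return str(alignment[0]), str(alignment[1])


def _identity_from_gapped(ga: str, gb: str) -> float:
    n = len(ga)
    start = 0
    while start < n and (ga[start] == "-" or gb[start] == "-"):
        start += 1
    end = n
    while end > start and (ga[end - 1] == "-" or gb[end - 1] == "-"):
        end -= 1
    # End-gap columns are free, but the denominator is never smaller than
    # the shorter sequence: a tiny accidental overlap between unrelated
    # sequences must not score as high identity.
    min_len = min(len(ga.replace("-", "")), len(gb.replace("-", "")))
    columns = max(end - start, min_len)
    if columns == 0:
        return 0.0
    matches = sum(
        1 for i in range(start, end) if ga[i] == gb[i] and ga[i] != "-"
    )
    return matches / columns


def identity(a: str, b: str) -> float:
    """Pairwise identity in [0, 1] under the package-wide definition."""
    if a == b:
        return 1.0
    best = 0.0
    if len(a) == len(b):
        best = sum(x == y for x, y in zip(a, b)) / len(a)
    ga, gb = pairwise_align(a, b)
    return max(best, _identity_from_gapped(ga, gb))


def meets_identity(a: str, b: str, threshold: float) -> bool:
    """True iff identity(a, b) >= threshold, with a Hamming fast path for
    equal-length pairs."""
    if a == b:
        return True
    if len(a) == len(b):
        if sum(x == y for x, y in zip(a, b)) / len(a) >= threshold:
            return True
    ga, gb = pairwise_align(a, b)
    return _identity_from_gapped(ga, gb) >= threshold


def center_star(center: str, members: list[str]) -> tuple[str, list[str]]:
    """Center-star multiple alignment.

    Returns the gapped centroid row and one gapped row per member, all the
    same length. Removing gaps from any row recovers the input sequence.
    """
    n = len(center)
    # per-member: insertions[i] = member characters inserted before center
    # position i (i == n means after the last center base), and aligned[i] =
    # the member character (or '-') aligned to center base i.
    per_member: list[tuple[list[str], list[str]]] = []
    max_ins = [0] * (n + 1)
    for mem in members:
        gc, gm = pairwise_align(center, mem)
        inserts = [""] * (n + 1)
        aligned = ["-"] * n
        ci = 0
        for cch, mch in zip(gc, gm):
            if cch == "-":
                inserts[ci] += mch
            else:
                if mch != "-":
                    aligned[ci] = mch
                ci += 1
        per_member.append((inserts, aligned))
        for i, ins in enumerate(inserts):
            max_ins[i] = max(max_ins[i], len(ins))

    center_row_parts = []
    for i in range(n + 1):
        center_row_parts.append("-" * max_ins[i])
        if i < n:
            center_row_parts.append(center[i])
    center_row = "".join(center_row_parts)

    rows: list[str] = []
    for inserts, aligned in per_member:
        parts = []
        for i in range(n + 1):
            ins = inserts[i]
            parts.append(ins + "-" * (max_ins[i] - len(ins)))
            if i < n:
                parts.append(aligned[i])
        rows.append("".join(parts))
    return center_row, rows
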