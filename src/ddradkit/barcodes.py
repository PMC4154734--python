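"""Inline barcode set construction with Hamming-code guarantees.

Barcodes are short in-read tags ligated ahead of the restriction site. The
design constraints keep them sequencer-friendly (balanced GC, no
homopolymer runs of three) while a minimum pairwise Hamming distance of 2
guarantees that any single sequencing error in the barcode is *detected*
(the read falls in the unassigned bin) rather than silently misassigned.

Construction is deterministic: candidates meeting the composition
constraints are enumerated in lexicographic order; those satisfying a
single parity check over GF(4) are kept first (a length-n single
parity-check code over GF(4) has minimum distance 2), then remaining
candidates are added greedily whenever they preserve the distance bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

_BASES = "ACGT"
_GF4 = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class Barcode:
    sequence: str
    sample_id: str = ""


@dataclass
class BarcodeSet:
    barcodes: list[Barcode] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.barcodes)

    def sequences(self) -> list[str]:
        return [b.sequence for b in self.barcodes]

    def min_pairwise_distance(self) -> int:
        seqs = self.sequences()
        best = min((hamming(a, b) for i, a in enumerate(seqs) for b in seqs[i + 1 :]),
                   default=0)
        return best


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def _max_run(seq: str) -> int:
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


def _gf4_parity(seq: str) -> int:
    # GF(4) addition is XOR on the 2-bit representation.
    acc = 0
    for base in seq:
        acc ^= _GF4[base]
    return acc


def enumerate_candidates(length: int = 6, gc_count: int = 3, max_run: int = 2) -> list[str]:
    """All sequences of the given length with exactly ``gc_count`` G/C bases
    and no run of more than ``max_run`` identical bases, in lexicographic
    order."""
    out = []
    for tup in product(_BASES, repeat=length):
        seq = "".join(tup)
        if sum(b in "GC" for b in seq) != gc_count:
            continue
        if _max_run(seq) > max_run:
            continue
        out.append(seq)
    return out


def generate_barcode_set(
    length: int = 6,
    gc_count: int = 3,
    max_run: int = 2,
    min_dist: int = 2,
) -> BarcodeSet:
    """Build a barcode set under composition and distance constraints.

    Candidates with GF(4) parity 0 form a distance-2 code and are all
    retained (when ``min_dist`` <= 2); remaining candidates are then added
    greedily in lexicographic order whenever they keep every pairwise
    distance >= ``min_dist``. Infeasible constraints yield an empty set
    with a warning rather than an exception.
    """
    if length <= 0 or gc_count < 0 or max_run <= 0 or min_dist < 1:
        warnings.warn("infeasible barcode constraints; returning empty set")
        return BarcodeSet([])
    if gc_count > length:
        warnings.warn("gc_count exceeds barcode length; returning empty set")
        return BarcodeSet([])

    candidates = enumerate_candidates(length, gc_count, max_run)
    selected: list[str] = []
    if min_dist <= 2:
        parity = [c for c in candidates if _gf4_parity(c) == 0]
        if min_dist == 1:
            selected = list(parity)
        else:
            selected = list(parity)  # parity-check code: pairwise distance >= 2
        rest = [c for c in candidates if _gf4_parity(c) != 0]
    else:
        rest = list(candidates)

    for cand in rest:
        if all(hamming(cand, s) >= min_dist for s in selected):
            selected.append(cand)

    if not selected:
        warnings.warn("no barcode satisfies the constraints; returning empty set")
    return BarcodeSet([Barcode(s) for s in selected])


def read_barcode_map(path: str | Path) -> dict[str, str]:
    """Read a TSV of (barcode, sample_id) into a mapping; duplicate barcode
    rows are a configuration error."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() in ("barcode", "sequence"):
                continue
            barcode, sample = fields[0], fields[1]
            if barcode in mapping:
                raise ValueError(f"duplicate barcode {barcode!r} in {path}")
            mapping[barcode] = sample
    return mapping


def write_barcode_map(mapping: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("barcode\tsample_id\n")
        for barcode, sample in mapping.items():
            fh.write(f"{barcode}\t{sample}\n")
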