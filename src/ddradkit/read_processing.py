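"""Read processing: demultiplexing, site reconstruction, adapter trimming,
concatemer screening, condensation and within-sample quality filtering.

Reads are sequenced from the SbfI end of each fragment. The SbfI sticky end
(TGCA) means the first two bases of the recognition site are lost to the
barcode side of the ligation, so after removing the barcode the leading
``CC`` is synthesized to reconstruct the full 8-base ``CCTGCAGG`` site.
Fragments shorter than the read length run through the EcoRI site into the
P2 adapter; the adapter is removed by an overlap alignment tolerant of
mismatches and a trailing ``C`` is appended to complete ``GAATTC``.
Synthesized bases carry a fixed sentinel quality (they are shared by every
read and are never variant positions in practice).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._align import meets_identity

SBFI_SITE = "CCTGCAGG"
ECORI_SITE = "GAATTC"
SENTINEL_QUALITY = 40
PHRED_OFFSET = 33


@dataclass
class RawRead:
    id: str
    sequence: str
    qualities: np.ndarray  # Phred scores, one per base

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")
        if self.qualities.size and (
            self.qualities.min() < 0 or self.qualities.max() > 41
        ):
            raise ValueError(f"read {self.id}: Phred scores outside [0, 41]")


@dataclass
class ProcessedRead:
    sample_id: str
    id: str
    sequence: str
    qualities: np.ndarray
    adapter_trimmed: bool = False
    ecori_internal_trimmed: bool = False


@dataclass
class CondensedRead:
    """A unique processed sequence for one sample, with multiplicity and the
    per-position maximum quality over all identical reads."""

    sample_id: str
    sequence: str
    count: int
    max_quals: np.ndarray

    def __post_init__(self) -> None:
        self.max_quals = np.asarray(self.max_quals, dtype=np.int16)
        if self.count < 1:
            raise ValueError("condensed read count must be >= 1")
        if len(self.sequence) != len(self.max_quals):
            raise ValueError("condensed read sequence/quality length mismatch")

    @property
    def mean_qual(self) -> float:
        return float(self.max_quals.mean()) if self.max_quals.size else 0.0


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    """Stream a Phred+33 FASTQ (optionally gzipped)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            quals = np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int16)
            yield RawRead(title.split()[0], seq.upper(), quals - PHRED_OFFSET)


def write_fastq(reads: Iterable[tuple[str, str, np.ndarray]], path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq, quals in reads:
            qstr = "".join(chr(int(q) + PHRED_OFFSET) for q in quals)
            fh.write(f"@{rid}\n{seq}\n+\n{qstr}\n")


@dataclass
class DemultiplexResult:
    by_sample: dict[str, list[ProcessedRead]]
    unassigned: list[RawRead]
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = {s: len(r) for s, r in self.by_sample.items()}

    @property
    def n_assigned(self) -> int:
        return sum(len(r) for r in self.by_sample.values())


def demultiplex(
    reads: Iterable[RawRead], barcode_map: dict[str, str]
) -> DemultiplexResult:
    """Assign reads to samples by exact inline-barcode match.

    Distance-2 barcode sets detect single errors but cannot correct them, so
    only exact matches are assigned; everything else lands in the unassigned
    bin. Assigned reads have the barcode removed and ``CC`` prepended (with
    sentinel quality) to reconstruct the SbfI site.
    """
    if not barcode_map:
        raise ValueError("empty barcode map")
    lengths = {len(b) for b in barcode_map}
    if len(lengths) != 1:
        raise ValueError("all barcodes must have the same length")
    if len(set(barcode_map.values())) != len(barcode_map):
        # many-to-one barcode->sample is legal; duplicate *barcodes* cannot
        # occur in a dict, so nothing further to check here.
        pass
    (bc_len,) = lengths

    by_sample: dict[str, list[ProcessedRead]] = {
        s: [] for s in dict.fromkeys(barcode_map.values())
    }
    unassigned: list[RawRead] = []
    for read in reads:
        sample = barcode_map.get(read.sequence[:bc_len])
        if sample is None:
            unassigned.append(read)
            continue
        seq = "CC" + read.sequence[bc_len:]
        quals = np.concatenate(
            [[SENTINEL_QUALITY, SENTINEL_QUALITY], read.qualities[bc_len:]]
        ).astype(np.int16)
        by_sample[sample].append(ProcessedRead(sample, read.id, seq, quals))
    return DemultiplexResult(by_sample, unassigned)


def trim_p2_adapter(
    read: ProcessedRead,
    adapter: str,
    min_overlap: int = 8,
    max_err: float = 0.2,
) -> ProcessedRead:
    """Remove a 3' P2-adapter run-through and complete the EcoRI site.

    The adapter prefix is slid along the read 3' region (overlap alignment
    with unit mismatch cost, no gaps); the position with the lowest error
    rate wins, leftmost on ties. If the best overlap spans at least
    ``min_overlap`` bases with an error rate <= ``max_err`` the read is
    truncated at the overlap start and a single ``C`` (sentinel quality) is
    appended, completing ``GAATTC``; otherwise the read is unchanged.
    """
    if not adapter:
        raise ValueError("empty adapter sequence")
    seq = read.sequence
    best: Optional[tuple[float, int]] = None
    for start in range(len(seq) - min_overlap + 1):
        k = min(len(seq) - start, len(adapter))
        if k < min_overlap:
            break
        mismatches = sum(a != b for a, b in zip(seq[start : start + k], adapter[:k]))
        err = mismatches / k
        if err <= max_err and (best is None or err < best[0]):
            best = (err, start)
    if best is None:
        return replace(read, adapter_trimmed=False)
    start = best[1]
    new_seq = seq[:start] + "C"
    new_quals = np.concatenate([read.qualities[:start], [SENTINEL_QUALITY]]).astype(
        np.int16
    )
    return replace(
        read, sequence=new_seq, qualities=new_quals, adapter_trimmed=True
    )


def screen_internal_sites(read: ProcessedRead) -> tuple[str, Optional[ProcessedRead]]:
    """Concatemer screen.

    A complete internal SbfI site marks a chimera of two restriction
    fragments: the read is discarded. An internal EcoRI site marks the true
    locus terminus followed by concatemer sequence: the read is truncated
    immediately after that site (the site itself is retained). Returns one
    of ("discard", None), ("trim", read) or ("keep", read). The scan starts
    after the leading reconstructed SbfI site.
    """
    seq = read.sequence
    if seq.find(SBFI_SITE, 1) != -1:
        return "discard", None
    idx = seq.find(ECORI_SITE, len(SBFI_SITE))
    if idx != -1:
        end = idx + len(ECORI_SITE)
        if end < len(seq):
            trimmed = replace(
                read,
                sequence=seq[:end],
                qualities=read.qualities[:end].copy(),
                ecori_internal_trimmed=True,
            )
            return "trim", trimmed
    return "keep", read


def condense_reads(reads: Iterable[ProcessedRead]) -> list[CondensedRead]:
    """Collapse identical sequences for one sample, keeping the multiplicity
    and the position-wise maximum quality (conservative: repeated identical
    observations only increase confidence)."""
    groups: dict[str, CondensedRead] = {}
    sample_ids = set()
    for read in reads:
        sample_ids.add(read.sample_id)
        if len(sample_ids) > 1:
            raise ValueError("condense_reads expects reads from a single sample")
        existing = groups.get(read.sequence)
        if existing is None:
            groups[read.sequence] = CondensedRead(
                read.sample_id, read.sequence, 1, read.qualities.copy()
            )
        else:
            existing.count += 1
            np.maximum(existing.max_quals, read.qualities, out=existing.max_quals)
    return list(groups.values())


def within_sample_quality_filter(
    condensed: list[CondensedRead],
    identity_threshold: float = 0.90,
    min_mean_q: float = 20.0,
) -> list[CondensedRead]:
    """Drop low-quality singletons with no within-sample neighbor.

    A condensed read is removed only when its mean quality is below
    ``min_mean_q``, it was observed once, and no other condensed read from
    the sample is within the identity threshold; such reads are most likely
    pure sequencing error.
    """
    kept: list[CondensedRead] = []
    for i, cr in enumerate(condensed):
        if cr.mean_qual >= min_mean_q or cr.count > 1:
            kept.append(cr)
            continue
        has_neighbor = any(
            meets_identity(cr.sequence, other.sequence, identity_threshold)
            for j, other in enumerate(condensed)
            if j != i
        )
        if has_neighbor:
            kept.append(cr)
    return kept


def process_sample_reads(
    reads: Iterable[ProcessedRead],
    adapter: str,
    min_overlap: int = 8,
    max_err: float = 0.2,
    identity_threshold: float = 0.90,
    min_mean_q: float = 20.0,
) -> tuple[list[CondensedRead], dict[str, int]]:
    """Adapter-trim, concatemer-screen, condense and quality-filter the
    reads of one sample; returns the condensed reads and step counters."""
    stats = {"input": 0, "discarded_internal_sbfi": 0, "trimmed_internal_ecori": 0,
             "adapter_trimmed": 0, "condensed": 0, "low_quality_removed": 0}
    surviving: list[ProcessedRead] = []
    for read in reads:
        stats["input"] += 1
        read = trim_p2_adapter(read, adapter, min_overlap, max_err)
        if read.adapter_trimmed:
            stats["adapter_trimmed"] += 1
        decision, read = screen_internal_sites(read)
        if decision == "discard":
            stats["discarded_internal_sbfi"] += 1
            continue
        if decision == "trim":
            stats["trimmed_internal_ecori"] += 1
        surviving.append(read)
    condensed = condense_reads(surviving) if surviving else []
    stats["condensed"] = len(condensed)
    filtered = within_sample_quality_filter(condensed, identity_threshold, min_mean_q)
    stats["low_quality_removed"] = len(condensed) - len(filtered)
    return filtered, stats


def write_condensed_tsv(condensed: Iterable[CondensedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tsequence\tcount\tmax_quals\n")
        for cr in condensed:
            quals = ",".join(str(int(q)) for q in cr.max_quals)
            fh.write(f"{cr.sample_id}\t{cr.sequence}\t{cr.count}\t{quals}\n")


def read_condensed_tsv(path: str | Path) -> list[CondensedRead]:
    out: list[CondensedRead] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sample_id"):
            raise ValueError(f"{path}: not a condensed-read TSV")
        for line in fh:
            sample, seq, count, quals = line.rstrip("\n").split("\t")
            out.append(
                CondensedRead(
                    sample, seq, int(count),
                    np.array([int(q) for q in quals.split(",")], dtype=np.int16),
                )
            )
    return out
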