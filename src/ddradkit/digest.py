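"""In silico double digestion and ddRAD locus prediction.

A ddRAD locus is the genomic interval between a site of the rare cutter
(enzyme A, e.g. SbfI) and the nearest site of the frequent cutter (enzyme B,
e.g. EcoRI), with no intervening site of either enzyme. Coordinates are
0-based half-open on the top strand and span the *full* recognition sites at
both ends, because sample processing reconstructs the complete sites on each
read. Recognition sites of the two enzymes may overlap; the shortest
reconstructible SbfI-EcoRI locus is therefore |recA| + |recB| - 1 = 13 bp
(sites overlapping by one base).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from .enzymes import Enzyme, UnsupportedEnzymeError, reverse_complement
from .genome import ReferenceGenome


@dataclass(frozen=True)
class CutSite:
    """One exact recognition-site match: ``pos`` is the 0-based start of the
    recognition sequence on the top strand."""

    contig: str
    pos: int
    enzyme: Enzyme


@dataclass(frozen=True)
class Fragment:
    """Interval between two consecutive recognition-site matches (or a
    chromosome end). ``left_enzyme``/``right_enzyme`` are None at contig ends.
    Coordinates include both full recognition sites."""

    contig: str
    start: int
    end: int
    left_enzyme: Optional[Enzyme]
    right_enzyme: Optional[Enzyme]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SizeWindow:
    """Inclusive bounds on locus length (full sites included)."""

    min_bp: int
    max_bp: int

    def __post_init__(self) -> None:
        if not 0 < self.min_bp <= self.max_bp:
            raise ValueError(f"invalid size window [{self.min_bp}, {self.max_bp}]")

    def __contains__(self, length: int) -> bool:
        return self.min_bp <= length <= self.max_bp


@dataclass
class PredictedLocus:
    """A predicted enzyme-A-to-enzyme-B fragment.

    ``sequence`` always begins with the enzyme-A recognition site: for
    minus-orientation loci (A-site rightmost on the top strand) it is the
    reverse complement of the genomic interval. ``contains_n`` flags loci
    with ambiguous bases, which are retained but marked.
    """

    contig: str
    start: int
    end: int
    orientation: str  # "+" or "-"
    length_bp: int
    gc_fraction: float
    sequence: str
    single_copy: Optional[bool] = None
    contains_n: bool = False

    @property
    def locus_id(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}{self.orientation}"


def gc_fraction(sequence: str) -> float:
    """GC fraction of ``sequence``: (#G + #C) / (length - #N).

    N bases are excluded from the denominator; an empty or all-N sequence
    raises, since its base composition is undefined.
    """
    if not sequence:
        raise ValueError("gc_fraction of empty sequence")
    seq = sequence.upper()
    n = seq.count("N")
    denom = len(seq) - n
    if denom == 0:
        raise ValueError("gc_fraction undefined: sequence is all N")
    return (seq.count("G") + seq.count("C")) / denom


def find_cut_sites(genome: ReferenceGenome, enzyme: Enzyme) -> list[CutSite]:
    """All exact recognition-site matches, sorted per contig.

    Palindromic enzymes only: a palindromic match on the top strand is its
    own reverse-complement match, so no separate minus-strand scan is done.
    Sites containing N never match (matching is exact).
    """
    if not enzyme.palindromic:
        raise UnsupportedEnzymeError(
            f"{enzyme.name}: only palindromic enzymes are supported"
        )
    if len(genome) == 0:
        raise ValueError("empty genome")
    sites: list[CutSite] = []
    rec = enzyme.recognition
    for contig, seq in genome.items():
        i = seq.find(rec)
        while i != -1:
            sites.append(CutSite(contig, i, enzyme))
            i = seq.find(rec, i + 1)
    return sites


def expected_radseq_fragments(n_sites: int) -> int:
    """Single-enzyme RAD-seq yields one sequenced fragment upstream and one
    downstream of every cut site: 2 x number of sites."""
    return 2 * n_sites


def double_digest(
    genome: ReferenceGenome, enz_a: Enzyme, enz_b: Enzyme
) -> list[Fragment]:
    """Pool both enzymes' sites per contig and return the intervals between
    consecutive recognition-site matches, labelled by their end enzymes.

    Overlapping sites are legal and produce fragments down to
    |recA| + |recB| - 1 bp. Fragments flanking contig ends carry ``None``
    for the missing end.
    """
    if enz_a.recognition == enz_b.recognition:
        raise ValueError("the two enzymes must have distinct recognition sequences")
    by_contig: dict[str, list[CutSite]] = {}
    for enz in (enz_a, enz_b):
        for site in find_cut_sites(genome, enz):
            by_contig.setdefault(site.contig, []).append(site)
    fragments: list[Fragment] = []
    for contig, seq in genome.items():
        sites = sorted(by_contig.get(contig, []), key=lambda s: (s.pos, s.enzyme.name))
        if not sites:
            fragments.append(Fragment(contig, 0, len(seq), None, None))
            continue
        first, last = sites[0], sites[-1]
        fragments.append(
            Fragment(contig, 0, first.pos + first.enzyme.site_length, None, first.enzyme)
        )
        for left, right in zip(sites, sites[1:]):
            fragments.append(
                Fragment(
                    contig,
                    left.pos,
                    right.pos + right.enzyme.site_length,
                    left.enzyme,
                    right.enzyme,
                )
            )
        fragments.append(Fragment(contig, last.pos, len(seq), last.enzyme, None))
    return fragments


def predict_ddrad_loci(
    genome: ReferenceGenome,
    enz_a: Enzyme,
    enz_b: Enzyme,
    window: SizeWindow,
) -> list[PredictedLocus]:
    """Predict ddRAD loci: A-B fragments within the size window.

    Both orientations are reported. When the A site is leftmost on the top
    strand the orientation is "+" and the sequence is the genomic interval;
    when the B site is leftmost ("-") the sequence is reverse complemented so
    the A site always leads, matching the structure of sequencing reads.
    Output is sorted by (contig, start).
    """
    loci: list[PredictedLocus] = []
    for frag in double_digest(genome, enz_a, enz_b):
        if frag.left_enzyme is None or frag.right_enzyme is None:
            continue
        ends = (frag.left_enzyme.name, frag.right_enzyme.name)
        if ends == (enz_a.name, enz_b.name):
            orientation = "+"
        elif ends == (enz_b.name, enz_a.name):
            orientation = "-"
        else:
            continue
        if frag.length not in window:
            continue
        seq = genome[frag.contig][frag.start : frag.end]
        if orientation == "-":
            seq = reverse_complement(seq)
        loci.append(
            PredictedLocus(
                contig=frag.contig,
                start=frag.start,
                end=frag.end,
                orientation=orientation,
                length_bp=frag.length,
                gc_fraction=gc_fraction(seq),
                sequence=seq,
                contains_n="N" in seq,
            )
        )
    loci.sort(key=lambda l: (l.contig, l.start))
    return loci


def _count_occurrences(haystack: str, needle: str) -> int:
    count = 0
    i = haystack.find(needle)
    while i != -1:
        count += 1
        i = haystack.find(needle, i + 1)
    return count


def single_copy_filter(
    loci: Iterable[PredictedLocus], genome: ReferenceGenome, tag_len: int = 100
) -> list[PredictedLocus]:
    """Mark loci whose leading tag is unique in the genome and return the
    single-copy ("stringent") subset.

    The tag is the first ``tag_len`` bases of the locus sequence (the whole
    sequence for shorter loci). A locus is single-copy iff the tag occurs
    exactly once in the genome counting both strands — a deterministic
    exact-occurrence criterion standing in for a unique high-quality
    alignment hit. All input loci get ``single_copy`` set in place.
    """
    retained: list[PredictedLocus] = []
    for locus in loci:
        tag = locus.sequence[:tag_len]
        rc = reverse_complement(tag)
        hits = 0
        for _, seq in genome.items():
            hits += _count_occurrences(seq, tag)
            if rc != tag:
                hits += _count_occurrences(seq, rc)
        locus.single_copy = hits == 1
        if locus.single_copy:
            retained.append(locus)
    return retained


def write_loci_tsv(loci: Iterable[PredictedLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\torientation\tlength\tgc\tsingle_copy\n")
        for l in loci:
            sc = "" if l.single_copy is None else str(l.single_copy)
            fh.write(
                f"{l.contig}\t{l.start}\t{l.end}\t{l.orientation}\t"
                f"{l.length_bp}\t{l.gc_fraction:.4f}\t{sc}\n"
            )


def write_loci_fasta(loci: Iterable[PredictedLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f">{l.locus_id}\n{l.sequence}\n")
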