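"""Across-sample locus clustering, reference mapping, positional merging
and per-cluster alignment.

Condensed reads from all samples are pooled and clustered greedily: reads
are processed in descending mean quality (ties: descending count, then
lexicographic sequence) and each read joins the first existing centroid it
matches at the identity threshold, else founds a new cluster. Cluster
centroids are mapped to a reference; clusters hitting (approximately) the
same position on the same strand are merged, which re-unites alleles that
differ by a long indel and therefore failed to cluster at the identity
threshold. Unmapped clusters are retained as anonymous loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional
import warnings

import edlib

from ._align import center_star, meets_identity
from .enzymes import reverse_complement
from .genome import ReferenceGenome
from .read_processing import CondensedRead


@dataclass
class ReferenceHit:
    contig: str
    pos: int  # 0-based start of the best match on the top strand
    strand: str  # "+" or "-"
    score: float  # alignment identity fraction in [0, 1]
    unique: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("hit identity must be in [0, 1]")


@dataclass
class MultipleAlignment:
    rows: list[str]
    members: list[CondensedRead]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __post_init__(self) -> None:
        if len(self.rows) != len(self.members):
            raise ValueError("one alignment row per member required")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows must have equal length")
        for row, mem in zip(self.rows, self.members):
            if row.replace("-", "") != mem.sequence:
                raise ValueError("removing gaps must recover the member sequence")


@dataclass
class LocusCluster:
    cluster_id: int
    centroid: CondensedRead
    members: list[CondensedRead] = field(default_factory=list)
    hit: Optional[ReferenceHit] = None
    alignment: Optional[MultipleAlignment] = None

    @property
    def anonymous(self) -> bool:
        return self.hit is None

    @property
    def n_samples(self) -> int:
        return len({m.sample_id for m in self.members})

    @property
    def n_reads(self) -> int:
        return sum(m.count for m in self.members)


def _sort_key(cr: CondensedRead) -> tuple:
    return (-cr.mean_qual, -cr.count, cr.sequence)


def cluster_across_samples(
    condensed: Iterable[CondensedRead], identity_threshold: float = 0.85
) -> list[LocusCluster]:
    """Greedy centroid clustering of pooled condensed reads into putative
    loci. Every input read ends up in exactly one cluster."""
    ordered = sorted(condensed, key=_sort_key)
    clusters: list[LocusCluster] = []
    for cr in ordered:
        placed = False
        for cluster in clusters:
            if meets_identity(cr.sequence, cluster.centroid.sequence, identity_threshold):
                cluster.members.append(cr)
                placed = True
                break
        if not placed:
            clusters.append(LocusCluster(len(clusters), cr, [cr]))
    return clusters


Mapper = Callable[[str], list[ReferenceHit]]


class ExactishMapper:
    """Built-in mapper for synthetic genomes: edit-distance search of the
    centroid against both strands of every contig. A strict pass tolerates
    ``max_err`` errors per base; when it finds nothing, a relaxed pass at
    ``relaxed_max_err`` rescues alleles separated from the reference by a
    long indel (which a local aligner would bridge with one gap but edit
    distance charges per base). ``unique`` is set when exactly one optimal
    location exists genome-wide."""

    def __init__(
        self,
        genome: ReferenceGenome,
        max_err: float = 0.10,
        relaxed_max_err: float = 0.30,
    ) -> None:
        self.genome = genome
        self.max_err = max_err
        self.relaxed_max_err = relaxed_max_err

    def __call__(self, sequence: str) -> list[ReferenceHit]:
        hits = self._search(sequence, self.max_err)
        if not hits and self.relaxed_max_err > self.max_err:
            hits = self._search(sequence, self.relaxed_max_err)
        return hits

    def _search(self, sequence: str, max_err: float) -> list[ReferenceHit]:
        k = int(max_err * len(sequence))
        best_dist: Optional[int] = None
        locations: list[tuple[str, int, str]] = []
        for contig, seq in self.genome.items():
            for strand, text in (("+", seq), ("-", reverse_complement(seq))):
                res = edlib.align(sequence, text, mode="HW", task="locations", k=k)
                if res["editDistance"] == -1:
                    continue
                dist = res["editDistance"]
                if best_dist is None or dist < best_dist:
                    best_dist = dist
                    locations = []
                if dist == best_dist:
                    seen = set()
                    for start, end in res["locations"]:
                        if start in seen:
                            continue
                        seen.add(start)
                        if strand == "+":
                            pos = start
                        else:
                            pos = len(seq) - (end + 1)
                        locations.append((contig, pos, strand))
        if best_dist is None:
            return []
        score = 1.0 - best_dist / len(sequence)
        uniq = len(set(locations)) == 1
        return [
            ReferenceHit(contig, pos, strand, score, uniq)
            for contig, pos, strand in sorted(set(locations))
        ]


def map_clusters(clusters: list[LocusCluster], mapper: Mapper) -> list[LocusCluster]:
    """Attach the best reference hit to each cluster; clusters with no hit
    (or a failing mapper) stay anonymous and are retained."""
    for cluster in clusters:
        try:
            hits = mapper(cluster.centroid.sequence)
        except Exception as exc:  # mapper failure is not fatal
            warnings.warn(f"mapper failed on cluster {cluster.cluster_id}: {exc}")
            hits = []
        cluster.hit = hits[0] if hits else None
    return clusters


def merge_by_position(
    clusters: list[LocusCluster], tol_bp: int = 50, chain: bool = True
) -> list[LocusCluster]:
    """Merge clusters whose hits share contig and strand and lie within
    ``tol_bp`` of each other.

    With ``chain=True`` (default) merging is single-link: positions are
    chained while each consecutive gap is <= ``tol_bp``. With
    ``chain=False`` each cluster must be within ``tol_bp`` of the group's
    first (anchor) position. Anonymous clusters never merge. The merged
    cluster keeps the highest-quality centroid and that centroid's hit.
    """
    anonymous = [c for c in clusters if c.anonymous]
    mapped = [c for c in clusters if not c.anonymous]
    groups: dict[tuple[str, str], list[LocusCluster]] = {}
    for c in mapped:
        groups.setdefault((c.hit.contig, c.hit.strand), []).append(c)

    merged: list[LocusCluster] = []
    for _, group in sorted(groups.items()):
        group.sort(key=lambda c: (c.hit.pos, _sort_key(c.centroid)))
        current: list[LocusCluster] = []
        anchor_pos = None
        last_pos = None
        for c in group:
            if not current:
                current = [c]
                anchor_pos = last_pos = c.hit.pos
                continue
            ref = last_pos if chain else anchor_pos
            if c.hit.pos - ref <= tol_bp:
                current.append(c)
                last_pos = c.hit.pos
            else:
                merged.append(_fuse(current))
                current = [c]
                anchor_pos = last_pos = c.hit.pos
        if current:
            merged.append(_fuse(current))

    out = merged + anonymous
    for new_id, c in enumerate(out):
        c.cluster_id = new_id
    return out


def _fuse(group: list[LocusCluster]) -> LocusCluster:
    if len(group) == 1:
        return group[0]
    best = min(group, key=lambda c: _sort_key(c.centroid))
    members = [m for c in group for m in c.members]
    return LocusCluster(best.cluster_id, best.centroid, members, best.hit)


def align_cluster(cluster: LocusCluster) -> MultipleAlignment:
    """Center-star multiple alignment of the cluster members against the
    centroid; deterministic, columns consistent across rows."""
    if not cluster.members:
        raise ValueError("cannot align an empty cluster")
    order = sorted(cluster.members, key=_sort_key)
    _, rows = center_star(cluster.centroid.sequence, [m.sequence for m in order])
    alignment = MultipleAlignment(rows, order)
    cluster.alignment = alignment
    return alignment


def write_cluster_tsv(clusters: Iterable[LocusCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tn_samples\tn_reads\tcontig\tpos\tstrand\tanonymous\n")
        for c in clusters:
            if c.hit is None:
                contig = pos = strand = ""
            else:
                contig, pos, strand = c.hit.contig, c.hit.pos, c.hit.strand
            fh.write(
                f"{c.cluster_id}\t{c.n_samples}\t{c.n_reads}\t"
                f"{contig}\t{pos}\t{strand}\t{c.anonymous}\n"
            )
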