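"""Concordance of pipeline output with simulator truth.

Matches merged clusters to true loci by their reference hit (the cluster's
mapped position against the locus coordinates) and compares each sample's
genotype call with the truth-observable genotype: the multiset of
read-visible allele sequences. An allele is read-visible when it is not a
null allele; two alleles that only differ beyond the read capacity are
indistinguishable, so a true heterozygote for such a pair is observably
homozygous (as it would be in real data).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .genotyping import HET, HET_PROVISIONAL_PASSED, HOM, LOW_DEPTH, LocusGenotypes
from .clustering import LocusCluster
from .pipeline import PipelineResult
from .simulate import DepthDraw, TruthTable, expected_processed_sequence

HET_LIKE = {HET, HET_PROVISIONAL_PASSED}
CALLED = {HOM, HET, HET_PROVISIONAL_PASSED, LOW_DEPTH}


def match_clusters_to_truth(
    result: PipelineResult, truth: TruthTable, tol_bp: int = 60
) -> dict[str, LocusCluster]:
    """Map truth locus_id -> mapped cluster whose hit lies within
    ``tol_bp`` of the locus start on the expected strand."""
    matches: dict[str, LocusCluster] = {}
    for lt in truth.loci:
        locus = lt.locus
        strand = locus.orientation
        best: Optional[LocusCluster] = None
        for cluster in result.clusters:
            hit = cluster.hit
            if hit is None or hit.contig != locus.contig or hit.strand != strand:
                continue
            # reads start at the SbfI end: on the plus strand the mapped
            # leftmost coordinate is the locus start; on the minus strand it
            # is the locus end minus the mapped read length
            if strand == "+":
                delta = hit.pos - locus.start
            else:
                delta = (hit.pos + len(cluster.centroid.sequence)) - locus.end
            if abs(delta) <= tol_bp:
                if best is None or cluster.n_reads > best.n_reads:
                    best = cluster
        if best is not None:
            matches[lt.locus_id] = best
    return matches


def _called_allele_sequences(
    lg: LocusGenotypes, cluster: LocusCluster, sample: str
) -> Optional[frozenset[str]]:
    """Reconstruct the called alleles of one sample as full (ungapped)
    sequences: for each called haplotype, the most frequent member read
    carrying it."""
    call = lg.calls[sample]
    if call.status not in CALLED:
        return None
    assert cluster.alignment is not None
    seqs = []
    for hap_idx in {call.allele1, call.allele2}:
        hap = lg.haplotypes[hap_idx]
        best_seq, best_count = None, -1
        for row, mem in zip(cluster.alignment.rows, cluster.alignment.members):
            states = "".join(row[c.index] for c in lg.columns)
            if states == hap.states and mem.count > best_count:
                best_seq, best_count = mem.sequence, mem.count
        if best_seq is None:
            return None
        seqs.append(best_seq)
    return frozenset(seqs)


@dataclass
class ConcordanceReport:
    n_compared: int
    n_concordant: int
    mismatches: list[tuple[str, str]]  # (locus_id, sample)

    @property
    def fraction(self) -> float:
        return self.n_concordant / self.n_compared if self.n_compared else float("nan")


def genotype_concordance(
    result: PipelineResult,
    truth: TruthTable,
    depths: list[DepthDraw],
    min_allele_depth: int = 10,
    read_len: int = 100,
) -> ConcordanceReport:
    """Fraction of (locus, sample) cells whose call matches truth.

    Only cells where every read-visible allele reached
    ``min_allele_depth`` realized reads are compared (low-depth cells are
    not informative about caller correctness). A call is concordant when
    the set of called allele sequences equals the set of truth-observable
    processed allele sequences.
    """
    depth_by = {(d.sample, d.locus_id, d.allele): d.realized for d in depths}
    matches = match_clusters_to_truth(result, truth)
    by_cluster = result.genotypes_by_cluster_id()
    n = ok = 0
    mismatches: list[tuple[str, str]] = []
    for lt in truth.loci:
        cluster = matches.get(lt.locus_id)
        lg = None
        if cluster is not None:
            lg = by_cluster.get(f"cluster{cluster.cluster_id:05d}")
        for sample in lt.genotypes:
            visible = lt.observable_alleles(sample)
            if not visible:
                continue
            if any(
                depth_by.get((sample, lt.locus_id, a), 0) < min_allele_depth
                for a in set(visible)
            ):
                continue
            expected = frozenset(
                expected_processed_sequence(lt.alleles[a].sequence, read_len)
                for a in visible
            )
            n += 1
            if lg is None:
                mismatches.append((lt.locus_id, sample))
                continue
            called = _called_allele_sequences(lg, cluster, sample)
            if called == expected:
                ok += 1
            else:
                mismatches.append((lt.locus_id, sample))
    return ConcordanceReport(n, ok, mismatches)
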