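"""End-to-end orchestration: raw reads to genotype calls.

This is the canonical order of operations: demultiplex by inline barcode,
trim P2 adapter run-through, screen concatemers, condense and
quality-filter within each sample, pool and cluster across samples at 85%
identity, map cluster centroids to the reference, merge clusters hitting
the same position, align each cluster and genotype it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .clustering import (
    ExactishMapper,
    LocusCluster,
    align_cluster,
    cluster_across_samples,
    map_clusters,
    merge_by_position,
)
from .genome import ReferenceGenome
from .genotyping import (
    GenotypeThresholds,
    LocusGenotypes,
    LocusScreenResult,
    genotype_locus,
    screen_duplicate_loci,
)
from .read_processing import (
    CondensedRead,
    RawRead,
    demultiplex,
    process_sample_reads,
)
from .simulate import P2_ADAPTER


@dataclass
class PipelineConfig:
    adapter: str = P2_ADAPTER
    adapter_min_overlap: int = 8
    adapter_max_err: float = 0.2
    within_identity: float = 0.90
    min_mean_q: float = 20.0
    across_identity: float = 0.85
    merge_tol_bp: int = 50
    merge_chain: bool = True
    mapper_max_err: float = 0.10
    min_cluster_reads: int = 1
    thresholds: GenotypeThresholds = field(default_factory=GenotypeThresholds)


@dataclass
class PipelineResult:
    clusters: list[LocusCluster]
    genotypes: list[LocusGenotypes]
    screens: list[LocusScreenResult]
    samples: list[str]
    stats: dict[str, object]

    def genotypes_by_cluster_id(self) -> dict[str, LocusGenotypes]:
        return {lg.locus_id: lg for lg in self.genotypes}


def run_pipeline(
    reads: Iterable[RawRead],
    barcode_map: dict[str, str],
    genome: Optional[ReferenceGenome] = None,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run the whole pipeline in memory. ``genome`` enables reference
    mapping and positional merging; without it every cluster is anonymous.
    """
    demux = demultiplex(reads, barcode_map)
    samples = sorted(demux.by_sample)
    stats: dict[str, object] = {
        "n_input": demux.n_assigned + len(demux.unassigned),
        "n_assigned": demux.n_assigned,
        "n_unassigned": len(demux.unassigned),
        "per_sample": {},
    }
    pooled: list[CondensedRead] = []
    for sample in samples:
        condensed, sstats = process_sample_reads(
            demux.by_sample[sample],
            config.adapter,
            config.adapter_min_overlap,
            config.adapter_max_err,
            config.within_identity,
            config.min_mean_q,
        )
        stats["per_sample"][sample] = sstats
        pooled.extend(condensed)

    clusters = cluster_across_samples(pooled, config.across_identity)
    if genome is not None:
        clusters = map_clusters(clusters, ExactishMapper(genome, config.mapper_max_err))
        clusters = merge_by_position(clusters, config.merge_tol_bp, config.merge_chain)
    stats["n_clusters"] = len(clusters)

    genotypes: list[LocusGenotypes] = []
    for cluster in clusters:
        if cluster.n_reads < config.min_cluster_reads:
            continue
        msa = align_cluster(cluster)
        genotypes.append(
            genotype_locus(msa, samples, config.thresholds, f"cluster{cluster.cluster_id:05d}")
        )
    screens = screen_duplicate_loci(genotypes, max_flagged=config.thresholds.flagged_locus_max)
    return PipelineResult(clusters, genotypes, screens, samples, stats)
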