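"""Haplotype-count genotype calling with Mendelian ratio thresholds.

For each putative locus the aligned reads are scanned for variant columns
(SNPs and indels; a gap is a state). Each read's states at the variant
columns form its haplotype, and per-sample haplotype read counts are
compared with Mendelian expectations: a diploid should show one haplotype
(homozygote) or two at roughly equal frequency (heterozygote). Fractions in
between flag ambiguous calls that usually betray duplicated loci or
artifacts. Trailing low-quality variable positions truncate the locus
before scoring. Unique indels are additionally gap-coded as single
presence/absence characters regardless of length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .clustering import MultipleAlignment

# Genotype statuses
HOM = "HOM"
HET = "HET"
HET_PROVISIONAL_PASSED = "HET_PROVISIONAL_PASSED"
BAD_RATIO = "BAD_RATIO"
EXTRA_READS = "EXTRA_READS"
LOW_DEPTH = "LOW_DEPTH"
MISSING = "MISSING"

FLAGGED = {BAD_RATIO, EXTRA_READS}


@dataclass(frozen=True)
class GenotypeThresholds:
    """Haplotype-ratio thresholds.

    A sample is homozygous when more than ``hom_min_frac`` of its reads
    carry a single haplotype, heterozygous when the second haplotype holds
    strictly more than ``het_min_frac`` of reads. Second-haplotype
    fractions in the inclusive band [``prov_low``, ``prov_high``] are
    provisional heterozygotes, rescued only when both haplotypes occur in
    other samples; fractions in [``ambig_low``, ``prov_low``) are flagged
    as bad ratios. A putative heterozygote whose third haplotype exceeds
    ``third_hap_max`` is flagged as extra reads. At variable loci,
    homozygotes with depth below ``min_hom_depth`` are low-depth. Variable
    positions whose read-weighted mean quality drops below ``trunc_mean_q``
    truncate the locus. Loci with more than ``flagged_locus_max`` flagged
    genotypes are excluded downstream.
    """

    hom_min_frac: float = 0.93
    het_min_frac: float = 0.29  # strict > in both cases
    prov_low: float = 0.20
    prov_high: float = 0.29
    ambig_low: float = 0.07
    third_hap_max: float = 0.10
    min_hom_depth: int = 5
    trunc_mean_q: float = 25.0
    flagged_locus_max: int = 2
    min_state_reads: int = 2
    min_state_frac: float = 0.20

    def __post_init__(self) -> None:
        if not 0 < self.ambig_low < self.prov_low <= self.prov_high < self.hom_min_frac <= 1:
            raise ValueError("inconsistent genotype threshold bands")


@dataclass
class VariantColumn:
    index: int
    kind: str  # "SNP" or "indel"
    states: list[str]
    mean_quality: float


@dataclass
class Haplotype:
    states: str  # one character per variant column; '-' for a gap state
    counts: dict[str, int] = field(default_factory=dict)  # sample -> reads

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class GenotypeCall:
    sample_id: str
    locus_id: str
    status: str
    allele1: Optional[int]  # haplotype indices; equal for homozygotes
    allele2: Optional[int]
    depth: int
    allele_depths: dict[int, int] = field(default_factory=dict)


def _column_states_and_quality(
    msa: MultipleAlignment, col: int
) -> tuple[dict[str, int], dict[str, dict[str, int]], float]:
    """Pooled and per-sample read counts per state, and the read-weighted
    mean quality, for one column.

    A gap carries the member's mean quality (the member has no base there);
    real bases carry the member's per-position maximum quality.
    """
    counts: dict[str, int] = {}
    per_sample: dict[str, dict[str, int]] = {}
    q_sum = 0.0
    n = 0
    for row, mem in zip(msa.rows, msa.members):
        state = row[col]
        counts[state] = counts.get(state, 0) + mem.count
        sample_counts = per_sample.setdefault(mem.sample_id, {})
        sample_counts[state] = sample_counts.get(state, 0) + mem.count
        if state == "-":
            q = mem.mean_qual
        else:
            seq_pos = len(row[:col].replace("-", ""))
            q = float(mem.max_quals[seq_pos])
        q_sum += q * mem.count
        n += mem.count
    return counts, per_sample, (q_sum / n if n else 0.0)


def detect_variant_columns(
    msa: MultipleAlignment, thresholds: GenotypeThresholds = GenotypeThresholds()
) -> tuple[list[VariantColumn], Optional[int]]:
    """Find variant columns, truncating at the first low-quality one.

    A column is variant when at least two states occur across all reads
    (gap counts as a state). To establish a variable site, a state must be
    backed by at least ``min_state_reads`` reads making up at least
    ``min_state_frac`` of the reads of some single sample — the initial
    identification threshold that keeps isolated sequencing errors from
    spawning spurious variant columns. (A genuine allele always clears it:
    a heterozygote carries it in about half its reads.) Singleton reads
    are still retained and counted once a site is established. Scanning
    left to right, the first variant column whose read-weighted mean
    quality is below ``trunc_mean_q`` truncates the locus at that column:
    it and everything to its right are discarded. Returns the retained
    variant columns and the truncation point (None when nothing was
    truncated).
    """
    if not msa.rows:
        raise ValueError("empty alignment")
    columns: list[VariantColumn] = []
    truncate_at: Optional[int] = None
    for col in range(msa.n_columns):
        counts, per_sample, mean_q = _column_states_and_quality(msa, col)
        supported = set()
        for sample_counts in per_sample.values():
            depth = sum(sample_counts.values())
            for state, c in sample_counts.items():
                if c >= thresholds.min_state_reads and c >= thresholds.min_state_frac * depth:
                    supported.add(state)
        if len(supported) < 2:
            continue
        if mean_q < thresholds.trunc_mean_q:
            truncate_at = col
            break
        kind = "indel" if "-" in counts else "SNP"
        columns.append(
            VariantColumn(col, kind, sorted(counts), mean_q)
        )
    return columns, truncate_at


def count_haplotypes(
    msa: MultipleAlignment, columns: Sequence[VariantColumn]
) -> list[Haplotype]:
    """Tally per-sample read counts for each haplotype over the variant
    columns; condensed-read multiplicities accumulate. With no variant
    columns a single empty haplotype holds every read. Haplotypes are
    ordered by total count descending (ties lexicographic)."""
    table: dict[str, Haplotype] = {}
    for row, mem in zip(msa.rows, msa.members):
        key = "".join(row[c.index] for c in columns)
        hap = table.setdefault(key, Haplotype(key))
        hap.counts[mem.sample_id] = hap.counts.get(mem.sample_id, 0) + mem.count
    return sorted(table.values(), key=lambda h: (-h.total, h.states))


def call_genotype(
    sample_counts: dict[int, int],
    population_presence: set[int],
    thresholds: GenotypeThresholds = GenotypeThresholds(),
    locus_variable: bool = True,
    sample_id: str = "",
    locus_id: str = "",
) -> GenotypeCall:
    """Score one sample at one locus from its haplotype read counts.

    ``sample_counts`` maps haplotype index -> reads for this sample;
    ``population_presence`` is the set of haplotype indices observed (>= 1
    read) in at least one *other* sample, used to rescue provisional
    heterozygotes. Fractions are taken over all reads the sample has at the
    locus. Decision order: heterozygote band (with the extra-reads check on
    the third haplotype), provisional band with population rescue,
    bad-ratio band, homozygote (downgraded to low depth at variable loci
    with depth below the minimum).
    """
    if any(c < 0 for c in sample_counts.values()):
        raise ValueError("negative haplotype count")
    depth = sum(sample_counts.values())
    if depth == 0:
        return GenotypeCall(sample_id, locus_id, MISSING, None, None, 0, {})
    ranked = sorted(sample_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    h1, c1 = ranked[0]
    h2, c2 = ranked[1] if len(ranked) > 1 else (None, 0)
    c3 = ranked[2][1] if len(ranked) > 2 else 0
    f1, f2, f3 = c1 / depth, c2 / depth, c3 / depth
    t = thresholds
    allele_depths = dict(sample_counts)

    if f2 > t.het_min_frac:
        status = EXTRA_READS if f3 > t.third_hap_max else HET
        return GenotypeCall(sample_id, locus_id, status, h1, h2, depth, allele_depths)
    if t.prov_low <= f2 <= t.prov_high:
        if h1 in population_presence and h2 in population_presence:
            return GenotypeCall(
                sample_id, locus_id, HET_PROVISIONAL_PASSED, h1, h2, depth, allele_depths
            )
        return GenotypeCall(sample_id, locus_id, BAD_RATIO, h1, h2, depth, allele_depths)
    if t.ambig_low <= f2 < t.prov_low:
        return GenotypeCall(sample_id, locus_id, BAD_RATIO, h1, h2, depth, allele_depths)
    # f2 < ambig_low: homozygote territory
    if f1 > t.hom_min_frac:
        if locus_variable and depth < t.min_hom_depth:
            return GenotypeCall(sample_id, locus_id, LOW_DEPTH, h1, h1, depth, allele_depths)
        return GenotypeCall(sample_id, locus_id, HOM, h1, h1, depth, allele_depths)
    # many low-frequency haplotypes with no clear major: ambiguous
    return GenotypeCall(sample_id, locus_id, BAD_RATIO, h1, h2, depth, allele_depths)


@dataclass
class IndelCharacter:
    """One unique indel event, gap-coded as presence/absence."""

    start_column: int
    length: int
    presence: dict[int, int]  # haplotype index -> 1 if the deletion is carried


def gap_code_indels(
    haplotypes: Sequence[Haplotype], columns: Sequence[VariantColumn]
) -> list[IndelCharacter]:
    """Collapse runs of adjacent gap columns with identical haplotype
    support into single presence/absence characters.

    Two adjacent indel columns belong to one event when exactly the same
    haplotypes carry the gap in both; each unique event (start, length)
    becomes one binary character, regardless of its length.
    """
    events: list[IndelCharacter] = []
    run_start = None
    run_support: Optional[frozenset[int]] = None
    prev_index = None

    def close(run_start: int, end_index: int, support: frozenset[int]) -> None:
        presence = {i: (1 if i in support else 0) for i in range(len(haplotypes))}
        events.append(IndelCharacter(run_start, end_index - run_start + 1, presence))

    for pos, col in enumerate(columns):
        if col.kind != "indel":
            continue
        support = frozenset(
            i for i, hap in enumerate(haplotypes) if hap.states[pos] == "-"
        )
        if not support:
            continue
        if (
            run_start is not None
            and prev_index == col.index - 1
            and support == run_support
        ):
            prev_index = col.index
            continue
        if run_start is not None:
            close(run_start, prev_index, run_support)
        run_start = col.index
        prev_index = col.index
        run_support = support
    if run_start is not None:
        close(run_start, prev_index, run_support)
    return events


@dataclass
class LocusGenotypes:
    """All genotype information for one locus."""

    locus_id: str
    columns: list[VariantColumn]
    haplotypes: list[Haplotype]
    calls: dict[str, GenotypeCall]
    indels: list[IndelCharacter] = field(default_factory=list)
    truncated_at: Optional[int] = None
    alignment_length: Optional[int] = None

    @property
    def variable(self) -> bool:
        return len(self.columns) > 0

    @property
    def n_flagged(self) -> int:
        return sum(1 for c in self.calls.values() if c.status in FLAGGED)


def genotype_locus(
    msa: MultipleAlignment,
    all_samples: Sequence[str],
    thresholds: GenotypeThresholds = GenotypeThresholds(),
    locus_id: str = "",
) -> LocusGenotypes:
    """Full per-locus genotyping: variant detection with quality
    truncation, haplotype counting, per-sample threshold calls with
    population rescue, and gap coding of indels. Samples with no reads at
    the locus are scored MISSING."""
    columns, truncated_at = detect_variant_columns(msa, thresholds)
    haplotypes = count_haplotypes(msa, columns)
    variable = len(columns) > 0
    calls: dict[str, GenotypeCall] = {}
    for sample in all_samples:
        counts = {
            i: hap.counts[sample]
            for i, hap in enumerate(haplotypes)
            if hap.counts.get(sample, 0) > 0
        }
        presence = {
            i
            for i, hap in enumerate(haplotypes)
            if any(s != sample and c > 0 for s, c in hap.counts.items())
        }
        calls[sample] = call_genotype(
            counts, presence, thresholds, variable, sample, locus_id
        )
    indels = gap_code_indels(haplotypes, columns)
    return LocusGenotypes(
        locus_id, columns, haplotypes, calls, indels, truncated_at, msa.n_columns
    )


def _lgamma(n: float) -> float:
    return math.lgamma(n + 1)


def hwe_het_excess_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-sided exact test for heterozygote *excess* under Hardy-Weinberg.

    Conditional on the observed allele counts, the probability of each
    possible heterozygote count follows the standard exact distribution;
    the p-value sums the probabilities of heterozygote counts at least as
    large as observed.
    """
    n = n_hom_ref + n_het + n_hom_alt
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n == 0 or rare == 0:
        return 1.0

    def log_prob(het: int) -> float:
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        return (
            _lgamma(n)
            - _lgamma(hom_rare)
            - _lgamma(het)
            - _lgamma(hom_common)
            + het * math.log(2)
            + _lgamma(rare)
            + _lgamma(2 * n - rare)
            - _lgamma(2 * n)
        )

    hets = range(rare % 2, rare + 1, 2)
    log_probs = {h: log_prob(h) for h in hets if h <= n and (rare - h) // 2 + h <= n}
    log_norm = math.log(sum(math.exp(lp) for lp in log_probs.values()))
    p = sum(
        math.exp(lp - log_norm) for h, lp in log_probs.items() if h >= n_het
    )
    return min(1.0, p)


@dataclass
class LocusScreenResult:
    locus_id: str
    keep: bool
    reasons: list[str]


def screen_duplicate_loci(
    loci: Iterable[LocusGenotypes],
    max_flagged: int = 2,
    max_mean_depth: float = 500.0,
    hwe_alpha: float = 0.01,
    min_allele_divergence: float = 0.10,
    het_hom_depth_ratio: float = 2.0,
) -> list[LocusScreenResult]:
    """Screen loci for signatures of collapsed duplicates.

    A locus is excluded when any of the following hold: (a) more than
    ``max_flagged`` genotypes are flagged (bad ratio / extra reads); (b)
    mean depth per genotyped sample exceeds ``max_mean_depth``; (c) a
    one-sided exact test detects heterozygote excess relative to
    Hardy-Weinberg at ``hwe_alpha`` (biallelic loci); (d) the two most
    common haplotypes differ at more than ``min_allele_divergence`` of
    their columns; (e) heterozygotes have more than
    ``het_hom_depth_ratio`` times the mean depth of homozygotes. The depth
    and divergence cutoffs are pragmatic defaults, configurable per study.
    """
    results: list[LocusScreenResult] = []
    for locus in loci:
        reasons: list[str] = []
        calls = [c for c in locus.calls.values() if c.status != MISSING]
        if locus.n_flagged > max_flagged:
            reasons.append("flagged_genotypes")
        depths = [c.depth for c in calls]
        if depths and float(np.mean(depths)) > max_mean_depth:
            reasons.append("high_depth")
        het_statuses = {HET, HET_PROVISIONAL_PASSED}
        if locus.variable and len(locus.haplotypes) >= 2:
            n_het = sum(1 for c in calls if c.status in het_statuses)
            homs = [c for c in calls if c.status == HOM]
            n_hom_major = sum(1 for c in homs if c.allele1 == 0)
            n_hom_minor = len(homs) - n_hom_major
            if calls and hwe_het_excess_pvalue(n_hom_major, n_het, n_hom_minor) < hwe_alpha:
                reasons.append("het_excess")
            # allele divergence over the aligned locus length (paralogs show
            # many differences; variant columns alone would overstate it).
            # A gap run counts once, like the gap coding: an indel is one
            # mutational difference regardless of length.
            h1, h2 = locus.haplotypes[0].states, locus.haplotypes[1].states
            denom = locus.alignment_length or max(len(h1), 1)
            diffs = 0
            prev_gap_diff_at = None
            for col, a, b in zip(locus.columns, h1, h2):
                if a == b:
                    continue
                is_gap = "-" in (a, b)
                if is_gap and prev_gap_diff_at == col.index - 1:
                    prev_gap_diff_at = col.index
                    continue
                diffs += 1
                prev_gap_diff_at = col.index if is_gap else None
            if h1 and diffs / denom > min_allele_divergence:
                reasons.append("divergent_alleles")
            het_depths = [c.depth for c in calls if c.status in het_statuses]
            hom_depths = [c.depth for c in homs]
            if het_depths and hom_depths:
                if np.mean(het_depths) > het_hom_depth_ratio * np.mean(hom_depths):
                    reasons.append("het_hom_depth")
        results.append(LocusScreenResult(locus.locus_id, not reasons, reasons))
    return results


def genotype_matrix(loci: Sequence[LocusGenotypes]) -> "pd.DataFrame":
    """Samples x loci matrix of genotype strings ``allele1/allele2`` (or
    the flag status for non-called cells)."""
    import pandas as pd

    samples = sorted({s for locus in loci for s in locus.calls})
    data = {}
    for locus in loci:
        col = []
        for s in samples:
            call = locus.calls.get(s)
            if call is None or call.status == MISSING:
                col.append("./.")
            elif call.status in (HOM, HET, HET_PROVISIONAL_PASSED, LOW_DEPTH):
                col.append(f"{call.allele1}/{call.allele2}")
            else:
                col.append(call.status)
        data[locus.locus_id] = col
    return pd.DataFrame(data, index=samples)


def write_genotypes_tsv(loci: Sequence[LocusGenotypes], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tsample_id\tstatus\tallele1\tallele2\tdepth\tallele_depths\n")
        for locus in loci:
            for sample, call in locus.calls.items():
                ad = ",".join(f"{k}:{v}" for k, v in sorted(call.allele_depths.items()))
                a1 = "" if call.allele1 is None else call.allele1
                a2 = "" if call.allele2 is None else call.allele2
                fh.write(
                    f"{locus.locus_id}\t{sample}\t{call.status}\t{a1}\t{a2}\t"
                    f"{call.depth}\t{ad}\n"
                )


def write_snp_table(loci: Sequence[LocusGenotypes], path: str | Path) -> None:
    """One row per SNP column per locus with the haplotype states."""
    with open(path, "w") as fh:
        fh.write("locus_id\tcolumn\tstates\n")
        for locus in loci:
            for i, col in enumerate(locus.columns):
                if col.kind != "SNP":
                    continue
                states = "".join(h.states[i] for h in locus.haplotypes)
                fh.write(f"{locus.locus_id}\t{col.index}\t{states}\n")


def write_indel_table(loci: Sequence[LocusGenotypes], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tstart_column\tlength\tpresence\n")
        for locus in loci:
            for ev in locus.indels:
                pres = "".join(str(ev.presence[i]) for i in range(len(locus.haplotypes)))
                fh.write(f"{locus.locus_id}\t{ev.start_column}\t{ev.length}\t{pres}\n")


def write_vcf(
    loci: Sequence[LocusGenotypes],
    path: str | Path,
    reference_name: str = "synthetic",
) -> None:
    """Minimal VCF 4.2 with one record per SNP column (indels emitted as
    symbolic <DEL> records). Positions are alignment columns (1-based) on a
    per-locus pseudo-contig, which is sufficient for downstream tools that
    only need genotypes."""
    samples = sorted({s for locus in loci for s in locus.calls})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={reference_name}\n")
        fh.write('##ALT=<ID=DEL,Description="Gap-coded deletion">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for locus in loci:
            fh.write(f"##contig=<ID={_sanitize(locus.locus_id)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for locus in loci:
            contig = _sanitize(locus.locus_id)
            for i, col in enumerate(locus.columns):
                states = [h.states[i] for h in locus.haplotypes]
                alleles = sorted(set(states) - {"-"})
                if col.kind == "SNP":
                    ref, alts = alleles[0], alleles[1:]
                else:
                    ref, alts = (alleles[0] if alleles else "N"), ["<DEL>"]
                allele_index = {ref: 0}
                for j, a in enumerate(alts, start=1):
                    allele_index[a] = j
                row = [contig, str(col.index + 1), ".", ref, ",".join(alts) or ".",
                       ".", "PASS", ".", "GT:DP"]
                for s in samples:
                    call = locus.calls.get(s)
                    if call is None or call.allele1 is None:
                        row.append("./.:0")
                        continue
                    gts = []
                    for hap_idx in (call.allele1, call.allele2):
                        state = locus.haplotypes[hap_idx].states[i]
                        if col.kind != "SNP" and state == "-":
                            gts.append("1")
                        else:
                            gts.append(str(allele_index.get(state, 0)))
                    row.append("/".join(gts) + f":{call.depth}")
                fh.write("\t".join(row) + "\n")


def _sanitize(locus_id: str) -> str:
    return locus_id.replace(":", "_").replace("-", "_").replace("+", "p") or "locus"
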