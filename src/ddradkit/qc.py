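"""Quality-control summaries and diagnostics.

Covers the standard post-genotyping checks for a ddRAD run: a missingness
accounting over constant/variable x complete/partial locus categories,
exact binomial tests of heterozygote allele balance (Mendelian sampling is
Binomial(depth, 0.5)), variance components of sequencing depth (locus vs
sample effects), per-locus depth CV, the site frequency spectrum against
the constant-size neutral expectation, and the four-way classification of
recovered loci against the reference digest (canonical fragment,
near-canonical star site, lone SbfI site, SbfI-SbfI fragment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import LocusCluster
from .digest import Fragment, PredictedLocus
from .enzymes import ENZYMES, reverse_complement
from .genome import ReferenceGenome
from .genotyping import (
    BAD_RATIO,
    EXTRA_READS,
    HET,
    HET_PROVISIONAL_PASSED,
    HOM,
    LOW_DEPTH,
    MISSING,
    LocusGenotypes,
)

SBFI_SITE = ENZYMES["SbfI"].recognition
ECORI_SITE = ENZYMES["EcoRI"].recognition


# ---------------------------------------------------------------------------
# missingness accounting


@dataclass
class CategoryCounts:
    """Genotype-cell bookkeeping for one locus category."""

    name: str
    n_loci: int
    n_low_depth: int = 0
    n_missing: int = 0
    n_bad_ratio: int = 0
    n_extra_reads: int = 0

    def cells(self, n_samples: int) -> int:
        return self.n_loci * n_samples


@dataclass
class MissingnessSummary:
    categories: list[CategoryCounts]
    n_samples: int

    @property
    def total_loci(self) -> int:
        return sum(c.n_loci for c in self.categories)

    @property
    def total_cells(self) -> int:
        return self.total_loci * self.n_samples

    def total(self, attr: str) -> int:
        return sum(getattr(c, attr) for c in self.categories)

    def percent(self, attr: str) -> float:
        """Percentage of the grand total of genotype cells, to one decimal."""
        if self.total_cells == 0:
            return 0.0
        return round(100.0 * self.total(attr) / self.total_cells, 1)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "category": c.name,
                "n_loci": c.n_loci,
                "cells": c.cells(self.n_samples),
                "low_depth": c.n_low_depth,
                "missing": c.n_missing,
                "bad_ratio": c.n_bad_ratio,
                "extra_reads": c.n_extra_reads,
            }
            for c in self.categories
        ]
        rows.append(
            {
                "category": "total",
                "n_loci": self.total_loci,
                "cells": self.total_cells,
                "low_depth": self.total("n_low_depth"),
                "missing": self.total("n_missing"),
                "bad_ratio": self.total("n_bad_ratio"),
                "extra_reads": self.total("n_extra_reads"),
            }
        )
        return pd.DataFrame(rows)


def summarize_counts(
    categories: Sequence[CategoryCounts], n_samples: int
) -> MissingnessSummary:
    """Build the summary directly from per-category locus and cell counts
    (e.g. when re-tabulating a published genotyping-success table)."""
    return MissingnessSummary(list(categories), n_samples)


def missingness_summary(
    loci: Sequence[LocusGenotypes],
    min_depth: int = 5,
    min_samples_frac: float = 42 / 46,
) -> MissingnessSummary:
    """Partition loci into constant/variable x complete/partial and count
    genotype cells by outcome.

    A locus is *complete* when every sample was genotyped with at least
    ``min_depth`` reads; *partial* when at least ``min_samples_frac`` of
    samples have data. Loci below the partial threshold are excluded.
    """
    all_samples = sorted({s for lg in loci for s in lg.calls})
    n_samples = len(all_samples)
    need = int(np.ceil(min_samples_frac * n_samples))
    cats = {
        name: CategoryCounts(name, 0)
        for name in (
            "constant_complete",
            "constant_partial",
            "variable_complete",
            "variable_partial",
        )
    }
    for lg in loci:
        calls = [lg.calls[s] for s in all_samples]
        with_data = sum(1 for c in calls if c.status != MISSING)
        if with_data < need:
            continue
        complete = all(
            c.status in (HOM, HET, HET_PROVISIONAL_PASSED) and c.depth >= min_depth
            for c in calls
        )
        kind = "variable" if lg.variable else "constant"
        cat = cats[f"{kind}_{'complete' if complete else 'partial'}"]
        cat.n_loci += 1
        for c in calls:
            if c.status == MISSING:
                cat.n_missing += 1
            elif c.status == LOW_DEPTH or (
                c.status in (HOM, HET, HET_PROVISIONAL_PASSED) and c.depth < min_depth
            ):
                cat.n_low_depth += 1
            elif c.status == BAD_RATIO:
                cat.n_bad_ratio += 1
            elif c.status == EXTRA_READS:
                cat.n_extra_reads += 1
    return MissingnessSummary(list(cats.values()), n_samples)


# ---------------------------------------------------------------------------
# allele balance


def heterozygote_balance_test(a: int, b: int) -> float:
    """Exact two-sided binomial p-value for the allele-depth pair of a
    heterozygote under Mendelian sampling (p = 0.5): the sum of the
    probabilities of all outcomes no more likely than the observed one."""
    if a < 0 or b < 0 or a + b < 1:
        raise ValueError("allele depths must be non-negative with depth >= 1")
    return float(stats.binomtest(a, a + b, 0.5).pvalue)


# ---------------------------------------------------------------------------
# depth structure


def depth_variance_components(depth: np.ndarray | pd.DataFrame) -> dict[str, float]:
    """Partial eta-squared for locus (rows) and sample (columns) effects in
    a two-way ANOVA without interaction on a complete depth matrix:
    SS_effect / (SS_effect + SS_residual)."""
    m = np.asarray(depth, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a complete matrix with >= 2 loci and >= 2 samples")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    n_loci, n_samples = m.shape
    ss_locus = n_samples * float(((row_means - grand) ** 2).sum())
    ss_sample = n_loci * float(((col_means - grand) ** 2).sum())
    ss_total = float(((m - grand) ** 2).sum())
    ss_resid = ss_total - ss_locus - ss_sample
    return {
        "locus": ss_locus / (ss_locus + ss_resid) if ss_locus + ss_resid > 0 else 0.0,
        "sample": ss_sample / (ss_sample + ss_resid) if ss_sample + ss_resid > 0 else 0.0,
    }


def per_locus_depth_cv(depth: np.ndarray | pd.DataFrame) -> dict[str, object]:
    """Coefficient of variation of depth across samples for each locus
    (rows), with the mean +/- sd summary over loci. Loci with zero mean
    depth have undefined CV and are excluded from the summary."""
    m = np.asarray(depth, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    means = m.mean(axis=1)
    sds = m.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(means > 0, sds / means, np.nan)
    defined = cv[~np.isnan(cv)]
    return {
        "cv": cv,
        "mean": float(defined.mean()) if defined.size else float("nan"),
        "sd": float(defined.std(ddof=1)) if defined.size > 1 else float("nan"),
        "n_undefined": int(np.isnan(cv).sum()),
    }


def depth_bias_regression(survey: pd.DataFrame) -> dict[str, float]:
    """Ordinary least squares of log depth on fragment length and GC over
    recovered loci (depth >= 1). Returns the full-model R-squared and the
    partial R-squared of each predictor, SS_effect / (SS_effect + SS_res),
    from the single-term deletion sums of squares."""
    df = survey[survey["depth"] >= 1]
    y = np.log(df["depth"].to_numpy(dtype=float))
    X = np.column_stack(
        [np.ones(len(df)), df["length"].to_numpy(float), df["gc"].to_numpy(float)]
    )

    def sse(cols: list[int]) -> float:
        beta, *_ = np.linalg.lstsq(X[:, cols], y, rcond=None)
        resid = y - X[:, cols] @ beta
        return float(resid @ resid)

    sse_full = sse([0, 1, 2])
    sst = float(((y - y.mean()) ** 2).sum())
    ss_len = sse([0, 2]) - sse_full
    ss_gc = sse([0, 1]) - sse_full
    return {
        "r2": 1.0 - sse_full / sst,
        "partial_len": ss_len / (ss_len + sse_full),
        "partial_gc": ss_gc / (ss_gc + sse_full),
        "n": int(len(df)),
    }


# ---------------------------------------------------------------------------
# site frequency spectrum


def site_frequency_spectrum(
    allele_counts: Iterable[int], n_chromosomes: int
) -> tuple[dict[int, int], dict[int, float]]:
    """Observed unfolded spectrum of derived/rare allele counts together
    with the constant-size neutral expectation, proportional to 1/i and
    normalized over the observed frequency classes.

    ``allele_counts`` holds, per polymorphic locus, the number of
    chromosomes (0 < i < n) carrying the minor/derived allele; monomorphic
    entries are ignored. Returns ({i: observed}, {i: expected count}).
    """
    observed: dict[int, int] = {}
    for i in allele_counts:
        if 0 < i < n_chromosomes:
            observed[i] = observed.get(i, 0) + 1
    if not observed:
        return {}, {}
    total = sum(observed.values())
    classes = sorted(observed)
    norm = sum(1.0 / i for i in classes)
    expected = {i: total * (1.0 / i) / norm for i in classes}
    return dict(sorted(observed.items())), expected


def sfs_allele_counts(loci: Sequence[LocusGenotypes]) -> list[int]:
    """Minor-haplotype chromosome counts for biallelic loci genotyped in
    every sample (input to the site frequency spectrum)."""
    counts: list[int] = []
    het_like = {HET, HET_PROVISIONAL_PASSED}
    for lg in loci:
        if len(lg.haplotypes) != 2 or not lg.variable:
            continue
        calls = list(lg.calls.values())
        if any(c.status not in (HOM, *het_like) for c in calls):
            continue
        alt = sum(
            (c.allele1 == 1) + (c.allele2 == 1) for c in calls
        )
        n_chrom = 2 * len(calls)
        if 0 < alt < n_chrom:
            counts.append(min(alt, n_chrom - alt))
    return counts


# ---------------------------------------------------------------------------
# locus classification against the reference digest

CANONICAL_AB = "CANONICAL_AB"
NEAR_CANONICAL = "NEAR_CANONICAL"
NO_ECORI_NEARBY = "NO_ECORI_NEARBY"
SBFI_SBFI = "SBFI_SBFI"
UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class LocusClassification:
    category: str
    mismatch_count: int = 0
    mismatch_positions: tuple[int, ...] = ()


def classify_recovered_locus(
    cluster: LocusCluster,
    genome: ReferenceGenome,
    predicted_ab: Sequence[PredictedLocus],
    predicted_ss: Sequence[Fragment],
    max_insert: int = 328,
) -> LocusClassification:
    """Classify a uniquely mapped cluster against the reference digest.

    Priority order: (1) the SbfI end coincides with a predicted in-range
    SbfI-EcoRI locus; (2) the genomic 8-mer at the SbfI end differs from
    the canonical recognition sequence at 1-4 positions (star activity or a
    site polymorphism), mismatch positions reported 1-based; (3) a true
    SbfI site with no EcoRI site within ``max_insert``; (4) the position
    falls inside a predicted SbfI-SbfI fragment no longer than
    ``max_insert``. Unmapped clusters cannot be classified.
    """
    if cluster.hit is None:
        raise ValueError("cannot classify an unmapped cluster")
    hit = cluster.hit
    contig_seq = genome[hit.contig]
    read_len = len(cluster.centroid.sequence)
    if hit.strand == "+":
        a_pos = hit.pos
    else:
        a_pos = hit.pos + read_len - 8
    if a_pos < 0 or a_pos + 8 > len(contig_seq):
        return LocusClassification(UNCLASSIFIED)
    eight = contig_seq[a_pos : a_pos + 8]
    if hit.strand == "-":
        eight = reverse_complement(eight)

    ab_keys = set()
    for locus in predicted_ab:
        if locus.length_bp > max_insert:
            continue
        if locus.orientation == "+":
            ab_keys.add((locus.contig, "+", locus.start))
        else:
            ab_keys.add((locus.contig, "-", locus.end - 8))
    if (hit.contig, hit.strand, a_pos) in ab_keys:
        return LocusClassification(CANONICAL_AB)

    mismatches = tuple(
        i + 1 for i, (x, y) in enumerate(zip(eight, SBFI_SITE)) if x != y
    )
    if 1 <= len(mismatches) <= 4:
        return LocusClassification(NEAR_CANONICAL, len(mismatches), mismatches)

    if eight == SBFI_SITE:
        if hit.strand == "+":
            region = contig_seq[a_pos : a_pos + max_insert]
        else:
            region = reverse_complement(
                contig_seq[max(0, a_pos + 8 - max_insert) : a_pos + 8]
            )
        if ECORI_SITE not in region:
            return LocusClassification(NO_ECORI_NEARBY)

    for frag in predicted_ss:
        if frag.length <= max_insert and frag.contig == hit.contig:
            if frag.start <= a_pos < frag.end:
                return LocusClassification(SBFI_SBFI)
    return LocusClassification(UNCLASSIFIED)
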