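"""Haplotype-count genotype calling, thresholds, gap coding and screens."""

from __future__ import annotations

import numpy as np
import pytest

from ddradkit.clustering import MultipleAlignment
from ddradkit.genotyping import (
    BAD_RATIO,
    EXTRA_READS,
    HET,
    HET_PROVISIONAL_PASSED,
    HOM,
    LOW_DEPTH,
    MISSING,
    GenotypeThresholds,
    LocusGenotypes,
    call_genotype,
    count_haplotypes,
    detect_variant_columns,
    gap_code_indels,
    genotype_locus,
    genotype_matrix,
    hwe_het_excess_pvalue,
    screen_duplicate_loci,
    write_genotypes_tsv,
    write_vcf,
)
from ddradkit.read_processing import CondensedRead

T = GenotypeThresholds()


def cr(seq, sample="s1", count=1, q=38):
    return CondensedRead(sample, seq, count, np.full(len(seq), q, dtype=np.int16))


def msa_from(rows_counts, q=38):
    """rows_counts: list of (ungapped-or-gapped row, sample, count[, quals])."""
    members, rows = [], []
    for spec in rows_counts:
        row, sample, count = spec[:3]
        seq = row.replace("-", "")
        quals = spec[3] if len(spec) > 3 else np.full(len(seq), q, dtype=np.int16)
        members.append(CondensedRead(sample, seq, count, quals))
        rows.append(row)
    return MultipleAlignment(rows, members)


class TestCallGenotypeBands:
    """Band-edge behavior is pinned at the published threshold fractions."""

    @pytest.mark.parametrize(
        "f2_counts,expected",
        [
            ({0: 931, 1: 69}, HOM),  # f2 = 0.069 < 0.07, f1 = 0.931 > 0.93
            ({0: 930, 1: 70}, BAD_RATIO),  # f2 = 0.07: bad-ratio band opens
            ({0: 800, 1: 200}, BAD_RATIO),  # f2 = 0.20 enters provisional band
            ({0: 710, 1: 290}, BAD_RATIO),  # f2 = 0.29 still provisional
            ({0: 709, 1: 291}, HET),  # f2 = 0.291 > 0.29: heterozygote
        ],
    )
    def test_band_edges_without_population_support(self, f2_counts, expected):
        call = call_genotype(f2_counts, population_presence=set(), thresholds=T)
        assert call.status == expected

    @pytest.mark.parametrize("f2_count,expected",
                             [(200, HET_PROVISIONAL_PASSED), (290, HET_PROVISIONAL_PASSED)])
    def test_provisional_band_rescued_by_population(self, f2_count, expected):
        call = call_genotype(
            {0: 1000 - f2_count, 1: f2_count}, population_presence={0, 1}, thresholds=T
        )
        assert call.status == expected

    def test_rescue_requires_both_haplotypes(self):
        call = call_genotype({0: 750, 1: 250}, population_presence={0}, thresholds=T)
        assert call.status == BAD_RATIO


class TestCallGenotypeExamples:
    def test_hom_94(self):
        assert call_genotype({0: 94, 1: 6}, set()).status == HOM

    def test_het_60_40(self):
        call = call_genotype({0: 60, 1: 40}, set())
        assert call.status == HET and call.allele1 != call.allele2

    def test_extra_reads(self):
        assert call_genotype({0: 50, 1: 39, 2: 11}, set()).status == EXTRA_READS

    def test_het_with_small_third_haplotype(self):
        assert call_genotype({0: 50, 1: 40, 2: 10}, set()).status == HET

    def test_low_depth_homozygote_at_variable_locus(self):
        assert call_genotype({0: 4}, set(), locus_variable=True).status == LOW_DEPTH
        assert call_genotype({0: 4}, set(), locus_variable=False).status == HOM

    def test_depth_zero_is_missing(self):
        assert call_genotype({}, set()).status == MISSING

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            call_genotype({0: -1, 1: 5}, set())

    def test_statuses_partition(self, rng):
        """Exactly one status per call over random count tables."""
        for _ in range(200):
            n_h = int(rng.integers(1, 5))
            counts = {i: int(rng.integers(0, 60)) for i in range(n_h)}
            counts = {k: v for k, v in counts.items() if v > 0}
            if not counts:
                continue
            call = call_genotype(counts, set())
            assert call.status in {HOM, HET, HET_PROVISIONAL_PASSED, BAD_RATIO,
                                   EXTRA_READS, LOW_DEPTH}
            assert call.depth == sum(counts.values())


class TestDetectVariantColumns:
    def test_snp_column_detected(self):
        msa = msa_from([("ACGT", "s1", 30), ("AGGT", "s2", 28)])
        cols, trunc = detect_variant_columns(msa)
        assert trunc is None
        assert [(c.index, c.kind) for c in cols] == [(1, "SNP")]

    def test_invariant_alignment_no_columns(self):
        msa = msa_from([("ACGT", "s1", 30), ("ACGT", "s2", 28)])
        cols, trunc = detect_variant_columns(msa)
        assert cols == [] and trunc is None

    def test_low_quality_variant_column_truncates(self):
        quals_low = np.array([38, 20, 38, 38], dtype=np.int16)
        msa = msa_from([
            ("ACGT", "s1", 10, quals_low),
            ("AGGT", "s2", 10, np.array([38, 24, 38, 38], dtype=np.int16)),
        ])
        cols, trunc = detect_variant_columns(msa)
        assert trunc == 1
        assert cols == []

    def test_columns_after_truncation_discarded(self):
        msa = msa_from([
            ("ACGTA", "s1", 10, np.array([38, 20, 38, 38, 38], dtype=np.int16)),
            ("AGGTT", "s2", 10, np.array([38, 24, 38, 38, 38], dtype=np.int16)),
        ])
        cols, trunc = detect_variant_columns(msa)
        assert trunc == 1 and cols == []

    def test_isolated_error_does_not_create_column(self):
        msa = msa_from([("ACGT", "s1", 50), ("AGGT", "s1", 1), ("ACGT", "s2", 40)])
        cols, _ = detect_variant_columns(msa)
        assert cols == []

    def test_gap_state_counts(self):
        msa = msa_from([("ACGT", "s1", 30), ("AC-T", "s2", 25)])
        cols, _ = detect_variant_columns(msa)
        assert [(c.index, c.kind) for c in cols] == [(2, "indel")]

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            detect_variant_columns(MultipleAlignment([], []))


class TestCountHaplotypes:
    def test_two_column_haplotypes(self):
        msa = msa_from([
            ("AxCyT".replace("x", "A").replace("y", "G"), "s1", 40),
            ("AxCyT".replace("x", "C").replace("y", "T"), "s1", 38),
        ])
        cols, _ = detect_variant_columns(msa)
        haps = count_haplotypes(msa, cols)
        assert [(h.states, h.counts["s1"]) for h in haps] == [("AG", 40), ("CT", 38)]

    def test_no_columns_single_empty_haplotype(self):
        msa = msa_from([("ACGT", "s1", 30), ("ACGT", "s2", 12)])
        haps = count_haplotypes(msa, [])
        assert len(haps) == 1 and haps[0].states == "" and haps[0].total == 42

    def test_counts_match_simulator_truth(self, clean_run, clean_result):
        """Zero-error haplotype counts equal realized allele depths."""
        from ddradkit.evaluate import match_clusters_to_truth

        depth_by = {}
        for d in clean_run.depths:
            depth_by[(d.sample, d.locus_id, d.allele)] = d.realized
        matches = match_clusters_to_truth(clean_result, clean_run.truth)
        by_cluster = clean_result.genotypes_by_cluster_id()
        checked = 0
        for lt in clean_run.truth.loci:
            cluster = matches.get(lt.locus_id)
            if cluster is None or len(lt.alleles) != 2 or any(a.null for a in lt.alleles):
                continue
            lg = by_cluster[f"cluster{cluster.cluster_id:05d}"]
            if not lg.variable:
                continue
            for sample, (a1, a2) in lt.genotypes.items():
                total_truth = sum(
                    depth_by.get((sample, lt.locus_id, a), 0) for a in set((a1, a2))
                )
                total_called = lg.calls[sample].depth
                assert total_called == total_truth
                checked += 1
        assert checked > 50


class TestGapCodeIndels:
    def make_cols(self, msa):
        cols, _ = detect_variant_columns(msa)
        haps = count_haplotypes(msa, cols)
        return haps, cols

    def test_shared_deletion_single_character(self):
        msa = msa_from([
            ("ACGTACGT", "s1", 20),
            ("AC---CGT", "s2", 18),
            ("AC---CGT", "s3", 22),
        ])
        haps, cols = self.make_cols(msa)
        chars = gap_code_indels(haps, cols)
        assert len(chars) == 1
        assert chars[0].length == 3
        carriers = [i for i, v in chars[0].presence.items() if v]
        assert all(haps[i].states == "---" for i in carriers)

    def test_two_distinct_deletions_two_characters(self):
        msa = msa_from([
            ("ACGTACGTA", "s1", 20),
            ("A-GTACGTA", "s2", 18),
            ("ACGT----A", "s3", 22),
        ])
        haps, cols = self.make_cols(msa)
        chars = gap_code_indels(haps, cols)
        assert len(chars) == 2
        assert sorted(c.length for c in chars) == [1, 4]

    def test_no_gaps_no_characters(self):
        msa = msa_from([("ACGT", "s1", 20), ("AGGT", "s2", 20)])
        haps, cols = self.make_cols(msa)
        assert gap_code_indels(haps, cols) == []


class TestHweExcess:
    def test_all_het_matches_exact_enumeration_oracle(self):
        # 46 samples all heterozygous for the same two alleles: exact
        # conditional distribution of het counts given 46/92 rare alleles,
        # enumerated with rational arithmetic
        from fractions import Fraction
        from math import comb

        n, rare = 46, 46
        weights = {}
        for h in range(rare % 2, rare + 1, 2):
            hom_rare = (rare - h) // 2
            hom_common = n - h - hom_rare
            if hom_common < 0:
                continue
            weights[h] = Fraction(
                comb(n, hom_rare) * comb(n - hom_rare, h) * 2**h
            )
        total = sum(weights.values())
        oracle = float(sum(w for h, w in weights.items() if h >= 46) / total)
        p = hwe_het_excess_pvalue(0, 46, 0)
        assert p == pytest.approx(oracle, rel=1e-9)
        assert p < 1e-6

    def test_hardy_weinberg_proportions_not_flagged(self):
        # 46 samples at allele frequency 0.5 in HW proportions
        assert hwe_het_excess_pvalue(12, 23, 11) > 0.05

    def test_monomorphic_returns_one(self):
        assert hwe_het_excess_pvalue(46, 0, 0) == 1.0


class TestScreenDuplicateLoci:
    def make_locus(self, statuses, depths=None, haps=("A", "T"), locus_id="L"):
        from ddradkit.genotyping import GenotypeCall, Haplotype, VariantColumn

        depths = depths or [30] * len(statuses)
        calls = {}
        for i, (st, dp) in enumerate(zip(statuses, depths)):
            a1, a2 = (0, 1) if st in (HET, HET_PROVISIONAL_PASSED) else (0, 0)
            calls[f"s{i}"] = GenotypeCall(f"s{i}", locus_id, st, a1, a2, dp, {0: dp})
        haplotypes = [Haplotype(h, {"s0": 10}) for h in haps]
        cols = [VariantColumn(j, "SNP", ["A", "T"], 38.0) for j in range(len(haps[0]))]
        return LocusGenotypes(locus_id, cols, haplotypes, calls, [], None, 96)

    def test_three_flagged_genotypes_excluded(self):
        locus = self.make_locus([BAD_RATIO, BAD_RATIO, EXTRA_READS] + [HOM] * 10)
        (res,) = screen_duplicate_loci([locus])
        assert not res.keep and "flagged_genotypes" in res.reasons

    def test_universal_heterozygosity_excluded(self):
        locus = self.make_locus([HET] * 46)
        (res,) = screen_duplicate_loci([locus])
        assert not res.keep and "het_excess" in res.reasons

    def test_extreme_depth_excluded(self):
        locus = self.make_locus([HOM] * 10, depths=[800] * 10)
        (res,) = screen_duplicate_loci([locus])
        assert not res.keep and "high_depth" in res.reasons

    def test_well_behaved_locus_retained(self):
        locus = self.make_locus([HOM] * 30 + [HET] * 14 + [HOM] * 2)
        # genotype mix approximating HW at moderate frequency
        (res,) = screen_duplicate_loci([locus])
        assert res.keep and res.reasons == []

    def test_simulated_single_copy_loci_retained(self, clean_run, clean_result):
        screens = {s.locus_id: s for s in clean_result.screens}
        n_checked = 0
        for lg in clean_result.genotypes:
            if lg.variable and len(lg.haplotypes) == 2:
                n_checked += 1
        assert n_checked > 0
        # no well-behaved simulated locus should be screened out
        assert all(s.keep for s in clean_result.screens)


class TestWriters:
    def make_two_locus_result(self):
        msa1 = msa_from([("ACGT", "s1", 30), ("AGGT", "s1", 28), ("ACGT", "s2", 40)])
        msa2 = msa_from([("TTAA", "s1", 25), ("TTAA", "s2", 9)])
        lg1 = genotype_locus(msa1, ["s1", "s2"], locus_id="locus1")
        lg2 = genotype_locus(msa2, ["s1", "s2"], locus_id="locus2")
        return [lg1, lg2]

    def test_matrix_dimensions(self):
        loci = self.make_two_locus_result()
        m = genotype_matrix(loci)
        assert m.shape == (2, 2)

    def test_genotypes_tsv_round_trip(self, tmp_path):
        import pandas as pd

        loci = self.make_two_locus_result()
        path = tmp_path / "g.tsv"
        write_genotypes_tsv(loci, path)
        df = pd.read_csv(path, sep="\t")
        assert len(df) == 4
        assert set(df["status"]) <= {HOM, HET, HET_PROVISIONAL_PASSED, BAD_RATIO,
                                     EXTRA_READS, LOW_DEPTH, MISSING}

    def test_vcf_parses_with_pysam(self, tmp_path):
        import pysam

        loci = self.make_two_locus_result()
        path = tmp_path / "out.vcf"
        write_vcf(loci, path)
        with pysam.VariantFile(str(path)) as vcf:
            records = list(vcf)
        assert len(records) == 1  # one SNP column at locus1
        rec = records[0]
        assert rec.ref in "ACGT" and len(rec.alts) == 1
        gts = [rec.samples[s]["GT"] for s in ("s1", "s2")]
        assert (0, 1) in gts or (1, 0) in gts  # s1 is heterozygous
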