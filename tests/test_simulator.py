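"""Simulator: toy genome construction, population model, depth law, FASTQ
emission and truth accounting."""

from __future__ import annotations

import numpy as np
import pytest

from ddradkit.digest import SizeWindow, find_cut_sites, predict_ddrad_loci
from ddradkit.enzymes import ENZYMES
from ddradkit.simulate import (
    BiasModel,
    PopulationConfig,
    SizeSelectionModel,
    StarActivityModel,
    _allele_weight,
    make_toy_genome,
    simulate_ddrad_run,
    simulate_depth_survey,
    simulate_depths,
    simulate_population,
)

SBFI = ENZYMES["SbfI"]
ECORI = ENZYMES["EcoRI"]


class TestMakeToyGenome:
    def test_planted_in_range_loci_recovered_exactly(self, toy):
        loci = predict_ddrad_loci(toy.genome, SBFI, ECORI, SizeWindow(178, 328))
        assert len(loci) == len(
            [f for f in toy.features_of("ab") if f.size_class == "in_range"]
        )

    def test_deterministic_per_seed(self):
        a = make_toy_genome(seed=7, n_ab_in_range=5, n_star=3, n_ss=2)
        b = make_toy_genome(seed=7, n_ab_in_range=5, n_star=3, n_ss=2)
        assert a.genome.sequences == b.genome.sequences
        c = make_toy_genome(seed=8, n_ab_in_range=5, n_star=3, n_ss=2)
        assert a.genome.sequences != c.genome.sequences

    def test_no_unplanned_recognition_sites(self, toy):
        planted_sbfi = set()
        planted_ecori = set()
        seq = toy.genome["chr1"]
        for f in toy.features:
            block = seq[f.start : f.end]
            for motif, bag in ((SBFI.recognition, planted_sbfi), (ECORI.recognition, planted_ecori)):
                i = block.find(motif)
                while i != -1:
                    bag.add(f.start + i)
                    i = block.find(motif, i + 1)
        assert {s.pos for s in find_cut_sites(toy.genome, SBFI)} == planted_sbfi
        assert {s.pos for s in find_cut_sites(toy.genome, ECORI)} == planted_ecori

    def test_star_features_have_requested_mismatch(self, toy):
        for f in toy.features_of("star"):
            eight = f.sequence[:8]
            diffs = [i + 1 for i, (a, b) in enumerate(zip(eight, SBFI.recognition)) if a != b]
            assert diffs == [f.mismatch_pos]


class TestSimulatePopulation:
    def test_zero_rates_all_identical_homozygotes(self, toy):
        cfg = PopulationConfig(n_individuals=5, poly_rate=0.0, site_poly_rate=0.0)
        truth = simulate_population(toy, cfg, seed=1)
        for lt in truth.loci:
            assert len(lt.alleles) == 1
            assert set(lt.genotypes.values()) == {(0, 0)}

    def test_fixed_null_locus_emits_no_reads(self, toy):
        cfg = PopulationConfig(
            n_individuals=4,
            poly_rate=0.0,
            site_poly_rate=1.0,
            min_allele_freq=1.0,
            max_allele_freq=1.0,
        )
        truth = simulate_population(toy, cfg, seed=1)
        draws = simulate_depths(truth, total_reads=10_000, seed=2)
        assert all(lt.alleles[1].null for lt in truth.loci)
        assert all(g == (1, 1) for lt in truth.loci for g in lt.genotypes.values())
        assert draws == []

    def test_allele_frequencies_follow_configured_distribution(self, toy):
        cfg = PopulationConfig(n_individuals=60, min_allele_freq=0.3, max_allele_freq=0.7)
        rng_freqs = []
        hw_het = []
        for seed in range(8):
            truth = simulate_population(toy, cfg, seed=seed)
            for lt in truth.loci:
                if len(lt.alleles) == 2 and not lt.alleles[1].null:
                    rng_freqs.append(lt.alt_freq)
                    emp = sum(
                        g.count(1) for g in lt.genotypes.values()
                    ) / (2 * cfg.n_individuals)
                    hw_het.append((lt.alt_freq, emp))
        freqs = np.array(rng_freqs)
        assert 0.3 <= freqs.min() and freqs.max() <= 0.7
        assert freqs.mean() == pytest.approx(0.5, abs=0.03)
        # empirical allele frequencies track the drawn values
        drawn, emp = np.array(hw_het).T
        assert np.corrcoef(drawn, emp)[0, 1] > 0.8


class TestSimulateDepths:
    def test_flat_model_gives_equal_expected_depth(self, toy):
        truth = simulate_population(toy, PopulationConfig(n_individuals=2), seed=3)
        flat_bias = BiasModel(beta_len=0.0, beta_gc=0.0, carryover_prob=1.0,
                              carryover_gc_coeff=0.0)
        flat_size = SizeSelectionModel(taper_min_weight=1.0)
        draws = simulate_depths(truth, flat_bias, flat_size, total_reads=50_000, seed=4)
        hom_expected = {
            round(d.expected, 6)
            for d in draws
            if truth.locus(d.locus_id).genotypes[d.sample]
            == (d.allele, d.allele)
            and truth.locus(d.locus_id).depth_class != "above_range"
        }
        assert len(hom_expected) == 1

    def test_shorter_same_gc_fragment_has_higher_expected_depth(self):
        bias, size = BiasModel(), SizeSelectionModel(taper_min_weight=1.0)
        assert _allele_weight(250, 0.5, bias, size) > _allele_weight(300, 0.5, bias, size)

    def test_above_window_gets_zero(self):
        bias, size = BiasModel(), SizeSelectionModel()
        assert _allele_weight(400, 0.5, bias, size) == 0.0

    def test_taper_weights(self):
        size = SizeSelectionModel()
        assert size.weight(178) == pytest.approx(0.5)
        assert size.weight(328) == pytest.approx(1.0)
        assert size.weight(253) == pytest.approx(0.75)

    def test_regression_r2_near_configured_target(self):
        df = simulate_depth_survey(n_loci=2000, seed=123)
        from ddradkit.qc import depth_bias_regression

        res = depth_bias_regression(df)
        assert res["r2"] == pytest.approx(0.43, abs=0.1)
        assert res["partial_len"] > 0 and res["partial_gc"] > 0

    def test_het_allele_split_is_binomial(self, toy):
        """Conditional on total depth, heterozygote allele depths split
        binomially; the exact-test rejection fraction at the 5% level is
        consistent with Mendelian sampling."""
        from ddradkit.qc import heterozygote_balance_test

        cfg = PopulationConfig(n_individuals=20, indel_frac=0.0, site_poly_rate=0.0)
        pvals = []
        for seed in (1, 2):
            truth = simulate_population(toy, cfg, seed=seed)
            draws = simulate_depths(truth, total_reads=150_000, seed=seed + 10)
            pairs: dict[tuple, list] = {}
            for d in draws:
                pairs.setdefault((d.sample, d.locus_id), []).append(d)
            for (s, lid), ds in pairs.items():
                if len(ds) != 2:
                    continue
                lt = truth.locus(lid)
                if lt.alleles[0].length != lt.alleles[1].length:
                    continue  # equal weights -> p = 0.5
                a, b = ds[0].realized, ds[1].realized
                if a + b >= 20:
                    pvals.append(heterozygote_balance_test(a, b))
        pvals = np.array(pvals)
        assert len(pvals) >= 150
        frac = float((pvals <= 0.05).mean())
        half_width = 1.96 * np.sqrt(0.05 * 0.95 / len(pvals))
        assert abs(frac - 0.05) <= half_width


class TestEmitFastq:
    def test_same_seed_identical_output(self):
        kwargs = dict(
            pop=PopulationConfig(n_individuals=3),
            total_reads=3000,
            n_ab_in_range=6,
            n_ab_short=2,
            n_ab_long=1,
            n_star=4,
            n_ss=2,
            n_duplications=1,
        )
        a = simulate_ddrad_run(seed=21, **kwargs)
        b = simulate_ddrad_run(seed=21, **kwargs)
        assert [(r, s, list(q)) for r, s, q in a.reads] == [
            (r, s, list(q)) for r, s, q in b.reads
        ]

    def test_read_conservation(self, noisy_run):
        assert len(noisy_run.reads) == len(noisy_run.truth.reads)
        by_id = {r[0] for r in noisy_run.reads}
        assert {rt.read_id for rt in noisy_run.truth.reads} == by_id

    def test_zero_error_reads_have_no_error_positions(self, clean_run):
        assert all(rt.error_positions == () for rt in clean_run.truth.reads)

    def test_star_edge_share_matches_configuration(self):
        """Among recovered star loci the fraction with the mismatch at
        recognition position 1 or 8 reproduces the configured edge share
        (~0.9) within Monte-Carlo error."""
        edge = internal = 0
        star = StarActivityModel()
        for seed in range(6):
            run = simulate_ddrad_run(
                seed=seed,
                pop=PopulationConfig(n_individuals=8),
                total_reads=5000,
                error_rate=0.0,
                n_ab_in_range=4,
                n_star=40,
            )
            star_feats = run.toy.features_of("star")
            recovered = set()
            for rt in run.truth.reads:
                if rt.origin == "star":
                    recovered.add(rt.source_id)
            for sid in recovered:
                feat = star_feats[int(sid[4:])]
                if feat.mismatch_pos in (1, 8):
                    edge += 1
                else:
                    internal += 1
        share = edge / (edge + internal)
        # expected edge share from the configured rates with positions
        # planted uniformly over 1-8 (per-feature recovery probability over
        # 8 samples)
        p_edge = 1 - (1 - star.rate_edge) ** 8
        p_int = 1 - (1 - star.rate_internal) ** 8
        expected = 0.25 * p_edge / (0.25 * p_edge + 0.75 * p_int)
        se = np.sqrt(expected * (1 - expected) / (edge + internal))
        assert abs(share - expected) <= 3 * se

    def test_star_reads_low_depth(self, noisy_run):
        star_depth: dict[tuple, int] = {}
        locus_depth: dict[tuple, int] = {}
        for rt in noisy_run.truth.reads:
            key = (rt.sample, rt.source_id)
            if rt.origin == "star":
                star_depth[key] = star_depth.get(key, 0) + 1
            elif rt.origin == "locus":
                locus_depth[key] = locus_depth.get(key, 0) + 1
        if star_depth:
            assert np.median(list(star_depth.values())) <= 5
            assert np.median(list(star_depth.values())) < np.median(
                list(locus_depth.values())
            )

    def test_chimera_reads_logged(self):
        run = simulate_ddrad_run(
            seed=13,
            pop=PopulationConfig(n_individuals=6),
            total_reads=5000,
            error_rate=0.0,
            star=StarActivityModel(rate_edge=0.0, rate_internal=0.0, chimera_rate=0.5),
            n_ss=4,
        )
        chimeras = [rt for rt in run.truth.reads if rt.origin == "chimera"]
        assert chimeras
        by_id = {r[0]: r[1] for r in run.reads}
        # chimera reads start like ordinary reads (barcode + SbfI remnant)
        for rt in chimeras[:10]:
            seq = by_id[rt.read_id]
            assert seq[6:12] == "TGCAGG"


class TestNullAlleleSignature:
    def test_het_with_null_scored_hom_at_half_depth(self, toy):
        """Samples heterozygous for a null allele are observably homozygous
        with about half the depth of true homozygotes."""
        cfg = PopulationConfig(
            n_individuals=40, poly_rate=0.0, site_poly_rate=1.0,
            min_allele_freq=0.5, max_allele_freq=0.5,
        )
        truth = simulate_population(toy, cfg, seed=9)
        draws = simulate_depths(truth, total_reads=200_000, seed=10)
        depth: dict[tuple, int] = {}
        for d in draws:
            depth[(d.sample, d.locus_id)] = depth.get((d.sample, d.locus_id), 0) + d.realized
        hom_depths, het_null_depths = [], []
        for lt in truth.loci:
            if len(lt.alleles) != 2 or lt.depth_class == "above_range":
                continue
            for sample, g in lt.genotypes.items():
                d = depth.get((sample, lt.locus_id), 0)
                if g == (0, 0):
                    hom_depths.append(d)
                elif g == (0, 1):  # one null copy
                    het_null_depths.append(d)
        assert hom_depths and het_null_depths
        ratio = np.mean(het_null_depths) / np.mean(hom_depths)
        assert ratio == pytest.approx(0.5, abs=0.08)
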