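"""Bias-aware synthetic ddRAD library simulator.

The simulator builds a toy genome with planted restriction-fragment
structure, evolves a diploid population over its predicted loci, draws
per-allele sequencing depths under an amplification-bias model, and emits
multiplexed Phred+33 FASTQ together with a complete truth table, so that
every pipeline stage is testable at desk scale.

The statistical structure emulated:

* a log-linear depth law in fragment length (negative coefficient: shorter
  fragments amplify better) and GC content (positive coefficient), with
  overdispersed counts — under the default coefficients an ordinary
  regression of log depth on length and GC over in-range loci explains
  roughly 43% of the variance;
* tapered size selection across the target window (inclusion weight rising
  linearly from 0.5 at the window minimum to 1.0 at the maximum, the effect
  of cutting a wedge-shaped gel slice);
* small-fragment carryover: fragments below the window are retained with a
  single length-independent probability and a weaker GC effect;
* restriction-site polymorphisms and long indels creating null alleles;
* star activity (non-specific cutting) concentrated at near-canonical
  SbfI sites with the mismatch at the first or last recognition position,
  recovered at low depth;
* chimeras of SbfI-SbfI fragments ligated to SbfI-EcoRI fragments;
* per-base sequencing errors with quality scores drawn from a low-quality
  distribution (correct bases from a high-quality one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .digest import PredictedLocus, SizeWindow, find_cut_sites, gc_fraction, predict_ddrad_loci
from .enzymes import ENZYMES, reverse_complement
from .genome import ReferenceGenome

SBFI = ENZYMES["SbfI"]
ECORI = ENZYMES["EcoRI"]

#: P2 adapter bases as seen when a short fragment reads through the EcoRI
#: site (trailing "C" of the site is replaced by the adapter on the read).
P2_ADAPTER = "AGATCGGAAGAGCGGTTCAGCAGGAATGCCGAGACCGATCTCGTATGCCGTCTTCTGCTTG"

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class PopulationConfig:
    """Diploid population model over the toy genome's loci.

    ``poly_rate`` is the per-site polymorphism rate (expected polymorphisms
    per locus = rate x length; about 1.3 per 100 bp at the default),
    ``indel_frac`` the fraction of polymorphisms that are deletions rather
    than SNPs, ``site_poly_rate`` the per-locus probability that the
    alternate allele carries a restriction-site mutation and is therefore a
    null allele. Alternate-allele frequencies are uniform on
    [``min_allele_freq``, ``max_allele_freq``] and individuals are drawn
    under Hardy-Weinberg.
    """

    n_individuals: int = 46
    poly_rate: float = 0.013
    indel_frac: float = 0.10
    indel_length_p: float = 0.5
    site_poly_rate: float = 0.03
    min_allele_freq: float = 0.05
    max_allele_freq: float = 0.95

    def __post_init__(self) -> None:
        for r in (self.poly_rate, self.indel_frac, self.site_poly_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")


@dataclass(frozen=True)
class BiasModel:
    """Log-linear amplification-bias law for in-window fragments:
    mean depth proportional to exp(b0 + b_len * length + b_gc * gc), with
    gamma-Poisson (negative binomial) dispersion. Below-window fragments
    are carried over with probability ``carryover_prob`` and a weaker GC
    coefficient, independent of length; above-window fragments get zero.
    """

    beta0: float = 0.0
    beta_len: float = -0.011  # per bp; shorter fragments amplify better
    beta_gc: float = 3.5  # per GC fraction unit
    dispersion: float = 0.15  # NB dispersion; var = mu + dispersion * mu^2
    carryover_prob: float = 0.35
    carryover_gc_coeff: float = 1.5

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0 <= self.carryover_prob <= 1:
            raise ValueError("carryover_prob must lie in [0, 1]")


@dataclass(frozen=True)
class SizeSelectionModel:
    """Target insert window with a tapered inclusion weight rising linearly
    from ``taper_min_weight`` at the window minimum to 1.0 at the maximum
    (a wedge-shaped gel slice: half lane width at the small end, full width
    at the large end)."""

    min_bp: int = 178
    max_bp: int = 328
    taper_min_weight: float = 0.5

    def weight(self, length: int) -> float:
        if length < self.min_bp or length > self.max_bp:
            return 0.0
        frac = (length - self.min_bp) / (self.max_bp - self.min_bp)
        return self.taper_min_weight + (1.0 - self.taper_min_weight) * frac


@dataclass(frozen=True)
class StarActivityModel:
    """Non-specific cutting at near-canonical SbfI sites.

    ``rate_edge`` / ``rate_internal``: per sample, the probability that a
    1-mismatch site with the mismatch at recognition position 1 or 8
    (respectively 2-7) yields any star reads. With mismatch positions
    planted uniformly (edge fraction 1/4), the defaults make about 90% of
    recovered star loci edge-mismatch loci. ``chimera_rate``: per sample,
    the probability that an SbfI-SbfI fragment ligates to a locus fragment
    and is sequenced. ``depth_p``: geometric parameter for star depth
    (median depth 2 at the default).
    """

    rate_edge: float = 0.60
    rate_internal: float = 0.0207
    chimera_rate: float = 0.01
    depth_p: float = 0.6

    def __post_init__(self) -> None:
        if self.rate_edge < 0 or self.rate_internal < 0:
            raise ValueError("star rates must be non-negative")
        if not 0 <= self.chimera_rate <= 1:
            raise ValueError("chimera_rate must lie in [0, 1]")


# ---------------------------------------------------------------------------
# toy genome


@dataclass
class PlantedFeature:
    kind: str  # "ab", "star", "ss", "dup"
    start: int
    end: int
    strand: str
    sequence: str  # locus-oriented (A site first) for "ab"/"star"
    size_class: str = ""  # "in_range" | "short" | "long" for "ab"
    mismatch_pos: Optional[int] = None  # 1-based recognition position, "star"
    source_index: Optional[int] = None  # for "dup": index of copied feature

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ToyGenome:
    genome: ReferenceGenome
    features: list[PlantedFeature]
    contig: str = "chr1"

    def features_of(self, kind: str) -> list[PlantedFeature]:
        return [f for f in self.features if f.kind == kind]


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    is_gc = rng.random(n) < gc
    pick = rng.integers(0, 2, n)
    out = np.where(is_gc, np.where(pick == 0, "G", "C"), np.where(pick == 0, "A", "T"))
    return "".join(out)


_FORBIDDEN = (SBFI.recognition, ECORI.recognition)


def _scrub(rng: np.random.Generator, seq: str) -> str:
    """Remove every occurrence of either recognition sequence by mutating
    one interior base, repeating until clean."""
    chars = list(seq)
    for _ in range(200):
        text = "".join(chars)
        hit = -1
        for motif in _FORBIDDEN:
            i = text.find(motif)
            if i != -1:
                hit = i + len(motif) // 2
                break
        if hit == -1:
            return text
        old = chars[hit]
        choices = [b for b in "ACGT" if b != old]
        chars[hit] = choices[int(rng.integers(0, 3))]
    raise RuntimeError("could not scrub recognition sites from random sequence")


def _interior(rng: np.random.Generator, n: int, gc: float) -> str:
    return _scrub(rng, _random_seq(rng, n, gc))


def _ab_fragment(rng: np.random.Generator, length: int, gc: float) -> str:
    interior = _interior(rng, length - 14, gc)
    seq = SBFI.recognition + interior + ECORI.recognition
    # junction bases could recreate a site; scrub interior-adjacent copies
    assert len(seq) == length
    return seq


def make_toy_genome(
    seed: int = 0,
    n_ab_in_range: int = 30,
    n_ab_short: int = 6,
    n_ab_long: int = 4,
    n_star: int = 16,
    n_ss: int = 4,
    n_duplications: int = 2,
    window: SizeWindow = SizeWindow(178, 328),
    gc_mean: float = 0.48,
    gc_sd: float = 0.06,
    background_gc: float = 0.45,
    spacer_range: tuple[int, int] = (340, 420),
    minus_frac: float = 0.3,
) -> ToyGenome:
    """Build a single-contig toy genome with planted ddRAD structure.

    Planted features: SbfI-EcoRI fragments in-range, below range ("small
    fragment carryover" territory) and above range; near-canonical SbfI
    sites (one mismatch, position uniform over 1-8) paired with a
    downstream EcoRI site; SbfI-SbfI fragments; and duplicated locus tags.
    Spacers are longer than the size window so no unintended in-window
    fragment arises between features, and the random background is free of
    both recognition sequences. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    blocks: list[str] = []
    features: list[PlantedFeature] = []
    pos = 0

    def add_spacer() -> None:
        nonlocal pos
        n = int(rng.integers(*spacer_range))
        blocks.append(_interior(rng, n, background_gc))
        pos += n

    def add_feature(feature_seq: str, strand: str, **kw) -> PlantedFeature:
        nonlocal pos
        placed = feature_seq if strand == "+" else reverse_complement(feature_seq)
        feat = PlantedFeature(
            kw.pop("kind"), pos, pos + len(placed), strand, feature_seq, **kw
        )
        blocks.append(placed)
        features.append(feat)
        pos += len(placed)
        return feat

    def draw_gc() -> float:
        return float(np.clip(rng.normal(gc_mean, gc_sd), 0.30, 0.65))

    add_spacer()
    specs: list[tuple[str, int]] = []
    for _ in range(n_ab_in_range):
        specs.append(("in_range", int(rng.integers(window.min_bp, window.max_bp + 1))))
    for _ in range(n_ab_short):
        specs.append(("short", int(rng.integers(38, window.min_bp))))
    for _ in range(n_ab_long):
        specs.append(("long", int(rng.integers(window.max_bp + 12, window.max_bp + 100))))
    rng.shuffle(specs)
    for size_class, length in specs:
        strand = "-" if rng.random() < minus_frac else "+"
        add_feature(
            _ab_fragment(rng, length, draw_gc()),
            strand,
            kind="ab",
            size_class=size_class,
        )
        add_spacer()

    for _ in range(n_star):
        mm_pos = int(rng.integers(1, 9))
        site = list(SBFI.recognition)
        old = site[mm_pos - 1]
        site[mm_pos - 1] = [b for b in "ACGT" if b != old][int(rng.integers(0, 3))]
        length = int(rng.integers(window.min_bp, window.max_bp + 1))
        seq = "".join(site) + _interior(rng, length - 14, draw_gc()) + ECORI.recognition
        add_feature(seq, "+", kind="star", mismatch_pos=mm_pos)
        add_spacer()

    for _ in range(n_ss):
        length = int(rng.integers(60, window.max_bp + 1))
        seq = SBFI.recognition + _interior(rng, length - 16, draw_gc()) + SBFI.recognition
        add_feature(seq, "+", kind="ss")
        add_spacer()

    # duplications: copy the leading 100 bp tag of an in-range locus
    in_range = [f for f in features if f.kind == "ab" and f.size_class == "in_range"]
    for i in range(n_duplications):
        src = in_range[i % len(in_range)]
        tag = src.sequence[:100]
        add_feature(tag, "+", kind="dup", source_index=features.index(src))
        add_spacer()

    contig = "".join(blocks)
    genome = ReferenceGenome({"chr1": contig})
    toy = ToyGenome(genome, features)
    _repair_junction_sites(toy, rng)
    _verify_sites(toy)
    return toy


def _expected_site_positions(toy: ToyGenome) -> tuple[set[int], set[int]]:
    sbfi: set[int] = set()
    ecori: set[int] = set()
    for f in toy.features:
        seq = toy.genome[toy.contig][f.start : f.end]
        i = seq.find(SBFI.recognition)
        while i != -1:
            sbfi.add(f.start + i)
            i = seq.find(SBFI.recognition, i + 1)
        i = seq.find(ECORI.recognition)
        while i != -1:
            ecori.add(f.start + i)
            i = seq.find(ECORI.recognition, i + 1)
    return sbfi, ecori


def _repair_junction_sites(toy: ToyGenome, rng: np.random.Generator) -> None:
    """Accidental recognition sites can only arise where a block junction
    completes a motif; such an occurrence always includes spacer bases,
    which are safe to mutate. Patch until the site sets match the plan."""
    footprints = [(f.start, f.end) for f in toy.features]

    def in_feature(p: int) -> bool:
        return any(s <= p < e for s, e in footprints)

    for _ in range(100):
        exp_sbfi, exp_ecori = _expected_site_positions(toy)
        seq = toy.genome[toy.contig]
        bad: list[tuple[int, int]] = []
        for enz, expected in ((SBFI, exp_sbfi), (ECORI, exp_ecori)):
            for site in find_cut_sites(toy.genome, enz):
                if site.pos not in expected:
                    bad.append((site.pos, enz.site_length))
        if not bad:
            return
        pos, length = bad[0]
        editable = [p for p in range(pos, pos + length) if not in_feature(p)]
        if not editable:
            raise RuntimeError("unplanned recognition site inside a planted feature")
        p = editable[int(rng.integers(0, len(editable)))]
        old = seq[p]
        new = [b for b in "ACGT" if b != old][int(rng.integers(0, 3))]
        toy.genome.sequences[toy.contig] = seq[:p] + new + seq[p + 1 :]
    raise RuntimeError("could not repair unplanned recognition sites")


def _verify_sites(toy: ToyGenome) -> None:
    exp_sbfi, exp_ecori = _expected_site_positions(toy)
    got_sbfi = {s.pos for s in find_cut_sites(toy.genome, SBFI)}
    got_ecori = {s.pos for s in find_cut_sites(toy.genome, ECORI)}
    if got_sbfi != exp_sbfi or got_ecori != exp_ecori:
        raise RuntimeError(
            "toy genome assembly produced unplanned recognition sites; "
            "this indicates an infeasible packing"
        )


# ---------------------------------------------------------------------------
# population


@dataclass
class AlleleTruth:
    index: int
    sequence: str  # full locus-oriented sequence (A site first)
    null: bool = False  # restriction-site mutation: emits no reads
    n_snps: int = 0
    n_indels: int = 0

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_fraction(self.sequence)


@dataclass
class LocusTruth:
    locus: PredictedLocus
    alleles: list[AlleleTruth]
    alt_freq: float  # frequency of allele 1 (0 when monomorphic)
    genotypes: dict[str, tuple[int, int]]  # sample -> (allele, allele)
    depth_class: str  # "in_range" | "carryover" | "above_range"

    @property
    def locus_id(self) -> str:
        return self.locus.locus_id

    def observable_alleles(self, sample: str) -> list[int]:
        return [a for a in self.genotypes[sample] if not self.alleles[a].null]


@dataclass
class ReadTruth:
    read_id: str
    sample: str
    origin: str  # "locus" | "star" | "chimera"
    source_id: str
    allele: Optional[int]
    error_positions: tuple[int, ...] = ()


@dataclass
class TruthTable:
    loci: list[LocusTruth]
    reads: list[ReadTruth] = field(default_factory=list)

    def locus(self, locus_id: str) -> LocusTruth:
        for lt in self.loci:
            if lt.locus_id == locus_id:
                return lt
        raise KeyError(locus_id)


def _sample_ids(n: int) -> list[str]:
    return [f"ind{i:02d}" for i in range(n)]


def _mutate_allele(
    rng: np.random.Generator, sequence: str, cfg: PopulationConfig, n_poly: int
) -> tuple[str, int, int]:
    """Derive an alternate allele by placing SNPs and deletions in the
    interior (terminal recognition sites stay intact here; site
    polymorphisms are handled separately). Re-draws mutations that would
    create a new recognition site."""
    left, right = len(SBFI.recognition), len(ECORI.recognition)
    seq = sequence
    n_snps = n_indels = 0
    for _ in range(n_poly):
        for _attempt in range(20):
            interior_len = len(seq) - left - right
            if interior_len <= 2:
                break
            if rng.random() < cfg.indel_frac:
                del_len = 1 + int(rng.geometric(cfg.indel_length_p))
                if interior_len - del_len < 2:
                    continue
                at = left + int(rng.integers(0, interior_len - del_len))
                cand = seq[:at] + seq[at + del_len :]
                is_indel = True
            else:
                at = left + int(rng.integers(0, interior_len))
                old = seq[at]
                new = [b for b in "ACGT" if b != old][int(rng.integers(0, 3))]
                cand = seq[:at] + new + seq[at + 1 :]
                is_indel = False
            if (
                cand.count(SBFI.recognition) == 1
                and cand.count(ECORI.recognition) == 1
            ):
                seq = cand
                n_snps += 0 if is_indel else 1
                n_indels += 1 if is_indel else 0
                break
    return seq, n_snps, n_indels


def simulate_population(
    toy: ToyGenome,
    cfg: PopulationConfig,
    size: SizeSelectionModel = SizeSelectionModel(),
    seed: int = 0,
) -> TruthTable:
    """Draw diploid genotypes for every predicted A-B locus of the toy
    genome. Polymorphic loci are biallelic: a reference allele and one
    alternate carrying SNPs/deletions, or a restriction-site mutation that
    makes it a null allele. Individuals are sampled under Hardy-Weinberg.
    """
    rng = np.random.default_rng(seed)
    samples = _sample_ids(cfg.n_individuals)
    loci = predict_ddrad_loci(
        toy.genome, SBFI, ECORI, SizeWindow(13, 10**6)
    )
    truths: list[LocusTruth] = []
    for locus in loci:
        if locus.length_bp > size.max_bp:
            depth_class = "above_range"
        elif locus.length_bp < size.min_bp:
            depth_class = "carryover"
        else:
            depth_class = "in_range"
        ref = AlleleTruth(0, locus.sequence)
        alleles = [ref]
        alt_freq = 0.0
        n_poly = int(rng.poisson(cfg.poly_rate * locus.length_bp))
        site_poly = rng.random() < cfg.site_poly_rate
        if n_poly > 0 or site_poly:
            if site_poly:
                # mutate one base of the SbfI site on the alternate allele
                mm = int(rng.integers(0, len(SBFI.recognition)))
                old = locus.sequence[mm]
                new = [b for b in "ACGT" if b != old][int(rng.integers(0, 3))]
                alt_seq = locus.sequence[:mm] + new + locus.sequence[mm + 1 :]
                alt = AlleleTruth(1, alt_seq, null=True)
            else:
                alt_seq, n_snps, n_indels = _mutate_allele(
                    rng, locus.sequence, cfg, n_poly
                )
                # a deletion can push the allele past the window top only by
                # lengthening; deletions shorten, so only below-window moves
                # occur and those stay observable through carryover
                null = len(alt_seq) > size.max_bp
                alt = AlleleTruth(1, alt_seq, null=null, n_snps=n_snps, n_indels=n_indels)
            alleles.append(alt)
            alt_freq = float(
                rng.uniform(cfg.min_allele_freq, cfg.max_allele_freq)
            )
        genotypes = {}
        for s in samples:
            if len(alleles) == 1:
                genotypes[s] = (0, 0)
            else:
                a1 = int(rng.random() < alt_freq)
                a2 = int(rng.random() < alt_freq)
                genotypes[s] = (min(a1, a2), max(a1, a2))
        truths.append(LocusTruth(locus, alleles, alt_freq, genotypes, depth_class))
    return TruthTable(truths)


# ---------------------------------------------------------------------------
# depths


@dataclass(frozen=True)
class DepthDraw:
    sample: str
    locus_id: str
    allele: int
    expected: float
    realized: int


def _allele_weight(
    length: int, gc: float, bias: BiasModel, size: SizeSelectionModel
) -> float:
    if length > size.max_bp:
        return 0.0
    if length < size.min_bp:
        return bias.carryover_prob * float(
            np.exp(bias.beta0 + bias.carryover_gc_coeff * gc)
        )
    return float(
        np.exp(bias.beta0 + bias.beta_len * length + bias.beta_gc * gc)
    ) * size.weight(length)


def simulate_depths(
    truth: TruthTable,
    bias: BiasModel = BiasModel(),
    size: SizeSelectionModel = SizeSelectionModel(),
    total_reads: int = 200_000,
    seed: int = 0,
) -> list[DepthDraw]:
    """Draw per-sample per-allele read counts under the bias model.

    Expected depth per allele copy is proportional to the allele weight
    (log-linear in length and GC inside the window, tapered; carryover
    below; zero above); realized counts are gamma-Poisson with the model's
    dispersion. Null alleles draw nothing.
    """
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    rng = np.random.default_rng(seed)
    # one unit per (sample, locus): the amplification jackpot (gamma
    # dispersion) is a property of the locus in that sample's library, so
    # it is shared by the two alleles; conditional on the total, reads
    # split binomially between alleles in proportion to their weights.
    # This keeps heterozygote allele-depth pairs Binomial(depth, ~0.5).
    units: list[tuple[str, str, list[tuple[int, float]]]] = []
    for lt in truth.loci:
        for sample, (a1, a2) in lt.genotypes.items():
            allele_w: list[tuple[int, float]] = []
            for allele_idx in sorted(set((a1, a2))):
                allele = lt.alleles[allele_idx]
                if allele.null:
                    continue
                copies = (a1, a2).count(allele_idx)
                w = _allele_weight(allele.length, allele.gc, bias, size)
                if w > 0:
                    allele_w.append((allele_idx, copies * w))
            if allele_w:
                units.append((sample, lt.locus_id, allele_w))
    total_w = sum(w for _, _, aw in units for _, w in aw)
    if total_w == 0:
        return []
    draws: list[DepthDraw] = []
    for sample, locus_id, allele_w in units:
        unit_w = sum(w for _, w in allele_w)
        mu = total_reads * unit_w / total_w
        lam = rng.gamma(1.0 / bias.dispersion, bias.dispersion * mu)
        n = int(rng.poisson(lam))
        probs = np.array([w for _, w in allele_w]) / unit_w
        counts = rng.multinomial(n, probs)
        for (allele_idx, w), c in zip(allele_w, counts):
            draws.append(
                DepthDraw(sample, locus_id, allele_idx, mu * w / unit_w, int(c))
            )
    return draws


def simulate_depth_survey(
    n_loci: int = 2000,
    bias: BiasModel = BiasModel(),
    size: SizeSelectionModel = SizeSelectionModel(),
    length_range: tuple[int, int] = (200, 328),
    gc_mean: float = 0.48,
    gc_sd: float = 0.08,
    mean_depth: float = 40.0,
    seed: int = 0,
) -> "pd.DataFrame":
    """Monte-Carlo survey of the depth law over many independent loci.

    Builds monomorphic single-sample locus truths with lengths uniform over
    ``length_range`` and GC around ``gc_mean``, runs them through
    ``simulate_depths``, and returns a DataFrame (length, gc, depth) for
    regression diagnostics. The default length range covers the upper part
    of the size window, where depth falls with length.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    loci: list[LocusTruth] = []
    for i in range(n_loci):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        gc = float(np.clip(rng.normal(gc_mean, gc_sd), 0.25, 0.75))
        seq = _random_seq(rng, length, gc)
        locus = PredictedLocus(
            contig="sim",
            start=i * 1000,
            end=i * 1000 + length,
            orientation="+",
            length_bp=length,
            gc_fraction=gc_fraction(seq),
            sequence=seq,
        )
        loci.append(
            LocusTruth(locus, [AlleleTruth(0, seq)], 0.0, {"ind00": (0, 0)}, "in_range")
        )
    truth = TruthTable(loci)
    draws = simulate_depths(
        truth, bias, size, total_reads=int(mean_depth * n_loci), seed=seed
    )
    by_id = {lt.locus_id: lt for lt in loci}
    rows = [
        {
            "length": by_id[d.locus_id].alleles[0].length,
            "gc": by_id[d.locus_id].alleles[0].gc,
            "depth": d.realized,
        }
        for d in draws
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FASTQ emission


def expected_processed_sequence(
    allele_seq: str,
    read_len: int = 100,
    barcode_len: int = 6,
    adapter: str = P2_ADAPTER,
    min_overlap: int = 8,
) -> str:
    """The processed-read sequence the pipeline should produce for an
    allele at zero sequencing error.

    Long alleles are truncated to read capacity (with the full SbfI site
    reconstructed). Short alleles run into the P2 adapter, which is
    trimmed and the EcoRI site completed — except when the adapter overlap
    is below the trimming floor (alleles just under the read capacity), in
    which case the few adapter bases are indistinguishable from genomic
    sequence and stay on the read.
    """
    body_cap = read_len - barcode_len
    genomic = len(allele_seq) - 3  # bases past the reconstructed "CC"
    if genomic >= body_cap:
        return allele_seq[: body_cap + 2]
    overlap = body_cap - genomic
    if overlap >= min_overlap:
        return allele_seq
    return allele_seq[:-1] + adapter[:overlap]


def _draw_qualities(
    rng: np.random.Generator, n: int, error_mask: np.ndarray
) -> np.ndarray:
    quals = np.clip(np.rint(rng.normal(38, 2, n)), 33, 41).astype(np.int16)
    if error_mask.any():
        low = np.clip(
            np.rint(rng.normal(12, 3, int(error_mask.sum()))), 2, 20
        ).astype(np.int16)
        quals[error_mask] = low
    return quals


def _apply_errors(
    rng: np.random.Generator, seq: str, error_rate: float
) -> tuple[str, np.ndarray, tuple[int, ...]]:
    n = len(seq)
    mask = rng.random(n) < error_rate
    if mask.any():
        chars = np.array(list(seq))
        for i in np.flatnonzero(mask):
            chars[i] = [b for b in "ACGT" if b != chars[i]][int(rng.integers(0, 3))]
        seq = "".join(chars)
    quals = _draw_qualities(rng, n, mask)
    return seq, quals, tuple(int(i) for i in np.flatnonzero(mask))


def _fragment_read(fragment: str, barcode: str, read_len: int) -> str:
    """Raw read for a locus-oriented fragment sequence: the barcode, then
    the fragment from the third base of its (near-)SbfI site; short
    fragments run through the EcoRI sticky end into the P2 adapter."""
    body_cap = read_len - len(barcode)
    body = fragment[2 : len(fragment) - 1]  # sticky ends: CC lost, final C lost
    if len(body) < body_cap:
        body = (body + P2_ADAPTER + "A" * read_len)[:body_cap]
    else:
        body = body[:body_cap]
    return barcode + body


def emit_fastq(
    toy: ToyGenome,
    truth: TruthTable,
    depths: Sequence[DepthDraw],
    barcodes: dict[str, str],
    star: StarActivityModel = StarActivityModel(),
    error_rate: float = 0.001,
    read_len: int = 100,
    seed: int = 0,
) -> list[tuple[str, str, np.ndarray]]:
    """Emit multiplexed reads (id, sequence, Phred qualities) and log every
    read in the truth table. ``barcodes`` maps sample -> barcode sequence.
    Star reads come from the genome's planted near-canonical sites at the
    model's edge/internal rates; chimera reads join an SbfI-SbfI fragment
    to a locus fragment. Deterministic per seed."""
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str, np.ndarray]] = []
    truth.reads = []
    counter = 0

    def emit(fragment: str, sample: str, origin: str, source_id: str,
             allele: Optional[int]) -> None:
        nonlocal counter
        raw = _fragment_read(fragment, barcodes[sample], read_len)
        seq, quals, errs = _apply_errors(rng, raw, error_rate)
        rid = f"read{counter:07d}"
        counter += 1
        reads.append((rid, seq, quals))
        truth.reads.append(ReadTruth(rid, sample, origin, source_id, allele, errs))

    by_locus = {lt.locus_id: lt for lt in truth.loci}
    for draw in depths:
        lt = by_locus[draw.locus_id]
        allele = lt.alleles[draw.allele]
        for _ in range(draw.realized):
            emit(allele.sequence, draw.sample, "locus", draw.locus_id, draw.allele)

    samples = sorted(barcodes)
    for fi, feat in enumerate(toy.features_of("star")):
        rate = star.rate_edge if feat.mismatch_pos in (1, 8) else star.rate_internal
        for sample in samples:
            if rng.random() >= rate:
                continue
            depth = int(rng.geometric(star.depth_p))
            for _ in range(depth):
                emit(feat.sequence, sample, "star", f"star{fi:02d}", None)

    ab_in_range = [
        lt for lt in truth.loci if lt.depth_class == "in_range" and not lt.alleles[0].null
    ]
    for fi, feat in enumerate(toy.features_of("ss")):
        for sample in samples:
            if rng.random() >= star.chimera_rate or not ab_in_range:
                continue
            partner = ab_in_range[int(rng.integers(0, len(ab_in_range)))]
            chimera = feat.sequence + partner.alleles[0].sequence[8:]
            emit(chimera, sample, "chimera", f"ss{fi:02d}", None)
    return reads


# ---------------------------------------------------------------------------
# one-call wrapper


@dataclass
class SimulatedRun:
    toy: ToyGenome
    truth: TruthTable
    depths: list[DepthDraw]
    reads: list[tuple[str, str, np.ndarray]]
    barcodes: dict[str, str]  # sample -> barcode

    @property
    def barcode_map(self) -> dict[str, str]:
        return {bc: sample for sample, bc in self.barcodes.items()}


def simulate_ddrad_run(
    seed: int = 0,
    pop: PopulationConfig = PopulationConfig(),
    bias: BiasModel = BiasModel(),
    size: SizeSelectionModel = SizeSelectionModel(),
    star: StarActivityModel = StarActivityModel(),
    total_reads: int = 200_000,
    error_rate: float = 0.001,
    read_len: int = 100,
    toy: Optional[ToyGenome] = None,
    **toy_kwargs,
) -> SimulatedRun:
    """End-to-end simulation: toy genome, population, depths, FASTQ.

    Sub-seeds are derived deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_toy, s_pop, s_depth, s_reads = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4))
    if toy is None:
        toy = make_toy_genome(seed=s_toy, window=SizeWindow(size.min_bp, size.max_bp), **toy_kwargs)
    truth = simulate_population(toy, pop, size, seed=s_pop)
    depths = simulate_depths(truth, bias, size, total_reads, seed=s_depth)
    from .barcodes import generate_barcode_set

    samples = _sample_ids(pop.n_individuals)
    bc_set = generate_barcode_set()
    if len(bc_set) < len(samples):
        raise ValueError("not enough barcodes for the requested individuals")
    barcodes = {s: bc_set.barcodes[i].sequence for i, s in enumerate(samples)}
    reads = emit_fastq(
        toy, truth, depths, barcodes, star, error_rate, read_len, seed=s_reads
    )
    return SimulatedRun(toy, truth, depths, reads, barcodes)
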