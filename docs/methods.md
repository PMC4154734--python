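# Methods

This note records the models, conventions and numerical choices behind
`ddradkit`, and what the synthetic data can and cannot establish.

## Digest model and coordinates

Coordinates are 0-based, half-open, on the top strand. Only palindromic
enzymes are supported (the built-in table — SbfI, EcoRI, MspI, MseI, PstI —
is entirely palindromic): a palindromic recognition sequence is its own
reverse complement, so one top-strand scan finds all sites, and a
non-palindromic enzyme raises an explicit error rather than silently
missing minus-strand sites. Fragment boundaries are defined on
recognition-site coordinates, not cut offsets, because sample processing
reconstructs the complete site on every read; cut offsets are kept for
sticky-end bookkeeping. Overlapping sites of the two enzymes are legal and
give the 13-bp minimum SbfI–EcoRI locus. Recognition sites never match
across an ambiguous base (N); GC fractions exclude N from the denominator
(an all-N sequence has no defined composition and raises); loci containing
N are flagged but retained.

Minus-orientation loci (B site leftmost on the top strand) are reported
reverse-complemented so the A site always leads, matching read structure.
The single-copy filter counts exact occurrences of each locus's leading
100-bp tag (or whole sequence when shorter) on both strands — a
deterministic criterion for "maps to one place" that needs no external
aligner; the mapper interface is pluggable where a full aligner is wanted.

## Read processing

Barcode matching is exact. The barcode sets are single parity-check codes
over GF(4) (minimum distance 2) extended greedily, so any single
sequencing error in the barcode is detected but cannot be corrected;
tolerating one mismatch would silently misassign such reads. Synthesized
bases (the `CC` completing the SbfI site, the trailing `C` completing
EcoRI) carry a fixed sentinel quality of 40; they are shared by every read
at a locus and are never variant positions. Adapter trimming slides the
adapter prefix along the read 3' end (unit mismatch cost, no gaps; lowest
error rate wins, leftmost on ties) and requires ≥ 8 bases overlap at ≤ 20%
error. Alleles within 7 bp of the read capacity therefore keep a short
untrimmable adapter remnant — a genuine ambiguity, harmless because the
remnant is shared by all reads of the locus. Quality encoding is fixed to
Phred+33.

## Identity and alignment

Pairwise identity is matching columns / alignment columns with end gaps
free, computed from the better (by identity) of the ungapped alignment
(equal lengths) and the score-optimal global alignment (match +1, mismatch
−1, gap open −2, extend −1, end gaps free). The denominator is floored at
the shorter sequence's length: without the floor, the score-optimal
end-gap-free alignment of two *unrelated* sequences can degenerate to a
one-column overlap and report identity 1.0, which silently absorbs short
loci into foreign clusters. Cluster alignments are center-star against the
centroid — adequate because members are ≥ 85% identical to the centroid by
construction — and fully deterministic, as are all tie-breaks (descending
mean quality, then count, then lexicographic sequence).

Positional merging of clusters (same contig and strand, positions within
±50 bp) is single-link chained by default (config-disableable to
anchor-based grouping). This re-unites alleles separated by a long indel,
which fall below the 85% identity threshold but map to the same place. The
built-in mapper searches both strands by edit distance (edlib), with a
strict pass at 10% errors and, when that finds nothing, a relaxed pass at
30% that rescues long-indel alleles (edit distance charges an indel per
base where a local aligner would open one gap); a hit is unique when
exactly one optimal location exists genome-wide.

## Genotype caller

Band edges follow the stated fractions with strict/inclusive boundaries:
heterozygote at f₂ > 0.29 (extra-reads flag when f₃ > 0.10), provisional
band inclusive [0.20, 0.29] (rescued when both haplotypes have ≥ 1 read in
≥ 1 other sample — the weakest reading of "present in other individuals",
upgradeable in config), bad-ratio [0.07, 0.20), homozygote at f₁ > 0.93,
with the low-depth downgrade (< 5 reads) applied only at variable loci.
Fraction denominators use all reads the sample has at the locus. When
f₂ < 0.07 but f₁ ≤ 0.93 (many scattered low-frequency haplotypes, no clear
major), the call is flagged bad-ratio so statuses remain a partition.

Variable-site identification uses an initial support threshold: a state
establishes a variant column only when some single sample carries it in
≥ 2 reads making up ≥ 20% of that sample's reads. A genuine allele always
clears this (a heterozygote carries it in roughly half its reads); isolated
sequencing errors essentially never do. Without the threshold, at realistic
depths every locus accumulates error-supported variant columns, every
error-bearing read becomes its own haplotype, and f₁ drifts below the 0.93
homozygote bound — genotype concordance against simulator truth drops from
≥ 99.5% to about 92% at a 0.1%/base error rate. Once a site is established,
singleton reads are still counted (they carry information at genuinely
polymorphic positions). The first variant column whose read-weighted mean
quality (gaps contribute the member's mean quality) falls below Q25
truncates the locus.

The duplicate screens quantify "unusually high depth" as mean depth > 500,
"highly divergent alleles" as > 10% of aligned columns (counting a gap run
once, like the gap coding — an indel is one mutation regardless of length),
and het/hom depth imbalance as a ratio > 2; all three are pragmatic
artifact choices exposed in config. Heterozygote excess is a one-sided
exact test on the conditional distribution of heterozygote counts given
the allele counts.

## Simulator

The generator's defaults are the study conditions: 46 individuals, 100-bp
single-end reads, a 178–328 bp insert window, polymorphism rate 0.013 per
site (≈ 1.3 polymorphisms per 100 bp locus, 10% of them deletions),
restriction-site polymorphism probability 0.03 per locus, alternate-allele
frequencies uniform on [0.05, 0.95] under Hardy–Weinberg.

Depth law: the published evidence is a descriptive regression (depth
falling with length above ~200 bp, rising with GC, R² ≈ 0.43 with partial
R² ≈ 0.20/0.23), not a generative model. The minimal generative law
matching the signs and magnitudes is log-linear,
`E[depth] ∝ exp(β₀ + β_len·L + β_gc·GC) · taper(L)`, with gamma–Poisson
dispersion. The gel taper is a linear inclusion weight 0.5 → 1.0 across
the window (half lane width cut at the small end, full width at the large
end). Below the window, fragments are carried over with a single
length-independent probability (0.35) and a weaker GC coefficient (1.5);
above it, depth is zero. Defaults β_len = −0.011/bp, β_gc = 3.5,
dispersion 0.15 were calibrated once so that regressing log realized depth
on length and GC over a 2,000-locus survey in the 200–328 bp range yields
R² ≈ 0.43; the published partial R² pair (0.20/0.23) is not exactly
attainable simultaneously with that R² under any two-predictor generative
model and the partial-R² definition SS_eff/(SS_eff + SS_res), so the
defaults preserve their ordering and rough ratio (measured ≈ 0.25/0.32).

The dispersion (the amplification "jackpot") is drawn once per locus per
sample and shared by the two alleles, which then split the total
binomially in proportion to their weights. Independent per-allele draws
would make heterozygote allele-depth pairs beta-binomial — visibly
overdispersed relative to the Binomial(depth, 0.5) behavior real
heterozygotes show — and is the single most consequential structural choice
in the depth model.

Star activity: near-canonical SbfI sites are planted with the mismatch
position uniform over 1–8; per sample, an edge-mismatch site (position 1
or 8) yields reads with probability 0.60 and an internal-mismatch site
with probability 0.0207. The 29:1 ratio makes ~90% of *recovered* star
loci edge-mismatch loci, the empirically observed concentration; star
depths are geometric with median 2. Chimeras ligate an SbfI–SbfI fragment
to a locus fragment (probability 0.01 per fragment per sample); when the
reconstituted junction site falls inside the read, the concatemer screen
discards it, otherwise the read survives and maps to the SbfI–SbfI
fragment, as in real libraries.

Toy genomes separate planted features with spacers longer than the size
window, so no unintended in-window fragment arises between features;
accidental recognition sites at block junctions are repaired by mutating
spacer bases. Everything is deterministic per seed (sub-seeds derived via
`SeedSequence`).

What the simulator does not emulate: machine-specific error and quality
profiles (errors are uniform per base with a low-quality signature), PCR
duplicates and cycle-explicit amplification, paired-end structure,
population structure beyond a single panmictic deme, and more than two
alleles per locus. Passing tests therefore show the pipeline's logic is
correct under the stated statistical structure, not that real libraries
meet that structure.

## Problem sizes

The test suite runs desk-scale: toy genomes of ~40 kb with ~60 planted
features, 6–8 individuals and 20,000–40,000 reads for the end-to-end
checks, 2,000 loci for the depth-law survey, 50 random genomes of 1–50 kb
for the digest oracle. These sizes were chosen so the whole suite completes
in about a minute while every statistical check retains enough resolution
to fail when the implementation is wrong. Genome-scale digests (a ~1 Gb
assembly) run through the same engine in minutes via `ddradkit digest` but
require the assembly FASTA locally.

## Known limitations

Greedy centroid clustering is order-dependent by design (quality-sorted,
deterministic) and, like any fixed identity threshold, can split highly
divergent alleles (mitigated by positional merging) or lump recent
paralogs (mitigated by the duplicate screens). The exact binomial
allele-balance test is conservative at low depth because the statistic is
discrete — its achieved level at the 5% nominal level sits near 3.5–4.5%
for depths of 20–80 — so Monte-Carlo checks compare against the nominal
level with sampling-error tolerances, or against the exactly computed
achieved level where the point is the test itself. The VCF writer emits
per-locus pseudo-contigs with alignment-column positions; it is meant for
downstream tools that consume genotypes, not for coordinate-level
comparisons against a reference.
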