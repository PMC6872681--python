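# Methods

This note documents the statistical models implemented in `popdog`, the
defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical conventions used throughout.

## Genotype representation and QC

A panel is an individuals × SNPs matrix of codes in {0, 1, 2, missing}
counting copies of `allele_b`, the minor allele. Keeping the coding
minor-allele-anchored makes MAF, heterozygosity and the F_ST frequency
bookkeeping uniform; every statistic here is invariant to which allele is
counted, and tests assert that invariance. Positions are 1-based physical
coordinates (PLINK MAP/BIM convention) and all interval outputs are
1-based inclusive. Ties for the minor allele at frequency exactly 0.5 go
to the lexicographically first allele, for determinism.

QC defaults follow standard SNP-array practice for this study design:
SNPs with MAF < 0.01 or call rate < 90% are removed, then individuals
with call rate < 95%. The individual call rate is computed on the SNP set
as it stands when the filter runs, so applying the filters in the stated
order reproduces the conventional sequence. Population labels come from
the PED/FAM family-ID column; a two-column sidecar TSV overrides them,
since family-ID conventions vary across archives.

## Diversity indices

* **P_N** — fraction of SNPs segregating within a population, evaluated on
  the cohort-level common-SNP subset (default cohort MAF > 0.1). Defining
  the denominator cohort-wide is what makes breed-level P_N < 1
  meaningful.
* **H_E, H_O** — per SNP, H_E = 2p(1−p) at the sample frequency and H_O
  the fraction of heterozygous calls; means are over SNPs with ≥1 call.
* **A_R** — rarefied allelic richness at a standardized size of g allele
  copies: per SNP, Σ_a [1 − C(N−N_a, g)/C(N, g)], i.e. the expected number
  of distinct alleles in a random g-copy subsample. Computed with
  log-gamma binomials for numerical safety; bounded by [1, 2] for
  biallelic data. The default g is twice the smallest compared
  population's size — the largest standardized size all groups support.
* **F** — per individual, (O_hom − E_hom)/(L − E_hom) with E_hom summed
  over the individual's called SNPs as 1 − 2p(1−p)·n/(n−1), n in allele
  copies. The n/(n−1) factor is the small-sample correction of expected
  heterozygosity used by the standard tooling for this statistic.
* **1 − IBS distances** — pair similarity is shared allele copies over
  2 × jointly called SNPs, with het–het counted as 2 shared copies (the
  PLINK convention). Pairs with no jointly called SNP are an error rather
  than a silent NaN.

## LD, LD decay, and r²₀.₃

LD is the squared Pearson correlation of genotype dosages (composite LD):
no phasing is required and the measure is invariant to allele recoding.
Pairs are formed within chromosomes up to 500 kb apart by default, over
individuals called at both SNPs; zero-variance SNPs make a pair undefined
and it is skipped. For unlinked loci the expectation is the sampling
floor 1/(n−1), which the tests verify by Monte Carlo.

The LD-extent summary r²₀.₃ is the distance at which mean r² decays to
0.3. Because binned means are noisy and not exactly monotone, the decay
curve (10-kb bins) is first forced monotone non-increasing by
pair-count-weighted isotonic regression, then the crossing is located by
linear interpolation between flanking bin midpoints. This rule is
deterministic and parameter-free; a curve that never reaches 0.3 yields
0, and one that never falls below it yields the maximum binned distance
with a warning.

Greedy LD pruning slides a window of SNPs along each chromosome and,
while any intra-window pair has r² ≥ the cutoff, removes the lower-MAF
member (ties: the later position). The retained set provably has no
intra-window pair at or above the cutoff.

## Runs of homozygosity

ROH are detected with the 50-SNP window vote: a window is
homozygous-eligible if it has ≤1 heterozygous and ≤5 missing calls; a SNP
is in-ROH if ≥ `hit_fraction` of the windows covering it are eligible;
maximal runs of in-ROH SNPs become segments if they span ≥200 kb and
contain ≥ `min_snps` SNPs. The window size, het/missing allowances and
200-kb minimum are the standard settings for dog SNP-array data; the vote
threshold (0.05) and SNP minimum (25) follow the defaults of the
conventional implementation at a 50-SNP window, and both are exposed as
parameters. Chromosomes with fewer SNPs than one window yield no calls.
ROH analyses are autosome-only, and the conventional pre-step is pruning
at r² ≥ 0.8 (left to the caller / pipeline so the detector itself can be
tested against an exhaustive oracle).

## F_ST

The per-SNP estimator is the mean-square (ANOVA-style) form

    MSG  = [Σᵢ nᵢ pᵢ(1−pᵢ)] / Σᵢ (nᵢ − 1)
    MSP  = [Σᵢ nᵢ (pᵢ − p̄)²] / (s − 1),   p̄ = Σ nᵢpᵢ / Σ nᵢ
    n_c  = [Σ nᵢ − Σ nᵢ²/Σ nᵢ] / (s − 1)
    F_ST = (MSP − MSG) / (MSP + (n_c − 1)·MSG)

with nᵢ the i-th population's allele-copy count (2 × called individuals)
at that SNP. The MSG denominator is the within-group degrees of freedom
Σ(nᵢ−1); because typeset sources are often ambiguous between Σ(nᵢ−1) and
Σnᵢ, the alternative is available via `msg_denominator="n"`. The default
reduces to the textbook limits: equal frequencies give a raw value of
exactly −1/(n_c−1), and a fixed difference gives exactly 1.

SNPs monomorphic across all populations are 0/0 and excluded
("informative SNPs only"); negative raw values are truncated to 0 for
reported/pairwise means but preserved untruncated for the d_i scan, where
truncation would bias the genome-wide moments. Pairwise matrices average
per-SNP reported values over defined SNPs; F_ST and D analyses are
autosome-restricted.

## d_i selection scan

For breed i, per SNP, d_i = Σ_{j≠i} (F_ST^{ij} − E[F_ST^{ij}]) /
sd[F_ST^{ij}], with each pair's moments (mean and population-SD, divisor
N) estimated from all scan SNPs where that pair is defined. SNPs with any
undefined constituent pair are dropped from that breed's track (count
logged) rather than imputed. When every pair is defined everywhere, each
term is exactly mean-centered and the genome-wide mean of d_i is 0 — a
property the tests assert.

Windows tile each autosome on a fixed 200-kb grid anchored at position 1
([1, 200000], [200001, 400000], …) — a deterministic reading of
"non-overlapping 200-kb windows" that also makes adjacency merging
well-defined. Windows with fewer than 6 SNPs are discarded. The outlier
cut is the 99.5th linear-interpolation percentile of the breed's own
retained-window means, ties included; note that with W windows this calls
⌈0.005·W⌉ windows (plus ties) by construction, so the realized "0.5%"
rate carries a discreteness ceiling at small W (e.g. 2/244 ≈ 0.8%).
Grid-adjacent called windows merge into regions.

Group contrasts (e.g. plateau vs non-plateau breeds) pool the populations
of each side into one super-population; d_i then reduces to the
single-pair standardization (F_ST − E)/sd, with moments re-estimated from
the two-group track itself so that the contrast is self-calibrating.

## D-statistic

The 4-taxon ABBA-BABA test is computed from population allele frequencies
(not sampled pseudo-haploids, matching population-level array data):

    D = Σ[(1−p₁)p₂p₃(1−p_O) − p₁(1−p₂)p₃(1−p_O)] /
        Σ[(1−p₁)p₂p₃(1−p_O) + p₁(1−p₂)p₃(1−p_O)]

over SNPs defined in all four populations. Significance comes from a
delete-one jackknife over contiguous blocks of 300 map-ordered SNPs —
well beyond the LD extent of dog breeds at array densities — with the
remainder absorbed into the blocks.

## The simulator

The generator's purpose is ground truth, at desk scale, for every
downstream stage; its defaults mirror the study system it emulates
(~12.5 SNPs per 200-kb window, 38-autosome-style maps, breed samples of
~12, divergence F ≈ 0.1).

1. SNP counts per chromosome are Poisson at the configured density;
   positions are uniform and sorted (so per-window SNP counts vary, which
   the ≥6-SNP rule must handle).
2. Ancestral frequencies are Uniform(0.05, 0.95); population frequencies
   follow the Balding–Nichols Beta with parameter F, whose expectation
   under the mean-square estimator is F itself — the analytic recovery
   target. F = 0 collapses to the ancestral frequency; F = 1 is rejected.
3. Planted admixture mixes target frequencies toward a source population;
   planted sweeps shift the focal population's frequencies inside chosen
   windows (clipped to [0.02, 0.98]) before the genotype draw.
4. Each population draws `founders_per_pop` founder haplotypes at its
   frequencies; individual haplotypes are recombinant founder mosaics
   (Poisson crossovers at `recomb_rate` per bp). Founder count is the LD
   and ROH dial: 2 founders give chromosome-scale haplotype sharing, 100
   give a near-panmictic background.
5. `consanguinity` is the inbreeding dial: with that probability per
   chromosome, an individual's second haplotype copies the first's
   founder mosaic, creating whole-chromosome autozygosity, H_O < H_E,
   and positive F. This dial is explicit because founder-mosaic sampling
   with replacement is, by itself, exactly Hardy–Weinberg at the realized
   pool frequency — a small founder pool shortens haplotypes and inflates
   LD/ROH but cannot produce a heterozygote deficit; only mate
   correlation can.
6. Missingness is i.i.d.; finally the allele coding is canonicalized so
   `allele_b` is the realized minor allele (flip mask recorded in the
   truth record), which is what makes PLINK write→read round-trips
   bit-identical under the reader's minor-allele convention.

Randomness is one seed split into four named streams (frequencies →
founders → mosaics → missingness), so growing one stage leaves the
others' draws unchanged.

What the simulator does **not** emulate: realistic mutation/recombination
heterogeneity, demographic history (bottleneck timing, growth), sex
chromosomes, genotyping-error processes, or ascertainment bias of array
content. Passing tests therefore demonstrate correctness of the
estimators and the scan machinery under controlled divergence/LD/
admixture — not that real dog data would yield any particular value.

## Numerical conventions and degenerate inputs

Missing genotypes are −1 internally and excluded from every frequency,
correlation and distance denominator. Undefined quantities (monomorphic
F_ST, zero-variance LD pairs, pairs with zero SD in the d_i moments) are
NaN/skipped and never zero-filled; zero-SD pairs are excluded from d_i
with a warning. Neighbor joining breaks Q-criterion ties by the
lexicographically smallest label pair and clamps negative branch lengths
to zero, moving the deficit to the sibling edge; it is exact (1e−9) on
additive matrices. PCA standardizes by √(2p(1−p)), mean-imputes missing
entries after centering, excludes monomorphic SNPs, and orders components
by eigenvalue; coordinates are eigenvectors scaled by √eigenvalue.

## Problem sizes

The test suite and acceptance script run on simulated panels of roughly
1,000–12,000 SNPs and 20–120 individuals (e.g. the scan studies use 10
breeds × 12 dogs on two 25-Mb chromosomes at array density — ~240 windows
per breed), sizes at which every property they check is already stable
and the full run completes in well under a minute per study.

## Known limitations

* The d_i percentile cut is per breed over that breed's retained windows;
  with few windows the threshold is unstable (warned below 20).
* The r²₀.₃ summary depends on bin width (default 10 kb) at sharp decay.
* The ROH caller does not implement segment-level het/missing caps or
  inter-SNP gap limits beyond the window vote itself.
* The D-statistic jackknife assumes blocks exceed the LD scale; at very
  low SNP counts (<2 blocks) Z is undefined and reported as NaN.
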