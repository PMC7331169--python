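# Methods

This note documents the models implemented in `admixkit`, the defaults
and why they were chosen, the numerical decisions, and what the
synthetic cohorts do and do not establish about real data.

## The single-pulse admixture model

All dating machinery assumes one admixture event: `t` generations ago a
fraction `m` of the recipient gene pool was replaced by donor lineages,
and recombination at a uniform per-bp rate `r` has since broken donor
haplotypes into tracts. Under this model a haplotype is a two-state
Markov mosaic along the genome: between positions `d` bp apart ancestry
persists with probability `e^(−r·d·t)` and is otherwise redrawn
`Bernoulli(m)` toward the donor. Donor tract lengths are then
exponential with rate `(1−m)·r·t`.

`r` is obtained, in the absence of a genetic map, by assuming one
crossover per chromosome per generation: `r = n_chromosomes /
mapped_length`. For a 37-chromosome, ~2.03 Gb chromosome-anchored
genome this gives 1.82e-8 /bp/generation, the default throughout.

## Synthetic cohorts (`simdata`)

The generator produces exactly the data structure the estimators
assume, plus ground truth:

- **Panels.** Shared ancestral frequencies `p ~ U(0.05, 0.95)`; each
  wild panel drifts as Balding–Nichols
  `Beta(p(1−F)/F, (1−p)(1−F)/F)`. The default `F = 0.5` per panel
  emulates two distinct wild species and yields ~27% of sites with
  |pA − pB| ≥ 0.5 — the regime in which ancestry-informative markers are
  plentiful and panel-frequency estimates from 8 diploids are
  informative. The outgroup carries the derived allele at only 5% of
  sites (low frequency), exercising the polarization filters.
- **Admixed haplotypes.** Ancestry-switch opportunities fall as a
  Poisson process of rate `r·t` per bp; each redraws ancestry
  `Bernoulli(m)`. This is simulated directly (not via a coalescent): it
  is precisely the generative model the HMM assumes, making parameter
  recovery a clean test of the inference machinery rather than of model
  mismatch. Haplotypes within a diploid are independent chains, matching
  the HMM's composite-dosage assumption. Defaults: `m = 0.36`,
  `t = 120`, 8 admixed diploids, 5 × 20 Mb chromosomes, ~10,000 sites
  per chromosome (1 SNP / 2 kb).
- **Reads.** Per-sample depth `Poisson(16)`; alt reads
  `Binomial(depth, f)` with `f = (g/2)(1−ε) + (1−g/2)ε` and per-read
  error `ε = 0.01`. Written genotypes are the true (phased) genotypes:
  genotype-calling error is not modeled, only read-level evidence.
- **Sexed depth.** X scaffolds at half depth in males, terminal
  pseudo-autosomal windows restored to full depth, Poisson noise.
- **Not emulated:** selection within the simulator, variable
  recombination, gene conversion, genotype-calling and phasing error,
  linked-selection background, and coalescent noise in panel divergence
  (drift is site-independent). Passing recovery tests therefore shows
  the estimators are correct and well calibrated under their own model;
  robustness to model misspecification on real data is a separate
  question. An independent coalescent generator (msprime) is used only
  for the LD-based Ne recovery test, where genuine linkage structure is
  the quantity of interest.

## ABBA-BABA (`introgression`)

Per site, with derived frequencies `(p1, p2, p3, pO)` after outgroup
polarization: `ABBA = (1−p1)p2·p3(1−pO)`, `BABA = p1(1−p2)p3(1−pO)`;
`D` from genome sums. Standard errors resample contiguous 30-Mb blocks
(bootstrap default, 1000 replicates; delete-one jackknife as a
cross-check — the two agree within 20% on genome-scale runs). The
normal z approximation gives the two-tailed p.

`f_d` is computed in 100-kb windows, substituting the donor frequency
`p_D = max(p2, p3)` for both P2 and P3 in the denominator. Windows with
fewer than 10 informative sites, window-level `D < 0`, or a
non-positive denominator are reported missing rather than zero or
negative: `f_d` estimates the introgressed fraction in the
excess-sharing direction only, and missing windows cannot dilute the
outlier quantiles. Outliers are the empirical top 1% with threshold
ties included.

On synthetic cohorts the genome-mean `f_d` tracks the pulse proportion
within ±0.05 at `m ∈ {0.1, 0.36}`; this requires the strongly diverged
panel regime above — with weakly diverged panels `f_d` is attenuated,
a known property of the estimator.

## Local ancestry HMM and dating (`ancestry`)

**AIMs.** Sites with |pA − pB| ≥ 0.5 after the depth filter (≥ 90% of
samples at depth ≥ 10), thinned greedily left-to-right to ≥ 10 kb
spacing. Panel frequencies entering the emission model are
Jeffreys-shrunk, `(p·n + 0.5)/(n + 1)`: finite panels otherwise produce
estimates of exactly 0/1 whose overconfident emissions bias `t` upward
substantially.

**Model.** Donor-dosage states {0, 1, 2} as the product of two
independent haploid pulse chains; stationary distribution
`Binomial(2, m)`; transitions are convolutions of the haploid kernel
with stay probability `e^(−r·d·t)`. Emissions: read-count mode
(default) mixes `P(genotype | dosage)` from panel frequencies with
`Binomial(depth, f_g)` read likelihoods (`ε = 0.01`); genotype mode
uses `P(genotype | dosage)` directly. Forward–backward runs in scaled
arithmetic (numba kernels); posterior dosage probabilities sum to 1 to
1e−9 and the likelihood is invariant to chromosome order.

**Fitting.** `t` is searched on a 25-point log grid over [1, 2000]
generations with `m` profiled at each `t` by bounded 1-D likelihood
maximization, followed by golden-section refinement of `t`; a boundary
optimum raises a warning. This profile-likelihood search was chosen
over EM for robustness and reproducibility of the 1-D profile.

**Confidence intervals.** 1000 block bootstraps of contiguous AIM
blocks, percentile method. Replicates are evaluated on precomputed
per-block log-likelihood surfaces over a fine local (t, m) grid
(31 × 31; t within ×e^±0.4, m within ±0.08 of the MLE), so each
replicate is a resampled sum and argmax — equivalent to refitting under
the block-independence approximation at a fraction of the cost. At the
synthetic scale (~5,000–6,000 AIMs) the block size is 250 AIMs,
matching the blocks-per-genome ratio that 5000-AIM blocks give at
real-data marker counts (~100× more); with ~24 blocks the 95% CIs cover the true
`t` in ≥ 17/20 seeds.

**Tracts and tract dating.** Tracts are maximal runs of AIMs with donor
posterior `P(dosage ≥ 1) ≥ 0.8`; boundaries at inter-AIM midpoints
(a deterministic convention), chromosome-end runs flagged
censored and excluded from dating. Because unphased dosage decoding
yields the *union* of the two haplotypes' donor segments, the mean
donor-present run under the stationary two-haplotype chain is
`L̄ = (2−m) / (2(1−m)²·r·t)` (renewal-reward, exact), which
`tract_time` inverts by default; `ploidy="haploid"` gives the plain
exponential inversion `t = 1/((1−m)·r·L̄)` for haploid tracts. Tract
dating carries a mild downward bias (~5–10%) from short tracts falling
below the posterior threshold; the HMM likelihood date does not share
it, and the two are reported side by side.

**Masking.** Sites inside qualifying tracts are set missing per sample;
masked runs separated by fewer than 3 contiguous clean sites are merged
before emitting mask intervals. On synthetic cohorts, masking then
rebuilding the NJ tree moves the admixed samples into their
majority-ancestry clade with full support.

## Selection scans (`selection`)

Windowed F_ST sums per-site Weir–Cockerham (1984) variance components
(`Σa / Σ(a+b+c)`; observed heterozygosity enters `h̄`); negative window
values are retained. The Hudson estimator is available and correlates
> 0.99 with WC84 on balanced designs. θπ is the unbiased per-site
heterozygosity `2p(1−p)·n/(n−1)` summed per window, reported per
variant site and per bp.

XP-EHH: EHH is the probability two random haplotypes are identical over
the interval from the core out to `x` (`Σ C(n_h,2)/C(n,2)`; 1 at the
core, monotone non-increasing), trapezoid-integrated in physical
distance until it falls below 0.05 on each side. No genetic map exists
for the target taxa, so integration is in bp. Cores require pooled
MAF ≥ 0.05 (standard practice). Scores are
`ln(iHH_A/iHH_B)`, standardized globally (mean 0, SD 1); cores whose
EHH fails to decay before a chromosome end or a > 200-kb gap are
missing — the standard guard against assembly gaps inflating iHH.
Significant SNPs (top 1%) merge into regions tolerating one embedded
non-significant SNP, extending half the distance to the flanking
non-significant markers; isolated significant SNPs are discarded. A
painted 500-kb hard sweep (one haplotype copied to 90% of carriers) is
localized by the merged regions in ≥ 18/20 seeds.

## Recent Ne (`demography`)

Pairs of SNPs (MAF ≥ 0.05, the SNeP default — without it the
rare-variant-heavy frequency spectrum dilutes bin means and inflates Ne
~2×) are binned by physical distance; distance maps to recombination
fraction via Sved `c = dr/(1+dr)` (Haldane optional); each bin is
assigned `t = 1/(2c)` generations. Genotypic r² minus the sample-size
term (1/n unphased, 1/(2n) phased) inverts to
`Ne = (1/(4c))(1/E[r²_adj] − α)` with `α = 2.2` when mutation is
modeled (2 otherwise). Bins with < 100 pairs, or at the `1/α` boundary,
are missing. On analytic input the inversion is exact; on coalescent
genotypes (24 diploids, ~9,000 SNPs, truth Ne = 1000) the bin median
recovers Ne well within a factor of 1.5.

Slope-change detection fits the global least-squares slope of Ne
against t and reports each interval's local finite-difference slope
relative to it, signed so that values below zero mean a
steeper-than-trend decline toward the present. A localized extra drop
injected at t = 110 generations is localized to within ±2 bins.

Calendar conversion is `years = round-half-up(t × g)` per
generation-length scenario and
`g = (reference_year − event_year)/t` for event anchoring (reference
year 2020 by default).

## Phylogeny (`phylo`)

Diploid P-distance is `Σ|dosage_i − dosage_j| / (2 × shared called
sites)` — the uncorrected P-distance generalized to genotypes (the
per-site diploid definition is not standardized; this one is symmetric,
metric on dosages, and missing-data aware). Neighbor-joining is
delegated to scikit-bio; support values are the percentage of 100
site-resampling bootstrap replicates containing each bipartition.

The quartet tally assigns each ≥ 50-informative-site window the
topology minimizing the four-point sum of group-mean distances; windows
inside the margin are ambiguous. The proportions are a deliberately
simplified discordance proxy: they are comparable across topologies in
sign and ordering (donor-pairing excess indicates admixture), **not**
in absolute value to coalescent-HMM discordance estimates.

## Problem sizes

Test and acceptance runs use 5 × 20 Mb genomes with ~50,000 SNPs and
8 + 8 + 8 + 4 diploids — large enough that tract statistics, block
resampling and window scans operate in their asymptotic regime, while a
complete 20-seed recovery study runs in minutes. Real-data headline values (genome-wide D on real species panels,
absolute ancestry fractions) require the original resequencing data and
are outside what synthetic recovery can or should reproduce.
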