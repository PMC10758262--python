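# Methods

## The statistic

cLD applies the two-locus LD formulas to region-level carrier
frequencies. For regions A and B on phased haplotypes, the carrier
indicator of a haplotype is 1 iff it carries at least one *rare* variant
(MAF strictly below a cutoff, default 0.005) inside the region's
interval. With P_A, P_B the carrier frequencies (cMAFs), P_AB the joint
carrier frequency and D = P_AB − P_A·P_B:

- r² = D² / (P_A(1−P_A) P_B(1−P_B)) — identical to the squared Pearson
  correlation of the two indicator vectors under population moments
  (divide by n, never n−1). This identity is the master oracle of the
  test suite and holds to 1e-12.
- D′ = D / D_max, with D_max = min(P_A(1−P_B), P_B(1−P_A)) for D > 0 and
  min(P_A·P_B, (1−P_A)(1−P_B)) for D < 0; D′ = 0 at D = 0.

A statistic is *undefined* when either margin is 0 or 1. Undefined values
carry an explicit flag and NaN; they are excluded from every average and
never silently reported as 0 (which would bias bin means downward).

When each region contains exactly one rare variant, cLD reduces to the
single-variant LD of that pair, exactly. Adding to a region a variant
whose carriers are a subset of the region's existing carriers leaves the
indicator, and hence every statistic, unchanged.

### Input conventions

- Phased VCF only; an unphased (`/`) genotype is a hard error naming the
  record. Two haplotype rows per diploid sample.
- Alleles are re-oriented on load so the stored allele is the minor one in
  the loaded sample; at exactly 0.5 the ALT allele is kept.
- Multi-allelic records expand to one binary column per ALT allele.
- Missing alleles count as major (non-carrier) and are tallied per
  variant. This is a convention, not imputation, and is a documented
  limitation: cLD under high missingness is biased toward fewer carriers.
- Coordinates are 0-based half-open internally (BED convention); a
  variant belongs to a region iff its 0-based position lies in
  [start, end). The rare filter is strict (< cutoff), and monomorphic
  columns are always dropped.

## Asymptotic variance (delta method)

The 2×2 carrier table (both / A-only / B-only / neither) is modelled as
multinomial with cells p = (p11, p10, p01, p00). The statistic
g(p) = D²/(pA qA pB qB) has first-order variance ∇gᵀ Σ ∇g / n over the
three free coordinates (p11, p10, p01) — p00 is eliminated because the
4-cell multinomial covariance is singular on the simplex, and any
full-rank parameterization gives the same value (the finite-difference
oracle in the tests confirms the analytic gradient to 1e-4 relative).

The same formula serves single-variant LD: only the table changes (two-SNV
haplotype counts instead of two-region carrier counts). Var(cLD)/Var(LD)
is therefore a ratio of one closed form at two tables, and is invariant to
n. At rare-variant tables (MAF ~0.002–0.005) against carrier tables
(cMAF ~0.05–0.4) the ratio is ≪ 1 — the quantitative content of the
stability claim.

Caveats, by construction of the first-order method:

- At D = 0 the gradient of the squared term vanishes and the first-order
  variance is exactly 0. The approximation degenerates there; the code
  warns, and verification grids avoid D = 0.
- No exact finite-sample variance, and no variance for D′.

ΔcLD = cLD_case − cLD_control gets Var(Δ) = Var_case + Var_control under
cohort independence. Folding to |Δ| is left to callers since the
half-normal correction depends on the null location.

## Bootstrap stability protocol

Per iteration, floor(n/2) haplotypes are drawn *without replacement*
(half-sampling, not a classical with-replacement bootstrap); over the
sampled gene pairs the bin-averaged cLD and the bin-averaged gene-pair LD
are recorded; after all iterations each (bin, statistic) series is
divided by its own mean, so spread is read relative to location. Design
choices where the protocol was open:

- Pair-level cMAF summary for bin assignment = mean of the two cMAFs
  (configurable to min/max); bins are half-open with the right edge
  exclusive, and assignment is fixed from the full-sample cMAFs so the
  same pairs are compared across iterations.
- The gene-pair LD inside the bootstrap is the exact mean over *all*
  cross-region variant pairs defined in the subsample, computed by a
  sparse co-occurrence decomposition: a non-co-occurring pair contributes
  p_a p_b/(q_a q_b) in closed form, so only co-carried variant pairs are
  enumerated. This makes 200 iterations over ~5,000 gene pairs take
  seconds. (The 2,000-pair subsampling cap applies to `gene_pair_ld` used
  in the enrichment machinery, where it is part of that protocol.)
- Mean-normalization is per (bin, statistic) series; a population-wide
  divisor is an alternative reading and would change location, not the
  spread ordering.

### What the stability experiment shows at desk scale

The stability ordering — sd of normalized cLD below sd of normalized LD
per cMAF bin — is evaluated on synthetic panels of 200 haplotypes, 100
regions, 30–100 variants per region at the rarest frequencies the sample
size can express (target MAF 0.004–0.005, i.e. singletons/doubletons;
filter cutoff 0.011 because at n = 200 the MAF grid has step 0.005), with
region cMAFs drawn in 0.015–0.042. That band keeps carrier co-occurrence
a rare event (cMAF²·n_sub ≲ 1), which is the regime the statistic
targets: there the per-iteration LD bin average is driven by heavy-tailed
singleton co-occurrence counts while the cLD average pools thousands of
bounded per-pair values. At this sample size the ordering genuinely
reverses for common carriers (cMAF ≳ 0.15, i.e. >30 carriers per 200
haplotypes): carrier co-carriage is then frequent, the LD average
stabilizes, and aggregation buys nothing — so the experiment deliberately
does not populate the upper cMAF bins, and a passing test says nothing
about them. Three replicate fixtures are pooled per evaluation, and the
test allows one repeat at an independent seed: the effect size at n = 200
(sd ratio ≈ 0.9) is a few times the sampling error of an sd estimated
from 200 iterations.

## Enrichment machinery

- Distance groups are a geometric progression of upper edges 35 kb·2^k,
  k = 0..12 (13 groups, top edge 143,360,000 bp, under the longest human
  chromosome). Bin k covers (edge_{k−1}, edge_k].
- Gene-pair distance is midpoint-to-midpoint (configurable to gap
  distance); a gene is "in" an interaction region when its interval
  overlaps any anchor by ≥ 1 bp; pairs with exactly one member in an
  anchor are discarded, as are cross-chromosome pairs.
- The dichotomizing cutoff is the per-stratum median (0.5 quantile) of
  defined statistics, recomputed within each distance bin (pooled-median
  alternative by flag). Strata missing either label are dropped with a
  note.
- Mantel–Haenszel: common odds ratio and chi-square test via statsmodels,
  continuity correction on by default (sparse long-distance strata);
  calibration studies should switch it off, since the correction is
  deliberately conservative. Fisher exact (scipy) is emitted both per
  stratum and pooled, because which of the two the original protocol used
  is ambiguous.
- The cutoff-ratio curve reports both the raw count ratio and the
  class-size-normalized ratio (each count divided by its class total);
  0/0 is NaN and k/0 is ∞, never silently dropped.
- Gene-set enrichment is the hypergeometric upper tail
  P(X ≥ q) with q = |selected ∩ database|, m = |database|,
  n = |universe \ database|, k = |selected|.

## Case/control ΔcLD

cLD is computed per cohort on a shared variant universe: rare status is
decided on the pooled cohorts by default so both arms aggregate identical
columns (per-cohort filtering available, but then the two statistics
aggregate different variant sets). Records undefined in either cohort are
flagged and excluded from ranking; ranks are descending in
Δ = |cLD_case − cLD_control| with lexicographic tie-breaks for
determinism. No significance threshold is applied: Δ ranking is a
screening device, and the delta-method variance can annotate records with
an exploratory z-like score only.

## Forward simulator

A haploid two-region Wright–Fisher variant with, per generation, in
order: fitness-proportional parent sampling with
w = (1+s_neg)^(m_A+m_B) · (1+s_syn)^(c_A·c_B) (m = per-region mutant
counts, c = carrier indicators; the synergy term only when interactions
are on); recombination exchanging the region-B segment with a second
parent with probability `rec`; Poisson(mu) new singleton mutations per
region; deterministic exponential growth n0·g^t. Defaults: n0 = 500,
growth 1.02, mu = 0.5, s_neg = −0.01, s_syn = 0.05, founders initialized
with carrier frequency 0.2 per region and carrier correlation 0.5 (decay
is only observable from a nonzero starting association). These update
rules and defaults are this package's own modelling choices; the decay
experiments are interpreted qualitatively (orderings across matched
seeds), never as curve matching. Negative selection plus growth keeps
variants rare — the two forces that enrich rare variants in human
populations — and synergy between joint carriers decelerates the
recombination-driven cLD decay, which the seed-matched comparison
detects at 50 replicates.

Switch errors model phasing mistakes as contiguous segment swaps: walking
an individual's variant positions in genomic order, a swap state toggles
with probability `rate` at each heterozygous position (switches are
undetectable at homozygous sites) and takes effect at subsequent
positions. Re-phasing never changes an individual's per-site allele
content, and swapping an individual's two haplotypes wholesale permutes
the carrier indicator multiset, leaving every cLD exactly unchanged — both
asserted in the tests. The robustness experiment reports the mean of
|cLD_err − cLD_true|/cLD_true over pairs with true r² ≥ 0.01: the
relative change is ill-conditioned when the true value sits at the 1/n
noise floor, so near-null pairs are excluded from the mean.

## Synthetic fixture generator

The generator draws each region's carrier indicator first (Bernoulli with
the target cMAF; joint draws with a specified correlation ρ for designated
region pairs, validated against the Fréchet bounds), then assigns each
carrier ≥ 1 rare allele with carrier-conditional variant probabilities
calibrated by fixed-point iteration so the unconditional per-variant
frequencies land on their MAF targets despite the ≥ 1-allele rejection
step. The target cMAF defaults to the independent-variant bound
1 − Π(1−maf_s) and can be set lower to emulate real data, where carrier
haplotypes stack several private variants and region cMAF is far below
that bound. Infeasible targets (cMAF above the summed variant MAF mass,
or ρ outside the Fréchet bounds for the margins) raise informative
errors rather than silently drifting.

What the generator does *not* emulate: within-region variant LD structure
beyond carrier stacking, recombination maps, mutation-age frequency
spectra, population structure, genotyping error, or missingness. Tests
passing on these fixtures therefore validate the estimators and
protocols, not the demographic realism of any particular dataset.

## Numerical and engineering choices

- Frequencies use population moments (1/n) throughout, matching the
  statistic's definition.
- `gene_pair_ld` excludes undefined variant pairs from its average and
  reports the count used; sampling beyond the 2,000-pair cap is uniform
  without replacement and seeded.
- All stochastic procedures take explicit seeds and are bit-reproducible;
  the CLI echoes the resolved configuration into every output header.
- The bootstrap's sparse fast path requires regions with disjoint variant
  columns and raises otherwise; every other operation supports
  overlapping regions.
- Ties in ΔcLD ranking break lexicographically on region names; ties in
  distance matching resolve toward the smaller distance.

## Known limitations

- Missing genotypes as non-carriers can only deflate carrier frequencies.
- The first-order variance is useless in a neighbourhood of D = 0.
- Diploid-genotype (unphased) approximations of cLD are out of scope; so
  are phasing, imputation and polyploid samples.
- The worked six-haplotype example yields D = 0 exactly from its own
  frequencies, hence r² = 0; a commonly quoted value of 0.375 for that
  configuration is not derivable from those frequencies under the r²
  formula and is treated as an inconsistency of the illustration, not of
  the statistic.
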