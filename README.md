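# cld — cumulative linkage disequilibrium between genomic regions

Standard linkage disequilibrium (LD) is unusable for rare variants: with
minor allele frequencies (MAF) near zero, the frequency products in the
denominator of r² make the estimator wildly unstable, which is why LD
analyses conventionally discard everything below MAF ≈ 0.05 — the vast
majority of human variation. `cld` implements **cumulative LD (cLD)**, a
region-level statistic that rescues rare variants by aggregating them
first: each region (typically a gene) is collapsed to a per-haplotype
*carrier indicator* (1 iff the haplotype carries ≥ 1 rare variant in the
region), and the classical LD formulas are applied to the carrier
frequencies instead of single-variant allele frequencies.

With cumulative frequencies

- P_A = (1/n) Σᵢ I(haplotype *i* carries ≥ 1 rare variant in region A),
- P_AB = fraction of haplotypes carrying ≥ 1 rare variant in *both* regions,
- D = P_AB − P_A·P_B,

the r² form is

```
cLD = D² / ( P_A (1 − P_A) P_B (1 − P_B) )
```

which equals the squared Pearson correlation of the two binary carrier
vectors. D′ (D normalized by its theoretical maximum given the margins) is
also provided. Because P_A and P_B are cumulative, they sit far from 0 and
the estimator is orders of magnitude more stable than per-variant rare LD.

The package is aimed at statistical geneticists working with phased
haplotype panels (e.g. 1000 Genomes-style VCFs) and provides, beyond the
statistic itself:

- **haplotype_io** — phased VCF → binary haplotype matrix (minor-allele
  oriented, multi-allelic sites split), BED regions, strict rare-variant
  filtering (MAF < cutoff, default 0.5%);
- **core_stats** — cLD (D, D′, r²), single-variant LD, gene-pair-averaged
  LD over sampled cross-region variant pairs, rare-common cLD;
- **asymptotics** — closed-form delta-method variance of r̂² under a
  multinomial model of the 2×2 carrier table, Var(cLD)/Var(LD) ratios, and
  the variance of the case/control difference ΔcLD;
- **resampling** — the half-sample bootstrap protocol comparing the
  stability of bin-averaged cLD vs LD in cMAF bins;
- **enrichment** — geometric distance groups (35 kb doubling, 13 groups),
  interaction-label stratification, Mantel–Haenszel and Fisher exact
  tests, cutoff-ratio curves, hypergeometric gene-set enrichment;
- **casecontrol** — ΔcLD = |cLD_case − cLD_control| screening and top-k
  gene-set extraction;
- **simulation** — a forward-time two-region Wright–Fisher simulator
  (growth, negative selection, carrier synergy, recombination) for cLD
  decay experiments, a phasing switch-error model, and the synthetic
  fixture generator used throughout the tests.

## Worked example

The canonical toy: six haplotypes, two regions; haplotypes 1 and 4 carry a
rare variant in region A, haplotypes 3, 4 and 5 in region B.

```python
import cld

H, regions, truth = cld.make_fixture(
    n_hap=200, n_regions=2, variants_per_region=30,
    maf_low=0.004, maf_high=0.005, rho=0.5,
    correlated_pairs=[(0, 1)], cmaf=0.1, seed=1,
)
pairs = cld.pairwise_cld(H, regions)
print(pairs[["region_a", "region_b", "p_a", "p_b", "p_ab", "r2"]])
```

prints

```
  region_a region_b   p_a  p_b   p_ab        r2
0       G0       G1  0.09  0.1  0.055  0.287071
```

two regions whose carrier frequencies are ≈ 0.1 and whose carrier
correlation was calibrated to 0.5, so r² ≈ 0.5² = 0.25 up to sampling
noise. The same computation on the six-haplotype toy above gives
P(A) = 2/6 ≈ 0.33, P(B) = 3/6 = 0.50 and P(AB) = 1/6 ≈ 0.17 — for which
D = 1/6 − (2/6)(3/6) = 0 exactly, i.e. the two regions are uncorrelated
and r² = 0.

From the shell, the same pipeline runs as:

```bash
cld fixture --out-vcf toy.vcf --out-bed toy.bed --n-hap 200 --regions 4 \
    --variants 20 --maf-low 0.001 --maf-high 0.004 --seed 7
cld compute --vcf toy.vcf --bed toy.bed --maf-cutoff 0.005 --out pairs.tsv
cld variance --table 0.3,0.2,0.1,0.4 --n 500 --out var.tsv
cld simulate decay --generations 50 --rec 0.1 --seed 1 --out decay.tsv
```

Every output TSV carries a `#`-prefixed header echoing the resolved
configuration and seed.

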