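"""Forward-time simulation of cLD decay, phasing-error experiments, and
the synthetic haplotype fixture generator.

Decay simulator
---------------
A haploid Wright–Fisher-style model of two linked regions (A | B) in a
growing population.  Each generation, in order: (1) offspring sample
parental haplotypes with probability proportional to fitness
``w = (1 + s_neg)^(m_A + m_B) * (1 + s_syn)^(c_A * c_B)`` where m_A, m_B
count the haplotype's mutant alleles per region and c_A, c_B are the
regional carrier indicators (the synergy term applies only when
``interaction_on``); (2) with probability ``rec`` an offspring takes its
region-B segment from a second, independently drawn parent;
(3) new mutations arise at rate ``mu`` per region per generation, each a
new singleton variant on a random haplotype; (4) the population size
follows the ``growth_rate`` schedule.  The per-generation cLD r² between
the two regions is recorded.

Negative selection on individual mutations plus growth keeps variants
rare; synergy between joint carriers slows the recombination-driven cLD
decay — the qualitative behaviour the decay experiments measure.

Switch errors
-------------
Phasing mistakes are modelled as contiguous segment swaps: walking an
individual's variant positions left to right, a swap state toggles with
probability ``rate`` at each heterozygous position and, while active,
the two haplotypes' alleles are exchanged at subsequent positions.
Re-phasing never changes an individual's allele content at any site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_stats import _ld_stats, carrier_profile, cld
from .haplotype_io import HaplotypeMatrix, Region, RegionSet, VariantRecord

DEFAULT_SWITCH_RATES = tuple(np.round(np.arange(0.01, 0.101, 0.01), 2))


# ---------------------------------------------------------------------------
# decay simulator


@dataclass(frozen=True)
class SimParams:
    """Parameters of the two-region decay simulator.

    Defaults emulate a growing population under weak negative selection
    with a modest synergy reward for joint carriers; founder haplotypes
    start with correlated carrier status so that decay is observable.
    """

    n0: int = 500
    growth_rate: float = 1.02
    mu: float = 0.5  # new mutations per region per generation
    s_neg: float = -0.01  # selection against each mutant allele (<= 0)
    s_syn: float = 0.05  # synergy between joint carriers (>= 0)
    rec: float = 0.0  # recombination probability between the regions
    generations: int = 50
    interaction_on: bool = True
    seed: int = 0
    init_cmaf: float = 0.2  # founder carrier frequency per region
    init_rho: float = 0.5  # founder carrier correlation between regions
    init_variants: int = 8  # founder variant columns per region

    def __post_init__(self):
        if self.n0 < 2:
            raise ValueError("n0 must be >= 2")
        if not (0.0 <= self.rec <= 0.5):
            raise ValueError("rec must be in [0, 0.5]")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.s_neg > 0 or self.s_syn < 0:
            raise ValueError("require s_neg <= 0 and s_syn >= 0")


@dataclass
class SimTrajectory:
    """Per-generation population size, regional cMAFs and cLD r²."""

    table: pd.DataFrame  # generation, pop_size, cmaf_a, cmaf_b, cld, defined
    final_a: np.ndarray = field(repr=False, default=None)
    final_b: np.ndarray = field(repr=False, default=None)


def _correlated_indicators(
    n: int, qa: float, qb: float, rho: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Joint Bernoulli draw with margins (qa, qb) and correlation rho."""
    p11 = qa * qb + rho * np.sqrt(qa * (1 - qa) * qb * (1 - qb))
    lo = max(0.0, qa + qb - 1.0)
    hi = min(qa, qb)
    if not (lo - 1e-12 <= p11 <= hi + 1e-12):
        raise ValueError(
            f"rho={rho} infeasible for margins ({qa}, {qb}): "
            f"Fréchet bounds give p11 in [{lo:.6g}, {hi:.6g}], need {p11:.6g}"
        )
    p11 = min(max(p11, lo), hi)
    probs = [p11, qa - p11, qb - p11, 1 - qa - qb + p11]
    cells = rng.choice(4, size=n, p=probs)
    return (cells <= 1).astype(np.uint8), ((cells == 0) | (cells == 2)).astype(np.uint8)


def _spread_carriers(
    ind: np.ndarray, n_variants: int, rng: np.random.Generator
) -> np.ndarray:
    """Variant columns whose row-wise OR equals the carrier indicator."""
    n = ind.size
    M = np.zeros((n, n_variants), dtype=np.uint8)
    carriers = np.flatnonzero(ind)
    for i in carriers:
        k = 1 + rng.binomial(n_variants - 1, 0.5 / n_variants)
        cols = rng.choice(n_variants, size=k, replace=False)
        M[i, cols] = 1
    return M


def _region_cld(A: np.ndarray, B: np.ndarray) -> tuple[float, float, float, bool]:
    ca = (A.sum(axis=1) >= 1).astype(np.float64)
    cb = (B.sum(axis=1) >= 1).astype(np.float64)
    pa, pb = float(ca.mean()), float(cb.mean())
    pab = float((ca * cb).mean())
    _, _, r2, defined = _ld_stats(pa, pb, pab)
    return pa, pb, r2, defined


def simulate(params: SimParams) -> SimTrajectory:
    """Run the decay simulator and record the per-generation trajectory."""
    rng = np.random.default_rng(params.seed)
    ia, ib = _correlated_indicators(
        params.n0, params.init_cmaf, params.init_cmaf, params.init_rho, rng
    )
    A = _spread_carriers(ia, params.init_variants, rng)
    B = _spread_carriers(ib, params.init_variants, rng)

    records = []
    pa, pb, r2, defined = _region_cld(A, B)
    records.append(
        {
            "generation": 0,
            "pop_size": params.n0,
            "cmaf_a": pa,
            "cmaf_b": pb,
            "cld": r2 if defined else float("nan"),
            "defined": defined,
        }
    )
    for gen in range(1, params.generations + 1):
        n_now = A.shape[0]
        # 1) selection: parents sampled proportional to fitness
        m = A.sum(axis=1) + B.sum(axis=1)
        w = (1.0 + params.s_neg) ** m
        if params.interaction_on and params.s_syn > 0:
            joint = ((A.sum(axis=1) >= 1) & (B.sum(axis=1) >= 1)).astype(float)
            w = w * (1.0 + params.s_syn) ** joint
        w = w / w.sum()
        n_next = max(2, int(round(params.n0 * params.growth_rate**gen)))
        parents = rng.choice(n_now, size=n_next, p=w)
        A_next, B_next = A[parents].copy(), B[parents].copy()
        # 2) recombination: region-B segment taken from a second parent
        rec_mask = rng.random(n_next) < params.rec
        if rec_mask.any():
            donors = rng.choice(n_now, size=int(rec_mask.sum()), p=w)
            B_next[rec_mask] = B[donors]
        # 3) mutation: new singleton variant columns
        for block in ("A", "B"):
            n_mut = rng.poisson(params.mu)
            if n_mut == 0:
                continue
            new = np.zeros((n_next, n_mut), dtype=np.uint8)
            new[rng.integers(0, n_next, size=n_mut), np.arange(n_mut)] = 1
            if block == "A":
                A_next = np.hstack([A_next, new])
            else:
                B_next = np.hstack([B_next, new])
        # drop lost columns to bound memory
        A = A_next[:, A_next.any(axis=0)]
        B = B_next[:, B_next.any(axis=0)]
        if A.shape[1] == 0:
            A = np.zeros((n_next, 1), dtype=np.uint8)
        if B.shape[1] == 0:
            B = np.zeros((n_next, 1), dtype=np.uint8)
        pa, pb, r2, defined = _region_cld(A, B)
        records.append(
            {
                "generation": gen,
                "pop_size": n_next,
                "cmaf_a": pa,
                "cmaf_b": pb,
                "cld": r2 if defined else float("nan"),
                "defined": defined,
            }
        )
    return SimTrajectory(table=pd.DataFrame(records), final_a=A, final_b=B)


# ---------------------------------------------------------------------------
# switch errors


def inject_switch_errors(
    H: HaplotypeMatrix, rate: float, seed: int = 0
) -> HaplotypeMatrix:
    """Apply contiguous-segment phasing errors to paired haplotype rows.

    Rows (2i, 2i+1) form individual i.  Walking variant positions in
    genomic order, the swap state toggles with probability ``rate`` at
    each heterozygous position and takes effect at subsequent positions;
    while active the two rows' alleles are exchanged.  The per-site
    allele multiset of every individual is preserved.
    """
    if H.n_haplotypes % 2:
        raise ValueError("row count must be even (two haplotypes per individual)")
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    order = sorted(range(H.n_variants), key=lambda j: (H.variants[j].chrom, H.variants[j].pos))
    V = H.values.copy()
    for i in range(H.n_haplotypes // 2):
        r0, r1 = 2 * i, 2 * i + 1
        swapped = False
        for j in order:
            if swapped:
                V[r0, j], V[r1, j] = V[r1, j], V[r0, j]
            if H.values[r0, j] != H.values[r1, j] and rng.random() < rate:
                swapped = not swapped
    return HaplotypeMatrix(V, list(H.variants), list(H.sample_ids))


def swap_individuals(H: HaplotypeMatrix, individuals: list[int]) -> HaplotypeMatrix:
    """Exchange the two haplotypes of whole individuals (for invariance checks)."""
    V = H.values.copy()
    for i in individuals:
        V[[2 * i, 2 * i + 1]] = V[[2 * i + 1, 2 * i]]
    return HaplotypeMatrix(V, list(H.variants), list(H.sample_ids))


def switch_error_experiment(
    H: HaplotypeMatrix,
    regions: RegionSet,
    rates: tuple[float, ...] = DEFAULT_SWITCH_RATES,
    seed: int = 0,
    min_r2: float = 0.01,
) -> pd.DataFrame:
    """Mean proportion of cLD change per switching-error rate.

    For each rate the matrix is perturbed, all pairwise cLDs are
    recomputed, and |cLD_err − cLD_true| / cLD_true is averaged over
    pairs defined in both matrices.  Pairs with true r² below ``min_r2``
    are excluded: the relative change is ill-conditioned when the true
    value sits at the noise floor.
    """
    region_list = list(regions)
    profiles = {r.name: carrier_profile(H, r) for r in region_list}
    from itertools import combinations

    true_vals = {}
    for ra, rb in combinations(region_list, 2):
        res = cld(profiles[ra.name], profiles[rb.name])
        if res.defined and res.r2 >= min_r2:
            true_vals[(ra.name, rb.name)] = res.r2
    if not true_vals:
        raise ValueError("no region pair with defined nonzero cLD")
    rows = []
    for idx, rate in enumerate(rates):
        Hp = inject_switch_errors(H, rate, seed=seed + idx)
        prof_p = {r.name: carrier_profile(Hp, r) for r in region_list}
        props = []
        for (na, nb), true_r2 in true_vals.items():
            res = cld(prof_p[na], prof_p[nb])
            if res.defined:
                props.append(abs(res.r2 - true_r2) / true_r2)
        rows.append(
            {
                "error_rate": rate,
                "mean_proportion_change": float(np.mean(props)) if props else float("nan"),
                "n_pairs": len(props),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic fixtures


def make_fixture(
    n_hap: int,
    n_regions: int,
    variants_per_region: int | list[int],
    maf_low: float,
    maf_high: float,
    rho: float = 0.0,
    correlated_pairs: list[tuple[int, int]] | None = None,
    cmaf: float | list[float] | None = None,
    chrom: str = "chr1",
    region_span: int = 50_000,
    region_gap: int = 50_000,
    seed: int = 0,
) -> tuple[HaplotypeMatrix, RegionSet, pd.DataFrame]:
    """Synthetic phased rare-variant haplotypes with known truth.

    Per region the carrier indicator is drawn first — Bernoulli with the
    target cMAF — with correlation ``rho`` between the members of each
    designated region pair (default: none).  Carriers are then assigned
    at least one rare allele spread over the region's variants, with the
    carrier-conditional probabilities calibrated so the per-variant
    frequencies land near their MAF targets.  The target cMAF defaults
    to the value implied by independent variants, ``q = 1 − Π(1 −
    maf_s)``; pass ``cmaf`` (scalar or per-region) to decouple it — real
    rare-variant data has cMAF well below that bound because carrier
    haplotypes stack several private variants.  Returns the matrix, the
    region set, and a truth table of intended cMAFs and pairwise
    correlations.

    Raises if ``rho`` violates the Fréchet bounds for the drawn margins.
    """
    if not (0.0 < maf_low <= maf_high < 0.5):
        raise ValueError("require 0 < maf_low <= maf_high < 0.5")
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    if n_hap % 2:
        raise ValueError("n_hap must be even (diploid samples)")
    rng = np.random.default_rng(seed)
    correlated_pairs = list(correlated_pairs or [])
    in_pair = {i for ab in correlated_pairs for i in ab}
    if isinstance(variants_per_region, int):
        n_var = [variants_per_region] * n_regions
    else:
        n_var = list(variants_per_region)
        if len(n_var) != n_regions:
            raise ValueError("variants_per_region list must match n_regions")

    # per-region variant MAF targets and target cMAFs
    mafs = [rng.uniform(maf_low, maf_high, size=m) for m in n_var]
    if cmaf is None:
        qs = [float(1.0 - np.prod(1.0 - m)) for m in mafs]
    else:
        qs = [float(cmaf)] * n_regions if np.isscalar(cmaf) else [float(x) for x in cmaf]
        if len(qs) != n_regions:
            raise ValueError("cmaf list must match n_regions")
        for q, m in zip(qs, mafs):
            if not (m.max() <= q < 1.0):
                raise ValueError("each target cmaf must be in [max variant MAF, 1)")
            # every carrier holds >= 1 allele, so unconditional allele mass
            # must cover the carrier mass
            if q > m.sum():
                raise ValueError(
                    f"target cmaf {q:.4g} infeasible: exceeds summed variant "
                    f"MAFs {m.sum():.4g} (each carrier needs >= 1 rare allele)"
                )

    indicators: dict[int, np.ndarray] = {}
    for a, b in correlated_pairs:
        ia, ib = _correlated_indicators(n_hap, qs[a], qs[b], rho, rng)
        indicators[a], indicators[b] = ia, ib
    for r in range(n_regions):
        if r not in in_pair:
            indicators[r] = (rng.random(n_hap) < qs[r]).astype(np.uint8)

    columns, variants, regions = [], [], []
    for r in range(n_regions):
        start = r * (region_span + region_gap)
        end = start + region_span
        regions.append(Region(chrom=chrom, start=start, end=end, name=f"G{r}"))
        q = qs[r]
        m = n_var[r]
        # carrier-conditional per-variant probabilities, corrected for the
        # >=1-allele rejection step so unconditional frequencies hit maf_s:
        # freq_s = q * p_s / (1 - prod(1 - p)) = maf_s, solved by iteration
        p_cond = np.minimum(mafs[r] / q, 1.0)
        for _ in range(25):
            accept = 1.0 - np.prod(1.0 - p_cond)
            p_new = np.minimum(mafs[r] * accept / q, 1.0)
            if np.allclose(p_new, p_cond, atol=1e-12):
                p_cond = p_new
                break
            p_cond = p_new
        if 1.0 - np.prod(1.0 - p_cond) < 1e-3:
            raise ValueError(
                f"region {r}: cmaf/MAF targets leave no feasible carrier "
                "allele assignment (acceptance collapsed)"
            )
        block = np.zeros((n_hap, m), dtype=np.uint8)
        for i in np.flatnonzero(indicators[r]):
            draw = rng.random(m) < p_cond
            while not draw.any():  # carriers carry at least one rare allele
                draw = rng.random(m) < p_cond
            block[i] = draw
        pos = np.sort(rng.choice(np.arange(start, end), size=m, replace=False))
        for j in range(m):
            variants.append(
                VariantRecord(
                    chrom=chrom,
                    pos=int(pos[j]) + 1,  # VCF 1-based
                    ref_alt="A>T",
                    maf=min(float(block[:, j].mean()), 0.5),
                )
            )
        columns.append(block)

    values = np.hstack(columns) if columns else np.zeros((n_hap, 0), dtype=np.uint8)
    sample_ids = [(f"S{i}", h) for i in range(n_hap // 2) for h in (0, 1)]
    H = HaplotypeMatrix(values, variants, sample_ids)

    truth_rows = [
        {"region": f"G{r}", "target_cmaf": qs[r], "empirical_cmaf": float(indicators[r].mean())}
        for r in range(n_regions)
    ]
    truth = pd.DataFrame(truth_rows)
    truth.attrs["correlated_pairs"] = [
        {"region_a": f"G{a}", "region_b": f"G{b}", "rho": rho}
        for a, b in correlated_pairs
    ]
    return H, RegionSet(regions), truth
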