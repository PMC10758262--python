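"""Cumulative linkage disequilibrium (cLD) and standard LD.

The cLD statistic applies the classical two-locus LD formulas to
*region-level* carrier frequencies instead of single-variant allele
frequencies.  For a region A the cumulative minor allele frequency
(cMAF) is

    P_A = (1/n) * sum_i I(haplotype i carries >= 1 rare variant in A)

and P_AB is the fraction of haplotypes carrying at least one rare
variant in both regions.  With D = P_AB - P_A * P_B,

    r^2 = D^2 / (P_A (1 - P_A) P_B (1 - P_B))

and D' normalizes D by its theoretical maximum given the margins.
All frequencies are population moments (divide by n, never n - 1).

Statistics are *undefined* (``defined=False``) when a margin is 0 or 1;
undefined values are propagated as NaN and excluded from every average,
never silently reported as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np
import pandas as pd

from .haplotype_io import HaplotypeMatrix, Region, RegionSet

DEFAULT_MAX_PAIRS = 2000


@dataclass(frozen=True)
class CarrierProfile:
    """Per-haplotype carrier indicator for one region and its cMAF."""

    region_name: str
    indicator: np.ndarray
    cmaf: float

    def __post_init__(self):
        ind = np.asarray(self.indicator, dtype=np.uint8)
        object.__setattr__(self, "indicator", ind)


@dataclass(frozen=True)
class CLDResult:
    region_a: str
    region_b: str
    p_a: float
    p_b: float
    p_ab: float
    d: float
    d_prime: float
    r2: float
    n: int
    defined: bool


@dataclass(frozen=True)
class LDResult:
    variant_a: str
    variant_b: str
    p_a: float
    p_b: float
    p_ab: float
    d: float
    d_prime: float
    r2: float
    n: int
    defined: bool


def _ld_stats(p_a: float, p_b: float, p_ab: float) -> tuple[float, float, float, bool]:
    """(D, D', r2, defined) from margins and joint frequency."""
    d = p_ab - p_a * p_b
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return d, float("nan"), float("nan"), False
    r2 = d * d / (p_a * (1.0 - p_a) * p_b * (1.0 - p_b))
    if d > 0:
        d_max = min(p_a * (1.0 - p_b), p_b * (1.0 - p_a))
        d_prime = d / d_max
    elif d < 0:
        d_max = min(p_a * p_b, (1.0 - p_a) * (1.0 - p_b))
        d_prime = d / d_max
    else:
        d_prime = 0.0
    return d, d_prime, r2, True


def carrier_profile(H: HaplotypeMatrix, region: Region) -> CarrierProfile:
    """Carrier indicator (>=1 rare allele in ``region``) and cMAF.

    A region overlapping no variant column yields an all-zero indicator
    with cMAF 0.
    """
    cols = H.columns_in(region)
    if cols.size:
        ind = (H.values[:, cols].sum(axis=1) >= 1).astype(np.uint8)
    else:
        ind = np.zeros(H.n_haplotypes, dtype=np.uint8)
    cmaf = float(ind.mean()) if ind.size else 0.0
    return CarrierProfile(region_name=region.name, indicator=ind, cmaf=cmaf)


def joint_carrier_freq(a: CarrierProfile, b: CarrierProfile) -> float:
    """Fraction of haplotypes that are carriers in both regions."""
    if a.indicator.shape != b.indicator.shape:
        raise ValueError(
            f"indicator length mismatch: {a.indicator.size} vs {b.indicator.size}"
        )
    if a.indicator.size == 0:
        return 0.0
    return float((a.indicator & b.indicator).mean())


def cld(a: CarrierProfile, b: CarrierProfile) -> CLDResult:
    """cLD between two regions from their carrier profiles."""
    if a.indicator.shape != b.indicator.shape:
        raise ValueError("indicator length mismatch")
    n = int(a.indicator.size)
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    p_ab = joint_carrier_freq(a, b)
    d, d_prime, r2, defined = _ld_stats(a.cmaf, b.cmaf, p_ab)
    return CLDResult(
        region_a=a.region_name,
        region_b=b.region_name,
        p_a=a.cmaf,
        p_b=b.cmaf,
        p_ab=p_ab,
        d=d,
        d_prime=d_prime,
        r2=r2,
        n=n,
        defined=defined,
    )


def ld(H: HaplotypeMatrix, i: int, j: int) -> LDResult:
    """Standard two-variant LD from minor-allele columns ``i`` and ``j``."""
    if i == j:
        raise ValueError("need two distinct variant columns")
    col_i = H.values[:, i]
    col_j = H.values[:, j]
    p_a = float(col_i.mean())
    p_b = float(col_j.mean())
    p_ab = float((col_i & col_j).mean())
    d, d_prime, r2, defined = _ld_stats(p_a, p_b, p_ab)
    va, vb = H.variants[i], H.variants[j]
    return LDResult(
        variant_a=f"{va.chrom}:{va.pos}:{va.ref_alt}",
        variant_b=f"{vb.chrom}:{vb.pos}:{vb.ref_alt}",
        p_a=p_a,
        p_b=p_b,
        p_ab=p_ab,
        d=d,
        d_prime=d_prime,
        r2=r2,
        n=H.n_haplotypes,
        defined=defined,
    )


def _pairwise_r2_matrix(block_a: np.ndarray, block_b: np.ndarray) -> np.ndarray:
    """r² for every cross column pair; NaN where a column is monomorphic."""
    n = block_a.shape[0]
    pa = block_a.mean(axis=0)
    pb = block_b.mean(axis=0)
    pab = (block_a.T.astype(np.float64) @ block_b.astype(np.float64)) / n
    d = pab - np.outer(pa, pb)
    den = np.outer(pa * (1.0 - pa), pb * (1.0 - pb))
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(den > 0, d * d / den, np.nan)
    return r2


def gene_pair_ld(
    H: HaplotypeMatrix,
    region_a: Region,
    region_b: Region,
    max_pairs: int = DEFAULT_MAX_PAIRS,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[float, int]:
    """Average r² over cross-region rare-variant pairs.

    When the number of cross pairs exceeds ``max_pairs``, that many pairs
    are sampled uniformly without replacement (seeded).  Pairs with an
    undefined r² (monomorphic column in the subsample) are excluded from
    the mean and not re-drawn.

    Returns
    -------
    (mean_r2, n_pairs_used) — ``(nan, 0)`` when no pair is usable.
    """
    cols_a = H.columns_in(region_a)
    cols_b = H.columns_in(region_b)
    if cols_a.size == 0 or cols_b.size == 0:
        return float("nan"), 0
    r2 = _pairwise_r2_matrix(H.values[:, cols_a], H.values[:, cols_b]).ravel()
    if r2.size > max_pairs:
        rng = (
            rng_seed
            if isinstance(rng_seed, np.random.Generator)
            else np.random.default_rng(rng_seed)
        )
        r2 = r2[rng.choice(r2.size, size=max_pairs, replace=False)]
    r2 = r2[~np.isnan(r2)]
    if r2.size == 0:
        return float("nan"), 0
    return float(r2.mean()), int(r2.size)


def rare_common_cld(
    H: HaplotypeMatrix, common_variant: int, region: Region, rare: HaplotypeMatrix | None = None
) -> CLDResult:
    """cLD between a single common variant and a rare-variant region.

    P_A is the MAF of ``common_variant`` (a column of ``H``); P_B is the
    cMAF of ``region`` computed on ``rare`` (defaults to ``H``); P_AB is
    the fraction of haplotypes carrying the common minor allele and at
    least one regional rare allele.
    """
    rare_H = H if rare is None else rare
    col = H.values[:, common_variant]
    v = H.variants[common_variant]
    a = CarrierProfile(
        region_name=f"{v.chrom}:{v.pos}:{v.ref_alt}",
        indicator=col,
        cmaf=float(col.mean()),
    )
    b = carrier_profile(rare_H, region)
    return cld(a, b)


def pairwise_cld(
    H: HaplotypeMatrix, regions: RegionSet, same_chrom_only: bool = False
) -> pd.DataFrame:
    """cLD for every unordered region pair.

    Returns a table with one row per pair, sorted by
    (chrom, region_a, region_b); cross-chromosome pairs carry the two
    chromosome names joined by ``,``.
    """
    region_list = list(regions)
    if len(region_list) < 2:
        raise ValueError("need at least 2 regions")
    profiles = {r.name: carrier_profile(H, r) for r in region_list}
    rows = []
    for ra, rb in combinations(region_list, 2):
        if same_chrom_only and ra.chrom != rb.chrom:
            continue
        res = cld(profiles[ra.name], profiles[rb.name])
        chrom = ra.chrom if ra.chrom == rb.chrom else f"{ra.chrom},{rb.chrom}"
        rows.append(
            {
                "region_a": res.region_a,
                "region_b": res.region_b,
                "chrom": chrom,
                "n_hap": res.n,
                "p_a": res.p_a,
                "p_b": res.p_b,
                "p_ab": res.p_ab,
                "D": res.d,
                "Dprime": res.d_prime,
                "r2": res.r2,
                "defined": res.defined,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "region_a",
            "region_b",
            "chrom",
            "n_hap",
            "p_a",
            "p_b",
            "p_ab",
            "D",
            "Dprime",
            "r2",
            "defined",
        ],
    )
    return df.sort_values(["chrom", "region_a", "region_b"], ignore_index=True)
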