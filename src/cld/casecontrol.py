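"""ΔcLD screening between case and control cohorts.

For every region pair the cLD r² is computed separately in the two
cohorts and the absolute difference ΔcLD = |cLD_case − cLD_control| is
ranked descending.  Top-ranked pairs are candidate disease-relevant
interactions; the member genes of the top-k pairs feed gene-set
enrichment (see :func:`cld.enrichment.hypergeom_enrichment`).

Rare-variant status is determined on the pooled cohorts by default so
both cohorts aggregate the identical variant set; per-cohort filtering
is available but makes the two statistics aggregate different columns.

No significance threshold is applied to ΔcLD itself; the delta-method
variance (``cld.asymptotics.delta_cld_variance``) can annotate records
with an exploratory z-like score.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .core_stats import carrier_profile, cld
from .haplotype_io import DEFAULT_MAF_CUTOFF, HaplotypeMatrix, RegionSet, filter_rare


def _pooled_rare_columns(
    H_case: HaplotypeMatrix, H_control: HaplotypeMatrix, maf_cutoff: float
) -> np.ndarray:
    pooled = np.vstack([H_case.values, H_control.values])
    mafs = pooled.mean(axis=0)
    mafs = np.minimum(mafs, 1.0 - mafs)
    return np.flatnonzero((mafs > 0) & (mafs < maf_cutoff))


def delta_cld(
    H_case: HaplotypeMatrix,
    H_control: HaplotypeMatrix,
    regions: RegionSet,
    maf_cutoff: float = DEFAULT_MAF_CUTOFF,
    pooled_filter: bool = True,
    same_chrom_only: bool = True,
) -> pd.DataFrame:
    """Per-pair cLD in both cohorts and ΔcLD with descending ranks.

    Both matrices must be built against the same variant universe (same
    loader, same regions).  Pairs undefined in either cohort are kept in
    the table with ``defined=False`` and excluded from ranking.
    """
    for name, H in (("case", H_case), ("control", H_control)):
        if H.n_haplotypes < 4:
            raise ValueError(f"{name} cohort has < 4 haplotypes")
    if H_case.n_variants != H_control.n_variants:
        raise ValueError("cohorts must share the variant universe")

    if pooled_filter:
        keep = _pooled_rare_columns(H_case, H_control, maf_cutoff)
        Hc = HaplotypeMatrix(
            H_case.values[:, keep],
            [H_case.variants[j] for j in keep],
            list(H_case.sample_ids),
        )
        Ht = HaplotypeMatrix(
            H_control.values[:, keep],
            [H_control.variants[j] for j in keep],
            list(H_control.sample_ids),
        )
    else:
        Hc = filter_rare(H_case, maf_cutoff)
        Ht = filter_rare(H_control, maf_cutoff)

    prof_c = {r.name: carrier_profile(Hc, r) for r in regions}
    prof_t = {r.name: carrier_profile(Ht, r) for r in regions}
    rows = []
    for ra, rb in combinations(list(regions), 2):
        if same_chrom_only and ra.chrom != rb.chrom:
            continue
        res_c = cld(prof_c[ra.name], prof_c[rb.name])
        res_t = cld(prof_t[ra.name], prof_t[rb.name])
        defined = res_c.defined and res_t.defined
        delta = abs(res_c.r2 - res_t.r2) if defined else float("nan")
        rows.append(
            {
                "region_a": ra.name,
                "region_b": rb.name,
                "cld_case": res_c.r2,
                "cld_control": res_t.r2,
                "delta": delta,
                "defined": defined,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(
            ["defined", "delta", "region_a", "region_b"],
            ascending=[False, False, True, True],
            ignore_index=True,
        )
        n_def = int(df["defined"].sum())
        ranks = np.full(len(df), np.nan)
        ranks[:n_def] = np.arange(1, n_def + 1)
        df["rank"] = ranks
    return df


def top_pairs(records: pd.DataFrame, k: int) -> tuple[pd.DataFrame, set[str]]:
    """First ``k`` defined records by descending ΔcLD and their gene union.

    Ties are broken by (region_a, region_b) lexicographic order (already
    applied by :func:`delta_cld`).  ``k`` beyond the defined-record count
    truncates with a warning.
    """
    defined = records[records["defined"]].sort_values("rank")
    if k > len(defined):
        import warnings

        warnings.warn(
            f"k={k} exceeds {len(defined)} defined pairs; truncating", stacklevel=2
        )
        k = len(defined)
    top = defined.head(k)
    genes = set(top["region_a"]) | set(top["region_b"])
    return top, genes
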