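"""Distance-stratified enrichment of cLD/LD in labelled region pairs.

Gene pairs are stratified into geometric distance groups (35 kb doubling,
13 groups by default), labelled by membership of both genes in a set of
interaction intervals (e.g. Hi-C contact anchors or database-derived
regions), dichotomised at a per-stratum median cutoff, and compared with
Mantel–Haenszel and Fisher exact tests.  A cutoff-ratio curve counts
labelled vs unlabelled pairs above a sliding statistic cutoff, and a
hypergeometric test scores gene-set enrichment against a database list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable as _SMStratifiedTable

from .core_stats import _pairwise_r2_matrix
from .haplotype_io import HaplotypeMatrix, Region, RegionSet

DEFAULT_FIRST_EDGE = 35_000
DEFAULT_RATIO = 2.0
DEFAULT_N_BINS = 13
LONGEST_HUMAN_CHROM = 248_956_422  # GRCh38 chr1

IN_INTERACTION = "in_interaction"
NOT_IN_INTERACTION = "not_in_interaction"
DISCARDED = "discarded"


def distance_bins(
    first_edge: float = DEFAULT_FIRST_EDGE,
    ratio: float = DEFAULT_RATIO,
    n_bins: int = DEFAULT_N_BINS,
) -> np.ndarray:
    """Upper edges of the geometric distance groups.

    Bin k covers (edge_{k-1}, edge_k] with edge_k = first_edge * ratio**k;
    the defaults give 13 groups topping out at 35 kb × 2¹² = 143,360,000 bp
    (under the longest human chromosome).
    """
    if first_edge <= 0:
        raise ValueError("first_edge must be positive")
    if ratio <= 1:
        raise ValueError("ratio must be > 1")
    return first_edge * ratio ** np.arange(n_bins)


def assign_distance_bin(distance: float, edges: np.ndarray) -> int:
    """0-based bin index for a distance, or -1 if above the top edge.

    Distances of 0 fall in bin 0 (the first group has no lower bound).
    """
    if distance > edges[-1]:
        return -1
    return int(np.searchsorted(edges, distance, side="left"))


def _overlaps_any(region: Region, intervals: list[tuple[str, int, int]]) -> bool:
    return any(
        region.chrom == c and region.start < e and s < region.end
        for c, s, e in intervals
    )


def label_pairs(
    pairs: pd.DataFrame,
    regions: RegionSet,
    interaction_regions: list[tuple[str, int, int]],
    statistic: str = "r2",
    distance_mode: str = "midpoint",
) -> pd.DataFrame:
    """Annotate region pairs with distance and interaction label.

    A gene is "in" an interaction region when its interval overlaps any
    listed anchor by >= 1 bp.  Both genes in -> ``in_interaction``;
    neither -> ``not_in_interaction``; exactly one -> ``discarded``.
    Distance is midpoint-to-midpoint by default (``distance_mode="gap"``
    uses the inter-interval gap, 0 when overlapping); cross-chromosome
    pairs get NaN distance and are discarded.
    """
    member = {r.name: _overlaps_any(r, interaction_regions) for r in regions}
    coords = {r.name: r for r in regions}
    rows = []
    for _, row in pairs.iterrows():
        ra, rb = coords[row["region_a"]], coords[row["region_b"]]
        if ra.chrom != rb.chrom:
            dist, label = float("nan"), DISCARDED
        else:
            if distance_mode == "midpoint":
                dist = abs(ra.midpoint - rb.midpoint)
            elif distance_mode == "gap":
                dist = max(0, max(ra.start, rb.start) - min(ra.end, rb.end))
            else:
                raise ValueError(f"unknown distance_mode {distance_mode!r}")
            a_in, b_in = member[ra.name], member[rb.name]
            if a_in and b_in:
                label = IN_INTERACTION
            elif not a_in and not b_in:
                label = NOT_IN_INTERACTION
            else:
                label = DISCARDED
        rows.append(
            {
                "region_a": row["region_a"],
                "region_b": row["region_b"],
                "distance": dist,
                "label": label,
                "statistic": row[statistic] if row.get("defined", True) else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def matched_ld_sample(
    pairs: pd.DataFrame,
    H: HaplotypeMatrix,
    regions: RegionSet,
    n_pairs: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Distance-matched variant-pair LD for labelled vs unlabelled gene pairs.

    For every ``in_interaction`` gene pair, up to ``n_pairs`` cross-region
    variant pairs are sampled; each is matched to the unlabelled variant
    pair minimizing the absolute distance difference (ties resolved toward
    the smaller distance).  Returns one row per draw with both r² values
    and both distances.
    """
    rng = np.random.default_rng(seed)
    coords = {r.name: r for r in regions}

    def variant_pairs(label: str) -> tuple[np.ndarray, np.ndarray]:
        dists, r2s = [], []
        for _, row in pairs[pairs["label"] == label].iterrows():
            ra, rb = coords[row["region_a"]], coords[row["region_b"]]
            cols_a, cols_b = H.columns_in(ra), H.columns_in(rb)
            if cols_a.size == 0 or cols_b.size == 0:
                continue
            r2 = _pairwise_r2_matrix(H.values[:, cols_a], H.values[:, cols_b])
            pos_a = np.array([H.variants[j].pos0 for j in cols_a])
            pos_b = np.array([H.variants[j].pos0 for j in cols_b])
            dd = np.abs(pos_a[:, None] - pos_b[None, :]).astype(float)
            ok = ~np.isnan(r2)
            dists.append(dd[ok])
            r2s.append(r2[ok])
        if not dists:
            return np.array([]), np.array([])
        return np.concatenate(dists), np.concatenate(r2s)

    d_in, r_in = variant_pairs(IN_INTERACTION)
    d_out, r_out = variant_pairs(NOT_IN_INTERACTION)
    if d_out.size == 0:
        raise ValueError("no unlabelled variant pairs available for matching")
    if d_in.size == 0:
        raise ValueError("no labelled variant pairs available")
    if d_in.size > n_pairs:
        take = rng.choice(d_in.size, size=n_pairs, replace=False)
        d_in, r_in = d_in[take], r_in[take]

    order = np.argsort(d_out, kind="stable")
    d_sorted, r_sorted = d_out[order], r_out[order]
    rows = []
    for dist, r2 in zip(d_in, r_in):
        k = np.searchsorted(d_sorted, dist)
        # candidates: nearest below and at/above; ties -> smaller distance
        best, best_diff = None, np.inf
        for j in (k - 1, k):
            if 0 <= j < d_sorted.size:
                diff = abs(d_sorted[j] - dist)
                if diff < best_diff or (diff == best_diff and best is not None
                                        and d_sorted[j] < d_sorted[best]):
                    best, best_diff = j, diff
        rows.append(
            {
                "distance_in": dist,
                "r2_in": r2,
                "distance_matched": d_sorted[best],
                "r2_matched": r_sorted[best],
            }
        )
    return pd.DataFrame(rows)


@dataclass
class StratifiedCounts:
    """2×2 tables (rows: in/not-in label; cols: above/at-or-below cutoff)."""

    tables: list[np.ndarray]
    stratum_labels: list[str]
    cutoffs: list[float]
    dropped: list[str] = field(default_factory=list)


def stratified_counts(
    p: pd.DataFrame,
    edges: np.ndarray | None = None,
    pooled_cutoff: bool = False,
) -> StratifiedCounts:
    """Label × above-cutoff counts per distance stratum.

    The cutoff is the median (0.5 quantile) of the defined statistics —
    per stratum by default, pooled over strata with ``pooled_cutoff``.
    Strata missing either label are dropped with a note.
    """
    if edges is None:
        edges = distance_bins()
    use = p[(p["label"] != DISCARDED) & p["statistic"].notna() & p["distance"].notna()]
    use = use[use["distance"] <= edges[-1]]
    bins = np.searchsorted(edges, use["distance"].to_numpy(), side="left")
    pooled_med = float(np.median(use["statistic"])) if len(use) else float("nan")
    tables, labels, cutoffs, dropped = [], [], [], []
    for k in range(len(edges)):
        sub = use[bins == k]
        lab = f"({0 if k == 0 else edges[k - 1]:.0f}, {edges[k]:.0f}]"
        n_in = (sub["label"] == IN_INTERACTION).sum()
        n_out = (sub["label"] == NOT_IN_INTERACTION).sum()
        if n_in == 0 or n_out == 0:
            dropped.append(lab)
            continue
        cut = pooled_med if pooled_cutoff else float(np.median(sub["statistic"]))
        hi = sub["statistic"] > cut
        t = np.array(
            [
                [(hi & (sub["label"] == IN_INTERACTION)).sum(), (~hi & (sub["label"] == IN_INTERACTION)).sum()],
                [(hi & (sub["label"] == NOT_IN_INTERACTION)).sum(), (~hi & (sub["label"] == NOT_IN_INTERACTION)).sum()],
            ],
            dtype=int,
        )
        tables.append(t)
        labels.append(lab)
        cutoffs.append(cut)
    if not tables:
        raise ValueError("every distance stratum lacked one of the two labels")
    return StratifiedCounts(tables, labels, cutoffs, dropped)


@dataclass(frozen=True)
class MHResult:
    odds_ratio: float
    statistic: float
    p_value: float
    n_strata: int
    defined: bool = True


def mantel_haenszel(t: StratifiedCounts, correction: bool = True) -> MHResult:
    """Mantel–Haenszel common odds ratio and chi-square test.

    The 0.5 continuity correction is on by default (sparse long-distance
    strata); switch it off for exact null calibration studies.
    """
    arr = np.stack(t.tables, axis=-1).astype(float)  # 2 x 2 x K
    margins_ok = any(
        tab.sum(axis=0).min() > 0 and tab.sum(axis=1).min() > 0 for tab in t.tables
    )
    if not margins_ok:
        return MHResult(float("nan"), float("nan"), float("nan"), len(t.tables), False)
    st = _SMStratifiedTable(arr)
    res = st.test_null_odds(correction=correction)
    return MHResult(
        odds_ratio=float(st.oddsratio_pooled),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_strata=len(t.tables),
    )


def fisher_exact(table: np.ndarray) -> float:
    """Two-sided Fisher exact p-value (sum of tables as or less probable)."""
    table = np.asarray(table)
    if table.min() < 0:
        raise ValueError("counts must be non-negative")
    if table.sum() == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def cutoff_ratio_curve(p: pd.DataFrame, cutoffs: list[float]) -> pd.DataFrame:
    """Labelled/unlabelled counts above each statistic cutoff and ratios.

    Reports the raw count ratio and the class-size-normalized
    (proportion) ratio; a zero denominator with a nonzero numerator maps
    to ``inf``, and 0/0 to NaN.
    """
    if list(cutoffs) != sorted(cutoffs):
        raise ValueError("cutoffs must be sorted ascending")
    use = p[(p["label"] != DISCARDED) & p["statistic"].notna()]
    v_in = use.loc[use["label"] == IN_INTERACTION, "statistic"].to_numpy()
    v_out = use.loc[use["label"] == NOT_IN_INTERACTION, "statistic"].to_numpy()
    rows = []
    for c in cutoffs:
        n_in = int((v_in > c).sum())
        n_out = int((v_out > c).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.float64(n_in) / n_out if n_out else (np.inf if n_in else np.nan)
            prop_in = n_in / v_in.size if v_in.size else np.nan
            prop_out = n_out / v_out.size if v_out.size else np.nan
            norm = (
                prop_in / prop_out
                if prop_out
                else (np.inf if prop_in else np.nan)
            )
        rows.append(
            {
                "cutoff": c,
                "n_in": n_in,
                "n_out": n_out,
                "ratio_raw": float(raw),
                "ratio_normalized": float(norm),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EnrichmentResult:
    q: int  # selected genes validated in the database
    m: int  # database genes in the universe
    n: int  # universe genes outside the database
    k: int  # selected genes
    p_value: float


def hypergeom_enrichment(
    selected: set[str], database: set[str], universe: set[str]
) -> EnrichmentResult:
    """Over-representation of ``selected`` in ``database`` within ``universe``.

    p = P(X >= q) for X ~ Hypergeometric(m + n, m, k) with
    q = |selected ∩ database|.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not selected <= universe:
        raise ValueError("selected must be a subset of the universe")
    if not database <= universe:
        raise ValueError("database must be a subset of the universe")
    q = len(selected & database)
    m = len(database)
    n = len(universe) - m
    k = len(selected)
    p = float(stats.hypergeom.sf(q - 1, m + n, m, k))
    return EnrichmentResult(q=q, m=m, n=n, k=k, p_value=p)
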