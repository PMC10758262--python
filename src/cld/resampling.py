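"""Bootstrap stability of cLD versus standard LD in cMAF bins.

Protocol: repeatedly subsample half of the haplotypes without
replacement; in each iteration compute, per cMAF bin, the average cLD
over the sampled gene pairs and the average gene-pair LD (mean r² over
cross-region rare-variant pairs); after all iterations divide each
series by its own mean so that spread is read relative to location.
A narrower normalized cLD series than LD series is the stability claim
this module quantifies.

Bin membership of a gene pair is fixed from the full-sample cMAFs (the
pair-level summary is configurable: mean, min or max of the two cMAFs)
so the same pairs are compared across iterations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .core_stats import carrier_profile, cld
from .haplotype_io import HaplotypeMatrix, RegionSet

DEFAULT_CMAF_EDGES = (0.05, 0.10, 0.20, 0.40)
DEFAULT_N_ITER = 1000
DEFAULT_N_GENES = 1000


@dataclass
class BootstrapDistribution:
    """Mean-normalized per-iteration bin averages for cLD and LD."""

    bin_label: str
    values_cld: np.ndarray
    values_ld: np.ndarray
    n_iter: int
    n_pairs: int = 0
    unstable: bool = False  # bin empty/undefined in >= 10% of iterations


def _pair_summary(p_a: float, p_b: float, how: str) -> float:
    if how == "mean":
        return 0.5 * (p_a + p_b)
    if how == "min":
        return min(p_a, p_b)
    if how == "max":
        return max(p_a, p_b)
    raise ValueError(f"unknown summary {how!r}")


def bin_labels(edges: tuple[float, ...] = DEFAULT_CMAF_EDGES) -> list[str]:
    labels = [f"<{edges[0]:g}"]
    labels += [f"{lo:g}-{hi:g}" for lo, hi in zip(edges[:-1], edges[1:])]
    return labels


def bin_by_cmaf(
    pairs: pd.DataFrame,
    edges: tuple[float, ...] = DEFAULT_CMAF_EDGES,
    summary: str = "mean",
) -> tuple[pd.Series, int]:
    """Assign each defined pair to a cMAF bin (half-open, right edge out).

    Bins are [0, e1), [e1, e2), ...; a summary exactly on an edge falls in
    the right-hand bin.  Pairs at or above the last edge are discarded.

    Returns the per-row bin label (NaN for discarded/undefined rows) and
    the discarded-above-top count.
    """
    edges = tuple(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    labels = bin_labels(edges)
    svals = np.array(
        [_pair_summary(pa, pb, summary) for pa, pb in zip(pairs["p_a"], pairs["p_b"])]
    )
    idx = np.searchsorted(edges, svals, side="right")  # edge -> right-hand bin
    out = pd.Series([None] * len(pairs), index=pairs.index, dtype=object)
    discarded = 0
    for i, (k, defined) in enumerate(zip(idx, pairs["defined"])):
        if not defined:
            continue
        if k >= len(labels):
            discarded += 1
            continue
        out.iloc[i] = labels[k]
    return out, discarded


def bootstrap_stability(
    H: HaplotypeMatrix,
    regions: RegionSet,
    n_iter: int = DEFAULT_N_ITER,
    n_genes: int = DEFAULT_N_GENES,
    seed: int = 0,
    edges: tuple[float, ...] = DEFAULT_CMAF_EDGES,
    summary: str = "mean",
) -> dict[str, BootstrapDistribution]:
    """Half-sample bootstrap of bin-averaged cLD and gene-pair LD.

    Per iteration, floor(n_hap/2) haplotypes are drawn without
    replacement; gene pairs are all same-chromosome pairs among
    ``n_genes`` sampled regions (capped at the region count).  The
    gene-pair LD is the exact mean r² over *all* cross-region variant
    pairs defined in the subsample, computed through a sparse
    co-occurrence decomposition (non-co-occurring pairs contribute
    p_a p_b / (q_a q_b) in closed form, so only co-carried pairs need
    enumeration).  All randomness derives from ``seed``.
    """
    if H.n_haplotypes < 4:
        raise ValueError("need at least 4 haplotypes")
    if len(regions) < 2:
        raise ValueError("need at least 2 regions")
    from scipy import sparse

    rng = np.random.default_rng(seed)
    region_list = list(regions)
    n_genes = min(n_genes, len(region_list))
    chosen = [region_list[i] for i in rng.choice(len(region_list), n_genes, replace=False)]
    pairs = [(a, b) for a, b in combinations(chosen, 2) if a.chrom == b.chrom]
    if not pairs:
        raise ValueError("no same-chromosome region pairs among sampled genes")

    # fixed bin assignment from full-sample cMAFs
    full_rows = []
    full_profiles = {r.name: carrier_profile(H, r) for r in chosen}
    for a, b in pairs:
        res = cld(full_profiles[a.name], full_profiles[b.name])
        full_rows.append({"p_a": res.p_a, "p_b": res.p_b, "defined": res.defined})
    full_df = pd.DataFrame(full_rows)
    assignment, _ = bin_by_cmaf(full_df, edges, summary)
    labels = bin_labels(edges)
    pair_bins = list(assignment)

    n_reg = len(chosen)
    cols_cache = [H.columns_in(r) for r in chosen]
    col_region = np.full(H.n_variants, -1, dtype=int)
    shared_column = False
    for rid, cols in enumerate(cols_cache):
        if (col_region[cols] != -1).any():
            shared_column = True
        col_region[cols] = rid
    if shared_column:
        raise NotImplementedError(
            "bootstrap_stability requires regions with disjoint variant columns"
        )
    # map (min rid, max rid) -> pair position; -1 for untracked pairs
    name_to_rid = {r.name: i for i, r in enumerate(chosen)}
    pair_pos = np.full((n_reg, n_reg), -1, dtype=int)
    for k, (a, b) in enumerate(pairs):
        i, j = sorted((name_to_rid[a.name], name_to_rid[b.name]))
        pair_pos[i, j] = k

    Hs = sparse.csr_matrix(H.values)
    # variant-to-region membership matrix: carrier counts in one matmul
    tracked = col_region >= 0
    member = sparse.csr_matrix(
        (
            np.ones(int(tracked.sum())),
            (np.flatnonzero(tracked), col_region[tracked]),
        ),
        shape=(H.n_variants, n_reg),
    )
    half = H.n_haplotypes // 2
    cld_series: dict[str, list[float]] = {lb: [] for lb in labels}
    ld_series: dict[str, list[float]] = {lb: [] for lb in labels}

    for _ in range(n_iter):
        rows = rng.choice(H.n_haplotypes, size=half, replace=False)
        S = Hs[rows]
        c = np.asarray(S.sum(axis=0)).ravel()
        pa_col = c / half
        def_col = (c > 0) & (c < half)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_col = np.where(def_col, pa_col / (1.0 - pa_col), 0.0)

        # per-region defined-column totals and carrier indicators
        t_sum = np.bincount(
            col_region[tracked], weights=t_col[tracked], minlength=n_reg
        )
        n_def = np.bincount(
            col_region[tracked],
            weights=def_col[tracked].astype(float),
            minlength=n_reg,
        ).astype(int)
        ind = (np.asarray((S @ member).todense()) >= 1).astype(float)

        # exact correction for co-carried variant pairs
        G = (S.T @ S).tocoo()
        gr, gc, gd = G.row, G.col, G.data
        ra, rb = col_region[gr], col_region[gc]
        sel = (
            (gr < gc)
            & (ra >= 0)
            & (rb >= 0)
            & (ra != rb)
            & def_col[gr]
            & def_col[gc]
        )
        gr, gc, gd, ra, rb = gr[sel], gc[sel], gd[sel], ra[sel], rb[sel]
        pp = pair_pos[np.minimum(ra, rb), np.maximum(ra, rb)]
        keep = pp >= 0
        gr, gc, gd, pp = gr[keep], gc[keep], gd[keep], pp[keep]
        pa, pb = pa_col[gr], pa_col[gc]
        d = gd / half - pa * pb
        r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
        correction = np.zeros(len(pairs))
        np.add.at(correction, pp, r2 - t_col[gr] * t_col[gc])

        # per-pair means
        p_reg = ind.mean(axis=0)
        p11 = (ind.T @ ind) / half
        bin_cld: dict[str, list[float]] = {lb: [] for lb in labels}
        bin_ld: dict[str, list[float]] = {lb: [] for lb in labels}
        for k, ((a, b), lb) in enumerate(zip(pairs, pair_bins)):
            if lb is None:
                continue
            i, j = name_to_rid[a.name], name_to_rid[b.name]
            qa, qb = p_reg[i], p_reg[j]
            if qa not in (0.0, 1.0) and qb not in (0.0, 1.0):
                dd = p11[i, j] - qa * qb
                bin_cld[lb].append(dd * dd / (qa * (1 - qa) * qb * (1 - qb)))
            n_pairs_def = n_def[i] * n_def[j]
            if n_pairs_def:
                bin_ld[lb].append(
                    (t_sum[i] * t_sum[j] + correction[k]) / n_pairs_def
                )
        for lb in labels:
            cld_series[lb].append(np.mean(bin_cld[lb]) if bin_cld[lb] else np.nan)
            ld_series[lb].append(np.mean(bin_ld[lb]) if bin_ld[lb] else np.nan)

    out = {}
    for lb in labels:
        c = np.asarray(cld_series[lb], dtype=float)
        l = np.asarray(ld_series[lb], dtype=float)
        n_bad = int(np.isnan(c).sum() + np.isnan(l).sum())
        unstable = (np.isnan(c).mean() >= 0.10) or (np.isnan(l).mean() >= 0.10)
        c_ok, l_ok = c[~np.isnan(c)], l[~np.isnan(l)]
        if c_ok.size and c_ok.mean() > 0:
            c_ok = c_ok / c_ok.mean()
        if l_ok.size and l_ok.mean() > 0:
            l_ok = l_ok / l_ok.mean()
        out[lb] = BootstrapDistribution(
            bin_label=lb,
            values_cld=c_ok,
            values_ld=l_ok,
            n_iter=n_iter,
            n_pairs=sum(1 for x in pair_bins if x == lb),
            unstable=unstable,
        )
    return out


@dataclass(frozen=True)
class StabilitySummary:
    bin_label: str
    sd_cld: float
    sd_ld: float
    ratio: float
    defined: bool


def stability_summary(d: BootstrapDistribution) -> StabilitySummary:
    """Standard deviations of the normalized series and their cLD/LD ratio."""
    if d.values_cld.size == 0 or d.values_ld.size == 0:
        return StabilitySummary(d.bin_label, float("nan"), float("nan"), float("nan"), False)
    sd_c = float(np.std(d.values_cld))
    sd_l = float(np.std(d.values_ld))
    ratio = sd_c / sd_l if sd_l > 0 else float("nan")
    return StabilitySummary(d.bin_label, sd_c, sd_l, ratio, not math.isnan(ratio))
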