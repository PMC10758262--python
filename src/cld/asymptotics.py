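"""Delta-method asymptotic variance of the r² statistic.

The observed 2×2 carrier table (both / A-only / B-only / neither) is
modelled as multinomial with cell probabilities p = (p11, p10, p01, p00).
Writing pA = p11 + p10, pB = p11 + p01 and D = p11 − pA·pB, the statistic

    g(p) = D² / (pA (1 − pA) pB (1 − pB))

has first-order asymptotic variance ∇gᵀ Σ ∇g / n, where Σ is the
multinomial covariance of the *free* coordinates (p11, p10, p01) —
p00 is eliminated because the full 4-cell covariance is singular on the
simplex — and the gradient is analytic.

The same formula serves cLD (cells = two-region carrier table) and
standard LD (cells = two-SNV haplotype table); only the table differs.

At D = 0 the gradient of the squared term vanishes and the first-order
variance is exactly 0: the approximation degenerates there, which the
result flags via a note.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_stats import CarrierProfile, joint_carrier_freq

_SIMPLEX_TOL = 1e-12


@dataclass(frozen=True)
class CellProbs:
    """Probabilities of the four carrier/allele combinations."""

    p11: float
    p10: float
    p01: float
    p00: float

    def __post_init__(self):
        for name in ("p11", "p10", "p01", "p00"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(self.p11 + self.p10 + self.p01 + self.p00 - 1.0) > 1e-9:
            raise ValueError("cell probabilities must sum to 1")

    @property
    def p_a(self) -> float:
        return self.p11 + self.p10

    @property
    def p_b(self) -> float:
        return self.p11 + self.p01

    @property
    def d(self) -> float:
        return self.p11 - self.p_a * self.p_b


@dataclass(frozen=True)
class VarianceEstimate:
    """r² at the given cell probabilities and its asymptotic variance at n."""

    statistic_value: float
    variance: float
    n: int
    defined: bool = True
    note: str = ""


def cell_probs_from_profiles(a: CarrierProfile, b: CarrierProfile) -> CellProbs:
    """Empirical 2×2 cell frequencies from two carrier profiles."""
    if a.indicator.shape != b.indicator.shape:
        raise ValueError("indicator length mismatch")
    ia = a.indicator.astype(bool)
    ib = b.indicator.astype(bool)
    n = ia.size
    return CellProbs(
        p11=float((ia & ib).sum()) / n,
        p10=float((ia & ~ib).sum()) / n,
        p01=float((~ia & ib).sum()) / n,
        p00=float((~ia & ~ib).sum()) / n,
    )


def r2_from_cells(p: CellProbs) -> float:
    pa, pb, d = p.p_a, p.p_b, p.d
    den = pa * (1.0 - pa) * pb * (1.0 - pb)
    if den <= 0:
        return float("nan")
    return d * d / den


def _gradient(p: CellProbs) -> np.ndarray:
    """Analytic ∇g over the free coordinates (p11, p10, p01).

    g = D²/den with D = p11 − pA·pB, den = pA qA pB qB; pA = p11 + p10,
    pB = p11 + p01 (p00 enters only through the simplex constraint, and
    g does not depend on it directly).
    """
    pa, pb = p.p_a, p.p_b
    qa, qb = 1.0 - pa, 1.0 - pb
    d = p.p11 - pa * pb
    den = pa * qa * pb * qb
    # dD/dx for x in (p11, p10, p01); pA and pB both contain p11
    dD = np.array([1.0 - pb - pa, -pb, -pa])
    # dden/dx via dpa/dx = (1, 1, 0), dpb/dx = (1, 0, 1)
    dden_dpa = (1.0 - 2.0 * pa) * pb * qb
    dden_dpb = (1.0 - 2.0 * pb) * pa * qa
    dden = np.array([dden_dpa + dden_dpb, dden_dpa, dden_dpb])
    return (2.0 * d * dD * den - d * d * dden) / (den * den)


def delta_variance(p: CellProbs, n: int) -> VarianceEstimate:
    """First-order delta-method variance of r̂² at sample size ``n``.

    Requires all four cells strictly positive and non-degenerate margins;
    otherwise the estimate is flagged undefined with a reason.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cells = (p.p11, p.p10, p.p01, p.p00)
    if min(cells) <= 0.0:
        return VarianceEstimate(
            float("nan"), float("nan"), n, defined=False, note="zero cell probability"
        )
    if p.p_a in (0.0, 1.0) or p.p_b in (0.0, 1.0):
        return VarianceEstimate(
            float("nan"), float("nan"), n, defined=False, note="degenerate margin"
        )
    free = np.array([p.p11, p.p10, p.p01])
    sigma = np.diag(free) - np.outer(free, free)
    grad = _gradient(p)
    var = float(grad @ sigma @ grad) / n
    var = max(var, 0.0)
    note = ""
    if abs(p.d) < _SIMPLEX_TOL:
        note = "D = 0: first-order variance degenerates to 0"
        warnings.warn(note, stacklevel=2)
    return VarianceEstimate(r2_from_cells(p), var, n, defined=True, note=note)


def variance_ratio(p_cld: CellProbs, p_ld: CellProbs, n: int) -> float:
    """Var(cLD)/Var(LD) at matched sample size; invariant to n."""
    v_cld = delta_variance(p_cld, n)
    v_ld = delta_variance(p_ld, n)
    if not (v_cld.defined and v_ld.defined) or v_ld.variance <= 0:
        return float("nan")
    return v_cld.variance / v_ld.variance


def delta_cld_variance(
    v_case: VarianceEstimate, v_control: VarianceEstimate
) -> VarianceEstimate:
    """Asymptotic variance of cLD_case − cLD_control under independence.

    Assumes no correlation between the cohorts, so the variances add.
    Folding to the absolute difference |ΔcLD| is left to callers (the
    half-normal adjustment depends on the null location).
    """
    if not (v_case.defined and v_control.defined):
        return VarianceEstimate(
            float("nan"),
            float("nan"),
            min(v_case.n, v_control.n),
            defined=False,
            note="undefined component variance",
        )
    return VarianceEstimate(
        statistic_value=v_case.statistic_value - v_control.statistic_value,
        variance=v_case.variance + v_control.variance,
        n=min(v_case.n, v_control.n),
        defined=True,
    )


def sample_r2(p: CellProbs, n: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo draws of r̂² from the multinomial table model.

    Used by verification tests and the acceptance checks as the empirical
    counterpart of :func:`delta_variance`; draws with degenerate margins
    come back NaN.
    """
    counts = rng.multinomial(n, [p.p11, p.p10, p.p01, p.p00], size=size)
    f = counts / n
    pa = f[:, 0] + f[:, 1]
    pb = f[:, 0] + f[:, 2]
    d = f[:, 0] - pa * pb
    den = pa * (1.0 - pa) * pb * (1.0 - pb)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, d * d / den, np.nan)
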