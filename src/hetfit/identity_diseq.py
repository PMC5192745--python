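"""The g2 estimator of identity disequilibrium and its permutation test.

Identity disequilibrium (ID) — correlation in heterozygosity across loci —
arises when inbreeding varies among individuals, and is the prerequisite for
marker heterozygosity to reflect genomewide inbreeding. g2 measures the excess
two-locus heterozygosity covariance:

    g2 = A / B - 1,
    A  = (1 / (n L (L-1)))      sum_i sum_{k != l} h_ik h_il
    B  = (1 / (n (n-1) L (L-1))) sum_{i != j} sum_{k != l} h_ik h_jl

with h the 0/1 single-locus heterozygosity indicators. With missing genotypes
each sum runs over the observed terms only, with matching denominators, which
reduces exactly to the formulas above for complete data. Under a model where
individual inbreeding f varies, E[g2] = Var(f) / (1 - E[f])^2; g2 = 0 means no
ID. Significance is assessed by permuting each locus column independently
among individuals, which destroys across-locus correlation while preserving
per-locus heterozygosity frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("hetfit")


@dataclass
class G2Result:
    g2_hat: float
    p_value: float
    B: int
    n: int
    L: int
    seed: int
    subset: str = "total"
    alternative: str = "greater"


def _ratio_terms(h: np.ndarray) -> tuple[float, float, float, float]:
    """Numerators/denominators of the A and B averages over observed pairs."""
    h = np.asarray(h, dtype=float)
    mask = (~np.isnan(h)).astype(float)
    hv = np.where(np.isnan(h), 0.0, h)

    # within-individual across-locus pairs (k != l)
    row_h = hv.sum(axis=1)
    row_m = mask.sum(axis=1)
    a_num = float((row_h ** 2 - (hv ** 2).sum(axis=1)).sum())
    a_den = float((row_m ** 2 - (mask ** 2).sum(axis=1)).sum())

    # between-individual pairs (i != j), loci k != l
    col_h = hv.sum(axis=0)
    col_m = mask.sum(axis=0)
    cross_h_all = float(col_h.sum() ** 2 - (col_h ** 2).sum())   # all i,j; k != l
    cross_m_all = float(col_m.sum() ** 2 - (col_m ** 2).sum())
    # subtract the i == j diagonal, which is exactly the within-individual term
    b_num = cross_h_all - a_num
    b_den = cross_m_all - a_den
    return a_num, a_den, b_num, b_den


def g2_estimate(h: np.ndarray) -> float:
    """g2 from an individuals x loci heterozygosity-indicator matrix.

    ``h`` holds 0/1 values with NaN for untyped cells. Requires >= 2 loci and
    >= 3 individuals; raises if the between-individual average B is zero (at
    most one heterozygous cell), where the ratio is undefined.
    """
    h = np.asarray(h, dtype=float)
    if h.ndim != 2 or h.shape[1] < 2:
        raise ValueError("g2 needs a 2-D matrix with at least 2 loci")
    if h.shape[0] < 3:
        raise ValueError("g2 needs at least 3 individuals")
    a_num, a_den, b_num, b_den = _ratio_terms(h)
    if a_den == 0 or b_den == 0:
        raise ValueError("g2 undefined: no observed locus pairs")
    B = (b_num / b_den)
    if B == 0:
        raise ValueError("g2 undefined: between-individual heterozygosity average is zero")
    A = a_num / a_den
    return float(A / B - 1.0)


def g2_test(h: np.ndarray, B: int = 1000, seed: int = 0,
            alternative: str = "greater", subset: str = "total") -> G2Result:
    """Permutation test of g2 against the no-ID null.

    Each locus column is permuted independently among individuals B times.
    One-sided by default (ID predicts positive g2); p = (1 + #{g2* >= g2}) /
    (B + 1). ``alternative="two-sided"`` doubles the smaller tail.
    """
    if B < 100:
        raise ValueError("need B >= 100 permutations")
    h = np.asarray(h, dtype=float)
    obs = g2_estimate(h)
    rng = np.random.default_rng(seed)
    ge = le = 0
    skipped = 0
    for _ in range(B):
        perm = rng.permuted(h, axis=0)  # independent shuffle within each column
        try:
            g2p = g2_estimate(perm)
        except ValueError:
            skipped += 1
            continue
        ge += g2p >= obs - 1e-15
        le += g2p <= obs + 1e-15
    eff = B - skipped
    if eff < 100:
        raise ValueError("too many degenerate permutations for a calibrated test")
    p_ge = (1 + ge) / (eff + 1)
    if alternative == "greater":
        p = p_ge
    elif alternative == "two-sided":
        p_le = (1 + le) / (eff + 1)
        p = min(1.0, 2 * min(p_ge, p_le))
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    return G2Result(g2_hat=obs, p_value=float(p), B=eff, n=h.shape[0],
                    L=h.shape[1], seed=seed, subset=subset, alternative=alternative)


def g2_brute_force(h: np.ndarray) -> float:
    """Definitional double-sum g2 for complete data (reference oracle).

    O(n^2 L^2); intended for small matrices in tests and cross-checks.
    """
    h = np.asarray(h, dtype=float)
    if np.isnan(h).any():
        raise ValueError("brute-force oracle is defined for complete data only")
    n, L = h.shape
    A = 0.0
    for i in range(n):
        for k in range(L):
            for l in range(L):
                if k != l:
                    A += h[i, k] * h[i, l]
    A /= n * L * (L - 1)
    Bsum = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            for k in range(L):
                for l in range(L):
                    if k != l:
                        Bsum += h[i, k] * h[j, l]
    Bsum /= n * (n - 1) * L * (L - 1)
    if Bsum == 0:
        raise ValueError("g2 undefined")
    return A / Bsum - 1.0
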