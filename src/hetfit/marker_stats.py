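"""Per-locus diversity statistics and marker screening tests.

For each microsatellite locus: allelic richness A_R (distinct allele count),
observed heterozygosity H_O, and the plug-in expected heterozygosity
E_l = 1 - sum(p_a^2). E_l doubles as the per-locus weight of the
homozygosity-by-locus index. Hardy-Weinberg and pairwise linkage
disequilibrium are screened with Monte Carlo permutation tests, and marker
categories (neutral vs functional) are compared with one-way ANOVA.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import GenotypeMatrix, MarkerPanel

logger = logging.getLogger("hetfit")


@dataclass
class MarkerStats:
    locus: str
    n_typed: int
    n_alleles: int          # A_R
    observed_het: float     # H_O
    expected_het: float     # E_l
    hwe_p: float | None = None
    ld_partners: list = field(default_factory=list)


def marker_summary(G: GenotypeMatrix) -> list[MarkerStats]:
    """A_R, H_O and E_l for every locus, from all typed individuals."""
    out = []
    typed = G.typed_mask
    for k, locus in enumerate(G.loci):
        sel = typed[:, k]
        n_typed = int(sel.sum())
        if n_typed == 0:
            raise ValueError(f"locus {locus!r} has zero typed individuals")
        alleles = np.concatenate([G.a1[sel, k], G.a2[sel, k]])
        _, counts = np.unique(alleles, return_counts=True)
        p = counts / counts.sum()
        out.append(MarkerStats(
            locus=locus,
            n_typed=n_typed,
            n_alleles=len(counts),
            observed_het=float((G.a1[sel, k] != G.a2[sel, k]).mean()),
            expected_het=float(1.0 - (p ** 2).sum()),
        ))
    return out


def stats_frame(stats_list: list[MarkerStats]) -> pd.DataFrame:
    return pd.DataFrame([{
        "locus": s.locus, "n_typed": s.n_typed, "A_R": s.n_alleles,
        "H_O": s.observed_het, "E_l": s.expected_het, "hwe_p": s.hwe_p,
    } for s in stats_list])


def expected_het_weights(stats_list: list[MarkerStats]) -> dict[str, float]:
    """Per-locus E_l weights keyed by locus name (HL weighting)."""
    return {s.locus: s.expected_het for s in stats_list}


def hwe_test(G: GenotypeMatrix, locus: str, B: int = 999, seed: int = 0) -> float:
    """Monte Carlo Hardy-Weinberg test by random re-pairing of the allele pool.

    The statistic is the heterozygote count; the null distribution is obtained
    by shuffling the 2n observed allele copies and pairing them at random.
    Two-sided p by doubling the smaller tail, capped at 1.
    """
    if B < 100:
        raise ValueError("need B >= 100 permutations")
    k = G.locus_index([locus])[0]
    sel = G.typed_mask[:, k]
    if sel.sum() < 5:
        raise ValueError(f"locus {locus!r}: fewer than 5 typed individuals")
    a1, a2 = G.a1[sel, k], G.a2[sel, k]
    pool = np.concatenate([a1, a2])
    if len(np.unique(pool)) < 2:
        warnings.warn(f"locus {locus!r} is monomorphic; HWE p set to 1")
        return 1.0
    obs = int((a1 != a2).sum())
    rng = np.random.default_rng(seed)
    lo = hi = 0
    for _ in range(B):
        perm = rng.permutation(pool)
        half = len(perm) // 2
        het = int((perm[:half] != perm[half:]).sum())
        lo += het <= obs
        hi += het >= obs
    p_lo = (1 + lo) / (B + 1)
    p_hi = (1 + hi) / (B + 1)
    return min(1.0, 2 * min(p_lo, p_hi))


def _g_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """G (log-likelihood ratio) statistic of the contingency table of x vs y."""
    table = pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy().astype(float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    obs = table[table > 0]
    exp = expected[table > 0]
    return float(2.0 * (obs * np.log(obs / exp)).sum())


def ld_test(G: GenotypeMatrix, locus1: str, locus2: str, B: int = 999,
            seed: int = 0) -> float:
    """Permutation test of linkage disequilibrium between two loci.

    The two-locus genotype contingency table's G statistic is compared with
    its distribution under random permutation of locus2 genotypes among the
    individuals typed at both loci.
    """
    if B < 100:
        raise ValueError("need B >= 100 permutations")
    k1, k2 = G.locus_index([locus1, locus2])
    sel = G.typed_mask[:, k1] & G.typed_mask[:, k2]
    if sel.sum() < 5:
        raise ValueError(f"fewer than 5 individuals typed at both {locus1!r} and {locus2!r}")

    def genotype_codes(k):  # unordered genotype as a single label
        lo = np.minimum(G.a1[sel, k], G.a2[sel, k])
        hi = np.maximum(G.a1[sel, k], G.a2[sel, k])
        _, codes = np.unique(lo * 10_000 + hi, return_inverse=True)
        return codes

    g1, g2 = genotype_codes(k1), genotype_codes(k2)
    if len(np.unique(g1)) < 2 or len(np.unique(g2)) < 2:
        warnings.warn("fewer than 2 distinct genotypes at a locus; LD p set to 1")
        return 1.0
    obs = _g_statistic(g1, g2)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(B):
        exceed += _g_statistic(g1, rng.permutation(g2)) >= obs - 1e-12
    return (1 + exceed) / (B + 1)


def category_anova(stats_list: list[MarkerStats], panel: MarkerPanel,
                   response: str = "A_R") -> tuple[float, int, int, float]:
    """One-way ANOVA of a marker statistic (A_R or H_O) on marker category."""
    if response not in {"A_R", "H_O"}:
        raise ValueError("response must be 'A_R' or 'H_O'")
    values = {s.locus: (s.n_alleles if response == "A_R" else s.observed_het)
              for s in stats_list}
    groups = []
    for cat in ("neutral", "functional"):
        loci = [l for l in panel.subset(cat) if l in values]
        if len(loci) < 2:
            raise ValueError(f"category {cat!r} has fewer than 2 loci with statistics")
        groups.append(np.array([values[l] for l in loci], dtype=float))
    if all(np.ptp(g) == 0 for g in groups) and groups[0].mean() == groups[1].mean():
        # identical groups: F = 0 by convention, p = 1
        return 0.0, 1, sum(map(len, groups)) - 2, 1.0
    F, p = stats.f_oneway(*groups)
    return float(F), 1, sum(map(len, groups)) - 2, float(p)
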