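"""Individual genetic-diversity indices.

Homozygosity by locus (HL) weights each locus's contribution by its expected
heterozygosity E_l, so highly variable loci (where homozygosity is more
informative about inbreeding) count more:

    HL = sum_{homozygous loci} E_l / (sum_{homozygous} E_l + sum_{heterozygous} E_l)

computed over the loci actually typed for the individual (missing loci are
excluded from both sums). 1 - HL is the heterozygosity measure used in all
fitness models. Single-locus heterozygosities (SLH) are the per-locus 0/1
indicators, optionally standardized per locus.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import GenotypeMatrix

logger = logging.getLogger("hetfit")


def compute_hl(G: GenotypeMatrix, weights: dict[str, float],
               subset: list[str] | None = None) -> np.ndarray:
    """HL per individual over a locus subset; NaN when no subset locus typed.

    ``weights`` maps locus name -> E_l (see marker_stats.expected_het_weights).
    """
    loci = list(subset) if subset is not None else list(G.loci)
    missing_w = [l for l in loci if l not in weights]
    if missing_w:
        raise KeyError(f"no E_l weight for loci: {missing_w}")
    idx = G.locus_index(loci)
    w = np.array([weights[l] for l in loci], dtype=float)

    typed = G.typed_mask[:, idx]
    hom = (G.a1[:, idx] == G.a2[:, idx]) & typed
    het = (G.a1[:, idx] != G.a2[:, idx]) & typed

    sum_hom = hom @ w
    sum_het = het @ w
    denom = sum_hom + sum_het
    with np.errstate(invalid="ignore", divide="ignore"):
        hl = np.where(denom > 0, sum_hom / np.where(denom > 0, denom, 1.0), np.nan)
    untyped = ~typed.any(axis=1)
    if untyped.any():
        warnings.warn(f"{int(untyped.sum())} individual(s) typed at no subset locus; HL undefined")
        hl[untyped] = np.nan
    # all typed loci carry zero weight (all monomorphic): HL undefined too
    hl[(denom == 0) & ~untyped] = np.nan
    return hl


def het_estimates(G: GenotypeMatrix, weights: dict[str, float],
                  subsets: dict[str, list[str]]) -> pd.DataFrame:
    """Per-individual HL and 1-HL for each named marker subset.

    ``subsets`` maps subset name (e.g. total/neutral/functional) to locus
    lists. Columns: hl_<name>, het_<name>, n_typed_<name>.
    """
    out = {"individual_id": G.ids}
    for name, loci in subsets.items():
        hl = compute_hl(G, weights, loci)
        out[f"hl_{name}"] = hl
        out[f"het_{name}"] = 1.0 - hl
        out[f"n_typed_{name}"] = G.typed_mask[:, G.locus_index(loci)].sum(axis=1)
    return pd.DataFrame(out)


@dataclass
class SLHMatrix:
    """Single-locus heterozygosity indicators, raw and optionally standardized."""

    ids: np.ndarray
    loci: list[str]                  # loci of the raw columns
    raw: np.ndarray                  # (n, L) 0/1 with NaN for missing
    normalized: np.ndarray | None    # standardized columns, or None
    normalized_loci: list[str]       # loci of the normalized columns
    dropped: list[str]               # zero-variance loci removed from `normalized`

    def raw_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.raw, columns=self.loci).assign(individual_id=self.ids)


def slh_matrix(G: GenotypeMatrix, subset: list[str] | None = None,
               normalize: bool = False, scale: str = "zscore") -> SLHMatrix:
    """Per-locus 0/1 heterozygosity indicators over a subset of loci.

    With ``normalize=True`` each column is standardized over typed individuals
    (z-score with n-1 variance by default; ``scale="mean"`` divides by the
    column mean instead). Zero-variance columns cannot be standardized and are
    dropped with a warning.
    """
    loci = list(subset) if subset is not None else list(G.loci)
    h = G.select(loci).het_indicator()
    if not normalize:
        return SLHMatrix(G.ids, loci, h, None, [], [])

    cols, kept, dropped = [], [], []
    for k, locus in enumerate(loci):
        col = h[:, k]
        vals = col[~np.isnan(col)]
        if len(vals) < 2:
            raise ValueError(f"locus {locus!r}: need >= 2 typed individuals to normalize")
        if scale == "zscore":
            sd = vals.std(ddof=1)
            if sd == 0:
                dropped.append(locus)
                continue
            cols.append((col - vals.mean()) / sd)
        elif scale == "mean":
            m = vals.mean()
            if m == 0:
                dropped.append(locus)
                continue
            cols.append(col / m)
        else:
            raise ValueError("scale must be 'zscore' or 'mean'")
        kept.append(locus)
    if dropped:
        warnings.warn(f"dropped zero-variance SLH column(s): {dropped}")
    normalized = np.column_stack(cols) if cols else np.empty((G.n, 0))
    return SLHMatrix(G.ids, loci, h, normalized, kept, dropped)
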