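"""Per-year heterozygosity-fitness models, single-locus scans, and effect-size
meta-analysis.

Each study year contributes one dataset of breeders with their recruitment
outcome (recaptured breeding the following season or not). Multilocus models
relate recruitment to 1-HL heterozygosity alongside the nongenetic covariates
(body condition, fledging success, age) and factors (plot, sex, origin), with
a mating-pair random intercept; all subsets of the candidate covariates are
ranked by AICc and the equivalent models averaged. Single-locus scans fit one
model per locus with Holm (sequential Bonferroni) correction, and a linear
meta-model asks whether locus effect sizes track marker variability or the
neutral/functional category.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import glm_engine
from .heterozygosity import SLHMatrix
from .io_core import MarkerPanel
from .marker_stats import MarkerStats

logger = logging.getLogger("hetfit")

CANDIDATE_COVARIATES = ["body_condition", "fledging_success", "age"]
ALWAYS_FACTORS = ["plot", "sex", "origin"]


def body_condition(ind: pd.DataFrame, within_year: bool = True) -> pd.Series:
    """Body condition as residual body mass.

    OLS residuals of body mass on laying date, wing length and tarsus length,
    correcting mass for breeding timing and structural size. Fitted within
    year by default.
    """
    need = ["body_mass", "laying_date", "wing", "tarsus"]
    out = pd.Series(np.nan, index=ind.index, dtype=float)
    groups = (ind.groupby("year").groups.values() if within_year
              else [ind.index])
    for idx in groups:
        sub = ind.loc[idx]
        ok = sub[need].notna().all(axis=1)
        if ok.sum() < 5:
            raise ValueError("body_condition needs >= 5 complete rows per fit")
        preds = sub.loc[ok, ["laying_date", "wing", "tarsus"]].astype(float)
        corr = preds.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        if (corr > 0.9999).any().any():
            i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
            raise ValueError(f"collinear predictors: {corr.index[i]!r} and {corr.columns[j]!r}")
        fit = sm.OLS(sub.loc[ok, "body_mass"].astype(float), sm.add_constant(preds)).fit()
        out.loc[sub.index[ok]] = fit.resid
    return out


@dataclass
class YearDataset:
    """Modeled rows for one recruitment transition (year t -> t+1)."""

    year: int
    data: pd.DataFrame  # recruited, het columns, covariates, pair_id
    n_dropped: int      # rows removed by row-wise deletion


def build_year_datasets(ind: pd.DataFrame, het: pd.DataFrame,
                        min_rows: int = 20) -> list[YearDataset]:
    """Merge het estimates onto the phenotype table and split by year.

    Rows with undefined recruitment (the final year) or any missing modeled
    covariate are dropped; the per-year deletion count is logged.
    """
    df = ind.merge(het, on="individual_id", how="left")
    if "body_condition" not in df.columns:
        df["body_condition"] = body_condition(df)
    datasets = []
    modeled = ["recruited", "het_total", "body_condition", "fledging_success",
               "age", "plot", "sex", "origin", "pair_id"]
    for year, sub in df.groupby("year"):
        if sub["recruited"].isna().all():
            continue  # final study year: no t+1 to score
        ok = sub[modeled].notna().all(axis=1)
        dropped = int((~ok).sum())
        if dropped:
            logger.info("year %s: dropped %d rows with missing covariates", year, dropped)
        sub = sub[ok]
        if len(sub) < min_rows:
            raise ValueError(f"year {year}: only {len(sub)} modeled rows (< {min_rows})")
        datasets.append(YearDataset(year=int(year), data=sub.reset_index(drop=True),
                                    n_dropped=dropped))
    return datasets


def run_multilocus_hfc(yd: YearDataset, family: str = "total",
                       use_random_intercept: bool = True,
                       gh_nodes: int = 25) -> pd.DataFrame:
    """Model-averaged recruitment model for one year.

    ``family="total"`` uses 1-HL over all loci as the single heterozygosity
    term; ``family="neutral_plus_functional"`` enters the neutral and
    functional subset heterozygosities as two separate candidate terms.
    Returns the averaged coefficient table sorted by summed Akaike weight.
    """
    if family == "total":
        het_terms = ["het_total"]
    elif family == "neutral_plus_functional":
        het_terms = ["het_neutral", "het_functional"]
    else:
        raise ValueError(f"unknown family {family!r}")
    data = yd.data.dropna(subset=het_terms)
    ms = glm_engine.model_selection(
        data, "recruited",
        candidate_terms=het_terms + CANDIDATE_COVARIATES,
        always_terms=ALWAYS_FACTORS,
        groups="pair_id" if use_random_intercept else None,
        gh_nodes=gh_nodes)
    table = glm_engine.model_average(ms)
    table.insert(0, "year", yd.year)
    return table


def run_pooled_hfc(datasets: list[YearDataset], family: str = "total",
                   use_random_intercept: bool = True, gh_nodes: int = 25) -> pd.DataFrame:
    """All years stacked, with year as a fixed factor."""
    data = pd.concat([d.data.assign(year=str(d.year)) for d in datasets],
                     ignore_index=True)
    het_terms = ["het_total"] if family == "total" else ["het_neutral", "het_functional"]
    data = data.dropna(subset=het_terms)
    ms = glm_engine.model_selection(
        data, "recruited",
        candidate_terms=het_terms + CANDIDATE_COVARIATES,
        always_terms=ALWAYS_FACTORS + ["year"],
        groups="pair_id" if use_random_intercept else None,
        gh_nodes=gh_nodes)
    table = glm_engine.model_average(ms)
    table.insert(0, "year", "pooled")
    return table


def univariate_het_fit(yd: YearDataset, het_column: str = "het_total") -> glm_engine.FittedModel:
    """Logistic regression of recruitment on heterozygosity alone."""
    data = yd.data.dropna(subset=[het_column])
    X = np.column_stack([np.ones(len(data)), data[het_column].to_numpy(float)])
    return glm_engine.fit_logistic(data["recruited"].to_numpy(float), X,
                                   names=["(Intercept)", het_column])


# ---------------------------------------------------------------------------
# Holm (sequential Bonferroni)
# ---------------------------------------------------------------------------

def holm_correction(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Holm procedure.

    Returns (reject flags, per-test thresholds alpha/(m - rank)). Walking the
    sorted p-values, testing stops at the first p above its threshold; all
    larger p-values are retained regardless of their own thresholds.
    """
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    thresholds = np.empty(m)
    stopped = False
    for rank, idx in enumerate(order):
        thr = alpha / (m - rank)
        thresholds[idx] = thr
        if not stopped and p[idx] <= thr:
            reject[idx] = True
        else:
            stopped = True
    return reject, thresholds


# ---------------------------------------------------------------------------
# Single-locus scan
# ---------------------------------------------------------------------------

def single_locus_scan(yd: YearDataset, slh: SLHMatrix, alpha: float = 0.05,
                      covariates: bool = True, use_random_intercept: bool = True,
                      gh_nodes: int = 25, correct: bool = True) -> pd.DataFrame:
    """One recruitment model per locus for one year.

    Each model enters the locus's 0/1 heterozygosity with the nongenetic
    covariate set (and the pair random intercept). The effect size is the
    partial correlation r = z / sqrt(n). Holm correction is applied across the
    year's loci unless ``correct=False`` (e.g. when correcting across all
    year x locus tests externally).
    """
    slh_by_id = pd.DataFrame(slh.raw, columns=slh.loci)
    slh_by_id["individual_id"] = slh.ids
    data = yd.data.merge(slh_by_id, on="individual_id", how="left")
    rows = []
    for locus in slh.loci:
        sub = data.dropna(subset=[locus])
        h = sub[locus].to_numpy(float)
        if h.std() == 0:
            warnings.warn(f"locus {locus!r}: monomorphic heterozygosity in year {yd.year}; skipped")
            continue
        terms = ([f"__slh_{locus}"] + CANDIDATE_COVARIATES) if covariates else [f"__slh_{locus}"]
        sub = sub.rename(columns={locus: f"__slh_{locus}"})
        X, names = glm_engine.build_design(sub, terms + (ALWAYS_FACTORS if covariates else []))
        try:
            fm = glm_engine.fit_logistic(
                sub["recruited"].to_numpy(float), X, names=names,
                groups=sub["pair_id"].to_numpy() if use_random_intercept else None,
                gh_nodes=gh_nodes)
        except glm_engine.SeparationError:
            warnings.warn(f"locus {locus!r}, year {yd.year}: separation; skipped")
            continue
        est = fm.coef(f"__slh_{locus}")
        se = fm.se(f"__slh_{locus}")
        z = est / se if se > 0 else np.nan
        p_raw = 2 * stats.norm.sf(abs(z))
        rows.append({"year": yd.year, "locus": locus, "estimate": est, "z": z,
                     "p_raw": p_raw, "n": fm.n_obs,
                     "effect_size_r": float(np.clip(z / np.sqrt(fm.n_obs), -1, 1))})
    out = pd.DataFrame(rows)
    if correct and len(out):
        reject, thr = holm_correction(out["p_raw"].to_numpy(), alpha)
        out["p_holm_rank_threshold"] = thr
        out["significant_after_correction"] = reject
    return out


def effect_size_model(scan: pd.DataFrame, marker_stats: list[MarkerStats],
                      panel: MarkerPanel) -> pd.DataFrame:
    """Linear meta-model |r| ~ A_R + H_O + category across one year's loci."""
    stats_df = pd.DataFrame([{"locus": s.locus, "A_R": s.n_alleles, "H_O": s.observed_het}
                             for s in marker_stats])
    cat = panel.table[["locus", "category"]]
    df = scan.merge(stats_df, on="locus").merge(cat, on="locus")
    for c in ("neutral", "functional"):
        if (df["category"] == c).sum() < 3:
            raise ValueError(f"category {c!r} has fewer than 3 loci in the scan")
    df["abs_r"] = df["effect_size_r"].abs()
    X = pd.DataFrame({
        "A_R": df["A_R"].astype(float),
        "H_O": df["H_O"].astype(float),
        "category_neutral": (df["category"] == "neutral").astype(float),
    })
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("degenerate design in effect-size model")
    fit = sm.OLS(df["abs_r"], X).fit()
    return pd.DataFrame({"term": X.columns, "estimate": fit.params.values,
                         "se": fit.bse.values, "t": fit.tvalues.values,
                         "p": fit.pvalues.values})


def interaction_check(yd: YearDataset, het_column: str = "het_total",
                      factor: str = "plot", use_random_intercept: bool = True,
                      gh_nodes: int = 25) -> pd.DataFrame:
    """Post-hoc het x factor interaction model (population-stratification check)."""
    data = yd.data.dropna(subset=[het_column]).copy()
    dummies = pd.get_dummies(data[factor], prefix=factor, drop_first=True)
    terms = [het_column] + CANDIDATE_COVARIATES
    X, names = glm_engine.build_design(data, terms + ALWAYS_FACTORS)
    for c in dummies.columns:
        X = np.column_stack([X, data[het_column].to_numpy(float) * dummies[c].to_numpy(float)])
        names.append(f"{het_column}:{c}")
    fm = glm_engine.fit_logistic(
        data["recruited"].to_numpy(float), X, names=names,
        groups=data["pair_id"].to_numpy() if use_random_intercept else None,
        gh_nodes=gh_nodes)
    rows = []
    for nm in names:
        if ":" not in nm or nm not in fm.terms:
            continue
        est, se = fm.coef(nm), fm.se(nm)
        z = est / se if se > 0 else np.nan
        rows.append({"year": yd.year, "term": nm, "estimate": est, "se": se,
                     "z": z, "p": 2 * stats.norm.sf(abs(z))})
    return pd.DataFrame(rows)
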