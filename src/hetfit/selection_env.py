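"""Environmental harshness metrics and selection on heterozygosity.

The nonbreeding window runs from the end of reproduction (July 1 of the focal
year) to the start of the next breeding season (March 31 of the following
year). Three harshness cues are computed over that window: days outside the
thermal neutral zone (daily maximum >= 35 C or daily minimum <= 15 C),
freezing-degree days (daily minimum < 0 C), and accumulated precipitation.

The yearly selection differential on heterozygosity is
S = cov(omega, het) with omega = w / mean(w) the relative fitness from the
0/1 recruitment outcome and a denominator-n covariance, which makes S exactly
the recruits' mean heterozygosity minus the population mean. Simple linear
regressions then relate the yearly S series to each harshness cue and track
the temporal trend of annual mean heterozygosity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("hetfit")


@dataclass
class HarshnessMetrics:
    season_start_year: int
    tnz_days: int
    fdd: int
    accumulated_precip: float


def harshness_metrics(weather: pd.DataFrame, season_start_year: int,
                      strict: bool = True, temp_mode: str = "extremes") -> HarshnessMetrics:
    """Harshness cues over July 1 (year t) - March 31 (year t+1), inclusive.

    ``temp_mode="extremes"`` (default) applies the hot TNZ bound to the daily
    maximum and the cold bound to the daily minimum; ``"mean"`` applies both
    bounds to the daily mean temperature.
    """
    start = pd.Timestamp(season_start_year, 7, 1)
    end = pd.Timestamp(season_start_year + 1, 3, 31)
    w = weather[(weather["date"] >= start) & (weather["date"] <= end)]
    expected = pd.date_range(start, end, freq="D")
    if len(w) == 0:
        raise ValueError(f"no weather data in window {start.date()}..{end.date()}")
    missing = expected.difference(pd.DatetimeIndex(w["date"]))
    if len(missing):
        msg = (f"window {start.date()}..{end.date()} missing {len(missing)} day(s), "
               f"first {missing[0].date()}")
        if strict:
            raise ValueError(msg)
        logger.warning(msg)
    if temp_mode == "extremes":
        tnz = (w["tmax"] >= 35) | (w["tmin"] <= 15)
    elif temp_mode == "mean":
        tmean = (w["tmin"] + w["tmax"]) / 2.0
        tnz = (tmean >= 35) | (tmean <= 15)
    else:
        raise ValueError("temp_mode must be 'extremes' or 'mean'")
    return HarshnessMetrics(
        season_start_year=season_start_year,
        tnz_days=int(tnz.sum()),
        fdd=int((w["tmin"] < 0).sum()),
        accumulated_precip=float(w["precip"].sum()),
    )


def harshness_table(weather: pd.DataFrame, years: list[int], **kw) -> pd.DataFrame:
    rows = [harshness_metrics(weather, y, **kw) for y in years]
    return pd.DataFrame([{"year": m.season_start_year, "tnz_days": m.tnz_days,
                          "fdd": m.fdd, "accumulated_precip": m.accumulated_precip}
                         for m in rows])


def selection_differential(het, recruited, ddof: int = 0) -> float:
    """S = cov(relative fitness, heterozygosity).

    With the default denominator-n covariance (``ddof=0``), S equals
    mean(het | recruited) - mean(het). S is 0 when either variable is
    constant; undefined (error) with zero recruits.
    """
    het = np.asarray(het, dtype=float).ravel()
    w = np.asarray(recruited, dtype=float).ravel()
    if len(het) != len(w) or len(het) < 2:
        raise ValueError("need >= 2 paired observations")
    if np.isnan(het).any() or np.isnan(w).any():
        keep = ~(np.isnan(het) | np.isnan(w))
        het, w = het[keep], w[keep]
        if len(het) < 2:
            raise ValueError("need >= 2 complete observations")
    if w.sum() == 0:
        raise ValueError("relative fitness undefined: no recruits")
    omega = w / w.mean()
    if np.ptp(omega) == 0 or np.ptp(het) == 0:
        return 0.0
    n = len(het)
    cov = ((omega - omega.mean()) * (het - het.mean())).sum() / (n - ddof)
    return float(cov)


def selection_series(datasets, het_columns=("het_total", "het_neutral", "het_functional")) -> pd.DataFrame:
    """Per-year S and mean heterozygosity for each marker subset.

    ``datasets`` is an iterable of objects with ``year`` and ``data``
    attributes (see hfc_pipeline.YearDataset).
    """
    rows = []
    for yd in datasets:
        row: dict = {"year": yd.year, "n": len(yd.data)}
        for col in het_columns:
            sub = yd.data.dropna(subset=[col, "recruited"])
            name = col.replace("het_", "")
            row[f"S_{name}"] = selection_differential(sub[col], sub["recruited"])
            row[f"mean_het_{name}"] = float(sub[col].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def regress_series(x, y) -> tuple[float, float, float]:
    """Pearson r, OLS slope, and two-sided p (t distribution, n-2 df)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired years")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    res = stats.linregress(x, y)
    return float(res.rvalue), float(res.slope), float(res.pvalue)


def selection_vs_harshness(sel: pd.DataFrame, harsh: pd.DataFrame) -> pd.DataFrame:
    """One regression row per (marker subset x harshness cue), Table-3 layout."""
    df = sel.merge(harsh, on="year")
    rows = []
    for subset in ("total", "neutral", "functional"):
        for metric in ("tnz_days", "fdd", "accumulated_precip"):
            r, slope, p = regress_series(df[metric], df[f"S_{subset}"])
            rows.append({"subset": subset, "metric": metric, "r": r,
                         "slope": slope, "p": p})
    return pd.DataFrame(rows)


def heterozygosity_trend(sel: pd.DataFrame) -> pd.DataFrame:
    """Temporal trend of annual mean heterozygosity, one row per subset."""
    rows = []
    for subset in ("total", "neutral", "functional"):
        col = f"mean_het_{subset}"
        if col not in sel.columns:
            continue
        r, slope, p = regress_series(sel["year"], sel[col])
        rows.append({"subset": subset, "r": r, "slope": slope, "p": p})
    return pd.DataFrame(rows)
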