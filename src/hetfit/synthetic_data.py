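"""Synthetic study generator with known truth.

Emulates the statistical structure the analysis assumes, so every stage can be
tested without field data:

* **Genotypes** — L microsatellite loci with allele frequencies drawn once
  from a flat Dirichlet. Each individual carries an inbreeding coefficient f
  from a two-point mixture (a fraction ``pi`` of the population has
  ``f_high``, the rest 0; incestuous matings in an otherwise outbred
  population). At each locus a genotype is autozygous with probability f (one
  allele drawn and duplicated), otherwise two independent draws. Variance in f
  across individuals generates identity disequilibrium with the closed form
  E[g2] = Var(f) / (1 - E[f])^2.
* **Recruitment** — Bernoulli with P = logistic(beta0 + beta1(year) * het),
  where het is the individual's 1-HL and the year slope
  beta1 = beta1_base + beta1_precip_slope * z(accumulated precipitation)
  rises in wetter (harsher) winters. Recruits are carried over to the next
  breeding season, so sustained positive selection enriches heterozygosity
  over time.
* **Weather** — daily Mediterranean series: sinusoidal seasonal temperature
  (July mean ~25 C, January ~5 C), Bernoulli rain occurrence with gamma
  magnitudes, and a lognormal per-season wetness multiplier that gives annual
  accumulated precipitation a ~450 mm mean and ~160 mm interannual SD.

All randomness flows from one root seed through named ``SeedSequence``
substreams, so each sub-generator is independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .heterozygosity import compute_hl
from .io_core import GenotypeMatrix, MarkerPanel

logger = logging.getLogger("hetfit")


@dataclass
class SimConfig:
    """Study-design and generative parameters (defaults mirror the emulated
    field design: 26 loci split 14 neutral / 12 functional, ~150 breeders per
    season, 7 monitored years giving 6 recruitment transitions)."""

    seed: int
    n_per_year: int = 150
    n_years: int = 7
    L: int = 26
    allele_range: tuple[int, int] = (4, 16)   # per-locus allele counts, uniform
    n_neutral: int = 14
    n_functional: int = 12
    # inbreeding mixture: fraction pi with f = f_high, otherwise f = f_low
    pi: float = 0.2
    f_high: float = 0.25
    f_low: float = 0.0
    constant_f: float | None = None           # overrides the mixture if set
    # recruitment model on the logit scale; the heterozygosity term is centred
    # so beta0 sets the mean yearly rate and beta1 only the selection strength
    beta0: float = -0.5
    beta1_base: float = 3.0
    beta1_precip_slope: float = 5.0
    het_center: float = 0.78
    # weather model
    t_july: float = 25.0
    t_january: float = 5.0
    diurnal_range: float = 12.0
    temp_noise_sd: float = 3.0
    rain_prob: float = 0.18
    rain_gamma_shape: float = 0.7
    rain_mean_mm: float = 9.0
    wetness_log_sd: float = 0.33
    # nominal window-precipitation scale used to standardize precip
    precip_norm_mean: float = 450.0
    precip_norm_sd: float = 160.0
    first_year: int = 2008
    functional_diversity_factor: float = 1.0  # <1 lowers functional-locus allele counts
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 <= self.pi <= 1:
            raise ValueError("pi must be in [0, 1]")
        if not 0 <= self.f_high < 1:
            raise ValueError("f_high must be in [0, 1)")
        if self.allele_range[0] < 2:
            raise ValueError("need >= 2 alleles per locus")
        if self.n_neutral + self.n_functional != self.L:
            raise ValueError("n_neutral + n_functional must equal L")

    _STREAM_REGISTRY = ("freqs", "f", "genotypes", "covariates", "recruit",
                        "pairs", "weather")

    def streams(self, *names: str) -> dict[str, np.random.Generator]:
        """Named, independent random substreams derived from the root seed.

        Each registered name maps to a fixed spawn key, so the same substream
        is reproduced no matter which subset of generators a caller uses.
        """
        out = {}
        for nm in names:
            idx = self._STREAM_REGISTRY.index(nm)
            ss = np.random.SeedSequence(self.seed, spawn_key=(idx,))
            out[nm] = np.random.default_rng(ss)
        return out


@dataclass
class SimTruth:
    f_by_individual: dict[str, float]
    beta1_by_year: dict[int, float]
    expected_g2: float
    allele_freqs: list[np.ndarray]
    precip_z_by_year: dict[int, float] = field(default_factory=dict)


@dataclass
class SimulatedStudy:
    genotypes: GenotypeMatrix
    panel: MarkerPanel
    individuals: pd.DataFrame
    truth: SimTruth
    weather: pd.DataFrame


def expected_g2(cfg: SimConfig) -> float:
    """Closed-form g2 of the inbreeding model: Var(f) / (1 - E[f])^2."""
    if cfg.constant_f is not None:
        return 0.0
    mean_f = cfg.pi * cfg.f_high + (1 - cfg.pi) * cfg.f_low
    var_f = (cfg.pi * cfg.f_high ** 2 + (1 - cfg.pi) * cfg.f_low ** 2) - mean_f ** 2
    return float(var_f / (1.0 - mean_f) ** 2)


def draw_allele_freqs(cfg: SimConfig, rng: np.random.Generator) -> list[np.ndarray]:
    lo, hi = cfg.allele_range
    freqs = []
    for k in range(cfg.L):
        n_alleles = int(rng.integers(lo, hi + 1))
        if k >= cfg.n_neutral and cfg.functional_diversity_factor < 1.0:
            n_alleles = max(2, int(round(n_alleles * cfg.functional_diversity_factor)))
        freqs.append(rng.dirichlet(np.ones(n_alleles)))
    return freqs


def draw_f(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if cfg.constant_f is not None:
        return np.full(n, cfg.constant_f)
    return np.where(rng.random(n) < cfg.pi, cfg.f_high, cfg.f_low)


def simulate_genotypes(cfg: SimConfig, f: np.ndarray, freqs: list[np.ndarray],
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(a1, a2) allele-code arrays for individuals with inbreeding levels f."""
    n = len(f)
    a1 = np.empty((n, cfg.L), dtype=np.int64)
    a2 = np.empty_like(a1)
    for k, p in enumerate(freqs):
        codes = np.arange(1, len(p) + 1)
        first = rng.choice(codes, size=n, p=p)
        second = rng.choice(codes, size=n, p=p)
        auto = rng.random(n) < f
        a1[:, k] = first
        a2[:, k] = np.where(auto, first, second)
    if cfg.missing_rate > 0:
        miss = rng.random((n, cfg.L)) < cfg.missing_rate
        # never blank an entire row: keep the first locus typed
        miss[miss.all(axis=1), 0] = False
        a1[miss] = 0
        a2[miss] = 0
    return a1, a2


def true_el_weights(cfg: SimConfig, freqs: list[np.ndarray]) -> dict[str, float]:
    return {f"L{k + 1:02d}": float(1.0 - (p ** 2).sum()) for k, p in enumerate(freqs)}


def make_panel(cfg: SimConfig) -> MarkerPanel:
    loci = [f"L{k + 1:02d}" for k in range(cfg.L)]
    cats = ["neutral"] * cfg.n_neutral + ["functional"] * cfg.n_functional
    chrom = [str(1 + k % 10) for k in range(cfg.L)]
    return MarkerPanel(pd.DataFrame({"locus": loci, "chromosome": chrom, "category": cats}))


def simulate_weather(cfg: SimConfig, years: list[int] | None = None) -> pd.DataFrame:
    """Daily tmin/tmax/precip covering Jan 1 of the first year through Dec 31
    of the year after the last, so every July-March window is complete."""
    if years is None:
        years = list(range(cfg.first_year, cfg.first_year + cfg.n_years))
    rng = cfg.streams("weather")["weather"]
    dates = pd.date_range(f"{min(years)}-01-01", f"{max(years) + 1}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    # seasonal mean temperature: peak mid-July (doy ~197), trough mid-January
    mid = (cfg.t_july + cfg.t_january) / 2.0
    amp = (cfg.t_july - cfg.t_january) / 2.0
    tmean = mid + amp * np.cos(2 * np.pi * (doy - 197) / 365.25)
    noise = rng.normal(0.0, cfg.temp_noise_sd, size=(2, len(dates)))
    tmin = tmean - cfg.diurnal_range / 2.0 + noise[0]
    tmax = tmean + cfg.diurnal_range / 2.0 + noise[1]
    swap = tmax < tmin
    tmin[swap], tmax[swap] = tmax[swap], tmin[swap].copy()

    # per-season wetness multiplier (season y = July y .. June y+1)
    season = np.where(dates.month >= 7, dates.year, dates.year - 1)
    season_years = np.unique(season)
    mult = {int(y): float(rng.lognormal(-cfg.wetness_log_sd ** 2 / 2, cfg.wetness_log_sd))
            for y in season_years}
    wet = rng.random(len(dates)) < cfg.rain_prob
    scale = cfg.rain_mean_mm / cfg.rain_gamma_shape
    mag = rng.gamma(cfg.rain_gamma_shape, scale, size=len(dates))
    precip = np.where(wet, mag * np.array([mult[int(s)] for s in season]), 0.0)
    return pd.DataFrame({"date": dates, "tmin": np.round(tmin, 2),
                         "tmax": np.round(tmax, 2), "precip": np.round(precip, 2)})


def precip_z(cfg: SimConfig, accumulated_precip_mm: float) -> float:
    """Standardize a window's accumulated precipitation on the nominal scale."""
    return (accumulated_precip_mm - cfg.precip_norm_mean) / cfg.precip_norm_sd


def simulate_recruitment(het: np.ndarray, year_precip_mm: float, cfg: SimConfig,
                         rng_or_seed) -> np.ndarray:
    """0/1 recruitment draws: P = logistic(beta0 + beta1(year) * het)."""
    rng = (rng_or_seed if isinstance(rng_or_seed, np.random.Generator)
           else np.random.default_rng(rng_or_seed))
    beta1 = cfg.beta1_base + cfg.beta1_precip_slope * precip_z(cfg, year_precip_mm)
    eta = cfg.beta0 + beta1 * (np.asarray(het, dtype=float) - cfg.het_center)
    p = 1.0 / (1.0 + np.exp(-eta))
    return (rng.random(len(p)) < p).astype(int)


def _covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    tarsus = rng.normal(16.5, 0.5, n)
    wing = rng.normal(65.0, 2.0, n)
    laying = np.round(rng.normal(100.0, 7.0, n))
    mass = 2.0 + 0.45 * tarsus + 0.02 * wing - 0.005 * laying + rng.normal(0, 0.35, n)
    return pd.DataFrame({
        "tarsus": np.round(tarsus, 2), "wing": np.round(wing, 1),
        "laying_date": laying, "body_mass": np.round(mass, 2),
        "fledging_success": rng.poisson(5.0, n),
        "plot": rng.choice(["A", "B"], n),
        "origin": rng.choice(["local", "immigrant"], n, p=[0.7, 0.3]),
    })


def _assign_pairs(df: pd.DataFrame, year: int, rng: np.random.Generator) -> pd.Series:
    """Pair individuals within plot; each pair id is shared by at most 2."""
    pair = pd.Series(index=df.index, dtype=object)
    counter = 0
    for plot, sub in df.groupby("plot"):
        idx = rng.permutation(sub.index.to_numpy())
        for i in range(0, len(idx), 2):
            members = idx[i:i + 2]
            pair[members] = f"P{year}_{plot}{counter:03d}"
            counter += 1
    return pair


def simulate_dataset(cfg: SimConfig) -> SimulatedStudy:
    """Generate the full multi-year study: genotypes, panel, phenotype table
    with recruitment outcomes, daily weather, and the generative truth.

    Year-to-year dynamics: recruits of season t return as breeders in season
    t+1 (same genotype, age + 1); fresh individuals top the population back up
    to ``n_per_year``. The final monitored year has undefined recruitment.
    """
    streams = cfg.streams("freqs", "f", "genotypes", "covariates", "recruit", "pairs")
    freqs = draw_allele_freqs(cfg, streams["freqs"])
    panel = make_panel(cfg)
    weights = true_el_weights(cfg, freqs)
    weather = simulate_weather(cfg)
    years = list(range(cfg.first_year, cfg.first_year + cfg.n_years))

    from .selection_env import harshness_metrics  # late import avoids a cycle
    precip = {y: harshness_metrics(weather, y).accumulated_precip for y in years}

    next_id = 1
    geno_rows: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    f_by_id: dict[str, float] = {}
    static: dict[str, dict] = {}
    beta1_by_year: dict[int, float] = {}

    ind_rows = []
    carry: list[str] = []   # ids recruited from the previous season
    ages: dict[str, int] = {}
    for t, year in enumerate(years):
        n_new = cfg.n_per_year - len(carry)
        new_ids = [f"B{next_id + i:04d}" for i in range(n_new)]
        next_id += n_new
        f_new = draw_f(cfg, n_new, streams["f"])
        a1, a2 = simulate_genotypes(cfg, f_new, freqs, streams["genotypes"])
        cov = _covariates(n_new, streams["covariates"])
        sexes = streams["covariates"].choice(["M", "F"], n_new)
        for i, iid in enumerate(new_ids):
            geno_rows[iid] = (a1[i], a2[i])
            f_by_id[iid] = float(f_new[i])
            static[iid] = {"sex": sexes[i], "plot": cov.loc[i, "plot"],
                           "origin": cov.loc[i, "origin"], "tarsus": cov.loc[i, "tarsus"],
                           "wing": cov.loc[i, "wing"]}
            ages[iid] = int(streams["covariates"].integers(1, 4))

        cohort = carry + new_ids
        ydf = pd.DataFrame({"individual_id": cohort, "year": year})
        ydf["sex"] = [static[i]["sex"] for i in cohort]
        ydf["plot"] = [static[i]["plot"] for i in cohort]
        ydf["origin"] = [static[i]["origin"] for i in cohort]
        ydf["age"] = [ages[i] for i in cohort]
        ydf["tarsus"] = [static[i]["tarsus"] for i in cohort]
        ydf["wing"] = [static[i]["wing"] for i in cohort]
        rng_cov = streams["covariates"]
        laying = np.round(rng_cov.normal(100.0, 7.0, len(cohort)))
        ydf["laying_date"] = laying
        ydf["body_mass"] = np.round(
            2.0 + 0.45 * ydf["tarsus"].to_numpy() + 0.02 * ydf["wing"].to_numpy()
            - 0.005 * laying + rng_cov.normal(0, 0.35, len(cohort)), 2)
        ydf["fledging_success"] = rng_cov.poisson(5.0, len(cohort))
        ydf["pair_id"] = _assign_pairs(ydf, year, streams["pairs"]).to_numpy()

        G_cohort = GenotypeMatrix(
            np.array(cohort, dtype=object), panel.loci,
            np.vstack([geno_rows[i][0] for i in cohort]),
            np.vstack([geno_rows[i][1] for i in cohort]))
        het = 1.0 - compute_hl(G_cohort, weights)

        if t < len(years) - 1:
            z = precip_z(cfg, precip[year])
            beta1_by_year[year] = cfg.beta1_base + cfg.beta1_precip_slope * z
            rec = simulate_recruitment(het, precip[year], cfg, streams["recruit"])
            ydf["recruited"] = rec.astype(float)
            carry = [iid for iid, r in zip(cohort, rec) if r == 1]
            for iid in carry:
                ages[iid] += 1
        else:
            ydf["recruited"] = np.nan
            carry = []
        ind_rows.append(ydf)

    individuals = pd.concat(ind_rows, ignore_index=True)
    all_ids = list(geno_rows)
    G = GenotypeMatrix(np.array(all_ids, dtype=object), panel.loci,
                       np.vstack([geno_rows[i][0] for i in all_ids]),
                       np.vstack([geno_rows[i][1] for i in all_ids]))
    truth = SimTruth(
        f_by_individual=f_by_id,
        beta1_by_year=beta1_by_year,
        expected_g2=expected_g2(cfg),
        allele_freqs=freqs,
        precip_z_by_year={y: precip_z(cfg, precip[y]) for y in years},
    )
    logger.info("simulate_dataset: %d individuals, %d loci, %d years (seed %d)",
                G.n, cfg.L, cfg.n_years, cfg.seed)
    return SimulatedStudy(genotypes=G, panel=panel, individuals=individuals,
                          truth=truth, weather=weather)
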