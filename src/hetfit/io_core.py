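"""Input tables, validation, and recruitment coding.

Four tables drive the analysis: a marker panel (locus metadata), a genotype
matrix (two allele columns per locus), an individual/phenotype table with the
recruitment outcome, and a daily weather series. All are read and written as
plain CSV. Missing genotypes are encoded as empty cells or "NA" (written back
as "NA"); an individual is missing at a locus iff *both* allele fields are
missing.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("hetfit")

MISSING = 0  # internal allele code for a missing allele

_SEXES = {"M", "F"}
_ORIGINS = {"local", "immigrant"}
_CATEGORIES = {"neutral", "functional"}


class FormatError(ValueError):
    """File does not match the expected column schema."""


class ValidationError(ValueError):
    """File parses but violates a table invariant."""


def setup_logging(log_file: str | None = None, level: int = logging.INFO) -> None:
    """Log to stderr and optionally to a run-log file."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if log_file:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(level=level, handlers=handlers, force=True,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")


# ---------------------------------------------------------------------------
# Marker panel
# ---------------------------------------------------------------------------

@dataclass
class MarkerPanel:
    """Locus metadata: name, chromosome, and neutral/functional category."""

    table: pd.DataFrame  # columns: locus, chromosome, category

    def __post_init__(self) -> None:
        required = {"locus", "chromosome", "category"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"marker panel missing columns: {sorted(missing)}")
        if self.table["locus"].duplicated().any():
            dups = self.table.loc[self.table["locus"].duplicated(), "locus"].tolist()
            raise ValidationError(f"duplicate locus names in panel: {dups}")
        bad = set(self.table["category"].dropna()) - _CATEGORIES
        if bad or self.table["category"].isna().any():
            raise ValidationError(f"panel category must be one of {sorted(_CATEGORIES)}, got {bad or 'missing values'}")
        if len(self.table) < 2:
            raise ValidationError("marker panel needs at least 2 loci")

    @property
    def loci(self) -> list[str]:
        return self.table["locus"].tolist()

    def subset(self, category: str) -> list[str]:
        """Locus names in one category, or all loci for 'total'."""
        if category == "total":
            return self.loci
        if category not in _CATEGORIES:
            raise ValueError(f"unknown marker category {category!r}")
        sel = self.table["category"] == category
        return self.table.loc[sel, "locus"].tolist()


def read_panel(path) -> MarkerPanel:
    return MarkerPanel(pd.read_csv(path, dtype={"locus": str, "chromosome": str, "category": str}))


def write_panel(panel: MarkerPanel, path) -> None:
    panel.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Individuals x loci allele pairs.

    Alleles are opaque positive integer codes; 0 marks a missing allele, and
    missingness is always pairwise (both alleles absent together).
    """

    ids: np.ndarray           # (n,) individual ids, str
    loci: list[str]           # (L,)
    a1: np.ndarray            # (n, L) int, 0 = missing
    a2: np.ndarray            # (n, L) int, 0 = missing

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.a1 = np.asarray(self.a1, dtype=np.int64)
        self.a2 = np.asarray(self.a2, dtype=np.int64)
        if self.a1.shape != self.a2.shape or self.a1.shape != (len(self.ids), len(self.loci)):
            raise ValidationError("genotype array shapes inconsistent with ids/loci")
        if ((self.a1 == MISSING) != (self.a2 == MISSING)).any():
            i, j = np.argwhere((self.a1 == MISSING) != (self.a2 == MISSING))[0]
            raise ValidationError(
                f"half-missing genotype for individual {self.ids[i]!r} at locus {self.loci[j]!r}: "
                "both alleles must be present or both missing")
        if (self.a1 < 0).any() or (self.a2 < 0).any():
            raise ValidationError("allele codes must be positive integers")
        if self.typed_mask.sum(axis=1).min(initial=1) == 0:
            i = int(np.argmin(self.typed_mask.sum(axis=1)))
            raise ValidationError(f"individual {self.ids[i]!r} has no typed loci")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def typed_mask(self) -> np.ndarray:
        """(n, L) bool, True where the genotype is present."""
        return self.a1 != MISSING

    def het_indicator(self) -> np.ndarray:
        """(n, L) float: 1 heterozygous, 0 homozygous, NaN missing."""
        h = (self.a1 != self.a2).astype(float)
        h[~self.typed_mask] = np.nan
        return h

    def locus_index(self, loci: list[str]) -> np.ndarray:
        pos = {name: k for k, name in enumerate(self.loci)}
        try:
            return np.array([pos[l] for l in loci], dtype=int)
        except KeyError as e:
            raise KeyError(f"locus {e.args[0]!r} not in genotype matrix") from None

    def select(self, loci: list[str]) -> "GenotypeMatrix":
        idx = self.locus_index(loci)
        return GenotypeMatrix(self.ids, list(loci), self.a1[:, idx], self.a2[:, idx])


def read_genotypes(path, panel: MarkerPanel) -> GenotypeMatrix:
    """Read a genotype CSV: column ``id`` plus ``<locus>.a1``/``<locus>.a2``."""
    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns:
        raise FormatError("genotype file must have an 'id' column")
    allele_cols = [c for c in df.columns if c != "id"]
    loci_in_file: list[str] = []
    for c in allele_cols:
        if not (c.endswith(".a1") or c.endswith(".a2")):
            raise FormatError(f"unexpected genotype column {c!r} (want <locus>.a1/<locus>.a2)")
        locus = c[:-3]
        if locus not in loci_in_file:
            loci_in_file.append(locus)
    orphans = sorted(set(loci_in_file) - set(panel.loci))
    if orphans:
        raise FormatError(f"genotype columns for loci absent from the marker panel: {orphans}")
    incomplete = [l for l in loci_in_file if f"{l}.a1" not in df.columns or f"{l}.a2" not in df.columns]
    if incomplete:
        raise FormatError(f"loci with only one allele column: {incomplete}")

    n = len(df)
    a1 = np.zeros((n, len(loci_in_file)), dtype=np.int64)
    a2 = np.zeros_like(a1)
    for k, locus in enumerate(loci_in_file):
        c1 = pd.to_numeric(df[f"{locus}.a1"], errors="coerce")
        c2 = pd.to_numeric(df[f"{locus}.a2"], errors="coerce")
        half = c1.isna() != c2.isna()
        if half.any():
            row = int(np.argmax(half.to_numpy()))
            raise ValidationError(
                f"individual {df['id'].iloc[row]!r}, locus {locus!r}: one of two alleles missing")
        a1[:, k] = c1.fillna(MISSING).astype(np.int64)
        a2[:, k] = c2.fillna(MISSING).astype(np.int64)
    all_missing = (a1 == MISSING).all(axis=1)
    if all_missing.any():
        bad = df["id"][all_missing].tolist()
        raise ValidationError(f"individuals typed at no locus: {bad}")
    G = GenotypeMatrix(df["id"].to_numpy(dtype=object), loci_in_file, a1, a2)
    logger.info("read_genotypes: %d individuals x %d loci, %d missing cells",
                G.n, len(G.loci), int((~G.typed_mask).sum()))
    return G


def write_genotypes(G: GenotypeMatrix, path) -> None:
    data: dict[str, object] = {"id": G.ids}
    for k, locus in enumerate(G.loci):
        data[f"{locus}.a1"] = np.where(G.a1[:, k] == MISSING, np.nan, G.a1[:, k])
        data[f"{locus}.a2"] = np.where(G.a2[:, k] == MISSING, np.nan, G.a2[:, k])
    pd.DataFrame(data).to_csv(path, index=False, na_rep="NA", float_format="%.0f")


# ---------------------------------------------------------------------------
# Individual / phenotype table
# ---------------------------------------------------------------------------

INDIVIDUAL_COLUMNS = ["individual_id", "year", "plot", "sex", "age", "origin",
                      "body_mass", "tarsus", "wing", "laying_date",
                      "fledging_success", "pair_id", "recruited"]


def _validate_individuals(df: pd.DataFrame, require_recruited: bool = True) -> pd.DataFrame:
    need = set(INDIVIDUAL_COLUMNS) - ({"recruited"} if not require_recruited else set())
    missing = need - set(df.columns)
    if missing:
        raise FormatError(f"individual table missing columns: {sorted(missing)}")
    df = df.copy()
    df["individual_id"] = df["individual_id"].astype(str)
    df["year"] = df["year"].astype(int)
    dup = df.duplicated(subset=["individual_id", "year"])
    if dup.any():
        key = df.loc[dup, ["individual_id", "year"]].iloc[0].tolist()
        raise ValidationError(f"duplicate (individual_id, year): {tuple(key)}")
    for col, levels in (("sex", _SEXES), ("origin", _ORIGINS)):
        bad = ~df[col].isin(levels)
        if bad.any():
            raise ValidationError(
                f"row {int(np.argmax(bad.to_numpy()))}: {col} value {df.loc[bad, col].iloc[0]!r} "
                f"not in {sorted(levels)}")
    if (df["fledging_success"].dropna() < 0).any():
        raise ValidationError("negative fledging_success")
    counts = df.groupby(["year", "pair_id"])["individual_id"].count()
    if (counts > 2).any():
        year, pair = counts.idxmax()
        raise ValidationError(f"pair_id {pair!r} shared by >2 individuals in year {year}")
    if "recruited" in df.columns:
        last = df["year"].max()
        vals = df.loc[df["year"] < last, "recruited"]
        if vals.isna().any():
            raise ValidationError("recruited must be defined for every year except the last")
        if not set(vals.unique()) <= {0, 1}:
            raise ValidationError("recruited must be 0/1")
    return df


def read_individuals(path) -> pd.DataFrame:
    """Read and validate the per-individual, per-year phenotype table."""
    df = pd.read_csv(path, dtype={"individual_id": str, "pair_id": str})
    df = _validate_individuals(df)
    logger.info("read_individuals: %d rows, years %d-%d", len(df),
                df["year"].min(), df["year"].max())
    return df


def write_individuals(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, na_rep="NA")


def derive_recruitment(captures: pd.DataFrame) -> pd.DataFrame:
    """Code interannual local recruitment from capture histories.

    recruited(id, t) = 1 iff the individual was captured breeding in year t+1
    in *any* plot of the study area, 0 otherwise; undefined (NaN) for the last
    observed year, whose transition cannot be scored.
    """
    df = _validate_individuals(captures, require_recruited=False)
    years = np.sort(df["year"].unique())
    if len(years) < 2:
        raise ValidationError("derive_recruitment needs capture records from >= 2 years")
    present: dict[int, set[str]] = {
        int(y): set(sub["individual_id"]) for y, sub in df.groupby("year")}
    last = int(years.max())

    def code(row) -> float:
        if row["year"] == last:
            return np.nan
        return float(row["individual_id"] in present.get(int(row["year"]) + 1, set()))

    out = df.copy()
    out["recruited"] = df.apply(code, axis=1)
    return out


# ---------------------------------------------------------------------------
# Weather series
# ---------------------------------------------------------------------------

def read_weather(path) -> pd.DataFrame:
    """Read the daily weather CSV (date, tmin, tmax, precip); returned sorted."""
    df = pd.read_csv(path, parse_dates=["date"])
    return validate_weather(df)


def validate_weather(df: pd.DataFrame) -> pd.DataFrame:
    need = {"date", "tmin", "tmax", "precip"}
    missing = need - set(df.columns)
    if missing:
        raise FormatError(f"weather table missing columns: {sorted(missing)}")
    df = df.sort_values("date").reset_index(drop=True)
    if df["date"].duplicated().any():
        d = df.loc[df["date"].duplicated(), "date"].iloc[0]
        raise ValidationError(f"duplicate weather date {d.date()}")
    bad = df["tmax"] < df["tmin"]
    if bad.any():
        d = df.loc[bad, "date"].iloc[0]
        raise ValidationError(f"tmax < tmin on {d.date()}")
    if (df["precip"] < 0).any():
        raise ValidationError("negative precipitation")
    return df


def write_weather(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Paths, marker subsets, model terms, permutation counts, and seeds."""

    genotypes: str | None = None
    panel: str | None = None
    individuals: str | None = None
    weather: str | None = None
    out_dir: str = "."
    seed: int = 1
    permutations: int = 1000
    candidate_terms: list = field(default_factory=lambda: [
        "het", "body_condition", "fledging_success", "age"])
    always_terms: list = field(default_factory=lambda: ["plot", "sex", "origin"])
    min_rows_per_year: int = 20
    extra: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__ if f != "extra"}
    kwargs = {k: v for k, v in raw.items() if k in known}
    extra = {k: v for k, v in raw.items() if k not in known}
    return RunConfig(extra=extra, **kwargs)
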