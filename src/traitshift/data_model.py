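"""Tabular containers, validation, and delimited-text IO for the pipeline.

All on-disk formats are plain delimited text (CSV by default, TSV
selectable).  Floats are written with ``repr`` precision so that a
write/read round trip is lossless for float64 data.

Containers
----------
``CoverMatrix``
    Site x species relative cover, rows normalized to sum to 1.
``TraitRecordTable``
    Long-format individual-level trait measurements.
``SiteSpeciesMeans``
    Per-(site, species, trait) arithmetic means of individual records.
``GlobalSpeciesMeans``
    Per-(species, trait) means across the sites where the species was
    sampled (one vote per site by default).
``EnvironmentTable``
    Site x environmental-variable table with optional per-variable log
    transforms.
``SiteCoordinates``
    Site latitude/longitude in decimal degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("traitshift")

__all__ = [
    "ValidationError",
    "CoverMatrix",
    "TraitRecordTable",
    "SiteSpeciesMeans",
    "GlobalSpeciesMeans",
    "EnvironmentTable",
    "SiteCoordinates",
    "read_cover_matrix",
    "write_cover_matrix",
    "read_trait_records",
    "write_trait_records",
    "read_environment",
    "write_environment",
    "read_coordinates",
    "write_coordinates",
    "site_species_means",
    "global_species_means",
]

TRAIT_RECORD_COLUMNS = ["site", "species", "individual", "trait", "value"]

#: traits constrained to lie in (0, 1] (dimensionless mass fractions)
FRACTION_TRAITS = frozenset({"ldmc"})


class ValidationError(ValueError):
    """Raised when input data violate a container invariant."""


def _check_unique(values, what: str) -> None:
    counts = pd.Index(values).value_counts()
    dupes = counts[counts > 1]
    if len(dupes):
        raise ValidationError(f"duplicate {what}: {sorted(dupes.index.tolist())}")


# ---------------------------------------------------------------------------
# CoverMatrix
# ---------------------------------------------------------------------------


@dataclass
class CoverMatrix:
    """Site x species relative-cover matrix; rows sum to 1 after normalization."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "site identifiers")
        _check_unique(df.columns, "species identifiers")
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("cover matrix contains non-finite values")
        if (values < 0).any():
            bad = df.index[(values < 0).any(axis=1)].tolist()
            raise ValidationError(f"negative cover values in sites {bad}")
        row_sums = values.sum(axis=1)
        if (row_sums <= 0).any():
            bad = df.index[row_sums <= 0].tolist()
            raise ValidationError(f"sites with zero total cover: {bad}")
        if not np.allclose(row_sums, 1.0, atol=1e-9, rtol=0):
            df = df.div(row_sums, axis=0)
        df.index.name = "site"
        self.data = df

    @property
    def sites(self) -> list:
        return list(self.data.index)

    @property
    def species(self) -> list:
        return list(self.data.columns)

    @property
    def n_sites(self) -> int:
        return len(self.data.index)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def read_cover_matrix(path, delimiter: str = ",") -> CoverMatrix:
    """Read a wide site x species cover table (first column = site ids)."""
    df = pd.read_csv(path, sep=delimiter, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CoverMatrix(df.astype(float))


def write_cover_matrix(cover: CoverMatrix, path, delimiter: str = ",") -> None:
    cover.data.to_csv(path, sep=delimiter, index_label="site")


# ---------------------------------------------------------------------------
# TraitRecordTable
# ---------------------------------------------------------------------------


@dataclass
class TraitRecordTable:
    """Long-format individual trait records: site, species, individual, trait, value."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in TRAIT_RECORD_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"trait table missing columns: {missing}")
        df = df[TRAIT_RECORD_COLUMNS].copy()
        for c in ("site", "species", "trait"):
            df[c] = df[c].astype(str)
        df["value"] = df["value"].astype(float)
        if not np.isfinite(df["value"].to_numpy()).all():
            raise ValidationError("trait values contain non-finite entries")
        if (df["value"] <= 0).any():
            n = int((df["value"] <= 0).sum())
            raise ValidationError(f"{n} non-positive trait values")
        frac = df["trait"].str.lower().isin(FRACTION_TRAITS)
        if (df.loc[frac, "value"] > 1).any():
            raise ValidationError("mass-fraction trait values must lie in (0, 1]")
        key = df[["site", "species", "individual", "trait"]]
        if key.duplicated().any():
            raise ValidationError("duplicate (site, species, individual, trait) records")
        self.data = df

    @property
    def traits(self) -> list:
        return sorted(self.data["trait"].unique())

    @property
    def sites(self) -> list:
        return sorted(self.data["site"].unique())


def read_trait_records(path, delimiter: str = ",") -> TraitRecordTable:
    return TraitRecordTable(
        pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    )


def write_trait_records(traits: TraitRecordTable, path, delimiter: str = ",") -> None:
    traits.data.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Site-specific and global species means
# ---------------------------------------------------------------------------


@dataclass
class SiteSpeciesMeans:
    """Arithmetic mean trait value per (site, species, trait) where sampled."""

    data: pd.DataFrame  # columns: site, species, trait, mean, n_individuals

    def pivot(self, trait: str) -> pd.DataFrame:
        """Site x species matrix of means for one trait; NaN where unsampled."""
        sub = self.data[self.data["trait"] == trait]
        if sub.empty:
            raise KeyError(f"trait {trait!r} not present")
        return sub.pivot(index="site", columns="species", values="mean")

    @property
    def traits(self) -> list:
        return sorted(self.data["trait"].unique())

    def sampled(self, trait: str) -> pd.DataFrame:
        return self.pivot(trait).notna()


@dataclass
class GlobalSpeciesMeans:
    """One mean per (species, trait)."""

    data: pd.DataFrame  # columns: species, trait, mean

    def series(self, trait: str) -> pd.Series:
        sub = self.data[self.data["trait"] == trait]
        if sub.empty:
            raise KeyError(f"trait {trait!r} not present")
        return sub.set_index("species")["mean"]


def _shifted_group_mean(df: pd.DataFrame, keys: list, value: str) -> pd.DataFrame:
    """Group means computed as first + mean(x - first).

    The shift reduces cancellation error and makes the mean of identical
    values exactly that value (a plain sum-and-divide can be off by an ulp).
    """
    grp = df.groupby(keys, sort=True)[value]
    resid = df[value] - grp.transform("first")
    agg = resid.groupby([df[k] for k in keys], sort=True).agg(["mean", "size"])
    out = agg.rename(columns={"size": "n"})
    out["mean"] = grp.first() + out["mean"]
    return out.reset_index()


def site_species_means(traits: TraitRecordTable) -> SiteSpeciesMeans:
    """Average individual records to site-specific species mean trait values."""
    grouped = _shifted_group_mean(
        traits.data, ["site", "species", "trait"], "value"
    ).rename(columns={"n": "n_individuals"})
    grouped = grouped[["site", "species", "trait", "mean", "n_individuals"]]
    return SiteSpeciesMeans(grouped)


def global_species_means(
    ssm: SiteSpeciesMeans,
    method: str = "site_means",
    records: TraitRecordTable | None = None,
) -> GlobalSpeciesMeans:
    """Species-level means across all sites where the species was measured.

    ``method="site_means"`` (default) averages the site-specific means with
    one vote per site, making the result insensitive to unequal numbers of
    individuals per site.  ``method="pooled"`` averages the raw individual
    records instead and requires ``records``.
    """
    if method == "site_means":
        out = _shifted_group_mean(ssm.data, ["species", "trait"], "mean")
        out = out.rename(columns={"mean": "mean"})[["species", "trait", "mean"]]
    elif method == "pooled":
        if records is None:
            raise ValueError("method='pooled' requires the raw TraitRecordTable")
        out = _shifted_group_mean(records.data, ["species", "trait"], "value")
        out = out[["species", "trait", "mean"]]
    else:
        raise ValueError(f"unknown method {method!r}")
    return GlobalSpeciesMeans(out)


# ---------------------------------------------------------------------------
# EnvironmentTable
# ---------------------------------------------------------------------------


@dataclass
class EnvironmentTable:
    """Site x environmental-variable table with per-variable log-transform flags."""

    data: pd.DataFrame
    log_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "site identifiers")
        _check_unique(df.columns, "variable names")
        df = df.astype(float)
        for var, flag in self.log_flags.items():
            if not flag:
                continue
            if var not in df.columns:
                raise ValidationError(f"log-transform flag for unknown variable {var!r}")
            if (df[var] <= 0).any():
                raise ValidationError(
                    f"variable {var!r} flagged for log transform has non-positive values"
                )
        df.index.name = "site"
        self.data = df

    @property
    def sites(self) -> list:
        return list(self.data.index)

    @property
    def variables(self) -> list:
        return list(self.data.columns)

    def transformed(self, variables=None) -> pd.DataFrame:
        """Return the table with flagged variables log-transformed."""
        cols = list(variables) if variables is not None else self.variables
        unknown = [v for v in cols if v not in self.data.columns]
        if unknown:
            raise ValidationError(f"unknown environmental variables: {unknown}")
        df = self.data[cols].copy()
        for var in cols:
            if self.log_flags.get(var, False):
                df[var] = np.log(df[var])
        return df

    def scaled(self, variables=None) -> pd.DataFrame:
        """Z-score (mean 0, population sd 1) the transformed variables."""
        df = self.transformed(variables)
        sd = df.std(axis=0, ddof=0)
        zero = sd[sd == 0]
        if len(zero):
            raise ValidationError(
                f"zero-variance environmental variable(s): {list(zero.index)}"
            )
        return (df - df.mean(axis=0)) / sd

    def subset_complete(self, variables) -> "EnvironmentTable":
        df = self.data[list(variables)]
        if df.isna().any().any():
            raise ValidationError("missing environmental values for requested variables")
        return EnvironmentTable(df, {v: self.log_flags.get(v, False) for v in variables})


def read_environment(path, delimiter: str = ",", log_vars=()) -> EnvironmentTable:
    df = pd.read_csv(path, sep=delimiter, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    return EnvironmentTable(df, {v: True for v in log_vars})


def write_environment(env: EnvironmentTable, path, delimiter: str = ",") -> None:
    env.data.to_csv(path, sep=delimiter, index_label="site")


# ---------------------------------------------------------------------------
# SiteCoordinates
# ---------------------------------------------------------------------------


@dataclass
class SiteCoordinates:
    """Latitude/longitude per site, decimal degrees."""

    data: pd.DataFrame  # index site, columns lat, lon

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "site identifiers")
        if not {"lat", "lon"}.issubset(df.columns):
            raise ValidationError("coordinates need 'lat' and 'lon' columns")
        df = df[["lat", "lon"]].astype(float)
        if ((df["lat"] < -90) | (df["lat"] > 90)).any():
            raise ValidationError("latitude outside [-90, 90]")
        if ((df["lon"] < -180) | (df["lon"] > 180)).any():
            raise ValidationError("longitude outside [-180, 180]")
        df.index.name = "site"
        self.data = df

    @property
    def sites(self) -> list:
        return list(self.data.index)


def read_coordinates(path, delimiter: str = ",") -> SiteCoordinates:
    df = pd.read_csv(path, sep=delimiter, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    return SiteCoordinates(df)


def write_coordinates(coords: SiteCoordinates, path, delimiter: str = ",") -> None:
    coords.data.to_csv(path, sep=delimiter, index_label="site")
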