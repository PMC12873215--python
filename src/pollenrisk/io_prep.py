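"""Tabular input/output, abundance and prevalence filtering, climate joins.

The canonical in-memory representation of compositions is a *long* pandas
DataFrame with the fixed columns ``sample_id, site_id, year, month, round,
taxon_id, rra``; relative read abundances (RRA) of a sample sum to 1.  A wide
dialect (one column per taxon) is accepted on read and pivoted to long form.

The preparation chain mirrors standard pollen-metabarcoding practice:

1. aggregate synonymous taxa (e.g. multiple sequence variants of a species),
2. drop taxa contributing < 1% to a sample (noise floor) and renormalise,
3. retain only taxa observed at >5 distinct sites and in >=10 samples,
4. attach each sample's monthly climate and site coordinates.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "COMPOSITION_COLUMNS",
    "TAXON_COLUMNS",
    "SITE_COLUMNS",
    "CLIMATE_COLUMNS",
    "ParseError",
    "JoinError",
    "read_composition_table",
    "write_composition_table",
    "read_taxon_table",
    "read_site_table",
    "read_climate_table",
    "aggregate_taxa",
    "apply_rra_filter",
    "prevalence_filter",
    "filter_to_taxa",
    "join_climate",
    "sample_table",
]

logger = logging.getLogger(__name__)

COMPOSITION_COLUMNS = ["sample_id", "site_id", "year", "month", "round", "taxon_id", "rra"]
TAXON_COLUMNS = ["taxon_id", "family", "crop_flag"]
SITE_COLUMNS = ["site_id", "latitude", "longitude"]
CLIMATE_COLUMNS = ["site_id", "year", "month", "t_mean", "p_sum"]

SAMPLE_KEY = ["sample_id", "site_id", "year", "month", "round"]


class ParseError(ValueError):
    """A table violates the documented schema; the message names the rows."""


class JoinError(KeyError):
    """A sample lacks its climate record or site; the message lists keys."""


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")


def read_composition_table(path: str | Path, dialect: str = "long", sep: str = "\t") -> pd.DataFrame:
    """Read a composition table in long (canonical) or wide dialect.

    Wide tables carry the sample-key columns plus one numeric column per
    taxon and are melted to long form (zero entries dropped).  Validation
    rejects missing columns, non-numeric or negative abundances and duplicate
    (sample, taxon) rows, naming the offending rows.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    if dialect == "wide":
        _require_columns(df, SAMPLE_KEY, path)
        taxon_cols = [c for c in df.columns if c not in SAMPLE_KEY]
        df = df.melt(id_vars=SAMPLE_KEY, value_vars=taxon_cols, var_name="taxon_id", value_name="rra")
        df = df[df["rra"] != 0.0].reset_index(drop=True)
    elif dialect == "long":
        _require_columns(df, COMPOSITION_COLUMNS, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    rra = pd.to_numeric(df["rra"], errors="coerce")
    bad = df.index[rra.isna()]
    if len(bad):
        raise ParseError(f"{path}: non-numeric rra in rows {list(bad[:5])}")
    df["rra"] = rra
    neg = df.index[df["rra"] < 0]
    if len(neg):
        raise ParseError(f"{path}: negative rra in rows {list(neg[:5])}")
    dup = df.duplicated(subset=["sample_id", "taxon_id"])
    if dup.any():
        raise ParseError(f"{path}: duplicate (sample_id, taxon_id) rows {list(df.index[dup][:5])}")
    # preserve input sample order
    return df[COMPOSITION_COLUMNS].reset_index(drop=True)


def write_composition_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    df[COMPOSITION_COLUMNS].to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_taxon_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    _require_columns(df, TAXON_COLUMNS, path)
    if df["taxon_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate taxon_id")
    empty_fam = df["family"].isna() | (df["family"].astype(str).str.len() == 0)
    if empty_fam.any():
        raise ParseError(f"{path}: empty family in rows {list(df.index[empty_fam][:5])}")
    df["crop_flag"] = df["crop_flag"].astype(bool)
    return df


def read_site_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    _require_columns(df, SITE_COLUMNS, path)
    if df["site_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate site_id")
    return df


def read_climate_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    _require_columns(df, CLIMATE_COLUMNS, path)
    if df.duplicated(subset=["site_id", "year", "month"]).any():
        raise ParseError(f"{path}: duplicate (site_id, year, month) records")
    if (df["p_sum"] < 0).any():
        raise ParseError(f"{path}: negative p_sum")
    return df


def aggregate_taxa(comp: pd.DataFrame, synonym_map: Mapping[str, str]) -> pd.DataFrame:
    """Sum abundances of taxon ids mapping to the same canonical id.

    Ids absent from ``synonym_map`` map to themselves.  Total abundance per
    sample is conserved exactly (pure regrouping).
    """
    out = comp.copy()
    out["taxon_id"] = out["taxon_id"].map(lambda t: synonym_map.get(t, t))
    grouped = (
        out.groupby(SAMPLE_KEY + ["taxon_id"], as_index=False, sort=False)["rra"].sum()
    )
    return grouped[COMPOSITION_COLUMNS].reset_index(drop=True)


def apply_rra_filter(
    comp: pd.DataFrame, threshold: float = 0.01, renormalise: bool = True
) -> tuple[pd.DataFrame, list[str]]:
    """Drop entries with RRA below ``threshold``; optionally renormalise.

    Entries strictly below the threshold (default 1%) are removed.  With
    ``renormalise`` the surviving entries of each sample are rescaled to sum
    to 1, which preserves their relative ratios.  Samples losing every taxon
    are excluded and returned as the second element (logged, not an error).
    """
    if not (0.0 <= threshold < 1.0):
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    kept = comp[comp["rra"] >= threshold].copy()
    emptied = sorted(set(comp["sample_id"]) - set(kept["sample_id"]))
    if emptied:
        logger.warning("rra filter emptied %d sample(s): %s", len(emptied), emptied[:10])
    if renormalise and len(kept):
        totals = kept.groupby("sample_id")["rra"].transform("sum")
        kept["rra"] = kept["rra"] / totals
    return kept.reset_index(drop=True), emptied


def prevalence_filter(
    comp: pd.DataFrame, min_sites: int = 6, min_samples: int = 10
) -> tuple[set[str], pd.DataFrame]:
    """Retain taxa observed at >= ``min_sites`` sites and in >= ``min_samples`` samples.

    Counts are taken on the table as given (normally after the 1% filter).
    Returns the retained taxon-id set and a per-taxon report with columns
    ``taxon_id, n_sites, n_samples, retained``.
    """
    g = comp.groupby("taxon_id")
    report = pd.DataFrame(
        {
            "n_sites": g["site_id"].nunique(),
            "n_samples": g["sample_id"].nunique(),
        }
    ).reset_index()
    report["retained"] = (report["n_sites"] >= min_sites) & (report["n_samples"] >= min_samples)
    report = report.sort_values("taxon_id", kind="stable").reset_index(drop=True)
    retained = set(report.loc[report["retained"], "taxon_id"])
    return retained, report


def filter_to_taxa(comp: pd.DataFrame, taxa_ids: Iterable[str]) -> pd.DataFrame:
    """Restrict a composition table to the given taxa (no renormalisation).

    Downstream risk aggregation works on the retained-taxon abundance mass,
    so excluded taxa leave both numerator and denominator.
    """
    keep = set(taxa_ids)
    return comp[comp["taxon_id"].isin(keep)].reset_index(drop=True)


def sample_table(comp: pd.DataFrame) -> pd.DataFrame:
    """One row per sample with its key columns, in first-appearance order."""
    return comp[SAMPLE_KEY].drop_duplicates("sample_id").reset_index(drop=True)


def join_climate(
    comp: pd.DataFrame, climate: pd.DataFrame, sites: pd.DataFrame
) -> pd.DataFrame:
    """Attach each row's monthly climate and site coordinates.

    Joins on (site_id, year, month) against the climate table and on site_id
    against the site table; rounds within a month share the month's record.
    Missing keys raise :class:`JoinError` listing them.
    """
    merged = comp.merge(climate, on=["site_id", "year", "month"], how="left", validate="m:1")
    miss = merged["t_mean"].isna()
    if miss.any():
        keys = merged.loc[miss, ["site_id", "year", "month"]].drop_duplicates()
        raise JoinError(f"missing climate records for {keys.to_dict('records')[:10]}")
    merged = merged.merge(sites[SITE_COLUMNS], on="site_id", how="left", validate="m:1")
    miss = merged["latitude"].isna()
    if miss.any():
        keys = sorted(merged.loc[miss, "site_id"].unique())
        raise JoinError(f"missing site coordinates for {keys[:10]}")
    return merged
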