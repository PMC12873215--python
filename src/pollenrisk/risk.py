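"""Scenario grid, percentile-exceedance risk classification and aggregation.

A scenario is a uniform perturbation (delta_t, delta_p) applied to a sample's
observed monthly climate: warming from 0 to +5 deg C in 0.5 steps, drying
from 0 to -50 mm/month in -5 steps (11 x 11 = 121 scenarios including the
unperturbed baseline).  For each taxon present in a sample, the perturbed
temperature is compared with the upper tail of the taxon's temperature niche
(low <= p90 < moderate <= p95 < high <= p99 < critical) and the perturbed
precipitation — clamped at 0 mm — with the lower tail of its precipitation
niche (low >= p10 > moderate >= p05 > high >= p01 > critical).  The combined
class is the ordinal maximum of the two axes, so a taxon is "at risk"
(moderate or worse) as soon as either axis exceeds its threshold.
"""

from __future__ import annotations

import enum
import logging
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .niche import NicheProfile

__all__ = [
    "RiskClass",
    "Scenario",
    "scenario_grid",
    "classify_temperature_risk",
    "classify_precipitation_risk",
    "attach_thresholds",
    "classify_records",
    "assess_sample",
    "aggregate_risk",
    "sample_at_risk_fraction",
]

logger = logging.getLogger(__name__)


class RiskClass(enum.IntEnum):
    """Ordinal exceedance risk level; 'at risk' means moderate or worse."""

    LOW = 0
    MODERATE = 1
    HIGH = 2
    CRITICAL = 3

    @property
    def at_risk(self) -> bool:
        return self >= RiskClass.MODERATE


class Scenario(NamedTuple):
    """Uniform climate offset: warming (deg C) and precipitation change (mm/month)."""

    delta_t: float
    delta_p: float


def scenario_grid(
    dt_max: float = 5.0, dt_step: float = 0.5, dp_min: float = -50.0, dp_step: float = 5.0
) -> list[Scenario]:
    """Full warming x drying cross product, baseline (0, 0) included.

    Default 11 x 11 = 121 scenarios; ordered delta_t-major ascending with
    delta_p descending towards the driest offset.
    """
    n_t = int(round(dt_max / dt_step)) + 1
    n_p = int(round(-dp_min / dp_step)) + 1
    dts = np.round(np.arange(n_t) * dt_step, 6)
    dps = np.round(-np.arange(n_p) * dp_step, 6)
    return [Scenario(float(dt), float(dp)) for dt in dts for dp in dps]


def _thresholds_of(profile) -> dict[str, float]:
    return profile.thresholds if isinstance(profile, NicheProfile) else dict(profile)


def classify_temperature_risk(value: float, profile) -> RiskClass:
    """Upper-tail classification: value <= p90 is low, > p99 critical."""
    if isinstance(profile, NicheProfile) and profile.axis != "temperature":
        raise ValueError(f"profile axis {profile.axis!r} is not temperature")
    t = _thresholds_of(profile)
    return RiskClass(int(value > t["p90"]) + int(value > t["p95"]) + int(value > t["p99"]))


def classify_precipitation_risk(value: float, profile) -> RiskClass:
    """Lower-tail classification: value >= p10 is low, < p01 critical."""
    if isinstance(profile, NicheProfile) and profile.axis != "precipitation":
        raise ValueError(f"profile axis {profile.axis!r} is not precipitation")
    t = _thresholds_of(profile)
    return RiskClass(int(value < t["p10"]) + int(value < t["p05"]) + int(value < t["p01"]))


def attach_thresholds(
    joined: pd.DataFrame,
    profiles: dict[tuple[str, str], NicheProfile],
    taxa: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build the classification record table: one row per sample x taxon.

    Joins each composition row with its taxon's six niche thresholds (and,
    when a taxon table is given, family and crop flag).  Taxa lacking a
    profile on either axis are dropped with a log message — they never enter
    risk numerators or denominators.
    """
    rows = []
    for (tid, axis), prof in profiles.items():
        row = {"taxon_id": tid, "axis": axis}
        row.update(prof.thresholds)
        rows.append(row)
    thr = pd.DataFrame(rows)
    t_thr = thr[thr["axis"] == "temperature"][["taxon_id", "p90", "p95", "p99"]]
    p_thr = thr[thr["axis"] == "precipitation"][["taxon_id", "p01", "p05", "p10"]]
    profiled = set(t_thr["taxon_id"]) & set(p_thr["taxon_id"])
    dropped = sorted(set(joined["taxon_id"]) - profiled)
    if dropped:
        logger.info("dropping %d taxa without full profiles: %s", len(dropped), dropped[:10])
    records = joined[joined["taxon_id"].isin(profiled)].copy()
    records = records.merge(t_thr, on="taxon_id").merge(p_thr, on="taxon_id")
    if taxa is not None:
        records = records.merge(taxa[["taxon_id", "family", "crop_flag"]], on="taxon_id", how="left")
    return records.reset_index(drop=True)


def classify_records(records: pd.DataFrame, scenario: Scenario) -> pd.DataFrame:
    """Vectorised classification of every record under one scenario.

    Returns a copy with perturbed climate and ``t_class``, ``p_class``,
    ``combined_class`` integer columns (values of :class:`RiskClass`).
    Perturbed precipitation is clamped at 0 mm.
    """
    out = records.copy()
    t, p = _perturb(records, scenario)
    tc, pc = _classify_arrays(records, t, p)
    out["t_pert"], out["p_pert"] = t, p
    out["t_class"], out["p_class"] = tc, pc
    out["combined_class"] = np.maximum(tc, pc)
    out["delta_t"], out["delta_p"] = scenario.delta_t, scenario.delta_p
    return out


def _perturb(records: pd.DataFrame, scenario: Scenario):
    t = records["t_mean"].to_numpy(dtype=float) + scenario.delta_t
    p = np.maximum(records["p_sum"].to_numpy(dtype=float) + scenario.delta_p, 0.0)
    return t, p


def _classify_arrays(records: pd.DataFrame, t: np.ndarray, p: np.ndarray):
    tc = (
        (t > records["p90"].to_numpy()).astype(np.int8)
        + (t > records["p95"].to_numpy())
        + (t > records["p99"].to_numpy())
    )
    pc = (
        (p < records["p10"].to_numpy()).astype(np.int8)
        + (p < records["p05"].to_numpy())
        + (p < records["p01"].to_numpy())
    )
    return tc, pc


def assess_sample(
    sample_records: pd.DataFrame,
    scenario: Scenario,
    profiles: dict[tuple[str, str], NicheProfile],
) -> pd.DataFrame:
    """Classify one joined sample's taxa under one scenario.

    ``sample_records`` are the joined composition rows of a single sample
    (with t_mean / p_sum attached); taxa without both profiles are skipped.
    Returns one row per classified taxon with per-axis and combined classes.
    """
    recs = attach_thresholds(sample_records, profiles)
    return classify_records(recs, scenario)


def aggregate_risk(
    classified: pd.DataFrame, group_by: Iterable[str] = ("latitude_band", "month", "crop_flag")
) -> pd.DataFrame:
    """RRA mass per risk class within groups, plus the at-risk proportion.

    ``latitude_band`` (floor of latitude in whole degrees) is derived on the
    fly if requested.  ``prop_at_risk`` is the summed RRA of classes moderate
    and worse over the group's total RRA.
    """
    work = classified
    group_by = list(group_by)
    if "latitude_band" in group_by and "latitude_band" not in work.columns:
        work = work.copy()
        work["latitude_band"] = np.floor(work["latitude"]).astype(int)
    g = work.groupby(group_by + ["combined_class"], observed=True)["rra"].sum().unstack(
        "combined_class", fill_value=0.0
    )
    for cls in RiskClass:
        if cls.value not in g.columns:
            g[cls.value] = 0.0
    g = g[[c.value for c in RiskClass]]
    g.columns = [f"rra_{c.name.lower()}" for c in RiskClass]
    total = g.sum(axis=1)
    at_risk = g[["rra_moderate", "rra_high", "rra_critical"]].sum(axis=1)
    g["total_rra"] = total
    g["prop_at_risk"] = np.where(total > 0, at_risk / total, 0.0)
    return g.reset_index()


def sample_at_risk_fraction(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-sample RRA-weighted at-risk proportion under one scenario."""
    return aggregate_risk(classified, group_by=["sample_id"])
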