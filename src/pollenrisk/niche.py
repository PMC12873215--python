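"""Realised climatic niche profiles from abundance-weighted kernel densities.

Each retained taxon's niche on one climate axis (monthly mean temperature or
accumulated precipitation) is estimated by pairing the taxon's relative read
abundance in every sample with that sample's climate value, and fitting a
one-dimensional Gaussian kernel density with the RRAs as weights.  The
resulting density is a distribution-free approximation of the conditions
under which the taxon was actually foraged, weighted by how much of it was
foraged.  Tail percentiles of the integrated density (1/5/10 and 90/95/99)
become the exceedance thresholds used by the risk engine.

Bandwidth defaults to Silverman's rule evaluated at the weighted sample's
effective sample size  n_eff = (sum w)^2 / sum w^2;  Scott's rule and a fixed
bandwidth (in axis units) are available.  The precipitation axis has no
negative support: its grid is truncated at 0 and the density renormalised.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid, trapezoid

__all__ = [
    "AXES",
    "AXIS_COLUMNS",
    "PERCENTILES",
    "NicheProfile",
    "DegenerateProfileError",
    "collect_weighted_observations",
    "effective_sample_size",
    "weighted_quantile",
    "silverman_bandwidth",
    "scott_bandwidth",
    "fit_weighted_kde",
    "percentile_thresholds",
    "fit_niche_profiles",
    "profiles_to_table",
]

logger = logging.getLogger(__name__)

AXES = ("temperature", "precipitation")
AXIS_COLUMNS = {"temperature": "t_mean", "precipitation": "p_sum"}
PERCENTILES = (1, 5, 10, 90, 95, 99)

_SQRT2PI = math.sqrt(2.0 * math.pi)


class DegenerateProfileError(ValueError):
    """All observation values identical — no density can be fitted."""


@dataclass
class NicheProfile:
    """Fitted niche density for one taxon on one climate axis."""

    taxon_id: str
    axis: str
    grid: np.ndarray
    density: np.ndarray
    thresholds: dict[str, float]
    n_obs: int
    n_sites: int
    bandwidth: float
    cdf: np.ndarray = field(repr=False, default=None)


def collect_weighted_observations(
    taxon_id: str, joined: pd.DataFrame, axis: str = "temperature"
) -> pd.DataFrame:
    """(value, weight) pairs for one taxon: sample climate value, taxon RRA.

    One observation per sample containing the taxon; two rounds at a site in
    different months contribute separately.  Raises if the taxon is absent.
    """
    col = AXIS_COLUMNS[axis]
    rows = joined[(joined["taxon_id"] == taxon_id) & (joined["rra"] > 0)]
    if rows.empty:
        raise ValueError(f"taxon {taxon_id!r} absent from all samples")
    return pd.DataFrame(
        {
            "value": rows[col].to_numpy(dtype=float),
            "weight": rows["rra"].to_numpy(dtype=float),
            "sample_id": rows["sample_id"].to_numpy(),
            "site_id": rows["site_id"].to_numpy(),
        }
    )


def effective_sample_size(weights: np.ndarray) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2."""
    w = np.asarray(weights, dtype=float)
    return float(w.sum() ** 2 / (w**2).sum())


def weighted_quantile(values, weights, q) -> np.ndarray | float:
    """Weighted empirical quantile(s), midpoint-interpolated.

    The inverse of the step CDF with each sorted observation placed at the
    midpoint of its weight increment; reduces to the usual interpolated
    percentile for equal weights.  ``q`` in [0, 1].
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cw = np.cumsum(w)
    midpoints = (cw - 0.5 * w) / cw[-1]
    return np.interp(q, midpoints, v)


def _weighted_sd(values: np.ndarray, weights: np.ndarray) -> float:
    w = weights / weights.sum()
    mu = float(w @ values)
    return float(math.sqrt(max(w @ (values - mu) ** 2, 0.0)))


def silverman_bandwidth(values, weights) -> float:
    """0.9 * min(sd, IQR/1.34) * n_eff^(-1/5) on the weighted sample."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    sd = _weighted_sd(v, w)
    q75, q25 = weighted_quantile(v, w, [0.75, 0.25])
    iqr = q75 - q25
    sigma = min(sd, iqr / 1.34) if iqr > 0 else sd
    if sigma <= 0:
        raise DegenerateProfileError("zero spread in observations")
    return 0.9 * sigma * effective_sample_size(w) ** (-0.2)


def scott_bandwidth(values, weights) -> float:
    """1.06 * sd * n_eff^(-1/5) on the weighted sample."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    sd = _weighted_sd(v, w)
    if sd <= 0:
        raise DegenerateProfileError("zero spread in observations")
    return 1.06 * sd * effective_sample_size(w) ** (-0.2)


def fit_weighted_kde(
    observations: pd.DataFrame,
    *,
    axis: str = "temperature",
    taxon_id: str = "",
    bandwidth_rule: str = "silverman",
    bandwidth: float | None = None,
    grid_points: int = 512,
    grid_pad: float = 3.0,
    weighted: bool = True,
) -> NicheProfile:
    """Fit the weighted Gaussian KDE and extract percentile thresholds.

    ``observations`` needs columns ``value`` and ``weight`` (plus optionally
    ``site_id`` for the profile's site count).  ``bandwidth_rule`` is one of
    ``silverman``, ``scott`` or ``fixed`` (the latter takes ``bandwidth`` in
    axis units).  ``weighted=False`` ignores the RRA weights (diagnostic
    mode).  The grid spans the data range padded by ``grid_pad`` bandwidths,
    truncated at 0 for the precipitation axis, and the density is
    renormalised to integrate to 1 on the grid.
    """
    if axis not in AXES:
        raise ValueError(f"unknown axis {axis!r}")
    v = observations["value"].to_numpy(dtype=float)
    w = observations["weight"].to_numpy(dtype=float)
    if not weighted:
        w = np.ones_like(v)
    if len(v) < 2 or np.unique(v).size < 2:
        raise DegenerateProfileError(
            f"taxon {taxon_id!r} axis {axis}: need >=2 distinct values, got {np.unique(v).size}"
        )
    if np.any(w <= 0):
        raise ValueError("all weights must be positive")
    if bandwidth_rule == "silverman":
        h = silverman_bandwidth(v, w)
    elif bandwidth_rule == "scott":
        h = scott_bandwidth(v, w)
    elif bandwidth_rule == "fixed":
        if bandwidth is None or bandwidth <= 0:
            raise ValueError("fixed rule requires a positive bandwidth")
        h = float(bandwidth)
    else:
        raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")

    lo = v.min() - grid_pad * h
    hi = v.max() + grid_pad * h
    if axis == "precipitation":
        lo = max(lo, 0.0)
    grid = np.linspace(lo, hi, grid_points)
    wn = w / w.sum()
    # sum of Gaussian kernels, chunked over observations to bound memory
    density = np.zeros_like(grid)
    for start in range(0, len(v), 4096):
        vv = v[start : start + 4096, None]
        ww = wn[start : start + 4096, None]
        density += (ww * np.exp(-0.5 * ((grid[None, :] - vv) / h) ** 2)).sum(axis=0)
    density /= h * _SQRT2PI
    mass = trapezoid(density, grid)
    if mass <= 0:
        raise DegenerateProfileError(f"taxon {taxon_id!r} axis {axis}: zero density mass")
    density /= mass

    cdf = cumulative_trapezoid(density, grid, initial=0.0)
    cdf /= cdf[-1]
    thresholds = percentile_thresholds(grid, density, cdf=cdf)
    n_sites = observations["site_id"].nunique() if "site_id" in observations else 0
    return NicheProfile(
        taxon_id=taxon_id,
        axis=axis,
        grid=grid,
        density=density,
        thresholds=thresholds,
        n_obs=len(v),
        n_sites=int(n_sites),
        bandwidth=h,
        cdf=cdf,
    )


def percentile_thresholds(
    grid: np.ndarray, density: np.ndarray, percentiles=PERCENTILES, cdf: np.ndarray | None = None
) -> dict[str, float]:
    """Invert the trapezoid-integrated CDF at the given percentiles.

    Returns e.g. ``{"p01": ..., "p05": ..., ..., "p99": ...}``; linear
    interpolation between grid nodes.  The density must be normalised on the
    grid (checked to 1e-6).
    """
    if cdf is None:
        cdf = cumulative_trapezoid(density, grid, initial=0.0)
        if abs(cdf[-1] - 1.0) > 1e-6:
            raise ValueError(f"density does not integrate to 1 on grid (mass={cdf[-1]:.6g})")
        cdf = cdf / cdf[-1]
    return {f"p{q:02d}": float(np.interp(q / 100.0, cdf, grid)) for q in percentiles}


def fit_niche_profiles(
    joined: pd.DataFrame,
    taxa_ids=None,
    *,
    bandwidth_rule: str = "silverman",
    bandwidth: float | None = None,
    grid_points: int = 512,
    grid_pad: float = 3.0,
    weighted: bool = True,
) -> tuple[dict[tuple[str, str], NicheProfile], list[tuple[str, str]]]:
    """Fit temperature and precipitation profiles for every taxon.

    Returns ``(profiles, skipped)`` where profiles maps (taxon_id, axis) to
    :class:`NicheProfile` and skipped lists the (taxon_id, axis) pairs
    rejected as degenerate (logged, not fatal).
    """
    if taxa_ids is None:
        taxa_ids = sorted(joined["taxon_id"].unique())
    profiles: dict[tuple[str, str], NicheProfile] = {}
    skipped: list[tuple[str, str]] = []
    pos = joined[joined["rra"] > 0]
    for axis in AXES:
        col = AXIS_COLUMNS[axis]
        grouped = {
            tid: g for tid, g in pos.groupby("taxon_id")[[col, "rra", "sample_id", "site_id"]]
        }
        for tid in taxa_ids:
            g = grouped.get(tid)
            if g is None:
                skipped.append((tid, axis))
                logger.warning("taxon %s absent; no %s profile", tid, axis)
                continue
            obs = g.rename(columns={col: "value", "rra": "weight"})
            try:
                profiles[(tid, axis)] = fit_weighted_kde(
                    obs,
                    axis=axis,
                    taxon_id=tid,
                    bandwidth_rule=bandwidth_rule,
                    bandwidth=bandwidth,
                    grid_points=grid_points,
                    grid_pad=grid_pad,
                    weighted=weighted,
                )
            except DegenerateProfileError as exc:
                skipped.append((tid, axis))
                logger.warning("degenerate profile skipped: %s", exc)
    return profiles, skipped


def profiles_to_table(profiles: dict[tuple[str, str], NicheProfile]) -> pd.DataFrame:
    """Flat per-profile table of thresholds and fit metadata."""
    rows = []
    for (tid, axis), prof in sorted(profiles.items()):
        row = {
            "taxon_id": tid,
            "axis": axis,
            "n_obs": prof.n_obs,
            "n_sites": prof.n_sites,
            "bandwidth": prof.bandwidth,
        }
        row.update(prof.thresholds)
        rows.append(row)
    return pd.DataFrame(rows)
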