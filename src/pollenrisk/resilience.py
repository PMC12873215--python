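"""Community resistance and resilience under combined climate scenarios.

For one sample under one scenario, with every profiled taxon classified on
both climate axes:

* resistance = 1 - S_risk / (S_no_risk + S_risk), where S_risk counts taxa
  whose combined class is at least moderate (at risk on either axis) and
  S_no_risk counts taxa classified low on both.  Taxon counts, not RRA.
* resilience = S_replacement / S_risk: the fraction of at-risk taxa for
  which a qualifying replacement taxon exists.

A replacement for an at-risk focal taxon must (1) occur within a search
radius (default 500 km great-circle) of the focal site, (2) be classified
low risk on *both* axes in at least one sample inside that radius under the
same scenario (evaluated at the candidate's own location), (3) belong to the
same plant family, and (4) not already be used as a replacement in the focal
sample.  At-risk taxa are processed greedily in descending focal-sample RRA
(ties lexicographic by taxon id); each picks its geographically nearest
qualifying candidate (ties lexicographic), making the search deterministic.

When a sample has no at-risk taxa, resilience is reported as 1.0 with a
``zero_risk`` flag by default (convention "one"); convention "exclude"
reports NaN instead.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

import numpy as np
import pandas as pd

from .risk import Scenario, classify_records

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_km",
    "site_distance_matrix",
    "compute_resistance",
    "compute_resilience",
    "find_replacements",
    "resilience_for_scenario",
    "resilience_surface",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km on a sphere of radius 6371 km.

    Accepts scalars or arrays (broadcast); symmetric, zero iff the
    coordinates coincide.  Latitudes outside [-90, 90] raise ValueError.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    if np.any(np.abs(lat1) > 90) or np.any(np.abs(lat2) > 90):
        raise ValueError("latitude out of [-90, 90]")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def site_distance_matrix(sites: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """All pairwise site distances; returns (site_id order, km matrix)."""
    lat = sites["latitude"].to_numpy(dtype=float)
    lon = sites["longitude"].to_numpy(dtype=float)
    D = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    return list(sites["site_id"]), np.asarray(D, dtype=float)


def compute_resistance(s_risk: int, s_no_risk: int) -> float:
    """1 - S_risk / (S_no_risk + S_risk); undefined for an empty community."""
    total = s_risk + s_no_risk
    if total == 0:
        raise ValueError("resistance undefined for a community with zero taxa")
    return 1.0 - s_risk / total


def compute_resilience(
    s_replacement: int, s_risk: int, zero_risk_convention: str = "one"
) -> float:
    """S_replacement / S_risk; the zero-risk case follows the configured convention."""
    if s_replacement > s_risk:
        raise ValueError(f"s_replacement={s_replacement} exceeds s_risk={s_risk}")
    if s_risk == 0:
        if zero_risk_convention == "one":
            return 1.0
        if zero_risk_convention == "exclude":
            return float("nan")
        raise ValueError(f"unknown zero-risk convention {zero_risk_convention!r}")
    return s_replacement / s_risk


def find_replacements(
    sample_id: str,
    classified: pd.DataFrame,
    taxa: pd.DataFrame,
    sites: pd.DataFrame,
    radius_km: float = 500.0,
) -> dict[str, str]:
    """Replacement map for one sample (reference implementation).

    ``classified`` is the full dataset classified under one scenario (output
    of :func:`pollenrisk.risk.classify_records` on records carrying a
    ``family`` column).  Returns {at-risk taxon_id -> replacement taxon_id};
    unreplaceable taxa are absent from the map.  The optimised per-scenario
    path in :func:`resilience_for_scenario` must agree with this function.
    """
    focal = classified[classified["sample_id"] == sample_id]
    if focal.empty:
        raise KeyError(f"sample {sample_id!r} not in classified records")
    site_coords = sites.set_index("site_id")[["latitude", "longitude"]]
    f_lat, f_lon = site_coords.loc[focal["site_id"].iloc[0]]
    fam_of = taxa.set_index("taxon_id")["family"]

    lowlow = classified[(classified["t_class"] == 0) & (classified["p_class"] == 0)]
    lowlow_sites = lowlow.groupby("taxon_id")["site_id"].agg(lambda s: sorted(set(s)))

    at_risk = focal[focal["combined_class"] >= 1].sort_values(
        ["rra", "taxon_id"], ascending=[False, True], kind="stable"
    )
    used: set[str] = set()
    mapping: dict[str, str] = {}
    for rec in at_risk.itertuples(index=False):
        fam = fam_of[rec.taxon_id]
        best: tuple[float, str] | None = None
        for cand, cand_sites in lowlow_sites.items():
            if cand == rec.taxon_id or cand in used or fam_of.get(cand) != fam:
                continue
            coords = site_coords.loc[cand_sites]
            d = haversine_km(f_lat, f_lon, coords["latitude"].to_numpy(), coords["longitude"].to_numpy())
            dmin = float(np.min(d))
            if dmin <= radius_km and (best is None or dmin < best[0]):
                best = (dmin, cand)
        if best is not None:
            mapping[rec.taxon_id] = best[1]
            used.add(best[1])
    return mapping


class _SearchIndex:
    """Scenario-independent precomputation for the fast replacement search."""

    def __init__(self, records: pd.DataFrame, taxa: pd.DataFrame, sites: pd.DataFrame):
        self.taxon_ids = sorted(records["taxon_id"].unique())
        self.site_ids, self.D = site_distance_matrix(sites)
        t_code = {t: i for i, t in enumerate(self.taxon_ids)}
        s_code = {s: i for i, s in enumerate(self.site_ids)}
        self.rec_taxon = records["taxon_id"].map(t_code).to_numpy(dtype=np.int32)
        self.rec_site = records["site_id"].map(s_code).to_numpy(dtype=np.int32)
        # same-family candidates per taxon, lexicographically ordered
        fam_of = taxa.set_index("taxon_id")["family"]
        by_family: dict[str, list[int]] = {}
        for t in self.taxon_ids:
            by_family.setdefault(fam_of[t], []).append(t_code[t])
        self.candidates = [
            [c for c in by_family[fam_of[t]] if c != t_code[t]] for t in self.taxon_ids
        ]
        # greedy processing order: sample-major, descending RRA, taxon id
        order = np.lexsort(
            (records["taxon_id"].to_numpy(), -records["rra"].to_numpy(), records["sample_id"].to_numpy())
        )
        self.order = order
        sample_sorted = records["sample_id"].to_numpy()[order]
        uniq, starts = np.unique(sample_sorted, return_index=True)
        # np.unique sorts, and sample_sorted is sorted, so starts are increasing
        self.sample_ids = list(uniq)
        self.bounds = np.append(starts, len(sample_sorted))


def resilience_for_scenario(
    classified: pd.DataFrame,
    taxa: pd.DataFrame,
    sites: pd.DataFrame,
    radius_km: float = 500.0,
    zero_risk_convention: str = "one",
    index: "_SearchIndex | None" = None,
    return_maps: bool = False,
):
    """Per-sample resistance/resilience for one classified scenario.

    Returns a DataFrame with one row per sample (``s_risk, s_no_risk,
    s_replacement, resistance, resilience, zero_risk``), and the per-sample
    replacement maps too when ``return_maps`` is set.
    """
    idx = index or _SearchIndex(classified, taxa, sites)
    n_taxa, n_sites = len(idx.taxon_ids), len(idx.site_ids)
    combined = classified["combined_class"].to_numpy()
    lowlow_mask = (classified["t_class"].to_numpy() == 0) & (classified["p_class"].to_numpy() == 0)

    L = np.zeros((n_taxa, n_sites), dtype=bool)
    L[idx.rec_taxon[lowlow_mask], idx.rec_site[lowlow_mask]] = True
    # nearest low/low occurrence of each taxon from each site
    ND = np.full((n_taxa, n_sites), np.inf)
    for t in range(n_taxa):
        cols = L[t]
        if cols.any():
            ND[t] = idx.D[:, cols].min(axis=1)
    nd = ND.tolist()  # python floats: fast scalar access in the greedy loop

    order = idx.order
    comb_o = combined[order].tolist()
    taxon_o = idx.rec_taxon[order].tolist()
    site_o = idx.rec_site[order].tolist()
    cands = idx.candidates
    radius = float(radius_km)

    rows = []
    maps: dict[str, dict[str, str]] = {}
    for k, sample in enumerate(idx.sample_ids):
        lo, hi = idx.bounds[k], idx.bounds[k + 1]
        s_total = hi - lo
        used: set[int] = set()
        assigned: dict[int, int] = {}
        s_risk = 0
        for j in range(lo, hi):
            if comb_o[j] >= 1:
                s_risk += 1
                f = taxon_o[j]
                s = site_o[j]
                best_d, best_c = math.inf, -1
                for c in cands[f]:
                    if c in used:
                        continue
                    d = nd[c][s]
                    if d <= radius and d < best_d:
                        best_d, best_c = d, c
                if best_c >= 0:
                    used.add(best_c)
                    assigned[f] = best_c
        s_no_risk = s_total - s_risk
        rows.append(
            {
                "sample_id": sample,
                "s_risk": s_risk,
                "s_no_risk": s_no_risk,
                "s_replacement": len(assigned),
                "resistance": compute_resistance(s_risk, s_no_risk),
                "resilience": compute_resilience(len(assigned), s_risk, zero_risk_convention),
                "zero_risk": s_risk == 0,
            }
        )
        if return_maps:
            maps[sample] = {
                idx.taxon_ids[f]: idx.taxon_ids[c] for f, c in assigned.items()
            }
    out = pd.DataFrame(rows)
    return (out, maps) if return_maps else out


def resilience_surface(
    records: pd.DataFrame,
    scenarios: Iterable[Scenario],
    taxa: pd.DataFrame,
    sites: pd.DataFrame,
    radius_km: float = 500.0,
    zero_risk_convention: str = "one",
) -> pd.DataFrame:
    """Resistance/resilience of every sample under every scenario.

    ``records`` is the threshold-attached record table (see
    :func:`pollenrisk.risk.attach_thresholds`); output has one row per
    sample x scenario, suitable for the resistance-vs-resilience density
    plane.
    """
    index = _SearchIndex(records, taxa, sites)
    frames = []
    for scn in scenarios:
        classified = classify_records(records, scn)
        res = resilience_for_scenario(
            classified, taxa, sites, radius_km, zero_risk_convention, index=index
        )
        res.insert(1, "delta_t", scn.delta_t)
        res.insert(2, "delta_p", scn.delta_p)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
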