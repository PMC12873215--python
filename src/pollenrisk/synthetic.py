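"""Seeded synthetic pollen-foraging datasets.

Emulates a continental pollen-metabarcoding survey: stationary apiary sites
spread over a latitudinal gradient, monthly site climate (mean temperature,
accumulated precipitation), plant taxa with unimodal climatic preferences,
and compositional samples (relative read abundances on the simplex) collected
in repeated within-month rounds.  Every generator is deterministic for a
fixed seed; a dataset-level seed is split into independent child streams so
stages can also be reproduced in isolation.

The generator is an emulation of the study design, not a model of honey-bee
foraging behaviour: realised compositions are driven purely by climatic
suitability and a per-taxon propensity, plus Dirichlet sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_sites",
    "generate_climate",
    "generate_taxa",
    "generate_compositions",
    "expected_composition",
    "generate_dataset",
]

#: months of the sampling campaign (May–August)
DEFAULT_MONTHS: tuple[tuple[int, int], ...] = tuple((2023, m) for m in (5, 6, 7, 8))


class ConfigurationError(ValueError):
    """Invalid generator settings (bad ranges, empty inputs, ...)."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Default study conditions for the bundled fixture.

    310 sites x 4 months x 2 rounds = 2480 samples over 150 taxa in 30
    families, 10% of taxa flagged as crops with a May mass-flowering pulse.
    """

    n_sites: int = 310
    lat_range: tuple[float, float] = (35.0, 65.0)
    lon_range: tuple[float, float] = (-10.0, 30.0)
    n_taxa: int = 150
    n_families: int = 30
    crop_fraction: float = 0.1
    months: tuple[tuple[int, int], ...] = DEFAULT_MONTHS
    rounds_per_month: int = 2
    concentration: float = 50.0
    crop_pulse_month: int = 5
    crop_pulse_factor: float = 10.0
    seed: int = 0


@dataclass
class SyntheticDataset:
    """Bundle of the four generated tables plus the generating parameters."""

    sites: pd.DataFrame
    climate: pd.DataFrame
    taxa: pd.DataFrame
    compositions: pd.DataFrame
    config: SyntheticConfig = field(default_factory=SyntheticConfig)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all tables as TSV plus a small manifest; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("sites", "climate", "taxa", "compositions"):
            p = outdir / f"{name}.tsv"
            getattr(self, name).to_csv(p, sep="\t", index=False, float_format="%.10g")
            paths[name] = p
        manifest = outdir / "manifest.tsv"
        pd.DataFrame(
            {"key": list(vars(self.config)), "value": [repr(v) for v in vars(self.config).values()]}
        ).to_csv(manifest, sep="\t", index=False)
        paths["manifest"] = manifest
        return paths


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_sites(
    n_sites: int,
    lat_range: tuple[float, float] = (35.0, 65.0),
    lon_range: tuple[float, float] = (-10.0, 30.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Uniformly scattered apiary sites on a latitude x longitude band.

    Returns a table with columns ``site_id, latitude, longitude, country``.
    The country label is a coarse 5-degree grid-cell tag; it is cosmetic and
    plays no role downstream.
    """
    if n_sites < 1:
        raise ConfigurationError(f"n_sites must be >= 1, got {n_sites}")
    if not (lat_range[0] < lat_range[1]) or not (lon_range[0] < lon_range[1]):
        raise ConfigurationError(f"invalid ranges lat={lat_range} lon={lon_range}")
    rng = _rng(seed)
    lat = rng.uniform(*lat_range, n_sites)
    lon = rng.uniform(*lon_range, n_sites)
    width = len(str(n_sites))
    return pd.DataFrame(
        {
            "site_id": [f"S{i:0{width}d}" for i in range(1, n_sites + 1)],
            "latitude": lat,
            "longitude": lon,
            "country": [
                f"G{int(np.floor(la / 5.0)):+03d}{int(np.floor(lo / 5.0)):+03d}"
                for la, lo in zip(lat, lon)
            ],
        }
    )


def generate_climate(
    sites: pd.DataFrame,
    months: Sequence[tuple[int, int]] = DEFAULT_MONTHS,
    seed: int = 0,
    *,
    t_intercept: float = 36.0,
    t_lapse: float = 0.45,
    t_amplitude: float = 8.0,
    t_peak_month: int = 7,
    t_noise_sd: float = 1.5,
    p_intercept: float = -10.0,
    p_lat_slope: float = 1.3,
    p_noise_sd: float = 15.0,
) -> pd.DataFrame:
    """Monthly site climate: latitude-lapsed seasonal temperature, wetter north.

    One record per site x (year, month).  Temperature (deg C) is
    ``intercept - lapse*latitude + amplitude*cos(2*pi*(month - peak)/12)`` plus
    Gaussian noise; precipitation (mm/month) is a latitude trend plus noise,
    clipped at zero.  Defaults give roughly 10–28 deg C and 20–110 mm over a
    35–65 deg N May–August campaign.
    """
    if len(sites) == 0 or len(months) == 0:
        raise ConfigurationError("sites and months must be non-empty")
    rng = _rng(seed)
    rows = []
    lat = sites["latitude"].to_numpy()
    for year, month in months:
        seas = t_amplitude * np.cos(2.0 * np.pi * (month - t_peak_month) / 12.0)
        t = t_intercept - t_lapse * lat + seas + rng.normal(0.0, t_noise_sd, len(sites))
        p = p_intercept + p_lat_slope * lat + rng.normal(0.0, p_noise_sd, len(sites))
        rows.append(
            pd.DataFrame(
                {
                    "site_id": sites["site_id"].to_numpy(),
                    "year": year,
                    "month": month,
                    "t_mean": t,
                    "p_sum": np.clip(p, 0.0, None),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def generate_taxa(
    n_taxa: int,
    n_families: int = 30,
    crop_fraction: float = 0.1,
    t_mean_range: tuple[float, float] = (10.0, 28.0),
    p_mean_range: tuple[float, float] = (20.0, 90.0),
    t_sd: float = 3.0,
    p_sd: float = 25.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Plant taxa with Gaussian climatic niches and lognormal base propensity.

    Niche centres are uniform over the climate envelope; niche widths default
    to 3 deg C / 25 mm.  ``round(n_taxa * crop_fraction)`` taxa are flagged as
    crops.  Each of the ``n_families`` family labels is used at least once
    (required for the replacement-taxon search to have same-family candidates).
    """
    if n_taxa < 1:
        raise ConfigurationError(f"n_taxa must be >= 1, got {n_taxa}")
    if not (0.0 <= crop_fraction <= 1.0):
        raise ConfigurationError(f"crop_fraction must be in [0,1], got {crop_fraction}")
    if n_families < 1 or n_families > n_taxa:
        raise ConfigurationError(f"need 1 <= n_families <= n_taxa, got {n_families}")
    if t_sd <= 0 or p_sd <= 0:
        raise ConfigurationError("niche sds must be positive")
    rng = _rng(seed)
    width = len(str(n_taxa))
    taxon_ids = [f"T{i:0{width}d}" for i in range(1, n_taxa + 1)]
    fam_labels = [f"Fam{j:02d}" for j in range(1, n_families + 1)]
    # first one taxon per family, remainder at random: every label occurs
    fam_idx = np.concatenate(
        [np.arange(n_families), rng.integers(0, n_families, n_taxa - n_families)]
    )
    rng.shuffle(fam_idx)
    n_crops = int(round(n_taxa * crop_fraction))
    crop = np.zeros(n_taxa, dtype=bool)
    crop[rng.choice(n_taxa, size=n_crops, replace=False)] = True
    return pd.DataFrame(
        {
            "taxon_id": taxon_ids,
            "family": [fam_labels[j] for j in fam_idx],
            "crop_flag": crop,
            "niche_t_mean": rng.uniform(*t_mean_range, n_taxa),
            "niche_t_sd": np.full(n_taxa, float(t_sd)),
            "niche_p_mean": rng.uniform(*p_mean_range, n_taxa),
            "niche_p_sd": np.full(n_taxa, float(p_sd)),
            "base_abundance": rng.lognormal(0.0, 1.0, n_taxa),
        }
    )


def expected_composition(
    taxa: pd.DataFrame,
    t_mean: float,
    p_sum: float,
    month: int | None = None,
    crop_pulse_month: int = 5,
    crop_pulse_factor: float = 10.0,
) -> np.ndarray:
    """Noise-free expected composition at the given monthly climate.

    Suitability of taxon *i* is its base propensity times a product of
    independent Gaussian kernels in temperature and precipitation centred on
    the niche; crop taxa get a mass-flowering multiplier in the pulse month.
    The returned vector is suitability normalised to the simplex, in taxon
    table order.
    """
    s = taxa["base_abundance"].to_numpy(dtype=float).copy()
    s = s * np.exp(
        -0.5 * ((t_mean - taxa["niche_t_mean"].to_numpy()) / taxa["niche_t_sd"].to_numpy()) ** 2
    )
    s = s * np.exp(
        -0.5 * ((p_sum - taxa["niche_p_mean"].to_numpy()) / taxa["niche_p_sd"].to_numpy()) ** 2
    )
    if month is not None and month == crop_pulse_month:
        s = np.where(taxa["crop_flag"].to_numpy(), s * crop_pulse_factor, s)
    total = s.sum()
    if total <= 0:
        # degenerate underflow: fall back to base propensities
        s = taxa["base_abundance"].to_numpy(dtype=float)
        total = s.sum()
    return s / total


def generate_compositions(
    sites: pd.DataFrame,
    climate: pd.DataFrame,
    taxa: pd.DataFrame,
    rounds_per_month: int = 2,
    concentration: float = 50.0,
    crop_pulse_month: int = 5,
    crop_pulse_factor: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Dirichlet-sampled compositions for every site x month x round.

    The Dirichlet is centred on the noise-free expected composition with total
    concentration ``concentration``; larger values give less sample-to-sample
    noise.  Rounds within a month share the month's climate record, mirroring
    monthly climate joined to biweekly sampling.  Returns the canonical long
    table ``sample_id, site_id, year, month, round, taxon_id, rra``.
    """
    if len(sites) == 0 or len(taxa) == 0:
        raise ConfigurationError("sites and taxa must be non-empty")
    if rounds_per_month < 1:
        raise ConfigurationError("rounds_per_month must be >= 1")
    if concentration <= 0:
        raise ConfigurationError("concentration must be positive")
    rng = _rng(seed)
    taxon_ids = taxa["taxon_id"].to_numpy()
    n_taxa = len(taxon_ids)
    clim = climate.sort_values(["site_id", "year", "month"], kind="stable")
    out_frames = []
    for row in clim.itertuples(index=False):
        p_exp = expected_composition(
            taxa, row.t_mean, row.p_sum, row.month, crop_pulse_month, crop_pulse_factor
        )
        alpha = np.maximum(concentration * p_exp, 1e-9)
        for r in range(1, rounds_per_month + 1):
            rra = rng.dirichlet(alpha)
            out_frames.append(
                pd.DataFrame(
                    {
                        "sample_id": f"{row.site_id}-{row.year}{row.month:02d}-r{r}",
                        "site_id": row.site_id,
                        "year": row.year,
                        "month": row.month,
                        "round": r,
                        "taxon_id": taxon_ids,
                        "rra": rra,
                    }
                )
            )
    return pd.concat(out_frames, ignore_index=True)


def generate_dataset(config: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """Generate the full linked dataset from one root seed.

    The root seed is split into four independent child streams (sites,
    climate, taxa, compositions) via :class:`numpy.random.SeedSequence`, so a
    dataset is reproducible as a whole while each stage stays independently
    seeded.
    """
    config = config or SyntheticConfig()
    if seed is not None:
        config = SyntheticConfig(**{**vars(config), "seed": seed})
    child = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(config.seed).spawn(4)]
    sites = generate_sites(config.n_sites, config.lat_range, config.lon_range, seed=child[0])
    climate = generate_climate(sites, config.months, seed=child[1])
    taxa = generate_taxa(
        config.n_taxa, config.n_families, config.crop_fraction, seed=child[2]
    )
    comps = generate_compositions(
        sites,
        climate,
        taxa,
        rounds_per_month=config.rounds_per_month,
        concentration=config.concentration,
        crop_pulse_month=config.crop_pulse_month,
        crop_pulse_factor=config.crop_pulse_factor,
        seed=child[3],
    )
    return SyntheticDataset(sites, climate, taxa, comps, config)
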