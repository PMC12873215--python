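"""Per-sample diversity and crop-contribution summaries.

Shannon entropy H' = -sum p_i ln p_i (nats) and its exponential e^H, the
Hill number of order 1 ("effective species richness"): the number of equally
common taxa that would produce the observed entropy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "shannon_entropy",
    "effective_richness",
    "crop_fraction",
    "diversity_summary",
    "top_taxa",
]


def shannon_entropy(p) -> float:
    """H' in nats of a composition; zero-abundance entries contribute 0."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty composition")
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def effective_richness(h: float) -> float:
    """e^H, the effective number of equally common taxa."""
    if h < 0:
        raise ValueError(f"entropy must be >= 0, got {h}")
    return float(np.exp(h))


def crop_fraction(composition: pd.Series | dict, taxa: pd.DataFrame) -> float:
    """Summed RRA over crop-flagged taxa of one sample.

    ``composition`` maps taxon_id -> rra; every taxon must appear in the
    taxon table (unknown ids raise KeyError).
    """
    comp = pd.Series(composition, dtype=float)
    flags = taxa.set_index("taxon_id")["crop_flag"]
    unknown = comp.index.difference(flags.index)
    if len(unknown):
        raise KeyError(f"unknown taxa in composition: {list(unknown[:5])}")
    return float(comp[flags.reindex(comp.index).astype(bool)].sum())


def diversity_summary(comp: pd.DataFrame, taxa: pd.DataFrame) -> pd.DataFrame:
    """Per-sample table: shannon_h, effective_richness, crop_fraction, n_taxa."""
    flags = taxa.set_index("taxon_id")["crop_flag"]
    unknown = set(comp["taxon_id"]) - set(flags.index)
    if unknown:
        raise KeyError(f"unknown taxa in composition table: {sorted(unknown)[:5]}")
    work = comp.copy()
    work["is_crop"] = work["taxon_id"].map(flags).astype(bool)
    pos = work[work["rra"] > 0]
    plogp = pos["rra"] * np.log(pos["rra"])
    g = pos.assign(plogp=plogp).groupby("sample_id", sort=False)
    out = pd.DataFrame(
        {
            "shannon_h": -g["plogp"].sum(),
            "n_taxa": g["taxon_id"].nunique(),
            "crop_fraction": work.groupby("sample_id", sort=False).apply(
                lambda s: s.loc[s["is_crop"], "rra"].sum(), include_groups=False
            ),
        }
    )
    out["effective_richness"] = np.exp(out["shannon_h"])
    out = out.reset_index()
    return out[["sample_id", "shannon_h", "effective_richness", "crop_fraction", "n_taxa"]]


def top_taxa(comp: pd.DataFrame, k: int = 25) -> pd.DataFrame:
    """The k most abundant taxa by RRA summed over all samples.

    Ties are broken lexicographically by taxon_id; k beyond the number of
    taxa returns all of them.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    totals = (
        comp.groupby("taxon_id", as_index=False)["rra"]
        .sum()
        .rename(columns={"rra": "total_rra"})
        .sort_values(["total_rra", "taxon_id"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    return totals.head(k)
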