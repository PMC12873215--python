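"""Shared fixtures: a small desk-scale dataset and the full default fixture.

Everything is generated programmatically from fixed seeds; nothing is read
from disk.  The expensive full-scale chain (simulate -> filter -> profiles ->
records) is session-scoped so the acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import pollenrisk as pr
from pollenrisk.io_prep import filter_to_taxa


class RunArtifacts:
    """Prepared chain outputs for one synthetic dataset."""

    def __init__(self, config: pr.SyntheticConfig):
        self.dataset = pr.generate_dataset(config)
        ds = self.dataset
        self.filtered, self.emptied = pr.apply_rra_filter(ds.compositions)
        self.retained, self.prevalence_report = pr.prevalence_filter(self.filtered)
        self.joined = pr.join_climate(
            filter_to_taxa(self.filtered, self.retained), ds.climate, ds.sites
        )
        self.profiles, self.skipped = pr.fit_niche_profiles(self.joined, sorted(self.retained))
        self.records = pr.attach_thresholds(self.joined, self.profiles, ds.taxa)


@pytest.fixture(scope="session")
def small_run() -> RunArtifacts:
    """40 sites x 30 taxa in 8 families: fast, structurally complete."""
    return RunArtifacts(pr.SyntheticConfig(n_sites=40, n_taxa=30, n_families=8, seed=1))


@pytest.fixture(scope="session")
def default_run() -> RunArtifacts:
    """The full default fixture: 310 sites, 150 taxa, ~2480 samples."""
    return RunArtifacts(pr.SyntheticConfig(seed=1))


@pytest.fixture()
def tiny_composition() -> pd.DataFrame:
    """Two hand-built samples at two sites, long format."""
    rows = [
        ("s1", "A", 2023, 5, 1, "tx1", 0.6),
        ("s1", "A", 2023, 5, 1, "tx2", 0.3),
        ("s1", "A", 2023, 5, 1, "tx3", 0.1),
        ("s2", "B", 2023, 6, 1, "tx1", 0.5),
        ("s2", "B", 2023, 6, 1, "tx3", 0.5),
    ]
    return pd.DataFrame(rows, columns=pr.io_prep.COMPOSITION_COLUMNS)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
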