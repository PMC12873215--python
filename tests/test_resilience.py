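"""Resistance/resilience arithmetic, haversine, and the replacement search."""

import numpy as np
import pandas as pd
import pytest

import pollenrisk as pr
from pollenrisk.resilience import resilience_for_scenario, site_distance_matrix
from pollenrisk.risk import Scenario


class TestHaversine:
    def test_identity_is_zero(self):
        assert pr.haversine_km(48.2, 16.4, 48.2, 16.4) == 0.0

    def test_one_degree_longitude_at_equator(self):
        assert pr.haversine_km(0, 0, 0, 1) == pytest.approx(111.19, abs=0.01)

    def test_antipodal_half_circumference(self):
        assert pr.haversine_km(0, 0, 0, 180) == pytest.approx(20015.1, abs=0.1)

    def test_symmetry(self):
        assert pr.haversine_km(40, -3, 52, 13) == pytest.approx(pr.haversine_km(52, 13, 40, -3))

    def test_latitude_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pr.haversine_km(95, 0, 0, 0)

    def test_distance_matrix_symmetric_zero_diagonal(self, small_run):
        _, D = site_distance_matrix(small_run.dataset.sites)
        np.testing.assert_allclose(D, D.T, atol=1e-9)
        np.testing.assert_allclose(np.diag(D), 0.0, atol=1e-9)


class TestEquationArithmetic:
    @pytest.mark.parametrize(
        "s_risk,s_no_risk,expected", [(2, 2, 0.5), (0, 5, 1.0), (4, 0, 0.0), (1, 3, 0.75)]
    )
    def test_resistance(self, s_risk, s_no_risk, expected):
        assert pr.compute_resistance(s_risk, s_no_risk) == pytest.approx(expected)

    def test_resistance_undefined_for_empty_community(self):
        with pytest.raises(ValueError):
            pr.compute_resistance(0, 0)

    @pytest.mark.parametrize("s_repl,s_risk,expected", [(1, 2, 0.5), (0, 3, 0.0), (3, 3, 1.0)])
    def test_resilience(self, s_repl, s_risk, expected):
        assert pr.compute_resilience(s_repl, s_risk) == pytest.approx(expected)

    def test_zero_risk_conventions(self):
        assert pr.compute_resilience(0, 0, "one") == 1.0
        assert np.isnan(pr.compute_resilience(0, 0, "exclude"))

    def test_replacement_exceeding_risk_rejected(self):
        with pytest.raises(ValueError):
            pr.compute_resilience(3, 2)


def _toy_world(candidate_lon: float):
    """Focal site at (45, 0); candidate's low/low site at a controlled longitude.

    Taxa: fA (at-risk focal, family F), cand (family F, low/low only at the
    remote site), other (different family, low/low everywhere).
    """
    sites = pd.DataFrame(
        {
            "site_id": ["focal", "remote"],
            "latitude": [45.0, 45.0],
            "longitude": [0.0, candidate_lon],
        }
    )
    taxa = pd.DataFrame(
        {
            "taxon_id": ["fA", "cand", "other"],
            "family": ["F", "F", "G"],
            "crop_flag": [False] * 3,
        }
    )
    rows = [
        # sample at the focal site: fA at risk, other low/low
        ("s_f", "focal", "fA", 0.6, 2, 0),
        ("s_f", "focal", "other", 0.4, 0, 0),
        # sample at the remote site: cand low/low there
        ("s_r", "remote", "cand", 1.0, 0, 0),
    ]
    classified = pd.DataFrame(
        rows, columns=["sample_id", "site_id", "taxon_id", "rra", "t_class", "p_class"]
    )
    classified["combined_class"] = classified[["t_class", "p_class"]].max(axis=1)
    return sites, taxa, classified


class TestFindReplacements:
    def test_same_family_lowlow_within_radius_is_used(self):
        sites, taxa, classified = _toy_world(candidate_lon=1.0)  # ~79 km at 45N
        mapping = pr.find_replacements("s_f", classified, taxa, sites, radius_km=500)
        assert mapping == {"fA": "cand"}

    def test_candidate_beyond_radius_unused(self):
        sites, taxa, classified = _toy_world(candidate_lon=8.0)  # ~630 km at 45N
        mapping = pr.find_replacements("s_f", classified, taxa, sites, radius_km=500)
        assert mapping == {}

    def test_different_family_never_qualifies(self):
        sites, taxa, classified = _toy_world(candidate_lon=1.0)
        taxa.loc[taxa["taxon_id"] == "cand", "family"] = "H"
        mapping = pr.find_replacements("s_f", classified, taxa, sites, radius_km=500)
        assert mapping == {}

    def test_no_reuse_higher_rra_taxon_wins(self):
        """Two same-family at-risk taxa, one candidate: the greedy order gives
        it to the higher-RRA taxon and the map has size one (brute-force over
        the single possible assignment agrees)."""
        sites, taxa, classified = _toy_world(candidate_lon=1.0)
        taxa = pd.concat(
            [taxa, pd.DataFrame({"taxon_id": ["fB"], "family": ["F"], "crop_flag": [False]})],
            ignore_index=True,
        )
        extra = pd.DataFrame(
            [["s_f", "focal", "fB", 0.2, 1, 0, 1]],
            columns=["sample_id", "site_id", "taxon_id", "rra", "t_class", "p_class", "combined_class"],
        )
        classified = pd.concat([classified, extra], ignore_index=True)
        mapping = pr.find_replacements("s_f", classified, taxa, sites, radius_km=500)
        assert mapping == {"fA": "cand"}  # fA has rra 0.6 > 0.2

    def test_unknown_sample_rejected(self):
        sites, taxa, classified = _toy_world(1.0)
        with pytest.raises(KeyError):
            pr.find_replacements("nope", classified, taxa, sites)


class TestFastPathAgainstReference:
    @pytest.mark.parametrize("scenario", [Scenario(0.0, 0.0), Scenario(2.5, -20.0), Scenario(5.0, -50.0)])
    def test_maps_identical(self, small_run, scenario):
        ds = small_run.dataset
        classified = pr.classify_records(small_run.records, scenario)
        fast, maps = resilience_for_scenario(
            classified, ds.taxa, ds.sites, return_maps=True
        )
        for sample_id in fast["sample_id"].iloc[::17]:
            ref = pr.find_replacements(sample_id, classified, ds.taxa, ds.sites)
            assert ref == maps[sample_id]

    def test_map_injective_and_counts_consistent(self, small_run):
        ds = small_run.dataset
        classified = pr.classify_records(small_run.records, Scenario(3.0, -25.0))
        table, maps = resilience_for_scenario(classified, ds.taxa, ds.sites, return_maps=True)
        for row in table.itertuples(index=False):
            m = maps[row.sample_id]
            assert len(m) == row.s_replacement <= row.s_risk
            assert len(set(m.values())) == len(m)  # criterion 4: no reuse
            assert row.resistance == pytest.approx(
                1 - row.s_risk / (row.s_risk + row.s_no_risk)
            )

    def test_determinism(self, small_run):
        ds = small_run.dataset
        classified = pr.classify_records(small_run.records, Scenario(2.0, -10.0))
        a, am = resilience_for_scenario(classified, ds.taxa, ds.sites, return_maps=True)
        b, bm = resilience_for_scenario(classified, ds.taxa, ds.sites, return_maps=True)
        pd.testing.assert_frame_equal(a, b)
        assert am == bm

    def test_radius_monotonicity(self, small_run):
        ds = small_run.dataset
        classified = pr.classify_records(small_run.records, Scenario(3.0, -30.0))
        prev = None
        for radius in (100.0, 300.0, 500.0, 1500.0):
            res = resilience_for_scenario(classified, ds.taxa, ds.sites, radius_km=radius)
            cur = res.set_index("sample_id")["s_replacement"]
            if prev is not None:
                assert (cur >= prev).all()
            prev = cur


class TestSurface:
    def test_row_count_is_samples_times_scenarios(self, small_run):
        ds = small_run.dataset
        scns = [Scenario(0.0, 0.0), Scenario(5.0, -50.0)]
        surf = pr.resilience_surface(small_run.records, scns, ds.taxa, ds.sites)
        n_samples = small_run.records["sample_id"].nunique()
        assert len(surf) == n_samples * len(scns)

    def test_severe_scenario_lowers_mean_resistance(self, small_run):
        ds = small_run.dataset
        surf = pr.resilience_surface(
            small_run.records, [Scenario(0.0, 0.0), Scenario(5.0, -50.0)], ds.taxa, ds.sites
        )
        base = surf[(surf["delta_t"] == 0.0)]["resistance"].mean()
        severe = surf[(surf["delta_t"] == 5.0)]["resistance"].mean()
        assert severe < base

    def test_baseline_mostly_high_resistance(self, small_run):
        ds = small_run.dataset
        surf = pr.resilience_surface(small_run.records, [Scenario(0.0, 0.0)], ds.taxa, ds.sites)
        assert (surf["resistance"] > 0.5).mean() >= 0.8
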