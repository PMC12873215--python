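"""Weighted KDE niche profiles: densities, bandwidths, percentile thresholds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import gaussian_kde

import pollenrisk as pr
from pollenrisk.niche import (
    DegenerateProfileError,
    effective_sample_size,
    fit_weighted_kde,
    weighted_quantile,
)


def _obs(values, weights=None):
    values = np.asarray(values, dtype=float)
    weights = np.ones_like(values) if weights is None else np.asarray(weights, dtype=float)
    return pd.DataFrame({"value": values, "weight": weights})


class TestCollectObservations:
    def test_direct_mapping(self, small_run):
        tid = sorted(small_run.retained)[0]
        obs = pr.collect_weighted_observations(tid, small_run.joined, "temperature")
        rows = small_run.joined[small_run.joined["taxon_id"] == tid]
        assert len(obs) == len(rows)
        np.testing.assert_allclose(np.sort(obs["value"]), np.sort(rows["t_mean"]))
        np.testing.assert_allclose(np.sort(obs["weight"]), np.sort(rows["rra"]))

    def test_absent_taxon_raises(self, small_run):
        with pytest.raises(ValueError):
            pr.collect_weighted_observations("no-such-taxon", small_run.joined)


class TestWeightedKde:
    def test_symmetry_about_zero(self, rng):
        v = np.concatenate([rng.normal(3, 1, 200), -rng.normal(3, 1, 200)])
        v = np.concatenate([v, -v])  # exactly symmetric sample
        prof = fit_weighted_kde(_obs(v), bandwidth_rule="fixed", bandwidth=1.0)
        flipped = np.interp(-prof.grid[::-1], prof.grid, prof.density)
        np.testing.assert_allclose(prof.density[::-1], flipped, atol=1e-9)

    def test_weight_scale_invariance(self, rng):
        v = rng.normal(10, 2, 100)
        w = rng.uniform(0.1, 1.0, 100)
        a = fit_weighted_kde(_obs(v, w), bandwidth_rule="fixed", bandwidth=0.8)
        b = fit_weighted_kde(_obs(v, 7.5 * w), bandwidth_rule="fixed", bandwidth=0.8)
        np.testing.assert_allclose(a.density, b.density, atol=1e-12)
        assert a.thresholds == b.thresholds

    def test_density_integrates_to_one_and_thresholds_ordered(self, default_run):
        from scipy.integrate import trapezoid

        for prof in default_run.profiles.values():
            assert abs(trapezoid(prof.density, prof.grid) - 1.0) < 1e-6
            t = prof.thresholds
            assert t["p01"] <= t["p05"] <= t["p10"] <= t["p90"] <= t["p95"] <= t["p99"]
            assert np.all(np.diff(prof.grid) > 0)
            assert np.all(prof.density >= 0)

    def test_mode_recovery_normal_sample(self, rng):
        v = rng.normal(15, 3, 5000)
        prof = fit_weighted_kde(_obs(v), bandwidth_rule="silverman")
        mode = prof.grid[np.argmax(prof.density)]
        assert abs(mode - 15.0) < 0.5

    def test_matches_scipy_gaussian_kde(self, rng):
        """Independent cross-check: same bandwidth, same weighted density."""
        v = rng.normal(20, 4, 300)
        w = rng.uniform(0.05, 1.0, 300)
        h = 0.9
        prof = fit_weighted_kde(_obs(v, w), bandwidth_rule="fixed", bandwidth=h)
        cov = np.cov(v, aweights=w, bias=False)
        ref = gaussian_kde(v, bw_method=h / np.sqrt(float(cov)), weights=w)
        expected = ref(prof.grid)
        expected /= np.trapezoid(expected, prof.grid)
        np.testing.assert_allclose(prof.density, expected, rtol=1e-6, atol=1e-9)

    def test_precipitation_support_truncated_at_zero(self):
        v = np.array([1.0, 2.0, 4.0, 8.0, 0.5])
        prof = fit_weighted_kde(_obs(v), axis="precipitation", bandwidth_rule="fixed", bandwidth=3.0)
        assert prof.grid[0] >= 0.0
        from scipy.integrate import trapezoid

        assert abs(trapezoid(prof.density, prof.grid) - 1.0) < 1e-6

    def test_degenerate_single_value_rejected(self):
        with pytest.raises(DegenerateProfileError):
            fit_weighted_kde(_obs([5.0, 5.0, 5.0]), bandwidth_rule="fixed", bandwidth=1.0)

    @given(shift=st.floats(-50, 50))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_shift_equivariance_fixed_bandwidth(self, shift):
        rng = np.random.default_rng(5)
        v = rng.normal(0, 2, 80)
        w = rng.uniform(0.1, 1, 80)
        a = fit_weighted_kde(_obs(v, w), bandwidth_rule="fixed", bandwidth=0.7)
        b = fit_weighted_kde(_obs(v + shift, w), bandwidth_rule="fixed", bandwidth=0.7)
        for key in a.thresholds:
            assert b.thresholds[key] - a.thresholds[key] == pytest.approx(shift, abs=1e-8)


class TestThresholds:
    def test_symmetric_density_symmetric_tails(self, rng):
        v = rng.normal(15, 3, 4000)
        v = np.concatenate([v, 30 - v])  # symmetrise about 15
        prof = fit_weighted_kde(_obs(v), bandwidth_rule="silverman")
        t = prof.thresholds
        assert (t["p90"] - 15.0) == pytest.approx(15.0 - t["p10"], abs=0.05)
        assert (t["p99"] - 15.0) == pytest.approx(15.0 - t["p01"], abs=0.1)

    def test_normal_p90_matches_analytic_quantile(self, rng):
        v = rng.normal(15, 3, 8000)
        prof = fit_weighted_kde(_obs(v), bandwidth_rule="silverman")
        assert prof.thresholds["p90"] == pytest.approx(15 + 1.2816 * 3, abs=0.3)

    def test_small_bandwidth_matches_weighted_quantile_oracle(self):
        """As bandwidth shrinks the KDE inverse CDF approaches the weighted
        empirical quantile (brute-force oracle)."""
        v = np.arange(1.0, 101.0)
        w = np.ones_like(v)
        prof = fit_weighted_kde(_obs(v, w), bandwidth_rule="fixed", bandwidth=0.25)
        oracle = weighted_quantile(v, w, 0.90)
        assert prof.thresholds["p90"] == pytest.approx(oracle, abs=1.0)

    def test_unnormalised_density_rejected(self):
        grid = np.linspace(0, 1, 100)
        with pytest.raises(ValueError):
            pr.percentile_thresholds(grid, np.full(100, 5.0))


class TestHelpers:
    def test_effective_sample_size(self):
        assert effective_sample_size(np.ones(50)) == pytest.approx(50.0)
        assert effective_sample_size(np.array([1.0, 0.0001])) == pytest.approx(1.0, abs=1e-3)

    def test_weighted_quantile_reduces_to_percentile(self, rng):
        v = rng.uniform(0, 10, 501)
        for q in (0.1, 0.5, 0.9):
            assert weighted_quantile(v, np.ones_like(v), q) == pytest.approx(
                np.quantile(v, q), abs=0.05
            )

    def test_weighted_quantile_respects_weights(self):
        v = np.array([0.0, 10.0])
        w = np.array([9.0, 1.0])
        assert weighted_quantile(v, w, 0.5) < 5.0


def test_profiles_table_contents(small_run):
    table = pr.niche.profiles_to_table(small_run.profiles)
    assert set(table["axis"]) == {"temperature", "precipitation"}
    assert (table["n_obs"] >= 2).all()
    assert (table["bandwidth"] > 0).all()
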