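"""Hegyi competition index and the power-law growth relation."""

import numpy as np
import pandas as pd
import pytest

from dendrostand.competition import (
    ci_summary,
    fit_power,
    hegyi_ci,
    hegyi_ci_all,
    interior_targets,
)
from dendrostand.errors import DegenerateInputError, ValidationError
from dendrostand.io_formats import StemMap


def brute_force_ci(df, target, radius=8.0, min_dbh=5.0):
    """Independent O(N^2)-style direct evaluation of the Hegyi sum."""
    row = df[df.tree_id == target].iloc[0]
    total = 0.0
    n = 0
    for _, other in df.iterrows():
        if other.tree_id == target:
            continue
        L = np.sqrt((other.x - row.x) ** 2 + (other.y - row.y) ** 2)
        if L <= radius and other.dbh >= min_dbh:
            total += (other.dbh / row.dbh) / L
            n += 1
    return total, n


def random_stand(rng, n=200, plot=50.0):
    df = pd.DataFrame(
        {
            "tree_id": [f"T{i}" for i in range(n)],
            "x": rng.uniform(0, plot, n),
            "y": rng.uniform(0, plot, n),
            "dbh": rng.lognormal(np.log(18), 0.35, n),
        }
    )
    return StemMap(df, plot_size=plot)


def two_tree_map(d_i, d_j, dist):
    df = pd.DataFrame(
        {
            "tree_id": ["i", "j"],
            "x": [25.0, 25.0 + dist],
            "y": [25.0, 25.0],
            "dbh": [d_i, d_j],
        }
    )
    return StemMap(df)


class TestHegyi:
    @pytest.mark.parametrize(
        "d_i,d_j,dist,expected",
        [(20.0, 20.0, 1.0, 1.0), (10.0, 20.0, 2.0, 1.0), (20.0, 10.0, 4.0, 0.125)],
    )
    def test_single_competitor_closed_form(self, d_i, d_j, dist, expected):
        res = hegyi_ci(two_tree_map(d_i, d_j, dist), "i")
        assert res.ci == pytest.approx(expected)
        assert res.n_competitors == 1

    def test_isolated_tree_scores_zero(self):
        res = hegyi_ci(two_tree_map(20.0, 20.0, 9.0), "i")  # beyond 8 m
        assert res.ci == 0.0 and res.n_competitors == 0

    def test_small_competitors_excluded(self):
        res = hegyi_ci(two_tree_map(20.0, 4.0, 2.0), "i")  # dbh < 5 cm
        assert res.ci == 0.0

    def test_coincident_stems_degenerate(self):
        df = pd.DataFrame(
            {"tree_id": ["a", "b"], "x": [1.0, 1.0], "y": [2.0, 2.0],
             "dbh": [10.0, 12.0]}
        )
        with pytest.raises(DegenerateInputError, match="share coordinates"):
            hegyi_ci(StemMap(df), "a")

    def test_matches_brute_force_on_random_stand(self):
        rng = np.random.default_rng(31)
        stand = random_stand(rng)
        targets = interior_targets(stand, sampled_only=False)
        assert len(targets) > 10
        results = hegyi_ci_all(stand, targets=targets)
        for t in targets:
            ci_bf, n_bf = brute_force_ci(stand.df, t)
            assert results[t].ci == pytest.approx(ci_bf, abs=1e-12)
            assert results[t].n_competitors == n_bf

    def test_terms_sum_to_ci(self):
        rng = np.random.default_rng(8)
        stand = random_stand(rng, n=80)
        t = interior_targets(stand, sampled_only=False)[0]
        res = hegyi_ci(stand, t)
        assert res.ci == pytest.approx(sum(c[3] for c in res.competitors), abs=1e-12)

    def test_scale_consistency(self):
        rng = np.random.default_rng(9)
        stand = random_stand(rng, n=120)
        t = interior_targets(stand, sampled_only=False)[0]
        base = hegyi_ci(stand, t).ci
        # doubling every DBH leaves CI unchanged
        df2 = stand.df.copy()
        df2["dbh"] *= 2.0
        assert hegyi_ci(StemMap(df2), t).ci == pytest.approx(base, rel=1e-12)
        # scaling all coordinates by c divides CI by c (shrink: radius catches
        # at least the same neighbours, restrict to the original set)
        c = 0.5
        df3 = stand.df.copy()
        df3[["x", "y"]] *= c
        res3 = hegyi_ci(StemMap(df3, plot_size=stand.plot_size), t,
                        radius=8.0 * c)
        assert res3.ci == pytest.approx(base / c, rel=1e-12)

    def test_monotone_in_dbh_and_distance(self):
        base = hegyi_ci(two_tree_map(20.0, 15.0, 3.0), "i").ci
        assert hegyi_ci(two_tree_map(20.0, 18.0, 3.0), "i").ci > base
        assert hegyi_ci(two_tree_map(20.0, 15.0, 4.0), "i").ci < base

    def test_buffer_mode_restricts_targets_to_core(self):
        rng = np.random.default_rng(10)
        stand = random_stand(rng)
        res = hegyi_ci_all(stand, edge_mode="none")
        assert set(res) == set(stand.df.tree_id)
        # nothing is flagged sampled here: buffer mode falls back to every
        # interior stem
        core = hegyi_ci_all(stand)
        assert set(core) == set(interior_targets(stand, sampled_only=False))


class TestSummary:
    def test_two_value_statistics(self):
        class R:
            def __init__(self, ci):
                self.ci = ci

        s = ci_summary([R(1.0), R(3.0)])
        assert s["mean"] == 2.0
        assert s["sd"] == pytest.approx(np.sqrt(2.0))

    def test_single_value_sd_flagged(self):
        class R:
            def __init__(self, ci):
                self.ci = ci

        s = ci_summary([R(2.0)])
        assert s["sd"] == 0.0 and not s["sd_defined"]

    def test_synthetic_stand_summary_matches_recomputation(self, default_dataset):
        _, stand, _, truth = default_dataset
        results = hegyi_ci_all(stand)
        s = ci_summary(results)
        vals = np.array([r.ci for r in results.values()])
        assert s["mean"] == pytest.approx(vals.mean())
        assert s["sd"] == pytest.approx(vals.std(ddof=1))
        assert 2.0 <= s["mean"] <= 6.0
        assert s["max"] / s["min"] > 3.0
        # generator truth stores the same CI values
        np.testing.assert_allclose(
            sorted(vals), sorted(truth.true_ci.values()), rtol=1e-12
        )


class TestPowerFit:
    def test_noiseless_recovery(self):
        x = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        y = 2.0 * x**-1.0
        f = fit_power(x, y)
        assert f.a == pytest.approx(2.0, abs=1e-8)
        assert f.b == pytest.approx(1.0, abs=1e-8)
        assert f.r2 == pytest.approx(1.0, abs=1e-8)

    def test_flat_data_gives_zero_exponent(self):
        x = np.array([1.0, 2.0, 3.0, 5.0, 9.0])
        y = np.full(5, 7.0)
        f = fit_power(x, y)
        assert abs(f.b) < 1e-6

    def test_validates_positivity_and_size(self):
        with pytest.raises(ValidationError):
            fit_power(np.array([1, 2, 3, 4, -1.0]), np.ones(5))
        with pytest.raises(ValidationError):
            fit_power(np.ones(4), np.ones(4))

    def test_noisy_recovery_at_study_scale(self):
        # y = 434.52 x^-1.056 with 10% lognormal noise, n = 53
        rng = np.random.default_rng(1234)
        bs = []
        for _ in range(100):
            x = rng.uniform(1.0, 11.0, 53)
            y = 434.52 * x**-1.056 * rng.lognormal(0.0, 0.10, 53)
            bs.append(fit_power(x, y).b)
        assert abs(float(np.median(bs)) - 1.056) < 0.10
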