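"""Detrending, biweight chronology and chronology statistics."""

import numpy as np
import pytest

from dendrostand.chronology import (
    IndexSeries,
    biweight_mean,
    build_chronology,
    chronology_stats,
    detrend_series,
    eps_from_snr,
    mean_sensitivity,
    qc_flag_series,
    smoothing_spline,
    spline_lambda,
)
from dendrostand.errors import DegenerateInputError
from dendrostand.io_formats import RingSeries
from conftest import make_rings


def dense_spline_oracle(y: np.ndarray, period: float) -> np.ndarray:
    """Independent dense-matrix solution of the penalized-smoother system."""
    n = len(y)
    lam = spline_lambda(period)
    D = np.zeros((n - 2, n))
    for i in range(n - 2):
        D[i, i : i + 3] = [1.0, -2.0, 1.0]
    return np.linalg.solve(np.eye(n) + lam * (D.T @ D), y)


class TestDetrend:
    def test_mean_method_constant_series(self):
        s = RingSeries("C1A", "C1", 2000, np.ones(5))
        idx = detrend_series(s, method="mean")
        np.testing.assert_allclose(idx.indices, 1.0)

    def test_negexp_self_fit_recovers_unity(self):
        t = np.arange(30)
        w = 2.5 * np.exp(-0.08 * t) + 0.8
        s = RingSeries("N1A", "N1", 1980, w)
        idx = detrend_series(s, method="negexp")
        np.testing.assert_allclose(idx.indices, 1.0, atol=1e-6)

    @pytest.mark.parametrize("n", [10, 23, 42])
    def test_spline_matches_dense_oracle(self, n):
        rng = np.random.default_rng(42 + n)
        y = rng.lognormal(0.0, 0.4, n) + 0.5
        period = 0.67 * n
        fitted = smoothing_spline(y, period)
        oracle = dense_spline_oracle(y, period)
        assert np.max(np.abs(fitted - oracle)) < 1e-8

    def test_all_zero_series_degenerate(self):
        s = RingSeries("Z1A", "Z1", 2000, np.zeros(8))
        with pytest.raises(DegenerateInputError):
            detrend_series(s, method="mean")

    def test_spline_is_halfway_at_cutoff_period(self):
        # frequency response: a pure sinusoid at the cutoff period comes
        # through with ~half its amplitude (long series, edge effects small)
        n, period = 400, 40.0
        t = np.arange(n)
        y = np.sin(2 * np.pi * t / period)
        sm = smoothing_spline(y, period)
        core = slice(100, 300)
        gain = np.dot(sm[core], y[core]) / np.dot(y[core], y[core])
        assert abs(gain - 0.5) < 0.02


class TestBiweight:
    def test_outlier_downweighted(self):
        # a majority of ties: MAD = 0, the median is the robust centre
        vals = np.array([1.0, 1.0, 1.0, 1.0, 10.0])
        bw = biweight_mean(vals)
        assert bw == 1.0
        assert abs(bw - 1.0) < abs(np.mean(vals) - 1.0)

    def test_matches_direct_formula(self):
        # independent direct evaluation of the weight formula
        vals = np.array([0.9, 1.0, 1.05, 1.1, 1.2, 6.0])
        bw = biweight_mean(vals)
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        u = (vals - med) / (9.0 * mad)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        assert abs(bw - np.sum(w * vals) / np.sum(w)) < 1e-10
        assert abs(bw - 1.05) < abs(np.mean(vals) - 1.05)

    def test_identical_values_pass_through(self):
        assert biweight_mean(np.full(7, 3.25)) == 3.25

    def test_chronology_of_identical_series(self):
        s = [
            IndexSeries(f"S{i}A", f"S{i}", 2000, np.array([1.0, 1.2, 0.8]))
            for i in range(4)
        ]
        chron = build_chronology(s)
        np.testing.assert_allclose(chron.index, [1.0, 1.2, 0.8])
        np.testing.assert_array_equal(chron.sample_depth, [4, 4, 4])

    def test_single_series_chronology_is_that_series(self):
        s = IndexSeries("S0A", "S0", 1990, np.array([0.9, 1.1, 1.0]))
        chron = build_chronology([s])
        np.testing.assert_allclose(chron.index, s.indices)


class TestStats:
    def test_ms_alternating_series(self):
        # 1,2,1,2,... each step: 2*1/3
        x = np.array([1.0, 2.0] * 6)
        assert abs(mean_sensitivity(x) - 2.0 / 3.0) < 1e-12

    def test_ms_scale_invariant_sd_not(self):
        rng = np.random.default_rng(5)
        x = rng.lognormal(0, 0.2, 50)
        assert abs(mean_sensitivity(3.7 * x) - mean_sensitivity(x)) < 1e-12
        assert abs(np.std(3.7 * x, ddof=1) - 3.7 * np.std(x, ddof=1)) < 1e-9

    def test_eps_snr_printed_pair(self):
        # the classical identity EPS = SNR/(1+SNR) on a published-scale SNR
        assert round(eps_from_snr(201.715), 3) == 0.995

    def test_identical_series_give_rbar_one(self):
        base = np.array([1.0, 1.3, 0.7, 1.1, 0.9, 1.2, 0.8, 1.0, 1.1, 0.95,
                         1.05, 0.9])
        series = [IndexSeries(f"T{i}A", f"T{i}", 2000, base) for i in range(3)]
        chron = build_chronology(series)
        stats = chronology_stats(series, chron, (2000, 2011))
        assert stats.rbar == pytest.approx(1.0)
        assert stats.eps == 1.0
        assert np.isinf(stats.snr)

    def test_eps_snr_identity_on_synthetic_stand(self, default_dataset):
        _, _, rings, _ = default_dataset
        series = [detrend_series(s) for s in rings]
        chron = build_chronology(series)
        stats = chronology_stats(series, chron)
        assert stats.eps * (1.0 + stats.snr) == pytest.approx(stats.snr, abs=1e-12)
        assert stats.eps_cores * (1.0 + stats.snr_cores) == pytest.approx(
            stats.snr_cores, abs=1e-12
        )
        n_trees = len({s.tree_id for s in rings})
        assert stats.n_trees == n_trees and stats.n_cores == 2 * n_trees
        assert stats.period == (1975, 2016)

    def test_mean_detrended_chronology_centers_on_one(self, default_dataset):
        _, _, rings, _ = default_dataset
        series = [detrend_series(s, method="mean") for s in rings]
        chron = build_chronology(series)
        assert abs(float(np.mean(chron.index)) - 1.0) < 0.05


class TestQC:
    def test_random_walk_outlier_flagged(self):
        rng = np.random.default_rng(12)
        n = 42
        signal = rng.lognormal(0.0, 0.25, n)
        series = []
        for i in range(9):
            idx = signal * rng.lognormal(0.0, 0.08, n)
            series.append(IndexSeries(f"G{i}A", f"G{i}", 1975, idx))
        walk = np.exp(np.cumsum(rng.normal(0, 0.15, n)))
        walk /= walk.mean()
        series.append(IndexSeries("BADA", "BAD", 1975, walk))
        report = qc_flag_series(series, threshold=0.32)
        worst = report.iloc[0]
        assert worst["series_id"] == "BADA"
        assert bool(worst["flagged"])
        assert not report[report["series_id"] != "BADA"]["flagged"].any()

    def test_identical_series_never_flagged(self):
        base = np.array([1.0, 1.2, 0.8, 1.1, 0.9, 1.3, 0.7, 1.0])
        series = [IndexSeries(f"I{i}A", f"I{i}", 2000, base) for i in range(4)]
        report = qc_flag_series(series, threshold=0.32)
        np.testing.assert_allclose(report["r_master"], 1.0)
        assert not report["flagged"].any()

    def test_unattainable_threshold_flags_all(self):
        series = [
            IndexSeries(f"R{i}A", f"R{i}", 2000,
                        np.random.default_rng(i).lognormal(0, 0.2, 20))
            for i in range(4)
        ]
        report = qc_flag_series(series, threshold=1.01)
        assert report["flagged"].all()
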