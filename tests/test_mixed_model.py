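"""Random-intercept REML: closed forms, cross-checks and invariants."""

import numpy as np
import pandas as pd
import pytest

from dendrostand.errors import ValidationError
from dendrostand.mixed_model import (
    DEFAULT_FORMULA,
    GrowthLMM,
    build_design,
    fit_lmm,
    recover_parameters,
    simulate_lmm_records,
)


def one_way_layout(g=12, m=6, tau=4.0, sigma=1.0, seed=0):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, np.sqrt(tau), g)
    rows = []
    for i in range(g):
        for _ in range(m):
            rows.append(dict(tree_id=f"g{i}", y=5.0 + u[i] + rng.normal(0, sigma)))
    return pd.DataFrame(rows)


def anova_reml_closed_form(df, g, m):
    """Balanced one-way ANOVA estimators (equal to REML when positive)."""
    grand = df["y"].mean()
    means = df.groupby("tree_id")["y"].mean()
    ssb = m * float(((means - grand) ** 2).sum())
    ssw = float(((df["y"] - df["tree_id"].map(means)) ** 2).sum())
    msb = ssb / (g - 1)
    msw = ssw / (g * (m - 1))
    return max((msb - msw) / m, 0.0), msw


class TestClosedForms:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_balanced_one_way_matches_anova(self, seed):
        g, m = 12, 6
        df = one_way_layout(g=g, m=m, seed=seed)
        fit = GrowthLMM.from_formula("y ~ 1", df.assign(one=1.0),
                                     groups="tree_id").fit(reml=True)
        tau_cf, sigma_cf = anova_reml_closed_form(df, g, m)
        assert fit.tau00 == pytest.approx(tau_cf, abs=1e-6)
        assert fit.sigma2 == pytest.approx(sigma_cf, abs=1e-6)

    def test_theta_zero_reduces_to_ols(self, default_design):
        model = GrowthLMM.from_formula(DEFAULT_FORMULA, default_design)
        fit0 = model.fit(theta=0.0)
        X, y = model.exog, model.endog
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit0.params, beta_ols, atol=1e-10)
        assert fit0.tau00 == 0.0 and fit0.boundary

    def test_tau_zero_truth_detected_at_boundary(self):
        # simulated without a group effect -> near-zero ICC
        rng = np.random.default_rng(3)
        hits = 0
        reps = 40
        for _ in range(reps):
            df = one_way_layout(g=53, m=24, tau=0.0, sigma=1.0,
                                seed=int(rng.integers(2**31)))
            fit = GrowthLMM.from_formula("y ~ 1", df, groups="tree_id").fit()
            hits += fit.icc < 0.05
        assert hits >= int(0.9 * reps)


class TestAgainstStatsmodels:
    def test_estimates_match_mixedlm(self, default_design):
        import statsmodels.formula.api as smf

        fit = fit_lmm(default_design)
        d2 = default_design.rename(columns={"mjj_scpdsi": "pdsi",
                                            "mjj_vpd": "vpd"})
        sm_fit = smf.mixedlm("bai ~ age + ci + pdsi + vpd + ci:pdsi", d2,
                             groups=d2["tree_id"]).fit(reml=True)
        # term order differs (patsy puts the interaction last as well)
        mine = dict(zip(fit.exog_names, fit.params))
        theirs = dict(zip(
            ["Intercept", "age", "ci", "pdsi", "vpd", "ci:pdsi"],
            sm_fit.fe_params,
        ))
        for k_m, k_t in [("Intercept", "Intercept"), ("age", "age"),
                         ("ci", "ci"), ("mjj_scpdsi", "pdsi"),
                         ("mjj_vpd", "vpd"), ("ci:mjj_scpdsi", "ci:pdsi")]:
            assert mine[k_m] == pytest.approx(theirs[k_t], rel=1e-5)
        # variance components agree up to the two optimizers' tolerances
        assert fit.sigma2 == pytest.approx(sm_fit.scale, rel=1e-3)
        assert fit.tau00 == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]),
                                          rel=1e-3)


class TestInvariants:
    def test_icc_identity_and_r2_ordering(self, default_design):
        fit = fit_lmm(default_design)
        assert fit.icc == pytest.approx(
            fit.tau00 / (fit.tau00 + fit.sigma2), abs=1e-12
        )
        assert 0.0 <= fit.marginal_r2 <= fit.conditional_r2 <= 1.0
        assert fit.sigma2 > 0 and fit.tau00 >= 0

    def test_deviance_is_global_minimum_among_probes(self, default_design):
        model = GrowthLMM.from_formula(DEFAULT_FORMULA, default_design)
        fit = model.fit()
        rng = np.random.default_rng(17)
        probes = np.exp(rng.uniform(-10, 6, 50))
        for theta in probes:
            assert fit.deviance <= model._neg2_profiled(theta, True) + 1e-8

    def test_record_order_permutation_invariance(self, default_design):
        fit1 = fit_lmm(default_design)
        shuffled = default_design.sample(frac=1.0, random_state=9)
        fit2 = fit_lmm(shuffled)
        np.testing.assert_allclose(fit1.params, fit2.params, rtol=1e-8)
        assert fit1.sigma2 == pytest.approx(fit2.sigma2, rel=1e-7)
        assert fit1.tau00 == pytest.approx(fit2.tau00, rel=1e-5)

    def test_rank_deficiency_names_columns(self, default_design):
        df = default_design.assign(ci_copy=default_design["ci"])
        with pytest.raises(ValidationError, match="rank deficient"):
            fit_lmm(df, formula="bai ~ age + ci + ci_copy")


class TestDesignAssembly:
    def test_may_july_mean_is_arithmetic(self, default_dataset):
        climate, _, _, truth = default_dataset
        from dendrostand.climate_response import may_july_mean

        y = 2000
        vals = [climate.value(y, m, "scPDSI") for m in (5, 6, 7)]
        assert may_july_mean(climate, "scPDSI", y) == pytest.approx(
            float(np.mean(vals))
        )
        assert truth.mjj_scpdsi.loc[y] == pytest.approx(float(np.mean(vals)))

    def test_full_design_has_one_record_per_tree_year(self, default_design):
        n_trees = default_design["tree_id"].nunique()
        assert len(default_design) == n_trees * 24
        assert default_design.groupby("tree_id")["age"].apply(
            lambda a: (np.diff(np.sort(a)) == 1).all()
        ).all()
        assert (default_design.groupby("tree_id")["ci"].nunique() == 1).all()

    def test_tree_without_ci_dropped(self, default_dataset):
        climate, stand, rings, _ = default_dataset
        from dendrostand.competition import hegyi_ci_all
        from dendrostand.growth import bai_series, reconstruct_radii
        from dendrostand.io_formats import average_cores_by_tree

        ci = hegyi_ci_all(stand)
        bai = {}
        for tr in average_cores_by_tree(rings):
            row = stand.tree(tr.tree_id)
            bai[tr.tree_id] = bai_series(reconstruct_radii(tr, float(row["dbh"])))
        victim = sorted(bai)[0]
        ci_short = {k: v for k, v in ci.items() if k != victim}
        design = build_design(bai, ci_short, climate, (1993, 2016))
        assert victim not in set(design["tree_id"])
        assert len(design) == (len(bai) - 1) * 24


class TestRecovery:
    TRUTH = {
        "Intercept": 1800.0, "age": 32.0, "ci": -197.0,
        "mjj_scpdsi": 111.0, "mjj_vpd": -726.0, "ci:mjj_scpdsi": -16.6,
    }

    def test_noiseless_limit_recovers_exactly(self, default_design):
        rng = np.random.default_rng(0)
        df = simulate_lmm_records(default_design, self.TRUTH, tau00=0.0,
                                  sigma2=1e-10, rng=rng)
        fit = fit_lmm(df)
        rep = recover_parameters(self.TRUTH, fit)
        assert (rep["bias"].abs() < 1e-4).all()

    def test_interval_coverage_under_own_model(self, default_design):
        rng = np.random.default_rng(100)
        reps = 100
        covered = {k: 0 for k in self.TRUTH}
        for _ in range(reps):
            df = simulate_lmm_records(default_design, self.TRUTH,
                                      tau00=96_000.0, sigma2=218_000.0, rng=rng)
            rep = recover_parameters(self.TRUTH, fit_lmm(df)).set_index("term")
            for k in covered:
                covered[k] += int(rep.loc[k, "covered"])
        for k, c in covered.items():
            assert 0.88 * reps <= c <= reps, (k, c / reps)
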