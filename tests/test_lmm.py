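"""Mixed-model fitter: statsmodels cross-check, recovery, weights, LRT."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cogrisk.cohort import SimConfig, generate_cohort
from cogrisk.errors import ConfigError, DataError
from cogrisk.lmm import fit_mixed_model
from cogrisk.longitudinal import (build_long_table, compare_models, fit_lmm,
                                  fit_lmm_moderation)
from cogrisk.scoring import zscore


def simulate_table(n=500, seed=0, interaction=-0.2, residual_sd=1.0,
                   slope_sd=0.1, **kw):
    cfg = SimConfig(n_participants=n, seed=seed,
                    attrition_coefficients={}, item_missingness_rates={},
                    baseline_moca_mean_sd=(20.0, 2.0),
                    level_per_risk_unit=-1.0, base_slope_per_year=-0.2,
                    slope_per_risk_unit=interaction / 0.6,
                    person_slope_sd=slope_sd, residual_sd=residual_sd, **kw)
    coh = generate_cohort(cfg)
    z = zscore(coh["true_risk"].to_numpy()).z
    truth = cfg.slope_per_risk_unit * coh["true_risk"].std(ddof=1)
    return coh, build_long_table(coh, z), truth


class TestAgainstStatsmodels:
    @pytest.fixture(scope="class")
    def table(self):
        return simulate_table(n=600, seed=51)[1]

    @pytest.mark.parametrize("reml", [False, True])
    def test_random_intercept_fit_matches(self, table, reml):
        mine = fit_lmm(table, reml=reml, random_slope=False)
        ref = sm.MixedLM.from_formula("moca ~ score_z * time", groups="id",
                                      data=table).fit(reml=reml)
        np.testing.assert_allclose(mine.fe_params, ref.fe_params.to_numpy(),
                                   atol=1e-5)
        np.testing.assert_allclose(mine.fe_se, ref.bse_fe.to_numpy(),
                                   atol=1e-4)
        assert mine.cov_re[0, 0] == pytest.approx(
            float(ref.cov_re.iloc[0, 0]), abs=1e-3)
        assert mine.sigma2 == pytest.approx(float(ref.scale), abs=1e-3)
        if not reml:
            assert mine.llf == pytest.approx(float(ref.llf), abs=1e-4)

    def test_random_slope_fit_at_least_as_good(self, table):
        # statsmodels may stall on the weakly identified slope variance;
        # require our optimum to be no worse, and identical when both agree
        import warnings
        mine = fit_lmm(table, reml=False, random_slope=True)
        assert not mine.fell_back_to_intercept
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sm.MixedLM.from_formula("moca ~ score_z * time",
                                          groups="id", re_formula="~time",
                                          data=table).fit(reml=False)
        assert mine.llf >= float(ref.llf) - 1e-3
        if abs(mine.llf - float(ref.llf)) < 1e-3:
            np.testing.assert_allclose(mine.fe_params,
                                       ref.fe_params.to_numpy(), atol=1e-3)


class TestWeights:
    def test_unit_weights_reproduce_unweighted_fit(self):
        table = simulate_table(n=300, seed=53)[1]
        a = fit_lmm(table)
        table2 = table.copy()
        table2["weight"] = 1.0
        b = fit_lmm(table2)
        np.testing.assert_array_equal(a.fe_params, b.fe_params)
        assert a.llf == b.llf

    def test_doubling_weights_leaves_estimates_unchanged(self):
        table = simulate_table(n=300, seed=54)[1]
        a = fit_lmm(table)
        table2 = table.copy()
        table2["weight"] = 2.0
        b = fit_lmm(table2)
        np.testing.assert_allclose(a.fe_params, b.fe_params, atol=1e-4)

    def test_varying_weight_within_participant_rejected(self):
        table = simulate_table(n=50, seed=55)[1]
        table.loc[1, "weight"] = 3.0
        with pytest.raises(DataError):
            fit_lmm(table)


class TestRecovery:
    def test_interaction_recovered_within_ci(self):
        _, table, truth = simulate_table(n=2000, seed=57, interaction=-0.2)
        fit = fit_lmm(table)
        i = fit.param_names.index("time:score_z")
        lo, hi = fit.conf_int()[i]
        assert lo <= truth <= hi

    def test_shuffled_scores_give_null_interaction(self):
        coh, table, _ = simulate_table(n=1500, seed=58, interaction=-0.2)
        rng = np.random.default_rng(0)
        z = zscore(coh["true_risk"].to_numpy()).z
        perm = rng.permutation(len(z))
        table_null = build_long_table(coh, z[perm])
        fit = fit_lmm(table_null)
        est = fit["time:score_z"]
        assert abs(est) < 3 * fit.se_of("time:score_z")

    def test_noiseless_linear_trajectories_exact(self):
        rng = np.random.default_rng(4)
        n = 300
        z = rng.normal(size=n)
        b0 = 20 + 2 * rng.normal(size=n)
        t2 = rng.uniform(3, 5, size=n)
        beta_t, beta_tz = -0.3, -0.15
        rows = []
        for i in range(n):
            for t in (0.0, t2[i]):
                rows.append((i, t, b0[i] - 1.2 * z[i]
                             + (beta_t + beta_tz * z[i]) * t, z[i], 1.0))
        table = pd.DataFrame(rows, columns=["id", "time", "moca", "score_z",
                                            "weight"])
        fit = fit_lmm(table, random_slope=False)
        assert fit["time:score_z"] == pytest.approx(beta_tz, abs=1e-3)
        assert fit["time"] == pytest.approx(beta_t, abs=1e-3)

    def test_singular_slope_variance_falls_back_flagged(self):
        _, table, _ = simulate_table(n=800, seed=59, slope_sd=0.0)
        fit = fit_lmm(table)
        if fit.fell_back_to_intercept:
            assert fit.singular and not fit.random_slope
        else:  # tiny estimated slope variance is also acceptable
            assert fit.cov_re[1, 1] < 0.05


class TestModelComparison:
    def test_self_comparison(self):
        table = simulate_table(n=300, seed=60)[1]
        fit = fit_lmm(table, reml=False, random_slope=False)
        out = compare_models(fit, fit)
        assert out["lrt_stat"] == pytest.approx(0.0, abs=1e-9)
        assert out["delta_aic"] == pytest.approx(0.0, abs=1e-9)

    def test_random_slope_wins_under_heterogeneity(self):
        _, table, _ = simulate_table(n=2000, seed=61, slope_sd=0.5)
        restricted = fit_lmm(table, reml=False, random_slope=False)
        full = fit_lmm(table, reml=False, random_slope=True)
        out = compare_models(restricted, full)
        assert out["lrt_stat"] >= 0.0
        assert out["delta_aic"] < 0  # slope model fits better
        assert out["boundary_caveat"]

    def test_nested_ml_lrt_nonnegative(self):
        table = simulate_table(n=500, seed=62)[1]
        restricted = fit_lmm(table, reml=False, random_slope=False)
        full = fit_lmm(table, reml=False, random_slope=True)
        assert compare_models(restricted, full)["lrt_stat"] >= -1e-6

    def test_differing_rows_rejected(self):
        t1 = simulate_table(n=300, seed=63)[1]
        t2 = simulate_table(n=301, seed=63)[1]
        with pytest.raises(DataError):
            compare_models(fit_lmm(t1, reml=False), fit_lmm(t2, reml=False))


class TestLongTable:
    def test_row_counting(self):
        coh = generate_cohort(SimConfig(n_participants=5, seed=3,
                                        attrition_coefficients={},
                                        item_missingness_rates={}))
        coh.loc[coh.index[:2], "moca_visit2"] = pd.NA
        coh.loc[coh.index[:2], "attended_followup"] = False
        table = build_long_table(coh, np.zeros(5))
        assert len(table) == 8  # 5 baseline rows + 3 follow-up rows
        assert (table.groupby("id").first()["time"] == 0).all()

    def test_tertile_reference_coding(self):
        coh = generate_cohort(SimConfig(n_participants=9, seed=4,
                                        attrition_coefficients={},
                                        item_missingness_rates={}))
        labels = np.array(["low", "medium", "high"] * 3)
        table = build_long_table(coh, labels, form="tertile")
        low_rows = table[(table["score_medium"] == 0)
                         & (table["score_high"] == 0)]
        assert len(low_rows) == 6  # 3 low-group participants x 2 visits

    def test_visit2_without_visit1_rejected(self):
        coh = generate_cohort(SimConfig(n_participants=5, seed=5,
                                        attrition_coefficients={},
                                        item_missingness_rates={}))
        coh.loc[coh.index[0], "moca_visit1"] = pd.NA
        with pytest.raises(DataError):
            build_long_table(coh, np.zeros(5))


class TestModeration:
    def moderated_cohort(self, n=4000, seed=70, extra_slope=-0.25):
        """Steeper score-linked decline only in men over 65."""
        cfg = SimConfig(n_participants=n, seed=seed,
                        attrition_coefficients={}, item_missingness_rates={},
                        baseline_moca_mean_sd=(20.0, 2.0),
                        level_per_risk_unit=-1.0, base_slope_per_year=-0.2,
                        slope_per_risk_unit=0.0, person_slope_sd=0.1,
                        residual_sd=1.0)
        coh = generate_cohort(cfg)
        older_men = ((coh["age_baseline"] >= 65)
                     & (coh["sex"] == "male")).to_numpy()
        z = zscore(coh["true_risk"].to_numpy()).z
        extra = extra_slope * z * older_men
        fu = coh["followup_years"].to_numpy()
        m2 = coh["moca_visit2"].astype(float) + extra * fu
        coh["moca_visit2"] = pd.array(np.clip(np.round(m2), 0, 30),
                                      dtype="Int64")
        return coh, z

    def test_three_way_term_recovered(self):
        coh, z = self.moderated_cohort()
        table = build_long_table(coh, z, moderators=True)
        fit = fit_lmm_moderation(table)
        # steeper decline for males>=65 is split between the two three-way
        # terms; their sum estimates the older-men-specific extra slope
        est = fit["time:score_z:age_ge65"] + fit["time:score_z:male"]
        i1 = fit.param_names.index("time:score_z:age_ge65")
        i2 = fit.param_names.index("time:score_z:male")
        se = np.sqrt(fit.cov_fe[i1, i1] + fit.cov_fe[i2, i2]
                     + 2 * fit.cov_fe[i1, i2])
        assert est < 0
        assert abs(est - (-0.25)) < 2.5 * se

    def test_null_moderation(self):
        coh, _, _ = simulate_table(n=2000, seed=71, interaction=-0.1)
        z = zscore(coh["true_risk"].to_numpy()).z
        table = build_long_table(coh, z, moderators=True)
        fit = fit_lmm_moderation(table)
        for term in ("time:score_z:age_ge65", "time:score_z:male"):
            assert abs(fit[term]) < 3 * fit.se_of(term)

    def test_age_65_splits_cohort(self, default_cohort):
        older = (default_cohort["age_baseline"] >= 65).mean()
        assert 0.2 < older < 0.8

    def test_empty_moderator_cell_rejected(self):
        coh, z = self.moderated_cohort(n=300, seed=72)
        coh = coh[~((coh["age_baseline"] >= 65)
                    & (coh["sex"] == "male"))].reset_index(drop=True)
        z = zscore(coh["true_risk"].to_numpy()).z
        table = build_long_table(coh, z, moderators=True)
        with pytest.raises(DataError):
            fit_lmm_moderation(table)

    def test_unmoderated_table_rejected(self):
        table = simulate_table(n=200, seed=73)[1]
        with pytest.raises(ConfigError):
            fit_lmm_moderation(table)
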