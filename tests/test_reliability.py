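"""ICC forms, variance components, SEM/SDC, omnibus tests, post hocs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import long_table
from lesioneval.reliability import (
    SDC_FACTOR,
    VarianceComponents,
    check_balanced,
    friedman,
    icc_absolute_agreement,
    icc_consistency,
    posthoc_pairwise,
    rm_anova,
    sem_sdc,
    variance_components_between,
    variance_components_within,
)
from oracles import anova_mean_squares, friedman_chi2


class TestICCAbsoluteAgreement:
    def test_identical_runs_give_one(self, rng):
        x = rng.normal(10, 3, size=(6, 1))
        df = long_table(np.repeat(x, 2, axis=1).reshape(6, 1, 2)[:, 0, :][:, None, :])
        # one "scanner", two runs
        res = icc_absolute_agreement(df)
        assert res.icc == pytest.approx(1.0)

    def test_constant_offset_pulls_icc_below_one(self, rng):
        r1 = rng.normal(10, 3, size=8)
        x = np.stack([r1, r1 + 2.0], axis=1)[:, None, :]
        res = icc_absolute_agreement(long_table(x))
        assert res.icc < 1.0

    def test_toy_table_matches_mean_squares_formula(self):
        x = np.array([[10.0, 11.0], [12.0, 13.5], [9.0, 9.5],
                      [14.0, 15.0], [11.0, 10.5], [13.0, 13.0]])
        msr, msc, mse = anova_mean_squares(x)
        n, k = x.shape
        expect = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
        res = icc_absolute_agreement(long_table(x[:, None, :]))
        assert res.icc == pytest.approx(expect)
        assert res.ci_low <= res.icc <= res.ci_high

    def test_too_few_subjects_rejected(self):
        df = long_table(np.ones((2, 1, 2)))
        with pytest.raises(ValueError, match="3 subjects"):
            icc_absolute_agreement(df)

    def test_zero_between_subject_variance_returns_missing(self):
        df = long_table(np.full((5, 1, 2), 7.0))
        with pytest.warns(UserWarning, match="undefined"):
            res = icc_absolute_agreement(df)
        assert np.isnan(res.icc)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_pingouin_on_random_tables(self, seed):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 12)
        x = rng.normal(10, 3, size=(n, 2)) + rng.normal(0, 2, size=(n, 1))
        df = long_table(x[:, None, :])
        res = icc_absolute_agreement(df)
        pg = df.rename(columns={"run": "rater"})
        tab = pingouin.intraclass_corr(pg, targets="subject", raters="rater", ratings="value")
        row = tab[tab["Type"] == "ICC(A,1)"].iloc[0]
        assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
        # pingouin rounds the interval to 2 decimals
        assert (res.ci_low, res.ci_high) == pytest.approx(tuple(row["CI95"]), abs=0.006)


class TestICCConsistency:
    def test_constant_scanner_offset_still_one(self, rng):
        a = rng.normal(10, 3, size=8)
        df = long_table(np.stack([a, a + 5.0], axis=1))
        res = icc_consistency(df)
        assert res.icc == pytest.approx(1.0)

    def test_identical_scanners_give_one(self, rng):
        a = rng.normal(10, 3, size=8)
        df = long_table(np.stack([a, a], axis=1))
        assert icc_consistency(df).icc == pytest.approx(1.0)

    def test_consistency_at_least_absolute_agreement(self, rng):
        # when MSC >= MSE the agreement form is penalized by the offset term
        a = rng.normal(10, 3, size=10)
        x = np.stack([a, a + 3.0 + rng.normal(0, 0.5, 10)], axis=1)
        icc_c = icc_consistency(long_table(x)).icc
        icc_aa = icc_absolute_agreement(long_table(x[:, None, :])).icc
        assert icc_c >= icc_aa

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_pingouin_on_random_tables(self, seed):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(seed + 1000)
        n = rng.integers(4, 12)
        x = rng.normal(10, 3, size=(n, 2)) + rng.normal(0, 2, size=(n, 1))
        df = long_table(x)
        res = icc_consistency(df)
        pg = pingouin.intraclass_corr(df, targets="subject", raters="scanner", ratings="value")
        row = pg[pg["Type"] == "ICC(C,1)"].iloc[0]
        assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
        assert (res.ci_low, res.ci_high) == pytest.approx(tuple(row["CI95"]), abs=0.006)


class TestVarianceComponents:
    def test_identical_runs_zero_error(self, rng):
        base = rng.normal(10, 2, size=(6, 3))
        x = np.repeat(base[:, :, None], 2, axis=2)
        vc = variance_components_within(long_table(x))
        assert vc.sigma2_error == 0.0
        assert sem_sdc(vc).sem_pct == 0.0

    def test_two_cell_moment_formula(self):
        # run pairs (10, 12) and (20, 20): mean of squared diffs / 2 over cells
        rows = [("s1", "sc1", 1, "volume_ml", 10.0), ("s1", "sc1", 2, "volume_ml", 12.0),
                ("s2", "sc1", 1, "volume_ml", 20.0), ("s2", "sc1", 2, "volume_ml", 20.0)]
        df = pd.DataFrame(rows, columns=["subject", "scanner", "run", "metric", "value"])
        vc = variance_components_within(df)
        assert vc.sigma2_error == pytest.approx((4.0 / 2 + 0.0) / 2)

    def test_identical_scanners_zero_components(self, rng):
        a = rng.normal(10, 2, size=8)
        df = long_table(np.stack([a, a, a], axis=1))
        vc = variance_components_between(df)
        assert vc.sigma2_condition == pytest.approx(0.0, abs=1e-12)
        assert vc.sigma2_error == pytest.approx(0.0, abs=1e-12)

    def test_toy_grid_matches_explicit_anova_sums(self):
        x = np.array([[10.0, 12.0, 11.0], [14.0, 15.0, 14.5],
                      [9.0, 10.0, 9.5], [13.0, 12.5, 14.0]])
        msr, msc, mse = anova_mean_squares(x)
        vc = variance_components_between(long_table(x))
        n, k = x.shape
        assert vc.sigma2_condition == pytest.approx(max((msc - mse) / n, 0))
        assert vc.sigma2_subject == pytest.approx(max((msr - mse) / k, 0))
        assert vc.sigma2_error == pytest.approx(mse)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_statsmodels_anova_mean_squares(self, seed):
        smf = pytest.importorskip("statsmodels.formula.api")
        anova_lm = pytest.importorskip("statsmodels.stats.anova").anova_lm
        rng = np.random.default_rng(seed + 2000)
        n, k = int(rng.integers(4, 9)), int(rng.integers(3, 5))
        x = rng.normal(10, 2, size=(n, k)) + rng.normal(0, 1.5, size=(n, 1))
        df = long_table(x)
        fit = smf.ols("value ~ C(subject) + C(scanner)", data=df).fit()
        tab = anova_lm(fit, typ=2)
        ms = tab["sum_sq"] / tab["df"]
        vc = variance_components_between(df)
        assert vc.sigma2_error == pytest.approx(ms["Residual"], rel=1e-8)
        assert vc.sigma2_condition == pytest.approx(
            max((ms["C(scanner)"] - ms["Residual"]) / n, 0), rel=1e-8, abs=1e-12
        )
        assert vc.sigma2_subject == pytest.approx(
            max((ms["C(subject)"] - ms["Residual"]) / k, 0), rel=1e-8, abs=1e-12
        )

    def test_unbalanced_design_reports_missing_cells(self):
        df = long_table(np.ones((4, 3, 2)))
        df = df.drop(df.index[0])
        with pytest.raises(ValueError, match="missing cells"):
            variance_components_within(df)

    def test_simulation_recovery_is_unbiased(self):
        from lesioneval.synthetic import simulate_measurement_table

        est_err, est_subj, est_scan = [], [], []
        for rep in range(500):
            df = simulate_measurement_table(
                n_subjects=12, mu=20.0, sigma2_subject=4.0,
                sigma2_scanner=0.25, sigma2_error=0.04, seed=10_000 + rep,
            )
            est_err.append(variance_components_within(df).sigma2_error)
            vb = variance_components_between(df[df["run"] == 1])
            est_subj.append(vb.sigma2_subject)
            est_scan.append(vb.sigma2_condition)
        assert np.mean(est_err) == pytest.approx(0.04, rel=0.10)
        assert np.mean(est_subj) == pytest.approx(4.0, rel=0.10)
        assert np.mean(est_scan) == pytest.approx(0.25, rel=0.25)


class TestSemSdc:
    @pytest.mark.parametrize("sem_pct,sdc_pct", [(10.37, 28.74), (31.00, 85.93),
                                                 (9.49, 26.30), (9.02, 25.00),
                                                 (50.75, 140.67), (23.23, 64.39)])
    def test_sdc_from_sem_reproduces_reported_pairs(self, sem_pct, sdc_pct):
        vc = VarianceComponents((0.0), 0.0, (sem_pct / 100) ** 2, 1.0, "within_scanner")
        rep = sem_sdc(vc, components="error")
        assert rep.sem_pct == pytest.approx(sem_pct)
        assert round(rep.sdc_pct, 2) == sdc_pct

    def test_ratio_is_196_sqrt2_to_machine_precision(self, rng):
        vc = VarianceComponents(1.0, 0.3, 0.2, 5.0, "between_scanner")
        rep = sem_sdc(vc)
        assert rep.sdc_pct / rep.sem_pct == pytest.approx(SDC_FACTOR, rel=1e-15)
        assert rep.sdc_abs / rep.sem_abs == pytest.approx(SDC_FACTOR, rel=1e-15)

    def test_between_design_sums_scanner_and_error(self):
        vc = VarianceComponents(9.0, 0.16, 0.09, 10.0, "between_scanner")
        rep = sem_sdc(vc)
        assert rep.sem_abs == pytest.approx(np.sqrt(0.25))
        assert rep.sem_pct == pytest.approx(5.0)

    def test_zero_variance_gives_zero(self):
        vc = VarianceComponents(1.0, 0.0, 0.0, 5.0, "within_scanner")
        rep = sem_sdc(vc)
        assert rep.sem_pct == rep.sdc_pct == 0.0

    def test_nonpositive_mean_rejected(self):
        vc = VarianceComponents(1.0, 0.0, 1.0, 0.0, "within_scanner")
        with pytest.raises(ValueError, match="mean"):
            sem_sdc(vc)


class TestOmnibus:
    def test_identical_columns_f_zero_p_one(self):
        df = long_table(np.tile(np.arange(5.0)[:, None], (1, 3)))
        res = rm_anova(df)
        assert res.statistic == 0.0 and res.p == 1.0

    @pytest.mark.parametrize("seed", range(100))
    def test_f_matches_explicit_sums_of_squares(self, seed):
        rng = np.random.default_rng(seed + 3000)
        n, k = int(rng.integers(4, 10)), 3
        x = rng.normal(10, 2, size=(n, k))
        msr, msc, mse = anova_mean_squares(x)
        res = rm_anova(long_table(x))
        assert res.statistic == pytest.approx(msc / mse)
        assert res.p == pytest.approx(stats.f.sf(msc / mse, k - 1, (n - 1) * (k - 1)))

    def test_location_invariance(self, rng):
        x = rng.normal(10, 2, size=(6, 3))
        a = rm_anova(long_table(x))
        b = rm_anova(long_table(x + 100.0))
        assert a.statistic == pytest.approx(b.statistic)

    def test_identical_columns_friedman_zero(self):
        df = long_table(np.tile(np.arange(4.0)[:, None], (1, 3)))
        res = friedman(df)
        assert res.statistic == 0.0 and res.p == 1.0

    @pytest.mark.parametrize("seed", range(100))
    def test_friedman_matches_brute_force_ranks(self, seed):
        rng = np.random.default_rng(seed + 4000)
        n = int(rng.integers(4, 10))
        x = rng.integers(0, 6, size=(n, 3)).astype(float)  # ties likely
        if np.allclose(x, x[:, [0]]):
            return
        res = friedman(long_table(x))
        assert res.statistic == pytest.approx(friedman_chi2(x), rel=1e-9)

    def test_rank_preserving_transform_leaves_friedman_unchanged(self, rng):
        x = rng.normal(10, 2, size=(6, 3))
        a = friedman(long_table(x))
        b = friedman(long_table(np.exp(x / 5.0)))
        assert a.statistic == pytest.approx(b.statistic)


class TestPosthoc:
    def test_bonferroni_multiplies_and_caps(self, rng):
        x = rng.normal(10, 2, size=(8, 3))
        out = posthoc_pairwise(long_table(x), method="paired_t")
        assert len(out) == 3
        expect = np.minimum(out["p_raw"] * 3, 1.0)
        assert np.allclose(out["p_corrected"], expect)

    def test_t_statistic_matches_closed_form(self, rng):
        x = rng.normal(10, 2, size=(10, 2))
        out = posthoc_pairwise(long_table(x), method="paired_t")
        d = x[:, 0] - x[:, 1]
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert out["statistic"].iloc[0] == pytest.approx(t)

    def test_degenerate_pair_returns_missing_with_warning(self):
        x = np.tile(np.arange(5.0)[:, None], (1, 2))
        with pytest.warns(UserWarning, match="degenerate"):
            out = posthoc_pairwise(long_table(x), method="paired_t")
        assert out["p_raw"].isna().all()

    def test_wilcoxon_runs(self, rng):
        x = rng.normal(10, 2, size=(10, 3))
        out = posthoc_pairwise(long_table(x), method="wilcoxon")
        assert out["p_corrected"].between(0, 1).all()


class TestBalanced:
    def test_complete_design_passes(self):
        check_balanced(long_table(np.ones((4, 3, 2))))

    def test_missing_cell_detected(self):
        df = long_table(np.ones((4, 3, 2))).drop(index=[0])
        with pytest.raises(ValueError, match="unbalanced"):
            check_balanced(df)


class TestInvariances:
    def test_icc_invariant_under_common_rescaling(self, rng):
        x = rng.normal(10, 3, size=(8, 2))
        a = icc_absolute_agreement(long_table(x[:, None, :])).icc
        b = icc_absolute_agreement(long_table((x * 3.7)[:, None, :])).icc
        assert a == pytest.approx(b)

    def test_icc_c_invariant_under_per_condition_offsets(self, rng):
        x = rng.normal(10, 3, size=(8, 3))
        a = icc_consistency(long_table(x)).icc
        b = icc_consistency(long_table(x + np.array([1.0, -2.0, 5.0]))).icc
        assert a == pytest.approx(b)
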