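"""Cox/Fine-Gray associations, concordance, FDR, correlation panels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from protclock import (DiseaseSpec, SimulationParams, bh_fdr, compare_models_c,
                       correlation_panel, cumulative_incidence, default_tiers,
                       fit_cox, fit_fine_gray, generate_cohort, harrell_c,
                       run_association_suite)

from conftest import brute_force_bh, brute_force_concordance, newton_cox_breslow


def _two_group_exponential(n, hr, seed):
    rng = np.random.default_rng(seed)
    g = rng.integers(0, 2, n)
    t = rng.exponential(1 / (0.1 * hr**g))
    c = rng.uniform(0, 20, n)
    return (pd.DataFrame({"g": g.astype(float)}), np.minimum(t, c),
            (t <= c).astype(int))


class TestCox:
    def test_two_group_hr_recovery(self):
        X, t, d = _two_group_exponential(10_000, 2.0, 0)
        res = fit_cox(X, t, d)
        coef, se = res.loc["g", "coef"], res.loc["g", "se"]
        assert abs(coef - np.log(2)) < 3 * se
        assert res.loc["g", "ci_low"] < res.loc["g", "hr"] < res.loc["g", "ci_high"]

    def test_tiny_dataset_matches_newton_oracle(self):
        X = pd.DataFrame({"x": [0.5, -1.2, 0.3, 2.0, -0.7, 1.1]})
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        d = np.array([1, 0, 1, 1, 0, 1])
        res = fit_cox(X, t, d)
        oracle = newton_cox_breslow(X.to_numpy(), t, d)
        # tie-free data: Efron == Breslow
        assert res.loc["x", "coef"] == pytest.approx(oracle[0], abs=1e-6)

    def test_null_pvalues_uniform(self):
        """Covariate independent of survival: Wald p ~ U(0,1) over 200 reps."""
        rng = np.random.default_rng(42)
        ps = []
        for _ in range(200):
            n = 120
            x = rng.normal(size=n)
            t = rng.exponential(1.0, n)
            c = rng.uniform(0, 2.5, n)
            res = fit_cox(pd.DataFrame({"x": x}), np.minimum(t, c), (t <= c).astype(int))
            ps.append(res.loc["x", "p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            fit_cox(pd.DataFrame({"x": [1.0, 2.0]}), [1, 2], [0, 0])


class TestFineGray:
    def test_reduces_to_cox_without_competing_events(self):
        rng = np.random.default_rng(5)
        n = 400
        x = rng.normal(size=(n, 2))
        t = rng.exponential(1 / np.exp(0.5 * x[:, 0] - 0.3 * x[:, 1]))
        c = rng.uniform(0, 2, n)
        time, ev = np.minimum(t, c), (t <= c).astype(int)
        X = pd.DataFrame(x, columns=["a", "b"])
        fg = fit_fine_gray(X, time, ev)
        cox = fit_cox(X, time, ev)
        assert np.max(np.abs(fg["coef"].to_numpy() - cox["coef"].to_numpy())) < 1e-6

    def test_subdistribution_beta_recovery(self):
        """Simulate directly from a proportional subdistribution-hazards model
        (Fine-Gray 1999 mixture construction) and recover beta = 0.5."""
        rng = np.random.default_rng(7)
        n, b, pmix = 10_000, 0.5, 0.6
        x = rng.normal(size=n)
        expb = np.exp(b * x)
        u = rng.random(n)
        cause1 = u < 1 - (1 - pmix) ** expb
        v = rng.random(n)
        # inverse of the conditional cause-1 subdistribution CDF
        T1 = -np.log(1 - (1 - (1 - v * (1 - (1 - pmix) ** expb)) ** (1 / expb)) / pmix)
        t2 = rng.exponential(1.0, n)
        time = np.where(cause1, T1, t2)
        cens = rng.uniform(0, 5, n)
        status = np.where(time <= cens, np.where(cause1, 1, 2), 0)
        res = fit_fine_gray(pd.DataFrame({"x": x}), np.minimum(time, cens), status)
        assert abs(res.loc["x", "coef"] - b) < 3 * res.loc["x", "se"]

    def test_cumulative_incidences_sum_below_one(self):
        rng = np.random.default_rng(9)
        n = 2000
        t1 = rng.exponential(2.0, n)
        t2 = rng.exponential(3.0, n)
        c = rng.uniform(0, 4, n)
        time = np.minimum(np.minimum(t1, t2), c)
        status = np.where(c < np.minimum(t1, t2), 0, np.where(t1 < t2, 1, 2))
        cif1 = cumulative_incidence(time, status, cause=1)
        cif2 = cumulative_incidence(time, status, cause=2)
        total = (cif1["cif"].reindex(cif1.index.union(cif2.index)).ffill().fillna(0)
                 + cif2["cif"].reindex(cif1.index.union(cif2.index)).ffill().fillna(0))
        assert (total <= 1.0 + 1e-9).all()

    def test_no_primary_events_rejected(self):
        with pytest.raises(ValueError):
            fit_fine_gray(pd.DataFrame({"x": [1.0, 2.0]}), [1, 2], [0, 2])

    def test_matches_reference_r_implementation(self, tmp_path):
        """Coefficients agree with cmprsk::crr (the reference Fine-Gray
        implementation) on a 300-row competing-risks dataset."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; reference cross-check cannot run")
        rng = np.random.default_rng(19)
        n = 300
        x1 = rng.normal(size=n)
        x2 = rng.binomial(1, 0.5, n).astype(float)
        t1 = rng.exponential(1 / np.exp(0.5 * x1 - 0.4 * x2))
        t2 = rng.exponential(1.2, n)
        c = rng.uniform(0.2, 3.0, n)
        time = np.minimum(np.minimum(t1, t2), c)
        status = np.where(c < np.minimum(t1, t2), 0, np.where(t1 < t2, 1, 2))
        df = pd.DataFrame({"time": time, "status": status, "x1": x1, "x2": x2})
        df.to_csv(tmp_path / "dat.csv", index=False)
        (tmp_path / "fg.R").write_text(
            'library(cmprsk)\n'
            f'd <- read.csv("{tmp_path}/dat.csv")\n'
            'fit <- crr(d$time, d$status, cbind(d$x1, d$x2), failcode=1, cencode=0)\n'
            'cat(sprintf("%.10f %.10f\\n", fit$coef[1], fit$coef[2]))\n')
        out = subprocess.run(["Rscript", str(tmp_path / "fg.R")],
                             capture_output=True, text=True, check=True)
        ref = np.array([float(v) for v in out.stdout.split()])
        mine = fit_fine_gray(df[["x1", "x2"]], df["time"], df["status"])
        assert np.max(np.abs(mine["coef"].to_numpy() - ref)) < 1e-6


class TestBhFdr:
    def test_worked_example(self):
        got = bh_fdr([0.005, 0.011, 0.02, 0.04, 0.13])
        expect = [0.025, 0.0275, 1 / 30, 0.05, 0.13]
        assert np.allclose(got, expect)

    def test_single_and_equal(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])
        assert np.allclose(bh_fdr([0.02, 0.02, 0.02]), 0.02)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_brute_force_step_up(self, ps):
        assert np.allclose(bh_fdr(ps), brute_force_bh(ps), atol=1e-12)


class TestHarrellC:
    def test_perfect_concordance(self):
        assert harrell_c([1, 2, 3], [1, 1, 1], [3, 2, 1]).c == 1.0

    def test_all_risk_ties(self):
        assert harrell_c([1, 2, 3], [1, 1, 1], [5, 5, 5]).c == 0.5

    def test_worked_example_matches_enumeration(self):
        t = [2, 4, 5, 7]
        d = [1, 0, 1, 1]
        r = [9, 8, 3, 4]
        got = harrell_c(t, d, r)
        expect_c, expect_pairs = brute_force_concordance(t, d, r)
        assert got.c == pytest.approx(expect_c)
        assert got.n_pairs == expect_pairs

    def test_random_fixtures_match_brute_force(self):
        rng = np.random.default_rng(1)
        for n in (10, 50, 200):
            t = rng.exponential(1.0, n)  # continuous: no time ties
            d = rng.integers(0, 2, n)
            d[0] = 1
            r = rng.integers(0, 5, n).astype(float)  # risk ties happen
            got = harrell_c(t, d, r)
            expect_c, expect_pairs = brute_force_concordance(t, d, r)
            assert got.c == pytest.approx(expect_c, abs=1e-12)
            assert got.n_pairs == expect_pairs

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            harrell_c([1, 2], [0, 0], [1, 2])


@pytest.fixture(scope="module")
def scored_cohort():
    params = SimulationParams(
        n_participants=1500, n_proteins=5, n_causal_proteins=0,
        disease_specs=(DiseaseSpec("hf", 0.01, age_effect=0.04),), seed=33)
    cohort, _, _ = generate_cohort(params)
    rng = np.random.default_rng(2)
    cohort = cohort.copy()
    cohort["deviation"] = rng.normal(size=len(cohort))  # null exposure
    return cohort


class TestSuite:
    def test_single_outcome_single_tier_matches_direct_call(self, scored_cohort):
        tiers = [default_tiers()[0]]
        table = run_association_suite(scored_cohort, "deviation", ["mortality"], tiers)
        direct = fit_cox(scored_cohort[["deviation", "age"]],
                         scored_cohort["time_death"], scored_cohort["died"])
        assert table.loc[0, "hr"] == pytest.approx(
            float(direct.loc["deviation", "hr"]))
        assert table.loc[0, "p_adj"] == pytest.approx(table.loc[0, "p"])

    def test_tier_covariates_checked(self, scored_cohort):
        from protclock.validation import AdjustmentTier
        with pytest.raises(ValueError):
            run_association_suite(scored_cohort, "deviation", ["mortality"],
                                  [AdjustmentTier("bad", ("age", "nope"))])

    def test_null_suite_controls_fdr(self):
        """Null exposure: across 10 seeds the FDR-significant count stays at
        the level expected under 5% FDR (i.e. rarely any discovery)."""
        n_disc = 0
        n_total = 0
        for seed in range(10):
            params = SimulationParams(
                n_participants=800, n_proteins=3, n_causal_proteins=0,
                disease_specs=(DiseaseSpec("d1", 0.015),
                               DiseaseSpec("d2", 0.01)), seed=200 + seed)
            cohort, _, _ = generate_cohort(params)
            rng = np.random.default_rng(seed)
            cohort["deviation"] = rng.normal(size=len(cohort))
            table = run_association_suite(cohort, "deviation",
                                          ["mortality", "d1", "d2"],
                                          default_tiers())
            n_disc += int((table["p_adj"] < 0.05).sum())
            n_total += len(table)
        assert n_disc <= 0.05 * n_total + 2 * np.sqrt(0.05 * n_total)


class TestCompareModels:
    def test_true_risk_scores_highest(self):
        params = SimulationParams(n_participants=2000, n_proteins=3,
                                  n_causal_proteins=0, seed=44)
        cohort, _, truth = generate_cohort(params)
        rng = np.random.default_rng(0)
        df = cohort.copy()
        df["true_risk"] = 0.08 * df["age"]  # the generating linear predictor
        df["noise"] = rng.normal(size=len(df))
        df["weak"] = 0.08 * df["age"] + rng.normal(0, 3.0, len(df))
        out = compare_models_c(df, ["true_risk", "weak", "noise"],
                               "time_death", "died")
        assert out.loc["true_risk", "c"] == out["c"].max()

    def test_null_score_near_half(self):
        rng = np.random.default_rng(3)
        n = 3000
        df = pd.DataFrame({
            "s": rng.normal(size=n),
            "t": rng.exponential(1, n),
            "e": 1,
        })
        out = compare_models_c(df, ["s"], "t", "e")
        se = 1 / np.sqrt(out.loc["s", "n_pairs"] / 4)  # rough pair-level SE
        assert abs(out.loc["s", "c"] - 0.5) < max(3 * se, 0.03)

    def test_duplicated_score_identical_c(self, scored_cohort):
        df = scored_cohort.copy()
        df["dev2"] = df["deviation"]
        out = compare_models_c(df, ["deviation", "dev2"], "time_death", "died")
        assert out.loc["deviation", "c"] == pytest.approx(out.loc["dev2", "c"])

    def test_empty_complete_case_rejected(self):
        df = pd.DataFrame({"s": [np.nan], "t": [1.0], "e": [1]})
        with pytest.raises(ValueError):
            compare_models_c(df, ["s"], "t", "e")


class TestCorrelationPanel:
    def test_monotone_transform_spearman_one(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 5.0, 9.0]})
        df["y"] = 2 * df["x"] + 1
        out = correlation_panel(df, ["x", "y"], "spearman")
        assert out.loc["x", "y"] == pytest.approx(1.0)

    def test_rank_formula_example(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [3.0, 1.0, 2.0]})
        out = correlation_panel(df, ["x", "y"], "spearman")
        assert out.loc["x", "y"] == pytest.approx(-0.5)

    def test_age_adjusted_panel_equals_residual_correlation(self):
        from protclock import age_adjusted_residuals
        rng = np.random.default_rng(6)
        n = 300
        df = pd.DataFrame({"age": rng.uniform(39, 70, n)})
        df["m1"] = 0.5 * df["age"] + rng.normal(size=n)
        df["m2"] = 0.2 * df["age"] + rng.normal(size=n)
        out = correlation_panel(df, ["m1", "m2"], "pearson", age_adjust=True)
        r1 = age_adjusted_residuals(df["m1"], df["age"])
        r2 = age_adjusted_residuals(df["m2"], df["age"])
        assert out.loc["m1", "m2"] == pytest.approx(np.corrcoef(r1, r2)[0, 1])
        # and each residualized measure is uncorrelated with age
        assert abs(np.corrcoef(r1, df["age"])[0, 1]) < 1e-10

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            correlation_panel(df, ["x", "y"])
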