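import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import fcomix
from fcomix import FcomixError
from fcomix.comparison import (
    CovariateSpec,
    adjusted_linear_model,
    build_design,
    compare_groups,
    format_pvalue,
    randomization_test,
    rank_sum_test,
    residual_diagnostics,
    screen_covariates,
)

NO_COVARIATES = CovariateSpec((), ())


def plain_sheet(group):
    return pd.DataFrame({"group": group},
                        index=pd.Index(group.index, name="sample_id"))


class TestRankSum:
    def test_separated_triples_exact_p(self):
        """Fully separated 3-vs-3 samples: exact two-sided p over all
        C(6,3)=20 rank assignments is 2/20 = 0.1."""
        w, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert w == 6.0
        assert p == pytest.approx(0.1)

    def test_identical_constant_groups(self):
        _, p = rank_sum_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.random(12), rng.random(9)
        assert rank_sum_test(x, y)[1] == pytest.approx(rank_sum_test(y, x)[1])

    def test_matches_scipy_on_large_tied_samples(self):
        rng = np.random.default_rng(1)
        x = np.round(rng.random(30), 1)
        y = np.round(rng.random(25) + 0.2, 1)
        _, p = rank_sum_test(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic").pvalue
        assert p == pytest.approx(ref)

    def test_exact_matches_scipy_exact(self):
        x, y = [0.3, 1.7, 2.2, 9.0], [0.9, 4.4, 5.1]
        _, p = rank_sum_test(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="exact").pvalue
        assert p == pytest.approx(ref)

    def test_empty_group_fatal(self):
        with pytest.raises(FcomixError):
            rank_sum_test([], [1.0])


class TestScreenCovariates:
    def test_single_level_dropped(self, tiny_sheet):
        sheet = tiny_sheet.assign(gender="female")
        spec = screen_covariates(sheet)
        assert "gender" not in spec.used
        assert spec.dropped_reasons["gender"] == "single level"

    def test_missingness_dropped(self, tiny_sheet):
        sheet = tiny_sheet.copy()
        sheet.loc[sheet.index[:10], "race"] = np.nan
        spec = screen_covariates(sheet)
        assert "race" not in spec.used
        assert spec.dropped_reasons["race"] == "missingness"

    def test_complete_covariates_all_used(self, tiny_sheet):
        spec = screen_covariates(tiny_sheet)
        assert spec.used == spec.requested
        assert not spec.dropped_reasons

    def test_absent_column_dropped(self, tiny_sheet):
        spec = screen_covariates(tiny_sheet.drop(columns="age"))
        assert spec.dropped_reasons["age"] == "absent"


class TestAdjustedLinearModel:
    def test_equal_means_zero_coefficient(self):
        fco = pd.Series([0.1, 0.2, 0.3, 0.1, 0.2, 0.3],
                        index=[f"s{i}" for i in range(6)])
        group = pd.Series(["tumor"] * 3 + ["nontumor"] * 3, index=fco.index)
        res = adjusted_linear_model(fco, group, plain_sheet(group), NO_COVARIATES)
        assert res.coef == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_statsmodels_on_toy_table(self, tiny_sheet):
        """Coefficient/t/p agree with an independent statsmodels fit."""
        rng = np.random.default_rng(2)
        fco = pd.Series(rng.random(len(tiny_sheet)) * 0.3,
                        index=tiny_sheet.index)
        spec = screen_covariates(tiny_sheet)
        res = adjusted_linear_model(fco, tiny_sheet["group"], tiny_sheet, spec)
        _, X = build_design(fco, tiny_sheet["group"], tiny_sheet, spec)
        ref = sm.OLS(fco.loc[X.index], X).fit()
        assert res.coef == pytest.approx(ref.params["group"], abs=1e-10)
        assert res.t == pytest.approx(ref.tvalues["group"], abs=1e-8)
        assert res.p == pytest.approx(ref.pvalues["group"], abs=1e-10)

    def test_normal_equations_oracle_eight_rows(self):
        # 4 tumor/4 nontumor, one numeric covariate, solved via the
        # closed-form normal equations independently of the implementation
        fco = pd.Series([0.30, 0.25, 0.20, 0.28, 0.45, 0.50, 0.40, 0.55],
                        index=[f"s{i}" for i in range(8)])
        group = pd.Series(["tumor"] * 4 + ["nontumor"] * 4, index=fco.index)
        age = pd.Series([50, 60, 70, 55, 52, 66, 71, 48.0], index=fco.index)
        sheet = pd.DataFrame({"group": group, "age": age})
        spec = CovariateSpec(("age",), ("age",))
        X = np.column_stack([np.ones(8), age.to_numpy(),
                             (group == "tumor").astype(float)])
        beta = np.linalg.solve(X.T @ X, X.T @ fco.to_numpy())
        resid = fco.to_numpy() - X @ beta
        s2 = resid @ resid / (8 - 3)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[2, 2])
        res = adjusted_linear_model(fco, group, sheet, spec)
        assert res.coef == pytest.approx(beta[2], abs=1e-8)
        assert res.t == pytest.approx(beta[2] / se, abs=1e-8)

    def test_shift_invariance_of_group_effect(self, tiny_sheet):
        rng = np.random.default_rng(3)
        fco = pd.Series(rng.random(len(tiny_sheet)) * 0.3,
                        index=tiny_sheet.index)
        spec = screen_covariates(tiny_sheet)
        a = adjusted_linear_model(fco, tiny_sheet["group"], tiny_sheet, spec)
        b = adjusted_linear_model(fco + 0.1, tiny_sheet["group"], tiny_sheet,
                                  spec)
        assert b.coef == pytest.approx(a.coef, abs=1e-12)
        assert b.params["const"] == pytest.approx(a.params["const"] + 0.1,
                                                  abs=1e-10)

    def test_rank_deficiency_names_columns(self, tiny_sheet):
        sheet = tiny_sheet.assign(age2=tiny_sheet["age"])
        fco = pd.Series(np.linspace(0.1, 0.4, len(sheet)), index=sheet.index)
        spec = CovariateSpec(("age", "age2"), ("age", "age2"))
        with pytest.raises(FcomixError, match="age"):
            adjusted_linear_model(fco, sheet["group"], sheet, spec)

    def test_complete_case_restriction(self, tiny_sheet):
        sheet = tiny_sheet.copy()
        sheet.loc[sheet.index[0], "age"] = np.nan
        fco = pd.Series(np.linspace(0.0, 0.5, len(sheet)), index=sheet.index)
        spec = CovariateSpec(("age",), ("age",))
        res = adjusted_linear_model(fco, sheet["group"], sheet, spec)
        assert res.n == len(sheet) - 1


class TestRandomizationTest:
    def test_exhaustive_matches_independent_enumeration(self):
        """Exact permutation p at n=6 vs an explicit statsmodels loop
        over all 20 label assignments."""
        from itertools import combinations as icomb

        fco = pd.Series([0.05, 0.22, 0.11, 0.30, 0.41, 0.18],
                        index=[f"s{i}" for i in range(6)])
        group = pd.Series(["tumor"] * 3 + ["nontumor"] * 3, index=fco.index)
        sheet = plain_sheet(group)
        obs = adjusted_linear_model(fco, group, sheet, NO_COVARIATES)
        t_null = []
        for idx in icomb(range(6), 3):
            g = np.zeros(6)
            g[list(idx)] = 1.0
            X = sm.add_constant(g)
            fit = sm.OLS(fco.to_numpy(), X).fit()
            t_null.append(fit.tvalues[1])
        exact_p = np.mean(np.abs(t_null) >= abs(obs.t) - 1e-12)
        res = randomization_test(fco, group, sheet, NO_COVARIATES,
                                 B=1000, method="exhaustive")
        assert res.p == pytest.approx(exact_p)

    def test_seed_determinism(self, tiny_sheet):
        rng = np.random.default_rng(4)
        fco = pd.Series(rng.random(len(tiny_sheet)) * 0.3,
                        index=tiny_sheet.index)
        spec = screen_covariates(tiny_sheet)
        a = randomization_test(fco, tiny_sheet["group"], tiny_sheet, spec,
                               B=500, seed=9)
        b = randomization_test(fco, tiny_sheet["group"], tiny_sheet, spec,
                               B=500, seed=9)
        assert a.p == b.p and a.t_obs == b.t_obs

    def test_null_centered_statistic_gives_p_near_one(self):
        # mirror-symmetric design: observed t == 0, every |t*| >= 0
        fco = pd.Series([0.1, 0.2, 0.3, 0.1, 0.2, 0.3],
                        index=[f"s{i}" for i in range(6)])
        group = pd.Series(["tumor"] * 3 + ["nontumor"] * 3, index=fco.index)
        res = randomization_test(fco, group, plain_sheet(group), NO_COVARIATES,
                                 B=2000, seed=0)
        assert res.t_obs == pytest.approx(0.0, abs=1e-12)
        assert res.p > 1 - 3 * np.sqrt(0.25 / 2000)

    def test_floor_reporting(self, tiny_sheet):
        # huge group effect: no permutation should reach the observed t
        fco = pd.Series(
            np.r_[np.full(8, 0.02), np.full(8, 0.82)] +
            np.linspace(0, 0.001, 16),
            index=tiny_sheet.index,
        )
        res = randomization_test(fco, tiny_sheet["group"], tiny_sheet,
                                 NO_COVARIATES, B=2000, seed=1)
        assert res.floor and res.p == pytest.approx(1 / 2000)
        assert format_pvalue(res.p, res.floor, res.B) == "<5E-04"

    def test_vectorized_stats_match_statsmodels_refits(self, tiny_sheet):
        """The fast partialled-out permutation t-statistics must equal
        per-permutation statsmodels refits."""
        rng = np.random.default_rng(6)
        fco = pd.Series(rng.random(len(tiny_sheet)) * 0.3,
                        index=tiny_sheet.index)
        spec = screen_covariates(tiny_sheet)
        y, X = build_design(fco, tiny_sheet["group"], tiny_sheet, spec)
        Z = X.drop(columns="group").to_numpy()
        g = X["group"].to_numpy()
        from fcomix.comparison import _permutation_t_stats

        G = np.column_stack([rng.permutation(g) for _ in range(25)])
        fast = _permutation_t_stats(y.to_numpy(), Z, G)
        for b in range(25):
            fit = sm.OLS(y.to_numpy(), np.column_stack([Z, G[:, b]])).fit()
            assert fast[b] == pytest.approx(fit.tvalues[-1], abs=1e-8)

    def test_agrees_with_t_test_large_n_no_covariates(self):
        rng = np.random.default_rng(7)
        n = 120
        fco = pd.Series(rng.normal(0.2, 0.05, n).clip(0, 1),
                        index=[f"s{i}" for i in range(n)])
        fco.iloc[: n // 2] += 0.012
        group = pd.Series(["tumor"] * (n // 2) + ["nontumor"] * (n // 2),
                          index=fco.index)
        lm = adjusted_linear_model(fco, group, plain_sheet(group), NO_COVARIATES)
        perm = randomization_test(fco, group, plain_sheet(group), NO_COVARIATES,
                                  B=4000, seed=2)
        mc_se = np.sqrt(lm.p * (1 - lm.p) / 4000)
        assert abs(perm.p - lm.p) < 4 * mc_se + 1e-3

    def test_bad_B_fatal(self, tiny_sheet):
        fco = pd.Series(np.linspace(0, 0.5, len(tiny_sheet)),
                        index=tiny_sheet.index)
        with pytest.raises(FcomixError):
            randomization_test(fco, tiny_sheet["group"], tiny_sheet,
                               NO_COVARIATES, B=0)


class TestResidualDiagnostics:
    def test_exact_fit_all_zero(self):
        fco = pd.Series([0.1, 0.1, 0.4, 0.4],
                        index=[f"s{i}" for i in range(4)])
        group = pd.Series(["nontumor", "nontumor", "tumor", "tumor"],
                          index=fco.index)
        res = adjusted_linear_model(fco, group, plain_sheet(group), NO_COVARIATES)
        diag = residual_diagnostics(res)
        assert (diag["std_resid"] == 0).all()
        assert len(diag) == 4

    def test_matches_statsmodels_internal_studentization(self, tiny_sheet):
        rng = np.random.default_rng(8)
        fco = pd.Series(rng.random(len(tiny_sheet)) * 0.3,
                        index=tiny_sheet.index)
        spec = screen_covariates(tiny_sheet)
        res = adjusted_linear_model(fco, tiny_sheet["group"], tiny_sheet, spec)
        diag = residual_diagnostics(res)
        _, X = build_design(fco, tiny_sheet["group"], tiny_sheet, spec)
        fit = sm.OLS(fco.loc[X.index].to_numpy(), X.to_numpy()).fit()
        ref = fit.get_influence().resid_studentized_internal
        np.testing.assert_allclose(diag["std_resid"], ref, atol=1e-8)

    def test_quantile_convention(self):
        fco = pd.Series([0.0, 0.1, 0.25, 0.32, 0.5, 0.61],
                        index=[f"s{i}" for i in range(6)])
        group = pd.Series(["tumor"] * 3 + ["nontumor"] * 3, index=fco.index)
        res = adjusted_linear_model(fco, group, plain_sheet(group), NO_COVARIATES)
        diag = residual_diagnostics(res)
        expected = stats.norm.ppf((np.arange(1, 7) - 0.5) / 6)
        np.testing.assert_allclose(np.sort(diag["theoretical_quantile"]),
                                   expected, atol=1e-12)


class TestCompareGroups:
    def test_small_group_returns_na(self):
        fco = pd.Series([0.1, 0.2, 0.3, 0.4],
                        index=[f"s{i}" for i in range(4)])
        group = pd.Series(["tumor", "tumor", "tumor", "nontumor"],
                          index=fco.index)
        res = compare_groups(fco, plain_sheet(group), B=100, study="TINY")
        assert res.na_reason == "small_group"
        assert res.wilcoxon_p is None and res.perm_p is None

    def test_all_zero_fco_returns_degenerate_na(self):
        # uniformly zero fractions in both groups (the prostate-like case)
        fco = pd.Series(np.zeros(12), index=[f"s{i}" for i in range(12)])
        group = pd.Series(["tumor"] * 6 + ["nontumor"] * 6, index=fco.index)
        res = compare_groups(fco, plain_sheet(group), B=100)
        assert res.na_reason == "degenerate_variance"
        assert format_pvalue(res.lm_p) == "NA"

    def test_full_result_fields(self, tiny_sheet):
        rng = np.random.default_rng(10)
        fco = pd.Series(
            np.r_[rng.random(8) * 0.1, rng.random(8) * 0.1 + 0.2],
            index=tiny_sheet.index,
        )
        res = compare_groups(fco, tiny_sheet, B=500, seed=3, study="TOY")
        assert res.n_tumor == res.n_nontumor == 8
        assert 0 < res.wilcoxon_p <= 1 and 0 < res.perm_p <= 1
        assert res.lm_coef < 0  # tumor minus nontumor, built negative
        assert res.mean_fco_tumor < res.mean_fco_nontumor


class TestFormatting:
    @pytest.mark.parametrize(
        "p,floor,B,expected",
        [
            (1.0 / 50_000, True, 50_000, "<2E-05"),
            (0.00052, False, None, "0.00052"),
            (1.6e-12, False, None, "1.6E-12"),
            (None, False, None, "NA"),
            (0.396, False, None, "0.396"),
        ],
    )
    def test_render(self, p, floor, B, expected):
        assert fcomix.format_pvalue(p, floor, B) == expected
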