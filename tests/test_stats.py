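"""Inference engine: OLS, LOOCV selection, correlations, Holm correction."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from neurocohort.errors import DegenerateDataError, SingularDesignError, ValidationError
from neurocohort.stats import (
    fit_ols,
    holm_bonferroni,
    loocv_residuals,
    loocv_rmse,
    median_split,
    partial_correlation,
    residualize,
    select_model,
    spearman,
    two_sample_t,
)


def _normal_equations(y, X):
    A = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(A.T @ A, A.T @ y)


def _loocv_oracle(y, X):
    """Literal n-refit leave-one-out loop (independent of the hat-matrix path)."""
    X2 = np.asarray(X, dtype=float)
    if X2.ndim == 1:
        X2 = X2[:, None]
    n = len(y)
    out = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        A = np.column_stack([np.ones(n - 1), X2[keep]])
        beta, *_ = np.linalg.lstsq(A, y[keep], rcond=None)
        out[i] = y[i] - np.concatenate([[1.0], X2[i]]) @ beta
    return out


class TestOLS:
    def test_exact_linear_relationship(self, rng):
        X = rng.normal(size=(15, 2))
        y = 1.5 + X @ np.array([2.0, -3.0])
        fit = fit_ols(y, X)
        assert np.abs(fit.residuals).max() < 1e-10
        assert fit.params == pytest.approx([1.5, 2.0, -3.0], abs=1e-10)

    def test_constant_outcome(self, rng):
        X = rng.normal(size=(10, 2))
        fit = fit_ols(np.full(10, 4.2), X)
        assert fit.params[0] == pytest.approx(4.2)
        assert np.abs(fit.params[1:]).max() < 1e-10

    def test_matches_normal_equations_and_statsmodels(self, rng):
        for _ in range(20):
            n, p = int(rng.integers(10, 30)), int(rng.integers(1, 4))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            fit = fit_ols(y, X)
            assert fit.params == pytest.approx(_normal_equations(y, X), abs=1e-8)
            ref = sm.OLS(y, sm.add_constant(X)).fit()
            assert fit.bse == pytest.approx(np.asarray(ref.bse), abs=1e-8)
            assert fit.tvalues == pytest.approx(np.asarray(ref.tvalues), abs=1e-6)
            assert fit.pvalues == pytest.approx(np.asarray(ref.pvalues), abs=1e-8)
            assert fit.df_resid == ref.df_resid

    def test_rank_deficiency_raises(self, rng):
        x = rng.normal(size=10)
        with pytest.raises(SingularDesignError):
            fit_ols(rng.normal(size=10), np.column_stack([x, 2 * x]))

    def test_too_few_observations(self, rng):
        with pytest.raises(ValidationError):
            fit_ols(np.ones(3), rng.normal(size=(3, 2)))


class TestLOOCV:
    def test_exact_fit_gives_zero(self, rng):
        X = rng.normal(size=(12, 2))
        y = 0.5 + X @ np.array([1.0, 2.0])
        assert loocv_rmse(y, X) < 1e-8

    def test_fast_path_equals_refit_loop(self, rng):
        for n, p in [(5, 1), (7, 2), (20, 3)]:
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            assert loocv_residuals(y, X) == pytest.approx(_loocv_oracle(y, X), abs=1e-8)

    def test_bias_corrected_is_sd_of_loocv_residuals(self, rng):
        X = rng.normal(size=(25, 2))
        y = rng.normal(size=25)
        e = _loocv_oracle(y, X)
        assert loocv_rmse(y, X) == pytest.approx(np.sqrt(np.mean(e**2) - np.mean(e) ** 2))
        assert loocv_rmse(y, X, bias_corrected=False) == pytest.approx(np.sqrt(np.mean(e**2)))

    def test_noise_predictor_inflates_rmse_in_expectation(self):
        worse = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x1 = rng.normal(size=50)
            y = 2 * x1 + rng.normal(size=50)
            noise = rng.normal(size=50)
            if loocv_rmse(y, np.column_stack([x1, noise])) > loocv_rmse(y, x1):
                worse += 1
        assert worse > 120  # clearly above chance


class TestSelectModel:
    def test_single_candidate(self, rng):
        y = rng.normal(size=20)
        comp = select_model(y, pd.DataFrame({"a": rng.normal(size=20)}))
        assert comp.selected == ("a",)
        assert len(comp.table) == 1

    def test_enumerates_all_nonempty_subsets(self, rng):
        X = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("abc"))
        comp = select_model(rng.normal(size=25), X)
        assert len(comp.table) == 7
        assert comp.criterion == comp.table["loocv_rmse_bc"].min()

    def test_selection_invariant_to_column_order(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        y = 2 * X["a"].to_numpy() + rng.normal(size=30)
        sel1 = select_model(y, X).selected
        sel2 = select_model(y, X[["c", "b", "a"]]).selected
        assert sel1 == sel2

    def test_full_fit_refit_on_selected(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        y = 3 * X["a"].to_numpy() + rng.normal(size=40)
        comp = select_model(y, X)
        assert comp.fit.predictors == comp.selected
        assert comp.fit.n == 40


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman(x, x**3).estimate == pytest.approx(1.0)
        assert spearman(x, -x).estimate == pytest.approx(-1.0)

    def test_tied_data_matches_midrank_oracle(self, rng):
        x = np.array([1, 1, 2, 3, 3, 3, 4, 5, 5, 6], dtype=float)
        y = rng.normal(size=10).round(0)  # induces ties in y as well

        def midranks(v):
            order = np.argsort(v, kind="mergesort")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2
                i = j
            return ranks

        r_oracle = np.corrcoef(midranks(x), midranks(y))[0, 1]
        res = spearman(x, y)
        assert res.estimate == pytest.approx(r_oracle, abs=1e-12)
        t = r_oracle * np.sqrt(8 / (1 - r_oracle**2))
        assert res.pvalue == pytest.approx(2 * sps.t.sf(abs(t), 8), abs=1e-10)

    def test_constant_input_raises(self):
        with pytest.raises(DegenerateDataError):
            spearman(np.ones(5), np.arange(5.0))


class TestPartialCorrelation:
    def test_single_covariate_closed_form(self, rng):
        for _ in range(50):
            x, y, z = rng.normal(size=(3, 40))
            y = y + 0.5 * z
            x = x + 0.3 * z
            r = partial_correlation(x, y, z).estimate
            rxy = np.corrcoef(x, y)[0, 1]
            rxz = np.corrcoef(x, z)[0, 1]
            ryz = np.corrcoef(y, z)[0, 1]
            closed = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
            assert r == pytest.approx(closed, abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x, y = rng.normal(size=(2, 60))
        cov = pd.DataFrame(rng.normal(size=(60, 2)), columns=["c1", "c2"])
        y = y + 0.6 * cov["c1"].to_numpy()
        res = partial_correlation(x, y, cov)
        df = cov.assign(x=x, y=y)
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert res.estimate == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert res.pvalue == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_orthogonal_covariate_keeps_marginal_r(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        z = np.array([-1.0, 1.0, 1.0, -1.0])  # orthogonal to both after centering
        xc, yc = x - x.mean(), y - y.mean()
        assert abs(z @ xc) < 1e-12 and abs(z @ yc) < 1e-12
        assert partial_correlation(x, y, z).estimate == pytest.approx(
            np.corrcoef(x, y)[0, 1], abs=1e-12
        )

    def test_fully_explained_variable_raises(self, rng):
        z = rng.normal(size=20)
        with pytest.raises(DegenerateDataError):
            partial_correlation(rng.normal(size=20), z.copy(), z)


class TestResidualize:
    def test_orthogonality_and_zero_mean(self, rng):
        cov = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        r = residualize(y, cov)
        assert abs(r.mean()) < 1e-10
        assert np.abs(r @ cov).max() < 1e-8

    def test_exact_dependence_gives_zero(self, rng):
        age = rng.uniform(50, 70, 25)
        assert np.abs(residualize(3 * age, age)).max() < 1e-9


class TestMedianSplit:
    def test_midrank_median_example(self):
        res = median_split([0, 0, 1, 1, 2, 3])
        assert res.attrs["median"] == 1.0
        assert list(res["group"]) == ["low", "low", "low", "low", "high", "high"]

    def test_no_or_one_versus_more(self):
        # a combined-risk-like distribution with median 1 splits <=1 vs >1
        scores = [0] * 46 + [1] * 56 + [2] * 33 + [3] * 5 + [4, 5]
        res = median_split(scores)
        assert res.attrs["median"] == 1.0
        assert res.attrs["n_low"] == 102 and res.attrs["n_high"] == 40

    def test_two_subjects(self):
        res = median_split([0, 5])
        assert res.attrs["n_low"] == 1 and res.attrs["n_high"] == 1

    def test_identical_scores_degenerate(self):
        with pytest.raises(DegenerateDataError):
            median_split([2, 2, 2, 2])


class TestTwoSampleT:
    def test_identical_groups(self):
        t, df, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert df == 4
        assert p == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=8), rng.normal(1, 1, size=9)
        t1, df1, p1 = two_sample_t(a, b)
        t2, df2, p2 = two_sample_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)
        assert df1 == df2 == 15

    def test_hand_computed_pooled_formula(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 6.0])
        sp2 = ((a.var(ddof=1) * 2) + (b.var(ddof=1) * 2)) / 4
        expected_t = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 3))
        t, df, p = two_sample_t(a, b)
        assert t == pytest.approx(expected_t)
        assert p == pytest.approx(2 * sps.t.sf(abs(expected_t), 4))

    def test_welch_flag(self, rng):
        a, b = rng.normal(size=10), rng.normal(0, 5, size=12)
        t, df, p = two_sample_t(a, b, welch=True)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert df == pytest.approx(ref.df)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateDataError):
            two_sample_t([1.0, 1.0], [2.0, 2.0])

    def test_type_one_error_rate_under_null(self):
        """Pooled t at alpha = .05 rejects ~5% of null replicates (n = 20 + 20)."""
        rng = np.random.default_rng(7)
        a = rng.normal(size=(5000, 20))
        b = rng.normal(size=(5000, 20))
        res = sps.ttest_ind(a, b, axis=1)  # vectorized for speed
        rate = float((res.pvalue < 0.05).mean())
        assert 0.04 <= rate <= 0.06
        # spot-check agreement with the package implementation
        t, df, p = two_sample_t(a[0], b[0])
        assert p == pytest.approx(float(res.pvalue[0]))


class TestHolm:
    def test_worked_example(self):
        adj = holm_bonferroni([0.01, 0.03, 0.04], alpha=0.05)
        assert adj.pvalues_adjusted == pytest.approx([0.03, 0.06, 0.06])
        assert list(adj.reject) == [True, False, False]

    def test_single_and_extreme_pvalues(self):
        assert holm_bonferroni([0.2]).pvalues_adjusted == pytest.approx([0.2])
        assert holm_bonferroni([0.0, 0.0, 0.0]).reject.all()

    def test_invalid_pvalues(self):
        with pytest.raises(ValidationError):
            holm_bonferroni([0.1, 1.2])
        with pytest.raises(ValidationError):
            holm_bonferroni([0.1], alpha=1.5)

    def test_invariants_against_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            m = int(rng.integers(1, 12))
            p = rng.uniform(size=m)
            adj = holm_bonferroni(p, alpha=0.05)
            assert (adj.pvalues_adjusted >= p - 1e-15).all()
            order = np.argsort(p)
            assert (np.diff(adj.pvalues_adjusted[order]) >= -1e-15).all()
            reject_sm, p_sm, *_ = multipletests(p, alpha=0.05, method="holm")
            assert adj.pvalues_adjusted == pytest.approx(p_sm, abs=1e-12)
            assert (adj.reject == reject_sm).all()
            # Bonferroni-rejections subset Holm subset unadjusted
            bonf = p * m <= 0.05
            assert (adj.reject | ~bonf).all()
            assert (~adj.reject | (p <= 0.05)).all()
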