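"""Regression layer against closed-form and library oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from phoskit import stats
from phoskit.errors import CollinearityError, DomainError


@pytest.fixture()
def design(rng):
    n = 60
    X = pd.DataFrame(
        {
            "a": rng.standard_normal(n),
            "b": rng.standard_normal(n),
            "c": rng.standard_normal(n),
        }
    )
    y = 0.5 * X["a"] - 0.3 * X["b"] + rng.standard_normal(n)
    return y, X


class TestOlsStandardized:
    def test_exact_linear_relation_no_intercept(self):
        x = np.arange(1.0, 21.0)
        fit = stats.ols_standardized(2 * x, pd.DataFrame({"x": x}), intercept=False)
        pred = fit.predictors[0]
        assert pred.beta == pytest.approx(2.0, rel=1e-12)
        assert pred.partial_r == pytest.approx(1.0, rel=1e-9)
        assert pred.p < 1e-20

    def test_matches_normal_equations_oracle(self, design):
        y, X = design
        fit = stats.ols_standardized(y, X)
        A = np.column_stack([np.ones(len(y)), X.to_numpy()])
        coef = np.linalg.pinv(A) @ np.asarray(y)
        for j, pred in enumerate(fit.predictors):
            assert pred.beta == pytest.approx(coef[j + 1], abs=1e-9)

    def test_null_design_rarely_significant(self):
        # independent response: smallest p across 3 predictors should behave
        # like a null test family in the vast majority of seeded replicates
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.standard_normal((200, 3)), columns=list("abc"))
            y = rng.standard_normal(200)
            fit = stats.ols_standardized(y, X)
            if min(p.p for p in fit.predictors) <= 0.01:
                hits += 1
        assert hits <= 5

    def test_rank_deficient_design_names_columns(self, rng):
        x = rng.standard_normal(30)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(CollinearityError, match="a"):
            stats.ols_standardized(rng.standard_normal(30), X)


class TestPartialCorrelation:
    def test_empty_control_set_is_pearson(self, rng):
        x = rng.standard_normal(50)
        y = x + rng.standard_normal(50)
        r, p = stats.partial_correlation(y, x)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-9)
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_x_in_span_of_controls_rejected(self, rng):
        z = rng.standard_normal(40)
        with pytest.raises(DomainError):
            stats.partial_correlation(rng.standard_normal(40), 3 * z + 1, pd.DataFrame({"z": z}))

    def test_matches_inverse_correlation_matrix_oracle(self, rng):
        n = 120
        Z = pd.DataFrame(rng.standard_normal((n, 2)), columns=["z1", "z2"])
        x = Z["z1"] * 0.4 + rng.standard_normal(n)
        y = x * 0.5 + Z["z2"] * 0.3 + rng.standard_normal(n)
        r, _ = stats.partial_correlation(y, x, Z)
        # oracle: precision-matrix formula on the full correlation matrix
        M = np.corrcoef(np.column_stack([y, x, Z]), rowvar=False)
        P = np.linalg.inv(M)
        r_ref = -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
        assert r == pytest.approx(r_ref, abs=1e-9)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 80
        df = pd.DataFrame(rng.standard_normal((n, 4)), columns=["y", "x", "z1", "z2"])
        r, p = stats.partial_correlation(df["y"], df["x"], df[["z1", "z2"]])
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)


class TestMixedEffects:
    def test_single_group_matches_pooled_ols(self, design):
        y, X = design
        pooled = stats.ols_standardized(y, X)
        mixed = stats.mixed_effects(y, X, np.zeros(len(y), dtype=int))
        for a, b in zip(pooled.predictors, mixed.predictors):
            assert a.beta == pytest.approx(b.beta, abs=1e-5)

    def test_zero_between_group_variance_detected(self, rng):
        n = 300
        X = pd.DataFrame({"x": rng.standard_normal(n)})
        groups = np.repeat([0, 1, 2], n // 3)
        y = 0.4 * X["x"] + rng.standard_normal(n)  # no group offsets
        fit = stats.mixed_effects(y, X, groups)
        assert fit.predictor("x").beta == pytest.approx(0.4, abs=0.15)


class TestWelchT:
    def test_identical_groups(self):
        t, df, p = stats.welch_t([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert t == 0.0 and p == 1.0

    def test_matches_textbook_formula_and_scipy(self, rng):
        a = rng.normal(0, 1, 25)
        b = rng.normal(0.5, 2, 40)
        t, df, p = stats.welch_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        df_ref = (va / 25 + vb / 40) ** 2 / (
            (va / 25) ** 2 / 24 + (vb / 40) ** 2 / 39
        )
        assert df == pytest.approx(df_ref, rel=1e-12)

    def test_equal_variance_case_matches_pooled_t(self, rng):
        a = rng.normal(0, 1, 30)
        b = a + 0.3  # exactly equal variances
        t, df, p = stats.welch_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic, rel=1e-9)


class TestVif:
    def test_orthogonal_design_all_one(self):
        X = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0]})
        assert all(v == pytest.approx(1.0) for v in stats.vif(X).values())

    def test_duplicated_column_infinite(self, rng):
        x = rng.standard_normal(20)
        out = stats.vif(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(out["a"]) and np.isinf(out["b"])

    def test_matches_r_squared_oracle(self, rng):
        n = 100
        a = rng.standard_normal(n)
        b = 0.7 * a + rng.standard_normal(n)
        c = rng.standard_normal(n)
        X = pd.DataFrame({"a": a, "b": b, "c": c})
        out = stats.vif(X)
        for col in X:
            others = X.drop(columns=[col]).to_numpy()
            A = np.column_stack([np.ones(n), others])
            resid = X[col] - A @ np.linalg.lstsq(A, X[col], rcond=None)[0]
            r2 = 1 - (resid @ resid) / ((X[col] - X[col].mean()) ** 2).sum()
            assert out[col] == pytest.approx(1 / (1 - r2), abs=1e-9)


class TestBonferroni:
    def test_examples_and_clipping(self):
        adj, stars = stats.bonferroni([0.01, 0.5], m=4)
        assert adj[0] == pytest.approx(0.04) and stars[0] == "*"
        adj, stars = stats.bonferroni([0.5], m=10)
        assert adj[0] == 1.0 and stars[0] == ""

    def test_order_preserving(self, rng):
        p = np.sort(rng.random(20))
        adj, _ = stats.bonferroni(p, m=25)
        assert (np.diff(adj) >= 0).all()

    def test_family_smaller_than_pvals_rejected(self):
        with pytest.raises(DomainError):
            stats.bonferroni([0.1, 0.2, 0.3], m=2)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        p=st.lists(st.floats(0, 1), min_size=1, max_size=12),
        extra=st.integers(0, 20),
    )
    def test_adjustment_properties(self, p, extra):
        adj, stars = stats.bonferroni(p, m=len(p) + extra)
        assert (adj >= np.asarray(p) - 1e-15).all()  # never less significant
        assert (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()  # order preserved


class TestCompareModels:
    def test_identical_specs_no_preference(self, rng):
        df = pd.DataFrame({"y": rng.standard_normal(50), "x": rng.standard_normal(50)})
        cmp_ = stats.compare_models(df, "y", ["x"], ["x"])
        assert cmp_.delta_aic == 0.0
        assert cmp_.verdict_aic == "no preference"

    def test_pure_noise_predictor_penalty_arithmetic(self, rng):
        n = 80
        df = pd.DataFrame(
            {
                "y": rng.standard_normal(n),
                "x": rng.standard_normal(n),
                "noise": rng.standard_normal(n),
            }
        )
        cmp_ = stats.compare_models(df, "y", ["x"], ["x", "noise"])
        # adding a useless predictor can improve AIC by at most 2
        assert cmp_.model_b.aic >= cmp_.model_a.aic - 2.0
        # BIC penalizes the extra parameter harder for n > 7
        assert cmp_.delta_bic <= cmp_.delta_aic

    def test_affine_response_rescaling_keeps_deltas(self, rng):
        n = 60
        df = pd.DataFrame(
            {
                "y": rng.standard_normal(n),
                "x1": rng.standard_normal(n),
                "x2": rng.standard_normal(n),
            }
        )
        df["y"] = 0.4 * df["x1"] + df["y"]
        base = stats.compare_models(df, "y", ["x1"], ["x2"])
        df2 = df.assign(y=3.0 * df["y"] + 7.0)
        scaled = stats.compare_models(df2, "y", ["x1"], ["x2"])
        assert scaled.delta_aic == pytest.approx(base.delta_aic, abs=1e-6)

    def test_generative_recovery_prefers_true_model(self):
        wins = 0
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            n = 60
            between = rng.uniform(0, 3000, n)
            along = rng.uniform(0, 3000, n)
            p_two = 1 / (1 + np.exp(-(between - 1500) / 500))
            y = (rng.random(n) < p_two) + 1.0
            df = pd.DataFrame({"y": y, "between": between, "along": along})
            cmp_ = stats.compare_models(df, "y", ["along"], ["between"])
            if cmp_.delta_aic >= 2:
                wins += 1
        assert wins >= 27  # >= 90 percent of replicates


class TestSummationRegression:
    @staticmethod
    def _points(slope, n, rng, noise=0.0):
        singles = []
        paired = []
        for i in range(n):
            e1, e2 = f"A{i}", f"B{i}"
            a1, a2 = rng.uniform(50, 150, 2)
            for e, a in [(e1, a1), (e2, a2)]:
                singles.append(
                    {"participant": "P1", "electrode_key": e, "amplitude": 2.0,
                     "frequency": 20.0, "area": a, "perimeter": a / 10,
                     "major": a / 20, "minor": a / 40}
                )
            s = a1 + a2
            eps = 1 + noise * rng.standard_normal()
            paired.append(
                {"participant": "P1", "electrode_key": f"{e1}+{e2}", "amplitude": 2.0,
                 "frequency": 20.0, "area": slope * s * eps,
                 "perimeter": slope * s / 10 * eps, "major": slope * s / 20 * eps,
                 "minor": slope * s / 40 * eps}
            )
        return pd.DataFrame(paired), pd.DataFrame(singles)

    def test_exact_sum_gives_unit_slope(self, rng):
        paired, singles = self._points(1.0, 20, rng)
        fits, matched, excluded = stats.summation_regression(paired, singles)
        assert excluded == []
        assert fits["area"].predictors[0].beta == pytest.approx(1.0, rel=1e-12)
        assert fits["area"].predictors[0].partial_r == pytest.approx(1.0, rel=1e-9)

    def test_exact_half_sum(self, rng):
        paired, singles = self._points(0.5, 15, rng)
        fits, _, _ = stats.summation_regression(paired, singles)
        assert fits["minor"].predictors[0].beta == pytest.approx(0.5, rel=1e-12)

    def test_planted_slope_recovered_under_noise(self):
        rng = np.random.default_rng(42)
        paired, singles = self._points(0.65, 100, rng, noise=0.05)
        fits, _, _ = stats.summation_regression(paired, singles)
        assert 0.60 <= fits["area"].predictors[0].beta <= 0.70

    def test_unmatched_pair_excluded_with_log(self, rng):
        paired, singles = self._points(1.0, 5, rng)
        singles = singles[singles.electrode_key != "A0"]
        fits, matched, excluded = stats.summation_regression(paired, singles)
        assert len(excluded) == 1
        assert excluded[0]["electrode_key"] == "A0+B0"
        assert len(matched) == 4
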