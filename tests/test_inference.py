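"""Model enumeration, AICc ranking, averaging, VIF and t-tests."""

import numpy as np
import pandas as pd
import pytest

from avitherm import inference as inf


def _table_from_data(rng, n=24, terms=inf.DEFAULT_TERMS):
    data = pd.DataFrame({
        "sex": ["M"] * (n // 2) + ["F"] * (n - n // 2),
        "bill_index": rng.normal(0, 0.05, n),
        "tarsi_index": rng.normal(0, 0.04, n),
        "Mb": rng.normal(16.5, 0.8, n),
    })
    data["y"] = 1.0 + 0.5 * data["tarsi_index"] + rng.normal(0, 0.05, n)
    return data, inf.rank_models(data, "y", terms=terms)


class TestFitLM:
    def test_intercept_only_hand_ols(self):
        X = pd.DataFrame({"Intercept": [1.0, 1.0, 1.0]})
        fit = inf.fit_lm(X, np.array([1.0, 2.0, 3.0]))
        assert fit.params["Intercept"] == pytest.approx(2.0)
        assert fit.rss == pytest.approx(2.0)
        assert fit.k == 2  # intercept + residual variance

    def test_perfect_fit_flagged_degenerate(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        X = pd.DataFrame({"Intercept": np.ones(4), "x": x})
        fit = inf.fit_lm(X, 2.0 * x)
        assert "degenerate_perfect_fit" in fit.flags
        assert fit.r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        x1 = np.array([1.0, 2.0, 3.0, 4.0])
        x2 = np.array([0.5, -0.5, 1.5, 0.0])
        y = np.array([2.0, 3.1, 4.9, 5.2])
        X = pd.DataFrame({"Intercept": np.ones(4), "x1": x1, "x2": x2})
        fit = inf.fit_lm(X, y)
        A = X.to_numpy()
        beta = np.linalg.solve(A.T @ A, A.T @ y)  # normal equations
        assert fit.params.to_numpy() == pytest.approx(beta, abs=1e-10)
        rss = float(np.sum((y - A @ beta) ** 2))
        assert fit.rss == pytest.approx(rss, abs=1e-10)
        n = 4
        assert fit.loglik == pytest.approx(
            -n / 2 * (np.log(2 * np.pi * rss / n) + 1))

    def test_rank_deficiency_rejected(self):
        X = pd.DataFrame({"Intercept": np.ones(5), "a": np.arange(5.0),
                          "b": 2 * np.arange(5.0)})
        with pytest.raises(ValueError):
            inf.fit_lm(X, np.arange(5.0) + 1.0)


class TestAICc:
    @pytest.mark.parametrize("loglik,expected", [
        (16.39, -28.208571428571428),
        (36.28, -67.98857142857143),
    ])
    def test_small_sample_values(self, loglik, expected):
        assert inf.aicc(loglik, 2, 24) == pytest.approx(expected, abs=1e-12)

    def test_large_n_limit_is_aic(self):
        assert inf.aicc(10.0, 3, 10 ** 9) == \
            pytest.approx(-2 * 10.0 + 2 * 3, abs=1e-6)

    def test_undefined_for_tiny_n(self):
        with pytest.raises(ValueError):
            inf.aicc(0.0, 3, 4)


class TestEnumerate:
    def test_standard_pool_gives_13(self):
        assert len(inf.enumerate_models()) == 13

    def test_single_main_effect_gives_2(self):
        specs = inf.enumerate_models(("sex",))
        assert len(specs) == 2
        assert frozenset() in {s.terms for s in specs}

    def test_marginality_everywhere(self):
        for spec in inf.enumerate_models():
            for term in spec.terms:
                if ":" in term:
                    assert all(m in spec.terms for m in term.split(":"))

    def test_spec_rejects_orphan_interaction(self):
        with pytest.raises(ValueError):
            inf.ModelSpec("y", frozenset({"bill_index:sex"}))


class TestRanking:
    def test_weights_sum_to_one(self, rng):
        _, table = _table_from_data(rng)
        assert table.table["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert table.table["dAICc"].iloc[0] == 0.0
        assert (table.table["dAICc"] >= 0).all()

    def test_known_delta_weights(self):
        """Delta = (0, 2, 4) maps to weights (0.665, 0.245, 0.090)."""
        d = np.array([0.0, 2.0, 4.0])
        w = np.exp(-d / 2)
        w = w / w.sum()
        assert w == pytest.approx([0.66524096, 0.24472847, 0.09003057],
                                  abs=1e-8)

    def test_single_model(self, rng):
        data, _ = _table_from_data(rng)
        table = inf.rank_models(data, "y",
                                specs=[inf.ModelSpec("y", frozenset())])
        assert table.table["weight"].iloc[0] == pytest.approx(1.0)
        assert table.table["dAICc"].iloc[0] == 0.0


def _fit(terms, params, se, weightless_spec="y"):
    spec = inf.ModelSpec(weightless_spec, frozenset(terms))
    names = ["Intercept"] + sorted(terms)
    return inf.LinearFit(spec=spec, params=pd.Series(params, index=names),
                         bse=pd.Series(se, index=names), rss=1.0,
                         loglik=0.0, k=len(names) + 1, n=24, r2=0.5)


def _manual_table(fits, weights):
    rows = pd.DataFrame({
        "model": [f.spec.label for f in fits],
        "k": [f.k for f in fits],
        "logLik": [f.loglik for f in fits],
        "AICc": np.zeros(len(fits)),
        "dAICc": np.zeros(len(fits)),
        "weight": weights,
        "R2": [f.r2 for f in fits],
    })
    return inf.ModelTable(rows, fits)


class TestAveraging:
    def test_two_models_hand_formula(self):
        """Equal weights, estimates 1 and 3 with zero SE: mean 2 and
        unconditional SE 1 (pure between-model spread)."""
        fits = [_fit({"tarsi_index"}, [0.0, 1.0], [0.0, 0.0]),
                _fit({"tarsi_index"}, [0.0, 3.0], [0.0, 0.0])]
        table = _manual_table(fits, [0.5, 0.5])
        avg = inf.model_average(table)
        assert avg.table.loc["tarsi_index", "estimate"] == pytest.approx(2.0)
        assert avg.table.loc["tarsi_index", "se"] == pytest.approx(1.0)

    def test_predictor_in_single_model_passthrough(self):
        fits = [_fit({"tarsi_index"}, [0.0, 1.5], [0.0, 0.2]),
                _fit(set(), [0.1], [0.05])]
        table = _manual_table(fits, [0.5, 0.5])
        avg = inf.model_average(table)
        assert avg.table.loc["tarsi_index", "estimate"] == pytest.approx(1.5)
        assert avg.table.loc["tarsi_index", "se"] == pytest.approx(0.2)

    def test_significance_iff_ci_excludes_zero(self):
        fits = [_fit({"tarsi_index"}, [0.0, 1.5], [0.0, 0.2]),
                _fit({"bill_index"}, [0.0, 0.1], [0.0, 0.2])]
        table = _manual_table(fits, [0.5, 0.5])
        avg = inf.model_average(table)
        for term in ("tarsi_index", "bill_index"):
            row = avg.table.loc[term]
            assert row["significant"] == (row["ci_lo"] > 0 or row["ci_hi"] < 0)
        assert avg.table.loc["tarsi_index", "significant"]
        assert not avg.table.loc["bill_index", "significant"]

    def test_estimate_in_convex_hull(self, rng):
        _, table = _table_from_data(rng)
        avg = inf.model_average(table)
        for term in avg.table.index:
            ests = [f.params[term] for f in table.top_set().fits
                    if term in f.params.index]
            if ests:
                assert min(ests) - 1e-12 <= avg.table.loc[term, "estimate"] \
                    <= max(ests) + 1e-12


class TestRIW:
    def test_bounds_cases(self):
        everywhere = [_fit({"tarsi_index"}, [0.0, 1.0], [0.0, 0.1]),
                      _fit({"tarsi_index", "sex"}, [0.0, 0.5, 1.0],
                           [0.0, 0.1, 0.1])]
        table = _manual_table(everywhere, [0.6, 0.4])
        assert inf.riw("tarsi_index", table) == pytest.approx(1.0)
        assert inf.riw("sex", table) == pytest.approx(0.4)
        with pytest.raises(ValueError):
            inf.riw("unknown_term", table)

    def test_matches_manual_summation(self, rng):
        _, table = _table_from_data(rng)
        manual = sum(w for f, w in zip(table.fits, table.table["weight"])
                     if "tarsi_index" in f.spec.terms)
        assert inf.riw("tarsi_index", table) == pytest.approx(manual)


class TestVIF:
    def test_orthogonal_predictors(self):
        X = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0],
                          "c": [1, -1, -1, 1.0]})
        assert inf.vif(X).to_numpy() == pytest.approx([1.0, 1.0, 1.0])

    def test_duplicated_predictor_infinite(self):
        x = np.arange(6.0)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": np.ones(6)})
        out = inf.vif(X)
        assert np.isinf(out["a"]) and np.isinf(out["b"])

    def test_matches_r2_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        X["a"] = X["a"] + 0.8 * X["b"]
        got = inf.vif(X)
        import statsmodels.api as sm
        for col in X.columns:
            others = sm.add_constant(X.drop(columns=col))
            r2 = sm.OLS(X[col], others).fit().rsquared
            assert got[col] == pytest.approx(1.0 / (1.0 - r2))


class TestTTests:
    def test_identical_groups(self):
        t, df, p = inf.two_sample_t([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert (t, p) == (0.0, 1.0)
        assert df == 4

    def test_pooled_two_sample_hand_oracle(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [2.0, 4.0, 6.0, 8.0, 10.0]
        t, df, p = inf.two_sample_t(a, b)
        assert df == 8
        assert t == pytest.approx(-1.8973665961010275, abs=1e-12)
        assert p == pytest.approx(0.09434977284243762, abs=1e-10)

    def test_paired_constant_difference(self):
        t, df, p = inf.paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert np.isinf(t) and p == 0.0 and df == 2

    def test_paired_matches_two_sample_on_differences(self, rng):
        a = rng.normal(1.0, 0.3, 12)
        b = rng.normal(0.9, 0.3, 12)
        t, df, p = inf.paired_t(a, b)
        d = a - b
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert t == pytest.approx(t_manual, abs=1e-10)
        assert df == 11
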