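"""AICc machinery, collinearity screening, group comparisons, and candidate
mixed-model fits, checked against published-table arithmetic and oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from arcrange import hr_models as hm, synthetic_data as sd

TABLE6_AICC = [
    -74.01, -73.68, -72.11, -60.01, -45.74, -39.73,
    -30.19, -29.22, -27.76, 7.80, 16.23, 22.28,
]
TABLE6_TERMS = [
    ("rs", "s1lsi"), ("s1lsi",), ("rs", "s1lsi", "wlsi"), ("rs", "s1lsi^2"),
    ("rs", "s3prop", "s3lsi"), ("rs", "s3prop", "s3lsi", "wlsi"),
    ("s2lsi", "s2prop"), ("rs", "s2prop", "s2lsi"), ("s2lsi", "s2prop", "wlsi"),
    ("rs", "wlsi"), ("rs",), (),
]


def table6_records():
    deltas, weights = hm.akaike_weights(TABLE6_AICC)
    recs = [
        hm.ModelRecord(terms=t, k=1 + len(t), logl=0.0, aicc=a,
                       daicc=float(d), weight=float(w))
        for t, a, d, w in zip(TABLE6_TERMS, TABLE6_AICC, deltas, weights)
    ]
    return recs


class TestAkaikeWeights:
    def test_reproduces_final_candidate_table(self):
        deltas, weights = hm.akaike_weights(TABLE6_AICC)
        assert [round(w, 2) for w in weights[:3]] == [0.45, 0.38, 0.17]
        assert all(round(w, 2) == 0.0 for w in weights[3:])
        # printed delta column to rounding
        printed = [0.0, 0.3, 1.9, 14.0, 28.3, 34.3, 43.8, 44.8, 46.2, 81.8, 90.2, 96.3]
        np.testing.assert_allclose(deltas, printed, atol=0.05)

    def test_season1_null_delta(self):
        deltas, _ = hm.akaike_weights([-74.01, 22.28])
        assert deltas[1] == pytest.approx(96.29, abs=0.005)  # prints as 96.3
        assert round(float(deltas[1]), 1) == 96.3

    def test_two_equal_models_split_weight(self):
        _, w = hm.akaike_weights([10.0, 10.0])
        np.testing.assert_allclose(w, [0.5, 0.5])

    def test_single_model_weight_one(self):
        _, w = hm.akaike_weights([3.0])
        assert w[0] == 1.0

    @given(st.floats(-500, 500, allow_nan=False))
    def test_invariant_to_constant_shift(self, c):
        _, w1 = hm.akaike_weights(TABLE6_AICC)
        _, w2 = hm.akaike_weights([a + c for a in TABLE6_AICC])
        np.testing.assert_allclose(w1, w2, atol=1e-9)


class TestConfidenceSet:
    def test_published_set_has_three_models(self):
        conf = hm.confidence_set(table6_records())
        assert len(conf) == 3
        assert {r.name for r in conf} == {"rs+s1lsi", "s1lsi", "rs+s1lsi+wlsi"}

    def test_equal_weights_keep_all(self):
        recs = [
            hm.ModelRecord(terms=(t,), k=2, logl=0, aicc=1.0, weight=0.25)
            for t in "abcd"
        ]
        assert len(hm.confidence_set(recs)) == 4

    def test_dominant_model_is_singleton(self):
        recs = [
            hm.ModelRecord(terms=("a",), k=2, logl=0, aicc=0.0, weight=0.99),
            hm.ModelRecord(terms=("b",), k=2, logl=0, aicc=20.0, weight=0.01),
        ]
        assert len(hm.confidence_set(recs)) == 1


class TestImportance:
    def test_published_importance_and_plausibility(self):
        conf = hm.confidence_set(table6_records())
        imp = hm.importance_weights(conf)
        assert round(imp["s1lsi"], 2) == 1.00
        assert round(imp["rs"], 2) == 0.62
        assert round(hm.plausibility_ratio(imp, "s1lsi", "rs"), 2) == 1.61

    def test_singleton_set_gives_unit_importance(self):
        recs = [hm.ModelRecord(terms=("a", "b"), k=3, logl=0, aicc=0.0, weight=1.0)]
        imp = hm.importance_weights(recs)
        assert imp == {"a": 1.0, "b": 1.0}

    def test_absent_term_zero(self):
        recs = [hm.ModelRecord(terms=("a",), k=2, logl=0, aicc=0.0, weight=1.0)]
        assert hm.importance_weights(recs, terms=["zzz"])["zzz"] == 0.0


class TestModelAverage:
    def test_singleton_returns_best_coefficients(self):
        rec = hm.ModelRecord(
            terms=("a",), k=2, logl=0, aicc=0.0, weight=1.0,
            coef={"intercept": 1.0, "a": 0.5},
        )
        out = hm.model_average([rec])
        assert out.averaged_coef == rec.coef

    def test_weighted_mean_arithmetic(self):
        recs = [
            hm.ModelRecord(terms=("a",), k=2, logl=0, aicc=0.0, weight=0.5,
                           coef={"a": 1.0}),
            hm.ModelRecord(terms=("a",), k=2, logl=0, aicc=1.0, weight=0.3,
                           coef={"a": 2.0}),
            hm.ModelRecord(terms=("b",), k=2, logl=0, aicc=2.0, weight=0.2,
                           coef={"b": -1.0}),
        ]
        out = hm.model_average(recs)
        assert out.averaged_coef["a"] == pytest.approx((0.5 + 0.6) / 0.8)
        assert out.averaged_coef["b"] == pytest.approx(-1.0)

    def test_identical_coefficient_unchanged(self):
        recs = [
            hm.ModelRecord(terms=("a",), k=2, logl=0, aicc=0.0, weight=0.6,
                           coef={"a": 0.7}),
            hm.ModelRecord(terms=("a",), k=2, logl=0, aicc=0.5, weight=0.4,
                           coef={"a": 0.7}),
        ]
        assert hm.model_average(recs).averaged_coef["a"] == pytest.approx(0.7)


class TestCollinearity:
    def test_duplicate_covariate_excluded(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=50)})
        y = pd.Series(x + rng.normal(0, 0.1, 50))
        kept, pairs, _ = hm.collinearity_screen(df, y)
        assert len(pairs) == 1 and ("a" in kept) != ("b" in kept)
        assert "c" in kept

    def test_independent_covariates_rarely_excluded(self, rng):
        excl = 0
        for rep in range(40):
            df = pd.DataFrame(rng.normal(size=(43, 4)), columns=list("abcd"))
            y = pd.Series(rng.normal(size=43))
            _, pairs, _ = hm.collinearity_screen(df, y)
            excl += bool(pairs)
        assert excl <= 2  # n=43, |r|>=0.6 under independence is very rare

    def test_near_duplicate_flagged_by_vif(self, rng):
        x1 = rng.normal(size=60)
        df = pd.DataFrame(
            {"x1": x1, "x2": x1 + rng.normal(0, 0.05, 60), "x3": rng.normal(size=60)}
        )
        y = pd.Series(rng.normal(size=60))
        _, _, vif_check = hm.collinearity_screen(df, y, r_threshold=1.1)
        ok, vifs = vif_check(["x1", "x2"])
        assert not ok and vifs["x1"] > 10
        # VIF oracle: 1 / (1 - R^2) of the auxiliary regression
        r2 = np.corrcoef(df["x1"], df["x2"])[0, 1] ** 2
        assert vifs["x1"] == pytest.approx(1 / (1 - r2), rel=0.05)
        ok2, _ = vif_check(["x1", "x3"])
        assert ok2

    def test_constant_covariate_excluded(self, rng):
        df = pd.DataFrame({"a": np.ones(30), "b": rng.normal(size=30)})
        kept, _, _ = hm.collinearity_screen(df, pd.Series(rng.normal(size=30)))
        assert kept == ["b"]


class TestGroupCompare:
    def test_equal_samples_give_zero_t(self):
        vals = np.array([2.0, 2.5, 3.0, 3.5])
        df = pd.DataFrame(
            {
                "rs": ["solitary"] * 8 + ["cub-of-year"] * 2 + ["cub1plus"] * 2,
                "age_class": ["subadult"] * 4 + ["adult"] * 4 + ["adult"] * 4,
                "log10_area": np.concatenate([vals, vals, [2.0, 3.0], [2.2, 3.2]]),
            }
        )
        out = hm.group_compare(df)
        assert out["subadult_t"] == pytest.approx(0.0, abs=1e-12)
        assert out["pooled"]

    def test_power_at_field_sample_sizes(self, rng):
        # 3x area separation between cub-of-year and cub>=1yr, n = 6/19/18
        detected = 0
        for rep in range(100):
            r = np.random.default_rng(rep)
            df = pd.DataFrame(
                {
                    "rs": ["cub-of-year"] * 6 + ["solitary"] * 19 + ["cub1plus"] * 18,
                    "log10_area": np.concatenate(
                        [
                            r.normal(np.log10(290), 0.25, 6),
                            r.normal(np.log10(600), 0.25, 19),
                            r.normal(np.log10(870), 0.25, 18),
                        ]
                    ),
                }
            )
            out = hm.group_compare(df, age_col=None)
            tuk = out["tukey"]
            row = tuk[
                tuk[["group1", "group2"]]
                .apply(lambda s: set(s) == {"cub-of-year", "cub1plus"}, axis=1)
            ]
            if float(row["p-adj"].iloc[0]) < 0.05:
                detected += 1
        assert detected >= 80

    def test_null_anova_p_uniform(self):
        ps = []
        for rep in range(200):
            r = np.random.default_rng(10_000 + rep)
            df = pd.DataFrame(
                {
                    "rs": ["cub-of-year"] * 6 + ["solitary"] * 19 + ["cub1plus"] * 18,
                    "log10_area": r.normal(2.7, 0.3, 43),
                }
            )
            ps.append(hm.group_compare(df, age_col=None)["anova_p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


@pytest.fixture(scope="module")
def sim():
    return sd.simulate_range_covariates(seed=0)


class TestFitCandidates:

    def test_null_model_r2_zero(self, sim):
        rec = hm.fit_one(sim, ())
        assert rec.r2 == 0.0

    def test_k_convention(self):
        assert hm.count_k(()) == 1
        assert hm.count_k(("rs",)) == 2
        assert hm.count_k(("rs", "s1lsi")) == 3
        assert hm.count_k(("rs", "s1lsi", "s1lsi^2")) == 4
        assert hm.count_k(("rs",), convention="standard") == 4

    def test_nested_models_never_lose_loglik(self, sim):
        base = hm.fit_one(sim, ("s1lsi",))
        bigger = hm.fit_one(sim, ("rs", "s1lsi"))
        assert bigger.logl >= base.logl - 1e-6

    def test_overparameterized_model_rejected(self, sim):
        with pytest.raises(ValueError):
            hm.aicc(0.0, k=42, n=43)

    def test_delta_zero_once_and_weights_sum_to_one(self, sim):
        recs = hm.fit_candidates(sim, [[], ["rs"], ["s1lsi"], ["rs", "s1lsi"]])
        assert sum(r.daicc == 0.0 for r in recs) == 1
        assert sum(r.weight for r in recs) == pytest.approx(1.0, abs=1e-9)


class TestRandomEffectCheck:
    def test_single_year_per_animal_skipped(self):
        df = sd.simulate_range_covariates(n_animals=43, n_ranges=43, seed=1)
        out = hm.random_effect_check(df, ("rs",))
        assert out["status"] == "skipped"

    def test_null_variance_rarely_rejects(self):
        hits = 0
        for rep in range(10):
            df = sd.simulate_range_covariates(seed=100 + rep)  # no animal effect
            out = hm.random_effect_check(df, ("rs", "s1lsi"))
            hits += out["p"] > 0.05
        assert hits >= 9

    def test_strong_animal_effect_detected(self):
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(200 + rep)
            df = sd.simulate_range_covariates(seed=200 + rep, noise_sd=0.05)
            effect = dict(
                zip(sorted(df["animal_id"].unique()),
                    rng.normal(0, 0.5, df["animal_id"].nunique()))
            )
            df["log10_area"] += df["animal_id"].map(effect)
            out = hm.random_effect_check(df, ("rs", "s1lsi"))
            hits += out["p"] < 0.05
        assert hits >= 9
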