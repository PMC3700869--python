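"""Resource selection: RSI arithmetic, classification, splits, availability
sampling, the mixed-logit fit, and Manly selection ratios."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st
from shapely.geometry import Polygon, box

from arcrange import geo_io, home_range as hr, rsf
from arcrange.mixed_logit import fit_mixed_logit


class TestRSI:
    @pytest.mark.parametrize(
        "beta, expected",
        [
            (3.20, 24.5),  # season-2 sparse vegetation
            (-1.71, 5.5),  # season-3 water reference
            (2.19, 8.9),  # season-3 low shrub lowland
            (-2.31, 10.1),  # season-2 water reference
            (0.0, 1.0),  # no-selection identity
        ],
    )
    def test_published_odds_ratios(self, beta, expected):
        assert rsf.rsi_from_coefficient(beta) == expected

    @given(st.floats(-6, 6, allow_nan=False))
    def test_symmetric_in_sign_and_at_least_one(self, beta):
        assert rsf.rsi_from_coefficient(beta) == rsf.rsi_from_coefficient(-beta)
        assert rsf.rsi_from_coefficient(beta) >= 1.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            rsf.rsi_from_coefficient(np.inf)


class TestClassification:
    @pytest.mark.parametrize(
        "beta, rsi, expected",
        [
            (0.78, 2.2, "h"),  # low shrub upland, selected
            (-0.49, 1.6, "m"),  # tussock/lichen, weakly avoided
            (-2.35, 10.4, "m"),  # deciduous forest: avoided despite RSI >= 2
            (2.0, 7.4, "h"),
            (0.5, 1.6, "m"),
        ],
    )
    def test_sign_and_threshold_rule(self, beta, rsi, expected):
        assert rsf.classify_cover(beta, rsi) == expected

    def test_selection_map_conserves_cells_and_water(self, landscape):
        effects = [
            rsf.CoverEffect(
                cover=label, beta=1.0, se=0.1, z=10, ci_lo=0.8, ci_hi=1.2,
                wald=100, p=0.0, rsi=2.7, use_class="h",
            )
            for label in ["sparse vegetation", "tall shrub"]
        ]
        smap = rsf.build_selection_map(landscape, effects, season_id=1)
        n = smap.values.size
        counts = {
            code: int((smap.values == code).sum())
            for code in (rsf.H_CODE, rsf.M_CODE, rsf.R_CODE)
        }
        assert sum(counts.values()) == n
        assert counts[rsf.R_CODE] == int(
            (landscape.values == landscape.water_code).sum()
        )


class TestTrainTestSplit:
    def test_exact_ratio_10(self):
        fixes = pd.DataFrame(
            {"animal_id": "A", "x": range(10), "y": range(10)}
        )
        train, test = rsf.train_test_split(fixes, seed=1)
        assert (len(train), len(test)) == (8, 2)

    def test_field_mean_599_splits_479_120(self):
        fixes = pd.DataFrame(
            {"animal_id": "A", "x": range(599), "y": range(599)}
        )
        train, test = rsf.train_test_split(fixes, seed=1)
        assert (len(train), len(test)) == (479, 120)

    def test_deterministic_and_partition(self):
        rng = np.random.default_rng(3)
        fixes = pd.DataFrame(
            {
                "animal_id": rng.choice(["A", "B", "C"], 97),
                "x": rng.normal(size=97),
                "y": rng.normal(size=97),
            }
        )
        t1, s1 = rsf.train_test_split(fixes, seed=9)
        t2, s2 = rsf.train_test_split(fixes, seed=9)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(s1, s2)
        assert len(t1) + len(s1) == len(fixes)
        assert set(t1.index).isdisjoint(s1.index)

    def test_tiny_animal_all_to_train(self):
        fixes = pd.DataFrame({"animal_id": "A", "x": range(4), "y": range(4)})
        train, test = rsf.train_test_split(fixes, seed=0)
        assert len(train) == 4 and len(test) == 0


class TestAvailability:
    def test_count_and_containment_100km2(self, rng):
        poly = box(0, 0, 10_000, 10_000)  # 100 km^2
        pts = rsf.sample_availability(poly, density=1.0, rng=rng)
        assert len(pts) == 100
        assert (pts >= 0).all() and (pts <= 10_000).all()

    def test_zero_density_rejected(self, rng):
        with pytest.raises(ValueError):
            rsf.sample_availability(box(0, 0, 1000, 1000), density=0.0, rng=rng)

    def test_uniform_in_l_shaped_polygon(self, rng):
        l_shape = Polygon(
            [(0, 0), (2000, 0), (2000, 1000), (1000, 1000), (1000, 2000), (0, 2000)]
        )
        pts = rsf.sample_availability(l_shape, density=1.0, rng=rng, min_points=10_000)
        # three unit squares of equal area: counts binomial around 1/3
        n = len(pts)
        for xlo, ylo in ((0, 0), (1000, 0), (0, 1000)):
            inside = (
                (pts[:, 0] >= xlo) & (pts[:, 0] < xlo + 1000)
                & (pts[:, 1] >= ylo) & (pts[:, 1] < ylo + 1000)
            ).sum()
            p = 1 / 3
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(inside - n * p) < 3 * sigma


class TestMixedLogit:
    def test_zero_variance_limit_matches_plain_logistic(self, rng):
        n = 1500
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
        eta = -0.4 + 1.1 * X[:, 1]
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
        groups = rng.integers(0, 8, n)
        res = fit_mixed_logit(y, X, groups)
        plain = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(res.params, plain.params, atol=1e-3)
        assert res.sigma < 0.05

    def test_recovers_slope_and_intercept_variance(self, rng):
        m, ni = 30, 150
        g = np.repeat(np.arange(m), ni)
        b = rng.normal(0, 1.0, m)[g]
        x = rng.integers(0, 2, m * ni).astype(float)
        eta = -0.3 + 0.9 * x + b
        y = (rng.uniform(size=m * ni) < 1 / (1 + np.exp(-eta))).astype(float)
        X = np.column_stack([np.ones(m * ni), x])
        res = fit_mixed_logit(y, X, g)
        assert res.params[1] == pytest.approx(0.9, abs=0.15)
        assert res.sigma == pytest.approx(1.0, abs=0.35)


@pytest.fixture(scope="module")
def null_fit(landscape):
    """Zero-preference tracks and their fitted effects."""
    from arcrange import synthetic_data as sd

    spec = sd.MovementSpec(
        n_animals=8, fixes_per_animal=(250, 250), seed=31, step_scale=250.0,
        seasonal_preference={1: {}, 2: {}, 3: {}},
    )
    fixes, _ = sd.simulate_tracks(landscape, spec)
    fixes = geo_io.annotate_fixes(fixes, landscape)
    rng = np.random.default_rng(77)
    avail = []
    for animal, sub in fixes.groupby("animal_id"):
        m = hr.mcp(sub[["x", "y"]].to_numpy())
        pts = rsf.sample_availability(m, density=1.0, rng=rng, min_points=250)
        avail.append(
            pd.DataFrame(
                {
                    "animal_id": animal,
                    "timestamp": pd.Timestamp("2000-01-01"),
                    "x": pts[:, 0],
                    "y": pts[:, 1],
                }
            )
        )
    avail = geo_io.annotate_fixes(pd.concat(avail, ignore_index=True), landscape)
    return rsf.fit_rsf(fixes, avail, landscape)


class TestFitRSF:
    def test_reference_is_water_with_unit_rsi(self, null_fit):
        refs = [e for e in null_fit if e.use_class == "r"]
        assert len(refs) == 1
        assert refs[0].cover == "water" and refs[0].rsi == 1.0

    def test_wald_equals_z_squared_and_ci_multiplier(self, null_fit):
        for e in null_fit:
            if np.isfinite(e.z) and np.isfinite(e.se):
                assert e.wald == pytest.approx(e.z**2, rel=1e-12)
                assert e.ci_hi - e.beta == pytest.approx(1.96 * e.se, rel=1e-9)

    def test_null_preferences_give_small_coefficients(self, null_fit):
        finite = [e for e in null_fit if np.isfinite(e.beta) and e.use_class != "r"]
        assert len(finite) >= 8
        frac_small = np.mean([abs(e.z) < 1.96 for e in finite])
        assert frac_small >= 0.8


class TestSelectionRatio:
    def _map_and_fixes(self, u_cells, a_frac=0.25):
        """4x4 selection map with a_frac highly selected; synthetic fixes."""
        vals = np.full((10, 10), rsf.M_CODE, np.int16)
        n_h = int(round(a_frac * 100))
        vals.ravel()[:n_h] = rsf.H_CODE
        smap = rsf.SelectionMap(values=vals, cell_size=10.0, origin=(0.0, 0.0))
        mcp_poly = hr.RangePolygon("mcp100", box(0, 0, 100, 100), 1e-2)
        return smap, mcp_poly

    def _fixes_with_u(self, u, n=40):
        # u*n fixes on h cells (first rows), rest on m cells
        n_h = int(round(u * n))
        xs = np.concatenate([np.full(n_h, 5.0), np.full(n - n_h, 5.0)])
        ys = np.concatenate(
            [np.full(n_h, 5.0), np.full(n - n_h, 95.0)]
        )  # row 0 is h, row 9 is m
        return xs, ys

    def test_w_definition(self):
        smap, poly = self._map_and_fixes(None, a_frac=0.25)
        frames = []
        for animal, u in (("A", 0.5), ("B", 0.5)):
            xs, ys = self._fixes_with_u(u)
            frames.append(
                pd.DataFrame({"animal_id": animal, "x": xs, "y": ys})
            )
        res = rsf.selection_ratio(
            pd.concat(frames, ignore_index=True), {"A": poly, "B": poly}, smap
        )
        np.testing.assert_allclose(res.w_s, 2.0)
        assert res.df == (1, 1)

    def test_u_equals_a_gives_unit_ratio(self):
        smap, poly = self._map_and_fixes(None, a_frac=0.25)
        frames = []
        for animal in ("A", "B", "C"):
            xs, ys = self._fixes_with_u(0.25)
            frames.append(pd.DataFrame({"animal_id": animal, "x": xs, "y": ys}))
        res = rsf.selection_ratio(
            pd.concat(frames, ignore_index=True),
            {a: poly for a in "ABC"},
            smap,
        )
        np.testing.assert_allclose(res.w_s, 1.0)
        assert res.mean_w == pytest.approx(1.0)

    def test_zero_availability_excluded(self):
        vals = np.full((10, 10), rsf.M_CODE, np.int16)
        vals[9, :] = rsf.H_CODE  # h exists only outside the small MCP
        smap = rsf.SelectionMap(values=vals, cell_size=10.0, origin=(0.0, 0.0))
        small = hr.RangePolygon("mcp100", box(0, 0, 100, 50), 1e-2)
        big = hr.RangePolygon("mcp100", box(0, 0, 100, 100), 1e-2)
        frames = []
        for animal in ("A", "B", "C"):
            frames.append(
                pd.DataFrame(
                    {"animal_id": animal, "x": [5.0, 15.0], "y": [95.0, 5.0]}
                )
            )
        res = rsf.selection_ratio(
            pd.concat(frames, ignore_index=True),
            {"A": small, "B": big, "C": big},
            smap,
        )
        assert res.excluded == ["A"]
        assert res.df == (1, 1)
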