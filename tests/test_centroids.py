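"""Weighted centroids, bootstrap CIs, OLS trends and normality tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from mackmix import centroids as cen


class TestWeightedCentroid:
    def test_single_point(self):
        assert cen.weighted_centroid([150.0], [40.0], [0.7]) == (150.0, 40.0)

    def test_hand_arithmetic(self):
        lon, lat = cen.weighted_centroid([150.0, 152.0], [40.0, 42.0], [1.0, 3.0])
        assert (lon, lat) == (151.5, 41.5)

    def test_equal_weights_reduce_to_mean(self):
        rng = np.random.default_rng(0)
        lons = rng.uniform(140, 160, 30)
        lats = rng.uniform(30, 50, 30)
        lon, lat = cen.weighted_centroid(lons, lats, np.full(30, 0.4))
        assert lon == pytest.approx(lons.mean())
        assert lat == pytest.approx(lats.mean())

    def test_all_zero_weights_error(self):
        with pytest.raises(ValueError, match="zero"):
            cen.weighted_centroid([1.0, 2.0], [1.0, 2.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            cen.weighted_centroid([1.0], [1.0], [-0.5])

    def test_translation_equivariance(self):
        rng = np.random.default_rng(1)
        lons = rng.uniform(140, 160, 20)
        lats = rng.uniform(30, 50, 20)
        w = rng.uniform(0, 1, 20)
        lon0, lat0 = cen.weighted_centroid(lons, lats, w)
        lon1, lat1 = cen.weighted_centroid(lons + 2.5, lats - 1.25, w)
        assert lon1 == pytest.approx(lon0 + 2.5)
        assert lat1 == pytest.approx(lat0 - 1.25)

    def test_species_weight_duality(self):
        """Blue-weighted and chub-weighted centroids average (weighted by
        total proportions) to the unweighted record centroid."""
        rng = np.random.default_rng(2)
        n = 100
        lons = rng.uniform(140, 160, n)
        lats = rng.uniform(30, 50, n)
        p = rng.uniform(0, 1, n)
        blue = cen.weighted_centroid(lons, lats, p)
        chub = cen.weighted_centroid(lons, lats, 1 - p)
        wb, wc = p.sum(), (1 - p).sum()
        assert (wb * blue[0] + wc * chub[0]) / (wb + wc) == pytest.approx(lons.mean())
        assert (wb * blue[1] + wc * chub[1]) / (wb + wc) == pytest.approx(lats.mean())


class TestBootstrapCI:
    def test_identical_points_zero_width(self):
        ci = cen.bootstrap_ci([150.0] * 5, [40.0] * 5, [1.0] * 5, B=100, seed=0)
        assert ci["lon_lower"] == ci["lon_upper"] == 150.0
        assert ci["lat_lower"] == ci["lat_upper"] == 40.0

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        lons = rng.uniform(140, 160, 40)
        lats = rng.uniform(30, 50, 40)
        w = rng.uniform(0, 1, 40)
        a = cen.bootstrap_ci(lons, lats, w, B=200, seed=9)
        b = cen.bootstrap_ci(lons, lats, w, B=200, seed=9)
        assert a == b

    def test_width_scales_roughly_inverse_sqrt_n(self):
        rng = np.random.default_rng(4)
        widths = []
        for n in (100, 400):
            lons = rng.normal(150, 2, n)
            lats = rng.normal(40, 2, n)
            w = rng.uniform(0.2, 1, n)
            ci = cen.bootstrap_ci(lons, lats, w, B=400, seed=5)
            widths.append(ci["lon_upper"] - ci["lon_lower"])
        ratio = widths[0] / widths[1]
        assert 1.4 < ratio < 2.9  # ~2 expected, loose tolerance

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            cen.bootstrap_ci([150.0], [40.0], [1.0], B=10, seed=0)


class TestOlsTrend:
    def test_exact_linear_input_recovers_slope(self):
        years = np.arange(2014, 2024)
        values = 40.61 + 0.3062 * (years - 2014)
        fit = cen.ols_trend(years, values)
        assert fit.slope == pytest.approx(0.3062, abs=1e-12)
        assert fit.intercept == pytest.approx(40.61 - 0.3062 * 2014, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_values_degenerate(self):
        fit = cen.ols_trend(np.arange(2014, 2020), np.full(6, 41.0))
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0
        assert fit.degenerate

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(5)
        x = np.arange(2014.0, 2024.0)
        y = rng.normal(42, 1.5, 10)
        fit = cen.ols_trend(x, y)
        # closed-form simple regression with t-based p-value
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - intercept - slope * x
        s2 = resid @ resid / (len(x) - 2)
        se = np.sqrt(s2 / sxx)
        from scipy.stats import t as t_dist

        p = 2 * t_dist.sf(abs(slope / se), len(x) - 2)
        r2 = 1 - (resid @ resid) / np.sum((y - y.mean()) ** 2)
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10)
        assert fit.r_squared == pytest.approx(r2, rel=1e-10)
        assert fit.p_value == pytest.approx(p, rel=1e-10)
        assert fit.slope_se == pytest.approx(se, rel=1e-10)

    def test_too_few_years(self):
        with pytest.raises(ValueError):
            cen.ols_trend([2014, 2015], [1.0, 2.0])


class TestJarqueBera:
    def test_null_statistic_zero(self):
        # symmetric 8-point sample {-b, -1 x3, 1 x3, b} with b chosen so the
        # sample kurtosis is exactly 3: skewness 0 by symmetry, so JB = 0
        b = np.sqrt((18 + np.sqrt(384)) / 2)
        r = np.array([-b, -1, -1, -1, 1, 1, 1, b])
        stat, p = cen.jarque_bera(r)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_matches_moment_formula_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            r = rng.standard_normal(rng.integers(10, 200))
            stat, p = cen.jarque_bera(r)
            n = len(r)
            z = r - r.mean()
            m2 = np.mean(z**2)
            S = np.mean(z**3) / m2**1.5
            K = np.mean(z**4) / m2**2
            jb = n / 6 * (S**2 + (K - 3) ** 2 / 4)
            assert stat == pytest.approx(jb, rel=1e-10)
            assert p == pytest.approx(chi2.sf(jb, 2), rel=1e-10)

    def test_power_against_skewed_sample(self):
        rng = np.random.default_rng(7)
        r = rng.exponential(1.0, 500)
        _, p = cen.jarque_bera(r)
        assert p < 0.01

    def test_degenerate_input(self):
        with pytest.raises(ValueError):
            cen.jarque_bera(np.ones(10))
        with pytest.raises(ValueError):
            cen.jarque_bera([1.0, 2.0, 3.0])


class TestOmnibus:
    def test_size_on_standard_normal(self):
        rng = np.random.default_rng(8)
        rejections = 0
        for _ in range(200):
            r = rng.standard_normal(200)
            _, p = cen.omnibus_normtest(r)
            rejections += p < 0.05
        assert 0.01 <= rejections / 200 <= 0.12

    def test_matches_dagostino_reference(self):
        """Hand-coded D'Agostino-Pearson K^2: transformed skewness and
        kurtosis z-scores, summed squares against chi-square(2)."""
        rng = np.random.default_rng(9)
        r = rng.standard_normal(150)
        stat, p = cen.omnibus_normtest(r)
        n = len(r)
        z = r - r.mean()
        m2 = np.mean(z**2)
        b1 = np.mean(z**3) / m2**1.5
        b2 = np.mean(z**4) / m2**2
        # D'Agostino (1970) skewness transform
        Y = b1 * np.sqrt((n + 1) * (n + 3) / (6 * (n - 2)))
        beta2 = 3 * (n**2 + 27 * n - 70) * (n + 1) * (n + 3) / (
            (n - 2) * (n + 5) * (n + 7) * (n + 9)
        )
        W2 = -1 + np.sqrt(2 * (beta2 - 1))
        delta = 1 / np.sqrt(0.5 * np.log(W2))
        alpha = np.sqrt(2 / (W2 - 1))
        Zs = delta * np.log(Y / alpha + np.sqrt((Y / alpha) ** 2 + 1))
        # Anscombe-Glynn (1983) kurtosis transform
        Eb2 = 3 * (n - 1) / (n + 1)
        Vb2 = 24 * n * (n - 2) * (n - 3) / ((n + 1) ** 2 * (n + 3) * (n + 5))
        xk = (b2 - Eb2) / np.sqrt(Vb2)
        sqrtb1 = 6 * (n**2 - 5 * n + 2) / ((n + 7) * (n + 9)) * np.sqrt(
            6 * (n + 3) * (n + 5) / (n * (n - 2) * (n - 3))
        )
        A = 6 + 8 / sqrtb1 * (2 / sqrtb1 + np.sqrt(1 + 4 / sqrtb1**2))
        Zk = (
            (1 - 2 / (9 * A))
            - ((1 - 2 / A) / (1 + xk * np.sqrt(2 / (A - 4)))) ** (1 / 3)
        ) / np.sqrt(2 / (9 * A))
        k2 = Zs**2 + Zk**2
        assert stat == pytest.approx(k2, abs=1e-8)
        assert p == pytest.approx(chi2.sf(k2, 2), abs=1e-8)

    def test_small_and_degenerate_input(self):
        with pytest.raises(ValueError):
            cen.omnibus_normtest(np.arange(5.0))
        with pytest.raises(ValueError):
            cen.omnibus_normtest(np.ones(20))


class TestDistanceSeries:
    def make_series(self, lats, lons, years=None):
        years = years if years is not None else 2014 + np.arange(len(lats))
        return pd.DataFrame({"year": years, "lon": lons, "lat": lats})

    def test_identical_series_zero_distance(self):
        s = self.make_series([40, 41, 42], [150, 151, 152])
        dist, trend = cen.centroid_distance_series(s, s)
        assert np.allclose(dist["distance_km"], 0.0)

    def test_one_degree_latitude_is_111km(self):
        a = self.make_series([40.0, 41.0, 42.0], [150.0] * 3)
        b = self.make_series([41.0, 42.0, 43.0], [150.0] * 3)
        dist, _ = cen.centroid_distance_series(a, b)
        assert np.allclose(dist["distance_km"], 111.2, atol=0.5)

    def test_linear_convergence_detected(self):
        years = 2014 + np.arange(10)
        a = self.make_series(np.full(10, 40.0), np.full(10, 150.0), years)
        b = self.make_series(40.0 + 2.0 - 0.2 * np.arange(10), np.full(10, 150.0), years)
        dist, trend = cen.centroid_distance_series(a, b)
        assert trend.slope < 0
        assert trend.r_squared > 0.99

    def test_disjoint_years_error(self):
        a = self.make_series([40.0] * 3, [150.0] * 3, [2014, 2015, 2016])
        b = self.make_series([40.0] * 3, [150.0] * 3, [2020, 2021, 2022])
        with pytest.raises(ValueError, match="common years"):
            cen.centroid_distance_series(a, b)


class TestAnnualCentroids:
    def test_table_shape_and_flags(self):
        rng = np.random.default_rng(10)
        n = 60
        df = pd.DataFrame(
            {
                "year": np.repeat([2014, 2015, 2016], 20),
                "lon": rng.uniform(140, 160, n),
                "lat": rng.uniform(30, 50, n),
                "p": rng.uniform(0, 1, n),
            }
        )
        out = cen.annual_centroids(df, "p", B=100, seed=0, min_records=10)
        assert list(out.year) == [2014, 2015, 2016]
        assert (~out.flagged).all()
        assert (out.lon_lower <= out.lon).all() and (out.lon <= out.lon_upper).all()
        small = cen.annual_centroids(df, "p", B=100, seed=0, min_records=50)
        assert small.flagged.all()

    def test_centroid_inside_point_cloud(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(
            {
                "year": np.full(30, 2020),
                "lon": rng.uniform(150, 152, 30),
                "lat": rng.uniform(40, 42, 30),
                "p": rng.uniform(0.01, 1, 30),
            }
        )
        out = cen.annual_centroids(df, "p", B=50, seed=1)
        assert 150 <= out.lon.iloc[0] <= 152
        assert 40 <= out.lat.iloc[0] <= 42
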