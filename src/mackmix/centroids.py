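"""Abundance-weighted centroid trajectories and drift statistics.

The annual centre of gravity of a species is the proportion-weighted mean
position of that year's records,

    weighted_lon = sum(lon_i * w_i) / sum(w_i),
    weighted_lat = sum(lat_i * w_i) / sum(w_i),

computed in plain degree space.  Year-over-year drift is quantified by an
OLS trend on the annual centroids, with percentile-bootstrap confidence
intervals (resampling whole records), residual normality screened by the
D'Agostino-Pearson omnibus and Jarque-Bera tests, and between-species
convergence measured by the haversine distance between same-year
centroids and its own trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "weighted_centroid",
    "bootstrap_ci",
    "annual_centroids",
    "ols_trend",
    "jarque_bera",
    "omnibus_normtest",
    "haversine_km",
    "centroid_distance_series",
    "TrendFit",
]

EARTH_RADIUS_KM = 6371.0088


def weighted_centroid(lon, lat, weights) -> tuple[float, float]:
    """Weighted arithmetic mean of longitude and latitude separately."""
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    w = np.asarray(weights, float)
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    total = w.sum()
    if total <= 0:
        raise ValueError("centroid undefined: all weights are zero")
    return float(np.sum(lon * w) / total), float(np.sum(lat * w) / total)


def bootstrap_ci(
    lon,
    lat,
    weights,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    max_retries: int = 100,
) -> dict[str, float]:
    """Percentile bootstrap CI for the weighted centroid.

    Records (position + weight) are resampled with replacement B times;
    resamples whose weights are all zero are redrawn (capped).  Returns
    ``{"lon_lower", "lon_upper", "lat_lower", "lat_upper"}``.
    """
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    w = np.asarray(weights, float)
    n = len(lon)
    if n < 2:
        raise ValueError("bootstrap needs at least 2 points")
    rng = np.random.default_rng([int(seed) % (2**31), 2654435769])
    lon_bs = np.empty(B)
    lat_bs = np.empty(B)
    for b in range(B):
        for _ in range(max_retries):
            idx = rng.integers(0, n, n)
            if w[idx].sum() > 0:
                break
        else:
            raise RuntimeError("could not draw a resample with positive total weight")
        lon_bs[b], lat_bs[b] = weighted_centroid(lon[idx], lat[idx], w[idx])
    alpha = (1 - level) / 2
    return {
        "lon_lower": float(np.quantile(lon_bs, alpha)),
        "lon_upper": float(np.quantile(lon_bs, 1 - alpha)),
        "lat_lower": float(np.quantile(lat_bs, alpha)),
        "lat_upper": float(np.quantile(lat_bs, 1 - alpha)),
    }


def annual_centroids(
    df: pd.DataFrame,
    weight_col: str,
    year_col: str | None = None,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    min_records: int = 10,
) -> pd.DataFrame:
    """Per-year weighted centroid table with bootstrap CIs.

    ``df`` needs ``lon``, ``lat``, the weight column, and either a
    ``year`` column or a parseable ``date``.  Years with fewer than
    ``min_records`` rows are flagged (column ``flagged``), not dropped.
    """
    if year_col is None:
        years = pd.to_datetime(df["date"]).dt.year if "year" not in df else df["year"]
    else:
        years = df[year_col]
    rows = []
    for i, (year, g) in enumerate(df.groupby(years.values)):
        lon_c, lat_c = weighted_centroid(g["lon"], g["lat"], g[weight_col])
        ci = bootstrap_ci(g["lon"], g["lat"], g[weight_col], B=B, level=level, seed=seed + i)
        rows.append(
            {
                "year": int(year),
                "lon": lon_c,
                "lat": lat_c,
                **ci,
                "n_points": len(g),
                "flagged": len(g) < min_records,
            }
        )
    return pd.DataFrame(rows).sort_values("year").reset_index(drop=True)


@dataclass
class TrendFit:
    """OLS trend with residual-normality diagnostics."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    slope_se: float
    slope_ci: tuple[float, float]
    omnibus_p: float
    jarque_bera_p: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["slope_ci"] = list(self.slope_ci)
        return d


def ols_trend(years, values, ci_level: float = 0.95) -> TrendFit:
    """Least-squares linear trend of an annual series.

    Slope/intercept/R^2 and the two-sided slope p-value come from the
    classical t-based simple regression; residual normality is screened
    with the omnibus and Jarque-Bera tests (NaN when the sample is too
    small for either).  Constant input returns a zero slope flagged
    degenerate with R^2 = 0.
    """
    x = np.asarray(years, float)
    y = np.asarray(values, float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct years")
    if np.allclose(y, y[0]):
        resid = y - y.mean()
        return TrendFit(0.0, float(y[0]), 0.0, 1.0, 0.0, (0.0, 0.0),
                        np.nan, np.nan, degenerate=True)
    res = stats.linregress(x, y)
    n = len(x)
    tcrit = stats.t.ppf(0.5 + ci_level / 2, df=n - 2)
    resid = y - (res.intercept + res.slope * x)
    try:
        _, omni_p = omnibus_normtest(resid)
    except ValueError:
        omni_p = np.nan
    try:
        _, jb_p = jarque_bera(resid)
    except ValueError:
        jb_p = np.nan
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        slope_se=float(res.stderr),
        slope_ci=(float(res.slope - tcrit * res.stderr), float(res.slope + tcrit * res.stderr)),
        omnibus_p=float(omni_p),
        jarque_bera_p=float(jb_p),
    )


def jarque_bera(residuals) -> tuple[float, float]:
    """Jarque-Bera normality test: JB = n/6 (S^2 + (K-3)^2 / 4),
    p from chi-square(2)."""
    r = np.asarray(residuals, float)
    if len(r) < 4:
        raise ValueError("Jarque-Bera needs n >= 4")
    if np.std(r) == 0:
        raise ValueError("zero-variance residuals: test degenerate")
    res = stats.jarque_bera(r)
    return float(res.statistic), float(res.pvalue)


def omnibus_normtest(residuals) -> tuple[float, float]:
    """D'Agostino-Pearson K^2 omnibus normality test, p from chi-square(2)."""
    r = np.asarray(residuals, float)
    if len(r) < 8:
        raise ValueError("omnibus test needs n >= 8")
    if np.std(r) == 0:
        raise ValueError("zero-variance residuals: test degenerate")
    res = stats.normaltest(r)
    return float(res.statistic), float(res.pvalue)


def haversine_km(lon1, lat1, lon2, lat2) -> float:
    """Great-circle distance in kilometres."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def centroid_distance_series(
    series_a: pd.DataFrame, series_b: pd.DataFrame
) -> tuple[pd.DataFrame, TrendFit]:
    """Per-year great-circle distance between two centroid series and its
    OLS trend (a negative slope indicates convergence)."""
    merged = series_a.merge(series_b, on="year", suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("centroid series share no common years")
    merged["distance_km"] = [
        haversine_km(r.lon_a, r.lat_a, r.lon_b, r.lat_b) for r in merged.itertuples()
    ]
    out = merged[["year", "distance_km"]]
    trend = ols_trend(out["year"], out["distance_km"])
    return out, trend
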