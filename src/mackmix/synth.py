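"""Synthetic logbook, sampling-event and environmental-field generator.

Emulates the statistical structure the downstream analysis assumes, with
known ground truth:

* daily gridded covariate fields (SST, CHLA, SSS, SSH, UO, VO, MLD) built
  from deterministic large-scale structure (latitudinal SST gradient,
  seasonal cycles) plus smooth random low-order harmonic surfaces; CHLA
  lives on a coarser grid than the physics variables, and SSH is an
  affine function of SSS plus residualized noise so their field-wide
  Pearson correlation hits a configurable target (default 0.72);
* vessel-day mixed-catch logbook records whose yearly spatial density
  drifts north-eastward at configurable rates, each carrying a latent
  true species proportion drawn from the ZOIB process at its matched,
  standardized covariates;
* sampling events that binomially thin the latent proportion into
  per-species counts (boundary states map to counts 0 or n exactly).

Every generator is deterministic under a fixed (config, seed): random
streams are derived from the master seed with fixed named substreams, so
stages can be regenerated independently and in any order.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .envmatch import EnvField, EnvFieldSet, VARIABLES, match, regrid
from .zoib import ZOIBParams, make_design, simulate

__all__ = [
    "SimConfig",
    "LogbookRecord",
    "SamplingEvent",
    "default_true_params",
    "generate_env_fields",
    "generate_logbook",
    "generate_sampling_events",
    "write_logbook_csv",
    "write_events_csv",
]

# ZOIB-truth covariate order (post-collinearity-filter set; SSH is the
# collinear decoy present in the fields but absent from the truth).
TRUE_COVARIATES = ["SST", "CHLA", "SSS", "MLD", "UO", "VO"]

_VAR_STREAM = {v: i + 10 for i, v in enumerate(VARIABLES)}
_STREAM_LOGBOOK = 101
_STREAM_PROPORTION = 102
_STREAM_EVENTS = 103


def default_true_params() -> ZOIBParams:
    """Data-generating truth used by the simulator.

    Blue Mackerel favours warmer, saltier water, so SST and SSS carry
    positive effects in both the Beta mean and the one-inflation
    component; boundary records (single-species hauls) occur for roughly
    30% of records at average conditions.  Coefficient order:
    [intercept, SST, CHLA, SSS, MLD, UO, VO] on standardized covariates.
    """
    return ZOIBParams(
        beta_mu=[0.0, 0.8, 0.3, 0.5, 0.2, -0.2, -0.3],
        beta_phi=[1.6, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        beta_zoi=[-0.85, -0.4, 0.0, 0.0, 0.0, 0.0, 0.0],
        beta_coi=[0.0, 0.6, 0.0, 0.3, 0.0, 0.0, 0.0],
        u=np.zeros(0),
        sigma_u=0.3,
        prior_scale=1.0,
    )


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults mirror the Northwest Pacific high-seas purse-seine fishery
    setting: a 140-175 degE x 30-50 degN box, 2014-2023, physics fields at
    0.083 degrees and CHLA at 0.25 degrees, an SSS-SSH correlation of
    0.72, and a north-eastward abundance drift of 0.3 deg lat and
    0.55 deg lon per year.
    """

    lon_min: float = 140.0
    lon_max: float = 175.0
    lat_min: float = 30.0
    lat_max: float = 50.0
    year_start: int = 2014
    year_end: int = 2023
    n_records_per_year: int = 500
    n_days_per_year: int = 36
    fine_resolution: float = 0.083
    coarse_resolution: float = 0.25
    true_params: ZOIBParams = dc_field(default_factory=default_true_params)
    drift_lat_per_year: float = 0.3
    drift_lon_per_year: float = 0.55
    sss_ssh_target_corr: float = 0.72
    center_lon: float = 150.8
    center_lat: float = 40.6
    spread_lon: float = 3.0
    spread_lat: float = 2.0
    catch_log_mean: float = np.log(15000.0)  # median mixed catch ~15 t/day
    catch_log_sd: float = 0.7
    n_vessels: int = 25
    block_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fine_resolution <= 0 or self.coarse_resolution <= 0:
            raise ValueError("resolutions must be > 0")
        if self.year_end < self.year_start:
            raise ValueError("years must be a non-empty range")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("spatial domain box is degenerate")
        if self.lon_max >= 180.0:
            raise ValueError("domain must not cross the antimeridian (lon max < 180)")
        if not -1.0 <= self.sss_ssh_target_corr <= 1.0:
            raise ValueError("sss_ssh_target_corr must lie in [-1, 1]")
        if self.n_records_per_year < 0:
            raise ValueError("n_records_per_year must be >= 0")

    @property
    def years(self) -> list[int]:
        return list(range(self.year_start, self.year_end + 1))

    def axes(self, coarse: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Cell-centre axes at the fine (default) or coarse resolution."""
        res = self.coarse_resolution if coarse else self.fine_resolution
        lon = np.arange(self.lon_min + res / 2, self.lon_max, res)
        lat = np.arange(self.lat_min + res / 2, self.lat_max, res)
        return lon, lat

    def field_dates(self) -> list[dt.date]:
        """Evenly spaced fishing days: n_days_per_year per year."""
        out = []
        for year in self.years:
            n_days = (dt.date(year, 12, 31) - dt.date(year, 1, 1)).days + 1
            for k in range(self.n_days_per_year):
                out.append(
                    dt.date(year, 1, 1)
                    + dt.timedelta(days=int(k * n_days / self.n_days_per_year))
                )
        return out


@dataclass
class LogbookRecord:
    """One vessel-day mixed-catch observation."""

    vessel_id: str
    date: dt.date
    lon: float
    lat: float
    sets: int
    mixed_catch_kg: float

    def __post_init__(self) -> None:
        if self.mixed_catch_kg < 0:
            raise ValueError("mixed_catch_kg must be >= 0")
        if self.sets < 1:
            raise ValueError("sets must be >= 1")


@dataclass
class SamplingEvent:
    """One morphological-identification sampling event."""

    date: dt.date
    lon: float
    lat: float
    n_individuals: int
    n_blue: int
    n_chub: int

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.n_blue + self.n_chub != self.n_individuals:
            raise ValueError("species counts must sum to n_individuals")

    @property
    def proportion_blue(self) -> float:
        return self.n_blue / self.n_individuals


# ---------------------------------------------------------------------------
# environmental fields

def _harmonic_surface(rng: np.random.Generator, lon, lat, n_modes: int = 12) -> np.ndarray:
    """Smooth zero-mean unit-SD random surface from low-order Fourier modes.

    Mode amplitudes decay with wavenumber, so the surface is dominated by
    basin-scale structure (what spline-stage recovery needs) with mild
    mesoscale texture.
    """
    gx = (lon - lon.min()) / (lon.max() - lon.min() + 1e-9)
    gy = (lat - lat.min()) / (lat.max() - lat.min() + 1e-9)
    GX, GY = np.meshgrid(gx, gy)
    out = np.zeros_like(GX)
    for _ in range(n_modes):
        kx = rng.integers(0, 4)
        ky = rng.integers(0, 4)
        if kx == 0 and ky == 0:
            kx = 1
        amp = 1.0 / (1.0 + kx**2 + ky**2)
        phase = rng.uniform(0, 2 * np.pi)
        out += amp * np.cos(2 * np.pi * (kx * GX + ky * GY) + phase)
    out -= out.mean()
    sd = out.std()
    return out / sd if sd > 0 else out


def _day_rng(config: SimConfig, variable: str, date: dt.date) -> np.random.Generator:
    return np.random.default_rng(
        [int(config.seed) % (2**31), _VAR_STREAM[variable], date.toordinal()]
    )


def _field_for_day(config: SimConfig, variable: str, date: dt.date) -> EnvField:
    coarse = variable == "CHLA"
    lon, lat = config.axes(coarse=coarse)
    LAT = np.meshgrid(lon, lat)[1]
    doy = date.timetuple().tm_yday
    season = np.cos(2 * np.pi * (doy - 232) / 365.25)  # peak late August
    rng = _day_rng(config, variable, date)
    noise = _harmonic_surface(rng, lon, lat)

    if variable == "SST":
        vals = 14.0 + 4.0 * season - 0.45 * (LAT - 40.0) + 1.5 * noise
    elif variable == "CHLA":
        vals = np.exp(-1.0 + 0.05 * (LAT - 40.0) - 0.2 * season + 0.5 * noise)
    elif variable == "SSS":
        # pure harmonic structure (no deterministic gradient): keeps the
        # SSS-SSH correlation scale-free, so record-level extractions see
        # the same correlation as the full field
        vals = 33.9 + 0.25 * noise
    elif variable == "SSH":
        # built from SSS below; placeholder never returned
        raise AssertionError("SSH is derived from SSS")
    elif variable == "UO":
        vals = 0.05 + 0.12 * noise
    elif variable == "VO":
        vals = 0.0 + 0.12 * noise
    elif variable == "MLD":
        # seasonal amplitude kept below the noise so the (anti-phased)
        # shared cycle with SST stays safely under the 0.7 filter threshold
        vals = np.clip(35.0 + 9.0 * np.cos(2 * np.pi * (doy - 45) / 365.25) + 12.0 * noise, 5.0, None)
    else:
        raise ValueError(f"unknown variable {variable!r}")
    return EnvField(variable, date, lon, lat, vals)


def _ssh_from_sss(config: SimConfig, sss: EnvField) -> EnvField:
    """SSH as a noisy affine function of SSS with an exact per-day sample
    correlation equal to the target (the residual surface is empirically
    orthogonalized against the standardized SSS field)."""
    r = config.sss_ssh_target_corr
    rng = _day_rng(config, "SSH", sss.date)
    z = sss.values - sss.values.mean()
    z /= z.std() if z.std() > 0 else 1.0
    g = _harmonic_surface(rng, sss.lon, sss.lat)
    g = g - (g * z).mean() / (z * z).mean() * z  # residualize
    g -= g.mean()
    gsd = g.std()
    g = g / gsd if gsd > 0 else g
    combined = r * z + np.sqrt(max(0.0, 1.0 - r**2)) * g
    vals = 0.45 + 0.12 * combined
    return EnvField("SSH", sss.date, sss.lon, sss.lat, vals)


def generate_env_fields(
    config: SimConfig, dates: list[dt.date] | None = None
) -> EnvFieldSet:
    """One field per variable per simulated day.

    SST carries a latitudinal gradient, a seasonal cycle and smooth noise;
    CHLA is produced on the coarse grid, all other variables on the fine
    grid; SSH is derived from SSS at the target correlation.  Identical
    (config, seed) reproduce identical rasters.
    """
    dates = dates if dates is not None else config.field_dates()
    out = EnvFieldSet()
    for date in dates:
        sss = _field_for_day(config, "SSS", date)
        out.add(sss)
        out.add(_ssh_from_sss(config, sss))
        for var in ("SST", "CHLA", "UO", "VO", "MLD"):
            out.add(_field_for_day(config, var, date))
    return out


# ---------------------------------------------------------------------------
# logbook

def generate_logbook(config: SimConfig, fields: EnvFieldSet) -> pd.DataFrame:
    """Vessel-day records with a latent true species proportion attached.

    Positions are drawn per year from a Gaussian density whose centre
    moves by (drift_lon_per_year, drift_lat_per_year) annually; each
    record's latent proportion is a ZOIB draw at its matched, standardized
    covariates; mixed catch is log-normal and haul counts uniform on 1-5.
    Returns a table with columns vessel_id, date, lon, lat, sets,
    mixed_catch_kg, p_true plus the matched covariate columns.
    """
    for var in TRUE_COVARIATES:
        if var not in fields.variables:
            raise ValueError(f"fields are missing required variable {var!r}")
    rng = np.random.default_rng([int(config.seed) % (2**31), _STREAM_LOGBOOK])
    all_dates = fields.dates
    rows = []
    for year in config.years:
        year_dates = [d for d in all_dates if d.year == year]
        if not year_dates and config.n_records_per_year > 0:
            raise ValueError(f"fields cover no dates in year {year}")
        k = year - config.year_start
        c_lon = config.center_lon + k * config.drift_lon_per_year
        c_lat = config.center_lat + k * config.drift_lat_per_year
        for _ in range(config.n_records_per_year):
            # truncate the Gaussian to the domain by rejection, then clip
            for _attempt in range(50):
                lon = rng.normal(c_lon, config.spread_lon)
                lat = rng.normal(c_lat, config.spread_lat)
                if (
                    config.lon_min <= lon <= config.lon_max
                    and config.lat_min <= lat <= config.lat_max
                ):
                    break
            lon = float(np.clip(lon, config.lon_min, config.lon_max))
            lat = float(np.clip(lat, config.lat_min, config.lat_max))
            rows.append(
                {
                    "vessel_id": f"V{rng.integers(0, config.n_vessels):03d}",
                    "date": year_dates[rng.integers(0, len(year_dates))],
                    "lon": lon,
                    "lat": lat,
                    "sets": int(rng.integers(1, 6)),
                    "mixed_catch_kg": float(
                        np.exp(rng.normal(config.catch_log_mean, config.catch_log_sd))
                    ),
                }
            )
    columns = ["vessel_id", "date", "lon", "lat", "sets", "mixed_catch_kg"]
    df = pd.DataFrame(rows, columns=columns)
    if df.empty:
        df["p_true"] = pd.Series(dtype=float)
        return df

    matched = match(df, fields, variables=TRUE_COVARIATES)
    data, scaler = make_design(matched, TRUE_COVARIATES, block_size=config.block_size)
    truth = config.true_params.copy()
    if len(truth.u) == 0 and truth.sigma_u > 0:
        # realize spatial effects from their prior, one per observed block
        u_rng = np.random.default_rng([int(config.seed) % (2**31), _STREAM_PROPORTION, 1])
        truth.u = u_rng.normal(0.0, truth.sigma_u, data.n_blocks)
    p_rng = np.random.default_rng([int(config.seed) % (2**31), _STREAM_PROPORTION, 2])
    matched["p_true"] = simulate(truth, data.X, data.block, seed=p_rng)
    matched.attrs["covariate_scaler"] = scaler
    return matched


# ---------------------------------------------------------------------------
# sampling events

def generate_sampling_events(
    records: pd.DataFrame,
    n_individuals: int = 1000,
    subsample_fraction: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Binomially thinned species counts at a random subset of records.

    ``n_blue ~ Binomial(n_individuals, p_true)``; latent boundary states
    (p_true exactly 0 or 1) are preserved as counts 0 or n_individuals.
    """
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must lie in (0, 1]")
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng([int(seed) % (2**31), _STREAM_EVENTS])
    n_events = int(round(subsample_fraction * len(records)))
    idx = np.sort(rng.choice(len(records), size=n_events, replace=False))
    sub = records.iloc[idx].reset_index(drop=True)
    p = sub["p_true"].to_numpy(float)
    n_blue = rng.binomial(n_individuals, p)
    keep = [c for c in ("date", "lon", "lat") if c in sub]
    extra = [c for c in sub.columns if c not in keep + ["p_true"]]
    out = sub[keep + ["p_true"] + extra].copy()
    out["n_individuals"] = n_individuals
    out["n_blue"] = n_blue
    out["n_chub"] = n_individuals - n_blue
    out["proportion_blue"] = n_blue / n_individuals
    return out


# ---------------------------------------------------------------------------
# CSV writers

def write_logbook_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = ["vessel_id", "date", "lon", "lat", "sets", "mixed_catch_kg"]
    extra = [c for c in df.columns if c not in cols]
    out = df[cols + extra].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
    return path


def write_events_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = ["date", "lon", "lat", "n_individuals", "n_blue", "n_chub", "proportion_blue"]
    extra = [c for c in df.columns if c not in cols]
    out = df[cols + extra].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
    return path
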