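"""Gridded environmental fields: regridding, record matching, collinearity.

Seven candidate covariates are carried: sea-surface temperature (SST, deg
C), chlorophyll-a (CHLA, mg m-3), salinity (SSS, per mille), sea-surface
height (SSH, m), eastward and northward surface velocity (UO/VO, m s-1)
and mixed-layer depth (MLD, m).  CHLA arrives on a coarser grid than the
physics variables and is regridded (nearest neighbour) to the fine grid
before records are matched to same-day field values at the nearest cell
centre.  Covariates whose pairwise Pearson correlation magnitude reaches
the threshold (default 0.7) are then pruned, keeping the higher-priority
member of each offending pair.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "EnvField",
    "EnvFieldSet",
    "VARIABLES",
    "UNITS",
    "DEFAULT_PRIORITY",
    "regrid",
    "match",
    "correlation_filter",
]

logger = logging.getLogger(__name__)

VARIABLES = ["SST", "CHLA", "SSS", "SSH", "UO", "VO", "MLD"]
UNITS = {
    "SST": "degC",
    "CHLA": "mg m-3",
    "SSS": "1e-3",
    "SSH": "m",
    "UO": "m s-1",
    "VO": "m s-1",
    "MLD": "m",
}
LONG_NAMES = {
    "SST": "sea surface temperature",
    "CHLA": "mass concentration of chlorophyll a",
    "SSS": "sea surface salinity",
    "SSH": "sea surface height",
    "UO": "eastward sea water velocity",
    "VO": "northward sea water velocity",
    "MLD": "ocean mixed layer thickness",
}
# SSH last: when it collides with SSS (the ecologically more informative
# salinity signal) it is the one removed.
DEFAULT_PRIORITY = ["SST", "CHLA", "SSS", "MLD", "UO", "VO", "SSH"]


@dataclass
class EnvField:
    """One dated environmental raster on a regular lon/lat grid.

    Axes hold cell centres in decimal degrees and must be strictly
    increasing; ``values`` is (lat, lon) with NaN marking missing cells.
    """

    variable: str
    date: dt.date
    lon: np.ndarray
    lat: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, float)
        self.lat = np.asarray(self.lat, float)
        self.values = np.asarray(self.values, float)
        if self.lon.size == 0 or self.lat.size == 0:
            raise ValueError("empty source grid")
        if np.any(np.diff(self.lon) <= 0) or np.any(np.diff(self.lat) <= 0):
            raise ValueError("coordinate axes must be strictly increasing")
        if self.values.shape != (len(self.lat), len(self.lon)):
            raise ValueError("values shape must be (len(lat), len(lon))")

    def resolution(self) -> tuple[float, float]:
        """(lon spacing, lat spacing) in degrees."""
        return float(np.median(np.diff(self.lon))), float(np.median(np.diff(self.lat)))


class EnvFieldSet:
    """Collection of EnvFields keyed by (variable, date)."""

    def __init__(self, fields: list[EnvField] | None = None):
        self._fields: dict[tuple[str, dt.date], EnvField] = {}
        for f in fields or []:
            self.add(f)

    def add(self, f: EnvField) -> None:
        self._fields[(f.variable, f.date)] = f

    def get(self, variable: str, date: dt.date) -> EnvField:
        try:
            return self._fields[(variable, date)]
        except KeyError:
            raise KeyError(f"no {variable} field for date {date.isoformat()}") from None

    def __len__(self) -> int:
        return len(self._fields)

    def __iter__(self):
        return iter(self._fields.values())

    @property
    def variables(self) -> list[str]:
        return sorted({v for v, _ in self._fields})

    @property
    def dates(self) -> list[dt.date]:
        return sorted({d for _, d in self._fields})

    # ---------------- I/O: CF-convention NetCDF, one file per variable ----
    def to_netcdf(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for var in self.variables:
            fields = sorted(
                (f for f in self if f.variable == var), key=lambda f: f.date
            )
            times = np.array(
                [(f.date - dt.date(2000, 1, 1)).days for f in fields], dtype="int32"
            )
            cube = np.stack([f.values for f in fields])
            da = xr.DataArray(
                cube.astype("float32"),
                dims=("time", "lat", "lon"),
                coords={
                    "time": ("time", times, {"units": "days since 2000-01-01", "calendar": "standard"}),
                    "lat": ("lat", fields[0].lat, {"units": "degrees_north"}),
                    "lon": ("lon", fields[0].lon, {"units": "degrees_east"}),
                },
                name=var,
                attrs={"units": UNITS.get(var, ""), "long_name": LONG_NAMES.get(var, var)},
            )
            path = directory / f"{var}.nc"
            da.to_dataset().to_netcdf(path, engine="scipy")
            written.append(path)
        return written

    @classmethod
    def from_netcdf(cls, directory: str | Path, variables=None) -> "EnvFieldSet":
        directory = Path(directory)
        out = cls()
        for path in sorted(directory.glob("*.nc")):
            var = path.stem
            if variables is not None and var not in variables:
                continue
            with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
                da = ds[var]
                epoch = dt.date(2000, 1, 1)
                for i, t in enumerate(np.asarray(da["time"].values)):
                    out.add(
                        EnvField(
                            var,
                            epoch + dt.timedelta(days=int(t)),
                            da["lon"].values.astype(float),
                            da["lat"].values.astype(float),
                            da.isel(time=i).values.astype(float),
                        )
                    )
        return out


def _nearest_index(axis: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Index of the nearest axis value; exact midpoints go to the lower index."""
    pos = np.searchsorted(axis, targets)
    pos = np.clip(pos, 1, len(axis) - 1)
    lower = axis[pos - 1]
    upper = axis[pos]
    # strict inequality: ties (equidistant) resolve to the lower index
    choose_upper = (targets - lower) > (upper - targets)
    idx = pos - 1 + choose_upper.astype(int)
    # targets below the first centre
    idx[targets <= axis[0]] = 0
    return idx


def regrid(
    field: EnvField,
    target_lon: np.ndarray,
    target_lat: np.ndarray,
    method: str = "nearest",
) -> EnvField:
    """Nearest-neighbour regrid onto new cell-centre axes.

    Each target cell takes the value of the nearest source cell centre
    (Euclidean in degrees, separable by axis on regular grids); missing
    values propagate.
    """
    if method != "nearest":
        raise ValueError("only nearest-neighbour regridding is supported")
    target_lon = np.asarray(target_lon, float)
    target_lat = np.asarray(target_lat, float)
    if np.any(np.diff(target_lon) <= 0) or np.any(np.diff(target_lat) <= 0):
        raise ValueError("target axes must be strictly increasing")
    ilon = _nearest_index(field.lon, target_lon)
    ilat = _nearest_index(field.lat, target_lat)
    return EnvField(
        field.variable, field.date, target_lon, target_lat, field.values[np.ix_(ilat, ilon)]
    )


def match(
    records: pd.DataFrame,
    fields: EnvFieldSet,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Join records to same-day environmental values at the nearest cell.

    ``records`` needs ``date`` (datetime-like or ISO string), ``lon`` and
    ``lat`` columns.  Ties toward the lower (lat, then lon) index.  Rows
    matching only missing (NaN) cells are dropped; the count is logged and
    stored in ``result.attrs["n_dropped_missing"]``.
    Raises KeyError naming the date when a required field is absent.
    """
    variables = variables or fields.variables
    out = records.copy()
    dates = pd.to_datetime(out["date"]).dt.date
    lon = out["lon"].to_numpy(float)
    lat = out["lat"].to_numpy(float)
    values = {v: np.full(len(out), np.nan) for v in variables}
    for day in sorted(set(dates)):
        sel = (dates == day).to_numpy()
        for var in variables:
            f = fields.get(var, day)
            ilon = _nearest_index(f.lon, lon[sel])
            ilat = _nearest_index(f.lat, lat[sel])
            values[var][sel] = f.values[ilat, ilon]
    for var in variables:
        out[var] = values[var]
    complete = ~out[variables].isna().any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("match: dropped %d records with missing covariate cells", n_dropped)
    out = out[complete].reset_index(drop=True)
    out.attrs["n_dropped_missing"] = n_dropped
    return out


def correlation_filter(
    matched: pd.DataFrame,
    candidate_vars: list[str] | None = None,
    threshold: float = 0.7,
    priority: list[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Iterative greedy collinearity pruning.

    While any retained pair has |Pearson r| >= ``threshold``, drop the
    lower-priority member of the worst-offending pair.  Constant columns
    contribute zero correlation (with a warning).  Returns the retained
    variable list (in priority order) and the full correlation matrix.
    """
    candidate_vars = list(candidate_vars or [v for v in VARIABLES if v in matched])
    priority = list(priority or DEFAULT_PRIORITY)
    missing = [v for v in candidate_vars if v not in priority]
    if missing:
        raise ValueError(f"priority list does not cover: {missing}")
    if len(matched) < 2:
        raise ValueError("need at least 2 complete-case rows")

    sub = matched[candidate_vars].astype(float)
    const = [v for v in candidate_vars if sub[v].nunique() <= 1]
    if const:
        import warnings

        warnings.warn(
            f"constant columns treated as uncorrelated: {const}", stacklevel=2
        )
    corr = sub.corr().fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)

    rank = {v: i for i, v in enumerate(priority)}
    retained = sorted(candidate_vars, key=lambda v: rank[v])
    while True:
        worst, worst_pair = 0.0, None
        for i, a in enumerate(retained):
            for b in retained[i + 1 :]:
                r = abs(corr.loc[a, b])
                if r >= threshold and r > worst:
                    worst, worst_pair = r, (a, b)
        if worst_pair is None:
            break
        a, b = worst_pair
        drop = a if rank[a] > rank[b] else b
        logger.info(
            "correlation_filter: |r(%s, %s)| = %.3f >= %.2f, dropping %s",
            a, b, worst, threshold, drop,
        )
        retained.remove(drop)
    return retained, corr
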