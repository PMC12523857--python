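"""Zero-one inflated beta (ZOIB) distribution and regression structure.

The ZOIB distribution is a three-part mixture on the closed unit interval:
a point mass at 0, a point mass at 1, and a Beta density on the open
interval.  With ``zoi`` the probability of a boundary value and ``coi`` the
conditional probability that a boundary value is 1,

    P(y = 0) = zoi * (1 - coi)
    P(y = 1) = zoi * coi
    y | interior ~ Beta(mu * phi, (1 - mu) * phi)

using the mean-precision parameterization (mean ``mu`` in (0,1), precision
``phi`` > 0).  The regression layer links all four quantities to a shared
design matrix of standardized environmental covariates: logit links for
``mu``, ``zoi`` and ``coi``, a log link for ``phi``, plus a Gaussian spatial
random effect (indexed by 1-degree grid block) entering the ``mu``
predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, xlog1py, xlogy

__all__ = [
    "ZOIBParams",
    "ZOIBData",
    "logpdf",
    "expected_value",
    "linpred",
    "simulate",
    "assign_blocks",
    "make_design",
]

_EPS = 1e-12


@dataclass
class ZOIBParams:
    """Full parameter vector of the ZOIB regression.

    Coefficient vectors conform to the design matrix (intercept first).
    ``u`` holds one spatial random-effect value per spatial block and
    enters the Beta-mean predictor; ``sigma_u`` is its standard deviation.
    ``prior_scale`` is the common Laplace prior scale applied to all
    non-intercept regression coefficients.
    """

    beta_mu: np.ndarray
    beta_phi: np.ndarray
    beta_zoi: np.ndarray
    beta_coi: np.ndarray
    u: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sigma_u: float = 1.0
    prior_scale: float = 1.0

    def __post_init__(self) -> None:
        self.beta_mu = np.atleast_1d(np.asarray(self.beta_mu, dtype=float))
        self.beta_phi = np.atleast_1d(np.asarray(self.beta_phi, dtype=float))
        self.beta_zoi = np.atleast_1d(np.asarray(self.beta_zoi, dtype=float))
        self.beta_coi = np.atleast_1d(np.asarray(self.beta_coi, dtype=float))
        self.u = np.atleast_1d(np.asarray(self.u, dtype=float))
        if self.sigma_u <= 0:
            raise ValueError("sigma_u must be > 0")
        if self.prior_scale <= 0:
            raise ValueError("prior_scale must be > 0")

    @property
    def n_coef(self) -> int:
        return len(self.beta_mu)

    def copy(self) -> "ZOIBParams":
        return ZOIBParams(
            self.beta_mu.copy(),
            self.beta_phi.copy(),
            self.beta_zoi.copy(),
            self.beta_coi.copy(),
            self.u.copy(),
            self.sigma_u,
            self.prior_scale,
        )


@dataclass
class ZOIBData:
    """Response vector, design matrix and spatial block index.

    ``y`` holds proportions in [0, 1] (exact 0s and 1s allowed), ``X`` the
    standardized covariates with a leading intercept column, ``block`` an
    integer spatial-block label per row (contiguous, starting at 0).
    """

    y: np.ndarray
    X: np.ndarray
    block: np.ndarray
    covariate_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.block = np.asarray(self.block, dtype=int)
        if self.y.ndim != 1 or self.X.ndim != 2:
            raise ValueError("y must be 1-D and X 2-D")
        if len(self.y) != self.X.shape[0] or len(self.y) != len(self.block):
            raise ValueError("y, X and block must have matching row counts")
        if np.any(~np.isfinite(self.y)) or np.any(~np.isfinite(self.X)):
            raise ValueError("y and X must not contain missing values")
        if np.any((self.y < 0) | (self.y > 1)):
            raise ValueError("responses must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_blocks(self) -> int:
        return int(self.block.max()) + 1 if len(self.block) else 0

    def subset(self, idx: np.ndarray) -> "ZOIBData":
        return ZOIBData(self.y[idx], self.X[idx], self.block[idx], self.covariate_names)


def linpred(
    params: ZOIBParams, X: np.ndarray, block: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate the four linked predictors row-wise.

    Returns ``(mu, phi, zoi, coi)`` with mu = expit(X b_mu + u[block]),
    phi = exp(X b_phi), zoi = expit(X b_zoi), coi = expit(X b_coi).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(params.beta_mu):
        raise ValueError(
            f"design matrix has {X.shape[-1] if X.ndim == 2 else '?'} columns, "
            f"expected {len(params.beta_mu)}"
        )
    eta_mu = X @ params.beta_mu
    if block is not None and len(params.u):
        block = np.asarray(block, dtype=int)
        # unseen blocks (index >= len(u)) get a zero random effect
        u_full = np.where(block < len(params.u), params.u[np.minimum(block, len(params.u) - 1)], 0.0)
        eta_mu = eta_mu + u_full
    mu = expit(eta_mu)
    phi = np.exp(X @ params.beta_phi)
    zoi = expit(X @ params.beta_zoi)
    coi = expit(X @ params.beta_coi)
    return mu, phi, zoi, coi


def logpdf(y, mu, phi, zoi, coi) -> np.ndarray:
    """Log density/mass of the ZOIB distribution, vectorized.

    log[zoi*coi] at y = 1, log[zoi*(1-coi)] at y = 0, and
    log(1-zoi) + log Beta(y; mu*phi, (1-mu)*phi) on the interior.
    """
    y, mu, phi, zoi, coi = np.broadcast_arrays(
        np.asarray(y, float), mu, phi, zoi, coi
    )
    if np.any((y < 0) | (y > 1)):
        raise ValueError("y must lie in [0, 1]")
    out = np.empty(y.shape, dtype=float)

    at0 = y == 0.0
    at1 = y == 1.0
    interior = ~(at0 | at1)

    with np.errstate(divide="ignore"):
        out[at0] = np.log(zoi[at0]) + np.log1p(-coi[at0])
        out[at1] = np.log(zoi[at1]) + np.log(coi[at1])
        yi = y[interior]
        a = mu[interior] * phi[interior]
        b = (1.0 - mu[interior]) * phi[interior]
        out[interior] = (
            np.log1p(-zoi[interior])
            + xlogy(a - 1.0, yi)
            + xlog1py(b - 1.0, -yi)
            - betaln(a, b)
        )
    return out


def expected_value(mu, zoi, coi) -> np.ndarray:
    """Mean of the ZOIB distribution: zoi*coi + (1 - zoi)*mu."""
    mu, zoi, coi = np.broadcast_arrays(np.asarray(mu, float), zoi, coi)
    return zoi * coi + (1.0 - zoi) * mu


def predict_mean(params: ZOIBParams, X: np.ndarray, block=None) -> np.ndarray:
    """Predicted proportion: distribution mean at the linked predictors."""
    mu, _, zoi, coi = linpred(params, X, block)
    return expected_value(mu, zoi, coi)


def simulate(
    params: ZOIBParams,
    X: np.ndarray,
    block: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw one ZOIB response per design-matrix row.

    Per row: with probability ``zoi`` emit a boundary value (1 with
    probability ``coi``, else 0); otherwise draw from the mean-precision
    Beta.  Deterministic under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu, phi, zoi, coi = linpred(params, X, block)
    n = len(mu)
    y = rng.beta(np.clip(mu * phi, _EPS, None), np.clip((1.0 - mu) * phi, _EPS, None))
    # guard against numerically boundary Beta draws: fold into the open interval
    y = np.clip(y, 1e-12, 1.0 - 1e-12)
    boundary = rng.random(n) < zoi
    ones = rng.random(n) < coi
    y[boundary] = ones[boundary].astype(float)
    return y


def assign_blocks(
    lon: np.ndarray, lat: np.ndarray, size: float = 1.0
) -> tuple[np.ndarray, pd.Index]:
    """Map positions to contiguous spatial-block indices on a size-degree grid.

    Returns ``(block, labels)`` where ``labels[i]`` names block ``i`` as
    ``"lonbin_latbin"`` of the lower-left cell corner.
    """
    if size <= 0:
        raise ValueError("block size must be > 0")
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    key = pd.Series(
        [
            f"{np.floor(lo / size) * size:g}_{np.floor(la / size) * size:g}"
            for lo, la in zip(lon, lat)
        ]
    )
    codes, labels = pd.factorize(key, sort=True)
    return codes.astype(int), labels


def make_design(
    df: pd.DataFrame,
    covariates: list[str],
    response: str | None = None,
    block_size: float = 1.0,
    standardizer: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[ZOIBData, tuple[np.ndarray, np.ndarray]]:
    """Build a ZOIBData from a matched-record table.

    Covariates are standardized to zero mean and unit SD (computed from
    ``df`` unless a ``(mean, sd)`` pair is supplied) and prefixed with an
    intercept column; the spatial block is the ``block_size``-degree grid
    cell of each record position.  Returns the data object and the
    ``(mean, sd)`` used, so held-out data can reuse the training scaling.
    """
    Xraw = df[covariates].to_numpy(dtype=float)
    if standardizer is None:
        mean = Xraw.mean(axis=0)
        sd = Xraw.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
    else:
        mean, sd = standardizer
    Xs = (Xraw - mean) / sd
    X = np.column_stack([np.ones(len(df)), Xs])
    block, _ = assign_blocks(df["lon"].to_numpy(), df["lat"].to_numpy(), block_size)
    y = (
        df[response].to_numpy(dtype=float)
        if response is not None
        else np.zeros(len(df))
    )
    names = ["intercept"] + list(covariates)
    return ZOIBData(y, X, block, names), (mean, sd)
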