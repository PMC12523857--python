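import numpy as np
import pytest

from mackmix import synth, zoib


def small_config(**overrides) -> synth.SimConfig:
    """A desk-scale study configuration: same structure as the default
    North-west Pacific setting, smaller domain and coarser grids."""
    kwargs = dict(
        lon_min=144.0,
        lon_max=160.0,
        lat_min=35.0,
        lat_max=48.0,
        year_start=2014,
        year_end=2023,
        n_records_per_year=120,
        n_days_per_year=8,
        fine_resolution=0.25,
        coarse_resolution=0.5,
        center_lon=148.0,
        center_lat=38.5,
        spread_lon=1.8,
        spread_lat=1.4,
        seed=7,
    )
    kwargs.update(overrides)
    return synth.SimConfig(**kwargs)


@pytest.fixture(scope="session")
def sim_config() -> synth.SimConfig:
    return small_config()


@pytest.fixture(scope="session")
def env_fields(sim_config):
    return synth.generate_env_fields(sim_config)


@pytest.fixture(scope="session")
def logbook(sim_config, env_fields):
    return synth.generate_logbook(sim_config, env_fields)


@pytest.fixture(scope="session")
def events(logbook):
    return synth.generate_sampling_events(logbook, 1000, 0.6, seed=11)


def simulate_zoib_dataset(
    n=1000, n_cov=3, n_blocks=6, seed=0, sigma_u=0.3
) -> tuple[zoib.ZOIBData, zoib.ZOIBParams]:
    """Self-simulated regression dataset with known truth."""
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, n_cov))])
    block = rng.integers(0, n_blocks, n)

    def coef(*v):
        out = np.zeros(n_cov + 1)
        k = min(len(v), n_cov + 1)
        out[:k] = v[:k]
        return out

    truth = zoib.ZOIBParams(
        beta_mu=coef(0.2, 0.6, -0.4, 0.3),
        beta_phi=coef(1.5),
        beta_zoi=coef(-0.8, 0.5),
        beta_coi=coef(0.1, 0.4),
        u=rng.normal(0, sigma_u, n_blocks),
        sigma_u=sigma_u,
        prior_scale=1.0,
    )
    y = zoib.simulate(truth, X, block, seed=rng)
    names = ["intercept"] + [f"x{j}" for j in range(1, n_cov + 1)]
    return zoib.ZOIBData(y, X, block, names), truth
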