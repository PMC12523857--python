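"""MAP/MCMC fitting, convergence diagnostics, CV and catch splitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from mackmix import infer, zoib
from mackmix.synth import LogbookRecord

from conftest import simulate_zoib_dataset

import datetime as dt


@pytest.fixture(scope="module")
def dataset():
    return simulate_zoib_dataset(n=1000, n_cov=3, seed=1)


@pytest.fixture(scope="module")
def map_fit(dataset):
    data, truth = dataset
    return infer.fit_map(data, init=infer.default_init(data, sigma_u=truth.sigma_u))


@pytest.fixture(scope="module")
def mcmc_draws(dataset, map_fit):
    data, _ = dataset
    return infer.fit_mcmc(
        data, chains=4, iterations=1200, burn_in=600, seed=3, map_fit=map_fit
    )


class TestNegLogPosterior:
    def test_vanishing_penalty_reduces_to_likelihood(self, dataset):
        data, truth = dataset
        loose = truth.copy()
        loose.prior_scale = 1e12
        loose.sigma_u = 1e6
        mu, phi, zoi, coi = zoib.linpred(loose, data.X, data.block)
        pure_nll = -float(np.sum(zoib.logpdf(data.y, mu, phi, zoi, coi)))
        got = infer.neg_log_posterior(loose, data)
        # the sigma_u normalizer is a constant offset; compare after removing it
        assert got - len(loose.u) * np.log(loose.sigma_u) == pytest.approx(pure_nll, abs=1e-3)

    def test_single_row_hand_case(self):
        params = zoib.ZOIBParams([0.0], [np.log(2.0)], [np.log(0.25)], [0.0])
        data = zoib.ZOIBData([0.5], np.ones((1, 1)), [0])
        # mu=0.5, phi=2 -> uniform Beta; zoi=0.2 -> density 0.8; no slopes, no u
        assert infer.neg_log_posterior(params, data) == pytest.approx(-np.log(0.8), abs=1e-12)

    def test_matches_row_sum_oracle(self, dataset):
        data, truth = dataset
        mu, phi, zoi, coi = zoib.linpred(truth, data.X, data.block)
        by_row = -sum(
            float(zoib.logpdf(data.y[i], mu[i], phi[i], zoi[i], coi[i]))
            for i in range(data.n)
        )
        slopes = np.concatenate(
            [truth.beta_mu[1:], truth.beta_phi[1:], truth.beta_zoi[1:], truth.beta_coi[1:]]
        )
        expected = (
            by_row
            + float(np.sum(np.abs(slopes))) / truth.prior_scale
            + float(np.sum(truth.u**2)) / (2 * truth.sigma_u**2)
            + len(truth.u) * np.log(truth.sigma_u)
        )
        assert infer.neg_log_posterior(truth, data, smooth=False) == pytest.approx(
            expected, rel=1e-10
        )


class TestFitMap:
    def test_stationary_at_truth_init(self, dataset, map_fit):
        data, truth = dataset
        refit = infer.fit_map(data, init=map_fit.params, compute_hessian=False)
        packed0 = np.concatenate([map_fit.params.beta_mu, map_fit.params.beta_zoi])
        packed1 = np.concatenate([refit.params.beta_mu, refit.params.beta_zoi])
        assert np.allclose(packed0, packed1, atol=1e-3)

    def test_intercept_only_moment_match(self):
        data, truth = simulate_zoib_dataset(n=2000, n_cov=0, n_blocks=1, seed=2, sigma_u=0.3)
        fit = infer.fit_map(data, compute_hessian=False)
        mu, phi, zoi, coi = zoib.linpred(
            fit.params, np.ones((1, 1)), np.zeros(1, dtype=int)
        )
        y = data.y
        f0, f1 = np.mean(y == 0), np.mean(y == 1)
        interior = y[(y > 0) & (y < 1)]
        # bootstrap SEs of the sample fractions / interior mean
        rng = np.random.default_rng(0)
        bs = lambda v, stat: np.std(
            [stat(v[rng.integers(0, len(v), len(v))]) for _ in range(200)]
        )
        assert abs(zoi[0] * (1 - coi[0]) - f0) < 3 * bs(y, lambda s: np.mean(s == 0))
        assert abs(zoi[0] * coi[0] - f1) < 3 * bs(y, lambda s: np.mean(s == 1))
        assert abs(mu[0] - interior.mean()) < 3 * bs(interior, np.mean) + 0.02

    def test_two_covariate_recovery(self):
        data, truth = simulate_zoib_dataset(n=2000, n_cov=2, seed=3)
        fit = infer.fit_map(
            data, init=infer.default_init(data, sigma_u=truth.sigma_u),
            compute_hessian=False,
        )
        assert np.all(np.abs(fit.params.beta_mu[1:] - truth.beta_mu[1:]) < 0.2)
        assert np.all(np.abs(fit.params.beta_zoi[1:] - truth.beta_zoi[1:]) < 0.2)
        assert np.all(np.abs(fit.params.beta_coi[1:] - truth.beta_coi[1:]) < 0.2)

    def test_few_rows_warns(self):
        data, _ = simulate_zoib_dataset(n=60, n_cov=3, seed=4)
        with pytest.warns(UserWarning, match="rows"):
            infer.fit_map(data, compute_hessian=False)


class TestRhat:
    def test_permuted_single_stream_is_near_one(self):
        rng = np.random.default_rng(0)
        stream = rng.standard_normal((4 * 500, 2))
        chains = stream.reshape(4, 500, 2)
        r = infer.rhat(chains)
        assert np.all((r > 0.99) & (r < 1.01))

    def test_gross_nonconvergence_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, (1, 400, 1))
        b = rng.normal(10, 1, (1, 400, 1))
        r = infer.rhat(np.concatenate([a, b]))
        assert r.iloc[0] > 3

    def test_matches_textbook_split_formula(self):
        rng = np.random.default_rng(2)
        arr = rng.standard_normal((4, 200, 3)) + rng.normal(0, 0.3, (4, 1, 3))
        got = infer.rhat(arr)
        # independent textbook implementation
        for j in range(3):
            halves = []
            for c in range(4):
                x = arr[c, :, j]
                halves += [x[:100], x[100:]]
            m = len(halves)
            nh = 100
            means = np.array([h.mean() for h in halves])
            B = nh * means.var(ddof=1)
            W = np.mean([h.var(ddof=1) for h in halves])
            vhat = (nh - 1) / nh * W + B / nh
            assert got.iloc[j] == pytest.approx(np.sqrt(vhat / W), abs=1e-12)

    def test_matches_arviz_reference(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        arr = rng.standard_normal((4, 300, 2)) * [1.0, 2.0]
        got = infer.rhat(arr)
        ref = az.rhat(az.convert_to_dataset(arr), method="split")
        np.testing.assert_allclose(got.to_numpy(), ref["x"].values, rtol=1e-10)

    def test_single_chain_rejected_and_zero_variance_flagged(self):
        with pytest.raises(ValueError):
            infer.rhat(np.zeros((1, 200, 1)))
        r = infer.rhat(np.zeros((2, 200, 1)))
        assert np.isnan(r.iloc[0])


class TestMcmc:
    def test_deterministic_under_seed(self, dataset, map_fit):
        data, _ = dataset
        a = infer.fit_mcmc(data, chains=2, iterations=300, burn_in=150, seed=5, map_fit=map_fit)
        b = infer.fit_mcmc(data, chains=2, iterations=300, burn_in=150, seed=5, map_fit=map_fit)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_posterior_means_consistent_with_map(self, dataset, map_fit, mcmc_draws):
        data, _ = dataset
        pooled = mcmc_draws.post_burn_in.reshape(-1, mcmc_draws.draws.shape[2])
        n_core = 4 * data.X.shape[1] + len(map_fit.params.u)
        theta_map = np.concatenate(
            [map_fit.params.beta_mu, map_fit.params.beta_phi,
             map_fit.params.beta_zoi, map_fit.params.beta_coi, map_fit.params.u]
        )
        mean = pooled[:, :n_core].mean(axis=0)
        sd = pooled[:, :n_core].std(axis=0)
        assert np.all(np.abs(mean - theta_map) < 2 * sd)

    def test_acceptance_reported(self, mcmc_draws):
        assert mcmc_draws.acceptance.shape[0] == 4
        assert np.all(mcmc_draws.acceptance > 0.05)

    def test_draws_long_format(self, mcmc_draws):
        df = mcmc_draws.to_frame()
        assert set(df.columns) == {"chain", "iteration", "parameter", "value"}
        c, n, p = mcmc_draws.draws.shape
        assert len(df) == c * n * p


class TestPosteriorPredictive:
    def test_replicate_count_and_shape(self, dataset, map_fit, mcmc_draws):
        data, _ = dataset
        ppc = infer.posterior_predictive(mcmc_draws, data, map_fit.params, n_rep=100, seed=1)
        assert ppc.y_rep.shape == (100, data.n)

    def test_observed_inside_envelope_for_self_simulated_data(
        self, dataset, map_fit, mcmc_draws
    ):
        data, _ = dataset
        ppc = infer.posterior_predictive(mcmc_draws, data, map_fit.params, n_rep=100, seed=2)
        key = ["frac_zeros", "frac_ones", "mean"]
        assert ppc.summary.loc[key, "inside_envelope"].all()


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([0.1, 0.5, 0.9])
        m = infer.metrics(y, y)
        assert m == (0.0, 0.0, 1.0)

    def test_hand_arithmetic_case(self):
        m = infer.metrics(np.array([0.0, 1.0]), np.array([1.0, 0.0]))
        assert m.rmse == pytest.approx(1.0)
        assert m.mae == pytest.approx(1.0)
        assert m.r2 == pytest.approx(-3.0)

    def test_null_predictor_r2_zero(self):
        y = np.array([0.2, 0.4, 0.9])
        m = infer.metrics(y, np.full(3, y.mean()))
        assert m.r2 == pytest.approx(0.0, abs=1e-12)

    def test_constant_y_flagged(self):
        with pytest.warns(UserWarning):
            m = infer.metrics(np.ones(4), np.zeros(4))
        assert np.isnan(m.r2)

    def test_mae_never_exceeds_rmse(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(2, 50)
            m = infer.metrics(rng.standard_normal(n), rng.standard_normal(n))
            assert m.mae <= m.rmse + 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            infer.metrics(np.ones(3), np.ones(4))


class TestKfoldCV:
    def test_partition_and_fold_sizes(self):
        data, truth = simulate_zoib_dataset(n=1000, n_cov=2, seed=6)
        out = infer.kfold_cv(data, k=5, blocking="record", seed=0)
        folds = out[out.fold != "mean"]
        assert folds["n_test"].sum() == 1000
        assert (folds["n_test"] == 200).all()

    def test_spatial_blocking_partitions_blocks(self):
        data, _ = simulate_zoib_dataset(n=600, n_cov=2, n_blocks=10, seed=7)
        out = infer.kfold_cv(data, k=5, blocking="spatial_block", seed=0)
        folds = out[out.fold != "mean"]
        assert folds["n_test"].sum() == 600

    def test_heldout_r2_near_oracle(self):
        data, truth = simulate_zoib_dataset(n=4000, n_cov=2, seed=8)
        mu, _, zoi, coi = zoib.linpred(truth, data.X, data.block)
        oracle = infer.metrics(data.y, zoib.expected_value(mu, zoi, coi))
        out = infer.kfold_cv(data, k=5, blocking="record", seed=1)
        mean_r2 = float(out.loc[out.fold == "mean", "r2"].iloc[0])
        assert abs(mean_r2 - oracle.r2) < 0.1

    def test_invalid_k(self):
        data, _ = simulate_zoib_dataset(n=100, n_cov=1, seed=9)
        with pytest.raises(ValueError):
            infer.kfold_cv(data, k=1)


class TestSplitCatch:
    def make_record(self, mixed=1000.0, sets=2):
        return LogbookRecord("V001", dt.date(2020, 5, 1), 150.0, 40.0, sets, mixed)

    def test_hand_arithmetic(self):
        blue, chub, bps, cps = infer.split_catch(self.make_record(), 0.3)
        assert (blue, chub, bps, cps) == (300.0, 700.0, 150.0, 350.0)

    def test_all_blue(self):
        blue, chub, _, _ = infer.split_catch(self.make_record(), 1.0)
        assert blue == 1000.0 and chub == 0.0

    def test_exact_conservation(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            mixed = float(rng.uniform(0, 5e4))
            p = float(rng.uniform(0, 1))
            rec = self.make_record(mixed, int(rng.integers(1, 9)))
            blue, chub, _, _ = infer.split_catch(rec, p)
            assert blue + chub == mixed  # exact, to the last bit

    def test_table_version_conserves(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {"mixed_catch_kg": rng.uniform(0, 1e4, 50), "sets": rng.integers(1, 6, 50)}
        )
        out = infer.split_catch_table(df, rng.uniform(0, 1, 50))
        np.testing.assert_array_equal(
            out.blue_kg + out.chub_kg, df.mixed_catch_kg
        )

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            infer.split_catch(self.make_record(), 1.2)


def test_parameter_recovery_coverage_scaled_down():
    """MAP Wald 95% intervals cover the generating coefficients in most of
    a small batch of self-simulated datasets (scaled-down calibration)."""
    n_rep = 8
    covered = total = 0
    for rep in range(n_rep):
        data, truth = simulate_zoib_dataset(n=2000, n_cov=3, seed=100 + rep)
        fit = infer.fit_map(data, init=infer.default_init(data, sigma_u=truth.sigma_u))
        wi = fit.wald_interval()
        truth_vec = np.concatenate(
            [truth.beta_mu, truth.beta_phi, truth.beta_zoi, truth.beta_coi]
        )
        sub = wi.iloc[: len(truth_vec)]
        covered += int(np.sum((sub.lower <= truth_vec) & (truth_vec <= sub.upper)))
        total += len(truth_vec)
    assert covered / total >= 0.85
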