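"""Longitudinal Gaussian mixture: density, EM, BIC selection, splitting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from nwstress.longclust import (
    fit_em,
    gaussian_density_cholesky,
    gaussian_logdensity_cholesky,
    modified_cholesky,
    n_params,
    prescreen_profiles,
    reconstruct_sigma,
    select_G,
    split_up_down,
)


def random_spd(dim, rng):
    A = rng.normal(size=(dim, dim))
    return A @ A.T + dim * np.eye(dim)


class TestCholeskyDensity:
    def test_standard_normal_at_mean(self):
        mu = np.zeros(5)
        val = gaussian_density_cholesky(mu, mu, np.eye(5), np.ones(5))
        assert val == pytest.approx((2 * np.pi) ** -2.5, rel=1e-12)

    def test_at_mean_general_covariance(self, rng):
        sigma = random_spd(5, rng)
        T, d = modified_cholesky(sigma)
        mu = rng.normal(size=5)
        val = gaussian_density_cholesky(mu, mu, T, d)
        expected = (2 * np.pi) ** -2.5 * np.prod(d) ** -0.5
        assert val == pytest.approx(expected, rel=1e-10)

    def test_against_dense_oracle_on_random_points(self, rng):
        """Agrees with an explicitly inverted dense multivariate normal on
        100 random points."""
        sigma = random_spd(5, rng)
        T, d = modified_cholesky(sigma)
        mu = rng.normal(size=5)
        X = rng.normal(size=(100, 5))
        got = gaussian_logdensity_cholesky(X, mu, T, d)
        inv = np.linalg.inv(sigma)
        _sign, logdet = np.linalg.slogdet(sigma)
        diff = X - mu
        quad = np.einsum("ij,jk,ik->i", diff, inv, diff)
        expected = -0.5 * (5 * np.log(2 * np.pi) + logdet + quad)
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_cholesky_roundtrip(self, rng):
        for _ in range(20):
            sigma = random_spd(5, rng)
            T, d = modified_cholesky(sigma)
            assert np.allclose(np.tril(T), T)
            np.testing.assert_allclose(np.diag(T), 1.0, atol=1e-12)
            assert (d > 0).all()
            np.testing.assert_allclose(reconstruct_sigma(T, d), sigma, atol=1e-10)

    def test_nonpositive_innovation_variance_rejected(self):
        with pytest.raises(ValueError):
            gaussian_logdensity_cholesky(np.zeros(5), np.zeros(5), np.eye(5), np.zeros(5))


class TestParameterCounting:
    @pytest.mark.parametrize(
        "G,cov,expected",
        [(4, "full", 83), (1, "full", 20), (2, "diagonal", 21), (3, "tied", 32)],
    )
    def test_free_parameter_counts(self, G, cov, expected):
        assert n_params(G, 5, cov) == expected


class TestFitEM:
    def test_single_component_matches_gaussian_mle(self, rng):
        """G=1 reduces to the closed-form Gaussian MLE: sample mean, 1/n
        covariance, and the matching log-likelihood."""
        X = rng.multivariate_normal(np.arange(5.0), random_spd(5, rng), size=150)
        model, assign = fit_em(X, G=1, n_restarts=2, seed=0)
        np.testing.assert_allclose(model.means[0], X.mean(axis=0), atol=1e-8)
        S = np.cov(X.T, bias=True)
        np.testing.assert_allclose(model.covariances()[0], S, atol=1e-6)
        _sign, logdet = np.linalg.slogdet(S)
        ll = -0.5 * len(X) * (5 * np.log(2 * np.pi) + logdet + 5)
        assert model.loglik == pytest.approx(ll, abs=1e-8 * abs(ll))
        assert (assign["map_group"] == 1).all()

    def test_loglik_monotone_within_run(self, rng):
        X = rng.normal(size=(200, 5))
        model, _ = fit_em(X, G=3, n_restarts=3, seed=1, max_iter=300)
        trace = model.loglik_trace
        assert (np.diff(trace) >= -1e-9 * np.maximum(np.abs(trace[:-1]), 1.0)).all()

    def test_responsibilities_rows_sum_to_one(self, leaf_profiles):
        model, assign = fit_em(leaf_profiles, G=3, n_restarts=3, seed=2)
        z = assign[[c for c in assign.columns if c.startswith("z")]].to_numpy()
        np.testing.assert_allclose(z.sum(axis=1), 1.0, atol=1e-12)
        assert assign["map_group"].between(1, 3).all()

    def test_two_separated_clusters_fully_recovered(self, rng):
        centers = np.zeros((2, 5))
        centers[1, :] = 3.0  # 6-sigma separation per coordinate at sigma=0.5... generous
        labels = rng.integers(0, 2, size=500)
        X = centers[labels] + rng.normal(0, 0.5, size=(500, 5))
        model, assign = fit_em(X, G=2, n_restarts=5, seed=3)
        assert adjusted_rand_score(labels, assign["map_group"]) == 1.0

    def test_seed_invariance_on_separated_data(self, rng):
        centers = np.array([[0.0] * 5, [4.0] * 5, [-4.0, 0, 4.0, 0, -4.0]])
        labels = rng.integers(0, 3, size=300)
        X = centers[labels] + rng.normal(0, 0.4, size=(300, 5))
        _m1, a1 = fit_em(X, G=3, n_restarts=5, seed=10)
        _m2, a2 = fit_em(X, G=3, n_restarts=5, seed=99)
        assert adjusted_rand_score(a1["map_group"], a2["map_group"]) == 1.0

    def test_loglik_competitive_with_sklearn(self, rng):
        """Independent cross-check: our best log-likelihood is no worse
        than sklearn's GaussianMixture on the same data."""
        from sklearn.mixture import GaussianMixture

        centers = np.array([[0.0] * 5, [3.0] * 5])
        labels = rng.integers(0, 2, size=300)
        X = centers[labels] + rng.normal(0, 0.5, size=(300, 5))
        model, _ = fit_em(X, G=2, n_restarts=5, seed=4)
        gm = GaussianMixture(2, covariance_type="full", n_init=5, random_state=0,
                             tol=1e-8, reg_covar=1e-10).fit(X)
        assert model.loglik >= gm.score(X) * len(X) - 1e-3

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_em(rng.normal(size=(3, 5)), G=4)

    @pytest.mark.parametrize("covariance", ["tied", "diagonal"])
    def test_constrained_covariance_families(self, covariance, rng):
        """Tied/diagonal variants fit, respect their structure, and still
        separate well-separated clusters."""
        centers = np.array([[0.0] * 5, [4.0] * 5])
        labels = rng.integers(0, 2, size=300)
        X = centers[labels] + rng.normal(0, 0.5, size=(300, 5))
        model, assign = fit_em(X, G=2, n_restarts=3, seed=0, covariance=covariance)
        assert adjusted_rand_score(labels, assign["map_group"]) == 1.0
        covs = model.covariances()
        if covariance == "tied":
            np.testing.assert_allclose(covs[0], covs[1], atol=1e-8)
        else:
            for c in covs:
                off = c - np.diag(np.diag(c))
                np.testing.assert_allclose(off, 0.0, atol=1e-8)


class TestSelectG:
    def test_single_flat_cluster_selects_one(self, rng):
        X = rng.normal(0, 0.3, size=(300, 5))
        model, _assign, table = select_G(X, range(1, 5), n_restarts=4, seed=0,
                                         max_iter=300)
        assert model.G == 1

    def test_bic_convention_larger_is_better(self, rng):
        X = rng.normal(size=(100, 5))
        model, _a, _t = fit_em(X, G=1, n_restarts=2, seed=0)[0], None, None
        assert model.bic == pytest.approx(2 * model.loglik - 20 * np.log(100))


class TestPrescreenAndSplit:
    def test_prescreen_threshold_arithmetic(self):
        profiles = pd.DataFrame(
            [
                [0.0, 1.7, 0.0, 0.0, 0.0],   # 2^1.7 ~ 3.25-fold under mild
                [0.0, 0.0, 0.0, 0.0, 0.0],   # flat
                [0.0, 0.5, -1.7, 0.0, 0.0],  # severe response only
            ],
            columns=["W1", "W2", "W3", "W4", "W5"],
            index=["a", "b", "c"],
        )
        assert prescreen_profiles(profiles, 3.0) == ["a", "c"]
        assert prescreen_profiles(profiles, 1.0) == ["a", "b", "c"]

    def test_split_up_down_rules(self):
        profiles = pd.DataFrame(
            [[0.0, 1.0, 0, 0, 0], [0.0, -1.0, 0, 0, 0], [0.5, 0.5, 0, 0, 0]],
            columns=["W1", "W2", "W3", "W4", "W5"],
            index=["up1", "dn1", "tie"],
        )
        assign = pd.DataFrame({"map_group": [1, 1, 1]}, index=profiles.index)
        sub = split_up_down(assign, profiles, split_pair=(2, 1))
        assert sub.tolist() == ["up", "down", "down"]

    def test_mirrored_profiles_share_component_but_split(self, rng):
        """The mixture is symmetric: x and -x trajectories with a common
        shape land in one component and are separated by the splitter."""
        shape = np.array([0.0, 1.5, 3.0, 1.0, 0.3])
        n = 120
        sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        X = sign[:, None] * shape + rng.normal(0, 0.2, size=(n, 5))
        # mirrored pairs around zero form a single zero-mean component
        profiles = pd.DataFrame(X, columns=["W1", "W2", "W3", "W4", "W5"])
        model, assign = fit_em(profiles, G=1, n_restarts=3, seed=5)
        sub = split_up_down(assign, profiles, split_pair=(2, 1))
        np.testing.assert_array_equal(
            sub.to_numpy() == "up", sign > 0
        )

    def test_invalid_split_pair(self, leaf_profiles):
        assign = pd.DataFrame({"map_group": [1] * len(leaf_profiles)},
                              index=leaf_profiles.index)
        with pytest.raises(ValueError):
            split_up_down(assign, leaf_profiles, split_pair=(0, 1))
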