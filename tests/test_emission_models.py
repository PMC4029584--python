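import numpy as np
import pytest

from haplocn.emission_models import (
    MODEL_MEMBERS,
    EmissionModel,
    in_shaded_region,
    emission_logdensity,
    mahalanobis,
    seed_bank,
    seed_models,
    select_group,
    update_models,
)
from haplocn.haplotype_tree import AllelicState
from haplocn.signal_io import SeedClusters
from tests.conftest import make_seeds


class TestPartition:
    def test_all_36_states_covered_exactly_once(self):
        seen = set()
        for members in MODEL_MEMBERS:
            for h1, h2 in members:
                assert (h1, h2) not in seen
                seen.add((h1, h2))
        assert len(seen) == 36

    def test_asymmetric_pairs_in_same_model(self):
        # both orders of an asymmetric pair share a model
        for members in MODEL_MEMBERS:
            s = set(members)
            for h1, h2 in members:
                assert (h2, h1) in s


class TestSeedGrid:
    def test_extrapolated_center_distances(self, unit_bank):
        mu = unit_bank.means[0]
        # dist(M1, M0) == dist(M1, M4) along the A axis
        assert np.linalg.norm(mu[0] - mu[1]) == pytest.approx(np.linalg.norm(mu[4] - mu[1]))
        # dist(M9, M10) == dist(M9, M8) along the B axis
        assert np.linalg.norm(mu[10] - mu[9]) == pytest.approx(np.linalg.norm(mu[8] - mu[9]))

    def test_anchor_centers_are_seeds(self, unit_bank):
        mu = unit_bank.means[0]
        np.testing.assert_allclose(mu[1], [2, 0])
        np.testing.assert_allclose(mu[5], [1, 1])
        np.testing.assert_allclose(mu[9], [0, 2])

    def test_mirror_symmetry_of_swapped_seeds(self):
        seeds = make_seeds(1)
        means, _, _ = seed_models(seeds, 0)
        # swap the two intensity axes and the AA/BB roles
        sw = SeedClusters(seeds.means[:, ::-1, ::-1].copy(), seeds.covs.copy())
        means_sw, _, _ = seed_models(sw, 0)
        mirror = {0: 10, 1: 9, 2: 6, 3: 3, 4: 8, 5: 5, 6: 2, 7: 7, 8: 4, 9: 1, 10: 0}
        for mid, mirrored in mirror.items():
            np.testing.assert_allclose(means_sw[mid], means[mirrored][::-1], atol=1e-12)

    def test_degenerate_seeds_flagged_with_cohort_fallback(self):
        seeds = make_seeds(3)
        seeds.means[1, 0] = seeds.means[1, 1]  # a_hi == a_mid at SNP 1
        bank = seed_bank(seeds)
        assert bank.flagged.tolist() == [False, True, False]
        np.testing.assert_allclose(bank.means[1], bank.means[0])

    def test_degenerate_without_fallback_raises(self):
        seeds = make_seeds(1)
        seeds.means[0, 0] = seeds.means[0, 1]
        with pytest.raises(ValueError, match="degenerate"):
            seed_models(seeds, 0)


class TestMahalanobis:
    def test_zero_at_center(self, unit_bank):
        assert mahalanobis(unit_bank.means[0, 5], unit_bank.model(0, 5)) == 0.0

    def test_identity_covariance_is_euclidean(self):
        model = EmissionModel(5, np.zeros(2), np.eye(2))
        assert mahalanobis((3.0, 4.0), model) == pytest.approx(5.0)

    def test_matches_brute_force_quadratic_form(self):
        rng = np.random.default_rng(6)
        A = rng.normal(size=(2, 2))
        cov = A @ A.T + 0.1 * np.eye(2)
        mu = rng.normal(size=2)
        model = EmissionModel(0, mu, cov)
        for _ in range(10):
            s = rng.normal(size=2)
            expected = np.sqrt((s - mu) @ np.linalg.inv(cov) @ (s - mu))
            assert mahalanobis(s, model) == pytest.approx(expected, rel=1e-10)


class TestGroupSelection:
    def test_center_selects_own_model(self, unit_bank):
        for mid in range(11):
            assert select_group(unit_bank.means[0, mid], unit_bank, 0) == mid

    def test_midway_tie_breaks_to_lower_id(self, unit_bank):
        mid_point = (unit_bank.means[0, 4] + unit_bank.means[0, 5]) / 2
        assert select_group(mid_point, unit_bank, 0) == 4

    def test_random_signals_match_exhaustive_argmin(self, unit_bank):
        rng = np.random.default_rng(8)
        for _ in range(25):
            s = rng.uniform(-0.5, 3.5, size=2)
            d = [mahalanobis(s, unit_bank.model(0, m)) for m in range(11)]
            assert select_group(s, unit_bank, 0) == int(np.argmin(d))

    def test_batch_distances_match_scalar(self, unit_bank):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 3, size=(1, 5))
        b = rng.uniform(0, 3, size=(1, 5))
        d2 = unit_bank.distances_sq(a, b)
        for s in range(5):
            for m in range(11):
                expected = mahalanobis((a[0, s], b[0, s]), unit_bank.model(0, m)) ** 2
                assert d2[0, s, m] == pytest.approx(expected, rel=1e-9)


class TestLogDensity:
    def test_closed_form_at_center_identity_cov(self):
        seeds = make_seeds(1, sd=1.0)
        bank = seed_bank(seeds)
        s = bank.means[0, 5]
        val = emission_logdensity(s, (AllelicState.A, AllelicState.B), bank, 0)
        assert val == pytest.approx(np.log(1 / (2 * np.pi)))

    def test_states_of_one_model_share_density(self, unit_bank):
        s = (1.7, 0.2)
        d1 = emission_logdensity(s, (AllelicState.A, AllelicState.A), unit_bank, 0)
        d2 = emission_logdensity(s, (AllelicState.A_MINUS, AllelicState.A_PLUS), unit_bank, 0)
        assert d1 == d2  # both genotypic states belong to M1

    def test_density_integrates_to_one(self, unit_bank):
        # numeric quadrature on a +-6 sigma grid around M5
        mu = unit_bank.means[0, 5]
        sd = 0.2
        xs = np.linspace(mu[0] - 6 * sd, mu[0] + 6 * sd, 301)
        ys = np.linspace(mu[1] - 6 * sd, mu[1] + 6 * sd, 301)
        X, Y = np.meshgrid(xs, ys)
        from scipy.stats import multivariate_normal

        total = multivariate_normal(mu, unit_bank.covs[0, 5]).pdf(
            np.stack([X.ravel(), Y.ravel()], axis=1)
        ).sum() * (xs[1] - xs[0]) * (ys[1] - ys[0])
        assert total == pytest.approx(1.0, abs=1e-3)
        # and the bank's log density agrees with scipy's at the center
        val = emission_logdensity(mu, (AllelicState.A, AllelicState.B), unit_bank, 0)
        assert val == pytest.approx(multivariate_normal(mu, unit_bank.covs[0, 5]).logpdf(mu))


class TestShadedRegion:
    def test_normal_centers_inside(self, unit_bank):
        for mid in (1, 5, 9):
            assert in_shaded_region(unit_bank.means[0, mid], unit_bank, 0)

    def test_far_aberrant_center_outside(self, unit_bank):
        assert not in_shaded_region(unit_bank.means[0, 0], unit_bank, 0)

    def test_boundary_point_included(self, unit_bank):
        from scipy.stats import chi2

        r = np.sqrt(chi2.ppf(0.99, 2)) * 0.2  # sd = 0.2 isotropic
        s = unit_bank.means[0, 5] + np.array([r, 0.0])
        assert in_shaded_region(s, unit_bank, 0, quantile=0.99)
        s_out = unit_bank.means[0, 5] + np.array([r * 1.01, 0.0])
        # still inside? only if within M1's or M9's ellipse; it is not
        assert not in_shaded_region(s_out, unit_bank, 0, quantile=0.99)


class TestUpdateModels:
    def test_recovers_known_normal_within_three_se(self, unit_bank):
        rng = np.random.default_rng(5)
        n = 200
        true_mu = np.array([1.4, 0.9])
        true_cov = np.array([[0.04, 0.01], [0.01, 0.03]])
        pts = rng.multivariate_normal(true_mu, true_cov, size=n)
        a, b = pts[None, :, 0], pts[None, :, 1]
        assignments = np.full((1, n), 5)
        bank = update_models(unit_bank, assignments, a, b)
        se_mu = np.sqrt(np.diag(true_cov) / n)
        assert np.all(np.abs(bank.means[0, 5] - true_mu) <= 3 * se_mu)
        se_var = true_cov.diagonal() * np.sqrt(2.0 / (n - 1))
        assert np.all(np.abs(np.diag(bank.covs[0, 5]) - np.diag(true_cov)) <= 3 * se_var)

    def test_empty_model_reseeded_from_grid(self, unit_bank):
        rng = np.random.default_rng(1)
        # samples populate only the three normal clusters
        n = 60
        assignments = np.repeat([1, 5, 9], n // 3)[None, :]
        centers = unit_bank.means[0, assignments[0]]
        noise = rng.normal(scale=0.05, size=(n, 2))
        a, b = (centers + noise)[None, :, 0], (centers + noise)[None, :, 1]
        bank = update_models(unit_bank, assignments, a, b)
        mu = bank.means[0]
        # grid equalities hold to machine precision after the re-seed
        assert np.linalg.norm(mu[0] - mu[1]) == pytest.approx(np.linalg.norm(mu[4] - mu[1]))
        assert np.linalg.norm(mu[10] - mu[9]) == pytest.approx(np.linalg.norm(mu[8] - mu[9]))
        # M0's center sits one A-grid-step beyond the updated M1
        np.testing.assert_allclose(mu[0], [2 * mu[1][0] - mu[5][0], mu[1][1]], atol=1e-12)

    def test_degenerate_members_ridge_regularized(self, unit_bank):
        a = np.full((1, 4), 1.3)
        b = np.full((1, 4), 0.7)
        assignments = np.full((1, 4), 5)
        bank = update_models(unit_bank, assignments, a, b)
        cov = bank.covs[0, 5]
        assert np.linalg.det(cov) > 0  # identical signals, still invertible
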