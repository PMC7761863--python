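"""IAS MAP estimation, MNE/MCE special cases and the Gibbs sampler."""

import numpy as np
import pytest
from scipy import optimize, stats

import cghbm as c
from cghbm.forward_synthetic import (GeometryConfig, LeadField, SensorArray,
                                     SourceSpace)
from cghbm.hyperprior import HyperpriorSpec
from cghbm.inversion import (ROI, IASDivergenceError, ReconstructionResult,
                             SamplerChain, cm_estimate, gibbs_sample, ias_map,
                             log_posterior, mce, mne, x_update)
from conftest import random_problem


def tikhonov_mne(L, y, sigma, theta0):
    """Source-space Tikhonov oracle: (L^T L + (sigma^2/theta0) I)^-1 L^T y."""
    n = L.shape[1]
    return np.linalg.solve(L.T @ L + (sigma**2 / theta0) * np.eye(n), L.T @ y)


def toy_leadfield(L):
    """Wrap a raw matrix as a LeadField on a minimal one-region source space."""
    n_pos = L.shape[1] // 3
    geo = GeometryConfig()
    pos = np.column_stack([np.linspace(71, 77, n_pos),
                           np.zeros(n_pos), np.zeros(n_pos)])
    normals = np.tile([1.0, 0.0, 0.0], (n_pos, 1))
    space = SourceSpace(pos, normals, np.array(["cortical"] * n_pos),
                        "dense", geo)
    sensors = SensorArray("EEG", np.zeros((L.shape[0], 3)))
    return LeadField(L, space, sensors)


class TestLogPosterior:
    def test_matches_direct_density_evaluation(self, rng):
        """Differences of log p equal the brute-force three-density sums."""
        L, y, sigma = random_problem(rng, m=6, n_pos=1)
        spec = HyperpriorSpec("G", 3.0, 0.8)

        def brute(x, theta):
            lp = stats.gamma.logpdf(theta, a=3.0, scale=0.8).sum()
            lp += stats.norm.logpdf(x, scale=np.sqrt(theta)).sum()
            lp += stats.norm.logpdf(y - L @ x, scale=sigma).sum()
            return lp

        x1, x2 = rng.normal(size=(2, 3))
        t1, t2 = rng.uniform(0.1, 2.0, size=(2, 3))
        got = (log_posterior(x1, t1, y, L, sigma, spec)
               - log_posterior(x2, t2, y, L, sigma, spec))
        assert got == pytest.approx(brute(x1, t1) - brute(x2, t2), abs=1e-10)

    def test_nonpositive_theta_gives_minus_inf(self, rng):
        L, y, sigma = random_problem(rng, m=6, n_pos=1)
        spec = HyperpriorSpec("G", 3.0, 1.0)
        assert log_posterior(np.zeros(3), [1.0, 0.0, 1.0], y, L, sigma,
                             spec) == -np.inf

    def test_maximizer_in_x_is_the_tikhonov_update(self, rng):
        """For fixed theta, argmax_x log p equals the weighted Tikhonov solve."""
        L, y, sigma = random_problem(rng, m=8, n_pos=2)
        theta = rng.uniform(0.2, 2.0, size=6)
        spec = HyperpriorSpec("G", 3.0, 1.0)
        res = optimize.minimize(
            lambda x: -log_posterior(x, theta, y, L, sigma, spec),
            np.zeros(6), method="BFGS", options={"gtol": 1e-12})
        np.testing.assert_allclose(res.x, x_update(L, y, sigma, theta),
                                   rtol=1e-4, atol=1e-6)


class TestXUpdate:
    def test_sensor_and_source_space_forms_agree(self, rng):
        for _ in range(5):
            L = rng.normal(size=(20, 60))
            y = rng.normal(size=20)
            theta = rng.uniform(0.05, 3.0, size=60)
            direct = np.linalg.solve(L.T @ L / 0.04 + np.diag(1.0 / theta),
                                     L.T @ y / 0.04)
            np.testing.assert_allclose(x_update(L, y, 0.2, theta), direct,
                                       rtol=1e-8, atol=1e-12)

    def test_zero_theta_prunes_to_zero(self, rng):
        L, y, sigma = random_problem(rng)
        assert np.all(x_update(L, y, sigma, np.zeros(L.shape[1])) == 0.0)

    def test_partial_pruning_exact(self, rng):
        """theta_i = 0 columns are pruned exactly (match reduced problem)."""
        L, y, sigma = random_problem(rng, m=10, n_pos=4)
        theta = rng.uniform(0.1, 1.0, size=12)
        theta[[1, 5, 6]] = 0.0
        x = x_update(L, y, sigma, theta)
        assert np.all(x[[1, 5, 6]] == 0.0)
        keep = theta > 0
        x_red = x_update(L[:, keep], y, sigma, theta[keep])
        np.testing.assert_allclose(x[keep], x_red, rtol=1e-10)

    def test_negative_theta_rejected(self, rng):
        L, y, sigma = random_problem(rng)
        with pytest.raises(ValueError):
            x_update(L, y, sigma, -np.ones(L.shape[1]))


class TestIASMap:
    def test_first_iterate_is_tikhonov_mne(self, rng):
        """With (G, beta=1.5), IAS iterate 1 is the closed-form MNE."""
        L, y, sigma = random_problem(rng, m=14, n_pos=6)
        theta0 = 0.5
        res = ias_map(L, y, sigma, HyperpriorSpec("G", 1.5, theta0),
                      n_iterations=3)
        np.testing.assert_allclose(res.iterates[0],
                                   tikhonov_mne(L, y, sigma, theta0),
                                   rtol=1e-8, atol=1e-12)

    def test_objective_monotone_over_50_random_problems(self):
        """Coordinate descent: the negative log posterior never increases."""
        rng = np.random.default_rng(123)
        specs = [HyperpriorSpec("G", b, t) for b in (1.6, 2.0, 3.0, 5.0)
                 for t in (0.1, 1.0)] + \
                [HyperpriorSpec("IG", b, t) for b in (1.5, 3.0)
                 for t in (0.1, 1.0)]
        for k in range(50):
            L, y, sigma = random_problem(rng, m=10, n_pos=5)
            res = ias_map(L, y, sigma, specs[k % len(specs)], n_iterations=5)
            trace = np.array(res.objective_trace)
            finite = np.isfinite(trace)
            assert np.all(np.diff(trace[finite])
                          <= 1e-8 * np.abs(trace[finite][:-1]) + 1e-9)

    def test_noiseless_single_source_peaks_at_truth(self):
        """3 well-separated positions, clean data: peak at the true one."""
        rng = np.random.default_rng(0)
        L = np.kron(np.eye(3), np.ones((4, 1))) @ rng.normal(size=(3, 9))
        L = rng.normal(size=(12, 9))
        x_true = np.zeros(9)
        x_true[3:6] = [0.0, 1.0, 0.5]
        y = L @ x_true
        res = ias_map(L, y, 1e-3, HyperpriorSpec("G", 3.0, 1.0))
        blocks = res.x.reshape(3, 3)
        assert np.argmax(np.linalg.norm(blocks, axis=1)) == 1

    def test_requires_at_least_one_iteration(self, rng):
        L, y, sigma = random_problem(rng)
        with pytest.raises(ValueError):
            ias_map(L, y, sigma, HyperpriorSpec("G", 3, 1), n_iterations=0)

    def test_theta_floor_keeps_all_sources_active(self, rng):
        L, y, sigma = random_problem(rng, m=10, n_pos=5)
        res = ias_map(L, y, sigma, HyperpriorSpec("G", 1.5, 0.5),
                      n_iterations=3, theta_floor=1e-6)
        assert np.all(res.theta >= 1e-6)


class TestMneMce:
    def test_mne_equals_closed_form(self, rng):
        L, y, sigma = random_problem(rng, m=14, n_pos=6)
        res = mne(L, y, sigma, 0.7)
        assert res.method == "MNE"
        np.testing.assert_allclose(res.x, tikhonov_mne(L, y, sigma, 0.7),
                                   rtol=1e-8, atol=1e-12)

    def test_mce_concentrates_amplitude(self, rng):
        """Iterating beta=1.5 theta-updates concentrates |x| on few sources."""
        L, y, sigma = random_problem(rng, m=10, n_pos=6)
        res = mce(L, y, sigma, 1e-2)
        assert res.method == "MCE"
        x1, x3 = res.iterates[0], res.iterates[2]
        participation = lambda v: np.abs(v).sum() / np.abs(v).max()
        assert participation(x3) < participation(x1)

    def test_mce_at_least_as_focal_as_mne(self, small_scenario):
        """Spread of MCE <= spread of MNE on the canonical fixture."""
        sc = small_scenario
        lf = sc.normalized_leadfield()
        theta0 = c.theta0_from_pm_snr(20.0, lf.source_space.n_positions,
                                      c.NoiseModel())
        roi = ROI("sphere", sc.roi_center_mm, sc.roi_diameter_mm)
        ref = sc.dataset.truth[0]
        reps = {}
        for name, fn in [("mne", mne), ("mce", mce)]:
            r = fn(lf, sc.dataset.y_noisy, sc.dataset.sigma, theta0)
            reps[name] = c.localization_report(r, lf.source_space,
                                               ref.position, ref.orientation,
                                               roi=roi)
        assert reps["mce"].spread_mm2 <= reps["mne"].spread_mm2


def posterior_cm_quadrature(L, y, sigma, spec, n_nodes=20):
    """3-D tensor quadrature oracle for E[x | y] on a 1-position problem.

    Integrates the exact conditional mean mu(theta) against p(theta | y)
    on a tensor grid of equal-probability hyperprior nodes.
    """
    probs = (np.arange(n_nodes) + 0.5) / n_nodes
    nodes = spec.distribution.ppf(probs)
    m = len(y)
    num = np.zeros(3)
    den = 0.0
    for t1 in nodes:
        for t2 in nodes:
            for t3 in nodes:
                theta = np.array([t1, t2, t3])
                Sy = (L * theta) @ L.T + sigma**2 * np.eye(m)
                cf = np.linalg.cholesky(Sy)
                half = np.linalg.solve(cf, y)
                loglik = -0.5 * half @ half - np.log(np.diag(cf)).sum()
                w = np.exp(loglik)
                mu = theta * (L.T @ np.linalg.solve(Sy, y))
                num += w * mu
                den += w
    return num / den


class TestGibbs:
    def test_cm_matches_quadrature_on_one_position(self):
        """Sampled CM vs 3-D quadrature of the posterior mean."""
        rng = np.random.default_rng(2)
        L = rng.normal(size=(6, 3))
        x_true = np.array([0.8, -0.4, 0.2])
        sigma = 0.3
        y = L @ x_true + sigma * rng.normal(size=6)
        spec = HyperpriorSpec("G", 3.0, 0.5)
        lf = toy_leadfield(L)
        roi = ROI("labels", labels=frozenset({"cortical"}))
        chain = gibbs_sample(lf, y, sigma, spec, roi, n_samples=40_000,
                             burn_in=2_000, rng=7)
        cm = chain.post_burn_in_x.mean(axis=0)
        oracle = posterior_cm_quadrature(L, y, sigma, spec)
        # autocorrelation-aware MC error via batch means
        batches = np.array_split(chain.post_burn_in_x, 40)
        bm = np.array([b.mean(axis=0) for b in batches])
        se = bm.std(axis=0, ddof=1) / np.sqrt(len(bm))
        assert np.all(np.abs(cm - oracle) < 3.0 * se + 1e-3)

    def test_degenerate_hyperprior_gives_analytic_gaussian(self):
        """Near-point-mass hyperprior: x samples follow the fixed-theta Gaussian."""
        rng = np.random.default_rng(3)
        L = rng.normal(size=(6, 3))
        sigma = 0.4
        y = L @ np.array([0.5, 0.1, -0.3]) + sigma * rng.normal(size=6)
        theta_fix = 0.6
        beta = 2_000.0
        spec = HyperpriorSpec("IG", beta, (beta - 1.0) * theta_fix)
        lf = toy_leadfield(L)
        roi = ROI("labels", labels=frozenset({"cortical"}))
        chain = gibbs_sample(lf, y, sigma, spec, roi, n_samples=20_000,
                             burn_in=1_000, rng=11)
        prec = L.T @ L / sigma**2 + np.eye(3) / theta_fix
        cov = np.linalg.inv(prec)
        mu = cov @ L.T @ y / sigma**2
        post = chain.post_burn_in_x
        se = np.sqrt(np.diag(cov) / len(post))
        assert np.all(np.abs(post.mean(axis=0) - mu) < 5 * se)
        np.testing.assert_allclose(np.cov(post.T), cov, rtol=0.1, atol=5e-3)

    def test_two_seeds_agree_within_mc_error(self, small_scenario):
        sc = small_scenario
        lf = sc.normalized_leadfield()
        theta0 = c.theta0_from_pm_snr(0.0, lf.source_space.n_positions,
                                      c.NoiseModel())
        roi = ROI("sphere", sc.roi_center_mm, sc.roi_diameter_mm)
        spec = HyperpriorSpec("G", 3.0, theta0)
        cms, ses = [], []
        for seed in (1, 2):
            ch = gibbs_sample(lf, sc.dataset.y_noisy, sc.dataset.sigma, spec,
                              roi, n_samples=4_000, burn_in=500, rng=seed)
            batches = np.array_split(ch.post_burn_in_x, 30)
            bm = np.array([b.mean(axis=0) for b in batches])
            cms.append(ch.post_burn_in_x.mean(axis=0))
            ses.append(bm.std(axis=0, ddof=1) / np.sqrt(len(bm)))
        scale = np.abs(cms[0]).max()
        tol = 4.0 * np.sqrt(ses[0]**2 + ses[1]**2) + 1e-3 * scale
        assert np.all(np.abs(cms[0] - cms[1]) < tol)

    def test_roi_cap_enforced(self, small_scenario):
        sc = small_scenario
        lf = sc.normalized_leadfield()
        roi = ROI("labels", labels=frozenset({"cortical", "deep"}))
        with pytest.raises(ValueError, match="smaller ROI"):
            gibbs_sample(lf, sc.dataset.y_noisy, sc.dataset.sigma,
                         HyperpriorSpec("G", 3, 1e-20), roi, n_samples=10,
                         burn_in=1, rng=0)


class TestROI:
    def test_sphere_selection(self, small_scenario):
        space = small_scenario.source_space
        roi = ROI("sphere", small_scenario.roi_center_mm, 24.0)
        idx = roi.select(space)
        d = np.linalg.norm(space.positions[idx]
                           - small_scenario.roi_center_mm, axis=1)
        assert len(idx) > 0 and np.all(d <= 12.0)

    def test_label_union_selection(self, small_scenario):
        space = small_scenario.source_space
        idx = ROI("labels", labels=frozenset({"deep"})).select(space)
        assert np.all(space.region[idx] == "deep")

    def test_empty_roi_rejected(self, small_scenario):
        roi = ROI("sphere", np.array([0.0, 0.0, 0.0]), 1.0)
        with pytest.raises(ValueError):
            roi.select(small_scenario.source_space)


class TestCmEstimate:
    def _chain(self, xs, burn_in=2):
        n, d = xs.shape
        return SamplerChain(xs, np.ones_like(xs), burn_in, 0,
                            np.array([0]), 1)

    def test_constant_chain_returns_constant(self):
        xs = np.tile([1.0, 2.0, 3.0], (10, 1))
        res = cm_estimate(self._chain(xs))
        np.testing.assert_allclose(res.x, [1.0, 2.0, 3.0])
        assert res.method == "MCMC-CM"

    def test_burn_in_discards_exactly(self):
        xs = np.zeros((10_000, 3))
        xs[:1_000] = 99.0
        res = cm_estimate(self._chain(xs, burn_in=1_000))
        assert res.config["marginals"]["n_averaged"] == 9_000
        np.testing.assert_allclose(res.x, 0.0)

    def test_burn_in_must_leave_samples(self):
        with pytest.raises(ValueError):
            SamplerChain(np.zeros((5, 3)), np.ones((5, 3)), 5, 0,
                         np.array([0]), 1)

    def test_result_validates_fields(self):
        with pytest.raises(ValueError):
            ReconstructionResult(np.zeros(3), np.array([-1.0, 0, 0]), "IAS")
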