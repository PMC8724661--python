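"""SAEM engine: schedules, samplers, M-steps and the full fit loop."""

import numpy as np
import pytest
from scipy.integrate import quad

from qlmm.ald import ALDParams, CheckRegressionProblem, ald_logpdf, ald_sample, check_loss, weighted_check_regression
from qlmm.data import ModelSpec, build_designs
from qlmm.saem import (
    SAEMConfig,
    SAState,
    ThetaState,
    complete_loglik,
    delta_schedule,
    fit_qrlmm,
    initialize_params,
    mh_sample_subject,
    mstep_beta,
    mstep_psi,
    mstep_sigma,
    mvn_logpdf,
    sa_update,
    _Padded,
)
from qlmm.simulate import CohortConfig, TruthRecord, generate_cohort


class TestDeltaSchedule:
    def test_memory_phase_is_one(self):
        W, c = 100, 0.25
        for k in range(1, 26):
            assert delta_schedule(k, c, W) == 1.0

    def test_decay_phase_formula(self):
        W, c = 100, 0.25
        for k in range(26, 101):
            assert delta_schedule(k, c, W) == pytest.approx(1.0 / (k - 25))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            delta_schedule(0, 0.25, 100)
        with pytest.raises(ValueError):
            delta_schedule(101, 0.25, 100)

    def test_nonincreasing(self):
        vals = [delta_schedule(k, 0.4, 50) for k in range(1, 51)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestSAUpdate:
    def test_delta_one_replaces(self):
        assert np.allclose(sa_update([1.0, 2.0], [5.0, -1.0], 1.0), [5.0, -1.0])

    def test_delta_zero_keeps(self):
        assert np.allclose(sa_update([1.0, 2.0], [5.0, -1.0], 0.0), [1.0, 2.0])

    def test_convex_combination(self):
        out = sa_update(np.eye(2), 3 * np.eye(2), 0.25)
        assert np.allclose(out, 1.5 * np.eye(2))

    def test_constant_stream_is_fixed_point(self):
        x = np.array([2.0, -1.0])
        for k in range(1, 20):
            x = sa_update(x, [2.0, -1.0], 1.0 / k)
        assert np.allclose(x, [2.0, -1.0])

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            sa_update([1.0], [1.0], 1.5)
        with pytest.raises(ValueError):
            sa_update([1.0, 2.0], [1.0], 0.5)


class TestCompleteLoglik:
    def test_composition_against_independent_pieces(self):
        """Equals sum of ALD log-densities plus the Gaussian prior term."""
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(6), rng.normal(size=6)])
        Z = np.column_stack([np.ones(6), np.arange(6.0)])
        y = rng.normal(size=6)
        beta = np.array([0.5, -1.0])
        psi = np.array([[2.0, 0.3], [0.3, 1.0]])
        b = np.array([0.7, -0.2])
        sigma, tau = 1.3, 0.35
        theta = ThetaState(beta=beta, sigma=sigma, psi=psi)
        got = complete_loglik(theta, X, Z, y, b, tau)
        mu = X @ beta + Z @ b
        ald_part = sum(ald_logpdf(yi, ALDParams(mi, sigma, tau)) for yi, mi in zip(y, mu))
        from scipy.stats import multivariate_normal

        prior = multivariate_normal.logpdf(b, mean=np.zeros(2), cov=psi)
        assert got == pytest.approx(ald_part + prior, abs=1e-10)

    def test_mvn_logpdf_matches_scipy(self):
        from scipy.stats import multivariate_normal

        psi = np.array([[1.5, 0.4, 0.0], [0.4, 0.8, 0.1], [0.0, 0.1, 2.0]])
        b = np.array([0.3, -1.2, 0.5])
        assert mvn_logpdf(b, psi) == pytest.approx(
            multivariate_normal.logpdf(b, mean=np.zeros(3), cov=psi), abs=1e-12
        )

    def test_r_zero_prior_is_zero(self):
        assert mvn_logpdf(np.zeros(0), np.empty((0, 0))) == 0.0


class TestMHSampler:
    def test_no_observations_recovers_prior(self):
        """A subject with zero rows has posterior equal to the N(0, Psi) prior."""
        psi = np.array([[1.0, 0.5], [0.5, 2.0]])
        theta = ThetaState(beta=np.zeros(1), sigma=1.0, psi=psi)
        rng = np.random.default_rng(5)
        chunks = [
            mh_sample_subject(
                np.empty((0, 1)), np.empty((0, 2)), np.empty(0), theta, 0.5,
                m=400, burn_in=200, scale=2.0, rng=rng,
            ).draws[0]
            for _ in range(30)
        ]
        draws = np.vstack(chunks)
        emp = draws.T @ draws / len(draws)
        assert np.allclose(draws.mean(axis=0), 0.0, atol=0.12)
        assert np.allclose(emp, psi, atol=0.25)

    def test_large_sigma_posterior_approaches_prior(self):
        """When the data carry no information (sigma huge), the posterior
        second moment is the prior's."""
        rng = np.random.default_rng(7)
        X = np.ones((5, 1))
        Z = np.ones((5, 1))
        y = rng.normal(size=5)
        psi = np.array([[0.8]])
        theta = ThetaState(beta=np.zeros(1), sigma=1e8, psi=psi)
        chunks = [
            mh_sample_subject(X, Z, y, theta, 0.5, m=500, burn_in=200, scale=2.0, rng=rng).draws[0]
            for _ in range(20)
        ]
        draws = np.vstack(chunks)
        assert np.var(draws) == pytest.approx(0.8, abs=0.12)

    def test_deterministic_given_rng_seed(self):
        theta = ThetaState(beta=np.zeros(1), sigma=1.0, psi=np.eye(1))
        X = np.ones((4, 1))
        Z = np.ones((4, 1))
        y = np.array([1.0, -0.5, 0.2, 0.9])
        a = mh_sample_subject(X, Z, y, theta, 0.5, m=50, rng=np.random.default_rng(3)).draws
        b = mh_sample_subject(X, Z, y, theta, 0.5, m=50, rng=np.random.default_rng(3)).draws
        assert np.array_equal(a, b)


class TestMStepSigma:
    def test_worked_example(self):
        # residuals {-1, 0, 2}, tau = 0.5: mean of {0.5, 0, 1} = 0.5
        assert mstep_sigma([-1.0, 0.0, 2.0], 0.5) == pytest.approx(0.5)

    def test_weight_invariance_under_scaling(self):
        r = np.array([-1.0, 0.3, 2.0, -0.7])
        w = np.array([1.0, 2.0, 0.5, 3.0])
        assert mstep_sigma(r, 0.3, w) == pytest.approx(mstep_sigma(r, 0.3, 10 * w))

    def test_floor(self):
        assert mstep_sigma(np.zeros(5), 0.5) == pytest.approx(1e-8)

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError):
            mstep_sigma([1.0], 0.5, [0.0])

    def test_matches_definition(self):
        rng = np.random.default_rng(2)
        r = rng.normal(size=50)
        w = rng.uniform(0.1, 1.0, 50)
        expect = np.sum(w * check_loss(r, 0.7)) / w.sum()
        assert mstep_sigma(r, 0.7, w) == pytest.approx(expect, abs=1e-14)


class TestMStepPsi:
    def test_mean_of_moments(self):
        S2 = np.stack([np.diag([1.0, 2.0]), np.diag([3.0, 4.0])])
        assert np.allclose(mstep_psi(S2), np.diag([2.0, 3.0]))

    def test_spd_projection(self):
        S2 = np.array([[[1.0, 2.0], [2.0, 1.0]]])  # eigenvalues 3, -1
        psi = mstep_psi(S2)
        assert np.all(np.linalg.eigvalsh(psi) >= 1e-8 - 1e-15)

    def test_symmetrized(self):
        S2 = np.array([[[1.0, 0.5], [0.1, 1.0]]])
        psi = mstep_psi(S2)
        assert np.allclose(psi, psi.T)


class TestMStepBeta:
    def test_degenerate_pool_reduces_to_plain_quantile_regression(self):
        """One pool entry with zero random effects: M-step beta must equal
        the LP solution on (X, y) in objective value."""
        rng = np.random.default_rng(4)
        truth = TruthRecord()
        ds, _ = generate_cohort(CohortConfig(n_subjects=12, followup_mean=6, followup_sd=2, followup_max=10), truth, seed=4)
        designs = build_designs(ds, ModelSpec())
        pad = _Padded(designs)
        sa = SAState()
        sa.update_pool(np.zeros((designs.n, 1, designs.r)), 1.0, 0.0)
        beta = mstep_beta(pad, sa, 0.5, beta0=np.zeros(designs.p))
        X, y = designs.stacked()
        direct = weighted_check_regression(
            CheckRegressionProblem(X, y, np.ones(len(y)), 0.5), method="lp"
        )
        obj = lambda b: float(np.sum(check_loss(y - X @ b, 0.5)))
        assert obj(beta) == pytest.approx(obj(direct), rel=1e-8)

    def test_pool_weight_decay_and_prune(self):
        sa = SAState()
        sa.update_pool(np.zeros((2, 3, 1)), 1.0, 1e-4)
        sa.update_pool(np.ones((2, 3, 1)), 0.5, 1e-4)
        assert len(sa.pool) == 2
        assert sa.pool[0].weight == pytest.approx((1 - 0.5) * (1.0 / 3))
        assert sa.pool[1].weight == pytest.approx(0.5 / 3)
        # a delta = 1 update wipes the history
        sa.update_pool(np.ones((2, 3, 1)), 1.0, 1e-4)
        assert len(sa.pool) == 1


class TestInitializeParams:
    def test_deterministic(self):
        ds, _ = generate_cohort(CohortConfig(n_subjects=30), seed=9)
        designs = build_designs(ds, ModelSpec())
        a = initialize_params(designs, 0.5)
        b = initialize_params(designs, 0.5)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.psi, b.psi)
        assert a.sigma == b.sigma

    def test_moment_psi_is_spd_and_tracks_scale(self):
        big = TruthRecord(psi_true=((9.0, 0, 0), (0, 0.04, 0), (0, 0, 0.25)))
        small = TruthRecord(psi_true=((0.09, 0, 0), (0, 0.04, 0), (0, 0, 0.25)))
        cfg = CohortConfig(n_subjects=80)
        psis = {}
        for name, truth in (("big", big), ("small", small)):
            ds, _ = generate_cohort(cfg, truth, seed=12)
            designs = build_designs(ds, ModelSpec())
            psi = initialize_params(designs, 0.5).psi
            assert np.all(np.linalg.eigvalsh(psi) > 0)
            psis[name] = psi
        # the moment init is inflated by projection noise, so only the
        # ordering (not the ratio) is a reliable property
        assert psis["big"][0, 0] > 2 * psis["small"][0, 0]

    def test_identity_fallback(self):
        ds, _ = generate_cohort(CohortConfig(n_subjects=20), seed=9)
        designs = build_designs(ds, ModelSpec())
        theta = initialize_params(designs, 0.5, psi_init="identity")
        assert np.allclose(theta.psi, 0.1 * np.eye(3))


class TestFitQrlmm:
    def test_same_seed_same_result(self, short_cohort, quick_saem_cfg):
        ds, _ = short_cohort
        spec = ModelSpec()
        a = fit_qrlmm(ds, spec, quick_saem_cfg, compute_loglik=False, compute_se=False)
        b = fit_qrlmm(ds, spec, quick_saem_cfg, compute_loglik=False, compute_se=False)
        assert np.array_equal(a.theta.beta, b.theta.beta)
        assert a.theta.sigma == b.theta.sigma
        assert np.array_equal(a.theta.psi, b.theta.psi)

    def test_r_zero_matches_lp(self, fixed_only_data):
        ds, spec = fixed_only_data
        res = fit_qrlmm(ds, spec, SAEMConfig(seed=0))
        designs = build_designs(ds, spec)
        X, y = designs.stacked()
        direct = weighted_check_regression(
            CheckRegressionProblem(X, y, np.ones(len(y)), spec.tau), method="lp"
        )
        obj = lambda b: float(np.sum(check_loss(y - X @ b, spec.tau)))
        assert obj(res.theta.beta) == pytest.approx(obj(direct), rel=1e-10)
        assert res.theta.r == 0
        assert np.isfinite(res.loglik)

    def test_response_shift_moves_intercept_only(self, short_cohort, quick_saem_cfg):
        """Adding a constant to the response shifts the intercept by that
        constant and leaves sigma and Psi essentially unchanged."""
        ds, _ = short_cohort
        spec = ModelSpec()
        base = fit_qrlmm(ds, spec, quick_saem_cfg, compute_loglik=False, compute_se=False)
        shifted_frame = ds.frame.copy()
        shifted_frame["response"] += 100.0
        from qlmm.data import LongitudinalDataset

        shifted = fit_qrlmm(
            LongitudinalDataset(shifted_frame), spec, quick_saem_cfg,
            compute_loglik=False, compute_se=False,
        )
        # the two runs follow different stochastic paths, so allow Monte-Carlo
        # slack around the exact equivariance
        diff = shifted.theta.beta - base.theta.beta
        assert diff[0] == pytest.approx(100.0, abs=1.0)
        assert np.allclose(diff[1:], 0.0, atol=0.5)
        assert shifted.theta.sigma == pytest.approx(base.theta.sigma, rel=0.15)

    def test_traces_and_metadata(self, fitted_short_cohort):
        _, _, res = fitted_short_cohort
        t = res.traces
        assert {"iteration", "delta", "sigma", "objective", "rel_change"} <= set(t.columns)
        assert (t["delta"].iloc[: int(0.4 * 60)] == 1.0).all()
        assert res.subject_effects.shape == (res.n_subjects, 3)
        assert 0.05 < res.acceptance_rate < 0.8
        assert res.theta.sigma > 0
        assert np.all(np.linalg.eigvalsh(res.theta.psi) > 0)

    def test_tau_domain(self, short_cohort):
        with pytest.raises(ValueError):
            fit_qrlmm(short_cohort[0], ModelSpec(tau=0.005), SAEMConfig(W=5, seed=0))

    def test_mcem_limit_pool_has_single_entry(self, short_cohort):
        """With c -> 1 every iteration uses delta = 1, so the pool always
        contains exactly the latest draws (the MCEM special case)."""
        ds, _ = short_cohort
        spec = ModelSpec()
        cfg = SAEMConfig(W=12, c=0.99, m=4, burn_in_per_iteration=5, seed=1)
        res = fit_qrlmm(ds, spec, cfg, compute_loglik=False, compute_se=False)
        sa = res._sa
        assert len(sa.pool) == 1
        assert sa.pool[0].weight == pytest.approx(1.0 / 4)
        assert (res.traces["delta"] == 1.0).all()


class TestQuadratureCrossCheck:
    def test_r1_posterior_mean_matches_quadrature(self):
        """For a random-intercept model the MH posterior mean of b_i matches
        deterministic quadrature of the exact unnormalized posterior."""
        rng = np.random.default_rng(8)
        tau, sigma = 0.5, 1.0
        psi = np.array([[1.5]])
        beta = np.array([2.0])
        X = np.ones((8, 1))
        Z = np.ones((8, 1))
        b_true = 1.2
        y = X @ beta + Z[:, 0] * b_true + ald_sample(8, ALDParams(0, sigma, tau), rng)
        theta = ThetaState(beta=beta, sigma=sigma, psi=psi)

        def unnorm(b):
            resid = (y - X @ beta - Z[:, 0] * b) / sigma
            return np.exp(-np.sum(check_loss(resid, tau)) - 0.5 * b**2 / psi[0, 0])

        norm_const, _ = quad(unnorm, -10, 10)
        mean_num, _ = quad(lambda b: b * unnorm(b), -10, 10)
        exact_mean = mean_num / norm_const

        chunks = [
            mh_sample_subject(X, Z, y, theta, tau, m=800, burn_in=300, scale=1.5, rng=rng).draws[0]
            for _ in range(10)
        ]
        mc_mean = np.vstack(chunks).mean()
        assert mc_mean == pytest.approx(exact_mean, abs=0.08)
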