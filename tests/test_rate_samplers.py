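import numpy as np
import pytest
from scipy import stats

from snapnet.rate_samplers import (
    DEFAULT_JITTER,
    AMHState,
    HMCConfig,
    HMCTarget,
    amh_propose,
    hamiltonian,
    hmc_update,
    mh_accept,
    strang_trajectory,
    update_covariance,
)


def flat_target(omega=1.0, mu=0.0, sigma=1.0):
    """Likelihood-free target: the Gaussian prior alone."""
    return HMCTarget(
        neg_log_lik=lambda x: 0.0,
        grad_neg_log_lik=lambda x: np.zeros_like(x),
        prior_mu=mu,
        prior_sigma=sigma,
        omega=omega,
    )


def gaussian_likelihood_target(mean, sigma_lik, prior_sigma=1e6):
    """Near-flat prior + Gaussian likelihood => Gaussian target."""
    mean = np.asarray(mean, dtype=float)

    def nll(x):
        return 0.5 * float(((x - mean) / sigma_lik) @ ((x - mean) / sigma_lik))

    def grad(x):
        return (x - mean) / sigma_lik**2

    return HMCTarget(nll, grad, prior_mu=0.0, prior_sigma=prior_sigma)


class TestAMHState:
    def test_default_jitter_value(self):
        assert AMHState(dim=2).jitter == 3.7508e-17
        assert DEFAULT_JITTER == 3.7508e-17

    def test_two_identical_samples_zero_covariance(self):
        amh = AMHState(dim=2)
        x = np.array([1.0, -2.0])
        update_covariance(amh, x)
        update_covariance(amh, x.copy())
        np.testing.assert_allclose(amh.history_cov, 0.0, atol=1e-15)

    def test_running_matches_batch(self, rng):
        amh = AMHState(dim=3)
        xs = rng.normal(size=(1000, 3)) * np.array([1.0, 5.0, 0.1])
        for x in xs:
            update_covariance(amh, x)
        np.testing.assert_allclose(
            amh.history_cov, np.cov(xs.T, ddof=1), atol=1e-10
        )
        np.testing.assert_allclose(amh.history_mean, xs.mean(axis=0), atol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            update_covariance(AMHState(dim=2), np.zeros(3))


class TestAMHPropose:
    def test_degenerate_covariance_jitter_only(self, rng):
        amh = AMHState(dim=2, warmup=0)
        x = np.array([1.0, 2.0])
        for _ in range(5):
            update_covariance(amh, x)
        props = np.array([amh_propose(x, amh, rng) for _ in range(100)])
        assert np.abs(props - x).max() < 100 * np.sqrt(DEFAULT_JITTER)

    def test_adapted_variance_recovered(self, rng):
        v = 0.5
        amh = AMHState(dim=2, warmup=10)
        for _ in range(3000):
            update_covariance(amh, rng.normal(0, np.sqrt(v), 2))
        n = 20000
        props = np.array([amh_propose(np.zeros(2), amh, rng) for _ in range(n)])
        scale = 2.38**2 / 2
        target_var = scale * amh.history_cov[0, 0]
        emp = props[:, 0].var(ddof=1)
        se = target_var * np.sqrt(2.0 / n)
        assert abs(emp - target_var) < 3 * se

    def test_warmup_uses_fixed_diagonal(self, rng):
        amh = AMHState(dim=2, warmup=10**6, warmup_scale=0.04)
        n = 20000
        props = np.array([amh_propose(np.zeros(2), amh, rng) for _ in range(n)])
        emp = props.var(ddof=1, axis=0)
        se = 0.04 * np.sqrt(2.0 / n)
        assert np.all(np.abs(emp - 0.04) < 4 * se)

    def test_subset_proposal(self, rng):
        amh = AMHState(dim=3, warmup=0)
        for _ in range(50):
            update_covariance(amh, rng.normal(size=3))
        out = amh_propose(np.zeros(2), amh, rng, subset=[0, 2])
        assert out.shape == (2,)


class TestMHAccept:
    def test_equal_posteriors_always_accept(self, rng):
        assert all(mh_accept(-5.0, -5.0, 0.0, 0.0, rng) for _ in range(100))

    def test_minus_inf_always_rejects(self, rng):
        assert not any(mh_accept(-5.0, -np.inf, 0.0, 0.0, rng) for _ in range(100))

    def test_acceptance_frequency(self, rng):
        n = 10**5
        ratio = np.log(0.3)
        acc = sum(mh_accept(0.0, ratio, 0.0, 0.0, rng) for _ in range(n))
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(acc / n - 0.3) < 3 * se

    def test_asymmetric_correction(self, rng):
        # backward much more likely than forward: log ratio pushed up
        assert mh_accept(0.0, -1.0, -10.0, 0.0, rng)

    def test_nonfinite_current_raises(self, rng):
        with pytest.raises(ValueError):
            mh_accept(-np.inf, 0.0, 0.0, 0.0, rng)

    def test_detailed_balance_three_point_enumeration(self, rng):
        # discrete 3-point target pi; symmetric uniform proposals over the
        # other two points: verify pi_i P(i->j) == pi_j P(j->i) using the
        # exact acceptance probabilities
        pi = np.array([0.6, 0.3, 0.1])
        lp = np.log(pi)
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                a_ij = min(1.0, pi[j] / pi[i])
                a_ji = min(1.0, pi[i] / pi[j])
                flow_ij = pi[i] * 0.5 * a_ij
                flow_ji = pi[j] * 0.5 * a_ji
                assert flow_ij == pytest.approx(flow_ji, abs=1e-14)
                # empirical acceptance of mh_accept matches a_ij
                n = 4000
                acc = sum(
                    mh_accept(lp[i], lp[j], 0.0, 0.0, rng) for _ in range(n)
                )
                assert abs(acc / n - a_ij) < 4 * np.sqrt(a_ij * (1 - a_ij) / n + 1e-12)


class TestHamiltonian:
    def test_zero_momentum(self):
        t = flat_target(sigma=2.0)
        x = np.array([1.0, -1.0])
        H = hamiltonian(x, np.zeros(2), t)
        assert H == pytest.approx(t.prior_energy(x))

    def test_kinetic_arithmetic(self):
        t = flat_target()
        H = hamiltonian(np.zeros(2), np.array([3.0, 4.0]), t)
        assert H - hamiltonian(np.zeros(2), np.zeros(2), t) == pytest.approx(12.5)

    def test_matches_log_density_up_to_constant(self, rng):
        sig = 1.7
        t = flat_target(sigma=sig)
        consts = []
        for _ in range(5):
            x = rng.normal(size=2)
            p = rng.normal(size=2)
            logdens = stats.norm.logpdf(x, 0, sig).sum() + stats.norm.logpdf(
                p, 0, 1
            ).sum()
            consts.append(hamiltonian(x, p, t) + logdens)
        np.testing.assert_allclose(consts, consts[0], atol=1e-10)

    def test_nonfinite_likelihood_energy(self):
        t = HMCTarget(lambda x: np.inf, lambda x: np.zeros_like(x))
        assert hamiltonian(np.zeros(1), np.zeros(1), t) == np.inf


class TestStrangTrajectory:
    def test_flat_likelihood_conserves_energy_exactly(self, rng):
        t = flat_target(sigma=1.4)
        cfg = HMCConfig(step_size=0.3, n_steps=100)
        x0, p0 = rng.normal(size=2), rng.normal(size=2)
        h0 = hamiltonian(x0, p0, t)
        x1, p1, ok = strang_trajectory(x0, p0, cfg, t)
        assert ok
        assert hamiltonian(x1, p1, t) == pytest.approx(h0, abs=1e-12)

    def test_reversibility(self, rng):
        t = gaussian_likelihood_target([1.0, -2.0], 0.7, prior_sigma=3.0)
        cfg = HMCConfig(step_size=0.1, n_steps=25)
        x0, p0 = rng.normal(size=2), rng.normal(size=2)
        x1, p1, ok = strang_trajectory(x0, p0, cfg, t)
        xb, pb, ok2 = strang_trajectory(x1, -p1, cfg, t)
        assert ok and ok2
        np.testing.assert_allclose(xb, x0, atol=1e-8)
        np.testing.assert_allclose(-pb, p0, atol=1e-8)

    def test_energy_error_second_order(self, rng):
        t = gaussian_likelihood_target([0.5], 0.6, prior_sigma=2.0)
        x0, p0 = np.array([2.0]), np.array([0.7])
        h0 = hamiltonian(x0, p0, t)
        errs = []
        for step in (0.2, 0.1, 0.05):
            n_steps = int(round(2.0 / step))
            cfg = HMCConfig(step_size=step, n_steps=n_steps)
            x1, p1, _ = strang_trajectory(x0, p0, cfg, t)
            errs.append(abs(hamiltonian(x1, p1, t) - h0))
        # halving the step should reduce |dH| roughly 4x
        assert errs[0] / errs[1] > 2.5
        assert errs[1] / errs[2] > 2.5

    def test_nonfinite_gradient_aborts(self):
        t = HMCTarget(
            lambda x: 0.0, lambda x: np.full_like(x, np.nan), prior_sigma=1.0
        )
        x1, p1, ok = strang_trajectory(np.zeros(2), np.ones(2), HMCConfig(), t)
        assert not ok


class TestHMCUpdate:
    def test_zero_steps_accepts_identity(self, rng):
        t = flat_target()
        cfg = HMCConfig(n_steps=0)
        x0 = np.array([0.3, -0.4])
        x1, accepted = hmc_update(x0, cfg, t, rng)
        assert accepted
        np.testing.assert_array_equal(x1, x0)

    def test_recovers_2d_gaussian(self, rng):
        # standard 2-D Gaussian via near-flat prior
        t = gaussian_likelihood_target([0.0, 0.0], 1.0, prior_sigma=50.0)
        cfg = HMCConfig(step_size=0.3, n_steps=10)
        x = np.zeros(2)
        n = 20000
        xs = np.empty((n, 2))
        for i in range(n):
            x, _ = hmc_update(x, cfg, t, rng)
            xs[i] = x
        # autocorrelation-adjusted standard errors
        from snapnet.diagnostics import autocorrelation

        for d in range(2):
            tau = autocorrelation(xs[:, d], 200).tau
            assert abs(xs[:, d].mean()) < 3 * np.sqrt(tau / n)
            tau2 = autocorrelation(xs[:, d] ** 2, 200).tau
            assert abs(xs[:, d].var(ddof=1) - 1.0) < 3 * np.sqrt(2 * tau2 / n)

    def test_acceptance_improves_with_smaller_steps(self, rng):
        t = gaussian_likelihood_target([0.0], 0.5, prior_sigma=5.0)
        rates = []
        for step in (0.45, 0.2, 0.05):
            cfg = HMCConfig(step_size=step, n_steps=10)
            x = np.array([1.5])
            acc = 0
            for _ in range(800):
                x, a = hmc_update(x, cfg, t, rng)
                acc += a
            rates.append(acc / 800)
        assert rates[0] <= rates[1] + 0.05 <= rates[2] + 0.1

    def test_prior_only_stationary_distribution(self, rng):
        # both kernels must leave the 2-parameter prior-only target
        # invariant: long-run KS against the prior
        sigma = 1.3
        t = flat_target(sigma=sigma)
        cfg = HMCConfig(step_size=0.25, n_steps=8)
        x = np.zeros(2)
        xs = []
        for i in range(4000):
            x, _ = hmc_update(x, cfg, t, rng)
            xs.append(x.copy())
        xs = np.array(xs)[500::5]
        stat, p = stats.kstest(xs[:, 0] / sigma, "norm")
        assert p > 0.01


class TestKernelAgreement:
    def test_amh_and_hmc_same_stationary_distribution(self, rng):
        # same scalar Gaussian target through both kernels: two-sample KS
        sigma = 0.8
        mean = 1.2
        t = gaussian_likelihood_target([mean], sigma, prior_sigma=100.0)

        def log_target(x):
            return -t.neg_log_lik(x) - t.prior_energy(x)

        # HMC stream
        cfg = HMCConfig(step_size=0.2, n_steps=8)
        x = np.array([0.0])
        hmc_samples = []
        for _ in range(6000):
            x, _ = hmc_update(x, cfg, t, rng)
            hmc_samples.append(x[0])
        # AMH stream
        amh = AMHState(dim=1, warmup=200, warmup_scale=0.25)
        y = np.array([0.0])
        ly = log_target(y)
        amh_samples = []
        for _ in range(20000):
            yp = amh_propose(y, amh, rng)
            lp = log_target(yp)
            if mh_accept(ly, lp, 0.0, 0.0, rng):
                y, ly = yp, lp
            update_covariance(amh, y)
            amh_samples.append(y[0])
        a = np.array(hmc_samples)[1000::10]
        b = np.array(amh_samples)[4000::30]
        stat, p = stats.ks_2samp(a, b)
        assert p > 0.01
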