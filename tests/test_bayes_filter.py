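"""Sequential reliability learning: grid filter, VB backend, adaptation."""

import numpy as np
import pytest
from scipy.special import logsumexp

from avlearn import bayes_filter as bf
from avlearn import sequences as sq
from avlearn.observers import ObserverParams, VisualSummary


def _cloud(v_bar: float, sigma: float, n: int, seed: int = 0) -> VisualSummary:
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, n)
    x = v_bar + sigma * (x - x.mean()) / x.std(ddof=1)
    return VisualSummary.from_dots(x)


class TestPredictStep:
    def test_infinite_kappa_is_identity(self):
        post = bf.initial_prior()
        out = bf.predict_step(post, kappa=1e9)
        assert np.allclose(out.log_weights, post.log_weights)

    def test_uniform_stays_uniform_in_the_interior(self):
        grid = bf.make_grid()
        post = bf.ReliabilityPosterior(grid, np.zeros_like(grid) - np.log(len(grid)))
        out = bf.predict_step(post, kappa=10.0)
        inner = out.weights[35:-35]  # away from the kernel's edge reach
        assert np.allclose(inner, inner[0], rtol=1e-6)

    def test_two_point_posterior_matches_gaussian_mixture(self):
        """Diffusing two point masses must equal the explicit mixture of two
        Gaussians evaluated on the grid."""
        grid = bf.make_grid()
        i, j = 50, 70
        logw = np.full_like(grid, -np.inf)
        logw[i] = np.log(0.3)
        logw[j] = np.log(0.7)
        out = bf.predict_step(bf.ReliabilityPosterior(grid, logw), kappa=4.0)
        sd = np.sqrt(1 / 4.0)
        mix = 0.3 * np.exp(-0.5 * ((grid - grid[i]) / sd) ** 2) + 0.7 * np.exp(
            -0.5 * ((grid - grid[j]) / sd) ** 2
        )
        mix /= mix.sum()
        assert np.max(np.abs(out.weights - mix)) < 1e-6

    def test_invalid_kappa(self):
        with pytest.raises(ValueError):
            bf.predict_step(bf.initial_prior(), kappa=0.0)


class TestFilterUpdate:
    def test_single_trial_mode_matches_instantaneous_reliability(self):
        """With a flat prior, one 20-dot cloud pins the posterior mode near
        the instantaneous estimate (within two grid steps; the small upward
        pull comes from the cloud-mean term, which carries reliability
        information the dispersion-only instantaneous estimate ignores)."""
        from avlearn.observers import instantaneous_reliability

        grid = bf.make_grid()
        flat = bf.ReliabilityPosterior(grid, np.zeros_like(grid) - np.log(len(grid)))
        params = ObserverParams(6.0, 0.7, 12.0, kappa=15.0)
        vs = _cloud(0.0, 8.0, 20, seed=1)
        post, *_ = bf.filter_update(flat, vs, 3.0, params)
        mode = grid[np.argmax(post.log_weights)]
        step = grid[1] - grid[0]
        assert abs(mode - np.log(instantaneous_reliability(vs))) <= 2 * step + 1e-12

    def test_segregating_observer_ignores_audition(self):
        params = ObserverParams(6.0, 0.0, 12.0, kappa=15.0)
        prior = bf.initial_prior()
        vs = _cloud(2.0, 6.0, 10, seed=2)
        post_a, *_ = bf.filter_update(prior, vs, -20.0, params)
        post_b, *_ = bf.filter_update(prior, vs, 20.0, params)
        assert np.allclose(post_a.log_weights, post_b.log_weights)

    @pytest.mark.parametrize("kappa", [2.0, 8.0, 30.0])
    def test_single_trial_adaptation_is_asymmetric(self, kappa):
        """A surprisingly dispersed cloud moves a low-variance belief more
        than a surprisingly tight cloud moves a high-variance belief."""
        params = ObserverParams(6.0, 0.7, 12.0, kappa=kappa)
        grid = bf.make_grid()
        lo, hi = 4.0, 14.0  # cloud STDs

        def concentrated(sigma):
            logw = -0.5 * ((grid - 2 * np.log(1 / sigma)) / 0.05) ** 2
            return bf.ReliabilityPosterior(grid, logw - logsumexp(logw))

        up_prior = bf.predict_step(concentrated(lo), kappa)
        up_post, *_ = bf.filter_update(up_prior, _cloud(0, hi, 5, 3), 0.0, params)
        shift_up = abs(up_post.mean_log_lambda() - up_prior.mean_log_lambda())

        dn_prior = bf.predict_step(concentrated(hi), kappa)
        dn_post, *_ = bf.filter_update(dn_prior, _cloud(0, lo, 5, 3), 0.0, params)
        shift_dn = abs(dn_post.mean_log_lambda() - dn_prior.mean_log_lambda())
        assert shift_up > shift_dn


class TestThreeTrialOracle:
    def test_grid_filter_matches_joint_integration(self):
        """The sequential filter must agree with brute-force integration of
        the full 3-trial joint over (lambda_1, lambda_2, lambda_3), with the
        per-trial evidence computed by 2-D numeric integration over the
        source and cloud-centre variables."""
        params = ObserverParams(6.0, 0.7, 12.0, kappa=6.0)
        n = 5
        clouds = [_cloud(0.0, 5.0, n, 4), _cloud(2.0, 9.0, n, 5), _cloud(-1.0, 12.0, n, 6)]
        a_int = [1.0, -2.0, 3.0]

        grid = bf.make_grid(60)
        lam = np.exp(grid)
        p = params.p_common

        def npdf(x, var):
            return np.exp(-0.5 * x * x / var) / np.sqrt(2 * np.pi * var)

        # per-trial per-node evidence by numeric integration over (S, U)
        s_ax = np.linspace(-90, 90, 601)
        u_ax = np.linspace(-90, 90, 601)
        ev = np.empty((3, len(grid)))
        for t, (vs, a) in enumerate(zip(clouds, a_int)):
            ss = vs.s2 * (n - 1)
            for k, lk in enumerate(lam):
                disp = np.exp(0.5 * (n - 1) * grid[k] - 0.5 * lk * ss) / np.sqrt(n)
                f = (
                    npdf(s_ax[:, None], params.sigma_0**2)
                    * npdf(u_ax[None, :] - s_ax[:, None], 1 / lk)
                    * npdf(vs.v_bar - u_ax[None, :], 1 / (n * lk))
                )
                fa_c1 = npdf(a - s_ax, params.sigma_a**2)
                e1 = disp * np.trapezoid(np.trapezoid(f, u_ax, axis=1) * fa_c1, s_ax)
                pa = np.trapezoid(npdf(a - s_ax, params.sigma_a**2) * npdf(s_ax, params.sigma_0**2), s_ax)
                e2 = disp * pa * np.trapezoid(np.trapezoid(f, u_ax, axis=1), s_ax)
                ev[t, k] = p * e1 + (1 - p) * e2

        # brute-force chain over the lambda grid
        step = grid[1] - grid[0]
        trans = npdf(grid[None, :] - grid[:, None], 1.0 / params.kappa)
        trans /= trans.sum(axis=1, keepdims=True)
        prior0 = bf.initial_prior(grid).weights
        w = prior0 * ev[0]
        w /= w.sum()
        for t in (1, 2):
            w = (w @ trans) * ev[t]
            w /= w.sum()
        oracle_mean = w @ grid

        # sequential filter under test
        ds_trials = []
        rng = np.random.default_rng(0)
        seq = sq.make_sinusoid(duration=30.0)
        onsets = [0.2, 2.0, 4.0]
        trials = [
            sq.Trial(o, 0.0, 5.0, 5.0, _dots(vs), np.zeros(n))
            for o, vs in zip(onsets, clouds)
        ]
        dataset = sq.Dataset(trials, seq, 0)
        estimates, trace = bf.run_learner(dataset, params, np.array(a_int), grid=grid)
        assert abs(trace[-1].mean_log_lambda() - oracle_mean) < 0.02


def _dots(vs: VisualSummary) -> np.ndarray:
    """Reconstruct a dot vector with exactly the summary's moments."""
    n = vs.n
    base = np.linspace(-1, 1, n)
    base = (base - base.mean()) / base.std(ddof=1)
    return vs.v_bar + np.sqrt(vs.s2) * base


class TestRunLearner:
    def test_constant_noise_estimate_converges(self):
        """Long run at fixed cloud STD: the posterior-mean STD settles within
        10% of the truth."""
        params = ObserverParams(6.0, 0.7, 12.0, kappa=15.0)
        seq = sq.NoiseSequence(
            np.arange(0, 400.0, 0.2), np.full(2000, 8.0), "sinusoid", 30.0
        )
        sched = sq.schedule_trials(399.0, seed=8)
        ds = sq.build_dataset(seq, sched, 20, seed=9)
        rng = np.random.default_rng(1)
        a_int = np.array([rng.normal(t.a_loc, 6.0) for t in ds.trials])
        _, trace = bf.run_learner(ds, params, a_int)
        tail = [np.sqrt(p.mean_inv_lambda()) for p in trace[-40:]]
        assert abs(np.mean(tail) - 8.0) / 8.0 < 0.10

    def test_frozen_reliability_limit_matches_instantaneous_readout(self):
        """kappa -> inf with the prior glued at the true reliability: the
        location estimates equal the fixed-reliability causal-inference
        readout."""
        from avlearn.observers import estimate_trial, mean_reliability

        sigma = 8.0
        params = ObserverParams(6.0, 0.7, 12.0, kappa=1e12)
        grid = bf.make_grid()
        ds = sq.make_session("sinusoid", duration=60.0, n_dots=20, seed=13)
        for t in ds.trials:  # force every cloud to the same spread
            t.dots_x = _dots(_cloud(t.v_mean, sigma, 20, seed=int(t.onset * 5)))
        a_int = np.array([t.a_loc for t in ds.trials])

        # delta prior at the true lambda (nearest grid node)
        node = np.argmin(np.abs(grid - np.log(1 / sigma**2)))
        logw = np.full_like(grid, -1e9)
        logw[node] = 0.0
        import avlearn.bayes_filter as bfm

        orig = bfm.initial_prior
        bfm.initial_prior = lambda g=None: bf.ReliabilityPosterior(grid, logw.copy())
        try:
            estimates, _ = bf.run_learner(ds, params, a_int)
        finally:
            bfm.initial_prior = orig

        lam_v = mean_reliability(float(np.exp(grid[node])), 20)
        for est, trial, a in zip(estimates, ds.trials, a_int):
            vs = VisualSummary.from_dots(trial.dots_x)
            _, _, _, s_ref = estimate_trial(a, vs, lam_v, params)
            assert est.s_hat == pytest.approx(float(s_ref), abs=1e-6)

    def test_sinusoidal_noise_induces_hysteresis(self):
        """The estimated STD lags the true STD: ascending-phase estimates sit
        below the matched descending-phase estimates."""
        params = ObserverParams(6.0, 0.7, 12.0, kappa=15.0)
        ds = sq.make_session("sinusoid", duration=600.0, n_dots=5, seed=14,
                             exact_moments=True)
        sig_hat = bf.estimate_std_timecourse(ds, params, "bayesian", seed=3)
        phase = np.array([t.onset % 30.0 for t in ds.trials])
        true = np.array([t.sigma_true for t in ds.trials])
        rising = (phase > 3) & (phase < 12)
        falling = (phase > 18) & (phase < 27)
        # compare estimate-vs-truth residuals between the two phases
        assert np.mean(sig_hat[rising] - true[rising]) < np.mean(
            sig_hat[falling] - true[falling]
        )


class TestGridResolution:
    def test_estimates_stable_under_grid_doubling(self):
        params = ObserverParams(6.0, 0.7, 12.0, kappa=15.0)
        ds = sq.make_session("sinusoid", duration=150.0, n_dots=20, seed=15)
        rng = np.random.default_rng(2)
        a_int = np.array([rng.normal(t.a_loc, 6.0) for t in ds.trials])
        est_a, _ = bf.run_learner(ds, params, a_int, grid=bf.make_grid(120))
        est_b, _ = bf.run_learner(ds, params, a_int, grid=bf.make_grid(240))
        diffs = [abs(a.s_hat - b.s_hat) for a, b in zip(est_a, est_b)]
        assert max(diffs) < 0.05


class TestVariationalBackend:
    def test_convergence_criterion_is_reached(self):
        params = ObserverParams(6.0, 0.7, 12.0, kappa=8.0)
        vs = _cloud(1.0, 7.0, 20, seed=3)
        c1, c2, _ = bf.vb_fit_trial((-4.6, 2.25), vs, 2.0, params, tol=1e-4)
        assert c1.converged and c2.converged
        assert c1.n_iter < 500

    def test_free_energy_decreases_across_sweeps(self):
        params = ObserverParams(6.0, 0.7, 12.0, kappa=8.0)
        vs = _cloud(1.0, 7.0, 20, seed=3)
        trace = []
        state = bf._vb_chain(vs, params, -4.6, 2.25, 2.0, tol=1e-10,
                             max_iter=200, elbo_trace=trace)
        assert len(trace) >= 2
        assert np.all(np.diff(trace) >= -1e-9)  # ELBO non-decreasing

    def test_vb_location_close_to_grid_filter(self):
        """Fuzz across clouds: the VB posterior-mean location under C=1 stays
        within 0.25 deg of the grid filter's."""
        params = ObserverParams(6.0, 0.7, 12.0, kappa=8.0)
        rng = np.random.default_rng(6)
        prior = bf.initial_prior()
        worst = 0.0
        for k in range(50):
            vs = _cloud(rng.uniform(-10, 10), rng.uniform(2.5, 16), 20, seed=k)
            a = rng.uniform(-15, 15)
            _, _, _, s1_grid, _ = bf.filter_update(prior, vs, a, params)
            c1, _, _ = bf.vb_fit_trial(
                (prior.mean_log_lambda(), prior.var_log_lambda()), vs, a, params
            )
            worst = max(worst, abs(c1.q_s[0] - s1_grid))
        assert worst < 0.25

    def test_backends_agree_on_responses(self, session20, params_bayes):
        """Session-level cross-validation: per-trial location estimates and
        causal posteriors from the two inference backends stay close, so
        derived response likelihoods differ by far less than 2%."""
        rng = np.random.default_rng(3)
        a_int = np.array([rng.normal(t.a_loc, 6.0) for t in session20.trials])
        est_g, _ = bf.run_learner(session20, params_bayes, a_int, backend="grid")
        est_v, _ = bf.run_learner(session20, params_bayes, a_int, backend="vb")
        d_s = max(abs(a.s_hat - b.s_hat) for a, b in zip(est_g, est_v))
        d_p = max(abs(a.p_c1 - b.p_c1) for a, b in zip(est_g, est_v))
        assert d_s < 0.25
        assert d_p < 0.02

    def test_nonconvergence_carries_last_state(self):
        params = ObserverParams(6.0, 0.7, 12.0, kappa=8.0)
        vs = _cloud(1.0, 7.0, 20, seed=3)
        with pytest.raises(bf.VBNonConvergence) as exc:
            bf._vb_chain(vs, params, -4.6, 2.25, 2.0, tol=1e-15, max_iter=2)
        assert exc.value.state.n_iter == 2


class TestStdTimecourse:
    def test_instantaneous_readout_is_sample_sd(self, session20, params_inst):
        out = bf.estimate_std_timecourse(session20, params_inst, "instantaneous")
        expect = [t.dots_x.std(ddof=1) for t in session20.trials]
        assert np.allclose(out, expect)

    def test_bayesian_readout_within_grid_support(self, session5, params_bayes):
        out = bf.estimate_std_timecourse(session5, params_bayes, "bayesian", seed=0)
        assert np.all(out > 0.5) and np.all(out < 27.0)

    def test_exponential_gamma_zero_equals_instantaneous(self, session20):
        p = ObserverParams(6.0, 0.7, 12.0, gamma=0.0)
        out_e = bf.estimate_std_timecourse(session20, p, "exponential")
        out_i = bf.estimate_std_timecourse(session20, p, "instantaneous")
        assert np.array_equal(out_e, out_i)
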