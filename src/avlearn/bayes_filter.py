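"""The Bayesian reliability learner.

The learner maintains a posterior over the log visual reliability
``l = log lambda_V`` which drifts between trials as a Gaussian random walk,
``l_t ~ N(l_{t-1}, 1/kappa)``, and is updated on every trial by the evidence
the dot cloud (and, through causal inference, the auditory sample) carries
about the current cloud spread.

Two inference backends are provided:

* a **grid filter** (the reference): the posterior is represented by weights
  on a fixed grid of log-reliability nodes; the per-node evidence of a trial
  is available in closed form because, conditional on lambda, the source and
  cloud-centre variables integrate out analytically;
* a **variational filter**: a factorised Gaussian approximation
  q(S) q(U) q(log lambda) optimised per trial by coordinate ascent on the
  evidence lower bound, with the converged free energy standing in for the
  per-structure log evidence.  The log-reliability belief is propagated as
  Gaussian moments (an assumed-density filter).

Conditional on lambda, a trial with n dots factorises as

    P(A, V_1:n | lambda, C) = g(lambda) * P(A, V_bar | lambda, C)

where g collects the dot-dispersion term lambda^{(n-1)/2} exp(-lambda SS/2)
(identical under both causal structures) and the mean term is bivariate
normal under C=1 and a product of univariate normals under C=2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from avlearn.observers import (
    ObserverEstimate,
    ObserverParams,
    VisualSummary,
    S2_FLOOR,
    fuse_independent,
    mean_reliability,
)
from avlearn.sequences import Dataset

#: Default grid: 120 nodes uniform in log lambda covering sigma in
#: [0.5, 27] deg -- the experimental 2-18 deg range with ample margin.
GRID_SIZE = 120
GRID_SIGMA_RANGE = (0.5, 27.0)

#: Initial prior on log lambda: centred on sigma = 10 deg (the middle of the
#: experimental range) with SD 1.5 log units -- weakly informative.
PRIOR_LOC_SIGMA = 10.0
PRIOR_SD_LOG = 1.5


def make_grid(
    n_nodes: int = GRID_SIZE,
    sigma_range: tuple[float, float] = GRID_SIGMA_RANGE,
) -> np.ndarray:
    """Uniform grid in log lambda; lambda = 1/sigma^2."""
    lo, hi = sigma_range
    return np.linspace(-2.0 * np.log(hi), -2.0 * np.log(lo), n_nodes)


@dataclass
class ReliabilityPosterior:
    """Discretised belief over log visual reliability."""

    log_lambda_nodes: np.ndarray
    log_weights: np.ndarray  # normalised: logsumexp == 0
    trial_idx: int = -1

    def normalised(self) -> "ReliabilityPosterior":
        z = logsumexp(self.log_weights)
        return ReliabilityPosterior(
            self.log_lambda_nodes, self.log_weights - z, self.trial_idx
        )

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.log_weights - logsumexp(self.log_weights))

    def mean_log_lambda(self) -> float:
        return float(self.weights @ self.log_lambda_nodes)

    def var_log_lambda(self) -> float:
        m = self.mean_log_lambda()
        return float(self.weights @ (self.log_lambda_nodes - m) ** 2)

    def mean_lambda(self) -> float:
        return float(self.weights @ np.exp(self.log_lambda_nodes))

    def mean_inv_lambda(self) -> float:
        """Posterior-mean variance E[1/lambda]."""
        return float(self.weights @ np.exp(-self.log_lambda_nodes))


def initial_prior(grid: np.ndarray | None = None) -> ReliabilityPosterior:
    grid = make_grid() if grid is None else grid
    m = -2.0 * np.log(PRIOR_LOC_SIGMA)
    logw = -0.5 * ((grid - m) / PRIOR_SD_LOG) ** 2
    return ReliabilityPosterior(grid, logw - logsumexp(logw), -1)


def predict_step(post: ReliabilityPosterior, kappa: float) -> ReliabilityPosterior:
    """Diffuse the belief by the log random walk: convolve the grid weights
    with a Gaussian kernel of variance 1/kappa."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    grid = post.log_lambda_nodes
    step = grid[1] - grid[0]
    sd = np.sqrt(1.0 / kappa)
    if sd < step / 10.0:  # effectively no diffusion at this resolution
        return ReliabilityPosterior(grid, post.log_weights, post.trial_idx)
    half = int(np.ceil(5.0 * sd / step))
    kernel = np.exp(-0.5 * (np.arange(-half, half + 1) * step / sd) ** 2)
    kernel /= kernel.sum()
    w = np.convolve(post.weights, kernel, mode="same")
    w = np.maximum(w, 1e-300)
    logw = np.log(w)
    return ReliabilityPosterior(grid, logw - logsumexp(logw), post.trial_idx)


def _trial_log_evidences(
    grid: np.ndarray, vs: VisualSummary, a: float, params: ObserverParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node log P(A, V_1:n | lambda, C) for C=1 and C=2.

    Includes the dot-dispersion factor g(lambda), which informs the
    reliability posterior; it is common to both causal structures.
    """
    lam = np.exp(grid)
    n = vs.n
    ss = max(vs.s2, S2_FLOOR) * (n - 1)
    log_g = (
        0.5 * (n - 1) * grid
        - 0.5 * lam * ss
        - 0.5 * (n - 1) * np.log(2 * np.pi)
        - 0.5 * np.log(n)
    )

    var_a = 1.0 / params.lambda_a + 1.0 / params.lambda_s
    tau2 = (1.0 + 1.0 / n) / lam  # variance of V_bar about the source
    var_v = tau2 + 1.0 / params.lambda_s
    cov = 1.0 / params.lambda_s

    det = var_a * var_v - cov**2
    quad = (var_v * a**2 - 2 * cov * a * vs.v_bar + var_a * vs.v_bar**2) / det
    log_n2 = -0.5 * quad - 0.5 * np.log(det) - np.log(2 * np.pi)

    log_na = -0.5 * a**2 / var_a - 0.5 * np.log(2 * np.pi * var_a)
    log_nv = -0.5 * vs.v_bar**2 / var_v - 0.5 * np.log(2 * np.pi * var_v)

    return log_g + log_n2, log_g + log_na + log_nv


def filter_update(
    prior: ReliabilityPosterior,
    vs: VisualSummary,
    a_internal: float,
    params: ObserverParams,
    mixing: str = "average",
) -> tuple[ReliabilityPosterior, float, float, float, float]:
    """One measurement update of the grid filter.

    Returns ``(posterior, log_e1, log_e2, s_hat_c1, s_hat_c2)`` where the
    log evidences are grid marginals of P(A, V | C) and ``s_hat_c1`` is the
    posterior-mean source location under C=1.

    ``mixing``: how the reliability belief combines the two causal
    structures -- "average" mixes the per-structure evidence by ``p_common``
    (matching the model-averaging readout); "common" updates with the C=1
    evidence alone.
    """
    grid = prior.log_lambda_nodes
    log_e1_nodes, log_e2_nodes = _trial_log_evidences(grid, vs, a_internal, params)

    log_joint_1 = prior.log_weights + log_e1_nodes
    log_joint_2 = prior.log_weights + log_e2_nodes
    log_e1 = float(logsumexp(log_joint_1))
    log_e2 = float(logsumexp(log_joint_2))

    p = params.p_common
    if mixing == "average":
        if p == 0:
            logw = log_joint_2
        elif p == 1:
            logw = log_joint_1
        else:
            logw = np.logaddexp(np.log(p) + log_joint_1, np.log1p(-p) + log_joint_2)
    elif mixing == "common":
        logw = log_joint_1
    else:
        raise ValueError(f"unknown mixing rule: {mixing!r}")
    posterior = ReliabilityPosterior(grid, logw - logsumexp(logw), prior.trial_idx + 1)

    # posterior-mean location under C=1: mix the per-lambda fused estimates
    # by the lambda posterior conditional on C=1
    lam_bar = mean_reliability(np.exp(grid), vs.n)
    mu1 = (params.lambda_a * a_internal + lam_bar * vs.v_bar) / (
        params.lambda_a + lam_bar + params.lambda_s
    )
    w_c1 = np.exp(log_joint_1 - log_e1)
    s_hat_c1 = float(w_c1 @ mu1)
    s_hat_c2 = float(fuse_independent(a_internal, params))
    return posterior, log_e1, log_e2, s_hat_c1, s_hat_c2


def _causal_posterior_log(log_e1: float, log_e2: float, p: float) -> float:
    if p == 1.0:
        return 1.0
    if p == 0.0:
        return 0.0
    return float(
        1.0 / (1.0 + np.exp(np.log1p(-p) + log_e2 - np.log(p) - log_e1))
    )


def run_learner(
    dataset: Dataset,
    params: ObserverParams,
    a_internal: np.ndarray,
    backend: str = "grid",
    grid: np.ndarray | None = None,
    mixing: str = "average",
) -> tuple[list[ObserverEstimate], list[ReliabilityPosterior]]:
    """Run the Bayesian learner across a session.

    ``a_internal`` holds one internal auditory sample per trial (in onset
    order).  Returns per-trial estimates and the per-trial (post-update)
    reliability posteriors; with ``backend="vb"`` the returned posteriors
    are Gaussian moment summaries mapped onto the grid representation.
    """
    if params.kappa is None:
        raise ValueError("Bayesian learner needs kappa")
    if len(a_internal) != len(dataset):
        raise ValueError("need one internal auditory sample per trial")
    if backend == "vb":
        return _run_learner_vb(dataset, params, a_internal)
    if backend != "grid":
        raise ValueError(f"unknown backend: {backend!r}")

    post = initial_prior(grid)
    estimates: list[ObserverEstimate] = []
    trace: list[ReliabilityPosterior] = []
    for i, trial in enumerate(dataset.trials):
        if i > 0:
            post = predict_step(post, params.kappa)
        vs = VisualSummary.from_dots(trial.dots_x)
        post, log_e1, log_e2, s1, s2 = filter_update(
            post, vs, float(a_internal[i]), params, mixing
        )
        p_c1 = _causal_posterior_log(log_e1, log_e2, params.p_common)
        s_hat = p_c1 * s1 + (1 - p_c1) * s2
        estimates.append(
            ObserverEstimate(s1, s2, p_c1, s_hat, np.exp(post.mean_log_lambda()))
        )
        trace.append(post)
    return estimates, trace


# ---------------------------------------------------------------------------
# Variational backend
# ---------------------------------------------------------------------------


@dataclass
class VBState:
    """Converged factorised posterior for one trial and causal structure."""

    q_s: tuple[float, float]  # mean (deg), variance (deg^2)
    q_u: tuple[float, float]
    q_loglambda: tuple[float, float]  # mean, variance on the log scale
    free_energy: float  # negative evidence lower bound
    n_iter: int
    converged: bool = True


class VBNonConvergence(RuntimeError):
    """Raised when coordinate ascent exceeds the iteration cap; carries the
    last state."""

    def __init__(self, state: VBState):
        super().__init__(f"VB did not converge within {state.n_iter} iterations")
        self.state = state


def _solve_q_loglambda(
    a_coef: float, b_coef: float, m0: float, v0: float, m: float, v: float
) -> tuple[float, float]:
    """ELBO-optimal Gaussian q(log lambda) for fixed q(S), q(U).

    Maximises a*m - b*E[lambda] - KL-to-prior + entropy.  The stationarity
    conditions
        m = m0 + v0 (a - t),   1/v = 1/v0 + t,   t = b e^{m + v/2}
    reduce to one monotone scalar equation in t = b E[lambda], solved by
    bisection (the exact inner maximiser keeps coordinate ascent monotone).
    """

    def g(log_t: float) -> float:
        t = np.exp(log_t)
        return log_t - np.log(b_coef) - (
            m0 + v0 * (a_coef - t) + 0.5 * v0 / (1.0 + v0 * t)
        )

    lo, hi = -40.0, np.log(b_coef) + m0 + v0 * a_coef + 1.0
    if g(lo) > 0:  # root below bracket: effectively zero evidence weight
        t = np.exp(lo)
    else:
        while g(hi) < 0:
            hi += 5.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if g(mid) < 0:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-13:
                break
        t = np.exp(0.5 * (lo + hi))
    m_new = m0 + v0 * (a_coef - t)
    v_new = 1.0 / (1.0 / v0 + t)
    return float(m_new), float(v_new)


def _vb_chain(
    vs: VisualSummary,
    params: ObserverParams,
    m0: float,
    v0: float,
    a_obs: float | None,
    tol: float = 1e-4,
    max_iter: int = 500,
    elbo_trace: list | None = None,
) -> VBState:
    """Coordinate ascent for one causal chain.

    With ``a_obs`` the chain is the common-source structure (the source S is
    also observed through A); with ``a_obs=None`` it is the visual-only
    chain of the independent-source structure.
    """
    n, v_bar = vs.n, vs.v_bar
    ss = max(vs.s2, S2_FLOOR) * (n - 1)
    lam_a = params.lambda_a if a_obs is not None else 0.0
    lam_s = params.lambda_s

    m, v = m0, v0
    mu_s, var_s = 0.0, 1.0 / lam_s
    mu_u, var_u = v_bar, 1.0

    def elbo() -> float:
        e_lam = np.exp(m + 0.5 * v)
        e_l = m
        val = -0.5 * np.log(2 * np.pi / lam_s) - 0.5 * lam_s * (mu_s**2 + var_s)
        if a_obs is not None:
            val += -0.5 * np.log(2 * np.pi / lam_a) - 0.5 * lam_a * (
                (a_obs - mu_s) ** 2 + var_s
            )
        val += 0.5 * e_l - 0.5 * np.log(2 * np.pi) - 0.5 * e_lam * (
            (mu_u - mu_s) ** 2 + var_u + var_s
        )
        val += (
            0.5 * n * e_l
            - 0.5 * n * np.log(2 * np.pi)
            - 0.5 * e_lam * (ss + n * (v_bar - mu_u) ** 2 + n * var_u)
        )
        val += -0.5 * np.log(2 * np.pi * v0) - ((m - m0) ** 2 + v) / (2 * v0)
        val += 0.5 * np.log(2 * np.pi * np.e * var_s)
        val += 0.5 * np.log(2 * np.pi * np.e * var_u)
        val += 0.5 * np.log(2 * np.pi * np.e * v)
        return float(val)

    prev = np.array([mu_s, var_s, mu_u, var_u, m, v])
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        e_lam = np.exp(m + 0.5 * v)
        prec_s = lam_s + lam_a + e_lam
        mu_s = ((lam_a * a_obs if a_obs is not None else 0.0) + e_lam * mu_u) / prec_s
        var_s = 1.0 / prec_s
        prec_u = e_lam * (1.0 + n)
        mu_u = (mu_s + n * v_bar) / (1.0 + n)
        var_u = 1.0 / prec_u
        b = 0.5 * (
            (mu_u - mu_s) ** 2
            + var_u
            + var_s
            + ss
            + n * (v_bar - mu_u) ** 2
            + n * var_u
        )
        m, v = _solve_q_loglambda(0.5 * (n + 1), b, m0, v0, m, v)
        if elbo_trace is not None:
            elbo_trace.append(elbo())
        cur = np.array([mu_s, var_s, mu_u, var_u, m, v])
        if np.all(np.abs(cur - prev) < tol):
            prev = cur
            break
        prev = cur
    else:
        raise VBNonConvergence(
            VBState((mu_s, var_s), (mu_u, var_u), (m, v), -elbo(), max_iter, False)
        )
    return VBState((mu_s, var_s), (mu_u, var_u), (m, v), -elbo(), n_iter)


def vb_fit_trial(
    prior_moments: tuple[float, float],
    vs: VisualSummary,
    a_internal: float,
    params: ObserverParams,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> tuple[VBState, VBState, float]:
    """Variational fit of one trial under both causal structures.

    Returns ``(state_c1, state_c2_visual, log_evidence_c2_audio)``; the C=2
    audio evidence N(A; 0, sigma_a^2 + sigma_0^2) is exact.
    """
    m0, v0 = prior_moments
    c1 = _vb_chain(vs, params, m0, v0, a_internal, tol, max_iter)
    c2 = _vb_chain(vs, params, m0, v0, None, tol, max_iter)
    var_a = 1.0 / params.lambda_a + 1.0 / params.lambda_s
    log_pa = float(
        -0.5 * a_internal**2 / var_a - 0.5 * np.log(2 * np.pi * var_a)
    )
    return c1, c2, log_pa


def _run_learner_vb(
    dataset: Dataset, params: ObserverParams, a_internal: np.ndarray
) -> tuple[list[ObserverEstimate], list[ReliabilityPosterior]]:
    m = -2.0 * np.log(PRIOR_LOC_SIGMA)
    v = PRIOR_SD_LOG**2
    grid = make_grid()
    estimates: list[ObserverEstimate] = []
    trace: list[ReliabilityPosterior] = []
    for i, trial in enumerate(dataset.trials):
        if i > 0:
            v = v + 1.0 / params.kappa
        vs = VisualSummary.from_dots(trial.dots_x)
        c1, c2, log_pa = vb_fit_trial((m, v), vs, float(a_internal[i]), params)
        log_e1 = -c1.free_energy
        log_e2 = -c2.free_energy + log_pa
        p_c1 = _causal_posterior_log(log_e1, log_e2, params.p_common)
        s1 = c1.q_s[0]
        s2 = float(fuse_independent(float(a_internal[i]), params))
        s_hat = p_c1 * s1 + (1 - p_c1) * s2
        # assumed-density step: moment-match the causal mixture of the two
        # Gaussian log-reliability beliefs
        m1, v1 = c1.q_loglambda
        m2, v2 = c2.q_loglambda
        m = p_c1 * m1 + (1 - p_c1) * m2
        v = p_c1 * (v1 + m1**2) + (1 - p_c1) * (v2 + m2**2) - m**2
        logw = -0.5 * (grid - m) ** 2 / v
        trace.append(ReliabilityPosterior(grid, logw - logsumexp(logw), i))
        estimates.append(ObserverEstimate(s1, s2, p_c1, s_hat, np.exp(m)))
    return estimates, trace


# ---------------------------------------------------------------------------
# Uncertainty-estimate time courses
# ---------------------------------------------------------------------------


def estimate_std_timecourse(
    dataset: Dataset,
    params: ObserverParams,
    model: str,
    seed: int = 0,
    readout: str = "mean_variance",
    backend: str = "grid",
) -> np.ndarray:
    """Per-trial STD of the learner's visual uncertainty estimate (deg).

    The estimate refers to the dot-dispersion STD of the cloud (the
    quantity the noise sequences manipulate).  For the Bayesian learner
    ``readout`` selects the posterior summary: "mean_variance" returns
    sqrt(E[1/lambda]) (the posterior-mean variance, optimal under squared
    variance loss), "mean_lambda" returns 1/sqrt(E[lambda]).
    """
    from avlearn.observers import (
        dispersion_reliability,
        exponential_reliability_update,
    )

    n_trials = len(dataset)
    out = np.empty(n_trials)
    if model == "instantaneous":
        for i, t in enumerate(dataset.trials):
            out[i] = np.sqrt(1.0 / dispersion_reliability(VisualSummary.from_dots(t.dots_x)))
    elif model == "exponential":
        if params.gamma is None:
            raise ValueError("exponential model needs gamma")
        lam = None
        for i, t in enumerate(dataset.trials):
            vs = VisualSummary.from_dots(t.dots_x)
            if lam is None:
                lam = dispersion_reliability(vs)
            else:
                lam = exponential_reliability_update(lam, vs, params.gamma)
            out[i] = np.sqrt(1.0 / lam)
    elif model == "bayesian":
        rng = np.random.default_rng(seed)
        a_internal = np.array(
            [rng.normal(t.a_loc, params.sigma_a) for t in dataset.trials]
        )
        _, trace = run_learner(dataset, params, a_internal, backend=backend)
        if readout == "mean_variance":
            out = np.sqrt([p.mean_inv_lambda() for p in trace])
        elif readout == "mean_lambda":
            out = 1.0 / np.sqrt([p.mean_lambda() for p in trace])
        else:
            raise ValueError(f"unknown readout: {readout!r}")
    else:
        raise ValueError(f"unknown model: {model!r}")
    return out
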