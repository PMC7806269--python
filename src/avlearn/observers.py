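"""Shared observer computations for the three learner models.

All observers are Bayesian causal-inference observers: on each trial they
receive an internal auditory sample ``A_t`` and a visual dot cloud, infer
whether the two signals share a common source (C=1) or not (C=2), and report
the model-averaged auditory location estimate

    S_hat = P(C=1 | A, V) * S_hat_C1 + (1 - P(C=1 | A, V)) * S_hat_C2.

The models differ only in the visual reliability used for the fusion:

* instantaneous -- reliability from the current cloud's sample variance,
* exponential   -- a leaky integration of past sample reliabilities with
  discount factor gamma (learning rate 1 - gamma),
* bayesian      -- a full posterior over log reliability propagated by a log
  random walk (implemented in :mod:`avlearn.bayes_filter`).

Reliabilities are precisions in deg^-2.  ``lambda_v`` arguments denote the
reliability of the cloud's sample mean as an estimate of the source location,
i.e. the dot-dispersion reliability scaled by n/(n+1): under the generative
model the cloud mean scatters about the source with variance
sigma_V^2 (1 + 1/n) because of the hidden cloud-centre variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from avlearn.sequences import Dataset, V_LOCATIONS

#: Sample-variance floor (0.1 deg)^2: dispersion below the dot size is not
#: physically meaningful and would imply unbounded reliability.
S2_FLOOR = 0.01

BUTTONS = np.asarray(V_LOCATIONS)


@dataclass
class ObserverParams:
    """Observer model parameters.

    sigma_a  auditory noise STD (deg); lambda_a = 1/sigma_a^2
    p_common prior probability of a common audiovisual source
    sigma_0  STD of the zero-mean spatial prior (deg); lambda_s = 1/sigma_0^2
    kappa    Bayesian learner: 1/kappa is the variance of the log-reliability
             random walk per trial
    gamma    exponential learner: discount factor in [0, 1]
    """

    sigma_a: float
    p_common: float
    sigma_0: float
    kappa: float | None = None
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_a <= 0 or self.sigma_0 <= 0:
            raise ValueError("sigma_a and sigma_0 must be positive")
        if not 0 <= self.p_common <= 1:
            raise ValueError("p_common must lie in [0, 1]")
        if self.kappa is not None and self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.gamma is not None and not 0 <= self.gamma <= 1:
            raise ValueError("gamma must lie in [0, 1]")

    @property
    def lambda_a(self) -> float:
        return 1.0 / self.sigma_a**2

    @property
    def lambda_s(self) -> float:
        return 1.0 / self.sigma_0**2


@dataclass
class VisualSummary:
    """Sufficient statistics of one dot cloud (horizontal positions)."""

    v_bar: float  # sample mean (deg)
    s2: float  # sample variance, n-1 denominator (deg^2)
    n: int  # dot count

    @classmethod
    def from_dots(cls, dots_x: np.ndarray) -> "VisualSummary":
        dots_x = np.asarray(dots_x, dtype=float)
        if dots_x.size < 2:
            raise ValueError("need at least two dots")
        return cls(float(dots_x.mean()), float(dots_x.var(ddof=1)), dots_x.size)


@dataclass
class ObserverEstimate:
    """Per-trial location estimates and causal posterior."""

    s_hat_c1: float
    s_hat_c2: float
    p_c1: float
    s_hat: float
    lambda_v_hat: float  # reliability of the cloud mean used at fusion


def _floored_s2(s2: float | np.ndarray) -> float | np.ndarray:
    return np.maximum(s2, S2_FLOOR)


def instantaneous_reliability(vs: VisualSummary) -> float:
    """Reliability of the cloud mean from the current cloud alone:
    lambda_hat = 1 / (s2 + s2/n)."""
    return float(vs.n / ((vs.n + 1) * _floored_s2(vs.s2)))


def dispersion_reliability(vs: VisualSummary) -> float:
    """Dot-dispersion reliability 1/s2 (no mean-uncertainty correction)."""
    return float(1.0 / _floored_s2(vs.s2))


def exponential_reliability_update(
    lambda_prev: float, vs: VisualSummary, gamma: float
) -> float:
    """Leaky integration of dispersion reliabilities:
    lambda_t = (1/s2) (1 - gamma) + lambda_{t-1} gamma.

    The state tracks the dot-dispersion reliability; the constant n/(n+1)
    mean-uncertainty factor is applied at fusion time, which keeps gamma=0
    exactly equivalent to the instantaneous learner.
    """
    if lambda_prev <= 0:
        raise ValueError("lambda_prev must be positive")
    return float((1.0 - gamma) / _floored_s2(vs.s2) + gamma * lambda_prev)


def mean_reliability(lambda_disp: float | np.ndarray, n: int) -> float | np.ndarray:
    """Convert dot-dispersion reliability into cloud-mean reliability."""
    return lambda_disp * n / (n + 1)


def fuse_common(a, v_bar, lambda_v, params: ObserverParams):
    """Precision-weighted fusion under a common source (zero-mean prior):
    S_hat_C1 = (lambda_v V_bar + lambda_a A) / (lambda_v + lambda_a + lambda_s)."""
    num = lambda_v * v_bar + params.lambda_a * np.asarray(a)
    return num / (lambda_v + params.lambda_a + params.lambda_s)


def fuse_independent(a, params: ObserverParams):
    """Auditory-only estimate under independent sources:
    S_hat_C2 = lambda_a A / (lambda_a + lambda_s)."""
    return params.lambda_a * np.asarray(a) / (params.lambda_a + params.lambda_s)


def _norm_pdf(x, var):
    return np.exp(-0.5 * x**2 / var) / np.sqrt(2 * np.pi * var)


def component_evidence(a, v_bar, lambda_v, params: ObserverParams):
    """Gaussian marginals P(A, V_bar | C) with the source(s) integrated out.

    Under C=1 both signals scatter about one source S ~ N(0, sigma_0^2), so
    (A, V_bar) is bivariate normal with covariance sigma_0^2 between them;
    under C=2 the evidence factorises into two independent marginals.  The
    dot-dispersion factor of the visual likelihood is identical under both
    structures (and independent of the fused location), so it cancels from
    the causal posterior and is omitted here.
    """
    a = np.asarray(a, dtype=float)
    var_a = 1.0 / params.lambda_a + 1.0 / params.lambda_s
    var_v = 1.0 / lambda_v + 1.0 / params.lambda_s
    cov = 1.0 / params.lambda_s
    # bivariate normal at (a, v_bar), zero mean
    det = var_a * var_v - cov**2
    quad = (var_v * a**2 - 2 * cov * a * v_bar + var_a * v_bar**2) / det
    e1 = np.exp(-0.5 * quad) / (2 * np.pi * np.sqrt(det))
    e2 = _norm_pdf(a, var_a) * _norm_pdf(np.asarray(v_bar), var_v)
    return e1, e2


def causal_posterior(evidence_c1, evidence_c2, p_common: float):
    """P(C=1 | A, V) = e1 p / (e1 p + e2 (1 - p))."""
    num = np.asarray(evidence_c1, dtype=float) * p_common
    den = num + np.asarray(evidence_c2, dtype=float) * (1.0 - p_common)
    if np.any(den == 0):
        raise ValueError("both component evidences are zero")
    return num / den


def model_average(s1, s2, p_c1):
    """Model-averaged location estimate (convex combination)."""
    return np.asarray(p_c1) * s1 + (1.0 - np.asarray(p_c1)) * s2


def respond(s_hat):
    """Button nearest to the location estimate; ties go to the leftward
    (smaller) button."""
    s_hat = np.asarray(s_hat, dtype=float)
    if not np.all(np.isfinite(s_hat)):
        raise ValueError("location estimate must be finite")
    d = np.abs(BUTTONS - s_hat[..., None])
    return BUTTONS[np.argmin(d, axis=-1)]


def estimate_trial(a, vs: VisualSummary, lambda_v, params: ObserverParams):
    """Full causal-inference readout for one trial at a given cloud-mean
    reliability; ``a`` may be an array of internal auditory samples."""
    s1 = fuse_common(a, vs.v_bar, lambda_v, params)
    s2 = fuse_independent(a, params)
    e1, e2 = component_evidence(a, vs.v_bar, lambda_v, params)
    p_c1 = causal_posterior(e1, e2, params.p_common)
    return s1, s2, p_c1, model_average(s1, s2, p_c1)


def simulate_observer(
    dataset: Dataset,
    params: ObserverParams,
    model: str,
    seed: int = 0,
) -> np.ndarray:
    """Simulate button responses for every trial of a session.

    The internal auditory sample A_t ~ N(a_loc, sigma_a^2) is drawn per
    trial; sequential reliability state is threaded across trials in onset
    order.  Returns the responded button positions (deg).
    """
    rng = np.random.default_rng(seed)
    a_internal = np.array(
        [rng.normal(t.a_loc, params.sigma_a) for t in dataset.trials]
    )
    s_hat = np.empty(len(dataset))

    if model == "bayesian":
        from avlearn import bayes_filter

        estimates, _ = bayes_filter.run_learner(dataset, params, a_internal)
        s_hat = np.array([e.s_hat for e in estimates])
    elif model in ("instantaneous", "exponential"):
        lam_state = None
        for i, trial in enumerate(dataset.trials):
            vs = VisualSummary.from_dots(trial.dots_x)
            if model == "instantaneous":
                lam_disp = dispersion_reliability(vs)
            else:
                if params.gamma is None:
                    raise ValueError("exponential model needs gamma")
                if lam_state is None:
                    lam_state = dispersion_reliability(vs)
                else:
                    lam_state = exponential_reliability_update(
                        lam_state, vs, params.gamma
                    )
                lam_disp = lam_state
            lam_v = mean_reliability(lam_disp, vs.n)
            _, _, _, s_hat[i] = estimate_trial(a_internal[i], vs, lam_v, params)
    else:
        raise ValueError(f"unknown model: {model!r}")
    return respond(s_hat)
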