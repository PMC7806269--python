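# Methods

`avlearn` simulates a spatial ventriloquist paradigm with dynamically
changing visual noise and implements three observer models that differ only
in how they estimate the visual reliability they use for audiovisual cue
combination. This note documents the generative assumptions, the inference
machinery, the numerical choices, and what the synthetic experiments do and
do not establish.

## Stimulus model

A session is a 5 Hz stream of visual dot clouds whose horizontal standard
deviation sigma_V(t) follows one of four periodic time courses spanning
2–18 degrees:

* **sinusoid** — period 30 s, starting at the minimum so the first
  half-period is rising noise. The phase convention is a package choice;
  it makes "first half = increasing noise" hold exactly, which the
  half-symmetry analyses rely on.
* **rw1** — a 76-state Markov chain (stay/up/down with probability 1/3
  each) over 60 s, concatenated with its time reversal into a
  mirror-symmetric 120 s segment and tiled. At the boundary states the
  out-of-range move is converted into a stay, which keeps the chain's
  stationary distribution uniform; other boundary conventions (reflection)
  would concentrate mass at the edges.
* **rw2** — as rw1 but 38 states over 15 s, mirrored to 30 s, then smoothed
  with a zero-phase three-tap kernel [0.125, 0.75, 0.125]. A 250 ms moving
  average at 5 Hz covers 1.25 frames; this kernel is the closest symmetric,
  mass-preserving discrete approximation and, applied circularly, preserves
  the segment's mirror symmetry exactly.
* **jump** — the sinusoid with one abrupt +8° and one −8° STD step per
  cycle. Up-steps trigger at STD levels {7.2, 8.6, 9.6}°, down-steps at
  {15.3, 16.7, 17.7}°, crossed factorially (nine cycle types). A jump is
  implemented as a phase teleport along the underlying sinusoid, so the
  trajectory never leaves the 2–18° envelope and each cycle shortens by the
  skipped phase. Phase advances continuously across cycles; with a zero
  jump magnitude the construction reduces exactly to the plain sinusoid.

Audiovisual trials are scheduled with inter-trial gaps drawn uniformly from
{1.4, 1.6, …, 2.8} s. Per trial the cloud mean is resampled from
{−10, −5, 0, 5, 10}° and the sound is placed at ±5° of it (fair coin). Dot
clouds have 20 dots (main experiments) or 5 dots (discriminability
simulations); with `exact_moments` the horizontal sample mean and sample SD
(n−1 denominator) are affinely matched to their nominal values, as in the
5-dot simulations. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; a session is bitwise reproducible.

## Observer models

All three observers perform Bayesian causal inference on each trial: with
prior probability `p_common` the internal auditory sample A_t and the cloud
share one source S ~ N(0, sigma_0²); otherwise they have independent
sources. Writing lambda_A = 1/sigma_A² and lambda-hat_V for the reliability
of the cloud mean, the location estimates are the precision-weighted
fusion (common source) and the prior-shrunk auditory estimate (independent
sources), combined by the causal posterior (model averaging). The observer
presses the button nearest the model-averaged estimate; ties break to the
smaller (leftward) position, a measure-zero convention.

Under the generative model the cloud centre is itself displaced around the
source with the dot-dispersion variance, so the cloud mean carries variance
sigma_V²(1 + 1/n) about the source; reliabilities of the cloud mean
therefore include the factor n/(n+1).

The models differ in the dispersion reliability they carry across trials:

* **instantaneous** — 1/s² from the current cloud's sample variance
  (n−1 denominator), no memory.
* **exponential** — a leaky integrator,
  lambda_t = (1−gamma)/s²_t + gamma·lambda_{t−1}. The n/(n+1) factor is
  applied at fusion time; because it is a constant it commutes with the
  smoothing, and gamma = 0 reproduces the instantaneous model bit for bit.
* **Bayesian** — a full posterior over log lambda propagated by a Gaussian
  random walk, log lambda_t ~ N(log lambda_{t−1}, 1/kappa), and updated by
  each trial's evidence.

Learners update once per audiovisual trial in the response models; the
model equations index time by trial, and the exponential learner's
reported memory (about 5% weight 4–5 s back) is consistent with updates at
the ~2.1 s mean trial asynchrony. The uncertainty benchmark (below) is the
exception: there the learners consume every 5 Hz cloud.

A sample-variance floor of (0.1°)² guards against degenerate clouds;
sub-dot-size dispersion is not physically meaningful.

## Bayesian filter

The reference implementation represents the belief over log lambda on a
fixed grid of 120 nodes, uniform in log lambda over sigma in [0.5°, 27°] —
the stimulus range with margin; doubling the density changes per-trial
location estimates by well under 0.05°. The initial prior is Gaussian in
log lambda, centred on sigma = 10° with SD 1.5 log units (weakly
informative). The transition step convolves the grid weights with a
Gaussian kernel of variance 1/kappa.

Conditional on lambda, a trial's evidence factorises into a dot-dispersion
term lambda^((n−1)/2)·exp(−lambda·SS/2) — identical under both causal
structures but informative about lambda — and a cloud-mean term that is a
bivariate Gaussian in (A, V-bar) under a common source and a product of
Gaussians otherwise. Both closed forms are validated against numerical
integration over the latent source and cloud-centre variables (relative
error < 1e−6 in tests, machine precision in practice). The reliability
belief is updated with the two structures' evidence mixed by `p_common`
(matching the model-averaging readout); pure common-source updating is
available as an argument. All weight arithmetic runs in log space.

A variational backend approximates the per-trial posterior by a factorised
Gaussian q(S)·q(U)·q(log lambda) optimised by coordinate ascent. The
q(log lambda) step is solved exactly (the stationarity conditions collapse
to one monotone scalar equation, solved by bisection), which keeps the
evidence lower bound monotone across sweeps; iteration stops when every
variational parameter changes by less than 1e−4 (cap 500, non-convergence
raises with the last state attached). The converged free energies stand in
for the per-structure log evidence, and the log-reliability belief
propagates as Gaussian moments (assumed-density filtering, with the causal
mixture moment-matched). Across sessions the two backends agree to within
0.25° in location estimates and 0.02 in causal posteriors; the grid filter
is the default and the reference. No claim is made that the variational
scheme equals any particular alternative derivation term by term — the
grid filter is the accuracy anchor.

## Experimenter's likelihood and fitting

The internal sample A_t is unknown to the experimenter, so per trial the
response distribution over the five buttons is a Monte-Carlo histogram of
1000 draws of A_t ~ N(a_loc, sigma_A²) pushed through the observer
(configurable; a stratified variant replaces draws by Gaussian quantiles,
removing Monte-Carlo jitter — used for optimisation). Histograms are
floored at 1/(2·n_samples) and renormalised so observed responses never
have zero probability. For the sequential learners the reliability state is
computed once per parameter vector from the full stimulus stream, with the
Bayesian learner's state pass taking A_t at its expectation; the state is a
pure function of the stimuli, so caching it across the auditory samples is
exact for the exponential learner and an O(1000×) saving for the Bayesian
learner at the cost of ignoring the per-sample perturbation of the
reliability belief (the causal readout still sees every sample).

Posterior sampling is symmetric-proposal Metropolis-Hastings on
transformed parameters (log sigma_A, logit p_common, log sigma_0,
log kappa or logit gamma) with weakly informative priors
(log-normal around 6°, 10°, 8 for the scales; uniform for the
probabilities). Proposal scales adapt during burn-in towards 20–40%
acceptance, including a component-wise reshaping to the posterior spread;
burn-in is discarded and chains thinned (default 4 chains, 4000 kept,
thin 4 — scalable down). Convergence is judged by split-chain potential
scale reduction (R < 1.1). WAIC uses the variance-form penalty on the
pointwise log-likelihoods of every kept sample. Maximum-likelihood fitting
uses Nelder-Mead multi-start on the same transformed scale with the
stratified likelihood.

Fixed-effects comparison sums WAIC across subjects (differences quoted
against the Bayesian learner). The random-effects analysis is hierarchical
Bayesian model selection over model frequencies (Dirichlet prior alpha = 1):
frequencies are estimated variationally, the exceedance probability is
estimated by Monte-Carlo from the exact posterior via a collapsed Gibbs
chain over per-subject model labels (the variational Dirichlet is
overconfident for exceedance by up to ~0.1 at realistic evidence levels),
and protection uses the Bayes omnibus risk computed from the variational
free energy against the equal-frequency null:
PXP = (1−BOR)·EP + BOR/K.

## Behavioural analyses

Trials are sorted into 20 temporally adjacent phase bins per period
(15 for the jump sequence, where bins subdivide the three within-cycle
segments so that both jump times are bin edges in every cycle). Per bin,
responses are regressed on the true auditory and visual locations; the
relative auditory weight is w_A = beta_A/(beta_A + beta_V), left undefined
(and excluded, with the bin flagged) when the design is rank deficient.
An optional lagged-location regressor absorbs the previous trial's visual
location as a control.

Half-symmetry compares bin k with bin n_bins+1−k (the noise extremes sit on
bin boundaries): with 20 bins the minimum-noise pair is dropped, leaving
9 bins per half; with 15 bins the unpaired centre bin is dropped, leaving
7. The repeated measures ANOVA is a general fully-within-subjects
decomposition (any number of factors): each effect is tested on its
orthonormalised contrast scores against the effect-by-subject error term,
with Mauchly's test on the contrast covariance and Greenhouse-Geisser
corrected degrees of freedom when sphericity is rejected at p < 0.05;
partial eta squared accompanies every effect. The implementation is
validated against a brute-force sums-of-squares oracle and an independent
statistics package on two-factor designs.

The lag regression predicts w_A per bin from the bin's mean visual STD and
its difference from the previous bin (cyclically, since the sequences are
periodic), with group-level two-sided one-sample t tests and Cohen's d.

Jump cycles are recombined by pairing first halves (grouped by up-jump
level) with second halves (grouped by down-jump level) into outer/middle/
inner types — low with low, middle with middle, high with high — under the
simplifying assumption that the first half's jump position has negligible
effect on the second half. Level groups are identified by clustering the
realised pre-jump STDs (frame quantisation scatters them slightly within a
group).

## Uncertainty-estimate accuracy benchmark

The benchmark asks how accurately each learner tracks the true cloud
variance when a fresh cloud appears at the 5 Hz re-display rate — the rate
at which the generative model lets reliability drift. Learners therefore
update per frame here: the instantaneous learner reads the current sample
variance s², the exponential learner discounts past variance estimates
(variance-space smoothing; discounting raw reciprocal reliabilities would
be dominated by the heavy upper tail of 1/s² at small n — for 5-dot clouds
E[1/s²] is twice the true reliability — and systematically halves the
variance estimate), and the Bayesian learner filters the dot evidence with
kappa = 15 (the value used for the simulated observers). The error summary
is the median absolute deviation of the variance estimate from the true
variance, in percent of the true variance, averaged across sessions; the
mean-based summary is also reported. The median has a sharp closed-form
anchor for the instantaneous learner (the median absolute relative
deviation of chi²_{n−1}/(n−1): 46.5% at n = 5, 21.8% at n = 20), which
pins the whole pipeline to an independent analytic oracle. Clouds enter
the benchmark unmatched (moment matching would remove the sampling noise
the benchmark measures). The exponential learner's discount grid is 0 to
0.95 in steps of 0.05, with the argmin reported (rounded to one decimal
for headline numbers). Defaults: 20 sessions of 3900 s per condition.

Sufficient statistics of the per-frame clouds (sample mean, sample
variance) are drawn directly from their exact sampling distributions
(Gaussian and scaled chi-square), which is distributionally identical to
rendering the dots and keeps the benchmark fast.

## Validation studies

**Parameter recovery** simulates responses from known parameters and
refits the same model. The headline configuration uses 840 s sessions
(~400 trials) with 5-dot moment-matched clouds, maximum-likelihood fitting
with the stratified likelihood, and at least 10 replicates per model;
relative bias is computed on the replicate-averaged estimates. Full-scale
Metropolis-Hastings recovery is available through the same interface but
takes hours per model.

**Discriminability** simulates observers with the Bayesian learner
(sigma_A = 6°, kappa = 15, p_common = 0.7, sigma_0 = 12°, 5-dot
moment-matched clouds) and fits both the Bayesian and the exponential
learner by likelihood maximisation, reporting the mean fitted
log-likelihood difference. Because the Monte-Carlo response histogram
makes the objective piecewise constant, the exponential competitor (whose
evaluations are cheap) is optimised with a finer likelihood and several
restarts — an under-converged competitor would spuriously inflate the
Bayesian advantage — and both fitted models are re-evaluated with one
common high-resolution stratified likelihood before differencing. At full
scale (12 observers, 3900 s) this is an hours-long computation; the test
suite runs a reduced version (4 observers, half-length sessions) that
checks the direction of the effect — a Bayesian advantage, larger for the
jump than for the sinusoidal sequence — rather than its exact size.

**Adaptation asymmetry**: after up-jumps the Bayesian learner's STD
estimate reaches the midpoint (in log STD) to the new level in fewer trials
than an exponential learner with the discount fitted in the
discriminability regime (gamma ≈ 0.7); after down-jumps the ordering
reverses. The single-trial version of the asymmetry — a dispersed cloud
moves a tight-reliability belief further than a tight cloud moves a
dispersed-reliability belief — holds across kappa from 2 to 30.

## What the synthetic data do and do not show

The generator reproduces the stimulus statistics (noise time courses,
trial scheduling, cloud sampling, the ±5° audiovisual disparity) and ideal
observers responding through five buttons. It does not emulate human motor
noise, lapses, attention drifts, spatially non-uniform auditory precision,
or learning of the periodic structure itself. Passing tests therefore
establish that the pipeline's statistics recover the behaviour of the
model observers they were designed around — e.g. that the half-symmetry
asymmetry appears for memory-bearing learners and vanishes for the
instantaneous one — not that human observers behave this way. Analyses of
human sessions would re-use exactly the same response-side code path
(binning, regression, ANOVA, fitting, comparison).

## Known limitations

* The variational backend is an assumed-density approximation; its
  evidence gaps are small but not zero, and the grid filter remains the
  reference for all quantitative results.
* The Bayesian learner's likelihood caches the reliability trajectory at
  the expected internal auditory sample; the exact per-sample filtering
  variant is prohibitively slow at the 1000-sample setting and is not used
  in the shipped studies.
* The jump-cycle recombination inherits the assumption that first-half
  jump positions do not leak into second-half weights; at the session
  lengths used here some bins hold a few dozen trials, so per-bin weights
  are noisier than in the pooled continuous sequences.
* Metropolis-Hastings settings (priors, proposal adaptation, burn-in) are
  package choices; they are validated on analytic posteriors and by
  recovery, not against any external sampler configuration.
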