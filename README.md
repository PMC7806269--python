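# avlearn

Simulation and model-fitting toolkit for studying how observers estimate
**visual uncertainty over time** in an audiovisual ventriloquist paradigm.

In the paradigm a listener localises brief sounds that are paired with a
spatially discrepant cloud of dots whose spread (the visual noise,
sigma_V) changes dynamically — as a sinusoid, as mirror-symmetric random
walks, or with abrupt ±8° jumps. Because the sound is pulled toward the
cloud in proportion to how *reliable* the observer believes vision to be,
the time course of the auditory weight reveals how the observer's visual
uncertainty estimate is formed. The package implements the three candidate
observer models inside Bayesian causal inference:

* **instantaneous learner** — visual reliability from the current cloud
  only: lambda-hat = 1/(s² + s²/n);
* **Bayesian learner** — a posterior over log reliability propagated by a
  log random walk, log lambda_t ~ N(log lambda_{t−1}, 1/kappa);
* **exponential learner** — leaky integration,
  lambda_t = (1−gamma)/s²_t + gamma·lambda_{t−1}.

All observers integrate or segregate the audiovisual pair by the causal
posterior P(C=1 | A, V) and answer through five response buttons. The
package provides the synthetic experiments (noise sequences, trial
schedules, dot clouds), per-trial simulation, the experimenter's
Monte-Carlo response likelihood, Metropolis-Hastings and maximum-likelihood
fitting, WAIC and protected-exceedance-probability model comparison, the
behavioural analyses (phase binning, relative auditory weights
w_A = beta_A/(beta_A+beta_V), half-symmetry repeated measures ANOVAs,
lagged-noise regression, jump-cycle recombination), and the validation
simulations (uncertainty-estimate accuracy, parameter recovery,
Bayesian-vs-exponential discriminability).

Intended users: computational cognitive scientists and psychophysicists who
want to simulate such experiments, fit the observer models to button
responses (their own or synthetic), or reuse the sequential
reliability-learning machinery.

## Worked example

Simulate a session of the sinusoidal experiment, let a Bayesian-learner
observer respond, and recover the hallmark asymmetry of the auditory
weights between the rising- and falling-noise halves of the period:

```python
import numpy as np
from avlearn import sequences, behavior
from avlearn.observers import ObserverParams, simulate_observer

profiles = []
for subject in range(8):
    ds = sequences.make_session("sinusoid", duration=1560.0, n_dots=5,
                                seed=100 + subject)
    params = ObserverParams(sigma_a=6.0, p_common=0.7, sigma_0=12.0, kappa=15.0)
    responses = simulate_observer(ds, params, "bayesian", seed=200 + subject)
    profiles.append(behavior.weight_profile(ds, responses, subject=subject))

table = behavior.half_symmetry_anova(profiles)
first = np.mean([behavior.half_symmetry_split(p)[0] for p in profiles])
second = np.mean([behavior.half_symmetry_split(p)[1] for p in profiles])
print(f"w_A rising half  = {first:.3f}")
print(f"w_A falling half = {second:.3f}")
print(f"part effect: F(1,7) = {table.f['part']:.2f}, p = {table.p['part']:.4f}")
```

Output:

```
w_A rising half  = 0.694
w_A falling half = 0.837
part effect: F(1,7) = 10.34, p = 0.0148
```

The auditory weight is *smaller* while the noise rises than at the
mirror-symmetric times while it falls — the observer's uncertainty
estimate lags the stimulus because it blends past and current evidence. An
instantaneous-learner observer run through the same pipeline shows no such
asymmetry (F ≈ 1, n.s.), which is exactly the discriminating signature the
behavioural analyses are built around.

The same steps are available from the shell:

```bash
avlearn generate --kind sinusoid --duration 1560 --n-dots 5 --seed 100 --out run/
avlearn simulate --model bayesian \
    --params '{"sigma_a": 6, "p_common": 0.7, "sigma_0": 12, "kappa": 15}' \
    --data run/ --seed 200
avlearn analyze --data run/ --responses run/responses_bayesian.csv
```

## Layout

| module | contents |
| --- | --- |
| `avlearn.sequences` | noise sequences, trial schedules, dot clouds, sessions |
| `avlearn.observers` | causal-inference fusion, reliability estimators, response rule |
| `avlearn.bayes_filter` | grid filter and variational backend for the Bayesian learner |
| `avlearn.fitting` | response likelihood, MH sampling, WAIC, fixed/random-effects comparison |
| `avlearn.behavior` | binning, weight regression, ANOVAs, lag regression, jump recombination |
| `avlearn.validation` | benchmark, parameter recovery, discriminability simulations |
| `avlearn.io_utils`, `avlearn.cli` | CSV/JSON formats, run configs, command-line interface |

Methodological details and design rationale: [docs/methods.md](docs/methods.md).
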