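"""Synthetic audiovisual ventriloquist sessions.

The visual stimulus is a Gaussian cloud of dots whose horizontal standard
deviation (the "visual noise") is re-drawn at 5 Hz and follows one of four
session-long time courses:

* ``sinusoid`` -- a 30 s period sinusoid spanning 2-18 deg,
* ``rw1``      -- a 76-state Markov random walk, 60 s, mirrored to 120 s,
* ``rw2``      -- a 38-state Markov random walk, 15 s, mirrored to 30 s and
  smoothed with a zero-phase 250 ms moving average,
* ``jump``     -- the sinusoid with one abrupt +8 deg and one abrupt -8 deg
  STD step per cycle, at three possible levels each (3 x 3 factorial).

Audiovisual trials are scheduled on top of the 5 Hz frame grid with
inter-trial asynchronies jittered between 1.4 and 2.8 s in 200 ms steps.
On each trial the cloud mean is resampled from {-10, -5, 0, 5, 10} deg and
the sound is placed at +/-5 deg of the cloud mean.

All angles are in degrees of visual angle, all times in seconds, and every
stochastic operation takes an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import periodogram

FRAME_DT = 0.2  # 5 Hz cloud re-display interval
SIGMA_MIN = 2.0
SIGMA_MAX = 18.0
V_LOCATIONS = (-10.0, -5.0, 0.0, 5.0, 10.0)
AV_DISPARITY = 5.0
ITA_GRID = (1.4, 1.6, 1.8, 2.0, 2.2, 2.4, 2.6, 2.8)
DOT_Y_STD = 1.5

UP_LEVELS = (7.2, 8.6, 9.6)
DOWN_LEVELS = (15.3, 16.7, 17.7)
JUMP_SIZE = 8.0


@dataclass
class NoiseSequence:
    """Visual-cloud STD time course on the 0.2 s frame grid."""

    frame_times: np.ndarray  # seconds
    sigma_v: np.ndarray  # degrees
    kind: str  # sinusoid | rw1 | rw2 | jump
    period: float  # seconds
    jump_spec: list[tuple[float, float]] | None = None  # (time, delta) for kind=jump

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.sigma_v = np.asarray(self.sigma_v, dtype=float)
        if self.frame_times.shape != self.sigma_v.shape:
            raise ValueError("frame_times and sigma_v must have equal length")

    @property
    def duration(self) -> float:
        return float(len(self.sigma_v) * FRAME_DT)

    def sigma_at(self, t: float | np.ndarray) -> np.ndarray:
        """STD at time(s) ``t`` (zero-order hold on the frame grid)."""
        idx = np.round(np.asarray(t, dtype=float) / FRAME_DT).astype(int)
        if np.any(idx < 0) or np.any(idx >= len(self.sigma_v)):
            raise ValueError("time outside the sequence")
        return self.sigma_v[idx]


@dataclass
class TrialSchedule:
    onsets: np.ndarray  # seconds, strictly increasing, on the frame grid

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")


@dataclass
class Trial:
    onset: float
    v_mean: float
    a_loc: float
    sigma_true: float
    dots_x: np.ndarray
    dots_y: np.ndarray

    @property
    def n_dots(self) -> int:
        return len(self.dots_x)


@dataclass
class Dataset:
    trials: list[Trial]
    sequence: NoiseSequence
    seed: int
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)


def _frame_grid(duration: float) -> np.ndarray:
    n = int(round(duration / FRAME_DT))
    if not np.isclose(n * FRAME_DT, duration):
        raise ValueError("duration must be a multiple of 0.2 s")
    return np.arange(n) * FRAME_DT


def make_sinusoid(
    period: float = 30.0,
    sigma_min: float = SIGMA_MIN,
    sigma_max: float = SIGMA_MAX,
    duration: float = 3900.0,
) -> NoiseSequence:
    """Sinusoidal STD sequence; each period starts at ``sigma_min`` and
    rises monotonically during the first half."""
    if period <= 0 or duration <= 0:
        raise ValueError("period and duration must be positive")
    if not 0 < sigma_min < sigma_max:
        raise ValueError("need 0 < sigma_min < sigma_max")
    t = _frame_grid(duration)
    mid = 0.5 * (sigma_min + sigma_max)
    amp = 0.5 * (sigma_max - sigma_min)
    sigma = mid - amp * np.cos(2 * np.pi * t / period)
    return NoiseSequence(t, sigma, "sinusoid", period)


def _markov_walk(n_steps: int, n_states: int, rng: np.random.Generator) -> np.ndarray:
    """Integer random walk with stay/down/up probabilities 1/3 each; at the
    boundary states the out-of-range move is converted into a stay."""
    moves = rng.integers(-1, 2, size=n_steps - 1)
    states = np.empty(n_steps, dtype=int)
    states[0] = rng.integers(0, n_states)
    for i, m in enumerate(moves):
        s = states[i] + m
        states[i + 1] = min(max(s, 0), n_states - 1)
    return states


def _states_to_sigma(states: np.ndarray, n_states: int) -> np.ndarray:
    return SIGMA_MIN + (SIGMA_MAX - SIGMA_MIN) * states / (n_states - 1)


def _tile(segment: np.ndarray, duration: float) -> np.ndarray:
    n = int(round(duration / FRAME_DT))
    reps = int(np.ceil(n / len(segment)))
    return np.tile(segment, reps)[:n]


def make_rw1(seed: int, duration: float = 3900.0) -> NoiseSequence:
    """76-state Markov random walk over 60 s, concatenated with its time
    reversal into a mirror-symmetric 120 s segment and tiled."""
    rng = np.random.default_rng(seed)
    half = _states_to_sigma(_markov_walk(300, 76, rng), 76)
    segment = np.concatenate([half, half[::-1]])
    return NoiseSequence(_frame_grid(duration), _tile(segment, duration), "rw1", 120.0)


# 250 ms at 5 Hz is 1.25 frames; closest symmetric zero-phase kernel.
_RW2_KERNEL = np.array([0.125, 0.75, 0.125])


def make_rw2(seed: int, duration: float = 3900.0) -> NoiseSequence:
    """38-state Markov random walk over 15 s, mirrored to 30 s, smoothed with
    a zero-phase ~250 ms moving average (circular, so the mirror symmetry of
    the tiled segment is preserved exactly)."""
    rng = np.random.default_rng(seed)
    half = _states_to_sigma(_markov_walk(75, 38, rng), 38)
    segment = np.concatenate([half, half[::-1]])
    pad = np.concatenate([segment[-1:], segment, segment[:1]])
    smooth = np.convolve(pad, _RW2_KERNEL, mode="valid")
    smooth = np.clip(smooth, SIGMA_MIN, SIGMA_MAX)
    return NoiseSequence(_frame_grid(duration), _tile(smooth, duration), "rw2", 30.0)


def _sine_time_of_sigma(sigma: float, period: float, branch: str) -> float:
    """Time within one cycle at which the base sinusoid attains ``sigma``.

    ``branch`` is "up" (ascending, first half-cycle) or "down" (descending).
    """
    mid, amp = 10.0, 8.0
    phase = np.arccos(np.clip((mid - sigma) / amp, -1.0, 1.0))  # in [0, pi]
    if branch == "up":
        return float(period * phase / (2 * np.pi))
    return float(period - period * phase / (2 * np.pi))


def make_jump_sequence(
    up_levels: tuple[float, ...] = UP_LEVELS,
    down_levels: tuple[float, ...] = DOWN_LEVELS,
    jump: float = JUMP_SIZE,
    period: float = 30.0,
    duration: float = 3900.0,
) -> NoiseSequence:
    """Sinusoid with one up-jump and one down-jump of ``jump`` deg per cycle.

    A jump teleports the phase along the 2-18 deg sinusoid: an up-jump at
    level L skips from the ascending-branch time of L to the ascending-branch
    time of L + jump (and the cycle shortens accordingly); down-jumps are the
    mirror image on the descending branch.  The 3 x 3 combinations of
    (up level x down level) are realised in a fixed factorial order and tiled
    to the session duration.  Jump times and signed magnitudes are recorded
    in ``jump_spec``.
    """
    if len(up_levels) != 3 or len(down_levels) != 3:
        raise ValueError("need exactly three up and three down levels")
    if jump < 0:
        raise ValueError("jump must be non-negative")
    if max(up_levels) + jump > SIGMA_MAX or min(down_levels) - jump < SIGMA_MIN:
        raise ValueError("a jump would leave the [2, 18] deg range")

    mid, amp = 10.0, 8.0
    # per cycle type: phase at which each jump triggers, and the phase skip
    types = []
    for up in up_levels:
        for down in down_levels:
            t_up = _sine_time_of_sigma(up, period, "up")
            skip_up = _sine_time_of_sigma(up + jump, period, "up") - t_up
            t_down = _sine_time_of_sigma(down, period, "down")
            skip_down = _sine_time_of_sigma(down - jump, period, "down") - t_down
            types.append((t_up, skip_up, t_down, skip_down))

    times = _frame_grid(duration)
    n = len(times)
    sigma_v = np.empty(n)
    jump_spec: list[tuple[float, float]] = []
    ct = 0  # index into the 3 x 3 factorial cycle order
    p = 0.0  # continuous phase along the underlying sinusoid
    done_up = done_down = False
    for f in range(n):
        t_up, skip_up, t_down, skip_down = types[ct]
        if not done_up and p >= t_up:
            p += skip_up
            done_up = True
            if jump > 0:
                jump_spec.append((round(f * FRAME_DT, 10), jump))
        if not done_down and p >= t_down:
            p += skip_down
            done_down = True
            if jump > 0:
                jump_spec.append((round(f * FRAME_DT, 10), -jump))
        if p >= period:
            p -= period
            ct = (ct + 1) % len(types)
            done_up = done_down = False
        sigma_v[f] = mid - amp * np.cos(2 * np.pi * p / period)
        p += FRAME_DT
    return NoiseSequence(times, sigma_v, "jump", period, jump_spec)


def schedule_trials(duration: float, seed: int) -> TrialSchedule:
    """Trial onsets with inter-trial gaps drawn uniformly from the 1.4-2.8 s
    grid, accumulated until the session duration is exceeded."""
    if duration <= max(ITA_GRID):
        raise ValueError("duration too short for a single trial")
    rng = np.random.default_rng(seed)
    onsets = []
    t = 0.0
    while True:
        t += rng.choice(ITA_GRID)
        t = round(t / FRAME_DT) * FRAME_DT  # keep on the frame grid exactly
        if t >= duration:
            break
        onsets.append(t)
    return TrialSchedule(np.array(onsets))


def render_cloud(
    mean: float,
    sigma: float,
    n_dots: int = 20,
    exact_moments: bool = False,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the dot cloud for one frame.

    With ``exact_moments`` the horizontal positions are affinely rescaled so
    the sample mean and sample SD (n-1 denominator) equal ``mean`` and
    ``sigma`` exactly (used for 5-dot clouds).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if n_dots < 2 and exact_moments:
        raise ValueError("exact moments need at least 2 dots")
    if n_dots < 1:
        raise ValueError("need at least one dot")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, n_dots)
    if exact_moments:
        x = (x - x.mean()) / x.std(ddof=1)
    x = mean + sigma * x
    y = rng.normal(0.0, DOT_Y_STD, n_dots)
    return x, y


def build_dataset(
    seq: NoiseSequence,
    schedule: TrialSchedule,
    n_dots: int = 20,
    seed: int = 0,
    exact_moments: bool = False,
) -> Dataset:
    """Assemble trials: per onset draw the cloud mean from the five standard
    locations, place the sound at +/-5 deg, and render the onset cloud."""
    rng = np.random.default_rng(seed)
    if schedule.onsets[-1] >= seq.duration:
        raise ValueError("schedule extends past the end of the sequence")
    sigma_true = seq.sigma_at(schedule.onsets)
    trials = []
    for onset, sig in zip(schedule.onsets, sigma_true):
        v_mean = float(rng.choice(V_LOCATIONS))
        a_loc = v_mean + AV_DISPARITY * (1.0 if rng.random() < 0.5 else -1.0)
        dots_x, dots_y = render_cloud(v_mean, sig, n_dots, exact_moments, rng)
        trials.append(Trial(float(onset), v_mean, a_loc, float(sig), dots_x, dots_y))
    meta = {
        "kind": seq.kind,
        "n_dots": n_dots,
        "seed": seed,
        "exact_moments": exact_moments,
    }
    return Dataset(trials, seq, seed, meta)


def make_session(
    kind: str,
    duration: float = 3900.0,
    n_dots: int = 20,
    seed: int = 0,
    exact_moments: bool = False,
) -> Dataset:
    """One-call session builder: sequence + schedule + trials.

    Distinct sub-seeds are derived for the sequence, the schedule and the
    trial assembly so a single integer reproduces the whole session.
    """
    makers = {
        "sinusoid": lambda s: make_sinusoid(duration=duration),
        "rw1": lambda s: make_rw1(s, duration=duration),
        "rw2": lambda s: make_rw2(s, duration=duration),
        "jump": lambda s: make_jump_sequence(duration=duration),
    }
    if kind not in makers:
        raise ValueError(f"unknown sequence kind: {kind!r}")
    ss = np.random.SeedSequence(seed).spawn(3)
    seq = makers[kind](int(ss[0].generate_state(1)[0] % 2**31))
    schedule = schedule_trials(duration, int(ss[1].generate_state(1)[0] % 2**31))
    return build_dataset(
        seq, schedule, n_dots, int(ss[2].generate_state(1)[0] % 2**31), exact_moments
    )


def spectral_peak(seq: NoiseSequence, fmax: float = 0.2) -> float:
    """Frequency (Hz) of the periodogram maximum in (0, ``fmax``]."""
    if np.ptp(seq.sigma_v) == 0:
        raise ValueError("constant sequence has no spectral peak")
    freqs, power = periodogram(seq.sigma_v, fs=1.0 / FRAME_DT)
    mask = (freqs > 0) & (freqs <= fmax)
    if not np.any(power[mask] > 0):
        raise ValueError("no spectral power below fmax")
    return float(freqs[mask][np.argmax(power[mask])])
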