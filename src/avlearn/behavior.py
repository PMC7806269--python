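"""Response-side statistics.

The influence of vision on sound localisation is quantified by sorting
trials into temporally adjacent phase bins of the periodic noise sequence
and regressing, per bin, the localisation responses on the true auditory
and visual locations:

    R = L_A * beta_A + L_V * beta_V + beta_const + e

The relative auditory weight w_A = beta_A / (beta_A + beta_V) indexes the
observer's visual uncertainty estimate (1 = purely auditory, 0 = purely
visual).  Because every sequence is time-symmetric within a period, a
learner that uses past noise shows an asymmetry between the first and the
(time-flipped) second half of the period; this is tested with repeated
measures ANOVAs and with a lagged regression of w_A on the current bin's
visual STD and its change from the previous bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from avlearn.sequences import Dataset

N_BINS_CONTINUOUS = 20
N_BINS_JUMP = 15


@dataclass
class BinnedData:
    bin_idx: np.ndarray  # 1..n_bins per trial
    n_bins: int
    mean_sigma: np.ndarray  # per-bin mean true STD
    edges: np.ndarray  # phase boundaries (s), length n_bins + 1


@dataclass
class WeightProfile:
    subject: str | int
    beta_a: np.ndarray
    beta_v: np.ndarray
    beta_const: np.ndarray
    w_a: np.ndarray  # nan where undefined (rank-deficient bin)
    mean_sigma: np.ndarray
    n_bins: int


@dataclass
class AnovaTable:
    effects: list[str]
    f: dict[str, float]
    df1: dict[str, float]
    df2: dict[str, float]
    p: dict[str, float]
    partial_eta_sq: dict[str, float]
    gg_applied: dict[str, bool] = field(default_factory=dict)


@dataclass
class LagRegressionResult:
    beta_sigma: np.ndarray  # per subject
    beta_delta: np.ndarray
    beta_const: np.ndarray
    t_sigma: float
    t_delta: float
    p_sigma: float
    p_delta: float
    d_sigma: float
    d_delta: float


def assign_bins(
    dataset: Dataset, n_bins: int | None = None, period: float | None = None
) -> BinnedData:
    """Sort trials into temporally adjacent phase bins covering one period.

    Bins are left-closed right-open intervals of stimulus phase.  For jump
    sequences the boundaries are shifted so that every jump time falls on a
    bin edge ("positioned to capture the jumps").
    """
    seq = dataset.sequence
    period = seq.period if period is None else period
    if n_bins is None:
        n_bins = N_BINS_JUMP if seq.kind == "jump" else N_BINS_CONTINUOUS
    onsets = np.array([t.onset for t in dataset.trials])
    sigma = np.array([t.sigma_true for t in dataset.trials])

    if seq.kind == "jump" and seq.jump_spec:
        bin_idx, edges = _jump_bins(seq, onsets, n_bins)
    else:
        phase = onsets % period
        edges = np.linspace(0.0, period, n_bins + 1)
        bin_idx = np.floor(n_bins * phase / period).astype(int) + 1
        bin_idx = np.clip(bin_idx, 1, n_bins)
    mean_sigma = np.array(
        [sigma[bin_idx == b].mean() if np.any(bin_idx == b) else np.nan
         for b in range(1, n_bins + 1)]
    )
    return BinnedData(bin_idx, n_bins, mean_sigma, edges)


def _jump_cycle_table(seq) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per complete cycle: (start, up-jump time, down-jump time, end).

    Cycles start at the sigma minimum; boundaries are reconstructed from the
    recorded jump times by stepping back along the ascending branch.
    """
    sigma = seq.sigma_v
    ups = np.array([t for t, d in seq.jump_spec if d > 0])
    downs = np.array([t for t, d in seq.jump_spec if d < 0])
    starts = []
    for u in ups:
        j = int(round(u / 0.2))
        while j > 0 and sigma[j - 1] <= sigma[j]:
            j -= 1
        starts.append(j * 0.2)
    starts = np.asarray(starts)
    ends = np.append(starts[1:], seq.duration)
    # keep only cycles whose down-jump exists and which end within the session
    keep = np.array(
        [np.any((downs > s) & (downs < e)) for s, e in zip(starts, ends)]
    )
    down_per = np.array(
        [downs[(downs > s) & (downs < e)][0] if k else np.nan
         for s, e, k in zip(starts, ends, keep)]
    )
    return starts[keep], ups[keep], down_per[keep], ends[keep]


def _jump_segment_counts(starts, ups, downs, ends, n_bins: int) -> np.ndarray:
    """Allocate bins to the three within-cycle segments (before the up-jump,
    between the jumps, after the down-jump) proportionally to their average
    durations; every segment gets at least one bin."""
    spans = np.array(
        [np.mean(ups - starts), np.mean(downs - ups), np.mean(ends - downs)]
    )
    counts = np.maximum(np.floor(n_bins * spans / spans.sum()).astype(int), 1)
    while counts.sum() < n_bins:
        counts[np.argmax(spans / counts)] += 1
    while counts.sum() > n_bins:
        counts[np.argmax(counts)] -= 1
    return counts


def _jump_bins(seq, onsets: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Bin assignment for jump sequences: bins subdivide the three segments
    of each cycle, so both jump times are bin edges in every cycle."""
    starts, ups, downs, ends = _jump_cycle_table(seq)
    counts = _jump_segment_counts(starts, ups, downs, ends, n_bins)
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    bin_idx = np.zeros(len(onsets), dtype=int)
    for i, onset in enumerate(onsets):
        k = int(np.searchsorted(starts, onset, side="right")) - 1
        if k < 0 or onset >= ends[k]:
            bin_idx[i] = 0  # outside any complete cycle
            continue
        bounds = (starts[k], ups[k], downs[k], ends[k])
        for seg in range(3):
            if onset < bounds[seg + 1]:
                frac = (onset - bounds[seg]) / (bounds[seg + 1] - bounds[seg])
                b = offsets[seg] + int(frac * counts[seg])
                bin_idx[i] = min(b, offsets[seg] + counts[seg] - 1) + 1
                break
    # normalised-phase edges of the first cycle (descriptive)
    edges = np.concatenate(
        [np.linspace(0, 1, counts[0] + 1)[:-1] * (ups[0] - starts[0]) / (ends[0] - starts[0]),
         (ups[0] - starts[0] + np.linspace(0, 1, counts[1] + 1)[:-1] * (downs[0] - ups[0]))
         / (ends[0] - starts[0]),
         (downs[0] - starts[0] + np.linspace(0, 1, counts[2] + 1)[:-1] * (ends[0] - downs[0]))
         / (ends[0] - starts[0]),
         [1.0]]
    )
    return bin_idx, edges


def bin_regression(
    responses: np.ndarray,
    a_loc: np.ndarray,
    v_mean: np.ndarray,
    lagged_v: np.ndarray | None = None,
) -> tuple[float, float, float, float]:
    """OLS of responses on the true auditory and visual locations for the
    trials of one bin; returns (beta_A, beta_V, beta_const, w_A).

    ``lagged_v`` optionally adds the previous trial's visual location as a
    nuisance regressor (control analysis).  Rank-deficient designs yield
    nan weights.
    """
    responses = np.asarray(responses, dtype=float)
    if len(responses) < 3:
        return np.nan, np.nan, np.nan, np.nan
    cols = [np.asarray(a_loc, dtype=float), np.asarray(v_mean, dtype=float)]
    if lagged_v is not None:
        cols.append(np.asarray(lagged_v, dtype=float))
    x = np.column_stack(cols + [np.ones_like(responses)])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        return np.nan, np.nan, np.nan, np.nan
    beta, *_ = np.linalg.lstsq(x, responses, rcond=None)
    beta_a, beta_v, beta_const = float(beta[0]), float(beta[1]), float(beta[-1])
    denom = beta_a + beta_v
    w_a = beta_a / denom if denom != 0 else np.nan
    return beta_a, beta_v, beta_const, w_a


def weight_profile(
    dataset: Dataset,
    responses: np.ndarray,
    binned: BinnedData | None = None,
    subject: str | int = 0,
    lagged_location: bool = False,
) -> WeightProfile:
    """Per-bin auditory/visual weights and relative auditory weight."""
    binned = assign_bins(dataset) if binned is None else binned
    a_loc = np.array([t.a_loc for t in dataset.trials])
    v_mean = np.array([t.v_mean for t in dataset.trials])
    lagged = np.concatenate([[v_mean[0]], v_mean[:-1]]) if lagged_location else None
    nb = binned.n_bins
    beta_a = np.empty(nb)
    beta_v = np.empty(nb)
    beta_c = np.empty(nb)
    w_a = np.empty(nb)
    for b in range(1, nb + 1):
        m = binned.bin_idx == b
        lv = lagged[m] if lagged is not None else None
        beta_a[b - 1], beta_v[b - 1], beta_c[b - 1], w_a[b - 1] = bin_regression(
            responses[m], a_loc[m], v_mean[m], lv
        )
    return WeightProfile(subject, beta_a, beta_v, beta_c, w_a, binned.mean_sigma, nb)


def half_symmetry_split(profile: WeightProfile) -> tuple[np.ndarray, np.ndarray]:
    """First half vs time-flipped second half of the w_A profile.

    Bin k mirrors bin n_bins + 1 - k (the sequence is time-symmetric about
    the noise extremes, which sit on bin boundaries).  With 20 bins the
    minimum-noise pair (bins 1 and 20) is dropped, leaving 9 bins per half;
    with 15 bins the unpaired centre bin 8 is dropped, leaving 7 per half.
    """
    w = profile.w_a
    if profile.n_bins == 20:
        first = w[1:10]  # bins 2..10
        second = w[10:19][::-1]  # bins 19..11
    elif profile.n_bins == 15:
        first = w[0:7]  # bins 1..7
        second = w[8:15][::-1]  # bins 15..9
    else:
        half = profile.n_bins // 2
        first = w[1:half]
        second = w[profile.n_bins - half:profile.n_bins - 1][::-1]
    return first, second


def rm_anova(data: np.ndarray, factors: list[str]) -> AnovaTable:
    """Fully within-subjects repeated measures ANOVA.

    ``data``: array of shape (subjects, l1, l2, ...) with one trailing axis
    per within factor, named by ``factors``.  F ratios use the
    effect-by-subject interaction as the error term.  When a Mauchly test
    on an effect's orthonormalised contrast scores rejects sphericity
    (p < 0.05), Greenhouse-Geisser corrected degrees of freedom and p value
    are reported for that effect.
    """
    data = np.asarray(data, dtype=float)
    if np.any(np.isnan(data)):
        raise ValueError("missing cells in the ANOVA design")
    n_sub = data.shape[0]
    shape = data.shape[1:]
    if len(shape) != len(factors):
        raise ValueError("factor names must match the data axes")

    table = AnovaTable([], {}, {}, {}, {}, {}, {})
    from itertools import combinations

    axes = list(range(1, len(shape) + 1))
    rms = float(np.sqrt(np.mean(data**2)))
    for k in range(1, len(axes) + 1):
        for combo in combinations(range(len(axes)), k):
            if any(shape[i] < 2 for i in combo):
                continue  # single-level factors carry no effect
            name = " x ".join(factors[i] for i in combo)
            scores = _effect_scores(data, combo)
            # snap roundoff dust to exact zero (identical-cell designs)
            scores[np.abs(scores) < 1e-10 * max(rms, 1e-300)] = 0.0
            f, df1, df2, p, peta, gg = _effect_f(scores, n_sub)
            table.effects.append(name)
            table.f[name] = f
            table.df1[name] = df1
            table.df2[name] = df2
            table.p[name] = p
            table.partial_eta_sq[name] = peta
            table.gg_applied[name] = gg
    return table


def _effect_scores(data: np.ndarray, combo: tuple[int, ...]) -> np.ndarray:
    """Subject-wise contrast scores for one effect: average over the other
    factors, then apply the (tensor product of) orthonormal contrast bases
    of the involved factors.  Shape (subjects, prod(levels-1))."""
    n_factors = data.ndim - 1
    other = [ax + 1 for ax in range(n_factors) if ax not in combo]
    marg = data.mean(axis=tuple(other)) if other else data
    # marg: (subjects, levels of combo factors...)
    out = marg
    for pos, ax in enumerate(combo):
        levels = out.shape[1 + pos]
        c = _orthonormal_contrasts(levels)
        out = np.moveaxis(np.tensordot(out, c, axes=([1 + pos], [0])), -1, 1 + pos)
    return out.reshape(out.shape[0], -1)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k, k-1) orthonormal basis orthogonal to the constant vector."""
    full, _ = np.linalg.qr(np.column_stack([np.ones(k), np.eye(k)[:, :-1]]))
    return full[:, 1:]


def _effect_f(scores: np.ndarray, n_sub: int):
    """F test that the mean contrast score vector is zero (univariate
    repeated-measures approach with sphericity handling)."""
    q = scores.shape[1]
    mean = scores.mean(axis=0)
    ss_effect = n_sub * float(mean @ mean)
    resid = scores - mean
    ss_error = float(np.sum(resid**2))
    df1 = float(q)
    df2 = float(q * (n_sub - 1))
    ms_e = ss_error / df2
    f = ss_effect / df1 / ms_e if ms_e > 0 else 0.0
    peta = ss_effect / (ss_effect + ss_error) if (ss_effect + ss_error) > 0 else 0.0

    gg = False
    eps = 1.0
    if q > 1 and n_sub > q:
        cov = np.cov(scores, rowvar=False, ddof=1)
        eig = np.linalg.eigvalsh(cov)
        eig = np.maximum(eig, 0.0)
        eps = float(eig.sum() ** 2 / (q * np.sum(eig**2))) if np.sum(eig**2) > 0 else 1.0
        p_mauchly = _mauchly_p(cov, n_sub)
        gg = p_mauchly < 0.05
    if gg:
        df1, df2 = df1 * eps, df2 * eps
    p = float(stats.f.sf(f, df1, df2)) if f > 0 else 1.0
    return float(f), df1, df2, p, float(peta), gg


def _mauchly_p(cov: np.ndarray, n_sub: int) -> float:
    q = cov.shape[0]
    eig = np.linalg.eigvalsh(cov)
    eig = np.maximum(eig, 1e-300)
    w = float(np.prod(eig / eig.mean()))
    if w <= 0:
        return 0.0
    df = q * (q + 1) / 2 - 1
    dd = 1 - (2 * q**2 + q + 2) / (6 * q * (n_sub - 1))
    chi2 = -(n_sub - 1) * dd * np.log(w)
    return float(stats.chi2.sf(chi2, df))


def half_symmetry_anova(
    profiles: list[WeightProfile], jump_groups: list[list[WeightProfile]] | None = None
) -> AnovaTable:
    """Part (1st vs flipped 2nd half) x bin repeated measures ANOVA on w_A,
    optionally with a jump-position factor (inner/middle/outer)."""
    if jump_groups is None:
        rows = []
        for p in profiles:
            first, second = half_symmetry_split(p)
            rows.append(np.stack([first, second]))
        data = np.asarray(rows)  # (subjects, 2, bins)
        return rm_anova(data, ["part", "bin"])
    rows = []
    for subj_profiles in jump_groups:
        per_jump = []
        for p in subj_profiles:  # one profile per jump type
            first, second = half_symmetry_split(p)
            per_jump.append(np.stack([first, second]))
        rows.append(np.stack(per_jump))  # (jump, 2, bins)
    data = np.asarray(rows)
    return rm_anova(data, ["jump", "part", "bin"])


def lag_regression(profiles: list[WeightProfile]) -> LagRegressionResult:
    """Regress each subject's w_A per bin on the bin's mean visual STD and
    the STD difference to the previous bin (cyclic), then test the group
    coefficients against zero (two-sided one-sample t, Cohen's d)."""
    if len(profiles) < 2:
        raise ValueError("group statistics need >= 2 subjects")
    b_sig, b_del, b_con = [], [], []
    for p in profiles:
        sigma = p.mean_sigma
        if np.ptp(sigma[~np.isnan(sigma)]) == 0:
            raise ValueError("constant visual STD across bins")
        delta = sigma - np.roll(sigma, 1)
        x = np.column_stack([sigma, delta, np.ones_like(sigma)])
        ok = ~np.isnan(p.w_a) & ~np.isnan(sigma) & ~np.isnan(delta)
        beta, *_ = np.linalg.lstsq(x[ok], p.w_a[ok], rcond=None)
        b_sig.append(beta[0])
        b_del.append(beta[1])
        b_con.append(beta[2])
    b_sig, b_del, b_con = map(np.asarray, (b_sig, b_del, b_con))
    t_s, p_s = stats.ttest_1samp(b_sig, 0.0)
    t_d, p_d = stats.ttest_1samp(b_del, 0.0)
    d_s = float(b_sig.mean() / b_sig.std(ddof=1))
    d_d = float(b_del.mean() / b_del.std(ddof=1))
    return LagRegressionResult(
        b_sig, b_del, b_con, float(t_s), float(t_d), float(p_s), float(p_d), d_s, d_d
    )


def _cluster_ranks(values: np.ndarray, k: int) -> np.ndarray:
    """Rank each value into one of ``k`` level groups, splitting the sorted
    values at the k-1 largest gaps (jump levels are quantised to the frame
    grid, so values within a group scatter slightly)."""
    order = np.sort(np.unique(values))
    if len(order) <= k:
        cuts = order[:-1] + np.diff(order) / 2 if len(order) > 1 else np.array([])
    else:
        gaps = np.diff(order)
        cut_idx = np.sort(np.argsort(gaps)[-(k - 1):])
        cuts = order[cut_idx] + gaps[cut_idx] / 2
    return np.searchsorted(cuts, values)


def recombine_jump_cycles(
    dataset: Dataset, responses: np.ndarray
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Recombine the 3 x 3 jump cycles into outer/middle/inner types.

    First half-cycles are grouped by their up-jump level and second halves
    by their down-jump level, pairing low with low ("outer"), middle with
    middle and high with high ("inner") visual noise.  Returns, per type,
    the trial indices and responses of the combined halves.
    """
    seq = dataset.sequence
    if not seq.jump_spec:
        raise ValueError("dataset has no jump metadata")
    responses = np.asarray(responses)
    onsets = np.array([t.onset for t in dataset.trials])
    sigma = seq.sigma_v
    starts, ups, downs, ends = _jump_cycle_table(seq)
    up_levels = sigma[np.round(ups / 0.2).astype(int) - 1]
    down_levels = sigma[np.round(downs / 0.2).astype(int) - 1]
    up_rank = _cluster_ranks(up_levels, 3)
    down_rank = _cluster_ranks(down_levels, 3)

    types = ("outer", "middle", "inner")
    out: dict[str, list[int]] = {t: [] for t in types}
    for i, onset in enumerate(onsets):
        k = int(np.searchsorted(starts, onset, side="right")) - 1
        if k < 0 or onset >= ends[k]:
            continue  # outside any complete cycle
        if onset < downs[k]:  # first half: cycle start up to the down-jump
            rank = up_rank[k]
        else:
            rank = down_rank[k]
        out[types[rank]].append(i)
    return {
        t: (np.asarray(idx, dtype=int), responses[np.asarray(idx, dtype=int)])
        for t, idx in out.items()
    }
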