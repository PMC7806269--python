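"""Phase binning, weight regression, half-symmetry ANOVA, lag regression."""

import numpy as np
import pytest
from scipy import stats

from avlearn import behavior as bh
from avlearn import sequences as sq
from avlearn.behavior import WeightProfile


class TestAssignBins:
    def test_phase_zero_goes_to_bin_one(self, session20):
        binned = bh.assign_bins(session20)
        onsets = np.array([t.onset for t in session20.trials])
        first_bin = onsets % 30.0 < 30.0 / 20
        assert np.all(binned.bin_idx[first_bin] == 1)

    def test_uniform_onsets_spread_over_bins(self):
        ds = sq.make_session("sinusoid", duration=3900.0, n_dots=5, seed=3)
        binned = bh.assign_bins(ds)
        counts = np.bincount(binned.bin_idx, minlength=21)[1:]
        expect = len(ds) / 20
        assert np.all(np.abs(counts - expect) < 5 * np.sqrt(expect))

    def test_every_jump_time_is_a_bin_edge(self):
        ds = sq.make_session("jump", duration=1200.0, n_dots=5, seed=4)
        seq = ds.sequence
        starts, ups, downs, ends = bh._jump_cycle_table(seq)
        counts = bh._jump_segment_counts(starts, ups, downs, ends, 15)
        # a trial just before a jump and one just after must land in
        # different, predetermined bins in every cycle
        onsets = np.concatenate([ups - 0.05, ups + 0.05, downs - 0.05, downs + 0.05])
        bins, _ = bh._jump_bins(seq, onsets, 15)
        n = len(ups)
        assert np.all(bins[:n] == counts[0])  # last bin before the up-jump
        assert np.all(bins[n:2 * n] == counts[0] + 1)  # first bin after
        assert np.all(bins[2 * n:3 * n] == counts[0] + counts[1])
        assert np.all(bins[3 * n:] == counts[0] + counts[1] + 1)

    def test_default_bin_counts_by_kind(self, session20):
        assert bh.assign_bins(session20).n_bins == 20
        ds = sq.make_session("jump", duration=600.0, n_dots=5, seed=5)
        assert bh.assign_bins(ds).n_bins == 15


class TestBinRegression:
    def test_pure_auditory_responses(self, rng):
        a = rng.choice([-10, -5, 0, 5, 10], 60).astype(float)
        v = a + rng.choice([-5, 5], 60)
        beta_a, beta_v, _, w = bh.bin_regression(a, a, v)
        assert beta_a == pytest.approx(1.0, abs=1e-9)
        assert beta_v == pytest.approx(0.0, abs=1e-9)
        assert w == pytest.approx(1.0)

    def test_pure_visual_responses(self, rng):
        a = rng.choice([-10, -5, 0, 5, 10], 60).astype(float)
        v = a + rng.choice([-5, 5], 60)
        *_, w = bh.bin_regression(v, a, v)
        assert w == pytest.approx(0.0, abs=1e-9)

    def test_mixture_recovers_weights_and_matches_normal_equations(self, rng):
        a = rng.choice([-10, -5, 0, 5, 10], 400).astype(float)
        v = a + rng.choice([-5, 5], 400)
        resp = 0.3 * a + 0.7 * v + rng.normal(0, 0.5, 400)
        beta_a, beta_v, beta_c, w = bh.bin_regression(resp, a, v)
        x = np.column_stack([a, v, np.ones_like(a)])
        oracle = np.linalg.solve(x.T @ x, x.T @ resp)
        assert beta_a == pytest.approx(oracle[0], abs=1e-10)
        assert beta_v == pytest.approx(oracle[1], abs=1e-10)
        assert w == pytest.approx(0.3, abs=0.05)

    def test_rank_deficient_design_flagged(self):
        a = np.array([5.0, 5.0, 5.0, 5.0])
        out = bh.bin_regression(np.array([1.0, 2, 3, 4]), a, a)
        assert np.isnan(out[3])


class TestHalfSymmetrySplit:
    def _profile(self, w):
        w = np.asarray(w, dtype=float)
        return WeightProfile(0, w, w, w, w, np.linspace(2, 18, len(w)), len(w))

    def test_symmetric_profile_has_identical_halves(self):
        phases = (np.arange(20) + 0.5) / 20
        w = np.sin(np.pi * phases)  # symmetric about mid-period
        first, second = bh.half_symmetry_split(self._profile(w))
        assert np.allclose(first, second, atol=1e-12)

    def test_output_lengths(self):
        f20, s20 = bh.half_symmetry_split(self._profile(np.arange(20)))
        assert len(f20) == len(s20) == 9
        f15, s15 = bh.half_symmetry_split(self._profile(np.arange(15)))
        assert len(f15) == len(s15) == 7

    def test_lagged_profile_shows_first_half_deficit(self):
        # a weight profile lagging the (ascending-then-descending) noise by
        # one bin sits lower in the first half than the flipped second half
        noise = np.concatenate([np.linspace(0, 1, 10), np.linspace(1, 0, 10)])
        lagged = np.roll(noise, 1)
        first, second = bh.half_symmetry_split(self._profile(lagged))
        assert first.mean() < second.mean()


def _oracle_two_way_f(data):
    """Brute-force sums-of-squares for a fully within-subject 2-factor
    design; returns uncorrected F per effect."""
    n, a, b = data.shape
    grand = data.mean()
    m_s = data.mean(axis=(1, 2))
    m_a = data.mean(axis=(0, 2))
    m_b = data.mean(axis=(0, 1))
    m_ab = data.mean(axis=0)
    m_sa = data.mean(axis=2)
    m_sb = data.mean(axis=1)
    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_sa = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_sb = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_sab = np.sum(
        (
            data
            - m_ab[None]
            - m_sa[:, :, None]
            - m_sb[:, None, :]
            + m_s[:, None, None]
            + m_a[None, :, None]
            + m_b[None, None, :]
            - grand
        )
        ** 2
    )
    f_a = (ss_a / (a - 1)) / (ss_sa / ((a - 1) * (n - 1)))
    f_b = (ss_b / (b - 1)) / (ss_sb / ((b - 1) * (n - 1)))
    f_ab = (ss_ab / ((a - 1) * (b - 1))) / (ss_sab / ((a - 1) * (b - 1) * (n - 1)))
    return f_a, f_b, f_ab


class TestRmAnova:
    def test_two_level_factor_equals_squared_paired_t(self, rng):
        x = rng.normal(0, 1, (12, 2, 1))
        x[:, 1, 0] += 0.8
        table = bh.rm_anova(x, ["part", "bin"])
        t, p = stats.ttest_rel(x[:, 1, 0], x[:, 0, 0])
        assert table.f["part"] == pytest.approx(t**2, rel=1e-9)
        assert table.p["part"] == pytest.approx(p, rel=1e-9)

    def test_identical_halves_give_zero_f(self, rng):
        half = rng.normal(0, 1, (10, 1, 9))
        data = np.concatenate([half, half], axis=1)
        table = bh.rm_anova(data, ["part", "bin"])
        assert table.f["part"] == pytest.approx(0.0, abs=1e-18)

    def test_matches_brute_force_sums_of_squares(self, rng):
        data = rng.normal(0, 1, (14, 2, 5))
        data += 0.4 * np.arange(5)[None, None, :]
        data[:, 1] += 0.3
        table = bh.rm_anova(data, ["part", "bin"])
        f_a, f_b, f_ab = _oracle_two_way_f(data)
        assert table.f["part"] == pytest.approx(f_a, rel=1e-8)
        assert table.f["bin"] == pytest.approx(f_b, rel=1e-8)
        assert table.f["part x bin"] == pytest.approx(f_ab, rel=1e-8)

    def test_matches_pingouin_with_sphericity_correction(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        data = rng.normal(0, 1, (11, 2, 4))
        data[:, :, 2] *= 2.5  # break sphericity on the bin factor
        data[:, 1] += 0.5
        rows = [
            {"subject": s, "part": i, "bin": j, "y": data[s, i, j]}
            for s in range(11)
            for i in range(2)
            for j in range(4)
        ]
        df = pd.DataFrame(rows)
        ref = pg.rm_anova(df, dv="y", within=["part", "bin"], subject="subject",
                          correction=True, detailed=True)
        table = bh.rm_anova(data, ["part", "bin"])
        for eff_name, pg_name in [("part", "part"), ("bin", "bin"),
                                  ("part x bin", "part * bin")]:
            row = ref[ref["Source"] == pg_name].iloc[0]
            assert table.f[eff_name] == pytest.approx(row["F"], rel=1e-6)
            p_ref = row["p_GG_corr"] if table.gg_applied[eff_name] else row["p_unc"]
            assert table.p[eff_name] == pytest.approx(p_ref, rel=1e-3)

    def test_missing_cells_rejected(self):
        data = np.full((5, 2, 3), np.nan)
        with pytest.raises(ValueError):
            bh.rm_anova(data, ["part", "bin"])

    def test_three_factor_design_runs(self, rng):
        data = rng.normal(0, 1, (9, 3, 2, 7))
        table = bh.rm_anova(data, ["jump", "part", "bin"])
        assert "jump x part x bin" in table.effects
        assert all(table.df1[e] > 0 for e in table.effects)
        assert all(0 <= table.partial_eta_sq[e] <= 1 for e in table.effects)


class TestLagRegression:
    def _profiles(self, w_list, sigma):
        return [
            WeightProfile(i, w, w, w, np.asarray(w, dtype=float), sigma, len(sigma))
            for i, w in enumerate(w_list)
        ]

    def test_pure_current_noise_dependence_zeroes_delta(self, rng):
        sigma = 10 + 8 * np.sin(2 * np.pi * (np.arange(20) + 0.5) / 20)
        profiles = self._profiles(
            [0.03 * sigma + 0.1 + rng.normal(0, 1e-12, 20) for _ in range(6)], sigma
        )
        out = bh.lag_regression(profiles)
        assert np.allclose(out.beta_delta, 0.0, atol=1e-6)

    def test_lagged_noise_dependence_gives_negative_delta(self, rng):
        sigma = 10 + 8 * np.sin(2 * np.pi * (np.arange(20) + 0.5) / 20)
        prev = np.roll(sigma, 1)
        profiles = self._profiles(
            [0.03 * prev + rng.normal(0, 0.002, 20) for _ in range(8)], sigma
        )
        out = bh.lag_regression(profiles)
        assert out.t_delta < 0 and out.p_delta < 0.01
        assert out.t_sigma > 0
        # group stats match a direct t test
        t_ref, p_ref = stats.ttest_1samp(out.beta_delta, 0.0)
        assert out.t_delta == pytest.approx(t_ref)
        d_ref = out.beta_delta.mean() / out.beta_delta.std(ddof=1)
        assert out.d_delta == pytest.approx(d_ref)

    def test_constant_noise_rejected(self):
        profiles = self._profiles([np.ones(20)], np.full(20, 8.0))
        with pytest.raises(ValueError):
            bh.lag_regression(profiles * 2)


class TestRecombineJumpCycles:
    def test_partition_into_three_types(self):
        ds = sq.make_session("jump", duration=1560.0, n_dots=5, seed=6)
        responses = np.zeros(len(ds))
        rec = bh.recombine_jump_cycles(ds, responses)
        assert set(rec) == {"outer", "middle", "inner"}
        idx = np.concatenate([v[0] for v in rec.values()])
        assert len(idx) == len(set(idx))  # disjoint
        assert len(idx) >= 0.95 * len(ds)  # only tail-cycle trials excluded

    def test_missing_jump_metadata_rejected(self, session20):
        with pytest.raises(ValueError):
            bh.recombine_jump_cycles(session20, np.zeros(len(session20)))

    def test_full_session_bin_counts(self):
        """At the full session scale every recombined type keeps a healthy
        trial count in each of its 15 bins."""
        ds = sq.make_session("jump", duration=4800.0, n_dots=5, seed=7)
        binned = bh.assign_bins(ds)
        rec = bh.recombine_jump_cycles(ds, np.zeros(len(ds)))
        for name, (idx, _) in rec.items():
            counts = np.bincount(binned.bin_idx[idx], minlength=16)[1:]
            assert counts.min() >= 15, (name, counts)


class TestWeightProfilePipeline:
    def test_weight_profile_shapes_and_range(self, session20, params_inst, rng):
        from avlearn.observers import simulate_observer

        resp = simulate_observer(session20, params_inst, "instantaneous", seed=9)
        profile = bh.weight_profile(session20, resp)
        assert profile.n_bins == 20
        ok = ~np.isnan(profile.w_a)
        assert ok.sum() >= 15
        assert np.nanmean(profile.w_a[ok]) > 0.0
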