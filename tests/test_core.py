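"""Irreversibility estimation: correlations, FS matrices, levels, FC."""

import warnings

import numpy as np
import pytest

import braintime as bt
from braintime.core import fs_entry


def _neg_lag_corr(x, y, shift):
    """Independent oracle: forward Pearson correlation at lag -shift by
    direct summation over the time-aligned overlap."""
    L = len(x)
    pairs_x = x[shift:]
    pairs_y = y[: L - shift]
    a = pairs_x - pairs_x.mean()
    b = pairs_y - pairs_y.mean()
    return float((a @ b) / np.sqrt((a @ a) * (b @ b)))


class TestLaggedCorr:
    def test_self_correlation_and_sign_flip(self, rng):
        x = rng.normal(size=200)
        assert bt.lagged_corr(x, x, 0) == pytest.approx(1.0)
        assert bt.lagged_corr(x, -x, 0) == pytest.approx(-1.0)

    def test_quarter_period_sinusoid(self):
        t = np.arange(6400)
        omega = 2 * np.pi / 64
        x = np.sin(omega * t)
        y = np.sin(omega * t + np.pi / 2)
        # cos(omega*16 + pi/2) = cos(pi) = -1
        assert bt.lagged_corr(x, y, 16) == pytest.approx(-1.0, abs=0.01)

    def test_constant_segment_flagged(self):
        x = np.zeros(100)
        y = np.arange(100.0)
        assert np.isnan(bt.lagged_corr(x, y, 1))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            bt.lagged_corr(np.arange(5.0), np.arange(5.0), 3)

    def test_reversal_identity_against_negative_lag(self, rng):
        """Correlating explicitly flipped series equals the forward
        correlation at negative lag (direct-summation oracle)."""
        for _ in range(30):
            x = rng.normal(size=500)
            y = rng.normal(size=500)
            shift = int(rng.integers(1, 20))
            lhs = bt.lagged_corr(bt.reverse(x), bt.reverse(y), shift)
            assert lhs == pytest.approx(_neg_lag_corr(x, y, shift), abs=1e-10)


class TestReverse:
    def test_flip_involution_and_fixed_point(self):
        np.testing.assert_array_equal(bt.reverse(np.array([1, 2, 3])), [3, 2, 1])
        x = np.arange(10.0)
        np.testing.assert_array_equal(bt.reverse(bt.reverse(x)), x)
        np.testing.assert_array_equal(bt.reverse(np.array([5.0])), [5.0])


class TestPairwiseIrreversibility:
    def test_zero_phase_pair_is_reversible(self):
        s = bt.make_sinusoid_pair(2 * np.pi / 64, 0.0, 6400)
        assert bt.pairwise_irreversibility(s.data[0], s.data[1], 16) < 1e-6

    @pytest.mark.parametrize("phi,expected", [
        (np.pi / 2, 2.0),
        (np.pi / 4, 2 * np.sin(np.pi / 4)),
    ])
    def test_closed_form_quarter_shift(self, phi, expected):
        omega = 2 * np.pi / 64
        s = bt.make_sinusoid_pair(omega, phi, 6400)
        # omega * 16 = pi/2, so I = 2|sin(pi/2) sin(phi)| = 2|sin(phi)|
        got = bt.pairwise_irreversibility(s.data[0], s.data[1], 16)
        assert got == pytest.approx(expected, abs=0.02)

    def test_white_noise_null(self):
        vals = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = r.normal(size=20_000)
            y = r.normal(size=20_000)
            vals.append(bt.pairwise_irreversibility(x, y, 1))
        assert np.mean(vals) < 0.02


class TestFsEntry:
    def test_analytic_values(self):
        assert fs_entry(0.0) == 0.0
        assert fs_entry(np.sqrt(0.5)) == pytest.approx(0.5 * np.log(2))
        # r = 1 hits the clamp: -1/2 ln(1e-12)
        assert fs_entry(1.0) == pytest.approx(-0.5 * np.log(1e-12))
        assert np.isnan(fs_entry(np.nan))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fs_entry(1.5)


class TestFsMatrices:
    def test_identical_signals_give_zero_diff(self):
        ramp = np.linspace(0, 1, 50) + 1.0
        w = np.vstack([ramp, ramp])
        fs = bt.fs_matrices(w, 1)
        np.testing.assert_allclose(fs.diff, 0.0, atol=1e-20)

    def test_diagonal_lag_symmetry(self, rng):
        # autocorrelation is lag-symmetric up to edge effects
        w = rng.normal(size=(4, 400)).cumsum(axis=1) * 0.1 + rng.normal(size=(4, 400))
        fs = bt.fs_matrices(w, 2)
        np.testing.assert_allclose(np.diag(fs.forward), np.diag(fs.reversal), atol=0.05)

    def test_asymmetric_var_breaks_pair_symmetry(self):
        model = bt.make_var_model(2, kappa=1.0, seed=3)
        s = bt.simulate_var(model, 5000, seed=4)
        fs = bt.fs_matrices(s.data, 1)
        assert abs(fs.forward[0, 1] - fs.forward[1, 0]) > 0.01

    def test_matrix_consistency_with_scalar_path(self, rng):
        w = rng.normal(size=(3, 80))
        fs = bt.fs_matrices(w, 2)
        for i in range(3):
            for j in range(3):
                expected = fs_entry(bt.lagged_corr(w[i], w[j], 2))
                assert fs.forward[i, j] == pytest.approx(expected, abs=1e-12)


class TestGlobalNodal:
    def test_stated_elements(self):
        # FSdiff = [[0,0],[4,0]] via forward-reversal difference [[0,0],[2,0]]
        fs = bt.FSMatrices(shift=1, forward=np.array([[1.0, 1.0], [3.0, 1.0]]),
                           reversal=np.array([[1.0, 1.0], [1.0, 1.0]]))
        I, sd = bt.global_irreversibility(fs)
        assert I == pytest.approx(1.0)
        assert sd == pytest.approx(np.std([0.0, 0.0, 4.0, 0.0]))

    def test_nodal_row_means(self):
        fs = bt.FSMatrices(shift=1, forward=np.array([[0.0, 2.0], [2.0, 0.0]]),
                           reversal=np.zeros((2, 2)))
        np.testing.assert_allclose(bt.nodal_irreversibility(fs), [2.0, 2.0])

    def test_mean_nodal_equals_global_exactly(self, rng):
        w = rng.normal(size=(7, 120)) + np.sin(np.arange(120) / 5)
        fs = bt.fs_matrices(w, 2)
        I, _ = bt.global_irreversibility(fs)
        assert float(np.mean(bt.nodal_irreversibility(fs))) == I  # exact

    def test_shift_zero_gives_exact_zero(self, rng):
        w = rng.normal(size=(5, 100))
        fs = bt.fs_matrices(w, 0)
        I, sd = bt.global_irreversibility(fs)
        assert I == 0.0 and sd == 0.0

    def test_scale_offset_invariance(self, rng):
        w = rng.normal(size=(5, 200))
        fs1 = bt.fs_matrices(w, 1)
        fs2 = bt.fs_matrices(3.7 * w + 11.0, 1)
        I1, _ = bt.global_irreversibility(fs1)
        I2, _ = bt.global_irreversibility(fs2)
        assert I1 == pytest.approx(I2, abs=1e-10)


class TestDetailedBalance:
    def test_reversible_null_much_smaller_than_irreversible(self):
        ratios = []
        for seed in range(10):
            s0 = bt.simulate_var(bt.make_var_model(10, 0.0, seed=seed), 5000, seed=seed + 100)
            s1 = bt.simulate_var(bt.make_var_model(10, 1.0, seed=seed), 5000, seed=seed + 100)
            I0, _ = bt.global_irreversibility(bt.fs_matrices(s0.data, 1))
            I1, _ = bt.global_irreversibility(bt.fs_matrices(s1.data, 1))
            ratios.append(I0 / I1)
        assert np.median(ratios) < 0.05

    def test_null_estimate_shrinks_with_length(self):
        wins = 0
        for seed in range(10):
            m = bt.make_var_model(5, 0.0, seed=seed)
            short = bt.simulate_var(m, 500, seed=seed + 50)
            long = bt.simulate_var(m, 20_000, seed=seed + 50)
            I_s, _ = bt.global_irreversibility(bt.fs_matrices(short.data, 1))
            I_l, _ = bt.global_irreversibility(bt.fs_matrices(long.data, 1))
            wins += I_l < I_s
        assert wins >= 9


class TestNetworkLevel:
    def test_all_regions_partition_reproduces_global(self, rng):
        w = rng.normal(size=(6, 150))
        labels = [f"r{i}" for i in range(6)]
        part = bt.NetworkPartition({l: "whole" for l in labels})
        fs = bt.fs_matrices(w, 1)
        I, _ = bt.global_irreversibility(fs)
        nets = bt.network_irreversibility(w, 1, part, labels)
        assert nets["whole"] == I  # exact restriction identity

    def test_block_diagonal_reversible_vs_irreversible(self):
        nA, nB = 5, 5
        mA = bt.make_var_model(nA, 0.0, seed=11)
        mB = bt.make_var_model(nB, 1.0, seed=12)
        sA = bt.simulate_var(mA, 5000, seed=13)
        sB = bt.simulate_var(mB, 5000, seed=14)
        data = np.vstack([sA.data, sB.data])
        labels = [f"a{i}" for i in range(nA)] + [f"b{i}" for i in range(nB)]
        part = bt.NetworkPartition(
            {**{f"a{i}": "netA" for i in range(nA)},
             **{f"b{i}": "netB" for i in range(nB)}})
        nets = bt.network_irreversibility(data, 1, part, labels)
        assert nets["netB"] > 5 * nets["netA"]

    def test_singleton_network_omitted_with_warning(self, rng):
        w = rng.normal(size=(3, 100))
        labels = ["r0", "r1", "r2"]
        part = bt.NetworkPartition({"r0": "big", "r1": "big", "r2": "lonely"})
        with pytest.warns(UserWarning, match="lonely"):
            nets = bt.network_irreversibility(w, 1, part, labels)
        assert set(nets) == {"big"}


class TestSubjectPipeline:
    def test_single_window_series(self, rng):
        s = bt.ParcellatedSeries("s", "fmri", 2.6, ["a", "b", "c"],
                                 rng.normal(size=(3, 20)))
        res = bt.subject_irreversibility(s, bt.WindowSpec(20, 1, 1))
        assert res.variability_temporal == 0.0
        fs = bt.fs_matrices(s.data, 1)
        I, _ = bt.global_irreversibility(fs)
        assert res.global_I == pytest.approx(I)
        assert res.global_I == pytest.approx(float(np.mean(res.per_window_I)), abs=1e-12)

    def test_hop_robustness(self):
        model = bt.make_var_model(10, 0.8, seed=21)
        s = bt.simulate_var(model, 300, seed=22)
        r1 = bt.subject_irreversibility(s, bt.WindowSpec(20, 1, 1))
        r2 = bt.subject_irreversibility(s, bt.WindowSpec(20, 2, 1))
        assert r2.global_I == pytest.approx(r1.global_I, rel=0.10)

    def test_constant_stretch_drops_windows(self, rng):
        data = rng.normal(size=(4, 120))
        data[0, 40:80] = 0.0  # flat stretch makes correlations undefined
        s = bt.ParcellatedSeries("s", "fmri", 2.6, list("abcd"), data)
        res = bt.subject_irreversibility(s, bt.WindowSpec(20, 1, 1))
        assert res.n_windows_dropped >= 1
        assert np.isfinite(res.global_I)

    def test_group_ordering_recovered(self, small_cohort, small_cohort_results):
        truth = small_cohort.truth
        highs = [r.global_I for r in small_cohort_results if truth[r.subject_id] > 0.55]
        lows = [r.global_I for r in small_cohort_results if truth[r.subject_id] <= 0.55]
        assert np.median(highs) > np.median(lows)


class TestSelectShift:
    def test_white_noise_gives_lag_one(self, white_noise_series):
        assert bt.select_shift(white_noise_series) == 1

    def test_ar_coefficient_point_nine_gives_ten(self):
        from scipy.signal import lfilter

        rng = np.random.default_rng(5)
        eps = rng.normal(size=(2, 200_000))
        x = lfilter([1.0], [1.0, -0.9], eps, axis=1)
        s = bt.ParcellatedSeries("ar", "fmri", 2.6, ["a", "b"], x)
        # analytic decay 0.9^lag crosses 1/e between lags 9 and 10
        assert bt.select_shift(s) == 10

    def test_constant_signal_returns_cap_with_warning(self):
        data = np.full((2, 400), 7.0)
        s = bt.ParcellatedSeries("flat", "fmri", 2.6, ["a", "b"], data)
        with pytest.warns(UserWarning, match="cap"):
            assert bt.select_shift(s) == 100


class TestFunctionalConnectivity:
    def test_identical_regions_fc_one(self, rng):
        x = rng.normal(size=500)
        s = bt.ParcellatedSeries("s", "fmri", 2.6, ["a", "b"], np.vstack([x, x]))
        fc = bt.fc_pearson(s)
        assert fc[0, 1] == pytest.approx(1.0)

    def test_fc_symmetric_and_null_small(self, rng):
        s = bt.ParcellatedSeries("s", "fmri", 2.6, list("abc"),
                                 rng.normal(size=(3, 100_000)))
        fc = bt.fc_pearson(s)
        np.testing.assert_array_equal(fc - fc.T, np.zeros((3, 3)))
        assert np.max(np.abs(fc[np.triu_indices(3, 1)])) < 0.02
        assert abs(bt.mean_fc(fc)) < 0.02

    def test_constant_region_flagged(self, rng):
        data = rng.normal(size=(3, 50))
        data[1] = 2.0
        s = bt.ParcellatedSeries("s", "fmri", 2.6, list("abc"), data)
        fc = bt.fc_pearson(s)
        assert np.isnan(fc[1]).all() and np.isnan(fc[:, 1]).all()

    def test_coherence_identical_signals(self, rng):
        fs_hz = 512.0
        x = rng.normal(size=8192)
        s = bt.ParcellatedSeries("s", "eeg", 1 / fs_hz, ["a", "b"], np.vstack([x, x]))
        coh = bt.fc_coherence(s, bt.CANONICAL_BANDS["alpha"])
        assert coh[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_coherence_shared_sinusoid_high(self, rng):
        fs_hz = 512.0
        t = np.arange(int(32 * fs_hz)) / fs_hz
        carrier = np.sin(2 * np.pi * 10.0 * t)
        x = carrier + 0.5 * rng.normal(size=t.size)
        y = carrier + 0.5 * rng.normal(size=t.size)
        s = bt.ParcellatedSeries("s", "eeg", 1 / fs_hz, ["a", "b"], np.vstack([x, y]))
        coh = bt.fc_coherence(s, bt.BandSpec("narrow", 9.0, 11.0, 1))
        assert coh[0, 1] > 0.8

    def test_coherence_independent_noise_low(self, rng):
        fs_hz = 512.0
        n = int(40 * fs_hz)  # ~79 half-overlapping 1 s segments
        s = bt.ParcellatedSeries("s", "eeg", 1 / fs_hz, ["a", "b"],
                                 rng.normal(size=(2, n)))
        coh = bt.fc_coherence(s, bt.CANONICAL_BANDS["alpha"])
        assert coh[0, 1] < 0.2
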