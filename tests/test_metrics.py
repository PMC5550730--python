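import numpy as np
import pytest
from scipy.stats import pearsonr

from bgdbs.metrics import (
    ap_count_functions,
    cost,
    count_misses,
    instantaneous_phase,
    mutual_information,
    net_grid,
    plv,
    plv_from_phases,
    smoothed_rate,
    synchronization_level,
)
from bgdbs.waveforms import make_preset, sample


class TestCountMisses:
    def test_all_hits(self):
        onsets = np.arange(0.0, 100.0, 10.0)
        spikes = onsets + 3.0
        assert count_misses(onsets, spikes, period=10.0) == 0

    def test_empty_train_all_missed(self):
        onsets = np.arange(0.0, 100.0, 10.0)
        assert count_misses(onsets, np.array([]), period=10.0) == 10

    def test_alternating_hit_miss(self):
        onsets = np.arange(0.0, 200.0, 10.0)  # 20 pulses
        spikes = onsets[::2] + 4.0            # answer every other pulse
        assert count_misses(onsets, spikes, period=10.0) == 10

    def test_spike_credited_to_one_pulse_only(self):
        # a spike inside pulse k's window cannot also rescue pulse k+1
        onsets = np.array([0.0, 10.0])
        spikes = np.array([9.5])
        assert count_misses(onsets, spikes, period=10.0) == 1

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            count_misses(np.array([0.0, 5.0]), np.array([1.0]), period=10.0)


class TestCost:
    def test_zero_misses_is_pure_energy(self):
        sw = sample(make_preset("Pulse"), 0.01, 1000.0 / 130.0)
        rep = cost(sw, Z=1.0, M=0)
        assert rep.total == rep.energy

    def test_rectangular_pulse_with_two_misses(self):
        # 12 + 0.4 nJ of energy plus 2 x 3 nJ of penalty
        sw = sample(make_preset("Pulse"), 0.01, 1000.0 / 130.0)
        rep = cost(sw, Z=1.0, M=2)
        assert rep.total == pytest.approx(18.4, rel=1e-9)

    def test_monotone_in_misses(self):
        sw = sample(make_preset("GDG"), 0.01, 1000.0 / 130.0)
        totals = [cost(sw, M=m).total for m in range(5)]
        assert np.all(np.diff(totals) > 0)

    def test_negative_misses_rejected(self):
        sw = sample(make_preset("Pulse"), 0.01, 10.0)
        with pytest.raises(ValueError):
            cost(sw, M=-1)


class TestMutualInformation:
    def test_symmetry(self, rng):
        y1 = rng.normal(size=2000)
        y2 = y1 + rng.normal(size=2000)
        assert mutual_information(y1, y2).mi == pytest.approx(
            mutual_information(y2, y1).mi
        )

    def test_identity_equals_binned_entropy(self, rng):
        y = rng.normal(size=5000)
        est = mutual_information(y, y, bins=8)
        counts, _ = np.histogram(y, bins=8)
        p = counts / counts.sum()
        entropy = -np.sum(p[p > 0] * np.log(p[p > 0]))
        assert est.mi == pytest.approx(entropy, rel=1e-9)

    def test_independent_signals_near_zero(self, rng):
        y1 = rng.normal(size=10_000)
        y2 = rng.permutation(y1)
        assert mutual_information(y1, y2).mi < 0.02

    def test_data_processing_sanity(self, rng):
        y = rng.normal(size=4000)
        assert mutual_information(y, y).mi >= mutual_information(
            y, rng.permutation(y)).mi

    def test_constant_signal_zero_mi(self):
        assert mutual_information(np.ones(100), np.arange(100.0)).mi == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mutual_information(np.ones(10), np.ones(11))


class TestInstantaneousPhase:
    def test_sine_phase_advances_at_signal_frequency(self):
        dt, f = 0.001, 7.0  # s, Hz
        t = np.arange(0, 4, dt)
        phi = instantaneous_phase(np.sin(2 * np.pi * f * t))
        slope = np.polyfit(t[500:-500], np.unwrap(phi)[500:-500], 1)[0]
        assert slope == pytest.approx(2 * np.pi * f, rel=0.01)

    def test_quadrature_pair_lag(self):
        t = np.arange(0, 4, 0.001)
        phi_sin = instantaneous_phase(np.sin(2 * np.pi * 5 * t))
        phi_cos = instantaneous_phase(np.cos(2 * np.pi * 5 * t))
        diff = np.angle(np.exp(1j * (phi_cos - phi_sin)))
        assert np.median(diff) == pytest.approx(np.pi / 2, abs=0.02)

    def test_amplitude_invariance(self):
        t = np.arange(0, 2, 0.001)
        y = np.sin(2 * np.pi * 3 * t) + 0.2 * np.sin(2 * np.pi * 11 * t)
        np.testing.assert_allclose(
            instantaneous_phase(y), instantaneous_phase(2.0 * y), atol=1e-9
        )

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_phase(np.zeros(100))


class TestPLV:
    def test_identical_signals(self):
        t = np.arange(0, 2, 0.001)
        y = np.sin(2 * np.pi * 8 * t)
        assert plv(y, y).plv == pytest.approx(1.0)

    def test_constant_lag(self):
        phi = np.linspace(0, 40 * np.pi, 5000)
        assert plv_from_phases(phi, phi - 1.234).plv == pytest.approx(1.0)

    def test_independent_phases_vanish(self, rng):
        L = 10_000
        a = rng.uniform(-np.pi, np.pi, L)
        b = rng.uniform(-np.pi, np.pi, L)
        assert plv_from_phases(a, b).plv < 0.03

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            plv_from_phases(np.zeros(5), np.zeros(6))


class TestAPCountFunctions:
    def test_frame_count(self):
        trains = [np.array([10.0, 40.0]), np.array([100.0])]
        F = ap_count_functions(trains, frame=15.0, duration=200.0)
        assert F.shape == (2, 13)  # floor(200 / 15)

    def test_empty_train_all_zero(self):
        F = ap_count_functions([np.array([])], frame=15.0, duration=100.0)
        assert np.all(F == 0)

    def test_spike_conservation(self, rng):
        times = np.sort(rng.uniform(0, 150, 40))
        F = ap_count_functions([times], frame=15.0, duration=150.0)
        assert F.sum() == np.sum(times < 150.0)


class TestSynchronizationLevel:
    def test_identical_nonconstant_functions_fully_synchronized(self, rng):
        base = rng.integers(0, 5, size=30)
        F = np.tile(base, (8, 1))
        rep = synchronization_level(F)
        assert rep.sl == 1.0
        assert rep.n_total == 8 * 7 // 2

    def test_independence_null_calibrates_to_alpha(self, rng):
        # 100 independent Poisson trains, 2 s, 15 ms frames: the fraction of
        # significant pairs is the test's type-I error rate
        F = rng.poisson(1.5, size=(100, 133))
        rep = synchronization_level(F, alpha=0.05)
        assert 0.01 <= rep.sl <= 0.07

    def test_matches_double_loop_pearson_oracle(self, rng):
        F = rng.poisson(2.0, size=(20, 40)).astype(float)
        rep = synchronization_level(F)
        for i in range(20):
            for j in range(i + 1, 20):
                r, p = pearsonr(F[i], F[j])
                assert rep.corr[i, j] == pytest.approx(r, abs=1e-10)
                assert rep.pvalues[i, j] == pytest.approx(p, abs=1e-8)

    def test_symmetric_handling(self, rng):
        F = rng.poisson(2.0, size=(12, 50)).astype(float)
        rep = synchronization_level(F)
        np.testing.assert_allclose(rep.corr, rep.corr.T, atol=1e-12)
        # lower triangle gives the same SL as the upper
        il, jl = np.tril_indices(12, k=-1)
        n_sig_lower = int(np.sum(rep.pvalues[il, jl] <= rep.alpha))
        assert n_sig_lower == rep.n_significant

    def test_zero_variance_functions_excluded(self, rng):
        F = rng.poisson(2.0, size=(5, 40)).astype(float)
        F[2] = 3.0  # constant -> undefined correlation
        rep = synchronization_level(F)
        assert rep.n_excluded == 1
        assert rep.n_total == 4 * 3 // 2

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            synchronization_level(np.ones((4, 30)))


class TestSmoothedRate:
    def test_total_mass_preserved(self):
        times = np.array([100.0, 200.0, 300.0])
        rate = smoothed_rate([times], duration=400.0, dt=1.0, sigma=10.0)
        # integral of rate (Hz) over time (s) ~ spike count
        assert np.trapezoid(rate, dx=1e-3) == pytest.approx(3.0, rel=0.02)


class TestNETGrid:
    def test_minmax_normalization_and_determinism(self):
        delays = np.array([0.0, 0.3])
        freqs = np.array([80.0, 130.0])
        a = net_grid("gaussian", delays, freqs, window=50.0, amp_resolution=5.0)
        b = net_grid("gaussian", delays, freqs, window=50.0, amp_resolution=5.0)
        finite = np.isfinite(a.net)
        assert finite.any()
        assert a.net[finite].min() == pytest.approx(0.0)
        assert a.net[finite].max() == pytest.approx(1.0) or np.sum(finite) == 1
        np.testing.assert_array_equal(
            a.raw[np.isfinite(a.raw)], b.raw[np.isfinite(b.raw)]
        )

    def test_empty_axes_rejected(self):
        with pytest.raises(ValueError):
            net_grid("gaussian", [], [100.0])
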