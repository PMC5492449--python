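"""Morlet family arithmetic, normalized energy, PLF properties, partitioning."""

import numpy as np
import pytest
from p300speller.design import SpellerConfig, ssvep_band
from p300speller.exceptions import AliasingError, BookkeepingError
from p300speller.preprocess import EpochArray
from p300speller.timefreq import (Wavelet, collapse_time_median,
                                  make_wavelet_family, normalized_energy,
                                  partition_trials_by_outcome,
                                  phase_locking_factor, plf_from_phase_traces,
                                  PlfMatrix)


class TestWaveletFamily:
    def test_printed_width_arithmetic(self):
        family = make_wavelet_family(k=7)
        by_f0 = {w.f0: w for w in family}
        assert round(2 * by_f0[5.0].sigma_f, 2) == 1.43
        assert round(2 * by_f0[5.0].sigma_t * 1000, 2) == 445.63
        assert round(2 * by_f0[20.0].sigma_f, 2) == 5.71
        assert round(2 * by_f0[20.0].sigma_t * 1000, 2) == 111.41

    def test_constant_ratio_and_uncertainty_identity(self):
        family = make_wavelet_family(k=7)
        assert len(family) == 16
        for w in family:
            assert w.f0 / w.sigma_f == pytest.approx(7.0)
            assert w.sigma_t * w.sigma_f == pytest.approx(1 / (2 * np.pi))

    def test_low_k_warns_but_builds(self):
        with pytest.warns(UserWarning):
            family = make_wavelet_family(k=4)
        assert len(family) == 16

    def test_undersampled_rate_rejected(self):
        with pytest.raises(AliasingError):
            make_wavelet_family(sampling_rate_hz=30.0)


class TestNormalizedEnergy:
    def _wavelet(self, f0=10.0, fs=256.0):
        return [w for w in make_wavelet_family(f0_grid=(f0,),
                                               sampling_rate_hz=fs)][0]

    def test_sinusoid_gives_unit_modulus_constant_rotation(self):
        fs, f0 = 256.0, 10.0
        t = np.arange(int(3 * fs)) / fs
        P, defined = normalized_energy(np.cos(2 * np.pi * f0 * t),
                                       self._wavelet(f0))
        assert defined.any()
        np.testing.assert_allclose(np.abs(P[defined]), 1.0, atol=1e-9)
        phase_step = np.diff(np.unwrap(np.angle(P[defined])))
        np.testing.assert_allclose(phase_step, 2 * np.pi * f0 / fs, atol=1e-6)

    def test_amplitude_invariance(self):
        fs = 256.0
        t = np.arange(int(2 * fs)) / fs
        s = np.cos(2 * np.pi * 10 * t) + 0.3 * np.sin(2 * np.pi * 7 * t)
        P1, d1 = normalized_energy(s, self._wavelet())
        P2, d2 = normalized_energy(10.0 * s, self._wavelet())
        np.testing.assert_array_equal(d1, d2)
        np.testing.assert_allclose(P1[d1], P2[d2], atol=1e-9)

    def test_wavelet_normalization_constant_cancels(self):
        fs = 256.0
        t = np.arange(int(2 * fs)) / fs
        s = np.cos(2 * np.pi * 10 * t)
        w = self._wavelet()
        doubled = Wavelet(f0=w.f0, sigma_f=w.sigma_f, sigma_t=w.sigma_t,
                          amplitude=2 * w.amplitude, waveform=2 * w.waveform,
                          times_s=w.times_s)
        P1, d1 = normalized_energy(s, w)
        P2, d2 = normalized_energy(s, doubled)
        np.testing.assert_array_equal(d1, d2)
        np.testing.assert_allclose(P1[d1], P2[d2], atol=1e-9)

    def test_zero_signal_fully_undefined(self):
        P, defined = normalized_energy(np.zeros(512), self._wavelet())
        assert not defined.any()

    def test_chirp_phase_matches_analytic_instantaneous_phase(self):
        """Slow linear chirp crossing f0: output phase tracks the closed-form
        chirp phase within 0.1 rad near the crossing."""
        fs, f0 = 256.0, 10.0
        dur, flo, fhi = 10.0, 8.0, 12.0
        t = np.arange(int(dur * fs)) / fs
        rate = (fhi - flo) / dur
        phase = 2 * np.pi * (flo * t + 0.5 * rate * t**2)
        s = np.cos(phase)
        P, defined = normalized_energy(s, self._wavelet(f0))
        t_cross = (f0 - flo) / rate
        near = defined & (np.abs(t - t_cross) < 0.1)
        err = np.angle(P[near] * np.exp(-1j * phase[near]))
        assert np.max(np.abs(err)) < 0.1

    def test_strict_edges_undefined_where_support_leaves_epoch(self):
        w = self._wavelet(5.0)           # 4 sigma_t = 891 ms at k=7
        P, defined = normalized_energy(np.random.default_rng(0).standard_normal(205),
                                       w)
        assert not defined.any()          # support exceeds an 800 ms epoch
        P2, defined2 = normalized_energy(
            np.random.default_rng(0).standard_normal(205), w, edge="pad")
        assert defined2.all()


class TestPhaseLockingFactor:
    def test_identical_trials_plf_one(self, rng):
        family = make_wavelet_family(f0_grid=(10.0, 15.0))
        trial = rng.standard_normal(768)
        plf = phase_locking_factor(np.tile(trial, (8, 1)), family)
        defined = np.isfinite(plf.values)
        assert defined.any()
        np.testing.assert_allclose(plf.values[defined], 1.0, atol=1e-9)

    def test_single_trial_plf_one(self, rng):
        family = make_wavelet_family(f0_grid=(12.0,))
        plf = phase_locking_factor(rng.standard_normal(512), family)
        defined = np.isfinite(plf.values)
        np.testing.assert_allclose(plf.values[defined], 1.0, atol=1e-9)

    def test_random_phase_matches_rayleigh_expectation(self, rng):
        """Monte-Carlo oracle: E|mean of N unit phasors| ~ sqrt(pi)/(2 sqrt(N))."""
        N, reps, samples = 90, 200, 5
        phases = rng.uniform(0, 2 * np.pi, size=(reps, N, samples))
        values = []
        for r in range(reps):
            plf, counts = plf_from_phase_traces(np.exp(1j * phases[r]))
            assert (counts == N).all()
            values.extend(plf)
        expected = np.sqrt(np.pi) / (2 * np.sqrt(N))
        assert np.mean(values) == pytest.approx(expected, abs=0.005)

    def test_plf_decreases_with_phase_jitter(self, rng):
        """Monotone over the jitter ladder 0, pi/8, pi/4, pi/2 (50 seeds)."""
        n_trials, n_samples = 40, 4
        means = []
        for jitter in (0.0, np.pi / 8, np.pi / 4, np.pi / 2):
            vals = []
            for _ in range(50):
                ph = rng.normal(0.0, jitter, size=(n_trials, n_samples))
                plf, _ = plf_from_phase_traces(np.exp(1j * ph))
                vals.append(plf.mean())
            means.append(np.mean(vals))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_values_bounded_and_effective_n_recorded(self, rng):
        family = make_wavelet_family(f0_grid=(12.0, 16.0, 20.0))
        trials = rng.standard_normal((12, 205))
        plf = phase_locking_factor(trials, family,
                                   times_ms=-100 + np.arange(205) * 1000 / 256)
        finite = np.isfinite(plf.values)
        assert ((plf.values[finite] >= 0) & (plf.values[finite] <= 1)).all()
        assert (plf.effective_n[finite] == 12).all()
        assert (plf.effective_n[~finite] == 0).all()

    def test_stronger_evoked_response_increases_plf(self, rng):
        """Correct-vs-wrong contract: weaker target templates give lower PLF."""
        from p300speller.templates import ComponentTemplate
        grid = -100 + np.arange(205) * 1000 / 256
        family = make_wavelet_family(f0_grid=(12.0,))
        def median_plf(amp, seed):
            r = np.random.default_rng(seed)
            bump = ComponentTemplate(amp, 353.516, 200.0).evaluate(grid)
            trials = bump + 8.0 * r.standard_normal((60, 205))
            plf = phase_locking_factor(trials, family, times_ms=grid)
            return np.nanmedian(plf.values)
        strong = [median_plf(8.0, s) for s in range(20)]
        weak = [median_plf(1.0, s + 500) for s in range(20)]
        assert np.mean(strong) > np.mean(weak)


class TestCollapseAndPartition:
    def _plf(self, values, times=None):
        values = np.atleast_2d(values)
        return PlfMatrix(values=values, effective_n=np.ones_like(values, int),
                         freqs_hz=np.arange(values.shape[0], dtype=float),
                         times_ms=times, n_trials=1)

    def test_constant_plf_collapses_to_constant(self):
        out = collapse_time_median(self._plf(np.full((16, 50), 0.37)))
        assert out.shape == (16,)
        np.testing.assert_allclose(out, 0.37)

    def test_symmetric_bump_median_below_peak(self):
        bump = 0.2 + 0.6 * np.exp(-0.5 * ((np.arange(101) - 50) / 10) ** 2)
        out = collapse_time_median(self._plf(bump))
        assert out[0] < bump.max()
        assert out[0] == pytest.approx(np.sort(bump)[len(bump) // 2], abs=1e-12)

    def test_post_stimulus_only_by_default(self):
        times = np.linspace(-100, 60, 17)     # 10 pre-stimulus, 7 post samples
        values = np.where(times < 0, 1.0, 0.0)[None, :]
        assert collapse_time_median(self._plf(values, times))[0] == 0.0
        full = collapse_time_median(self._plf(values, times), post_only=False)
        assert full[0] == 1.0

    def test_fully_undefined_frequency_is_missing(self):
        values = np.vstack([np.full(10, np.nan), np.full(10, 0.5)])
        out = collapse_time_median(self._plf(values))
        assert np.isnan(out[0]) and out[1] == 0.5

    def test_partition_counts_follow_selection_outcomes(self):
        """3 of 5 correct selections: 90/450 correct, 60/300 wrong epochs."""
        from p300speller.classify import SelectionResult

        reps, symbols = 15, 5
        n = 12 * reps * symbols
        units = np.tile(np.arange(12), reps * symbols)
        symbol_index = np.repeat(np.arange(symbols), 12 * reps)
        labels = np.isin(units, [0, 6])
        epochs = EpochArray(data=np.zeros((n, 1, 5)), ch_names=["Oz"],
                            sampling_rate_hz=256.0, labels=labels,
                            symbol_index=symbol_index, units=units,
                            repetition=np.zeros(n, int))
        selections = [
            SelectionResult(cumulative=[np.ones(1)] * 12, chosen=(0, 0),
                            truth=(0, 0) if s < 3 else (1, 1), symbol_index=s)
            for s in range(symbols)
        ]
        parts, counts = partition_trials_by_outcome(epochs, selections)
        assert counts[("target", "correct")] == 3 * 30
        assert counts[("nontarget", "correct")] == 3 * 150
        assert counts[("target", "wrong")] == 2 * 30
        assert counts[("nontarget", "wrong")] == 2 * 150
        assert sum(counts.values()) == n
        assert parts[("target", "correct")].n_trials == 90

    def test_all_correct_leaves_wrong_sets_empty(self):
        from p300speller.classify import SelectionResult
        units = np.tile(np.arange(12), 2)
        epochs = EpochArray(data=np.zeros((24, 1, 5)), ch_names=["Oz"],
                            sampling_rate_hz=256.0,
                            labels=np.isin(units, [0, 6]),
                            symbol_index=np.zeros(24, int), units=units,
                            repetition=np.zeros(24, int))
        sel = [SelectionResult(cumulative=[np.ones(1)] * 12, chosen=(0, 0),
                               truth=(0, 0), symbol_index=0)]
        parts, counts = partition_trials_by_outcome(epochs, sel)
        assert counts[("target", "wrong")] == 0
        assert parts[("target", "wrong")].n_trials == 0

    def test_selection_epoch_mismatch_rejected(self):
        from p300speller.classify import SelectionResult
        units = np.tile(np.arange(12), 2)
        epochs = EpochArray(data=np.zeros((24, 1, 5)), ch_names=["Oz"],
                            sampling_rate_hz=256.0,
                            labels=np.isin(units, [0, 6]),
                            symbol_index=np.zeros(24, int), units=units,
                            repetition=np.zeros(24, int))
        sel = [SelectionResult(cumulative=[np.ones(1)] * 12, chosen=(0, 0),
                               truth=(0, 0), symbol_index=3)]
        with pytest.raises(BookkeepingError):
            partition_trials_by_outcome(epochs, sel)


class TestSsvepDetection:
    def test_flicker_band_peak_on_nontarget_posterior_channel(self, fast_session):
        """Fast-mode non-target epochs show a PLF peak inside the 12-15 Hz
        steady-state band at Oz."""
        epochs = fast_session["perf_epochs"]
        nontarget = epochs.subset(~epochs.labels.astype(bool))
        family = make_wavelet_family()
        plf = phase_locking_factor(nontarget.channel("Oz"), family,
                                   times_ms=nontarget.times_ms, channel="Oz")
        medians = collapse_time_median(plf)
        defined = np.isfinite(medians)
        assert defined.any()
        f_min, f_max = ssvep_band(SpellerConfig.fast())
        peak_freq = plf.freqs_hz[defined][np.nanargmax(medians[defined])]
        assert f_min <= peak_freq <= f_max
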