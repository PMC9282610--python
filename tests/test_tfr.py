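"""Wavelet decomposition, ITPC, induced power, and frequency tagging."""

import numpy as np
import pytest

from phrasal import synth, tfr
from phrasal.containers import TrialTensor


def _sinusoid_trials(freq, fs=256.0, n_trials=3, amp=1.0, phase=0.0):
    t0, t1 = -1.0, 2.0
    n = int((t1 - t0) * fs)
    times = np.arange(n) / fs + t0
    data = amp * np.cos(2 * np.pi * freq * times + phase)
    return TrialTensor(np.tile(data, (n_trials, 1, 1)), fs, int(-t0 * fs)), times


class TestTransform:
    def test_unit_sinusoid_magnitude_constant_and_one(self, small_bank):
        k = small_bank.nearest(10.0)
        trials, _ = _sinusoid_trials(small_bank.freqs[k])
        tf = tfr.tfr_transform(trials, small_bank)
        interior = tf.valid[k]
        mags = np.abs(tf.coeffs[0, 0, k, interior])
        assert np.all(np.abs(mags - 1.0) < 0.05)

    def test_phase_advances_with_analytic_phase(self, small_bank):
        trials, times = _sinusoid_trials(10.0)
        tf = tfr.tfr_transform(trials, small_bank)
        k = small_bank.nearest(10.0)
        sel = tf.valid[k]
        phases = np.unwrap(np.angle(tf.coeffs[0, 0, k, sel]))
        # 10 Hz: phase advances 2*pi per 100 ms
        slope = np.polyfit(times[sel], phases, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 10.0, rel=0.01)

    def test_zero_signal_gives_zero_coefficients(self, small_bank):
        trials = TrialTensor(np.zeros((2, 1, 600)), 256.0, 300)
        tf = tfr.tfr_transform(trials, small_bank)
        assert np.abs(tf.coeffs).max() < 1e-12

    def test_low_fs_rejected(self, small_bank):
        trials = TrialTensor(np.zeros((2, 1, 300)), 64.0, 150)
        with pytest.raises(ValueError, match="too low"):
            tfr.tfr_transform(trials, small_bank)

    def test_agrees_with_mne_phase(self, small_bank, rng):
        mne = pytest.importorskip("mne")
        data = rng.normal(size=(2, 1, 2560))
        trials = TrialTensor(data, 256.0, 1280)
        tf = tfr.tfr_transform(trials, small_bank)
        ref = mne.time_frequency.tfr_array_morlet(
            data, 256.0, small_bank.freqs, n_cycles=small_bank.cycles,
            output="complex", zero_mean=False,
        )
        k = small_bank.nearest(8.0)
        sel = tf.valid[k]
        ours = np.angle(tf.coeffs[0, 0, k, sel])
        theirs = np.angle(ref[0, 0, k, sel])
        # independent implementation: phases agree up to numerical wobble
        dphi = np.angle(np.exp(1j * (ours - theirs)))
        assert np.abs(dphi).max() < 0.05


def _resultant_oracle(phases_by_trial):
    """Direct mean-resultant-length computation (independent oracle)."""
    return np.abs(np.mean(np.exp(1j * phases_by_trial), axis=0))


class TestITPC:
    def test_identical_trials_give_one(self, small_bank, clean_locked_trials):
        tf = tfr.tfr_transform(clean_locked_trials, small_bank)
        vals = tfr.itpc(tf)
        k = small_bank.nearest(2.0)
        j = np.argmin(np.abs(tf.times - 0.4))
        assert vals[0, k, j] == pytest.approx(1.0, abs=1e-9)

    def test_roots_of_unity_cancel(self, small_bank):
        n = 5
        fs, f = 256.0, 8.0
        times = np.arange(768) / fs - 1.0
        data = np.stack([
            np.cos(2 * np.pi * f * times + 2 * np.pi * k / n)[None, :]
            for k in range(n)
        ])
        tf = tfr.tfr_transform(TrialTensor(data, fs, 256), small_bank)
        k_ = small_bank.nearest(f)
        j = np.argmin(np.abs(tf.times - 0.4))
        assert tfr.itpc(tf)[0, k_, j] == pytest.approx(0.0, abs=1e-6)

    def test_matches_resultant_oracle_on_random_coeffs(self, rng):
        coeffs = rng.normal(size=(9, 2, 3, 4)) + 1j * rng.normal(size=(9, 2, 3, 4))
        tf = tfr.TFRTensor(coeffs, np.ones(3), np.zeros(4), 100.0)
        got = tfr.itpc(tf)
        want = _resultant_oracle(np.angle(coeffs))
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_uniform_phase_expectation(self, rng):
        # mean ITPC over many replicates matches the Monte-Carlo resultant
        # expectation for n=10 uniform phases, within 3 SE
        n, reps = 10, 10000
        phases = rng.uniform(-np.pi, np.pi, size=(n, reps))
        mc = _resultant_oracle(phases)
        coeffs = np.exp(1j * rng.uniform(-np.pi, np.pi, size=(n, 1, 1, reps)))
        got = tfr.itpc(tfr.TFRTensor(coeffs, np.ones(1), np.zeros(reps), 1.0))
        se = mc.std() / np.sqrt(reps) + got.std() / np.sqrt(reps)
        assert abs(got.mean() - mc.mean()) < 3 * se

    def test_decreases_with_trial_count(self, rng):
        means = []
        for n in (10, 100, 1000):
            coeffs = np.exp(1j * rng.uniform(-np.pi, np.pi, size=(n, 1, 1, 200)))
            means.append(
                tfr.itpc(tfr.TFRTensor(coeffs, np.ones(1), np.zeros(200), 1.0)).mean()
            )
        assert means[0] > means[1] > means[2]


class TestInducedPower:
    def test_stationary_signal_near_zero_db(self):
        truth = synth.GroundTruth(
            phase_lock_strength=0.0, lock_amp=0.0, alpha_power_change=0.0,
            pac_amp=0.0, pac_modulation=0.0, noise_sd=1.0, seed=11,
        )
        trials = synth.gen_trials(truth, n_trials=200, n_channels=1, fs=128.0)
        bank = tfr.WaveletBank(np.geomspace(2, 30, 8), np.geomspace(3, 12, 8))
        tf = tfr.tfr_transform(trials, bank)
        db = tfr.induced_power(tf)
        sel = tf.valid & (tf.times >= -0.8)[None, :] & (tf.times <= 1.5)[None, :]
        # approximately 0 dB: tight on the per-frequency time average, loose
        # on single bins (finite-trial sampling noise)
        for i in range(len(bank.freqs)):
            assert abs(db[0, i][sel[i]].mean()) < 0.5
        assert np.abs(db[0][sel]).max() < 1.5

    def test_amplitude_doubling_gives_6db(self, small_bank):
        fs = 256.0
        times = np.arange(768) / fs - 1.0
        amp = np.where(times >= 0, 2.0, 1.0)
        data = amp * np.cos(2 * np.pi * 10.0 * times)
        trials = TrialTensor(np.tile(data, (3, 1, 1)), fs, 256)
        tf = tfr.tfr_transform(trials, small_bank)
        db = tfr.induced_power(tf)
        k = small_bank.nearest(10.0)
        j = np.argmin(np.abs(tf.times - 0.6))
        assert db[0, k, j] == pytest.approx(10 * np.log10(4.0), abs=0.3)

    def test_planted_alpha_change_recovered(self):
        truth = synth.GroundTruth(
            phase_lock_strength=0.0, lock_amp=0.0, alpha_power_change=-3.0,
            alpha_amp=2.0, pac_amp=0.0, pac_modulation=0.0,
            noise_sd=0.3, seed=21,
        )
        trials = synth.gen_trials(truth, n_trials=80, n_channels=1, fs=128.0)
        bank = tfr.WaveletBank.subset([10.0])
        tf = tfr.tfr_transform(trials, bank)
        db = tfr.induced_power(tf)
        j = (tf.times >= 0.3) & (tf.times <= 0.8)
        assert db[0, 0, j].mean() == pytest.approx(-3.0, abs=0.5)

    def test_missing_baseline_rejected(self, small_bank):
        trials = TrialTensor(np.random.default_rng(0).normal(size=(2, 1, 256)),
                             256.0, 10)
        tf = tfr.tfr_transform(trials, small_bank)
        with pytest.raises(ValueError, match="baseline"):
            tfr.induced_power(tf)


class TestFrequencyTagging:
    def test_resolution_and_target_bins(self):
        trials = synth.gen_null_trials(20, 1, fs=128.0, seed=0)
        freqs, spec, tests = tfr.frequency_tagging(trials, seed=0)
        assert freqs[1] - freqs[0] == pytest.approx(1.0 / 15.0)
        assert 1.0 in freqs and 4.0 in freqs

    def test_modulated_drive_yields_significant_peak(self):
        truth = synth.GroundTruth(
            phase_lock_strength=0.9, lock_freq=4.0, lock_amp=2.0,
            alpha_amp=0.2, alpha_power_change=0.0,
            pac_amp=0.0, pac_modulation=0.0, noise_sd=0.5, seed=3,
        )
        trials = synth.gen_trials(truth, n_trials=150, n_channels=1, fs=128.0)
        _, _, tests = tfr.frequency_tagging(trials, n_trials_out=10, seed=1)
        t4, p4 = tests[4.0]
        assert t4 > 0 and p4 < 0.001

    def test_white_noise_mostly_non_significant(self):
        n_sig = 0
        runs = 20
        for i in range(runs):
            trials = synth.gen_null_trials(160, 1, fs=128.0, seed=100 + i)
            _, _, tests = tfr.frequency_tagging(trials, n_trials_out=10, seed=i)
            if tests[4.0][1] < 0.01 and tests[4.0][0] > 0:
                n_sig += 1
        assert n_sig <= runs * 0.10

    def test_non_multiple_concat_rejected(self):
        trials = synth.gen_null_trials(10, 1, fs=128.0, seed=0)
        with pytest.raises(ValueError):
            tfr.frequency_tagging(trials, concat_len=14.5)
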