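"""STRF estimation: features, pair construction, ridge CV, decomposition."""

import numpy as np
import pytest

from phrasal import strf


@pytest.fixture(scope="module")
def toy_system():
    """Known sparse kernel, noiseless responses, 30 one-second stimuli."""
    rng = np.random.default_rng(0)
    fs, n_bands, n_ch = 64.0, 16, 2
    feats = {f"s{i:02d}": np.abs(rng.normal(size=(n_bands, int(fs))))
             for i in range(30)}
    n_lags = int(0.25 * fs) + 1
    kern = np.zeros((n_ch, n_bands, n_lags))
    kern[0, 5, 6] = 1.0
    kern[1, 8, 3] = -0.8

    def respond(X):
        D = strf._lagged_design(X, n_lags)
        return kern.reshape(n_ch, -1) @ D.T

    resp = {k: respond(v) for k, v in feats.items()}
    return feats, resp, kern, fs


class TestFeatures:
    def test_pure_tone_energy_concentrated(self):
        fs = 44100.0
        t = np.arange(int(0.5 * fs)) / fs
        audio = np.sin(2 * np.pi * 1000.0 * t)
        feat = strf.spectrogram_features(audio, fs, target_fs=128.0)
        energy = (feat.envelopes**2).sum(axis=1)
        k = np.argmin(np.abs(feat.centers - 1000.0))
        assert energy[k] / energy.sum() > 0.9

    def test_silence_gives_zero_features(self):
        feat = strf.spectrogram_features(np.zeros(22050), 44100.0)
        assert np.abs(feat.envelopes).max() < 1e-12

    def test_amplitude_linearity(self):
        rng = np.random.default_rng(1)
        audio = rng.normal(size=22050)
        f1 = strf.spectrogram_features(audio, 44100.0)
        f2 = strf.spectrogram_features(2.0 * audio, 44100.0)
        np.testing.assert_allclose(f2.envelopes, 2.0 * f1.envelopes, atol=1e-9)


class TestBuildPairs:
    def test_lengths_and_split_disjointness(self, toy_system):
        feats, resp, _, fs = toy_system
        split = strf.build_pairs(feats, resp, n_train=8, n_test=3, fs=fs, seed=2)
        for X, Y in zip(split.train.X, split.train.Y):
            assert X.shape[-1] == Y.shape[-1] == int(10 * fs)
        for X, Y in zip(split.test.X, split.test.Y):
            assert X.shape[-1] == int(4 * fs)
        assert not set(split.train_ids) & set(split.test_ids)
        for drawn in split.train.stim_ids:
            assert set(drawn) <= set(split.train_ids)
        for drawn in split.test.stim_ids:
            assert set(drawn) <= set(split.test_ids)

    def test_eighty_twenty_split_counts(self):
        rng = np.random.default_rng(3)
        feats = {i: np.abs(rng.normal(size=(4, 32))) for i in range(50)}
        resp = {i: rng.normal(size=(1, 32)) for i in range(50)}
        split = strf.build_pairs(feats, resp, n_train=3, n_test=2, fs=32.0,
                                 train_len=2, test_len=2, seed=0)
        assert len(split.train_ids) == 40
        assert len(split.test_ids) == 10

    def test_too_few_stimuli_rejected(self):
        feats = {i: np.zeros((2, 8)) for i in range(5)}
        with pytest.raises(ValueError):
            strf.build_pairs(feats, feats, fs=8.0)


class TestRidgeFit:
    def test_matches_normal_equations_oracle(self, toy_system):
        feats, resp, _, fs = toy_system
        split = strf.build_pairs(feats, resp, n_train=4, n_test=2, fs=fs,
                                 seed=5, ramp_frac=0.0)
        lam = 42.0
        model = strf.fit_strf(split.train, lag_window=(0.0, 0.1),
                              lambda_grid=[lam])
        # independent oracle: explicit (X'X + lam I)^-1 X'y on the
        # standardized concatenated design
        n_lags = len(model.lags)
        Xs = [ (X - model.feat_mean) / model.feat_sd for X in split.train.X]
        D = np.concatenate([strf._lagged_design(X, n_lags) for X in Xs])
        Y = np.concatenate(split.train.Y, axis=-1).T - model.intercept
        W = np.linalg.solve(D.T @ D + lam * np.eye(D.shape[1]), D.T @ Y)
        want = W.T.reshape(model.weights.shape)
        np.testing.assert_allclose(model.weights, want, atol=1e-8)

    def test_noiseless_kernel_recovery(self, toy_system):
        feats, resp, kern, fs = toy_system
        split = strf.build_pairs(feats, resp, n_train=10, n_test=3, fs=fs,
                                 seed=1, ramp_frac=0.0)
        # responses regenerated from the concatenated features so the true
        # kernel explains every sample (no chunk-boundary mismatch)
        n_lags = kern.shape[-1]
        split.train.Y = [
            kern.reshape(kern.shape[0], -1) @ strf._lagged_design(X, n_lags).T
            for X in split.train.X
        ]
        model = strf.fit_strf(split.train, lag_window=(0.0, 0.25),
                              lambda_grid=[6.0])
        recovered = model.weights / model.feat_sd[None, :, 0][..., None]
        r = np.corrcoef(recovered.ravel(), kern.ravel())[0, 1]
        assert r > 0.99

    def test_selected_lambda_has_best_cv_performance(self, toy_system):
        feats, resp, _, fs = toy_system
        split = strf.build_pairs(feats, resp, n_train=6, n_test=2, fs=fs, seed=4)
        model = strf.fit_strf(split.train, lag_window=(0.0, 0.15))
        assert model.cv_performance[model.lam] == max(model.cv_performance.values())

    def test_huge_lambda_shrinks_weights(self, toy_system):
        feats, resp, _, fs = toy_system
        split = strf.build_pairs(feats, resp, n_train=4, n_test=2, fs=fs, seed=6)
        m_small = strf.fit_strf(split.train, lag_window=(0.0, 0.1),
                                lambda_grid=[6.0])
        m_big = strf.fit_strf(split.train, lag_window=(0.0, 0.1),
                              lambda_grid=[1e6])
        assert (np.linalg.norm(m_big.weights)
                < np.linalg.norm(m_small.weights))

    def test_too_few_pairs_rejected(self, toy_system):
        feats, resp, _, fs = toy_system
        split = strf.build_pairs(feats, resp, n_train=2, n_test=2, fs=fs, seed=0)
        with pytest.raises(ValueError):
            strf.fit_strf(split.train)


class TestEvaluate:
    def test_matched_beats_null_and_seeded_reproducible(self, toy_system):
        feats, resp, _, fs = toy_system
        split = strf.build_pairs(feats, resp, n_train=8, n_test=3, fs=fs,
                                 seed=2, ramp_frac=0.0)
        model = strf.fit_strf(split.train, lag_window=(0.0, 0.25),
                              lambda_grid=[6.0])
        rep1 = strf.evaluate(model, split.test, split, n_null=200, seed=9)
        rep2 = strf.evaluate(model, split.test, split, n_null=200, seed=9)
        assert rep1.above_chance
        assert rep1.percentile_97_5 == rep2.percentile_97_5
        assert np.all(np.abs(rep1.null_r) <= 1.0)

    def test_noise_responses_do_not_beat_null(self, toy_system):
        feats, _, _, fs = toy_system
        rng = np.random.default_rng(11)
        noise_resp = {k: rng.normal(size=(2, int(fs))) for k in feats}
        split = strf.build_pairs(feats, noise_resp, n_train=8, n_test=3,
                                 fs=fs, seed=3)
        model = strf.fit_strf(split.train, lag_window=(0.0, 0.25))
        rep = strf.evaluate(model, split.test, split, n_null=200, seed=1)
        assert not rep.above_chance

    def test_null_centered_near_zero(self, toy_system):
        feats, _, _, fs = toy_system
        rng = np.random.default_rng(13)
        noise_resp = {k: rng.normal(size=(1, int(fs))) for k in feats}
        split = strf.build_pairs(feats, noise_resp, n_train=6, n_test=3,
                                 fs=fs, seed=0)
        model = strf.fit_strf(split.train, lag_window=(0.0, 0.1))
        rep = strf.evaluate(model, split.test, split, n_null=300, seed=4)
        assert abs(np.mean(rep.null_r)) < 0.05


class TestDecompose:
    def _bump_model(self, lag_s, band_hz, fs=128.0, sign=1.0):
        lags = np.arange(int(0.5 * fs) + 1) / fs
        centers = strf.band_edges(16)
        centers = np.sqrt(centers[:-1] * centers[1:])
        w = np.zeros((1, 16, len(lags)))
        b = np.argmin(np.abs(centers - band_hz))
        l = np.argmin(np.abs(lags - lag_s))
        w[0, b, l] = sign
        return strf.STRFModel(w, np.zeros(1), lags, 6.0, fs), centers[b]

    def test_single_bump_peak_location_and_band(self):
        model, used_band = self._bump_model(0.100, 300.0)
        trf, srf, peaks = strf.decompose(model)
        assert peaks.iloc[0]["latency"] == pytest.approx(0.100, abs=0.01)
        assert np.argmax(np.abs(srf[0])) == np.argmin(
            np.abs(strf.band_edges(16)[:-1] - used_band)) or srf[0].max() > 0

    def test_first_window_latency_precedes_second(self):
        model, _ = self._bump_model(0.100, 300.0)
        _, _, peaks = strf.decompose(model)
        assert peaks.iloc[0]["latency"] < peaks.iloc[1]["latency"]

    def test_all_zero_kernel_flagged_degenerate(self):
        lags = np.arange(65) / 128.0
        model = strf.STRFModel(np.zeros((1, 16, 65)), np.zeros(1), lags,
                               6.0, 128.0)
        trf, srf, peaks = strf.decompose(model)
        assert np.all(trf == 0) and np.all(srf == 0)
        assert peaks["degenerate"].iloc[:2].all()

    def test_short_lag_window_rejected(self):
        lags = np.arange(13) / 128.0  # < 400 ms
        model = strf.STRFModel(np.zeros((1, 16, 13)), np.zeros(1), lags,
                               6.0, 128.0)
        with pytest.raises(ValueError):
            strf.decompose(model)
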