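"""Synthetic stimulus envelopes and multichannel trial data with planted truth.

Every downstream analysis in the package is exercised on data whose
structure is known exactly. :func:`gen_trials` plants, per the
:class:`GroundTruth` parameters:

* a stimulus-locked oscillation whose intertrial phase concentration
  equals ``phase_lock_strength`` (von Mises phase draws);
* a post-onset change of alpha-band amplitude equal to
  ``alpha_power_change`` dB relative to the pre-stimulus baseline;
* amplitude at ``pac_amp_freq`` modulated by the cosine of the
  ``pac_phase_freq`` phase with depth ``pac_modulation``;
* a response component equal to ``encoding_kernel`` convolved with the
  trial's 16-band stimulus envelope features;
* an inter-channel phase-lag structure (``connectivity_lag`` radians per
  channel applied to the locked oscillation);
* additive Gaussian white noise of SD ``noise_sd`` (optionally with a 1/f
  component).

:func:`gen_envelopes` produces syllable-like amplitude envelopes at 400 Hz
(Hann-windowed bursts of 140-230 ms), RMS-normalized to -16 dB full scale,
with phrase/sentence item pairs sharing burst onsets so that
acoustic-matching analyses pass by construction. :func:`gen_null_trials`
produces stationary noise satisfying the null of every test in the
package. All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import signal as sps

from phrasal.containers import EnvelopeSet, TrialTensor

__all__ = [
    "GroundTruth",
    "gen_envelopes",
    "gen_trials",
    "gen_null_trials",
    "vonmises_kappa",
    "save_ground_truth",
    "load_ground_truth",
]


def vonmises_kappa(r: float) -> float:
    """Concentration parameter giving mean resultant length ``r``.

    Piecewise approximation (Fisher, Statistical Analysis of Circular
    Data); accurate to ~1% over (0, 1).
    """
    if not 0 <= r <= 1:
        raise ValueError("resultant length must be in [0, 1]")
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    if r == 1.0:
        return np.inf
    return 1.0 / (r**3 - 4 * r**2 + 3 * r)


@dataclass
class GroundTruth:
    """Planted-effect parameters for :func:`gen_trials`.

    Amplitudes are in the same arbitrary units as ``noise_sd``; the seed
    fully determines the generated tensor.
    """

    phase_lock_strength: float = 0.5  # target ITPC in [0, 1]
    lock_freq: float = 2.0  # Hz of the stimulus-locked oscillation
    lock_amp: float = 1.0
    alpha_power_change: float = -3.0  # dB post-onset re baseline
    alpha_freq: float = 10.0
    alpha_amp: float = 1.0
    pac_modulation: float = 0.5  # in [0, 1]
    pac_phase_freq: float = 4.0
    pac_amp_freq: float = 40.0
    pac_amp: float = 0.5
    encoding_kernel: np.ndarray | None = None  # (n_channels, n_bands, n_lags)
    encoding_gain: float = 1.0
    connectivity_lag: np.ndarray | float = 0.0  # radians per channel
    noise_sd: float = 1.0
    pink_noise: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.phase_lock_strength <= 1:
            raise ValueError("phase_lock_strength must be in [0, 1]")
        if not 0 <= self.pac_modulation <= 1:
            raise ValueError("pac_modulation must be in [0, 1]")
        if self.encoding_kernel is not None:
            self.encoding_kernel = np.asarray(self.encoding_kernel, dtype=float)
            if self.encoding_kernel.ndim != 3:
                raise ValueError("encoding_kernel must be (channel, band, lag)")


def _burst_params(rng, n_times, fs, rate, duration_range=(0.140, 0.230)):
    """Random onsets, durations, and amplitudes: one burst per 1/rate window."""
    window = 1.0 / rate
    n_bursts = int(np.floor(n_times / fs * rate))
    lo = min(duration_range[0], 0.9 * window)
    hi = min(duration_range[1], window)
    durs = rng.uniform(lo, hi, n_bursts)
    onsets = np.arange(n_bursts) * window + rng.uniform(0, 1, n_bursts) * (window - durs)
    amps = rng.uniform(0.4, 1.0, n_bursts)
    return onsets, durs, amps


def _smooth_noise(rng, n_times, fs, scale_s=0.030):
    """Unit-variance Gaussian noise smoothed to a ~``scale_s`` time scale."""
    white = rng.normal(size=n_times)
    k = max(1, int(round(scale_s * fs)))
    kernel = np.hanning(2 * k + 1)
    kernel /= kernel.sum()
    out = np.convolve(white, kernel, mode="same")
    sd = out.std()
    return out / (sd if sd > 0 else 1.0)


def _render_bursts(n_times, fs, onsets, durs, amps):
    env = np.zeros(n_times)
    for onset, dur, amp in zip(onsets, durs, amps):
        i0 = int(round(onset * fs))
        n = max(2, int(round(dur * fs)))
        i1 = min(i0 + n, n_times)
        env[i0:i1] += np.hanning(n)[: i1 - i0] * amp
    return env


def _hann_burst_train(
    rng, n_times, fs, rate, onsets=None, duration_range=(0.140, 0.230)
):
    """Amplitude envelope made of Hann bursts, one per 1/rate window."""
    o, d, a = _burst_params(rng, n_times, fs, rate, duration_range)
    if onsets is not None:
        o = np.asarray(onsets)[: len(d)]
    return _render_bursts(n_times, fs, o, d, a), o


def gen_envelopes(
    n_items: int,
    duration: float,
    syllable_rate: float,
    seed: int | np.random.Generator = 0,
    fs: float = 400.0,
    rms_target_db: float = -16.0,
) -> EnvelopeSet:
    """Paired phrase/sentence amplitude envelopes at 400 Hz.

    Each item carries ``syllable_rate`` Hann-windowed bursts per second
    (duration 140-230 ms, clipped to the syllable window); the phrase and
    sentence member of a pair share identical burst onsets, durations, and
    (up to a small per-burst jitter) amplitudes, so the two conditions are
    acoustically matched by construction. Every envelope is RMS-normalized
    to ``rms_target_db`` dB full scale.
    """
    if duration <= 0 or syllable_rate <= 0:
        raise ValueError("duration and syllable_rate must be positive")
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    rng = np.random.default_rng(seed)
    n_times = int(round(duration * fs))
    target_rms = 10.0 ** (rms_target_db / 20.0)
    envs, labels = [], []
    for _ in range(n_items):
        onsets, durs, amps = _burst_params(rng, n_times, fs, syllable_rate)
        base = _render_bursts(n_times, fs, onsets, durs, amps)
        # item-specific fine structure (smooth random AM, ~30 ms scale),
        # shared within the pair up to a small jitter
        mod = _smooth_noise(rng, n_times, fs, scale_s=0.030)
        phrase = base * np.clip(1.0 + 0.5 * mod, 0.05, None)
        jitter = _smooth_noise(rng, n_times, fs, scale_s=0.030)
        sentence = base * np.clip(1.0 + 0.5 * mod + 0.05 * jitter, 0.05, None)
        for env, label in ((phrase, "phrase"), (sentence, "sentence")):
            rms = np.sqrt(np.mean(env**2))
            envs.append(env * target_rms / rms)
            labels.append(label)
    return EnvelopeSet(np.stack(envs), fs, np.array(labels), rms_target_db)


def _epoch_grid(fs, epoch_window):
    t0, t1 = epoch_window
    if t1 <= t0:
        raise ValueError("epoch window must be increasing")
    onset_index = int(round(-t0 * fs))
    n_times = int(round((t1 - t0) * fs))
    times = (np.arange(n_times) - onset_index) / fs
    return n_times, onset_index, times


def _pink(rng, shape, fs):
    """1/f-amplitude noise, unit variance, via spectral shaping."""
    white = rng.normal(size=shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(shape[-1], d=1.0 / fs)
    f[0] = f[1]
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n=shape[-1], axis=-1)
    return out / out.std(axis=-1, keepdims=True)


def gen_trials(
    truth: GroundTruth,
    n_trials: int = 60,
    n_channels: int = 4,
    fs: float = 256.0,
    epoch_window: tuple = (-1.0, 2.0),
    stim_duration: float = 1.0,
    n_bands: int = 16,
    syllable_rate: float = 4.0,
    condition: str = "stim",
) -> TrialTensor:
    """Generate trial-epoched multichannel data with the planted effects.

    The stimulus-locked, PAC, and encoding components live in the
    ``stim_duration`` seconds after onset; alpha activity is present
    throughout with its post-onset amplitude scaled by
    ``alpha_power_change`` dB. Stimulus features (the 16-band envelopes
    driving the encoding component) are returned in ``features``.
    """
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    rng = np.random.default_rng(truth.seed)
    n_times, onset_index, times = _epoch_grid(fs, epoch_window)
    if onset_index / fs < 0.8:
        raise ValueError("epoch must include >= 800 ms of pre-onset baseline")
    data = np.zeros((n_trials, n_channels, n_times))
    stim_mask = (times >= 0) & (times < stim_duration)
    lags = np.broadcast_to(
        np.atleast_1d(np.asarray(truth.connectivity_lag, dtype=float)),
        (n_channels,),
    )

    # (i) stimulus-locked oscillation with controlled phase concentration
    r = truth.phase_lock_strength
    if r >= 1.0:
        phases = np.zeros(n_trials)
    elif r <= 0.0:
        phases = rng.uniform(-np.pi, np.pi, n_trials)
    else:
        phases = rng.vonmises(0.0, vonmises_kappa(r), n_trials)
    arg = 2 * np.pi * truth.lock_freq * times[None, None, :]
    locked = truth.lock_amp * np.cos(
        arg + phases[:, None, None] + lags[None, :, None]
    )
    data += locked * stim_mask[None, None, :]

    # (ii) alpha activity, post-onset amplitude scaled in dB
    gain = 10.0 ** (truth.alpha_power_change / 20.0)
    alpha_phase = rng.uniform(-np.pi, np.pi, (n_trials, n_channels))
    alpha = np.cos(
        2 * np.pi * truth.alpha_freq * times[None, None, :]
        + alpha_phase[..., None]
    )
    amp = np.where(times >= 0, truth.alpha_amp * gain, truth.alpha_amp)
    data += alpha * amp[None, None, :]

    # (iii) phase-amplitude coupling inside the stimulus window
    slow_phase = rng.uniform(-np.pi, np.pi, (n_trials, n_channels))
    slow_arg = (2 * np.pi * truth.pac_phase_freq * times[None, None, :]
                + slow_phase[..., None])
    carrier_phase = rng.uniform(-np.pi, np.pi, (n_trials, n_channels))
    envelope = 1.0 + truth.pac_modulation * np.cos(slow_arg)
    pac_sig = truth.pac_amp * envelope * np.cos(
        2 * np.pi * truth.pac_amp_freq * times[None, None, :]
        + carrier_phase[..., None]
    )
    data += truth.pac_amp * np.cos(slow_arg) * stim_mask  # the slow rhythm itself
    data += pac_sig * stim_mask[None, None, :]

    # (iv) encoding component: kernel convolved with 16-band features
    features = np.zeros((n_trials, n_bands, n_times))
    n_stim = int(round(stim_duration * fs))
    for tr in range(n_trials):
        base, onsets = _hann_burst_train(rng, n_stim, fs, syllable_rate)
        for b in range(n_bands):
            mod, _ = _hann_burst_train(rng, n_stim, fs, syllable_rate,
                                       onsets=onsets)
            features[tr, b, onset_index:onset_index + n_stim] = (
                0.5 * base + 0.5 * mod
            )
    if truth.encoding_kernel is not None:
        kern = truth.encoding_kernel
        if kern.shape[0] != n_channels or kern.shape[1] != n_bands:
            raise ValueError(
                "encoding_kernel shape must match (n_channels, n_bands, lags)"
            )
        n_lags = kern.shape[2]
        for tr in range(n_trials):
            design = np.stack(
                [np.roll(features[tr], l, axis=-1) for l in range(n_lags)], -1
            )
            for l in range(n_lags):
                design[:, :l, l] = 0.0
            data[tr] += truth.encoding_gain * np.einsum(
                "cbl,btl->ct", kern, design
            )

    # (v) background noise
    if truth.noise_sd > 0:
        data += truth.noise_sd * rng.normal(size=data.shape)
        if truth.pink_noise:
            data += truth.noise_sd * _pink(rng, data.shape, fs)

    return TrialTensor(
        data, fs, onset_index,
        np.array([condition] * n_trials), features,
    )


def gen_null_trials(
    n_trials: int,
    n_channels: int,
    fs: float = 256.0,
    seed: int | np.random.Generator = 0,
    epoch_window: tuple = (-1.0, 2.0),
) -> TrialTensor:
    """Stationary white noise with no condition-dependent structure."""
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    rng = np.random.default_rng(seed)
    n_times, onset_index, _ = _epoch_grid(fs, epoch_window)
    data = rng.normal(size=(n_trials, n_channels, n_times))
    return TrialTensor(data, fs, onset_index)


def envelopes_to_wav(env: EnvelopeSet, directory, fs_out: float | None = None) -> list:
    """Write each envelope to a 16-bit mono WAV file; returns the paths."""
    from pathlib import Path

    from scipy.io import wavfile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fs_out = int(fs_out or env.fs)
    paths = []
    for i, (e, label) in enumerate(zip(env.envelopes, env.condition)):
        if fs_out != env.fs:
            g = np.gcd(int(fs_out), int(env.fs))
            e = sps.resample_poly(e, int(fs_out) // g, int(env.fs) // g)
        scaled = np.clip(e / max(np.abs(e).max(), 1e-12), -1, 1)
        path = directory / f"{label}_{i:03d}.wav"
        wavfile.write(path, fs_out, (scaled * 32767).astype(np.int16))
        paths.append(path)
    return paths


def save_ground_truth(truth: GroundTruth, path) -> None:
    with h5py.File(path, "w") as f:
        for k, v in vars(truth).items():
            if v is None:
                continue
            if isinstance(v, np.ndarray):
                f.create_dataset(k, data=v)
            else:
                f.attrs[k] = v


def load_ground_truth(path) -> GroundTruth:
    kwargs = {}
    with h5py.File(path, "r") as f:
        kwargs.update({k: f.attrs[k] for k in f.attrs})
        for k in f:
            kwargs[k] = f[k][()]
    if "pink_noise" in kwargs:
        kwargs["pink_noise"] = bool(kwargs["pink_noise"])
    return GroundTruth(**kwargs)
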