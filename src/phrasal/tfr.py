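"""Morlet wavelet time-frequency decomposition and derived readouts.

Single-trial epochs are convolved with a bank of complex Morlet wavelets
(by default 70 log-spaced center frequencies from 1 to 50 Hz whose cycle
counts grow log-spaced from 3 to 30, trading temporal for spectral
resolution with frequency). From the complex coefficients the module
derives intertrial phase coherence (ITPC; the resultant length of
unit-normalized coefficients across trials), induced power in dB relative
to a pre-stimulus baseline, and frequency-tagging spectra of concatenated
responses.

Wavelets are normalized so that a unit-amplitude sinusoid at a center
frequency yields coefficients of magnitude 1 at that frequency, making
magnitudes comparable across the bank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from phrasal.containers import TrialTensor

__all__ = [
    "WaveletBank",
    "TFRTensor",
    "tfr_transform",
    "itpc",
    "induced_power",
    "frequency_tagging",
]

BASELINE_WINDOW = (-0.8, -0.2)  # seconds relative to onset


@dataclass
class WaveletBank:
    """Log-spaced Morlet bank; cycles matched index-wise to frequencies."""

    freqs: np.ndarray = field(
        default_factory=lambda: np.geomspace(1.0, 50.0, 70)
    )
    cycles: np.ndarray = field(
        default_factory=lambda: np.geomspace(3.0, 30.0, 70)
    )

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.cycles = np.asarray(self.cycles, dtype=float)
        if self.freqs.shape != self.cycles.shape:
            raise ValueError("freqs and cycles must have equal length")
        if np.any(np.diff(self.freqs) <= 0) or np.any(np.diff(self.cycles) < 0):
            raise ValueError("freqs must be strictly increasing, cycles nondecreasing")

    @property
    def sigma_t(self) -> np.ndarray:
        """Temporal SD (s) of each wavelet's Gaussian envelope."""
        return self.cycles / (2 * np.pi * self.freqs)

    def nearest(self, freq: float) -> int:
        """Index of the center frequency closest to ``freq``."""
        return int(np.argmin(np.abs(self.freqs - freq)))

    @classmethod
    def subset(cls, freqs) -> "WaveletBank":
        """Bank restricted to the default-bank wavelets nearest ``freqs``."""
        full = cls()
        idx = sorted({full.nearest(f) for f in np.atleast_1d(freqs)})
        return cls(full.freqs[idx], full.cycles[idx])


@dataclass
class TFRTensor:
    """Complex wavelet coefficients (trial x channel x freq x time)."""

    coeffs: np.ndarray
    freqs: np.ndarray
    times: np.ndarray  # seconds relative to onset
    fs: float
    valid: np.ndarray = None  # (freq, time) bool; False inside edge zones

    def __post_init__(self):
        if self.valid is None:
            self.valid = np.ones(self.coeffs.shape[2:], dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.coeffs.shape[0]

    def time_mask(self, t0: float, t1: float) -> np.ndarray:
        return (self.times >= t0) & (self.times <= t1)


def _morlet_fft(freqs, cycles, fs, n_fft):
    """FFT of the wavelet bank, peak-normalized per wavelet.

    Normalizing the wavelet spectrum to 2 at the center frequency makes a
    unit-amplitude real sinusoid produce coefficients of magnitude 1.
    """
    fftfreq = np.fft.fftfreq(n_fft, d=1.0 / fs)
    sigma_t = cycles / (2 * np.pi * freqs)
    sigma_f = 1.0 / (2 * np.pi * sigma_t)
    w = np.exp(-0.5 * ((fftfreq[None, :] - freqs[:, None]) / sigma_f[:, None]) ** 2)
    w *= 2.0 / w.max(axis=1, keepdims=True)
    return w


def tfr_transform(trials: TrialTensor, bank: WaveletBank | None = None) -> TFRTensor:
    """Convolve single-trial time series with the complex wavelet bank.

    Convolution is done in the frequency domain. Samples within 3 temporal
    SDs of either epoch edge for a given wavelet are flagged invalid in
    ``valid`` rather than dropped.
    """
    bank = bank or WaveletBank()
    if trials.fs < 2 * bank.freqs.max():
        raise ValueError(
            f"fs={trials.fs} too low for max analysis frequency {bank.freqs.max()}"
        )
    data = trials.data
    n_times = data.shape[-1]
    n_fft = int(2 ** np.ceil(np.log2(2 * n_times)))
    wfft = _morlet_fft(bank.freqs, bank.cycles, trials.fs, n_fft)
    dfft = np.fft.fft(data, n=n_fft, axis=-1)
    prod = dfft[:, :, None, :] * wfft[None, None, :, :]
    coeffs = np.fft.ifft(prod, axis=-1)[..., :n_times]
    edge = np.ceil(3 * bank.sigma_t * trials.fs).astype(int)
    valid = np.ones((len(bank.freqs), n_times), dtype=bool)
    for i, e in enumerate(edge):
        e = min(e, n_times)
        valid[i, :e] = False
        if e > 0:
            valid[i, n_times - e:] = False
    return TFRTensor(coeffs, bank.freqs.copy(), trials.times, trials.fs, valid)


def itpc(tfr: TFRTensor) -> np.ndarray:
    """Intertrial phase coherence, (channel x freq x time) in [0, 1].

    Coefficients are divided by their magnitude and averaged across trials;
    the magnitude of the average is the ITPC. Bins where any trial has a
    zero-magnitude coefficient are returned as NaN (missing), not 0.
    """
    if tfr.n_trials < 2:
        raise ValueError("ITPC requires at least 2 trials")
    mag = np.abs(tfr.coeffs)
    bad = (mag == 0).any(axis=0)
    mag = np.where(mag == 0, 1.0, mag)
    out = np.abs((tfr.coeffs / mag).mean(axis=0))
    out[bad] = np.nan
    return out


def induced_power(
    tfr: TFRTensor, baseline: tuple = BASELINE_WINDOW
) -> np.ndarray:
    """Trial-averaged power in dB relative to the pre-onset baseline.

    Power is the squared coefficient magnitude averaged over trials; each
    (channel, frequency) is converted to ``10*log10(power / baseline)``
    where the baseline is the mean power over ``baseline`` seconds
    (default -800 to -200 ms).
    """
    t0, t1 = baseline
    bmask = tfr.time_mask(t0, t1)
    if not bmask.any():
        raise ValueError("baseline window outside epoch")
    power = (np.abs(tfr.coeffs) ** 2).mean(axis=0)  # (ch, freq, time)
    base = power[:, :, bmask].mean(axis=-1, keepdims=True)
    if np.any(base == 0):
        raise ValueError("zero baseline power; dB conversion undefined")
    return 10.0 * np.log10(power / base)


def frequency_tagging(
    trials: TrialTensor,
    concat_len: float = 15.0,
    n_trials_out: int = 40,
    flank_bins: int = 5,
    tag_freqs=(1.0, 4.0),
    epoch_len: float = 1.0,
    seed: int | np.random.Generator = 0,
):
    """Frequency tagging of concatenated 1-s responses.

    Builds ``n_trials_out`` long trials, each the concatenation of
    ``concat_len`` randomly selected ``epoch_len``-second post-onset
    responses, computes the amplitude spectrum of each, and runs a paired t
    test per tag frequency of the target-bin response against the mean of
    ``flank_bins`` flanking bins on each side.

    Returns ``(freqs, spectra, tests)`` where ``spectra`` is
    (n_trials_out, n_channels, n_bins) in dB relative to the mean spectrum,
    and ``tests`` maps tag frequency to ``(t, p)`` computed on the
    channel-averaged spectra.
    """
    n_chunks = concat_len / epoch_len
    if abs(n_chunks - round(n_chunks)) > 1e-9:
        raise ValueError("concat_len must be a multiple of the epoch length")
    n_chunks = int(round(n_chunks))
    rng = np.random.default_rng(seed)
    nsamp = int(round(epoch_len * trials.fs))
    post = trials.data[:, :, trials.onset_index: trials.onset_index + nsamp]
    if post.shape[-1] < nsamp:
        raise ValueError("epoch too short for the requested 1-s response")
    long_trials = np.empty((n_trials_out, trials.n_channels, n_chunks * nsamp))
    # Chunk reuse matters for the t test: repeating an epoch within one long
    # trial inflates the integer-Hz bins, and sharing epochs across long
    # trials makes them dependent. With enough epochs each one is used at
    # most once globally; otherwise we fall back to per-trial sampling
    # without replacement (the t test is then anti-conservative).
    if trials.n_trials >= n_trials_out * n_chunks:
        perm = rng.permutation(trials.n_trials)[: n_trials_out * n_chunks]
        chunk_idx = perm.reshape(n_trials_out, n_chunks)
    else:
        replace = trials.n_trials < n_chunks
        chunk_idx = np.stack([
            rng.choice(trials.n_trials, size=n_chunks, replace=replace)
            for _ in range(n_trials_out)
        ])
    for i in range(n_trials_out):
        long_trials[i] = np.concatenate(post[chunk_idx[i]], axis=-1)
    spec = np.abs(np.fft.rfft(long_trials, axis=-1))
    freqs = np.fft.rfftfreq(long_trials.shape[-1], d=1.0 / trials.fs)
    ref = spec.mean(axis=(0, 2), keepdims=True)
    ref = np.where(ref == 0, 1.0, ref)
    spectra_db = 20.0 * np.log10(np.where(spec == 0, np.finfo(float).tiny, spec) / ref)
    tests = {}
    chan_avg = spectra_db.mean(axis=1)  # (n_trials_out, n_bins)
    for f in tag_freqs:
        k = int(np.argmin(np.abs(freqs - f)))
        flanks = np.r_[k - flank_bins: k, k + 1: k + 1 + flank_bins]
        flanks = flanks[(flanks >= 0) & (flanks < len(freqs))]
        res = stats.ttest_rel(chan_avg[:, k], chan_avg[:, flanks].mean(axis=1))
        tests[f] = (float(res.statistic), float(res.pvalue))
    return freqs, spectra_db, tests
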