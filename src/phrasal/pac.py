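"""Phase-amplitude coupling over a phase x amplitude frequency grid.

The raw coupling statistic is the mean vector length: the magnitude of the
time-average of the high-frequency amplitude envelope attached as a weight
to the low-frequency phase phasor, ``|mean(amp(t) * exp(i*phase(t)))|``.
Because the raw value scales with amplitude, each bin is z-normalized
against a permutation null built by circularly shifting the amplitude
series by random offsets (PAC-Z). Significance over the grid uses a
Bonferroni-corrected one-tailed normal threshold.

The default grid follows the analysis convention of 11 linearly spaced
phase frequencies (1-16 Hz, step 1.5) by 12 log-spaced amplitude
frequencies (8-50 Hz), evaluated from 50 ms before to 1500 ms after
stimulus onset with 1000 permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from phrasal.containers import TrialTensor
from phrasal.tfr import WaveletBank, tfr_transform

__all__ = [
    "PHASE_FREQS",
    "AMP_FREQS",
    "PAC_WINDOW",
    "PACGrid",
    "pac_raw",
    "pac_z",
    "bonferroni_z",
    "pac_grid",
]

PHASE_FREQS = np.arange(1.0, 16.0 + 1e-9, 1.5)  # 11 values
AMP_FREQS = np.geomspace(8.0, 50.0, 12)
PAC_WINDOW = (-0.05, 1.5)  # seconds around onset


def pac_raw(phase_series: np.ndarray, amp_series: np.ndarray) -> float:
    """Mean-vector-length coupling of a phase series (radians) and an
    amplitude series; all-zero amplitude gives a valid 0."""
    phase_series = np.asarray(phase_series, dtype=float)
    amp_series = np.asarray(amp_series, dtype=float)
    if phase_series.shape != amp_series.shape:
        raise ValueError("phase and amplitude series must have equal length")
    if phase_series.size < 100:
        raise ValueError("series too short (< 100 samples) for a stable PAC")
    return float(np.abs(np.mean(amp_series * np.exp(1j * phase_series))))


def pac_z(
    phase_series: np.ndarray,
    amp_series: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation z-score of the raw PAC.

    The null re-pairs the phase series with the amplitude series circularly
    shifted by a random offset of at least one sample, ``n_perm`` times;
    z = (observed - null mean) / null SD. Returns NaN when the null SD is 0
    (degenerate, e.g. constant amplitude).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    observed = pac_raw(phase_series, amp_series)
    n = len(amp_series)
    offsets = rng.integers(1, n, size=n_perm)
    phasor = np.exp(1j * np.asarray(phase_series))
    # PAC of shifted amplitude = |sum over t of amp[(t - k) % n] e^{i phase t}| / n
    idx = (np.arange(n)[None, :] - offsets[:, None]) % n
    null = np.abs((np.asarray(amp_series)[idx] * phasor[None, :]).mean(axis=1))
    sd = null.std()
    # degenerate null (constant amplitude, or perfectly periodic series where
    # every shift reproduces the same coupling): z is not defined
    if sd <= 1e-12 * max(null.mean(), 1e-300):
        return float("nan")
    return float((observed - null.mean()) / sd)


def bonferroni_z(alpha: float, n_tests: int) -> float:
    """One-tailed standard-normal quantile at ``alpha / n_tests``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(stats.norm.isf(alpha / n_tests))


@dataclass
class PACGrid:
    """Raw PAC and PAC-Z per (channel, phase frequency, amplitude frequency)."""

    raw: np.ndarray
    z: np.ndarray
    phase_freqs: np.ndarray = field(default_factory=lambda: PHASE_FREQS.copy())
    amp_freqs: np.ndarray = field(default_factory=lambda: AMP_FREQS.copy())
    window: tuple = PAC_WINDOW
    n_perm: int = 1000

    def significant(self, alpha: float = 0.05, n_conditions: int = 4) -> np.ndarray:
        """Boolean mask of bins above the Bonferroni z threshold."""
        n_tests = len(self.phase_freqs) * len(self.amp_freqs) * n_conditions
        return self.z > bonferroni_z(alpha, n_tests)


def pac_grid(
    trials: TrialTensor,
    phase_freqs: np.ndarray = PHASE_FREQS,
    amp_freqs: np.ndarray = AMP_FREQS,
    window: tuple = PAC_WINDOW,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> PACGrid:
    """PAC-Z over the full phase x amplitude grid for every channel.

    Phase and amplitude series come from the wavelet bank at the nearest
    center frequencies, restricted to ``window`` and concatenated across
    trials; the amplitude shift of the permutation null is drawn per
    permutation on the concatenated series.
    """
    rng = np.random.default_rng(seed)
    all_freqs = np.concatenate([phase_freqs, amp_freqs])
    bank = WaveletBank.subset(all_freqs)
    tf = tfr_transform(trials, bank)
    tmask = tf.time_mask(*window)
    coeffs = tf.coeffs[..., tmask]  # (trial, ch, freq, time)
    n_tr, n_ch = coeffs.shape[:2]
    phase_idx = [bank.nearest(f) for f in phase_freqs]
    amp_idx = [bank.nearest(f) for f in amp_freqs]
    raw = np.empty((n_ch, len(phase_freqs), len(amp_freqs)))
    z = np.empty_like(raw)
    for ch in range(n_ch):
        for i, pi in enumerate(phase_idx):
            phase = np.angle(coeffs[:, ch, pi]).reshape(-1)
            for j, ai in enumerate(amp_idx):
                amp = np.abs(coeffs[:, ch, ai]).reshape(-1)
                raw[ch, i, j] = pac_raw(phase, amp)
                z[ch, i, j] = pac_z(phase, amp, n_perm=n_perm, seed=rng)
    return PACGrid(raw, z, np.asarray(phase_freqs), np.asarray(amp_freqs),
                   window, n_perm)
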