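"""Phase and power connectivity across channel pairs, with graph thresholding.

Phase connectivity (intersite phase clustering, ISPC) is the resultant
length across trials of the unit-normalized cross-spectral density between
two channels at each time-frequency bin. Power connectivity is the Spearman
rank correlation across trials between two channels' power values at a bin.

Either connectivity stack can be reduced to a degree map: at every
time-frequency bin the pairwise values of both conditions are pooled, a
threshold of median + 0.5 SD of the pool is applied (strictly greater
than), and the count of super-threshold pairs (the graph degree) is
baseline-normalized to percent change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from phrasal.tfr import BASELINE_WINDOW, TFRTensor

__all__ = [
    "ConnectivityStack",
    "DegreeMap",
    "ispc",
    "power_connectivity",
    "threshold_degree",
    "seed_connectivity_export",
    "select_top_channels",
]


@dataclass
class ConnectivityStack:
    """Symmetric channel x channel x freq x time connectivity values."""

    values: np.ndarray
    kind: str  # "phase" or "power"
    freqs: np.ndarray = None
    times: np.ndarray = None

    def __post_init__(self):
        if self.kind not in ("phase", "power"):
            raise ValueError("kind must be 'phase' or 'power'")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def pair_values(self) -> np.ndarray:
        """Upper-triangle pair values, shape (n_pairs, freq, time)."""
        iu = np.triu_indices(self.n_channels, k=1)
        return self.values[iu]


@dataclass
class DegreeMap:
    """Super-threshold connection counts per time-frequency bin."""

    counts: np.ndarray  # (freq, time) global counts
    counts_per_channel: np.ndarray  # (channel, freq, time)
    percent_change: np.ndarray  # (freq, time), % relative to baseline mean
    threshold: np.ndarray  # (freq, time)
    binary: np.ndarray  # (channel, channel, freq, time) bool


def ispc(tfr: TFRTensor) -> ConnectivityStack:
    """Intersite phase clustering for all channel pairs.

    The cross-spectral density (one channel's coefficient times the
    conjugate of the other's) is unit-normalized per trial-frequency-time
    bin and averaged across trials; its magnitude is the ISPC. Bins with a
    zero-magnitude CSD in any trial are NaN.
    """
    if tfr.n_trials < 2:
        raise ValueError("ISPC requires at least 2 trials")
    mag = np.abs(tfr.coeffs)
    safe = np.where(mag == 0, 1.0, mag)
    unit = tfr.coeffs / safe  # unit phasors per trial/channel/freq/time
    n_ch = unit.shape[1]
    out = np.empty((n_ch, n_ch) + unit.shape[2:])
    for a in range(n_ch):
        # csd phasor of (a,b) = phasor_a * conj(phasor_b)
        csd = unit[:, a, None] * np.conj(unit[:, a:])
        vals = np.abs(csd.mean(axis=0))
        bad = (mag[:, a, None] == 0).any(axis=0) | (mag[:, a:] == 0).any(axis=0)
        vals[bad] = np.nan
        out[a, a:] = vals
        out[a:, a] = vals
    return ConnectivityStack(out, "phase", tfr.freqs, tfr.times)


def power_connectivity(power: np.ndarray, freqs=None, times=None) -> ConnectivityStack:
    """Spearman correlation across trials of per-bin power between channels.

    ``power`` is (trial, channel, freq, time). Pairs with constant power
    across trials at a bin are NaN (rank correlation undefined).
    """
    if power.shape[0] < 3:
        raise ValueError("power connectivity requires at least 3 trials")
    ranks = stats.rankdata(power, axis=0)
    ranks = ranks - ranks.mean(axis=0, keepdims=True)
    norm = np.sqrt((ranks**2).sum(axis=0))
    constant = norm == 0
    norm = np.where(constant, 1.0, norm)
    z = ranks / norm
    n_ch = z.shape[1]
    out = np.einsum("tafx,tbfx->abfx", z, z)
    bad = constant[:, None] | constant[None, :]
    out[bad] = np.nan
    np.clip(out, -1.0, 1.0, out=out)
    return ConnectivityStack(out, "power", freqs, times)


def threshold_degree(
    stack_a: ConnectivityStack,
    stack_b: ConnectivityStack,
    times: np.ndarray,
    baseline: tuple = BASELINE_WINDOW,
) -> tuple:
    """Threshold two conditions' stacks into degree maps.

    At each frequency-time bin, the pairwise values of BOTH conditions are
    pooled; the threshold is the pool's median plus half its standard
    deviation; each condition's pair values are binarized at strictly
    greater than the threshold. The global degree (super-threshold pair
    count) is converted to percent change relative to the mean degree in
    the baseline window.

    Returns ``(degree_a, degree_b)``.
    """
    if stack_a.values.shape != stack_b.values.shape:
        raise ValueError("conditions must have identical shapes")
    pooled = np.concatenate([stack_a.pair_values(), stack_b.pair_values()])
    if pooled.size == 0:
        raise ValueError("empty pooled distribution")
    thresh = np.nanmedian(pooled, axis=0) + 0.5 * np.nanstd(pooled, axis=0)
    bmask = (times >= baseline[0]) & (times <= baseline[1])

    def one(stack):
        vals = stack.values
        binary = vals > thresh  # NaNs compare False
        iu = np.triu_indices(stack.n_channels, k=1)
        counts = binary[iu].sum(axis=0)
        per_channel = binary.sum(axis=1)
        base = counts[:, bmask].mean(axis=-1, keepdims=True)
        pct = np.where(base == 0, np.nan, 100.0 * (counts - base) / base)
        return DegreeMap(counts, per_channel, pct, thresh, binary)

    return one(stack_a), one(stack_b)


def seed_connectivity_export(binary: np.ndarray, seeds) -> np.ndarray:
    """Mean binary connection strength from a seed channel set to each channel.

    ``binary`` is (channel, channel, ...); returns (channel, ...) profiles
    averaged over the seed rows.
    """
    seeds = np.atleast_1d(seeds)
    if seeds.size == 0:
        raise ValueError("empty seed set")
    return np.asarray(binary, dtype=float)[seeds].mean(axis=0)


def select_top_channels(metric_map: np.ndarray, k: int, hemisphere_map=None):
    """Indices of the ``k`` channels with the largest metric, per hemisphere.

    ``metric_map`` is (channel,); ``hemisphere_map`` optionally assigns each
    channel a label, in which case a dict label -> indices is returned.
    """
    metric_map = np.asarray(metric_map, dtype=float)
    if hemisphere_map is None:
        return np.argsort(metric_map)[::-1][:k]
    hemisphere_map = np.asarray(hemisphere_map)
    out = {}
    for label in np.unique(hemisphere_map):
        idx = np.flatnonzero(hemisphere_map == label)
        order = idx[np.argsort(metric_map[idx])[::-1]]
        out[label] = order[:k]
    return out
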