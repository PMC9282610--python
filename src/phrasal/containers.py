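"""Shared in-memory containers for epoched time series and stimulus envelopes."""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np


@dataclass
class TrialTensor:
    """Trial-epoched multichannel time series.

    Attributes
    ----------
    data : ndarray, shape (n_trials, n_channels, n_times)
        Signal in arbitrary units.
    fs : float
        Sampling rate in Hz.
    onset_index : int
        Sample index of stimulus onset within the epoch.
    condition : ndarray of str, shape (n_trials,)
        Condition label per trial.
    features : ndarray or None, shape (n_trials, n_bands, n_times)
        Optional stimulus features aligned to the epoch (used by the
        encoding-model analyses; zero before onset).
    """

    data: np.ndarray
    fs: float
    onset_index: int
    condition: np.ndarray = field(default=None)
    features: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_times)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("trial data contains non-finite samples")
        if self.condition is None:
            self.condition = np.array(["stim"] * self.data.shape[0])
        self.condition = np.asarray(self.condition)
        if self.condition.shape[0] != self.data.shape[0]:
            raise ValueError("one condition label per trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds relative to stimulus onset."""
        return (np.arange(self.n_times) - self.onset_index) / self.fs

    def baseline_ok(self, min_pre: float = 0.8) -> bool:
        """Whether the epoch holds at least ``min_pre`` seconds before onset."""
        return self.onset_index / self.fs >= min_pre

    def select(self, condition: str) -> "TrialTensor":
        mask = self.condition == condition
        if not mask.any():
            raise ValueError(f"no trials with condition {condition!r}")
        feats = self.features[mask] if self.features is not None else None
        return TrialTensor(
            self.data[mask], self.fs, self.onset_index, self.condition[mask], feats
        )

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.attrs["fs"] = self.fs
            f.attrs["onset_index"] = self.onset_index
            f.create_dataset(
                "condition", data=np.asarray(self.condition, dtype="S")
            )
            if self.features is not None:
                f.create_dataset("features", data=self.features)

    @classmethod
    def from_hdf5(cls, path) -> "TrialTensor":
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            fs = float(f.attrs["fs"])
            onset = int(f.attrs["onset_index"])
            condition = f["condition"][()].astype(str)
            features = f["features"][()] if "features" in f else None
        return cls(data, fs, onset, condition, features)


@dataclass
class EnvelopeSet:
    """Per-item amplitude envelopes, conventionally sampled at 400 Hz."""

    envelopes: np.ndarray  # (n_items, n_times), all >= 0
    fs: float
    condition: np.ndarray = field(default=None)
    rms_target_db: float = -16.0

    def __post_init__(self):
        self.envelopes = np.atleast_2d(np.asarray(self.envelopes, dtype=float))
        if self.condition is None:
            self.condition = np.array(["item"] * self.envelopes.shape[0])
        self.condition = np.asarray(self.condition)

    @property
    def n_items(self) -> int:
        return self.envelopes.shape[0]

    def select(self, condition: str) -> "EnvelopeSet":
        mask = self.condition == condition
        return EnvelopeSet(
            self.envelopes[mask], self.fs, self.condition[mask], self.rms_target_db
        )
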