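"""Epoched multichannel EEG container.

The :class:`EpochSet` is the in-memory currency of the package: a stack of
fixed-length trials (``trials x channels x samples``) with integer class
labels, channel names in canonical montage order, and the sampling rate.
Trial identifiers survive subsetting so that augmentation provenance can be
audited against the trials that were actually available for training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["EpochSet"]


@dataclass
class EpochSet:
    """Trials x channels x samples EEG epochs with labels.

    Parameters
    ----------
    data
        Array of shape ``(n_trials, n_channels, n_samples)``.
    labels
        Integer class label per trial, shape ``(n_trials,)``.
    channel_names
        Channel labels in the canonical order of the channel axis.
    fs
        Sampling rate in Hz.
    trial_ids
        Stable per-trial identifiers (default ``0..n-1``); preserved by
        :meth:`subset` so provenance can refer to trials of the parent set.
    subject
        Optional subject index the trials belong to.
    """

    data: np.ndarray
    labels: np.ndarray
    channel_names: tuple[str, ...]
    fs: float
    trial_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    subject: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (trials, channels, samples), got shape {self.data.shape}")
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError("labels must be one integer per trial")
        self.channel_names = tuple(str(c) for c in self.channel_names)
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[1]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.trial_ids is None:
            self.trial_ids = np.arange(self.data.shape[0])
        else:
            self.trial_ids = np.asarray(self.trial_ids)
            if self.trial_ids.shape != (self.data.shape[0],):
                raise ValueError("trial_ids must be one id per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def classes(self) -> np.ndarray:
        """Sorted unique class labels present."""
        return np.unique(self.labels)

    def class_indices(self, label: int) -> np.ndarray:
        """Positional indices of trials with the given label."""
        return np.flatnonzero(self.labels == label)

    def subset(self, indices: np.ndarray | list[int]) -> "EpochSet":
        """Select trials by position, keeping their original trial ids."""
        idx = np.asarray(indices)
        return replace(
            self,
            data=self.data[idx],
            labels=self.labels[idx],
            trial_ids=self.trial_ids[idx],
        )

    def copy(self) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy(),
            labels=self.labels.copy(),
            trial_ids=self.trial_ids.copy(),
        )
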