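"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class Recording:
    """A labeled multichannel EEG recording.

    data is a real [n_channels x n_samples] matrix in microvolts. reference
    names the recording reference (an electrode label such as "A1", or
    "average" after re-referencing). annotations are (start_s, end_s, text)
    triples carried through preprocessing.
    """

    channel_names: list[str]
    fs: float
    data: np.ndarray
    reference: str = "A1"
    annotations: list[tuple[float, float, str]] = field(default_factory=list)
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D [channels x samples]")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{len(self.channel_names)} channel names but "
                f"{self.data.shape[0]} data rows"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if np.isnan(self.data).any():
            raise ValueError("data contains NaNs")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **changes) -> "Recording":
        if "data" not in changes:
            changes["data"] = self.data.copy()
        return replace(self, **changes)


@dataclass
class EpochSet:
    """Non-overlapping fixed-length windows cut from one recording.

    epochs is [n_epochs x n_channels x n_times]; each epoch is exactly
    ``epoch_s`` seconds (n_times = fs * epoch_s).
    """

    epochs: np.ndarray
    fs: float
    channel_names: list[str]
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D [epochs x channels x times]")
        if self.epochs.shape[1] != len(self.channel_names):
            raise ValueError("channel count mismatch")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_times(self) -> int:
        return self.epochs.shape[2]

    def concatenated(self) -> np.ndarray:
        """Epochs re-joined along time: [n_channels x n_epochs*n_times]."""
        return np.concatenate(list(self.epochs), axis=1) if self.n_epochs else (
            np.empty((self.n_channels, 0))
        )
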