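"""Shared in-memory containers for multichannel recordings and epochs."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class Recording:
    """Continuous multichannel signal.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Montage channel names, one per row of ``signal``.
    """

    signal: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def with_signal(self, signal: np.ndarray) -> "Recording":
        """Copy of this recording (subclass-preserving) with a new signal array."""
        return replace(self, signal=signal)


@dataclass
class EpochSet:
    """Stack of fixed-length epochs with time-on-task block assignments.

    ``data`` has shape (n_epochs, n_channels, n_samples_per_epoch).
    ``block_labels`` holds the time-on-task level (1, 2, 3, ...) of each
    epoch; ``kept_mask`` marks epochs that survived artifact rejection.
    """

    data: np.ndarray
    fs: float
    block_labels: np.ndarray
    kept_mask: np.ndarray = None  # type: ignore[assignment]
    channel_labels: list[str] = field(default_factory=list)
    epoch_len_ms: float = 1200.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (epochs x channels x samples)")
        self.block_labels = np.asarray(self.block_labels, dtype=int)
        if self.block_labels.shape != (self.n_epochs,):
            raise ValueError("block_labels must have one entry per epoch")
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.n_epochs, dtype=bool)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(self.data.shape[1])]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def kept(self, block: int | None = None) -> np.ndarray:
        """Kept epochs, optionally restricted to one time-on-task block."""
        mask = self.kept_mask.copy()
        if block is not None:
            mask &= self.block_labels == block
        return self.data[mask]
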