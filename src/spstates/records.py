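"""Core containers for multichannel EEG recordings and fixed-length epochs.

Amplitudes are microvolts throughout; arrays are channels x samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(eq=False)
class EEGRecord:
    """A continuous multichannel EEG recording.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        10/20-style channel names; must be unique.
    subject_id : str
    condition : str
        Condition label (e.g. "closed_eyes").
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass(eq=False)
class Epoch:
    """A fixed-length cut of a record; sample count is exactly fs * length."""

    samples: np.ndarray
    fs: float
    length: float
    channel_labels: list[str]
    subject_id: str = ""
    condition: str = ""
    index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        expected = int(round(self.fs * self.length))
        if self.samples.shape[1] != expected:
            raise ValueError(
                f"epoch has {self.samples.shape[1]} samples, "
                f"expected fs*length = {expected}"
            )
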