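"""Preprocessing: resampling, drift removal, epoching, artifact rejection.

The pipeline analyses 1-30 Hz activity, so recordings taken at higher
rates are downsampled to 128 Hz (alias-free below the new Nyquist), DC
drift is removed with a 1 Hz high-pass, the stream is cut into
consecutive fixed-length epochs, and any epoch containing a sample with
|amplitude| > 80 uV on any channel is dropped. The amplitude rule is
applied after drift removal, which it presupposes (a zero-mean signal).
Re-referencing is deliberately not performed: the reference affects the
magnitude and spatial distribution of power but not the spectral shapes
the classifier works on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy.signal import butter, resample_poly, sosfiltfilt

from .records import EEGRecord, Epoch

__all__ = [
    "PreprocessConfig",
    "resample_to_target",
    "remove_drift",
    "make_epochs",
    "reject_artifact_epochs",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters (units: Hz, uV, seconds)."""

    target_fs: float = 128.0
    highpass_cutoff: float = 1.0
    artifact_amp: float = 80.0
    epoch_len: float = 60.0

    def __post_init__(self) -> None:
        if min(self.target_fs, self.highpass_cutoff, self.artifact_amp,
               self.epoch_len) <= 0:
            raise ValueError("all preprocessing parameters must be positive")
        if self.highpass_cutoff >= self.target_fs / 2:
            raise ValueError("highpass cutoff must be below target Nyquist")


def resample_to_target(record: EEGRecord, cfg: PreprocessConfig | None = None) -> EEGRecord:
    """Polyphase-resample a record down to the target rate.

    Upsampling is not in the contract: a record below the target rate is
    rejected. A record already at the target rate is returned unchanged.
    """
    cfg = cfg or PreprocessConfig()
    if record.fs < cfg.target_fs:
        raise ValueError(
            f"record at {record.fs} Hz is below target {cfg.target_fs} Hz; "
            "upsampling is not supported"
        )
    if record.fs == cfg.target_fs:
        return record
    ratio = Fraction(cfg.target_fs / record.fs).limit_denominator(10000)
    samples = resample_poly(record.samples, ratio.numerator, ratio.denominator, axis=1)
    return EEGRecord(samples, cfg.target_fs, list(record.channel_labels),
                     record.subject_id, record.condition)


def remove_drift(record: EEGRecord, cfg: PreprocessConfig | None = None) -> EEGRecord:
    """Zero-phase 1 Hz high-pass (4th-order Butterworth, filtfilt).

    Attenuates DC and slow drift to ~0 while leaving 10 Hz content within
    1% of its amplitude.
    """
    cfg = cfg or PreprocessConfig()
    sos = butter(4, cfg.highpass_cutoff, btype="highpass", fs=record.fs, output="sos")
    samples = sosfiltfilt(sos, record.samples, axis=1)
    return EEGRecord(samples, record.fs, list(record.channel_labels),
                     record.subject_id, record.condition)


def make_epochs(record: EEGRecord, cfg: PreprocessConfig | None = None) -> list[Epoch]:
    """Cut consecutive non-overlapping epochs; trailing remainder dropped."""
    cfg = cfg or PreprocessConfig()
    step = int(round(record.fs * cfg.epoch_len))
    n = record.n_samples // step
    return [
        Epoch(record.samples[:, k * step:(k + 1) * step], record.fs, cfg.epoch_len,
              list(record.channel_labels), record.subject_id, record.condition, k)
        for k in range(n)
    ]


def reject_artifact_epochs(
    epochs: list[Epoch], cfg: PreprocessConfig | None = None
) -> list[Epoch]:
    """Drop epochs with any sample strictly above the amplitude threshold.

    The rule is |amplitude| > artifact_amp on any channel; a sample at
    exactly the threshold is retained. Order is preserved and the
    operation is idempotent.
    """
    cfg = cfg or PreprocessConfig()
    return [e for e in epochs if np.max(np.abs(e.samples)) <= cfg.artifact_amp]


def preprocess(
    record: EEGRecord,
    cfg: PreprocessConfig | None = None,
    exclude_epochs: set[int] | None = None,
) -> list[Epoch]:
    """Full chain: resample -> drift removal -> epoch -> artifact rejection.

    ``exclude_epochs`` drops additional epochs by index (0-based, counted
    before rejection) — the hook for manually marked residual artifacts
    that the amplitude rule does not catch.
    """
    cfg = cfg or PreprocessConfig()
    rec = resample_to_target(record, cfg)
    rec = remove_drift(rec, cfg)
    epochs = make_epochs(rec, cfg)
    if exclude_epochs:
        epochs = [e for e in epochs if e.index not in exclude_epochs]
    return reject_artifact_epochs(epochs, cfg)
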