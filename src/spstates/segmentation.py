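"""SP-segments: maximal runs of one spectral class on one channel.

A run of consecutive windows carrying the same class label is one
occurrence of an EEG oscillatory state; the moment the label changes
marks a state transition. Boundaries inherit the 0.390625 s lag of the
sliding analysis; durations span from the first window's onset to the
last window's offset, so a single-window segment lasts the window length
(2 s) and an n-window segment lasts (n-1)*shift/fs + window_len seconds.
Segments never cross epoch boundaries (epochs are processed
independently) and no smoothing is applied: the minimum segment is one
window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StateSegment",
    "run_length_segments",
    "segment_duration",
    "transition_counts",
    "segments_frame",
]

WINDOW_S = 2.0
SHIFT_S = 50.0 / 128.0  # 0.390625 s


@dataclass(frozen=True)
class StateSegment:
    """Inclusive window span [start_window, end_window] with one class."""

    class_id: object
    start_window: int
    end_window: int
    channel_label: str = ""

    @property
    def n_windows(self) -> int:
        return self.end_window - self.start_window + 1


def segment_duration(seg: StateSegment, shift_s: float = SHIFT_S,
                     window_s: float = WINDOW_S) -> float:
    """Seconds from the first window's onset to the last window's offset."""
    return (seg.n_windows - 1) * shift_s + window_s


def run_length_segments(labels, channel_label: str = "") -> list[StateSegment]:
    """Split a label sequence into maximal equal-label runs.

    The concatenated runs reproduce the input exactly (tiling, no gaps);
    consecutive segments carry different class ids by maximality.
    """
    labels = np.asarray(getattr(labels, "labels", labels))
    if labels.size == 0:
        raise ValueError("empty label sequence")
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [labels.size - 1]))
    return [StateSegment(labels[s], int(s), int(e), channel_label)
            for s, e in zip(starts, ends)]


def transition_counts(segments: list[StateSegment], class_ids=None) -> pd.DataFrame:
    """Count adjacent segment transitions i -> j.

    The diagonal is zero by segment maximality; row sums over all
    preceding classes total len(segments) - 1.
    """
    if class_ids is None:
        class_ids = sorted({s.class_id for s in segments})
    idx = {c: k for k, c in enumerate(class_ids)}
    mat = np.zeros((len(class_ids), len(class_ids)), dtype=int)
    for a, b in zip(segments[:-1], segments[1:]):
        mat[idx[a.class_id], idx[b.class_id]] += 1
    return pd.DataFrame(mat, index=class_ids, columns=class_ids)


def segments_frame(segments: list[StateSegment], epoch: int = 0,
                   shift_s: float = SHIFT_S, window_s: float = WINDOW_S) -> pd.DataFrame:
    """Tabulate segments (0-based inclusive window indices, seconds)."""
    return pd.DataFrame([
        {
            "epoch": epoch,
            "channel": s.channel_label,
            "start_window": s.start_window,
            "end_window": s.end_window,
            "start_s": s.start_window * shift_s,
            "end_s": s.end_window * shift_s + window_s,
            "class_id": s.class_id,
        }
        for s in segments
    ])
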