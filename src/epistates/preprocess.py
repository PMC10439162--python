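"""Preprocessing of continuous single-channel recordings.

Mirrors the minimal preprocessing applied to LFP/iEEG data before
featurization: centering around zero with polarity inversion (so slice and
depth-electrode recordings have the same orientation as the model output),
a 50 Hz notch against line noise, and non-overlapping five-second
segmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .model import BrainStateLabel, Segment

__all__ = [
    "Recording",
    "LabelSequence",
    "center_and_invert",
    "notch_filter",
    "segment",
]


@dataclass
class Recording:
    """A continuous single-channel time series with provenance."""

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    channel_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.size < 1:
            raise ValueError("recording must contain at least one sample")


@dataclass
class LabelSequence:
    """Per-segment brain-state labels, aligned 1:1 with the segment list."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        valid = {int(v) for v in BrainStateLabel}
        if not set(np.unique(self.labels)).issubset(valid):
            raise ValueError(f"labels must be in {sorted(valid)}")

    def __len__(self) -> int:
        return len(self.labels)


def center_and_invert(rec: Recording) -> Recording:
    """Center the recording at zero and invert its polarity.

    Returns ``-(x - mean(x))``; applying the operation twice recovers the
    centered original.
    """
    x = rec.samples
    return Recording(-(x - x.mean()), rec.fs, rec.subject_id, rec.channel_id)


def notch_filter(rec: Recording, freq: float = 50.0, quality: float = 30.0) -> Recording:
    """Remove line noise with a second-order IIR notch at ``freq`` Hz.

    The filter is applied forward-backward (zero phase).  ``freq`` must be
    below the Nyquist frequency.
    """
    if freq >= rec.fs / 2:
        raise ValueError(f"notch frequency {freq} must be below Nyquist {rec.fs / 2}")
    b, a = sps.iirnotch(freq, quality, fs=rec.fs)
    y = sps.filtfilt(b, a, rec.samples)
    return Recording(y, rec.fs, rec.subject_id, rec.channel_id)


def segment(rec: Recording, window: float = 5.0) -> list[Segment]:
    """Cut a recording into consecutive non-overlapping windows.

    Windows are ``round(window * fs)`` samples, anchored at the first
    sample; a trailing remainder shorter than one window is dropped.  A
    recording shorter than one window yields an empty list with a warning.
    """
    n_win = int(round(window * rec.fs))
    if n_win < 2:
        raise ValueError("window must span at least 2 samples")
    n_seg = len(rec.samples) // n_win
    if n_seg == 0:
        warnings.warn(
            f"recording of {len(rec.samples)} samples is shorter than one "
            f"{n_win}-sample window; no segments produced"
        )
        return []
    return [
        Segment(rec.samples[i * n_win : (i + 1) * n_win].copy(), fs=rec.fs)
        for i in range(n_seg)
    ]
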