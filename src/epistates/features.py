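"""The 11 per-segment signal features and dataset-wise z-normalization.

The feature set combines spectral descriptors (average band power in
0–0.5, 0.5–4, 4–12, 12–64 and >64 Hz), amplitude/spike descriptors
(0.05–0.95 inter-quantile distance, Tukey-fence outlier count), and
waveform descriptors (mean, variance, autocorrelation at 5 ms lag, line
length).  These features separate the four epileptic brain-state types:
ictal rhythmic activity loads on 4–12 Hz power, fast onset oscillations on
12–64 Hz power, preonset spiking on the Tukey spike count, and line
length / variance track overall signal activity.

Features are computed on raw segments and then z-normalized column-wise
across all segments of one dataset (one individual, or the whole set of
simulated segments), which removes scale differences between datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .model import Segment

__all__ = [
    "FEATURE_NAMES",
    "BANDS",
    "FeatureMatrix",
    "compute_features",
    "compute_feature_matrix",
    "autocorrelation_at_lag",
    "znormalize",
]

#: Fixed feature order; all downstream matrices and serializations use it.
FEATURE_NAMES: tuple[str, ...] = (
    "mean",
    "b0power",
    "b1power",
    "b2power",
    "b3power",
    "b4power",
    "alphdiff",
    "spikeabs",
    "sigvar",
    "autocorrel",
    "linelen",
)

#: Band edges in Hz; the last band runs from 64 Hz to the segment's Nyquist.
BANDS: tuple[tuple[float, float | None], ...] = (
    (0.0, 0.5),
    (0.5, 4.0),
    (4.0, 12.0),
    (12.0, 64.0),
    (64.0, None),
)


@dataclass
class FeatureMatrix:
    """Segments x 11 feature values plus the normalization statistics.

    ``norm_stats`` is None until :func:`znormalize` is applied; afterwards
    it holds the per-feature (mean, std) used, so the same transform can
    be re-applied or serialized with a prototype set.
    """

    values: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES
    norm_stats: dict | None = None
    dataset_id: str = ""
    true_labels: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise ValueError(
                f"values must be (n_segments, {len(self.feature_names)})"
            )

    @property
    def n_segments(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        if self.true_labels is not None:
            df["true_label"] = self.true_labels
        return df


def autocorrelation_at_lag(x: np.ndarray, lag_s: float, fs: float) -> float:
    """Pearson autocorrelation of ``x`` at a lag given in seconds.

    The lag in samples is ``round(lag_s * fs)``, floored at 1.  A
    zero-variance input (or a lag leaving no overlap) is degenerate; the
    correlation is reported as 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    k = max(1, int(round(lag_s * fs)))
    if k >= len(x):
        raise ValueError(f"lag of {k} samples exceeds segment length {len(x)}")
    a, b = x[:-k], x[k:]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        warnings.warn("zero-variance signal: autocorrelation undefined, using 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _band_powers(x: np.ndarray, fs: float) -> list[float]:
    """Average Welch PSD per band (1 s Hann windows, 50% overlap).

    "Average band power" is the mean of the PSD over the frequency bins
    whose center falls in the half-open band [lo, hi); the top band is
    closed at Nyquist.
    """
    nperseg = min(int(round(fs)), len(x))
    f, pxx = sps.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)
    powers = []
    for lo, hi in BANDS:
        hi_edge = fs / 2 if hi is None else hi
        if hi is None:
            mask = (f >= lo) & (f <= hi_edge)
        else:
            mask = (f >= lo) & (f < hi_edge)
        powers.append(float(pxx[mask].mean()) if mask.any() else 0.0)
    return powers


def _tukey_outlier_count(x: np.ndarray) -> int:
    """Count samples outside the Tukey fences [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quantiles use the linear-interpolation convention.  Each outlying
    sample counts individually (no merging into spike events).
    """
    q1, q3 = np.quantile(x, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return int(np.count_nonzero((x < lo) | (x > hi)))


def compute_features(seg: Segment) -> np.ndarray:
    """Compute the 11 features of one raw (un-normalized) segment.

    Returns a length-11 vector in :data:`FEATURE_NAMES` order.
    """
    x = seg.samples
    if len(x) < 2 * max(1, int(round(0.005 * seg.fs))):
        raise ValueError("segment too short for feature computation")
    q05, q95 = np.quantile(x, [0.05, 0.95])
    # degenerate (constant) segments trigger the autocorrelation guard below
    autoc = autocorrelation_at_lag(x, 0.005, seg.fs)
    return np.array(
        [
            float(x.mean()),
            *_band_powers(x, seg.fs),
            float(q95 - q05),
            float(_tukey_outlier_count(x)),
            float(x.var(ddof=1)),
            autoc,
            float(np.abs(np.diff(x)).sum()),
        ]
    )


def compute_feature_matrix(
    segments: list[Segment], dataset_id: str = ""
) -> FeatureMatrix:
    """Stack per-segment feature vectors into a raw FeatureMatrix."""
    values = np.vstack([compute_features(s) for s in segments])
    labels = [s.true_label for s in segments]
    true_labels = (
        np.array([int(l) for l in labels]) if all(l is not None for l in labels) else None
    )
    return FeatureMatrix(values, dataset_id=dataset_id, true_labels=true_labels)


def znormalize(fm: FeatureMatrix) -> FeatureMatrix:
    """Z-normalize each feature column across all segments of the dataset.

    Uses the sample (n-1) standard deviation.  A zero-variance column is
    degenerate and mapped to all zeros with a warning.  The (mean, std)
    statistics are stored on the result for reuse when projecting other
    data into the same space.
    """
    if fm.n_segments < 2:
        raise ValueError("z-normalization needs at least 2 segments")
    mean = fm.values.mean(axis=0)
    std = fm.values.std(axis=0, ddof=1)
    zero = std == 0
    if zero.any():
        bad = [fm.feature_names[i] for i in np.flatnonzero(zero)]
        warnings.warn(f"zero-variance feature(s) {bad} set to 0 after normalization")
    safe_std = np.where(zero, 1.0, std)
    z = (fm.values - mean) / safe_std
    z[:, zero] = 0.0
    return FeatureMatrix(
        z,
        feature_names=fm.feature_names,
        norm_stats={"mean": mean.tolist(), "std": std.tolist()},
        dataset_id=fm.dataset_id,
        true_labels=fm.true_labels,
    )
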