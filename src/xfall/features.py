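"""The 36-dimensional per-segment feature representation.

For each of the four channels — the three accelerometer axes x, y, z and
the summation channel s(t) combining them — nine statistics are computed:
mean, median, standard deviation, variance, min, max, 0.25 quantile,
0.75 quantile and spectral entropy. Feature order is fixed (x block, y
block, z block, s block; the statistic order above within each block) and
exposed in :data:`FEATURE_NAMES`.

The summation channel is, literally, the absolute summation
``s(t) = |ax(t)| + |ay(t)| + |az(t)|``; the Euclidean norm is available
behind the ``mode`` switch since both readings are common in the field.
Spectral entropy is the Shannon entropy of the normalized one-sided power
spectrum (DC bin included), divided by ``ln(n_bins)`` so it lies in
[0, 1]: 0 for a constant or single-tone signal, near 1 for white noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import Segment

__all__ = [
    "FEATURE_NAMES",
    "STAT_NAMES",
    "FeatureMatrix",
    "summation_channel",
    "spectral_entropy",
    "extract_features",
    "feature_matrix",
    "standardize",
]

STAT_NAMES = (
    "mean",
    "median",
    "std",
    "var",
    "min",
    "max",
    "q25",
    "q75",
    "spectral_entropy",
)

CHANNELS = ("x", "y", "z", "s")

FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{ch}_{stat}" for ch in CHANNELS for stat in STAT_NAMES
)


def summation_channel(samples, mode: str = "l1") -> np.ndarray:
    """Collapse a tri-axial window to one magnitude-like channel.

    ``mode='l1'`` gives the absolute summation |ax|+|ay|+|az|;
    ``mode='l2'`` the Euclidean norm.
    """
    arr = samples.samples if isinstance(samples, Segment) else np.asarray(samples, float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("expected samples of shape (n, 3)")
    if arr.shape[0] == 0:
        raise ValueError("empty segment")
    if mode == "l1":
        return np.abs(arr).sum(axis=1)
    if mode == "l2":
        return np.linalg.norm(arr, axis=1)
    raise ValueError("mode must be 'l1' or 'l2'")


def spectral_entropy(series, rate: float | None = None, include_dc: bool = True) -> float:
    """Normalized spectral entropy of a 1-D signal, in [0, 1].

    The one-sided power spectrum ``P_i = |FFT_i|^2`` is normalized to a
    probability distribution and its Shannon entropy divided by
    ``ln(n_bins)``. An all-zero series is defined as 0 by convention.
    ``rate`` is accepted for interface symmetry; the normalized entropy
    does not depend on it.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 8:
        raise ValueError("series must have at least 8 samples")
    spectrum = np.abs(np.fft.rfft(x)) ** 2
    if not include_dc:
        spectrum = spectrum[1:]
    total = spectrum.sum()
    if total == 0.0:
        return 0.0
    p = spectrum / total
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    n_bins = len(p)
    if n_bins < 2:
        return 0.0
    return entropy / np.log(n_bins)


def _channel_stats(series: np.ndarray) -> list[float]:
    return [
        float(np.mean(series)),
        float(np.median(series)),
        float(np.std(series, ddof=1)),
        float(np.var(series, ddof=1)),
        float(np.min(series)),
        float(np.max(series)),
        float(np.quantile(series, 0.25)),  # linear interpolation (default)
        float(np.quantile(series, 0.75)),
        spectral_entropy(series),
    ]


def extract_features(segment, mode: str = "l1") -> np.ndarray:
    """The 36-entry feature vector of one segment, ordered as FEATURE_NAMES."""
    arr = segment.samples if isinstance(segment, Segment) else np.asarray(segment, float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("expected samples of shape (n, 3)")
    if arr.shape[0] < 8:
        raise ValueError("segment must have at least 8 samples")
    values: list[float] = []
    for k in range(3):
        values.extend(_channel_stats(arr[:, k]))
    values.extend(_channel_stats(summation_channel(arr, mode)))
    return np.asarray(values, dtype=float)


@dataclass
class FeatureMatrix:
    """Feature vectors with labels and subject ids for grouped splitting."""

    X: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    trials: np.ndarray | None = None
    trace_ids: np.ndarray | None = None
    peak_magnitude: np.ndarray | None = None
    feature_names: tuple[str, ...] = FEATURE_NAMES
    standardization: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not (len(self.X) == len(self.labels) == len(self.subject_ids)):
            raise ValueError("rows, labels and subject_ids must align")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def y(self) -> np.ndarray:
        return self.labels

    def subset(self, mask) -> "FeatureMatrix":
        mask = np.asarray(mask)
        return FeatureMatrix(
            X=self.X[mask],
            labels=self.labels[mask],
            subject_ids=self.subject_ids[mask],
            trials=None if self.trials is None else self.trials[mask],
            trace_ids=None if self.trace_ids is None else self.trace_ids[mask],
            peak_magnitude=None
            if self.peak_magnitude is None
            else self.peak_magnitude[mask],
            feature_names=self.feature_names,
            standardization=self.standardization,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df["label"] = self.labels
        df["subject_id"] = self.subject_ids
        if self.trials is not None:
            df["trial"] = self.trials
        return df


def feature_matrix(segments, mode: str = "l1") -> FeatureMatrix:
    """Extract features from a list of segments into a FeatureMatrix."""
    segments = list(segments)
    if not segments:
        raise ValueError("no segments given")
    X = np.stack([extract_features(s, mode) for s in segments])
    labels = np.array([s.label for s in segments])
    subjects = np.array([s.subject_id for s in segments])
    trials = np.array([s.trial if s.trial is not None else -1 for s in segments])
    trace_ids = np.array([s.source_trace for s in segments])
    peaks = np.array([float(np.max(s.magnitude())) for s in segments])
    return FeatureMatrix(
        X=X,
        labels=labels,
        subject_ids=subjects,
        trials=trials,
        trace_ids=trace_ids,
        peak_magnitude=peaks,
    )


def standardize(
    train: FeatureMatrix, others=()
) -> tuple[FeatureMatrix, list[FeatureMatrix], np.ndarray, np.ndarray]:
    """Standardize to mean 0 / SD 1 using *training* statistics only.

    Every matrix in ``others`` is transformed with the training mean and SD,
    never its own. Features that are constant in training keep SD treated as
    1 (with a warning) so they map to zeros rather than NaN.
    """
    if len(train) == 0:
        raise ValueError("training matrix is empty")
    mean = train.X.mean(axis=0)
    sd = train.X.std(axis=0, ddof=0)
    degenerate = sd == 0
    if np.any(degenerate):
        names = [train.feature_names[i] for i in np.flatnonzero(degenerate)]
        warnings.warn(
            f"constant training feature(s) {names}: SD treated as 1", stacklevel=2
        )
        sd = np.where(degenerate, 1.0, sd)

    def _apply(fm: FeatureMatrix) -> FeatureMatrix:
        out = fm.subset(np.ones(len(fm), dtype=bool))
        out.X = (fm.X - mean) / sd
        out.standardization = (mean.copy(), sd.copy())
        return out

    return _apply(train), [_apply(o) for o in others], mean, sd
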