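"""Epoching, sample entropy, impact alignment and the fixed labeling rule.

Lab-style trials are cut into fixed-length windows (0% or 50% overlap).
For trials known to contain a fall, the window holding the impact is found
by sample entropy (SampEn): the impact transient is the most irregular part
of the trace, so the window with maximal SampEn above a calibrated
threshold is labeled FALL and the remaining windows of that trial are
discarded. Real-world traces with a known impact time are labeled by the
fixed convention instead: the 2.5 s span from 1.5 s before to 1.0 s after
the impact is the FALL segment and the 4 s before that is ADL context.

SampEn here is the Richman-Moorman statistic: with tolerance
``r * SD(series)`` and Chebyshev distance, ``B`` counts pairs of matching
length-``m`` templates (self-matches excluded), ``A`` the matching
length-``m+1`` pairs, and ``SampEn = -ln(A/B)``. When no ``m+1`` template
pair matches the statistic is undefined; ``math.inf`` is returned as the
undefined marker (maximal irregularity), which sorts above any threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from .signal_io import LABEL_ADL, LABEL_FALL, AccelTrace

__all__ = [
    "Segment",
    "SampEnParams",
    "AlignmentResult",
    "NoEventFoundError",
    "CalibrationError",
    "LabelingError",
    "epoch",
    "sample_entropy",
    "locate_fall_window",
    "extract_fall_segment",
    "calibrate_threshold",
    "label_realworld",
]


class NoEventFoundError(RuntimeError):
    """No window of a supposed fall trial reached the SampEn threshold."""


class CalibrationError(RuntimeError):
    """ADL and fall SampEn ranges overlap; no separating threshold exists."""

    def __init__(self, adl_max: float, fall_min: float):
        super().__init__(
            f"no separating threshold: max ADL SampEn {adl_max:.4f} >= "
            f"min per-trial fall SampEn {fall_min:.4f}"
        )
        self.adl_max = adl_max
        self.fall_min = fall_min


class LabelingError(ValueError):
    """The fixed labeling convention cannot be applied to this trace."""


@dataclass
class Segment:
    """A fixed-length labeled window of a trace (0-based, half-open)."""

    samples: np.ndarray
    rate: float
    label: str
    source_trace: str = ""
    start_index: int = 0
    aligned: bool = False
    subject_id: str = ""
    trial: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("segment samples must have shape (W, 3)")

    @property
    def length(self) -> int:
        return self.samples.shape[0]

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.samples, axis=1)


@dataclass(frozen=True)
class SampEnParams:
    """Sample-entropy parameters: embedding ``m``, tolerance fraction ``r``
    (of the window SD) and the channel the statistic is computed on."""

    m: int = 2
    r: float = 0.2
    channel: str = "magnitude"  # or "per-axis"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not self.r > 0:
            raise ValueError("r must be positive")
        if self.channel not in ("magnitude", "per-axis"):
            raise ValueError("channel must be 'magnitude' or 'per-axis'")


@dataclass
class AlignmentResult:
    """Outcome of SampEn-based impact localization on one fall trial."""

    fall_segment_index: int
    sampen_values: np.ndarray
    threshold: float


def epoch(
    trace: AccelTrace,
    window_samples: int,
    overlap_fraction: float = 0.0,
    label: str | None = None,
) -> list[Segment]:
    """Cut a trace into fixed-length windows, trailing partial window dropped.

    ``overlap_fraction`` is 0 (adjacent windows) or 0.5 (half-window step;
    ``window_samples`` must then be even). Non-overlapping windows number
    ``floor(N / W)``; 50%-overlap windows ``floor((N - W) / (W/2)) + 1``
    when ``N >= W``, else zero.
    """
    if window_samples < 2:
        raise ValueError("window_samples must be >= 2")
    if overlap_fraction not in (0, 0.0, 0.5):
        raise ValueError("overlap_fraction must be 0 or 0.5")
    if overlap_fraction == 0.5 and window_samples % 2:
        raise ValueError("window_samples must be even for 50% overlap")
    n = trace.n_samples
    w = window_samples
    if n < w:
        return []
    step = w if overlap_fraction == 0 else w // 2
    if label is None:
        label = trace.label_hint if trace.label_hint in (LABEL_ADL, LABEL_FALL) else LABEL_ADL
    segments = []
    for start in range(0, n - w + 1, step):
        segments.append(
            Segment(
                samples=trace.samples[start : start + w].copy(),
                rate=trace.rate,
                label=label,
                source_trace=trace.trace_id,
                start_index=start,
                subject_id=trace.subject_id,
                trial=trace.trial,
            )
        )
    return segments


def sample_entropy(series, params: SampEnParams | None = None) -> float:
    """Sample entropy of a 1-D series; ``inf`` marks the undefined case.

    A constant series returns 0 (every template matches every other at both
    lengths). Raises for series of length ``<= m + 1``.

    Both template sets have ``n - m`` members (the final length-``m``
    template is dropped), so the length-``m`` and length-``m+1`` match
    counts are comparable. Matching is evaluated on a single pairwise
    sample-distance matrix: a pair of templates matches iff every aligned
    sample pair is within tolerance, so the Chebyshev template distance
    never has to be materialized.
    """
    p = params or SampEnParams()
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if n <= p.m + 1:
        raise ValueError(f"series length {n} too short for m={p.m}")
    sd = float(x.std())
    if sd == 0.0:
        return 0.0
    tol = p.r * sd
    close = np.abs(x[:, None] - x[None, :]) <= tol
    length = n - p.m
    acc = close[:length, :length].copy()
    for k in range(1, p.m):
        acc &= close[k : k + length, k : k + length]
    b = int((np.count_nonzero(acc) - length) // 2)
    acc &= close[p.m : p.m + length, p.m : p.m + length]
    a = int((np.count_nonzero(acc) - length) // 2)
    if a == 0 or b == 0:
        return math.inf
    return float(-np.log(a / b))


def _window_series(segment: Segment, channel: str) -> np.ndarray | list[np.ndarray]:
    if channel == "magnitude":
        return segment.magnitude()
    return [segment.samples[:, k] for k in range(3)]


def window_entropies(
    trace: AccelTrace,
    window_samples: int,
    params: SampEnParams | None = None,
    overlap_fraction: float = 0.0,
) -> np.ndarray:
    """SampEn of every epoch window of a trace (channel per ``params``)."""
    p = params or SampEnParams()
    values = []
    for seg in epoch(trace, window_samples, overlap_fraction):
        series = _window_series(seg, p.channel)
        if p.channel == "magnitude":
            values.append(sample_entropy(series, p))
        else:
            values.append(max(sample_entropy(s, p) for s in series))
    return np.asarray(values, dtype=float)


def locate_fall_window(
    trace: AccelTrace,
    window_samples: int,
    params: SampEnParams | None = None,
    threshold: float = 0.0,
    overlap_fraction: float = 0.0,
) -> AlignmentResult:
    """Find the impact window of a trial known to contain one fall.

    Among the windows whose SampEn reaches ``threshold``, the one with
    maximal SampEn is the FALL window (ties to the earliest). Every other
    window of the trial is discarded by the caller — pre- and post-fall
    windows are transient-contaminated, not clean ADL.
    """
    values = window_entropies(trace, window_samples, params, overlap_fraction)
    if values.size == 0:
        raise NoEventFoundError(f"{trace.trace_id}: trace shorter than one window")
    eligible = values >= threshold
    if not np.any(eligible):
        raise NoEventFoundError(
            f"{trace.trace_id}: no window reached SampEn threshold {threshold:.4f} "
            f"(max was {np.max(values):.4f})"
        )
    masked = np.where(eligible, values, -np.inf)
    idx = int(np.argmax(masked))
    return AlignmentResult(fall_segment_index=idx, sampen_values=values, threshold=threshold)


def extract_fall_segment(
    trace: AccelTrace,
    window_samples: int,
    params: SampEnParams | None = None,
    threshold: float = 0.0,
    overlap_fraction: float = 0.0,
) -> tuple[Segment, AlignmentResult]:
    """Locate the impact window and return it as an aligned FALL segment."""
    result = locate_fall_window(trace, window_samples, params, threshold, overlap_fraction)
    segments = epoch(trace, window_samples, overlap_fraction, label=LABEL_FALL)
    seg = segments[result.fall_segment_index]
    seg.aligned = True
    return seg, result


def calibrate_threshold(
    fall_traces,
    adl_traces,
    window_samples: int,
    params: SampEnParams | None = None,
    overlap_fraction: float = 0.0,
) -> float:
    """Empirical SampEn threshold separating impact windows from ADL windows.

    Returns the midpoint between the largest SampEn over all ADL windows and
    the smallest per-trial maximal SampEn over the fall trials. Raises
    :class:`CalibrationError` when the two ranges overlap.
    """
    fall_traces = list(fall_traces)
    adl_traces = list(adl_traces)
    if not fall_traces or not adl_traces:
        raise ValueError("need at least one fall trace and one ADL trace")
    adl_values = [
        v
        for trace in adl_traces
        for v in window_entropies(trace, window_samples, params, overlap_fraction)
    ]
    if not adl_values:
        raise ValueError("ADL traces yielded no full windows")
    adl_max = float(np.max(adl_values))
    fall_maxima = []
    for trace in fall_traces:
        values = window_entropies(trace, window_samples, params, overlap_fraction)
        if values.size == 0:
            raise ValueError(f"{trace.trace_id}: fall trace shorter than one window")
        fall_maxima.append(float(np.max(values)))
    fall_min = float(np.min(fall_maxima))
    if adl_max >= fall_min:
        raise CalibrationError(adl_max, fall_min)
    if math.isinf(fall_min):
        return adl_max * 2.0 if adl_max > 0 else 1.0
    return 0.5 * (adl_max + fall_min)


# Fixed labeling convention for real-world traces (seconds).
_FALL_BEFORE_S = 1.5
_FALL_AFTER_S = 1.0
_ADL_CONTEXT_S = 4.0


def label_realworld(
    trace: AccelTrace,
    impact_time: float | None = None,
    window_seconds: float = 2.5,
) -> list[Segment]:
    """Label a real-world trace around a known impact time.

    The FALL segment spans ``[impact - 1.5 s, impact + 1.0 s)`` — 2.5 s
    always, independent of ``window_seconds``. The 4 s of ADL context
    ``[impact - 5.5 s, impact - 1.5 s)`` are epoched into
    ``window_seconds`` sub-windows with 50% overlap (4 s holds only one
    non-overlapping 2.5 s window; the overlap keeps the ADL class
    non-degenerate). Requires at least 5.5 s of data before the impact and
    1.0 s after.
    """
    if impact_time is None:
        impact_time = trace.impact_time
    if impact_time is None:
        raise LabelingError("no impact_time given and none on the trace")
    needed_before = _ADL_CONTEXT_S + _FALL_BEFORE_S
    if impact_time < needed_before:
        raise LabelingError(
            f"impact at {impact_time:.2f} s but {needed_before} s of pre-impact "
            "data are required (4 s ADL context + 1.5 s pre-impact span)"
        )
    if impact_time + _FALL_AFTER_S > trace.duration + 1e-9:
        raise LabelingError("less than 1.0 s of data after the impact")
    rate = trace.rate
    fall_start = int(round((impact_time - _FALL_BEFORE_S) * rate))
    fall_end = fall_start + int(round((_FALL_BEFORE_S + _FALL_AFTER_S) * rate))
    ctx_start = int(round((impact_time - needed_before) * rate))
    ctx_end = fall_start

    w = int(round(window_seconds * rate))
    if w < 2 or w > ctx_end - ctx_start:
        raise LabelingError(
            f"window_seconds={window_seconds} does not fit the 4 s ADL context"
        )
    if w % 2:
        w -= 1  # 50% overlap needs an even window
    step = w // 2
    segments: list[Segment] = []
    for start in range(ctx_start, ctx_end - w + 1, step):
        segments.append(
            Segment(
                samples=trace.samples[start : start + w].copy(),
                rate=rate,
                label=LABEL_ADL,
                source_trace=trace.trace_id,
                start_index=start,
                subject_id=trace.subject_id,
                trial=trace.trial,
            )
        )
    segments.append(
        Segment(
            samples=trace.samples[fall_start:fall_end].copy(),
            rate=rate,
            label=LABEL_FALL,
            source_trace=trace.trace_id,
            start_index=fall_start,
            aligned=True,
            subject_id=trace.subject_id,
            trial=trace.trial,
        )
    )
    return segments
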