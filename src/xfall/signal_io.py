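"""Reading, writing and resampling tri-axial accelerometer recordings.

The on-disk formats are the two dialects found in public fall repositories:

* a delimited-text dialect in which each row holds nine comma-separated
  integer ADC counts (first accelerometer x/y/z, gyroscope x/y/z, second
  accelerometer x/y/z), rows optionally terminated with a semicolon, and
  the filename encodes ``<ACT>_<SUBJ>_<TRIAL>``;
* generic CSV with an ``ax,ay,az`` header holding accelerations in g,
  used for real-world continuous traces.

A ``manifest.csv`` sidecar carries the metadata that the file bodies do not
(sample rate, label, ground-truth impact time). All in-memory accelerations
are expressed in g; ADC count conversion happens only at the file boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

LABEL_ADL = "ADL"
LABEL_FALL = "FALL"
LABEL_UNKNOWN = "UNKNOWN"

__all__ = [
    "AccelTrace",
    "AdcSpec",
    "TraceDataset",
    "ParseError",
    "FormatError",
    "AdcRangeError",
    "counts_to_g",
    "g_to_counts",
    "read_sisfall_dialect",
    "write_sisfall_dialect",
    "read_csv_trace",
    "write_csv_trace",
    "read_dataset",
    "write_dataset",
    "resample_trace",
]


class ParseError(ValueError):
    """A data row could not be parsed; the message carries the line number."""


class FormatError(ValueError):
    """The file as a whole does not look like the expected dialect."""


class AdcRangeError(ValueError):
    """A raw count lies outside the ADC's representable range."""


@dataclass
class AccelTrace:
    """One continuous tri-axial recording in g.

    Parameters
    ----------
    samples:
        Array of shape ``(n, 3)`` holding ``(ax, ay, az)`` per time step.
    rate:
        Sampling rate in Hz (uniform sampling; time is implicit).
    subject_id, activity:
        Free-text metadata; the activity is a human-readable archetype name.
    label_hint:
        ``"ADL"``, ``"FALL"`` or ``"UNKNOWN"`` — the trial-level class.
    impact_time:
        Ground-truth fall-impact time in seconds from trace start, if known.
    domain:
        ``"lab"`` (scripted trials) or ``"realworld"`` (continuous traces).
    trial:
        Trial index within (subject, activity), 1-based, when applicable.
    """

    samples: np.ndarray
    rate: float
    subject_id: str = ""
    activity: str = ""
    label_hint: str = LABEL_UNKNOWN
    impact_time: float | None = None
    domain: str = "lab"
    trial: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if self.label_hint not in (LABEL_ADL, LABEL_FALL, LABEL_UNKNOWN):
            raise ValueError(f"bad label_hint {self.label_hint!r}")
        if self.impact_time is not None and not (
            0.0 <= self.impact_time <= self.duration
        ):
            raise ValueError("impact_time outside [0, duration]")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.samples.shape[0] / self.rate

    def magnitude(self) -> np.ndarray:
        """Euclidean norm of the acceleration vector per sample, in g."""
        return np.linalg.norm(self.samples, axis=1)

    @property
    def trace_id(self) -> str:
        act = self.activity.replace(" ", "-") or "trace"
        parts = [act, self.subject_id or "S"]
        if self.trial is not None:
            parts.append(f"R{self.trial:02d}")
        return "_".join(parts)


@dataclass(frozen=True)
class AdcSpec:
    """Linear ADC model: ``a = (2 * range_g / 2**resolution_bits) * raw``.

    Defaults match a +/-16 g, 13-bit accelerometer, the usual primary sensor
    configuration for waist-worn fall-repository recordings.
    """

    range_g: float = 16.0
    resolution_bits: int = 13

    def __post_init__(self) -> None:
        if not self.range_g > 0:
            raise ValueError("range_g must be positive")
        if not 8 <= self.resolution_bits <= 16:
            raise ValueError("resolution_bits must lie in [8, 16]")

    @property
    def step_g(self) -> float:
        """Acceleration difference of one ADC count."""
        return 2.0 * self.range_g / 2.0**self.resolution_bits

    @property
    def max_count(self) -> int:
        return 2 ** (self.resolution_bits - 1)


def counts_to_g(raw, spec: AdcSpec = AdcSpec()):
    """Convert integer ADC counts to acceleration in g (sign preserving)."""
    raw_arr = np.asarray(raw)
    if np.any(np.abs(raw_arr) > spec.max_count):
        raise AdcRangeError(
            f"count outside +/-{spec.max_count} for {spec.resolution_bits}-bit ADC"
        )
    out = raw_arr * spec.step_g
    return float(out) if np.isscalar(raw) or raw_arr.ndim == 0 else out


def g_to_counts(accel, spec: AdcSpec = AdcSpec()) -> np.ndarray:
    """Quantize accelerations in g to integer counts, saturating at full scale."""
    counts = np.round(np.asarray(accel, dtype=float) / spec.step_g)
    return np.clip(counts, -spec.max_count, spec.max_count).astype(int)


# ---------------------------------------------------------------------------
# Delimited-text dialect
# ---------------------------------------------------------------------------


def write_sisfall_dialect(trace: AccelTrace, path, adc: AdcSpec = AdcSpec()) -> None:
    """Write a trace as 9 comma-separated integer columns, rows ';'-terminated.

    Columns 1-3 hold the trace (first accelerometer); gyroscope and second
    accelerometer columns are zero-filled.
    """
    counts = g_to_counts(trace.samples, adc)
    with open(path, "w", encoding="ascii") as fh:
        for row in counts:
            fh.write(f"{row[0]},{row[1]},{row[2]},0,0,0,0,0,0;\n")


def _metadata_from_filename(path: Path) -> tuple[str, str, int | None, str]:
    """Parse ``<ACT>_<SUBJ>_<TRIAL>`` from a filename stem."""
    parts = path.stem.split("_")
    code = parts[0] if parts else path.stem
    subject = parts[1] if len(parts) > 1 else ""
    trial: int | None = None
    if len(parts) > 2:
        digits = "".join(ch for ch in parts[2] if ch.isdigit())
        trial = int(digits) if digits else None
    label = LABEL_FALL if code.upper().startswith("F") else LABEL_ADL
    return code, subject, trial, label


def read_sisfall_dialect(
    path,
    adc: AdcSpec = AdcSpec(),
    column_map: Sequence[int] = (0, 1, 2),
    rate: float = 200.0,
) -> AccelTrace:
    """Read a delimited-text recording, keeping the ``column_map`` columns.

    The default column map selects the first accelerometer; gyroscope and
    secondary-accelerometer columns are skipped. Metadata is parsed from the
    ``<ACT>_<SUBJ>_<TRIAL>`` filename pattern.
    """
    path = Path(path)
    if len(column_map) != 3:
        raise ValueError("column_map must select exactly three columns")
    rows: list[list[int]] = []
    with open(path, "r", encoding="ascii") as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip().rstrip(";").strip()
            if not text:
                continue
            fields = [f for f in text.replace(";", ",").split(",") if f.strip()]
            if len(fields) < 3:
                raise FormatError(f"{path.name}: line {lineno}: fewer than 3 columns")
            if max(column_map) >= len(fields):
                raise FormatError(
                    f"{path.name}: line {lineno}: column_map needs "
                    f"{max(column_map) + 1} columns, row has {len(fields)}"
                )
            try:
                rows.append([int(float(fields[i])) for i in column_map])
            except ValueError as exc:
                raise ParseError(f"{path.name}: line {lineno}: {exc}") from None
    if not rows:
        raise FormatError(f"{path.name}: empty file")
    samples = counts_to_g(np.array(rows, dtype=int), adc)
    code, subject, trial, label = _metadata_from_filename(path)
    return AccelTrace(
        samples=samples,
        rate=rate,
        subject_id=subject,
        activity=code,
        label_hint=label,
        trial=trial,
    )


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------


def write_csv_trace(trace: AccelTrace, path) -> None:
    """Write a trace as CSV with an ``ax,ay,az`` header (floats, in g)."""
    df = pd.DataFrame(trace.samples, columns=["ax", "ay", "az"])
    df.to_csv(path, index=False, float_format="%.6f")


def read_csv_trace(path, rate: float, **metadata) -> AccelTrace:
    df = pd.read_csv(path)
    for col in ("ax", "ay", "az"):
        if col not in df.columns:
            raise FormatError(f"{Path(path).name}: missing column {col!r}")
    return AccelTrace(samples=df[["ax", "ay", "az"]].to_numpy(float), rate=rate, **metadata)


# ---------------------------------------------------------------------------
# Dataset container and directory layout
# ---------------------------------------------------------------------------


@dataclass
class TraceDataset:
    """An ordered collection of :class:`AccelTrace` with manifest helpers."""

    traces: list[AccelTrace] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self) -> Iterator[AccelTrace]:
        return iter(self.traces)

    def __getitem__(self, i):
        return self.traces[i]

    def subjects(self) -> list[str]:
        return sorted({t.subject_id for t in self.traces})

    def fall_traces(self) -> list[AccelTrace]:
        return [t for t in self.traces if t.label_hint == LABEL_FALL]

    def adl_traces(self) -> list[AccelTrace]:
        return [t for t in self.traces if t.label_hint == LABEL_ADL]

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "trace_id": t.trace_id,
                "subject": t.subject_id,
                "activity": t.activity,
                "trial": t.trial,
                "label": t.label_hint,
                "impact_time_s": t.impact_time,
                "rate": t.rate,
                "domain": t.domain,
                "n_samples": t.n_samples,
            }
            for t in self.traces
        ]
        return pd.DataFrame(rows)


def write_dataset(
    dataset: TraceDataset,
    out_dir,
    adc: AdcSpec = AdcSpec(),
    code_map: dict[str, str] | None = None,
) -> Path:
    """Write a dataset as delimited-text files plus ``manifest.csv``.

    ``code_map`` maps activity names to short filename codes (e.g. F01/D02);
    without it a whitespace-free activity name is used directly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = dataset.manifest()
    file_names = []
    for trace in dataset:
        code = (code_map or {}).get(trace.activity, trace.activity.replace(" ", "-"))
        trial = trace.trial if trace.trial is not None else 1
        name = f"{code}_{trace.subject_id}_R{trial:02d}.txt"
        write_sisfall_dialect(trace, out_dir / name, adc)
        file_names.append(name)
    manifest.insert(0, "file", file_names)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return out_dir


def read_dataset(in_dir, adc: AdcSpec = AdcSpec()) -> TraceDataset:
    """Read a directory written by :func:`write_dataset` (manifest-driven)."""
    in_dir = Path(in_dir)
    manifest_path = in_dir / "manifest.csv"
    if not manifest_path.exists():
        raise FormatError(f"{in_dir}: no manifest.csv")
    manifest = pd.read_csv(manifest_path)
    traces = []
    for _, row in manifest.iterrows():
        path = in_dir / row["file"]
        if path.suffix == ".csv":
            trace = read_csv_trace(path, rate=float(row["rate"]))
        else:
            trace = read_sisfall_dialect(path, adc=adc, rate=float(row["rate"]))
        trace.subject_id = str(row["subject"])
        trace.activity = str(row["activity"])
        trace.label_hint = str(row["label"])
        trace.domain = str(row.get("domain", "lab"))
        trace.trial = None if pd.isna(row.get("trial")) else int(row["trial"])
        impact = row.get("impact_time_s")
        trace.impact_time = None if pd.isna(impact) else float(impact)
        traces.append(trace)
    return TraceDataset(traces)


def write_realworld_dataset(dataset: TraceDataset, out_dir) -> Path:
    """Write real-world-style traces as CSV files plus ``manifest.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = dataset.manifest()
    file_names = []
    for i, trace in enumerate(dataset):
        name = f"event_{i + 1:02d}.csv"
        write_csv_trace(trace, out_dir / name)
        file_names.append(name)
    manifest.insert(0, "file", file_names)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return out_dir


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def resample_trace(trace: AccelTrace, target_rate: float) -> AccelTrace:
    """Resample to ``target_rate`` with a polyphase FIR anti-aliasing filter.

    DC signals are preserved to numerical precision away from the edges, and
    the output length equals ``n * target_rate / rate`` rounded up to the
    polyphase grid. Metadata (including ``impact_time``, which is expressed
    in seconds) carries over unchanged.
    """
    if not target_rate > 0:
        raise ValueError("target_rate must be positive")
    if math.isclose(target_rate, trace.rate):
        return replace(trace, samples=trace.samples.copy())
    frac = Fraction(target_rate / trace.rate).limit_denominator(1000)
    # The polyphase branches of the default FIR carry a small DC ripple;
    # filtering the mean-free signal and restoring the mean keeps constants
    # exact (the filter is linear, so nothing else changes).
    mean = trace.samples.mean(axis=0, keepdims=True)
    resampled = mean + resample_poly(
        trace.samples - mean, frac.numerator, frac.denominator, axis=0, padtype="line"
    )
    return replace(trace, samples=resampled, rate=target_rate)
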