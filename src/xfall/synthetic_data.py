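"""Synthetic tri-axial accelerometer cohorts for fall-detection pipelines.

Two kinds of data are generated, mirroring the structure of the public fall
repositories the analysis is designed around:

* *lab-style* scripted trials: 15 s recordings at 200 Hz, one per
  (subject, activity, trial), where the activity is either a scripted
  activity of daily living (ADL) or an intentional fall with one sharp
  impact whose ground-truth time is recorded;
* *real-world-style* continuous traces: accidental-fall events with an ADL
  context before the fall, recorded by a differently placed sensor — a
  configurable domain shift (orientation, gain, noise, baseline, sample
  rate) applied on top of the same kinematic model.

The fall is modelled in four phases — pre-fall ADL, free fall (magnitude
dip well below 1 g), impact (a sharp spike reaching ``impact_peak``
followed by an irregular settling transient), and rest (lying still).
The phase model is deliberately simple: it is not biomechanically
validated, but it reproduces the quiet-impact-quiet signature of real
waist-sensor falls and gives every trace an unambiguous ground truth.

All accelerations are in g; gravity contributes a unit-norm baseline.
Identical seeds yield bit-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .signal_io import (
    LABEL_ADL,
    LABEL_FALL,
    AccelTrace,
    TraceDataset,
    resample_trace,
)

__all__ = [
    "FALL_TYPES",
    "ADL_TYPES",
    "ActivityCatalog",
    "FallPhaseParams",
    "DomainShift",
    "CohortSpec",
    "simulate_adl",
    "simulate_fall",
    "generate_lab_cohort",
    "generate_realworld_set",
    "apply_domain_shift",
]

#: The 15 intentional-fall archetypes of a standard lab fall repository.
FALL_TYPES: tuple[str, ...] = (
    "fall forward while walking caused by a slip",
    "fall backward while walking caused by a slip",
    "lateral fall while walking caused by a slip",
    "fall forward while walking caused by a trip",
    "fall forward while jogging caused by a trip",
    "vertical fall while walking caused by fainting",
    "fall while walking with use of hands on a table to dampen fall, caused by fainting",
    "fall forward when trying to get up",
    "lateral fall when trying to get up",
    "fall forward when trying to sit down",
    "fall backward when trying to sit down",
    "lateral fall when trying to sit down",
    "fall forward while sitting, caused by fainting or falling asleep",
    "fall backward while sitting, caused by fainting or falling asleep",
    "lateral fall while sitting, caused by fainting or falling asleep",
)

#: Scripted ADL archetypes forming the negative class.
ADL_TYPES: tuple[str, ...] = (
    "walking",
    "jogging",
    "sitting down",
    "standing up",
    "stair walking",
)

# Window grid (seconds) the impact placement is aligned to; matches the
# pipeline's canonical 2.5 s epoch so the impact always falls in the interior
# of exactly one non-overlapping window.
_GRID_S = 2.5

# Quiet-phase postural sway: slow oscillation that keeps "still" signal
# structure well above the sensor noise floor (real sensors see breathing and
# postural adjustments, never a flat line).
_SWAY_AMP = 0.06
_DEFAULT_NOISE_SD = 0.003

_ADL_PRESETS: dict[str, dict] = {
    "walking": {"kind": "gait", "amp": 0.30, "cadence": (1.6, 2.4), "harm": 0.30},
    "jogging": {"kind": "gait", "amp": 0.55, "cadence": (2.3, 3.1), "harm": 0.25},
    "stair walking": {"kind": "gait", "amp": 0.35, "cadence": (1.5, 2.0), "harm": 0.45},
    "sitting down": {"kind": "transition", "sign": -1.0},
    "standing up": {"kind": "transition", "sign": +1.0},
    # Pure gravity + sensor noise; used in API examples, not in the default
    # catalog (a trial-long flat line is not a scripted activity).
    "quiet standing": {"kind": "quiet"},
    # Quiet posture with sway; internal pre-fall context for non-gait falls.
    "standing": {"kind": "still"},
}


@dataclass(frozen=True)
class ActivityCatalog:
    """Named fall and ADL archetypes making up a cohort protocol."""

    fall_types: tuple[str, ...] = FALL_TYPES
    adl_types: tuple[str, ...] = ADL_TYPES

    def __post_init__(self) -> None:
        names = list(self.fall_types) + list(self.adl_types)
        if len(set(names)) != len(names):
            raise ValueError("activity names must be unique")
        if len(self.adl_types) < 1:
            raise ValueError("catalog needs at least one ADL type")

    @classmethod
    def default(cls) -> "ActivityCatalog":
        """The standard protocol: 15 fall types, 5 scripted ADLs."""
        return cls()

    @property
    def mirrors_protocol(self) -> bool:
        return len(self.fall_types) == 15

    def codes(self) -> dict[str, str]:
        """Short filename codes: F01..F15 for falls, D01.. for ADLs."""
        out = {name: f"F{i + 1:02d}" for i, name in enumerate(self.fall_types)}
        out.update({name: f"D{i + 1:02d}" for i, name in enumerate(self.adl_types)})
        return out


@dataclass
class FallPhaseParams:
    """Timing and intensity of the four-phase fall model (seconds / g)."""

    prefall_duration: float = 5.0
    freefall_duration: float = 0.40
    impact_peak: float = 5.0
    impact_duration: float = 2.10
    rest_duration: float = 2.0
    noise_sd: float = _DEFAULT_NOISE_SD

    def __post_init__(self) -> None:
        for name in ("prefall_duration", "freefall_duration", "impact_duration", "rest_duration"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.impact_peak > 2.0:
            raise ValueError("impact_peak must exceed 2 g to dominate ADL dynamics")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def total_duration(self) -> float:
        return (
            self.prefall_duration
            + self.freefall_duration
            + self.impact_duration
            + self.rest_duration
        )


@dataclass
class DomainShift:
    """Systematic sensor/placement difference between two recording domains.

    ``rotation`` is an xyz Euler perturbation in degrees (sensor mounted in a
    different orientation), ``gain`` a multiplicative amplitude factor,
    ``noise_sd_delta`` extra white noise in g, ``baseline_offset`` a constant
    bias in g added along the sensor z axis, and ``target_rate`` the recording
    rate of the shifted domain.
    """

    rotation: tuple[float, float, float] = (12.0, 8.0, 15.0)
    gain: float = 1.10
    noise_sd_delta: float = 0.002
    baseline_offset: float = 0.02
    target_rate: float = 100.0

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise ValueError("gain must be positive")
        if self.noise_sd_delta < 0:
            raise ValueError("noise_sd_delta must be non-negative")
        if not self.target_rate > 0:
            raise ValueError("target_rate must be positive")

    @classmethod
    def identity(cls, target_rate: float = 200.0) -> "DomainShift":
        """No shift at all (useful as a negative control)."""
        return cls((0.0, 0.0, 0.0), 1.0, 0.0, 0.0, target_rate)

    @classmethod
    def default(cls) -> "DomainShift":
        """Mild placement/electronics difference, 100 Hz recording."""
        return cls()

    @classmethod
    def strong(cls) -> "DomainShift":
        """A hard transfer problem: large orientation change, 1.5x gain and a
        clearly higher sensor noise floor (which also perturbs the spectral
        shape of quiet activity)."""
        return cls((25.0, 40.0, 60.0), 1.5, 0.03, 0.05, 100.0)

    def is_identity(self) -> bool:
        return (
            all(abs(a) < 1e-12 for a in self.rotation)
            and self.gain == 1.0
            and self.noise_sd_delta == 0.0
            and self.baseline_offset == 0.0
        )


@dataclass
class CohortSpec:
    """Size and recording parameters of a lab-style cohort."""

    n_subjects: int = 23
    n_trials_per_activity: int = 5
    trial_duration: float = 15.0
    sample_rate: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials_per_activity < 1:
            raise ValueError("cohort needs at least one subject and one trial")
        if not (self.trial_duration > 0 and self.sample_rate > 0):
            raise ValueError("trial_duration and sample_rate must be positive")


# ---------------------------------------------------------------------------
# Body-frame signal building blocks
# ---------------------------------------------------------------------------


def _sway(n: int, rate: float, rng: np.random.Generator, amp: float = _SWAY_AMP) -> np.ndarray:
    """Postural oscillation during quiet phases: a slow breathing-scale
    component plus a faster low-amplitude balance component (quiet stance is
    structured, never a flat noise floor)."""
    f_slow = rng.uniform(0.18, 0.35)
    f_fast = rng.uniform(0.8, 1.3)
    phi1, phi2 = rng.uniform(0, 2 * math.pi, size=2)
    t = np.arange(n) / rate
    return amp * np.sin(2 * math.pi * f_slow * t + phi1) + 0.4 * amp * np.sin(
        2 * math.pi * f_fast * t + phi2
    )


def _hann_bump(n: int, rate: float, center_s: float, width_s: float) -> np.ndarray:
    """Unit-amplitude raised-cosine bump centred at ``center_s``."""
    t = np.arange(n) / rate
    x = (t - center_s) / width_s
    out = np.zeros(n)
    inside = np.abs(x) <= 0.5
    out[inside] = 0.5 * (1 + np.cos(2 * math.pi * x[inside]))
    return out


def _adl_body_frame(
    activity: str,
    n: int,
    rate: float,
    rng: np.random.Generator,
    noise_sd: float,
    cadence_factor: float = 1.0,
) -> np.ndarray:
    """Body-frame acceleration (gravity along +z) for an ADL archetype."""
    preset = _ADL_PRESETS.get(activity)
    if preset is None:
        raise ValueError(f"unknown ADL archetype {activity!r}")
    t = np.arange(n) / rate
    v = np.zeros(n)
    h1 = np.zeros(n)
    h2 = np.zeros(n)
    kind = preset["kind"]
    if kind == "gait":
        lo, hi = preset["cadence"]
        f = rng.uniform(lo, hi) * cadence_factor
        phi = rng.uniform(0, 2 * math.pi)
        amp = preset["amp"]
        v = amp * (np.sin(2 * math.pi * f * t + phi)
                   + preset["harm"] * np.sin(4 * math.pi * f * t + 2 * phi))
        h1 = 0.35 * amp * np.sin(2 * math.pi * f * t + phi + 1.1)
        h2 = 0.25 * amp * np.sin(2 * math.pi * f * t + 2.3)
        v = v + _sway(n, rate, rng)
    elif kind == "transition":
        # One biphasic magnitude excursion (deceleration then settle).
        sign = preset["sign"]
        c = rng.uniform(1.0, max(1.5, n / rate - 1.5))
        v = sign * (-0.45) * _hann_bump(n, rate, c, 1.0)
        v = v + sign * 0.20 * _hann_bump(n, rate, c + 0.7, 0.6)
        h1 = 0.12 * _hann_bump(n, rate, c, 1.2)
        v = v + _sway(n, rate, rng)
    elif kind == "still":
        v = _sway(n, rate, rng)
    elif kind == "quiet":
        pass  # gravity + noise only
    else:  # pragma: no cover - presets are module-internal
        raise ValueError(f"bad preset kind {kind!r}")
    body = np.column_stack([h1, h2, 1.0 + v])
    if noise_sd > 0:
        body = body + rng.normal(0.0, noise_sd, size=body.shape)
    return body


def _rotation_or_none(rotation) -> Rotation | None:
    if rotation is None:
        return None
    if isinstance(rotation, Rotation):
        return rotation
    return Rotation.from_euler("xyz", rotation, degrees=True)


def _apply_frame(body: np.ndarray, rotation, gain: float) -> np.ndarray:
    rot = _rotation_or_none(rotation)
    out = body if rot is None else rot.apply(body)
    return gain * out


# ---------------------------------------------------------------------------
# Public simulators
# ---------------------------------------------------------------------------


def simulate_adl(
    activity: str,
    duration: float,
    rate: float,
    seed: int = 0,
    *,
    noise_sd: float = _DEFAULT_NOISE_SD,
    gain: float = 1.0,
    rotation=None,
    cadence_factor: float = 1.0,
    subject_id: str = "S00",
    trial: int | None = None,
    domain: str = "lab",
) -> AccelTrace:
    """Simulate one scripted activity-of-daily-living trial.

    The magnitude fluctuates around 1 g with archetype-specific dynamics
    (gait oscillation, a single postural transition, or quiet standing) and
    never exceeds 2.5 g. Identical seeds give identical traces.
    """
    if not (duration > 0 and rate > 0):
        raise ValueError("duration and rate must be positive")
    n = int(round(duration * rate))
    if n < 1:
        raise ValueError("duration * rate must be at least one sample")
    rng = np.random.default_rng(seed)
    body = _adl_body_frame(activity, n, rate, rng, noise_sd, cadence_factor)
    samples = _apply_frame(body, rotation, gain)
    return AccelTrace(
        samples=samples,
        rate=rate,
        subject_id=subject_id,
        activity=activity,
        label_hint=LABEL_ADL,
        domain=domain,
        trial=trial,
    )


def _smooth(x: np.ndarray, k: int) -> np.ndarray:
    if k <= 1:
        return x
    kernel = np.ones(k) / k
    return np.convolve(x, kernel, mode="same")


def simulate_fall(
    fall_type: str,
    phase_params: FallPhaseParams | None = None,
    context_adl: str = "walking",
    duration: float = 15.0,
    rate: float = 200.0,
    seed: int = 0,
    *,
    gain: float = 1.0,
    rotation=None,
    cadence_factor: float = 1.0,
    subject_id: str = "S00",
    trial: int | None = None,
    domain: str = "lab",
) -> tuple[AccelTrace, float]:
    """Simulate one fall trial; returns the trace and the impact time (s).

    Phase layout: ``context_adl`` dynamics until ``prefall_duration``, a
    free-fall dip (magnitude < 0.5 g), a spike whose apex reaches
    ``impact_peak`` exactly, an irregular settling transient for the rest of
    ``impact_duration``, then low-variance lying. The impact time is the
    spike apex, which is also the trace's magnitude argmax.
    """
    pp = phase_params or FallPhaseParams()
    if not (duration > 0 and rate > 0):
        raise ValueError("duration and rate must be positive")
    if pp.total_duration > duration + 1e-9:
        raise ValueError(
            f"phases ({pp.total_duration:.2f} s) exceed trial duration ({duration} s)"
        )
    n = int(round(duration * rate))
    rng = np.random.default_rng(seed)

    i0 = int(round(pp.prefall_duration * rate))           # free-fall onset
    i1 = i0 + int(round(pp.freefall_duration * rate))     # impact onset
    i2 = i1 + int(round(pp.impact_duration * rate))       # rest onset
    i2 = min(i2, n)

    # --- magnitude profile for free fall through rest -----------------------
    # The free-fall dip, spike and settling transient are all strongly
    # irregular at every scale: any smooth or low-variance stretch inside
    # the impact window would dominate the SampEn template matches (the
    # spike inflates the window SD and hence the match tolerance) and mask
    # the irregularity the alignment stage keys on.
    mag = np.empty(n)
    # Free fall: drop to ~0.2 g with heavy flailing noise; stays below 0.5 g.
    n_ff = i1 - i0
    n_ramp = max(n_ff // 4, 1)
    base_ff = np.full(n_ff, 0.20)
    base_ff[:n_ramp] = np.linspace(0.45, 0.20, n_ramp)
    ff = base_ff + rng.normal(0.0, 0.12, size=n_ff)
    mag[i0:i1] = np.clip(ff, 0.02, 0.48)

    # Impact spike: raised cosine of odd length, so its centre sample reaches
    # exactly impact_peak (the apex defines impact_time).
    n_spike = max(int(round(0.05 * rate)) | 1, 3)
    n_spike = min(n_spike, i2 - i1)
    window = 0.5 * (1 - np.cos(2 * math.pi * np.arange(n_spike) / (n_spike - 1)))
    spike = 0.3 + (pp.impact_peak - 0.3) * window
    mag[i1 : i1 + n_spike] = spike
    apex = i1 + n_spike // 2

    # Settling transient: the body bouncing/rolling to rest — white
    # high-variance magnitude fluctuation around 1 g with a mildly decaying
    # envelope tied to impact severity, folded at zero (magnitudes are
    # non-negative) and capped well below the spike apex.
    n_after = i2 - (i1 + n_spike)
    if n_after > 0:
        w = rng.normal(0.0, 1.0, size=n_after)
        envelope = 0.18 * pp.impact_peak * np.linspace(1.0, 0.55, n_after)
        after = np.abs(1.0 + envelope * w)
        mag[i1 + n_spike : i2] = np.minimum(after, 0.75 * pp.impact_peak)

    # Rest: lying still with sway + noise.
    n_rest = n - i2
    if n_rest > 0:
        rest = 1.0 + _sway(n_rest, rate, rng) + rng.normal(0.0, pp.noise_sd, size=n_rest)
        mag[i2:] = np.clip(rest, 0.05, None)

    # --- directions ---------------------------------------------------------
    body = np.empty((n, 3))
    body[:i0] = _adl_body_frame(context_adl, i0, rate, rng, pp.noise_sd, cadence_factor)
    # Tumbling direction: smoothed random drift away from the upright axis.
    n_fall = n - i0
    drift = np.cumsum(rng.normal(0.0, 1.0, size=(n_fall, 3)), axis=0)
    drift = drift / max(math.sqrt(n_fall), 1.0)
    dirs = np.array([0.0, 0.0, 1.0]) + 0.9 * drift
    if n_rest > 0:
        dirs[n - i0 - n_rest :] = dirs[i2 - i0 - 1]  # fixed lying orientation
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    body[i0:] = mag[i0:, None] * dirs

    samples = _apply_frame(body, rotation, gain)
    impact_time = apex / rate
    trace = AccelTrace(
        samples=samples,
        rate=rate,
        subject_id=subject_id,
        activity=fall_type,
        label_hint=LABEL_FALL,
        impact_time=impact_time,
        domain=domain,
        trial=trial,
    )
    return trace, impact_time


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _subject_params(seed_key: Sequence[int]) -> dict:
    """Per-subject placement/kinematics variability (fixed given the seed)."""
    rng = np.random.default_rng(np.random.SeedSequence(list(seed_key)))
    return {
        "rotation": Rotation.from_euler("xyz", rng.normal(0.0, 6.0, size=3), degrees=True),
        "gain": rng.uniform(0.85, 1.15),
        "cadence_factor": rng.uniform(0.9, 1.1),
    }


def _fall_context(fall_type: str) -> str:
    if "jogging" in fall_type:
        return "jogging"
    if "walking" in fall_type:
        return "walking"
    return "standing"


def _fall_phase_params(
    fall_type: str,
    rng: np.random.Generator,
    duration: float,
    min_window: int | None = None,
) -> FallPhaseParams:
    """Draw per-trial phase parameters with the impact centred in one window.

    The free-fall-to-settling span is placed inside a single 2.5 s window of
    the non-overlapping grid, so the ground-truth impact window is
    unambiguous.
    """
    n_windows = int(duration // _GRID_S)
    k_lo = 2 if duration >= 12.5 else 1
    if min_window is not None:
        k_lo = max(k_lo, min_window)
    k_lo = min(k_lo, max(n_windows - 2, 1))  # leave one trailing rest window
    k = int(rng.integers(k_lo, max(n_windows - 1, k_lo + 1)))
    # The fall (free fall + spike + settling) spans window k exactly: the
    # impact window is then wholly irregular, which is what the SampEn
    # alignment stage keys on, and the ground-truth window is unambiguous.
    u = rng.uniform(0.0, 0.08)
    freefall = 0.40
    prefall = k * _GRID_S + u
    impact_dur = _GRID_S - freefall - u
    peak = 5.0 * (1.1 if "jogging" in fall_type else 1.0) * rng.uniform(0.96, 1.12)
    rest = duration - prefall - freefall - impact_dur
    return FallPhaseParams(
        prefall_duration=prefall,
        freefall_duration=freefall,
        impact_peak=peak,
        impact_duration=impact_dur,
        rest_duration=max(rest, 0.5),
        noise_sd=_DEFAULT_NOISE_SD,
    )


def generate_lab_cohort(
    spec: CohortSpec | None = None,
    catalog: ActivityCatalog | None = None,
) -> TraceDataset:
    """Generate one trace per (subject, activity, trial) of a lab cohort.

    Fall trials carry ground-truth ``impact_time`` metadata; per-subject
    sensor orientation, gain (+/-15%) and cadence factors make subject-wise
    splitting meaningful. Trial count is
    ``n_subjects * (n_adl + n_fall) * n_trials``.
    """
    spec = spec or CohortSpec()
    catalog = catalog or ActivityCatalog.default()
    traces: list[AccelTrace] = []
    activities = [(name, LABEL_ADL) for name in catalog.adl_types] + [
        (name, LABEL_FALL) for name in catalog.fall_types
    ]
    for s_idx in range(spec.n_subjects):
        subject_id = f"SA{s_idx + 1:02d}"
        sp = _subject_params([spec.seed, 1, s_idx])
        for a_idx, (activity, kind) in enumerate(activities):
            for t_idx in range(spec.n_trials_per_activity):
                child = np.random.SeedSequence([spec.seed, 2, s_idx, a_idx, t_idx])
                rng = np.random.default_rng(child)
                trial_seed = int(rng.integers(2**31))
                if kind == LABEL_ADL:
                    trace = simulate_adl(
                        activity,
                        spec.trial_duration,
                        spec.sample_rate,
                        seed=trial_seed,
                        gain=sp["gain"],
                        rotation=sp["rotation"],
                        cadence_factor=sp["cadence_factor"],
                        subject_id=subject_id,
                        trial=t_idx + 1,
                    )
                else:
                    # Same placement rule as the real-world generator (first
                    # eligible grid window at 5.0 s needs 7.5 s of lead-in),
                    # so an identity domain shift is distribution-preserving.
                    pp = _fall_phase_params(
                        activity, rng, spec.trial_duration, min_window=3
                    )
                    trace, _ = simulate_fall(
                        activity,
                        pp,
                        context_adl=_fall_context(activity),
                        duration=spec.trial_duration,
                        rate=spec.sample_rate,
                        seed=trial_seed,
                        gain=sp["gain"],
                        rotation=sp["rotation"],
                        cadence_factor=sp["cadence_factor"],
                        subject_id=subject_id,
                        trial=t_idx + 1,
                    )
                traces.append(trace)
    return TraceDataset(traces)


def apply_domain_shift(
    trace: AccelTrace, shift: DomainShift, rng: np.random.Generator
) -> AccelTrace:
    """Rotate, scale, bias, noise and resample a trace into the shifted domain."""
    rot = Rotation.from_euler("xyz", shift.rotation, degrees=True)
    samples = shift.gain * rot.apply(trace.samples)
    samples[:, 2] += shift.baseline_offset
    if shift.noise_sd_delta > 0:
        samples = samples + rng.normal(0.0, shift.noise_sd_delta, size=samples.shape)
    shifted = AccelTrace(
        samples=samples,
        rate=trace.rate,
        subject_id=trace.subject_id,
        activity=trace.activity,
        label_hint=trace.label_hint,
        impact_time=trace.impact_time,
        domain="realworld",
        trial=trace.trial,
    )
    if not math.isclose(shift.target_rate, trace.rate):
        shifted = resample_trace(shifted, shift.target_rate)
    return shifted


def generate_realworld_set(
    n_events: int = 15,
    shift: DomainShift | None = None,
    seed: int = 0,
    catalog: ActivityCatalog | None = None,
    trial_duration: float = 15.0,
    base_rate: float = 200.0,
) -> TraceDataset:
    """Generate real-world-style accidental-fall traces with known impact times.

    Each event is drawn from the same kinematic model as the lab falls
    (identical parameter distributions, so an identity shift is
    distributionally indistinguishable from lab data), then pushed through
    ``shift``. Every trace contains at least 4 s of ADL context plus a 1.5 s
    margin before the impact, so the fixed labeling convention applies.
    """
    if n_events < 1:
        raise ValueError("n_events must be at least 1")
    shift = shift or DomainShift.default()
    catalog = catalog or ActivityCatalog.default()
    traces = []
    for e in range(n_events):
        sp = _subject_params([seed, 3, e])
        child = np.random.SeedSequence([seed, 4, e])
        rng = np.random.default_rng(child)
        trial_seed = int(rng.integers(2**31))
        fall_type = catalog.fall_types[int(rng.integers(len(catalog.fall_types)))]
        # Later grid windows only: the fixed labeling convention needs 5.5 s
        # of pre-impact data, and the first eligible window starts at 5.0 s.
        pp = _fall_phase_params(fall_type, rng, trial_duration, min_window=3)
        trace, _ = simulate_fall(
            fall_type,
            pp,
            context_adl=_fall_context(fall_type),
            duration=trial_duration,
            rate=base_rate,
            seed=trial_seed,
            gain=sp["gain"],
            rotation=sp["rotation"],
            cadence_factor=sp["cadence_factor"],
            subject_id=f"RW{e + 1:02d}",
            trial=1,
        )
        shift_rng = np.random.default_rng(np.random.SeedSequence([seed, 5, e]))
        traces.append(apply_domain_shift(trace, shift, shift_rng))
    return TraceDataset(traces)
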