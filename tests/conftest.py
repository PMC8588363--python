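"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from xfall import synthetic_data as sd


@pytest.fixture(scope="session")
def small_cohort() -> sd.TraceDataset:
    """6 subjects x (15 falls + 5 ADLs) x 2 trials at the standard 15 s / 200 Hz."""
    return sd.generate_lab_cohort(sd.CohortSpec(n_subjects=6, n_trials_per_activity=2, seed=1))


@pytest.fixture(scope="session")
def tiny_catalog() -> sd.ActivityCatalog:
    """A reduced protocol for fast end-to-end runs."""
    return sd.ActivityCatalog(
        fall_types=sd.FALL_TYPES[:3],
        adl_types=("walking", "sitting down"),
    )


@pytest.fixture(scope="session")
def fall_trace() -> tuple[sd.AccelTrace, float]:
    trace, impact = sd.simulate_fall("fall forward while walking caused by a slip", seed=5)
    return trace, impact


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
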