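"""Shared fixtures: deterministic signals and a session-scoped cohort."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from nleeg import (
    EventTable,
    Recording,
    SubjectDesign,
    default_cohort_spec,
    gen_cohort,
)
from nleeg.pipeline import extract_cohort

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

FS = 250.0


@pytest.fixture(scope="session")
def fs() -> float:
    return FS


def sine(freq_hz: float, duration_s: float, fs: float = FS,
         amp: float = 1.0, phase: float = 0.0) -> np.ndarray:
    t = np.arange(int(round(duration_s * fs))) / fs
    return amp * np.sin(2 * np.pi * freq_hz * t + phase)


def am_signal(depth: float, mod_hz: float = 2.0, carrier_hz: float = 10.0,
              duration_s: float = 20.0, fs: float = FS) -> np.ndarray:
    t = np.arange(int(round(duration_s * fs))) / fs
    return (1 + depth * np.cos(2 * np.pi * mod_hz * t)) * np.sin(
        2 * np.pi * carrier_hz * t)


@pytest.fixture
def small_recording() -> Recording:
    rng = np.random.default_rng(0)
    return Recording(
        data=rng.standard_normal((3, int(30 * FS))) * 20.0,
        fs=FS,
        channel_labels=["Fp1", "Cz", "O1"],
        subject_id="s01",
        group="control",
    )


@pytest.fixture
def small_events() -> EventTable:
    return EventTable(pd.DataFrame({
        "onset_s": [0.0, 11.0, 21.0],
        "duration_s": [10.0, 8.0, 8.0],
        "label": ["rest_closed", "laughter", "laughter"],
    }))


# --- session-scoped resting cohort reused by end-to-end checks -------------

REST_DESIGN = SubjectDesign(stimuli=(), n_epochs=0, epoch_s=30.0,
                            rest_s=40.0, include_rest_open=False)


@pytest.fixture(scope="session")
def rest_cohort():
    """Default 5-group cohort at rest (10 subjects/group, 40-s fragments)."""
    spec = default_cohort_spec(n_subjects=10, seed=1, design=REST_DESIGN)
    return gen_cohort(spec)


@pytest.fixture(scope="session")
def rest_tables(rest_cohort):
    """(features, psd) long tables extracted from the resting cohort."""
    return extract_cohort(rest_cohort)
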