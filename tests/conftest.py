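import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mammogist.trial_data import COLUMNS

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

_ROW_DEFAULTS = {
    "participant_id": "P01",
    "session_index": 1,
    "phase_type": "pretest",
    "phase_index": 0,
    "block_index": 0,
    "trial_index": 1,
    "trial_kind": "mammogram",
    "category": "normal",
    "ground_truth": "normal",
    "rating": 10,
    "viewing_time_ms": 500.0,
    "rating_time_ms": 1000.0,
    "max_viewing_time_ms": 500.0,
    "feedback_given": False,
}


def make_trials(rows):
    """Build a trial table from partial row dicts, filling schema defaults."""
    filled = [{**_ROW_DEFAULTS, **r} for r in rows]
    return pd.DataFrame(filled)[COLUMNS]


def training_attention_rows(pid, phase, n_attention=16, n_missed=0):
    """Attention trials of one training phase; the first ``n_missed`` are
    answered on the wrong side of 50."""
    rows = []
    for i in range(n_attention):
        beach = i % 2 == 0
        missed = i < n_missed
        rating = (100 if beach else 0) if missed else (0 if beach else 100)
        rows.append(
            {
                "participant_id": pid,
                "session_index": phase,
                "phase_type": "training",
                "phase_index": phase,
                "block_index": 1 + i % 4,
                "trial_index": i + 1,
                "trial_kind": "attention",
                "category": "scene_beach" if beach else "scene_forest",
                "ground_truth": "normal" if beach else "abnormal",
                "rating": rating,
                "feedback_given": True,
            }
        )
    return rows


def training_mammogram_rows(pid, phase, n=20, rating=30):
    rows = []
    for i in range(n):
        abnormal = i % 2 == 0
        rows.append(
            {
                "participant_id": pid,
                "session_index": phase,
                "phase_type": "training",
                "phase_index": phase,
                "block_index": 1 + i % 4,
                "trial_index": i + 1,
                "trial_kind": "mammogram",
                "category": "obvious" if abnormal else "normal",
                "ground_truth": "abnormal" if abnormal else "normal",
                "rating": rating,
                "feedback_given": True,
            }
        )
    return rows


def full_participant_rows(pid, missed_per_phase=0, fifty_training_phases=(),
                          n_mammograms=20):
    """Nine training phases with attention checks, plus a small pretest."""
    rows = []
    for i in range(10):
        rows.append(
            {
                "participant_id": pid,
                "trial_index": i + 1,
                "category": "obvious" if i % 2 else "normal",
                "ground_truth": "abnormal" if i % 2 else "normal",
                "rating": 80 if i % 2 else 20,
            }
        )
    for phase in range(1, 10):
        rows += training_attention_rows(pid, phase, n_missed=missed_per_phase)
        rating = 50 if phase in fifty_training_phases else 30
        rows += training_mammogram_rows(pid, phase, n=n_mammograms, rating=rating)
    return rows


@pytest.fixture(scope="session")
def small_cohort_trials():
    """Full simulated experiment for three observers (one of each kind)."""
    from mammogist import (
        learner_observer,
        random_observer,
        simulate_experiment,
        static_observer,
    )

    return simulate_experiment(
        [learner_observer(), static_observer(), random_observer()], seed=7
    )


@pytest.fixture(scope="session")
def small_cohort_summaries(small_cohort_trials):
    from mammogist import phase_summaries

    return phase_summaries(small_cohort_trials)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
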