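from __future__ import annotations

import numpy as np
import pytest

from pyrexia_score.cohort import (Analyte, Assessment, Cohort, LabObservation,
                                  PatientTimeline, Sex)


def make_normalized_timeline(rng: np.random.Generator, patient_id: str = "p1",
                             n_days: int = 8, missing_rate: float = 0.15,
                             pyrexia: bool = False) -> PatientTimeline:
    """Random normalized timeline spanning the value ranges the score sees."""
    days = np.sort(rng.choice(np.arange(-20, 120), size=n_days, replace=False))
    assessments = []
    for day in days:
        values = {}
        for analyte in Analyte:
            if rng.random() < missing_rate:
                continue
            # log-uniform over 10..2000 normalized percent, occasional zero
            norm = float(np.exp(rng.uniform(np.log(10), np.log(2000))))
            if rng.random() < 0.02:
                norm = 0.0
            values[analyte] = LabObservation(analyte, norm, normalized_value=norm)
        if values:
            assessments.append(Assessment(int(day), values))
    onset = [int(rng.integers(5, 80))] if pyrexia else []
    return PatientTimeline(patient_id, Sex.M, pyrexia, onset, assessments)


def make_random_cohort(rng: np.random.Generator, n_pyrexia: int = 5,
                       n_control: int = 5) -> Cohort:
    patients = [make_normalized_timeline(rng, f"P{i}", pyrexia=True)
                for i in range(n_pyrexia)]
    patients += [make_normalized_timeline(rng, f"C{i}", pyrexia=False)
                 for i in range(n_control)]
    return Cohort(patients)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220825)


@pytest.fixture
def random_timelines(rng):
    return [make_normalized_timeline(rng, f"t{i}") for i in range(200)]
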