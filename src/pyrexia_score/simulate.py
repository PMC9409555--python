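"""Synthetic patient-cohort simulator.

Generates longitudinal four-analyte laboratory series with the
statistical structure the pyrexia score assumes: irregular sampling that
is denser at treatment start and around the adverse event, per-patient
baselines scattered around the reference mean, a pyrexia signature in
which CRP and LDH rise while leukocytes and thrombocytes fall over the
two weeks before onset and resolve within about ten days after treatment
interruption, and occasional bacterial-infection episodes (CRP and
leukocytes rising together) in either group.  Trajectories are piecewise
log-linear and all noise is multiplicative, so values stay positive.

Onset days follow a log-normal distribution truncated to 5–79 days,
calibrated to a mean of about 31 and a median of about 26.5 days after
treatment start.  Ground truth (onset day, signature and infection
windows) is returned separately from the cohort so downstream analyses
cannot accidentally peek.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any

import numpy as np
import yaml

from .cohort import (Analyte, Assessment, Cohort, LabObservation,
                     PatientTimeline, Sex, denormalize_value)


@dataclass
class SimulationConfig:
    n_pyrexia: int = 50
    n_control: int = 50
    seed: int = 0

    # onset model: log-normal(log_mean, log_sd) on days, truncated to
    # [onset_min, onset_max]; defaults solved so the truncated distribution
    # has mean 31.0 and median 26.5 days exactly
    onset_log_mean: float = 3.5067660771565787
    onset_log_sd: float = 1.0615054352914985
    onset_min: int = 5
    onset_max: int = 79

    # sampling-gap model (days between blood draws): dense near treatment
    # start and around onset, sparse otherwise
    first_day_range: tuple[int, int] = (-21, -3)  # one pre-treatment draw
    dense_gap: tuple[int, int] = (2, 7)
    sparse_gap: tuple[int, int] = (7, 21)
    dense_until_day: int = 21
    dense_around_onset: int = 10
    follow_up_days: int = 120

    # baseline and noise (multiplicative, log-normal)
    baseline_cv: float = 0.15
    noise_cv: float = 0.05
    missing_rate: float = 0.10
    male_fraction: float = 0.65

    # pyrexia signature: fold changes reached at onset, built up over
    # signature_lead_days and resolved within resolution_days after onset
    crp_rise: tuple[float, float] = (4.0, 16.0)
    ldh_rise: tuple[float, float] = (1.3, 2.0)
    leu_fall: tuple[float, float] = (0.60, 0.85)
    thr_fall: tuple[float, float] = (0.60, 0.85)
    signature_lead_days: int = 14
    resolution_days: int = 10

    # bacterial-infection episodes (either group)
    infection_rate: float = 0.2
    infection_crp_rise: tuple[float, float] = (4.0, 10.0)
    infection_leu_rise: tuple[float, float] = (1.3, 2.0)
    infection_duration: int = 7

    label: str = "synthetic"

    def validate(self) -> None:
        if self.n_pyrexia < 0 or self.n_control < 0:
            raise ValueError("cohort sizes must be >= 0")
        if self.follow_up_days <= self.sparse_gap[1]:
            raise ValueError("follow-up shorter than the maximum sampling gap")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.onset_min >= self.onset_max:
            raise ValueError("onset_min must be below onset_max")

    def to_yaml(self, path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        fields = {f: tuple(v) if isinstance(v, list) else v
                  for f, v in data.items()}
        return cls(**fields)


def _cv_to_sigma(cv: float) -> float:
    """Log-space sigma of a log-normal with the given coefficient of variation."""
    return math.sqrt(math.log(1.0 + cv * cv))


def draw_onset_days(rng: np.random.Generator, config: SimulationConfig,
                    n: int) -> np.ndarray:
    """Integer onset days from the truncated log-normal onset model."""
    out = np.empty(n, dtype=int)
    filled = 0
    while filled < n:
        draw = rng.lognormal(config.onset_log_mean, config.onset_log_sd,
                             size=2 * (n - filled) + 8)
        keep = draw[(draw >= config.onset_min) & (draw <= config.onset_max)]
        take = keep[: n - filled]
        out[filled:filled + take.size] = np.rint(take).astype(int)
        filled += take.size
    return out


def _log_interp(day: float, start: float, peak: float, end: float,
                fold: float) -> float:
    """Piecewise log-linear bump: 1 at start, ``fold`` at peak, 1 at end."""
    if day <= start or day >= end:
        return 1.0
    if day <= peak:
        frac = (day - start) / (peak - start)
    else:
        frac = (end - day) / (end - peak)
    return float(math.exp(frac * math.log(fold)))


@dataclass
class PatientTruth:
    patient_id: str
    pyrexia: bool
    onset_day: int | None
    signature_window: tuple[int, int] | None
    infection_window: tuple[int, int] | None

    def to_dict(self) -> dict[str, Any]:
        return {"patient_id": self.patient_id, "pyrexia": self.pyrexia,
                "onset_day": self.onset_day,
                "signature_window": list(self.signature_window)
                if self.signature_window else None,
                "infection_window": list(self.infection_window)
                if self.infection_window else None}


def _sample_days(rng: np.random.Generator, config: SimulationConfig,
                 onset: int | None) -> list[int]:
    days = [int(rng.integers(config.first_day_range[0],
                             config.first_day_range[1] + 1)), 0]
    day = 0
    while day < config.follow_up_days:
        dense = day < config.dense_until_day or (
            onset is not None and abs(day - onset) <= config.dense_around_onset)
        lo, hi = config.dense_gap if dense else config.sparse_gap
        day += int(rng.integers(lo, hi + 1))
        if day <= config.follow_up_days:
            days.append(day)
    return days


def _fold_changes(rng: np.random.Generator, config: SimulationConfig,
                  pyrexia: bool) -> dict[Analyte, float]:
    """Per-analyte fold change reached at the signature peak (log-uniform)."""
    def draw(lo_hi):
        lo, hi = lo_hi
        return float(np.exp(rng.uniform(math.log(lo), math.log(hi))))

    if pyrexia:
        return {Analyte.CRP: draw(config.crp_rise),
                Analyte.LDH: draw(config.ldh_rise),
                Analyte.LEU: draw(config.leu_fall),
                Analyte.THR: draw(config.thr_fall)}
    return {Analyte.CRP: draw(config.infection_crp_rise),
            Analyte.LEU: draw(config.infection_leu_rise),
            Analyte.LDH: 1.0, Analyte.THR: 1.0}


def simulate_patient(rng: np.random.Generator, config: SimulationConfig,
                     patient_id: str, pyrexia: bool,
                     ) -> tuple[PatientTimeline, PatientTruth]:
    sex = Sex.M if rng.random() < config.male_fraction else Sex.F
    sigma_b = _cv_to_sigma(config.baseline_cv)
    sigma_n = _cv_to_sigma(config.noise_cv)
    baseline = {a: 100.0 * float(rng.lognormal(0.0, sigma_b)) for a in Analyte}

    onset = int(draw_onset_days(rng, config, 1)[0]) if pyrexia else None
    signature = None
    if pyrexia:
        signature = (onset - config.signature_lead_days,
                     onset + config.resolution_days)
        folds = _fold_changes(rng, config, pyrexia=True)

    infection = None
    if rng.random() < config.infection_rate:
        lo = 7
        hi = config.follow_up_days - config.infection_duration
        for _ in range(20):  # keep clear of the pyrexia signature window
            start = int(rng.integers(lo, hi + 1))
            window = (start, start + config.infection_duration)
            if signature is None or (window[1] < signature[0] - 7
                                     or window[0] > signature[1] + 7):
                infection = window
                break
        infection_folds = _fold_changes(rng, config, pyrexia=False) \
            if infection else None

    assessments = []
    for day in _sample_days(rng, config, onset):
        values: dict[Analyte, LabObservation] = {}
        for analyte in Analyte:
            if rng.random() < config.missing_rate:
                continue
            level = baseline[analyte]
            if signature is not None:
                level *= _log_interp(day, signature[0], onset, signature[1],
                                     folds[analyte])
            if infection is not None:
                mid = (infection[0] + infection[1]) / 2.0
                level *= _log_interp(day, infection[0], mid, infection[1],
                                     infection_folds[analyte])
            level *= float(rng.lognormal(0.0, sigma_n))
            raw = denormalize_value(analyte, level, sex)
            values[analyte] = LabObservation(analyte, raw)
        if values:
            assessments.append(Assessment(day, values))

    timeline = PatientTimeline(patient_id, sex, pyrexia,
                               [onset] if pyrexia else [], assessments)
    truth = PatientTruth(patient_id, pyrexia, onset, signature, infection)
    return timeline, truth


def simulate_cohort(config: SimulationConfig | None = None,
                    ) -> tuple[Cohort, list[PatientTruth]]:
    """Simulate a cohort plus its per-patient ground-truth records.

    Reproducible: two runs with the same config (including seed) return
    identical cohorts.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    patients, truths = [], []
    for i in range(config.n_pyrexia):
        timeline, truth = simulate_patient(rng, config, f"P{i + 1:03d}", True)
        patients.append(timeline)
        truths.append(truth)
    for i in range(config.n_control):
        timeline, truth = simulate_patient(rng, config, f"C{i + 1:03d}", False)
        patients.append(timeline)
        truths.append(truth)
    return Cohort(patients, label=config.label), truths


def worked_example_timeline() -> PatientTimeline:
    """The fixed three-assessment example timeline used throughout the docs.

    Normalized values (day: LEU, THR, LDH, CRP):
    0: 110, 100, 90, 100 — 14: 95, 85, 120, 400 — 28: 80, 75, 160, 900;
    a male pyrexia patient with onset on day 28.  Under the version-5
    defaults the day-28 score is 92.93.
    """
    rows = {0: (110.0, 100.0, 90.0, 100.0),
            14: (95.0, 85.0, 120.0, 400.0),
            28: (80.0, 75.0, 160.0, 900.0)}
    order = (Analyte.LEU, Analyte.THR, Analyte.LDH, Analyte.CRP)
    assessments = []
    for day, norms in rows.items():
        values = {}
        for analyte, norm in zip(order, norms):
            raw = denormalize_value(analyte, norm, Sex.M)
            values[analyte] = LabObservation(analyte, raw, normalized_value=norm)
        assessments.append(Assessment(day, values))
    return PatientTimeline("worked-example", Sex.M, True, [28], assessments)
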