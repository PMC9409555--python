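"""Domain model and I/O for irregular laboratory time series.

The pyrexia score works on four routine blood values — leukocyte count,
thrombocyte count, lactate dehydrogenase (LDH) and C-reactive protein
(CRP) — sampled at uneven intervals relative to the start of BRAF/MEK
inhibitor therapy (day 0).  Raw concentrations are normalized to a
dimensionless percentage of a reference mean (100 = reference), so that
changes of the four analytes live on a common scale.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd


class Analyte(str, Enum):
    """The four blood values entering the score."""

    LEU = "LEU"  # leukocyte count, /nl
    THR = "THR"  # thrombocyte count, /nl
    LDH = "LDH"  # lactate dehydrogenase, U/l
    CRP = "CRP"  # C-reactive protein, mg/l


class Sex(str, Enum):
    M = "M"
    F = "F"


#: Native units of the raw values, for CSV round-trips and display.
UNITS: dict[Analyte, str] = {
    Analyte.LEU: "/nl",
    Analyte.THR: "/nl",
    Analyte.LDH: "U/l",
    Analyte.CRP: "mg/l",
}

#: Reference means mapping raw concentrations to normalized 100.
#: Only the leukocyte count has a sex-specific reference; the other three
#: use a single value for both sexes.  Overridable wherever a
#: ``references`` mapping is accepted (same nesting as this dict).
DEFAULT_REFERENCES: dict[Analyte, object] = {
    Analyte.LEU: {Sex.M: 6.5, Sex.F: 6.0},
    Analyte.THR: 275.0,
    Analyte.LDH: 125.0,
    Analyte.CRP: 2.5,
}


def reference_value(analyte: Analyte, sex: Sex | None = None,
                    references: Mapping | None = None) -> float:
    """Reference concentration for ``analyte`` (sex-specific for LEU)."""
    refs = DEFAULT_REFERENCES if references is None else references
    ref = refs[Analyte(analyte)]
    if isinstance(ref, Mapping):
        if sex is None:
            raise ValueError(f"sex required to normalize {analyte}")
        ref = ref[Sex(sex)]
    return float(ref)


def normalize_value(analyte: Analyte, raw_value: float, sex: Sex | None = None,
                    references: Mapping | None = None) -> float:
    """Express ``raw_value`` as a percentage of the reference mean.

    ``normalized = 100 * raw / reference(analyte, sex)``; 100 means "at
    the reference".
    """
    if raw_value < 0:
        raise ValueError(f"negative laboratory value: {raw_value!r}")
    return 100.0 * float(raw_value) / reference_value(analyte, sex, references)


def denormalize_value(analyte: Analyte, normalized_value: float,
                      sex: Sex | None = None,
                      references: Mapping | None = None) -> float:
    """Inverse of :func:`normalize_value`."""
    if normalized_value < 0:
        raise ValueError(f"negative normalized value: {normalized_value!r}")
    return float(normalized_value) * reference_value(analyte, sex, references) / 100.0


@dataclass
class LabObservation:
    """One analyte measurement on one day (raw and, once computed, normalized)."""

    analyte: Analyte
    raw_value: float
    normalized_value: float | None = None

    def __post_init__(self) -> None:
        self.analyte = Analyte(self.analyte)
        if self.raw_value < 0:
            raise ValueError("raw_value must be >= 0")
        if self.normalized_value is not None and self.normalized_value < 0:
            raise ValueError("normalized_value must be >= 0")


@dataclass
class Assessment:
    """All observations drawn on one day; any subset of analytes may be present."""

    day: int
    values: dict[Analyte, LabObservation] = field(default_factory=dict)

    def normalized(self, analyte: Analyte) -> float | None:
        """Normalized value of ``analyte`` on this day, or None if missing."""
        obs = self.values.get(Analyte(analyte))
        return None if obs is None else obs.normalized_value


@dataclass
class PatientTimeline:
    """Ordered assessments of one patient plus pyrexia metadata.

    Days count from the first treatment day (day 0); negative days are
    pre-treatment.  ``onset_days`` holds the start day of each independent
    pyrexia episode; only the first episode drives evaluation labels.
    """

    patient_id: str
    sex: Sex
    pyrexia: bool
    onset_days: list[int] = field(default_factory=list)
    assessments: list[Assessment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        if self.pyrexia and not self.onset_days:
            raise ValueError(f"{self.patient_id}: pyrexia without onset day")
        if not self.pyrexia and self.onset_days:
            raise ValueError(f"{self.patient_id}: onset days without pyrexia")
        days = [a.day for a in self.assessments]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(f"{self.patient_id}: assessment days must strictly increase")

    @property
    def first_onset(self) -> int | None:
        return min(self.onset_days) if self.onset_days else None


@dataclass
class Cohort:
    patients: list[PatientTimeline] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient ids: {dup}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)


def normalize_timeline(timeline: PatientTimeline,
                       references: Mapping | None = None) -> PatientTimeline:
    """Return a copy of ``timeline`` with normalized values filled in."""
    out = copy.deepcopy(timeline)
    for assessment in out.assessments:
        for obs in assessment.values.values():
            obs.normalized_value = normalize_value(
                obs.analyte, obs.raw_value, out.sex, references)
    return out


def normalize_cohort(cohort: Cohort, references: Mapping | None = None) -> Cohort:
    return Cohort([normalize_timeline(p, references) for p in cohort.patients],
                  label=cohort.label)


def realign_days(timeline: PatientTimeline, anchor: str) -> PatientTimeline:
    """Shift the day axis so that ``anchor`` becomes day 0.

    ``anchor`` is ``"treatment_start"`` (identity) or
    ``"first_pyrexia_onset"``.  Display/evaluation convenience only; the
    input timeline is not mutated.
    """
    if anchor == "treatment_start":
        return copy.deepcopy(timeline)
    if anchor != "first_pyrexia_onset":
        raise ValueError(f"unknown anchor: {anchor!r}")
    onset = timeline.first_onset
    if onset is None:
        raise ValueError(
            f"{timeline.patient_id}: cannot realign to pyrexia onset of a "
            "non-pyrexia patient")
    out = copy.deepcopy(timeline)
    for assessment in out.assessments:
        assessment.day -= onset
    out.onset_days = [d - onset for d in out.onset_days]
    return out


# ---------------------------------------------------------------------------
# CSV I/O
#
# Long-format cohort CSV: patient_id, sex, day, analyte, value, unit.
# Metadata CSV: patient_id, pyrexia (0|1), onset_days (";"-separated ints).
# ---------------------------------------------------------------------------

COHORT_COLUMNS = ["patient_id", "sex", "day", "analyte", "value", "unit"]
META_COLUMNS = ["patient_id", "pyrexia", "onset_days"]


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_cohort(path, meta_path, label: str = "") -> Cohort:
    """Read a cohort from a long-format values CSV plus a metadata CSV.

    Rows with unparseable values are rejected with row-level diagnostics;
    duplicate (patient, day, analyte) keys are an error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, COHORT_COLUMNS[:5], path)
    meta = pd.read_csv(meta_path, dtype=str, keep_default_na=False)
    _require_columns(meta, META_COLUMNS[:2], meta_path)

    errors: list[str] = []
    parsed = []
    for idx, row in df.iterrows():
        rowno = idx + 2  # header is line 1
        try:
            day = int(row["day"])
            analyte = Analyte(row["analyte"])
            sex = Sex(row["sex"])
            value = float(row["value"])
            if value < 0:
                raise ValueError("negative value")
        except (ValueError, KeyError) as exc:
            errors.append(f"{path} line {rowno}: {exc} in {dict(row)}")
            continue
        parsed.append((row["patient_id"], sex, day, analyte, value))
    if errors:
        raise ValueError("unparseable rows:\n" + "\n".join(errors))

    seen: set[tuple] = set()
    for pid, _sex, day, analyte, _value in parsed:
        key = (pid, day, analyte.value)
        if key in seen:
            raise ValueError(f"duplicate (patient, day, analyte) row: {key}")
        seen.add(key)

    meta_map: dict[str, tuple[bool, list[int]]] = {}
    for idx, row in meta.iterrows():
        pid = row["patient_id"]
        if pid in meta_map:
            raise ValueError(f"{meta_path}: duplicate metadata for patient {pid}")
        pyrexia = bool(int(row["pyrexia"]))
        raw_onsets = str(row.get("onset_days", "") or "").strip()
        onsets = [int(t) for t in raw_onsets.split(";") if t != ""]
        meta_map[pid] = (pyrexia, onsets)

    by_patient: dict[str, dict] = {}
    for pid, sex, day, analyte, value in parsed:
        entry = by_patient.setdefault(pid, {"sex": sex, "days": {}})
        entry["days"].setdefault(day, {})[analyte] = LabObservation(analyte, value)

    patients = []
    for pid, entry in by_patient.items():
        if pid not in meta_map:
            raise ValueError(f"patient {pid} has values but no metadata row")
        pyrexia, onsets = meta_map[pid]
        assessments = [Assessment(day, values)
                       for day, values in sorted(entry["days"].items())]
        patients.append(PatientTimeline(pid, entry["sex"], pyrexia, onsets,
                                        assessments))
    # metadata-only patients (no lab rows yet) are kept with empty timelines
    for pid, (pyrexia, onsets) in meta_map.items():
        if pid not in by_patient:
            patients.append(PatientTimeline(pid, Sex.M, pyrexia, onsets, []))
    return Cohort(patients, label=label)


def write_cohort(cohort: Cohort, path, meta_path) -> None:
    """Write ``cohort`` as the long-format values CSV plus metadata CSV."""
    rows = []
    for p in cohort.patients:
        for a in p.assessments:
            for analyte in Analyte:  # stable column order
                obs = a.values.get(analyte)
                if obs is None:
                    continue
                rows.append({"patient_id": p.patient_id, "sex": p.sex.value,
                             "day": a.day, "analyte": analyte.value,
                             "value": repr(obs.raw_value),
                             "unit": UNITS[analyte]})
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)
    meta_rows = [{"patient_id": p.patient_id, "pyrexia": int(p.pyrexia),
                  "onset_days": ";".join(str(d) for d in p.onset_days)}
                 for p in cohort.patients]
    pd.DataFrame(meta_rows, columns=META_COLUMNS).to_csv(meta_path, index=False)


def load_references(path) -> dict:
    """Load a reference-value override mapping from a JSON or YAML file."""
    import json

    import yaml

    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    refs: dict[Analyte, object] = {}
    for key, val in data.items():
        analyte = Analyte(key)
        if isinstance(val, Mapping):
            refs[analyte] = {Sex(s): float(v) for s, v in val.items()}
        else:
            refs[analyte] = float(val)
    return refs
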