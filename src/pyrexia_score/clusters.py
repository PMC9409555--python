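"""Assignment of laboratory assessments to the four analysis time clusters.

Retrospective sampling is irregular, so the cohort statistics use four
windows that each contribute at most one assessment per patient: the last
evaluation before therapy start (pre_T), the first after it (post_T), the
last before pyrexia onset (pre_P) and the first at/after onset (post_P).
Patients who never developed pyrexia are processed through the same
windows around a pseudo-onset day — the cohort's mean first-onset day —
so that any purely time-driven drift shows up in both groups alike.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .cohort import Analyte, Assessment, Cohort, PatientTimeline


class Cluster(str, Enum):
    pre_T = "pre_T"
    post_T = "post_T"
    pre_P = "pre_P"
    post_P = "post_P"


#: window length in days on each side of the anchoring event:
#: pre_T = [T-33, T-1], post_T = [T+1, T+21],
#: pre_P = [P-23, P-1], post_P = [P, P+28]  (P0 inclusive).
WINDOWS = {
    Cluster.pre_T: (-33, -1),
    Cluster.post_T: (1, 21),
    Cluster.pre_P: (-23, -1),
    Cluster.post_P: (0, 28),
}


@dataclass
class ClusterAssignment:
    patient_id: str
    cluster: Cluster
    chosen_day: int
    assessment: Assessment


def _window_days(cluster: Cluster, onset: int) -> tuple[int, int]:
    lo, hi = WINDOWS[cluster]
    anchor = 0 if cluster in (Cluster.pre_T, Cluster.post_T) else onset
    return anchor + lo, anchor + hi


def _pick(candidates: list[Assessment], event_day: int,
          selection: str) -> Assessment | None:
    """Choose one assessment from a window.

    ``closest``: nearest to the window's defining event, ties toward the
    later day; ``first``/``last``: earliest/latest day in the window.
    """
    if not candidates:
        return None
    if selection == "closest":
        return min(candidates, key=lambda a: (abs(a.day - event_day), -a.day))
    if selection == "first":
        return min(candidates, key=lambda a: a.day)
    if selection == "last":
        return max(candidates, key=lambda a: a.day)
    raise ValueError(f"unknown selection rule: {selection!r}")


def assign_clusters(timeline: PatientTimeline,
                    pseudo_onset_day: int | None = None,
                    selection: str = "closest",
                    ) -> dict[Cluster, ClusterAssignment | None]:
    """One assessment per cluster (or None where the window is empty).

    Pyrexia patients anchor the P windows at their first onset;
    non-pyrexia patients require ``pseudo_onset_day``.  An assessment may
    serve only one cluster; when windows overlap the pyrexia-proximal
    clusters (pre_P, post_P) claim their assessment first, then pre_T and
    post_T pick from the remainder.
    """
    onset = timeline.first_onset
    if onset is None:
        if pseudo_onset_day is None:
            raise ValueError(
                f"{timeline.patient_id}: pseudo_onset_day required for a "
                "non-pyrexia patient")
        onset = int(pseudo_onset_day)

    available = list(timeline.assessments)
    out: dict[Cluster, ClusterAssignment | None] = {}
    # P-anchored clusters claim first; both orders of the dict literal below
    # keep cluster windows disjoint in their claims.
    for cluster in (Cluster.pre_P, Cluster.post_P, Cluster.pre_T, Cluster.post_T):
        lo, hi = _window_days(cluster, onset)
        event = 0 if cluster in (Cluster.pre_T, Cluster.post_T) else onset
        chosen = _pick([a for a in available if lo <= a.day <= hi], event, selection)
        if chosen is None:
            out[cluster] = None
        else:
            out[cluster] = ClusterAssignment(timeline.patient_id, cluster,
                                             chosen.day, chosen)
            available.remove(chosen)
    return {c: out[c] for c in Cluster}  # stable pre_T..post_P order


def mean_onset_day(cohort: Cohort) -> float:
    """Arithmetic mean of the first pyrexia-onset days of the cohort."""
    onsets = [p.first_onset for p in cohort if p.pyrexia]
    if not onsets:
        raise ValueError("cohort has no pyrexia patients")
    return float(sum(onsets)) / len(onsets)


def cohort_cluster_table(cohort: Cohort, selection: str = "closest",
                         pseudo_onset_day: int | None = None) -> pd.DataFrame:
    """Cluster assignments for a whole cohort as a long table.

    Non-pyrexia patients use ``pseudo_onset_day`` (default: the cohort
    mean onset, rounded to the nearest day).  Missing windows appear with
    NA day/values so per-cluster missingness is visible.
    """
    if pseudo_onset_day is None:
        pseudo_onset_day = round(mean_onset_day(cohort))
    rows = []
    for patient in cohort:
        assigned = assign_clusters(patient, pseudo_onset_day, selection)
        for cluster, assignment in assigned.items():
            row = {"patient_id": patient.patient_id, "cluster": cluster.value,
                   "pyrexia": patient.pyrexia}
            if assignment is None:
                row["day"] = pd.NA
                row.update({a.value: pd.NA for a in Analyte})
            else:
                row["day"] = assignment.chosen_day
                for a in Analyte:
                    v = assignment.assessment.normalized(a)
                    row[a.value] = v if v is not None else pd.NA
            rows.append(row)
    return pd.DataFrame(rows, columns=["patient_id", "cluster", "pyrexia", "day",
                                       *(a.value for a in Analyte)])
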