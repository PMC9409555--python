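"""The pyrexia-score algorithm, versions 1.0–5.0.

At each blood-sampling date tx the score compares the four normalized
values (leukocytes, thrombocytes, LDH, CRP) with the previous sampling
date tx-1 and, from version 2 on, repeats the comparison for tx-1 vs
tx-2.  Each comparison yields a binary change indicator S1..S8: a fall of
leukocytes or thrombocytes, or a rise of LDH or CRP, counts only when the
relative change exceeds a factor F AND the current value has already
crossed an absolute gate T.  The indicators are summed (weighted by
FS1..FS8 from version 3), multiplied by simultaneity factors OA1..OA6 for
pairs of co-occurring t0 changes (version 4), and finally damped by two
version-5 gates: a bacterial-infection signature (simultaneous CRP and
leukocyte RISE → factor IS) and a CRP floor (CRP at t0 below CT →
factor GC).

Missing values never fire an indicator; the only exception is the CRP
gate, which by design reports 1 (no damping) when CRP was not measured.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import pandas as pd

from .cohort import Analyte, Cohort, PatientTimeline
from .params import ParameterSet

#: analyte order of the indicator blocks: V1..V4.
ANALYTE_ORDER = (Analyte.LEU, Analyte.THR, Analyte.LDH, Analyte.CRP)

#: direction of the expected pyrexia change per analyte.
DIRECTIONS = ("falling", "falling", "rising", "rising")

#: index pairs (into S1..S4) of the six simultaneity multipliers OA1..OA6.
OA_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))

#: analyte order of the infection-signature conditions (IC/IM order).
INFECTION_ORDER = (Analyte.LEU, Analyte.CRP, Analyte.THR, Analyte.LDH)


@dataclass
class ScorePoint:
    """Pyrexia score of one assessment, with its component breakdown."""

    day: int
    ps: float
    s: tuple[int, ...]  # S1..S8
    base_sum: float
    oa_multiplier: float
    infection_flag: bool
    crp_gate_applied: bool


def change_indicator(current: float | None, previous: float | None,
                     factor: float, threshold: float, direction: str) -> int:
    """Binary change indicator for one analyte over one sampling interval.

    falling: 1 iff previous/current >= factor and current <= threshold;
    rising:  1 iff previous/current <= factor and current >= threshold.
    Absent values, or current = 0 (undefined ratio), give 0.
    """
    if direction not in ("falling", "rising"):
        raise ValueError(f"direction must be 'falling' or 'rising', got {direction!r}")
    if current is None or previous is None or current == 0:
        return 0
    ratio = previous / current
    if direction == "falling":
        return int(ratio >= factor and current <= threshold)
    return int(ratio <= factor and current >= threshold)


def _block(current_values, previous_values, factors, thresholds) -> tuple[int, ...]:
    return tuple(
        change_indicator(current_values[k], previous_values[k],
                         factors[k], thresholds[k], DIRECTIONS[k])
        for k in range(4))


def indicators(t0, t1, t2, params: ParameterSet) -> tuple[int, ...]:
    """S1..S8 for assessment ``t0`` given predecessors ``t1`` and ``t2``.

    ``t1``/``t2`` may be None (start of a timeline): a missing t-1 blanks
    all eight indicators, a missing t-2 blanks S5..S8.
    """
    if t1 is None:
        return (0,) * 8
    v0 = [t0.normalized(a) for a in ANALYTE_ORDER]
    v1 = [t1.normalized(a) for a in ANALYTE_ORDER]
    s_t0 = _block(v0, v1, params.f_t0, params.t_t0)
    if t2 is None:
        return s_t0 + (0,) * 4
    v2 = [t2.normalized(a) for a in ANALYTE_ORDER]
    return s_t0 + _block(v1, v2, params.f_t1, params.t_t1)


def base_sum(s: tuple[int, ...], params: ParameterSet) -> float:
    """Weighted sum of the eight indicators (unit weights below version 3)."""
    active = s[:4] + (0,) * 4 if params.version < 2 else s
    weights = params.weights if params.version >= 3 else (1.0,) * 8
    return float(sum(si * wi for si, wi in zip(active, weights)))


def simultaneity_multiplier(s_t0: tuple[int, ...], params: ParameterSet) -> float:
    """Product of the OA factors whose two t0 indicators both fired.

    Returns 1 below version 4 and for the empty set of pairs.
    """
    if params.version < 4:
        return 1.0
    mult = 1.0
    for oa, (i, j) in zip(params.oa, OA_PAIRS):
        if s_t0[i] and s_t0[j]:
            mult *= oa
    return mult


def _rise_condition(current, previous, ic, im) -> bool:
    if current is None or previous is None or current == 0:
        return False
    return previous / current <= ic and current >= im


def infection_conditions(t0, t1, params: ParameterSet) -> dict[Analyte, bool]:
    """The four per-analyte rise conditions of the infection signature."""
    ics = (params.IC1, params.IC2, params.IC3, params.IC4)
    ims = (params.IM1, params.IM2, params.IM3, params.IM4)
    out = {}
    for analyte, ic, im in zip(INFECTION_ORDER, ics, ims):
        cur = t0.normalized(analyte) if t0 is not None else None
        prev = t1.normalized(analyte) if t1 is not None else None
        out[analyte] = _rise_condition(cur, prev, ic, im)
    return out


def infection_signature(t0, t1, params: ParameterSet) -> bool:
    """True when the required rise conditions all hold (version 5 only).

    By default the leukocyte and CRP rises are required; the
    thrombocyte/LDH conditions are controlled by ``params.infection_mask``.
    """
    if params.version < 5 or t1 is None:
        return False
    conditions = infection_conditions(t0, t1, params)
    required = [conditions[a] for a, m in zip(INFECTION_ORDER, params.infection_mask) if m]
    return bool(required) and all(required)


def crp_gate(crp_at_t0: float | None, params: ParameterSet) -> float:
    """Damping factor of the CRP floor: GC when CRP at t0 is below CT.

    Reports 1 when CRP is at/above CT, when CRP was not measured, or
    below version 5.
    """
    if params.version < 5 or crp_at_t0 is None or crp_at_t0 >= params.CT:
        return 1.0
    return params.GC


def compute_scores(timeline: PatientTimeline,
                   params: ParameterSet | None = None) -> list[ScorePoint]:
    """One :class:`ScorePoint` per assessment of a normalized timeline."""
    if params is None:
        params = ParameterSet()
    _check_normalized(timeline)
    points: list[ScorePoint] = []
    assessments = timeline.assessments
    for i, t0 in enumerate(assessments):
        t1 = assessments[i - 1] if i >= 1 else None
        t2 = assessments[i - 2] if i >= 2 else None
        s = indicators(t0, t1, t2, params)
        base = base_sum(s, params)
        oa = simultaneity_multiplier(s[:4], params)
        infected = infection_signature(t0, t1, params)
        gate = crp_gate(t0.normalized(Analyte.CRP), params)
        ps = base * oa * (params.IS if infected else 1.0) * gate
        points.append(ScorePoint(day=t0.day, ps=ps, s=s, base_sum=base,
                                 oa_multiplier=oa, infection_flag=infected,
                                 crp_gate_applied=(gate != 1.0)))
    return points


def _check_normalized(timeline: PatientTimeline) -> None:
    for a in timeline.assessments:
        for obs in a.values.values():
            if obs.normalized_value is None:
                raise ValueError(
                    f"{timeline.patient_id} day {a.day}: timeline must be "
                    "normalized before scoring (see normalize_cohort)")


def max_attainable_score(params: ParameterSet | None = None) -> float:
    """Exact upper bound of the score for a given parameter set.

    Enumerates all 256 indicator patterns and maximizes the weighted sum
    times the simultaneity product of the t0 sub-pattern; the damping
    gates can only lower a score and are left inactive.
    """
    if params is None:
        params = ParameterSet()
    best = 0.0
    for s in product((0, 1), repeat=8):
        value = base_sum(s, params) * simultaneity_multiplier(s[:4], params)
        best = max(best, value)
    return best


def scores_frame(cohort: Cohort, params: ParameterSet | None = None) -> pd.DataFrame:
    """Score every patient; long table for the evaluation module.

    Columns: patient_id, day, ps, s1..s8, base_sum, oa_multiplier,
    infection_flag, crp_gate_applied, pyrexia, onset_day.
    """
    rows = []
    for patient in cohort:
        onset = patient.first_onset
        for pt in compute_scores(patient, params):
            row = {"patient_id": patient.patient_id, "day": pt.day, "ps": pt.ps}
            row.update({f"s{k + 1}": pt.s[k] for k in range(8)})
            rows.append({**row, "base_sum": pt.base_sum,
                         "oa_multiplier": pt.oa_multiplier,
                         "infection_flag": pt.infection_flag,
                         "crp_gate_applied": pt.crp_gate_applied,
                         "pyrexia": patient.pyrexia,
                         "onset_day": onset if onset is not None else pd.NA})
    columns = (["patient_id", "day", "ps"] + [f"s{k}" for k in range(1, 9)] +
               ["base_sum", "oa_multiplier", "infection_flag",
                "crp_gate_applied", "pyrexia", "onset_day"])
    return pd.DataFrame(rows, columns=columns)
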