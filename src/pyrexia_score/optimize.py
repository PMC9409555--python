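"""Objective ratios and the one-round heuristic parameter search.

The tuning objective compares mean scores between the groups:

* ``M0P``  — mean score over all assessments of non-pyrexia patients,
* ``MWP``  — mean score over all assessments of pyrexia patients,
* ``MWP14`` — mean over pyrexia patients' assessments within one week on
  either side of their first onset,

combined into ``ratio_all = MWP / (M0P + MWP)`` and
``ratio_14 = MWP14 / (M0P + MWP)``.

The search is deliberately primitive — a faithful single pass of
incremental coordinate steps: each variable in turn is nudged by one
family-specific increment, the step is kept while the ratios improve,
reversed once if the first step hurt, and the best value is retained
before moving on.  Exactly one round is performed; there is no gradient,
restart or cross-validation.

Scoring inside the search runs on a vectorized snapshot of the cohort
(:class:`CohortMatrix`), which computes the same scores as
:func:`pyrexia_score.score.compute_scores` (exact agreement is enforced
by the test suite) at a fraction of the cost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .params import ParameterSet, parameter_family
from .score import ANALYTE_ORDER, INFECTION_ORDER, OA_PAIRS

#: ±7-day window around onset defining the MWP14 observation set.
ONSET_WINDOW_DAYS = 7

#: default increment per variable family, matching the printed precision
#: of the published parameter table (0.01 on ratio/weight scales, 10 on
#: the normalized-percent scale of the absolute gates).
DEFAULT_STEPS: dict[str, float] = {
    "F": 0.01, "IC": 0.01, "FS": 0.01, "OA": 0.01, "GC": 0.01, "IS": 0.01,
    "T": 10.0, "IM": 10.0, "CT": 10.0,
}

#: default visiting order (the published listing order; CT is not listed).
DEFAULT_ORDER: tuple[str, ...] = (
    *(f"F{i}" for i in range(1, 9)),
    *(f"T{i}" for i in range(1, 9)),
    *(f"FS{i}" for i in range(1, 9)),
    *(f"OA{i}" for i in range(1, 7)),
    "IS", "GC",
    *(f"IC{i}" for i in range(1, 5)),
    *(f"IM{i}" for i in range(1, 5)),
)

# lower/upper bounds per family; steps never leave these.
_BOUNDS: dict[str, tuple[float, float]] = {
    "F": (1e-6, np.inf), "IC": (1e-6, np.inf),
    "T": (0.0, np.inf), "IM": (0.0, np.inf), "CT": (0.0, np.inf),
    "FS": (0.0, np.inf), "OA": (0.0, np.inf),
    "GC": (1e-6, 1.0), "IS": (1e-6, 1.0),
}


@dataclass
class ObjectiveSummary:
    m0p: float
    mwp: float
    mwp14: float
    ratio_all: float | None
    ratio_14: float | None
    n_control_obs: int
    n_pyrexia_obs: int
    n_window_obs: int

    @property
    def defined(self) -> bool:
        return self.ratio_all is not None


class CohortMatrix:
    """Vectorized snapshot of a normalized cohort for repeated scoring.

    One row per assessment; ``v0``/``v1``/``v2`` hold the normalized
    values at tx, tx-1 and tx-2 (NaN where an analyte was not measured or
    the predecessor does not exist), in the analyte order LEU, THR, LDH,
    CRP.
    """

    def __init__(self, cohort: Cohort):
        v0, v1, v2, pyrexia, window14 = [], [], [], [], []
        for patient in cohort:
            assessments = patient.assessments
            onset = patient.first_onset
            for i, t0 in enumerate(assessments):
                t1 = assessments[i - 1] if i >= 1 else None
                t2 = assessments[i - 2] if i >= 2 else None

                def row(a):
                    if a is None:
                        return [np.nan] * 4
                    vals = [a.normalized(k) for k in ANALYTE_ORDER]
                    if any(v is None for v in
                           (obs.normalized_value for obs in a.values.values())):
                        raise ValueError("cohort must be normalized before scoring")
                    return [np.nan if v is None else v for v in vals]

                v0.append(row(t0))
                v1.append(row(t1))
                v2.append(row(t2))
                pyrexia.append(patient.pyrexia)
                window14.append(patient.pyrexia and onset is not None
                                and abs(t0.day - onset) <= ONSET_WINDOW_DAYS)
        self.v0 = np.asarray(v0, dtype=float).reshape(-1, 4)
        self.v1 = np.asarray(v1, dtype=float).reshape(-1, 4)
        self.v2 = np.asarray(v2, dtype=float).reshape(-1, 4)
        self.pyrexia = np.asarray(pyrexia, dtype=bool)
        self.window14 = np.asarray(window14, dtype=bool)

    def __len__(self) -> int:
        return self.v0.shape[0]

    @staticmethod
    def _block(cur: np.ndarray, prev: np.ndarray, factors, thresholds) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = prev / cur
        valid = np.isfinite(cur) & np.isfinite(prev) & (cur > 0)
        s = np.zeros(cur.shape, dtype=bool)
        for k, direction in enumerate(("falling", "falling", "rising", "rising")):
            with np.errstate(invalid="ignore"):
                if direction == "falling":
                    hit = (ratio[:, k] >= factors[k]) & (cur[:, k] <= thresholds[k])
                else:
                    hit = (ratio[:, k] <= factors[k]) & (cur[:, k] >= thresholds[k])
            s[:, k] = valid[:, k] & hit
        return s

    def scores(self, params: ParameterSet) -> np.ndarray:
        """Pyrexia score of every assessment under ``params``."""
        s_t0 = self._block(self.v0, self.v1, params.f_t0, params.t_t0)
        s_t1 = self._block(self.v1, self.v2, params.f_t1, params.t_t1)
        if params.version < 2:
            s_t1 = np.zeros_like(s_t1)
        weights = np.asarray(params.weights if params.version >= 3 else (1.0,) * 8)
        base = np.hstack([s_t0, s_t1]).astype(float) @ weights

        oa = np.ones(len(self))
        if params.version >= 4:
            for factor, (i, j) in zip(params.oa, OA_PAIRS):
                oa = np.where(s_t0[:, i] & s_t0[:, j], oa * factor, oa)

        damping = np.ones(len(self))
        if params.version >= 5:
            infected = np.ones(len(self), dtype=bool)
            any_required = False
            ics = (params.IC1, params.IC2, params.IC3, params.IC4)
            ims = (params.IM1, params.IM2, params.IM3, params.IM4)
            for analyte, ic, im, required in zip(
                    INFECTION_ORDER, ics, ims, params.infection_mask):
                if not required:
                    continue
                any_required = True
                k = ANALYTE_ORDER.index(analyte)
                cur, prev = self.v0[:, k], self.v1[:, k]
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratio = prev / cur
                with np.errstate(invalid="ignore"):
                    cond = (np.isfinite(cur) & np.isfinite(prev) & (cur > 0)
                            & (ratio <= ic) & (cur >= im))
                infected &= cond
            if not any_required:
                infected[:] = False
            damping = np.where(infected, params.IS, 1.0)
            crp0 = self.v0[:, ANALYTE_ORDER.index("CRP")]
            with np.errstate(invalid="ignore"):
                gated = np.isfinite(crp0) & (crp0 < params.CT)
            damping = damping * np.where(gated, params.GC, 1.0)

        return base * oa * damping

    def objective(self, params: ParameterSet) -> ObjectiveSummary:
        ps = self.scores(params)
        control, pyrexia, window = ps[~self.pyrexia], ps[self.pyrexia], ps[self.window14]
        m0p = float(control.mean()) if control.size else 0.0
        mwp = float(pyrexia.mean()) if pyrexia.size else 0.0
        if window.size:
            mwp14 = float(window.mean())
        else:
            mwp14 = 0.0
            warnings.warn("no pyrexia assessments within ±7 days of onset; "
                          "MWP14 reported as 0", stacklevel=2)
        denom = m0p + mwp
        ratio_all = mwp / denom if denom > 0 else None
        ratio_14 = mwp14 / denom if denom > 0 else None
        return ObjectiveSummary(m0p, mwp, mwp14, ratio_all, ratio_14,
                                int((~self.pyrexia).sum()),
                                int(self.pyrexia.sum()),
                                int(self.window14.sum()))


def evaluate_objective(cohort: Cohort, params: ParameterSet | None = None
                       ) -> ObjectiveSummary:
    """M0P/MWP/MWP14 and the two discrimination ratios for a cohort.

    An all-zero score cohort has an undefined objective: the ratios are
    reported as None (``summary.defined`` is False).
    """
    return CohortMatrix(cohort).objective(params or ParameterSet())


@dataclass
class AuditRecord:
    """One variable's trace through the search."""

    variable: str
    start_value: float
    accepted_value: float
    steps_accepted: int
    ratio_all_before: float
    ratio_14_before: float
    ratio_all_after: float
    ratio_14_after: float
    trials: list[tuple[float, float | None, float | None, bool]] = field(
        default_factory=list)  # (candidate value, ratio_all, ratio_14, accepted)


_EPS = 1e-12


def _improves(candidate: ObjectiveSummary, current: ObjectiveSummary) -> bool:
    """Joint acceptance: neither ratio decreases, at least one increases."""
    if not candidate.defined:
        return False
    ra, r14 = candidate.ratio_all, candidate.ratio_14
    ca, c14 = current.ratio_all, current.ratio_14
    no_loss = ra >= ca - _EPS and r14 >= c14 - _EPS
    gain = ra > ca + _EPS or r14 > c14 + _EPS
    return no_loss and gain


def _worsens(candidate: ObjectiveSummary, current: ObjectiveSummary) -> bool:
    """Reversal condition: a ratio strictly decreased (or became undefined)."""
    if not candidate.defined:
        return True
    return (candidate.ratio_all < current.ratio_all - _EPS
            or candidate.ratio_14 < current.ratio_14 - _EPS)


def optimize_one_round(cohort: Cohort, params: ParameterSet | None = None,
                       step_table: dict[str, float] | None = None,
                       order: tuple[str, ...] | None = None,
                       max_steps_per_variable: int = 50,
                       ) -> tuple[ParameterSet, list[AuditRecord]]:
    """One pass of incremental coordinate steps over ``order``.

    For each variable the increment from ``step_table`` (keyed by family)
    is walked upward one step at a time until a ratio strictly decreases
    (the reversal condition) or ``max_steps_per_variable`` is reached;
    flat steps — common for the absolute gates, where a 10-point move
    often changes no indicator — are traversed but not kept.  The
    retained value is the best candidate of the walk: the last one at
    which both ratios were non-decreasing and at least one strictly
    increased.  If the upward walk retains nothing, the downward
    direction is tried the same way.  The final objective is therefore
    never below the initial one.  ``max_steps_per_variable`` bounds a
    coordinate walk (the published procedure states no bound).
    Deterministic given cohort, order and step table.
    """
    params = params or ParameterSet()
    steps = {**DEFAULT_STEPS, **(step_table or {})}
    order = tuple(order or DEFAULT_ORDER)
    matrix = CohortMatrix(cohort)

    current = matrix.objective(params)
    if not current.defined:
        raise ValueError("objective undefined at the starting parameters "
                         "(all scores zero); nothing to optimize")

    audit: list[AuditRecord] = []
    for name in order:
        family = parameter_family(name)
        step = steps[family]
        lo, hi = _BOUNDS[family]
        record = AuditRecord(name, getattr(params, name), getattr(params, name),
                             0, current.ratio_all, current.ratio_14,
                             current.ratio_all, current.ratio_14)
        audit.append(record)
        if step == 0:
            continue
        base_value = getattr(params, name)
        for direction in (+1.0, -1.0):
            best_params, best = params, current
            probe_value, n_probes = base_value, 0
            while n_probes < max_steps_per_variable:
                probe_value = probe_value + direction * step
                n_probes += 1
                if not lo <= probe_value <= hi:
                    break
                try:
                    candidate = best_params.replace(**{name: probe_value})
                except ValueError:
                    break
                summary = matrix.objective(candidate)
                ok = _improves(summary, best)
                record.trials.append((probe_value, summary.ratio_all,
                                      summary.ratio_14, ok))
                if ok:
                    best_params, best = candidate, summary
                    record.steps_accepted += 1
                elif _worsens(summary, best):
                    break  # reversal condition: a ratio decreased
            if best is not current:
                params, current = best_params, best
                break  # a productive upward walk forecloses the downward try
        record.accepted_value = getattr(params, name)
        record.ratio_all_after = current.ratio_all
        record.ratio_14_after = current.ratio_14
    return params, audit


def audit_frame(audit: list[AuditRecord]) -> pd.DataFrame:
    """Flatten an audit trail into one row per objective evaluation."""
    rows = []
    for rec in audit:
        if not rec.trials:
            rows.append({"variable": rec.variable, "trial": 0,
                         "candidate_value": rec.start_value,
                         "ratio_all": rec.ratio_all_before,
                         "ratio_14": rec.ratio_14_before,
                         "accepted": False, "final_value": rec.accepted_value})
        for t, (value, ra, r14, ok) in enumerate(rec.trials, start=1):
            rows.append({"variable": rec.variable, "trial": t,
                         "candidate_value": value, "ratio_all": ra,
                         "ratio_14": r14, "accepted": ok,
                         "final_value": rec.accepted_value})
    return pd.DataFrame(rows, columns=["variable", "trial", "candidate_value",
                                       "ratio_all", "ratio_14", "accepted",
                                       "final_value"])
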