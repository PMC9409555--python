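"""Cohort-level statistics of the pyrexia score.

Association analyses (group descriptives, quartile odds ratios,
observation-level ROC) treat every scored assessment as one observation
carrying its patient's pyrexia label; per-patient validation summarizes
each patient by the maximum score of their timeline and classifies
against a threshold.  The odds-ratio fit is a plain ML logistic
regression with a categorical quartile predictor — an approximation of a
nested mixed-effects model, documented as such — with 95% Wald
confidence intervals on the log-odds scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

#: z quantile of the 95% Wald interval.
WALD_Z = 1.959964


def _check_observations(observations: pd.DataFrame) -> pd.DataFrame:
    for col in ("patient_id", "ps", "pyrexia"):
        if col not in observations.columns:
            raise ValueError(f"observations table lacks column {col!r}")
    if (observations["ps"] < 0).any():
        raise ValueError("scores must be non-negative")
    return observations


def group_descriptives(observations: pd.DataFrame) -> pd.DataFrame:
    """Per-group {n, mean, median, min, max, std_error, std_dev, IQR}.

    Statistics are over ALL observations of a group, not per patient.
    """
    obs = _check_observations(observations)
    groups = obs.groupby(obs["pyrexia"].astype(bool))["ps"]
    if len(groups) < 2:
        raise ValueError("both pyrexia and non-pyrexia observations required")
    rows = {}
    for label, ps in groups:
        name = "pyrexia" if label else "non_pyrexia"
        q1, q3 = np.percentile(ps, [25, 75])
        rows[name] = {
            "n": int(ps.size), "mean": ps.mean(), "median": ps.median(),
            "min": ps.min(), "max": ps.max(),
            "std_error": ps.std(ddof=1) / np.sqrt(ps.size),
            "std_dev": ps.std(ddof=1), "iqr": q3 - q1,
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[
        ["non_pyrexia", "pyrexia"]]


@dataclass
class QuartileORRow:
    quartile: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    lower_bound: float
    upper_bound: float
    n_pyrexia: int
    n_control: int
    separated: bool


def score_quartile_bounds(pyrexia_scores: np.ndarray) -> np.ndarray:
    """Lower bounds of the four score quartiles of the pyrexia group.

    Inner boundaries use the inclusive-median (linear) quantile
    convention; bins are lower-closed, so a score equal to a boundary
    belongs to the upper quartile — matching threshold semantics of the
    form "predict pyrexia at score >= bound".
    """
    scores = np.asarray(pyrexia_scores, dtype=float)
    if scores.size < 8:
        raise ValueError("need at least 8 pyrexia observations to form quartiles")
    inner = np.quantile(scores, [0.25, 0.5, 0.75])
    return np.concatenate([[scores.min()], inner])


def quartile_or_thresholds(observations: pd.DataFrame, binning: str = "label",
                           ) -> tuple[pd.DataFrame, float | None]:
    """Quartile-dummy logistic odds ratios and the proposed threshold.

    ``binning="label"`` follows the published construction literally: the
    dummy is 0 for every non-pyrexia observation (the P0 reference) and
    the quartile index 1–4 for pyrexia observations.  Because the dummy
    then determines the label, maximum-likelihood logistic regression is
    completely separated; such quartiles are reported with an infinite
    odds ratio and the ``separated`` flag.

    ``binning="score"`` applies the pyrexia-derived quartile boundaries
    to ALL observations, with the first quartile as the reference level
    (its row carries an odds ratio of 1 with a NaN interval).  Whenever
    the two score distributions overlap this yields finite
    maximum-likelihood odds ratios.

    The proposed threshold is the lower bound of the lowest quartile
    whose 95% Wald CI excludes 1 (None if no quartile qualifies).
    """
    obs = _check_observations(observations)
    labels = obs["pyrexia"].astype(bool).to_numpy()
    scores = obs["ps"].to_numpy(dtype=float)
    bounds = score_quartile_bounds(scores[labels])
    inner = bounds[1:]
    quartile_of = 1 + np.searchsorted(inner, scores, side="right")

    if binning == "label":
        level = np.where(labels, quartile_of, 0)
        ref_level, report = 0, (1, 2, 3, 4)
    elif binning == "score":
        level = quartile_of
        # tied boundaries (e.g. zero-inflated scores) can empty the lowest
        # quartiles; the reference is the lowest occupied one
        occupied = [q for q in (1, 2, 3, 4) if (level == q).any()]
        ref_level = occupied[0]
        report = tuple(q for q in (1, 2, 3, 4) if q != ref_level)
    else:
        raise ValueError(f"binning must be 'label' or 'score', got {binning!r}")

    counts = {q: (int((labels & (level == q)).sum()),
                  int((~labels & (level == q)).sum()))
              for q in (ref_level, *report)}
    ref_pyr, ref_ctl = counts[ref_level]
    if ref_pyr + ref_ctl == 0:
        raise ValueError("reference category is empty")

    def collapse_state(q: int) -> str:
        a, b = counts[q]  # pyrexia / control counts in quartile q
        c, d = ref_pyr, ref_ctl
        if a > 0 and b > 0 and c > 0 and d > 0:
            return "estimable"
        if (b == 0 or c == 0) and a > 0 and d > 0:
            return "infinite"
        if (a == 0 or d == 0) and b > 0 and c > 0:
            return "zero"
        return "degenerate"

    state = {q: collapse_state(q) for q in report}
    estimates: dict[int, tuple[float, float, float]] = {}
    clean = [q for q in report if state[q] == "estimable"]
    if clean:
        mask = (level == ref_level) | np.isin(level, clean)
        dummies = pd.get_dummies(
            pd.Categorical(level[mask], categories=[ref_level] + clean),
            drop_first=True, dtype=float)
        design = sm.add_constant(dummies.to_numpy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(labels[mask].astype(float), design).fit(disp=False)
        for pos, q in enumerate(clean, start=1):
            beta, se = fit.params[pos], fit.bse[pos]
            estimates[q] = (np.exp(beta), np.exp(beta - WALD_Z * se),
                            np.exp(beta + WALD_Z * se))

    rows = []
    uppers = list(bounds[1:]) + [np.inf]
    for q in (1, 2, 3, 4):
        n_pyr = int((labels & (quartile_of == q)).sum())
        n_ctl = int((~labels & (quartile_of == q)).sum())
        if binning == "score" and q == ref_level:
            or_, lo, hi, sep = 1.0, np.nan, np.nan, False
        elif q in estimates:
            (or_, lo, hi), sep = estimates[q], False
        elif state.get(q) == "zero":
            or_, lo, hi, sep = 0.0, 0.0, np.nan, True
        else:
            or_, lo, hi, sep = np.inf, np.nan, np.inf, True
        rows.append(QuartileORRow(q, or_, lo, hi, bounds[q - 1], uppers[q - 1],
                                  n_pyr, n_ctl, sep))
    table = pd.DataFrame([r.__dict__ for r in rows])

    threshold = None
    for r in rows:
        if np.isfinite(r.ci_low) and r.ci_low > 1.0:
            threshold = float(r.lower_bound)
            break
    return table, threshold


def roc_analysis(observations: pd.DataFrame, level: str = "observation",
                 ) -> tuple[float, pd.DataFrame]:
    """Rank-based (tie-aware) ROC AUC plus the curve points.

    ``level="observation"`` ranks every scored assessment;
    ``level="patient_max"`` ranks each patient by their maximum score.
    """
    obs = _check_observations(observations)
    if level == "observation":
        y = obs["pyrexia"].astype(bool).to_numpy()
        s = obs["ps"].to_numpy(dtype=float)
    elif level == "patient_max":
        per_patient = obs.groupby("patient_id").agg(
            ps=("ps", "max"), pyrexia=("pyrexia", "any"))
        y = per_patient["pyrexia"].to_numpy()
        s = per_patient["ps"].to_numpy(dtype=float)
    else:
        raise ValueError(f"level must be 'observation' or 'patient_max', got {level!r}")
    if y.all() or not y.any():
        raise ValueError("ROC undefined: only one class present")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thresholds = roc_curve(y, s)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return auc, curve


def classify_patients(observations: pd.DataFrame, threshold: float) -> dict[str, int]:
    """Patient-level confusion counts: predicted pyrexic iff max PS >= threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    obs = _check_observations(observations)
    per_patient = obs.groupby("patient_id").agg(
        ps=("ps", "max"), pyrexia=("pyrexia", "any"))
    predicted = per_patient["ps"] >= threshold
    actual = per_patient["pyrexia"]
    return {
        "TP": int((predicted & actual).sum()),
        "FP": int((predicted & ~actual).sum()),
        "FN": int((~predicted & actual).sum()),
        "TN": int((~predicted & ~actual).sum()),
    }


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) of [[a, b], [c, d]]."""
    table = np.array([[a, b], [c, d]])
    if (table < 0).any() or table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        raise ValueError("counts must be non-negative with positive margins")
    result = stats.chi2_contingency(table, correction=False)
    return float(result.statistic), float(result.pvalue)
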