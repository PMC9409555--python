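"""The two display styles used for visual inspection of cohorts.

``semilog_analytes`` plots the four normalized analytes of one patient on
a semi-logarithmic scale, with a triangle marking pyrexia onset;
``score_scatter`` shows pyrexia scores of all patients over time, with
day 0 meaning treatment start for non-pyrexia patients and first onset
for pyrexia patients.  Plots are inspection artifacts only; no numeric
result depends on them.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .cohort import Analyte, Cohort, PatientTimeline  # noqa: E402

_COLORS = {Analyte.LEU: "tab:blue", Analyte.THR: "tab:green",
           Analyte.LDH: "tab:orange", Analyte.CRP: "tab:red"}


def plot_timeline(timeline: PatientTimeline, path,
                  scores: pd.DataFrame | None = None) -> None:
    """Semi-log analyte series of one patient, optionally with its scores."""
    if not timeline.assessments:
        raise ValueError(f"{timeline.patient_id}: empty timeline")
    n_rows = 2 if scores is not None else 1
    fig, axes = plt.subplots(n_rows, 1, figsize=(8, 3.2 * n_rows), sharex=True)
    ax = axes[0] if n_rows == 2 else axes
    for analyte in Analyte:
        pts = [(a.day, a.normalized(analyte)) for a in timeline.assessments
               if a.normalized(analyte) is not None]
        if pts:
            days, values = zip(*pts)
            ax.semilogy(days, values, "o-", label=analyte.value,
                        color=_COLORS[analyte])
    for onset in timeline.onset_days:
        ax.plot([onset], [ax.get_ylim()[1]], marker="v", color="black",
                clip_on=False, markersize=10)
    ax.axhline(100, color="grey", lw=0.5, ls="--")
    ax.set_ylabel("normalized value (100 = reference)")
    ax.legend(loc="best", fontsize=8)
    ax.set_title(f"{timeline.patient_id}")
    if scores is not None:
        ax2 = axes[1]
        ax2.plot(scores["day"], scores["ps"], "s-", color="tab:purple")
        ax2.set_ylabel("pyrexia score")
    (axes[1] if n_rows == 2 else ax).set_xlabel("day from treatment start")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_score_scatter(cohort: Cohort, scores: pd.DataFrame, path) -> None:
    """Scores of all patients over time; day 0 is onset for pyrexia patients."""
    if scores.empty:
        raise ValueError("no scores to plot")
    onset = {p.patient_id: p.first_onset for p in cohort}
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, label, title in ((axes[0], False, "without pyrexia (day 0 = start)"),
                             (axes[1], True, "with pyrexia (day 0 = onset)")):
        sub = scores[scores["pyrexia"] == label]
        shift = sub["patient_id"].map(lambda p: onset[p] or 0) if label else 0
        ax.plot(sub["day"] - shift, sub["ps"], "o", alpha=0.5, markersize=3)
        ax.axvline(0, color="grey", lw=0.5)
        ax.set_title(title, fontsize=9)
        ax.set_xlabel("day")
    axes[0].set_ylabel("pyrexia score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
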