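import numpy as np
import pandas as pd
import pytest

from pyrexia_score.evaluate import (chi_square_2x2, classify_patients,
                                    group_descriptives,
                                    quartile_or_thresholds, roc_analysis,
                                    score_quartile_bounds)


def _obs(scores, labels, patients=None):
    n = len(scores)
    return pd.DataFrame({
        "patient_id": patients if patients is not None
        else [f"p{i}" for i in range(n)],
        "day": range(n), "ps": scores, "pyrexia": labels})


def test_group_descriptives_zero_group():
    obs = _obs([0.0, 0.0, 0.0, 0.0, 1.0, 2.0],
               [False] * 4 + [True] * 2)
    table = group_descriptives(obs)
    assert table.loc["non_pyrexia", "mean"] == 0.0
    assert table.loc["non_pyrexia", "iqr"] == 0.0
    assert table.loc["pyrexia", "n"] == 2
    assert table.loc["pyrexia", "mean"] == pytest.approx(1.5)
    assert table.loc["pyrexia", "std_error"] == pytest.approx(
        np.std([1, 2], ddof=1) / np.sqrt(2))


def test_group_descriptives_requires_both_groups():
    with pytest.raises(ValueError):
        group_descriptives(_obs([1.0, 2.0], [True, True]))


@pytest.mark.parametrize("counts, expected_p, digits", [
    ((8, 6, 17, 7), 0.39, 2),     # cohort sex distribution by pyrexia
    ((6, 8, 4, 20), 0.077, 3),    # tumor stage III vs IV by pyrexia
])
def test_chi_square_published_tables(counts, expected_p, digits):
    _stat, p = chi_square_2x2(*counts)
    assert round(p, digits) == expected_p


def test_chi_square_independence_and_margins():
    stat, p = chi_square_2x2(10, 10, 10, 10)
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)
    with pytest.raises(ValueError):
        chi_square_2x2(0, 0, 5, 5)


def test_roc_auc_exhaustive_pairs():
    auc, curve = roc_analysis(_obs([1.0, 2.0, 3.0, 4.0],
                                   [False, False, True, True]))
    assert auc == 1.0
    assert {"fpr", "tpr", "threshold"} <= set(curve.columns)


def test_roc_auc_null_is_half(rng):
    scores = rng.exponential(size=4000)
    labels = rng.random(4000) < 0.5
    auc, _ = roc_analysis(_obs(scores, labels))
    assert auc == pytest.approx(0.5, abs=0.03)


def test_roc_auc_monotone_invariance(rng):
    scores = rng.exponential(size=300)
    labels = (scores + rng.normal(scale=1.0, size=300)) > 1.0
    base, _ = roc_analysis(_obs(scores, labels))
    warped, _ = roc_analysis(_obs(np.log1p(scores) * 7.0, labels))
    assert warped == pytest.approx(base, abs=1e-12)


def test_roc_single_class_flagged():
    with pytest.raises(ValueError, match="one class"):
        roc_analysis(_obs([1.0, 2.0], [True, True]))


def test_roc_patient_max_level():
    obs = _obs([0.0, 9.0, 1.0, 2.0], [True, True, False, False],
               patients=["a", "a", "b", "c"])
    auc, _ = roc_analysis(obs, level="patient_max")
    assert auc == 1.0  # patient a's max 9 outranks b and c


def test_classify_patients_threshold_extremes():
    obs = _obs([0.0, 3.0, 8.0], [False, False, True],
               patients=["a", "b", "c"])
    assert classify_patients(obs, 0.0) == {"TP": 1, "FP": 2, "FN": 0, "TN": 0}
    assert classify_patients(obs, 99.0) == {"TP": 0, "FP": 0, "FN": 1, "TN": 2}
    counts = classify_patients(obs, 5.0)
    assert sum(counts.values()) == 3
    assert counts == {"TP": 1, "FP": 0, "FN": 0, "TN": 2}


def test_quartile_bounds_partition_pyrexia_scores():
    scores = np.arange(1.0, 17.0)  # 16 values -> quartiles of 4
    bounds = score_quartile_bounds(scores)
    assert bounds[0] == 1.0
    assert list(bounds) == sorted(bounds)
    with pytest.raises(ValueError):
        score_quartile_bounds(np.arange(5.0))


def test_quartile_or_matches_contingency_closed_form():
    """Score-binned quartile ORs equal the 2x2 collapse (a*d)/(b*c).

    With a single categorical predictor the logistic model is saturated,
    so its ML odds ratios must reproduce the closed form computed here by
    direct counting — an independent brute-force oracle.
    """
    # 16 pyrexia scores defining quartiles 1..4 at bounds 1/5/9/13,
    # plus controls spread over the same range with known bin counts
    pyr = list(np.arange(1.0, 17.0))
    ctl = [1.5] * 12 + [5.5] * 6 + [9.5] * 4 + [13.5] * 2
    obs = _obs(pyr + ctl, [True] * len(pyr) + [False] * len(ctl))
    table, _threshold = quartile_or_thresholds(obs, binning="score")

    bounds = score_quartile_bounds(np.asarray(pyr))
    quart = lambda s: int(np.searchsorted(bounds[1:], s, side="right")) + 1
    a_ref = sum(quart(s) == 1 for s in pyr)
    b_ref = sum(quart(s) == 1 for s in ctl)
    for q in (2, 3, 4):
        a = sum(quart(s) == q for s in pyr)
        b = sum(quart(s) == q for s in ctl)
        expected = (a * b_ref) / (b * a_ref)
        row = table[table.quartile == q].iloc[0]
        assert row.odds_ratio == pytest.approx(expected, rel=1e-4)
        assert row.ci_low < row.odds_ratio < row.ci_high


def test_quartile_or_label_mode_reports_separation():
    """The literal construction (P0 dummy) is separated by design."""
    pyr = list(np.arange(1.0, 17.0))
    ctl = [0.5] * 10 + [2.0] * 10
    obs = _obs(pyr + ctl, [True] * len(pyr) + [False] * len(ctl))
    table, threshold = quartile_or_thresholds(obs, binning="label")
    assert table["separated"].all()
    assert np.isinf(table["odds_ratio"]).all()
    assert threshold is None


def test_quartile_or_null_near_one(rng):
    """Permuted labels: no quartile should show a significant odds ratio."""
    scores = rng.exponential(scale=3.0, size=800)
    labels = np.zeros(800, dtype=bool)
    labels[rng.permutation(800)[:300]] = True
    obs = _obs(scores, labels)
    table, threshold = quartile_or_thresholds(obs, binning="score")
    finite = table[np.isfinite(table.odds_ratio) & (table.quartile > 1)]
    assert ((finite.ci_low <= 1.0) & (finite.ci_high >= 1.0)).all()
    assert threshold is None


def test_quartile_threshold_is_lower_bound_of_significant_quartile(rng):
    """A strong top-quartile enrichment proposes that quartile's lower bound."""
    # controls overlap quartiles 1-3 but almost never reach quartile 4
    pyr = np.concatenate([rng.uniform(0.1, 6.0, 60), rng.uniform(6.3, 50.0, 20)])
    ctl = np.concatenate([rng.uniform(0.1, 6.0, 200), rng.uniform(6.3, 9.0, 6)])
    obs = _obs(list(pyr) + list(ctl), [True] * 80 + [False] * 206)
    table, threshold = quartile_or_thresholds(obs, binning="score")
    sig = table[np.isfinite(table.ci_low) & (table.ci_low > 1.0)]
    assert not sig.empty
    assert threshold == pytest.approx(sig.iloc[0].lower_bound)
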