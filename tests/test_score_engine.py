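import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pyrexia_score.cohort import (Analyte, Assessment, LabObservation,
                                  PatientTimeline, Sex)
from pyrexia_score.params import ParameterSet
from pyrexia_score.score import (base_sum, change_indicator, compute_scores,
                                 crp_gate, infection_signature,
                                 max_attainable_score, scores_frame,
                                 simultaneity_multiplier)
from pyrexia_score.simulate import worked_example_timeline

from conftest import make_normalized_timeline, make_random_cohort
from direct_oracle import oracle_score_series


def _assessment(day, leu=None, thr=None, ldh=None, crp=None):
    values = {}
    for analyte, v in ((Analyte.LEU, leu), (Analyte.THR, thr),
                       (Analyte.LDH, ldh), (Analyte.CRP, crp)):
        if v is not None:
            values[analyte] = LabObservation(analyte, v, normalized_value=v)
    return Assessment(day, values)


@pytest.mark.parametrize("current, previous, f, t, direction, expected", [
    (80.0, 95.0, 1.05, 100.0, "falling", 1),   # 95/80 >= 1.05 and 80 <= 100
    (900.0, 400.0, 0.70, 800.0, "rising", 1),  # 400/900 <= 0.70 and 900 >= 800
    (95.0, 95.0, 1.05, 100.0, "falling", 0),   # no change never triggers
    (500.0, 500.0, 0.70, 100.0, "rising", 0),
    (105.0, 120.0, 1.05, 100.0, "falling", 0),  # current above the T cap
    (700.0, 400.0, 0.70, 800.0, "rising", 0),   # current below the T floor
    (None, 95.0, 1.05, 100.0, "falling", 0),    # absence -> 0 by contract
    (80.0, None, 1.05, 100.0, "falling", 0),
    (0.0, 95.0, 1.05, 100.0, "falling", 0),     # ratio undefined at 0
    (0.0, 95.0, 0.70, 0.0, "rising", 0),
])
def test_change_indicator(current, previous, f, t, direction, expected):
    assert change_indicator(current, previous, f, t, direction) == expected


def test_base_sum_with_published_weights():
    p = ParameterSet()
    assert base_sum((1,) * 8, p) == pytest.approx(19.40)
    assert base_sum((1, 1, 1, 1, 1, 1, 1, 0), p) == pytest.approx(17.96)
    assert base_sum((0,) * 8, p) == 0.0
    # unit weights below version 3
    assert base_sum((1,) * 8, p.replace(version=2)) == 8.0
    # version 1 ignores the t-1 block
    assert base_sum((1,) * 8, p.replace(version=1)) == 4.0


def test_simultaneity_multiplier():
    p = ParameterSet()
    assert simultaneity_multiplier((1, 1, 1, 1), p) == pytest.approx(5.1744)
    assert simultaneity_multiplier((0, 0, 0, 0), p) == 1.0
    assert simultaneity_multiplier((1, 1, 0, 0), p) == pytest.approx(2.0)
    assert simultaneity_multiplier((1, 1, 1, 1), p.replace(version=3)) == 1.0


def test_infection_signature_requires_joint_leu_crp_rise():
    p = ParameterSet()
    rising = _assessment(10, leu=120.0, crp=400.0)
    before = _assessment(5, leu=90.0, crp=150.0)
    assert infection_signature(rising, before, p) is True
    # constant series: no increase
    flat = _assessment(10, leu=90.0, crp=150.0)
    assert infection_signature(flat, before, p) is False
    # leukocytes falling while CRP rises: the pyrexia pattern, not infection
    pyrexic = _assessment(10, leu=70.0, crp=400.0)
    assert infection_signature(pyrexic, before, p) is False
    # below version 5 the signature is off
    assert infection_signature(rising, before, p.replace(version=4)) is False


def test_infection_mask_can_require_all_four():
    p = ParameterSet(infection_mask=(True, True, True, True))
    before = _assessment(5, leu=90.0, crp=150.0, thr=90.0, ldh=100.0)
    partial = _assessment(10, leu=120.0, crp=400.0, thr=90.0, ldh=100.0)
    full = _assessment(10, leu=120.0, crp=400.0, thr=130.0, ldh=160.0)
    assert infection_signature(partial, before, p) is False
    assert infection_signature(full, before, p) is True


def test_crp_gate():
    p = ParameterSet()
    assert crp_gate(900.0, p) == 1.0           # at/above CT: no damping
    assert crp_gate(None, p) == 1.0            # not measured: no damping
    assert crp_gate(100.0, p) == pytest.approx(0.1)
    assert crp_gate(100.0, p.replace(version=4)) == 1.0


def test_worked_example_scores():
    """The packaged three-visit example: low CRP day, ramp-up, full signature."""
    tl = worked_example_timeline()
    pts = compute_scores(tl, ParameterSet())
    assert [p.day for p in pts] == [0, 14, 28]
    assert pts[0].ps == 0.0                     # no predecessor
    assert pts[2].s == (1, 1, 1, 1, 1, 1, 1, 0)  # CRP at t-1 below T8
    assert pts[2].base_sum == pytest.approx(17.96)
    assert pts[2].oa_multiplier == pytest.approx(5.1744)
    assert pts[2].ps == pytest.approx(92.93, abs=0.005)
    # the oracle agrees
    assert oracle_score_series(tl, ParameterSet())[2] == pytest.approx(
        pts[2].ps, abs=1e-12)


def test_constant_timeline_scores_zero():
    assessments = [_assessment(d, leu=100.0, thr=100.0, ldh=100.0, crp=100.0)
                   for d in (0, 7, 14, 21)]
    tl = PatientTimeline("flat", Sex.M, False, [], assessments)
    for version in (1, 2, 3, 4, 5):
        assert all(p.ps == 0.0 for p in
                   compute_scores(tl, ParameterSet(version=version)))


def test_single_assessment_scores_zero():
    tl = PatientTimeline("one", Sex.F, False, [],
                         [_assessment(0, leu=50.0, crp=900.0)])
    assert compute_scores(tl, ParameterSet())[0].ps == 0.0


def test_empty_timeline_gives_empty_list():
    tl = PatientTimeline("none", Sex.F, False, [], [])
    assert compute_scores(tl, ParameterSet()) == []


def test_unnormalized_timeline_rejected():
    tl = PatientTimeline("raw", Sex.M, False, [], [
        Assessment(0, {Analyte.CRP: LabObservation(Analyte.CRP, 4.0)})])
    with pytest.raises(ValueError, match="normalized"):
        compute_scores(tl, ParameterSet())


def test_max_attainable_score():
    p = ParameterSet()
    assert max_attainable_score(p) == pytest.approx(100.38336)
    zero_weights = p.replace(**{f"FS{i}": 0.0 for i in range(1, 9)})
    assert max_attainable_score(zero_weights) == 0.0
    assert max_attainable_score(p.replace(version=2)) == 8.0
    assert max_attainable_score(p.replace(version=1)) == 4.0


def test_scores_never_exceed_bound(random_timelines):
    p = ParameterSet()
    bound = max_attainable_score(p)
    for tl in random_timelines:
        for pt in compute_scores(tl, p):
            assert 0.0 <= pt.ps <= bound + 1e-9


@settings(deadline=None, max_examples=40, derandomize=True)
@given(data=st.data())
def test_bound_holds_for_random_parameters(data):
    """0 <= PS <= max_attainable_score for arbitrary valid parameter sets."""
    draw = data.draw
    kwargs = {}
    for i in range(1, 9):
        kwargs[f"F{i}"] = draw(st.floats(0.5, 2.0))
        kwargs[f"T{i}"] = draw(st.floats(0.0, 1000.0))
        kwargs[f"FS{i}"] = draw(st.floats(0.0, 6.0))
    for i in range(1, 7):
        kwargs[f"OA{i}"] = draw(st.floats(0.0, 3.0))
    kwargs["version"] = draw(st.integers(1, 5))
    kwargs["GC"] = draw(st.floats(0.01, 1.0))
    kwargs["IS"] = draw(st.floats(0.01, 1.0))
    p = ParameterSet(**kwargs)
    bound = max_attainable_score(p)
    rng = np.random.default_rng(draw(st.integers(0, 2**31 - 1)))
    tl = make_normalized_timeline(rng, n_days=6)
    for pt in compute_scores(tl, p):
        assert 0.0 <= pt.ps <= bound + 1e-9


def test_oracle_equivalence_across_versions(random_timelines):
    """compute_scores matches the independent direct-formula oracle to 1e-9."""
    for version in (1, 2, 3, 4, 5):
        p = ParameterSet(version=version)
        for tl in random_timelines:
            ours = [pt.ps for pt in compute_scores(tl, p)]
            theirs = oracle_score_series(tl, p)
            assert ours == pytest.approx(theirs, abs=1e-9)


def test_gate_monotonicity_and_version_nesting(random_timelines):
    base = ParameterSet()
    for tl in random_timelines:
        v5 = [pt.ps for pt in compute_scores(tl, base)]
        v4 = [pt.ps for pt in compute_scores(tl, base.replace(version=4))]
        v3 = [pt.ps for pt in compute_scores(tl, base.replace(version=3))]
        v2 = [pt.ps for pt in compute_scores(tl, base.replace(version=2))]
        # damping gates never increase a score
        assert all(a <= b + 1e-12 for a, b in zip(v5, v4))
        # unit OA factors collapse version 4 onto version 3
        oa_unit = base.replace(version=4, **{f"OA{i}": 1.0 for i in range(1, 7)})
        assert [pt.ps for pt in compute_scores(tl, oa_unit)] == pytest.approx(v3)
        # unit weights collapse version 3 onto version 2
        fs_unit = base.replace(version=3, **{f"FS{i}": 1.0 for i in range(1, 9)})
        assert [pt.ps for pt in compute_scores(tl, fs_unit)] == pytest.approx(v2)


def test_parameter_set_json_roundtrip(tmp_path):
    p = ParameterSet(FS6=5.0, version=4)
    p.to_json(tmp_path / "p.json")
    assert ParameterSet.from_json(tmp_path / "p.json") == p
    with pytest.raises(ValueError, match="unknown"):
        ParameterSet.from_dict({"F9": 1.0})


def test_parameter_validation():
    with pytest.raises(ValueError):
        ParameterSet(version=6)
    with pytest.raises(ValueError):
        ParameterSet(GC=0.0)
    with pytest.raises(ValueError):
        ParameterSet(FS1=-1.0)


def test_scores_frame_layout(rng):
    cohort = make_random_cohort(rng, 2, 2)
    frame = scores_frame(cohort)
    assert {"patient_id", "day", "ps", "pyrexia", "s1", "s8",
            "base_sum"} <= set(frame.columns)
    assert len(frame) == sum(len(p.assessments) for p in cohort)
    assert frame.groupby("patient_id")["pyrexia"].nunique().le(1).all()
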