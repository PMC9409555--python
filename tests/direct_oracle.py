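"""Independent direct-formula evaluator of the pyrexia score.

Deliberately written from scratch against the algorithm description —
spreadsheet style, one literal formula per quantity, no code shared with
the package — to serve as the oracle for equivalence testing.
"""

from __future__ import annotations


def _norm(timeline, i, analyte):
    """Normalized value of ``analyte`` at assessment index i, or None."""
    if i < 0 or i >= len(timeline.assessments):
        return None
    obs = timeline.assessments[i].values.get(analyte)
    return None if obs is None else obs.normalized_value


def oracle_score_series(timeline, p) -> list[float]:
    """Score every assessment of a normalized timeline under params ``p``."""
    out = []
    for i in range(len(timeline.assessments)):
        out.append(_oracle_one(timeline, i, p))
    return out


def _ind_fall(cur, prev, f, t):
    if cur is None or prev is None or cur == 0:
        return 0
    return 1 if (prev / cur >= f and cur <= t) else 0


def _ind_rise(cur, prev, f, t):
    if cur is None or prev is None or cur == 0:
        return 0
    return 1 if (prev / cur <= f and cur >= t) else 0


def _oracle_one(tl, i, p) -> float:
    from pyrexia_score.cohort import Analyte

    leu0, leu1, leu2 = (_norm(tl, i - k, Analyte.LEU) for k in (0, 1, 2))
    thr0, thr1, thr2 = (_norm(tl, i - k, Analyte.THR) for k in (0, 1, 2))
    ldh0, ldh1, ldh2 = (_norm(tl, i - k, Analyte.LDH) for k in (0, 1, 2))
    crp0, crp1, crp2 = (_norm(tl, i - k, Analyte.CRP) for k in (0, 1, 2))

    has_t1 = i >= 1
    has_t2 = i >= 2

    s1 = _ind_fall(leu0, leu1, p.F1, p.T1) if has_t1 else 0
    s2 = _ind_fall(thr0, thr1, p.F2, p.T2) if has_t1 else 0
    s3 = _ind_rise(ldh0, ldh1, p.F3, p.T3) if has_t1 else 0
    s4 = _ind_rise(crp0, crp1, p.F4, p.T4) if has_t1 else 0
    s5 = _ind_fall(leu1, leu2, p.F5, p.T5) if has_t2 else 0
    s6 = _ind_fall(thr1, thr2, p.F6, p.T6) if has_t2 else 0
    s7 = _ind_rise(ldh1, ldh2, p.F7, p.T7) if has_t2 else 0
    s8 = _ind_rise(crp1, crp2, p.F8, p.T8) if has_t2 else 0

    if p.version == 1:
        return float(s1 + s2 + s3 + s4)
    if p.version == 2:
        return float(s1 + s2 + s3 + s4 + s5 + s6 + s7 + s8)

    total = (s1 * p.FS1 + s2 * p.FS2 + s3 * p.FS3 + s4 * p.FS4
             + s5 * p.FS5 + s6 * p.FS6 + s7 * p.FS7 + s8 * p.FS8)
    if p.version == 3:
        return float(total)

    if s1 and s2:
        total *= p.OA1
    if s1 and s3:
        total *= p.OA2
    if s1 and s4:
        total *= p.OA3
    if s2 and s3:
        total *= p.OA4
    if s2 and s4:
        total *= p.OA5
    if s3 and s4:
        total *= p.OA6
    if p.version == 4:
        return float(total)

    # version 5: infection signature and CRP gate
    rise_leu = _ind_rise(leu0, leu1, p.IC1, p.IM1) if has_t1 else 0
    rise_crp = _ind_rise(crp0, crp1, p.IC2, p.IM2) if has_t1 else 0
    rise_thr = _ind_rise(thr0, thr1, p.IC3, p.IM3) if has_t1 else 0
    rise_ldh = _ind_rise(ldh0, ldh1, p.IC4, p.IM4) if has_t1 else 0
    conditions = (rise_leu, rise_crp, rise_thr, rise_ldh)
    required = [c for c, m in zip(conditions, p.infection_mask) if m]
    if required and all(required):
        total *= p.IS
    if crp0 is not None and crp0 < p.CT:
        total *= p.GC
    return float(total)
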