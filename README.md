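# pyrexia-score

Drug-induced pyrexia (fever ≥ 38.5 °C without infection) is the most
common adverse event of combined BRAF/MEK inhibition (dabrafenib +
trametinib) in metastatic melanoma, and a leading cause of dose
reduction and therapy interruption.  It announces itself in routine
blood work: C-reactive protein (CRP) and lactate dehydrogenase (LDH)
rise while leukocyte and thrombocyte counts fall, simultaneously,
starting shortly before fever onset.

This package implements a composite **pyrexia score (PS)** that turns
that four-value signature into a single number per blood draw, together
with everything needed to study it end to end: value normalization and
cohort I/O, the five algorithm versions, the four-window time-cluster
assignment, the one-round heuristic parameter search, cohort-level
statistics (group descriptives, quartile odds ratios, ROC/AUC,
per-patient classification, 2×2 chi-square), and a synthetic cohort
simulator so every component is testable without patient data.

## The score

Laboratory values are first normalized to a percentage of a reference
mean (100 = reference): CRP 2.5 mg/l, LDH 125 U/l, thrombocytes
275 /nl, leukocytes 6.5 /nl (male) / 6.0 /nl (female).

At each sampling date t0, eight binary change indicators S1…S8 compare
the four analytes with the previous draw (t0 vs t−1) and the previous
interval (t−1 vs t−2).  A fall of leukocytes or thrombocytes counts when

    previous / current ≥ F   and   current ≤ T,

a rise of LDH or CRP when

    previous / current ≤ F   and   current ≥ T,

with per-analyte change factors F1…F8 and absolute gates T1…T8.  The
score is then (version 5.0)

    PS = ( Σᵢ Sᵢ·FSᵢ ) × Π OA × IS[infection] × GC[CRP < CT]

where FS1…FS8 are indicator weights, OA1…OA6 multiply when two t0
changes co-occur (e.g. OA1 = 2.0 for a joint leukocyte + thrombocyte
fall), the infection gate damps the score by IS when CRP **and**
leukocytes rise together (a bacterial pattern, not pyrexia), and the CRP
gate damps by GC = 0.1 when CRP at t0 is below CT = 300 (i.e. < 7.5
mg/l).  Versions 1–4 switch these refinements on cumulatively; all
variable values default to the published version-5.0 parameter table.
With those defaults no score can exceed 100.383.

Missing values never fire an indicator; only the CRP gate treats a
missing CRP as "no damping".

## Worked example

The packaged three-visit example (normalized values; a male patient with
pyrexia onset on day 28):

| day | LEU | THR | LDH | CRP |
|----:|----:|----:|----:|----:|
|   0 | 110 | 100 |  90 | 100 |
|  14 |  95 |  85 | 120 | 400 |
|  28 |  80 |  75 | 160 | 900 |

```bash
pyrexia-score score --out scores.csv
# scored 1 patients (3 assessments); max attainable 100.383
```

`scores.csv` then contains (abridged):

```text
patient_id,day,ps,s1,...,s8,base_sum,oa_multiplier,...
worked-example,0,0.0,...
worked-example,14,28.1456,...
worked-example,28,92.932224,...
```

Reading the day-28 row: seven indicators fire — S8 stays 0 because CRP
at t−1 (400) is below its gate T8 = 500 — giving a weighted base sum of
17.96; all four t0 changes co-occur, so every OA factor applies
(2.0·1.4·1.2·1.4·1.0·1.1 = 5.1744); no gate damps (CRP 900 ≥ 300, no
infection pattern), hence PS = 17.96 × 5.1744 = **92.93**.  Day 0 scores
0 (no predecessor), day 14 scores 28.15 (three indicators, two OA
pairs).

The same pipeline runs on any cohort:

```bash
pyrexia-score simulate --n-pyrexia 50 --n-control 50 --seed 1 --out sim/
pyrexia-score score    --cohort sim/cohort.csv --meta sim/meta.csv --out sim/scores.csv
pyrexia-score evaluate --scores sim/scores.csv --out sim/report.json
pyrexia-score clusters --cohort sim/cohort.csv --meta sim/meta.csv --out sim/clusters.csv
pyrexia-score optimize --cohort sim/cohort.csv --meta sim/meta.csv --out sim/opt/
pyrexia-score plot     --cohort sim/cohort.csv --meta sim/meta.csv --style score_scatter --out sim/scatter.png
```

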