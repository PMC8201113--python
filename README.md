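# kanoqual

Kano-model analysis of paired functional/dysfunctional service-quality
surveys, built for health-services quality assessment.

A Kano questionnaire asks two five-point questions per service attribute:
a *functional* item ("how do you feel if the attribute is present?") and a
*dysfunctional* item ("... if it is absent?"), each answered on the scale
1 = "I like it" ... 5 = "I dislike it that way". Every answer pair maps
through a 5×5 evaluation matrix to one of six quality categories:
attractive (A), one-dimensional (O), must-be (M), indifferent (I),
reverse (R) and questionable (Q). Per attribute the package tallies the
six categories over respondents, assigns the modal category, and computes
the Berger coefficients

```
CS = (A + O) / (A + O + M + I)        ∈ [0, 1]
DS = −(M + O) / (A + O + M + I)       ∈ [−1, 0]
```

CS is the expected rise in satisfaction from providing the attribute, DS
the drop from withholding it; questionable and reverse answers carry no
satisfaction information and are excluded from the denominator.

The package is aimed at analysts running patient-satisfaction (or any
service-quality) Kano surveys: it covers instrument definition and CSV
I/O, classification and coefficients with exact rational arithmetic,
standardized Cronbach's alpha for questionnaire reliability, a seeded
synthetic-respondent simulator, CS–|DS| quadrant charts, and a CLI. It
ships a reference dataset: the per-attribute category counts of a
250-respondent outpatient survey over 31 attributes in 4 dimensions run
in two hospitals, together with a deterministic respondent-level
expansion of those counts.

## Worked example

```python
import kanoqual as kq

table = kq.hospital_survey_table()          # 250 respondents, 31 attributes
results = kq.analyze(table)                 # classify + aggregate + CS/DS

by_id = {r.attr_id: r for r in results}
for a in (1, 21, 31):
    r = by_id[a]
    c = r.counts
    print(f"attr {a:2d}  A={c.n_A:3d} Q={c.n_Q} I={c.n_I:2d} R={c.n_R:3d} "
          f"M={c.n_M:3d} O={c.n_O:3d}  class={r.classification}  "
          f"CS={r.cs_rounded:.2f}  DS={r.ds_rounded:.2f}")
```

prints

```
attr  1  A= 24 Q=0 I=21 R=  0 M= 85 O=120  class=O  CS=0.58  DS=-0.82
attr 21  A=  2 Q=0 I= 3 R=  0 M=127 O=118  class=M  CS=0.48  DS=-0.98
attr 31  A=  0 Q=1 I=28 R=220 M=  1 O=  0  class=R  CS=0.00  DS=-0.03
```

Attribute 1 (professionalism of health personnel) is one-dimensional:
its presence raises satisfaction (CS 0.58) and its absence hurts strongly
(DS −0.82). Attribute 21 (ease of arranging an appointment) is must-be:
providing it barely raises satisfaction (CS 0.48 < 0.5) but withholding it
is heavily punished (DS −0.98). Attribute 31 (medication side effects) is
reverse — respondents are satisfied by its *absence* — and its
coefficients are computed over the 29 non-R/Q respondents only.
Across all 31 attributes, `kq.summarize_classifications(results)` gives
27 one-dimensional, 3 must-be and 1 reverse attribute.

The same analysis from the shell:

```
kanoqual fixtures --out responses.csv
kanoqual report --responses responses.csv --out report/
```

which writes `results.csv`, `summary.txt` and one CS–|DS| quadrant chart
per dimension. `kanoqual simulate --profile profile.yaml --seed 7 --out
sim.csv` draws synthetic respondents from a per-attribute category or
cell distribution (see `docs/methods.md` for the profile format and
model assumptions).

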