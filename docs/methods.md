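# Methods

## Model

Each service attribute *k* is probed by a functional and a dysfunctional
five-point item. An answer pair (f, d) ∈ {1..5}² is mapped to one of six
Kano categories by a 5×5 evaluation matrix. The package uses the
canonical Kano/Berger table (functional code as row, dysfunctional as
column):

|       | d=1 | d=2 | d=3 | d=4 | d=5 |
|-------|-----|-----|-----|-----|-----|
| f=1   |  Q  |  A  |  A  |  A  |  O  |
| f=2   |  R  |  I  |  I  |  I  |  M  |
| f=3   |  R  |  I  |  I  |  I  |  M  |
| f=4   |  R  |  I  |  I  |  I  |  M  |
| f=5   |  R  |  R  |  R  |  R  |  Q  |

The matrix is a replaceable input (`EvaluationMatrix.from_yaml`); any
total assignment in which all six categories are reachable is accepted.
This table is consistent with the standard category definitions: liking
presence and disliking absence is one-dimensional, liking presence while
being neutral/tolerant about absence is attractive, tolerating presence
but disliking absence is must-be, the middle block is indifferent,
preferring absence is reverse, and the two self-contradictory corners are
questionable.

Per attribute, the six counts (n_A, n_Q, n_I, n_R, n_M, n_O) are tallied
over all respondents with a *complete* pair (a pair with either side
missing is excluded, so the valid n may differ across attributes). The
attribute classification is the **mode** of the six counts; ties break by
a configurable priority, default M > O > A > I > R > Q (a conservative
must-be-first convention; the bundled reference data contains no ties, so
the default never fires there). The Berger coefficients are

- CS = (n_A + n_O) / (n_A + n_O + n_M + n_I), in [0, 1]
- DS = −(n_M + n_O) / (n_A + n_O + n_M + n_I), in [−1, 0]

Q and R responses are excluded from the denominator. DS is reported with
a negative sign even though the defining ratio is sometimes printed
unsigned: the maximum dissatisfaction impact is −1. When n_A + n_O + n_M
+ n_I = 0 (all answers Q or R) the coefficients are *undefined* — the API
raises `UndefinedCoefficientError`, `analyze` stores `None`, and report
files leave the cells blank; the attribute is still classified by mode.

## Numerical choices

Coefficients are exact rationals (`fractions.Fraction`) internally.
Report rounding is **half away from zero to two decimals**, implemented
in exact rational arithmetic so binary float representation cannot flip a
boundary case: 155/248 = 0.625 rounds to 0.63, where banker's rounding
would print 0.62. The bundled reference tables discriminate between the
two conventions and match half-away-from-zero on all 62 coefficient
values. Results CSVs carry both the rounded and the exact values
(`cs_exact`/`ds_exact` as rational strings), which makes write → read
lossless.

## Reliability

Standardized Cronbach's alpha, α = k·r̄ / (1 + (k−1)·r̄), with k the
number of items and r̄ the mean pairwise Pearson correlation. The item
matrix can include the functional items, the dysfunctional items, or all
paired items (default, 62 items on the bundled instrument — the natural
reading of "the questionnaire's reliability"). Rows with any missing
selected pair are dropped listwise. A zero-variance item makes the
correlations undefined and raises an error naming the item; at least two
items and two respondents are required. α = 0.7 is the default
acceptability threshold, boundary inclusive. Note that reliability needs
respondent-level data: it cannot be recovered from per-attribute category
counts, so the bundled count dataset supports the classification and
coefficient surface but not an alpha recomputation.

## Synthetic respondents

`SyntheticProfile` + `generate` emulate a cross-sectional outpatient
survey: n respondents (default 250, the reference study size) draw
demographics independently from the study strata (ages 18–34/35–54/
55–74/75+ with probabilities 67/250, 101/250, 60/250, 22/250; male/female
122/250, 128/250; hospitals 128/250, 122/250) and, per attribute, one of
the 25 answer cells from a per-attribute distribution. Probability
vectors must be non-negative and sum to 1 within 1e−9; generation is
fully determined by the profile seed (NumPy `default_rng`).

A profile may give six category probabilities instead of 25 cell
probabilities; these are realized through one *representative cell* per
category — A→(1,3), O→(1,5), M→(3,5), I→(3,3), R→(5,1), Q→(1,1) — each of
which maps back to its own category under the canonical matrix. The same
mapping drives `expand_counts`/`expand_table`, the deterministic inverse
of aggregation: every counted respondent receives the representative cell
of its category (categories laid out in the printed column order A, Q, I,
R, M, O), so aggregate(expand(c)) = c exactly. The bundled
`hospital_survey_table()` is this expansion applied to all 31 published
count rows simultaneously, aligned by respondent index, with demographics
laid out in blocks to hit the published margins exactly.

What the simulator does **not** model, by design: correlation between
attributes, between respondents, or between demographics and answers
(only marginal strata are published), and nonresponse mechanisms. Tests
passing on synthetic data therefore validate the pipeline's arithmetic
and contracts, not claims about real respondent behaviour. Likewise the
respondent-level joint structure of the expanded reference table is
synthetic; only its per-attribute tallies and demographic margins are
observed quantities.

Problem sizes used in the randomized checks — 4-attribute instruments,
tables up to n ≈ 40 for oracle/property tests, n = 5000 × 10 seeds for the
goodness-of-fit check, and 200 replicates at n = 250 for parameter
recovery — keep the whole suite in the seconds range while leaving the
statistical margins wide (at 0.6 dominant-category mass the runner-up
overtaking the mode at n = 250 has vanishing probability). A blanket
"dominance margin ≥ 0.1 implies ≥ 99% recovery" claim would *not* hold
(e.g. 0.4 vs 0.3 misclassifies a few percent of replicates at n = 250);
the recovery check therefore pins the 0.6-mass condition.

## Reporting

Quadrant charts plot y = CS against x = |DS| in the unit square with
split lines at 0.5 (configurable): attractive = low x/high y,
one-dimensional = high x/high y, must-be = high x/low y, indifferent =
low x/low y. Points exactly on a split line count as the low side; the
axes convention is printed on the chart because other sign/orientation
conventions exist. Attributes with undefined coefficients are skipped
with a logged warning. File formats are UTF-8 comma-delimited CSV with
mandatory headers (wide responses layout `a{k}_f`/`a{k}_d`; an optional
`frequency_of_use` demographic column is accepted and ignored, as it
enters no analysis), YAML for instruments, matrices and simulation
profiles.

## Known limitations

- The evaluation matrix actually used by any given published study is
  rarely printed; analyses here take per-attribute counts as the ground
  truth and the canonical matrix as the default mapping.
- Mode-based classification ignores sampling uncertainty (no significance
  test of the modal category) and fuzzy/continuous Kano variants are out
  of scope.
- Alpha is the standardized (correlation-based) form only; covariance
  alpha, item-deleted alphas and omega are not implemented.
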