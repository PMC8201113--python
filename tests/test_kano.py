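import random
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import kanoqual as kq
from kanoqual.errors import FormatError, UndefinedCoefficientError, ValidationError

from _oracle import LITERAL_TABLE, brute_force_analyze

C = kq.KanoCategory


class TestEvaluationMatrix:
    @pytest.mark.parametrize("f,d,expected", [
        (1, 5, C.O),   # like when present, dislike when absent
        (3, 3, C.I),   # neutral both ways
        (5, 1, C.R),   # dislike when present, like when absent
        (1, 1, C.Q),   # contradictory: like both presence and absence
        (1, 3, C.A),
        (3, 5, C.M),
        (5, 5, C.Q),
        (2, 1, C.R),
    ])
    def test_canonical_cells(self, f, d, expected):
        assert kq.classify_pair(f, d) is expected

    def test_matches_literal_table_everywhere(self):
        m = kq.EvaluationMatrix.canonical()
        for (f, d), letter in LITERAL_TABLE.items():
            assert m.classify(f, d).value == letter

    @pytest.mark.parametrize("f,d", [(0, 3), (3, 6), (1, 0), (6, 6)])
    def test_out_of_range_codes_rejected(self, f, d):
        with pytest.raises(ValidationError):
            kq.classify_pair(f, d)

    def test_yaml_roundtrip_and_override(self, tmp_path):
        m = kq.EvaluationMatrix.canonical()
        path = tmp_path / "m.yaml"
        m.to_yaml(path)
        back = kq.EvaluationMatrix.from_yaml(path)
        assert all(back[(f, d)] is m[(f, d)]
                   for f in range(1, 6) for d in range(1, 6))

    def test_incomplete_or_unreachable_matrix_rejected(self):
        cells = {(f, d): C.I for f in range(1, 6) for d in range(1, 6)}
        with pytest.raises(FormatError, match="reachable"):
            kq.EvaluationMatrix(cells)
        cells.pop((1, 1))
        with pytest.raises(FormatError, match="missing"):
            kq.EvaluationMatrix(cells)


def _table(instrument, pairs_per_record):
    """Build a table from a list of {attr_id: (f, d)} mappings."""
    records = []
    for i, answers in enumerate(pairs_per_record):
        records.append(kq.RespondentRecord(
            f"r{i}", "18-34", "male", "barton",
            {a: kq.ResponsePair(f, d) for a, (f, d) in answers.items()}))
    return kq.ResponseTable(instrument, tuple(records))


class TestAggregate:
    def test_constant_input(self, mini_instrument):
        table = _table(mini_instrument, [{1: (1, 5)}] * 250)
        counts = kq.aggregate(table)
        by_id = {c.attr_id: c for c in counts}
        assert by_id[1].n_O == 250 and by_id[1].total == 250
        assert by_id[2].total == 0

    def test_empty_table_gives_all_zero_counts(self, mini_instrument):
        counts = kq.aggregate(_table(mini_instrument, []))
        assert len(counts) == 4
        assert all(c.total == 0 for c in counts)


class TestClassifyAttribute:
    @pytest.mark.parametrize("kw,expected", [
        (dict(n_A=2, n_Q=0, n_I=3, n_R=0, n_M=127, n_O=118), C.M),
        (dict(n_A=2, n_Q=0, n_I=35, n_R=3, n_M=104, n_O=106), C.O),
        (dict(n_A=0, n_Q=1, n_I=28, n_R=220, n_M=1, n_O=0), C.R),
        (dict(n_M=100, n_O=100), C.M),  # tie broken by must-be-first priority
    ])
    def test_modal_rule(self, kw, expected):
        assert kq.classify_attribute(kq.CategoryCounts(1, **kw)) is expected

    def test_custom_tie_order(self):
        counts = kq.CategoryCounts(1, n_M=100, n_O=100)
        order = (C.O, C.M, C.A, C.I, C.R, C.Q)
        assert kq.classify_attribute(counts, order) is C.O

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValidationError):
            kq.classify_attribute(kq.CategoryCounts(1))

    def test_tie_order_must_be_a_permutation(self):
        with pytest.raises(ValidationError):
            kq.classify_attribute(kq.CategoryCounts(1, n_M=1), (C.M, C.O))


class TestCoefficients:
    def test_exact_values(self):
        counts = kq.CategoryCounts(1, n_A=24, n_I=21, n_M=85, n_O=120)
        assert kq.satisfaction_coefficient(counts) == Fraction(144, 250)
        assert kq.dissatisfaction_coefficient(counts) == Fraction(-205, 250)

    def test_reverse_dominated_attribute(self):
        counts = kq.CategoryCounts(31, n_Q=1, n_I=28, n_R=220, n_M=1)
        assert kq.satisfaction_coefficient(counts) == 0
        assert kq.dissatisfaction_coefficient(counts) == Fraction(-1, 29)

    @pytest.mark.parametrize("kw,cs,ds", [
        (dict(n_I=10), 0, 0),                       # nothing satisfies/dissatisfies
        (dict(n_A=5, n_O=5), 1, Fraction(-1, 2)),   # CS upper bound
        (dict(n_O=10), 1, -1),                      # both bounds attained
        (dict(n_A=5, n_I=5), Fraction(1, 2), 0),
        (dict(n_A=1, n_I=6, n_M=98, n_O=144), Fraction(145, 249), Fraction(-242, 249)),
    ])
    def test_span(self, kw, cs, ds):
        counts = kq.CategoryCounts(1, **kw)
        assert kq.satisfaction_coefficient(counts) == cs
        assert kq.dissatisfaction_coefficient(counts) == ds

    def test_zero_denominator_is_undefined_not_zero(self):
        counts = kq.CategoryCounts(1, n_R=10, n_Q=5)
        with pytest.raises(UndefinedCoefficientError):
            kq.satisfaction_coefficient(counts)
        with pytest.raises(UndefinedCoefficientError):
            kq.dissatisfaction_coefficient(counts)
        result = kq.result_from_counts(counts)
        assert result.cs is None and result.classification is C.R


class TestRounding:
    @pytest.mark.parametrize("value,expected", [
        (Fraction(155, 248), 0.63),    # 0.625 rounds up, not to even
        (Fraction(-242, 249), -0.97),
        (Fraction(-975, 1000), -0.98),  # halves go away from zero
        (Fraction(1, 29), 0.03),
        (Fraction(0), 0.0),
    ])
    def test_half_away_from_zero(self, value, expected):
        assert kq.round_half_away(value) == pytest.approx(expected, abs=1e-12)

    @given(st.fractions(min_value=-1, max_value=1))
    def test_agrees_with_decimal_half_up(self, x):
        from decimal import ROUND_HALF_UP, Decimal, getcontext
        getcontext().prec = 60
        expected = (Decimal(x.numerator) / Decimal(x.denominator)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP)
        assert Decimal(str(kq.round_half_away(x))) == expected.normalize()


counts_strategy = st.builds(
    kq.CategoryCounts, st.just(1),
    *(st.integers(min_value=0, max_value=300) for _ in range(6)))


@given(counts_strategy)
def test_coefficient_bounds(counts):
    if counts.coefficient_denominator == 0:
        return
    cs = kq.satisfaction_coefficient(counts)
    ds = kq.dissatisfaction_coefficient(counts)
    assert 0 <= cs <= 1
    assert -1 <= ds <= 0


def _random_table(instrument, rng, n_max=20, missing_rate=0.15):
    n = rng.integers(0, n_max + 1)
    rows = []
    for _ in range(n):
        answers = {}
        for a in instrument.attr_ids:
            if rng.random() > missing_rate:
                answers[a] = (int(rng.integers(1, 6)), int(rng.integers(1, 6)))
        rows.append(answers)
    return _table(instrument, rows)


@pytest.mark.parametrize("seed", range(30))
def test_analyze_matches_bruteforce_oracle(mini_instrument, seed):
    """Random small tables: analyze() equals the naive literal-lookup loop."""
    rng = np.random.default_rng(seed)
    table = _random_table(mini_instrument, rng)
    expected = brute_force_analyze(table)
    results = {r.attr_id: r for r in kq.analyze(table)}
    assert set(results) == set(expected)
    for attr_id, (counts, letter, cs, ds) in expected.items():
        r = results[attr_id]
        assert {k: r.counts[C(k)] for k in counts} == counts
        assert r.classification.value == letter
        assert r.cs == cs and r.ds == ds
        assert r.counts.total == table.valid_n(attr_id)  # conservation


def test_analyze_invariant_under_respondent_shuffle(survey_table):
    shuffled = list(survey_table.records)
    random.Random(7).shuffle(shuffled)
    reordered = kq.ResponseTable(survey_table.instrument, tuple(shuffled))
    assert kq.analyze(reordered) == kq.analyze(survey_table)


def test_adding_one_respondent_moves_each_count_by_at_most_one(mini_instrument):
    rng = np.random.default_rng(11)
    table = _random_table(mini_instrument, rng, n_max=15)
    extra = kq.RespondentRecord("extra", "35-54", "female", "kaelin",
                                {1: kq.ResponsePair(1, 5), 3: kq.ResponsePair(2, 2)})
    bigger = kq.ResponseTable(mini_instrument, table.records + (extra,))
    before = {c.attr_id: c for c in kq.aggregate(table)}
    after = {c.attr_id: c for c in kq.aggregate(bigger)}
    for attr_id in mini_instrument.attr_ids:
        deltas = [after[attr_id][cat] - before[attr_id][cat] for cat in C]
        assert all(0 <= d <= 1 for d in deltas)


class TestSummarize:
    def test_values_sum_to_number_of_results(self, survey_results):
        summary = kq.summarize_classifications(survey_results)
        assert sum(summary.values()) == len(survey_results) == 31

    def test_empty_results(self):
        assert kq.summarize_classifications([]) == {cat: 0 for cat in C}

    def test_single_respondent_table(self, mini_instrument):
        table = _table(mini_instrument, [{1: (1, 5), 2: (3, 3)}])
        results = kq.analyze(table)
        assert {r.attr_id: r.classification for r in results} == {1: C.O, 2: C.I}
        assert all(r.counts.total == 1 for r in results)
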