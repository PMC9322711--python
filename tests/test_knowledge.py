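"""Indicator-sum regions, clinical score fixtures and patient classification."""

import numpy as np
import pytest

from survite.knowledge import (Effect, IndicatorTerm, InconsistencyError,
                               KnowledgeBase, KnowledgeRegion,
                               builtin_knowledge_bases, classify, cp_grade,
                               cp_score, indicator_sum, is_member,
                               load_knowledge_base)

HCC_NAMES = ["diameter", "number", "DM", "VI", "AC"]
ACTG_NAMES = ["AGE", "CD40", "CD80", "Z30", "RACE", "GENDER", "STE"]


@pytest.fixture(scope="module")
def kbs():
    return builtin_knowledge_bases()


class TestIndicatorSum:
    def test_small_tumor_criterion_counts_satisfied_conditions(self, kbs):
        region = kbs["small_hcc"].zero_regions[0]
        ok = [1.5, 1, 0, 0, 0]
        assert indicator_sum(ok, region, HCC_NAMES) == 5
        assert is_member(ok, region, HCC_NAMES)
        big = [3.0, 1, 0, 0, 0]          # diameter condition fails
        assert indicator_sum(big, region, HCC_NAMES) == 4
        assert not is_member(big, region, HCC_NAMES)

    def test_empty_region_sums_to_zero(self):
        region = KnowledgeRegion((), frozenset({0.0}))
        assert indicator_sum([1.0, 2.0], region) == 0.0
        assert is_member([1.0, 2.0], region)

    def test_out_of_range_index_errors(self):
        region = KnowledgeRegion((IndicatorTerm(5, 1.0, 0, 1),),
                                 frozenset({1.0}))
        with pytest.raises(IndexError):
            indicator_sum([1.0, 2.0], region)

    def test_half_integer_graded_sum(self, kbs):
        theta1 = kbs["actg_semi_synthetic"].positive_regions[0]
        x = dict(AGE=45, CD40=300, CD80=600, Z30=1, RACE=1, GENDER=1, STE=1)
        row = [x[n] for n in ACTG_NAMES]
        # 0.5 + 1 + 0.5 + 0 + 1 + 1 + 1 + 1
        assert indicator_sum(row, theta1, ACTG_NAMES) == 6.0
        assert is_member(row, theta1, ACTG_NAMES)

    def test_membership_invariant_to_term_order(self, kbs):
        theta1 = kbs["actg_semi_synthetic"].positive_regions[0]
        shuffled = KnowledgeRegion(tuple(reversed(theta1.terms)),
                                   theta1.admissible_values)
        rng = np.random.default_rng(0)
        for _ in range(200):
            row = [rng.uniform(18, 70), rng.uniform(50, 900),
                   rng.uniform(100, 1500), rng.integers(0, 2),
                   rng.integers(0, 2), rng.integers(0, 2), rng.integers(0, 2)]
            assert is_member(row, theta1, ACTG_NAMES) == \
                is_member(row, shuffled, ACTG_NAMES)

    def test_monotone_in_satisfied_indicators(self, kbs):
        region = kbs["small_hcc"].zero_regions[0]
        # satisfying one more nonnegative-coefficient indicator never lowers it
        worse = [3.0, 2, 1, 1, 1]
        better = [1.0, 1, 1, 1, 1]
        assert indicator_sum(better, region, HCC_NAMES) >= \
            indicator_sum(worse, region, HCC_NAMES)


class TestChildPugh:
    @pytest.mark.parametrize("args,score,grade", [
        ((0, 0, 30, 40, 3), 5, "A"),
        ((1, 1, 40, 30, 3), 9, "B"),
        ((4, 3, 60, 20, 8), 15, "OTHER"),
    ])
    def test_worked_examples(self, args, score, grade):
        assert cp_score(*args) == score
        assert cp_grade(score) == grade

    def test_boundary_ties_take_the_middle_score(self):
        assert cp_score(0, 0, 51, 40, 3) == 6    # TBIL exactly 51 scores 2
        assert cp_score(0, 0, 30, 35, 4) == 7    # ALB 35 and PT 4 both score 2

    @pytest.mark.parametrize("bad", [
        (5, 0, 30, 40, 3), (0, 0, -1, 40, 3), (0, 0, 30, 0, 3),
    ])
    def test_out_of_domain_errors(self, bad):
        with pytest.raises(ValueError):
            cp_score(*bad)

    @pytest.mark.parametrize("score", [4, 16])
    def test_grade_domain(self, score):
        with pytest.raises(ValueError):
            cp_grade(score)

    def test_region_encoding_agrees_with_score_on_random_patients(self, kbs):
        """The graded indicator-sum encoding of grade A must coincide with
        direct scoring on 10,000 random covariate tuples."""
        region = kbs["sorafenib_child_pugh"].positive_regions[0]
        names = ["HE", "AC", "TBIL", "ALB", "PT"]
        rng = np.random.default_rng(42)
        for _ in range(10_000):
            he = rng.integers(0, 5)
            ac = rng.integers(0, 4)
            tbil = rng.uniform(1, 100)
            alb = rng.uniform(5, 60)
            pt = rng.uniform(0.5, 12)
            by_score = cp_score(he, ac, tbil, alb, pt) in (5, 6)
            by_region = is_member([he, ac, tbil, alb, pt], region, names)
            assert by_score == by_region

    def test_printed_threshold_constants(self, kbs):
        region = kbs["sorafenib_child_pugh"].positive_regions[0]
        by_key = {(t.covariate, t.coefficient): t for t in region.terms}
        assert by_key[("TBIL", 3.0)].lower > 51.0         # open above 51
        assert by_key[("TBIL", 3.0)].upper == np.inf
        assert by_key[("HE", 2.0)].lower == 1.0
        assert by_key[("HE", 2.0)].upper == 2.0
        assert region.admissible_values == frozenset({5.0, 6.0})


class TestClassify:
    def test_zero_positive_unknown(self, kbs):
        kb = kbs["small_hcc"]
        assert classify([1.5, 1, 0, 0, 0], kb, HCC_NAMES) is Effect.ZERO
        assert classify([9.0, 4, 1, 1, 1], kb, HCC_NAMES) is Effect.UNKNOWN

    def test_benchmark_zero_region_value_set(self, kbs):
        theta3 = kbs["actg_semi_synthetic"].zero_regions[0]
        assert theta3.admissible_values == frozenset({0.0, 0.5, 1.0, 1.5, 2.0})

    def test_conflicting_regions_raise(self):
        region = KnowledgeRegion((IndicatorTerm(0, 1.0, 0, 1),),
                                 frozenset({1.0}), label="r")
        kb = KnowledgeBase([region], [region])
        with pytest.raises(InconsistencyError):
            classify([0.5], kb)

    def test_hcc_study_value_set_variants(self):
        default = builtin_knowledge_bases()["hcc_study"]
        strict = builtin_knowledge_bases(hcc_all_criteria=True)["hcc_study"]
        # as printed: four of five conditions; variant: all five
        all_five = [1.0, 1, 0, 0, 0]
        assert not is_member(all_five, default.zero_regions[0], HCC_NAMES)
        assert is_member(all_five, strict.zero_regions[0], HCC_NAMES)


def test_yaml_config_round_trip(tmp_path):
    text = """
regions:
  - label: young_responders
    effect: positive
    admissible_values: [2]
    terms:
      - {covariate: AGE, coeff: 1.0, low: null, high: 40}
      - {covariate: SEX, coeff: 1.0, low: 1, high: 1}
  - label: no_effect
    effect: zero
    admissible_values: [1]
    terms:
      - {covariate: AGE, coeff: 1.0, low: 65, high: inf}
"""
    path = tmp_path / "kb.yaml"
    path.write_text(text)
    kb = load_knowledge_base(path)
    names = ["AGE", "SEX"]
    assert classify([30, 1], kb, names) is Effect.POSITIVE
    assert classify([70, 0], kb, names) is Effect.ZERO
    assert classify([50, 0], kb, names) is Effect.UNKNOWN
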