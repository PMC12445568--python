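import numpy as np
import pytest
from hypothesis import given, strategies as st

import oracle
from conftest import make_table, random_table, to_oracle

from thalscreen.dominance import class_unions, lower_approximation
from thalscreen.rules import (
    AT_LEAST,
    AT_MOST,
    DecisionRule,
    ElementaryCondition,
    RuleParseError,
    RuleSet,
    induce_rules,
    parse_rules,
    rule_metrics,
    serialize_rules,
    vc_positive_region,
)


def union_of(table, kind, t):
    return next(u for u in class_unions(table) if u.kind == kind and u.t == t)


chain_table = lambda: make_table([(1, 0), (2, 0), (3, 1), (4, 1)], {"a": "gain"})


class TestVCPositiveRegion:
    def test_threshold_one_is_lower_approximation(self, worked_example):
        up1 = union_of(worked_example, "upward", 1)
        assert vc_positive_region(worked_example, up1, 1.0) == {"x5", "x9"}

    def test_identical_pair_admitted_at_half(self):
        t = make_table([(1, 0), (1, 1)], {"a": "gain"})
        up1 = union_of(t, "upward", 1)
        dn0 = union_of(t, "downward", 0)
        assert vc_positive_region(t, up1, 1.0) == set()
        assert vc_positive_region(t, up1, 0.5) == {"o1"}
        assert vc_positive_region(t, dn0, 0.5) == {"o0"}

    def test_matches_lower_approximation_on_random_tables(self):
        rng = np.random.default_rng(41)
        for _ in range(30):
            t = random_table(rng)
            for kind in ("upward", "downward"):
                for cls in (0, 1):
                    u = union_of(t, kind, cls)
                    assert vc_positive_region(t, u, 1.0) == lower_approximation(t, u)

    @pytest.mark.parametrize("l", [0.0, -0.2, 1.2])
    def test_threshold_domain(self, l):
        t = make_table([(1, 0)], {"a": "gain"})
        with pytest.raises(ValueError, match="consistency threshold"):
            vc_positive_region(t, union_of(t, "upward", 0), l)


class TestInduction:
    def test_forced_separation_single_rule(self):
        rs = induce_rules(chain_table())
        at_least = rs.at_least_rules(1)
        assert len(at_least) == 1
        (rule,) = at_least
        assert rule.conditions == (ElementaryCondition("a", ">=", 3.0),)
        assert rule.support == frozenset({"o2", "o3"})
        assert rule.consistency == 1.0

    def test_worked_example_rules_cover_exactly_the_carriers(self, worked_example):
        rs = induce_rules(worked_example, l=1.0)
        covered = set()
        for rule in rs.at_least_rules(1):
            covered |= rule.support
            assert rule.consistency == 1.0
        assert covered == {"x5", "x9"}

    def test_training_reclassification_zero_error_on_consistent_tables(self):
        """At l = 1 on consistent tables the covering is complete and
        correct: at-least rules fire on every carrier and on no
        non-carrier."""
        rng = np.random.default_rng(59)
        tried = 0
        from thalscreen.dominance import quality_of_approximation

        while tried < 15:
            t = random_table(rng, max_objects=10, max_criteria=3)
            if quality_of_approximation(t) < 1.0 or len(set(t.decisions)) < 2:
                continue
            tried += 1
            rs = induce_rules(t, l=1.0)
            fired = {
                oid
                for rule in rs.at_least_rules(1)
                for oid in t.object_ids
                if rule.fires(t.data.loc[oid])
            }
            carriers = {oid for oid in t.object_ids if t.data.loc[oid, "decision"] == 1}
            assert fired == carriers

    def test_rules_cover_positive_region_and_are_minimal(self):
        rng = np.random.default_rng(83)
        for _ in range(10):
            t = random_table(rng, max_objects=9, max_criteria=3)
            rs = induce_rules(t, l=1.0)
            for kind, rkind, cls in (("upward", AT_LEAST, 1), ("downward", AT_MOST, 0)):
                u = union_of(t, kind, cls)
                pos = vc_positive_region(t, u, 1.0)
                rules = [r for r in rs.rules if r.kind == rkind and r.t == cls]
                covered = {
                    oid
                    for r in rules
                    for oid in t.object_ids
                    if r.fires(t.data.loc[oid])
                }
                assert pos <= covered
                # minimality: dropping any single condition lets the
                # rule's cover escape the positive region
                for r in rules:
                    cover = {
                        oid for oid in t.object_ids if r.fires(t.data.loc[oid])
                    }
                    assert cover <= pos
                    if len(r.conditions) > 1:
                        for drop in r.conditions:
                            rest = [c for c in r.conditions if c is not drop]
                            weaker = {
                                oid
                                for oid in t.object_ids
                                if all(
                                    c.holds(t.data.loc[oid, c.criterion])
                                    for c in rest
                                )
                            }
                            assert not weaker <= pos

    def test_monotone_condition_relations(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            t = random_table(rng)
            directions = {c.name: c.direction for c in t.criteria}
            rs = induce_rules(t)
            for rule in rs.rules:
                for c in rule.conditions:
                    if rule.kind == AT_LEAST:
                        expected = ">=" if directions[c.criterion] == "gain" else "<="
                    else:
                        expected = "<=" if directions[c.criterion] == "gain" else ">="
                    assert c.relation == expected

    def test_thresholds_come_from_data(self):
        rng = np.random.default_rng(19)
        for _ in range(10):
            t = random_table(rng)
            rs = induce_rules(t)
            for rule in rs.rules:
                for c in rule.conditions:
                    assert c.threshold in set(t.data[c.criterion].tolist())

    def test_determinism_byte_identical(self, worked_example):
        a = serialize_rules(induce_rules(worked_example))
        b = serialize_rules(induce_rules(worked_example))
        assert a == b

    def test_empty_positive_region_no_rules(self):
        t = make_table([(1, 0), (1, 1)], {"a": "gain"})
        rs = induce_rules(t, l=1.0)  # nothing certain on either side
        assert rs.rules == []


class TestRuleMetrics:
    def test_one_class_full_cover(self):
        t = make_table([(1, 1), (2, 1)], {"a": "gain"})
        rule = DecisionRule((ElementaryCondition("a", ">=", 1.0),), AT_LEAST, 1)
        m = rule_metrics(rule, t)
        assert m == {"support": 2, "strength": 1.0, "confidence": 1.0}

    def test_toy_chain_rule(self):
        rule = DecisionRule((ElementaryCondition("a", ">=", 3.0),), AT_LEAST, 1)
        m = rule_metrics(rule, chain_table())
        assert m["support"] == 2 and m["strength"] == 0.5 and m["confidence"] == 1.0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            t = random_table(rng)
            rows, dirs = to_oracle(t)
            name = t.criterion_names[0]
            threshold = float(t.data[name].iloc[0])
            rule = DecisionRule((ElementaryCondition(name, ">=", threshold),), AT_LEAST, 1)
            cover = {i for i, v, _ in rows if v[name] >= threshold}
            support = {i for i, v, c in rows if v[name] >= threshold and c >= 1}
            m = rule_metrics(rule, t)
            assert m["support"] == len(support)
            assert m["strength"] == pytest.approx(len(support) / len(rows))
            expected_conf = len(support) / len(cover) if cover else 0.0
            assert m["confidence"] == pytest.approx(expected_conf)

    def test_unknown_criterion_rejected(self):
        t = chain_table()
        rule = DecisionRule((ElementaryCondition("zz", ">=", 1.0),), AT_LEAST, 1)
        with pytest.raises(KeyError, match="unknown criterion"):
            rule_metrics(rule, t)


conditions_strategy = st.lists(
    st.builds(
        ElementaryCondition,
        criterion=st.sampled_from(["mcv", "rbc", "hgb", "mi", "btd"]),
        relation=st.sampled_from([">=", "<="]),
        threshold=st.floats(
            min_value=-1e6, max_value=1e6, allow_nan=False, allow_infinity=False
        ),
    ),
    min_size=1,
    max_size=4,
    unique_by=lambda c: (c.criterion, c.relation),
)


class TestSerialization:
    def test_toy_rule_text(self):
        rule = DecisionRule((ElementaryCondition("a", ">=", 3.0),), AT_LEAST, 1)
        assert str(rule) == "(a>=3)=>(Class>=1)"

    def test_parse_two_condition_rule(self):
        rs = parse_rules("(MCHCgdL>=37)&(RDWCV>=30)=>(Class>=1)\n")
        (rule,) = rs.rules
        assert rule.kind == AT_LEAST and rule.t == 1
        assert rule.conditions == (
            ElementaryCondition("MCHCgdL", ">=", 37.0),
            ElementaryCondition("RDWCV", ">=", 30.0),
        )

    def test_whitespace_and_comments_tolerated(self):
        text = "# carrier rules\n( a >= 3 ) & ( b <= 2 ) => (Class >= 1)\n\n"
        rs = parse_rules(text)
        assert len(rs) == 1 and len(rs.rules[0].conditions) == 2

    @given(conds=conditions_strategy, kind=st.sampled_from([AT_LEAST, AT_MOST]), t=st.integers(0, 1))
    def test_round_trip_identity(self, conds, kind, t):
        rule = DecisionRule(tuple(conds), kind, t)
        rs = RuleSet([rule])
        assert parse_rules(serialize_rules(rs)).rules == [rule]

    @pytest.mark.parametrize(
        "bad",
        ["(a>=3)", "(a>3)=>(Class>=1)", "a>=3=>(Class>=1)", "(a>=3)(b<=2)=>(Class>=1)"],
    )
    def test_malformed_text_rejected_with_position(self, bad):
        with pytest.raises(RuleParseError, match="position"):
            parse_rules(bad)

    def test_duplicate_condition_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            DecisionRule(
                (
                    ElementaryCondition("a", ">=", 1.0),
                    ElementaryCondition("a", ">=", 2.0),
                ),
                AT_LEAST,
                1,
            )
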