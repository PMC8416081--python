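"""Rule engine: negation scope, slot matching, risk levels, corpus labeling."""

import itertools

import pytest

from treehole.ontology import Mention
from treehole.preprocess import CommentRecord
from treehole.rules import (
    NegationConfig,
    RiskAssessment,
    Rule,
    RuleSlot,
    assess_risk,
    collect_mentions,
    detect_negation,
    label_corpus,
    match_rule,
)


def mention(root, ontology, start, end, negated=False, cid="x"):
    return Mention(
        concept_id=cid,
        matched_root=root,
        ontology=ontology,
        span=(start, end),
        surface="",
        negated=negated,
    )


def rec(i, text):
    return CommentRecord(comment_id=f"c{i}", user_id=f"u{i}", text=text)


CUES = ["not", "never"]


class TestDetectNegation:
    def test_cue_immediately_before_mention(self):
        text = "i will not gatherkit today"
        m = mention("suicidePlan", "suicide", 11, 20)
        assert detect_negation(text, m, CUES) is True

    def test_no_cue_in_text(self):
        text = "i will surely gatherkit today"
        m = mention("suicidePlan", "suicide", 14, 23)
        assert detect_negation(text, m, CUES) is False

    def test_clause_boundary_blocks_scope(self):
        text = "why not, gatherkit"
        m = mention("suicidePlan", "suicide", 9, 18)
        assert detect_negation(text, m, CUES) is False

    def test_cue_outside_window_is_ignored(self):
        text = "never in a hundred years gatherkit"
        m = mention("suicidePlan", "suicide", 25, 34)
        assert detect_negation(text, m, CUES, window=8) is False
        assert detect_negation(text, m, CUES, window=50) is True

    def test_cue_must_be_a_whole_word(self):
        text = "the knot gatherkit"  # "knot" must not trigger "not"
        m = mention("suicidePlan", "suicide", 9, 18)
        assert detect_negation(text, m, CUES) is False

    def test_invalid_span_raises(self):
        with pytest.raises(ValueError, match="span"):
            detect_negation("ab", mention("r", "suicide", 0, 9), CUES)


LEVEL8_PLAN_TIME = Rule(
    rule_id="plan_time",
    level=8,
    slots=(
        RuleSlot("free_text"),
        RuleSlot("concept", "suicidePlan", "suicide"),
        RuleSlot("free_text"),
        RuleSlot("concept", "future", "time"),
        RuleSlot("free_text"),
    ),
)
LEVEL8_TIME_PLAN = Rule(
    rule_id="time_plan",
    level=8,
    slots=(
        RuleSlot("free_text"),
        RuleSlot("concept", "future", "time"),
        RuleSlot("free_text"),
        RuleSlot("concept", "suicidePlan", "suicide"),
        RuleSlot("free_text"),
    ),
)


class TestMatchRule:
    def test_slot_order_distinguishes_rule_variants(self):
        # [plan][future] text
        mentions = [
            mention("suicidePlan", "suicide", 0, 8),
            mention("future", "time", 10, 17),
        ]
        assert len(match_rule("t", LEVEL8_PLAN_TIME, mentions)) == 1
        assert len(match_rule("t", LEVEL8_TIME_PLAN, mentions)) == 0

    def test_negated_mention_blocks_both_variants(self):
        mentions = [
            mention("suicidePlan", "suicide", 0, 8, negated=True),
            mention("future", "time", 10, 17),
        ]
        assert match_rule("t", LEVEL8_PLAN_TIME, mentions) == []
        assert match_rule("t", LEVEL8_TIME_PLAN, mentions) == []

    def test_overlapping_mentions_cannot_fill_both_slots(self):
        mentions = [
            mention("suicidePlan", "suicide", 0, 8),
            mention("future", "time", 5, 12),  # overlaps the plan span
        ]
        assert match_rule("t", LEVEL8_PLAN_TIME, mentions) == []

    def test_all_assignments_match_brute_force_oracle(self):
        """Every ordered slot assignment is found, no more, no fewer."""
        roots = [("suicidePlan", "suicide"), ("future", "time"), ("suicidePlan", "suicide")]
        mentions = [
            mention(r, o, i * 10, i * 10 + 5) for i, (r, o) in enumerate(roots)
        ]
        for rule in (LEVEL8_PLAN_TIME, LEVEL8_TIME_PLAN):
            slots = rule.concept_slots()
            expected = set()
            for combo in itertools.permutations(mentions, len(slots)):
                ok = all(
                    m.matched_root == s.root_id and m.ontology == s.ontology
                    for m, s in zip(combo, slots)
                )
                increasing = all(
                    a.span[1] <= b.span[0] for a, b in zip(combo, combo[1:])
                )
                if ok and increasing:
                    expected.add(tuple(m.span for m in combo))
            got = {
                tuple(m.span for m in rm.mentions)
                for rm in match_rule("t", rule, mentions)
            }
            assert got == expected


class TestAssessRisk:
    def test_max_level_wins_over_lower_match(self, graph, rules):
        # plan + future matches both the level-8 pair and the level-6 plan rule
        a = assess_risk(rec(1, "maybe gatherkit tonight or so"), graph, rules)
        assert a.level == 8
        assert a.binary == "high"
        assert {m.level for m in a.matches} >= {6, 8}

    def test_wish_only_is_level_4_low(self, graph, rules):
        a = assess_risk(rec(1, "all this wishfade lately again"), graph, rules)
        assert (a.level, a.binary) == (4, "low")

    def test_no_mentions_is_level_0_low(self, graph, rules):
        a = assess_risk(rec(1, "a perfectly ordinary sentence here"), graph, rules)
        assert (a.level, a.binary, a.matches) == (0, "low", ())

    def test_negating_every_mention_forces_level_0(self, graph, rules):
        a = assess_risk(rec(1, "i would not gatherkit ever"), graph, rules)
        assert (a.level, a.binary) == (0, "low")

    def test_method_alone_is_high(self, graph, rules):
        a = assess_risk(rec(1, "thought about veinmark again today"), graph, rules)
        assert (a.level, a.binary) == (7, "high")

    def test_adding_a_rule_never_lowers_level(self, graph, rules):
        texts = [
            "maybe gatherkit tonight or so",
            "thought about veinmark again today",
            "all this wishfade lately again",
            "nothing at all in here",
        ]
        for text in texts:
            r = rec(1, text)
            for k in range(len(rules)):
                lvl_small = assess_risk(r, graph, rules[:k]).level
                lvl_big = assess_risk(r, graph, rules[: k + 1]).level
                assert lvl_big >= lvl_small

    def test_determinism(self, graph, rules):
        r = rec(1, "maybe gatherkit tonight or so")
        assert assess_risk(r, graph, rules) == assess_risk(r, graph, rules)


class TestRiskAssessmentInvariants:
    def test_binary_must_match_level(self):
        with pytest.raises(ValueError, match="inconsistent"):
            RiskAssessment(comment_id="c", level=7, binary="low")

    def test_level_zero_cannot_carry_matches(self, graph, rules):
        m = assess_risk(rec(1, "maybe gatherkit tonight or so"), graph, rules).matches
        with pytest.raises(ValueError, match="no matches"):
            RiskAssessment(comment_id="c", level=0, binary="low", matches=m)


class TestRuleSetShape:
    def test_two_slot_rules_ship_in_both_orderings(self, rules):
        """For each two-concept rule, the reversed slot order also exists."""
        two_slot = [r for r in rules if len(r.concept_slots()) == 2]
        assert two_slot, "default rule set must contain two-slot rules"
        signatures = {
            tuple((s.root_id, s.ontology) for s in r.concept_slots()): r.level
            for r in two_slot
        }
        for sig, level in signatures.items():
            assert signatures.get(sig[::-1]) == level

    def test_only_the_printed_level8_pair_is_not_extrapolated(self, rules):
        assert {r.level for r in rules if not r.extrapolated} == {8}

    def test_adjacent_concept_slots_rejected(self):
        with pytest.raises(ValueError, match="adjacent"):
            Rule(
                rule_id="bad",
                level=5,
                slots=(
                    RuleSlot("concept", "suicidePlan", "suicide"),
                    RuleSlot("concept", "future", "time"),
                ),
            )


class TestLabelCorpus:
    def test_counts_match_per_record_assessment(self, graph, rules):
        records = [
            rec(i, t)
            for i, t in enumerate(
                ["maybe gatherkit tonight or so"] * 2
                + ["thought about veinmark again today"] * 2
                + ["all this wishfade lately again"] * 3
                + ["a perfectly ordinary sentence here"] * 3
            )
        ]
        rows = label_corpus(records, graph, rules)
        assert sum(lab == "high" for _, lab, _ in rows) == 4
        for r, lab, lvl in rows:
            a = assess_risk(r, graph, rules)
            assert (a.binary, a.level) == (lab, lvl)

    def test_empty_corpus(self, graph, rules):
        assert label_corpus([], graph, rules) == []

    def test_labels_invariant_under_permutation(self, graph, rules):
        records = [
            rec(1, "maybe gatherkit tonight or so"),
            rec(2, "all this wishfade lately again"),
        ]
        fwd = {r.comment_id: (lab, lvl) for r, lab, lvl in label_corpus(records, graph, rules)}
        rev = {r.comment_id: (lab, lvl) for r, lab, lvl in label_corpus(records[::-1], graph, rules)}
        assert fwd == rev


def test_collect_mentions_marks_negation(graph, rules, neg_config):
    mentions = collect_mentions("do not gatherkit tonight", graph, rules, neg_config)
    by_root = {m.matched_root: m for m in mentions}
    assert by_root["suicidePlan"].negated is True
    assert by_root["future"].negated is False
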