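import numpy as np
import pytest

from drgrade import (FeatureVector, Predicate, Rule, RuleSet,
                     UncoveredRegionError, audit_ruleset, classify, explain,
                     explain_rule)
from drgrade.rules import SEVERITY_LABELS

from .oracles import printed_rule_matches


def _random_vectors(n, rng):
    for _ in range(n):
        yield FeatureVector(
            R_HE=float(rng.uniform(0, 0.5)), R_EX=float(rng.uniform(0, 0.1)),
            R_SE=float(rng.uniform(0, 0.5)), R_NV=float(rng.uniform(0, 0.05)),
            N_HE=int(rng.integers(0, 30)), N_EX=int(rng.integers(0, 12)),
            N_SE=int(rng.integers(0, 25)), N_AN=int(rng.integers(0, 15)),
            N_NV=int(rng.integers(0, 8)))


class TestBuiltinRuleset:
    def test_nine_rules_severity_ordered(self, ruleset):
        assert len(ruleset.rules) == 9
        severities = [r.severity for r in ruleset.rules]
        assert severities == sorted(severities)
        assert sorted(set(severities)) == [0, 1, 2, 3, 4]

    def test_no_dr_rule_has_three_predicates(self, ruleset):
        no_dr = ruleset.rules[0]
        assert no_dr.severity == 0
        assert len(no_dr.predicates) == 3

    def test_confidences_in_range(self, ruleset):
        assert all(0 < r.confidence <= 100 for r in ruleset.rules)

    def test_thresholds_are_the_printed_ones(self, ruleset):
        ratio_thresholds = sorted({
            p.threshold for r in ruleset.rules for p in r.predicates
            if p.feature.startswith("R_")})
        assert ratio_thresholds == [0.052, 0.111, 0.171, 0.18, 0.342, 0.343]

    def test_serialization_round_trip(self, ruleset, tmp_path):
        from drgrade import load_ruleset

        path = tmp_path / "rules.json"
        ruleset.save(path)
        loaded = load_ruleset(path)
        assert [r.rule_id for r in loaded.rules] == \
            [r.rule_id for r in ruleset.rules]
        assert all(a.predicates == b.predicates and
                   a.confidence == b.confidence
                   for a, b in zip(loaded.rules, ruleset.rules))


class TestClassify:
    @pytest.mark.parametrize("kwargs,severity,confidence", [
        (dict(), 0, 95.125),
        (dict(R_SE=0.05, R_HE=0.01, N_SE=5), 1, 99.396),
        (dict(R_SE=0.15, R_HE=0.02, N_SE=3), 2, 95.238),
        (dict(R_SE=0.10, R_HE=0.10), 2, 99.700),
        (dict(R_SE=0.10, R_HE=0.20), 3, 58.824),
        (dict(R_SE=0.25, R_HE=0.10), 3, 92.381),
        (dict(R_SE=0.25, N_NV=2), 4, 100.000),
        (dict(R_SE=0.40), 4, 100.000),
        (dict(R_SE=0.25, R_HE=0.40), 4, 100.000),
    ])
    def test_printed_rule_examples(self, ruleset, kwargs, severity,
                                   confidence):
        result = classify(FeatureVector(**kwargs), ruleset)
        assert result.severity == severity
        assert result.confidence == confidence
        assert result.label == SEVERITY_LABELS[severity]
        assert not result.fallback_used

    def test_deterministic_and_pure(self, ruleset):
        fv = FeatureVector(R_SE=0.15, R_HE=0.02, N_SE=3)
        first = classify(fv, ruleset)
        second = classify(fv, ruleset)
        assert first == second

    def test_matched_rule_self_consistency(self, ruleset, rng):
        by_id = {r.rule_id: r for r in ruleset.rules}
        for fv in _random_vectors(300, rng):
            res = classify(fv, ruleset)
            if not res.fallback_used:
                assert by_id[res.matched_rule].matches(fv)
                assert res.confidence == by_id[res.matched_rule].confidence

    def test_hemorrhage_monotonicity_at_printed_boundaries(self, ruleset):
        grades = [classify(FeatureVector(R_HE=v), ruleset).severity
                  for v in [0.0, 0.052, 0.0521, 0.171, 0.1711, 0.3]]
        assert grades == [0, 0, 2, 2, 3, 3]
        assert grades == sorted(grades)

    def test_fallback_error_policy(self):
        from drgrade import builtin_ruleset

        rs = builtin_ruleset(fallback_policy="error")
        with pytest.raises(UncoveredRegionError, match="N_SE"):
            classify(FeatureVector(R_SE=0.05, N_SE=30), rs)

    def test_fallback_widen_ranges_uses_lower_bounds(self, ruleset):
        # N_SE > 15 leaves the printed Mild range; widening treats it as >= 1
        res = classify(FeatureVector(R_SE=0.05, N_SE=30), ruleset)
        assert res.fallback_used
        assert res.severity == 1
        # N_NV > 3 widens the proliferative range
        res = classify(FeatureVector(R_SE=0.25, N_NV=9), ruleset)
        assert res.fallback_used
        assert res.severity == 4

    def test_fallback_nearest_rule(self):
        from drgrade import builtin_ruleset

        rs = builtin_ruleset(fallback_policy="nearest_rule")
        res = classify(FeatureVector(R_SE=0.25, N_NV=4), rs)
        assert res.fallback_used
        assert res.severity == 4


class TestExplain:
    def test_moderate_worked_interpretation(self, ruleset):
        rule = next(r for r in ruleset.rules if r.rule_id == "moderate_he")
        sentence = explain_rule(rule)
        assert sentence == (
            "If the ratio of soft exudate lesions is less than or equal 18% "
            "and the ratio of hemorrhage lesions is greater than 5.2% "
            "and the ratio of hemorrhage lesions is less than or equal "
            "17.1%, the severity is moderate.")

    def test_single_predicate_rule(self):
        rule = Rule(rule_id="r", severity=4, label="Proliferate DR",
                    confidence=90.0,
                    predicates=(Predicate("N_NV", "gt", 0),))
        sentence = explain_rule(rule)
        assert sentence == ("If the number of new vessel lesions is greater "
                            "than 0, the severity is proliferate.")

    def test_every_predicate_mentioned_once(self, ruleset):
        # each predicate renders exactly one "<subject> is <condition>" clause
        for rule in ruleset.rules:
            sentence = explain_rule(rule)
            assert sentence.count(" is ") == len(rule.predicates) + 1

    def test_integer_range_clause(self, ruleset):
        mild = next(r for r in ruleset.rules if r.rule_id == "mild")
        assert "between 1 and 15" in explain_rule(mild)

    def test_explain_checks_rule_identity(self, ruleset):
        res = classify(FeatureVector(), ruleset)
        with pytest.raises(ValueError):
            explain(res, ruleset.rules[3])
        assert explain(res, ruleset.rules[0]) == res.explanation


class TestAudit:
    def test_builtin_rules_mutually_exclusive(self, ruleset):
        assert audit_ruleset(ruleset).overlaps == []

    def test_builtin_uncovered_regions(self, ruleset):
        regions = audit_ruleset(ruleset).describe_uncovered()
        assert len(regions) == 2
        assert {"R_SE": "<= 0.18", "R_HE": "<= 0.052",
                "N_SE": "> 15"} in regions
        assert {"R_SE": "> 0.18", "N_NV": "> 3"} in regions

    def test_empty_ruleset_everything_uncovered(self):
        report = audit_ruleset(RuleSet(rules=[]))
        assert report.overlaps == []
        assert report.uncovered == [{}]  # whole domain, no constraint

    def test_overlapping_rules_detected(self):
        mk = lambda rid, thr: Rule(
            rule_id=rid, severity=0, label="No DR", confidence=50.0,
            predicates=(Predicate("R_HE", "le", thr),))
        report = audit_ruleset(RuleSet(rules=[mk("a", 0.1), mk("b", 0.2)]))
        assert ("a", "b") in report.overlaps

    def test_random_probe_agrees_with_interval_result(self, ruleset, rng):
        # every random vector matches at most one rule, and unmatched
        # vectors fall in one of the two described uncovered regions
        for fv in _random_vectors(2000, rng):
            matches = printed_rule_matches(fv.as_dict())
            assert len(matches) <= 1
            if not matches:
                d = fv.as_dict()
                in_r1 = (d["R_SE"] <= 0.18 and d["R_HE"] <= 0.052
                         and d["N_SE"] > 15)
                in_r2 = d["R_SE"] > 0.18 and d["N_NV"] > 3
                assert in_r1 or in_r2
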