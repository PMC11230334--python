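"""Rule predicates, feature extraction and the classic-ML baselines."""

import numpy as np
import pytest

from trialmatch import ConfigurationError, InputError, SyntheticSpec, generate_structured
from trialmatch.baseline import (
    CriterionRule,
    Event,
    StructuredRecord,
    default_rules,
    eligibility_from_rules,
    evaluate_rule,
    fit_baseline,
    load_records,
    load_rules,
    rule_feature_vector,
    save_records,
    save_rules,
)


def record(age=60.0, gender="F", events=()):
    return StructuredRecord("p0", list(events), age, gender)


class TestEvaluateRule:
    def test_age_range_inclusive(self):
        rule = CriterionRule("r", "inclusion", "age_range", lo=50, hi=90)
        assert evaluate_rule(record(age=60), rule)
        assert evaluate_rule(record(age=50), rule)
        assert not evaluate_rule(record(age=49.9), rule)

    def test_has_code_absent_is_false(self):
        rule = CriterionRule("r", "inclusion", "has_code",
                             event_type="diagnosis", code="G30")
        assert not evaluate_rule(record(), rule)
        assert evaluate_rule(record(events=[Event("diagnosis", "G30")]), rule)

    def test_numeric_threshold_boundary_inclusive(self):
        rule = CriterionRule("r", "inclusion", "numeric_threshold",
                             event_type="lab", code="MMSE", op=">=", bound=24)
        assert evaluate_rule(record(events=[Event("lab", "MMSE", 24.0)]), rule)
        assert not evaluate_rule(record(events=[Event("lab", "MMSE", 23.9)]), rule)

    def test_exclusion_polarity_not_negated_here(self):
        rule = CriterionRule("r", "exclusion", "has_code",
                             event_type="diagnosis", code="I63")
        assert evaluate_rule(record(events=[Event("diagnosis", "I63")]), rule)

    def test_unknown_event_type_rejected(self):
        with pytest.raises(InputError):
            Event("surgery", "X")
        rule = CriterionRule("r", "inclusion", "has_code",
                             event_type="diagnosis", code="X")
        rule.event_type = "surgery"  # corrupt after validation
        with pytest.raises(InputError):
            evaluate_rule(record(), rule)


class TestFeatureVector:
    def test_all_rules_satisfied(self):
        rules = default_rules()
        rec = record(age=70, events=[
            Event("diagnosis", "G30"), Event("lab", "MMSE", 22.0),
            Event("medication", "B01A"), Event("diagnosis", "I63"),
        ])
        assert rule_feature_vector(rec, rules) == pytest.approx(np.ones(len(rules)))

    def test_single_rule_flip_changes_one_component(self):
        rules = default_rules()
        a = record(age=70, events=[Event("diagnosis", "G30"), Event("lab", "MMSE", 22.0)])
        b = record(age=70, events=[Event("lab", "MMSE", 22.0)])
        va, vb = rule_feature_vector(a, rules), rule_feature_vector(b, rules)
        assert (va != vb).sum() == 1

    def test_length_is_rule_count(self):
        assert len(rule_feature_vector(record(), default_rules())) == len(default_rules())

    def test_empty_rule_list_rejected(self):
        with pytest.raises(InputError):
            rule_feature_vector(record(), [])

    def test_extraction_is_pure(self):
        rules = default_rules()
        rec = record(age=70, events=[Event("diagnosis", "G30")])
        before = (rec.age, rec.gender, len(rec.events))
        a = rule_feature_vector(rec, rules)
        b = rule_feature_vector(rec, rules)
        assert np.array_equal(a, b)
        assert (rec.age, rec.gender, len(rec.events)) == before


class TestFitBaseline:
    def _featurize(self, spec, rules):
        data = generate_structured(spec, rules)
        X = np.stack([rule_feature_vector(r, rules) for r, _ in data])
        y = np.array([lab for _, lab in data])
        return X, y

    def test_noiseless_labels_are_learnable_exactly(self):
        """With zero label noise the label is a deterministic Boolean
        function of the rule features, so a random forest recovers it."""
        rules = default_rules()
        spec = SyntheticSpec(n_pairs=120, pos_fraction=0.3, label_noise=0.0, seed=5)
        X, y = self._featurize(spec, rules)
        _, report = fit_baseline(X, y, model="random_forest", seed=0)
        assert report.mean_f1 == 1.0

    def test_full_label_noise_yields_chance(self):
        """At a 50% flip rate no signal remains; mean F1 sits at chance."""
        rules = default_rules()
        scores = []
        for seed in range(10):
            spec = SyntheticSpec(n_pairs=120, pos_fraction=0.3,
                                 label_noise=0.499, seed=seed)
            X, y = self._featurize(spec, rules)
            if y.min() == y.max():
                continue
            _, rep = fit_baseline(X, y, model="random_forest", seed=seed)
            scores.append(rep.mean_f1)
        assert 0.3 < np.mean(scores) < 0.65

    def test_same_seed_identical_report(self):
        rules = default_rules()
        spec = SyntheticSpec(n_pairs=60, pos_fraction=0.3, seed=2)
        X, y = self._featurize(spec, rules)
        _, a = fit_baseline(X, y, model="logreg", seed=3)
        _, b = fit_baseline(X, y, model="logreg", seed=3)
        assert a.to_json() == b.to_json()

    def test_unknown_model_rejected(self):
        with pytest.raises(ConfigurationError):
            fit_baseline(np.zeros((10, 2)), [0, 1] * 5, model="mlp")

    @pytest.mark.parametrize("model", ["logreg", "svm", "random_forest"])
    def test_all_baselines_run(self, model):
        rules = default_rules()
        spec = SyntheticSpec(n_pairs=60, pos_fraction=0.3, seed=4)
        X, y = self._featurize(spec, rules)
        _, report = fit_baseline(X, y, model=model, seed=0)
        assert 0.0 <= report.mean_f1 <= 1.0


class TestIO:
    def test_rules_yaml_round_trip(self, tmp_path):
        rules = default_rules()
        path = tmp_path / "rules.yaml"
        save_rules(rules, path)
        assert load_rules(path) == rules

    def test_records_jsonl_round_trip(self, tmp_path):
        data = generate_structured(SyntheticSpec(n_pairs=20, pos_fraction=0.3, seed=1),
                                   default_rules())
        path = tmp_path / "records.jsonl"
        save_records(data, path)
        back = load_records(path)
        assert back == data


def test_eligibility_formula():
    rules = default_rules()
    eligible = record(age=70, events=[Event("diagnosis", "G30"), Event("lab", "MMSE", 20.0)])
    assert eligibility_from_rules(eligible, rules) == 1
    excluded = record(age=70, events=[
        Event("diagnosis", "G30"), Event("lab", "MMSE", 20.0), Event("diagnosis", "I63"),
    ])
    assert eligibility_from_rules(excluded, rules) == 0
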