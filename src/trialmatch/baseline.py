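"""Rule-based baseline: criterion predicates over structured records feeding
classic ML classifiers.

This is the portable counterpart of cohort SQL queries against an
institutional EHR schema: each eligibility criterion becomes a predicate
over a patient's structured record (coded events, age, gender), the
predicates' raw truth values form a binary feature vector, and a standard
classifier (logistic regression / SVM / random forest) learns eligibility
from those features.  Exclusion-polarity rules are *not* negated during
feature extraction — the classifier learns the sign.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .evaluation import CVReport, TrainConfig, _fold_metrics, stratified_kfold
from .exceptions import ConfigurationError, InputError

EVENT_TYPES = frozenset(
    {"diagnosis", "medication", "allergy", "family_history", "lab", "admission"}
)

OPS = {
    "<": np.less,
    "<=": np.less_equal,
    ">": np.greater,
    ">=": np.greater_equal,
}


@dataclass
class Event:
    event_type: str
    code: str
    value: float | None = None

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise InputError(
                f"unknown event type {self.event_type!r}; known: {sorted(EVENT_TYPES)}"
            )


@dataclass
class StructuredRecord:
    patient_id: str
    events: list[Event] = field(default_factory=list)
    age: float = 0.0
    gender: str = "F"

    def __post_init__(self):
        if self.age < 0:
            raise InputError("age must be non-negative")


@dataclass
class CriterionRule:
    """One eligibility predicate.

    kind: has_code | numeric_threshold | age_range | gender_is, with the
    matching parameters filled in.
    """

    rule_id: str
    polarity: Literal["inclusion", "exclusion"]
    kind: str
    event_type: str | None = None
    code: str | None = None
    op: str | None = None
    bound: float | None = None
    lo: float | None = None
    hi: float | None = None
    gender: str | None = None

    def __post_init__(self):
        if self.polarity not in ("inclusion", "exclusion"):
            raise ConfigurationError(f"unknown polarity {self.polarity!r}")
        required = {
            "has_code": ("event_type", "code"),
            "numeric_threshold": ("event_type", "code", "op", "bound"),
            "age_range": ("lo", "hi"),
            "gender_is": ("gender",),
        }
        if self.kind not in required:
            raise ConfigurationError(f"unknown predicate kind {self.kind!r}")
        missing = [f for f in required[self.kind] if getattr(self, f) is None]
        if missing:
            raise ConfigurationError(
                f"rule {self.rule_id}: predicate {self.kind} missing {missing}"
            )
        if self.kind == "numeric_threshold" and self.op not in OPS:
            raise ConfigurationError(f"unknown comparison op {self.op!r}")


def evaluate_rule(record: StructuredRecord, rule: CriterionRule) -> bool:
    """Raw predicate truth on one record (polarity is NOT applied here)."""
    if rule.kind in ("has_code", "numeric_threshold") and rule.event_type not in EVENT_TYPES:
        raise InputError(f"rule {rule.rule_id}: unknown event type {rule.event_type!r}")
    if rule.kind == "has_code":
        return any(
            e.event_type == rule.event_type and e.code == rule.code
            for e in record.events
        )
    if rule.kind == "numeric_threshold":
        cmp = OPS[rule.op]
        return any(
            e.event_type == rule.event_type
            and e.code == rule.code
            and e.value is not None
            and bool(cmp(e.value, rule.bound))
            for e in record.events
        )
    if rule.kind == "age_range":
        return rule.lo <= record.age <= rule.hi
    return record.gender == rule.gender  # gender_is


def rule_feature_vector(record: StructuredRecord,
                        rules: Sequence[CriterionRule]) -> np.ndarray:
    """Binary indicator vector, one component per rule, order-stable."""
    if not rules:
        raise InputError("empty rule list")
    return np.array([int(evaluate_rule(record, r)) for r in rules], dtype=np.float64)


def eligibility_from_rules(record: StructuredRecord,
                           rules: Sequence[CriterionRule]) -> int:
    """The Boolean gold standard: all inclusions hold and no exclusion does."""
    for r in rules:
        holds = evaluate_rule(record, r)
        if r.polarity == "inclusion" and not holds:
            return 0
        if r.polarity == "exclusion" and holds:
            return 0
    return 1


BASELINE_MODELS = ("logreg", "svm", "random_forest")


def _make_classifier(name: str, seed: int):
    if name == "logreg":
        return LogisticRegression(random_state=seed, max_iter=1000)
    if name == "svm":
        return SVC(random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed)
    raise ConfigurationError(
        f"unknown baseline model {name!r}; choose from {BASELINE_MODELS}"
    )


def fit_baseline(features: np.ndarray, labels: Sequence[int],
                 model: str = "random_forest", seed: int = 0,
                 k_folds: int = 5):
    """Cross-validate a classic classifier on rule features.

    Uses the same stratified folds and F1 metrics as the neural evaluation
    harness, so baseline and siamese reports are directly comparable.
    Returns ``(final_classifier, CVReport)`` where the final classifier is
    refit on all data.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if features.ndim != 2 or len(features) != len(labels):
        raise InputError("features must be (n, r) aligned with labels")
    if labels.min() == labels.max():
        raise InputError("both classes must be present")
    folds = stratified_kfold(labels, k_folds, seed)
    results = []
    for fold_index, (train_idx, test_idx) in enumerate(folds):
        clf = _make_classifier(model, seed)
        clf.fit(features[train_idx], labels[train_idx])
        y_pred = clf.predict(features[test_idx])
        results.append(_fold_metrics(fold_index, labels[test_idx], y_pred))
    report = CVReport(
        folds=results,
        mean_f1=float(np.mean([r.f1_overall for r in results])),
        mean_f1_pos=float(np.mean([r.f1_pos for r in results])),
        mean_f1_neg=float(np.mean([r.f1_neg for r in results])),
        seed=seed,
        config={"baseline": {"model": model, "k_folds": k_folds, "seed": seed,
                             "hyperparameters": "library defaults"}},
    )
    final = _make_classifier(model, seed)
    final.fit(features, labels)
    return final, report


# ---------------------------------------------------------------- records IO


def save_records(records: Sequence[tuple[StructuredRecord, int]],
                 path: str | Path) -> None:
    """JSONL: one ``{patient_id, age, gender, events, label}`` per line."""
    import json

    with open(path, "w") as fh:
        for rec, label in records:
            fh.write(
                json.dumps(
                    {
                        "patient_id": rec.patient_id,
                        "age": rec.age,
                        "gender": rec.gender,
                        "events": [
                            {"event_type": e.event_type, "code": e.code, "value": e.value}
                            for e in rec.events
                        ],
                        "label": int(label),
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def load_records(path: str | Path) -> list[tuple[StructuredRecord, int]]:
    import json

    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            raw = json.loads(line)
            rec = StructuredRecord(
                patient_id=raw["patient_id"],
                events=[Event(**e) for e in raw["events"]],
                age=raw["age"],
                gender=raw["gender"],
            )
            out.append((rec, int(raw["label"])))
    return out


# ------------------------------------------------------------------ rules IO


def save_rules(rules: Sequence[CriterionRule], path: str | Path) -> None:
    items = []
    for r in rules:
        d = {k: v for k, v in asdict(r).items() if v is not None}
        items.append(d)
    Path(path).write_text(yaml.safe_dump(items, sort_keys=True))


def load_rules(path: str | Path) -> list[CriterionRule]:
    items = yaml.safe_load(Path(path).read_text())
    return [CriterionRule(**item) for item in items]


def default_rules() -> list[CriterionRule]:
    """A small eligibility rule set in the style of a cognitive-disorder
    trial: age window, diagnosis and cognitive-score inclusions, plus
    medication / comorbidity exclusions."""
    return [
        CriterionRule("age_window", "inclusion", "age_range", lo=55, hi=90),
        CriterionRule("dx_alzheimers", "inclusion", "has_code",
                      event_type="diagnosis", code="G30"),
        CriterionRule("mmse_floor", "inclusion", "numeric_threshold",
                      event_type="lab", code="MMSE", op=">=", bound=18),
        CriterionRule("anticoagulant_use", "exclusion", "has_code",
                      event_type="medication", code="B01A"),
        CriterionRule("recent_stroke", "exclusion", "has_code",
                      event_type="diagnosis", code="I63"),
    ]
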