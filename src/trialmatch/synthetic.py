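"""Synthetic patient-trial datasets with the statistical structure the
matcher assumes.

The generator emulates a small single-trial cohort (180 pairs, 50 eligible
vs 130 not, by default) in three forms:

* **coarse** — one embedding per document.  A latent trial direction ``t``
  is drawn once per dataset; every pair's criteria vector sits near ``t``.
  Eligible patients' EHR vectors mix ``t`` with an idiosyncratic direction
  ``g`` at coupling strength ``s`` (the *separation*), so the label is
  carried by the EHR-criteria semantic correlation, not by surface
  equality; ineligible patients' EHR vectors are independent of ``t``.
  At ``s = 0`` the two classes are distributionally identical (a null
  dataset for leakage checks).
* **fine** — token-embedding matrices: each document's tokens scatter
  around the document centroid built as in the coarse mode, with lengths
  drawn uniformly from a range.
* **structured** — coded event records plus demographics whose noiseless
  label is exactly "all inclusion rules hold and no exclusion rule does",
  for the rule-based baseline.

All randomness flows from ``SyntheticSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .baseline import CriterionRule, Event, StructuredRecord, eligibility_from_rules
from .embeddings import EmbeddedPair
from .exceptions import ConfigurationError, GenerationError, InputError


@dataclass
class SyntheticSpec:
    """Knobs of the synthetic cohort; defaults mirror a 180-patient trial
    with 50 eligible."""

    n_pairs: int = 180
    pos_fraction: float = 50 / 180
    embed_dim: int = 64
    separation: float = 0.9  # EHR-criteria semantic coupling for positives
    noise_sd: float = 0.1
    token_length_range: tuple[int, int] = (5, 30)
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs < 2:
            raise ConfigurationError("need at least two pairs")
        if not 0.0 < self.pos_fraction < 1.0:
            raise ConfigurationError("pos_fraction must be strictly between 0 and 1")
        if self.embed_dim < 2:
            raise ConfigurationError("embed_dim must be at least 2")
        if not 0.0 <= self.separation <= 1.0:
            raise ConfigurationError("separation must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if not 0.0 <= self.label_noise < 0.5:
            raise ConfigurationError("label_noise must be in [0, 0.5)")
        lo, hi = self.token_length_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("token_length_range must satisfy 1 <= lo <= hi")

    @property
    def n_pos(self) -> int:
        return int(round(self.n_pairs * self.pos_fraction))


def _unit(rng: np.random.Generator, d: int) -> np.ndarray:
    v = rng.standard_normal(d)
    return v / np.linalg.norm(v)


def _centroids(spec: SyntheticSpec, rng: np.random.Generator):
    """Per-pair (ehr_centroid, criteria_centroid, label) before noise."""
    d, s = spec.embed_dim, spec.separation
    t = _unit(rng, d)  # the latent trial direction
    labels = np.zeros(spec.n_pairs, dtype=int)
    labels[: spec.n_pos] = 1
    rng.shuffle(labels)
    out = []
    for y in labels:
        g = _unit(rng, d)
        if y == 1:
            mix = s * t + (1.0 - s) * g
            ehr = mix / np.linalg.norm(mix)
        else:
            ehr = g
        out.append((ehr, t, int(y)))
    return out


def _flip_labels(labels: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate == 0.0:
        return labels
    flips = rng.random(len(labels)) < rate
    return np.where(flips, 1 - labels, labels)


def generate_coarse(spec: SyntheticSpec) -> list[EmbeddedPair]:
    """Document-level embedded pairs with exact class counts."""
    rng = np.random.default_rng(spec.seed)
    sd = spec.noise_sd
    pairs = []
    labels = []
    for i, (ehr_c, crit_c, y) in enumerate(_centroids(spec, rng)):
        ehr = ehr_c + sd * rng.standard_normal(spec.embed_dim)
        crit = crit_c + sd * rng.standard_normal(spec.embed_dim)
        pairs.append((f"pair{i:04d}", ehr, crit))
        labels.append(y)
    labels = _flip_labels(np.array(labels), spec.label_noise, rng)
    return [
        EmbeddedPair(pid, "coarse", ehr, crit, int(y))
        for (pid, ehr, crit), y in zip(pairs, labels)
    ]


def generate_fine(spec: SyntheticSpec) -> list[EmbeddedPair]:
    """Token-level embedded pairs; rows scatter around document centroids."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.token_length_range
    sd = spec.noise_sd
    pairs = []
    labels = []
    for i, (ehr_c, crit_c, y) in enumerate(_centroids(spec, rng)):
        le = int(rng.integers(lo, hi + 1))
        lc = int(rng.integers(lo, hi + 1))
        ehr = ehr_c + sd * rng.standard_normal((le, spec.embed_dim))
        crit = crit_c + sd * rng.standard_normal((lc, spec.embed_dim))
        pairs.append((f"pair{i:04d}", ehr, crit))
        labels.append(y)
    labels = _flip_labels(np.array(labels), spec.label_noise, rng)
    return [
        EmbeddedPair(pid, "fine", ehr, crit, int(y))
        for (pid, ehr, crit), y in zip(pairs, labels)
    ]


# ----------------------------------------------------------------- structured

_DISTRACTOR_CODES = {
    "diagnosis": ["E11", "I10", "J45", "M54"],
    "medication": ["C09A", "N02B", "A10B"],
    "allergy": ["PCN", "SULFA"],
    "family_history": ["G30", "I25"],
    "lab": ["HBA1C", "LDL"],
    "admission": ["ER", "OUTPATIENT"],
}

_MAX_ATTEMPTS = 200


def _base_record(rng: np.random.Generator, patient_id: str) -> StructuredRecord:
    events = []
    for etype, codes in _DISTRACTOR_CODES.items():
        for code in codes:
            if rng.random() < 0.3:
                value = float(np.round(rng.uniform(0, 100), 1)) if etype == "lab" else None
                events.append(Event(etype, code, value))
    return StructuredRecord(
        patient_id=patient_id,
        events=events,
        age=float(np.round(rng.uniform(40, 95), 1)),
        gender=str(rng.choice(["F", "M"])),
    )


def _force_rule(record: StructuredRecord, rule: CriterionRule, hold: bool,
                rng: np.random.Generator) -> None:
    """Mutate the record so the raw predicate evaluates to ``hold``."""
    if rule.kind == "has_code":
        record.events = [
            e for e in record.events
            if not (e.event_type == rule.event_type and e.code == rule.code)
        ]
        if hold:
            record.events.append(Event(rule.event_type, rule.code))
    elif rule.kind == "numeric_threshold":
        record.events = [
            e for e in record.events
            if not (e.event_type == rule.event_type and e.code == rule.code)
        ]
        lo, hi = sorted((rule.bound * 0.5, rule.bound * 1.5)) if rule.bound else (0, 1)
        span = max(abs(rule.bound), 1.0)
        if rule.op in (">", ">="):
            value = rule.bound + rng.uniform(0.1, span) if hold else rule.bound - rng.uniform(0.1, span)
        else:
            value = rule.bound - rng.uniform(0.1, span) if hold else rule.bound + rng.uniform(0.1, span)
        record.events.append(Event(rule.event_type, rule.code, float(np.round(value, 2))))
    elif rule.kind == "age_range":
        if hold:
            record.age = float(np.round(rng.uniform(rule.lo, rule.hi), 1))
        else:
            below = rule.lo > 1
            if below and (rng.random() < 0.5 or rule.hi >= 120):
                record.age = float(np.round(rng.uniform(max(rule.lo - 30, 0), rule.lo - 1), 1))
            else:
                record.age = float(np.round(rng.uniform(rule.hi + 1, rule.hi + 30), 1))
    elif rule.kind == "gender_is":
        if hold:
            record.gender = rule.gender
        else:
            record.gender = "M" if rule.gender == "F" else "F"


def generate_structured(spec: SyntheticSpec, rules: Sequence[CriterionRule]
                        ) -> list[tuple[StructuredRecord, int]]:
    """Records whose noiseless label is the inclusion/exclusion formula.

    Eligible records satisfy every inclusion rule and no exclusion rule;
    ineligible records violate a random non-empty subset of that condition.
    Labels are then flipped with probability ``label_noise``.  Raises
    :class:`GenerationError` if the rule set admits no satisfying record
    (e.g. contradictory predicates) within a bounded number of attempts.
    """
    if not rules:
        raise InputError("rule set must be non-empty")
    rng = np.random.default_rng(spec.seed)
    labels = np.zeros(spec.n_pairs, dtype=int)
    labels[: spec.n_pos] = 1
    rng.shuffle(labels)
    out: list[tuple[StructuredRecord, int]] = []
    for i, y in enumerate(labels):
        record = None
        for _attempt in range(_MAX_ATTEMPTS):
            cand = _base_record(rng, f"patient{i:04d}")
            if y == 1:
                targets = [(r, r.polarity == "inclusion") for r in rules]
            else:
                # break at least one conjunct of the eligibility formula
                breaks = rng.random(len(rules)) < 0.4
                if not breaks.any():
                    breaks[rng.integers(len(rules))] = True
                targets = [
                    (r, (r.polarity == "inclusion") ^ bool(b))
                    for r, b in zip(rules, breaks)
                ]
            for rule, hold in targets:
                _force_rule(cand, rule, hold, rng)
            if eligibility_from_rules(cand, rules) == y:
                record = cand
                break
        if record is None:
            raise GenerationError(
                f"could not realize a record with label {y} under the given "
                f"rules after {_MAX_ATTEMPTS} attempts (unsatisfiable rule set?)"
            )
        out.append((record, int(y)))
    noisy = _flip_labels(np.array([y for _, y in out]), spec.label_noise, rng)
    return [(rec, int(y)) for (rec, _), y in zip(out, noisy)]
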