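"""Documents, criteria sets and embedding providers.

A patient-trial pair is an EHR document plus the trial's list of eligibility
criterion statements.  An :class:`EmbeddingProvider` turns text into vectors
at two granularities:

* **coarse** — one vector per document; the criteria list is mean-pooled
  into a single trial-level vector;
* **fine** — one vector per token, giving an ``L x D`` matrix per document;
  the criterion statements are concatenated in listed order.

The default :class:`HashedRandomProvider` is a deterministic stand-in for a
large pretrained language model: every distinct text maps to a reproducible
pseudo-random unit vector keyed by a SHA-256 hash of the text (and the
provider seed), so the whole pipeline runs offline and bit-reproducibly.
A real LM backend only needs to implement the two ``embed_*`` methods.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .exceptions import ConfigurationError, InputError

Role = Literal["ehr", "criterion"]
Granularity = Literal["coarse", "fine"]

#: hard cap on token-sequence length; longer documents are tail-truncated
MAX_TOKENS = 512


def tokenize(text: str) -> list[str]:
    """Whitespace tokenization — provider-agnostic and reversible enough
    for synthetic corpora; real backends bring their own tokenizers."""
    return text.split()


@dataclass
class Document:
    doc_id: str
    role: Role
    text: str
    tokens: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.role not in ("ehr", "criterion"):
            raise InputError(f"unknown document role {self.role!r}")
        if not self.tokens and self.text:
            self.tokens = tokenize(self.text)
        if self.text and not self.tokens:
            raise InputError("non-empty text must yield at least one token")


@dataclass
class CriteriaSet:
    trial_id: str
    statements: list[Document]
    polarities: list[Literal["inclusion", "exclusion"]]

    def __post_init__(self):
        if len(self.statements) < 1:
            raise InputError("a criteria set needs at least one statement")
        if len(self.polarities) != len(self.statements):
            raise InputError("one polarity per statement required")
        for s in self.statements:
            if s.role != "criterion":
                raise InputError(f"statement {s.doc_id} has role {s.role!r}")
        for p in self.polarities:
            if p not in ("inclusion", "exclusion"):
                raise InputError(f"unknown polarity {p!r}")


@dataclass
class EmbeddedPair:
    """An <EHR, Criteria> pair in embedding space with its eligibility label."""

    pair_id: str
    granularity: Granularity
    ehr_rep: np.ndarray  # (D,) coarse or (d, D) fine
    criteria_rep: np.ndarray  # (D,) coarse or (n_total, D) fine
    label: int

    def __post_init__(self):
        self.ehr_rep = np.asarray(self.ehr_rep, dtype=np.float64)
        self.criteria_rep = np.asarray(self.criteria_rep, dtype=np.float64)
        if self.label not in (0, 1):
            raise InputError(f"label must be 0 or 1, got {self.label!r}")
        expected_ndim = 1 if self.granularity == "coarse" else 2
        for name, rep in (("ehr", self.ehr_rep), ("criteria", self.criteria_rep)):
            if rep.ndim != expected_ndim:
                raise InputError(
                    f"{name} representation must be {expected_ndim}-d for "
                    f"{self.granularity} granularity, got ndim={rep.ndim}"
                )
            if rep.shape[0] < 1:
                raise InputError(f"{name} representation is empty")
            if not np.all(np.isfinite(rep)):
                raise InputError(f"{name} representation contains non-finite values")
        if self.ehr_rep.shape[-1] != self.criteria_rep.shape[-1]:
            raise InputError("EHR and criteria embeddings disagree on dimension")

    @property
    def dim(self) -> int:
        return self.ehr_rep.shape[-1]


class EmbeddingProvider:
    """Interface every embedding backend implements."""

    name: str = "base"
    deterministic: bool = True

    def __init__(self, dimension: int):
        if dimension < 1:
            raise ConfigurationError("embedding dimension must be positive")
        self.dimension = dimension

    def embed_text(self, text: str) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def embed_token(self, token: str) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class HashedRandomProvider(EmbeddingProvider):
    """Deterministic pseudo-random embeddings keyed by a hash of the text.

    Distinct texts map to (almost surely) distinct unit vectors; the same
    text always maps to the same vector, across processes and platforms.
    """

    name = "hashed-random"
    deterministic = True

    def __init__(self, dimension: int = 64, seed: int = 0):
        super().__init__(dimension)
        self.seed = int(seed)

    def _vector(self, key: str) -> np.ndarray:
        digest = hashlib.sha256(f"{self.seed}\x00{key}".encode()).digest()
        rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
        v = rng.standard_normal(self.dimension)
        return v / np.linalg.norm(v)

    def embed_text(self, text: str) -> np.ndarray:
        return self._vector("text:" + text)

    def embed_token(self, token: str) -> np.ndarray:
        return self._vector("token:" + token)


def embed_document(doc: Document, provider: EmbeddingProvider) -> np.ndarray:
    """Document-level (coarse) embedding of one document."""
    if not doc.text:
        raise InputError(f"document {doc.doc_id} has empty text")
    vec = np.asarray(provider.embed_text(doc.text), dtype=np.float64)
    if vec.shape != (provider.dimension,):
        raise ConfigurationError(
            f"provider {provider.name} returned shape {vec.shape}, "
            f"expected ({provider.dimension},)"
        )
    if not np.all(np.isfinite(vec)):
        raise ConfigurationError(f"provider {provider.name} produced non-finite values")
    return vec


def embed_tokens(doc: Document, provider: EmbeddingProvider) -> np.ndarray:
    """Token-level (fine) embedding: one row per token, order preserved.

    Sequences longer than :data:`MAX_TOKENS` are tail-truncated.
    """
    if not doc.tokens:
        raise InputError(f"document {doc.doc_id} has no tokens")
    tokens = doc.tokens[:MAX_TOKENS]
    rows = np.stack([provider.embed_token(t) for t in tokens])
    if rows.shape[1] != provider.dimension:
        raise ConfigurationError(
            f"provider {provider.name} dimension mismatch: {rows.shape[1]} "
            f"vs {provider.dimension}"
        )
    return rows


def pool_criteria(statement_vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Mean-pool per-statement vectors into one trial-level vector."""
    if len(statement_vectors) == 0:
        raise InputError("cannot pool an empty list of criterion vectors")
    arrs = [np.asarray(v, dtype=np.float64) for v in statement_vectors]
    dims = {a.shape for a in arrs}
    if len(dims) > 1 or any(a.ndim != 1 for a in arrs):
        raise InputError(f"criterion vectors have inconsistent shapes: {sorted(dims)}")
    return np.mean(arrs, axis=0)


def build_pair(
    ehr: Document,
    criteria: CriteriaSet,
    provider: EmbeddingProvider,
    granularity: Granularity,
    label: int = 0,
    pair_id: str | None = None,
) -> EmbeddedPair:
    """Embed one <EHR, Criteria> pair at the requested granularity.

    Coarse: the EHR is embedded as a single text; each criterion statement is
    embedded independently and the statement vectors are mean-pooled.
    Fine: token matrices; the criterion statements are concatenated in listed
    order (no separator) to form one criteria token sequence.
    """
    if granularity not in ("coarse", "fine"):
        raise ConfigurationError(f"unknown granularity {granularity!r}")
    pid = pair_id or f"{ehr.doc_id}|{criteria.trial_id}"
    if granularity == "coarse":
        ehr_rep = embed_document(ehr, provider)
        crit_rep = pool_criteria(
            [embed_document(s, provider) for s in criteria.statements]
        )
    else:
        ehr_rep = embed_tokens(ehr, provider)
        crit_rep = np.concatenate(
            [embed_tokens(s, provider) for s in criteria.statements], axis=0
        )[:MAX_TOKENS]
    return EmbeddedPair(pid, granularity, ehr_rep, crit_rep, label)


# --------------------------------------------------------------------- corpus


LABEL_NAMES = {"success": 1, "fail": 0}


def load_corpus(path: str | Path) -> list[dict]:
    """Read a JSONL corpus: one record per patient-trial pair.

    Record schema: ``{pair_id, ehr_text, criteria: [{text, polarity}], label}``
    with label "success" or "fail".  Returns parsed records with ``Document``
    / ``CriteriaSet`` objects and integer labels.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            raw = json.loads(line)
            try:
                label = LABEL_NAMES[raw["label"]]
            except KeyError as err:
                raise InputError(
                    f"{path}:{lineno}: label must be 'success' or 'fail'"
                ) from err
            pid = raw["pair_id"]
            ehr = Document(doc_id=f"{pid}:ehr", role="ehr", text=raw["ehr_text"])
            statements = [
                Document(doc_id=f"{pid}:crit{i}", role="criterion", text=c["text"])
                for i, c in enumerate(raw["criteria"])
            ]
            polarities = [c.get("polarity", "inclusion") for c in raw["criteria"]]
            crit = CriteriaSet(trial_id=pid, statements=statements, polarities=polarities)
            records.append({"pair_id": pid, "ehr": ehr, "criteria": crit, "label": label})
    return records


def save_corpus(records: Iterable[dict], path: str | Path) -> None:
    """Write records (as returned by :func:`load_corpus`) back to JSONL."""
    inv = {v: k for k, v in LABEL_NAMES.items()}
    with open(path, "w") as fh:
        for rec in records:
            crit: CriteriaSet = rec["criteria"]
            fh.write(
                json.dumps(
                    {
                        "pair_id": rec["pair_id"],
                        "ehr_text": rec["ehr"].text,
                        "criteria": [
                            {"text": s.text, "polarity": p}
                            for s, p in zip(crit.statements, crit.polarities)
                        ],
                        "label": inv[rec["label"]],
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def save_pairs_npz(pairs: Sequence[EmbeddedPair], path: str | Path) -> None:
    """Cache embedded pairs to an NPZ archive (granularity-tagged)."""
    if not pairs:
        raise InputError("no pairs to save")
    gran = pairs[0].granularity
    if any(p.granularity != gran for p in pairs):
        raise InputError("cannot mix granularities in one archive")
    arrays: dict[str, np.ndarray] = {
        "_meta_granularity": np.array([gran]),
        "_meta_pair_ids": np.array([p.pair_id for p in pairs]),
        "_meta_labels": np.array([p.label for p in pairs], dtype=np.int64),
    }
    for i, p in enumerate(pairs):
        arrays[f"ehr_{i}"] = p.ehr_rep
        arrays[f"crit_{i}"] = p.criteria_rep
    np.savez(path, **arrays)


def load_pairs_npz(path: str | Path) -> list[EmbeddedPair]:
    with np.load(path, allow_pickle=False) as data:
        gran = str(data["_meta_granularity"][0])
        pair_ids = [str(x) for x in data["_meta_pair_ids"]]
        labels = data["_meta_labels"]
        return [
            EmbeddedPair(pid, gran, data[f"ehr_{i}"], data[f"crit_{i}"], int(labels[i]))
            for i, pid in enumerate(pair_ids)
        ]
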