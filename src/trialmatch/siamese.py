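"""Weight-sharing dual-encoder matcher and its single-encoder counterpart.

The siamese matcher (intermediate fusion) passes the EHR and the criteria
representation through *one* encoder — weight sharing is structural, the
same parameter tensors serve both branches — fuses the two encodings
(concatenation by default) and scores eligibility with a one-unit linear
head plus sigmoid.  Under the contrastive objective the head is unused and
eligibility is thresholded on the cosine similarity of the two encodings.

The single-encoder matcher (early fusion) concatenates the pair on the
input side — vectors end to end for coarse inputs, token sequences along
the token axis for fine inputs — and trains one encoder on the merged
input.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .embeddings import EmbeddedPair
from .encoders import Encoder, EncoderConfig, build_encoder
from .exceptions import ConfigurationError, InputError
from .losses import LOSS_KINDS, cosine_rows
from .nn import Linear, Module

FUSION_METHODS = ("concat", "add", "multiply", "mean")


def fuse(a, b, method: str = "concat"):
    """Combine two encoded representations (vectors or batches of rows).

    ``concat`` doubles the width; ``add``/``multiply``/``mean`` are
    component-wise and require equal lengths.
    """
    if method not in FUSION_METHODS:
        raise ConfigurationError(
            f"unknown fusion method {method!r}; choose from {FUSION_METHODS}"
        )
    is_tensor = isinstance(a, Tensor) or isinstance(b, Tensor)
    av = a if isinstance(a, Tensor) else np.asarray(a, dtype=np.float64)
    bv = b if isinstance(b, Tensor) else np.asarray(b, dtype=np.float64)
    if method != "concat" and av.shape[-1] != bv.shape[-1]:
        raise InputError(
            f"element-wise fusion needs equal widths, got {av.shape[-1]} and {bv.shape[-1]}"
        )
    if method == "concat":
        if is_tensor:
            return ad.concat([ad.as_tensor(av), ad.as_tensor(bv)], axis=-1)
        return np.concatenate([av, bv], axis=-1)
    if method == "add":
        return av + bv
    if method == "multiply":
        return av * bv
    return (av + bv) * 0.5  # mean


def _pad_batch(mats: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Tail-pad a ragged list of (L_i, D) matrices -> (B, Lmax, D) + mask."""
    B = len(mats)
    L = max(m.shape[0] for m in mats)
    D = mats[0].shape[1]
    x = np.zeros((B, L, D))
    mask = np.zeros((B, L))
    for i, m in enumerate(mats):
        x[i, : m.shape[0]] = m
        mask[i, : m.shape[0]] = 1.0
    return x, mask


def batch_pairs(pairs: Sequence[EmbeddedPair]):
    """Stack a list of pairs into branch inputs (+ masks for fine pairs)."""
    if not pairs:
        raise InputError("empty pair batch")
    gran = pairs[0].granularity
    if any(p.granularity != gran for p in pairs):
        raise InputError("cannot batch mixed granularities")
    labels = np.array([p.label for p in pairs], dtype=np.float64)
    if gran == "coarse":
        xe = np.stack([p.ehr_rep for p in pairs])
        xc = np.stack([p.criteria_rep for p in pairs])
        return xe, None, xc, None, labels
    xe, me = _pad_batch([p.ehr_rep for p in pairs])
    xc, mc = _pad_batch([p.criteria_rep for p in pairs])
    return xe, me, xc, mc, labels


class SiameseMatcher(Module):
    """Dual-branch matcher with one shared encoder (intermediate fusion)."""

    def __init__(self, encoder: Encoder | EncoderConfig, fusion: str = "concat",
                 loss_kind: str = "bce", margin: float = 1.0):
        super().__init__()
        if isinstance(encoder, EncoderConfig):
            encoder = build_encoder(encoder)
        if fusion not in FUSION_METHODS:
            raise ConfigurationError(f"unknown fusion method {fusion!r}")
        if loss_kind not in LOSS_KINDS:
            raise ConfigurationError(f"unknown loss {loss_kind!r}")
        self.encoder = encoder
        self.fusion = fusion
        self.loss_kind = loss_kind
        self.margin = margin
        self.trained_epochs = 0
        head_rng = np.random.default_rng((encoder.config.seed + 2) * 7919)
        width = 2 * encoder.output_dim if fusion == "concat" else encoder.output_dim
        self.head = Linear(width, 1, head_rng)

    # -------------------------------------------------------------- forward
    def encode_branches(self, xe, me, xc, mc) -> tuple[Tensor, Tensor]:
        """Run both inputs through the single shared encoder."""
        re = self.encoder.forward(ad.as_tensor(xe), me)
        rc = self.encoder.forward(ad.as_tensor(xc), mc)
        return re, rc

    def forward_batch(self, xe, me, xc, mc) -> Tensor:
        """Probabilities (BCE/WBCE) or cosine similarities (contrastive)."""
        re, rc = self.encode_branches(xe, me, xc, mc)
        if self.loss_kind == "contrastive":
            return cosine_rows(re, rc)
        fused = fuse(re, rc, self.fusion)
        logits = self.head(fused)
        B = logits.shape[0]
        return ad.sigmoid(logits.reshape(B))

    def fused_batch(self, xe, me, xc, mc) -> Tensor:
        """Fused representations right before the output head."""
        re, rc = self.encode_branches(xe, me, xc, mc)
        return fuse(re, rc, self.fusion)

    def compatible_with(self, pair: EmbeddedPair) -> bool:
        wants_seq = self.encoder.accepts_sequences
        return (pair.granularity == "fine") == wants_seq


class SingleEncoderMatcher(Module):
    """Early-fusion counterpart: one encoder over the merged input.

    For coarse pairs the encoder's ``input_dim`` must equal 2D (the two
    document vectors are concatenated); for fine pairs it stays D (token
    sequences are concatenated along the token axis).
    """

    def __init__(self, encoder: Encoder | EncoderConfig, loss_kind: str = "bce",
                 margin: float = 1.0):
        super().__init__()
        if isinstance(encoder, EncoderConfig):
            encoder = build_encoder(encoder)
        if loss_kind == "contrastive":
            raise ConfigurationError(
                "the contrastive objective needs two branch representations; "
                "the early-fusion model has only one"
            )
        if loss_kind not in LOSS_KINDS:
            raise ConfigurationError(f"unknown loss {loss_kind!r}")
        self.encoder = encoder
        self.fusion = "early"
        self.loss_kind = loss_kind
        self.margin = margin
        self.trained_epochs = 0
        head_rng = np.random.default_rng((encoder.config.seed + 2) * 7919)
        self.head = Linear(encoder.output_dim, 1, head_rng)

    def forward_batch(self, xe, me, xc, mc) -> Tensor:
        if self.encoder.accepts_sequences:
            x = np.concatenate([np.asarray(xe), np.asarray(xc)], axis=1)
            mask = None
            if me is not None:
                mask = np.concatenate([me, mc], axis=1)
        else:
            x = np.concatenate([np.asarray(xe), np.asarray(xc)], axis=-1)
            mask = None
        rep = self.encoder.forward(Tensor(x), mask)
        logits = self.head(rep)
        return ad.sigmoid(logits.reshape(logits.shape[0]))

    def fused_batch(self, xe, me, xc, mc) -> Tensor:
        """Pre-head representation (the single encoder's output)."""
        if self.encoder.accepts_sequences:
            x = np.concatenate([np.asarray(xe), np.asarray(xc)], axis=1)
            mask = None if me is None else np.concatenate([me, mc], axis=1)
        else:
            x = np.concatenate([np.asarray(xe), np.asarray(xc)], axis=-1)
            mask = None
        return self.encoder.forward(Tensor(x), mask)

    def compatible_with(self, pair: EmbeddedPair) -> bool:
        return (pair.granularity == "fine") == self.encoder.accepts_sequences


def early_fusion_input(pair: EmbeddedPair) -> np.ndarray:
    """Merge one pair on the input side, EHR first then criteria."""
    if pair.granularity == "coarse":
        return np.concatenate([pair.ehr_rep, pair.criteria_rep])
    return np.concatenate([pair.ehr_rep, pair.criteria_rep], axis=0)


def forward_pair(model, pair: EmbeddedPair) -> float:
    """Score a single pair (probability, or d_w for contrastive models)."""
    if not model.compatible_with(pair):
        raise ConfigurationError(
            f"{pair.granularity} pair incompatible with "
            f"{model.encoder.config.family} encoder"
        )
    xe, me, xc, mc, _ = batch_pairs([pair])
    return float(model.forward_batch(xe, me, xc, mc).data[0])


def predict_label(p: float, threshold: float = 0.5) -> int:
    """Threshold a probability; the tie p == threshold resolves to 1."""
    if not 0.0 <= threshold <= 1.0:
        raise ConfigurationError(f"threshold must be in [0, 1], got {threshold}")
    if not 0.0 <= p <= 1.0:
        raise InputError(f"probability out of range: {p}")
    return int(p >= threshold)


def predict_contrastive(model, pair: EmbeddedPair, sim_threshold: float | None = None) -> int:
    """Eligibility from cosine similarity; default threshold margin / 2."""
    if getattr(model, "loss_kind", None) != "contrastive":
        raise ConfigurationError(
            "predict_contrastive requires a model trained with the contrastive loss"
        )
    thr = model.margin / 2.0 if sim_threshold is None else sim_threshold
    d_w = forward_pair(model, pair)
    return int(d_w >= thr)


# ---------------------------------------------------------------- checkpoint


def save_checkpoint(model, path: str | Path) -> None:
    """NPZ checkpoint with the encoder config and model kind embedded."""
    meta = {
        "kind": type(model).__name__,
        "fusion": model.fusion,
        "loss_kind": model.loss_kind,
        "margin": model.margin,
        "trained_epochs": model.trained_epochs,
        "encoder_config": model.encoder.config.__dict__,
    }
    state = {f"param:{k}": v for k, v in model.state_dict().items()}
    state["_meta"] = np.array([json.dumps(meta, sort_keys=True)])
    np.savez(path, **state)


def load_checkpoint(path: str | Path):
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["_meta"][0]))
        config = EncoderConfig(**meta["encoder_config"])
        if meta["kind"] == "SiameseMatcher":
            model = SiameseMatcher(config, fusion=meta["fusion"],
                                   loss_kind=meta["loss_kind"], margin=meta["margin"])
        elif meta["kind"] == "SingleEncoderMatcher":
            model = SingleEncoderMatcher(config, loss_kind=meta["loss_kind"],
                                         margin=meta["margin"])
        else:
            raise ConfigurationError(f"unknown checkpoint kind {meta['kind']!r}")
        state = {k[len("param:"):]: data[k] for k in data.files if k.startswith("param:")}
        model.load_state_dict(state)
        model.trained_epochs = meta["trained_epochs"]
    return model.eval()
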