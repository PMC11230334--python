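"""Training objectives: BCE, class-weighted BCE and the contrastive loss.

The weighted variant multiplies only the positive-class (eligible, minority)
term by beta, so misclassifying an eligible patient costs more.  The
contrastive loss operates on the cosine similarity d_w between the two
encoded representations: dissimilar (fail) pairs are pushed toward d_w = 0
and similar (success) pairs toward d_w >= margin via a squared hinge:

    L = sum_i (1 - y_i) * d_i^2 + y_i * max(0, margin - d_i)^2

All three are written as sums over the cohort; ``reduction="mean"`` divides
by the batch size (the default used in training, for learning-rate
stability across fold sizes), ``reduction="sum"`` is the literal form.
Every function accepts numpy arrays or autodiff tensors, so the same code
path serves closed-form tests and gradient-based training.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .exceptions import ConfigurationError, InputError

#: probabilities are clamped to [EPS, 1-EPS] before the log
EPS = 1e-7

LOSS_KINDS = ("bce", "wbce", "contrastive")


def _values(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def _check_batch(y, y_hat) -> None:
    yv, pv = _values(y), _values(y_hat)
    if yv.shape != pv.shape:
        raise InputError(f"label/prediction length mismatch: {yv.shape} vs {pv.shape}")
    if yv.size == 0:
        raise InputError("empty loss batch")
    if not np.all(np.isin(yv, (0.0, 1.0))):
        raise InputError("labels must be 0 or 1")


def _reduce(total, n: int, reduction: str):
    if reduction == "sum":
        return total
    if reduction == "mean":
        return total * (1.0 / n)
    raise ConfigurationError(f"unknown reduction {reduction!r}")


def bce(y, y_hat, reduction: str = "sum"):
    """Binary cross-entropy: -sum_i [y log p + (1-y) log(1-p)]."""
    _check_batch(y, y_hat)
    y = y if isinstance(y, Tensor) else _values(y)
    p = ad.clip(y_hat if isinstance(y_hat, Tensor) else _values(y_hat), EPS, 1.0 - EPS)
    terms = y * ad.log(p) + (1.0 - y) * ad.log(1.0 - p)
    return _reduce(-terms.sum() if isinstance(terms, Tensor) else -terms.sum(),
                   _values(y).size, reduction)


def wbce(y, y_hat, beta: float, reduction: str = "sum"):
    """Weighted BCE: the positive (minority) term is scaled by beta.

    Reduces to :func:`bce` at beta = 1.
    """
    if beta <= 0:
        raise ConfigurationError(f"beta must be positive, got {beta}")
    _check_batch(y, y_hat)
    y = y if isinstance(y, Tensor) else _values(y)
    p = ad.clip(y_hat if isinstance(y_hat, Tensor) else _values(y_hat), EPS, 1.0 - EPS)
    terms = beta * (y * ad.log(p)) + (1.0 - y) * ad.log(1.0 - p)
    return _reduce(-terms.sum(), _values(y).size, reduction)


def cosine_similarity(u, v):
    """Cosine of the angle between two vectors, in [-1, 1].

    A zero vector is rejected rather than mapped to 0: it signals encoder
    collapse, which should surface loudly.
    """
    uv, vv = _values(u), _values(v)
    nu, nv = np.linalg.norm(uv), np.linalg.norm(vv)
    if nu == 0.0 or nv == 0.0:
        raise InputError("cosine similarity of a zero vector is undefined")
    if isinstance(u, Tensor) or isinstance(v, Tensor):
        u = u if isinstance(u, Tensor) else Tensor(uv)
        v = v if isinstance(v, Tensor) else Tensor(vv)
        return (u * v).sum() / (ad.sqrt((u * u).sum()) * ad.sqrt((v * v).sum()))
    return float(uv @ vv / (nu * nv))


def cosine_rows(a, b):
    """Row-wise cosine similarity of two (B, F) arrays/tensors -> (B,)."""
    av, bv = _values(a), _values(b)
    na = np.sqrt((av * av).sum(axis=-1))
    nb = np.sqrt((bv * bv).sum(axis=-1))
    if np.any(na == 0.0) or np.any(nb == 0.0):
        raise InputError("cosine similarity of a zero vector is undefined")
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        a = a if isinstance(a, Tensor) else Tensor(av)
        b = b if isinstance(b, Tensor) else Tensor(bv)
        num = (a * b).sum(axis=-1)
        den = ad.sqrt((a * a).sum(axis=-1)) * ad.sqrt((b * b).sum(axis=-1))
        return num / den
    return (av * bv).sum(axis=-1) / (na * nb)


def contrastive(y, d_w, margin: float = 1.0, reduction: str = "sum"):
    """Squared-hinge contrastive loss over cosine similarities."""
    if margin <= 0:
        raise ConfigurationError(f"margin must be positive, got {margin}")
    _check_batch(y, d_w)
    yv = _values(y)
    if np.any(_values(d_w) < -1.0 - 1e-9) or np.any(_values(d_w) > 1.0 + 1e-9):
        raise InputError("similarities must lie in [-1, 1]")
    y = y if isinstance(y, Tensor) else yv
    d = d_w if isinstance(d_w, Tensor) else _values(d_w)
    hinge = ad.maximum_scalar(margin - d, 0.0)
    terms = (1.0 - y) * d * d + y * hinge * hinge
    return _reduce(terms.sum(), yv.size, reduction)


def default_beta(labels) -> float:
    """Imbalance-matched beta: N_fail / N_success of the training labels."""
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("beta needs both classes in the training labels")
    return n_neg / n_pos
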