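"""Stratified cross-validated training and evaluation.

Protocol: stratified k-fold (k = 5), Adam at learning rate 0.005 for 50
epochs, a fresh model per fold, and F1 reported per class plus macro.  The
headline ``mean_f1`` is the macro-F1 (mean of positive- and negative-class
F1) averaged over folds; the positive-class F1 ("F1-Pos", eligible
patients) is always reported alongside.

Nothing computed on a test fold leaks into training: the class-imbalance
weight beta and all shuffling derive from the training split and the run
seed only.  Within each fold 10% of the training split is held out purely
to monitor validation loss; the final model is always the last-epoch model.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import losses as L
from .autodiff import Adam
from .embeddings import EmbeddedPair
from .exceptions import ConfigurationError, InputError
from .siamese import batch_pairs

@dataclass
class TrainConfig:
    epochs: int = 50
    learning_rate: float = 0.005
    k_folds: int = 5
    seed: int = 0
    beta: float | None = None  # None -> N_fail / N_success of the training split
    margin: float = 1.0
    batch_size: int | None = None  # None -> full batch (coarse) / 16 (fine)
    threshold: float = 0.5
    reduction: str = "mean"
    val_fraction: float = 0.1

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.k_folds < 2:
            raise ConfigurationError("k_folds must be >= 2")
        if not 0.0 <= self.val_fraction < 0.5:
            raise ConfigurationError("val_fraction must be in [0, 0.5)")


@dataclass
class FoldResult:
    fold_index: int
    tp: int
    fp: int
    tn: int
    fn: int
    f1_overall: float
    f1_pos: float
    f1_neg: float
    loss_history: list[float] = field(default_factory=list)
    val_history: list[float] = field(default_factory=list)


@dataclass
class CVReport:
    folds: list[FoldResult]
    mean_f1: float
    mean_f1_pos: float
    mean_f1_neg: float
    seed: int
    config: dict

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "schema": "trialmatch.cv_report/1",
                "seed": self.seed,
                "config": self.config,
                "mean_f1": self.mean_f1,
                "mean_f1_pos": self.mean_f1_pos,
                "mean_f1_neg": self.mean_f1_neg,
                "folds": [asdict(f) for f in self.folds],
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "CVReport":
        src = str(source)
        try:
            is_file = Path(src).exists()
        except OSError:
            is_file = False
        text = Path(src).read_text() if is_file else src
        data = json.loads(text)
        return cls(
            folds=[FoldResult(**f) for f in data["folds"]],
            mean_f1=data["mean_f1"],
            mean_f1_pos=data["mean_f1_pos"],
            mean_f1_neg=data["mean_f1_neg"],
            seed=data["seed"],
            config=data["config"],
        )

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["fold", "tp", "fp", "tn", "fn", "f1_overall", "f1_pos", "f1_neg"])
            for f in self.folds:
                writer.writerow([f.fold_index, f.tp, f.fp, f.tn, f.fn,
                                 f"{f.f1_overall:.6f}", f"{f.f1_pos:.6f}", f"{f.f1_neg:.6f}"])
            writer.writerow(["mean", "", "", "", "",
                             f"{self.mean_f1:.6f}", f"{self.mean_f1_pos:.6f}",
                             f"{self.mean_f1_neg:.6f}"])


# ---------------------------------------------------------------------- folds


def stratified_kfold(labels: Sequence[int], k: int, seed: int):
    """Class-stratified fold assignment, reproducible from the seed."""
    labels = np.asarray(labels)
    counts = np.bincount(labels, minlength=2)
    if k > counts.min():
        raise InputError(
            f"k={k} exceeds the minority-class count ({counts.min()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(train.copy(), test.copy()) for train, test in skf.split(np.zeros(len(labels)), labels)]


def f1(tp: int, fp: int, fn: int) -> float:
    """F1 = 2TP / (2TP + FP + FN); 0 by convention on an empty denominator."""
    if min(tp, fp, fn) < 0:
        raise InputError("confusion counts must be non-negative")
    denom = 2 * tp + fp + fn
    return 0.0 if denom == 0 else 2 * tp / denom


def _fold_metrics(fold_index: int, y_true: np.ndarray, y_pred: np.ndarray,
                  loss_history=None, val_history=None) -> FoldResult:
    tp = int(((y_pred == 1) & (y_true == 1)).sum())
    fp = int(((y_pred == 1) & (y_true == 0)).sum())
    tn = int(((y_pred == 0) & (y_true == 0)).sum())
    fn = int(((y_pred == 0) & (y_true == 1)).sum())
    f1_pos = f1(tp, fp, fn)
    f1_neg = f1(tn, fn, fp)  # negative class: swap the roles
    return FoldResult(
        fold_index=fold_index, tp=tp, fp=fp, tn=tn, fn=fn,
        f1_overall=(f1_pos + f1_neg) / 2.0, f1_pos=f1_pos, f1_neg=f1_neg,
        loss_history=list(loss_history or []), val_history=list(val_history or []),
    )


# ------------------------------------------------------------------- training


def _batch_loss(model, batch: Sequence[EmbeddedPair], config: TrainConfig,
                beta: float):
    xe, me, xc, mc, y = batch_pairs(batch)
    out = model.forward_batch(xe, me, xc, mc)
    if model.loss_kind == "bce":
        return L.bce(y, out, reduction=config.reduction)
    if model.loss_kind == "wbce":
        return L.wbce(y, out, beta=beta, reduction=config.reduction)
    return L.contrastive(y, out, margin=config.margin, reduction=config.reduction)


def train(model, train_pairs: Sequence[EmbeddedPair], config: TrainConfig,
          monitor_pairs: Sequence[EmbeddedPair] | None = None):
    """Train in place with Adam; returns (loss_history, val_history).

    ``monitor_pairs`` (optional) get a per-epoch validation loss; they never
    influence the parameters.
    """
    if not train_pairs:
        raise InputError("empty training set")
    labels = np.array([p.label for p in train_pairs])
    if labels.min() == labels.max():
        raise InputError("training set must contain both classes")
    if not model.compatible_with(train_pairs[0]):
        raise ConfigurationError(
            f"{train_pairs[0].granularity} pairs incompatible with the "
            f"{model.encoder.config.family} encoder"
        )
    beta = config.beta if config.beta is not None else L.default_beta(labels)
    fine = train_pairs[0].granularity == "fine"
    batch_size = config.batch_size or (16 if fine else len(train_pairs))
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    shuffle_rng = np.random.default_rng((config.seed + 3) * 15485863 % (2**31))
    model.train()
    loss_history: list[float] = []
    val_history: list[float] = []
    order = np.arange(len(train_pairs))
    for _epoch in range(config.epochs):
        shuffle_rng.shuffle(order)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), batch_size):
            batch = [train_pairs[i] for i in order[start: start + batch_size]]
            optimizer.zero_grad()
            loss = _batch_loss(model, batch, config, beta)
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        loss_history.append(epoch_loss / n_batches)
        if monitor_pairs:
            model.eval()
            val = _batch_loss(model, monitor_pairs, config, beta)
            val_history.append(float(val.data))
            model.train()
        model.trained_epochs += 1
    model.eval()
    return loss_history, val_history


def evaluate(model, pairs: Sequence[EmbeddedPair], config: TrainConfig) -> np.ndarray:
    """Predicted labels for a list of pairs (model in eval mode)."""
    model.eval()
    xe, me, xc, mc, _ = batch_pairs(pairs)
    out = model.forward_batch(xe, me, xc, mc).data
    if model.loss_kind == "contrastive":
        thr = model.margin / 2.0
        return (out >= thr).astype(int)
    return (out >= config.threshold).astype(int)


def cross_validate(model_factory: Callable[[int], object],
                   pairs: Sequence[EmbeddedPair],
                   config: TrainConfig) -> CVReport:
    """k-fold CV with a fresh model per fold; returns the aggregated report.

    ``model_factory(seed)`` must build an untrained model; it is called once
    per fold with a fold-specific seed derived from ``config.seed``.
    """
    labels = np.array([p.label for p in pairs])
    folds = stratified_kfold(labels, config.k_folds, config.seed)
    results: list[FoldResult] = []
    for fold_index, (train_idx, test_idx) in enumerate(folds):
        fold_seed = int((config.seed * 1_000_003 + fold_index) % (2**31))
        model = model_factory(fold_seed)
        fold_train = [pairs[i] for i in train_idx]
        monitor: list[EmbeddedPair] = []
        if config.val_fraction > 0 and len(fold_train) >= 10:
            tr_labels = [p.label for p in fold_train]
            fit_idx, mon_idx = train_test_split(
                np.arange(len(fold_train)), test_size=config.val_fraction,
                random_state=fold_seed % (2**31), stratify=tr_labels,
            )
            monitor = [fold_train[i] for i in mon_idx]
            # monitoring only: the model still trains on the full fold-train
            # split minus the monitor set, keeping validation honest
            fold_train = [fold_train[i] for i in fit_idx]
        loss_hist, val_hist = train(model, fold_train, config, monitor or None)
        y_pred = evaluate(model, [pairs[i] for i in test_idx], config)
        results.append(
            _fold_metrics(fold_index, labels[test_idx], y_pred, loss_hist, val_hist)
        )
    return CVReport(
        folds=results,
        mean_f1=float(np.mean([r.f1_overall for r in results])),
        mean_f1_pos=float(np.mean([r.f1_pos for r in results])),
        mean_f1_neg=float(np.mean([r.f1_neg for r in results])),
        seed=config.seed,
        config={"train": asdict(config)},
    )


# ----------------------------------------------------------------- comparison


@dataclass
class ComparisonResult:
    fold_deltas: list[float]
    mean_a: float
    mean_b: float
    mean_relative_gain: float
    t_statistic: float
    p_value: float

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"schema": "trialmatch.comparison/1", **asdict(self)},
            indent=2, sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def compare_models(report_a: CVReport, report_b: CVReport) -> ComparisonResult:
    """Paired per-fold F1 comparison with a two-sided paired t-test.

    Requires both reports to come from the same fold structure (same k and
    fold seed).  With zero variance in the per-fold differences the t-test
    is undefined; p = 1.0 is returned with a warning.
    """
    if len(report_a.folds) != len(report_b.folds):
        raise InputError("reports have different fold counts")
    if report_a.seed != report_b.seed:
        raise InputError(
            "reports were built from different fold seeds; paired comparison "
            "requires identical folds"
        )
    a = np.array([f.f1_overall for f in report_a.folds])
    b = np.array([f.f1_overall for f in report_b.folds])
    deltas = a - b
    if np.allclose(deltas.std(), 0.0):
        if not np.allclose(deltas, 0.0):
            warnings.warn("constant non-zero per-fold difference; t-test undefined")
        else:
            warnings.warn("identical per-fold scores; t-test undefined")
        t_stat, p_val = 0.0, 1.0
    else:
        t_stat, p_val = stats.ttest_rel(a, b)
    mean_b = float(b.mean())
    gain = float((a.mean() - mean_b) / mean_b) if mean_b != 0 else float("inf")
    return ComparisonResult(
        fold_deltas=[float(d) for d in deltas],
        mean_a=float(a.mean()),
        mean_b=mean_b,
        mean_relative_gain=gain,
        t_statistic=float(t_stat),
        p_value=float(p_val),
    )
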