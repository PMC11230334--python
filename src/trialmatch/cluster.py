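"""Cluster inspection of the learned pair representations.

Extracts the fused representation right before the output head for every
pair, projects it to 2-D with PCA or (PCA-initialised) t-SNE, and writes
the coordinates to CSV (optionally a PNG scatter coloured by the ground
truth label).  Training should tighten the success/fail clusters; the
class-centroid distance quantifies that.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .embeddings import EmbeddedPair
from .exceptions import InputError
from .siamese import batch_pairs


@dataclass
class RepresentationMatrix:
    matrix: np.ndarray  # (n, F') fused representations
    labels: np.ndarray  # (n,) ground-truth {0, 1}
    pair_ids: list[str]
    epoch: int  # 0 flags an untrained model


def extract_fused(model, pairs: Sequence[EmbeddedPair]) -> RepresentationMatrix:
    """Fused pre-head representations for every pair (eval mode)."""
    if not pairs:
        raise InputError("no pairs to extract representations from")
    model.eval()
    xe, me, xc, mc, labels = batch_pairs(pairs)
    fused = model.fused_batch(xe, me, xc, mc).data
    if not np.all(np.isfinite(fused)):
        raise InputError("fused representations contain non-finite values")
    return RepresentationMatrix(
        matrix=fused,
        labels=labels.astype(int),
        pair_ids=[p.pair_id for p in pairs],
        epoch=int(getattr(model, "trained_epochs", 0)),
    )


def _fix_pca_signs(coords: np.ndarray, components: np.ndarray) -> np.ndarray:
    """Sign convention: the largest-magnitude loading of each component is
    positive, so PCA output is fully deterministic."""
    out = coords.copy()
    for j in range(components.shape[0]):
        k = np.argmax(np.abs(components[j]))
        if components[j, k] < 0:
            out[:, j] = -out[:, j]
    return out


def reduce_2d(matrix: np.ndarray, method: str = "pca", seed: int = 0) -> np.ndarray:
    """Project an (n, F') matrix to (n, 2).

    ``pca`` is deterministic (sign-fixed); ``tsne`` first reduces to at
    most 50 PCA dimensions, then runs seeded t-SNE with perplexity
    min(30, (n - 1) / 3).
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[0] < 3:
        raise InputError("need at least 3 rows to project")
    if np.allclose(matrix.std(axis=0), 0.0):
        raise InputError("constant matrix has no principal directions")
    if method == "pca":
        pca = PCA(n_components=2, svd_solver="full")
        coords = pca.fit_transform(matrix)
        return _fix_pca_signs(coords, pca.components_)
    if method == "tsne":
        n, d = matrix.shape
        if d > 50:
            pre = PCA(n_components=min(50, n, d), svd_solver="full")
            matrix = pre.fit_transform(matrix)
        perplexity = min(30.0, (n - 1) / 3.0)
        tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
                    init="pca")
        return np.asarray(tsne.fit_transform(matrix), dtype=np.float64)
    raise InputError(f"unknown reduction method {method!r}")


def export_scatter(coords: np.ndarray, labels: Sequence[int], path: str | Path,
                   pair_ids: Sequence[str] | None = None, epoch: int = 0,
                   png: bool = False) -> list[Path]:
    """Write coordinates to CSV (and optionally a PNG scatter).

    CSV columns: pair_id, x, y, label, epoch.  Returns the written paths.
    """
    coords = np.asarray(coords, dtype=np.float64)
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise InputError("empty label set")
    if coords.shape[0] != len(labels):
        raise InputError(
            f"{coords.shape[0]} coordinate rows vs {len(labels)} labels"
        )
    ids = list(pair_ids) if pair_ids is not None else [f"pair{i:04d}" for i in range(len(labels))]
    if len(ids) != len(labels):
        raise InputError("pair_ids length mismatch")
    path = Path(path)
    frame = pd.DataFrame(
        {"pair_id": ids, "x": coords[:, 0], "y": coords[:, 1],
         "label": labels, "epoch": epoch}
    )
    # default float formatting is the shortest round-trip repr: re-reading
    # the CSV reproduces the coordinates bit-exactly
    frame.to_csv(path, index=False)
    written = [path]
    if png:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for lab, color, name in ((0, "tab:blue", "fail"), (1, "tab:red", "success")):
            m = labels == lab
            ax.scatter(coords[m, 0], coords[m, 1], s=12, c=color, label=name, alpha=0.7)
        ax.legend()
        ax.set_title(f"epoch {epoch}")
        png_path = path.with_suffix(".png")
        fig.savefig(png_path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(png_path)
    return written


def centroid_distance(coords: np.ndarray, labels: Sequence[int]) -> float:
    """Euclidean distance between the 2-D class centroids."""
    coords = np.asarray(coords, dtype=np.float64)
    labels = np.asarray(labels)
    if set(np.unique(labels)) != {0, 1}:
        raise InputError("need both classes to measure centroid separation")
    c0 = coords[labels == 0].mean(axis=0)
    c1 = coords[labels == 1].mean(axis=0)
    return float(np.linalg.norm(c1 - c0))
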