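"""Patch embedding and diverse-sample selection.

Patches are summarised by the channel-wise global average of the deepest
encoder (bottleneck) activations of the segmentation model — the
high-dimensional space the model has learned — then laid out in 2-D so an
annotator (here, an automated policy) can pick dispersed patches that
maximise training-set diversity. The interactive click-selection of a human
user is simulated by greedy farthest-point (max-min) sampling on the
layout, a classical 2-approximation of the optimal dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .model import SegModel, bottleneck_features


@dataclass
class PatchFeature:
    patch_id: str
    vector: np.ndarray
    model_stage: str


@dataclass
class EmbeddingPoint:
    patch_id: str
    xy: np.ndarray


def extract_features(model: SegModel, patches) -> list[PatchFeature]:
    """One bottleneck feature vector per patch (deterministic given weights)."""
    vectors = bottleneck_features(model, patches)
    if not np.all(np.isfinite(vectors)):
        raise ValueError("non-finite feature values")
    return [
        PatchFeature(patch_id=p.patch_id, vector=v, model_stage=model.stage)
        for p, v in zip(patches, vectors)
    ]


def project_2d(features: list[PatchFeature], seed: int = 0, n_neighbors: int = 15,
               min_dist: float = 0.1, method: str = "umap") -> list[EmbeddingPoint]:
    """Project patch features to a seeded, reproducible 2-D layout.

    ``method='umap'`` is the default (neighbourhood-preserving nonlinear
    layout); ``method='pca'`` is a cheap deterministic alternative used by
    the simulation loop. ``n_neighbors`` is clamped to n-1 for small sets.
    """
    if len(features) < 2:
        raise DataError("projection requires at least 2 features")
    x = np.stack([f.vector for f in features]).astype(np.float64)
    if method == "umap":
        import umap  # deferred: numba-backed import is slow

        reducer = umap.UMAP(n_components=2, n_neighbors=min(n_neighbors, len(features) - 1),
                            min_dist=min_dist, random_state=seed)
        xy = reducer.fit_transform(x)
    elif method == "pca":
        from sklearn.decomposition import PCA

        k = min(2, x.shape[1], len(features))
        xy = PCA(n_components=k, random_state=seed).fit_transform(x)
        if xy.shape[1] < 2:  # degenerate feature dimension
            xy = np.column_stack([xy[:, 0], np.zeros(len(features))])
    else:
        raise ValueError(f"unknown projection method {method!r}")
    return [EmbeddingPoint(patch_id=f.patch_id, xy=np.asarray(p, dtype=np.float64))
            for f, p in zip(features, xy)]


def select_diverse(points: list[EmbeddingPoint], k: int, seed: int = 0) -> list[str]:
    """Greedy farthest-point (max-min) selection of ``k`` dispersed patches.

    The first pick is the point farthest from the layout centroid (ties
    broken by lowest index), so the selection is identical for every seed;
    each subsequent pick maximises its distance to the already-selected
    set. ``seed`` is accepted for interface stability. Returned patch ids
    are unique.
    """
    n = len(points)
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= {n}, got {k}")
    xy = np.stack([p.xy for p in points])
    chosen = [int(np.argmax(np.linalg.norm(xy - xy.mean(axis=0), axis=1)))]
    dmin = np.linalg.norm(xy - xy[chosen[0]], axis=1)
    while len(chosen) < k:
        nxt = int(np.argmax(dmin))
        chosen.append(nxt)
        dmin = np.minimum(dmin, np.linalg.norm(xy - xy[nxt], axis=1))
    return [points[i].patch_id for i in chosen]


def export_embedding(points: list[EmbeddingPoint], path) -> pd.DataFrame:
    """Write the layout as CSV (patch_id, x, y)."""
    df = pd.DataFrame([{"patch_id": p.patch_id, "x": p.xy[0], "y": p.xy[1]} for p in points])
    df.to_csv(path, index=False)
    return df
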