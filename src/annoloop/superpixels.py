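"""Over-segmentation from colour or learned feature rasters.

Superpixels are SLIC-style k-means clusters in (signal, position) space.
In ``intensity`` mode the signal is the RGB image itself; in
``dl_features`` mode it is a per-pixel feature raster taken from the
segmentation model's full-resolution decoder activations, so the
over-segmentation sharpens as the model trains. Annotations can be snapped
to superpixel regions for fast high-fidelity boundary selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.segmentation import find_boundaries, slic

from .errors import ShapeError


@dataclass
class SuperpixelMap:
    """Integer over-segmentation labels forming a connected partition.

    Labels are consecutive 0..L-1; every label's pixel set is connected.
    """

    labels: np.ndarray
    source: str                  # "intensity" or "dl_features"
    n_segments_requested: int
    compactness: float

    @property
    def n_segments(self) -> int:
        return int(self.labels.max()) + 1

    def region(self, label: int) -> np.ndarray:
        return self.labels == label


#: Default compactness per clustering signal. Standardized feature channels
#: carry far more contrast per unit than 8-bit colour, so the spatial term
#: needs a smaller weight to let boundaries follow the features.
DEFAULT_COMPACTNESS = {"intensity": 10.0, "dl_features": 0.3}


def compute_superpixels(image: np.ndarray, feature_map: np.ndarray | None = None,
                        n_segments: int = 200, compactness: float | None = None,
                        seed: int = 0) -> SuperpixelMap:
    """SLIC over-segmentation on colour (default) or learned features.

    ``feature_map`` (H, W, C), when given, replaces colour as the clustering
    signal (channels are z-scored first). ``compactness=None`` resolves to
    the per-mode default. Deterministic for fixed inputs; ``seed`` is
    accepted for interface stability but SLIC itself has no stochastic step.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if n_segments > h * w:
        raise ValueError(f"n_segments {n_segments} exceeds pixel count {h * w}")
    if compactness is None:
        compactness = DEFAULT_COMPACTNESS[
            "dl_features" if feature_map is not None else "intensity"]
    if feature_map is not None:
        feature_map = np.asarray(feature_map, dtype=np.float64)
        if feature_map.shape[:2] != (h, w):
            raise ShapeError("feature_map must be spatially aligned with the image")
        signal = feature_map - feature_map.mean(axis=(0, 1))
        sd = signal.std(axis=(0, 1))
        signal = signal / np.where(sd > 0, sd, 1.0)
        labels = slic(signal, n_segments=n_segments, compactness=compactness,
                      start_label=0, channel_axis=-1, convert2lab=False,
                      enforce_connectivity=True)
        source = "dl_features"
    else:
        labels = slic(image, n_segments=n_segments, compactness=compactness,
                      start_label=0, enforce_connectivity=True)
        source = "intensity"
    # renumber to consecutive 0..L-1 (SLIC may skip ids)
    _, labels = np.unique(labels, return_inverse=True)
    labels = labels.reshape(h, w).astype(np.int32)
    return SuperpixelMap(labels=labels, source=source,
                         n_segments_requested=n_segments, compactness=compactness)


def boundary_recall(sp: SuperpixelMap, gt: np.ndarray, tolerance: int = 2) -> float | None:
    """Fraction of ground-truth boundary pixels within ``tolerance`` of any
    superpixel boundary.

    Returns ``None`` (undefined, not zero) when the ground truth has no
    boundary at all — e.g. an empty or full mask.
    """
    gt = np.asarray(gt, dtype=bool)
    if gt.shape != sp.labels.shape:
        raise ShapeError("ground-truth shape must match the superpixel map")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    gt_boundary = find_boundaries(gt, mode="inner")
    if not gt_boundary.any():
        return None
    sp_boundary = find_boundaries(sp.labels, mode="thick")
    if not sp_boundary.any():
        return 0.0
    dist = ndimage.distance_transform_edt(~sp_boundary)
    return float(np.mean(dist[gt_boundary] <= tolerance))


def snap_annotation(seed_pixels, sp: SuperpixelMap) -> np.ndarray:
    """Union of every superpixel containing at least one seed pixel."""
    seeds = list(seed_pixels)
    if not seeds:
        raise ValueError("seed pixel set must not be empty")
    h, w = sp.labels.shape
    hit = set()
    for r, c in seeds:
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"seed pixel ({r}, {c}) out of bounds for {h}x{w} map")
        hit.add(int(sp.labels[r, c]))
    return np.isin(sp.labels, sorted(hit))


def save_superpixels(sp: SuperpixelMap, outdir, stem: str = "superpixels") -> dict[str, Path]:
    """Persist as a 16-bit label PNG plus a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if sp.n_segments > np.iinfo(np.uint16).max:
        raise ValueError("too many segments for 16-bit PNG")
    paths = {"labels": outdir / f"{stem}.png", "sidecar": outdir / f"{stem}.json"}
    Image.fromarray(sp.labels.astype(np.uint16)).save(paths["labels"])
    paths["sidecar"].write_text(json.dumps({
        "source": sp.source,
        "n_segments_requested": sp.n_segments_requested,
        "n_segments": sp.n_segments,
        "compactness": sp.compactness,
    }, indent=2))
    return paths
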