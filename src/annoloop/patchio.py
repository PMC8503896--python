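"""Tiles, patches, 3-class annotation masks and prediction reassembly.

Conventions used throughout the package:

* coordinates are 0-based, row-major, half-open (a patch at (r, c) covers
  rows ``r:r+patch_size`` and columns ``c:c+patch_size``);
* annotation masks hold exactly three per-pixel labels — unknown (the
  default: carries no supervision), negative (non-target tissue) and
  positive (the structure of interest);
* masks persist as indexed PNGs with a fixed 3-colour palette, and overlays
  render positive in turquoise, negative in fuchsia and model suggestions
  in white.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image

from .errors import CoverageError, DimensionError, MaskFormatError, ShapeError

LABEL_UNKNOWN = 0
LABEL_NEGATIVE = 1
LABEL_POSITIVE = 2

#: Display palette, indexed by label value.
PALETTE = {
    LABEL_UNKNOWN: (0, 0, 0),
    LABEL_NEGATIVE: (255, 0, 255),   # fuchsia
    LABEL_POSITIVE: (64, 224, 208),  # turquoise
}
SUGGESTION_COLOR = (255, 255, 255)


@dataclass
class AnnotationMask:
    """Per-pixel 3-class labels; a fresh mask is all-unknown."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        bad = set(np.unique(self.labels)) - {LABEL_UNKNOWN, LABEL_NEGATIVE, LABEL_POSITIVE}
        if bad:
            raise MaskFormatError(f"mask contains values outside the 3-class set: {sorted(bad)}")

    @classmethod
    def fresh(cls, shape: tuple[int, int]) -> "AnnotationMask":
        return cls(np.full(shape, LABEL_UNKNOWN, dtype=np.uint8))

    @classmethod
    def from_binary(cls, positive: np.ndarray) -> "AnnotationMask":
        """Fully-annotated mask: True -> positive, False -> negative."""
        labels = np.where(positive, LABEL_POSITIVE, LABEL_NEGATIVE).astype(np.uint8)
        return cls(labels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def is_annotated(self) -> bool:
        return bool(np.any(self.labels != LABEL_UNKNOWN))

    def positive(self) -> np.ndarray:
        return self.labels == LABEL_POSITIVE

    def __eq__(self, other) -> bool:
        return isinstance(other, AnnotationMask) and np.array_equal(self.labels, other.labels)


@dataclass
class Tile:
    """An RGB tile cut from a parent scene, with optional padding-validity mask."""

    pixels: np.ndarray
    tile_id: str
    origin: tuple[int, int] = (0, 0)
    valid: np.ndarray | None = None  # True where pixels are original (not padding)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise DimensionError("tile pixels must be (H, W, 3) 8-bit RGB")
        if self.origin[0] < 0 or self.origin[1] < 0:
            raise DimensionError("tile origin must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class Patch:
    """A fixed-size square crop: the unit of training, embedding and review."""

    pixels: np.ndarray
    tile_id: str
    row: int
    col: int
    mask: AnnotationMask = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.shape[0] != self.pixels.shape[1]:
            raise DimensionError("patches must be square")
        if self.mask is None:
            self.mask = AnnotationMask.fresh(self.pixels.shape[:2])
        if self.mask.shape != self.pixels.shape[:2]:
            raise ShapeError("mask shape must equal patch pixel shape")

    @property
    def patch_id(self) -> str:
        return f"{self.tile_id}_r{self.row}_c{self.col}"

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    @property
    def annotated_flag(self) -> bool:
        return self.mask.is_annotated


@dataclass
class PredictionMap:
    """Per-pixel positive-class probability in [0, 1]."""

    prob_positive: np.ndarray

    def __post_init__(self):
        self.prob_positive = np.asarray(self.prob_positive, dtype=np.float64)
        lo, hi = self.prob_positive.min(initial=0.0), self.prob_positive.max(initial=0.0)
        if lo < 0.0 or hi > 1.0:
            raise ValueError(f"probabilities must lie in [0, 1], got range [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.prob_positive.shape


def pad_to_multiple(arr: np.ndarray, patch_size: int, stride: int) -> tuple[np.ndarray, np.ndarray]:
    """Reflect-pad so a (patch_size, stride) grid covers the array exactly.

    Returns (padded array, validity mask) where the mask is True on original
    pixels. The padded side is the smallest P >= max(side, patch_size) with
    (P - patch_size) divisible by stride.
    """
    h, w = arr.shape[:2]

    def target(side):
        p = max(side, patch_size)
        rem = (p - patch_size) % stride
        if rem:
            p += stride - rem
        return p

    ph, pw = target(h), target(w)
    pad = [(0, ph - h), (0, pw - w)] + [(0, 0)] * (arr.ndim - 2)
    padded = np.pad(arr, pad, mode="reflect") if (ph > h or pw > w) else arr.copy()
    valid = np.zeros((ph, pw), dtype=bool)
    valid[:h, :w] = True
    return padded, valid


def extract_patches(tile: Tile, patch_size: int = 256, stride: int | None = None) -> list[Patch]:
    """Cut a tile into square patches on a regular grid.

    With ``stride == patch_size`` (the default) the patches partition the
    reflect-padded tile; smaller strides give overlapping patches for
    inference. Fresh patches carry all-unknown masks.
    """
    stride = patch_size if stride is None else stride
    if patch_size < 32:
        raise ValueError(f"patch_size must be >= 32, got {patch_size}")
    if not 1 <= stride <= patch_size:
        raise ValueError(f"stride must be in [1, patch_size], got {stride}")
    padded, _ = pad_to_multiple(tile.pixels, patch_size, stride)
    ph, pw = padded.shape[:2]
    patches = []
    for r in range(0, ph - patch_size + 1, stride):
        for c in range(0, pw - patch_size + 1, stride):
            patches.append(Patch(pixels=padded[r:r + patch_size, c:c + patch_size],
                                 tile_id=tile.tile_id, row=r, col=c))
    return patches


def encode_mask(mask: AnnotationMask) -> Image.Image:
    """Encode a 3-class mask as an indexed (palette) PNG-ready image."""
    img = Image.fromarray(mask.labels, mode="P")
    palette = []
    for label in (LABEL_UNKNOWN, LABEL_NEGATIVE, LABEL_POSITIVE):
        palette.extend(PALETTE[label])
    img.putpalette(palette)
    return img


def decode_mask(source) -> AnnotationMask:
    """Decode an indexed image (or raw index array) back to an AnnotationMask.

    Raises :class:`MaskFormatError` naming any value outside the 3-class
    palette. ``decode_mask(encode_mask(m)) == m`` bit-exactly.
    """
    if isinstance(source, Image.Image):
        if source.mode == "P":
            arr = np.asarray(source)
        else:
            rgb = np.asarray(source.convert("RGB"))
            arr = np.full(rgb.shape[:2], 255, dtype=np.uint8)
            for label, color in PALETTE.items():
                arr[np.all(rgb == color, axis=-1)] = label
            if np.any(arr == 255):
                bad = rgb[arr == 255][0]
                raise MaskFormatError(f"unknown palette colour {tuple(int(v) for v in bad)}")
    else:
        arr = np.asarray(source)
    bad_vals = set(np.unique(arr)) - {LABEL_UNKNOWN, LABEL_NEGATIVE, LABEL_POSITIVE}
    if bad_vals:
        raise MaskFormatError(f"unknown palette values {sorted(int(v) for v in bad_vals)}")
    return AnnotationMask(arr.astype(np.uint8))


def save_mask(mask: AnnotationMask, path) -> None:
    encode_mask(mask).save(path, format="PNG")


def load_mask(path) -> AnnotationMask:
    with Image.open(path) as img:
        img.load()
        return decode_mask(img)


def render_overlay(image: np.ndarray, mask: AnnotationMask | None = None,
                   suggestion: np.ndarray | None = None, alpha: float = 0.5) -> np.ndarray:
    """Blend annotation classes (and an optional binary suggestion) onto an image.

    Positive pixels render turquoise, negative fuchsia, suggestions white.
    """
    out = np.asarray(image, dtype=np.float64).copy()
    layers = []
    if mask is not None:
        layers.append((mask.labels == LABEL_POSITIVE, PALETTE[LABEL_POSITIVE]))
        layers.append((mask.labels == LABEL_NEGATIVE, PALETTE[LABEL_NEGATIVE]))
    if suggestion is not None:
        layers.append((np.asarray(suggestion, dtype=bool), SUGGESTION_COLOR))
    for sel, color in layers:
        out[sel] = (1 - alpha) * out[sel] + alpha * np.array(color, dtype=np.float64)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def assemble_predictions(patch_maps: list[tuple[tuple[int, int], PredictionMap]],
                         tile_shape: tuple[int, int]) -> PredictionMap:
    """Stitch per-patch probability maps back into a tile-level map.

    Overlapping pixels average their contributors; pixels beyond
    ``tile_shape`` (padding) are dropped. Every tile pixel must be covered.
    """
    if not patch_maps:
        raise CoverageError("no patch predictions supplied")
    max_r = max(rc[0] + pm.shape[0] for rc, pm in patch_maps)
    max_c = max(rc[1] + pm.shape[1] for rc, pm in patch_maps)
    acc = np.zeros((max_r, max_c))
    cnt = np.zeros((max_r, max_c))
    for (r, c), pm in patch_maps:
        if r < 0 or c < 0:
            raise CoverageError(f"patch origin ({r}, {c}) out of bounds")
        acc[r:r + pm.shape[0], c:c + pm.shape[1]] += pm.prob_positive
        cnt[r:r + pm.shape[0], c:c + pm.shape[1]] += 1
    h, w = tile_shape
    if max_r < h or max_c < w or np.any(cnt[:h, :w] == 0):
        raise CoverageError("patch predictions do not cover every tile pixel")
    return PredictionMap(prob_positive=acc[:h, :w] / cnt[:h, :w])


def write_manifest(patches: list[Patch], path) -> pd.DataFrame:
    """Write the patch manifest CSV (patch id, tile id, row, col, annotated flag)."""
    df = pd.DataFrame(
        [{"patch_id": p.patch_id, "tile_id": p.tile_id, "row": p.row, "col": p.col,
          "annotated_flag": p.annotated_flag} for p in patches]
    )
    df.to_csv(path, index=False)
    return df
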