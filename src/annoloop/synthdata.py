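"""Synthetic histology-like scenes with ground-truth instance masks.

Three structure scales mirror the annotation tasks the engine targets:

* ``nuclei`` — many small elliptical blobs (radii 4-12 px),
* ``tubules`` — mid-size annular structures with a bright lumen
  (outer radii 20-60 px; the instance is the ring, not the lumen),
* ``epithelium`` — few large irregular regions (radial-harmonic blobs,
  base radii 40-90 px).

Instance placement is a homogeneous Poisson point process with intensity
``density`` structures per megapixel; overlaps are resolved by draw order
(later structure wins), after which instances are re-labelled into
consecutive 4-connected regions of at least ``min_size`` pixels. Colours
default to a two-tone purple/pink scheme (configurable, the engine itself
is stain-agnostic), with Gaussian texture noise of amplitude ``noise``.

Scenes are deliberately simple: they provide controllable ground truth,
not photorealism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import draw as skdraw

from .errors import DimensionError
from .patchio import AnnotationMask, Tile

STRUCTURE_KINDS = ("nuclei", "tubules", "epithelium")

#: 4-connectivity structuring element for instance labelling.
_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])

_DEFAULT_DENSITY = {"nuclei": 300.0, "tubules": 12.0, "epithelium": 5.0}
_SIZE_RANGE = {"nuclei": (4.0, 12.0), "tubules": (20.0, 60.0), "epithelium": (40.0, 90.0)}


@dataclass(frozen=True)
class GeneratorParams:
    """Tunable generator knobs; defaults depend on the structure kind."""

    density: float          # structures per megapixel (Poisson intensity)
    size_range: tuple[float, float]
    noise: float            # texture noise amplitude in [0, 1]
    min_size: int = 10      # minimum surviving instance area, px
    background_color: tuple[int, int, int] = (231, 200, 221)  # eosin pink
    foreground_color: tuple[int, int, int] = (96, 61, 150)    # hematoxylin purple
    lumen_color: tuple[int, int, int] = (248, 246, 248)
    color_jitter: int = 14
    color_margin: float = 40.0  # required mean-channel fg/bg separation


@dataclass
class SyntheticScene:
    """A generated RGB image with per-pixel ground-truth instance ids.

    ``gt_instances`` is 0 on background; ids are consecutive 1..K, each a
    4-connected region of at least ``params.min_size`` pixels.
    """

    image: np.ndarray
    gt_instances: np.ndarray
    structure_kind: str
    seed: int
    params: GeneratorParams

    @property
    def shape(self) -> tuple[int, int]:
        return self.gt_instances.shape

    @property
    def n_instances(self) -> int:
        return int(self.gt_instances.max())

    @property
    def expected_count(self) -> float:
        """Poisson expectation of the number of placed structures."""
        h, w = self.shape
        return self.params.density * h * w / 1e6

    def gt_binary(self) -> np.ndarray:
        return self.gt_instances > 0


def _draw_nucleus(rng, h, w, params):
    r0 = rng.uniform(0, h)
    c0 = rng.uniform(0, w)
    lo, hi = params.size_range
    ra, rb = rng.uniform(lo, hi), rng.uniform(lo, hi)
    rot = rng.uniform(0, np.pi)
    rr, cc = skdraw.ellipse(r0, c0, ra, rb, shape=(h, w), rotation=rot)
    return [(rr, cc, "fg")]


def _draw_tubule(rng, h, w, params):
    r0 = rng.uniform(0, h)
    c0 = rng.uniform(0, w)
    lo, hi = params.size_range
    ra, rb = rng.uniform(lo, hi), rng.uniform(lo, hi)
    rot = rng.uniform(0, np.pi)
    frac = rng.uniform(0.4, 0.6)
    outer = np.zeros((h, w), dtype=bool)
    rr, cc = skdraw.ellipse(r0, c0, ra, rb, shape=(h, w), rotation=rot)
    outer[rr, cc] = True
    inner = np.zeros((h, w), dtype=bool)
    rr, cc = skdraw.ellipse(r0, c0, ra * frac, rb * frac, shape=(h, w), rotation=rot)
    inner[rr, cc] = True
    ring = outer & ~inner
    return [(*np.nonzero(inner), "lumen"), (*np.nonzero(ring), "fg")]


def _draw_blob(rng, h, w, params):
    # irregular region: radial polygon with low-order harmonic perturbation
    r0 = rng.uniform(0, h)
    c0 = rng.uniform(0, w)
    lo, hi = params.size_range
    base = rng.uniform(lo, hi)
    theta = np.linspace(0, 2 * np.pi, 72, endpoint=False)
    radius = np.full_like(theta, 1.0)
    for harmonic in (2, 3, 5):
        radius += 0.18 * rng.uniform(0.2, 1.0) * np.sin(harmonic * theta + rng.uniform(0, 2 * np.pi))
    radius = np.clip(radius, 0.25, None) * base
    rr, cc = skdraw.polygon(r0 + radius * np.sin(theta), c0 + radius * np.cos(theta), shape=(h, w))
    return [(rr, cc, "fg")]


_DRAWERS = {"nuclei": _draw_nucleus, "tubules": _draw_tubule, "epithelium": _draw_blob}


def _relabel_connected(labels: np.ndarray, min_size: int) -> np.ndarray:
    """Split instances into 4-connected components, drop fragments below
    ``min_size``, and renumber the survivors consecutively from 1."""
    out = np.zeros_like(labels, dtype=np.int32)
    next_id = 1
    for old_id in range(1, int(labels.max()) + 1):
        component_map, n_comp = ndimage.label(labels == old_id, structure=_FOUR_CONN)
        if n_comp == 0:
            continue
        sizes = np.bincount(component_map.ravel())
        for comp in range(1, n_comp + 1):
            if sizes[comp] >= min_size:
                out[component_map == comp] = next_id
                next_id += 1
    return out


def generate_scene(structure_kind: str, height: int = 1024, width: int = 1024,
                   density: float | None = None, seed: int = 0, noise: float = 0.08,
                   params: GeneratorParams | None = None) -> SyntheticScene:
    """Generate a seeded synthetic scene at one of the three structure scales.

    Identical arguments always produce bit-identical scenes. ``density`` is
    structures per megapixel; ``density=0`` yields an empty scene.
    """
    if structure_kind not in STRUCTURE_KINDS:
        raise ValueError(f"unknown structure_kind {structure_kind!r}; expected one of {STRUCTURE_KINDS}")
    if height < 256 or width < 256:
        raise DimensionError(f"scene dimensions must be >= 256, got {height}x{width}")
    if params is None:
        params = GeneratorParams(
            density=_DEFAULT_DENSITY[structure_kind] if density is None else float(density),
            size_range=_SIZE_RANGE[structure_kind],
            noise=float(noise),
        )
    if params.density < 0:
        raise ValueError("density must be >= 0")
    if not 0.0 <= params.noise <= 1.0:
        raise ValueError("noise must be in [0, 1]")

    rng = np.random.default_rng(seed)
    h, w = height, width
    labels = np.zeros((h, w), dtype=np.int32)
    lumen = np.zeros((h, w), dtype=bool)
    n_draw = rng.poisson(params.density * h * w / 1e6)
    drawer = _DRAWERS[structure_kind]
    for k in range(1, n_draw + 1):
        for rr, cc, role in drawer(rng, h, w, params):
            if role == "fg":
                labels[rr, cc] = k
                lumen[rr, cc] = False
            else:  # lumen erases anything beneath it
                labels[rr, cc] = 0
                lumen[rr, cc] = True
    labels = _relabel_connected(labels, params.min_size)
    lumen &= labels == 0

    image = np.empty((h, w, 3), dtype=np.float64)
    image[:] = params.background_color
    image[lumen] = params.lumen_color
    fg_base = np.array(params.foreground_color, dtype=np.float64)
    for inst in range(1, int(labels.max()) + 1):
        jitter = rng.uniform(-params.color_jitter, params.color_jitter, size=3)
        image[labels == inst] = fg_base + jitter
    if params.noise > 0:
        image += rng.normal(0.0, params.noise * 64.0, size=image.shape)
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    return SyntheticScene(image=image, gt_instances=labels,
                          structure_kind=structure_kind, seed=seed, params=params)


def scene_to_tiles(scene: SyntheticScene, tile_size: int = 256) -> list[tuple[Tile, AnnotationMask]]:
    """Cut a scene into non-overlapping tiles with binarized ground-truth masks.

    Non-multiple dimensions are reflect-padded; padded pixels are flagged
    False in each tile's validity mask. Masks binarize the ground truth
    (instance -> positive, background -> negative; no unknown pixels).
    """
    if tile_size <= 0:
        raise ValueError(f"tile_size must be positive, got {tile_size}")
    h, w = scene.shape
    ph = int(np.ceil(h / tile_size)) * tile_size
    pw = int(np.ceil(w / tile_size)) * tile_size
    pad = ((0, ph - h), (0, pw - w))
    img = np.pad(scene.image, pad + ((0, 0),), mode="reflect")
    gt = np.pad(scene.gt_instances, pad, mode="reflect")
    valid = np.zeros((ph, pw), dtype=bool)
    valid[:h, :w] = True
    out = []
    for r in range(0, ph, tile_size):
        for c in range(0, pw, tile_size):
            tile = Tile(pixels=img[r:r + tile_size, c:c + tile_size],
                        tile_id=f"t{r}_{c}", origin=(r, c),
                        valid=valid[r:r + tile_size, c:c + tile_size])
            mask = AnnotationMask.from_binary(gt[r:r + tile_size, c:c + tile_size] > 0)
            out.append((tile, mask))
    return out


def reassemble_tiles(tiles: list[Tile], scene_shape: tuple[int, int]) -> np.ndarray:
    """Inverse of the tiling: place tiles at their origins and crop padding."""
    max_r = max(t.origin[0] + t.shape[0] for t in tiles)
    max_c = max(t.origin[1] + t.shape[1] for t in tiles)
    canvas = np.zeros((max_r, max_c, 3), dtype=np.uint8)
    for t in tiles:
        r, c = t.origin
        canvas[r:r + t.shape[0], c:c + t.shape[1]] = t.pixels
    return canvas[:scene_shape[0], :scene_shape[1]]


def save_scene(scene: SyntheticScene, outdir, stem: str = "scene") -> dict[str, Path]:
    """Write image PNG, 16-bit instance-label PNG and a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": outdir / f"{stem}_image.png",
        "labels": outdir / f"{stem}_labels.png",
        "sidecar": outdir / f"{stem}.json",
    }
    Image.fromarray(scene.image).save(paths["image"])
    if scene.n_instances > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 instances cannot persist as 16-bit PNG")
    Image.fromarray(scene.gt_instances.astype(np.uint16)).save(paths["labels"])
    sidecar = {
        "structure_kind": scene.structure_kind,
        "seed": scene.seed,
        "n_instances": scene.n_instances,
        "params": asdict(scene.params),
    }
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2))
    return paths


def load_scene(outdir, stem: str = "scene") -> SyntheticScene:
    outdir = Path(outdir)
    with Image.open(outdir / f"{stem}_image.png") as im:
        image = np.asarray(im.convert("RGB"))
    with Image.open(outdir / f"{stem}_labels.png") as im:
        gt = np.asarray(im, dtype=np.int32)
    meta = json.loads((outdir / f"{stem}.json").read_text())
    p = meta["params"]
    params = GeneratorParams(density=p["density"], size_range=tuple(p["size_range"]),
                             noise=p["noise"], min_size=p["min_size"],
                             background_color=tuple(p["background_color"]),
                             foreground_color=tuple(p["foreground_color"]),
                             lumen_color=tuple(p["lumen_color"]),
                             color_jitter=p["color_jitter"],
                             color_margin=p["color_margin"])
    return SyntheticScene(image=image, gt_instances=gt,
                          structure_kind=meta["structure_kind"], seed=meta["seed"],
                          params=params)
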