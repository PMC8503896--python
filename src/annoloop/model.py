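"""Compact encoder-decoder segmentation network and its two training stages.

The network is a symmetric U-net: an encoder of double-convolution blocks
with 2x2 max pooling between levels, a mirrored decoder with learned
upsampling and skip concatenations, and a 1x1 two-class head. It is first
pretrained unsupervised as an autoencoder on unlabelled patches (a temporary
1x1 RGB reconstruction head replaces the class head for that stage), then
fine-tuned on sparse 3-class annotation masks where only positive/negative
pixels carry gradient.

The pinned reference configuration uses five levels with a width-tuned
channel ladder (5, 8, 16, 30, 62), batch normalization and transposed-conv
upsampling, which totals exactly 113,306 trainable parameters. The ladder
deviates slightly from pure doubling; it was fixed once, by a configuration
search over the width/upsampling/normalization space, to pin the network's
capacity, and is not meant to be re-tuned.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from . import nn
from .errors import ConfigError, DataError, GateError, ShapeError, StageError
from .patchio import Patch, PredictionMap, LABEL_UNKNOWN, LABEL_NEGATIVE, LABEL_POSITIVE

logger = logging.getLogger(__name__)

#: Channel ladder of the reference network (exactly 113,306 parameters).
REFERENCE_WIDTHS: tuple[int, ...] = (5, 8, 16, 30, 62)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``widths`` overrides the doubling ladder derived from ``base_width``;
    the reference configuration pins it to :data:`REFERENCE_WIDTHS`.
    """

    depth: int = 5
    base_width: int = 5
    in_channels: int = 3
    out_channels: int = 2
    upsample_mode: str = "transposed"  # or "interpolate"
    norm_mode: str = "batch"  # or "none"
    patch_size: int = 256
    widths: tuple[int, ...] | None = REFERENCE_WIDTHS

    def __post_init__(self):
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")
        if self.upsample_mode not in ("transposed", "interpolate"):
            raise ConfigError(f"unknown upsample_mode {self.upsample_mode!r}")
        if self.norm_mode not in ("batch", "none"):
            raise ConfigError(f"unknown norm_mode {self.norm_mode!r}")
        if self.widths is not None and len(self.widths) != self.depth:
            raise ConfigError("widths length must equal depth")
        factor = 2 ** (self.depth - 1)
        if self.patch_size % factor != 0 or self.patch_size // factor < 1:
            raise ConfigError(
                f"patch_size {self.patch_size} incompatible with depth {self.depth}: "
                f"bottleneck would be smaller than 1 px"
            )

    @property
    def channel_ladder(self) -> tuple[int, ...]:
        if self.widths is not None:
            return tuple(self.widths)
        return tuple(self.base_width * 2 ** i for i in range(self.depth))

    def to_json(self) -> str:
        d = asdict(self)
        d["widths"] = list(self.widths) if self.widths is not None else None
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        if d.get("widths") is not None:
            d["widths"] = tuple(d["widths"])
        return cls(**d)


@dataclass
class TrainingGate:
    """Minimum number of annotated patches before supervised training may run."""

    min_annotated_patches: int = 3

    def __post_init__(self):
        if self.min_annotated_patches < 1:
            raise ConfigError("min_annotated_patches must be >= 1")


class _Upsample2x(nn.Layer):
    """Parameter-free nearest-neighbour 2x upsampling."""

    def forward(self, x, train):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout):
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def _double_conv(cin: int, cout: int, norm: str, rng) -> nn.Sequential:
    layers: list[nn.Layer] = [nn.Conv2d(cin, cout, 3, rng)]
    if norm == "batch":
        layers.append(nn.BatchNorm2d(cout))
    layers.append(nn.ReLU())
    layers.append(nn.Conv2d(cout, cout, 3, rng))
    if norm == "batch":
        layers.append(nn.BatchNorm2d(cout))
    layers.append(nn.ReLU())
    return nn.Sequential(*layers)


class _UNet:
    """The network graph: encoder, decoder with skips, 1x1 head."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        chans = config.channel_ladder
        self.config = config
        self.enc = []
        prev = config.in_channels
        for c in chans:
            self.enc.append(_double_conv(prev, c, config.norm_mode, rng))
            prev = c
        self.pools = [nn.MaxPool2d() for _ in range(config.depth - 1)]
        self.ups: list[nn.Layer] = []
        self.dec = []
        for i in range(config.depth - 2, -1, -1):
            hi, lo = chans[i + 1], chans[i]
            if config.upsample_mode == "transposed":
                self.ups.append(nn.ConvTranspose2d(hi, lo, rng))
            else:
                self.ups.append(nn.Sequential(_Upsample2x(), nn.Conv2d(hi, lo, 1, rng)))
            self.dec.append(_double_conv(2 * lo, lo, config.norm_mode, rng))
        self.head = nn.Conv2d(chans[0], config.out_channels, 1, rng)
        # auxiliary 1x1 RGB head used only for autoencoder pretraining; not
        # part of the segmentation network's parameter count
        self.recon_head = nn.Conv2d(chans[0], config.in_channels, 1, rng)
        # populated by forward()
        self.bottleneck: np.ndarray | None = None
        self.pixel_features: np.ndarray | None = None

    def params(self) -> dict[str, nn.Param]:
        out = {}
        for i, blk in enumerate(self.enc):
            out.update({f"enc{i}.{k}": p for k, p in blk.params().items()})
        for i, up in enumerate(self.ups):
            out.update({f"up{i}.{k}": p for k, p in up.params().items()})
        for i, blk in enumerate(self.dec):
            out.update({f"dec{i}.{k}": p for k, p in blk.params().items()})
        out.update({f"head.{k}": p for k, p in self.head.params().items()})
        return out

    def recon_params(self) -> dict[str, nn.Param]:
        return {f"recon.{k}": p for k, p in self.recon_head.params().items()}

    def buffers(self) -> dict[str, np.ndarray]:
        out = {}
        for i, blk in enumerate(self.enc):
            out.update({f"enc{i}.{k}": b for k, b in blk.buffers().items()})
        for i, up in enumerate(self.ups):
            out.update({f"up{i}.{k}": b for k, b in up.buffers().items()})
        for i, blk in enumerate(self.dec):
            out.update({f"dec{i}.{k}": b for k, b in blk.buffers().items()})
        return out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        factor = 2 ** (self.config.depth - 1)
        if x.shape[2] % factor or x.shape[3] % factor:
            raise ShapeError(
                f"input spatial dims {x.shape[2:]} must be divisible by {factor} "
                f"for depth {self.config.depth}"
            )
        skips = []
        for i, blk in enumerate(self.enc):
            x = blk.forward(x, train)
            if i < len(self.enc) - 1:
                skips.append(x)
                x = self.pools[i].forward(x, train)
        self.bottleneck = x
        self._skip_channels = [s.shape[1] for s in skips]
        for j, (up, blk) in enumerate(zip(self.ups, self.dec)):
            x = up.forward(x, train)
            skip = skips[-(j + 1)]
            x = np.concatenate([skip, x], axis=1)
            x = blk.forward(x, train)
        self.pixel_features = x
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        self.backward_from_features(self.head.backward(dlogits))

    def backward_from_features(self, dfeat: np.ndarray) -> None:
        """Backpropagate a gradient arriving at the last decoder output."""
        dx = dfeat
        dskips = []
        for j in range(len(self.dec) - 1, -1, -1):
            dx = self.dec[j].backward(dx)
            c = dx.shape[1] // 2
            dskips.append(dx[:, :c])
            dx = self.ups[j].backward(dx[:, c:])
        for i in range(len(self.enc) - 1, -1, -1):
            if i < len(self.enc) - 1:
                dx = self.pools[i].backward(dx)
                dx = dx + dskips[i]  # dskips[i] pairs with encoder level i
            dx = self.enc[i].backward(dx)


@dataclass
class SegModel:
    """A built network plus its training state.

    ``stage`` advances untrained -> pretrained -> finetuned; fine-tuning an
    untrained model is allowed but logged. ``train_wall_time`` accumulates
    real elapsed training seconds and is monotone non-decreasing.
    """

    config: ModelConfig
    net: _UNet
    stage: str = "untrained"
    train_wall_time: float = 0.0
    history: list = field(default_factory=list)

    def count_parameters(self) -> int:
        return sum(p.size for p in self.net.params().values())


def build_model(config: ModelConfig | None = None, seed: int = 0) -> SegModel:
    """Construct an untrained segmentation model from ``config``.

    The same (config, seed) pair always yields identical initial weights.
    """
    config = config or ModelConfig()
    rng = np.random.default_rng(seed)
    return SegModel(config=config, net=_UNet(config, rng))


def count_parameters(model: SegModel) -> int:
    """Exact number of trainable scalars (conv weights/biases + norm affine)."""
    return model.count_parameters()


def _patches_to_array(patches: Sequence) -> np.ndarray:
    """Stack patch pixel rasters into a normalized (N, C, H, W) float array."""
    imgs = []
    for p in patches:
        px = p.pixels if isinstance(p, Patch) else np.asarray(p)
        imgs.append(np.asarray(px, dtype=np.float64).transpose(2, 0, 1) / 255.0)
    return np.stack(imgs)


def _mask_to_labels(mask_labels: np.ndarray) -> np.ndarray:
    """Map 3-class mask values to CE targets: negative->0, positive->1, unknown->-1."""
    out = np.full(mask_labels.shape, -1, dtype=np.int64)
    out[mask_labels == LABEL_NEGATIVE] = 0
    out[mask_labels == LABEL_POSITIVE] = 1
    return out


def pretrain_autoencoder(model: SegModel, patches: Sequence, epochs: int, seed: int,
                         lr: float = 1e-3, batch_size: int = 4) -> SegModel:
    """Unsupervised pretraining: reconstruct the input patch (MSE loss).

    The auxiliary 1x1 reconstruction head is trained jointly with the
    network body; it is not part of the segmentation network and does not
    contribute to :func:`count_parameters`. ``epochs=0`` is a no-op
    returning the model unchanged.
    """
    if len(patches) == 0:
        raise DataError("pretraining requires at least one patch")
    if model.stage == "finetuned":
        raise StageError("cannot pretrain a finetuned model")
    if epochs == 0:
        return model
    t0 = time.perf_counter()
    rng = np.random.default_rng(seed)
    x_all = _patches_to_array(patches)
    recon_head = model.net.recon_head
    params = {**model.net.params(), **model.net.recon_params()}
    params = {k: p for k, p in params.items() if not k.startswith("head.")}
    opt = nn.Adam(params, lr=lr)
    n = len(x_all)
    for epoch in range(epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            x = x_all[idx]
            opt.zero_grad()
            model.net.forward(x, train=True)
            recon = recon_head.forward(model.net.pixel_features, train=True)
            loss, dgrad = nn.mse_loss(recon, x)
            dfeat = recon_head.backward(dgrad)
            model.net.backward_from_features(dfeat)
            opt.step()
            ep_loss += loss * len(idx)
        model.history.append({"stage": "pretrain", "epoch": epoch, "loss": ep_loss / n})
    model.stage = "pretrained"
    model.train_wall_time += time.perf_counter() - t0
    return model


def n_annotated(patches: Iterable[Patch]) -> int:
    """Number of patches carrying at least one non-unknown pixel."""
    return sum(1 for p in patches if np.any(p.mask.labels != LABEL_UNKNOWN))


def finetune(model: SegModel, patches: Sequence[Patch], gate: TrainingGate | None = None,
             epochs: int = 10, seed: int = 0, lr: float = 2e-3,
             batch_size: int = 4) -> SegModel:
    """Supervised fine-tuning on sparse 3-class masks.

    Only positive/negative pixels contribute loss and gradient; unknown
    pixels (and entirely unannotated patches) are inert. Training is gated:
    fewer annotated patches than ``gate.min_annotated_patches`` raises
    :class:`GateError`.
    """
    gate = gate or TrainingGate()
    annotated = [p for p in patches if np.any(p.mask.labels != LABEL_UNKNOWN)]
    if len(annotated) < gate.min_annotated_patches:
        raise GateError(
            f"fine-tuning requires at least {gate.min_annotated_patches} annotated "
            f"patches, got {len(annotated)}"
        )
    if model.stage == "untrained":
        logger.info("fine-tuning an untrained model (no autoencoder pretraining)")
    t0 = time.perf_counter()
    rng = np.random.default_rng(seed)
    x_all = _patches_to_array(annotated)
    y_all = np.stack([_mask_to_labels(p.mask.labels) for p in annotated])
    opt = nn.Adam(model.net.params(), lr=lr)
    n = len(x_all)
    for epoch in range(epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            opt.zero_grad()
            logits = model.net.forward(x_all[idx], train=True)
            loss, dlogits = nn.cross_entropy_ignore(logits, y_all[idx])
            model.net.backward(dlogits)
            opt.step()
            ep_loss += loss * len(idx)
        model.history.append({"stage": "finetune", "epoch": epoch, "loss": ep_loss / n})
    model.stage = "finetuned"
    model.train_wall_time += time.perf_counter() - t0
    return model


def reconstruction_error(model: SegModel, patches: Sequence) -> float:
    """Mean-squared autoencoding error of the model on ``patches`` (eval mode)."""
    if len(patches) == 0:
        raise DataError("reconstruction error requires at least one patch")
    x = _patches_to_array(patches)
    model.net.forward(x, train=False)
    recon = model.net.recon_head.forward(model.net.pixel_features, train=False)
    return float(np.mean((recon - x) ** 2))


def predict(model: SegModel, patch: Patch | np.ndarray) -> PredictionMap:
    """Per-pixel positive-class probability for one patch (eval mode)."""
    x = _patches_to_array([patch])
    logits = model.net.forward(x, train=False)
    prob = nn.softmax(logits, axis=1)[0, 1]
    return PredictionMap(prob_positive=prob)


def predict_batch(model: SegModel, patches: Sequence) -> list[PredictionMap]:
    x = _patches_to_array(patches)
    logits = model.net.forward(x, train=False)
    probs = nn.softmax(logits, axis=1)[:, 1]
    return [PredictionMap(prob_positive=p) for p in probs]


def binarize(pred: PredictionMap, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map; ties (prob == threshold) map to positive."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return pred.prob_positive >= threshold


def pixel_features(model: SegModel, patch: Patch | np.ndarray) -> np.ndarray:
    """Full-resolution per-pixel feature raster (H, W, C) from the last
    decoder block, for feature-space superpixels."""
    if model.stage == "untrained":
        raise StageError("pixel features require a pretrained or finetuned model")
    x = _patches_to_array([patch])
    model.net.forward(x, train=False)
    return model.net.pixel_features[0].transpose(1, 2, 0)


def bottleneck_features(model: SegModel, patches: Sequence) -> np.ndarray:
    """Channel-wise global average of bottleneck activations, one row per patch."""
    if model.stage == "untrained":
        raise StageError("feature extraction requires a pretrained or finetuned model")
    x = _patches_to_array(patches)
    model.net.forward(x, train=False)
    return model.net.bottleneck.mean(axis=(2, 3))


def save_checkpoint(model: SegModel, path) -> None:
    """Persist weights, norm buffers, stage and config as a single .npz."""
    arrays = {f"param:{k}": p.value for k, p in model.net.params().items()}
    arrays.update({f"param:{k}": p.value for k, p in model.net.recon_params().items()})
    arrays.update({f"buffer:{k}": b for k, b in model.net.buffers().items()})
    arrays["meta:config"] = np.frombuffer(model.config.to_json().encode(), dtype=np.uint8)
    arrays["meta:stage"] = np.frombuffer(model.stage.encode(), dtype=np.uint8)
    arrays["meta:wall"] = np.array([model.train_wall_time])
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> SegModel:
    data = np.load(path)
    config = ModelConfig.from_json(bytes(data["meta:config"]).decode())
    model = build_model(config, seed=0)
    params = {**model.net.params(), **model.net.recon_params()}
    for key in data.files:
        if key.startswith("param:"):
            params[key[6:]].value[...] = data[key]
    buffers = model.net.buffers()
    for key in data.files:
        if key.startswith("buffer:"):
            buffers[key[7:]][...] = data[key]
    model.stage = bytes(data["meta:stage"]).decode()
    model.train_wall_time = float(data["meta:wall"][0])
    return model
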