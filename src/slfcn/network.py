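"""FCN-32s segmentation network with soft-weight loss support.

The architecture is the classic VGG16-lineage FCN-32s: five conv/pool stages,
two 4096-channel fully-convolutional heads, a 1x1 score layer, a single
64x64 stride-32 learned deconvolution, and a fixed-offset crop back to the
input size.  The first convolution pads its input by 100 pixels — the only
padding under which the published 512 -> 710 -> ... -> 17 -> 576 -> 512 shape
trace holds — and all pools are 2x2 stride-2 with ceil-mode sizing.

A ``width_multiplier`` shrinks every channel count proportionally so the same
topology can be trained at desk scale on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .layers import (Conv2d, ConvTranspose2d, CenterOffsetCrop, Dropout,
                     MaxPool2x2Ceil, ReLU)

__all__ = ["NetworkConfig", "LayerShape", "SLFCN", "build_slfcn",
           "layer_shape_trace", "initialize", "predict",
           "save_checkpoint", "load_checkpoint",
           "MIN_INPUT_SIDE", "INIT_SCHEMES"]

#: Contractual minimum input side (canonical FCN-32s sizing convention).
MIN_INPUT_SIDE = 26

#: Fixed crop offset into the deconvolution output (canonical FCN-32s alignment).
CROP_OFFSET = 19

_STAGES = ((64, 2), (128, 2), (256, 3), (512, 3), (512, 3))
_FC_CHANNELS = 4096

INIT_SCHEMES = ("vgg16_transfer", "random", "kaiming", "xavier",
                "kaiming_bilinear")


@dataclass(frozen=True)
class NetworkConfig:
    num_classes: int = 2
    width_multiplier: float = 1.0
    dropout: float = 0.5

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if not 0 < self.width_multiplier <= 1:
            raise ValueError("width_multiplier must be in (0, 1]")

    def scaled(self, channels: int) -> int:
        return max(1, round(channels * self.width_multiplier))


@dataclass(frozen=True)
class LayerShape:
    name: str
    height: int
    width: int
    channels: int


def layer_shape_trace(input_side: int, config: NetworkConfig
                      ) -> list[LayerShape]:
    """Analytic per-layer spatial/channel trace for a square input.

    Rules: conv1_1 pads 100 (side + 198), other 3x3 convs pad 1 (identity),
    pools ceil-halve, fc6 is a valid 7x7 (side - 6), the deconvolution maps
    side n to 32(n - 1) + 64, and the crop returns the input side.
    """
    if input_side < MIN_INPUT_SIDE:
        raise ValueError(
            f"input side {input_side} below the minimum supported size "
            f"{MIN_INPUT_SIDE}")
    shapes = []
    side = input_side
    for stage, (ch, reps) in enumerate(_STAGES, start=1):
        c = config.scaled(ch)
        for rep in range(1, reps + 1):
            if stage == 1 and rep == 1:
                side = side + 2 * 100 - 2
            shapes.append(LayerShape(f"conv{stage}_{rep}", side, side, c))
        side = -(-side // 2)  # ceil
        shapes.append(LayerShape(f"pool{stage}", side, side, c))
    side = side - 6
    if side < 1:
        raise ValueError("input too small for the 7x7 fc6 convolution")
    fc = config.scaled(_FC_CHANNELS)
    shapes.append(LayerShape("fc6", side, side, fc))
    shapes.append(LayerShape("fc7", side, side, fc))
    shapes.append(LayerShape("score", side, side, config.num_classes))
    side = (side - 1) * 32 + 64
    shapes.append(LayerShape("deconv", side, side, config.num_classes))
    shapes.append(LayerShape("crop", input_side, input_side, config.num_classes))
    return shapes


class SLFCN:
    """The network as an ordered list of named layers with shared plumbing."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        self.layers: list[tuple[str, object]] = []
        c_in = 3
        for stage, (ch, reps) in enumerate(_STAGES, start=1):
            c = config.scaled(ch)
            for rep in range(1, reps + 1):
                pad = 100 if (stage == 1 and rep == 1) else 1
                self.layers.append((f"conv{stage}_{rep}",
                                    Conv2d(c_in, c, 3, padding=pad)))
                self.layers.append((f"relu{stage}_{rep}", ReLU()))
                c_in = c
            self.layers.append((f"pool{stage}", MaxPool2x2Ceil()))
        fc = config.scaled(_FC_CHANNELS)
        self.layers.append(("fc6", Conv2d(c_in, fc, 7)))
        self.layers.append(("relu6", ReLU()))
        self.layers.append(("drop6", Dropout(config.dropout)))
        self.layers.append(("fc7", Conv2d(fc, fc, 1)))
        self.layers.append(("relu7", ReLU()))
        self.layers.append(("drop7", Dropout(config.dropout)))
        self.layers.append(("score", Conv2d(fc, config.num_classes, 1)))
        self.layers.append(("deconv",
                            ConvTranspose2d(config.num_classes,
                                            config.num_classes, 64, 32)))
        self.crop = CenterOffsetCrop(CROP_OFFSET)
        self.layers.append(("crop", self.crop))

    # -- plumbing ---------------------------------------------------------
    def named_layers(self):
        return list(self.layers)

    def parameters(self):
        """Flat dict {layer.param: array} over all trainable parameters."""
        out = {}
        for name, layer in self.layers:
            for pname, arr in layer.params().items():
                out[f"{name}.{pname}"] = arr
        return out

    def gradients(self):
        out = {}
        for name, layer in self.layers:
            for pname, arr in layer.grads.items():
                out[f"{name}.{pname}"] = arr
        return out

    def zero_grad(self):
        for _, layer in self.layers:
            layer.zero_grad()

    def set_rng(self, rng: np.random.Generator):
        for _, layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng

    # -- execution --------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 3 or x.shape[0] != 3:
            raise ValueError(f"expected (3, H, W) input, got {x.shape}")
        h, w = x.shape[1:]
        if min(h, w) < MIN_INPUT_SIDE:
            raise ValueError(
                f"input {h}x{w} below the minimum supported side "
                f"{MIN_INPUT_SIDE}")
        self.crop.target = (h, w)
        out = np.asarray(x, dtype=np.float32)
        for _, layer in self.layers:
            out = layer.forward(out, train=train)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        out = np.asarray(dy, dtype=np.float32)
        for _, layer in reversed(self.layers):
            out = layer.backward(out)
        return out


def build_slfcn(config: NetworkConfig) -> SLFCN:
    """Construct the FCN-32s topology for the given configuration."""
    return SLFCN(config)


# -- initialization -------------------------------------------------------

def bilinear_kernel(channels: int, k: int) -> np.ndarray:
    """(C, C, k, k) upsampling kernel that performs bilinear interpolation."""
    factor = (k + 1) // 2
    center = factor - 1 if k % 2 == 1 else factor - 0.5
    og = np.ogrid[:k, :k]
    filt = ((1 - abs(og[0] - center) / factor)
            * (1 - abs(og[1] - center) / factor)).astype(np.float32)
    w = np.zeros((channels, channels, k, k), dtype=np.float32)
    for c in range(channels):
        w[c, c] = filt
    return w


def _fans(shape):
    if len(shape) == 4:
        rec = shape[2] * shape[3]
        return shape[1] * rec, shape[0] * rec
    return shape[1], shape[0]


def initialize(network: SLFCN, scheme: str, seed: int = 0,
               vgg16_weights: str | None = None) -> SLFCN:
    """Initialize all parameters in place according to a named scheme.

    ``random`` draws N(0, 0.01) weights; ``kaiming``/``xavier`` use the usual
    fan-based variances; ``kaiming_bilinear`` is Kaiming for all convolutions
    plus a fixed bilinear deconvolution and a zeroed score layer (the stable
    desk-scale recipe).  ``vgg16_transfer`` copies shape-matched convolution
    weights from a user-supplied ``.npz`` archive (keys ``conv1_1.W`` etc.),
    zeroes the score layer, and sets the deconvolution to bilinear
    upsampling; it requires width_multiplier 1.
    """
    if scheme not in INIT_SCHEMES:
        raise ValueError(f"unknown init scheme {scheme!r}; "
                         f"choose from {INIT_SCHEMES}")
    rng = np.random.default_rng(seed)
    if scheme == "vgg16_transfer":
        if vgg16_weights is None:
            raise FileNotFoundError(
                "vgg16_transfer needs a pretrained-weight .npz archive "
                "(pass vgg16_weights=...)")
        if network.config.width_multiplier != 1.0:
            raise ValueError("vgg16_transfer requires width_multiplier = 1 "
                             "(pretrained shapes must match)")
        archive = np.load(vgg16_weights)
        for name, layer in network.layers:
            if isinstance(layer, Conv2d):
                if name == "score":
                    layer.W[...] = 0.0
                    layer.b[...] = 0.0
                elif f"{name}.W" in archive and \
                        archive[f"{name}.W"].shape == layer.W.shape:
                    layer.W[...] = archive[f"{name}.W"]
                    if f"{name}.b" in archive:
                        layer.b[...] = archive[f"{name}.b"]
                else:
                    _init_conv(layer, "kaiming", rng)
            elif isinstance(layer, ConvTranspose2d):
                layer.W[...] = bilinear_kernel(layer.out_channels, layer.k)
        return network

    for name, layer in network.layers:
        if isinstance(layer, Conv2d):
            if scheme == "kaiming_bilinear" and name == "score":
                layer.W[...] = 0.0
                layer.b[...] = 0.0
            else:
                _init_conv(layer, "kaiming" if scheme == "kaiming_bilinear"
                           else scheme, rng)
        elif isinstance(layer, ConvTranspose2d):
            if scheme == "kaiming_bilinear":
                layer.W[...] = bilinear_kernel(layer.out_channels, layer.k)
            else:
                _init_array(layer.W, scheme, rng)
    return network


def _init_conv(layer: Conv2d, scheme: str, rng):
    _init_array(layer.W, scheme, rng)
    layer.b[...] = 0.0


def _init_array(w: np.ndarray, scheme: str, rng):
    fan_in, fan_out = _fans(w.shape)
    if scheme == "random":
        w[...] = rng.normal(0.0, 0.01, w.shape).astype(np.float32)
    elif scheme == "kaiming":
        w[...] = rng.normal(0.0, np.sqrt(2.0 / fan_in), w.shape).astype(np.float32)
    elif scheme == "xavier":
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        w[...] = rng.uniform(-limit, limit, w.shape).astype(np.float32)
    else:  # pragma: no cover
        raise ValueError(scheme)


# -- inference ------------------------------------------------------------

def predict(network: SLFCN, image: np.ndarray):
    """Segment one image: returns (label map, per-class score maps).

    Inputs smaller than the minimum side are reflect-padded up, then the
    output is cropped back.  The label at each pixel is the argmax class;
    exact ties break toward the lowest class index.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 3 or image.shape[0] != 3:
        raise ValueError("predict expects a (3, H, W) image")
    h, w = image.shape[1:]
    ph = max(0, MIN_INPUT_SIDE - h)
    pw = max(0, MIN_INPUT_SIDE - w)
    if ph or pw:
        image = np.pad(image, ((0, 0), (0, ph), (0, pw)), mode="reflect")
    scores = network.forward(image, train=False)
    scores = scores[:, :h, :w]
    labels = scores.argmax(axis=0).astype(np.uint8)
    return labels, scores


# -- checkpointing --------------------------------------------------------

def save_checkpoint(path: str, network: SLFCN, meta: dict | None = None):
    payload = {f"param:{k}": v for k, v in network.parameters().items()}
    payload["config_json"] = np.frombuffer(
        json.dumps({**asdict(network.config), "meta": meta or {}}).encode(),
        dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path: str) -> tuple[SLFCN, dict]:
    archive = np.load(path)
    info = json.loads(bytes(archive["config_json"]).decode())
    meta = info.pop("meta", {})
    network = SLFCN(NetworkConfig(**info))
    params = network.parameters()
    for key in archive.files:
        if key.startswith("param:"):
            params[key[len("param:"):]][...] = archive[key]
    return network, meta
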