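"""Dataset plumbing: image/annotation I/O, tiling, stitching, augmentation.

File conventions
----------------
* images: 8-bit RGB PNG/TIFF;
* instance annotations: 16-bit single-channel PNG of instance ids
  (0 = background) plus a JSON sidecar mapping id -> class name;
* label maps: 8-bit single-channel PNG of class indices;
* weight maps: single-channel float32 TIFF;
* dataset manifest: JSON list of {key, split, image, annotation} records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from PIL import Image
from scipy import ndimage

from .softlabel import InstanceAnnotation

__all__ = [
    "Tile", "AugmentationPlan", "tile", "stitch", "augment",
    "read_image", "write_image", "read_label_map", "write_label_map",
    "read_weight_map", "write_weight_map",
    "write_instance_annotations", "read_instance_annotations",
    "write_manifest", "read_manifest", "to_network_input", "write_dataset",
]


# ---------------------------------------------------------------------------
# I/O

def read_image(path) -> np.ndarray:
    """8-bit RGB image as (H, W, 3) uint8."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def read_label_map(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im, dtype=np.uint8)


def write_label_map(path, labels: np.ndarray) -> None:
    Image.fromarray(np.asarray(labels, dtype=np.uint8), mode="L").save(path)


def read_weight_map(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.float32)


def write_weight_map(path, weights: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(weights, dtype=np.float32))


def write_instance_annotations(png_path, instances: Sequence[InstanceAnnotation],
                               image_shape: tuple[int, int]) -> None:
    """Instance-id PNG (16-bit) + JSON sidecar with the id -> class table."""
    id_map = np.zeros(image_shape, dtype=np.uint16)
    sidecar = {"instances": []}
    for inst in instances:
        id_map[inst.to_mask(image_shape)] = inst.instance_id
        sidecar["instances"].append(
            {"id": inst.instance_id, "class": inst.class_label})
    Image.fromarray(id_map).save(png_path)
    Path(str(png_path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_instance_annotations(png_path) -> list[InstanceAnnotation]:
    with Image.open(png_path) as im:
        id_map = np.asarray(im, dtype=np.uint16)
    sidecar = json.loads(Path(str(png_path) + ".json").read_text())
    classes = {rec["id"]: rec["class"] for rec in sidecar["instances"]}
    instances = []
    for inst_id in np.unique(id_map):
        if inst_id == 0:
            continue
        instances.append(InstanceAnnotation.from_mask(
            id_map == inst_id, classes[int(inst_id)], int(inst_id)))
    return instances


def write_manifest(path, records: Sequence[dict]) -> None:
    Path(path).write_text(json.dumps(list(records), indent=1))


def read_manifest(path) -> list[dict]:
    return json.loads(Path(path).read_text())


def to_network_input(image: np.ndarray) -> np.ndarray:
    """(H, W, 3) uint8 -> zero-centered (3, H, W) float32."""
    return (np.asarray(image, dtype=np.float32) / 255.0 - 0.5
            ).transpose(2, 0, 1)


def write_dataset(records, out_dir) -> str:
    """Write generated field records (image + annotations) plus a manifest.

    Each record needs keys ``key``, ``split``, ``image``, ``instances`` (and
    optionally ``seed``).  Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for rec in records:
        image_name = f"{rec['key']}.png"
        ann_name = f"{rec['key']}_inst.png"
        write_image(out / image_name, rec["image"])
        write_instance_annotations(out / ann_name, rec["instances"],
                                   rec["image"].shape[:2])
        manifest.append({"key": rec["key"], "split": rec["split"],
                         "image": image_name, "annotation": ann_name,
                         "seed": rec.get("seed")})
    path = out / "manifest.json"
    write_manifest(path, manifest)
    return str(path)


# ---------------------------------------------------------------------------
# Tiling

@dataclass
class Tile:
    """One tile: pixel data, origin (x, y) in the source, validity mask."""

    data: np.ndarray
    origin: tuple[int, int]
    valid: np.ndarray


def tile(image: np.ndarray, tile_side: int = 512,
         stride: int | None = None) -> list[Tile]:
    """Cover an image with fixed-size tiles, reflect-padding the borders.

    With stride = tile_side (the default) every source pixel lands in exactly
    one tile's valid region; stride > tile_side would leave gaps and is
    rejected.
    """
    stride = tile_side if stride is None else stride
    if stride > tile_side:
        raise ValueError("stride larger than the tile side leaves gaps")
    if stride < 1:
        raise ValueError("stride must be positive")
    h, w = image.shape[:2]
    if h == 0 or w == 0:
        raise ValueError("empty image")
    ny, nx = -(-h // stride), -(-w // stride)
    need_h = (ny - 1) * stride + tile_side
    need_w = (nx - 1) * stride + tile_side
    pad = [(0, need_h - h), (0, need_w - w)] + [(0, 0)] * (image.ndim - 2)
    padded = np.pad(image, pad, mode="reflect")
    tiles = []
    for iy in range(ny):
        for ix in range(nx):
            y, x = iy * stride, ix * stride
            block = padded[y:y + tile_side, x:x + tile_side]
            valid = np.zeros((tile_side, tile_side), dtype=bool)
            valid[:max(0, min(h - y, tile_side)),
                  :max(0, min(w - x, tile_side))] = True
            tiles.append(Tile(block.copy(), (x, y), valid))
    return tiles


def stitch(score_tiles: Sequence[tuple[np.ndarray, tuple[int, int], np.ndarray]],
           source_shape: tuple[int, int]) -> np.ndarray:
    """Reassemble per-class score tiles into a full-size (C, H, W) map.

    Each element is ``(scores (C, s, s), origin (x, y), valid (s, s))``.
    Overlapping valid contributions are averaged; padded regions are dropped;
    a pixel covered by no tile is an error.
    """
    h, w = source_shape
    c = score_tiles[0][0].shape[0]
    acc = np.zeros((c, h, w), dtype=np.float64)
    count = np.zeros((h, w), dtype=np.int64)
    for scores, (x, y), valid in score_tiles:
        s_h, s_w = scores.shape[1:]
        vh = min(s_h, h - y)
        vw = min(s_w, w - x)
        if vh <= 0 or vw <= 0:
            continue
        v = valid[:vh, :vw]
        acc[:, y:y + vh, x:x + vw] += scores[:, :vh, :vw] * v
        count[y:y + vh, x:x + vw] += v
    if np.any(count == 0):
        raise ValueError("tiles do not cover the full source image")
    return (acc / count).astype(np.float32)


# ---------------------------------------------------------------------------
# Augmentation

@dataclass(frozen=True)
class AugmentationPlan:
    """Which geometric transforms to apply to each training sample.

    The default plan expands one sample into 11: the original, five
    small-angle rotations in 5-degree steps, the three right-angle rotations,
    and the horizontal and vertical flips.
    """

    small_angles: tuple = (5.0, 10.0, 15.0, 20.0, 25.0)
    right_angles: tuple = (90, 180, 270)
    flip_horizontal: bool = True
    flip_vertical: bool = True
    small_enabled: bool = True
    right_enabled: bool = True
    flips_enabled: bool = True
    fill_weight: float = 1.0  # background-tier weight for rotated-in corners

    def __post_init__(self):
        for a in self.small_angles:
            if not 0 < a < 360:
                raise ValueError("rotation angles must be in (0, 360)")
        for a in self.right_angles:
            if a not in (90, 180, 270):
                raise ValueError("right-angle rotations must be 90/180/270")


def _rotate_small(image, labels, weights, angle, fill_weight):
    img = ndimage.rotate(image.astype(np.float32), angle, axes=(1, 0),
                         reshape=False, order=1, mode="constant", cval=0.0)
    img = np.clip(img, 0, 255).astype(image.dtype)
    lab = ndimage.rotate(labels, angle, axes=(1, 0), reshape=False,
                         order=0, mode="constant", cval=0)
    wgt = ndimage.rotate(weights, angle, axes=(1, 0), reshape=False,
                         order=0, mode="constant", cval=fill_weight)
    return img, lab, wgt.astype(np.float32)


def augment(sample, plan: AugmentationPlan = AugmentationPlan()):
    """Expand an (image, labels, weights) sample per the augmentation plan.

    Labels and weight maps use nearest-neighbour resampling so their value
    sets are preserved; images are bilinear.  Regions rotated in from outside
    the frame are filled with black / background class / background weight.
    """
    image, labels, weights = sample
    if image.shape[:2] != labels.shape or labels.shape != weights.shape:
        raise ValueError("sample planes are not aligned")
    out = [(image, labels, weights)]
    if plan.small_enabled:
        for angle in plan.small_angles:
            out.append(_rotate_small(image, labels, weights, angle,
                                     plan.fill_weight))
    if plan.right_enabled:
        for angle in plan.right_angles:
            k = angle // 90
            out.append((np.rot90(image, k, axes=(0, 1)).copy(),
                        np.rot90(labels, k).copy(),
                        np.rot90(weights, k).copy()))
    if plan.flips_enabled:
        if plan.flip_horizontal:
            out.append((np.flip(image, axis=1).copy(),
                        np.flip(labels, axis=1).copy(),
                        np.flip(weights, axis=1).copy()))
        if plan.flip_vertical:
            out.append((np.flip(image, axis=0).copy(),
                        np.flip(labels, axis=0).copy(),
                        np.flip(weights, axis=0).copy()))
    return out
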