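"""Soft-label region construction and per-pixel loss-weight maps.

Instance annotations are softened deterministically: each annotated region is
split into an eroded *core*, a *soft band* (the erosion band inside the
original outline plus a dilation band outside it), and background.  The square
structuring-element sizes are derived from the median bounding-box diagonal of
the whole training dataset, so a single pair of kernels applies to every image.
Per-pixel loss weights are then assigned by tier: core ``psi``, soft band
``pi_``, background ``aleph``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "InstanceAnnotation",
    "BoundingBox",
    "SoftLabelParams",
    "KernelPair",
    "RegionPartition",
    "WeightParams",
    "AnnotationError",
    "bounding_box",
    "diagonal",
    "median_diagonal",
    "kernel_sizes",
    "erode",
    "dilate",
    "region_partition",
    "weight_map",
    "build_target_labels",
    "soften_dataset",
    "SOFT_REGION_PRESETS",
    "WEIGHT_PRESETS",
]


class AnnotationError(ValueError):
    """Raised for invalid or conflicting instance annotations."""


@dataclass(frozen=True)
class InstanceAnnotation:
    """A single annotated instance: a pixel set plus a class label.

    Pixels are 0-based ``(i, j) = (column, row)`` coordinates.  The pixel set
    need not be connected; it must be non-empty and inside the image.
    """

    pixels: frozenset
    class_label: str
    instance_id: int

    def __post_init__(self):
        if not self.pixels:
            raise AnnotationError(
                f"instance {self.instance_id}: empty pixel set"
            )
        if self.instance_id <= 0:
            raise AnnotationError("instance_id must be a positive integer")

    @classmethod
    def from_mask(cls, mask: np.ndarray, class_label: str, instance_id: int
                  ) -> "InstanceAnnotation":
        rows, cols = np.nonzero(np.asarray(mask, dtype=bool))
        return cls(frozenset(zip(cols.tolist(), rows.tolist())),
                   class_label, instance_id)

    def to_mask(self, image_shape: tuple[int, int]) -> np.ndarray:
        h, w = image_shape
        mask = np.zeros((h, w), dtype=bool)
        cols, rows = zip(*self.pixels)
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        if rows.min() < 0 or cols.min() < 0 or rows.max() >= h or cols.max() >= w:
            raise AnnotationError(
                f"instance {self.instance_id}: pixels outside image {image_shape}"
            )
        mask[rows, cols] = True
        return mask


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box ``(x_min, y_min, width, height)``.

    Width and height are literal coordinate ranges ``max - min``: a
    single-pixel instance has width = height = 0.
    """

    x_min: int
    y_min: int
    width: int
    height: int

    def __post_init__(self):
        if self.width < 0 or self.height < 0:
            raise ValueError("negative box extent")


@dataclass(frozen=True)
class SoftLabelParams:
    """Kernel-size scaling parameters.

    phi scales the median diagonal; upsilon and tau multiply the shared floor
    term into the erosion and dilation kernel sides respectively.
    """

    phi: float = 0.01
    upsilon: int = 2
    tau: int = 6

    def __post_init__(self):
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.upsilon < 1 or self.tau < 1:
            raise ValueError("upsilon and tau must be >= 1")


#: Region-scale presets: default soft band, half-width band, double-width band.
SOFT_REGION_PRESETS: Mapping[str, SoftLabelParams] = {
    "default": SoftLabelParams(phi=0.01, upsilon=2, tau=6),
    "half": SoftLabelParams(phi=0.01, upsilon=1, tau=3),
    "double": SoftLabelParams(phi=0.01, upsilon=4, tau=12),
}


@dataclass(frozen=True)
class KernelPair:
    """Erosion / dilation square structuring-element side lengths (odd)."""

    kappa_e: int
    kappa_d: int

    def __post_init__(self):
        for name, k in (("kappa_e", self.kappa_e), ("kappa_d", self.kappa_d)):
            if k < 1 or k % 2 == 0:
                raise ValueError(f"{name} must be an odd positive integer, got {k}")


@dataclass(frozen=True)
class WeightParams:
    """Loss-weight tiers: core ``psi``, soft band ``pi_``, background ``aleph``."""

    psi: float = 2.0
    pi_: float = 1.5
    aleph: float = 1.0

    def __post_init__(self):
        for v in (self.psi, self.pi_, self.aleph):
            if not np.isfinite(v) or v <= 0:
                raise ValueError("weights must be finite positive reals")


WEIGHT_PRESETS: Mapping[str, WeightParams] = {
    "default": WeightParams(2.0, 1.5, 1.0),
    "low_background": WeightParams(2.0, 1.0, 0.1),
    "doubled": WeightParams(4.0, 2.0, 1.0),
}


@dataclass
class RegionPartition:
    """Disjoint core / soft-band / background decomposition of an image grid."""

    core: np.ndarray
    soft_band: np.ndarray
    background: np.ndarray
    image_shape: tuple[int, int]

    def validate(self) -> None:
        total = (self.core.astype(int) + self.soft_band.astype(int)
                 + self.background.astype(int))
        if not np.all(total == 1):
            raise ValueError("partition tiers are not disjoint and exhaustive")


def bounding_box(instance: InstanceAnnotation) -> BoundingBox:
    """Tight bounding box of an instance, extents as literal ``max - min``."""
    cols, rows = zip(*instance.pixels)
    return BoundingBox(min(cols), min(rows),
                       max(cols) - min(cols), max(rows) - min(rows))


def diagonal(box: BoundingBox) -> float:
    """Euclidean diagonal sqrt(w^2 + h^2) of a bounding box."""
    return float(np.hypot(box.width, box.height))


def median_diagonal(diagonals: Sequence[float]) -> float:
    """Median of the pooled bounding-box diagonals (even K: mean of middle two)."""
    if len(diagonals) == 0:
        raise ValueError("cannot take the median diagonal of an empty dataset")
    return float(np.median(np.asarray(diagonals, dtype=float)))


def kernel_sizes(psi_star: float, params: SoftLabelParams = SoftLabelParams()
                 ) -> KernelPair:
    """Erosion/dilation kernel sides from the median diagonal.

    kappa_e = upsilon * floor((phi*psi_star + 1) / 2) + 1 and likewise with tau
    for kappa_d.  Even multipliers always yield odd sides; an odd multiplier
    (the half-band preset) can yield an even side, which is bumped to the next
    odd integer so a centered square structuring element exists.
    """
    if psi_star < 0:
        raise ValueError("psi_star must be nonnegative")
    f = int(np.floor((params.phi * psi_star + 1.0) / 2.0))

    def _odd(k: int) -> int:
        return k if k % 2 == 1 else k + 1

    return KernelPair(_odd(params.upsilon * f + 1), _odd(params.tau * f + 1))


def _check_kappa(kappa: int) -> None:
    if kappa < 1 or kappa % 2 == 0:
        raise ValueError(f"structuring-element side must be odd and >= 1, got {kappa}")


def erode(mask: np.ndarray, kappa: int) -> np.ndarray:
    """Binary erosion by the kappa x kappa all-ones square.

    Pixels outside the image count as background, so instances touching the
    border erode from that side as well.  kappa = 1 is the identity.
    """
    _check_kappa(kappa)
    mask = np.asarray(mask, dtype=bool)
    if kappa == 1:
        return mask.copy()
    return ndimage.binary_erosion(mask, structure=np.ones((kappa, kappa), bool),
                                  border_value=0)


def dilate(mask: np.ndarray, kappa: int) -> np.ndarray:
    """Binary dilation by the kappa x kappa all-ones square, clipped to the image."""
    _check_kappa(kappa)
    mask = np.asarray(mask, dtype=bool)
    if kappa == 1:
        return mask.copy()
    return ndimage.binary_dilation(mask, structure=np.ones((kappa, kappa), bool),
                                   border_value=0)


def region_partition(instances: Iterable[InstanceAnnotation],
                     kernels: KernelPair,
                     image_shape: tuple[int, int]) -> RegionPartition:
    """Build the disjoint core / soft-band / background partition.

    Per instance: core = annotation eroded by kappa_e; the soft band is the
    erosion band (annotation minus core) united with the dilation band (core
    dilated by kappa_d, minus the annotation).  Across instances cores take
    priority over bands.  An instance that erodes to the empty set contributes
    no core and becomes pure soft band over its own pixels.
    """
    h, w = image_shape
    core = np.zeros((h, w), dtype=bool)
    soft = np.zeros((h, w), dtype=bool)
    for inst in instances:
        r_a = inst.to_mask(image_shape)
        r_c = erode(r_a, kernels.kappa_e)
        r_o = dilate(r_c, kernels.kappa_d)
        r_e = r_a & ~r_c
        r_d = r_o & ~r_a
        core |= r_c
        soft |= r_e | r_d
    soft &= ~core  # core tier wins where instances overlap
    background = ~(core | soft)
    part = RegionPartition(core, soft, background, (h, w))
    part.validate()
    return part


def weight_map(partition: RegionPartition,
               weights: WeightParams = WeightParams()) -> np.ndarray:
    """Per-pixel float32 loss weights: psi on core, pi_ on band, aleph elsewhere."""
    out = np.full(partition.image_shape, weights.aleph, dtype=np.float32)
    out[partition.soft_band] = weights.pi_
    out[partition.core] = weights.psi
    return out


def build_target_labels(instances: Iterable[InstanceAnnotation],
                        image_shape: tuple[int, int],
                        class_table: Mapping[str, int]) -> np.ndarray:
    """Per-pixel hard class indices (uint8); background is class 0.

    Targets stay hard: softening acts on the loss weights only, and
    dilation-band pixels outside any annotation keep the background class.
    Overlapping instances of different classes are rejected.
    """
    h, w = image_shape
    labels = np.zeros((h, w), dtype=np.uint8)
    owner = np.zeros((h, w), dtype=np.int64)
    for inst in instances:
        if inst.class_label not in class_table:
            raise AnnotationError(
                f"instance {inst.instance_id}: unknown class {inst.class_label!r}"
            )
        cls = class_table[inst.class_label]
        if not 0 < cls < 256:
            raise AnnotationError(f"class index {cls} out of range 1..255")
        mask = inst.to_mask(image_shape)
        clash = mask & (labels != 0) & (labels != cls)
        if clash.any():
            prev = int(owner[clash][0])
            raise AnnotationError(
                f"instances {prev} and {inst.instance_id} overlap with "
                "different classes"
            )
        labels[mask] = cls
        owner[mask] = inst.instance_id
    return labels


def soften_dataset(per_image_instances: Mapping[str, Sequence[InstanceAnnotation]],
                   image_shapes: Mapping[str, tuple[int, int]],
                   class_table: Mapping[str, int],
                   params: SoftLabelParams = SoftLabelParams(),
                   weights: WeightParams = WeightParams(),
                   per_image_median: bool = False,
                   kernels: KernelPair | None = None):
    """Soften a whole training dataset.

    By default the median diagonal is pooled over every instance in the
    dataset, giving one kernel pair applied to all images; ``per_image_median``
    recomputes it per image (experimental mode).  An explicit ``kernels``
    pair overrides the derived one (e.g. the identity pair for the hard-label
    baseline).

    Returns ``(outputs, psi_star, kernels)`` where ``outputs`` maps image key
    to ``(weight_map, label_field)``.  For ``per_image_median`` the returned
    psi_star/kernels are those of the pooled computation for reference.
    """
    all_diagonals = [diagonal(bounding_box(inst))
                     for insts in per_image_instances.values() for inst in insts]
    if not all_diagonals:
        raise ValueError("dataset contains no instances")
    psi_star = median_diagonal(all_diagonals)
    if kernels is None:
        kernels = kernel_sizes(psi_star, params)

    outputs = {}
    for key, insts in per_image_instances.items():
        shape = image_shapes[key]
        if per_image_median and insts:
            local = median_diagonal([diagonal(bounding_box(i)) for i in insts])
            k = kernel_sizes(local, params)
        else:
            k = kernels
        part = region_partition(insts, k, shape)
        outputs[key] = (weight_map(part, weights),
                        build_target_labels(insts, shape, class_table))
    return outputs, psi_star, kernels
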