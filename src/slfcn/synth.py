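"""Seeded generator of FISH/DISH-like synthetic fields.

Each field contains nucleus-like blobs with deliberately blurred borders on a
textured background, plus two classes of punctate in-situ-hybridisation-style
signals rendered inside the nuclei: "her2" (black in the brightfield DISH
palette) and "cen17" (red).  Ground-truth instance masks are taken from the
crisp pre-blur geometry, so annotations stay exact while the rendered image is
soft — the structure the soft-label method targets.  Visual realism is not a
goal; only this statistical structure is.

Signal-dot pixels are carved out of their nucleus' pixel set so that
instances of different classes never overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .softlabel import InstanceAnnotation

__all__ = ["SynthParams", "GenerationError", "CLASS_TABLE",
           "generate_field", "generate_dataset"]

#: Class-name -> label-index table shared across the pipeline.
CLASS_TABLE = {"nucleus": 1, "her2": 2, "cen17": 3}

_PALETTES = {
    "dish": {
        "background": (0.87, 0.82, 0.86),
        "nucleus": (0.55, 0.45, 0.70),
        "her2": (0.08, 0.06, 0.06),
        "cen17": (0.75, 0.12, 0.12),
    },
    "fish": {
        "background": (0.02, 0.02, 0.04),
        "nucleus": (0.10, 0.15, 0.50),
        "her2": (0.92, 0.35, 0.10),
        "cen17": (0.15, 0.90, 0.20),
    },
}


class GenerationError(RuntimeError):
    """Raised when a field cannot be packed within the retry budget."""


@dataclass(frozen=True)
class SynthParams:
    """Knobs of the synthetic field generator.

    ``boundary_blur_sigma`` is the Gaussian blur (pixels) applied to the
    rendered image only; larger values make nucleus borders harder to place
    exactly, which is the difficulty dial of the whole fixture family.
    """

    seed: int
    height: int = 256
    width: int = 256
    nucleus_count: int = 5
    nucleus_radius: tuple[float, float] = (16.0, 26.0)
    boundary_blur_sigma: float = 1.5
    dots_dark: int = 4     # "her2"-like dots per nucleus
    dots_red: int = 2      # "cen17"-like dots per nucleus
    dot_radius: tuple[float, float] = (1.5, 3.0)
    background_noise_sigma: float = 0.02
    style: str = "dish"

    def __post_init__(self):
        if self.style not in _PALETTES:
            raise ValueError(f"style must be one of {sorted(_PALETTES)}")
        if self.nucleus_count < 0 or self.dots_dark < 0 or self.dots_red < 0:
            raise ValueError("counts must be nonnegative")
        if self.nucleus_radius[0] < 1 or self.dot_radius[0] < 1:
            raise ValueError("radii must be >= 1")
        if self.boundary_blur_sigma < 0 or self.background_noise_sigma < 0:
            raise ValueError("sigmas must be nonnegative")


def _blob_mask(h, w, cy, cx, r_major, r_minor, theta, wobble_phase,
               wobble_amp=0.15, lobes=3):
    """Elliptical blob with a low-frequency radial wobble."""
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(theta), np.sin(theta)
    u = (ca * dx + sa * dy) / r_major
    v = (-sa * dx + ca * dy) / r_minor
    ang = np.arctan2(v, u)
    limit = 1.0 + wobble_amp * np.sin(lobes * ang + wobble_phase)
    return u * u + v * v <= limit * limit


def _disk_mask(h, w, cy, cx, r):
    yy, xx = np.mgrid[0:h, 0:w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def generate_field(params: SynthParams):
    """Render one field: returns (image (H, W, 3) uint8, instance list).

    Deterministic given the seed.  Nuclei are packed without overlap inside
    the frame (bounded retries, then :class:`GenerationError`); dots are
    placed strictly inside their nucleus, so no instance crosses the border.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    palette = _PALETTES[params.style]
    canvas = np.empty((h, w, 3), dtype=np.float64)
    canvas[...] = palette["background"]
    canvas += rng.normal(0.0, 0.015, (h, w, 3))  # fixed faint texture

    instances = []
    next_id = 1
    nucleus_masks = []
    occupied = np.zeros((h, w), dtype=bool)
    r_lo, r_hi = params.nucleus_radius
    margin = 2

    for _ in range(params.nucleus_count):
        for attempt in range(500):
            r_major = rng.uniform(r_lo, r_hi)
            r_minor = rng.uniform(r_lo, r_hi)
            rmax = max(r_major, r_minor) * 1.2  # wobble headroom
            if 2 * (rmax + margin) >= min(h, w):
                raise GenerationError("nucleus radius too large for the frame")
            cy = rng.uniform(rmax + margin, h - rmax - margin)
            cx = rng.uniform(rmax + margin, w - rmax - margin)
            mask = _blob_mask(h, w, cy, cx, r_major, r_minor,
                              rng.uniform(0, np.pi), rng.uniform(0, 2 * np.pi))
            if not (mask & occupied).any():
                break
        else:
            raise GenerationError(
                f"could not place nucleus {len(nucleus_masks) + 1} within the "
                "retry budget; reduce nucleus_count or radius")
        occupied |= mask
        nucleus_masks.append(mask)
        tint = np.asarray(palette["nucleus"]) + rng.normal(0, 0.04, 3)
        canvas[mask] = np.clip(tint, 0, 1)

    d_lo, d_hi = params.dot_radius
    for mask in nucleus_masks:
        dot_union = np.zeros((h, w), dtype=bool)
        dot_records = []
        for class_label, count in (("her2", params.dots_dark),
                                   ("cen17", params.dots_red)):
            for _ in range(count):
                for attempt in range(200):
                    r = rng.uniform(d_lo, d_hi)
                    interior = ndimage.binary_erosion(
                        mask, iterations=int(np.ceil(r)) + 1, border_value=0)
                    candidates = np.flatnonzero(interior & ~ndimage.binary_dilation(
                        dot_union, iterations=int(np.ceil(d_hi)) + 1))
                    if candidates.size == 0:
                        continue
                    flat = rng.choice(candidates)
                    cy, cx = divmod(int(flat), w)
                    dot = _disk_mask(h, w, cy, cx, r)
                    if not (dot & dot_union).any() and not (dot & ~mask).any():
                        break
                else:
                    raise GenerationError(
                        "could not place a signal dot; nucleus too small for "
                        "the requested dot count")
                dot_union |= dot
                dot_records.append((class_label, dot))
                canvas[dot] = palette[class_label]
        # carve dots out of the nucleus instance so classes never overlap
        nucleus_pixels = mask & ~dot_union
        instances.append(InstanceAnnotation.from_mask(
            nucleus_pixels, "nucleus", next_id))
        next_id += 1
        for class_label, dot in dot_records:
            instances.append(InstanceAnnotation.from_mask(
                dot, class_label, next_id))
            next_id += 1

    if params.boundary_blur_sigma > 0:
        canvas = ndimage.gaussian_filter(
            canvas, sigma=(params.boundary_blur_sigma,
                           params.boundary_blur_sigma, 0))
    if params.background_noise_sigma > 0:
        canvas += rng.normal(0.0, params.background_noise_sigma, canvas.shape)
    image = (np.clip(canvas, 0, 1) * 255).round().astype(np.uint8)
    return image, instances


def generate_dataset(n_train: int, n_test: int, params: SynthParams):
    """Generate a train/test fixture set with distinct derived seeds.

    Returns a list of records ``{key, split, seed, image, instances}`` in a
    fixed order; regenerating with the same master seed reproduces the set
    bit-identically.
    """
    if n_train < 1 or n_test < 0:
        raise ValueError("need at least one training image")
    seeds = np.random.SeedSequence(params.seed).generate_state(
        n_train + n_test) & 0x7FFFFFFF
    records = []
    for idx, child_seed in enumerate(seeds):
        split = "train" if idx < n_train else "test"
        p = replace(params, seed=int(child_seed))
        image, instances = generate_field(p)
        records.append({"key": f"{split}_{idx:03d}", "split": split,
                        "seed": int(child_seed), "image": image,
                        "instances": instances})
    return records
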