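"""Soft-label construction: boxes, kernels, morphology, partitions, weights."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import block_instance
from slfcn.softlabel import (
    AnnotationError, InstanceAnnotation, KernelPair, SOFT_REGION_PRESETS,
    SoftLabelParams, WeightParams, bounding_box, build_target_labels,
    diagonal, dilate, erode, kernel_sizes, median_diagonal, region_partition,
    soften_dataset, weight_map,
)


# ---------------------------------------------------------------------------
# bounding boxes and diagonals

@pytest.mark.parametrize("pixels, expected", [
    ({(2, 3), (5, 3), (2, 4)}, (2, 3, 3, 1)),
    ({(7, 7)}, (7, 7, 0, 0)),
    ({(x, y) for x in range(5) for y in range(5)}, (0, 0, 4, 4)),
])
def test_bounding_box_extents_are_coordinate_ranges(pixels, expected):
    box = bounding_box(InstanceAnnotation(frozenset(pixels), "nucleus", 1))
    assert (box.x_min, box.y_min, box.width, box.height) == expected


def test_empty_pixel_set_is_rejected():
    with pytest.raises(AnnotationError):
        InstanceAnnotation(frozenset(), "nucleus", 1)


@pytest.mark.parametrize("w, h, expected", [
    (3, 4, 5.0), (0, 0, 0.0), (4, 4, np.sqrt(32.0)),
])
def test_diagonal(w, h, expected):
    from slfcn.softlabel import BoundingBox
    assert diagonal(BoundingBox(0, 0, w, h)) == pytest.approx(expected)


@pytest.mark.parametrize("values, expected", [
    ([5, 3, 4], 4.0), ([6, 3, 5, 4], 4.5), ([7], 7.0),
])
def test_median_diagonal(values, expected):
    assert median_diagonal(values) == expected


def test_median_of_empty_dataset_raises():
    with pytest.raises(ValueError):
        median_diagonal([])


@given(st.lists(st.floats(0, 1e4), min_size=1, max_size=30))
@settings(deadline=None, derandomize=True)
def test_median_matches_sort_based_oracle(values):
    srt = sorted(values)
    k = len(srt)
    if k % 2 == 1:
        expected = srt[(k - 1) // 2]
    else:
        expected = (srt[k // 2 - 1] + srt[k // 2]) / 2
    assert median_diagonal(values) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# kernel sizes

@pytest.mark.parametrize("psi_star, expected", [
    (0.0, (1, 1)), (100.0, (3, 7)), (300.0, (5, 13)),
])
def test_kernel_sizes_at_defaults(psi_star, expected):
    k = kernel_sizes(psi_star)
    assert (k.kappa_e, k.kappa_d) == expected


def test_negative_psi_star_rejected():
    with pytest.raises(ValueError):
        kernel_sizes(-1.0)


@pytest.mark.parametrize("preset", ["default", "double"])
@given(psi=st.floats(0, 1e4))
@settings(deadline=None, derandomize=True)
def test_kernel_sizes_odd_and_monotone(preset, psi):
    params = SOFT_REGION_PRESETS[preset]
    k = kernel_sizes(psi, params)
    assert k.kappa_e % 2 == 1 and k.kappa_d % 2 == 1
    bigger = kernel_sizes(psi + 100.0, params)
    assert bigger.kappa_e >= k.kappa_e and bigger.kappa_d >= k.kappa_d


def test_default_preset_couples_kernel_sides():
    for psi in (0, 50, 100, 250, 700):
        k = kernel_sizes(float(psi))
        assert k.kappa_d == 3 * k.kappa_e - 2


def test_half_preset_bumps_even_sides_to_odd():
    # upsilon=1, psi*=100 gives the literal value 2; stored as next odd 3
    k = kernel_sizes(100.0, SOFT_REGION_PRESETS["half"])
    assert (k.kappa_e, k.kappa_d) == (3, 5)


# ---------------------------------------------------------------------------
# morphology

def _brute_erode(mask, kappa):
    h, w = mask.shape
    r = kappa // 2
    out = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            ok = True
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    y, x = i + di, j + dj
                    if not (0 <= y < h and 0 <= x < w) or not mask[y, x]:
                        ok = False
                        break
                if not ok:
                    break
            out[i, j] = ok
    return out


def _brute_dilate(mask, kappa):
    h, w = mask.shape
    r = kappa // 2
    out = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            hit = False
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    y, x = i + di, j + dj
                    if 0 <= y < h and 0 <= x < w and mask[y, x]:
                        hit = True
                        break
                if hit:
                    break
            out[i, j] = hit
    return out


def test_erosion_of_solid_block():
    mask = np.zeros((9, 9), bool)
    mask[2:7, 2:7] = True
    out = erode(mask, 3)
    expected = np.zeros_like(mask)
    expected[3:6, 3:6] = True
    assert (out == expected).all()


def test_dilation_of_solid_block():
    mask = np.zeros((9, 9), bool)
    mask[3:6, 3:6] = True
    out = dilate(mask, 3)
    expected = np.zeros_like(mask)
    expected[2:7, 2:7] = True
    assert (out == expected).all()


def test_kappa_one_is_identity(rng):
    mask = rng.random((12, 12)) < 0.4
    assert (erode(mask, 1) == mask).all()
    assert (dilate(mask, 1) == mask).all()


@pytest.mark.parametrize("op", [erode, dilate])
def test_even_kernel_rejected(op):
    with pytest.raises(ValueError):
        op(np.ones((4, 4), bool), 2)


def test_morphology_matches_brute_force_on_random_masks():
    rng = np.random.default_rng(77)
    for case in range(100):
        mask = rng.random((16, 16)) < rng.uniform(0.2, 0.8)
        kappa = int(rng.choice([3, 5]))
        assert (erode(mask, kappa) == _brute_erode(mask, kappa)).all()
        assert (dilate(mask, kappa) == _brute_dilate(mask, kappa)).all()


# ---------------------------------------------------------------------------
# region partitions

def test_partition_of_block_in_grid():
    inst = block_instance(5, 5, 5, 5)
    part = region_partition([inst], KernelPair(3, 7), (15, 15))
    assert part.core.sum() == 9
    assert part.soft_band.sum() == 72
    assert part.background.sum() == 15 * 15 - 81


def test_identity_kernels_reproduce_hard_labels():
    inst = block_instance(2, 3, 4, 6)
    part = region_partition([inst], KernelPair(1, 1), (20, 20))
    assert (part.core == inst.to_mask((20, 20))).all()
    assert part.soft_band.sum() == 0


def test_instance_eroded_away_becomes_pure_soft_band():
    inst = block_instance(5, 5, 2, 2)
    part = region_partition([inst], KernelPair(3, 7), (15, 15))
    assert part.core.sum() == 0
    assert part.soft_band.sum() == 4
    assert (part.soft_band == inst.to_mask((15, 15))).all()


def test_core_takes_priority_over_band_on_overlap():
    a = block_instance(2, 2, 8, 8, instance_id=1)
    b = block_instance(9, 2, 4, 8, instance_id=2)  # b sits in a's dilation zone
    part = region_partition([a, b], KernelPair(3, 7), (20, 20))
    b_core = erode(b.to_mask((20, 20)), 3)
    assert (part.core & b_core).sum() == b_core.sum()
    assert not (part.soft_band & part.core).any()


@given(st.integers(0, 2**31 - 1))
@settings(deadline=None, max_examples=25, derandomize=True)
def test_partition_is_disjoint_and_exhaustive(seed):
    rng = np.random.default_rng(seed)
    shape = (18, 18)
    instances = []
    for k in range(rng.integers(1, 4)):
        mask = rng.random(shape) < 0.2
        if mask.any():
            instances.append(InstanceAnnotation.from_mask(mask, "nucleus", k + 1))
    if not instances:
        return
    kappa_e = int(rng.choice([1, 3, 5]))
    part = region_partition(instances, KernelPair(kappa_e, kappa_e + 4), shape)
    total = part.core.astype(int) + part.soft_band.astype(int) \
        + part.background.astype(int)
    assert (total == 1).all()
    union = np.zeros(shape, bool)
    for inst in instances:
        union |= inst.to_mask(shape)
    assert not (part.core & ~union).any()  # core within annotations


def test_band_grows_with_dilation_kernel():
    inst = block_instance(8, 8, 9, 9)
    small = region_partition([inst], KernelPair(3, 5), (30, 30))
    large = region_partition([inst], KernelPair(3, 9), (30, 30))
    assert (small.soft_band & ~large.soft_band).sum() == 0


# ---------------------------------------------------------------------------
# weight maps and labels

def test_weight_map_tier_values(square_80_in_128):
    inst, shape = square_80_in_128
    part = region_partition([inst], KernelPair(3, 7), shape)
    w = weight_map(part)
    assert w[60, 60] == 2.0          # core
    assert w[20, 60] == 1.5          # outermost annotation row -> erosion band
    assert w[0, 0] == 1.0            # far background
    assert set(np.unique(w)) <= {1.0, 1.5, 2.0}


def test_weight_map_without_annotations_is_background():
    part = region_partition([], KernelPair(3, 7), (10, 10))
    w = weight_map(part, WeightParams(4.0, 2.0, 1.0))
    assert (w == 1.0).all()


def test_target_labels_per_class():
    a = block_instance(1, 1, 3, 3, class_label="nucleus", instance_id=1)
    b = block_instance(6, 6, 2, 2, class_label="her2", instance_id=2)
    labels = build_target_labels([a, b], (10, 10), {"nucleus": 1, "her2": 2})
    assert labels[2, 2] == 1 and labels[7, 7] == 2
    assert (labels == 0).sum() == 100 - 9 - 4


def test_cross_class_overlap_rejected():
    a = block_instance(1, 1, 4, 4, class_label="nucleus", instance_id=1)
    b = block_instance(3, 3, 4, 4, class_label="her2", instance_id=9)
    with pytest.raises(AnnotationError, match="9"):
        build_target_labels([a, b], (10, 10), {"nucleus": 1, "her2": 2})


# ---------------------------------------------------------------------------
# dataset-level softening

def test_soften_dataset_pools_the_median():
    imgs = {
        "a": [block_instance(0, 0, 4, 4, instance_id=1)],       # diag 3*sqrt2
        "b": [block_instance(0, 0, 6, 1, instance_id=1),        # diag 5
              block_instance(0, 0, 5, 4, instance_id=2)],       # diag 5
    }
    shapes = {"a": (10, 10), "b": (10, 10)}
    _, psi_star, _ = soften_dataset(imgs, shapes, {"nucleus": 1})
    assert psi_star == pytest.approx(5.0)


def test_soften_dataset_worked_example(square_80_in_128):
    inst, shape = square_80_in_128
    outputs, psi_star, kernels = soften_dataset(
        {"img": [inst]}, {"img": shape}, {"nucleus": 1})
    assert psi_star == pytest.approx(79 * np.sqrt(2), rel=1e-12)
    assert (kernels.kappa_e, kernels.kappa_d) == (3, 7)
    wmap, labels = outputs["img"]
    assert wmap[64, 64] == 2.0 and wmap[0, 0] == 1.0
    assert labels[64, 64] == 1


def test_soften_dataset_is_deterministic(square_80_in_128):
    inst, shape = square_80_in_128
    args = ({"img": [inst]}, {"img": shape}, {"nucleus": 1})
    out1, psi1, k1 = soften_dataset(*args)
    out2, psi2, k2 = soften_dataset(*args)
    assert psi1 == psi2 and k1 == k2
    assert (out1["img"][0] == out2["img"][0]).all()
    assert (out1["img"][1] == out2["img"][1]).all()


def test_soften_empty_dataset_raises():
    with pytest.raises(ValueError):
        soften_dataset({}, {}, {})
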