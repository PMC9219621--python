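"""Topographic region grower: equation ops, layer extraction, full runs."""

from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from mammocad.phantom import PhantomSpec, generate_roi
from mammocad.segmentation import (CONTINUE, STOP_CIRCULARITY, STOP_SIZE,
                                   SegmentationParams, boundary_contour,
                                   check_termination, circularity, dice,
                                   first_threshold, layer_contrast,
                                   layer_region, next_threshold,
                                   seed_intensity, segment_image,
                                   segment_lesion)


def bfs_flood_fill(image, seed, threshold, connectivity=8):
    """Independent brute-force oracle for layer_region (seed above threshold)."""
    h, w = image.shape
    if image[seed] < threshold:
        raise ValueError("oracle requires the seed to pass the threshold")
    if connectivity == 8:
        steps = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1),
                 (1, 0), (1, 1)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    mask = np.zeros((h, w), dtype=bool)
    mask[seed] = True
    q = deque([seed])
    while q:
        r, c = q.popleft()
        for dr, dc in steps:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc] \
                    and image[rr, cc] >= threshold:
                mask[rr, cc] = True
                q.append((rr, cc))
    return mask


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def test_seed_intensity_cases():
    uniform = np.full((9, 9), 100.0)
    assert seed_intensity(uniform, (4, 4), window=1) == 100.0
    img = np.zeros((5, 5))
    img[2, 2] = 55.0
    assert seed_intensity(img, (2, 2), window=0) == 55.0
    img2 = np.zeros((5, 5))
    img2[2, 3] = 200.0
    assert seed_intensity(img2, (2, 2), window=1) == 200.0
    with pytest.raises(ValueError):
        seed_intensity(img, (9, 0), window=1)


def test_threshold_recursions_match_stated_constants():
    assert first_threshold(100.0, 0.1) == pytest.approx(110.0)
    assert first_threshold(0.0, 0.1) == 0.0
    assert first_threshold(2048.0, 0.1) == pytest.approx(2252.8)
    assert next_threshold(110.0, -20.0, 0.5) == pytest.approx(100.0)
    assert next_threshold(87.0, 0.0, 0.5) == pytest.approx(87.0)
    assert next_threshold(100.0, -30.0, 0.5) == pytest.approx(85.0)


def test_boundary_contour_enumerations():
    full = np.ones((3, 3), dtype=bool)
    b = boundary_contour(full)
    assert b.sum() == 8 and not b[1, 1]
    single = np.zeros((4, 4), dtype=bool)
    single[2, 1] = True
    assert np.array_equal(boundary_contour(single), single)
    plus = np.zeros((5, 5), dtype=bool)
    plus[2, 1:4] = True
    plus[1:4, 2] = True
    b = boundary_contour(plus)
    # by the rule: every pixel with an exterior 4-neighbour; the centre has
    # all four neighbours inside the mask
    expected = plus.copy()
    expected[2, 2] = False
    assert np.array_equal(b, expected)
    with pytest.raises(ValueError):
        boundary_contour(np.zeros((3, 3), dtype=bool))


def test_layer_contrast_definition_and_oracle():
    uniform = np.full((6, 6), 42.0)
    mask = np.zeros((6, 6), dtype=bool)
    mask[1:5, 1:5] = True
    assert layer_contrast(uniform, mask) == 0.0

    img = np.full((5, 5), 100.0)
    img[2, 2] = 200.0
    mask3 = np.zeros((5, 5), dtype=bool)
    mask3[1:4, 1:4] = True
    assert layer_contrast(img, mask3) == pytest.approx(-100.0)

    rng = np.random.default_rng(3)
    patch = rng.uniform(0, 1000, (7, 7))
    yy, xx = np.mgrid[0:7, 0:7]
    disk = (yy - 3) ** 2 + (xx - 3) ** 2 <= 6
    b = boundary_contour(disk)
    interior = disk & ~b
    expected = patch[b].mean() - patch[interior].mean()
    assert layer_contrast(patch, disk) == pytest.approx(expected, abs=1e-12)


def test_circularity_disk_line_and_range():
    yy, xx = np.mgrid[0:61, 0:61]
    disk = (yy - 30) ** 2 + (xx - 30) ** 2 <= 20 ** 2
    assert circularity(disk) >= 0.98
    line = np.zeros((3, 120), dtype=bool)
    line[1, 10:110] = True
    assert circularity(line) < 0.3


@settings(derandomize=True, max_examples=50)
@given(st.integers(0, 2 ** 31 - 1))
def test_circularity_in_unit_interval(seed):
    rng = np.random.default_rng(seed)
    mask = rng.uniform(size=(12, 12)) < 0.4
    if not mask.any():
        mask[5, 5] = True
    v = circularity(mask)
    assert 0.0 < v <= 1.0


def test_check_termination_cases():
    p = SegmentationParams()
    assert check_termination(100, 350, 0.9, 0.9, p) == STOP_SIZE
    assert check_termination(100, 150, 0.8, 0.3, p) == STOP_CIRCULARITY
    assert check_termination(100, 150, 0.8, 0.7, p) == CONTINUE
    # size check evaluated first when both are violated
    assert check_termination(100, 500, 0.8, 0.1, p) == STOP_SIZE


# ---------------------------------------------------------------------------
# layer_region
# ---------------------------------------------------------------------------

def test_layer_region_two_level_disk():
    img = np.full((40, 40), 50.0)
    yy, xx = np.mgrid[0:40, 0:40]
    disk = (yy - 20) ** 2 + (xx - 20) ** 2 <= 100
    img[disk] = 200.0
    mask = layer_region(img, (20, 20), 100.0)
    assert np.array_equal(mask, disk)


def test_layer_region_threshold_above_maximum_returns_seed_singleton():
    img = np.random.default_rng(0).uniform(0, 100, (20, 20))
    mask = layer_region(img, (7, 9), threshold=1e9)
    assert mask.sum() == 1 and mask[7, 9]


def test_layer_region_never_leaks_to_disjoint_blob():
    img = np.full((40, 60), 10.0)
    yy, xx = np.mgrid[0:40, 0:60]
    blob_a = (yy - 20) ** 2 + (xx - 15) ** 2 <= 64
    blob_b = (yy - 20) ** 2 + (xx - 45) ** 2 <= 64
    img[blob_a] = 200.0
    img[blob_b] = 220.0
    mask = layer_region(img, (20, 15), 100.0)
    oracle = bfs_flood_fill(img, (20, 15), 100.0)
    assert np.array_equal(mask, oracle)
    assert not (mask & blob_b).any()


def test_layer_region_matches_bfs_on_random_images():
    rng = np.random.default_rng(11)
    for conn in (4, 8):
        for _ in range(60):
            img = rng.uniform(0, 255, (32, 32))
            seed = tuple(rng.integers(0, 32, 2))
            threshold = rng.uniform(0, img[seed])  # seed passes
            got = layer_region(img, seed, threshold, connectivity=conn)
            want = bfs_flood_fill(img, seed, threshold, connectivity=conn)
            assert np.array_equal(got, want)


# ---------------------------------------------------------------------------
# full segmentation
# ---------------------------------------------------------------------------

def noise_free_disk_roi(seed):
    spec = PhantomSpec(background_noise_sd=0.0,
                       margin_blur_sigma_range=(0.0, 0.0),
                       benign_elongation_range=(1.0, 1.0),
                       benign_radius_perturbation_amp=0.0,
                       edge_case_fraction=0.0)
    return generate_roi(spec, "benign", rng_seed=seed)


def test_noise_free_disk_dice():
    for seed in range(5):
        roi = noise_free_disk_roi(seed)
        seg = segment_lesion(roi)
        assert dice(seg.final_mask, roi.truth_mask) >= 0.85


def test_disjoint_disks_stay_separate():
    img = np.full((80, 80), 1000.0)
    yy, xx = np.mgrid[0:80, 0:80]
    a = (yy - 40) ** 2 + (xx - 20) ** 2 <= 100
    b = (yy - 40) ** 2 + (xx - 60) ** 2 <= 100
    img[a] += 2000.0
    img[b] += 2500.0
    seg = segment_image(img, (40, 20))
    assert seg.final_mask[40, 20]
    assert not (seg.final_mask & b).any()


def test_first_violation_returns_previous_layer():
    """Constructed three-plateau image: layer 1 is the 3x3 core, layer 2
    would more than triple it, so the core is the final region."""
    img = np.full((31, 31), 100.0)
    img[12:19, 12:19] = 238.0        # 7x7: becomes layer 2 (ratio 4.4 > 2)
    img[14:17, 14:17] = 245.0        # 3x3 ring: layer 1 (T1 = 260 - 16 = 244)
    img[15, 15] = 260.0              # gradient so C1 = 245 - 260 < 0
    params = SegmentationParams(min_region_size=1, seed_window=1)
    seg = segment_image(img, (15, 15), params)
    assert seg.termination_reason == "size_growth"
    expected = np.zeros_like(img, dtype=bool)
    expected[14:17, 14:17] = True
    assert np.array_equal(seg.final_mask, expected)


def test_no_growth_when_nothing_below_seed():
    img = np.full((21, 21), 100.0)
    img[10, 10] = 200.0
    params = SegmentationParams(min_region_size=1, seed_window=1)
    seg = segment_image(img, (10, 10), params)
    assert seg.final_mask.sum() == 1 and seg.final_mask[10, 10]
    assert seg.termination_reason == "no_growth"
    assert seg.singleton_fallback


def test_threshold_sequence_and_nesting_on_bright_phantom():
    spec = PhantomSpec(background_noise_sd=100.0, edge_case_fraction=0.0)
    roi = generate_roi(spec, "benign", rng_seed=8)
    seg = segment_lesion(roi)
    thresholds = [l.threshold_Tj for l in seg.layers]
    assert all(t2 <= t1 + 1e-9 for t1, t2 in zip(thresholds, thresholds[1:]))
    for prev, cur in zip(seg.layers, seg.layers[1:]):
        assert (prev.mask <= cur.mask).all()  # nested growth


def test_final_mask_contains_seed_and_is_connected(phantom_study):
    rois, segs = phantom_study
    structure = ndimage.generate_binary_structure(2, 2)
    for roi, seg in zip(rois[:40], segs[:40]):
        assert seg.final_mask.any()
        _, n = ndimage.label(seg.final_mask, structure=structure)
        assert n == 1
    # seed containment on low-noise phantoms, where the marked centre always
    # survives the first threshold
    spec = PhantomSpec(background_noise_sd=50.0, edge_case_fraction=0.0)
    for seed in range(10):
        roi = generate_roi(spec, "malignant", rng_seed=seed)
        seg = segment_lesion(roi)
        assert seg.final_mask[roi.seed_point]


def test_mirror_symmetry():
    spec = PhantomSpec(edge_case_fraction=0.0)
    roi = generate_roi(spec, "malignant", rng_seed=17)
    seg = segment_lesion(roi)
    flipped = roi.image[:, ::-1].copy()
    r, c = roi.seed_point
    seed_f = (r, roi.image.shape[1] - 1 - c)
    seg_f = segment_image(flipped, seed_f)
    assert np.array_equal(seg_f.final_mask, seg.final_mask[:, ::-1])


def test_padded_pixels_never_grown():
    spec = PhantomSpec(edge_case_fraction=1.0)
    for seed in range(5):
        roi = generate_roi(spec, "malignant", rng_seed=seed)
        seg = segment_lesion(roi)
        assert not (seg.final_mask & roi.padded_region).any()
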