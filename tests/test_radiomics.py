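"""Radiomics battery: per-category oracles, invariances, assembly contract."""

import numpy as np
import pytest
from scipy import stats
from skimage.draw import polygon
from skimage.morphology import convex_hull_image

from mammocad.phantom import PhantomSpec, generate_dataset
from mammocad.radiomics import (TRANSLATION_SENSITIVE, RadiomicsConfig,
                                default_schema, density_features, extract_all,
                                glcm_matrix, morphology_features,
                                texture_features, wavelet_features)
from mammocad.radiomics import _glcm_stats  # tested deliberately
from mammocad.segmentation import segment_lesion


def disk_mask(n=61, r=20):
    yy, xx = np.mgrid[0:n, 0:n]
    return (yy - n // 2) ** 2 + (xx - n // 2) ** 2 <= r * r


def star_mask(n=101, r_out=40, r_in=12, points=7):
    angles = np.linspace(0, 2 * np.pi, 2 * points, endpoint=False)
    radii = np.where(np.arange(2 * points) % 2 == 0, r_out, r_in)
    rr, cc = polygon(n // 2 + radii * np.sin(angles),
                     n // 2 + radii * np.cos(angles), (n, n))
    mask = np.zeros((n, n), dtype=bool)
    mask[rr, cc] = True
    return mask


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

def test_disk_is_round_and_convex():
    # hull pixelation costs O(1/r) in convexity, so use a generous radius
    f = morphology_features(disk_mask(101, 40))
    assert f["radial_cv"] < 0.05
    assert f["convexity"] >= 0.98
    assert f["circularity"] >= 0.98


def test_star_less_convex_than_its_hull():
    star = star_mask()
    hull = convex_hull_image(star)
    f_star = morphology_features(star)
    f_hull = morphology_features(hull)
    assert f_hull["convexity"] >= 0.98
    assert f_star["convexity"] < f_hull["convexity"]
    assert f_star["radial_cv"] > f_hull["radial_cv"]


def test_rotation_invariance_of_counting_features():
    mask = star_mask()
    rot = np.rot90(mask)
    a = morphology_features(mask)
    b = morphology_features(rot)
    for name in ("area", "circularity", "convexity"):
        assert a[name] == pytest.approx(b[name], abs=1e-9)
    for name in ("radial_mean", "radial_sd", "radial_max", "radial_cv"):
        assert a[name] == pytest.approx(b[name], abs=1e-6)


def test_morphology_rejects_empty_mask():
    with pytest.raises(ValueError):
        morphology_features(np.zeros((5, 5), dtype=bool))


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------

def test_density_uniform_image():
    img = np.full((40, 40), 500.0)
    f = density_features(img, disk_mask(40, 10))
    assert f["int_sd"] == 0.0
    assert f["boundary_contrast"] == 0.0
    assert f["int_skewness"] == 0.0


def test_density_boundary_contrast_forced_value():
    img = np.full((61, 61), 100.0)
    mask = disk_mask(61, 15)
    img[mask] = 200.0
    f = density_features(img, mask, band_width=5)
    assert f["boundary_contrast"] == pytest.approx(100.0)


def test_density_moments_match_direct_computation():
    rng = np.random.default_rng(5)
    img = rng.uniform(0, 4000, (61, 61))
    mask = disk_mask(61, 18)
    f = density_features(img, mask)
    vals = img[mask]
    assert f["int_skewness"] == pytest.approx(stats.skew(vals), rel=1e-12)
    assert f["int_kurtosis"] == pytest.approx(stats.kurtosis(vals), rel=1e-12)
    assert f["int_mean"] == pytest.approx(vals.mean(), rel=1e-12)


# ---------------------------------------------------------------------------
# texture
# ---------------------------------------------------------------------------

def test_glcm_constant_region():
    img = np.full((16, 16), 7.0)
    mask = np.ones((16, 16), dtype=bool)
    f = texture_features(img, mask, levels=8)
    assert f["glcm_d1_energy"] == pytest.approx(1.0)
    assert f["glcm_d1_contrast"] == 0.0
    assert f["glcm_d1_entropy"] == 0.0
    assert f["glcm_d1_correlation"] == 0.0  # degenerate convention


def test_glcm_checkerboard_enumerated_by_hand():
    """2-level checkerboard, offset (0,1): every horizontal pair is (0,1) or
    (1,0), so the symmetric GLCM is [[0,.5],[.5,0]]: contrast 1, energy 0.5."""
    img = np.indices((8, 8)).sum(axis=0) % 2
    m = glcm_matrix(img, levels=2, offset=(0, 1))
    assert np.allclose(m, [[0.0, 0.5], [0.5, 0.0]])
    s = _glcm_stats(m)
    assert s["contrast"] == pytest.approx(1.0)
    assert s["energy"] == pytest.approx(0.5)


def test_glcm_normalisation():
    rng = np.random.default_rng(2)
    img = rng.uniform(0, 100, (20, 20))
    m = glcm_matrix(img, levels=16, offset=(1, 1))
    assert m.sum() == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# wavelet
# ---------------------------------------------------------------------------

def test_wavelet_energy_fractions_sum_to_one():
    rng = np.random.default_rng(0)
    img = rng.normal(0, 1, (64, 64))
    f = wavelet_features(img)
    total = sum(v for k, v in f.items() if k.endswith("energy_frac"))
    assert total == pytest.approx(1.0, abs=1e-9)


def test_wavelet_constant_image_concentrates_in_approximation():
    f = wavelet_features(np.full((64, 64), 3.0))
    assert f["wav_a2_energy_frac"] == pytest.approx(1.0, abs=1e-9)
    assert f["wav_d1_energy_frac"] == pytest.approx(0.0, abs=1e-12)


def test_wavelet_parseval_on_white_noise():
    rng = np.random.default_rng(9)
    img = rng.normal(0, 1, (128, 128))
    import pywt

    coeffs = pywt.wavedec2(img, "db4", level=2, mode="periodization")
    total = float((coeffs[0] ** 2).sum()) + sum(
        float((c ** 2).sum()) for triple in coeffs[1:] for c in triple)
    assert total == pytest.approx(float((img ** 2).sum()), rel=1e-6)


def test_wavelet_rejects_tiny_image():
    with pytest.raises(ValueError):
        wavelet_features(np.ones((2, 2)), levels=2)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def test_extract_all_is_deterministic_and_schema_aligned(phantom_study):
    rois, segs = phantom_study
    schema = default_schema()
    a = extract_all(rois[0], segs[0])
    b = extract_all(rois[0], segs[0])
    assert np.array_equal(a.values, b.values)
    for roi, seg in zip(rois[:50], segs[:50]):
        fv = extract_all(roi, seg)
        assert len(fv.values) == len(schema)
        assert np.isfinite(fv.values).all()


def test_translation_invariance_except_documented_features(phantom_study):
    rois, segs = phantom_study
    roi, seg = rois[0], segs[0]
    schema = default_schema()
    base = extract_all(roi, seg).values
    shifted_roi = type(roi)(image=roi.image.astype(float) + 500.0,
                            seed_point=roi.seed_point, label=roi.label,
                            truth_mask=roi.truth_mask,
                            padded_region=roi.padded_region,
                            sample_id=roi.sample_id)
    shifted = extract_all(shifted_roi, seg).values
    for name, u, v in zip(schema.names, base, shifted):
        if name in TRANSLATION_SENSITIVE:
            continue
        assert u == pytest.approx(v, rel=1e-6, abs=1e-9), name


def test_mirror_invariance_of_orientation_agnostic_features(phantom_study):
    """Morphology, density and offset-averaged texture features are mirror
    invariant; wavelet subbands are orientation-sensitive by construction."""
    rois, segs = phantom_study
    roi, seg = rois[1], segs[1]
    schema = default_schema()
    base = extract_all(roi, seg).values
    mirrored_roi = type(roi)(image=roi.image[:, ::-1].copy(),
                             seed_point=(roi.seed_point[0],
                                         roi.image.shape[1] - 1 - roi.seed_point[1]),
                             label=roi.label,
                             truth_mask=roi.truth_mask[:, ::-1].copy(),
                             padded_region=roi.padded_region[:, ::-1].copy(),
                             sample_id=roi.sample_id)
    mirrored_seg = type(seg)(layers=seg.layers,
                             final_mask=seg.final_mask[:, ::-1].copy(),
                             final_layer_index=seg.final_layer_index,
                             termination_reason=seg.termination_reason,
                             seed_point=seg.seed_point, i_seed=seg.i_seed)
    mirrored = extract_all(mirrored_roi, mirrored_seg).values
    for name, u, v in zip(schema.names, base, mirrored):
        if schema.categories[name] == "wavelet":
            continue
        assert u == pytest.approx(v, rel=1e-6, abs=1e-6), name


def test_malignant_phantoms_have_higher_radial_cv():
    """Shape irregularity separates the classes: the radial-length CV on
    truth masks is stochastically larger for malignant lesions."""
    spec = PhantomSpec(edge_case_fraction=0.0)
    rois = generate_dataset(spec, 100, 100, rng_seed=31)
    cv = {"malignant": [], "benign": []}
    for roi in rois:
        cv[roi.label].append(morphology_features(roi.truth_mask)["radial_cv"])
    p = stats.mannwhitneyu(cv["malignant"], cv["benign"],
                           alternative="greater").pvalue
    assert p < 0.01
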