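"""Handcrafted radiomics feature battery for segmented mass lesions.

A fixed, versioned battery of ~50 named features spanning the five
characteristic groups classically used for mass classification: lesion
morphology, density heterogeneity, boundary contrast, grey-level
co-occurrence texture, and wavelet frequency-domain statistics.  Texture is
computed on the mask bounding box, wavelets on the whole ROI; both choices
are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage, stats
from skimage.measure import regionprops

from .segmentation import boundary_contour, circularity

log = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

GLCM_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))
GLCM_DISTANCES = (1, 3)
GLCM_LEVELS = 32
WAVELET = "db4"
WAVELET_LEVELS = 2
BAND_WIDTH = 5

_GLCM_STATS = ("energy", "contrast", "correlation", "homogeneity", "entropy")

MORPHOLOGY_NAMES = (
    "area", "perimeter", "circularity", "eccentricity", "compactness",
    "extent", "convexity", "equivalent_diameter",
    "radial_mean", "radial_sd", "radial_max", "radial_cv",
)
DENSITY_NAMES = (
    "int_mean", "int_sd", "int_skewness", "int_kurtosis", "int_entropy",
    "int_p10", "int_p90", "int_iqr", "boundary_contrast", "band_sd",
)
TEXTURE_NAMES = tuple(f"glcm_d{d}_{s}" for d in GLCM_DISTANCES
                      for s in _GLCM_STATS)
_SUBBANDS = ["a2", "h2", "v2", "d2", "h1", "v1", "d1"]
WAVELET_NAMES = tuple(f"wav_{sb}_{k}" for sb in _SUBBANDS
                      for k in ("energy_frac", "entropy"))

#: features whose value changes when a constant is added to the image
TRANSLATION_SENSITIVE = frozenset(
    {"int_mean", "int_p10", "int_p90"}
    | {f"wav_{sb}_energy_frac" for sb in _SUBBANDS}
    | {"wav_a2_entropy"}
)


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered, versioned feature name list with category mapping."""

    names: tuple[str, ...]
    categories: dict
    version: str = SCHEMA_VERSION

    def __len__(self) -> int:
        return len(self.names)


def default_schema() -> FeatureSchema:
    cats = {}
    for n in MORPHOLOGY_NAMES:
        cats[n] = "morphology"
    for n in DENSITY_NAMES:
        cats[n] = "density"
    for n in TEXTURE_NAMES:
        cats[n] = "texture"
    for n in WAVELET_NAMES:
        cats[n] = "wavelet"
    names = MORPHOLOGY_NAMES + DENSITY_NAMES + TEXTURE_NAMES + WAVELET_NAMES
    return FeatureSchema(names=names, categories=cats)


@dataclass
class FeatureVector:
    sample_id: str
    values: np.ndarray
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

def morphology_features(mask: np.ndarray) -> dict[str, float]:
    """Shape statistics of a connected binary lesion mask.

    Radial lengths are centroid-to-boundary distances; their coefficient of
    variation is a spiculation/irregularity proxy.  Convexity is the ratio of
    the mask area to its convex-hull area.
    """
    area = int(mask.sum())
    if area == 0:
        raise ValueError("empty mask")
    boundary = boundary_contour(mask)
    perimeter = int(boundary.sum())
    cy, cx = ndimage.center_of_mass(mask)
    by, bx = np.nonzero(boundary)
    radial = np.hypot(by - cy, bx - cx)
    r_mean = float(radial.mean())
    r_sd = float(radial.std())
    props = regionprops(mask.astype(np.uint8))[0]
    return {
        "area": float(area),
        "perimeter": float(perimeter),
        "circularity": circularity(mask),
        "eccentricity": float(props.eccentricity),
        "compactness": float(4.0 * np.pi * area / max(perimeter, 1) ** 2),
        "extent": float(props.extent),
        "convexity": float(area / props.area_convex),
        "equivalent_diameter": float(2.0 * np.sqrt(area / np.pi)),
        "radial_mean": r_mean,
        "radial_sd": r_sd,
        "radial_max": float(radial.max()),
        "radial_cv": float(r_sd / r_mean) if r_mean > 0 else 0.0,
    }


# ---------------------------------------------------------------------------
# density / boundary contrast
# ---------------------------------------------------------------------------

def density_features(image: np.ndarray, mask: np.ndarray,
                     band_width: int = BAND_WIDTH,
                     padded_region: np.ndarray | None = None
                     ) -> dict[str, float]:
    """First-order intensity statistics inside the lesion plus the contrast
    between the lesion interior and a morphological outer band."""
    if not mask.any():
        raise ValueError("empty mask")
    if band_width < 1:
        raise ValueError("band_width must be >= 1")
    image = np.asarray(image, dtype=float)
    vals = image[mask]
    sd = float(vals.std())
    hist, _ = np.histogram(vals, bins=32)
    p = hist[hist > 0] / hist.sum()
    entropy = float(-(p * np.log2(p)).sum())
    structure = ndimage.generate_binary_structure(2, 2)
    band = ndimage.binary_dilation(mask, structure, iterations=band_width) & ~mask
    if padded_region is not None:
        band &= ~padded_region
    if band.any():
        contrast = float(vals.mean() - image[band].mean())
        band_sd = float(image[band].std())
    else:
        log.warning("boundary band empty (fully padded/outside); contrast=0")
        contrast = 0.0
        band_sd = 0.0
    if sd > 0:
        skew = float(stats.skew(vals))
        kurt = float(stats.kurtosis(vals))
    else:
        skew = kurt = 0.0
    return {
        "int_mean": float(vals.mean()),
        "int_sd": sd,
        "int_skewness": skew,
        "int_kurtosis": kurt,
        "int_entropy": entropy,
        "int_p10": float(np.percentile(vals, 10)),
        "int_p90": float(np.percentile(vals, 90)),
        "int_iqr": float(np.percentile(vals, 75) - np.percentile(vals, 25)),
        "boundary_contrast": contrast,
        "band_sd": band_sd,
    }


# ---------------------------------------------------------------------------
# GLCM texture
# ---------------------------------------------------------------------------

def _glcm(quantised: np.ndarray, levels: int, offset: tuple[int, int]
          ) -> np.ndarray:
    """Symmetric, normalised grey-level co-occurrence matrix for one offset."""
    dr, dc = offset
    h, w = quantised.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = quantised[r0:r1, c0:c1].ravel()
    b = quantised[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    m = np.zeros((levels, levels))
    np.add.at(m, (a, b), 1.0)
    m = m + m.T
    total = m.sum()
    return m / total if total > 0 else m


def _glcm_stats(m: np.ndarray) -> dict[str, float]:
    levels = m.shape[0]
    i, j = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    energy = float((m ** 2).sum())
    contrast = float((m * (i - j) ** 2).sum())
    homogeneity = float((m / (1.0 + np.abs(i - j))).sum())
    nz = m[m > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    mu_i = (m * i).sum()
    mu_j = (m * j).sum()
    var_i = (m * (i - mu_i) ** 2).sum()
    var_j = (m * (j - mu_j) ** 2).sum()
    if var_i > 0 and var_j > 0:
        corr = float((m * (i - mu_i) * (j - mu_j)).sum() / np.sqrt(var_i * var_j))
    else:
        corr = 0.0  # degenerate (constant) region
    return {"energy": energy, "contrast": contrast, "correlation": corr,
            "homogeneity": homogeneity, "entropy": entropy}


def glcm_matrix(image: np.ndarray, levels: int = GLCM_LEVELS,
                offset: tuple[int, int] = (0, 1)) -> np.ndarray:
    """Quantise an image region and return one normalised symmetric GLCM."""
    q = _quantise(np.asarray(image, dtype=float), levels)
    return _glcm(q, levels, offset)


def _quantise(region: np.ndarray, levels: int) -> np.ndarray:
    lo, hi = region.min(), region.max()
    if hi <= lo:
        return np.zeros(region.shape, dtype=np.intp)
    q = ((region - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def texture_features(image: np.ndarray, mask: np.ndarray,
                     levels: int = GLCM_LEVELS,
                     offsets: tuple = GLCM_OFFSETS,
                     distances: tuple = GLCM_DISTANCES) -> dict[str, float]:
    """GLCM statistics on the mask bounding box, averaged over offsets."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if not mask.any():
        raise ValueError("empty mask")
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    region = np.asarray(image[r0:r1 + 1, c0:c1 + 1], dtype=float)
    q = _quantise(region, levels)
    out: dict[str, float] = {}
    for d in distances:
        acc = {s: 0.0 for s in _GLCM_STATS}
        for off in offsets:
            m = _glcm(q, levels, (off[0] * d, off[1] * d))
            for s, v in _glcm_stats(m).items():
                acc[s] += v
        for s in _GLCM_STATS:
            out[f"glcm_d{d}_{s}"] = acc[s] / len(offsets)
    return out


# ---------------------------------------------------------------------------
# wavelet frequency-domain
# ---------------------------------------------------------------------------

def wavelet_features(image: np.ndarray, levels: int = WAVELET_LEVELS,
                     wavelet: str = WAVELET) -> dict[str, float]:
    """Per-subband energy fractions and coefficient entropies.

    Uses an orthogonal decomposition in periodised mode, so the subband
    energies sum exactly to the image energy (Parseval).
    """
    image = np.asarray(image, dtype=float)
    if min(image.shape) < 2 ** levels:
        raise ValueError("image too small for requested decomposition depth")
    coeffs = pywt.wavedec2(image, wavelet, level=levels, mode="periodization")
    bands = {f"a{levels}": coeffs[0]}
    for lev, (ch, cv, cd) in zip(range(levels, 0, -1), coeffs[1:]):
        bands[f"h{lev}"] = ch
        bands[f"v{lev}"] = cv
        bands[f"d{lev}"] = cd
    energies = {k: float((v ** 2).sum()) for k, v in bands.items()}
    total = sum(energies.values())
    out = {}
    for k, v in bands.items():
        out[f"wav_{k}_energy_frac"] = energies[k] / total if total > 0 else 0.0
        e = v.ravel() ** 2
        s = e.sum()
        if s > 0:
            p = e[e > 0] / s
            out[f"wav_{k}_entropy"] = float(-(p * np.log2(p)).sum())
        else:
            out[f"wav_{k}_entropy"] = 0.0
    return out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RadiomicsConfig:
    band_width: int = BAND_WIDTH
    glcm_levels: int = GLCM_LEVELS
    glcm_offsets: tuple = GLCM_OFFSETS
    glcm_distances: tuple = GLCM_DISTANCES
    wavelet: str = WAVELET
    wavelet_levels: int = WAVELET_LEVELS
    texture_on_mask_bbox: bool = True
    wavelet_on_whole_roi: bool = True


def extract_all(roi, seg, config: RadiomicsConfig = RadiomicsConfig(),
                schema: FeatureSchema | None = None) -> FeatureVector:
    """Concatenate the four category extractors in schema order.

    Non-finite values are replaced by 0 and logged.  Deterministic.
    """
    if schema is None:
        schema = default_schema()
    mask = seg.final_mask
    if not mask.any():
        raise ValueError("segmentation produced an empty mask")
    image = np.asarray(roi.image, dtype=float)
    values = {}
    values.update(morphology_features(mask))
    values.update(density_features(image, mask, config.band_width,
                                   getattr(roi, "padded_region", None)))
    values.update(texture_features(image, mask, config.glcm_levels,
                                   config.glcm_offsets, config.glcm_distances))
    if config.wavelet_on_whole_roi:
        wav_img = image
    else:
        rows = np.any(mask, axis=1)
        cols = np.any(mask, axis=0)
        r0, r1 = np.flatnonzero(rows)[[0, -1]]
        c0, c1 = np.flatnonzero(cols)[[0, -1]]
        wav_img = image[r0:r1 + 1, c0:c1 + 1]
    values.update(wavelet_features(wav_img, config.wavelet_levels,
                                   config.wavelet))
    missing = set(schema.names) - set(values)
    if missing:
        raise ValueError(f"schema mismatch, missing features: {sorted(missing)}")
    vec = np.array([values[n] for n in schema.names], dtype=float)
    bad = ~np.isfinite(vec)
    if bad.any():
        log.warning("non-finite features replaced by 0: %s",
                    [schema.names[i] for i in np.flatnonzero(bad)])
        vec[bad] = 0.0
    return FeatureVector(sample_id=getattr(roi, "sample_id", ""), values=vec,
                         schema_version=schema.version)


def extract_dataset(rois, segs, config: RadiomicsConfig = RadiomicsConfig()):
    """Feature matrix as a DataFrame indexed by sample_id, plus labels."""
    import pandas as pd

    schema = default_schema()
    rows = []
    labels = []
    ids = []
    for roi, seg in zip(rois, segs):
        fv = extract_all(roi, seg, config, schema)
        rows.append(fv.values)
        labels.append(roi.label)
        ids.append(roi.sample_id)
    df = pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="sample_id"),
                      columns=list(schema.names))
    return df, pd.Series(labels, index=df.index, name="label")
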