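"""Adaptive multi-layer topographic region growing for mass lesions.

The segmenter grows a lesion from a marked seed point layer by layer, like a
descending contour level.  Each topographic layer j has an adaptive threshold
T_j: the first threshold is placed a fraction alpha of the available intensity
headroom above the seed, and every subsequent threshold moves by beta times
the previous layer's region contrast C_{j-1} (boundary mean minus interior
mean).  For a bright lesion the boundary is darker than the interior, C < 0,
and the threshold descends so the region grows outward.  Growth stops when a
new layer either more than triples the region area (size-growth ratio > 2.0)
or halves its circularity (circularity-reduction ratio > 0.5); the previous
layer is then the final lesion region.

The threshold recursions operate on inverted intensities internally (lesion
cores are intensity minima there), which is the reading under which the
additive first-threshold step, the signed-contrast update and the two
termination ratios form a growing sequence; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

CONTINUE = "continue"
STOP_SIZE = "stop_size"
STOP_CIRCULARITY = "stop_circularity"

TERM_SIZE = "size_growth"
TERM_CIRC = "circularity_reduction"
TERM_MAX = "max_layers"
TERM_NOGROWTH = "no_growth"


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the topographic grower.

    alpha and beta are the two pre-set coefficients of the threshold
    recursions; size_growth_limit and circularity_reduction_limit are the two
    termination ratios.  All four defaults are the published operating point.
    """

    alpha: float = 0.1
    beta: float = 0.5
    size_growth_limit: float = 2.0
    circularity_reduction_limit: float = 0.5
    connectivity: int = 8
    max_layers: int = 20
    seed_window: int = 3
    min_region_size: int = 300
    max_region_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        if self.size_growth_limit <= 0 or self.circularity_reduction_limit <= 0:
            raise ValueError("termination limits must be > 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.max_layers < 1:
            raise ValueError("max_layers must be >= 1")
        if self.seed_window < 0:
            raise ValueError("seed_window must be >= 0")
        if self.min_region_size < 1:
            raise ValueError("min_region_size must be >= 1")
        if not 0.0 < self.max_region_fraction <= 1.0:
            raise ValueError("max_region_fraction must be in (0, 1]")


@dataclass
class TopographicLayer:
    index_j: int
    threshold_Tj: float
    mask: np.ndarray
    area_Sj: int
    circularity_Vj: float
    contrast_Cj: float
    boundary: set = field(default_factory=set)


@dataclass
class SegmentationResult:
    layers: list[TopographicLayer]
    final_mask: np.ndarray
    final_layer_index: int
    termination_reason: str
    seed_point: tuple[int, int]
    i_seed: float
    singleton_fallback: bool = False  # flagged so callers can reject/skip


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def seed_intensity(image: np.ndarray, seed_point: tuple[int, int],
                   window: int) -> float:
    """Robust seed intensity: maximum over the (2w+1)^2 neighbourhood."""
    r, c = seed_point
    h, w = image.shape
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError("seed point out of bounds")
    r0, r1 = max(0, r - window), min(h, r + window + 1)
    c0, c1 = max(0, c - window), min(w, c + window + 1)
    return float(np.max(image[r0:r1, c0:c1]))


def first_threshold(i_seed: float, alpha: float) -> float:
    """T1 = Iseed + alpha * Iseed."""
    if i_seed < 0:
        raise ValueError("i_seed must be >= 0")
    return i_seed * (1.0 + alpha)


def next_threshold(t_prev: float, c_prev: float, beta: float) -> float:
    """Tj = T(j-1) + beta * C(j-1); C is signed."""
    return t_prev + beta * c_prev


def layer_region(image: np.ndarray, seed_point: tuple[int, int],
                 threshold: float, connectivity: int = 8,
                 seed_window: int = 3) -> np.ndarray:
    """Connected component of {intensity >= threshold} containing the seed.

    If the seed pixel itself fails the threshold, the component nearest to
    the seed among those intersecting its seed-window neighbourhood is
    returned; if none exists, the singleton {seed}.
    """
    r, c = seed_point
    h, w = image.shape
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError("seed point out of bounds")
    above = image >= threshold
    labels, n = ndimage.label(above, structure=_structure(connectivity))
    if labels[r, c] != 0:
        return labels == labels[r, c]
    singleton = np.zeros_like(above)
    singleton[r, c] = True
    if n == 0:
        return singleton
    r0, r1 = max(0, r - seed_window), min(h, r + seed_window + 1)
    c0, c1 = max(0, c - seed_window), min(w, c + seed_window + 1)
    near = np.unique(labels[r0:r1, c0:c1])
    near = near[near != 0]
    if len(near) == 0:
        return singleton
    best, best_d = None, np.inf
    for lab in near:
        idx = np.argwhere(labels == lab)
        d = np.min(np.hypot(idx[:, 0] - r, idx[:, 1] - c))
        if d < best_d:
            best, best_d = lab, d
    return labels == best


def boundary_contour(mask: np.ndarray) -> np.ndarray:
    """Inner boundary: mask pixels with a 4-neighbour outside the mask.

    Pixels on the array border count as boundary.  Returns a boolean mask.
    """
    if not mask.any():
        raise ValueError("empty mask")
    interior = ndimage.binary_erosion(
        mask, structure=_structure(4), border_value=0)
    return mask & ~interior


def layer_contrast(image: np.ndarray, mask: np.ndarray) -> float:
    """Region contrast C: boundary mean minus interior mean (signed).

    A bright lesion with a darker rim has C <= 0.  If the mask has no
    interior (every pixel is boundary), C is 0 by convention.
    """
    if not mask.any():
        raise ValueError("empty mask")
    boundary = boundary_contour(mask)
    interior = mask & ~boundary
    if not interior.any():
        return 0.0
    return float(image[boundary].mean() - image[interior].mean())


def circularity(mask: np.ndarray) -> float:
    """Overlap of the mask with its equivalent-area disk, in (0, 1].

    V = |mask intersect E| / |mask| where E is the disk of equal area centred
    at the mask centroid.  A centred disk scores ~1 (pixelation tolerance);
    elongated or star-shaped regions score low.
    """
    area = int(mask.sum())
    if area == 0:
        raise ValueError("empty mask")
    cy, cx = ndimage.center_of_mass(mask)
    r_eq = np.sqrt(area / np.pi)
    yy, xx = np.ogrid[0:mask.shape[0], 0:mask.shape[1]]
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_eq ** 2
    return float((mask & disk).sum() / area)


def check_termination(s_prev: int, s_j: int, v_prev: float, v_j: float,
                      params: SegmentationParams) -> str:
    """Apply the two growth-termination ratios; size check first."""
    if s_prev < 1 or v_prev <= 0:
        raise ValueError("previous layer must have area >= 1 and V > 0")
    if (s_j - s_prev) / s_prev > params.size_growth_limit:
        return STOP_SIZE
    if abs(v_prev - v_j) / v_prev > params.circularity_reduction_limit:
        return STOP_CIRCULARITY
    return CONTINUE


def _make_layer(image: np.ndarray, mask: np.ndarray, j: int,
                threshold: float) -> TopographicLayer:
    boundary = boundary_contour(mask)
    return TopographicLayer(
        index_j=j, threshold_Tj=float(threshold), mask=mask,
        area_Sj=int(mask.sum()), circularity_Vj=circularity(mask),
        contrast_Cj=layer_contrast(image, mask),
        boundary=set(map(tuple, np.argwhere(boundary))))


def segment_image(image: np.ndarray, seed_point: tuple[int, int],
                  params: SegmentationParams = SegmentationParams(),
                  padded_region: Optional[np.ndarray] = None
                  ) -> SegmentationResult:
    """Run the full multi-layer topographic grower on one image.

    Zero-padded pixels are excluded from growth.  Layer 1 is accepted
    unconditionally (it has no predecessor); the termination ratios are
    evaluated from layer 2 on, and on the first violation the previous layer
    is the final lesion region.
    """
    image = np.asarray(image, dtype=float)
    work = image.copy()
    if padded_region is not None and padded_region.any():
        work[padded_region] = -np.inf

    i_seed = seed_intensity(work, seed_point, params.seed_window)
    # effective growth seed: the brightest pixel in the seed window, so that
    # the first layer reliably starts at the lesion core even when the marked
    # centre pixel itself sits just below T1
    r, c = seed_point
    h, w = work.shape
    r0, c0 = max(0, r - params.seed_window), max(0, c - params.seed_window)
    win = work[r0:min(h, r + params.seed_window + 1),
               c0:min(w, c + params.seed_window + 1)]
    dr, dc = np.unravel_index(int(np.argmax(win)), win.shape)
    grow_seed = (r0 + dr, c0 + dc)
    # Threshold recursion in inverted intensity space: with I' = M - I the
    # lesion core is an intensity minimum, T1' = (1+alpha) * I'_seed, and the
    # update T_j = T_{j-1} + beta * C_{j-1} is form-invariant under the
    # inversion.  The reference M is placed so that the seed's inverted value
    # equals its prominence over the background (global median): the first
    # threshold then descends by alpha times the seed prominence instead of
    # by a fraction of an arbitrary detector offset.
    finite = work[np.isfinite(work)]
    growable = finite.size
    prominence = max(i_seed - float(np.median(finite)), 0.0)
    ref = i_seed + prominence
    t = ref - first_threshold(ref - i_seed, params.alpha)

    layers: list[TopographicLayer] = []
    reason = TERM_MAX
    for j in range(1, params.max_layers + 1):
        if j > 1:
            t = next_threshold(t, layers[-1].contrast_Cj, params.beta)
        mask = layer_region(work, grow_seed, t, params.connectivity,
                            params.seed_window)
        layer = _make_layer(image, mask, j, t)
        # flood guard: a mass lesion cannot plausibly cover most of the ROI;
        # a layer this large means the grower has leaked into background that
        # happens to expand with a sub-critical ratio each step
        if layers and layer.area_Sj > params.max_region_fraction * growable:
            reason = TERM_SIZE
            break
        if layers:
            prev = layers[-1]
            if np.array_equal(mask, prev.mask):
                layers.append(layer)
                reason = TERM_NOGROWTH
                break
            # the growth-ratio tests are statistically meaningless on
            # noise-island regions of a few dozen pixels; defer them until
            # the previous layer has a substantive area
            if prev.area_Sj < params.min_region_size:
                verdict = CONTINUE
            else:
                verdict = check_termination(prev.area_Sj, layer.area_Sj,
                                            prev.circularity_Vj,
                                            layer.circularity_Vj, params)
            if verdict == STOP_SIZE:
                reason = TERM_SIZE
                break
            if verdict == STOP_CIRCULARITY:
                reason = TERM_CIRC
                break
        layers.append(layer)

    final = layers[-1]
    return SegmentationResult(
        layers=layers, final_mask=final.mask,
        final_layer_index=len(layers) - 1, termination_reason=reason,
        seed_point=tuple(seed_point), i_seed=i_seed,
        singleton_fallback=final.area_Sj == 1)


def segment_lesion(roi, params: SegmentationParams = SegmentationParams()
                   ) -> SegmentationResult:
    """Segment a LesionROI (honours its zero-padded region)."""
    return segment_image(roi.image, roi.seed_point, params,
                         padded_region=roi.padded_region)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap coefficient between two binary masks."""
    inter = np.logical_and(mask_a, mask_b).sum()
    denom = mask_a.sum() + mask_b.sum()
    return float(2.0 * inter / denom) if denom else 0.0
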