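"""Synthetic mammogram-like lesion ROI phantoms.

Generates 150x150 grayscale patches that emulate the statistical structure of
mass-lesion regions of interest cut from processed full-field digital
mammograms: a bright soft-tissue mass on correlated parenchymal clutter, with
a radiologist-style seed point at the lesion centre and a known ground-truth
mask.  Benign lesions are near-elliptical with smooth margins; malignant
lesions carry a star-shaped boundary perturbation plus thin radial spicules.
A configurable fraction of lesions sits against a zero-padded band, emulating
patches extracted near the edge of the original image.

Polarity convention (fixed for the whole package): lesions are BRIGHTER than
the background, as in processed, display-oriented FFDM.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from scipy.ndimage import gaussian_filter

MALIGNANT = "malignant"
BENIGN = "benign"
LABELS = (MALIGNANT, BENIGN)


class PhantomSpecError(ValueError):
    """Raised when a PhantomSpec field is invalid; names the offending field."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the phantom population.

    Intensities are in raw display units of a ``bit_depth``-bit image; lengths
    are in pixels (0.35 mm at the emulated subsampled scale).
    """

    patch_size: int = 150
    background_mean: float = 8000.0
    background_noise_sd: float = 300.0
    background_correlation_sigma: float = 3.0
    lesion_radius_range: tuple[float, float] = (12.0, 30.0)
    lesion_contrast_range: tuple[float, float] = (1200.0, 3200.0)
    margin_blur_sigma_range: tuple[float, float] = (0.5, 2.5)
    n_spicules_range: tuple[int, int] = (4, 10)
    radius_perturbation_amp: float = 0.25
    benign_radius_perturbation_amp: float = 0.03
    benign_elongation_range: tuple[float, float] = (1.0, 1.3)
    spicule_contrast_fraction: float = 0.6
    spicule_length_fraction: float = 1.8
    spicule_width_sigma: float = 1.2
    core_taper: float = 0.25
    skirt_width_fraction: float = 0.15
    edge_case_fraction: float = 0.05
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.patch_size <= 0:
            raise PhantomSpecError("patch_size must be > 0")
        if self.bit_depth <= 0:
            raise PhantomSpecError("bit_depth must be > 0")
        if self.background_mean < 0:
            raise PhantomSpecError("background_mean must be >= 0")
        if self.background_noise_sd < 0:
            raise PhantomSpecError("background_noise_sd must be >= 0")
        for name in ("lesion_radius_range", "lesion_contrast_range",
                     "margin_blur_sigma_range", "benign_elongation_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise PhantomSpecError(f"{name} must be (low, high) with low <= high")
        if self.lesion_contrast_range[0] <= 0:
            raise PhantomSpecError(
                "lesion_contrast_range must be positive (lesions are brighter "
                "than background)")
        if self.lesion_radius_range[0] <= 0:
            raise PhantomSpecError("lesion_radius_range must be positive")
        lo, hi = self.n_spicules_range
        if lo < 0 or lo > hi:
            raise PhantomSpecError("n_spicules_range must be (low, high), low >= 0")
        if not 0.0 <= self.edge_case_fraction <= 1.0:
            raise PhantomSpecError("edge_case_fraction must be in [0, 1]")
        if self.radius_perturbation_amp < 0:
            raise PhantomSpecError("radius_perturbation_amp must be >= 0")
        if self.skirt_width_fraction <= 0:
            raise PhantomSpecError("skirt_width_fraction must be > 0")
        if not 0.0 <= self.core_taper < 0.5:
            raise PhantomSpecError("core_taper must be in [0, 0.5)")

    @property
    def intensity_max(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass
class LesionROI:
    """One grayscale patch with seed point, label and optional truth.

    Coordinates are (row, col), 0-based, origin at the top-left corner.
    Padded pixels (outside the emulated original image) are exactly 0.
    """

    image: np.ndarray
    seed_point: tuple[int, int]
    label: str
    truth_mask: Optional[np.ndarray] = None
    padded_region: Optional[np.ndarray] = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        r, c = self.seed_point
        h, w = self.image.shape
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError("seed_point outside image bounds")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        if self.truth_mask is not None and not self.truth_mask[r, c]:
            raise ValueError("seed_point not inside truth_mask")


def _radius_profile(theta: np.ndarray, base_radius: float, elongation: float,
                    orient: float, amp: float, harmonics: np.ndarray,
                    phases: np.ndarray) -> np.ndarray:
    """Angular radius R(theta) of the lesion core: ellipse x star perturbation."""
    ct = np.cos(theta - orient)
    st = np.sin(theta - orient)
    # ellipse with semi-axes a = base*sqrt(e), b = base/sqrt(e): area preserved
    a = base_radius * np.sqrt(elongation)
    b = base_radius / np.sqrt(elongation)
    r_ell = (a * b) / np.sqrt((b * ct) ** 2 + (a * st) ** 2)
    pert = np.zeros_like(theta)
    for k, (h, ph) in enumerate(zip(harmonics, phases)):
        pert += np.cos(h * theta + ph)
    if len(harmonics):
        pert /= np.sqrt(len(harmonics))
    return r_ell * (1.0 + amp * pert)


def _lesion_profile(spec: PhantomSpec, label: str, rng: np.random.Generator,
                    shape: tuple[int, int], centre: tuple[float, float],
                    radius: float) -> tuple[np.ndarray, float]:
    """Noiseless, unblurred lesion profile in [0, 1] (1 = core contrast)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dy = yy - centre[0]
    dx = xx - centre[1]
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    orient = rng.uniform(0, np.pi)
    if label == MALIGNANT:
        elong = 1.0
        amp = spec.radius_perturbation_amp
        harmonics = rng.integers(3, 9, size=4)
        n_spic = int(rng.integers(spec.n_spicules_range[0],
                                  spec.n_spicules_range[1] + 1))
    else:
        elong = rng.uniform(*spec.benign_elongation_range)
        amp = spec.benign_radius_perturbation_amp
        harmonics = rng.integers(2, 5, size=2)
        n_spic = 0
    phases = rng.uniform(0, 2 * np.pi, size=len(harmonics))
    r_core = _radius_profile(theta, radius, elong, orient, amp, harmonics, phases)

    # parabolic dome over the core (peak 1 at the centre, 1 - taper at the
    # core edge) followed by a raised-cosine skirt down to 0; the dome gives
    # the mass a radial intensity gradient so threshold descent crosses the
    # core gradually instead of all at once
    skirt = spec.skirt_width_fraction
    taper = spec.core_taper
    u = (r - r_core) / (r_core * skirt)
    dome = 1.0 - taper * np.clip(r / r_core, 0.0, 1.0) ** 2
    shoulder = (1.0 - taper) * 0.5 * (1.0 + np.cos(np.pi * np.clip(u, 0.0, 1.0)))
    profile = np.where(u <= 0, dome, np.where(u >= 1, 0.0, shoulder))

    # thin radial ridges of decaying contrast (malignant only)
    if n_spic:
        spic = np.zeros(shape)
        angles = rng.uniform(0, 2 * np.pi, size=n_spic)
        lengths = radius * spec.spicule_length_fraction * rng.uniform(
            0.7, 1.0, size=n_spic)
        for ang, length in zip(angles, lengths):
            dtheta = np.angle(np.exp(1j * (theta - ang)))
            perp = np.abs(r * np.sin(dtheta))  # distance to the ray
            along = r * np.cos(dtheta)
            ridge = (spec.spicule_contrast_fraction
                     * np.exp(-0.5 * (perp / spec.spicule_width_sigma) ** 2)
                     * np.clip(1.0 - along / length, 0.0, 1.0)
                     * (along > 0))
            spic = np.maximum(spic, ridge)
        profile = np.maximum(profile, spic)
    return profile, float(np.max(r_core))


def generate_roi(spec: PhantomSpec, label: str, rng_seed: int) -> LesionROI:
    """Generate one phantom ROI; bit-identical for identical arguments.

    The truth mask is the set of pixels where the noiseless (margin-blurred)
    lesion profile exceeds half the core contrast.
    """
    spec.validate()
    if label not in LABELS:
        raise PhantomSpecError(f"label must be one of {LABELS}")
    rng = np.random.default_rng(rng_seed)
    n = spec.patch_size
    radius = rng.uniform(*spec.lesion_radius_range)
    contrast = rng.uniform(*spec.lesion_contrast_range)
    blur = rng.uniform(*spec.margin_blur_sigma_range)

    edge_case = rng.uniform() < spec.edge_case_fraction
    pad_band = np.zeros((n, n), dtype=bool)
    if edge_case:
        side = int(rng.integers(0, 4))
        band_width = int(rng.integers(3, max(4, int(0.25 * n))))
        offset = rng.uniform(1.0, max(2.0, radius))  # centre within one radius
        pos = band_width + offset
        span = rng.uniform(0.35 * n, 0.65 * n)
        if side == 0:
            centre = (pos, span)
            pad_band[:band_width, :] = True
        elif side == 1:
            centre = (n - 1 - pos, span)
            pad_band[n - band_width:, :] = True
        elif side == 2:
            centre = (span, pos)
            pad_band[:, :band_width] = True
        else:
            centre = (span, n - 1 - pos)
            pad_band[:, n - band_width:] = True
    else:
        lo, hi = 0.30 * n, 0.70 * n
        centre = (rng.uniform(lo, hi), rng.uniform(lo, hi))

    profile, _ = _lesion_profile(spec, label, rng, (n, n), centre, radius)
    if blur > 0.05:
        profile = gaussian_filter(profile, sigma=blur, mode="constant")

    noise = rng.standard_normal((n, n))
    if spec.background_correlation_sigma > 0:
        noise = gaussian_filter(noise, sigma=spec.background_correlation_sigma,
                                mode="reflect")
        sd = noise.std()
        if sd > 0:
            noise /= sd
    image = spec.background_mean + spec.background_noise_sd * noise
    image = image + contrast * profile

    truth = profile > 0.5
    seed = (int(round(centre[0])), int(round(centre[1])))
    seed = (min(max(seed[0], 0), n - 1), min(max(seed[1], 0), n - 1))
    if not truth[seed]:
        # heavy blur can thin the profile; fall back to the truth-mask pixel
        # nearest to the nominal centre
        idx = np.argwhere(truth)
        if len(idx) == 0:
            truth[seed] = True
        else:
            d = np.hypot(idx[:, 0] - centre[0], idx[:, 1] - centre[1])
            seed = tuple(int(v) for v in idx[np.argmin(d)])

    image = np.clip(np.round(image), 0, spec.intensity_max).astype(np.uint16)
    if edge_case:
        image[pad_band] = 0
        truth &= ~pad_band
        if not truth[seed]:
            idx = np.argwhere(truth)
            d = np.hypot(idx[:, 0] - seed[0], idx[:, 1] - seed[1])
            seed = tuple(int(v) for v in idx[np.argmin(d)])

    return LesionROI(image=image, seed_point=seed, label=label,
                     truth_mask=truth, padded_region=pad_band,
                     sample_id="")


def generate_dataset(spec: PhantomSpec, n_malignant: int, n_benign: int,
                     rng_seed: int, id_prefix: str = "roi") -> list[LesionROI]:
    """Generate a labelled phantom dataset with reproducible per-sample seeds."""
    if n_malignant < 0 or n_benign < 0:
        raise ValueError("counts must be >= 0")
    spec.validate()
    ss = np.random.SeedSequence(rng_seed)
    children = ss.generate_state(n_malignant + n_benign) % (2 ** 31)
    rois: list[LesionROI] = []
    labels = [MALIGNANT] * n_malignant + [BENIGN] * n_benign
    for i, (label, child) in enumerate(zip(labels, children)):
        roi = generate_roi(spec, label, int(child))
        roi.sample_id = f"{id_prefix}_{label[:3]}_{i:04d}"
        rois.append(roi)
    return rois


# ---------------------------------------------------------------------------
# I/O: 16-bit TIFF images, 8-bit PNG masks, manifest CSV keyed by sample_id
# ---------------------------------------------------------------------------

def write_dataset(rois: Sequence[LesionROI], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for roi in rois:
        img_path = out / "images" / f"{roi.sample_id}.tif"
        tifffile.imwrite(img_path, roi.image)
        mask_path = ""
        if roi.truth_mask is not None:
            mask_path = str(Path("masks") / f"{roi.sample_id}.png")
            Image.fromarray((roi.truth_mask * 255).astype(np.uint8)).save(
                out / mask_path)
        rows.append({"sample_id": roi.sample_id,
                     "path": str(Path("images") / f"{roi.sample_id}.tif"),
                     "mask_path": mask_path,
                     "seed_row": roi.seed_point[0],
                     "seed_col": roi.seed_point[1],
                     "label": roi.label})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dataset(manifest_path: str | Path) -> list[LesionROI]:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path, keep_default_na=False)
    rois = []
    for row in df.itertuples(index=False):
        image = tifffile.imread(base / row.path)
        truth = None
        if row.mask_path:
            truth = np.asarray(Image.open(base / row.mask_path)) > 0
        padded = image == 0
        # a padded band is a full-width/height strip of exact zeros; isolated
        # zero pixels elsewhere are data
        rows_all = padded.all(axis=1)
        cols_all = padded.all(axis=0)
        band = np.zeros_like(padded)
        band[rows_all, :] = True
        band[:, cols_all] = True
        rois.append(LesionROI(image=image,
                              seed_point=(int(row.seed_row), int(row.seed_col)),
                              label=row.label, truth_mask=truth,
                              padded_region=band, sample_id=row.sample_id))
    return rois
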