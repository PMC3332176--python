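"""Deterministic generator of dermoscopy-like RGB images with exact masks.

Real dermoscopic lesion photographs show an irregular, darker pigmented
region on lighter skin.  The generator emulates that: an elliptical lesion
whose radius is modulated by a low-order random Fourier series (irregular
border), a radially graded interior (darker core), a slight zero-mean color
tint (browner lesion), and additive per-pixel Gaussian noise.  The binary
mask is the exact pre-noise region, so every fixture has a known ground
truth and, in the noiseless limit, thresholding at the contrast midpoint
recovers the mask exactly.

All randomness flows from one seed through numpy's PCG64 generator
(``numpy.random.default_rng``), so fixtures are bit-reproducible across
platforms.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

__all__ = ["LesionSpec", "generate", "generate_suite", "two_region_image"]

#: Radial grading amplitude relative to the contrast (kept < 0.5 so the
#: darkest-to-lightest lesion pixel stays below the midpoint threshold).
_GRADE_GAIN = 0.6


@dataclass(frozen=True)
class LesionSpec:
    """Parameters of one synthetic lesion image.

    contrast is the mean intensity gap (gray levels) between skin and lesion;
    noise_sigma the per-pixel Gaussian noise scale; irregularity the relative
    amplitude of the Fourier boundary perturbation.  The default 128 x 128
    size keeps runs fast; 600 x 600 matches full-resolution dermoscopy
    photographs.
    """

    size: tuple[int, int] = (128, 128)
    skin_rgb: tuple[float, float, float] = (210.0, 176.0, 150.0)
    lesion_tint: tuple[float, float, float] = (-9.0, 1.0, 8.0)  # zero-mean
    contrast: float = 60.0
    noise_sigma: float = 10.0
    irregularity: float = 0.25
    axes: tuple[float, float] = (0.30, 0.22)  # semi-axes as fractions of size
    center: tuple[float, float] = (0.5, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contrast <= 0:
            raise ValueError("contrast must be positive")
        if self.noise_sigma < 0 or self.irregularity < 0:
            raise ValueError("noise_sigma and irregularity must be nonnegative")
        if abs(sum(self.lesion_tint)) > 1e-9:
            raise ValueError("lesion_tint must sum to zero (it must not change the mean gap)")


def generate(spec: LesionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Build one (image, mask) pair from a spec.

    Returns an H x W x 3 float image in [0, 255] and a boolean H x W mask
    (True = lesion).  With noise_sigma = 0 the mean lesion intensity sits
    below the mean skin intensity by exactly ``contrast`` (the radial grading
    and tint are centered over the lesion).  Raises if the lesion covers less
    than 5% or more than 60% of the image.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = spec.center[0] * h, spec.center[1] * w
    dy = (yy - cy) / (spec.axes[0] * h)
    dx = (xx - cx) / (spec.axes[1] * w)
    r = np.hypot(dy, dx)
    phi = np.arctan2(dy, dx)

    # boundary radius modulated by harmonics 2..5 of the polar angle
    rho = np.ones_like(r)
    for harmonic in range(2, 6):
        a, b = rng.normal(0, 1.0 / harmonic, size=2)
        rho += spec.irregularity * (a * np.cos(harmonic * phi) + b * np.sin(harmonic * phi))
    rho = np.maximum(rho, 0.3)
    mask = r <= rho

    frac = mask.mean()
    if not 0.05 <= frac <= 0.6:
        raise ValueError(
            f"lesion area fraction {frac:.3f} outside [0.05, 0.6]; adjust axes/irregularity"
        )

    # radial grading, centered so the mean lesion offset is exactly the contrast
    r_norm = (r / rho)[mask]
    profile = 0.5 - r_norm**2
    profile -= profile.mean()
    offset = spec.contrast * (1.0 + _GRADE_GAIN * profile)

    image = np.broadcast_to(np.asarray(spec.skin_rgb, dtype=float), (h, w, 3)).copy()
    for ch in range(3):
        channel = image[..., ch]
        channel[mask] += spec.lesion_tint[ch] - offset
    if spec.noise_sigma > 0:
        image += rng.normal(0, spec.noise_sigma, size=image.shape)
    np.clip(image, 0.0, 255.0, out=image)
    return image, mask


#: The fixture grid the evaluation suite spans.
SUITE_CONTRASTS = (30.0, 60.0, 100.0)
SUITE_NOISE_SIGMAS = (5.0, 15.0, 25.0)


def suite_specs(
    n: int = 9,
    base_seed: int = 0,
    size: int = 128,
) -> list[LesionSpec]:
    """The n-fixture parameter grid: contrast x noise, cycled past 9."""
    if n < 1:
        raise ValueError("n must be >= 1")
    grid = itertools.cycle(itertools.product(SUITE_CONTRASTS, SUITE_NOISE_SIGMAS))
    return [
        LesionSpec(size=(size, size), contrast=c, noise_sigma=s, seed=base_seed + i)
        for i, (c, s) in zip(range(n), grid)
    ]


def generate_suite(
    out_dir: str,
    n: int = 9,
    base_seed: int = 0,
    size: int = 128,
) -> list[tuple[str, str]]:
    """Write the fixture suite to disk as 8-bit PNG image/mask pairs.

    Filenames encode parameters: ``lesion_c{contrast}_s{sigma}_{i}.png`` plus
    ``..._mask.png``.  Re-running with the same base_seed reproduces
    identical files.  Returns the (image path, mask path) list.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for i, spec in enumerate(suite_specs(n, base_seed, size)):
        image, mask = generate(spec)
        stem = f"lesion_c{int(spec.contrast):03d}_s{int(spec.noise_sigma):02d}_{i}"
        img_path = os.path.join(out_dir, stem + ".png")
        mask_path = os.path.join(out_dir, stem + "_mask.png")
        Image.fromarray(np.round(image).astype(np.uint8)).save(img_path)
        Image.fromarray((mask.astype(np.uint8)) * 255).save(mask_path)
        paths.append((img_path, mask_path))
    return paths


def two_region_image(
    shape: tuple[int, int] = (64, 64),
    skin_value: float = 200.0,
    lesion_value: float = 50.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless two-level RGB image with a block-aligned rectangular lesion.

    The lesion edges sit on even pixel coordinates, so a one-level 2-D Haar
    approximation contains no mixed blocks — the fixture on which lossless
    (sensitivity = specificity = 1) segmentation is attainable for wavelet
    and non-wavelet variants alike.
    """
    h, w = shape
    image = np.full((h, w, 3), float(skin_value))
    mask = np.zeros((h, w), dtype=bool)
    r0, r1 = (h // 4) & ~1, (3 * h // 4) & ~1  # even-aligned bounds
    c0, c1 = (w // 4) & ~1, (3 * w // 4) & ~1
    mask[r0:r1, c0:c1] = True
    image[mask] = float(lesion_value)
    return image, mask
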