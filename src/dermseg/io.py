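"""Reading and writing images, score maps and masks.

Inputs are 8-bit/channel RGB PNG or JPEG.  Score maps are written as 16-bit
grayscale PNG (score x 65535) to keep the continuous classifier output
lossless enough for ROC sweeps; masks as 8-bit PNG with {0, 255}.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

__all__ = ["read_rgb", "read_mask", "read_score", "write_score", "write_mask"]


def read_rgb(path: str) -> np.ndarray:
    """Load an RGB image as an H x W x 3 float array in [0, 255]."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=float)


def read_mask(path: str) -> np.ndarray:
    """Load a binary mask PNG; any nonzero pixel counts as lesion."""
    with Image.open(path) as im:
        return (np.asarray(im.convert("L")) > 0).astype(np.uint8)


def read_score(path: str) -> np.ndarray:
    """Load a 16-bit score PNG back into [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im, dtype=float)
    return arr / 65535.0


def write_score(path: str, score: np.ndarray) -> None:
    arr = np.clip(np.asarray(score, dtype=float), 0.0, 1.0)
    Image.fromarray(np.round(arr * 65535.0).astype(np.uint16)).save(path)


def write_mask(path: str, mask: np.ndarray) -> None:
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255).save(path)
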