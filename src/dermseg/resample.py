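"""Nearest-neighbor resampling with the half-pixel-center convention."""

from __future__ import annotations

import numpy as np

__all__ = ["nni_resample"]


def nni_resample(arr: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Resample a 2-D map to ``target_shape`` by nearest-neighbor copying.

    Source index per axis is floor((i + 0.5) * n_src / n_tgt), so pixel
    centers are compared, not corners.  Copying never introduces new values,
    which keeps label maps label-valued.
    """
    a = np.asarray(arr)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D map, got shape {a.shape}")
    ht, wt = int(target_shape[0]), int(target_shape[1])
    if ht <= 0 or wt <= 0:
        raise ValueError(f"target shape must be positive, got {target_shape}")
    hs, ws = a.shape
    rows = np.minimum((((np.arange(ht) + 0.5) * hs) // ht).astype(int), hs - 1)
    cols = np.minimum((((np.arange(wt) + 0.5) * ws) // wt).astype(int), ws - 1)
    return a[np.ix_(rows, cols)]
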