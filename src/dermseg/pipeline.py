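"""End-to-end lesion segmentation frameworks.

The pipeline implements six methods over one scheme:

    RGB image -> split channels -> per-channel feature image
              -> per-channel clustering -> lesion score per channel
              -> NNI fusion of R with G, then with B -> score map -> mask.

The three wavelet variants (``wkmeans``, ``wfcm``, ``wcpsfcm``) cluster a
wavelet feature image per channel (scale-J approximation by default); the
plain variants (``kmeans``, ``fcm``, ``cpsfcm``) cluster the raw channel.
``srm`` runs the statistical-region-merging baseline instead.

Each channel yields a continuous lesion score in [0, 1]: FCM membership of
the lesion cluster(s) for the fuzzy methods, a soft distance ratio for
K-means.  The lesion cluster is the one with the lowest center (pigmented
lesions are darker than surrounding skin; flip with polarity='light').  With
more than two clusters, every cluster whose center lies below the
membership-weighted mean intensity counts as lesion and their memberships
are summed — multi-cluster preselection may mark the principal lesion plus
smaller satellite regions.  Channel scores are resampled to the input shape
by nearest-neighbor interpolation and fused by per-pixel averaging, which
keeps the output continuous for ROC threshold sweeps; the default binary
mask thresholds the fused score at 0.5.

Everything is deterministic given the configuration and image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import clustering, preselect as _pre, srm as _srm, wavelets
from .resample import nni_resample

__all__ = [
    "METHODS",
    "ChannelSegmentation",
    "PipelineResult",
    "split_channels",
    "segment_channel",
    "fuse_two",
    "nni_resample",
    "run",
]

METHODS = ("kmeans", "fcm", "cpsfcm", "wkmeans", "wfcm", "wcpsfcm", "srm")


@dataclass
class ChannelSegmentation:
    labels: np.ndarray  # hard labels, 0-based
    score: np.ndarray  # lesion membership in [0, 1]
    centers: np.ndarray  # cluster centers in feature space
    n_clusters: int


@dataclass
class PipelineResult:
    score: np.ndarray  # fused H x W lesion score in [0, 1]
    mask: np.ndarray  # H x W binary mask, 1 = lesion
    channels: list[ChannelSegmentation] = field(default_factory=list)


def split_channels(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """R, G, B planes of an H x W x 3 image, as float arrays."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB image, got shape {img.shape}")
    return img[..., 0], img[..., 1], img[..., 2]


def _lesion_score_fuzzy(
    state: clustering.FCMState, shape: tuple[int, int], polarity: str
) -> tuple[np.ndarray, np.ndarray]:
    """Sum the memberships of the lesion-side clusters.

    Two clusters: the lower (dark polarity) center is the lesion.  More:
    every cluster whose center is below (above, for light polarity) the
    membership-weighted mean intensity.
    """
    centers = state.centers.ravel()
    U = state.memberships
    if centers.size == 1:
        return np.full(shape, 0.5), np.zeros(shape, dtype=int)
    cluster_mass = U.sum(axis=1)
    weighted_mean = float((cluster_mass * centers).sum() / cluster_mass.sum())
    if polarity == "dark":
        lesion = centers < weighted_mean
        fallback = int(np.argmin(centers))
    else:
        lesion = centers > weighted_mean
        fallback = int(np.argmax(centers))
    if not lesion.any():
        lesion[fallback] = True
    score = U[lesion].sum(axis=0).reshape(shape)
    labels = np.argmax(U, axis=0).reshape(shape)
    return np.clip(score, 0.0, 1.0), labels


def segment_channel(
    feature: np.ndarray,
    method: str = "fcm",
    n_clusters: int = 3,
    fuzziness: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int = 0,
    polarity: str = "dark",
    rulebase: _pre.FuzzyRuleBase | None = None,
    preselect_reference: np.ndarray | None = None,
) -> ChannelSegmentation:
    """Cluster one (feature) channel and score each pixel as lesion.

    ``method`` is 'kmeans', 'fcm' or 'cpsfcm'.  For 'cpsfcm' the cluster
    count is inferred by the fuzzy preselector from ``preselect_reference``
    (the raw channel; defaults to the feature itself) — the reference
    matters because feature images are rescaled to [0, 255], which erases
    the intensity range the preselector reads.
    """
    if method not in ("kmeans", "fcm", "cpsfcm"):
        raise ValueError(f"unknown channel method {method!r}")
    feat = np.asarray(feature, dtype=float)
    shape = feat.shape
    X = feat.reshape(-1, 1)
    lo, hi = float(feat.min()), float(feat.max())

    if hi == lo:
        warnings.warn("constant channel: returning a uniform single-cluster score")
        return ChannelSegmentation(
            labels=np.zeros(shape, dtype=int),
            score=np.full(shape, 0.5),
            centers=np.array([lo]),
            n_clusters=1,
        )

    if method == "cpsfcm":
        ref = feat if preselect_reference is None else np.asarray(preselect_reference, float)
        pre = _pre.preselect(ref, rulebase)
        n_clusters = pre.N
        init = _pre.initial_centers(lo, hi - lo, n_clusters).reshape(-1, 1)
        state = clustering.fcm(X, C=n_clusters, k=fuzziness,
                               init_centers=init, tol=tol, max_iter=max_iter)
        score, labels = _lesion_score_fuzzy(state, shape, polarity)
        return ChannelSegmentation(labels=labels, score=score,
                                   centers=state.centers.ravel(), n_clusters=n_clusters)

    if method == "fcm":
        state = clustering.fcm(X, C=n_clusters, k=fuzziness, seed=seed,
                               tol=tol, max_iter=max_iter)
        score, labels = _lesion_score_fuzzy(state, shape, polarity)
        return ChannelSegmentation(labels=labels, score=score,
                                   centers=state.centers.ravel(), n_clusters=n_clusters)

    if method == "kmeans":
        res = clustering.kmeans(X, K=n_clusters, seed=seed, tol=tol, max_iter=max_iter)
        centers = res.centroids.ravel()
        lesion_idx = int(np.argmin(centers) if polarity == "dark" else np.argmax(centers))
        d = np.abs(X - centers[None, :])  # (N, K)
        d_lesion = d[:, lesion_idx]
        if centers.size > 1:
            others = np.delete(d, lesion_idx, axis=1)
            d_other = others.min(axis=1)
            denom = d_lesion + d_other
            score = np.where(denom > 0, 1.0 - d_lesion / np.where(denom > 0, denom, 1.0), 1.0)
        else:
            score = np.full(X.shape[0], 0.5)
        return ChannelSegmentation(
            labels=res.assignment.reshape(shape),
            score=score.reshape(shape),
            centers=centers,
            n_clusters=centers.size,
        )

    raise ValueError(f"unknown channel method {method!r}")


def fuse_two(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-pixel mean of two score maps on a common shape (commutative,
    idempotent, keeps scores in [0, 1])."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(
            f"score maps must share a shape after resampling, got {a.shape} vs {b.shape}"
        )
    return (a + b) / 2.0


def run(
    image: np.ndarray,
    method: str = "wfcm",
    wavelet: str | wavelets.FilterBank = "db4",
    levels: int = 1,
    wavelet_mode: str = "approximation",
    magnitude_sqrt: bool = False,
    ext_mode: str = "symmetric",
    n_clusters: int = 3,
    fuzziness: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int = 0,
    polarity: str = "dark",
    threshold: float = 0.5,
    rulebase: _pre.FuzzyRuleBase | None = None,
    srm_q: int = 256,
    srm_predicate: str = "canonical",
) -> PipelineResult:
    """Run one segmentation framework end to end on an RGB image.

    Returns the fused score map, the binary mask (score >= threshold) and
    the three per-channel segmentations (empty for 'srm').  A constant image
    degenerates to a uniform score with a warning.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    img = np.asarray(image, dtype=float)
    h, w = img.shape[:2]

    if method == "srm":
        labels, region_means, _ = _srm.srm_segment(
            img, params=_srm.SRMParams(q=srm_q, delta=1.0 / (6.0 * (h * w) ** 2),
                                       predicate=srm_predicate)
        )
        score = _srm.srm_lesion_score(labels, region_means)
        if polarity == "light":
            score = 1.0 - score
        mask = (score >= threshold).astype(np.uint8)
        return PipelineResult(score=score, mask=mask, channels=[])

    use_wavelet = method.startswith("w")
    base_method = method[1:] if use_wavelet else method

    segs: list[ChannelSegmentation] = []
    scores: list[np.ndarray] = []
    for raw in split_channels(img):
        feat = (
            wavelets.feature_image(raw, family=wavelet, J=levels, mode=wavelet_mode,
                                   magnitude_sqrt=magnitude_sqrt, ext_mode=ext_mode)
            if use_wavelet
            else raw
        )
        seg = segment_channel(
            feat, method=base_method, n_clusters=n_clusters, fuzziness=fuzziness,
            tol=tol, max_iter=max_iter, seed=seed, polarity=polarity,
            rulebase=rulebase,
            preselect_reference=raw if base_method == "cpsfcm" else None,
        )
        segs.append(seg)
        scores.append(nni_resample(seg.score, (h, w)))

    fused = fuse_two(fuse_two(scores[0], scores[1]), scores[2])
    if fused.max() == fused.min():
        warnings.warn("uniform fused score: the mask is empty or full")
    mask = (fused >= threshold).astype(np.uint8)
    return PipelineResult(score=fused, mask=mask, channels=segs)
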