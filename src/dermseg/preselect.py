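"""Automatic cluster-count preselection for FCM (CPSFCM).

FCM needs its cluster count fixed up front; this stage infers it from two
cheap image statistics with a Mamdani fuzzy system:

- ``distance`` d0 = D = V_max - V_min, the intensity range of a grayscale
  image obtained by averaging the two most similar color channels (channel
  similarity is the sum of squared per-pixel differences, compared as
  printed, without a square root — a monotone-equivalent of the Euclidean
  distance);
- ``size`` s0 = H * W, the pixel count.

Three linguistic variables are modelled with Gaussian fuzzy sets
exp(-(x - center)^2 / (2 * spread^2)): six sets for Distance on the [0, 255]
universe, five for Size (up to ~1.44e6 pixels, i.e. 1200 x 1200), and five
for the output Cluster count.  Thirty rules — one per (distance, size)
antecedent pair — fire with strength min(mu_distance(d0), mu_size(s0)), and
the aggregated output

    Q(c) = max_i min(strength_i, mu_consequent_i(c))

is defuzzified by taking the argmax of Q over integer c in [2, 40] (smallest
c on ties).  The default rule base is a monotone grid: larger intensity
ranges and larger images map to more clusters; it can be replaced from a
text file, one rule per line, ``distance_label, size_label -> cluster_label``.

The inferred count N then seeds FCM with equidistant centers
c_j = V_min + j * D / N, which is why only a few FCM iterations remain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .clustering import FCMState, fcm

__all__ = [
    "GaussianFuzzySet",
    "FuzzyRuleBase",
    "ChannelDistances",
    "PreselectResult",
    "CPSFCMResult",
    "DISTANCE_SETS",
    "SIZE_SETS",
    "CLUSTER_SETS",
    "gauss_membership",
    "default_rule_base",
    "load_rule_base",
    "channel_pair_distances",
    "fuse_similar_channels",
    "infer_cluster_count",
    "initial_centers",
    "preselect",
    "cpsfcm",
]


@dataclass(frozen=True)
class GaussianFuzzySet:
    label: str
    center: float
    spread: float

    def __post_init__(self) -> None:
        if self.spread <= 0:
            raise ValueError(f"fuzzy set {self.label!r}: spread must be positive")

    def membership(self, x: float | np.ndarray) -> float | np.ndarray:
        return np.exp(-((np.asarray(x, dtype=float) - self.center) ** 2) / (2 * self.spread**2))


def gauss_membership(x: float, fuzzy_set: GaussianFuzzySet) -> float:
    """exp(-(x - center)^2 / (2 spread^2)); equals 1 at the center."""
    return float(fuzzy_set.membership(x))


# Linguistic variables: (label, center, spread).  Spreads are the Gaussian
# sigma of each set on its universe.
DISTANCE_SETS: tuple[GaussianFuzzySet, ...] = tuple(
    GaussianFuzzySet(*row)
    for row in [
        ("minimum", 15.0, 16.0),
        ("shorter", 53.0, 24.0),
        ("short", 105.0, 30.0),
        ("regular", 150.0, 30.0),
        ("large", 222.0, 45.0),
        ("maximum", 255.0, 15.0),
    ]
)

SIZE_SETS: tuple[GaussianFuzzySet, ...] = tuple(
    GaussianFuzzySet(*row)
    for row in [
        ("min", 9000.0, 1.789e5),
        ("small", 3.015e5, 1.626e5),
        ("medium", 6.53e5, 1.968e5),
        ("big", 9.728e5, 2.236e5),
        ("max", 1.44e6, 2.862e5),
    ]
)

CLUSTER_SETS: tuple[GaussianFuzzySet, ...] = tuple(
    GaussianFuzzySet(*row)
    for row in [
        ("very few", 2.0, 3.0),
        ("few", 7.0, 3.0),
        ("some", 16.0, 5.0),
        ("many", 23.0, 5.0),
        ("too many", 33.0, 7.0),
    ]
)


@dataclass
class FuzzyRuleBase:
    """Three linguistic variables plus the 30 (distance, size) -> cluster rules."""

    distance_sets: tuple[GaussianFuzzySet, ...] = DISTANCE_SETS
    size_sets: tuple[GaussianFuzzySet, ...] = SIZE_SETS
    cluster_sets: tuple[GaussianFuzzySet, ...] = CLUSTER_SETS
    rules: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rules:
            self.rules = _default_rules(self.distance_sets, self.size_sets, self.cluster_sets)
        self._check()

    def _check(self) -> None:
        dlabels = [s.label for s in self.distance_sets]
        slabels = [s.label for s in self.size_sets]
        clabels = [s.label for s in self.cluster_sets]
        pairs = [(d, s) for d, s, _ in self.rules]
        expected = [(d, s) for d in dlabels for s in slabels]
        if sorted(pairs) != sorted(expected):
            raise ValueError(
                "rule base must cover every (distance, size) antecedent pair exactly once"
            )
        for d, s, c in self.rules:
            if c not in clabels:
                raise ValueError(f"rule ({d}, {s}) names unknown cluster set {c!r}")

    def set_by_label(self, which: str, label: str) -> GaussianFuzzySet:
        sets = {"distance": self.distance_sets, "size": self.size_sets,
                "cluster": self.cluster_sets}[which]
        for s in sets:
            if s.label == label:
                return s
        raise KeyError(f"no {which} set labelled {label!r}")


def _default_rules(
    distance_sets: tuple[GaussianFuzzySet, ...],
    size_sets: tuple[GaussianFuzzySet, ...],
    cluster_sets: tuple[GaussianFuzzySet, ...],
) -> list[tuple[str, str, str]]:
    """Monotone grid: antecedent ranks (i, j) map to consequent rank
    clamp(round((i + j - 1) / 2), 1, n_cluster_sets), so small-range/small-image
    pairs select the fewest clusters and large/large the most."""
    rules = []
    for i, d in enumerate(distance_sets, start=1):
        for j, s in enumerate(size_sets, start=1):
            rank = int(np.floor((i + j - 1) / 2 + 0.5))
            rank = min(max(rank, 1), len(cluster_sets))
            rules.append((d.label, s.label, cluster_sets[rank - 1].label))
    return rules


def default_rule_base() -> FuzzyRuleBase:
    return FuzzyRuleBase()


def load_rule_base(path: str) -> FuzzyRuleBase:
    """Rules from a text file, one ``distance, size -> cluster`` per line.

    Blank lines and ``#`` comments are ignored; set labels are those of the
    default linguistic variables.
    """
    rules: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                antecedent, consequent = line.split("->")
                d, s = (part.strip().lower() for part in antecedent.split(","))
            except ValueError as exc:
                raise ValueError(f"{path}: malformed rule line {line!r}") from exc
            rules.append((d, s, consequent.strip().lower()))
    return FuzzyRuleBase(rules=rules)


@dataclass(frozen=True)
class ChannelDistances:
    """Pairwise channel dissimilarities (sums of squared differences)."""

    d_rb: float
    d_rg: float
    d_gb: float


def _check_rgb(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB image, got shape {img.shape}")
    return img


def channel_pair_distances(image: np.ndarray) -> ChannelDistances:
    """Sum of squared per-pixel differences for each channel pair, as printed
    (no square root; monotone-equivalent to the Euclidean distance)."""
    img = _check_rgb(image)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    return ChannelDistances(
        d_rb=float(((r - b) ** 2).sum()),
        d_rg=float(((r - g) ** 2).sum()),
        d_gb=float(((g - b) ** 2).sum()),
    )


def fuse_similar_channels(image: np.ndarray) -> np.ndarray:
    """Average the two most similar channels into one grayscale image.

    The pair with the smallest pairwise distance wins; ties go to the first
    of (R,B), (R,G), (G,B).
    """
    img = _check_rgb(image)
    d = channel_pair_distances(img)
    pairs = [(d.d_rb, (0, 2)), (d.d_rg, (0, 1)), (d.d_gb, (1, 2))]
    _, (i, j) = min(pairs, key=lambda t: t[0])
    return (img[..., i] + img[..., j]) / 2.0


def infer_cluster_count(
    D: float,
    size: float,
    rulebase: FuzzyRuleBase | None = None,
    c_range: tuple[int, int] = (2, 40),
) -> int:
    """Max–min Mamdani inference of the cluster count.

    Q(c) = max over rules of min(rule strength, consequent membership at c),
    evaluated on integer c in ``c_range``; returns the argmax (smallest c on
    ties), hence always >= 2 with the default range.
    """
    rb = rulebase or default_rule_base()
    cs = np.arange(c_range[0], c_range[1] + 1)
    q = np.zeros(cs.shape)
    for dlab, slab, clab in rb.rules:
        strength = min(
            gauss_membership(D, rb.set_by_label("distance", dlab)),
            gauss_membership(size, rb.set_by_label("size", slab)),
        )
        q = np.maximum(q, np.minimum(strength, rb.set_by_label("cluster", clab).membership(cs)))
    return int(cs[int(np.argmax(q))])


def initial_centers(v_min: float, D: float, N: int) -> np.ndarray:
    """Equidistant seeding c_j = V_min + j * D / N, j = 1..N."""
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    if D < 0:
        raise ValueError(f"D must be >= 0, got {D}")
    return v_min + np.arange(1, N + 1) * D / N


@dataclass
class PreselectResult:
    D: float
    v_min: float
    v_max: float
    image_size: int
    N: int
    centers: np.ndarray


def preselect(gray: np.ndarray, rulebase: FuzzyRuleBase | None = None) -> PreselectResult:
    """Infer the cluster count and seed centers from one grayscale image."""
    g = np.asarray(gray, dtype=float)
    v_min, v_max = float(g.min()), float(g.max())
    D = v_max - v_min
    size = g.size
    N = infer_cluster_count(D, size, rulebase)
    return PreselectResult(
        D=D, v_min=v_min, v_max=v_max, image_size=size,
        N=N, centers=initial_centers(v_min, D, N),
    )


@dataclass
class CPSFCMResult:
    state: FCMState | None
    labels: np.ndarray  # (H, W) hard labels, argmax membership
    preselection: PreselectResult
    fused: np.ndarray  # the fused grayscale image that was clustered


def cpsfcm(
    image: np.ndarray,
    rulebase: FuzzyRuleBase | None = None,
    fuzziness: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
) -> CPSFCMResult:
    """Full cluster-preselection FCM on an RGB image.

    Fuses the two most similar channels, infers the cluster count from the
    fused image's intensity range and pixel count, seeds FCM equidistantly,
    and iterates to convergence.  A constant image (D = 0) degenerates to a
    single-cluster segmentation with a warning.
    """
    img = _check_rgb(image)
    fused = fuse_similar_channels(img)
    pre = preselect(fused, rulebase)
    if pre.D == 0:
        warnings.warn("constant image: intensity range D = 0, returning one cluster")
        pre.N, pre.centers = 1, np.array([pre.v_min])
        labels = np.zeros(fused.shape, dtype=int)
        return CPSFCMResult(state=None, labels=labels, preselection=pre, fused=fused)
    state = fcm(
        fused.reshape(-1, 1), C=pre.N, k=fuzziness,
        init_centers=pre.centers.reshape(-1, 1), tol=tol, max_iter=max_iter,
    )
    labels = np.argmax(state.memberships, axis=0).reshape(fused.shape)
    return CPSFCMResult(state=state, labels=labels, preselection=pre, fused=fused)
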