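"""Adipose-vs-rest segmentation of a preprocessed slice.

Three interchangeable intensity-based backends produce a binary mask in
which 1 marks adipose tissue (the hyperintense class on opposed-phase T1)
and 0 marks lean tissue and background:

* Otsu thresholding — the threshold maximizing between-class variance over
  a 256-bin histogram; ties resolved to the lowest maximizing threshold.
* k-means (k=2) — Lloyd iterations on the flattened intensity samples with
  k-means++ seeding; the cluster with the brighter center is adipose.
* fuzzy c-means (c=2) — alternating membership/center updates with
  fuzziness exponent m; pixels are hardened by maximum membership.

All backends are deterministic given the configured seed, and cluster
labels are mapped to tissue by center intensity, never by label index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)


class DegenerateImageError(ValueError):
    """Raised when an image has too few distinct intensities to segment."""


@dataclass(frozen=True)
class SegmentationConfig:
    method: str = "otsu"  # otsu | kmeans | fcm
    n_clusters: int = 2
    fuzziness_m: float = 2.0
    tol: float = 1e-5
    max_iter: int = 300
    seed: int = 0
    histogram_bins: int = 256

    def validate(self) -> None:
        if self.method not in ("otsu", "kmeans", "fcm"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.fuzziness_m <= 1:
            raise ValueError("fuzziness_m must be > 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class SegmentationResult:
    mask: np.ndarray  # uint8, 1 = adipose
    method: str
    threshold: float | None = None
    cluster_centers: np.ndarray | None = None
    memberships: np.ndarray | None = None  # (H, W, c), FCM only
    n_iter: int = 0
    objective_history: list[float] = field(default_factory=list)


def _check_distinct(img: np.ndarray, needed: int) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    distinct = np.unique(img)
    if distinct.size < needed:
        raise DegenerateImageError(
            f"image has {distinct.size} distinct value(s) "
            f"({distinct.tolist()[:4]}); need >= {needed}"
        )
    return img


def otsu_segment(img: np.ndarray, cfg: SegmentationConfig | None = None) -> SegmentationResult:
    """Threshold at the 256-bin Otsu optimum; adipose = above threshold."""
    cfg = cfg or SegmentationConfig(method="otsu")
    cfg.validate()
    img = _check_distinct(img, 2)
    counts, edges = np.histogram(img, bins=cfg.histogram_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    # threshold_otsu's argmax picks the first (lowest) maximizing cut
    thr = float(threshold_otsu(hist=(counts, centers)))
    mask = (img > thr).astype(np.uint8)
    return SegmentationResult(mask=mask, method="otsu", threshold=thr)


def _kmeans_pp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding over 1-D samples."""
    centers = [x[rng.integers(x.size)]]
    for _ in range(1, k):
        d2 = np.min(np.abs(x[:, None] - np.asarray(centers)[None, :]) ** 2, axis=1)
        total = d2.sum()
        if total == 0:
            centers.append(x[rng.integers(x.size)])
            continue
        centers.append(x[rng.choice(x.size, p=d2 / total)])
    return np.asarray(centers, dtype=np.float64)


def kmeans_segment(img: np.ndarray, cfg: SegmentationConfig | None = None) -> SegmentationResult:
    """Lloyd's algorithm on flattened intensities, k=2 by default.

    Empty clusters are re-seeded at the sample farthest from its assigned
    center (logged), never silently dropped.  The within-cluster sum of
    squares is recorded per iteration and is non-increasing.
    """
    cfg = cfg or SegmentationConfig(method="kmeans")
    cfg.validate()
    img = _check_distinct(img, cfg.n_clusters)
    x = img.ravel()
    rng = np.random.default_rng(cfg.seed)
    centers = _kmeans_pp_init(x, cfg.n_clusters, rng)
    history: list[float] = []
    assign = np.zeros(x.size, dtype=np.intp)
    for it in range(1, cfg.max_iter + 1):
        dist = np.abs(x[:, None] - centers[None, :])
        assign = np.argmin(dist, axis=1)
        sse = float(np.sum((x - centers[assign]) ** 2))
        history.append(sse)
        new_centers = centers.copy()
        for j in range(cfg.n_clusters):
            members = x[assign == j]
            if members.size == 0:
                far = np.argmax(np.abs(x - centers[assign]))
                new_centers[j] = x[far]
                logger.warning(
                    "k-means: cluster %d emptied, re-seeded at farthest sample", j
                )
            else:
                new_centers[j] = members.mean()
        shift = float(np.max(np.abs(new_centers - centers)))
        centers = new_centers
        if shift < cfg.tol:
            break
    dist = np.abs(x[:, None] - centers[None, :])
    assign = np.argmin(dist, axis=1)
    adipose = int(np.argmax(centers))
    mask = (assign == adipose).astype(np.uint8).reshape(img.shape)
    return SegmentationResult(
        mask=mask,
        method="kmeans",
        cluster_centers=np.sort(centers),
        n_iter=it,
        objective_history=history,
    )


def fcm_segment(img: np.ndarray, cfg: SegmentationConfig | None = None) -> SegmentationResult:
    """Fuzzy c-means on flattened intensities, hardened by max membership.

    Memberships follow u_ij = 1 / sum_k (d_ij / d_ik)^(2/(m-1)); centers are
    membership^m-weighted means.  A pixel exactly at a center gets
    membership 1 for that center.  The fuzzy objective sum u^m d^2 is
    recorded per iteration and is non-increasing.
    """
    cfg = cfg or SegmentationConfig(method="fcm")
    cfg.validate()
    img = _check_distinct(img, cfg.n_clusters)
    x = img.ravel()
    c, m = cfg.n_clusters, cfg.fuzziness_m
    rng = np.random.default_rng(cfg.seed)
    centers = _kmeans_pp_init(x, c, rng)
    history: list[float] = []
    u = np.empty((x.size, c))
    for it in range(1, cfg.max_iter + 1):
        u = fcm_memberships(x, centers, m)
        d2 = (x[:, None] - centers[None, :]) ** 2
        history.append(float(np.sum(u**m * d2)))
        um = u**m
        new_centers = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        shift = float(np.max(np.abs(new_centers - centers)))
        centers = new_centers
        if shift < cfg.tol:
            break
    u = fcm_memberships(x, centers, m)
    assign = np.argmax(u, axis=1)
    adipose = int(np.argmax(centers))
    mask = (assign == adipose).astype(np.uint8).reshape(img.shape)
    order = np.argsort(centers)
    return SegmentationResult(
        mask=mask,
        method="fcm",
        cluster_centers=centers[order],
        memberships=u[:, order].reshape(img.shape + (c,)),
        n_iter=it,
        objective_history=history,
    )


def fcm_memberships(x: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    """Membership update for 1-D samples; rows sum to 1 exactly.

    Samples coinciding with one or more centers split membership equally
    among the coincident centers (membership 1 when unique).
    """
    d = np.abs(x[:, None] - centers[None, :])
    zero = d == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d ** (-2.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
    hit = zero.any(axis=1)
    if np.any(hit):
        u[hit] = zero[hit] / zero[hit].sum(axis=1, keepdims=True)
    return u


_BACKENDS = {"otsu": otsu_segment, "kmeans": kmeans_segment, "fcm": fcm_segment}


def segment(img: np.ndarray, cfg: SegmentationConfig) -> SegmentationResult:
    """Dispatch to the backend named in ``cfg.method``."""
    cfg.validate()
    return _BACKENDS[cfg.method](img, cfg)
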