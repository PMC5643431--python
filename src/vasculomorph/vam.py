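"""Vascular-area classification and skeleton post-processing.

Every pixel of a tile is described by 17 features — its distances to the
1st..5th nearest classified endothelial-cell (EC) nucleus and twelve eosin
intensity statistics (mean/SD/max/min in square sliding windows of
half-width 5, 15 and 30 px) — and classified vascular vs. non-vascular by
a random forest trained on pixels labeled from the CD31 vessel mask.  The
thresholded probability map is the vascular area mask (VAM).

Post-processing thins the VAM to a 1-px vascular skeleton, detects branch
points (skeleton pixels with >= 3 skeleton neighbors, 8-connectivity,
adjacent branch pixels merged into one cluster) and decomposes the rest of
the skeleton into arms with pixel chains, lengths and axial orientations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure, morphology
from sklearn.ensemble import RandomForestClassifier

from .config import (
    PIXEL_FEATURE_NAMES,
    PIXEL_WINDOW_HALF_WIDTHS,
)


@dataclass
class VascularAreaMask:
    mask: np.ndarray
    tile_id: str = "tile"


@dataclass
class VascularSkeleton:
    """1-px skeleton with branch points and arm decomposition."""

    skeleton: np.ndarray
    branch_points: list[tuple[float, float]]
    branch_pixels: np.ndarray  # binary mask of raw branch-pixel clusters
    arms: list[dict] = field(default_factory=list)

    @property
    def euler_components(self) -> int:
        return int(ndimage.label(self.skeleton, structure=np.ones((3, 3)))[1])


# ---------------------------------------------------------------------------
# Pixel features


def pixel_features(
    eosin: np.ndarray,
    ec_centroids: np.ndarray | list,
    stride: int = 1,
) -> np.ndarray:
    """Dense 17-feature map for vascular-area classification.

    Returns an array of shape (ceil(H/stride), ceil(W/stride), 17) in the
    order of :data:`vasculomorph.config.PIXEL_FEATURE_NAMES`.  Window
    statistics use edge-replicated padding.  With fewer than 5 EC
    centroids the missing distance ranks saturate at the tile diagonal.
    """
    eosin = np.asarray(eosin, dtype=float)
    if eosin.ndim != 2 or eosin.size == 0:
        raise ValueError("eosin must be a non-empty 2-D image")
    h, w = eosin.shape
    diag = float(np.hypot(h, w))
    pts = np.asarray(ec_centroids, dtype=float).reshape(-1, 2)

    rows = np.arange(0, h, stride)
    cols = np.arange(0, w, stride)
    grid_r, grid_c = np.meshgrid(rows, cols, indexing="ij")
    query = np.column_stack([grid_r.ravel(), grid_c.ravel()])

    k = 5
    if len(pts) == 0:
        dists = np.full((len(query), k), diag)
    else:
        kk = min(k, len(pts))
        d, _ = cKDTree(pts).query(query, k=kk)
        d = d.reshape(len(query), kk)
        if kk < k:
            pad = np.full((len(query), k - kk), diag)
            d = np.hstack([d, pad])
        dists = np.minimum(d, diag)
    dist_maps = dists.reshape(len(rows), len(cols), k)

    window_maps = []
    for hw in PIXEL_WINDOW_HALF_WIDTHS:
        size = 2 * hw + 1
        mean = ndimage.uniform_filter(eosin, size=size, mode="nearest")
        sq = ndimage.uniform_filter(eosin**2, size=size, mode="nearest")
        sd = np.sqrt(np.clip(sq - mean**2, 0, None))
        mx = ndimage.maximum_filter(eosin, size=size, mode="nearest")
        mn = ndimage.minimum_filter(eosin, size=size, mode="nearest")
        for m in (mean, sd, mx, mn):
            window_maps.append(m[::stride, ::stride])
    feat = np.concatenate(
        [dist_maps] + [m[..., None] for m in window_maps], axis=2
    )
    assert feat.shape[2] == len(PIXEL_FEATURE_NAMES) == 17
    return feat


# ---------------------------------------------------------------------------
# Classifier


def sample_training_pixels(
    feature_map: np.ndarray,
    cd31_labels: np.ndarray,
    n_samples: int = 6000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified sample of pixel feature vectors from vascular (CD31+)
    and non-vascular areas, half of ``n_samples`` from each class (capped
    by availability)."""
    labels = np.asarray(cd31_labels, dtype=bool)
    if labels.shape != feature_map.shape[:2]:
        raise ValueError("label mask and feature map disagree in shape")
    rng = np.random.default_rng(seed)
    pos = np.argwhere(labels)
    neg = np.argwhere(~labels)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    n_half = n_samples // 2
    pos = pos[rng.integers(0, len(pos), size=min(n_half, len(pos) * 4))][:n_half]
    neg = neg[rng.integers(0, len(neg), size=min(n_half, len(neg) * 4))][:n_half]
    take = np.vstack([pos, neg])
    x = feature_map[take[:, 0], take[:, 1]]
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return x, y


def train_vam_classifier(
    feature_samples: np.ndarray,
    cd31_labels: np.ndarray,
    n_trees: int = 100,
    seed: int = 0,
    oob_score: bool = False,
) -> RandomForestClassifier:
    """Train the random-forest vascular-pixel classifier.

    ``feature_samples`` is an (n, 17) matrix, ``cd31_labels`` the binary
    vascular/non-vascular labels of those pixels.
    """
    x = np.asarray(feature_samples, dtype=float)
    y = np.asarray(cd31_labels).astype(int).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("training sample contains a single class")
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        random_state=seed,
        oob_score=oob_score,
        n_jobs=1,
    )
    clf.fit(x, y)
    return clf


def predict_vam_probability(
    classifier: RandomForestClassifier, feature_map: np.ndarray
) -> np.ndarray:
    """Per-pixel vascular probability map from a dense feature map."""
    h, w, f = feature_map.shape
    proba = classifier.predict_proba(feature_map.reshape(h * w, f))[:, 1]
    return proba.reshape(h, w)


def predict_vam(
    classifier: RandomForestClassifier,
    feature_map: np.ndarray,
    threshold: float = 0.5,
    closing_radius: int = 3,
    min_component: int = 50,
    tile_id: str = "tile",
) -> VascularAreaMask:
    """Threshold the probability map into a cleaned vascular area mask.

    Morphological closing (disc of ``closing_radius``) bridges small gaps,
    then components below ``min_component`` pixels are dropped.
    """
    proba = predict_vam_probability(classifier, feature_map)
    mask = proba >= threshold
    if closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(closing_radius))
    if min_component > 0:
        mask = morphology.remove_small_objects(
            mask, max_size=min_component - 1, connectivity=2
        )
    return VascularAreaMask(mask=mask, tile_id=tile_id)


# ---------------------------------------------------------------------------
# Skeleton post-processing

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def _axial_orientation(pixels: np.ndarray) -> float:
    """Principal-axis orientation of a pixel chain, degrees in [0, 180).

    0 degrees = horizontal (along columns); angles grow toward the row
    axis.  Isotropic chains (single pixel) return 0.
    """
    if len(pixels) < 2:
        return 0.0
    xy = pixels - pixels.mean(axis=0)
    cov = xy.T @ xy
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]  # (d_row, d_col)
    ang = np.degrees(np.arctan2(v[0], v[1])) % 180.0
    return float(ang)


def postprocess_vam(vam: VascularAreaMask | np.ndarray) -> VascularSkeleton:
    """Thin the VAM into a vascular skeleton with branch points and arms.

    * Skeleton: topology-preserving thinning (``skimage.skeletonize``).
    * Branch pixels: skeleton pixels with >= 3 skeleton neighbors under
      8-connectivity; 8-connected runs of branch pixels are merged and
      each cluster is reported once at its centroid.
    * Arms: 8-connected components of the skeleton with branch clusters
      removed; each arm carries its pixel chain, length (pixel count) and
      axial principal-axis orientation in [0, 180).
    """
    mask = vam.mask if isinstance(vam, VascularAreaMask) else np.asarray(vam)
    mask = mask.astype(bool)
    if not mask.any():
        return VascularSkeleton(
            skeleton=np.zeros_like(mask),
            branch_points=[],
            branch_pixels=np.zeros_like(mask),
            arms=[],
        )
    skel = morphology.skeletonize(mask)
    neighbors = ndimage.convolve(
        skel.astype(int), _NEIGHBOR_KERNEL, mode="constant"
    )
    branch_px = skel & (neighbors >= 3)
    lab, n_clusters = ndimage.label(branch_px, structure=np.ones((3, 3)))
    centroids = ndimage.center_of_mass(branch_px, lab, range(1, n_clusters + 1))

    arm_lab, n_arms = ndimage.label(
        skel & ~branch_px, structure=np.ones((3, 3))
    )
    arms = []
    for a in range(1, n_arms + 1):
        px = np.argwhere(arm_lab == a)
        arms.append(
            {
                "arm_id": a,
                "pixels": px,
                "length_px": int(len(px)),
                "orientation_deg": _axial_orientation(px.astype(float)),
            }
        )
    return VascularSkeleton(
        skeleton=skel,
        branch_points=[tuple(c) for c in centroids],
        branch_pixels=branch_px,
        arms=arms,
    )


def branch_point_mask(
    skeleton: VascularSkeleton, radius: int = 2
) -> np.ndarray:
    """Binary mask marking each branch-point cluster (dilated for
    morphometry of the BP object set)."""
    out = np.zeros_like(skeleton.skeleton, dtype=bool)
    if skeleton.branch_points:
        pts = np.round(np.asarray(skeleton.branch_points)).astype(int)
        pts[:, 0] = np.clip(pts[:, 0], 0, out.shape[0] - 1)
        pts[:, 1] = np.clip(pts[:, 1], 0, out.shape[1] - 1)
        out[pts[:, 0], pts[:, 1]] = True
        if radius > 0:
            out = morphology.dilation(out, morphology.disk(radius))
    return out


def ec_mask_from_centroids(
    centroids: list | np.ndarray, shape: tuple[int, int], radius: int = 3
) -> np.ndarray:
    """Binary EC-nucleus mask stamped from classified centroids (the EC
    object set for morphometry)."""
    out = np.zeros(shape, dtype=bool)
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return out
    pts = np.round(pts).astype(int)
    keep = (
        (pts[:, 0] >= 0)
        & (pts[:, 0] < shape[0])
        & (pts[:, 1] >= 0)
        & (pts[:, 1] < shape[1])
    )
    pts = pts[keep]
    out[pts[:, 0], pts[:, 1]] = True
    if radius > 0:
        out = morphology.dilation(out, morphology.disk(radius))
    return out


__all__ = [
    "VascularAreaMask",
    "VascularSkeleton",
    "pixel_features",
    "sample_training_pixels",
    "train_vam_classifier",
    "predict_vam_probability",
    "predict_vam",
    "postprocess_vam",
    "branch_point_mask",
    "ec_mask_from_centroids",
]
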