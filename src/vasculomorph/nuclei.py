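"""Nucleus segmentation, 63-feature morphometry, three-class SVM.

Nuclei are segmented from the hematoxylin absorbance channel (median
filter, Otsu threshold, hole filling, watershed split on the distance
transform).  Each nucleus yields a fixed 63-element feature vector — 13
shape descriptors, 9 intensity statistics per stain channel, and 4 GLCM
texture properties at 4 offsets per channel (roster in
:mod:`vasculomorph.config`) — used to train a radial-kernel support vector
machine separating endothelial, lymphocyte and cancer nuclei.  All
features are translation-invariant; kurtosis is excess kurtosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage import draw, feature as skfeature, filters, measure, morphology, segmentation
from sklearn.metrics import cohen_kappa_score, confusion_matrix, roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import NUCLEUS_CLASSES, NUCLEUS_FEATURE_NAMES


@dataclass
class NucleusRecord:
    nucleus_id: int
    contour: np.ndarray  # closed polygon, (row, col) vertices
    centroid: tuple[float, float]
    features: np.ndarray | None = None
    true_class: str | None = None
    predicted_class: str | None = None
    class_scores: np.ndarray | None = None


@dataclass
class ClassifierReport:
    confusion: np.ndarray
    cohen_kappa: float
    observed_agreement: float
    auc_per_class: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Segmentation


def segment_nuclei(
    hematoxylin: np.ndarray,
    median_radius: int = 2,
    min_area: int = 15,
    max_area: int = 2000,
    min_peak_distance: int = 4,
) -> list[NucleusRecord]:
    """Segment nuclei from the hematoxylin absorbance channel.

    Median filter -> Otsu threshold -> fill holes -> watershed split of
    touching nuclei on the negated distance transform (markers at distance
    peaks at least ``min_peak_distance`` apart) -> area gate
    [min_area, max_area].  Contours are traced on the object boundary.
    """
    if median_radius < 1:
        raise ValueError("median_radius must be >= 1")
    img = np.asarray(hematoxylin, dtype=float)
    if img.size == 0 or not np.isfinite(img).any() or img.max() <= 0:
        return []
    smoothed = filters.median(img, morphology.disk(median_radius))
    if smoothed.max() == smoothed.min():
        return []
    thr = filters.threshold_otsu(smoothed)
    binary = ndimage.binary_fill_holes(smoothed > thr)
    if not binary.any():
        return []

    dist = ndimage.distance_transform_edt(binary)
    # smooth the ridge so elongated nuclei contribute a single marker
    dist = ndimage.gaussian_filter(dist, 1.0)
    peaks = skfeature.peak_local_max(
        dist, min_distance=min_peak_distance, labels=binary, exclude_border=False
    )
    markers = np.zeros_like(img, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels = measure.label(binary, connectivity=2)
    else:
        labels = segmentation.watershed(-dist, markers, mask=binary)

    records: list[NucleusRecord] = []
    nid = 0
    for prop in measure.regionprops(labels):
        if not (min_area <= prop.area <= max_area):
            continue
        region = labels[prop.slice] == prop.label
        contours = measure.find_contours(
            np.pad(region.astype(float), 1), 0.5
        )
        if not contours:
            continue
        contour = max(contours, key=len)
        offset = np.array([prop.slice[0].start - 1, prop.slice[1].start - 1])
        nid += 1
        records.append(
            NucleusRecord(
                nucleus_id=nid,
                contour=contour + offset,
                centroid=tuple(prop.centroid),
            )
        )
    return records


def contour_mask(contour: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed contour polygon into a filled binary mask."""
    rr, cc = draw.polygon(contour[:, 0], contour[:, 1], shape=shape)
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


# ---------------------------------------------------------------------------
# Feature extraction


def _shape_features(mask: np.ndarray) -> list[float]:
    props = measure.regionprops(mask.astype(int))
    if not props:
        raise ValueError("degenerate contour: empty interior")
    p = props[0]
    perim = max(p.perimeter, 1e-9)
    circ = 4 * np.pi * p.area / perim**2
    minor = p.axis_minor_length
    aspect = p.axis_major_length / minor if minor > 0 else 1.0
    convex_perim = measure.regionprops(p.image_convex.astype(int))[0].perimeter
    return [
        float(p.area),
        float(p.perimeter),
        float(circ),
        float(p.eccentricity),
        float(p.solidity),
        float(p.extent),
        float(p.axis_major_length),
        float(p.axis_minor_length),
        float(aspect),
        float(p.equivalent_diameter_area),
        float(p.orientation),
        float(p.area_convex),
        float(convex_perim / perim),
    ]


def _intensity_stats(values: np.ndarray) -> list[float]:
    v = values.astype(float)
    sd = v.std()
    if sd > 0:
        g1 = float(stats.skew(v))
        g2 = float(stats.kurtosis(v))  # excess kurtosis
    else:
        g1 = g2 = 0.0
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    return [
        float(v.mean()),
        float(sd),
        g1,
        g2,
        float(v.min()),
        float(v.max()),
        float(q25),
        float(med),
        float(q75),
    ]


def _glcm_features(channel: np.ndarray, mask: np.ndarray) -> list[float]:
    sub = channel[mask]
    lo, hi = sub.min(), sub.max()
    levels = 16
    if hi > lo:
        q = np.clip(((channel - lo) / (hi - lo) * (levels - 1)), 0, levels - 1)
    else:
        q = np.zeros_like(channel)
    q = (q + 1).astype(np.uint8)  # reserve level 0 for outside-mask
    q[~mask] = 0
    glcm = skfeature.graycomatrix(
        q,
        distances=[1],
        angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=levels + 1,
        symmetric=True,
        normed=False,
    )
    # drop co-occurrences involving the outside-mask level, renormalize
    glcm = glcm[1:, 1:, :, :].astype(float)
    sums = glcm.sum(axis=(0, 1), keepdims=True)
    sums[sums == 0] = 1.0
    glcm = glcm / sums
    out = []
    for prop in ("contrast", "correlation", "energy", "homogeneity"):
        vals = skfeature.graycoprops(glcm, prop)[0]
        out.extend(float(v) for v in vals)
    return out


def extract_nuclear_features(
    record: NucleusRecord,
    hematoxylin: np.ndarray,
    eosin: np.ndarray,
) -> np.ndarray:
    """Compute the 63-element nuclear feature vector in place and return it."""
    shape = hematoxylin.shape
    mask = contour_mask(record.contour, shape)
    if mask.sum() < 3:
        raise ValueError("degenerate contour")
    feats = _shape_features(mask)
    for ch in (hematoxylin, eosin):
        feats.extend(_intensity_stats(np.asarray(ch, dtype=float)[mask]))
    for ch in (hematoxylin, eosin):
        feats.extend(_glcm_features(np.asarray(ch, dtype=float), mask))
    vec = np.array(feats, dtype=float)
    assert vec.shape == (len(NUCLEUS_FEATURE_NAMES),) == (63,)
    record.features = vec
    return vec


# ---------------------------------------------------------------------------
# Classification


def train_nucleus_classifier(
    features: np.ndarray,
    labels: np.ndarray | list,
    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0),
    gamma_grid: tuple = ("scale", 0.01, 0.1),
    n_folds: int = 5,
    seed: int = 0,
) -> GridSearchCV:
    """Train the three-class RBF-SVM nucleus classifier.

    Features are z-scored on training statistics inside the pipeline;
    hyperparameters are chosen by stratified ``n_folds``-fold grid search;
    class weights are balanced.  The fitted search object retains fold
    scores (``cv_results_``).
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    present = set(np.unique(y))
    if len(present) < 2:
        raise ValueError("training data must contain more than one class")
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svm",
                SVC(
                    kernel="rbf",
                    class_weight="balanced",
                    decision_function_shape="ovr",
                    random_state=seed,
                ),
            ),
        ]
    )
    n_folds = min(n_folds, int(min(np.bincount(np.unique(y, return_inverse=True)[1]))))
    n_folds = max(n_folds, 2)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        pipe,
        {"svm__C": list(c_grid), "svm__gamma": list(gamma_grid)},
        cv=cv,
        n_jobs=1,
    )
    search.fit(x, y)
    return search


def evaluate_classifier(
    predictions: np.ndarray | list,
    truth: np.ndarray | list,
    scores: np.ndarray | None = None,
    classes: tuple[str, ...] = NUCLEUS_CLASSES,
) -> ClassifierReport:
    """Confusion matrix, observed agreement, Cohen's kappa and (when
    per-class scores are given) one-vs-rest AUC per class.

    Ties in the scores are handled by midranks, so constant scores give
    AUC 0.5.
    """
    y_pred = np.asarray(predictions)
    y_true = np.asarray(truth)
    if y_pred.shape != y_true.shape:
        raise ValueError("predictions and truth differ in length")
    if len(set(np.unique(y_true))) < 2:
        raise ValueError("truth must contain at least 2 classes")
    labels = [c for c in classes]
    conf = confusion_matrix(y_true, y_pred, labels=labels)
    agreement = float(np.trace(conf) / conf.sum())
    kappa = float(cohen_kappa_score(y_true, y_pred, labels=labels))
    auc: dict[str, float] = {}
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        for i, cls in enumerate(labels):
            mask = y_true == cls
            if mask.any() and not mask.all():
                auc[cls] = float(roc_auc_score(mask.astype(int), scores[:, i]))
    return ClassifierReport(
        confusion=conf,
        cohen_kappa=kappa,
        observed_agreement=agreement,
        auc_per_class=auc,
    )


__all__ = [
    "NucleusRecord",
    "ClassifierReport",
    "segment_nuclei",
    "contour_mask",
    "extract_nuclear_features",
    "train_nucleus_classifier",
    "evaluate_classifier",
]
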