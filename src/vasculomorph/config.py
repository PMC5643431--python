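"""Fixed, versioned feature rosters and shared constants.

The dimensionalities below are structural contracts of the pipeline:

* 17 pixel features (5 EC-distance + 12 eosin sliding-window statistics);
* 22 primary binary-image features per tile across the 4 object sets
  (EC nuclei, branch points, arms, VAM);
* 4 distribution moments per primary feature, hence 88 vascular features
  (VF) per case;
* 63 nuclear morphometry/texture features.

Rosters are module-level tuples so that their composition is explicit,
stable across versions, and testable.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# Stain optical-density basis (Ruifrok & Johnston style H/E vectors).
# Rows are stains, columns are (R, G, B) optical densities; unit-normalized.
HE_STAIN_VECTORS = np.array(
    [
        [0.650, 0.704, 0.286],  # hematoxylin
        [0.072, 0.990, 0.105],  # eosin
    ]
)
HE_STAIN_NAMES = ("hematoxylin", "eosin")
BACKGROUND_INTENSITY = np.array([255.0, 255.0, 255.0])

# Sentinel for morphometric features that are undefined on a given tile
# (e.g. lacunarity of an empty mask).  NaN propagates visibly and is
# excluded per-feature during case aggregation.
SENTINEL = float("nan")

# ---------------------------------------------------------------------------
# 17 pixel features for vascular-area classification.
PIXEL_DISTANCE_RANKS = (1, 2, 3, 4, 5)
PIXEL_WINDOW_HALF_WIDTHS = (5, 15, 30)
PIXEL_WINDOW_STATS = ("mean", "sd", "max", "min")

PIXEL_FEATURE_NAMES = tuple(
    [f"ec_dist_{k}" for k in PIXEL_DISTANCE_RANKS]
    + [
        f"eosin_{stat}_w{h}"
        for h in PIXEL_WINDOW_HALF_WIDTHS
        for stat in PIXEL_WINDOW_STATS
    ]
)
assert len(PIXEL_FEATURE_NAMES) == 17

# ---------------------------------------------------------------------------
# 22 primary tile features over the four object sets.
OBJECT_SETS = ("ec", "bp", "arm", "vam")

PRIMARY_FEATURE_NAMES = tuple(
    [f"{s}_{f}" for s in OBJECT_SETS for f in ("density", "lacunarity", "fractal_dim")]
    + [
        "vam_object_count",
        "vam_mean_object_area",
        "vam_mean_solidity",
        "vam_mean_eccentricity",
        "vam_euler",
        "arm_count",
        "arm_mean_length",
        "arm_orientation_circ_sd",
        "ec_mean_nn_distance",
        "bp_count",
    ]
)
assert len(PRIMARY_FEATURE_NAMES) == 22

CASE_MOMENTS = ("mean", "sd", "skewness", "kurtosis")

VF_NAMES = tuple(
    f"{feat}_{m}" for feat in PRIMARY_FEATURE_NAMES for m in CASE_MOMENTS
)
assert len(VF_NAMES) == 88

# Default box size (px) for sliding-box lacunarity inside the tile roster.
LACUNARITY_BOX = 32
# Dyadic box sizes for the box-counting fractal dimension.
BOX_SIZES = (2, 4, 8, 16, 32, 64, 128, 256)

# ---------------------------------------------------------------------------
# 63 nuclear features: 13 shape + 2 channels x 9 intensity statistics
# + 2 channels x (4 GLCM properties x 4 offsets).
NUCLEUS_SHAPE_FEATURES = (
    "area",
    "perimeter",
    "circularity",
    "eccentricity",
    "solidity",
    "extent",
    "major_axis_length",
    "minor_axis_length",
    "aspect_ratio",
    "equivalent_diameter",
    "orientation",
    "convex_area",
    "perimeter_convexity",
)
NUCLEUS_INTENSITY_STATS = (
    "mean",
    "sd",
    "skewness",
    "kurtosis",
    "min",
    "max",
    "q25",
    "median",
    "q75",
)
NUCLEUS_GLCM_PROPS = ("contrast", "correlation", "energy", "homogeneity")
NUCLEUS_GLCM_ANGLES_DEG = (0, 45, 90, 135)
NUCLEUS_CHANNELS = ("hematoxylin", "eosin")

NUCLEUS_FEATURE_NAMES = tuple(
    list(NUCLEUS_SHAPE_FEATURES)
    + [
        f"{ch}_{stat}"
        for ch in NUCLEUS_CHANNELS
        for stat in NUCLEUS_INTENSITY_STATS
    ]
    + [
        f"{ch}_glcm_{prop}_a{ang}"
        for ch in NUCLEUS_CHANNELS
        for prop in NUCLEUS_GLCM_PROPS
        for ang in NUCLEUS_GLCM_ANGLES_DEG
    ]
)
assert len(NUCLEUS_FEATURE_NAMES) == 63

NUCLEUS_CLASSES = ("endothelial", "lymphocyte", "cancer")
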