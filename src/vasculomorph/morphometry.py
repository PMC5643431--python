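"""Binary-image morphometry of the vascular architecture.

Computes 22 primary features per image tile over four object sets — EC
nucleus mask, branch-point mask, arm mask, and the vascular area mask (VAM)
— and aggregates each primary feature's distribution across a case's tiles
into four moments (mean, SD, skewness, excess kurtosis), yielding the
88-element vascular-feature (VF) profile of a case.

Conventions
-----------
* Euler-Poincare characteristic: 8-connected components minus 4-connected
  holes.
* Fractal dimension: box counting on a fixed dyadic grid anchored at (0, 0).
* Lacunarity: sliding-box Lambda = E[M^2] / E[M]^2 with dense (stride-1)
  box placement.
* Kurtosis is excess kurtosis (normal distribution = 0) throughout.
* Features that are undefined on a tile (empty object set, zero variance)
  carry the NaN sentinel and are excluded per-feature at aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import measure

from .config import (
    BOX_SIZES,
    CASE_MOMENTS,
    LACUNARITY_BOX,
    PRIMARY_FEATURE_NAMES,
    SENTINEL,
    VF_NAMES,
)


@dataclass
class PrimaryFeatureVector:
    """22 primary binary-image features of one tile."""

    tile_id: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if tuple(self.values) != PRIMARY_FEATURE_NAMES:
            raise ValueError("primary feature roster mismatch")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in PRIMARY_FEATURE_NAMES])


@dataclass
class CaseFeatureProfile:
    """88 vascular features (22 primaries x 4 moments) of one case."""

    case_id: str
    vf: dict[str, float]
    n_tiles: int
    n_valid: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.vf) != VF_NAMES:
            raise ValueError("VF roster mismatch")

    def as_series(self) -> pd.Series:
        return pd.Series(self.vf, name=self.case_id)


def _as_bool(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    return mask.astype(bool)


def euler_poincare(mask: np.ndarray) -> int:
    """Euler-Poincare characteristic: 8-connected components minus
    4-connected holes of the foreground."""
    mask = _as_bool(mask)
    if not mask.any():
        return 0
    n_comp = ndimage.label(mask, structure=np.ones((3, 3)))[1]
    # Holes: 4-connected background components not touching the border.
    padded = np.pad(~mask, 1, constant_values=True)
    bg_lab, n_bg = ndimage.label(padded)
    border_labels = np.unique(
        np.concatenate([bg_lab[0], bg_lab[-1], bg_lab[:, 0], bg_lab[:, -1]])
    )
    n_holes = n_bg - np.count_nonzero(border_labels)
    return int(n_comp - n_holes)


def box_counting_dimension(
    mask: np.ndarray, box_sizes: tuple[int, ...] = BOX_SIZES
) -> float:
    """Box-counting fractal dimension.

    Least-squares slope of log N(s) against log(1/s), where N(s) is the
    number of s x s boxes of a grid anchored at (0, 0) that contain at
    least one foreground pixel.  Box sizes larger than the mask are
    skipped; at least 3 usable sizes are required.
    """
    mask = _as_bool(mask)
    if not mask.any():
        warnings.warn("box_counting_dimension: empty mask", stacklevel=2)
        return SENTINEL
    h, w = mask.shape
    sizes = [s for s in box_sizes if s <= min(h, w)]
    if len(sizes) < 3:
        raise ValueError("need at least 3 usable box sizes")
    counts = []
    for s in sizes:
        hh = -(-h // s) * s
        ww = -(-w // s) * s
        m = np.zeros((hh, ww), dtype=bool)
        m[:h, :w] = mask
        blocks = m.reshape(hh // s, s, ww // s, s).any(axis=(1, 3))
        counts.append(int(blocks.sum()))
    log_n = np.log(counts)
    log_inv = -np.log(sizes)
    slope = np.polyfit(log_inv, log_n, 1)[0]
    return float(slope)


def sliding_box_lacunarity(mask: np.ndarray, box_size: int = LACUNARITY_BOX) -> float:
    """Sliding-box lacunarity Lambda = E[M^2] / E[M]^2.

    M is the foreground mass within a box_size x box_size window slid with
    stride 1 over all fully interior positions.  Lambda >= 1 always
    (Jensen); equals 1 for a translation-invariant (full) mask.  Returns
    the NaN sentinel for an empty mask or when every box is empty.
    """
    mask = _as_bool(mask)
    if box_size < 1 or box_size >= min(mask.shape):
        raise ValueError("box_size must be in [1, min(mask dims))")
    if not mask.any():
        return SENTINEL
    # Box sums via 2-D cumulative sums: exact integer masses.
    c = np.cumsum(np.cumsum(np.pad(mask.astype(np.int64), ((1, 0), (1, 0))), 0), 1)
    b = box_size
    masses = c[b:, b:] - c[:-b, b:] - c[b:, :-b] + c[:-b, :-b]
    mean = masses.mean()
    if mean == 0:
        return SENTINEL
    return float((masses.astype(float) ** 2).mean() / mean**2)


def _object_stats(mask: np.ndarray) -> tuple[int, float, float, float]:
    """(count, mean area, mean solidity, mean eccentricity) of 8-connected
    foreground objects."""
    lab = measure.label(mask, connectivity=2)
    props = measure.regionprops(lab)
    if not props:
        return 0, SENTINEL, SENTINEL, SENTINEL
    areas = [p.area for p in props]
    sol = [p.solidity for p in props]
    ecc = [p.eccentricity for p in props]
    return len(props), float(np.mean(areas)), float(np.mean(sol)), float(np.mean(ecc))


def _circular_sd_axial(angles_deg: np.ndarray) -> float:
    """Circular standard deviation of axial orientations in [0, 180).

    Angles are doubled to map the axial data onto the circle, the circular
    SD is computed there, and halved back; result in degrees.
    """
    if angles_deg.size == 0:
        return SENTINEL
    doubled = np.deg2rad(angles_deg * 2.0)
    r = np.abs(np.mean(np.exp(1j * doubled)))
    if r <= 0:
        return SENTINEL
    # circular SD on the doubled scale, halved back to axial degrees
    sd = np.sqrt(-2.0 * np.log(r)) / 2.0
    return float(np.rad2deg(sd))


def _safe_lacunarity(mask: np.ndarray, box_size: int) -> float:
    if box_size >= min(mask.shape):
        return SENTINEL
    return sliding_box_lacunarity(mask, box_size)


def _safe_fractal(mask: np.ndarray) -> float:
    if not mask.any():
        return SENTINEL
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return box_counting_dimension(mask)


def tile_primary_features(
    ec_mask: np.ndarray,
    bp_mask: np.ndarray,
    arm_records: list[dict],
    vam_mask: np.ndarray,
    tile_id: str = "tile",
    lacunarity_box: int = LACUNARITY_BOX,
) -> PrimaryFeatureVector:
    """Compute the 22 primary features of one tile.

    Parameters
    ----------
    ec_mask, bp_mask, vam_mask
        Binary masks of EC nuclei, branch points, and the vascular area,
        all of identical shape.
    arm_records
        One dict per skeleton arm with keys ``pixels`` (Nx2 int array),
        ``length_px`` and ``orientation_deg``; typically
        ``VascularSkeleton.arms`` from :mod:`vasculomorph.vam`.
    """
    ec_mask = _as_bool(ec_mask)
    bp_mask = _as_bool(bp_mask)
    vam_mask = _as_bool(vam_mask)
    if not (ec_mask.shape == bp_mask.shape == vam_mask.shape):
        raise ValueError("masks must share dimensions")

    arm_mask = np.zeros_like(vam_mask)
    for rec in arm_records:
        px = np.asarray(rec["pixels"], dtype=int)
        if px.size:
            arm_mask[px[:, 0], px[:, 1]] = True

    values: dict[str, float] = {}
    sets = {"ec": ec_mask, "bp": bp_mask, "arm": arm_mask, "vam": vam_mask}
    for name, m in sets.items():
        values[f"{name}_density"] = float(m.mean())
        values[f"{name}_lacunarity"] = _safe_lacunarity(m, lacunarity_box)
        values[f"{name}_fractal_dim"] = _safe_fractal(m)

    n_obj, mean_area, mean_sol, mean_ecc = _object_stats(vam_mask)
    values["vam_object_count"] = float(n_obj)
    values["vam_mean_object_area"] = mean_area
    values["vam_mean_solidity"] = mean_sol
    values["vam_mean_eccentricity"] = mean_ecc
    values["vam_euler"] = float(euler_poincare(vam_mask))

    values["arm_count"] = float(len(arm_records))
    if arm_records:
        values["arm_mean_length"] = float(
            np.mean([r["length_px"] for r in arm_records])
        )
        values["arm_orientation_circ_sd"] = _circular_sd_axial(
            np.array([r["orientation_deg"] for r in arm_records], dtype=float)
        )
    else:
        values["arm_mean_length"] = SENTINEL
        values["arm_orientation_circ_sd"] = SENTINEL

    ec_pts = np.argwhere(ec_mask)
    # EC spatial statistics use nucleus centroids (one point per object).
    lab = measure.label(ec_mask, connectivity=2)
    cents = np.array([p.centroid for p in measure.regionprops(lab)])
    if len(cents) >= 2:
        from scipy.spatial import cKDTree

        d, _ = cKDTree(cents).query(cents, k=2)
        values["ec_mean_nn_distance"] = float(d[:, 1].mean())
    else:
        values["ec_mean_nn_distance"] = SENTINEL
    del ec_pts

    values["bp_count"] = float(measure.label(bp_mask, connectivity=2).max())

    ordered = {k: values[k] for k in PRIMARY_FEATURE_NAMES}
    return PrimaryFeatureVector(tile_id=tile_id, values=ordered)


def aggregate_case(
    tiles: list[PrimaryFeatureVector], case_id: str = "case"
) -> CaseFeatureProfile:
    """Aggregate per-tile primaries into the case's 88 vascular features.

    For each of the 22 primary features, the distribution of its value
    across the case's tiles is summarized by the sample mean, sample SD
    (n-1), skewness (g1) and excess kurtosis (g2).  Tiles where a feature
    is sentinel-valued are excluded from that feature's moments, with the
    valid count recorded.  Zero-variance features get SD 0 and sentinel
    skewness/kurtosis (moments undefined).
    """
    if len(tiles) < 3:
        raise ValueError(
            f"case aggregation requires >= 3 tiles, got {len(tiles)}"
        )
    table = np.stack([t.as_array() for t in tiles])  # tiles x 22
    vf: dict[str, float] = {}
    n_valid: dict[str, int] = {}
    for j, feat in enumerate(PRIMARY_FEATURE_NAMES):
        col = table[:, j]
        col = col[np.isfinite(col)]
        n_valid[feat] = int(col.size)
        if col.size == 0:
            m = s = g1 = g2 = SENTINEL
        else:
            m = float(col.mean())
            s = float(col.std(ddof=1)) if col.size > 1 else 0.0
            if col.size > 2 and s > 0:
                g1 = float(stats.skew(col, bias=True))
                g2 = float(stats.kurtosis(col, bias=True))
            else:
                g1 = g2 = SENTINEL
        vf[f"{feat}_mean"] = m
        vf[f"{feat}_sd"] = s
        vf[f"{feat}_skewness"] = g1
        vf[f"{feat}_kurtosis"] = g2
    ordered = {k: vf[k] for k in VF_NAMES}
    return CaseFeatureProfile(
        case_id=case_id, vf=ordered, n_tiles=len(tiles), n_valid=n_valid
    )


def profiles_to_frame(profiles: list[CaseFeatureProfile]) -> pd.DataFrame:
    """Stack case profiles into a cases x 88 DataFrame."""
    return pd.DataFrame([p.as_series() for p in profiles])


__all__ = [
    "PrimaryFeatureVector",
    "CaseFeatureProfile",
    "euler_poincare",
    "box_counting_dimension",
    "sliding_box_lacunarity",
    "tile_primary_features",
    "aggregate_case",
    "profiles_to_frame",
    "CASE_MOMENTS",
]
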