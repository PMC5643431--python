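"""Stain unmixing, IHC color segmentation, co-registration, label transfer.

Color deconvolution follows the Beer-Lambert model: a pixel's optical
density ``OD = -log10(I / I0)`` is linear in the per-stain absorbance
densities, with known unit stain vectors in OD-RGB space.  Unmixing inverts
this with the pseudo-inverse of the stain matrix.

IHC tiles (CD31 purple for endothelium, CD45/DAB brown for lymphocytes,
hematoxylin counterstain) are segmented with a six-state Gaussian hidden
Markov model over RGB pixels, decoded row-by-row with the Viterbi
algorithm: three ink states (dab, cd31_purple, hematoxylin) and three
background states (white_bg, light_blue, light_brown).

Co-registration of an IHC tile onto its sibling H&E tile is an affine fit
maximizing intensity agreement of the shared hematoxylin channel, and the
resulting CD31/CD45 masks are dilated and projected onto H&E nuclear
segmentations to impose cell-class labels (majority-overlap rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM
from scipy import ndimage, optimize
from skimage import draw, morphology, transform

from .config import BACKGROUND_INTENSITY, HE_STAIN_NAMES, HE_STAIN_VECTORS

HMM_STATE_NAMES = (
    "dab",
    "cd31_purple",
    "hematoxylin",
    "white_bg",
    "light_blue",
    "light_brown",
)

_OD_EPS = 1e-6


@dataclass
class StainBasis:
    """Unit stain vectors in optical-density RGB space plus background I0."""

    stain_vectors: np.ndarray = field(
        default_factory=lambda: HE_STAIN_VECTORS.copy()
    )
    stain_names: tuple[str, ...] = HE_STAIN_NAMES
    background_intensity: np.ndarray = field(
        default_factory=lambda: BACKGROUND_INTENSITY.copy()
    )

    def __post_init__(self) -> None:
        v = np.asarray(self.stain_vectors, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 2:
            raise ValueError("stain_vectors must be (n_stains >= 2, 3)")
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero stain vector")
        self.stain_vectors = v / norms[:, None]
        # pairwise non-parallel check
        g = self.stain_vectors @ self.stain_vectors.T
        off = np.abs(g[~np.eye(len(v), dtype=bool)])
        if np.any(off > 1 - 1e-6):
            raise ValueError("stain vectors are (anti)parallel: basis degenerate")


@dataclass
class StainChannels:
    """Named non-negative absorbance images unmixed from an RGB tile."""

    channels: dict[str, np.ndarray]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


def rgb_to_od(rgb: np.ndarray, i0: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb, dtype=float)
    return -np.log10(np.clip(rgb, _OD_EPS, None) / np.asarray(i0, dtype=float))


def od_to_rgb(od: np.ndarray, i0: np.ndarray) -> np.ndarray:
    return np.asarray(i0, dtype=float) * 10.0 ** (-np.asarray(od, dtype=float))


def render_stains(densities: dict[str, np.ndarray], basis: StainBasis) -> np.ndarray:
    """Render an RGB image from per-stain absorbance densities (the exact
    inverse of :func:`unmix_stains` up to clipping/normalization).

    Returns a float image in [0, 255]; quantize to uint8 for file output.
    """
    names = list(basis.stain_names)
    first = densities[names[0]]
    od = np.zeros(first.shape + (3,), dtype=float)
    for i, name in enumerate(names):
        od += densities[name][..., None] * basis.stain_vectors[i]
    return np.clip(od_to_rgb(od, basis.background_intensity), 0, 255)


def unmix_stains(
    rgb: np.ndarray, basis: StainBasis | None = None, normalize: bool = True
) -> StainChannels:
    """Unmix an RGB tile into per-stain absorbance channels.

    Converts to optical density and projects onto the pseudo-inverse of the
    stain matrix; negative projections are clipped to 0.  With
    ``normalize=True`` each channel is scaled to [0, 1] by its own 99th
    percentile (channels that are identically 0 are left as is).
    """
    basis = basis or StainBasis()
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("rgb must be H x W x 3")
    od = rgb_to_od(rgb, basis.background_intensity)
    pinv = np.linalg.pinv(basis.stain_vectors)  # 3 x n_stains
    dens = od @ pinv
    dens = np.clip(dens, 0, None)
    channels = {}
    for i, name in enumerate(basis.stain_names):
        ch = dens[..., i]
        if normalize:
            p99 = np.percentile(ch, 99)
            if p99 > 0:
                ch = np.clip(ch / p99, 0, 1)
        channels[name] = ch
    return StainChannels(channels=channels)


# ---------------------------------------------------------------------------
# HMM color segmentation of IHC


@dataclass
class HMMColorModel:
    """Six-state Gaussian HMM over RGB pixel rows of an IHC tile."""

    state_names: tuple[str, ...]
    means: np.ndarray  # n_states x 3
    covariances: np.ndarray  # n_states x 3 x 3
    transition: np.ndarray  # n_states x n_states, row-stochastic
    initial: np.ndarray  # n_states

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def _hmm(self) -> GaussianHMM:
        m = GaussianHMM(n_components=self.n_states, covariance_type="full")
        m.startprob_ = self.initial
        m.transmat_ = self.transition
        m.means_ = self.means
        m.covars_ = self.covariances
        return m

    def decode_rows(self, rgb: np.ndarray) -> np.ndarray:
        """Viterbi-decode each image row independently (left to right).

        Returns an H x W integer state map.
        """
        rgb = np.asarray(rgb, dtype=float)
        h, w, _ = rgb.shape
        x = rgb.reshape(h * w, 3)
        lengths = [w] * h
        m = self._hmm()
        _, states = m.decode(x, lengths=lengths, algorithm="viterbi")
        return states.reshape(h, w)


def train_color_hmm(
    labeled_pixels: dict[str, np.ndarray],
    pseudo_count: float = 5.0,
    self_bias: float = 0.9,
    max_iter: int = 20,
) -> HMMColorModel:
    """Train the six-state color HMM from per-state RGB pixel samples.

    Emissions are Gaussian with the per-state sample mean and covariance
    (covariance regularized by ``pseudo_count * I``).  The transition
    matrix starts self-biased (``self_bias`` on the diagonal, remainder
    uniform) and is refined by segmental Viterbi training on the pooled
    training rows: decode, re-count transitions, repeat until the decoded
    assignments stabilize or ``max_iter`` sweeps.
    """
    missing = [s for s in HMM_STATE_NAMES if s not in labeled_pixels]
    if missing:
        raise ValueError(f"missing state samples: {missing}")
    n = len(HMM_STATE_NAMES)
    means = np.zeros((n, 3))
    covs = np.zeros((n, 3, 3))
    for i, name in enumerate(HMM_STATE_NAMES):
        x = np.asarray(labeled_pixels[name], dtype=float)
        if x.ndim != 2 or x.shape[1] != 3 or len(x) < 20:
            raise ValueError(f"state '{name}' needs >= 20 RGB samples")
        means[i] = x.mean(axis=0)
        covs[i] = np.cov(x.T) + pseudo_count * np.eye(3)
    # emission collision check
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(means[i] - means[j]) < 1.0:
                warnings.warn(
                    f"emission collision between states "
                    f"'{HMM_STATE_NAMES[i]}' and '{HMM_STATE_NAMES[j]}'",
                    stacklevel=2,
                )
    trans = np.full((n, n), (1 - self_bias) / (n - 1))
    np.fill_diagonal(trans, self_bias)
    initial = np.full(n, 1.0 / n)
    model = HMMColorModel(
        state_names=HMM_STATE_NAMES,
        means=means,
        covariances=covs,
        transition=trans,
        initial=initial,
    )
    # Segmental Viterbi refinement of the transition matrix on training
    # rows (each state's sample block treated as one observation row).
    rows = [np.asarray(labeled_pixels[s], dtype=float) for s in HMM_STATE_NAMES]
    x = np.vstack(rows)
    lengths = [len(r) for r in rows]
    prev = None
    for _ in range(max_iter):
        m = model._hmm()
        _, states = m.decode(x, lengths=lengths, algorithm="viterbi")
        if prev is not None and np.array_equal(states, prev):
            break
        prev = states
        counts = np.full((n, n), 1e-3)  # smoothing keeps rows stochastic
        start = 0
        for ln in lengths:
            seq = states[start : start + ln]
            np.add.at(counts, (seq[:-1], seq[1:]), 1.0)
            start += ln
        model.transition = counts / counts.sum(axis=1, keepdims=True)
    return model


@dataclass
class IHCLabelMask:
    """Binary masks of positive CD31 (endothelium) and CD45 (lymphocyte)
    IHC staining; disjoint by construction."""

    cd31_mask: np.ndarray
    cd45_mask: np.ndarray


def segment_ihc(
    rgb: np.ndarray, model: HMMColorModel, min_size: int = 20
) -> IHCLabelMask:
    """Segment an IHC tile into CD31/CD45 positive-staining masks.

    Rows are decoded independently by Viterbi; the CD31 mask collects
    pixels decoded as the purple ink state and the CD45 mask the DAB state.
    Both masks are despeckled by removing 8-connected components smaller
    than ``min_size`` pixels.
    """
    states = model.decode_rows(rgb)
    idx = {name: i for i, name in enumerate(model.state_names)}
    cd31 = states == idx["cd31_purple"]
    cd45 = states == idx["dab"]
    cd31 = morphology.remove_small_objects(cd31, max_size=min_size - 1, connectivity=2)
    cd45 = morphology.remove_small_objects(cd45, max_size=min_size - 1, connectivity=2)
    cd45 &= ~cd31
    return IHCLabelMask(cd31_mask=cd31, cd45_mask=cd45)


# ---------------------------------------------------------------------------
# Affine co-registration


@dataclass
class AffineTransform:
    """2x3 matrix mapping moving (row, col) coordinates into the fixed frame."""

    matrix: np.ndarray
    converged: bool = True
    final_metric: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 3)
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-12:
            raise ValueError("singular linear part")

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    def warp_image(self, image: np.ndarray, order: int = 1) -> np.ndarray:
        """Resample ``image`` (moving frame) onto the fixed frame."""
        a = np.vstack([self.matrix, [0, 0, 1]])
        inv = np.linalg.inv(a)
        return ndimage.affine_transform(
            np.asarray(image, dtype=float),
            inv[:2, :2],
            offset=inv[:2, 2],
            order=order,
            mode="constant",
            cval=0.0,
        )


def _params_to_matrix(p: np.ndarray, center: np.ndarray) -> np.ndarray:
    """(angle_rad, tr, tc, log_sr, log_sc, shear) -> 2x3 about the center."""
    ang, tr, tc, lsr, lsc, sh = p
    r = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    s = np.array([[np.exp(lsr), sh], [0.0, np.exp(lsc)]])
    lin = r @ s
    t = center - lin @ center + np.array([tr, tc])
    return np.hstack([lin, t[:, None]])


def register_affine(
    fixed: np.ndarray,
    moving: np.ndarray,
    max_iter: int = 200,
    levels: int = 3,
    tol: float = 1e-7,
) -> AffineTransform:
    """Intensity-based affine registration (MSE, multi-resolution Powell).

    Optimizes rotation, translation, anisotropic log-scale and shear about
    the image center over a Gaussian pyramid with ``levels`` levels, coarse
    to fine.  Images must share dimensions.  Returns the transform mapping
    moving coordinates into the fixed frame; ``converged`` is False when
    the optimizer exhausted ``max_iter`` at the finest level.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape or fixed.ndim != 2:
        raise ValueError("fixed and moving must be same-size 2-D images")

    center_full = (np.array(fixed.shape) - 1) / 2.0
    p = np.zeros(6)
    converged = True
    metric = np.inf
    for level in range(levels - 1, -1, -1):
        scale = 2**level
        if scale > 1:
            f = transform.rescale(
                ndimage.gaussian_filter(fixed, scale), 1 / scale, anti_aliasing=False
            )
            m = transform.rescale(
                ndimage.gaussian_filter(moving, scale), 1 / scale, anti_aliasing=False
            )
        else:
            f = ndimage.gaussian_filter(fixed, 0.5)
            m = ndimage.gaussian_filter(moving, 0.5)
        center = (np.array(f.shape) - 1) / 2.0

        def cost(q: np.ndarray) -> float:
            mat = _params_to_matrix(q, center)
            warped = AffineTransform(mat).warp_image(m)
            return float(np.mean((warped - f) ** 2))

        # translation scales with the pyramid level
        q0 = p.copy()
        q0[1:3] /= scale
        res = optimize.minimize(
            cost,
            q0,
            method="Powell",
            options={"maxiter": max_iter, "xtol": tol, "ftol": tol},
        )
        p = res.x.copy()
        p[1:3] *= scale
        metric = res.fun
        if level == 0:
            converged = bool(res.success)

    mat = _params_to_matrix(p, center_full)
    out = AffineTransform(mat, converged=converged, final_metric=metric)
    if not converged:
        warnings.warn(
            f"register_affine did not converge (MSE={metric:.4g})", stacklevel=2
        )
    return out


# ---------------------------------------------------------------------------
# Label transfer onto H&E nuclei


def _contour_interior(contour: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = draw.polygon(contour[:, 0], contour[:, 1], shape=shape)
    return rr, cc


def transfer_labels(
    ihc: IHCLabelMask,
    t: AffineTransform,
    nuclei: list[np.ndarray],
    dilation_radius: int = 5,
    overlap_frac: float = 0.5,
) -> list[str]:
    """Impose IHC cell-class labels on H&E nucleus contours.

    Each IHC mask is warped into the H&E frame with ``t``, dilated by a
    disc of ``dilation_radius``; a nucleus is labeled ``endothelial`` /
    ``lymphocyte`` when at least ``overlap_frac`` of its interior pixels
    fall inside the warped, dilated CD31 / CD45 mask (CD31 wins ties), and
    ``cancer`` otherwise.  Degenerate contours are labeled ``cancer`` with
    a warning.
    """
    if not 0 < overlap_frac <= 1:
        raise ValueError("overlap_frac must be in (0, 1]")
    shape = ihc.cd31_mask.shape
    disc = morphology.disk(dilation_radius)
    warped = []
    for mask in (ihc.cd31_mask, ihc.cd45_mask):
        w = t.warp_image(mask.astype(float)) > 0.5
        warped.append(morphology.dilation(w, disc))
    cd31_w, cd45_w = warped

    labels = []
    for contour in nuclei:
        contour = np.asarray(contour, dtype=float)
        if contour.size == 0:
            rr = cc = np.empty(0, dtype=int)
        else:
            rr, cc = _contour_interior(contour, shape)
        if rr.size == 0:
            warnings.warn("empty nucleus contour skipped", stacklevel=2)
            labels.append("cancer")
            continue
        f31 = cd31_w[rr, cc].mean()
        f45 = cd45_w[rr, cc].mean()
        if f31 >= overlap_frac and f31 >= f45:
            labels.append("endothelial")
        elif f45 >= overlap_frac and f45 > f31:
            labels.append("lymphocyte")
        else:
            labels.append("cancer")
    return labels


__all__ = [
    "StainBasis",
    "StainChannels",
    "HMMColorModel",
    "HMM_STATE_NAMES",
    "IHCLabelMask",
    "AffineTransform",
    "rgb_to_od",
    "od_to_rgb",
    "render_stains",
    "unmix_stains",
    "train_color_hmm",
    "segment_ihc",
    "register_affine",
    "transfer_labels",
]
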