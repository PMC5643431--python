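"""Synthetic vascular tiles and simulated cohorts with planted structure.

Two generators make the whole pipeline testable without slide archives:

``generate_vessel_network``
    Grows a branched tubular vessel network by a biased random walk with
    Bernoulli branching, lines its walls with endothelial-cell (EC) nuclei,
    fills the stroma with cancer (and a few lymphocyte) nuclei, and renders
    the scene twice — as an H&E tile (Beer-Lambert mixing of hematoxylin
    and eosin absorbances) and as a pseudo-IHC tile (CD31 purple vessel
    ink, DAB-brown lymphocytes, hematoxylin counterstain) — together with
    exact ground truth: vessel mask, ink masks, nucleus contours and the
    per-pixel IHC color-state map.

``simulate_cohort``
    Draws a cohort with two planted vascular-phenotype risk groups: tile-
    and case-level vascular features whose means differ between groups, a
    gene-expression matrix in which a designated subset of genes tracks
    designated features with a controlled Pearson correlation, and
    exponential disease-free-survival times with a planted hazard ratio
    between groups plus independent censoring.

Everything is driven by ``numpy.random.default_rng`` so that a fixed seed
reproduces tiles and cohorts bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import draw, morphology

from .config import VF_NAMES
from .stains import HMM_STATE_NAMES, StainBasis, render_stains

# ---------------------------------------------------------------------------
# Tiles

# Mean RGB of the six IHC color states used for rendering.
IHC_STATE_COLORS = {
    "dab": (140, 90, 40),
    "cd31_purple": (110, 45, 115),
    "hematoxylin": (70, 70, 150),
    "white_bg": (243, 243, 246),
    "light_blue": (205, 214, 236),
    "light_brown": (214, 196, 168),
}


@dataclass
class GroundTruthTile:
    """A rendered tile pair with exact ground truth."""

    rgb_he: np.ndarray
    rgb_ihc: np.ndarray
    vessel_mask: np.ndarray
    ec_centroids: list[tuple[float, float]]
    lymph_centroids: list[tuple[float, float]]
    cancer_centroids: list[tuple[float, float]]
    nucleus_contours: list[tuple[str, np.ndarray]]
    seed: int
    cd31_ink: np.ndarray = None
    cd45_ink: np.ndarray = None
    ihc_states: np.ndarray = None
    hematoxylin_density: np.ndarray = None
    eosin_density: np.ndarray = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.vessel_mask.shape


def _ellipse_polygon(
    center: tuple[float, float],
    axes: tuple[float, float],
    angle: float,
    n_vertices: int = 32,
) -> np.ndarray:
    """Closed polygon approximating a rotated ellipse (row, col vertices)."""
    t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = axes[0] * np.cos(t)
    c = axes[1] * np.sin(t)
    rot_r = r * np.cos(angle) - c * np.sin(angle) + center[0]
    rot_c = r * np.sin(angle) + c * np.cos(angle) + center[1]
    return np.column_stack([rot_r, rot_c])


def _paint_polygon(canvas: np.ndarray, poly: np.ndarray, value: float) -> None:
    rr, cc = draw.polygon(poly[:, 0], poly[:, 1], shape=canvas.shape)
    canvas[rr, cc] = value


def _poisson_sample(
    rng: np.random.Generator, candidates: np.ndarray, min_dist: float, n_max: int
) -> np.ndarray:
    """Greedy blue-noise subsample of candidate (row, col) points."""
    if len(candidates) == 0:
        return candidates.reshape(0, 2)
    order = rng.permutation(len(candidates))
    chosen: list[np.ndarray] = []
    d2 = min_dist**2
    for i in order:
        p = candidates[i]
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= d2 for q in chosen):
            chosen.append(p)
            if len(chosen) >= n_max:
                break
    return np.array(chosen, dtype=float).reshape(-1, 2)


def generate_vessel_network(
    width: int = 256,
    height: int = 256,
    n_seeds: int = 3,
    branch_prob: float = 0.02,
    thickness_range: tuple[int, int] = (4, 8),
    seed: int = 0,
    turn_sd: float = 0.15,
    noise_sd: float = 4.0,
    ec_spacing: float = 9.0,
    cancer_spacing: float = 13.0,
    lymph_fraction: float = 0.03,
    basis: StainBasis | None = None,
) -> GroundTruthTile:
    """Grow and render a branched vascular network tile.

    The vessel mask is laid down by ``n_seeds`` biased random walks: each
    step advances one pixel along the current heading, perturbs the heading
    by a Gaussian of SD ``turn_sd`` radians, stamps a disc whose radius is
    drawn per branch from ``thickness_range``, and spawns a new branch with
    probability ``branch_prob`` (heading deflected by 40-80 degrees).  EC
    nuclei are placed along the vessel wall band, cancer nuclei fill the
    stroma, and a fraction ``lymph_fraction`` of stromal nuclei are
    lymphocytes.  ``turn_sd=0`` with ``branch_prob=0`` gives perfectly
    straight vessels.

    With ``noise_sd=0`` the H&E rendering is the exact Beer-Lambert image
    of the returned hematoxylin/eosin density maps, so stain unmixing has a
    known inverse.
    """
    if width <= 0 or height <= 0:
        raise ValueError("tile dimensions must be positive")
    if not 0 <= branch_prob <= 1:
        raise ValueError("branch_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    basis = basis or StainBasis()
    shape = (height, width)

    vessel = np.zeros(shape, dtype=bool)
    max_branches = 12
    max_steps = int(0.7 * (width + height))
    stack: list[tuple[float, float, float]] = []
    for _ in range(n_seeds):
        stack.append(
            (
                rng.uniform(0.1 * height, 0.9 * height),
                rng.uniform(0.1 * width, 0.9 * width),
                rng.uniform(0, 2 * np.pi),
            )
        )
    n_branches = 0
    while stack and n_branches < max_branches:
        r, c, theta = stack.pop()
        n_branches += 1
        radius = int(rng.integers(thickness_range[0], thickness_range[1] + 1))
        for _ in range(max_steps):
            rr, cc = draw.disk((r, c), radius, shape=shape)
            vessel[rr, cc] = True
            r += np.cos(theta)
            c += np.sin(theta)
            if not (0 <= r < height and 0 <= c < width):
                break
            if turn_sd > 0:
                theta += rng.normal(0, turn_sd)
            if branch_prob > 0 and rng.random() < branch_prob:
                sign = 1 if rng.random() < 0.5 else -1
                stack.append(
                    (r, c, theta + sign * np.deg2rad(rng.uniform(40, 80)))
                )

    # Vessel wall band: where EC nuclei sit and where CD31 ink deposits.
    wall = vessel & ~morphology.erosion(vessel, morphology.disk(3))

    ec_pts = _poisson_sample(
        rng, np.argwhere(wall), ec_spacing, n_max=max(1, int(wall.sum() / 50))
    )
    stroma = ~morphology.dilation(vessel, morphology.disk(4))
    stroma[: int(0.02 * height)] = False
    stroma_pts = _poisson_sample(
        rng, np.argwhere(stroma), cancer_spacing, n_max=int(width * height / 450)
    )
    n_lymph = int(round(lymph_fraction * len(stroma_pts)))
    lymph_pts = stroma_pts[:n_lymph]
    cancer_pts = stroma_pts[n_lymph:]

    # Nucleus contours, exact as rendered.
    contours: list[tuple[str, np.ndarray]] = []
    hema = np.zeros(shape)
    for cls, pts, ax in (
        ("endothelial", ec_pts, (2.2, 4.2)),
        ("lymphocyte", lymph_pts, (2.6, 2.9)),
        ("cancer", cancer_pts, (3.4, 4.8)),
    ):
        for p in pts:
            axes = (
                ax[0] * rng.uniform(0.85, 1.15),
                ax[1] * rng.uniform(0.85, 1.15),
            )
            poly = _ellipse_polygon(tuple(p), axes, rng.uniform(0, np.pi))
            contours.append((cls, poly))
            _paint_polygon(hema, poly, rng.uniform(0.75, 1.0))

    eosin = np.where(vessel, 0.75, 0.06).astype(float)
    eosin += 0.02 * rng.standard_normal(shape)
    eosin = np.clip(eosin, 0, None)

    rgb_he = render_stains({"hematoxylin": hema, "eosin": eosin}, basis)
    if noise_sd > 0:
        rgb_he = rgb_he + rng.normal(0, noise_sd, rgb_he.shape)
    rgb_he = np.clip(rgb_he, 0, 255).astype(np.uint8)

    # ------------------------------------------------------------------
    # Pseudo-IHC rendering via a per-pixel color-state map.
    names = list(HMM_STATE_NAMES)
    idx = {n: i for i, n in enumerate(names)}
    states = np.full(shape, idx["white_bg"], dtype=np.int8)
    # light-blue cytoplasm halo around all nuclei
    nuc_mask = hema > 0
    halo = morphology.dilation(nuc_mask, morphology.disk(3)) & ~nuc_mask
    states[halo] = idx["light_blue"]
    # a few light-brown residual-DAB smudges
    for _ in range(3):
        ctr = (rng.uniform(0, height), rng.uniform(0, width))
        rr, cc = draw.disk(ctr, rng.uniform(8, 16), shape=shape)
        states[rr, cc] = idx["light_brown"]
    cd31_ink = wall.copy()
    states[cd31_ink] = idx["cd31_purple"]
    # hematoxylin counterstain on non-lymphocyte nuclei; DAB on lymphocytes
    cd45_ink = np.zeros(shape, dtype=bool)
    for cls, poly in contours:
        rr, cc = draw.polygon(poly[:, 0], poly[:, 1], shape=shape)
        if cls == "lymphocyte":
            cd45_ink[rr, cc] = True
            states[rr, cc] = idx["dab"]
        else:
            keep = ~cd31_ink[rr, cc]
            states[rr[keep], cc[keep]] = idx["hematoxylin"]

    palette = np.array([IHC_STATE_COLORS[n] for n in names], dtype=float)
    rgb_ihc = palette[states]
    if noise_sd > 0:
        rgb_ihc = rgb_ihc + rng.normal(0, noise_sd, rgb_ihc.shape)
    rgb_ihc = np.clip(rgb_ihc, 0, 255).astype(np.uint8)

    return GroundTruthTile(
        rgb_he=rgb_he,
        rgb_ihc=rgb_ihc,
        vessel_mask=vessel,
        ec_centroids=[tuple(p) for p in ec_pts],
        lymph_centroids=[tuple(p) for p in lymph_pts],
        cancer_centroids=[tuple(p) for p in cancer_pts],
        nucleus_contours=contours,
        seed=seed,
        cd31_ink=cd31_ink,
        cd45_ink=cd45_ink,
        ihc_states=np.asarray(states, dtype=int),
        hematoxylin_density=hema,
        eosin_density=eosin,
    )


def sample_state_pixels(
    tile: GroundTruthTile, n_per_state: int = 200, seed: int = 0
) -> dict[str, np.ndarray]:
    """Draw labeled RGB training pixels per IHC color state from a tile."""
    rng = np.random.default_rng(seed)
    out = {}
    rgb = tile.rgb_ihc.astype(float)
    for i, name in enumerate(HMM_STATE_NAMES):
        pts = np.argwhere(tile.ihc_states == i)
        if len(pts) == 0:
            raise ValueError(f"tile has no pixels of state '{name}'")
        take = pts[rng.integers(0, len(pts), size=n_per_state)]
        out[name] = rgb[take[:, 0], take[:, 1]]
    return out


# ---------------------------------------------------------------------------
# Cohorts

#: Vascular features carrying the planted group difference; chosen to span
#: EC density/texture, arm arrangement and lacunarity moments.
DEFAULT_INFORMATIVE_VF = (
    "ec_density_mean",
    "ec_density_sd",
    "ec_lacunarity_sd",
    "bp_lacunarity_sd",
    "arm_orientation_circ_sd_mean",
    "arm_orientation_circ_sd_sd",
    "arm_count_skewness",
    "ec_density_kurtosis",
    "arm_lacunarity_kurtosis",
)


@dataclass
class SyntheticCohortSpec:
    """Parameters of a planted two-risk-group cohort simulation."""

    n_cases: int = 64
    tiles_per_case: tuple[int, int] = (3, 74)
    n_genes: int = 2000
    n_signal_genes: int = 14
    planted_hazard_ratio: float = 2.4
    correlation_strength: float = 0.6
    censoring_rate: float = 0.3
    seed: int = 0
    feature_effect_size: float = 2.0
    n_informative_features: int = 9
    high_risk_fraction: float = 0.375
    baseline_median_months: float = 36.0
    max_followup_months: float = 120.0

    def __post_init__(self) -> None:
        if self.n_signal_genes > self.n_genes:
            raise ValueError("n_signal_genes must not exceed n_genes")
        if self.planted_hazard_ratio <= 0:
            raise ValueError("planted_hazard_ratio must be positive")
        if not 0 <= self.correlation_strength <= 1:
            raise ValueError("correlation_strength must be in [0, 1]")
        if not 0 <= self.censoring_rate <= 1:
            raise ValueError("censoring_rate must be in [0, 1]")
        if self.n_cases < 2:
            raise ValueError("need at least 2 cases")


@dataclass
class CohortTables:
    """Simulated cohort: expression, survival, features and planted truth."""

    expression: pd.DataFrame  # genes x cases
    survival: pd.DataFrame  # case_id, dfs_months, event, stage_high, grade_high
    features: pd.DataFrame  # cases x 88 VF
    tile_features: pd.DataFrame  # long: case_id, tile_id, feature, value
    risk_groups: pd.Series  # planted group per case (1 = high risk)
    signal_genes: list[str] = field(default_factory=list)
    informative_features: list[str] = field(default_factory=list)
    spec: SyntheticCohortSpec | None = None


def simulate_cohort(
    spec: SyntheticCohortSpec, signal_genes: list[str] | None = None
) -> CohortTables:
    """Simulate a cohort with two planted vascular-phenotype risk groups.

    Case-level vascular features are tile-mean aggregates; informative
    features differ between groups by ``feature_effect_size`` between-case
    SDs, with within-case (tile) noise half the between-case spread so that
    intra-case variance is smaller than inter-case variance.  Signal genes
    follow ``log2(expr + 1) = a + rho * z(feature) + sqrt(1 - rho^2) * eps``
    against their assigned informative feature.  Survival is exponential
    per group with the planted hazard ratio, subject to independent uniform
    censoring at the requested rate and administrative censoring at the
    maximum follow-up.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases
    case_ids = [f"case_{i:03d}" for i in range(n)]
    group = (rng.random(n) < spec.high_risk_fraction).astype(int)
    # guarantee both groups present
    if group.sum() == 0:
        group[0] = 1
    elif group.sum() == n:
        group[0] = 0

    informative = list(DEFAULT_INFORMATIVE_VF[: spec.n_informative_features])
    if len(informative) < spec.n_informative_features:
        extra = [f for f in VF_NAMES if f not in informative]
        informative += extra[: spec.n_informative_features - len(informative)]

    lo, hi = spec.tiles_per_case
    n_tiles = np.clip(
        np.round(rng.normal(25, 18, size=n)).astype(int), lo, hi
    )

    between_sd = 1.0
    within_sd = 0.5
    feat_rows = []
    tile_rows = []
    base_mu = {f: rng.uniform(1.0, 8.0) for f in VF_NAMES}
    base_scale = {f: base_mu[f] * rng.uniform(0.1, 0.6) for f in VF_NAMES}
    for f in informative:
        base_scale[f] = max(base_scale[f], 0.4 * base_mu[f])
    for i, cid in enumerate(case_ids):
        case_vals = {}
        for f in VF_NAMES:
            scale = base_scale[f]
            shift = (
                spec.feature_effect_size * between_sd * group[i]
                if f in informative
                else 0.0
            )
            case_mean = base_mu[f] + scale * (
                shift + between_sd * rng.normal()
            )
            tiles = case_mean + scale * within_sd * rng.normal(size=n_tiles[i])
            case_vals[f] = tiles.mean()
            if f in informative:
                for j, tv in enumerate(tiles):
                    tile_rows.append(
                        {
                            "case_id": cid,
                            "tile_id": f"{cid}_t{j:02d}",
                            "feature": f,
                            "value": tv,
                        }
                    )
        feat_rows.append(pd.Series(case_vals, name=cid))
    features = pd.DataFrame(feat_rows)[list(VF_NAMES)]
    tile_features = pd.DataFrame(tile_rows)

    # Expression ---------------------------------------------------------
    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    if signal_genes is None:
        signal_genes = list(
            rng.choice(gene_ids, size=spec.n_signal_genes, replace=False)
        )
    else:
        # fixed identities let a validation cohort share the discovery
        # cohort's planted gene-feature structure
        signal_genes = list(signal_genes)
        if not set(signal_genes) <= set(gene_ids):
            raise ValueError("signal_genes must be drawn from the gene panel")
    rho = spec.correlation_strength
    expr = np.empty((spec.n_genes, n))
    gene_base = rng.uniform(2.0, 8.0, size=spec.n_genes)
    noise = rng.standard_normal((spec.n_genes, n))
    sig_set = set(signal_genes)
    for gi, gid in enumerate(gene_ids):
        if gid in sig_set:
            rank = signal_genes.index(gid)
            f = informative[rank % len(informative)]
            # alternate correlation sign per pass over the feature list:
            # vascular programs contain both up- and down-regulated genes
            sign = 1.0 if (rank // len(informative)) % 2 == 0 else -1.0
            v = features[f].to_numpy()
            z = (v - v.mean()) / (v.std() if v.std() > 0 else 1.0)
            latent = 5.0 + sign * rho * z + np.sqrt(max(0.0, 1 - rho**2)) * noise[gi]
        else:
            latent = gene_base[gi] + noise[gi]
        expr[gi] = np.clip(2.0**latent - 1.0, 0, None)
    expression = pd.DataFrame(expr, index=gene_ids, columns=case_ids)

    # Survival -----------------------------------------------------------
    h0 = np.log(2.0) / spec.baseline_median_months
    hazard = h0 * spec.planted_hazard_ratio**group
    t_event = rng.exponential(1.0 / hazard)
    t_obs = np.minimum(t_event, spec.max_followup_months)
    event = (t_event <= spec.max_followup_months).astype(int)
    # independent censoring: each case is censored with probability
    # censoring_rate at a uniform fraction of its observed follow-up
    censored = rng.random(n) < spec.censoring_rate
    c_time = rng.uniform(0, 1, size=n) * t_obs
    t_obs = np.where(censored, c_time, t_obs)
    event = np.where(censored, 0, event)
    stage_high = (rng.random(n) < 0.25 + 0.3 * group).astype(int)
    grade_high = (rng.random(n) < 0.3 + 0.25 * group).astype(int)
    survival = pd.DataFrame(
        {
            "case_id": case_ids,
            "dfs_months": t_obs,
            "event": event,
            "stage_high": stage_high,
            "grade_high": grade_high,
        }
    ).set_index("case_id")

    return CohortTables(
        expression=expression,
        survival=survival,
        features=features,
        tile_features=tile_features,
        risk_groups=pd.Series(group, index=case_ids, name="risk_group"),
        signal_genes=signal_genes,
        informative_features=informative,
        spec=spec,
    )


__all__ = [
    "GroundTruthTile",
    "SyntheticCohortSpec",
    "CohortTables",
    "DEFAULT_INFORMATIVE_VF",
    "IHC_STATE_COLORS",
    "generate_vessel_network",
    "sample_state_pixels",
    "simulate_cohort",
]
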