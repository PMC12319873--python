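"""Laminar fMRI analysis on a cortical ribbon.

Implements the depth-resolved pipeline: equivolume cortical depth from a
pial/white mesh pair, equal-volume layer compartments, the block GLM in
percent signal change, the large-vein column-exclusion rule, depth
profiles, the amblyopic deficit index (ADI), ocular-bias ROI selection and
the split-half localizer scheme.

Equivolume depth
----------------
For a cortical column with pial neighborhood area ``A_p`` and white area
``A_w``, the local wedge with linearly interpolated area has volume
``\\int_0^x [(1-t) A_p + t A_w] dt`` up to Euclidean fraction ``x``.  The
intermediate surface enclosing volume fraction ``alpha`` of the column sits
at

    x(alpha) = (A_p - sqrt((1-alpha) A_p^2 + alpha A_w^2)) / (A_p - A_w)

(``x = alpha`` when ``A_p = A_w``).  A set of intermediate surfaces at
equispaced ``alpha`` is generated and each gray-matter voxel's depth is
linearly interpolated between the two nearest surfaces.  In this
coordinate, equal depth intervals enclose equal tissue volume, so the
superficial / middle / deep compartments are the depth tertiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .hrf import BlockHRF, build_design
from .synth.mesh import MeshPair

LAYERS = ("superficial", "middle", "deep")


# ---------------------------------------------------------------------------
# Ribbon voxelization


@dataclass
class RibbonGrid:
    """Voxel grid sampling of a cortical ribbon.

    Flat arrays index the gray-matter voxels; ``vertex_id`` assigns each
    voxel to the nearest cortical column and ``frac`` is its Euclidean
    fraction along that column (0 = pial, 1 = white).
    """

    affine: np.ndarray
    shape: tuple[int, int, int]
    flat_idx: np.ndarray  # (N,) indices into the flattened volume
    vertex_id: np.ndarray  # (N,)
    frac: np.ndarray  # (N,)
    voxel_size: float

    @property
    def n_voxels(self) -> int:
        return self.flat_idx.size

    def to_volume(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter per-gray-matter-voxel values into a full 3-D volume."""
        vol = np.full(int(np.prod(self.shape)), fill, dtype=float)
        vol[self.flat_idx] = values
        return vol.reshape(self.shape)

    def gm_mask_volume(self) -> np.ndarray:
        vol = np.zeros(int(np.prod(self.shape)), dtype=bool)
        vol[self.flat_idx] = True
        return vol.reshape(self.shape)


def sample_ribbon(mesh: MeshPair, voxel_size: float = 0.5, pad: float = 1.0) -> RibbonGrid:
    """Voxelize the ribbon: assign grid voxels to cortical columns.

    Voxel centers on a regular grid over the padded bounding box are
    assigned to the nearest column segment (among the 8 nearest-midpoint
    candidates); a voxel belongs to gray matter if its projection onto the
    column lies in [0, 1] and its perpendicular distance is below 0.75 of
    the local vertex spacing.  The spacing is interpolated between the
    pial and white surface spacings at the voxel's column fraction, so on
    curved ribbons the small edge spill scales with the local surface
    area and stays depth-unbiased.
    """
    pial, white = mesh.vertices_pial, mesh.vertices_white
    mid = 0.5 * (pial + white)
    lo = np.minimum(pial.min(0), white.min(0)) - pad
    hi = np.maximum(pial.max(0), white.max(0)) + pad
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / voxel_size)) for k in range(3))
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size
    affine[:3, 3] = lo + voxel_size / 2

    grids = [lo[k] + voxel_size / 2 + voxel_size * np.arange(shape[k]) for k in range(3)]
    xx, yy, zz = np.meshgrid(*grids, indexing="ij")
    centers = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], 1)

    tree = cKDTree(mid)
    # local vertex spacing from neighborhood areas (robust to anisotropy)
    area_p, area_w = mesh.neighborhood_areas()
    spacing_p = float(np.sqrt(np.median(area_p)))
    spacing_w = float(np.sqrt(np.median(area_w)))

    k = min(8, mid.shape[0])
    _, cand = tree.query(centers, k=k)
    cand = np.atleast_2d(cand.reshape(centers.shape[0], k))

    cols = white - pial
    col_len2 = np.einsum("ij,ij->i", cols, cols)
    best_d2 = np.full(centers.shape[0], np.inf)
    best_v = np.zeros(centers.shape[0], dtype=np.int64)
    best_t = np.zeros(centers.shape[0])
    for j in range(k):
        v = cand[:, j]
        rel = centers - pial[v]
        t = np.einsum("ij,ij->i", rel, cols[v]) / col_len2[v]
        tc = np.clip(t, 0.0, 1.0)
        perp = rel - tc[:, None] * cols[v]
        d2 = np.einsum("ij,ij->i", perp, perp)
        better = d2 < best_d2
        best_d2[better] = d2[better]
        best_v[better] = v[better]
        best_t[better] = t[better]

    tc = np.clip(best_t, 0.0, 1.0)
    radius = 0.8 * ((1.0 - tc) * spacing_p + tc * spacing_w)
    gm = (best_t >= 0.0) & (best_t <= 1.0) & (best_d2 <= radius**2)
    flat_idx = np.flatnonzero(gm)
    return RibbonGrid(
        affine=affine,
        shape=shape,
        flat_idx=flat_idx,
        vertex_id=best_v[gm],
        frac=np.clip(best_t[gm], 0.0, 1.0),
        voxel_size=voxel_size,
    )


# ---------------------------------------------------------------------------
# Equivolume depth and layers


def equivolume_fraction(alpha, a_p, a_w):
    """Euclidean fraction x(alpha) of the equivolume surface at fraction alpha.

    Solves ``A_p x - (A_p - A_w) x^2 / 2 = alpha (A_p + A_w) / 2`` for
    ``x`` in [0, 1]; reduces to ``x = alpha`` for equal areas.
    """
    alpha = np.asarray(alpha, float)
    a_p = np.asarray(a_p, float)
    a_w = np.asarray(a_w, float)
    diff = a_p - a_w
    with np.errstate(divide="ignore", invalid="ignore"):
        x = (a_p - np.sqrt((1 - alpha) * a_p**2 + alpha * a_w**2)) / diff
    near = np.abs(diff) <= 1e-9 * np.maximum(a_p, a_w)
    return np.where(near, alpha, x)


@dataclass
class DepthVolume:
    """Equivolume relative depth per gray-matter voxel (0 pial, 1 white)."""

    grid: RibbonGrid
    depth: np.ndarray  # (N,) in [0, 1]
    n_surfaces: int

    def layer_labels(self) -> np.ndarray:
        return assign_layers(self)


def equivolume_depth(
    mesh: MeshPair, grid: RibbonGrid, n_surfaces: int = 11
) -> DepthVolume:
    """Estimate equivolume depth for every gray-matter voxel.

    ``n_surfaces`` intermediate surfaces (>= 9) are generated at
    equispaced volume fractions; each voxel's depth is linearly
    interpolated between the two surfaces nearest to its Euclidean
    position along its column.
    """
    if n_surfaces < 9:
        raise ValueError("at least 9 intermediate surfaces are required")
    a_p, a_w = mesh.neighborhood_areas()
    bad = (a_p <= 0) & (a_w <= 0)  # vertices with no area information are excluded
    keep = ~bad[grid.vertex_id]
    alphas = np.linspace(0.0, 1.0, n_surfaces)
    # x positions of the intermediate surfaces per vertex: (V, K)
    x_surf = equivolume_fraction(alphas[None, :], a_p[:, None], a_w[:, None])

    xs = x_surf[grid.vertex_id]  # (N, K)
    t = grid.frac
    k_lo = np.clip((xs <= t[:, None]).sum(1) - 1, 0, n_surfaces - 2)
    rows = np.arange(t.size)
    x0 = xs[rows, k_lo]
    x1 = xs[rows, k_lo + 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(x1 > x0, (t - x0) / (x1 - x0), 0.0)
    depth = np.clip(alphas[k_lo] + w * (alphas[1] - alphas[0]), 0.0, 1.0)

    if not keep.all():
        grid = RibbonGrid(
            affine=grid.affine,
            shape=grid.shape,
            flat_idx=grid.flat_idx[keep],
            vertex_id=grid.vertex_id[keep],
            frac=grid.frac[keep],
            voxel_size=grid.voxel_size,
        )
        depth = depth[keep]
    return DepthVolume(grid=grid, depth=depth, n_surfaces=n_surfaces)


def assign_layers(depth: DepthVolume) -> np.ndarray:
    """Label voxels superficial / middle / deep by equivolume-depth tertiles.

    Because equal equivolume-depth intervals enclose equal volume, the
    cuts at 1/3 and 2/3 partition gray matter into three equal-volume
    compartments.
    """
    if depth.grid.n_voxels == 0:
        raise ValueError("empty gray-matter mask")
    d = depth.depth
    labels = np.where(d < 1 / 3, LAYERS[0], np.where(d < 2 / 3, LAYERS[1], LAYERS[2]))
    return labels


# ---------------------------------------------------------------------------
# Block GLM


@dataclass
class GLMResult:
    """Per-voxel block GLM fit in percent signal change."""

    beta: np.ndarray  # (n_conditions, N) PSC
    conditions: list[str]
    residual_sd: np.ndarray  # (N,) PSC
    mean_epi: np.ndarray  # (N,) raw intensity
    design: np.ndarray = field(repr=False, default=None)
    column_names: list[str] = field(default_factory=list)

    def beta_for(self, condition: str) -> np.ndarray:
        return self.beta[self.conditions.index(condition)]


def fit_block_glm(
    bold: np.ndarray,
    events: pd.DataFrame,
    tr: float,
    drift_order: int = 3,
    motion: np.ndarray | None = None,
    hrf: BlockHRF | None = None,
) -> GLMResult:
    """Fit the block GLM per voxel by ordinary least squares.

    ``bold`` is (N voxels, T volumes) in raw intensity units.  The design
    holds the HRF-convolved stimulus regressors, Legendre drift up to
    ``drift_order`` and optional motion nuisances.  Betas are rescaled to
    percent signal change relative to the voxel temporal mean.
    """
    bold = np.atleast_2d(np.asarray(bold, float))
    n_vox, n_vols = bold.shape
    X, names, conditions = build_design(
        events, n_vols, tr, hrf=hrf, drift_order=drift_order, motion=motion
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via the diagonal of R in a pivoted QR
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.flatnonzero(diag < 1e-10 * diag.max())]
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"offending columns: {bad or 'collinear combination'}"
        )
    coef, _, _, _ = np.linalg.lstsq(X, bold.T, rcond=None)
    resid = bold.T - X @ coef
    dof = max(1, n_vols - X.shape[1])
    resid_sd = np.sqrt((resid**2).sum(0) / dof)

    mean_epi = bold.mean(axis=1)
    safe_mean = np.where(np.abs(mean_epi) > 1e-12, mean_epi, 1.0)
    beta_psc = coef[: len(conditions)] / safe_mean[None, :] * 100.0
    resid_sd_psc = resid_sd / np.abs(safe_mean) * 100.0
    return GLMResult(
        beta=beta_psc,
        conditions=conditions,
        residual_sd=resid_sd_psc,
        mean_epi=mean_epi,
        design=X,
        column_names=names,
    )


# ---------------------------------------------------------------------------
# Vein exclusion


@dataclass
class VeinMask:
    """Large-vein exclusion: flagged vertices and surviving voxels."""

    vertex_flagged: np.ndarray  # (V,) bool
    voxel_keep: np.ndarray  # (N,) bool — False for any voxel of a flagged column


def surface_map(values: np.ndarray, grid: RibbonGrid, n_vertices: int) -> np.ndarray:
    """Map per-voxel values to vertices: mean over each vertex's column."""
    sums = np.zeros(n_vertices)
    counts = np.zeros(n_vertices)
    np.add.at(sums, grid.vertex_id, values)
    np.add.at(counts, grid.vertex_id, 1.0)
    with np.errstate(invalid="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out


def vein_mask(
    glm: GLMResult,
    mesh: MeshPair,
    grid: RibbonGrid,
    intensity_frac: float = 0.70,
    psc_max: float = 10.0,
) -> VeinMask:
    """Flag vein-contaminated columns and exclude them whole.

    A vertex is flagged when its column-mean EPI intensity falls below
    ``intensity_frac`` of the across-vertex average, or when its
    column-mean BOLD response (averaged across stimulus conditions)
    exceeds ``psc_max`` percent signal change.  All voxels across cortical
    depth are excluded for flagged vertices.
    """
    n_v = mesh.n_vertices
    epi_v = surface_map(glm.mean_epi, grid, n_v)
    resp_v = surface_map(glm.beta.mean(axis=0), grid, n_v)
    sampled = ~np.isnan(epi_v)
    avg_epi = np.nanmean(epi_v)
    flagged = np.zeros(n_v, dtype=bool)
    flagged[sampled] = (epi_v[sampled] < intensity_frac * avg_epi) | (
        resp_v[sampled] > psc_max
    )
    keep = ~flagged[grid.vertex_id]
    if not keep.any():
        raise ValueError(
            "vein exclusion removed every vertex "
            f"(avg EPI {avg_epi:.3g}, thresholds {intensity_frac}/{psc_max} PSC)"
        )
    return VeinMask(vertex_flagged=flagged, voxel_keep=keep)


# ---------------------------------------------------------------------------
# Depth profiles and ADI


def laminar_profile(
    glm: GLMResult,
    depth: DepthVolume,
    mask: VeinMask | None = None,
    roi: np.ndarray | None = None,
    n_bins: int = 3,
) -> pd.DataFrame:
    """Average betas across voxels within equivolume-depth bins.

    Returns a DataFrame indexed by bin with one PSC column per condition,
    ``depth_center`` and ``n_voxels``.  Empty bins hold NaN (flagged
    missing, never zero).  With ``n_bins=3`` the bins are the layer
    compartments.
    """
    sel = np.ones(depth.grid.n_voxels, dtype=bool)
    if mask is not None:
        sel &= mask.voxel_keep
    if roi is not None:
        sel &= np.isin(depth.grid.vertex_id, np.asarray(roi))
    if not sel.any():
        raise ValueError("no voxels remain after masking/ROI selection")
    d = depth.depth[sel]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    rows = {}
    rows["depth_center"] = 0.5 * (edges[:-1] + edges[1:])
    counts = np.bincount(which, minlength=n_bins).astype(float)
    for ci, cond in enumerate(glm.conditions):
        b = glm.beta[ci][sel]
        sums = np.bincount(which, weights=b, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            rows[cond] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    rows["n_voxels"] = counts.astype(int)
    df = pd.DataFrame(rows)
    df.index.name = "bin"
    return df


def compute_adi(profile_ae: np.ndarray, profile_fe: np.ndarray) -> np.ndarray:
    """Amblyopic deficit index per depth bin: ADI = (FE - AE) / FE.

    The proportional response loss of the amblyopic eye relative to the
    fellow eye; positive values mean AE loss.  Bins with FE <= 0 are
    undefined and returned as NaN.
    """
    ae = np.asarray(profile_ae, float)
    fe = np.asarray(profile_fe, float)
    if ae.shape != fe.shape:
        raise ValueError("AE and FE profiles must share the bin grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        adi = (fe - ae) / fe
    adi = np.where(fe > 0, adi, np.nan)
    return adi


def adi_table(profile: pd.DataFrame, ae: str = "AE", fe: str = "FE") -> pd.DataFrame:
    """ADI per depth bin from a laminar profile table."""
    out = profile[["depth_center", "n_voxels"]].copy()
    out["adi"] = compute_adi(profile[ae].to_numpy(), profile[fe].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Ocular-bias ROIs and split-half extraction


def select_ocular_rois(
    beta_ae: np.ndarray, beta_fe: np.ndarray, frac: float = 0.10
) -> dict[str, np.ndarray]:
    """Select ocular-biased vertices from the AE-FE beta distribution.

    Vertices are ranked by ``AE - FE``; the top ``frac`` fraction form the
    AE-biased ROI and the bottom ``frac`` the FE-biased ROI.  Ties are
    broken by stable (ascending) vertex index.
    """
    if not 0 < frac < 0.5:
        raise ValueError("frac must lie in (0, 0.5)")
    diff = np.asarray(beta_ae, float) - np.asarray(beta_fe, float)
    n = diff.size
    k = int(round(frac * n))
    if k < 1:
        raise ValueError(f"frac*N = {frac * n:.3g} selects no vertices")
    fe_biased = np.argsort(diff, kind="stable")[:k]
    ae_biased = np.argsort(-diff, kind="stable")[:k]
    return {"AE_biased": np.sort(ae_biased), "FE_biased": np.sort(fe_biased)}


def split_half_extract(
    run_maps: np.ndarray,
    conditions: list[str],
    frac: float = 0.10,
    ae: str = "AE",
    fe: str = "FE",
) -> pd.DataFrame:
    """Split-half localizer: odd runs select ROIs, even runs are read out.

    ``run_maps`` is (runs, conditions, vertices) of surface betas.  Betas
    from the odd runs (1st, 3rd, ...) define the ocular-biased vertices
    used to extract mean responses from the even runs, and vice versa; the
    two extractions are averaged, removing selection bias.

    Returns a DataFrame indexed by ROI with one column per condition.
    """
    run_maps = np.asarray(run_maps, float)
    if run_maps.ndim != 3 or run_maps.shape[0] < 2:
        raise ValueError("split-half requires at least two runs of surface maps")
    i_ae, i_fe = conditions.index(ae), conditions.index(fe)
    halves = (run_maps[0::2].mean(axis=0), run_maps[1::2].mean(axis=0))
    extractions = []
    for localizer, readout in ((halves[0], halves[1]), (halves[1], halves[0])):
        rois = select_ocular_rois(localizer[i_ae], localizer[i_fe], frac)
        extractions.append(
            {
                roi_name: readout[:, verts].mean(axis=1)
                for roi_name, verts in rois.items()
            }
        )
    rows = {
        roi_name: (extractions[0][roi_name] + extractions[1][roi_name]) / 2.0
        for roi_name in extractions[0]
    }
    return pd.DataFrame(rows, index=conditions).T
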