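"""Wall kinematics: mid-surface extraction, local frames, curvature, strain.

The circumferential strain of the wall between diastole and systole is
estimated pointwise as

    strain = u_n / R

where u_n is the wall displacement component along the outward surface
normal (positive for systolic expansion) and R the local radius of
curvature along the circumferential direction.  The displacement comes from
deformable registration; only its normal component is used, because
registration is most accurate along the image gradient, which at the wall
is the surface normal.

Local frames come from total-least-squares plane fits to the surface point
cloud; the circumferential curvature comes from local quadric fits with a
randomized consensus (RANSAC-style) outlier rejection, seeded and fully
vectorized across vertices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure
import trimesh

from .io import DisplacementField, LabelMap, LUMEN, ILT
from .surface import SurfaceMesh

logger = logging.getLogger("rsii")

__all__ = [
    "KinematicsParams",
    "WallFrame",
    "StrainSample",
    "extract_wall_surface",
    "sample_displacement",
    "fit_local_frame",
    "decompose_displacement",
    "estimate_radius",
    "circumferential_strain",
    "compute_wall_strain",
    "Centerline",
]

R_MIN_CAP = 2.0    # mm; sharper curvature than this is sub-voxel noise
R_MAX_CAP = 300.0  # mm; flatter than this is "near-flat"

FLAG_OK = 0
FLAG_LOW_CONSENSUS = 1
FLAG_NEAR_FLAT = 2
FLAG_R_MIN = 3


@dataclass
class KinematicsParams:
    """Neighborhood and consensus-loop settings for frames and curvature."""

    neighbors: int = 24              # k nearest points for plane fits
    radius_factor: float = 2.5       # plane-fit radius = factor * mean edge
    min_radius_mm: float = 3.75      # floor on the plane-fit radius (~3 voxels)
    curvature_neighbors: int = 220   # k nearest points for quadric fits
    curvature_radius_mm: float = 10.0  # curvature neighborhood radius floor
    ransac_iterations: int = 200
    ransac_threshold: float = 0.3    # mm residual for inliers
    min_inlier_fraction: float = 0.5
    seed: int = 0
    normal_sign: float = -1.0        # u_n = sign * (u . n); see module note
    sample_surface: str = "inner"    # sample u on the "inner", "mid" or "outer" wall face
    smoothing_iterations: int = 30   # taubin smoothing of the extracted surface


@dataclass
class WallFrame:
    """Orthonormal right-handed local frame: tangents t1, t2 and normal n."""

    t1: np.ndarray
    t2: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        m = np.stack([self.t1, self.t2, self.n], axis=-1)
        if not np.allclose(m.swapaxes(-1, -2) @ m, np.eye(3), atol=1e-9):
            raise ValueError("frame is not orthonormal")
        if np.linalg.det(m) < 0:
            raise ValueError("frame is not right-handed")


@dataclass
class StrainSample:
    """Per-point strain result with curvature diagnostics."""

    u_n: float
    u_t_mag: float
    radius: float
    strain: float
    residual: float
    inlier_count: int
    flag: int = FLAG_OK


# ---------------------------------------------------------------------------
# surface extraction
# ---------------------------------------------------------------------------

def extract_wall_surface(
    labels: LabelMap,
    thickness: float = 1.5,
    params: KinematicsParams | None = None,
) -> SurfaceMesh:
    """Triangulated wall mid-surface from a label map.

    Marching cubes on the outer wall boundary (any tissue vs. background),
    largest connected component, light taubin smoothing, then an inward
    offset of half the wall thickness along vertex normals.
    """
    params = params or KinematicsParams()
    solid = (labels.data > 0).astype(np.float64)
    if solid.sum() == 0:
        raise ValueError("label map contains no tissue")
    _check_closed_shell(labels)

    verts, faces, _, _ = measure.marching_cubes(
        solid, level=0.5, spacing=tuple(labels.spacing)
    )
    # index*spacing -> world
    verts = labels.origin + verts @ labels.direction.T

    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    comps = tm.split(only_watertight=False)
    if len(comps) > 1:
        sizes = [len(c.faces) for c in comps]
        tm = comps[int(np.argmax(sizes))]
        logger.warning(
            "wall surface has %d components; kept largest (%d of %d faces)",
            len(comps), max(sizes), sum(sizes),
        )
    vol_before = abs(tm.volume)
    if params.smoothing_iterations > 0:
        trimesh.smoothing.filter_taubin(
            tm, lamb=0.5, nu=0.53, iterations=params.smoothing_iterations
        )
    vol_after = abs(tm.volume)
    if vol_before > 0 and abs(vol_after / vol_before - 1.0) > 0.005:
        logger.warning(
            "smoothing changed enclosed volume by %.2f%%",
            100 * abs(vol_after / vol_before - 1.0),
        )

    mesh = SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    if mesh.signed_volume() < 0:
        mesh.faces = mesh.faces[:, ::-1].copy()
    normals = mesh.vertex_normals()
    mesh.vertices = mesh.vertices - (thickness / 2.0) * normals
    mesh.validate()
    return mesh


def _check_closed_shell(labels: LabelMap) -> None:
    """The wall label must seal lumen/ILT off from the background."""
    interior = np.isin(labels.data, (LUMEN, ILT))
    bg = labels.data == 0
    structure = ndimage.generate_binary_structure(3, 1)
    touching = ndimage.binary_dilation(interior, structure) & bg
    # interior touching the image border counts as open as well
    border = np.zeros_like(interior)
    border[[0, -1], :, :] = True
    border[:, [0, -1], :] = True
    border[:, :, [0, -1]] = True
    leaks = np.argwhere(touching | (interior & border))
    if len(leaks):
        raise ValueError(
            f"wall shell is open: lumen/ILT exposed to background at "
            f"{len(leaks)} voxels, first {leaks[:5].tolist()}"
        )


# ---------------------------------------------------------------------------
# displacement sampling and decomposition
# ---------------------------------------------------------------------------

def sample_displacement(fld: DisplacementField, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the field at world points (mm)."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    idx = fld.physical_to_index(points)
    hi = np.array(fld.shape) - 1.0
    outside = np.any((idx < -1e-9) | (idx > hi + 1e-9), axis=1)
    if np.any(outside):
        bad = int(np.argmax(outside))
        raise ValueError(
            f"point {bad} at {points[bad]} lies outside the field extent"
        )
    coords = [idx[:, 0], idx[:, 1], idx[:, 2]]
    return np.stack(
        [
            ndimage.map_coordinates(fld.data[..., c], coords, order=1, mode="nearest")
            for c in range(3)
        ],
        axis=-1,
    )


def decompose_displacement(
    u: np.ndarray, frame: WallFrame, sign: float = -1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Split displacement into signed normal and tangential parts.

    With the registration convention (fixed = systole, moving = diastole)
    the field points from systolic to diastolic positions, so outward
    systolic expansion has u . n < 0; ``sign = -1`` makes expansion
    positive, matching the reporting of tensile strains as positive.
    """
    u = np.asarray(u, dtype=np.float64)
    un_raw = u @ frame.n if u.ndim == 1 else np.einsum("ij,j->i", u, frame.n)
    u_t = u - np.multiply.outer(un_raw, frame.n) if u.ndim > 1 else u - un_raw * frame.n
    return sign * un_raw, u_t


# ---------------------------------------------------------------------------
# local frames
# ---------------------------------------------------------------------------

def fit_local_frame(
    points: np.ndarray,
    query: np.ndarray,
    radius: float | None = None,
    k: int | None = None,
    orientation_hint: np.ndarray | None = None,
) -> WallFrame:
    """Total-least-squares plane fit around a query point.

    The normal is the direction of least variance of the neighborhood,
    oriented outward: along ``orientation_hint`` if given, else away from
    the neighborhood centroid (valid for closed convex-ish surfaces).
    """
    points = np.asarray(points, dtype=np.float64)
    query = np.asarray(query, dtype=np.float64)
    if radius is None and k is None:
        k = 24
    tree = cKDTree(points)
    if radius is not None:
        nbr = tree.query_ball_point(query, radius)
        nb = points[nbr]
    else:
        _, nbr = tree.query(query, k=min(k, len(points)))
        nb = points[np.atleast_1d(nbr)]
    if len(nb) < 6:
        raise ValueError(f"only {len(nb)} neighbors; need at least 6")
    centroid = nb.mean(axis=0)
    q = nb - centroid
    _, s, vt = np.linalg.svd(q, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("rank-deficient (collinear) neighborhood")
    n = vt[2]
    ref = orientation_hint if orientation_hint is not None else (query - centroid)
    if np.linalg.norm(ref) > 0 and np.dot(n, ref) < 0:
        n = -n
    t1 = vt[0]
    t2 = np.cross(n, t1)
    if np.dot(np.cross(t1, t2), n) < 0:  # pragma: no cover - construction
        t2 = -t2
    return WallFrame(t1, t2, n)


# ---------------------------------------------------------------------------
# curvature with randomized consensus
# ---------------------------------------------------------------------------

def _poly_design(x: np.ndarray, y: np.ndarray, order: int) -> np.ndarray:
    """Bivariate polynomial design matrix; quadratic+linear terms lead so the
    curvature extraction always reads the same leading coefficients."""
    terms = [x**2, x * y, y**2, x, y, np.ones_like(x)]
    if order >= 4:
        terms += [
            x**3, x**2 * y, x * y**2, y**3,
            x**4, x**3 * y, x**2 * y**2, x * y**3, y**4,
        ]
    return np.stack(terms, axis=-1)


def _quadric_curvature(
    coef: np.ndarray, direction_2d: np.ndarray
) -> np.ndarray:
    """Normal curvature of z = a x^2 + b xy + c y^2 + d x + e y + f along a
    tangent-plane direction (vx, vy)."""
    a, b, c, d, e = (coef[..., i] for i in range(5))
    vx, vy = direction_2d[..., 0], direction_2d[..., 1]
    w = np.sqrt(1.0 + d**2 + e**2)
    L, M, N = 2 * a / w, b / w, 2 * c / w
    E, F, G = 1 + d**2, d * e, 1 + e**2
    num = L * vx**2 + 2 * M * vx * vy + N * vy**2
    den = E * vx**2 + 2 * F * vx * vy + G * vy**2
    return num / np.maximum(den, 1e-12)


def estimate_radius(
    points: np.ndarray,
    query: np.ndarray,
    frame: WallFrame,
    params: KinematicsParams | None = None,
    direction_2d: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict]:
    """Radius of curvature at one query point via consensus quadric fitting.

    Returns ``(R, diagnostics)``; R is clamped to (R_MIN_CAP, R_MAX_CAP] and
    diagnostics carry the inlier count, residual and flag.  ``direction_2d``
    is the circumferential direction in the (t1, t2) basis; default (1, 0).
    """
    params = params or KinematicsParams()
    rng = rng or np.random.default_rng(params.seed)
    points = np.asarray(points, dtype=np.float64)
    tree = cKDTree(points)
    dist, nbr = tree.query(query, k=min(params.curvature_neighbors, len(points)))
    nbr = np.atleast_1d(nbr)[np.atleast_1d(dist) <= params.curvature_radius_mm]
    nb = points[nbr]
    if len(nb) < 9:
        raise ValueError(f"only {len(nb)} neighbors; need at least 9")
    loc = nb - query
    x = loc @ frame.t1
    y = loc @ frame.t2
    z = loc @ frame.n
    A = _poly_design(x, y, 2)
    coef, inliers, resid = _ransac_quadric_single(A, z, params, rng)
    # quartic refit with a noise-adaptive ridge on the higher orders: absorbs
    # the wide-patch truncation bias of the quadric on clean surfaces while
    # degrading gracefully to the quadric on noisy ones
    rho_scale = 1.0
    if inliers.sum() >= 15:
        rho_p = max(float(np.sqrt((x[inliers] ** 2 + y[inliers] ** 2).max())), 1e-6)
        xs, ys, zs = x / rho_p, y / rho_p, z / rho_p
        A4 = _poly_design(xs, ys, 4)[inliers]
        G = A4.T @ A4 + 1e-9 * np.eye(15)
        b4 = A4.T @ zs[inliers]
        c4 = np.linalg.solve(G, b4)
        sig = 1.4826 * float(np.median(np.abs(A4 @ c4 - zs[inliers])))
        direction0 = np.array([1.0, 0.0]) if direction_2d is None else direction_2d
        kap2 = abs(float(_quadric_curvature(coef[:5], direction0)))
        sagitta = max(rho_p * kap2 / 2.0, 1e-3)
        ridge = np.zeros(15)
        ridge[6:] = 1.0
        G += (sig / sagitta) ** 2 * inliers.sum() * np.diag(ridge)
        coef = np.linalg.solve(G, b4)
        rho_scale = rho_p
    direction = np.array([1.0, 0.0]) if direction_2d is None else direction_2d
    kappa = float(_quadric_curvature(coef, direction)) / rho_scale
    r, flagmask = _clamp_radius(np.array([kappa]))
    flag = int(flagmask[0])
    n_inl = int(inliers.sum())
    if n_inl < params.min_inlier_fraction * len(nb):
        flag = FLAG_LOW_CONSENSUS
    return float(r[0]), {
        "inlier_count": n_inl,
        "residual": float(resid),
        "flag": flag,
        "n_neighbors": len(nb),
    }


def _ransac_quadric_single(A, z, params, rng):
    n = len(z)
    G0 = A.T @ A + 1e-9 * np.eye(6)
    coef0 = np.linalg.solve(G0, A.T @ z)
    thr = max(
        params.ransac_threshold, 3.0 * 1.4826 * float(np.median(np.abs(A @ coef0 - z)))
    )
    r0 = np.abs(A @ coef0 - z)
    best_coef, best_count = coef0, int((r0 < thr).sum())
    for _ in range(params.ransac_iterations):
        pick = rng.choice(n, size=6, replace=False)
        G = A[pick].T @ A[pick] + 1e-9 * np.eye(6)
        try:
            coef = np.linalg.solve(G, A[pick].T @ z[pick])
        except np.linalg.LinAlgError:  # pragma: no cover
            continue
        r = np.abs(A @ coef - z)
        count = int((r < thr).sum())
        if count > best_count:
            best_count, best_coef = count, coef
    r = np.abs(A @ best_coef - z)
    inl = r < thr
    if inl.sum() >= 6:
        G = A[inl].T @ A[inl] + 1e-9 * np.eye(6)
        best_coef = np.linalg.solve(G, A[inl].T @ z[inl])
        r = np.abs(A @ best_coef - z)
        inl = r < thr
    resid = float(np.sqrt((r[inl] ** 2).mean())) if inl.any() else float("inf")
    return best_coef, inl, resid


def _clamp_radius(kappa: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    r = 1.0 / np.maximum(np.abs(kappa), 1e-12)
    flags = np.full(r.shape, FLAG_OK, dtype=np.int8)
    flags[r > R_MAX_CAP] = FLAG_NEAR_FLAT
    flags[r <= R_MIN_CAP] = FLAG_R_MIN
    return np.clip(r, R_MIN_CAP + 1e-9, R_MAX_CAP), flags


def circumferential_strain(u_n: np.ndarray, radius: np.ndarray) -> np.ndarray:
    """Hoop strain u_n / R (signed: tensile positive, compressive negative)."""
    return np.asarray(u_n) / np.asarray(radius)


# ---------------------------------------------------------------------------
# vessel centerline (for the circumferential direction)
# ---------------------------------------------------------------------------

@dataclass
class Centerline:
    """Axial locus of lumen centroids, smoothed; tangent ~ vessel axis."""

    z: np.ndarray          # world z of each slab centre
    centroid: np.ndarray   # (m, 3) smoothed centroids
    tangent: np.ndarray    # (m, 3) unit tangents

    def axis_at(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        j = np.clip(
            np.searchsorted(self.z, pts[:, 2]), 0, len(self.z) - 1
        )
        return self.tangent[j]


def compute_centerline(labels: LabelMap, slab_mm: float = 3.0) -> Centerline:
    """Lumen-centroid centerline per axial slab, Gaussian-smoothed."""
    interior = np.isin(labels.data, (LUMEN, ILT))
    if interior.sum() == 0:
        interior = labels.data > 0
    idx = np.argwhere(interior)
    pts = labels.index_to_physical(idx)
    z = pts[:, 2]
    z0, z1 = z.min(), z.max()
    n_slab = max(int(np.ceil((z1 - z0) / slab_mm)), 2)
    edges = np.linspace(z0, z1 + 1e-9, n_slab + 1)
    which = np.digitize(z, edges) - 1
    cents, zs = [], []
    for s in range(n_slab):
        m = which == s
        if m.sum() < 5:
            continue
        cents.append(pts[m].mean(axis=0))
        zs.append(0.5 * (edges[s] + edges[s + 1]))
    cents = np.array(cents)
    zs = np.array(zs)
    if len(cents) >= 5:
        for c in range(2):
            cents[:, c] = ndimage.gaussian_filter1d(cents[:, c], sigma=2.0, mode="nearest")
    tang = np.gradient(cents, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    return Centerline(zs, cents, tang)


# ---------------------------------------------------------------------------
# batched driver
# ---------------------------------------------------------------------------

def _batched_frames(
    points: np.ndarray, nbr_idx: np.ndarray, valid: np.ndarray, hints: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """TLS plane normals for every vertex at once; returns (t1, t2, n)."""
    nb = points[nbr_idx]                      # (n, k, 3)
    w = valid[..., None].astype(np.float64)
    cnt = np.maximum(w.sum(axis=1), 1.0)
    centroid = (nb * w).sum(axis=1) / cnt
    q = (nb - centroid[:, None, :]) * w
    cov = np.einsum("nki,nkj->nij", q, q)
    evals, evecs = np.linalg.eigh(cov)
    n = evecs[..., 0]                         # smallest-variance direction
    flip = np.einsum("ni,ni->n", n, hints) < 0
    n[flip] *= -1.0
    t1 = evecs[..., 2]
    t2 = np.cross(n, t1)
    nrm = np.linalg.norm(t2, axis=1, keepdims=True)
    t2 /= np.maximum(nrm, 1e-12)
    t1 = np.cross(t2, n)
    return t1, t2, n


def _batched_ransac_radius(
    points: np.ndarray,
    nbr_idx: np.ndarray,
    valid: np.ndarray,
    t1: np.ndarray,
    t2: np.ndarray,
    n: np.ndarray,
    circ_2d: np.ndarray,
    params: KinematicsParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Consensus quadric fit at every vertex; returns (R, flags, inliers, resid)."""
    rng = np.random.default_rng(params.seed)
    nv, k = nbr_idx.shape
    nb = points[nbr_idx] - points[:, None, :]  # centred neighborhoods
    x = np.einsum("nki,ni->nk", nb, t1)
    y = np.einsum("nki,ni->nk", nb, t2)
    z = np.einsum("nki,ni->nk", nb, n)
    A = np.stack([x**2, x * y, y**2, x, y, np.ones_like(x)], axis=-1)  # (n,k,6)
    Aw = A * valid[..., None]
    zw = z * valid

    n_valid = valid.sum(axis=1)

    # pilot least-squares fit sets a per-vertex inlier threshold: at least the
    # configured floor, widened to 3 robust sigma on bumpy surfaces so the
    # consensus rejects gross outliers without trimming honest points
    w0 = valid[..., None].astype(np.float64)
    G0 = np.einsum("nka,nkb->nab", A * w0, A * w0) + 1e-9 * np.eye(6)
    b0 = np.einsum("nka,nk->na", A * w0, zw)
    coef0 = np.linalg.solve(G0, b0[..., None])[..., 0]
    res0 = np.abs(np.einsum("nka,na->nk", A, coef0) - z)
    res0 = np.where(valid, res0, np.nan)
    mad = np.nanmedian(res0, axis=1)
    thr = np.maximum(params.ransac_threshold, 3.0 * 1.4826 * mad)[:, None]

    # the pilot fit competes: on clean data it holds most inliers and the
    # randomized minimal sets only take over when gross outliers skew it
    best_count = ((np.nan_to_num(res0, nan=np.inf) < thr) & valid).sum(axis=1)
    best_coef = coef0.copy()
    eye = 1e-9 * np.eye(6)
    for _ in range(params.ransac_iterations):
        # 6 random picks among the (distance-sorted, valid-first) neighbors
        pick = (rng.random((nv, 6)) * np.maximum(n_valid, 6)[:, None]).astype(int)
        pick = np.minimum(pick, k - 1)
        rows = np.take_along_axis(A, pick[..., None], axis=1)       # (n,6,6)
        rhs = np.take_along_axis(z, pick, axis=1)                   # (n,6)
        G = np.einsum("nka,nkb->nab", rows, rows) + eye
        b = np.einsum("nka,nk->na", rows, rhs)
        coef = np.linalg.solve(G, b[..., None])[..., 0]
        resid = np.abs(np.einsum("nka,na->nk", A, coef) - z)
        count = ((resid < thr) & valid).sum(axis=1)
        better = count > best_count
        best_count = np.where(better, count, best_count)
        best_coef[better] = coef[better]

    # refit on the consensus set
    resid = np.abs(np.einsum("nka,na->nk", A, best_coef) - z)
    inl = (resid < thr) & valid
    w = inl[..., None].astype(np.float64)
    G = np.einsum("nka,nkb->nab", A * w, A * w) + 1e-9 * np.eye(6)
    b = np.einsum("nka,nk->na", A * w, z * inl)
    enough = inl.sum(axis=1) >= 6
    coef = best_coef.copy()
    coef[enough] = np.linalg.solve(G[enough], b[enough][..., None])[..., 0]
    resid = np.abs(np.einsum("nka,na->nk", A, coef) - z)
    inl = (resid < thr) & valid
    rms = np.sqrt(
        np.where(inl, resid**2, 0.0).sum(axis=1) / np.maximum(inl.sum(axis=1), 1)
    )

    # quartic refit on the consensus inliers removes the wide-patch
    # truncation bias of the quadric.  The cubic/quartic terms carry an
    # adaptive ridge, scaled by the residual noise relative to the patch
    # sagitta: on clean surfaces the ridge vanishes (full bias correction),
    # on noisy voxelized ones it shrinks the fit back toward the quadric.
    rho_p = np.sqrt(np.where(inl, x**2 + y**2, 0.0).max(axis=1))
    rho_p = np.maximum(rho_p, 1e-6)[:, None]
    xs, ys, zs = x / rho_p, y / rho_p, z / rho_p
    A4 = _poly_design(xs, ys, 4)
    w4 = inl[..., None].astype(np.float64)
    G4 = np.einsum("nka,nkb->nab", A4 * w4, A4 * w4) + 1e-9 * np.eye(15)
    b4 = np.einsum("nka,nk->na", A4 * w4, zs * inl)
    coef4 = np.linalg.solve(G4, b4[..., None])[..., 0]
    res4 = np.abs(np.einsum("nka,na->nk", A4, coef4) - zs)
    sig = 1.4826 * np.nanmedian(np.where(inl, res4, np.nan), axis=1)
    kap2 = np.abs(_quadric_curvature(coef[:, :5], circ_2d))
    sagitta = np.maximum(rho_p[:, 0] * kap2 / 2.0, 1e-3)
    gamma = (sig / sagitta) ** 2 * inl.sum(axis=1)
    ridge = np.zeros(15)
    ridge[6:] = 1.0
    G4 += gamma[:, None, None] * np.diag(ridge)
    ok4 = inl.sum(axis=1) >= 15
    coef4[ok4] = np.linalg.solve(G4[ok4], b4[ok4][..., None])[..., 0]

    kappa = np.where(
        ok4,
        _quadric_curvature(coef4[:, :5], circ_2d) / rho_p[:, 0],
        _quadric_curvature(coef[:, :5], circ_2d),
    )
    low = inl.sum(axis=1) < params.min_inlier_fraction * np.maximum(n_valid, 1)
    return kappa, low, inl.sum(axis=1), rms


def compute_wall_strain(
    labels: LabelMap,
    fld: DisplacementField,
    thickness: float = 1.5,
    params: KinematicsParams | None = None,
) -> SurfaceMesh:
    """Full strain stage: labels + registration field -> strain surface.

    Extracts the wall mid-surface from the (diastolic) label map, carries it
    to its systolic position with the registration field (fixed-point
    iteration on x_sys = x_dia - u(x_sys)), builds local frames on the
    systolic surface, and evaluates u_n, the circumferential radius R and
    the strain u_n / R there.  Adds the point-data arrays ``u_n``,
    ``u_t_mag``, ``R``, ``circ_strain`` and ``strain_flag``.
    """
    params = params or KinematicsParams()
    mesh = extract_wall_surface(labels, thickness, params)

    # displacement is sampled on the luminal face of the wall by default:
    # the strongest image gradients (blood/tissue contrast) sit there, and
    # registration is most accurate along the gradient direction
    offset = {"inner": -0.5, "mid": 0.0, "outer": 0.5}[params.sample_surface]
    x_d = mesh.vertices + (offset * thickness) * mesh.vertex_normals()
    x_s = x_d.copy()
    for _ in range(4):
        u = sample_displacement(fld, x_s)
        x_s = x_d - u
    u = sample_displacement(fld, x_s)
    sys_mesh = SurfaceMesh(x_s, mesh.faces.copy())

    edge = sys_mesh.mean_edge_length()
    tree = cKDTree(x_s)

    # plane fits: tight neighborhoods
    radius_p = max(params.min_radius_mm, params.radius_factor * edge)
    k_p = min(params.neighbors, len(x_s))
    dist_p, nbr_p = tree.query(x_s, k=k_p)
    valid_p = dist_p <= radius_p
    valid_p[:, : min(9, k_p)] = True  # always keep the closest few

    hints = sys_mesh.vertex_normals()
    t1, t2, n = _batched_frames(x_s, nbr_p, valid_p, hints)

    # quadric fits: wider neighborhoods so the sagitta dominates surface bumps
    radius_c = max(params.curvature_radius_mm, params.radius_factor * edge)
    k_c = min(params.curvature_neighbors, len(x_s))
    dist_c, nbr_idx = tree.query(x_s, k=k_c)
    valid = dist_c <= radius_c
    valid[:, : min(9, k_c)] = True

    u_n = params.normal_sign * np.einsum("ni,ni->n", u, n)
    u_t = u - np.einsum("ni,ni->n", u, n)[:, None] * n
    u_t_mag = np.linalg.norm(u_t, axis=1)

    cl = compute_centerline(labels)
    axis = cl.axis_at(x_s)
    circ = np.cross(axis, n)
    nrm = np.linalg.norm(circ, axis=1, keepdims=True)
    # fall back to t1 where the normal is parallel to the axis (caps)
    degenerate = nrm[:, 0] < 1e-6
    circ = np.where(degenerate[:, None], t1, circ / np.maximum(nrm, 1e-12))
    circ_2d = np.stack(
        [np.einsum("ni,ni->n", circ, t1), np.einsum("ni,ni->n", circ, t2)], axis=-1
    )
    circ_2d /= np.maximum(np.linalg.norm(circ_2d, axis=1, keepdims=True), 1e-12)

    kappa, low, inl, resid = _batched_ransac_radius(
        x_s, nbr_idx, valid, t1, t2, n, circ_2d, params
    )
    # curvature varies smoothly along a vessel: a median over the (small)
    # plane-fit neighborhoods suppresses per-vertex fit noise without
    # flattening the bulge-to-neck trend
    kap_nbr = np.where(valid_p, kappa[nbr_p], np.nan)
    kappa = np.nanmedian(kap_nbr, axis=1)
    r, flags = _clamp_radius(kappa)
    flags = np.where(low, FLAG_LOW_CONSENSUS, flags)
    strain = circumferential_strain(u_n, r)

    out = sys_mesh
    out.point_data.update(
        {
            "u_n": u_n,
            "u_t_mag": u_t_mag,
            "R": r,
            "circ_strain": strain,
            "strain_flag": flags.astype(np.float64),
            "curvature_inliers": inl.astype(np.float64),
            "curvature_residual": resid,
            "normal": n,
        }
    )
    return out
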