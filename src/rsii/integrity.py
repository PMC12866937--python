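"""Structural Integrity Index (SII) and its relative form (RSII).

SII = strain / tension (mm/N) is a local wall-compliance proxy: high
values mean the wall moves a lot for the tension it carries (weak,
compliant wall), low values a stiff wall.  RSII divides SII by the average
absolute SII over the included wall surface, which makes the map
dimensionless and cancels the blood-pressure magnitude: scaling the
pressure scales tension and 1/SII by the same factor and leaves RSII
untouched.  Summaries are 99th percentiles with a fixed linear-interpolation
rule so printed numbers reproduce bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from .surface import SurfaceMesh
from .tension import boundary_loops

logger = logging.getLogger("rsii")

__all__ = [
    "IntegrityField",
    "compute_sii",
    "exclusion_mask",
    "compute_rsii",
    "percentile_summary",
    "compare_regions",
    "compute_integrity",
]

T_FLOOR = 1e-3  # N/mm; guards the strain/tension division


@dataclass
class IntegrityField:
    """Per-vertex SII and RSII with the inclusion mask and summaries."""

    sii: np.ndarray
    rsii: np.ndarray
    included: np.ndarray
    mean_abs_sii: float
    summaries: dict


def compute_sii(
    strain: np.ndarray, tension: np.ndarray, t_floor: float = T_FLOOR
) -> tuple[np.ndarray, np.ndarray]:
    """SII = strain / max(tension, floor); returns (sii, floored_mask).

    The sign of the strain is preserved: tensile strain gives positive SII,
    compressive negative.  Floored vertices are flagged for exclusion.
    """
    strain = np.asarray(strain, dtype=np.float64)
    tension = np.asarray(tension, dtype=np.float64)
    if strain.shape != tension.shape:
        raise ValueError(
            f"strain ({strain.shape}) and tension ({tension.shape}) must be colocated"
        )
    floored = tension < t_floor
    if floored.any():
        logger.warning("%d vertices below the tension floor", int(floored.sum()))
    return strain / np.maximum(tension, t_floor), floored


def exclusion_mask(
    mesh: SurfaceMesh,
    boundary_distance_mm: float = 5.0,
    flags: np.ndarray | None = None,
    boundary_vertices: np.ndarray | None = None,
) -> np.ndarray:
    """Inclusion mask: drop flagged vertices and boundary neighborhoods.

    Vertices within ``boundary_distance_mm`` geodesic distance of the fixed
    end rings are artifacts of the artificial boundary conditions and are
    excluded.  For open meshes the rings are the boundary loops; for closed
    phantom tubes the axial extremes stand in (pass ``boundary_vertices`` to
    override).
    """
    n = mesh.n_vertices
    included = np.ones(n, dtype=bool)
    if flags is not None:
        included &= np.asarray(flags) == 0

    if boundary_vertices is None:
        loops = boundary_loops(mesh)
        if loops:
            boundary_vertices = np.concatenate(loops)
        else:
            z = mesh.vertices[:, 2]
            edge = mesh.mean_edge_length()
            boundary_vertices = np.flatnonzero(
                (z < z.min() + edge) | (z > z.max() - edge)
            )
    boundary_vertices = np.asarray(boundary_vertices, dtype=np.int64)

    if boundary_distance_mm > 0 and len(boundary_vertices):
        e = mesh.edges_unique()
        w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
        g = sp.csr_matrix(
            (np.concatenate([w, w]),
             (np.concatenate([e[:, 0], e[:, 1]]), np.concatenate([e[:, 1], e[:, 0]]))),
            shape=(n, n),
        )
        dist = dijkstra(g, indices=boundary_vertices, min_only=True, directed=False)
        included &= dist > boundary_distance_mm

    if not included.any():
        raise ValueError("exclusion mask removed every vertex")
    return included


def compute_rsii(
    sii: np.ndarray,
    included: np.ndarray,
    abs_numerator: bool = False,
    area_weights: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """RSII = SII / mean_included(|SII|); returns (rsii, mean_abs_sii).

    The numerator keeps the sign of SII by default; ``abs_numerator=True``
    selects the all-positive reading.  The normalization mean is unweighted
    over included vertices unless ``area_weights`` is given.
    """
    sii = np.asarray(sii, dtype=np.float64)
    included = np.asarray(included, dtype=bool)
    if not included.any():
        raise ValueError("no included vertices")
    vals = np.abs(sii[included])
    if area_weights is not None:
        w = np.asarray(area_weights, dtype=np.float64)[included]
        mean_abs = float((vals * w).sum() / w.sum())
    else:
        mean_abs = float(vals.mean())
    if mean_abs <= 0:
        raise ValueError("mean |SII| is zero; RSII undefined")
    num = np.abs(sii) if abs_numerator else sii
    return num / mean_abs, mean_abs


def percentile_summary(
    values: np.ndarray, included: np.ndarray | None = None, q: float = 99.0
) -> float:
    """Linear-interpolation percentile over included vertices."""
    values = np.asarray(values, dtype=np.float64)
    if included is not None:
        values = values[np.asarray(included, dtype=bool)]
    if values.size < 2:
        raise ValueError("need at least 2 included values for a percentile")
    return float(np.percentile(values, q, method="linear"))


def compare_regions(
    rsii: np.ndarray,
    region_labels: np.ndarray,
    included: np.ndarray | None = None,
    min_vertices: int = 10,
) -> dict:
    """Per-region RSII statistics (mean/median of RSII and |RSII|).

    Regions under ``min_vertices`` raise; with exactly two regions the
    result also carries their differences of means and medians.
    """
    rsii = np.asarray(rsii, dtype=np.float64)
    region_labels = np.asarray(region_labels)
    mask = (
        np.ones(len(rsii), dtype=bool)
        if included is None
        else np.asarray(included, dtype=bool)
    )
    out: dict = {"regions": {}}
    names = [r for r in np.unique(region_labels) if str(r) != ""]
    if len(names) < 2:
        raise ValueError("need at least 2 labeled regions")
    for name in names:
        sel = (region_labels == name) & mask
        if sel.sum() < min_vertices:
            raise ValueError(
                f"region {name!r} has {int(sel.sum())} vertices; need {min_vertices}"
            )
        vals = rsii[sel]
        out["regions"][str(name)] = {
            "n": int(sel.sum()),
            "mean": float(vals.mean()),
            "median": float(np.median(vals)),
            "mean_abs": float(np.abs(vals).mean()),
            "median_abs": float(np.median(np.abs(vals))),
        }
    if len(names) == 2:
        a, b = (out["regions"][str(n)] for n in names)
        out["difference"] = {
            "mean": a["mean"] - b["mean"],
            "median": a["median"] - b["median"],
            "mean_abs": a["mean_abs"] - b["mean_abs"],
        }
    return out


def compute_integrity(
    mesh: SurfaceMesh,
    strain: np.ndarray,
    tension: np.ndarray,
    strain_flags: np.ndarray | None = None,
    boundary_distance_mm: float = 5.0,
    boundary_vertices: np.ndarray | None = None,
    abs_numerator: bool = False,
    t_floor: float = T_FLOOR,
) -> IntegrityField:
    """SII/RSII maps plus the 99th-percentile summaries on one surface.

    Adds ``SII``, ``RSII`` and ``included`` point-data arrays to ``mesh``.
    """
    sii, floored = compute_sii(strain, tension, t_floor)
    flags = np.zeros(mesh.n_vertices) if strain_flags is None else np.asarray(
        strain_flags
    ).astype(float)
    flags = flags.copy()
    flags[floored] = np.maximum(flags[floored], 1.0)
    included = exclusion_mask(mesh, boundary_distance_mm, flags, boundary_vertices)
    rsii, mean_abs = compute_rsii(sii, included, abs_numerator=abs_numerator)
    summaries = {
        "t99": percentile_summary(tension, included),
        "eps99": percentile_summary(strain, included),
        "sii99": percentile_summary(sii, included),
        "rsii99": percentile_summary(rsii, included),
        "mean_abs_sii": mean_abs,
        "n_vertices": int(mesh.n_vertices),
        "n_included": int(included.sum()),
    }
    mesh.point_data.update(
        {"SII": sii, "RSII": rsii, "included": included.astype(np.float64)}
    )
    return IntegrityField(sii, rsii, included, mean_abs, summaries)
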