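"""Triangulated surface meshes with per-vertex attributes.

The wall mid-surface, the phantom ground-truth surfaces and every map the
pipeline produces (tension, strain, SII, RSII) live on instances of
:class:`SurfaceMesh`: vertices in world millimetres, triangle connectivity,
and a dictionary of named per-vertex data arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh


@dataclass
class SurfaceMesh:
    """Triangle mesh in world coordinates (mm) with per-vertex attributes.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex positions in millimetres.
    faces : (m, 3) int array
        Triangle connectivity (counter-clockwise seen from outside for
        outward-oriented surfaces).
    point_data : dict of str -> (n,) or (n, k) arrays
        Named per-vertex scalar or vector fields.
    """

    vertices: np.ndarray
    faces: np.ndarray
    point_data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be triangles, (m, 3)")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")
        for name, arr in self.point_data.items():
            arr = np.asarray(arr)
            if arr.shape[0] != len(self.vertices):
                raise ValueError(
                    f"point_data[{name!r}] has {arr.shape[0]} entries for "
                    f"{len(self.vertices)} vertices"
                )
            self.point_data[name] = arr

    # -- basic quantities ------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def area(self) -> float:
        return float(self.triangle_areas().sum())

    def face_normals(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        norm = np.linalg.norm(cross, axis=1, keepdims=True)
        norm[norm == 0.0] = 1.0
        return cross / norm

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals (unit length)."""
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        normals = np.zeros_like(v)
        for k in range(3):
            np.add.at(normals, f[:, k], cross)
        norm = np.linalg.norm(normals, axis=1, keepdims=True)
        norm[norm == 0.0] = 1.0
        return normals / norm

    def signed_volume(self) -> float:
        """Signed enclosed volume; positive for outward-oriented closed meshes."""
        v = self.vertices
        f = self.faces
        return float(
            np.einsum(
                "ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])
            ).sum()
            / 6.0
        )

    def boundary_edges(self) -> np.ndarray:
        """Edges referenced by exactly one triangle, as (k, 2) vertex pairs."""
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e_sorted = np.sort(e, axis=1)
        uniq, counts = np.unique(e_sorted, axis=0, return_counts=True)
        return uniq[counts == 1]

    def is_closed(self) -> bool:
        return len(self.boundary_edges()) == 0

    def edges_unique(self) -> np.ndarray:
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        return np.unique(np.sort(e, axis=1), axis=0)

    def mean_edge_length(self) -> float:
        e = self.edges_unique()
        return float(
            np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1).mean()
        )

    # -- conversions -----------------------------------------------------
    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "SurfaceMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces))

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(),
            self.faces.copy(),
            {k: np.array(v) for k, v in self.point_data.items()},
        )

    def validate(self, min_area: float = 1e-9) -> None:
        """Raise ValueError on degenerate triangles or non-finite vertices."""
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("non-finite vertex coordinates")
        areas = self.triangle_areas()
        if self.n_faces and areas.min() <= min_area:
            bad = int(np.argmin(areas))
            raise ValueError(
                f"degenerate triangle {bad} with area {areas.min():.3e} mm^2"
            )
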