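"""Image, surface and summary I/O with reproducible run manifests.

Images (NIfTI, MetaImage) are read and written through SimpleITK; world
coordinates are RAS (left-to-right, posterior-to-anterior,
inferior-to-superior) millimetres, converted from ITK's native LPS on the
way in and back on the way out.  Surfaces are VTK PolyData XML (``.vtp``,
with per-vertex data arrays), legacy ``.vtk``, STL or PLY.  Anisotropic
voxel spacing is preserved exactly; the physical-coordinate mapping
``origin + direction @ (index * spacing)`` is the single source of truth
and voxel centres are the sample points.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import trimesh

from .surface import SurfaceMesh

logger = logging.getLogger("rsii")

#: labels used throughout the pipeline
BACKGROUND, LUMEN, ILT, WALL = 0, 1, 2, 3

# ITK stores physical space in LPS; we expose RAS.
_LPS_TO_RAS = np.diag([-1.0, -1.0, 1.0])

_IMAGE_EXTS = (".nii", ".nii.gz", ".mha", ".mhd")
_SURFACE_EXTS = (".vtp", ".vtk", ".stl", ".ply")


def _check_direction(direction: np.ndarray) -> np.ndarray:
    direction = np.asarray(direction, dtype=np.float64).reshape(3, 3)
    if not np.allclose(direction @ direction.T, np.eye(3), atol=1e-6):
        raise ValueError("direction matrix is not orthonormal")
    if np.linalg.det(direction) < 0:
        raise ValueError("direction matrix has negative determinant")
    return direction


@dataclass
class ImageVolume:
    """3D scalar volume with physical geometry.

    ``data`` is indexed ``[i, j, k]`` along the image x/y/z axes; the world
    position of voxel ``(i, j, k)`` (its centre) is
    ``origin + direction @ (spacing * (i, j, k))`` in RAS millimetres.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError("data must be 3D (scalar) or 4D (vector)")
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.direction = _check_direction(self.direction)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (continuous) voxel indices (n, 3) to world mm."""
        idx = np.atleast_2d(np.asarray(idx, dtype=np.float64))
        return self.origin + (idx * self.spacing) @ self.direction.T

    def physical_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map world points (n, 3) to continuous voxel indices."""
        pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
        return ((pts - self.origin) @ self.direction) / self.spacing

    def same_grid(self, other: "ImageVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )

    def copy_geometry(self, data: np.ndarray) -> "ImageVolume":
        return ImageVolume(data, self.spacing.copy(), self.origin.copy(), self.direction.copy())


class DisplacementField(ImageVolume):
    """Per-voxel 3-vector displacement (mm, physical RAS axes) on a fixed grid.

    ``data[i, j, k]`` is the displacement of the voxel centre; by the
    registration contract the field lives on the fixed (systolic) grid and
    points to the corresponding diastolic position.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.data.ndim != 4 or self.data.shape[3] != 3:
            raise ValueError("displacement data must be (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("displacement field contains non-finite values")


class LabelMap(ImageVolume):
    """Integer label volume: 0 background, 1 lumen, 2 ILT, 3 wall."""

    CODES = (BACKGROUND, LUMEN, ILT, WALL)

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label map must be integer-valued")
        present = np.unique(self.data)
        if not np.isin(present, self.CODES).all():
            bad = sorted(set(present.tolist()) - set(self.CODES))
            raise ValueError(f"unknown label codes {bad}; allowed {self.CODES}")


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def _image_ext(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def read_image(path: str | Path) -> ImageVolume:
    """Read a NIfTI or MetaImage volume (scalar or 3-vector)."""
    path = Path(path)
    ext = _image_ext(path)
    if ext not in _IMAGE_EXTS:
        raise ValueError(f"unsupported image format {ext!r}; expected one of {_IMAGE_EXTS}")
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = sitk.ReadImage(str(path))
    ncomp = img.GetNumberOfComponentsPerPixel()
    arr = sitk.GetArrayFromImage(img)  # [z, y, x] (+components)
    if ncomp == 1:
        data = np.ascontiguousarray(arr.transpose(2, 1, 0))
    else:
        data = np.ascontiguousarray(arr.transpose(2, 1, 0, 3))
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    origin = np.asarray(img.GetOrigin())
    vol = ImageVolume(
        data,
        np.asarray(img.GetSpacing()),
        _LPS_TO_RAS @ origin,
        _LPS_TO_RAS @ direction,
    )
    if ncomp == 3:
        # vector voxels (displacement fields) are physical LPS; flip to RAS
        vol.data = vol.data * np.array([-1.0, -1.0, 1.0])
    return vol


def write_image(vol: ImageVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI or MetaImage, preserving geometry."""
    path = Path(path)
    ext = _image_ext(path)
    if ext not in _IMAGE_EXTS:
        raise ValueError(f"unsupported image format {ext!r}; expected one of {_IMAGE_EXTS}")
    data = vol.data
    if data.ndim == 3:
        img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    else:
        comp = data * np.array([-1.0, -1.0, 1.0])
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(comp.transpose(2, 1, 0, 3)), isVector=True
        )
    img.SetSpacing(tuple(vol.spacing))
    img.SetOrigin(tuple(_LPS_TO_RAS @ vol.origin))
    img.SetDirection(tuple((_LPS_TO_RAS @ vol.direction).ravel()))
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))
    return path


def read_labels(path: str | Path) -> LabelMap:
    vol = read_image(path)
    return LabelMap(
        np.rint(vol.data).astype(np.int16), vol.spacing, vol.origin, vol.direction
    )


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------

def _ascii_floats(arr: np.ndarray) -> str:
    flat = np.asarray(arr, dtype=np.float64).ravel()
    return " ".join(np.format_float_scientific(v, precision=17, trim="-") for v in flat)


def _ascii_ints(arr: np.ndarray) -> str:
    return " ".join(str(int(v)) for v in np.asarray(arr).ravel())


def write_surface(mesh: SurfaceMesh, path: str | Path) -> Path:
    """Write a mesh; ``.vtp``/``.vtk`` keep per-vertex arrays, STL/PLY do not."""
    path = Path(path)
    ext = path.suffix.lower()
    path.parent.mkdir(parents=True, exist_ok=True)
    if ext == ".vtp":
        _write_vtp(mesh, path)
    elif ext == ".vtk":
        _write_vtk_legacy(mesh, path)
    elif ext in (".stl", ".ply"):
        if mesh.point_data:
            logger.warning(
                "%s cannot carry per-vertex data; writing geometry only to %s",
                ext, path,
            )
        tm = mesh.to_trimesh()
        tm.export(str(path), file_type=ext[1:])
    else:
        raise ValueError(f"unsupported surface format {ext!r}; expected one of {_SURFACE_EXTS}")
    return path


def read_surface(path: str | Path) -> SurfaceMesh:
    path = Path(path)
    ext = path.suffix.lower()
    if not path.exists():
        raise FileNotFoundError(str(path))
    if ext == ".vtp":
        return _read_vtp(path)
    if ext == ".vtk":
        return _read_vtk_legacy(path)
    if ext in (".stl", ".ply"):
        tm = trimesh.load(str(path), file_type=ext[1:], process=False)
        faces = np.asarray(tm.faces)
        if faces.shape[1] != 3:
            raise ValueError("only triangle meshes are supported")
        return SurfaceMesh(np.asarray(tm.vertices), faces)
    raise ValueError(f"unsupported surface format {ext!r}; expected one of {_SURFACE_EXTS}")


def _write_vtp(mesh: SurfaceMesh, path: Path) -> None:
    root = ET.Element(
        "VTKFile", type="PolyData", version="1.0", byte_order="LittleEndian"
    )
    poly = ET.SubElement(root, "PolyData")
    piece = ET.SubElement(
        poly,
        "Piece",
        NumberOfPoints=str(mesh.n_vertices),
        NumberOfVerts="0",
        NumberOfLines="0",
        NumberOfStrips="0",
        NumberOfPolys=str(mesh.n_faces),
    )
    pdata = ET.SubElement(piece, "PointData")
    for name in sorted(mesh.point_data):
        arr = np.asarray(mesh.point_data[name], dtype=np.float64)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        da = ET.SubElement(
            pdata,
            "DataArray",
            type="Float64",
            Name=name,
            NumberOfComponents=str(ncomp),
            format="ascii",
        )
        da.text = _ascii_floats(arr)
    points = ET.SubElement(piece, "Points")
    da = ET.SubElement(
        points, "DataArray", type="Float64", NumberOfComponents="3", format="ascii"
    )
    da.text = _ascii_floats(mesh.vertices)
    polys = ET.SubElement(piece, "Polys")
    conn = ET.SubElement(
        polys, "DataArray", type="Int64", Name="connectivity", format="ascii"
    )
    conn.text = _ascii_ints(mesh.faces)
    offs = ET.SubElement(
        polys, "DataArray", type="Int64", Name="offsets", format="ascii"
    )
    offs.text = _ascii_ints(3 * (np.arange(mesh.n_faces, dtype=np.int64) + 1))
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def _read_vtp(path: Path) -> SurfaceMesh:
    root = ET.parse(path).getroot()
    piece = root.find("./PolyData/Piece")
    if piece is None:
        raise ValueError(f"{path}: not a VTK PolyData XML file")

    def _parse(da: ET.Element) -> np.ndarray:
        if da.get("format", "ascii") != "ascii":
            raise ValueError(f"{path}: only ascii-format DataArrays are supported")
        text = (da.text or "").split()
        dtype = np.int64 if da.get("type", "").startswith("Int") else np.float64
        return np.array(text, dtype=np.float64).astype(dtype)

    pts = _parse(piece.find("./Points/DataArray")).reshape(-1, 3)
    conn = _parse(piece.find("./Polys/DataArray[@Name='connectivity']"))
    offs = _parse(piece.find("./Polys/DataArray[@Name='offsets']"))
    counts = np.diff(np.concatenate([[0], offs]))
    if counts.size and not np.all(counts == 3):
        raise ValueError(f"{path}: non-triangle cells are not supported")
    faces = conn.reshape(-1, 3).astype(np.int64)
    point_data: dict[str, np.ndarray] = {}
    pd = piece.find("PointData")
    if pd is not None:
        for da in pd.findall("DataArray"):
            arr = _parse(da).astype(np.float64)
            ncomp = int(da.get("NumberOfComponents", "1"))
            if ncomp > 1:
                arr = arr.reshape(-1, ncomp)
            point_data[da.get("Name", "unnamed")] = arr
    return SurfaceMesh(pts, faces, point_data)


def _write_vtk_legacy(mesh: SurfaceMesh, path: Path) -> None:
    lines = [
        "# vtk DataFile Version 3.0",
        "rsii surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {mesh.n_vertices} double",
    ]
    for v in mesh.vertices:
        lines.append(" ".join(np.format_float_scientific(x, precision=17, trim="-") for x in v))
    lines.append(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}")
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    scalars = {k: v for k, v in mesh.point_data.items() if np.asarray(v).ndim == 1}
    vectors = {k: v for k, v in mesh.point_data.items()
               if np.asarray(v).ndim == 2 and np.asarray(v).shape[1] == 3}
    if scalars or vectors:
        lines.append(f"POINT_DATA {mesh.n_vertices}")
        for name in sorted(scalars):
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            for v in np.asarray(scalars[name], dtype=np.float64):
                lines.append(np.format_float_scientific(v, precision=17, trim="-"))
        for name in sorted(vectors):
            lines.append(f"VECTORS {name} double")
            for v in np.asarray(vectors[name], dtype=np.float64):
                lines.append(" ".join(np.format_float_scientific(x, precision=17, trim="-") for x in v))
    path.write_text("\n".join(lines) + "\n")


def _read_vtk_legacy(path: Path) -> SurfaceMesh:
    tokens = path.read_text().split("\n")
    it = iter(range(len(tokens)))
    i = 0

    def _next_line() -> str:
        nonlocal i
        while i < len(tokens) and not tokens[i].strip():
            i += 1
        if i >= len(tokens):
            return ""
        line = tokens[i]
        i += 1
        return line

    header = [_next_line() for _ in range(4)]
    if "ASCII" not in header[2].upper():
        raise ValueError(f"{path}: only ASCII legacy VTK is supported")
    if "POLYDATA" not in header[3].upper():
        raise ValueError(f"{path}: only POLYDATA legacy VTK is supported")
    line = _next_line()
    n_pts = int(line.split()[1])
    vals: list[float] = []
    while len(vals) < 3 * n_pts:
        vals.extend(float(x) for x in _next_line().split())
    pts = np.array(vals).reshape(-1, 3)
    line = _next_line()
    if not line.upper().startswith("POLYGONS"):
        raise ValueError(f"{path}: expected POLYGONS, got {line!r}")
    n_faces = int(line.split()[1])
    faces = np.zeros((n_faces, 3), dtype=np.int64)
    for k in range(n_faces):
        parts = _next_line().split()
        if int(parts[0]) != 3:
            raise ValueError(f"{path}: non-triangle cells are not supported")
        faces[k] = [int(p) for p in parts[1:4]]
    point_data: dict[str, np.ndarray] = {}
    line = _next_line()
    if line.upper().startswith("POINT_DATA"):
        line = _next_line()
        while line:
            up = line.upper()
            if up.startswith("SCALARS"):
                name = line.split()[1]
                _next_line()  # LOOKUP_TABLE
                vals = []
                while len(vals) < n_pts:
                    vals.extend(float(x) for x in _next_line().split())
                point_data[name] = np.array(vals)
            elif up.startswith("VECTORS"):
                name = line.split()[1]
                vals = []
                while len(vals) < 3 * n_pts:
                    vals.extend(float(x) for x in _next_line().split())
                point_data[name] = np.array(vals).reshape(-1, 3)
            line = _next_line()
    return SurfaceMesh(pts, faces, point_data)


# ---------------------------------------------------------------------------
# summaries and manifests
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        if not np.isfinite(v):
            logger.warning("non-finite value serialized as null")
            return None
        return v
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_summary(summary: dict, path: str | Path) -> Path:
    """Write a JSON result summary; non-finite values become null."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(summary), indent=2, sort_keys=True) + "\n")
    return path


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Snapshot of everything needed to re-run a stage identically."""

    stage: str
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)   # path -> sha256
    version: str = ""
    started: float = field(default_factory=time.time)

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__

    def add_input(self, path: str | Path) -> None:
        path = Path(path)
        if path.exists():
            self.inputs[str(path)] = sha256_of(path)

    def write(self, path: str | Path) -> Path:
        doc = {
            "stage": self.stage,
            "config": _jsonable(self.config),
            "seeds": _jsonable(self.seeds),
            "inputs": self.inputs,
            "version": self.version,
            "started": self.started,
            "finished": time.time(),
        }
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
        return path
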