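"""Synthetic pulsating-vessel phantoms with analytic ground truth.

The phantom emulates a contrast-enhanced CTA of an idealized aneurysmal
vessel: a tube of revolution along the image z axis whose outer-wall radius

    r(z) = r0 + (Rmax - r0) * exp(-(z - z0)^2 / (2 s^2))

carries a fusiform bulge, wrapped by a wall of thickness ``h`` and an
optional intraluminal-thrombus (ILT) layer, with a bright lumen inside and
dark background outside.  Between the diastolic and systolic frames the
vessel inflates radially by a known amplitude field

    A(z, theta) = a(z) * m(z, theta)

where ``a(z)`` is the axial inflation profile and ``m >= 1`` an optional
"soft patch" multiplier emulating a locally weakened (more compliant) wall.
The analytic circumferential strain of this motion is A / r, and for the
straight-cylinder preset the hoop tension has the Laplace closed form
p * r, so registration, strain, tension and the integrity indices can all
be checked against exact values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import trimesh

from .io import (
    BACKGROUND,
    ILT,
    LUMEN,
    WALL,
    DisplacementField,
    ImageVolume,
    LabelMap,
)
from .surface import SurfaceMesh

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "preset",
    "generate_surface",
    "generate_frame_pair",
    "analytic_strain",
]


@dataclass
class PhantomSpec:
    """Geometry, motion, intensity and grid parameters of a phantom."""

    # geometry (mm)
    length: float = 90.0          # axial extent of the vessel
    r0: float = 11.0              # baseline outer-wall radius
    r_max: float = 20.0           # outer-wall radius at the bulge peak
    bulge_center: float = 0.0     # z of the bulge peak, relative to vessel mid
    bulge_width: float = 16.0     # Gaussian width s of the bulge
    wall_thickness: float = 1.5
    ilt_thickness: float = 0.0    # peak ILT thickness (scaled by bulge profile)

    # diastole -> systole motion (mm)
    amplitude: float = 1.5        # peak outward inflation a0
    amplitude_width: float | None = 16.0  # Gaussian width of a(z); None = uniform
    end_taper: float = 10.0       # inflation ramps to zero within this distance of the ends

    # soft patch (locally more compliant wall): amplitude multiplier m >= 1
    patch_multiplier: float = 1.0
    patch_theta: float = 0.0      # patch centre angle (rad, 0 = +x)
    patch_z: float = 0.0          # patch centre z, relative to vessel mid
    patch_width_z: float = 10.0   # Gaussian widths of the patch
    patch_width_theta: float = 0.6

    # intensity model (arbitrary units) and noise
    intensity_background: float = 20.0
    intensity_wall: float = 80.0
    intensity_ilt: float = 60.0
    intensity_lumen: float = 300.0
    noise_sigma: float = 0.0

    # grid
    spacing: tuple[float, float, float] = (1.25, 1.25, 1.25)
    shape: tuple[int, int, int] = (64, 64, 80)
    seed: int = 0

    # numerical details
    blend_width: float | None = None  # interface blend (mm); default 1 voxel
    supersample: int = 3              # sub-voxel sampling for partial-volume averaging
    decay: float = 6.0                # radial decay of displacement outside the wall
    kind: str = "tube"                # "tube" or "sphere" (sphere: static mesh only)

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if self.r_max < self.r0:
            raise ValueError("r_max must be >= r0")
        if self.wall_thickness <= 0:
            raise ValueError("wall thickness must be positive")
        if self.amplitude < 0:
            raise ValueError("inflation amplitude must be >= 0")
        if self.patch_multiplier < 1.0:
            raise ValueError("soft-patch multiplier must be >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        i = (self.intensity_background, self.intensity_wall,
             self.intensity_ilt, self.intensity_lumen)
        if not (i[0] < min(i[1], i[2]) and max(i[1], i[2]) < i[3]):
            raise ValueError(
                "intensities must satisfy background < wall, ILT < lumen"
            )

    # -- analytic geometry ----------------------------------------------
    @property
    def z_half(self) -> float:
        return self.length / 2.0

    def outer_radius(self, z: np.ndarray) -> np.ndarray:
        """Diastolic outer-wall radius r(z); z measured from the vessel mid."""
        z = np.asarray(z, dtype=np.float64)
        bulge = (self.r_max - self.r0) * np.exp(
            -((z - self.bulge_center) ** 2) / (2.0 * self.bulge_width**2)
        )
        return self.r0 + bulge

    def inflation_profile(self, z: np.ndarray) -> np.ndarray:
        """Axial inflation a(z), tapered to zero at the vessel ends."""
        z = np.asarray(z, dtype=np.float64)
        if self.amplitude_width is None:
            a = np.full_like(z, self.amplitude)
        else:
            a = self.amplitude * np.exp(
                -((z - self.bulge_center) ** 2) / (2.0 * self.amplitude_width**2)
            )
        if self.end_taper > 0:
            d = np.minimum(z + self.z_half, self.z_half - z) / self.end_taper
            d = np.clip(d, 0.0, 1.0)
            a = a * d * d * (3.0 - 2.0 * d)  # smoothstep window
        return a

    def patch(self, z: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Soft-patch multiplier m(z, theta) >= 1."""
        z = np.asarray(z, dtype=np.float64)
        theta = np.asarray(theta, dtype=np.float64)
        if self.patch_multiplier == 1.0:
            return np.ones(np.broadcast(z, theta).shape)
        dth = np.angle(np.exp(1j * (theta - self.patch_theta)))
        bump = np.exp(
            -((z - self.patch_z) ** 2) / (2.0 * self.patch_width_z**2)
            - dth**2 / (2.0 * self.patch_width_theta**2)
        )
        return 1.0 + (self.patch_multiplier - 1.0) * bump

    def total_amplitude(self, z: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """A(z, theta) = a(z) * m(z, theta), the outward inflation in mm."""
        return self.inflation_profile(z) * self.patch(z, theta)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def preset(name: str, seed: int = 0, **overrides) -> PhantomSpec:
    """Named phantom configurations used throughout the test-bed.

    ``cylinder``   straight tube r=25 mm, uniform 1 mm inflation (closed-form
                   hoop tension p*r and uniform strain a/r away from the ends).
    ``fusiform``   aneurysmal bulge (r 11 -> 20 mm) with an ILT layer and a
                   bulge-centred inflation bump.
    ``soft-patch`` fusiform plus a compliant patch (inflation doubled inside).
    ``sphere``     static sphere of radius r0 (surface generation only).
    """
    presets = {
        "cylinder": dict(
            length=70.0, r0=25.0, r_max=25.0, amplitude=1.0,
            amplitude_width=None, ilt_thickness=0.0,
            spacing=(1.25, 1.25, 1.25), shape=(72, 72, 64),
        ),
        "fusiform": dict(
            length=90.0, r0=11.0, r_max=20.0, bulge_width=16.0,
            amplitude=1.5, amplitude_width=16.0, ilt_thickness=3.0,
            spacing=(1.25, 1.25, 1.25), shape=(64, 64, 80),
        ),
        "soft-patch": dict(
            length=90.0, r0=11.0, r_max=20.0, bulge_width=16.0,
            amplitude=1.5, amplitude_width=16.0, ilt_thickness=3.0,
            patch_multiplier=2.0, patch_width_z=10.0, patch_width_theta=0.6,
            noise_sigma=6.0,
            spacing=(1.25, 1.25, 1.25), shape=(64, 64, 80),
        ),
        "sphere": dict(r0=25.0, r_max=25.0, kind="sphere", amplitude=0.0),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    cfg = dict(presets[name])
    cfg.update(overrides)
    return PhantomSpec(seed=seed, **cfg)


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------

def _grid_center(spec: PhantomSpec) -> np.ndarray:
    """World position of the vessel axis mid-point (grid centre)."""
    ext = (np.array(spec.shape) - 1) * np.array(spec.spacing)
    return ext / 2.0


def generate_surface(
    spec: PhantomSpec,
    phase: str = "diastole",
    target_edge: float | None = None,
) -> SurfaceMesh:
    """Closed, outward-oriented triangulated outer-wall surface at a phase.

    Carries ground-truth point data: ``u_truth`` (displacement to the other
    phase, mm) and ``strain_truth`` (analytic circumferential strain).
    For tube phantoms the surface is a capped surface of revolution; the cap
    vertices are marked in the ``cap`` point-data array.
    """
    if phase not in ("diastole", "systole"):
        raise ValueError(f"phase must be 'diastole' or 'systole', got {phase!r}")
    if target_edge is None:
        target_edge = max(1.0, float(min(spec.spacing)))

    center = _grid_center(spec)

    if spec.kind == "sphere":
        tm = trimesh.creation.icosphere(
            subdivisions=max(2, int(np.ceil(np.log2(np.pi * spec.r0 / target_edge)))),
            radius=spec.r0,
        )
        mesh = SurfaceMesh(np.asarray(tm.vertices) + center, np.asarray(tm.faces))
        n = mesh.n_vertices
        mesh.point_data["u_truth"] = np.zeros((n, 3))
        mesh.point_data["strain_truth"] = np.zeros(n)
        mesh.point_data["cap"] = np.zeros(n)
        return mesh

    n_theta = max(16, int(np.ceil(2.0 * np.pi * spec.r_max / target_edge)))
    n_z = max(8, int(np.ceil(spec.length / target_edge)))
    z = np.linspace(-spec.z_half, spec.z_half, n_z + 1)
    theta = np.arange(n_theta) * (2.0 * np.pi / n_theta)

    zz, tt = np.meshgrid(z, theta, indexing="ij")
    r_dia = spec.outer_radius(zz)
    amp = spec.total_amplitude(zz, tt)
    r = r_dia + amp if phase == "systole" else r_dia
    if np.any(r <= 0):
        raise ValueError("degenerate phantom: non-positive surface radius")

    verts = np.stack(
        [
            center[0] + r * np.cos(tt),
            center[1] + r * np.sin(tt),
            center[2] + zz,
        ],
        axis=-1,
    ).reshape(-1, 3)

    def vid(i: int | np.ndarray, j: np.ndarray) -> np.ndarray:
        return i * n_theta + (j % n_theta)

    faces = []
    jj = np.arange(n_theta)
    for i in range(n_z):
        a0 = vid(i, jj)
        b0 = vid(i, jj + 1)
        a1 = vid(i + 1, jj)
        b1 = vid(i + 1, jj + 1)
        faces.append(np.stack([a0, b0, b1], axis=1))
        faces.append(np.stack([a0, b1, a1], axis=1))
    faces = np.concatenate(faces)

    # end caps: a fan to a centre vertex at each end
    n_tube = len(verts)
    bottom_c = np.array([[center[0], center[1], center[2] - spec.z_half]])
    top_c = np.array([[center[0], center[1], center[2] + spec.z_half]])
    verts = np.concatenate([verts, bottom_c, top_c])
    i_bot, i_top = n_tube, n_tube + 1
    bot_ring = vid(0, jj)
    top_ring = vid(n_z, jj)
    cap_faces = np.concatenate(
        [
            np.stack([np.full(n_theta, i_bot), vid(0, jj + 1), bot_ring], axis=1),
            np.stack([np.full(n_theta, i_top), top_ring, vid(n_z, jj + 1)], axis=1),
        ]
    )
    faces = np.concatenate([faces, cap_faces])

    mesh = SurfaceMesh(verts, faces)
    if mesh.signed_volume() < 0:
        mesh.faces = mesh.faces[:, ::-1].copy()
    mesh.validate()

    # ground truth point data (caps carry zero motion)
    vz = verts[:, 2] - center[2]
    vth = np.arctan2(verts[:, 1] - center[1], verts[:, 0] - center[0])
    amp_v = spec.total_amplitude(vz, vth)
    r_v = spec.outer_radius(vz)
    e_r = np.zeros_like(verts)
    e_r[:, 0] = np.cos(vth)
    e_r[:, 1] = np.sin(vth)
    cap = np.zeros(len(verts))
    cap[[i_bot, i_top]] = 1.0
    cap[np.abs(np.abs(vz) - spec.z_half) < 1e-9] = 1.0
    sign = 1.0 if phase == "diastole" else -1.0  # displacement to the other phase
    mesh.point_data["u_truth"] = sign * amp_v[:, None] * e_r
    mesh.point_data["strain_truth"] = amp_v / r_v
    mesh.point_data["cap"] = cap
    return mesh


# ---------------------------------------------------------------------------
# voxelized frame pair
# ---------------------------------------------------------------------------

def _smoothstep(d: np.ndarray, w: float) -> np.ndarray:
    """0 -> 1 transition of width w centred on d = 0 (d = signed distance)."""
    t = np.clip(d / w + 0.5, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


@dataclass
class PhantomTruth:
    """Analytic ground truth attached to a generated frame pair."""

    spec: PhantomSpec
    displacement: DisplacementField  # systolic grid -> diastolic positions
    labels: LabelMap                 # diastolic-frame labels

    def strain(self, points: np.ndarray, tol: float = 3.0) -> np.ndarray:
        return analytic_strain(self.spec, points, tol=tol)


def _cylindrical(spec: PhantomSpec, vol_like_points: np.ndarray) -> tuple:
    center = _grid_center(spec)
    d = vol_like_points - center
    rho = np.hypot(d[..., 0], d[..., 1])
    theta = np.arctan2(d[..., 1], d[..., 0])
    z = d[..., 2]
    return rho, theta, z


def _intensity(spec: PhantomSpec, rho, theta, z, phase: str) -> np.ndarray:
    """Plateau intensity model with smooth (~1 voxel) interface blending."""
    w = spec.blend_width if spec.blend_width is not None else float(
        np.mean(spec.spacing[:2])
    )
    h = spec.wall_thickness
    r_w = spec.outer_radius(z)
    ilt = spec.ilt_thickness * (
        (r_w - spec.r0) / max(spec.r_max - spec.r0, 1e-12)
        if spec.r_max > spec.r0
        else np.ones_like(r_w)
    )
    r_wi = r_w - h
    r_l = np.maximum(r_wi - ilt, 0.5)
    if phase == "systole":
        amp = spec.total_amplitude(z, theta)
        scale = amp / r_w
        r_l = r_l * (1.0 + scale)
        r_wi = r_wi * (1.0 + scale)
        r_w = r_w + amp

    z_half = spec.z_half
    sd_solid = np.minimum(r_w - rho, np.minimum(z + z_half, z_half - z))
    sd_inner_ax = np.minimum(z + z_half - h, z_half - h - z)
    sd_ilt = np.minimum(r_wi - rho, sd_inner_ax)
    sd_lum = np.minimum(r_l - rho, sd_inner_ax)

    img = np.full(rho.shape, spec.intensity_background)
    img += (spec.intensity_wall - spec.intensity_background) * _smoothstep(sd_solid, w)
    img += (spec.intensity_ilt - spec.intensity_wall) * _smoothstep(sd_ilt, w)
    img += (spec.intensity_lumen - spec.intensity_ilt) * _smoothstep(sd_lum, w)
    return img


def _labels(spec: PhantomSpec, rho, theta, z) -> np.ndarray:
    h = spec.wall_thickness
    r_w = spec.outer_radius(z)
    ilt = spec.ilt_thickness * (
        (r_w - spec.r0) / max(spec.r_max - spec.r0, 1e-12)
        if spec.r_max > spec.r0
        else np.ones_like(r_w)
    )
    r_wi = r_w - h
    r_l = np.maximum(r_wi - ilt, 0.5)
    z_half = spec.z_half
    inside_solid = (rho <= r_w) & (np.abs(z) <= z_half)
    inside_ax = np.abs(z) <= z_half - h
    lab = np.zeros(rho.shape, dtype=np.int16)
    lab[inside_solid] = WALL
    lab[(rho <= r_wi) & inside_ax] = ILT
    lab[(rho <= r_l) & inside_ax] = LUMEN
    return lab


def _truth_displacement(spec: PhantomSpec, rho_s, theta, z) -> np.ndarray:
    """Radial map from systolic positions back to diastolic ones (mm)."""
    amp = spec.total_amplitude(z, theta)
    r_w = spec.outer_radius(z)
    decay = spec.decay
    # forward map (diastole -> systole): rho' = rho*(1 + A/r_w)      rho <= r_w
    #                                    rho' = rho + A*(1-(rho-r_w)/decay)
    # invert both branches
    with np.errstate(divide="ignore", invalid="ignore"):
        rho_in = rho_s / (1.0 + amp / r_w)
        denom = 1.0 - amp / decay
        rho_out = (rho_s - amp * (1.0 + r_w / decay)) / denom
    rho_d = np.where(rho_s <= r_w + amp, rho_in, rho_out)
    rho_d = np.where(rho_s >= r_w + decay, rho_s, rho_d)
    du = rho_d - rho_s
    u = np.zeros(rho_s.shape + (3,))
    u[..., 0] = du * np.cos(theta)
    u[..., 1] = du * np.sin(theta)
    return u


def generate_frame_pair(
    spec: PhantomSpec,
) -> tuple[ImageVolume, ImageVolume, LabelMap, PhantomTruth]:
    """Voxelize a diastolic/systolic frame pair with labels and truth field.

    Returns ``(diastolic, systolic, labels, truth)``; the truth displacement
    field lives on the systolic grid and points to diastolic positions
    (the registration output contract).  Noise is additive Gaussian from the
    seeded generator; with ``amplitude = 0`` and ``noise_sigma = 0`` the two
    frames are bit-identical.
    """
    if spec.kind == "sphere":
        raise ValueError("frame pairs are defined for tube phantoms only")
    spacing = np.asarray(spec.spacing)
    shape = spec.shape
    margin = 3.0 * spacing
    half_extent = (np.array(shape) - 1) * spacing / 2.0
    max_amp = spec.amplitude * spec.patch_multiplier
    need_xy = spec.r_max + max_amp
    need_z = spec.z_half
    for ax, need in ((0, need_xy), (1, need_xy), (2, need_z)):
        if need > half_extent[ax] - margin[ax]:
            raise ValueError(
                f"phantom extent {need:.1f} mm exceeds grid half-extent "
                f"{half_extent[ax]:.1f} mm minus 3-voxel margin on axis {ax}"
            )

    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
    ).astype(np.float64)
    pts = idx * spacing  # identity direction, origin 0
    rho, theta, z = _cylindrical(spec, pts)

    # partial-volume anti-aliasing: average the analytic intensity over a
    # supersampled sub-voxel grid.  The systolic frame is the diastolic
    # intensity advected by the motion (evaluated at the pulled-back radius),
    # so the truth field explains the image pair exactly in the continuum.
    ss = max(1, int(spec.supersample))
    sub = (np.arange(ss) + 0.5) / ss - 0.5
    dia = np.zeros(shape)
    sys_ = np.zeros(shape)
    for dx in sub:
        for dy in sub:
            for dz in sub:
                off = pts + np.array([dx, dy, dz]) * spacing
                rho_o, th_o, z_o = _cylindrical(spec, off)
                dia += _intensity(spec, rho_o, th_o, z_o, "diastole")
                u_o = _truth_displacement(spec, rho_o, th_o, z_o)
                rho_d = rho_o + u_o[..., 0] * np.cos(th_o) + u_o[..., 1] * np.sin(th_o)
                sys_ += _intensity(spec, rho_d, th_o, z_o, "diastole")
    dia /= ss**3
    sys_ /= ss**3
    u = _truth_displacement(spec, rho, theta, z)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        dia = dia + rng.normal(0.0, spec.noise_sigma, dia.shape)
        sys_ = sys_ + rng.normal(0.0, spec.noise_sigma, sys_.shape)

    origin = np.zeros(3)
    dia_vol = ImageVolume(dia, spacing, origin)
    sys_vol = ImageVolume(sys_, spacing, origin)
    labels = LabelMap(_labels(spec, rho, theta, z), spacing, origin)
    truth = PhantomTruth(
        spec, DisplacementField(u, spacing, origin), labels
    )
    return dia_vol, sys_vol, labels, truth


def analytic_strain(
    spec: PhantomSpec, points: np.ndarray, tol: float = 3.0
) -> np.ndarray:
    """Exact circumferential strain A(z, theta) / r(z) at near-wall points.

    ``points`` are world coordinates on (or within ``tol`` mm of) the
    diastolic wall; points farther away are rejected.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    rho, theta, z = _cylindrical(spec, points)
    r_w = spec.outer_radius(z)
    off = np.abs(rho - r_w)
    if np.any(off > tol):
        bad = int(np.argmax(off))
        raise ValueError(
            f"point {bad} is {off[bad]:.2f} mm from the wall surface (tol {tol} mm)"
        )
    return spec.total_amplitude(z, theta) / r_w


def write_phantom(spec: PhantomSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write a phantom data set (volumes, truth surfaces, spec)."""
    from . import io as _io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if spec.kind == "sphere":
        mesh = generate_surface(spec, "diastole")
        paths["surface"] = _io.write_surface(mesh, out / "surface.vtp")
    else:
        dia, sys_, labels, truth = generate_frame_pair(spec)
        paths["diastole"] = _io.write_image(dia, out / "diastole.nii.gz")
        paths["systole"] = _io.write_image(sys_, out / "systole.nii.gz")
        paths["labels"] = _io.write_image(labels, out / "labels.nii.gz")
        paths["u_truth"] = _io.write_image(truth.displacement, out / "u_truth.mha")
        for phase in ("diastole", "systole"):
            mesh = generate_surface(spec, phase)
            paths[f"surface_{phase}"] = _io.write_surface(
                mesh, out / f"surface_{phase}.vtp"
            )
    (out / "phantom_spec.json").write_text(spec.to_json() + "\n")
    paths["spec"] = out / "phantom_spec.json"
    return paths
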