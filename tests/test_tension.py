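"""Tension recovery against pressure-vessel closed forms and Lame theory."""

import numpy as np
import pytest
import trimesh

from rsii import (
    SurfaceMesh,
    TensionConfig,
    build_shell_mesh,
    generate_surface,
    integrate_tension,
    preset,
    solve_membrane,
    solve_shell3d,
    uniform_stress_correction,
)
from tests.conftest import grid_center

P = 0.013  # 13 kPa in N/mm^2


def _sphere_mesh(radius, subdivisions=4):
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def lame_tension(a, b, p):
    """Exact through-thickness integral of the Lame hoop stress."""
    term = 1.5 * b + b**3 / (2 * a**2) - 2 * a
    return p * a**3 / (2 * (b**3 - a**3)) * term


@pytest.fixture(scope="module")
def sphere25():
    return _sphere_mesh(25.0)


@pytest.fixture(scope="module")
def cylinder_mesh():
    return generate_surface(preset("cylinder"), "diastole", target_edge=1.25)


# -- membrane ----------------------------------------------------------------

def test_sphere_tension_matches_laplace(sphere25):
    fld = solve_membrane(sphere25, TensionConfig())
    want = P * 25.0 / 2.0
    assert abs(fld.t_max.mean() / want - 1.0) < 0.02
    assert abs(fld.t_min.mean() / want - 1.0) < 0.02


def test_cylinder_hoop_and_axial_match_closed_form(cylinder_mesh):
    spec = preset("cylinder")
    fld = solve_membrane(cylinder_mesh, TensionConfig())
    z = cylinder_mesh.vertices[:, 2] - grid_center(spec)[2]
    mid = (np.abs(z) < 10) & (cylinder_mesh.point_data["cap"] == 0)
    assert abs(fld.t_max[mid].mean() / (P * 25.0) - 1.0) < 0.02
    assert abs(fld.t_min[mid].mean() / (P * 12.5) - 1.0) < 0.02


def test_membrane_is_linear_in_pressure(sphere25):
    f1 = solve_membrane(sphere25, TensionConfig(pressure_kpa=13.0))
    f2 = solve_membrane(sphere25, TensionConfig(pressure_kpa=26.0))
    np.testing.assert_allclose(f2.tensor, 2.0 * f1.tensor, rtol=1e-9)


def test_membrane_resultant_independent_of_thickness(sphere25):
    f1 = solve_membrane(sphere25, TensionConfig(thickness=1.5))
    f2 = solve_membrane(sphere25, TensionConfig(thickness=2.25))
    np.testing.assert_allclose(f2.t_max, f1.t_max, rtol=1e-9)


# -- shell construction ------------------------------------------------------

def test_shell_extrusion_offsets_and_count():
    mesh = _sphere_mesh(24.25, subdivisions=3)
    vm = build_shell_mesh(mesh, 1.5, layers=3)
    r_inner = np.linalg.norm(vm.nodes[vm.inner_nodes], axis=1)
    r_outer = np.linalg.norm(vm.nodes[vm.outer_nodes], axis=1)
    np.testing.assert_allclose(r_inner, 23.5, atol=0.1)
    np.testing.assert_allclose(r_outer, 25.0, atol=0.1)
    assert len(vm.tets) == 3 * 3 * mesh.n_faces


def test_shell_mesh_is_conforming():
    mesh = _sphere_mesh(24.25, subdivisions=2)
    vm = build_shell_mesh(mesh, 1.5, layers=2)
    faces = np.sort(
        np.concatenate([vm.tets[:, c] for c in ([0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3])]),
        axis=1,
    )
    _, counts = np.unique(faces, axis=0, return_counts=True)
    assert set(counts) <= {1, 2}
    n_boundary = (counts == 1).sum()
    assert n_boundary == 2 * mesh.n_faces  # inner + outer sheets only


def test_excessive_thickness_raises_self_intersection():
    mesh = _sphere_mesh(25.0, subdivisions=2)
    with pytest.raises(ValueError, match="self-intersect"):
        build_shell_mesh(mesh, 60.0, layers=2)


# -- shell3d solve -----------------------------------------------------------

@pytest.fixture(scope="module")
def lame_solution():
    mesh = _sphere_mesh(24.25, subdivisions=3)
    vm = build_shell_mesh(mesh, 1.5, layers=3)
    cfg = TensionConfig(backend="shell3d")
    sigma = solve_shell3d(vm, cfg)
    return mesh, vm, cfg, sigma


def test_thick_sphere_hoop_stress_matches_lame(lame_solution):
    mesh, vm, cfg, sigma = lame_solution
    cent = vm.nodes[vm.tets].mean(axis=1)
    r = np.linalg.norm(cent, axis=1)
    a, b = 23.5, 25.0
    want = P * a**3 * (b**3 + 2 * r**3) / (2 * r**3 * (b**3 - a**3))
    er = cent / r[:, None]
    srr = (
        sigma[:, 0] * er[:, 0] ** 2 + sigma[:, 1] * er[:, 1] ** 2
        + sigma[:, 2] * er[:, 2] ** 2
        + 2 * sigma[:, 3] * er[:, 0] * er[:, 1]
        + 2 * sigma[:, 4] * er[:, 1] * er[:, 2]
        + 2 * sigma[:, 5] * er[:, 0] * er[:, 2]
    )
    hoop = (sigma[:, :3].sum(axis=1) - srr) / 2.0
    # layer-wise means against the analytic profile
    for lay in range(vm.layers):
        sel = vm.tet_parent[:, 1] == lay
        assert abs(hoop[sel].mean() / want[sel].mean() - 1.0) < 0.05


def test_integrated_tension_matches_lame_integral(lame_solution):
    mesh, vm, cfg, sigma = lame_solution
    fld = integrate_tension(sigma, vm, mesh, 1.5)
    want = lame_tension(23.5, 25.0, P)
    assert abs(fld.t_max.mean() / want - 1.0) < 0.02


def test_shell_tension_insensitive_to_youngs_modulus(lame_solution):
    mesh, vm, cfg, sigma = lame_solution
    stiff = TensionConfig(backend="shell3d", youngs_modulus_mpa=cfg.youngs_modulus_mpa * 10)
    sigma10 = solve_shell3d(vm, stiff)
    f1 = integrate_tension(sigma, vm, mesh, 1.5)
    f2 = integrate_tension(sigma10, vm, mesh, 1.5)
    assert abs(f2.t_max.mean() / f1.t_max.mean() - 1.0) < 1e-3


def test_zero_pressure_gives_zero_stress():
    mesh = _sphere_mesh(24.25, subdivisions=2)
    vm = build_shell_mesh(mesh, 1.5, layers=2)
    cfg = TensionConfig(backend="shell3d", pressure_kpa=13.0)
    sigma = solve_shell3d(vm, cfg)
    cfg_half = TensionConfig(backend="shell3d", pressure_kpa=6.5)
    sigma_half = solve_shell3d(vm, cfg_half)
    np.testing.assert_allclose(sigma_half, 0.5 * sigma, atol=1e-9 * np.abs(sigma).max())


def test_mid_loaded_shell_agrees_with_membrane():
    mesh = _sphere_mesh(24.25, subdivisions=3)
    vm = build_shell_mesh(mesh, 1.5, layers=2)
    cfg = TensionConfig(backend="shell3d", layers=2, load_surface="mid")
    sigma = solve_shell3d(vm, cfg)
    shell = integrate_tension(sigma, vm, mesh, 1.5)
    mem = solve_membrane(mesh, TensionConfig())
    assert abs(shell.t_max.mean() / mem.t_max.mean() - 1.0) < 0.03


# -- uniform-stress correction ----------------------------------------------

def test_uniform_stress_correction_averages_profile():
    np.testing.assert_allclose(
        uniform_stress_correction([1.0, 2.0, 3.0]), [2.0, 2.0, 2.0]
    )


def test_uniform_stress_correction_conserves_integral():
    rng = np.random.default_rng(0)
    profile = rng.normal(size=17)
    out = uniform_stress_correction(profile)
    np.testing.assert_allclose(out.sum(), profile.sum(), atol=1e-12)


def test_uniform_stress_correction_single_sample_unchanged():
    np.testing.assert_allclose(uniform_stress_correction([4.2]), [4.2])


# -- equilibrium -------------------------------------------------------------

def test_pressure_loads_self_equilibrate_on_closed_surface(sphere25):
    from rsii.tension import _pressure_loads

    loads = _pressure_loads(sphere25, P)
    total = np.abs(loads.sum(axis=0)).max()
    scale = P * np.pi * 25.0**2  # projected-area force scale
    assert total < 0.005 * scale
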