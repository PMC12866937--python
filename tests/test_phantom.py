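"""Phantom generator: geometry, ground truth and self-consistency."""

import numpy as np
import pytest

from rsii import (
    analytic_strain,
    generate_frame_pair,
    generate_surface,
    preset,
    warp,
)
from rsii.io import BACKGROUND, ILT, LUMEN, WALL
from tests.conftest import grid_center


def test_cylinder_surface_is_at_constant_radius():
    spec = preset("cylinder")
    mesh = generate_surface(spec, "diastole")
    c = grid_center(spec)
    rr = np.hypot(*(mesh.vertices[:, :2] - c[:2]).T)
    tube = mesh.point_data["cap"] == 0
    np.testing.assert_allclose(rr[tube], 25.0, atol=1e-9)
    assert mesh.is_closed()
    assert mesh.signed_volume() > 0


def test_zero_inflation_gives_identical_phases():
    spec = preset("fusiform", amplitude=0.0)
    d = generate_surface(spec, "diastole")
    s = generate_surface(spec, "systole")
    np.testing.assert_array_equal(d.vertices, s.vertices)
    dia, sys_, _, _ = generate_frame_pair(spec)
    np.testing.assert_array_equal(dia.data, sys_.data)


def test_sphere_preset_area_matches_analytic():
    mesh = generate_surface(preset("sphere"))
    assert abs(mesh.area() / (4 * np.pi * 25.0**2) - 1.0) < 0.02


def test_same_seed_reproduces_noisy_volumes():
    a = generate_frame_pair(preset("soft-patch", seed=11))
    b = generate_frame_pair(preset("soft-patch", seed=11))
    np.testing.assert_array_equal(a[0].data, b[0].data)
    np.testing.assert_array_equal(a[1].data, b[1].data)


def test_degenerate_spec_rejected():
    with pytest.raises(ValueError):
        preset("cylinder", r0=-1.0, r_max=-1.0)
    with pytest.raises(ValueError, match="exceeds grid"):
        generate_frame_pair(preset("cylinder", r0=60.0, r_max=60.0))


@pytest.mark.parametrize(
    "kwargs, expected",
    [
        (dict(), 0.04),                                   # a/r = 1/25
        (dict(amplitude=0.0), 0.0),
        (dict(patch_multiplier=2.0, patch_width_theta=0.6), 0.08),
    ],
)
def test_analytic_strain_arithmetic(kwargs, expected):
    spec = preset("cylinder", end_taper=0.0, **kwargs)
    c = grid_center(spec)
    point = c + np.array([25.0, 0.0, 0.0])  # on the wall, patch centre angle
    np.testing.assert_allclose(analytic_strain(spec, point), expected, atol=1e-12)


def test_analytic_strain_rejects_off_surface_points():
    spec = preset("cylinder")
    c = grid_center(spec)
    with pytest.raises(ValueError, match="from the wall"):
        analytic_strain(spec, c + np.array([10.0, 0.0, 0.0]))


def test_strain_scales_with_amplitude_and_inverse_radius():
    base = preset("cylinder", end_taper=0.0)
    c = grid_center(base)
    pt = lambda r: c + np.array([r, 0.0, 0.0])
    e1 = analytic_strain(base, pt(25.0))[0]
    e2 = analytic_strain(preset("cylinder", end_taper=0.0, amplitude=2.0), pt(25.0))[0]
    assert np.isclose(e2, 2 * e1)
    small = preset("cylinder", end_taper=0.0, r0=12.5, r_max=12.5)
    e3 = analytic_strain(small, pt(12.5))[0]
    assert np.isclose(e3, 2 * e1)


def test_label_map_is_nested_and_wall_seals_interior():
    from scipy import ndimage

    spec = preset("fusiform")
    _, _, labels, _ = generate_frame_pair(spec)
    present = set(np.unique(labels.data))
    assert present == {BACKGROUND, LUMEN, ILT, WALL}
    interior = np.isin(labels.data, (LUMEN, ILT))
    grown = ndimage.binary_dilation(
        interior, ndimage.generate_binary_structure(3, 1)
    )
    assert not np.any(grown & (labels.data == BACKGROUND))


def test_warping_diastole_by_truth_reproduces_systole():
    spec = preset("fusiform")  # noise-free
    dia, sys_, _, truth = generate_frame_pair(spec)
    warped = warp(dia, truth.displacement, background=spec.intensity_background)
    err = np.abs(warped.data - sys_.data).mean()
    base = np.abs(dia.data - sys_.data).mean()
    contrast = spec.intensity_lumen - spec.intensity_background
    assert err < 0.01 * contrast  # only trilinear resampling error remains
    assert err < 0.5 * base


def test_truth_field_is_radial_with_unit_amplitude_on_cylinder_wall():
    spec = preset("cylinder")
    _, _, _, truth = generate_frame_pair(spec)
    c = grid_center(spec)
    ths = np.linspace(0, 2 * np.pi, 32, endpoint=False)
    pts = np.stack(
        [c[0] + 26.0 * np.cos(ths), c[1] + 26.0 * np.sin(ths), np.full_like(ths, c[2])],
        axis=1,
    )  # systolic outer wall radius (25 + a)
    from rsii import sample_displacement
    from rsii.phantom import _cylindrical, _truth_displacement

    # continuum field: exactly 1 mm inward at the systolic wall radius
    rho, th, zz = _cylindrical(spec, pts)
    u_exact = _truth_displacement(spec, rho, th, zz)
    er = np.stack([np.cos(ths), np.sin(ths), np.zeros_like(ths)], axis=1)
    np.testing.assert_allclose(-(u_exact * er).sum(1), 1.0, atol=1e-9)

    # voxelized field: trilinear sampling at the kink softens it slightly
    u = sample_displacement(truth.displacement, pts)
    np.testing.assert_allclose(-(u * er).sum(1), 1.0, atol=0.08)
    np.testing.assert_allclose(u[:, 2], 0.0, atol=1e-9)
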