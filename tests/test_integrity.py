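"""SII / RSII arithmetic, masking, percentiles and region comparison."""

import numpy as np
import pytest
import trimesh

from rsii import (
    SurfaceMesh,
    compare_regions,
    compute_rsii,
    compute_sii,
    exclusion_mask,
    generate_surface,
    percentile_summary,
    preset,
)


def _tube(length=80.0, radius=10.0, open_ends=True):
    spec = preset(
        "cylinder", length=length, r0=radius, r_max=radius,
        shape=(48, 48, 80), spacing=(1.25, 1.25, 1.25),
    )
    mesh = generate_surface(spec, "diastole", target_edge=2.0)
    if open_ends:
        keep = mesh.point_data["cap"] == 0
        # drop cap centre vertices and their fans
        idx = np.flatnonzero(keep)
        remap = -np.ones(mesh.n_vertices, dtype=int)
        remap[idx] = np.arange(len(idx))
        fmask = keep[mesh.faces].all(axis=1)
        mesh = SurfaceMesh(mesh.vertices[idx], remap[mesh.faces[fmask]])
    return mesh


# -- SII ---------------------------------------------------------------------

@pytest.mark.parametrize(
    "eps, t, want",
    [(0.04, 0.325, 0.12308), (-0.02, 0.325, -0.06154)],
)
def test_sii_ratio_keeps_sign(eps, t, want):
    sii, floored = compute_sii(np.array([eps]), np.array([t]))
    assert sii[0] == pytest.approx(want, abs=1e-5)
    assert not floored[0]


def test_sii_floors_tiny_tension_and_flags():
    sii, floored = compute_sii(np.array([0.01]), np.array([1e-6]))
    assert floored[0]
    assert sii[0] == pytest.approx(0.01 / 1e-3)


def test_sii_requires_colocated_fields():
    with pytest.raises(ValueError, match="colocated"):
        compute_sii(np.zeros(5), np.ones(4))


# -- exclusion mask ----------------------------------------------------------

def test_cylinder_exclusion_keeps_the_middle():
    mesh = _tube(length=80.0)
    included = exclusion_mask(mesh, boundary_distance_mm=5.0)
    z = mesh.vertices[:, 2]
    zc = 0.5 * (z.min() + z.max())
    # included band spans about the middle 70 mm
    zin = z[included]
    assert zin.min() - z.min() > 4.0
    assert z.max() - zin.max() > 4.0
    assert np.all(np.abs(zin - zc) < 36.0)


def test_all_flagged_raises():
    mesh = _tube()
    with pytest.raises(ValueError, match="every vertex"):
        exclusion_mask(mesh, 5.0, flags=np.ones(mesh.n_vertices))


def test_zero_distance_no_flags_includes_everything():
    mesh = _tube()
    included = exclusion_mask(mesh, 0.0)
    assert included.all()


# -- RSII --------------------------------------------------------------------

def test_rsii_small_example():
    sii = np.array([2.0, -2.0, 4.0])
    rsii, mean_abs = compute_rsii(sii, np.ones(3, bool))
    assert mean_abs == pytest.approx(8.0 / 3.0)
    np.testing.assert_allclose(rsii, [0.75, -0.75, 1.5])


def test_uniform_sii_gives_unit_rsii():
    rsii, _ = compute_rsii(np.full(10, 0.3), np.ones(10, bool))
    np.testing.assert_allclose(rsii, 1.0)


def test_rsii_normalization_invariant():
    rng = np.random.default_rng(0)
    sii = rng.normal(size=500)
    inc = rng.random(500) > 0.3
    rsii, _ = compute_rsii(sii, inc)
    assert abs(np.abs(rsii[inc]).mean() - 1.0) < 1e-9


def test_abs_numerator_reading():
    rsii, _ = compute_rsii(np.array([2.0, -2.0]), np.ones(2, bool), abs_numerator=True)
    np.testing.assert_allclose(rsii, [1.0, 1.0])


def test_all_zero_sii_rejected():
    with pytest.raises(ValueError, match="zero"):
        compute_rsii(np.zeros(5), np.ones(5, bool))


# -- percentile --------------------------------------------------------------

def test_percentile_linear_interpolation_rule():
    vals = np.arange(1.0, 101.0)
    assert percentile_summary(vals, q=99) == pytest.approx(99.01)


def test_percentile_constant_field():
    assert percentile_summary(np.full(50, 3.3)) == pytest.approx(3.3)


def test_percentile_q100_is_max():
    vals = np.array([5.0, 1.0, 9.0, 2.0])
    assert percentile_summary(vals, q=100) == 9.0


# -- regions -----------------------------------------------------------------

def test_region_difference_of_means():
    rsii = np.concatenate([np.full(20, 2.0), np.full(30, 1.0)])
    labels = np.array(["aaa"] * 20 + ["healthy"] * 30)
    out = compare_regions(rsii, labels)
    assert out["difference"]["mean"] == pytest.approx(1.0)


def test_identical_regions_differ_by_zero():
    rsii = np.tile([0.5, 1.5], 20)
    labels = np.array((["a"] * 2 + ["b"] * 2) * 10)
    out = compare_regions(rsii, labels)
    assert out["difference"]["mean"] == pytest.approx(0.0)


def test_undersized_region_rejected():
    rsii = np.ones(15)
    labels = np.array(["a"] * 12 + ["b"] * 3)
    with pytest.raises(ValueError, match="vertices"):
        compare_regions(rsii, labels)
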