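"""Wall surface extraction, local frames, curvature and strain."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st

from rsii import (
    DisplacementField,
    KinematicsParams,
    LabelMap,
    WallFrame,
    circumferential_strain,
    decompose_displacement,
    estimate_radius,
    extract_wall_surface,
    fit_local_frame,
    sample_displacement,
)


def _sphere_cloud(radius=25.0, n=4):
    tm = trimesh.creation.icosphere(subdivisions=n, radius=radius)
    return np.asarray(tm.vertices)


# -- surface extraction ------------------------------------------------------

def test_sphere_shell_extraction_radius_and_area(sphere_labels):
    mesh = extract_wall_surface(sphere_labels, 1.5)
    c = (np.array(sphere_labels.shape) - 1) * sphere_labels.spacing / 2.0
    rr = np.linalg.norm(mesh.vertices - c, axis=1)
    assert abs(rr.mean() - 24.25) < 0.2  # outer 25 offset inward by h/2
    assert abs(mesh.area() / (4 * np.pi * 24.25**2) - 1.0) < 0.02


def test_two_shells_largest_kept_with_warning(sphere_labels, caplog):
    lab = sphere_labels.data.copy()
    # add a tiny disjoint shell in a corner
    lab[2:8, 2:8, 2:8] = 3
    lab[4:6, 4:6, 4:6] = 1
    small = LabelMap(lab, sphere_labels.spacing, sphere_labels.origin)
    with caplog.at_level("WARNING", logger="rsii"):
        mesh = extract_wall_surface(small, 1.5)
    assert any("components" in r.message for r in caplog.records)
    c = (np.array(small.shape) - 1) * small.spacing / 2.0
    assert np.linalg.norm(mesh.vertices - c, axis=1).mean() > 20


def test_open_shell_rejected(sphere_labels):
    lab = sphere_labels.data.copy()
    c = np.array(sphere_labels.shape) // 2
    lab[c[0], c[1], :] = 1  # drill a lumen channel through the wall
    with pytest.raises(ValueError, match="open"):
        extract_wall_surface(
            LabelMap(lab, sphere_labels.spacing, sphere_labels.origin), 1.5
        )


# -- displacement sampling ---------------------------------------------------

def test_constant_field_sampled_exactly():
    u = np.tile([1.0, -2.0, 0.5], (8, 8, 8, 1))
    fld = DisplacementField(u, (1.2, 1.2, 1.0), (0, 0, 0))
    pts = np.array([[3.3, 4.1, 2.7], [1.0, 1.0, 1.0]])
    np.testing.assert_allclose(
        sample_displacement(fld, pts), [[1, -2, 0.5], [1, -2, 0.5]], atol=1e-12
    )


def test_affine_field_reproduced_exactly_by_trilinear():
    idx = np.stack(np.meshgrid(*[np.arange(8)] * 3, indexing="ij"), axis=-1).astype(float)
    A = np.array([[0.1, 0.02, 0], [0, -0.05, 0.01], [0.03, 0, 0.07]])
    u = idx @ A.T
    fld = DisplacementField(u, (1, 1, 1), (0, 0, 0))
    pts = np.array([[2.5, 3.25, 4.75], [1.1, 5.9, 2.2]])
    np.testing.assert_allclose(sample_displacement(fld, pts), pts @ A.T, atol=1e-12)


def test_point_outside_extent_rejected():
    fld = DisplacementField(np.zeros((8, 8, 8, 3)), (1, 1, 1), (0, 0, 0))
    with pytest.raises(ValueError, match="outside"):
        sample_displacement(fld, np.array([[20.0, 0.0, 0.0]]))


# -- local frames ------------------------------------------------------------

def test_plane_fit_recovers_exact_normal():
    rng = np.random.default_rng(0)
    pts = np.zeros((50, 3))
    pts[:, :2] = rng.uniform(-5, 5, (50, 2))
    frame = fit_local_frame(pts, np.zeros(3), k=20, orientation_hint=[0, 0, 1])
    np.testing.assert_allclose(frame.n, [0, 0, 1], atol=1e-12)


def test_sphere_patch_normal_within_one_degree():
    pts = _sphere_cloud()
    q = pts[123]
    frame = fit_local_frame(pts, q, k=24, orientation_hint=q)
    ang = np.degrees(np.arccos(np.clip(np.dot(frame.n, q / np.linalg.norm(q)), -1, 1)))
    assert ang < 1.0


def test_collinear_neighborhood_rejected():
    pts = np.stack([np.linspace(0, 9, 10), np.zeros(10), np.zeros(10)], axis=1)
    with pytest.raises(ValueError, match="collinear|rank"):
        fit_local_frame(pts, pts[0], k=10)


def test_frame_must_be_orthonormal():
    with pytest.raises(ValueError, match="orthonormal"):
        WallFrame(np.array([1.0, 0, 0]), np.array([1.0, 0.1, 0]), np.array([0, 0, 1.0]))


# -- displacement decomposition ---------------------------------------------

def test_decompose_normal_vector():
    frame = WallFrame(np.eye(3)[0], np.eye(3)[1], np.eye(3)[2])
    u_n, u_t = decompose_displacement(np.array([0.0, 0.0, 2.0]), frame, sign=+1.0)
    assert u_n == 2.0
    np.testing.assert_allclose(u_t, 0.0, atol=1e-15)


def test_decompose_tangential_vector_has_zero_normal_part():
    frame = WallFrame(np.eye(3)[0], np.eye(3)[1], np.eye(3)[2])
    u_n, u_t = decompose_displacement(np.array([3.0, -1.0, 0.0]), frame)
    assert u_n == 0.0
    np.testing.assert_allclose(u_t, [3.0, -1.0, 0.0])


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(-10, 10), min_size=3, max_size=3))
def test_decomposition_preserves_norm(u):
    u = np.array(u)
    frame = WallFrame(np.eye(3)[0], np.eye(3)[1], np.eye(3)[2])
    u_n, u_t = decompose_displacement(u, frame)
    np.testing.assert_allclose(
        u_n**2 + (u_t**2).sum(), (u**2).sum(), atol=1e-12
    )


# -- curvature ---------------------------------------------------------------

def test_dense_sphere_radius_within_one_percent():
    pts = _sphere_cloud(25.0)
    q = pts[200]
    frame = fit_local_frame(pts, q, k=24, orientation_hint=q)
    r, diag = estimate_radius(pts, q, frame)
    assert abs(r / 25.0 - 1.0) < 0.01
    assert diag["flag"] == 0


def test_sphere_with_gross_outliers_rejected_by_consensus():
    rng = np.random.default_rng(3)
    pts = _sphere_cloud(25.0)
    sel = rng.random(len(pts)) < 0.2
    radial = pts / np.linalg.norm(pts, axis=1, keepdims=True)
    pts_out = pts + sel[:, None] * rng.choice([-5.0, 5.0], (len(pts), 1)) * radial
    q = pts[200]
    frame = fit_local_frame(pts_out, q, k=24, orientation_hint=q)
    r, diag = estimate_radius(pts_out, q, frame, rng=rng)
    assert abs(r / 25.0 - 1.0) < 0.02
    assert diag["inlier_count"] >= 0.7 * diag["n_neighbors"]


def test_plane_clamps_to_near_flat_cap():
    rng = np.random.default_rng(4)
    pts = np.zeros((400, 3))
    pts[:, :2] = rng.uniform(-20, 20, (400, 2))
    frame = fit_local_frame(pts, np.zeros(3), k=24, orientation_hint=[0, 0, 1])
    r, diag = estimate_radius(pts, np.zeros(3), frame)
    assert r >= 299.0
    assert diag["flag"] == 2  # near-flat


# -- strain ------------------------------------------------------------------

@pytest.mark.parametrize(
    "u_n, r, expected",
    [(1.0, 25.0, 0.04), (0.0, 25.0, 0.0), (-0.5, 25.0, -0.02)],
)
def test_strain_is_signed_ratio(u_n, r, expected):
    assert circumferential_strain(u_n, r) == pytest.approx(expected)
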