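"""Registration: primitives, descent, and recovery of known motions."""

import numpy as np
import pytest

from rsii import (
    DisplacementField,
    ImageVolume,
    RegistrationParams,
    generate_frame_pair,
    normalize_intensities,
    preset,
    register_tv,
    registration_energy,
    warp,
)
from rsii.registration import tv_norm


def _small_pair(**overrides):
    spec = preset(
        "fusiform",
        length=46.0, r0=7.0, r_max=11.0, bulge_width=9.0,
        amplitude=1.2, amplitude_width=9.0, ilt_thickness=0.0,
        end_taper=6.0, spacing=(1.5, 1.5, 1.5), shape=(36, 36, 40),
        **overrides,
    )
    return spec, *generate_frame_pair(spec)


# -- intensity normalization -------------------------------------------------

def test_normalize_maps_window_to_unit_interval():
    img = ImageVolume(
        np.arange(101, dtype=float).reshape(101, 1, 1) * np.ones((1, 4, 4)),
        (1, 1, 1), (0, 0, 0),
    )
    out = normalize_intensities(img, 0.0, 100.0)
    assert out.data.min() == 0.0 and out.data.max() == 1.0


def test_normalize_constant_image_warns_and_zeros(caplog):
    img = ImageVolume(np.full((8, 8, 8), 7.0), (1, 1, 1), (0, 0, 0))
    with caplog.at_level("WARNING", logger="rsii"):
        out = normalize_intensities(img)
    assert np.all(out.data == 0.0)
    assert any("constant" in r.message for r in caplog.records)


def test_normalize_clips_outliers():
    data = np.zeros((10, 10, 10))
    data.flat[: 999] = np.linspace(0, 100, 999)
    data.flat[999] = 1e6
    img = ImageVolume(data, (1, 1, 1), (0, 0, 0))
    out = normalize_intensities(img, 1.0, 99.0)
    assert out.data.max() == 1.0
    assert (out.data == 1.0).sum() < 30  # the outlier was clipped, not dominant


# -- warping -----------------------------------------------------------------

def test_zero_field_warp_is_identity():
    rng = np.random.default_rng(0)
    img = ImageVolume(rng.normal(size=(12, 12, 12)), (1, 1, 1), (0, 0, 0))
    fld = DisplacementField(np.zeros((12, 12, 12, 3)), (1, 1, 1), (0, 0, 0))
    np.testing.assert_allclose(warp(img, fld).data, img.data, atol=1e-12)


def test_integer_shift_warp_is_exact_in_interior():
    rng = np.random.default_rng(1)
    img = ImageVolume(rng.normal(size=(12, 12, 12)), (1, 1, 1), (0, 0, 0))
    u = np.zeros((12, 12, 12, 3))
    u[..., 0] = 2.0
    fld = DisplacementField(u, (1, 1, 1), (0, 0, 0))
    out = warp(img, fld)
    np.testing.assert_allclose(out.data[:-2], img.data[2:], atol=1e-12)


def test_half_voxel_shift_on_ramp_is_linear():
    ramp = np.broadcast_to(
        np.arange(16, dtype=float)[:, None, None], (16, 16, 16)
    ).copy()
    img = ImageVolume(ramp, (1, 1, 1), (0, 0, 0))
    u = np.zeros((16, 16, 16, 3))
    u[..., 0] = 0.5
    out = warp(img, DisplacementField(u, (1, 1, 1), (0, 0, 0)))
    np.testing.assert_allclose(out.data[2:-2], ramp[2:-2] + 0.5, atol=1e-12)


# -- energy ------------------------------------------------------------------

def test_energy_zero_for_identical_images_and_zero_field():
    rng = np.random.default_rng(2)
    img = ImageVolume(rng.normal(size=(10, 10, 10)), (1, 1, 1), (0, 0, 0))
    fld = DisplacementField(np.zeros((10, 10, 10, 3)), (1, 1, 1), (0, 0, 0))
    assert registration_energy(img, img, fld, 0.5) == 0.0


def test_tv_of_constant_field_is_zero():
    assert tv_norm(np.full((6, 6, 6, 3), 3.2), np.array([1.0, 1.2, 0.8])) == 0.0


# -- solver behaviour --------------------------------------------------------

def test_identity_registration_returns_null_field():
    _, dia, sys_, _, _ = _small_pair()
    fld = register_tv(
        sys_, sys_, RegistrationParams(iterations=(20, 15, 10))
    )
    assert np.abs(fld.data).max() < 0.05 * 1.5  # < 0.05 voxel


def test_energy_never_increases_within_levels():
    _, dia, sys_, _, _ = _small_pair()
    log: list = []
    register_tv(sys_, dia, RegistrationParams(iterations=(30, 20, 15)), energy_log=log)
    assert log, "no levels recorded"
    for level in log:
        diffs = np.diff(level)
        assert np.all(diffs <= 1e-9 * np.abs(level[0]))


def test_final_energy_not_above_initial():
    _, dia, sys_, _, _ = _small_pair()
    params = RegistrationParams(iterations=(30, 20, 15))
    fld = register_tv(sys_, dia, params)
    f_n = normalize_intensities(sys_)
    m_n = normalize_intensities(dia)
    zero = DisplacementField(
        np.zeros(fld.data.shape), fld.spacing, fld.origin, fld.direction
    )
    e0 = registration_energy(f_n, m_n, zero, params.lambda_tv)
    e1 = registration_energy(f_n, m_n, fld, params.lambda_tv)
    assert e1 <= e0


def test_translation_recovered_within_fifth_of_voxel():
    spec, dia, sys_, lab, _ = _small_pair()
    shift = np.array([2.0, 1.0, 0.0]) * spec.spacing[0]
    moving = ImageVolume(sys_.data, sys_.spacing, sys_.origin - shift)
    fld = register_tv(sys_, moving)
    fg = sys_.data > 50
    err = np.abs(fld.data[fg].mean(axis=0) + shift)  # recovered u = -shift
    assert err.max() < 0.2 * spec.spacing[0]


def test_tv_decreases_with_stronger_regularization():
    _, dia, sys_, _, _ = _small_pair()
    tvs = []
    for lam in (0.002, 0.02, 0.2):
        fld = register_tv(
            sys_, dia, RegistrationParams(lambda_tv=lam, iterations=(40, 25, 15))
        )
        tvs.append(tv_norm(fld.data, fld.spacing))
    assert tvs[0] >= tvs[1] >= tvs[2]


def test_non_overlapping_extents_rejected():
    img = ImageVolume(np.zeros((8, 8, 8)), (1, 1, 1), (0, 0, 0))
    far = ImageVolume(np.zeros((8, 8, 8)), (1, 1, 1), (100, 100, 100))
    with pytest.raises(ValueError, match="overlap"):
        register_tv(img, far)
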