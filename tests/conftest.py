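"""Shared fixtures: small synthetic inputs and cached expensive stages."""

from __future__ import annotations

import numpy as np
import pytest

from rsii import (
    KinematicsParams,
    LabelMap,
    PipelineConfig,
    preset,
    run_pipeline,
)


def grid_center(spec) -> np.ndarray:
    return (np.array(spec.shape) - 1) * np.array(spec.spacing) / 2.0


@pytest.fixture(scope="session")
def sphere_labels() -> LabelMap:
    """Voxelized spherical shell: outer radius 25 mm, wall 1.5 mm, 1 mm voxels."""
    spacing = np.array([1.0, 1.0, 1.0])
    shape = (60, 60, 60)
    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
    ) * spacing
    c = (np.array(shape) - 1) * spacing / 2.0
    r = np.linalg.norm(idx - c, axis=-1)
    lab = np.zeros(shape, np.int16)
    lab[r <= 25.0] = 3
    lab[r <= 23.5] = 1
    return LabelMap(lab, spacing, np.zeros(3))


@pytest.fixture(scope="session")
def fusiform_pair():
    """Noise-free fusiform phantom frame pair with ground truth (seed 1)."""
    from rsii import generate_frame_pair

    spec = preset("fusiform", seed=1)
    dia, sys_, labels, truth = generate_frame_pair(spec)
    return spec, dia, sys_, labels, truth


@pytest.fixture(scope="session")
def fusiform_registered(fusiform_pair):
    """Registration of the fusiform pair (shared: this is the slow stage)."""
    from rsii import register_tv

    spec, dia, sys_, labels, truth = fusiform_pair
    fld = register_tv(sys_, dia)
    return spec, labels, truth, fld


@pytest.fixture(scope="session")
def cylinder_pipeline(tmp_path_factory):
    """Full pipeline run on the cylinder phantom (shared across tests)."""
    out = tmp_path_factory.mktemp("cyl")
    cfg = PipelineConfig(phantom="cylinder", seed=1, output_dir=str(out))
    return preset("cylinder"), run_pipeline(cfg)
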