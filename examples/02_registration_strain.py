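"""Recover wall strain from a synthetic systole/diastole image pair.

Registers the diastolic frame onto the systolic one with the TV-regularized
solver, extracts the wall mid-surface from the label map, and evaluates the
circumferential strain u_n / R on it.  The printed median error compares
the image-based estimate with the phantom's analytic strain.
"""

import numpy as np

from rsii import (
    KinematicsParams,
    compute_wall_strain,
    generate_frame_pair,
    preset,
    register_tv,
)

spec = preset("fusiform", seed=1)
dia, sys_, labels, truth = generate_frame_pair(spec)

print("registering diastole -> systole ...")
fld = register_tv(sys_, dia)
print(f"displacement field on the systolic grid: {fld.data.shape[:3]}, "
      f"max |u| = {np.abs(fld.data).max():.2f} mm")

mesh = compute_wall_strain(labels, fld, thickness=1.5, params=KinematicsParams(seed=1))
eps = mesh.point_data["circ_strain"]

c = (np.array(spec.shape) - 1) * np.array(spec.spacing) / 2.0
z = mesh.vertices[:, 2] - c[2]
d = mesh.vertices - c
ok = (np.abs(z) < 35) & (mesh.point_data["strain_flag"] == 0)
eps_true = spec.total_amplitude(z, np.arctan2(d[:, 1], d[:, 0])) / spec.outer_radius(z)

print(f"wall surface: {mesh.n_vertices} vertices ({int(ok.sum())} evaluated)")
print(f"99th-pct measured strain: {np.percentile(eps[ok], 99):.4f} "
      f"(true peak {eps_true.max():.4f})")
print(f"median |error|: {np.median(np.abs(eps - eps_true)[ok]):.4f} "
      f"= {np.median(np.abs(eps - eps_true)[ok]) / eps_true.max():.1%} of the peak")
# A median error of a few percent of the peak strain means the registration
# tracks the ~1 mm wall motion to a small fraction of a voxel.
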