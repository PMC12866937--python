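"""Check the tension solvers against pressure-vessel closed forms.

A thin sphere of radius R at pressure p carries t = pR/2 in every
direction; a cylinder carries hoop pR and axial pR/2; a thick sphere obeys
the Lame solution.  The membrane backend is solved directly on the surface;
the shell3d backend extrudes the wall and integrates the 3D stress through
the thickness.  Neither result depends on the stiffness used internally —
that is the property that lets the method skip patient material data.
"""

import numpy as np
import trimesh

from rsii import (
    SurfaceMesh,
    TensionConfig,
    build_shell_mesh,
    integrate_tension,
    solve_membrane,
    solve_shell3d,
)

P = 0.013  # 13 kPa in N/mm^2

tm = trimesh.creation.icosphere(subdivisions=4, radius=25.0)
sphere = SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
fld = solve_membrane(sphere, TensionConfig())
print(f"sphere R=25 mm, p=13 kPa: t = {fld.t_max.mean():.4f} N/mm "
      f"(Laplace pR/2 = {P * 12.5:.4f})")

fld10 = solve_membrane(sphere, TensionConfig(membrane_modulus_mpa=100.0))
print(f"with 10x stiffer wall:    t = {fld10.t_max.mean():.4f} N/mm "
      f"(rel change {abs(fld10.t_max.mean()/fld.t_max.mean()-1):.2e})")

# thick-walled sphere: shell3d vs the exact Lame tension integral
tm = trimesh.creation.icosphere(subdivisions=3, radius=24.25)
mid = SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
vm = build_shell_mesh(mid, 1.5, layers=3)
sigma = solve_shell3d(vm, TensionConfig(backend="shell3d"))
shell = integrate_tension(sigma, vm, mid, 1.5)
a, b = 23.5, 25.0
lame = P * a**3 / (2 * (b**3 - a**3)) * (1.5 * b + b**3 / (2 * a**2) - 2 * a)
print(f"thick sphere a=23.5, b=25: integrated tension {shell.t_max.mean():.4f} N/mm "
      f"(exact Lame integral {lame:.4f})")
# The shell carries slightly less tension than pR_mid/2 because the pressure
# acts on its inner face; the exact Lame integral reflects that.
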