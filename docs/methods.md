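# Methods

This note documents the models, numerical choices and limitations behind
`rsii`. Units are mm–N–MPa internally; pressures are accepted in kPa
(13 kPa = 0.013 N/mm²).

## Problem and pipeline

Given a diastolic and a systolic 3D frame of the same vessel, a label map
(background / lumen / intraluminal thrombus / wall) on the diastolic
frame, a blood pressure `p` (default 13 kPa) and an assumed wall thickness
`h` (default 1.5 mm), the pipeline computes per-vertex maps on the wall
mid-surface:

1. **Registration** estimates the dense displacement field `u` between the
   systolic (fixed) and diastolic (moving) frames.
2. **Kinematics** extracts the wall mid-surface, carries it to its
   systolic position, and computes the circumferential strain
   `ε = u_n / R`.
3. **Tension** recovers the stress resultant `t` (N/mm) that balances `p`
   on the deformed surface.
4. **Integrity** forms `SII = ε / t` and `RSII = SII / mean|SII|` with an
   exclusion mask and 99th-percentile summaries.

The three headline invariances are structural, not empirical: `t` is
independent of the elastic modulus because the recovery problem is linear
and (nearly) statically determinate; `t` is independent of `h` because it
is a through-thickness resultant; `RSII` is independent of the pressure
magnitude because `p` scales `t` and `1/SII` identically.

## Registration

Objective: `E(u) = Σ ½ (M(x+u) − F(x))² + λ · TV_iso(u)` on intensities
windowed to the [1, 99] percentile range and mapped to [0, 1]. `TV_iso` is
the isotropic vectorial total variation (Frobenius norm of the
forward-difference Jacobian, spacing-aware, Neumann boundaries); SSD is
appropriate because both frames come from one acquisition.

Solver: a monotone proximal-gradient scheme on a 3-level pyramid (factor
2, Gaussian anti-aliasing; fields upsampled trilinearly). Each outer
iteration applies:

- a Gauss–Newton (demons-style) data step
  `d = −res·∇I/(|∇I|² + η)` with symmetric (fixed + warped-moving)
  gradients and damping `η = 0.1·mean|∇I|²`;
- Gaussian "fluid" smoothing of the force (σ = 2 voxels at coarse levels,
  1 at the finest) plus a gradient-weighted **constant** step component:
  a constant field has zero TV, so the regularizer can never block bulk
  alignment;
- the isotropic-TV proximal map (Chambolle dual projection, 10 inner
  iterations) with weight `τλ`;
- a backtracking line search on `τ` that only accepts steps that do not
  increase `E`, so the recorded energy is non-increasing by construction.

`λ = 0.002` was frozen from a phantom sweep: wall-normal RMS error on the
fusiform phantom is ≈ 0.09 voxel at that value, degrading both for much
smaller λ (wiggly fields) and larger λ (contrast loss at the wall). The
solver is fully deterministic.

Displacement convention: with systole fixed and diastole moving, `u` maps
systolic positions to diastolic ones, so outward systolic expansion has
`u·n < 0`; the kinematics stage uses `u_n = −(u·n)` so that expansion (and
hence tensile strain) is positive. This sign convention is the only
reading consistent with predominantly tensile reported strains.

## Wall kinematics

**Surface.** Marching cubes on the tissue/background boundary of the label
map, largest connected component, 30 Taubin smoothing passes (volume drift
is checked against a 0.5 % guard), then an inward offset of `h/2` along
vertex normals gives the mid-surface.

**Sampling surface.** The displacement is interpolated on the *luminal*
face of the wall (mid-surface − `h/2`·normal). The blood/tissue boundary
carries the strongest image gradient, and registration is most accurate
along the gradient direction; sampling there measurably outperforms
mid-surface sampling on phantoms with a weak outer-wall contrast.

**Frames.** Per-vertex total-least-squares plane fits (k = 24 neighbors
within max(3.75 mm, 2.5 × mean edge)); the normal is the least-variance
direction, oriented along the mesh outward normal.

**Circumferential direction.** The vessel centerline is the locus of
lumen-centroid positions per 3 mm axial slab, Gaussian-smoothed; the
circumferential direction at a vertex is `axis × n`. This assumes the
vessel runs roughly along the image z axis (true for abdominal CTA and
for the phantoms).

**Curvature.** Per vertex, a quadric `z = a x² + b xy + c y² + d x + e y + f`
is fit to the ≤ 220 nearest surface points within 10 mm by a randomized
consensus loop (200 seeded iterations, minimal sets of 6). The inlier
threshold is `max(0.3 mm, 3 robust σ)` of a pilot least-squares fit, and
the pilot fit competes in the consensus, so on clean data the loop reduces
to least squares while gross outliers (e.g. segmentation spikes) are
rejected. The consensus inliers are then refit with a **quartic** whose
cubic/quartic terms carry a noise-adaptive ridge, `γ = (σ̂/sagitta)²·n`:
on smooth data the ridge vanishes and the quartic removes the wide-patch
truncation bias of the quadric (−4…−9 % on spheres at these patch sizes);
on bumpy voxelized surfaces it shrinks back toward the quadric.
Curvatures are median-filtered over the plane-fit neighborhoods (curvature
varies on cm scales; per-vertex fits are independent), and
`R = 1/|κ_circ|` is clamped to (2 mm, 300 mm], with near-flat and
low-consensus vertices flagged and excluded downstream.

**Strain reference.** `ε` is evaluated on the systolic surface with `R`
measured on that same surface; the difference from a diastolic reference
is O(ε²) and ignored.

## Tension recovery

**Membrane backend (default).** Constant-strain triangle membranes
assembled directly on the (deformed) wall surface; consistent nodal
pressure loads `p·A·n/3`; end rings pinned when the mesh is open, sparse
3-2-1 pin constraints (zero-reaction for the self-equilibrated load) when
it is closed. Faceted membranes have near-singular crumpling modes, so a
quadratic-bending stabilization `β·E·t·(L M⁻¹ L)` (cotangent Laplacian,
lumped masses) is added with `β = 0.01`, calibrated so the sphere-test
resultant shifts < 0.1 % while the stress field on marching-cubes surfaces
stays smooth. Element resultants `N = t·D·ε` are averaged to vertices
(area-weighted, rotated through a common frame) and diagonalized; the
scalar tension map is the maximum principal resultant `t_max`. The
membrane stiffness scale cancels exactly (verified to 1e-13), which is
the point: no patient material data enters.

**shell3d backend.** The volumetric construction for cross-validation:
the mid-surface is extruded ±h/2 along vertex normals into `layers`
wedge layers, each wedge split into 3 tetrahedra with a conforming
sorted-diagonal rule; linear isotropic elasticity (E = 100 GPa, ν = 0.49 —
the resultant is insensitive to both) with pressure on the inner sheet and
the same boundary handling. Element stresses are volume-averaged per
(vertex, layer) column, projected onto the tangent plane and summed
through the thickness. The Fung uniform-stress correction (through-
thickness averaging, `uniform_stress_correction`) leaves this integral
unchanged by construction.

**Loading surface.** Physically the blood pushes on the luminal face, and
that is the shell3d default; the thick-sphere result then matches the
exact Lamé integral `∫σ_θ dr = 0.1481 N/mm` (a = 23.5, b = 25, 13 kPa),
which is ~6 % below the membrane's `p·R_mid/2 = 0.1576` — a real O(h/R)
loading-surface effect, not an error. For backend-parity checks,
`load_surface="mid"` puts the shell's load on the mid-sheet; the two
backends then agree to < 0.1 %.

ILT handling: pressure is applied directly to the wall surface. The
thrombus is over an order of magnitude more compliant than the wall and
transmits the load essentially unattenuated; meshing patient-specific ILT
volumes is out of scope. This is the main fidelity gap when comparing
against volumetric models that pressurize the ILT's luminal surface.

## Integrity indices

`SII = ε / max(t, 10⁻³ N/mm)`; floored vertices are flagged and excluded.
The RSII numerator keeps the sign of SII (tensile vs. compressive); an
`abs_numerator` switch provides the all-positive reading, and an
area-weighted normalization is available (default unweighted, as the mean
over included vertices). Percentiles use the linear-interpolation rule so
printed summaries reproduce bit-for-bit. The exclusion mask removes
flagged vertices and everything within a geodesic distance (Dijkstra on
mesh edges) of the fixed end rings — boundary conditions there are
artificial. For the capped phantom tubes the pipeline default is 15 mm,
covering the caps plus the 10 mm zone where the phantom's inflation
tapers to zero (a static-end artifact of the same kind).

## The phantom generator

The phantom emulates a contrast-enhanced CTA of an idealized pulsating
vessel: outer-wall radius `r(z) = r0 + (Rmax−r0)·exp(−(z−z0)²/2s²)`, wall
thickness 1.5 mm, optional ILT layer scaled by the bulge profile, plateau
intensities 20/80/60/300 (background/wall/ILT/lumen) with ~1-voxel smooth
interfaces, partial-volume anti-aliasing by 3³ sub-voxel averaging, and
optional seeded additive Gaussian noise. Between frames the vessel
inflates radially by `A(z,θ) = a(z)·m(z,θ)`, where `a(z)` is a bulge-
centred Gaussian tapered to zero near the tube ends and `m ≥ 1` is a
Gaussian "soft patch" multiplier; the exact circumferential strain is
`A/r`. The systolic frame is the diastolic intensity *advected* by the
motion (evaluated at the pulled-back radius), so the analytic truth field
explains the image pair exactly up to voxel sampling; the truth field is
stored on the systolic grid pointing to diastolic positions, matching the
registration contract.

Default conditions: fusiform preset r0 = 11 mm, Rmax = 20 mm (a ~40 mm
aneurysm), amplitude 1.5 mm (peak strain 7.5 %, within the range reported
for AAAs), 1.25 mm isotropic voxels on 64×64×80 grids; cylinder preset
r = 25 mm with 1 mm uniform inflation (strain 4 %, hoop tension
0.325 N/mm at 13 kPa); soft-patch preset doubles the inflation inside a
(σ_z = 10 mm, σ_θ = 0.6 rad) window and adds noise with σ = 6 (2 % of the
lumen intensity). Problem sizes were chosen so a full pipeline run takes
tens of seconds.

What the phantom does *not* emulate: CT physics (beam hardening, motion
artifacts, anisotropic PSF), branch vessels, bent centerlines, axial wall
motion, and patient-specific ILT shapes. Passing the phantom suite
therefore demonstrates the correctness of the numerics and the method's
invariances — not clinical accuracy on patient data.

## Design choices made where the design was open

- The scalar "wall tension" map is the maximum principal resultant; the
  alternative invariants (trace/2, von-Mises-like) are recoverable from
  the stored tensor.
- The RSII numerator is signed (the Methods-style reading); the
  absolute-value reading is a config switch.
- The registration field's sign convention (expansion positive) is an
  interpretation; it is the only one consistent with tensile strains
  being reported positive.
- The consensus-loop constants (200 iterations, 0.3 mm threshold floor,
  0.5 minimum inlier fraction) follow common practice; the adaptive
  threshold and the pilot-fit candidate were added because a fixed 0.3 mm
  threshold over-trims honest points on voxelized surfaces and biases the
  curvature.

## Known limitations

- Strain uses only the normal displacement component; tangential motion
  is discarded as unreliable, so no full surface strain tensor is formed.
- The centerline heuristic assumes a roughly axial vessel; strongly bent
  or branching geometries would need an external centerline.
- Tension near flat caps and fixed ends is not meaningful (hence the
  exclusion zone), and the membrane model cannot represent bending-
  dominated regions.
- Registration accuracy degrades where the wall is thinner than about one
  voxel or the wall/background contrast is low; sub-voxel aliasing of
  sharp interfaces bounds the achievable accuracy at ~0.1 voxel.
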