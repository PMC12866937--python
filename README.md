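# rsii — structural-integrity mapping of the aneurysmal aortic wall

`rsii` assesses the structural integrity of an abdominal aortic aneurysm
(AAA) wall from a pair of 3D images taken at diastole and systole (e.g. two
frames of a time-resolved CT angiography) plus a blood-pressure value. It
is aimed at vascular-biomechanics researchers who want patient-specific
wall-compliance maps without patient-specific material data: every quantity
it computes is, by construction, independent of the wall's (unknowable)
stiffness and thickness, and the final map is independent of the accuracy
of the blood-pressure measurement as well.

## The method

Three quantities are computed on the wall mid-surface:

- **Wall tension** `t` (N/mm): the through-thickness resultant of the
  tangential stress that balances the blood pressure `p` on the *observed*
  (deformed) geometry. Because the geometry is known, this is a linear
  stress-recovery problem that is nearly statically determinate: the
  recovered resultant is insensitive to the elastic modulus (it cancels in
  the linear solve) and, being a resultant, integrates the assumed wall
  thickness out. Oracles: a sphere carries `t = pR/2`, a cylinder carries
  hoop `pR`, a thick sphere follows the Lamé solution.

- **Circumferential strain** `ε = u_n / R`: the wall displacement between
  diastole and systole comes from deformable image registration with
  isotropic total-variation regularization; only its component `u_n` along
  the outward surface normal is used (registration is most accurate along
  the image gradient, which at the wall is the normal), divided by the
  local radius of curvature `R` along the circumferential direction,
  estimated by local surface fitting with randomized outlier rejection.

- **Structural Integrity Index** `SII = ε / t` (mm/N), a local compliance
  proxy, and its relative form `RSII = SII / mean|SII|` over the wall
  surface. RSII is dimensionless, has `mean|RSII| = 1` by construction,
  and cancels the pressure magnitude, since `p` scales `t` and `1/SII`
  equally. High-RSII islands mark locally weakened (compliant) wall;
  low-RSII regions mark stiffening.

A synthetic-phantom generator (`rsii.phantom`) produces pulsating
contrast-CTA-like frame pairs of an idealized aneurysmal vessel with
analytically known displacement, strain, and (for straight segments)
tension, so every stage of the pipeline is testable without patient data.

## Worked example

Run the full pipeline on the "soft-patch" phantom — a bulged vessel whose
wall inflates twice as much inside a small patch, emulating a locally
weakened wall (`python examples/04_rsii_weak_spot.py`):

```
summary: t99 = 0.270 N/mm, eps99 = 0.1251, SII99 = 0.990 mm/N, RSII99 = 3.43
mean |SII| = 0.2889 mm/N over 5932/8552 included vertices
  patch: mean RSII +2.267 over 477 vertices
  rest : mean RSII +0.889 over 5455 vertices
  contrast (patch - rest): +1.378
```

The pipeline is never told where the patch is; it registers the two
frames, measures strain and tension, and the compliant patch appears as a
high-RSII island with more than twice the background level. The 99th
percentile summaries (`t99`, `eps99`, …) are the scalar outputs of a run;
the tension and strain magnitudes land in the physiological range for
aneurysmal aortas at 13 kPa.

The same machinery is scriptable from Python:

```python
from rsii import PipelineConfig, run_pipeline

cfg = PipelineConfig(phantom="soft-patch", seed=1, output_dir="out")
res = run_pipeline(cfg)          # writes wall_rsii.vtp + summary.json
print(res["summary"]["rsii99"])
```

or from the shell, stage by stage (`rsii phantom`, `rsii register`,
`rsii strain`, `rsii tension`, `rsii integrity`) or in one go
(`rsii run --preset soft-patch --seed 1 --out out`).

For patient-style data, pass NIfTI/MetaImage paths instead of a phantom
preset (`fixed_path` = systolic frame, `moving_path` = diastolic frame,
`labels_path` = background/lumen/ILT/wall label map).

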