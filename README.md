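# peritract

Patient-tailored longitudinal analysis of white-matter circuitry around
traumatic cerebral microbleeds (CMBs), from diffusion and susceptibility
MRI.

Mild traumatic brain injury often leaves small hemorrhagic lesions —
microbleeds — visible as spherical hypointensities on susceptibility-weighted
imaging (SWI). Whether the white matter *around* such lesions degrades over
the months after injury is hard to establish: between-session differences in
diffusion-tensor tractography are confounded by scanner noise, motion, and
reconstruction error, and template-based voxel statistics cannot separate
true change from local misregistration. `peritract` addresses this
within-subject instead: it detects CMBs and dates their etiology from paired
acute/chronic FLAIR, matches each subject's own tractography streamlines
across sessions, quantifies the spatial scale of measurement confounds, and
tests perilesional changes in mean fractional anisotropy (FA) against an
empirical reference distribution measured in rescanned healthy controls.

It is intended for neuroimaging researchers working on longitudinal
diffusion MRI — and ships a complete synthetic-phantom generator, so every
stage is testable and demonstrable without patient data.

## The core machinery

- **Tensor fit + deterministic tractography** — log-linear least-squares fit
  of `S = S0·exp(−b gᵀDg)`; fixed step-length propagation along the
  principal eigenvector (seed spacing 0.5 mm, Westin-CL start threshold 0.3,
  FA stop 0.17, lengths 20–110 mm).
- **Streamline matching** — streamlines as space curves with
  rigid-motion-invariant curvature κ = |r′×r″|/|r′|³ and torsion
  τ = (r′×r″)·r‴/|r′×r″|²; arc-length curve index correspondence; one-to-one
  assignment by mean-squared (Δκ, Δτ) feature distance; local and global
  rigid transforms from Schönemann's orthogonal-Procrustes solution.
- **CMB detection** — median-normalized SWI, robust hypointensity
  thresholding, isoperimetric sphericity `π^(1/3)(6V)^(2/3)/A`, MARS-style
  certain/doubtful labels, and the two-condition FLAIR rule (acute
  perilesional hyperintense ring that resolves by the chronic scan ⇒
  traumatic etiology).
- **Uncertainty ellipsoid** — per-voxel second moment `M = mean(d dᵀ)` of
  matched-point displacements between repeated control sessions; the
  *uncertainty radius* `2·√λ_max(M)` is the scale below which between-session
  differences should not be interpreted.
- **Along-tract inference** — pointwise FA statistics on the bundle's common
  arc-length domain; per-bundle ΔmeanFA tested as
  `z = (Δ − μ_ref)/σ_ref` against a control reference distribution, with
  Holm family-wise error correction within subject; per-subject fraction of
  CMBs with significant perilesional change; cohort ANCOVA
  (age group × diagnosis, sex covariate).

See `docs/methods.md` for the full model description, parameter defaults,
and limitations.

## Worked example

```python
import numpy as np
from peritract import cmbdetect, curvegeom, synthdata

# curvature/torsion of a helix with a = 3 mm, b = 4 mm
t = np.linspace(0, 4 * np.pi, 2000)
helix = curvegeom.Streamline(np.stack([3*np.cos(t), 3*np.sin(t), 4*t], axis=1))
inv = curvegeom.invariants(curvegeom.resample(helix, spacing=0.2))
print(f"helix kappa = {np.median(inv.kappa):.4f} 1/mm (analytic 0.1200)")
print(f"helix tau   = {np.nanmedian(inv.tau):.4f} 1/mm (analytic 0.1600)")

# detect a planted microbleed with a resolving FLAIR ring
scene = [synthdata.LesionSpec(centre_mm=(30, 30, 30), radius_mm=2.5,
                              acute_ring=True, chronic_ring=False)]
swi, flair_acute, flair_chronic, mask, _ = synthdata.make_lesion_volumes(
    scene, shape=(60, 60, 60), affine=np.eye(4), seed=7)
records = cmbdetect.detect_cmbs(swi, mask, np.eye(4),
                                flair_acute=flair_acute,
                                flair_chronic=flair_chronic)
cmb = records[0]
print(f"CMB at {np.round(cmb.centroid_world, 1)} mm, "
      f"volume {cmb.volume_mm3:.0f} mm3, sphericity {cmb.sphericity:.2f}, "
      f"{cmb.mars_label}/{cmb.etiology}")
```

prints

```
helix kappa = 0.1200 1/mm (analytic 0.1200)
helix tau   = 0.1600 1/mm (analytic 0.1600)
CMB at [30. 30. 30.] mm, volume 81 mm3, sphericity 0.98, certain/traumatic
```

The helix invariants match their closed forms (κ = a/(a²+b²),
τ = b/(a²+b²)), and the planted lesion is recovered at its true centroid,
graded *certain* (spherical, high contrast) with *traumatic* etiology
(acute ring present, chronic ring resolved).

A command-line interface mirrors the library
(`peritract simulate|detect|track|match|uncertainty|analyze|run-subject|run-cohort`);
`peritract run-cohort --seed 1 --out report.json` simulates and analyzes a
full synthetic cohort and reports each patient's fraction of CMBs with
significant perilesional FA change.

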