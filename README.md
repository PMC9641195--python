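# ventrivol

Cardiac chamber volumetry from 3D surface meshes and voxel masks, with the
paired agreement statistics used to compare volumetric measurement methods.

Clinical platforms estimate ventricular volumes with Simpson's rule: the
chamber is cut into parallel slices, the luminal area of each slice is
multiplied by the slice thickness, and the slice volumes are summed.  Mesh
based (VR-style) workflows instead export the segmented chamber surface as
an STL triangle mesh and compute the enclosed volume by polygon summation.
`ventrivol` implements both engines, generates synthetic ventricle phantoms
with known ground-truth volumes to validate them, and provides the full
statistical battery for paired method comparison (Lin's concordance
correlation coefficient, Bland–Altman analysis, MSE, paired *t*,
Shapiro–Wilk).  It is aimed at researchers evaluating mesh-based volumetry
pipelines against slice-summation references.

## The two volume computations

**Polygon (signed tetrahedron) summation.** Each surface triangle with
vertices *p*₁, *p*₂, *p*₃ forms a tetrahedron with the coordinate origin
whose signed volume is

&nbsp;&nbsp;&nbsp;&nbsp;*V*ᵢ = (1/6) (*p*ᵢ,₁ × *p*ᵢ,₂) · *p*ᵢ,₃

(equivalently ⅓·*a*·*h* with *a* the triangle area, signed by the vertex
winding: triangles whose normal points away from the origin count positive,
those pointing toward it negative).  Over a closed, consistently oriented
surface, *V* = Σᵢ *V*ᵢ is exactly the enclosed volume.  The package checks
watertightness and orientation consistency before trusting the result.

**Simpson's-rule slice summation.** For a binary voxel mask with spacing
(dx, dy, dz), the volume is Σ over slices of (voxel count · dx · dy) · dz —
the flat disk-area rule clinical platforms use, deliberately without
higher-order quadrature.

**Agreement statistics.** For paired measurements *x*, *y*, Lin's CCC is
ρ_c = 2s_xy / (s_x² + s_y² + (x̄ − ȳ)²) with a Fisher-z confidence
interval; Bland–Altman reports the mean difference and limits of agreement
d̄ ± 1.96·SD(d); MSE = (1/n)Σdᵢ²; the paired *t*-test and Shapiro–Wilk
complete the battery.

## Worked example

```python
import ventrivol as vv

# A bullet-shaped LV phantom: cylinder + hemispherical apex, r=20, L=80 mm,
# with a 2 mm trabeculated inner-blood-pool surface.
spec = vv.PhantomSpec("bullet_lv", {"radius": 20.0, "length": 80.0},
                      trabeculation_amplitude=2.0, seed=7)
pair = vv.make_phantom(spec)
print(pair.truth_volume_cm3)                              # 92.153...
print(vv.mesh_volume(pair.smooth_mesh).volume_cm3)        # 91.948...
print(vv.mesh_volume(pair.ibp_mesh).volume_cm3)           # 82.949...
print(vv.slice_stack_volume(pair.smooth_mask).volume_cm3) # 92.711...
```

The analytic bullet volume is π·r²·(L−r) + ⅔·π·r³ = 92.153 cm³; the
5040-face mesh recovers it to 0.2%, the 0.8 mm mask to 0.6%, and the
inward-perturbed inner-blood-pool surface is ~9 cm³ smaller, as intended.

The end-to-end study harness measures every phantom of a cohort with all
three methods — `pdp` (slice engine on the mask), `vrps` (mesh engine on the
smooth surface) and `vribp` (mesh engine on the inner blood pool) — and fits
the agreement battery per method pair:

```python
res = vv.VolumeStudy(vv.StudyConfig(n=20, seed=7, out_dir="study_out")).fit()
print(res.summary_text())
for key, rep in res.reports.items():
    print(key, f"CCC {rep.ccc:.4f}  mean diff {rep.mean_diff:.2f}  p {rep.p_value:.3g}")
```

```
Volumetric analysis by method (cm^3)
============================================================
[lv]  n = 20
  pdp      150.1 +/-  24.5   range 102.9-211.6
  vrps     148.9 +/-  26.4   range 104.2-211.8
  vribp    135.7 +/-  24.1   range 92.5-191.1
[rv]  n = 20
  pdp      173.3 +/-  23.6   range 135.8-221.7
  vrps     172.1 +/-  24.8   range 136.4-221.0
  vribp    153.1 +/-  23.9   range 117.8-198.8
lv_pdp_vs_vrps CCC 0.9623  mean diff 1.16  p 0.463
lv_vrps_vs_vribp CCC 0.8367  mean diff 13.20  p 1.96e-07
rv_pdp_vs_vrps CCC 0.9605  mean diff 1.16  p 0.448
rv_vrps_vs_vribp CCC 0.7108  mean diff 19.00  p 5.5e-09
```

Read: the slice and smooth-mesh measurements of the same phantoms agree
excellently (CCC ≈ 0.96, mean difference ~1 cm³, not significant), while the
inner-blood-pool volumes are systematically and significantly smaller —
the effect the study design is built to detect.

A CLI mirrors the library: `ventrivol volume mesh.stl`, `ventrivol slicevol
mask.nii.gz --axis z`, `ventrivol phantom --preset bullet-lv --n 20 --seed 7
--out dir/`, `ventrivol compare volumes.csv --a pdp --b vrps`, and
`ventrivol study --config study.yaml`.

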