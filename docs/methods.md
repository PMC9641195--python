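# Methods

## Volume from a closed surface mesh

The polygon-summation engine computes the enclosed volume of a triangle
mesh as the sum over faces of the signed volume of the tetrahedron spanned
by the triangle and the coordinate origin, V = (1/6) Σᵢ (pᵢ,₁ × pᵢ,₂) · pᵢ,₃.
The sign of each term comes solely from the vertex winding; stored STL
facet normals are never trusted, because files in the wild routinely carry
zero or inconsistent normals while the winding is what segmentation
exporters actually control.

The sum telescopes to the enclosed volume only for a *closed, consistently
oriented* surface, so the engine runs the topological diagnostics first
(every edge shared by exactly two faces; the two faces traverse each shared
edge in opposite directions) and, in the default strict mode, refuses
surfaces that fail them.  Lenient mode computes the origin-referenced sum
anyway and attaches the diagnostics; the number is then a property of the
surface *and* the origin, and interpreting it is the caller's
responsibility.

Numerical choices:

* For closed meshes the vertices are internally pre-translated to the
  bounding-box centre before summation.  For a closed surface the summed
  volume is exactly translation-invariant, so this is volume-neutral, but
  it removes the large (c·A)-sized terms that would otherwise cancel in
  floating point — relevant for meshes far from the origin.  Open meshes in
  lenient mode are *not* translated, preserving the origin-based sign
  convention.
* Per-face contributions are accumulated with numpy's pairwise summation,
  which keeps round-off growth logarithmic in the face count (10⁵-face
  meshes with millimetre coordinates are routine).
* Degenerate (zero-area) triangles contribute exactly 0 and are counted in
  the diagnostics rather than rejected.

Units: mesh coordinates are interpreted as millimetres; volumes are
reported in cm³ (with mm³ available on the result object).  Published
clinical comparisons of these methods mix mm³ and cm³ labels for the same
quantities; this package standardises every volume and volume difference
on cm³.

## Volume from a voxel mask

The slice engine reproduces the clinical Simpson's-rule procedure: the mask
is cut into slices along a designated long axis, each slice's area is the
voxel count times the in-plane pixel area, and the volume is the sum of
area × slice thickness.  This equals voxel count × voxel volume exactly, and
is therefore invariant under the choice of slicing axis — the axis matters
only for the per-slice diagnostics.  The rule is deliberately the flat
disk-area summation used by clinical platforms, not a higher-order
quadrature: the engine is a comparator that should reproduce the reference
platform's behaviour, not improve on it.

Masks use the half-open voxel convention (voxel (i,j,k) owns
[origin + i·dx, origin + (i+1)·dx) × …), and NIfTI interchange accepts only
axis-aligned affines, taking spacings from the diagonal.  Partial-volume
area estimation is out of scope.

## STL handling

Both STL dialects are supported; auto-detection treats a file as ASCII only
if it begins with a valid `solid` structure and decodes as ASCII, otherwise
as little-endian binary (binary files often begin with "solid" too).  The
80-byte binary header and 2-byte attribute words are ignored.  Parse errors
(truncated records, facet-count mismatch, non-numeric tokens) name the
offending byte or line.  On read, the triangle soup is merged into an
indexed mesh by exact bitwise vertex equality, with an optional epsilon
merge; exact merging is the default because volume computation does not
need shared topology — only the diagnostics do — and epsilon merging can
silently glue distinct features.  Vertex order after merging is the order
of first appearance in the facet stream, which makes re-reading a written
file idempotent.

## Synthetic phantoms

The generator emulates the two segmentation borders seen in practice: a
smoothed contour that includes trabeculae and papillary muscles in the
luminal volume, and an inner-blood-pool contour that excludes them and is
therefore strictly smaller.

* **bullet_lv** — cylinder (radius r) capped by a hemisphere at the apex
  and a flat disk at the base, total length L; the conventional LV bullet
  with closed-form volume π r²(L−r) + ⅔π r³.  Tessellated as a watertight
  surface of revolution (base fan, quad strips, apex fan).
* **ellipsoid** — subdivided-icosahedron sphere scaled to semi-axes
  (a, b, c); volume (4/3)π a b c.
* **crescent_rv** — an RV-like crescent: outer ellipsoid with an offset
  inner ellipsoid carved out of one side, defined implicitly as
  max(q_outer, −q_inner) ≤ 0 and tessellated watertight by marching cubes.
  No closed form exists, so ground truth comes from a voxel-centre-inside
  oracle at 0.25 mm grid pitch (an independent route from both engines'
  inputs at study resolution).

The inner-blood-pool surface applies a seeded, band-limited, strictly
inward radial perturbation: a sum of 24 random-direction plane-wave
cosines, min–max normalised to [0, 1] over the surface vertices, scaled by
the trabeculation amplitude (mm) and subtracted along the local inward
direction (radius for the revolved/star-shaped bodies, vertex normal for
the crescent).  Because the field is non-negative the expected volume
strictly decreases, and on the revolved bodies the perturbed surface stays
a graph over (θ, z), so it cannot self-intersect.  A spec-level bound
(amplitude < minimum local radius, conservatively half the smallest outer
semi-axis for the crescent) rejects amplitudes that could.  Amplitude and
spatial frequency (default 2 mm, 0.15 cycles/mm) are free parameters: no
quantitative description of trabecular geometry is available to calibrate
against, so they are documented as the knobs controlling the size of the
injected inner-blood-pool deficit, not as anatomy.

Cohort defaults are chosen for scale realism, not clinical fidelity: bullet
dimensions r ~ N(23.5, 2.5) mm, L ~ N(90, 8) mm give LV-like volumes
(~140 ± 35 cm³), and the crescent population gives RV-like volumes
(~170 ± 25 cm³), so cohort ranges bracket reported adult end-diastolic
ranges (LV ≈ 80–230 cm³, RV ≈ 80–255 cm³).  Per-method measurement error is
additive Gaussian noise (default SD 4 cm³ per method, bias 0), sized so the
SD of between-method differences (~5.7 cm³) matches the scale reported for
slice-vs-mesh LV comparisons.  Invalid dimension draws (non-positive, or
L ≤ r) are re-drawn with a 100-attempt bound.

What passing phantom tests does and does not show: the phantoms validate
the *engines* (convergence to known volumes, engine agreement, injected
effect recovery) and the *statistics* (calibration, effect detection).
They do not model real trabecular anatomy, papillary muscles as discrete
bodies, segmentation error from image contrast, outflow-tract contouring
policy, or inter-observer variability — conclusions about real hearts
require patient images.

## Agreement statistics

Lin's concordance correlation coefficient uses n-denominator moment
estimators, ρ_c = 2s_xy / (s_x² + s_y² + (x̄−ȳ)²), with the 95% CI from
the Fisher z-transform using Lin's large-sample variance, back-transformed.
At |ρ_c| = 1 the transform degenerates and the CI collapses onto the
estimate.  ρ_c factors as r·C_b with C_b ≤ 1, so it never exceeds Pearson's
r in magnitude, and it is invariant only under *joint* location–scale
changes of both vectors — both properties are tested.

Bland–Altman reports d̄, SD(d) (n−1 denominator) and limits of agreement
d̄ ± z·SD with z = 1.96 by default.  Published comparisons sometimes label
these limits a "95% CI" of the difference while printing mean ± 1.96·SD;
the output labels them limits of agreement and also carries the genuine
CI of the mean difference from the t distribution.

MSE defaults to the n-denominator mean of squared paired differences,
(1/n)Σdᵢ² = d̄² + s²(n−1)/n; the n−1 variant is exposed as
`mse_unbiased` because published values do not always state which
denominator was used, and the two differ by s²/n.

The paired t-test is two-tailed with df = n−1; `t_from_confidence_interval`
inverts a published mean difference and CI back to the t statistic
(SE = CI half-width / t_crit), which is how printed results arithmetic is
checked without patient data.  Degenerate inputs are errors, not silent
zeros: both-constant vectors for the CCC, zero-variance differences with
non-zero mean for the t-test, constant vectors for Shapiro–Wilk; the one
benign degenerate case (all differences exactly zero) returns t = 0 with a
warning.  Shapiro–Wilk delegates to scipy for 3 ≤ n ≤ 5000.

## Study harness

`run_study` measures every subject with the three methods — slice engine on
the mask ("pdp"), mesh engine on the smooth surface ("vrps"), mesh engine
on the inner blood pool ("vribp") — then fits the agreement battery for
each configured pair within each stratum (LV-like bullets, RV-like
crescents).  Default problem sizes are 20 subjects per stratum, 5000-face
meshes and 0.8 mm masks, at which the engine discretisation error (≲1%) is
small against both the population spread and the method noise.  All CSV and
JSON outputs are byte-reproducible from the seed; the run log additionally
records wall-clock timings and is the one non-reproducible file.  In
directory mode, per-subject failures (unreadable or missing files) are
logged, recorded as missing values, and reflected in exit status 2 while
the rest of the study completes.

## Known limitations

* Lenient-mode volumes of open surfaces are origin-dependent by
  construction; the package reports them only alongside diagnostics.
* The crescent's inner-blood-pool perturbation displaces along vertex
  normals without a global self-intersection proof; the conservative
  amplitude bound plus the volume-decrease check guard the cases the
  generator produces.
* Marching-cubes face counts track the requested mesh resolution only
  approximately (grid pitch is derived from a surface-area estimate).
* The slice engine assumes the mask's slicing axis is one of the grid axes;
  oblique reformats are out of scope.
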