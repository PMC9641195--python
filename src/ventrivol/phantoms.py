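"""Synthetic ventricle phantoms with known ground-truth volumes.

Real chamber segmentations come in two flavours: a smoothed contour that
includes the trabeculae and papillary muscles in the luminal volume
(producing a clean surface, as clinical platforms draw it), and an
inner-blood-pool contour that excludes them (producing a rougher surface
with a strictly smaller volume).  The generator emulates both:

* ``bullet_lv`` — the conventional left-ventricle bullet: a cylinder of
  radius ``r`` capped by a hemisphere at the apex and a flat disk at the
  base, total length ``L``; closed-form volume ``pi r^2 (L - r) +
  (2/3) pi r^3``.
* ``ellipsoid`` — a general ellipsoid with semi-axes ``a, b, c``;
  closed-form volume ``(4/3) pi a b c``.
* ``crescent_rv`` — a right-ventricle-like crescent: an outer ellipsoid
  with an offset inner ellipsoid carved out of one side, tessellated
  watertight from the implicit function by marching cubes.  No clean closed
  form exists, so the ground truth comes from a fine-grid voxel-centre
  oracle (0.25 mm).

Each phantom yields a matched pair of surfaces — the smooth reference mesh
and an "inner blood pool" mesh obtained by a seeded, band-limited, strictly
inward radial perturbation (so its volume is always smaller) — plus the
voxel-centre-inside binary mask of the smooth surface for the slice engine.

All dimensions in mm, volumes in cm^3.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .engines import MM3_PER_CM3, VoxelMask, mesh_volume, slice_stack_volume
from .mesh import TriangleMesh, write_stl

__all__ = [
    "PhantomSpec",
    "PhantomPair",
    "PopulationSpec",
    "make_phantom",
    "make_cohort",
    "export_phantom",
    "icosphere",
    "lv_population",
    "rv_population",
    "COHORT_COLUMNS",
]

logger = logging.getLogger(__name__)

SHAPES = ("bullet_lv", "ellipsoid", "crescent_rv")
COHORT_COLUMNS = ["subject_id", "shape", "truth_cm3", "pdp_cm3", "vrps_cm3", "vribp_cm3"]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Parametric description of one synthetic ventricle.

    Parameters
    ----------
    shape : {"bullet_lv", "ellipsoid", "crescent_rv"}
    dimensions : dict
        bullet_lv: ``radius``, ``length`` (L > r).
        ellipsoid: ``a``, ``b``, ``c`` semi-axes.
        crescent_rv: ``outer_a/b/c``, ``inner_a/b/c``, ``inner_offset``
        (displacement of the carved inner ellipsoid along +x).
    trabeculation_amplitude : float
        Peak inward surface displacement in mm applied to the
        inner-blood-pool surface; 0 disables it (IBP == smooth).
    trabeculation_frequency : float
        Spatial frequency of the perturbation field in cycles/mm.
    seed : int
        Seeds the perturbation field.
    mesh_resolution : int
        Target face count of the smooth mesh.
    voxel_spacing : float
        Isotropic voxel size of the generated mask in mm.
    truth_spacing : float
        Grid pitch of the voxel-centre oracle used when no closed form
        exists (crescent); must be <= 0.25 mm.
    """

    shape: str
    dimensions: dict
    trabeculation_amplitude: float = 0.0
    trabeculation_frequency: float = 0.15
    seed: int = 0
    mesh_resolution: int = 5000
    voxel_spacing: float = 0.8
    truth_spacing: float = 0.25

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; expected one of {SHAPES}")
        dims = {k: float(v) for k, v in self.dimensions.items()}
        if any(v <= 0 for v in dims.values()):
            raise ValueError(f"all dimensions must be strictly positive, got {dims}")
        if self.shape == "bullet_lv":
            if set(dims) != {"radius", "length"}:
                raise ValueError("bullet_lv needs dimensions {'radius', 'length'}")
            if dims["length"] <= dims["radius"]:
                raise ValueError("bullet_lv requires length > radius")
        elif self.shape == "ellipsoid":
            if set(dims) != {"a", "b", "c"}:
                raise ValueError("ellipsoid needs dimensions {'a', 'b', 'c'}")
        else:
            need = {"outer_a", "outer_b", "outer_c", "inner_a", "inner_b", "inner_c", "inner_offset"}
            if set(dims) != need:
                raise ValueError(f"crescent_rv needs dimensions {sorted(need)}")
        self.dimensions = dims
        if self.trabeculation_amplitude < 0:
            raise ValueError("trabeculation amplitude must be >= 0")
        amp_bound = self.min_local_radius()
        if self.trabeculation_amplitude >= amp_bound:
            raise ValueError(
                f"trabeculation amplitude {self.trabeculation_amplitude} mm would "
                f"self-intersect the surface: it must stay below the minimum local "
                f"radius {amp_bound:.2f} mm for shape {self.shape!r}"
            )
        if self.truth_spacing > 0.25:
            raise ValueError("truth_spacing must be <= 0.25 mm")
        if self.voxel_spacing <= 0 or self.mesh_resolution < 100:
            raise ValueError("voxel_spacing must be > 0 and mesh_resolution >= 100")

    def min_local_radius(self) -> float:
        """Lower bound on the local radius, limiting safe inward perturbation."""
        d = self.dimensions
        if self.shape == "bullet_lv":
            return d["radius"]
        if self.shape == "ellipsoid":
            return min(d["a"], d["b"], d["c"])
        # crescent: conservative wall-thickness proxy
        return 0.5 * min(d["outer_a"], d["outer_b"], d["outer_c"])

    def analytic_volume_cm3(self) -> Optional[float]:
        d = self.dimensions
        if self.shape == "bullet_lv":
            r, L = d["radius"], d["length"]
            return (np.pi * r * r * (L - r) + (2.0 / 3.0) * np.pi * r**3) / MM3_PER_CM3
        if self.shape == "ellipsoid":
            return (4.0 / 3.0) * np.pi * d["a"] * d["b"] * d["c"] / MM3_PER_CM3
        return None

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PhantomPair:
    """A phantom's matched artefacts: smooth and inner-blood-pool surface
    meshes, the smooth-surface voxel mask, and the ground-truth volume."""

    spec: PhantomSpec
    smooth_mesh: TriangleMesh
    ibp_mesh: TriangleMesh
    smooth_mask: VoxelMask
    truth_volume_cm3: float


# ---------------------------------------------------------------------------
# primitive surfaces
# ---------------------------------------------------------------------------

_ICO_T = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array(
    [
        (-1, _ICO_T, 0), (1, _ICO_T, 0), (-1, -_ICO_T, 0), (1, -_ICO_T, 0),
        (0, -1, _ICO_T), (0, 1, _ICO_T), (0, -1, -_ICO_T), (0, 1, -_ICO_T),
        (_ICO_T, 0, -1), (_ICO_T, 0, 1), (-_ICO_T, 0, -1), (-_ICO_T, 0, 1),
    ],
    dtype=float,
)
_ICO_FACES = np.array(
    [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ],
    dtype=np.int64,
)


def icosphere(radius: float = 1.0, subdivisions: int = 3, semiaxes=None) -> TriangleMesh:
    """Subdivided-icosahedron sphere (or ellipsoid via ``semiaxes``).

    ``subdivisions`` quadruples the face count each level: 20 * 4^k faces
    (k = 3 gives 1280).  Outward winding.
    """
    verts = _ICO_VERTS / np.linalg.norm(_ICO_VERTS[0])
    faces = _ICO_FACES.copy()
    for _ in range(subdivisions):
        verts, faces = _subdivide(verts, faces)
        verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    scale = np.asarray(semiaxes, float) if semiaxes is not None else radius
    return TriangleMesh(verts * scale, faces, name="icosphere")


def _subdivide(verts: np.ndarray, faces: np.ndarray):
    cache: dict = {}
    new_verts = [v for v in verts]

    def midpoint(i, j):
        key = (i, j) if i < j else (j, i)
        if key not in cache:
            cache[key] = len(new_verts)
            new_verts.append((verts[i] + verts[j]) / 2.0)
        return cache[key]

    out = np.empty((len(faces) * 4, 3), dtype=np.int64)
    for k, (a, b, c) in enumerate(faces):
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        out[4 * k : 4 * k + 4] = [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
    return np.array(new_verts), out


def _bullet_profile(r: float, L: float, z: np.ndarray) -> np.ndarray:
    """Radius of the bullet surface of revolution at heights z in [0, L]."""
    rho = np.full_like(z, r, dtype=float)
    cap = z > (L - r)
    rho[cap] = np.sqrt(np.maximum(r * r - (z[cap] - (L - r)) ** 2, 0.0))
    return rho


def _bullet_mesh(r, L, target_faces, radial_scale: Optional[Callable] = None) -> TriangleMesh:
    """Watertight surface-of-revolution bullet: flat base disk at z=0,
    cylinder barrel, hemispherical apex cap ending in a single apex vertex.

    ``radial_scale(points) -> per-vertex inward radial offset`` implements
    the trabeculation field; it receives ring vertex positions and returns
    the perturbed radius.
    """
    n_theta = max(16, int(round(np.sqrt(target_faces * np.pi * r / L))))
    m = max(8, int(round(target_faces / (2.0 * n_theta))))
    cyl_len, cap_len = L - r, np.pi * r / 2.0
    m_cyl = max(2, int(round(m * cyl_len / (cyl_len + cap_len))))
    m_cap = max(3, m - m_cyl)
    z_cyl = np.linspace(0.0, L - r, m_cyl + 1)
    phi = np.linspace(0.0, np.pi / 2.0, m_cap + 1)[1:-1]  # exclude equator & pole
    z_cap = (L - r) + r * np.sin(phi)
    z_rings = np.concatenate([z_cyl, z_cap])
    rho_rings = _bullet_profile(r, L, z_rings)

    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    n_rings = len(z_rings)
    ring_xyz = np.empty((n_rings, n_theta, 3))
    ring_xyz[:, :, 0] = rho_rings[:, None] * cos_t
    ring_xyz[:, :, 1] = rho_rings[:, None] * sin_t
    ring_xyz[:, :, 2] = z_rings[:, None]
    if radial_scale is not None:
        pts = ring_xyz.reshape(-1, 3)
        new_rho = radial_scale(pts, np.repeat(rho_rings, n_theta))
        frac = np.where(np.repeat(rho_rings, n_theta) > 0, new_rho / np.maximum(np.repeat(rho_rings, n_theta), 1e-12), 1.0)
        pts = pts.copy()
        pts[:, 0] *= frac
        pts[:, 1] *= frac
        ring_xyz = pts.reshape(n_rings, n_theta, 3)

    verts = [ring_xyz.reshape(-1, 3)]
    base_center_idx = n_rings * n_theta
    apex_idx = base_center_idx + 1
    verts.append(np.array([[0.0, 0.0, 0.0], [0.0, 0.0, L]]))
    vertices = np.vstack(verts)

    faces = []
    idx = lambda k, j: k * n_theta + (j % n_theta)  # noqa: E731
    for j in range(n_theta):  # base disk, outward normal -z
        faces.append((base_center_idx, idx(0, j + 1), idx(0, j)))
    for k in range(n_rings - 1):  # lateral bands, outward normals
        for j in range(n_theta):
            faces.append((idx(k, j), idx(k, j + 1), idx(k + 1, j + 1)))
            faces.append((idx(k, j), idx(k + 1, j + 1), idx(k + 1, j)))
    for j in range(n_theta):  # apex fan
        faces.append((idx(n_rings - 1, j), idx(n_rings - 1, j + 1), apex_idx))
    return TriangleMesh(vertices, np.array(faces, dtype=np.int64), name="bullet_lv")


def _crescent_implicit(d: dict):
    """Scalar field negative inside the crescent (outer minus inner)."""
    a, b, c = d["outer_a"], d["outer_b"], d["outer_c"]
    ia, ib, ic = d["inner_a"], d["inner_b"], d["inner_c"]
    off = d["inner_offset"]

    def f(x, y, z):
        q_out = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 - 1.0
        q_in = ((x - off) / ia) ** 2 + (y / ib) ** 2 + (z / ic) ** 2 - 1.0
        return np.maximum(q_out, -q_in)

    return f


def _crescent_mesh(d: dict, target_faces: int) -> TriangleMesh:
    from skimage.measure import marching_cubes

    a, b, c = d["outer_a"], d["outer_b"], d["outer_c"]
    # grid pitch sized so marching cubes yields roughly the target face count
    area_est = 1.2 * _ellipsoid_area(a, b, c)
    h = float(np.clip(np.sqrt(2.0 * area_est / target_faces), 0.6, 5.0))
    lo = np.array([-a, -b, -c]) - 2 * h
    hi = np.array([a, b, c]) + 2 * h
    ns = np.maximum(np.ceil((hi - lo) / h).astype(int) + 1, 8)
    xs = [np.linspace(lo[i], lo[i] + (ns[i] - 1) * h, ns[i]) for i in range(3)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    F = _crescent_implicit(d)(X, Y, Z)
    verts, faces, _, _ = marching_cubes(F, level=0.0, spacing=(h, h, h))
    verts = verts + lo
    mesh = TriangleMesh(verts, faces.astype(np.int64), name="crescent_rv")
    if mesh_volume(mesh, strict=False).signed_volume_cm3 < 0:
        mesh = mesh.flipped()
    return mesh


def _ellipsoid_area(a, b, c, p=1.6075):
    """Thomsen's approximation to the ellipsoid surface area."""
    return 4 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (1.0 / p)


# ---------------------------------------------------------------------------
# trabeculation field
# ---------------------------------------------------------------------------


def _bandlimited_field(points: np.ndarray, frequency: float, seed: int, n_waves: int = 24) -> np.ndarray:
    """Seeded band-limited scalar field in [0, 1] over the given points.

    A sum of plane-wave cosines with random directions, phases and weights,
    wavenumber 2*pi*frequency, min-max normalised over the supplied points.
    Smooth, deterministic given (frequency, seed), and non-negative so an
    amplitude-scaled subtraction is strictly inward.
    """
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(n_waves, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_waves)
    weights = rng.uniform(0.5, 1.0, size=n_waves)
    k = 2.0 * np.pi * frequency
    waves = np.cos(k * (points @ dirs.T) + phases)
    f = waves @ weights
    lo, hi = f.min(), f.max()
    if hi - lo < 1e-12:
        return np.zeros(len(points))
    return (f - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# phantom assembly
# ---------------------------------------------------------------------------


def _smooth_mesh(spec: PhantomSpec) -> TriangleMesh:
    d = spec.dimensions
    if spec.shape == "bullet_lv":
        return _bullet_mesh(d["radius"], d["length"], spec.mesh_resolution)
    if spec.shape == "ellipsoid":
        sub = max(1, int(round(np.log(spec.mesh_resolution / 20.0) / np.log(4.0))))
        return icosphere(subdivisions=sub, semiaxes=(d["a"], d["b"], d["c"]))
    return _crescent_mesh(d, spec.mesh_resolution)


def _ibp_mesh(spec: PhantomSpec, smooth: TriangleMesh) -> TriangleMesh:
    """Inward-perturbed copy of the smooth surface (the inner blood pool)."""
    amp = spec.trabeculation_amplitude
    if amp == 0.0:
        return TriangleMesh(smooth.vertices.copy(), smooth.faces.copy(), name=smooth.name + "_ibp")
    d = spec.dimensions
    if spec.shape == "bullet_lv":

        def radial_scale(points, rho):
            f = _bandlimited_field(points, spec.trabeculation_frequency, spec.seed)
            return np.maximum(rho - amp * f, 0.1 * rho)

        mesh = _bullet_mesh(d["radius"], d["length"], spec.mesh_resolution, radial_scale)
        return TriangleMesh(mesh.vertices, mesh.faces, name="bullet_lv_ibp")
    if spec.shape == "ellipsoid":
        f = _bandlimited_field(smooth.vertices, spec.trabeculation_frequency, spec.seed)
        radii = np.linalg.norm(smooth.vertices, axis=1)
        frac = np.maximum(1.0 - amp * f / np.maximum(radii, 1e-9), 0.1)
        return TriangleMesh(smooth.vertices * frac[:, None], smooth.faces, name="ellipsoid_ibp")
    # crescent: displace along inward vertex normals
    f = _bandlimited_field(smooth.vertices, spec.trabeculation_frequency, spec.seed)
    normals = _vertex_normals(smooth)
    verts = smooth.vertices - (amp * f)[:, None] * normals
    return TriangleMesh(verts, smooth.faces, name="crescent_rv_ibp")


def _vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Area-weighted outward unit vertex normals."""
    fn = mesh.face_normals(unit=False)  # area-weighted
    vn = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(vn, mesh.faces[:, k], fn)
    norms = np.linalg.norm(vn, axis=1, keepdims=True)
    return np.where(norms > 0, vn / norms, 0.0)


def _inside_fn(spec: PhantomSpec):
    d = spec.dimensions
    if spec.shape == "bullet_lv":
        r, L = d["radius"], d["length"]

        def inside(x, y, z):
            rho2 = x * x + y * y
            prof = np.where(
                z <= L - r, r * r, np.maximum(r * r - (z - (L - r)) ** 2, -1.0)
            )
            return (z >= 0.0) & (z <= L) & (rho2 <= prof)

        return inside
    if spec.shape == "ellipsoid":
        a, b, c = d["a"], d["b"], d["c"]
        return lambda x, y, z: (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0
    f = _crescent_implicit(d)
    return lambda x, y, z: f(x, y, z) <= 0.0


def _phantom_bounds(spec: PhantomSpec) -> np.ndarray:
    d = spec.dimensions
    if spec.shape == "bullet_lv":
        r = d["radius"]
        return np.array([[-r, -r, 0.0], [r, r, d["length"]]])
    if spec.shape == "ellipsoid":
        s = np.array([d["a"], d["b"], d["c"]])
        return np.array([-s, s])
    s = np.array([d["outer_a"], d["outer_b"], d["outer_c"]])
    return np.array([-s, s])


def voxelize(spec: PhantomSpec, spacing: Optional[float] = None, pad_voxels: int = 2) -> VoxelMask:
    """Voxel-centre-inside binary mask of the phantom's smooth surface."""
    h = float(spacing if spacing is not None else spec.voxel_spacing)
    lo, hi = _phantom_bounds(spec)
    lo = lo - pad_voxels * h
    n = np.ceil((hi - lo) / h).astype(int) + pad_voxels
    inside = _inside_fn(spec)
    xs = lo[0] + (np.arange(n[0]) + 0.5) * h
    ys = lo[1] + (np.arange(n[1]) + 0.5) * h
    occ = np.empty(tuple(n), dtype=np.uint8)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    for k in range(n[2]):
        z = lo[2] + (k + 0.5) * h
        occ[:, :, k] = inside(X, Y, np.full_like(X, z))
    return VoxelMask(occ, (h, h, h), tuple(lo), axis=2)


def _oracle_volume_cm3(spec: PhantomSpec) -> float:
    """Fine-grid voxel-centre volume oracle (for shapes with no closed form)."""
    h = spec.truth_spacing
    lo, hi = _phantom_bounds(spec)
    lo = lo - 2 * h
    n = np.ceil((hi - lo) / h).astype(int) + 2
    inside = _inside_fn(spec)
    xs = lo[0] + (np.arange(n[0]) + 0.5) * h
    ys = lo[1] + (np.arange(n[1]) + 0.5) * h
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    count = 0
    chunk = max(1, int(2e7 // (n[0] * n[1])))
    for k0 in range(0, n[2], chunk):
        zs = lo[2] + (np.arange(k0, min(k0 + chunk, n[2])) + 0.5) * h
        count += int(
            inside(X[:, :, None], Y[:, :, None], zs[None, None, :]).sum()
        )
    return count * h**3 / MM3_PER_CM3


def make_phantom(spec: PhantomSpec) -> PhantomPair:
    """Build the matched phantom pair described by *spec*.

    Returns the smooth reference mesh, the inward-perturbed inner-blood-pool
    mesh, the voxel mask of the smooth surface, and the ground-truth volume
    (closed form where available, fine-grid oracle otherwise).

    Raises
    ------
    ValueError
        If the trabeculation amplitude violates the self-intersection bound
        (checked by :class:`PhantomSpec`) or the perturbed surface fails to
        reduce the enclosed volume.
    """
    smooth = _smooth_mesh(spec)
    ibp = _ibp_mesh(spec, smooth)
    if spec.trabeculation_amplitude > 0:
        v_s = mesh_volume(smooth).volume_cm3
        v_i = mesh_volume(ibp).volume_cm3
        if not v_i < v_s:
            raise ValueError(
                "inner-blood-pool perturbation failed to reduce the volume "
                f"({v_i:.3f} >= {v_s:.3f} cm^3); amplitude too large for this surface"
            )
    mask = voxelize(spec)
    truth = spec.analytic_volume_cm3()
    if truth is None:
        truth = _oracle_volume_cm3(spec)
    return PhantomPair(spec, smooth, ibp, mask, float(truth))


def export_phantom(pair: PhantomPair, outdir, stem: str = "phantom") -> dict:
    """Write STL meshes, the NIfTI mask, and a JSON sidecar; returns paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "smooth_stl": os.path.join(outdir, f"{stem}_smooth.stl"),
        "ibp_stl": os.path.join(outdir, f"{stem}_ibp.stl"),
        "mask_nii": os.path.join(outdir, f"{stem}_mask.nii.gz"),
        "sidecar_json": os.path.join(outdir, f"{stem}.json"),
    }
    write_stl(pair.smooth_mesh, paths["smooth_stl"], dialect="binary")
    write_stl(pair.ibp_mesh, paths["ibp_stl"], dialect="binary")
    pair.smooth_mask.to_nifti(paths["mask_nii"])
    with open(paths["sidecar_json"], "w") as fh:
        json.dump(
            {"spec": pair.spec.as_dict(), "truth_volume_cm3": pair.truth_volume_cm3},
            fh,
            indent=2,
        )
    return paths


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass
class PopulationSpec:
    """Distribution of phantom dimensions across a synthetic cohort.

    Dimensions are drawn independently from normals (``dim_means`` /
    ``dim_sds``) with invalid draws (non-positive, or length <= radius)
    re-drawn; the trabeculation amplitude is drawn from a normal clipped at
    zero.  Defaults are sized so cohort volumes fall in the clinically
    reported adult range (LV roughly 80-230 cm^3, RV roughly 80-255 cm^3).
    """

    shape: str
    dim_means: dict
    dim_sds: dict
    amplitude_mean: float = 2.0
    amplitude_sd: float = 0.5

    def draw_spec(self, rng: np.random.Generator, **spec_kwargs) -> PhantomSpec:
        for attempt in range(100):
            dims = {
                k: rng.normal(self.dim_means[k], self.dim_sds[k]) for k in self.dim_means
            }
            amp = max(0.0, rng.normal(self.amplitude_mean, self.amplitude_sd))
            try:
                return PhantomSpec(
                    self.shape,
                    dims,
                    trabeculation_amplitude=amp,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    **spec_kwargs,
                )
            except ValueError as exc:
                logger.debug("re-drawing phantom dimensions (attempt %d): %s", attempt, exc)
        raise ValueError("could not draw a valid phantom spec in 100 attempts; "
                         "population parameters are degenerate")


def lv_population(amplitude_mean: float = 2.0, amplitude_sd: float = 0.5) -> PopulationSpec:
    """Bullet-LV cohort sized to adult end-diastolic LV volumes."""
    return PopulationSpec(
        shape="bullet_lv",
        dim_means={"radius": 23.5, "length": 90.0},
        dim_sds={"radius": 2.5, "length": 8.0},
        amplitude_mean=amplitude_mean,
        amplitude_sd=amplitude_sd,
    )


def rv_population(amplitude_mean: float = 2.0, amplitude_sd: float = 0.5) -> PopulationSpec:
    """Crescent-RV cohort sized to adult end-diastolic RV volumes."""
    return PopulationSpec(
        shape="crescent_rv",
        dim_means={
            "outer_a": 44.0, "outer_b": 35.0, "outer_c": 33.0,
            "inner_a": 34.0, "inner_b": 30.0, "inner_c": 29.0,
            "inner_offset": 42.0,
        },
        dim_sds={
            "outer_a": 3.5, "outer_b": 3.0, "outer_c": 3.0,
            "inner_a": 2.5, "inner_b": 2.0, "inner_c": 2.0,
            "inner_offset": 3.0,
        },
        amplitude_mean=amplitude_mean,
        amplitude_sd=amplitude_sd,
    )


def _as_method_dict(value, default: float = 0.0) -> dict:
    methods = ("pdp", "vrps", "vribp")
    if value is None:
        return {m: default for m in methods}
    if np.isscalar(value):
        return {m: float(value) for m in methods}
    out = {m: float(value.get(m, default)) for m in methods}
    return out


def make_cohort(
    n: int = 20,
    seed: int = 0,
    population: Optional[PopulationSpec] = None,
    method_noise: float | dict = 4.0,
    method_bias: float | dict = 0.0,
    mesh_resolution: int = 5000,
    voxel_spacing: float = 0.8,
    truth_spacing: float = 0.25,
) -> pd.DataFrame:
    """Simulate a paired-measurement cohort of synthetic ventricles.

    Per subject, three measurements of the same phantom are produced, the
    way the three clinical methods would see it:

    * ``pdp_cm3``   — slice (Simpson) engine on the smooth-surface mask;
    * ``vrps_cm3``  — polygon (mesh) engine on the smooth surface;
    * ``vribp_cm3`` — polygon engine on the inner-blood-pool surface;

    each plus its per-method additive bias and Gaussian measurement noise
    (both in cm^3).  The ground truth is included per subject.  Fully
    reproducible from *seed* (identical seeds give byte-identical tables).

    Returns a DataFrame with columns ``subject_id, shape, truth_cm3,
    pdp_cm3, vrps_cm3, vribp_cm3``.
    """
    if n < 2:
        raise ValueError("cohort needs n >= 2")
    noise = _as_method_dict(method_noise)
    bias = _as_method_dict(method_bias)
    if any(v < 0 for v in noise.values()):
        raise ValueError("method noise SDs must be >= 0")
    population = population or lv_population()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for i in range(n):
        spec = population.draw_spec(
            rng,
            mesh_resolution=mesh_resolution,
            voxel_spacing=voxel_spacing,
            truth_spacing=truth_spacing,
        )
        pair = make_phantom(spec)
        pdp = slice_stack_volume(pair.smooth_mask).volume_cm3
        vrps = mesh_volume(pair.smooth_mesh).volume_cm3
        vribp = mesh_volume(pair.ibp_mesh).volume_cm3
        eps = rng.normal(size=3)
        rows.append(
            {
                "subject_id": f"S{i + 1:03d}",
                "shape": spec.shape,
                "truth_cm3": pair.truth_volume_cm3,
                "pdp_cm3": pdp + bias["pdp"] + noise["pdp"] * eps[0],
                "vrps_cm3": vrps + bias["vrps"] + noise["vrps"] * eps[1],
                "vribp_cm3": vribp + bias["vribp"] + noise["vribp"] * eps[2],
            }
        )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
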