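"""The two chamber-volume computations: polygon (signed-tetrahedron)
summation over a closed surface mesh, and Simpson's-rule disk-area slice
summation over a binary voxel mask.

Polygon summation treats each surface triangle, together with the
coordinate origin, as a tetrahedron whose signed volume is

    V_i = (1/6) (p_{i,1} x p_{i,2}) . p_{i,3}

with the sign fixed by the vertex winding: triangles whose normal points
away from the origin contribute positive volume, triangles whose normal
points toward it contribute negative volume.  Summed over a closed,
consistently oriented surface the result is exactly the enclosed volume,
independently of where the origin sits.

The slice engine reproduces the clinical platform behaviour: cross-sectional
area per slice (voxel count x in-plane pixel area) multiplied by the slice
thickness and summed along the long axis.  It is deliberately the flat
disk-area rule, not a higher-order quadrature.

Mesh coordinates and voxel spacings are millimetres; volumes are reported in
cm^3 with mm^3 available.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .mesh import MeshDiagnostics, TriangleMesh, diagnose

__all__ = [
    "MeshNotClosedError",
    "VoxelMask",
    "VolumeResult",
    "EngineComparison",
    "tetra_signed_volume",
    "mesh_volume",
    "slice_area",
    "slice_stack_volume",
    "compare_engines",
]

MM3_PER_CM3 = 1000.0


class MeshNotClosedError(ValueError):
    """Strict-mode mesh volume requested on a non-closed or inconsistently
    oriented surface, for which the signed volume is not well defined."""


@dataclass(frozen=True)
class VolumeResult:
    """A computed chamber volume with its method tag and diagnostics."""

    volume_cm3: float
    signed_volume_cm3: float
    method: str  # "mesh_polygon_summation" | "slice_summation"
    diagnostics: Union[MeshDiagnostics, dict, None]
    n_elements: int  # triangles summed, or slices in the stack

    @property
    def volume_mm3(self) -> float:
        return self.volume_cm3 * MM3_PER_CM3

    def as_dict(self) -> dict:
        diag = self.diagnostics
        if isinstance(diag, MeshDiagnostics):
            diag = diag.as_dict()
        return {
            "volume_cm3": float(self.volume_cm3),
            "signed_volume_cm3": float(self.signed_volume_cm3),
            "volume_mm3": float(self.volume_mm3),
            "method": self.method,
            "n_elements": int(self.n_elements),
            "diagnostics": diag,
        }


@dataclass
class VoxelMask:
    """3D binary segmentation mask on an anisotropic axis-aligned grid.

    Voxel ``(i, j, k)`` occupies the half-open box
    ``[origin + i*dx, origin + (i+1)*dx) x ...``; the voxel centre sits at
    ``origin + (i + 0.5) * spacing``.

    Parameters
    ----------
    occupancy : 3D array of {0, 1}
    spacing : (dx, dy, dz) in mm, each > 0
    origin : corner of voxel (0, 0, 0) in mm
    axis : index of the slicing (long) axis used by the slice engine
    """

    occupancy: np.ndarray
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)
    axis: int = 2

    def __post_init__(self):
        occ = np.asarray(self.occupancy)
        if occ.ndim != 3:
            raise ValueError(f"occupancy must be 3D, got shape {occ.shape}")
        if occ.dtype != np.uint8:
            vals = np.unique(occ)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("occupancy must contain only 0/1")
            occ = occ.astype(np.uint8)
        self.occupancy = occ
        self.spacing = tuple(float(s) for s in np.atleast_1d(self.spacing).ravel())
        if len(self.spacing) == 1:
            self.spacing = self.spacing * 3
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be 0, 1 or 2")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_count(self) -> int:
        return int(self.occupancy.sum())

    # -- NIfTI interchange ----------------------------------------------

    @classmethod
    def from_nifti(cls, path: Union[str, os.PathLike], axis: int = 2) -> "VoxelMask":
        """Load a binary mask from NIfTI; spacing comes from the affine's
        diagonal.  Non-axis-aligned affines are rejected."""
        import nibabel as nib

        img = nib.load(os.fspath(path))
        affine = img.affine
        rot = affine[:3, :3]
        off_diag = rot - np.diag(np.diag(rot))
        if np.abs(off_diag).max() > 1e-6 * max(np.abs(rot).max(), 1.0):
            raise ValueError("non-axis-aligned NIfTI affine; mask grid must be axis-aligned")
        spacing = np.abs(np.diag(rot))
        data = np.asanyarray(img.dataobj)
        occ = (data > 0.5).astype(np.uint8)
        return cls(occ, tuple(spacing), tuple(affine[:3, 3]), axis=axis)

    def to_nifti(self, path: Union[str, os.PathLike]) -> None:
        import nibabel as nib

        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.occupancy, affine), os.fspath(path))


# ---------------------------------------------------------------------------
# polygon summation engine
# ---------------------------------------------------------------------------


def tetra_signed_volume(p1, p2, p3) -> float:
    """Signed volume of the tetrahedron (origin, p1, p2, p3).

    Equals (1/6) (p1 x p2) . p3 — i.e. (1/3) * a * h with a the triangle
    area and h its height over the origin, signed by the winding.
    Antisymmetric under swapping any two arguments; degenerate (collinear)
    triangles return 0.
    """
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    p3 = np.asarray(p3, dtype=np.float64)
    return float(np.dot(np.cross(p1, p2), p3) / 6.0)


def _signed_volume_mm3(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Sum of per-face tetrahedron volumes about the coordinate origin.

    Accumulated with numpy's pairwise summation over the per-face
    contributions to control round-off on large meshes.
    """
    tri = vertices[faces]
    cross = np.cross(tri[:, 0], tri[:, 1])
    contrib = np.einsum("ij,ij->i", cross, tri[:, 2]) / 6.0
    return float(np.sum(contrib))


def mesh_volume(mesh: TriangleMesh, strict: bool = True) -> VolumeResult:
    """Chamber volume by signed-tetrahedron (polygon) summation.

    For a closed, consistently oriented surface the summed signed volume is
    the enclosed volume: translation invariant and scaling as s^3.  A
    pre-translation to the bounding-box centre is applied internally to
    reduce floating-point cancellation; for a closed mesh this is provably
    volume-neutral.  An outward-wound surface yields a positive sign; the
    reported ``volume_cm3`` is the absolute value either way.

    Parameters
    ----------
    strict
        When True (default), raise :class:`MeshNotClosedError` if the mesh
        is not watertight and orientation-consistent.  When False, compute
        anyway (about the origin, matching the stated sign convention) and
        leave the interpretation to the caller via the diagnostics.
    """
    if mesh.n_faces == 0:
        raise ValueError("cannot compute the volume of an empty mesh")
    diag = diagnose(mesh)
    if strict and not diag.is_closed:
        raise MeshNotClosedError(
            "mesh is not closed (watertight="
            f"{diag.is_watertight}, orientation_consistent="
            f"{diag.is_orientation_consistent}); signed volume undefined. "
            "Pass strict=False to compute anyway."
        )
    if diag.is_closed:
        center = mesh.bounds().mean(axis=0)
        signed_mm3 = _signed_volume_mm3(mesh.vertices - center, mesh.faces)
    else:
        signed_mm3 = _signed_volume_mm3(mesh.vertices, mesh.faces)
    return VolumeResult(
        volume_cm3=abs(signed_mm3) / MM3_PER_CM3,
        signed_volume_cm3=signed_mm3 / MM3_PER_CM3,
        method="mesh_polygon_summation",
        diagnostics=diag,
        n_elements=mesh.n_faces,
    )


# ---------------------------------------------------------------------------
# slice summation engine
# ---------------------------------------------------------------------------


def slice_area(mask_slice: np.ndarray, spacing: Sequence[float]) -> float:
    """Cross-sectional area of one slice in mm^2: voxel count x dx x dy."""
    mask_slice = np.asarray(mask_slice)
    dx, dy = float(spacing[0]), float(spacing[1])
    if dx <= 0 or dy <= 0:
        raise ValueError("in-plane spacing must be strictly positive")
    return float(np.count_nonzero(mask_slice)) * dx * dy


def slice_stack_volume(mask: VoxelMask) -> VolumeResult:
    """Simpson's-rule volume: per-slice area times slice thickness, summed.

    Algebraically this equals (voxel count) x (voxel volume) and is
    therefore invariant under the choice of slicing axis; the slicing-axis
    bookkeeping mirrors the clinical procedure and feeds the diagnostics.
    """
    occ = mask.occupancy
    axis = mask.axis
    in_plane = [mask.spacing[a] for a in range(3) if a != axis]
    dz = mask.spacing[axis]
    counts = np.count_nonzero(occ, axis=tuple(a for a in range(3) if a != axis))
    areas_mm2 = counts.astype(np.float64) * in_plane[0] * in_plane[1]
    volume_mm3 = float(np.sum(areas_mm2) * dz)
    return VolumeResult(
        volume_cm3=volume_mm3 / MM3_PER_CM3,
        signed_volume_cm3=volume_mm3 / MM3_PER_CM3,
        method="slice_summation",
        diagnostics={
            "slicing_axis": axis,
            "slice_thickness_mm": dz,
            "n_slices_nonempty": int(np.count_nonzero(counts)),
            "voxel_count": int(counts.sum()),
            "spacing_mm": list(mask.spacing),
        },
        n_elements=int(occ.shape[axis]),
    )


# ---------------------------------------------------------------------------
# paired comparison harness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EngineComparison:
    """Both engines run on the same object, with their discrepancy."""

    mesh_result: VolumeResult
    slice_result: VolumeResult
    difference_cm3: float  # mesh - slice
    relative_difference: float  # difference over the engine mean

    def as_dict(self) -> dict:
        return {
            "mesh": self.mesh_result.as_dict(),
            "slice": self.slice_result.as_dict(),
            "difference_cm3": float(self.difference_cm3),
            "relative_difference": float(self.relative_difference),
        }


def compare_engines(mesh: TriangleMesh, mask: VoxelMask, strict: bool = True) -> EngineComparison:
    """Run polygon summation on *mesh* and slice summation on *mask*
    (assumed to represent the same object) and report their discrepancy."""
    mr = mesh_volume(mesh, strict=strict)
    sr = slice_stack_volume(mask)
    diff = mr.volume_cm3 - sr.volume_cm3
    mean = 0.5 * (mr.volume_cm3 + sr.volume_cm3)
    rel = diff / mean if mean > 0 else 0.0
    return EngineComparison(mr, sr, diff, rel)
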