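"""Polygon-summation and slice-summation volume engines."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ventrivol import (
    MeshNotClosedError,
    PhantomSpec,
    TriangleMesh,
    VoxelMask,
    compare_engines,
    icosphere,
    mesh_volume,
    slice_area,
    slice_stack_volume,
    tetra_signed_volume,
)
from ventrivol.phantoms import voxelize

from conftest import divergence_theorem_volume, random_closed_mesh

point = st.tuples(*[st.floats(-100, 100, allow_nan=False)] * 3)


class TestTetraSignedVolume:
    def test_unit_right_tetrahedron(self):
        assert tetra_signed_volume((1, 0, 0), (0, 1, 0), (0, 0, 1)) == pytest.approx(1 / 6)

    def test_swap_negates(self):
        assert tetra_signed_volume((0, 1, 0), (1, 0, 0), (0, 0, 1)) == pytest.approx(-1 / 6)

    def test_collinear_is_zero(self):
        assert tetra_signed_volume((1, 0, 0), (2, 0, 0), (3, 0, 0)) == 0.0

    @given(point, point, point)
    def test_antisymmetry_under_any_swap(self, p1, p2, p3):
        v = tetra_signed_volume(p1, p2, p3)
        assert tetra_signed_volume(p2, p1, p3) == pytest.approx(-v, abs=1e-6)
        assert tetra_signed_volume(p1, p3, p2) == pytest.approx(-v, abs=1e-6)
        assert tetra_signed_volume(p3, p2, p1) == pytest.approx(-v, abs=1e-6)


class TestMeshVolume:
    def test_10mm_cube_is_one_cm3(self, cube_10mm):
        res = mesh_volume(cube_10mm)
        assert res.signed_volume_cm3 == pytest.approx(1.0, abs=1e-12)
        assert res.volume_cm3 == pytest.approx(1.0, abs=1e-12)
        assert res.n_elements == 12
        assert res.method == "mesh_polygon_summation"

    def test_orientation_reversal_negates_signed_volume(self, cube_10mm):
        res = mesh_volume(cube_10mm.flipped())
        assert res.signed_volume_cm3 == pytest.approx(-1.0, abs=1e-12)
        assert res.volume_cm3 == pytest.approx(1.0, abs=1e-12)

    def test_icosphere_within_one_percent_of_analytic(self):
        mesh = icosphere(radius=10.0, subdivisions=3)
        assert mesh.n_faces == 1280
        analytic = 4.0 / 3.0 * np.pi * 10.0**3 / 1000.0
        assert mesh_volume(mesh).volume_cm3 == pytest.approx(analytic, rel=0.01)

    def test_translation_invariance(self, cube_10mm):
        far = mesh_volume(cube_10mm.translated((250.0, -40.0, 7.0)))
        assert far.volume_cm3 == pytest.approx(1.0, rel=1e-9)

    @pytest.mark.parametrize("s", [0.5, 3.0, 17.0])
    def test_cubic_scaling(self, cube_10mm, s):
        res = mesh_volume(cube_10mm.scaled(s))
        assert res.volume_cm3 == pytest.approx(s**3, rel=1e-12)

    def test_strict_mode_rejects_open_mesh(self, cube_10mm):
        open_mesh = TriangleMesh(cube_10mm.vertices, cube_10mm.faces[:-1])
        with pytest.raises(MeshNotClosedError):
            mesh_volume(open_mesh)
        res = mesh_volume(open_mesh, strict=False)
        assert not res.diagnostics.is_watertight

    def test_empty_mesh_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mesh_volume(TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), int)))

    def test_matches_divergence_theorem_oracle_on_random_closed_meshes(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            mesh = random_closed_mesh(rng)
            mine = mesh_volume(mesh).signed_volume_cm3 * 1000.0
            oracle = divergence_theorem_volume(mesh)
            assert mine == pytest.approx(oracle, rel=1e-9)

    def test_matches_trimesh_on_phantom_surface(self):
        trimesh = pytest.importorskip("trimesh")
        mesh = icosphere(radius=17.0, subdivisions=3, semiaxes=(17.0, 12.0, 9.0))
        tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
        assert mesh_volume(mesh).volume_cm3 * 1000.0 == pytest.approx(tm.volume, rel=1e-9)


class TestSliceEngine:
    def test_full_slice_area(self):
        assert slice_area(np.ones((10, 10)), (1.0, 1.0)) == 100.0

    def test_empty_slice_area(self):
        assert slice_area(np.zeros((4, 4)), (1.0, 1.0)) == 0.0

    def test_anisotropic_slice_area(self):
        sl = np.zeros((5, 5))
        sl[0, 0] = sl[1, 1] = sl[2, 2] = 1
        assert slice_area(sl, (0.5, 0.5)) == pytest.approx(0.75)

    def test_full_cube_mask_volume(self):
        mask = VoxelMask(np.ones((10, 10, 10), dtype=np.uint8), (1.0, 1.0, 1.0))
        res = slice_stack_volume(mask)
        assert res.volume_cm3 == pytest.approx(1.0)
        assert res.method == "slice_summation"
        assert res.n_elements == 10

    def test_all_zero_mask(self):
        mask = VoxelMask(np.zeros((5, 5, 5), dtype=np.uint8), (1.0, 1.0, 1.0))
        assert slice_stack_volume(mask).volume_cm3 == 0.0

    def test_equals_voxel_count_times_voxel_volume(self):
        rng = np.random.default_rng(5)
        occ = (rng.random((13, 9, 21)) > 0.6).astype(np.uint8)
        mask = VoxelMask(occ, (0.7, 1.1, 2.3))
        expected = occ.sum() * 0.7 * 1.1 * 2.3 / 1000.0
        assert slice_stack_volume(mask).volume_cm3 == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("axis", [0, 1, 2])
    def test_invariant_under_slicing_axis(self, axis):
        rng = np.random.default_rng(9)
        occ = (rng.random((8, 8, 8)) > 0.5).astype(np.uint8)
        mask = VoxelMask(occ, (1.0, 2.0, 0.5), axis=axis)
        ref = VoxelMask(occ, (1.0, 2.0, 0.5), axis=2)
        assert slice_stack_volume(mask).volume_cm3 == pytest.approx(
            slice_stack_volume(ref).volume_cm3, rel=1e-12
        )

    def test_bullet_mask_within_one_percent_at_half_mm(self):
        spec = PhantomSpec("bullet_lv", {"radius": 20.0, "length": 80.0})
        analytic = spec.analytic_volume_cm3()
        mask = voxelize(spec, spacing=0.5)
        assert slice_stack_volume(mask).volume_cm3 == pytest.approx(analytic, rel=0.01)

    def test_mask_validation(self):
        with pytest.raises(ValueError, match="0/1"):
            VoxelMask(np.full((2, 2, 2), 3.0), (1, 1, 1))
        with pytest.raises(ValueError, match="positive"):
            VoxelMask(np.ones((2, 2, 2), dtype=np.uint8), (1, -1, 1))


class TestNiftiInterchange:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(3)
        occ = (rng.random((6, 7, 8)) > 0.5).astype(np.uint8)
        mask = VoxelMask(occ, (0.5, 0.8, 1.25), origin=(-3.0, 0.0, 10.0))
        p = tmp_path / "mask.nii.gz"
        mask.to_nifti(p)
        back = VoxelMask.from_nifti(p)
        assert np.array_equal(back.occupancy, occ)
        assert back.spacing == pytest.approx(mask.spacing)
        assert back.origin == pytest.approx(mask.origin)

    def test_oblique_affine_rejected(self, tmp_path):
        nib = pytest.importorskip("nibabel")
        affine = np.eye(4)
        affine[0, 1] = 0.3  # shear
        img = nib.Nifti1Image(np.ones((4, 4, 4), dtype=np.uint8), affine)
        p = tmp_path / "oblique.nii.gz"
        nib.save(img, p)
        with pytest.raises(ValueError, match="axis-aligned"):
            VoxelMask.from_nifti(p)


class TestCompareEngines:
    def test_cube_and_exact_voxelization_agree(self, cube_10mm):
        mask = VoxelMask(np.ones((10, 10, 10), dtype=np.uint8), (1.0, 1.0, 1.0))
        cmp = compare_engines(cube_10mm, mask)
        assert cmp.difference_cm3 == pytest.approx(0.0, abs=1e-12)
        assert cmp.relative_difference == pytest.approx(0.0, abs=1e-12)

    def test_sphere_fine_voxelization_below_one_percent(self):
        mesh = icosphere(radius=20.0, subdivisions=3)
        spec = PhantomSpec("ellipsoid", {"a": 20.0, "b": 20.0, "c": 20.0})
        cmp = compare_engines(mesh, voxelize(spec, spacing=0.5))
        assert abs(cmp.relative_difference) < 0.01

    def test_discrepancy_shrinks_with_voxel_refinement(self):
        mesh = icosphere(radius=20.0, subdivisions=3)
        spec = PhantomSpec("ellipsoid", {"a": 20.0, "b": 20.0, "c": 20.0})
        coarse = compare_engines(mesh, voxelize(spec, spacing=4.0))
        fine = compare_engines(mesh, voxelize(spec, spacing=0.5))
        assert abs(fine.relative_difference) < abs(coarse.relative_difference)
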