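"""Boundary clouds, normals, surface reconstruction, CT clouds, reslicing."""

import numpy as np
import pytest
import trimesh

from cocoscan import mesh3d
from cocoscan.phantom import LABEL_IDS, make_water_cylinder
from cocoscan.recon import Volume


class TestBoundaryPoints:
    def test_cube_surface_voxels(self):
        labels = np.zeros((5, 5, 5), np.uint8)
        labels[1:4, 1:4, 1:4] = 1
        pts = mesh3d.boundary_points(labels, 1)
        assert len(pts) == 26  # all but the centre voxel

    def test_digital_sphere_radii(self):
        n = 48
        z, y, x = np.mgrid[0:n, 0:n, 0:n].astype(float)
        c = (n - 1) / 2.0
        labels = (
            ((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2) <= 20.0**2
        ).astype(np.uint8)
        pts = mesh3d.boundary_points(labels, 1)
        r = np.linalg.norm(pts, axis=1)
        # six-connected boundary voxel centres stay within one voxel of the
        # continuous radius (worst case just under the cell diagonal)
        assert np.all(np.abs(r - 20.0) <= 1.0)
        assert np.abs(r - 20.0).mean() < 0.5

    def test_absent_compartment_empty_cloud(self):
        pts = mesh3d.boundary_points(np.zeros((4, 4, 4), np.uint8), "shell")
        assert pts.shape == (0, 3)


class TestNormals:
    def test_plane_normals_are_z(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack(
            [rng.uniform(-10, 10, 200), rng.uniform(-10, 10, 200), np.zeros(200)]
        )
        normals = mesh3d.estimate_normals(pts, k_neighbors=8)
        assert np.allclose(np.abs(normals[:, 2]), 1.0, atol=1e-9)

    def test_sphere_normals_point_radially(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(600, 3))
        pts = 20.0 * v / np.linalg.norm(v, axis=1, keepdims=True)
        normals = mesh3d.estimate_normals(pts, k_neighbors=12)
        radial = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        cos = np.einsum("ij,ij->i", normals, radial)
        angles = np.degrees(np.arccos(np.clip(cos, -1, 1)))
        assert angles.mean() < 5.0
        assert (cos > 0).all()  # consistently outward

    def test_k_larger_than_cloud_rejected(self):
        with pytest.raises(ValueError):
            mesh3d.estimate_normals(np.zeros((5, 3)), k_neighbors=10)


def _sphere_cloud(radius, n=4000, seed=2):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    return radius * v / np.linalg.norm(v, axis=1, keepdims=True)


class TestSurfaceReconstruction:
    def test_sphere_volume_within_3pct(self):
        pts = _sphere_cloud(20.0)
        mesh = mesh3d.reconstruct_surface(pts, voxel_size_mm=1.0)
        assert mesh.is_watertight
        assert mesh3d.mesh_volume(mesh) == pytest.approx(33510.3, rel=0.03)

    def test_ellipsoid_volume_within_3pct(self):
        pts = _sphere_cloud(1.0, n=6000) * np.array([30.0, 25.0, 20.0])
        mesh = mesh3d.reconstruct_surface(pts, voxel_size_mm=1.0)
        expected = 4.0 / 3.0 * np.pi * 30 * 25 * 20
        assert mesh3d.mesh_volume(mesh) == pytest.approx(expected, rel=0.03)

    def test_surface_close_to_cloud(self):
        from scipy.spatial import cKDTree

        pts = _sphere_cloud(20.0)
        mesh = mesh3d.reconstruct_surface(pts, voxel_size_mm=1.0)
        # every cloud point lies within 1.5 grid cells of the mesh, and
        # every mesh vertex sits on the true surface to the same tolerance
        d1, _ = cKDTree(mesh.vertices).query(pts)
        assert d1.max() <= 1.5
        r = np.linalg.norm(mesh.vertices, axis=1)
        assert np.abs(r - 20.0).max() <= 1.5

    def test_sparse_cloud_rejected(self):
        with pytest.raises(ValueError, match="sparse"):
            mesh3d.reconstruct_surface(_sphere_cloud(20.0, n=50))


class TestMeshMeasures:
    def test_unit_cube(self):
        box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        assert mesh3d.mesh_volume(box) == pytest.approx(1.0)
        assert mesh3d.mesh_area(box) == pytest.approx(6.0)

    def test_icosphere_volume_half_percent(self):
        ico = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
        assert mesh3d.mesh_volume(ico) == pytest.approx(4188.8, rel=0.005)

    def test_inverted_orientation_normalized(self):
        ico = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
        ico.invert()
        assert mesh3d.mesh_volume(ico) > 0

    def test_open_mesh_volume_rejected(self):
        box = trimesh.creation.box()
        open_mesh = trimesh.Trimesh(
            vertices=box.vertices, faces=box.faces[:-2], process=False
        )
        with pytest.raises(ValueError):
            mesh3d.mesh_volume(open_mesh)
        assert mesh3d.mesh_area(open_mesh) > 0  # allowed, flagged


class TestPhantomMeshes:
    def test_compartment_mesh_volumes_within_3pct(self, fruit_phantom):
        spec, _, labels, gt = fruit_phantom
        vox = spec.voxel_size_mm
        for name, lid in LABEL_IDS.items():
            mask = labels == lid
            if lid == 0 or not mask.any():
                continue
            mesh = mesh3d.mesh_from_mask(mask, vox, name)
            assert mesh.is_watertight, name
            voxel_vol = mask.sum() * vox**3
            assert mesh3d.mesh_volume(mesh) == pytest.approx(
                voxel_vol, rel=0.03
            ), name

    def test_nested_compartments_yield_nested_meshes(self, fruit_phantom):
        """Inner-mesh vertices map into the filled outer voxel hull."""
        from scipy import ndimage as ndi

        spec, _, labels, _ = fruit_phantom
        vox = spec.voxel_size_mm
        hull = ndi.binary_dilation(ndi.binary_fill_holes(labels > 0))
        inner = mesh3d.mesh_from_mask(
            ndi.binary_fill_holes(labels == LABEL_IDS["shell"]), vox, "shell"
        )
        nz, ny, nx = labels.shape
        iz = np.clip(np.rint(inner.vertices[:, 2] / vox + (nz - 1) / 2).astype(int), 0, nz - 1)
        iy = np.clip(np.rint(inner.vertices[:, 1] / vox + (ny - 1) / 2).astype(int), 0, ny - 1)
        ix = np.clip(np.rint(inner.vertices[:, 0] / vox + (nx - 1) / 2).astype(int), 0, nx - 1)
        assert hull[iz, iy, ix].all()


class TestCTPointCloud:
    def test_point_count_conservation(self, fruit_phantom):
        spec, mu, labels, _ = fruit_phantom
        vol = Volume(200.0 * mu / spec.mu_water, spec.voxel_size_mm, units="ct")
        cloud = mesh3d.fill_ct_pointcloud(labels, vol)
        assert len(cloud.points) == (labels != 0).sum()
        assert np.array_equal(np.unique(cloud.labels), np.unique(labels[labels > 0]))


class TestReslice:
    def test_axial_reslice_recovers_stored_slice(self):
        rng = np.random.default_rng(0)
        vol = Volume(rng.random((16, 16, 16)), 1.0, units="ct")
        k = 8
        z = (k - 7.5) * 1.0
        img = mesh3d.reslice(
            vol, (0.0, 0.0, z), (0.0, 0.0, 1.0), pixel_pitch_mm=1.0,
            extent_mm=15.0,
        )
        # central region of the resliced plane matches the stored slice
        stored = vol.values[k]
        match = 0
        for v in img.ravel():
            if np.any(np.isclose(stored, v, atol=1e-12)):
                match += 1
        assert match / img.size > 0.9

    def test_tilted_cylinder_section_axis_ratio(self):
        vol_values = make_water_cylinder(10.0, 60.0, (96, 48, 48), 1.0, 1.0)
        vol = Volume(vol_values, 1.0, units="ct")
        img = mesh3d.reslice(
            vol,
            (0.0, 0.0, 0.0),
            (0.0, 1.0, 1.0),  # 45 degrees to the cylinder axis
            pixel_pitch_mm=0.25,
        )
        sec = img > 0.5
        rows = np.nonzero(sec.any(axis=1))[0]
        cols = np.nonzero(sec.any(axis=0))[0]
        ext = sorted(
            [(rows[-1] - rows[0] + 1) * 0.25, (cols[-1] - cols[0] + 1) * 0.25]
        )
        assert ext[1] / ext[0] == pytest.approx(np.sqrt(2.0), rel=0.02)

    def test_plane_outside_volume_empty(self):
        vol = Volume(np.ones((8, 8, 8)), 1.0, units="ct")
        img = mesh3d.reslice(
            vol, (0.0, 0.0, 100.0), (0.0, 0.0, 1.0), extent_mm=10.0
        )
        assert not img.any()
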