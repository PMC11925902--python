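"""Centerline extraction, wall reconstruction and component volumes."""

import numpy as np
import pytest

import plaquestress as ps
from plaquestress.geometry import compute_component_volumes
from plaquestress.labels import Label


def _tube_labelmap(radius=3.0, length=20.0, voxel=0.5, center=(0.0, 0.0)):
    half = radius + 4.0
    n = int(np.ceil(2 * half / voxel))
    nz = int(np.ceil(length / voxel))
    xs = (np.arange(n) + 0.5) * voxel - half
    zs = (np.arange(nz) + 0.5) * voxel
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    lumen = (X - center[0]) ** 2 + (Y - center[1]) ** 2 < radius**2
    data = np.where(lumen[:, :, None], int(Label.LUMEN), 0).astype(np.uint8)
    data = np.broadcast_to(data, (n, n, nz)).copy()
    return ps.LabelVolume(data, voxel, origin=np.array([xs[0], xs[0], zs[0]]))


class TestCenterline:
    def test_straight_tube_on_axis(self):
        vol = _tube_labelmap()
        cl = ps.extract_centerline(vol)
        assert np.abs(cl.points[:, :2]).max() < vol.voxel_size
        assert np.all(np.diff(cl.arclength) > 0)

    def test_translation_equivariance(self):
        a = ps.extract_centerline(_tube_labelmap())
        b = ps.extract_centerline(_tube_labelmap(center=(2.0, -1.5)))
        shift = b.points[:, :2] - a.points[:, :2]
        assert np.allclose(shift, [2.0, -1.5], atol=1e-9)

    def test_bent_arc_within_voxel(self):
        """Tube bent along a circular arc: centerline deviation < voxel."""
        R, r, voxel = 60.0, 3.0, 0.5
        phi = np.linspace(0.0, np.arcsin(30.0 / R), 400)
        curve = np.stack([R - R * np.cos(phi), np.zeros_like(phi), R * np.sin(phi)], axis=1)
        xs = np.arange(-6.0, 14.0, voxel)
        ys = np.arange(-6.0, 6.0, voxel)
        zs = np.arange(0.25, 30.0, voxel)
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
        d2 = ((pts[:, None, :] - curve[None, :, :]) ** 2).sum(-1).min(axis=1)
        lumen = (d2 < r**2).reshape(X.shape)
        vol = ps.LabelVolume(
            np.where(lumen, int(Label.LUMEN), 0).astype(np.uint8),
            voxel,
            origin=np.array([xs[0], ys[0], zs[0]]),
        )
        cl = ps.extract_centerline(vol)
        dev = np.sqrt(((cl.points[:, None, :] - curve[None, :, :]) ** 2).sum(-1)).min(axis=1)
        assert dev.max() < voxel

    def test_empty_and_disconnected_rejected(self):
        empty = ps.LabelVolume(np.zeros((5, 5, 5), np.uint8), 1.0)
        with pytest.raises(ValueError, match="no lumen"):
            ps.extract_centerline(empty)
        data = np.zeros((5, 5, 9), np.uint8)
        data[2, 2, :3] = int(Label.LUMEN)
        data[2, 2, 6:] = int(Label.LUMEN)
        with pytest.raises(ValueError, match="connected"):
            ps.extract_centerline(ps.LabelVolume(data, 1.0))


class TestReconstruction:
    def test_no_plaque_uniform_ring(self):
        vol = ps.generate_vessel_labelmap(ps.GeometryParams(stenosis_degree=0.0, voxel_size=0.5))
        model = ps.reconstruct_atherosclerotic_wall(vol)
        rep = compute_component_volumes(model)
        assert rep.absolute["fibrous"] == 0.0
        wall = model.volume.mask(Label.HEALTHY_WALL)
        per_slice = wall.sum(axis=(0, 1))
        assert np.all(per_slice == per_slice[0])  # identical ring at every station

    def test_components_conserved_and_contained(self):
        p = ps.GeometryParams(stenosis_degree=0.6, calcific_fraction=0.25, lipid_fraction=0.1,
                              voxel_size=0.5, seed=2)
        vol = ps.generate_vessel_labelmap(p)
        model = ps.reconstruct_atherosclerotic_wall(vol)
        for lab in (Label.CALCIFIC, Label.LIPID):
            assert np.array_equal(model.volume.mask(lab), vol.mask(lab))
        # components sit strictly inside the wall region (never background-adjacent
        # in-plane beyond the outer contour): the wall mask is a superset
        wall = model.volume.mask(Label.CALCIFIC, Label.LIPID, Label.FIBROUS, Label.HEALTHY_WALL)
        assert wall[model.volume.mask(Label.CALCIFIC, Label.LIPID)].all()

    def test_thin_lipid_blob_keeps_outer_surface(self):
        """A lipid blob thinner than the healthy wall leaves the outer
        contour identical to the plaque-free reconstruction."""
        base = _tube_labelmap(radius=3.0, voxel=0.5)
        ref = ps.reconstruct_atherosclerotic_wall(base.copy())
        blob = base.copy()
        # one-voxel-thick lipid layer hugging the lumen at mid-vessel
        k = blob.data.shape[2] // 2
        sl = blob.data[:, :, k]
        n = sl.shape[0]
        xs = np.arange(n) * blob.voxel_size + blob.origin[0]  # voxel centres
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        rr = np.sqrt(X**2 + Y**2)
        ring = (rr >= 3.0) & (rr < 3.5) & (X > 0)
        sl[ring] = int(Label.LIPID)
        model = ps.reconstruct_atherosclerotic_wall(blob)
        wall_ref = ref.volume.mask(*[l for l in (Label.FIBROUS, Label.HEALTHY_WALL, Label.CALCIFIC, Label.LIPID)])
        wall_new = model.volume.mask(*[l for l in (Label.FIBROUS, Label.HEALTHY_WALL, Label.CALCIFIC, Label.LIPID)])
        assert np.array_equal(wall_ref, wall_new)

    def test_idempotent(self):
        p = ps.GeometryParams(stenosis_degree=0.6, calcific_fraction=0.2, lipid_fraction=0.1,
                              voxel_size=0.5, seed=5)
        once = ps.reconstruct_atherosclerotic_wall(ps.generate_vessel_labelmap(p))
        twice = ps.reconstruct_atherosclerotic_wall(once.volume)
        assert np.array_equal(once.volume.data, twice.volume.data)

    def test_orphan_component_rejected(self):
        vol = _tube_labelmap(radius=3.0, voxel=0.5)
        vol.data[0, 0, 5] = int(Label.CALCIFIC)  # far corner, ~6.5 mm off the lumen
        with pytest.raises(ValueError, match="disconnected"):
            ps.reconstruct_atherosclerotic_wall(vol)

    def test_healthy_rim_minimum_thickness(self):
        p = ps.GeometryParams(stenosis_degree=0.6, calcific_fraction=0.2, voxel_size=0.5, seed=1)
        model = ps.reconstruct_atherosclerotic_wall(ps.generate_vessel_labelmap(p))
        # non-stenotic end station: ring spans at least wall_thickness radially
        wall = model.volume.mask(Label.HEALTHY_WALL)[:, :, 0]
        lum = model.volume.mask(Label.LUMEN)[:, :, 0]
        h = model.volume.voxel_size
        assert wall.sum() * h * h >= 0.9 * np.pi * (
            (4.0 + model.config.wall_thickness) ** 2 - 4.0**2
        )
        assert lum.any()


class TestVolumes:
    def test_single_component_is_100pct(self):
        data = np.zeros((6, 6, 6), np.uint8)
        data[2:4, 2:4, 2:4] = int(Label.CALCIFIC)
        rep = compute_component_volumes(ps.LabelVolume(data, 0.5))
        assert rep.relative["calcific"] == 100.0
        assert rep.absolute["calcific"] == 8 * 0.125

    def test_relative_volumes_sum_to_100(self, plaque_solution):
        model, rep, _, _ = plaque_solution
        assert sum(rep.relative.values()) == pytest.approx(100.0, abs=1e-9)

    def test_voxelized_sphere_volume(self):
        h, R = 0.2, 5.0
        n = int(2 * (R + 1) / h)
        xs = (np.arange(n) + 0.5) * h - (R + 1)
        X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
        data = np.where(X**2 + Y**2 + Z**2 < R**2, int(Label.CALCIFIC), 0).astype(np.uint8)
        rep = compute_component_volumes(ps.LabelVolume(data, h))
        assert rep.absolute["calcific"] == pytest.approx(4 / 3 * np.pi * R**3, rel=0.02)

    def test_zero_plaque_flagged(self):
        data = np.zeros((4, 4, 4), np.uint8)
        data[1:3, 1:3, :] = int(Label.HEALTHY_WALL)
        rep = compute_component_volumes(ps.LabelVolume(data, 1.0))
        assert not rep.plaque_defined
        assert np.isnan(rep.relative["calcific"])

    def test_monotone_in_voxel_count(self):
        data = np.zeros((6, 6, 6), np.uint8)
        data[2:4, 2:4, 2:4] = int(Label.LIPID)
        v1 = compute_component_volumes(ps.LabelVolume(data, 0.5)).absolute["lipid"]
        data[4, 4, 4] = int(Label.LIPID)
        v2 = compute_component_volumes(ps.LabelVolume(data, 0.5)).absolute["lipid"]
        assert v2 > v1


class TestLabelVolumeIO:
    def test_nifti_roundtrip(self, tmp_path):
        p = ps.GeometryParams(stenosis_degree=0.5, calcific_fraction=0.2, voxel_size=0.6,
                              vessel_length=15.0, seed=3)
        vol = ps.generate_vessel_labelmap(p)
        path = tmp_path / "vessel.nii.gz"
        vol.to_nifti(path)
        back = ps.LabelVolume.from_nifti(path)
        assert np.array_equal(back.data, vol.data)
        assert back.voxel_size == pytest.approx(vol.voxel_size)
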