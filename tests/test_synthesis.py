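"""Synthetic density generation: blobs, tube, coil, projections, noise, MRC I/O."""

import math

import numpy as np
import pytest

from sheathkit import geometry as geo
from sheathkit import synthesis as syn
from sheathkit.errors import MapFormatError, MeasurementError


def small_lattice_geometry(n_layers=4, rise=20.0, twist=30.0, n_start=3):
    sym = geo.HelicalSymmetry(twist, rise, n_start=n_start)
    return geo.SheathGeometry("x", 140.0, 60.0, n_layers * rise, sym)


class TestRenderVolume:
    def test_empty_lattice_is_zero(self):
        vol = syn.render_volume([], syn.BlobModel(), 32, 4.0)
        assert not vol.grid.any()

    def test_single_blob_peaks_at_center(self):
        pose = geo.SubunitPose(0, 0, 0.0, 0.0, 0.0)
        vol = syn.render_volume([pose], syn.BlobModel(sigma_ang=6.0), 33, 4.0)
        assert np.unravel_index(np.argmax(vol.grid), vol.grid.shape) == (16, 16, 16)

    def test_mass_conservation(self):
        blob = syn.BlobModel(sigma_ang=6.0)
        poses = geo.build_lattice(small_lattice_geometry())
        vol = syn.render_volume(poses, blob, 96, 4.0)
        total = float(vol.grid.sum(dtype=np.float64)) * 4.0**3
        assert total == pytest.approx(len(poses) * blob.mass, rel=0.01)

    def test_outside_pose_warns(self):
        far = geo.SubunitPose(0, 0, 1e4, 0.0, 0.0)
        with pytest.warns(UserWarning, match="clipped"):
            syn.render_volume([far], syn.BlobModel(), 32, 4.0, center_z=False)


class TestTube:
    def test_solid_cylinder_when_inner_zero(self):
        vol = syn.render_volume([], syn.BlobModel(), 32, 4.0)
        out = syn.add_tube(vol, 40.0, 0.0, amplitude=1.0)
        assert out.grid[16, 16, 16] == pytest.approx(1.0, abs=1e-4)

    def test_per_slice_mass_constant(self):
        vol = syn.render_volume([], syn.BlobModel(), 32, 4.0)
        out = syn.add_tube(vol, 60.0, 20.0)
        per_slice = out.grid.sum(axis=(1, 2))
        assert np.all(per_slice == per_slice[0])

    def test_annulus_area(self):
        vol = syn.render_volume([], syn.BlobModel(), 128, 2.0)
        out = syn.add_tube(vol, 100.0, 40.0, amplitude=1.0)
        voxel_area = 2.0**2
        measured = out.grid[0].sum() * voxel_area
        expected = math.pi * (50.0**2 - 20.0**2)
        assert measured == pytest.approx(expected, rel=0.03)


class TestProjection:
    def test_mass_conserved(self):
        vol = syn.simulate_sheath_map("non_contracted", box_voxels=48, voxel_size_ang=8.0)
        img = syn.project(vol, axis="y")
        assert img.data.sum() == pytest.approx(
            vol.grid.sum(dtype=np.float64) * vol.voxel_size_ang, rel=1e-6
        )

    def test_uniform_cylinder_projects_uniformly(self):
        vol = syn.add_tube(syn.render_volume([], syn.BlobModel(), 48, 4.0), 80.0, 0.0)
        img = syn.project(vol, axis="x")
        assert np.allclose(img.data, img.data[0][None, :])

    def test_projected_width_matches_diameter(self):
        vol = syn.add_tube(syn.render_volume([], syn.BlobModel(), 96, 4.0), 160.0, 0.0)
        img = syn.project(vol, axis="y")
        row = img.data[0]
        width_px = int((row > 0.5 * row.max()).sum())
        assert width_px * img.pixel_size_ang == pytest.approx(
            160.0 * math.sqrt(3) / 2, abs=2 * img.pixel_size_ang
        )

    def test_axial_projection_unsupported(self):
        vol = syn.render_volume([], syn.BlobModel(), 32, 4.0)
        with pytest.raises(ValueError, match="unsupported"):
            syn.project(vol, axis="z")


class TestNoise:
    def test_zero_sigma_identity(self):
        img = syn.ProjectionImage(np.ones((16, 16)), 3.0)
        out = syn.add_noise(img, 0.0, seed=1)
        assert np.array_equal(out.data, img.data)

    def test_seed_reproducibility(self):
        img = syn.ProjectionImage(np.zeros((64, 64)), 3.0)
        a = syn.add_noise(img, 2.5, seed=11)
        b = syn.add_noise(img, 2.5, seed=11)
        c = syn.add_noise(img, 2.5, seed=12)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_noise_variance(self):
        img = syn.ProjectionImage(np.zeros((224, 224)), 3.484)
        out = syn.add_noise(img, 4.0, seed=0)
        assert out.data.var() == pytest.approx(16.0, rel=0.05)

    def test_map_noise_seeded_and_snr(self):
        vol = syn.simulate_sheath_map("contracted", box_voxels=48, voxel_size_ang=8.0)
        a = syn.simulate_sheath_map("contracted", box_voxels=48, voxel_size_ang=8.0,
                                    snr=1.0, seed=3)
        b = syn.simulate_sheath_map("contracted", box_voxels=48, voxel_size_ang=8.0,
                                    snr=1.0, seed=3)
        assert np.array_equal(a.grid, b.grid)
        noise = a.grid.astype(np.float64) - vol.grid.astype(np.float64)
        # at SNR 1 the noise variance equals the in-mask signal variance
        n = vol.box_voxels
        ax = (np.arange(n) - vol.center_voxel) * vol.voxel_size_ang
        rr2 = ax[None, :] ** 2 + ax[:, None] ** 2
        mask3 = np.broadcast_to(rr2 <= 176.0**2, vol.grid.shape)
        sigma2 = syn.noise_sigma_for_snr(vol, 1.0, mask3) ** 2
        assert noise.var() == pytest.approx(sigma2, rel=0.05)


class TestCoil:
    @pytest.mark.parametrize("state,diameter", [("non_contracted", 390.0), ("contracted", 490.0)])
    def test_pitch_recovered_within_one_pixel(self, state, diameter):
        img = syn.simulate_projection(state, coil=True)
        pitch = syn.measure_coil_pitch(img)
        assert abs(pitch - 210.0) <= img.pixel_size_ang

    def test_pitch_invariant_to_pixel_size(self):
        # same physical scene sampled twice as coarsely gives the same Angstrom pitch
        fine = syn.simulate_projection("non_contracted", coil=True,
                                       box_voxels=224, voxel_size_ang=3.484)
        coarse = syn.simulate_projection("non_contracted", coil=True,
                                         box_voxels=112, voxel_size_ang=6.968)
        p_fine = syn.measure_coil_pitch(fine)
        p_coarse = syn.measure_coil_pitch(coarse)
        assert abs(p_fine - p_coarse) <= coarse.pixel_size_ang

    def test_coil_z_period(self):
        vol = syn.render_volume([], syn.BlobModel(), 160, 3.484)
        vol = syn.add_coil(vol, syn.CoilSpec(), syn.BlobModel())
        # autocorrelation along z of a flank column peaks at one pitch
        c = int(vol.center_voxel)
        flank = c + int(round(195.0 / vol.voxel_size_ang))
        col = vol.grid[:, c, flank].astype(np.float64)
        col -= col.mean()
        ac = np.correlate(col, col, mode="full")[col.size - 1:]
        lag_px = int(np.argmax(ac[10:])) + 10
        assert lag_px * 3.484 == pytest.approx(210.0, abs=3.484)

    def test_oversized_coil_rejected(self):
        vol = syn.render_volume([], syn.BlobModel(), 64, 3.484)
        with pytest.raises(ValueError, match="fit"):
            syn.add_coil(vol, syn.CoilSpec(diameter_ang=390.0), syn.BlobModel())

    def test_too_few_peaks_raises(self):
        img = syn.ProjectionImage(np.zeros((64, 64)), 3.0)
        with pytest.raises(MeasurementError):
            syn.measure_coil_pitch(img)


class TestMrcIO:
    def test_round_trip(self, tmp_path):
        vol = syn.simulate_sheath_map("contracted", box_voxels=48, voxel_size_ang=8.0)
        path = tmp_path / "map.mrc"
        syn.write_mrc(path, vol)
        back = syn.read_mrc(path)
        assert np.array_equal(back.grid, vol.grid)
        assert back.voxel_size_ang == pytest.approx(8.0, rel=1e-4)

    def test_malformed_file_raises(self, tmp_path):
        path = tmp_path / "bad.mrc"
        path.write_bytes(b"not an mrc header")
        with pytest.raises(MapFormatError):
            syn.read_mrc(path)
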