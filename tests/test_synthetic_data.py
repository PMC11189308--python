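"""Synthetic generator: projections, maps, wedge, bending."""

import numpy as np
import pytest

from vifhelix import synthetic_data as sd
from vifhelix.helix_core import params_from_units


def _point_model(params, sigma=4.0):
    return sd.FilamentModel(
        coords=np.zeros((1, 3)), mass=np.ones(1),
        chain_id=np.zeros(1, int), domain=np.array(["head"], object),
        tetramer_index=np.zeros(1, int), protofibril_index=np.zeros(1, int),
        params=params, radius=10.0, bead_sigma=sigma)


class TestImagingParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            sd.ImagingParams(box=111)
        with pytest.raises(ValueError):
            sd.ImagingParams(pixel_size=0)
        with pytest.raises(ValueError):
            sd.ImagingParams(noise_sigma=-0.1)


class TestProjectSegments:
    def test_determinism(self, default_model):
        im = sd.ImagingParams(seed=3, noise_sigma=0.5)
        a = sd.project_segments(default_model, im, 5, 100.0)
        b = sd.project_segments(default_model, im, 5, 100.0)
        assert np.array_equal(a.images, b.images)
        assert a.records.equals(b.records)

    def test_transform_reproduces_noiseless_image(self, default_model):
        """Rendering the canonical projection under the recorded transform
        reproduces the stored noiseless segment bit for bit."""
        im = sd.ImagingParams(seed=9, noise_sigma=0.7)
        st = sd.project_segments(default_model, im, 4, 150.0)
        for i, rec in enumerate(st.records.itertuples()):
            again = sd.render_projection(default_model, im,
                                         (rec.cx_A, rec.cz_A),
                                         psi=rec.psi_deg,
                                         dx=rec.dx_px, dy=rec.dy_px)
            assert np.array_equal(st.noiseless[i], again)

    def test_noise_level_matches_request(self, default_model):
        im = sd.ImagingParams(seed=4, noise_sigma=1.0)
        st = sd.project_segments(default_model, im, 10, 100.0)
        resid = st.images - st.noiseless
        rms = np.sqrt(np.mean(st.noiseless ** 2))
        assert resid.std() == pytest.approx(rms, rel=0.05)

    def test_identity_transform_is_canonical(self, default_model):
        im = sd.ImagingParams(seed=0, noise_sigma=0.0)
        st = sd.project_segments(default_model, im, 1, 10.0,
                                 psi_range=0.0, max_shift_px=0.0)
        rec = st.records.iloc[0]
        canon = sd.render_projection(default_model, im, (rec.cx_A, rec.cz_A))
        assert np.array_equal(st.images[0], canon)

    def test_too_many_segments_rejected(self, default_model):
        with pytest.raises(ValueError, match="segments"):
            sd.project_segments(default_model, sd.ImagingParams(seed=0),
                                n_segments=500, spacing=100.0)

    def test_bad_args(self, default_model):
        with pytest.raises(ValueError):
            sd.project_segments(default_model, sd.ImagingParams(seed=0), 0, 10.0)
        with pytest.raises(ValueError):
            sd.project_segments(default_model, sd.ImagingParams(seed=0), 1, -5.0)

    def test_wall_asymmetry_five_vs_four_protofibrils(self):
        """Odd protofibril counts make one projected wall stronger."""
        im = sd.ImagingParams(seed=0)

        def asym(model):
            zc = 0.5 * (model.coords[:, 2].min() + model.coords[:, 2].max())
            img = sd.render_projection(model, im, (0.0, zc))
            col = img.sum(axis=0)
            mid = im.box // 2
            left, right = col[:mid].sum(), col[mid:].sum()
            return abs(left - right) / (left + right)

        m5 = sd.build_filament_model(n_tetramers=60)
        m4 = sd.build_filament_model(n_tetramers=60,
                                     params=params_from_units(4.0, 47.0),
                                     n_protofibrils=4)
        assert asym(m5) > 0.01
        assert asym(m4) < 0.005


class TestDensityMap:
    def test_integral_tracks_mass(self):
        m = sd.build_filament_model(n_tetramers=5)
        dm = sd.render_density_map(m, voxel_size=3.44)
        integral = dm.grid.sum() * dm.voxel_size ** 3
        assert integral == pytest.approx(m.mass.sum(), rel=5e-3)

    def test_linearity_in_mass(self):
        m = sd.build_filament_model(n_tetramers=3)
        dm1 = sd.render_density_map(m, voxel_size=4.0)
        m.mass = 2.0 * m.mass
        dm2 = sd.render_density_map(m, voxel_size=4.0)
        assert np.allclose(dm2.grid, 2 * dm1.grid, atol=1e-12)

    def test_empty_model_zero_grid(self):
        m = sd.build_filament_model(n_tetramers=1)
        empty = sd.FilamentModel(
            coords=np.empty((0, 3)), mass=np.empty(0),
            chain_id=np.empty(0, int), domain=np.empty(0, object),
            tetramer_index=np.empty(0, int), protofibril_index=np.empty(0, int),
            params=m.params, radius=55.0)
        dm = sd.render_density_map(empty, voxel_size=4.0, box=(16, 16, 16))
        assert not dm.grid.any()

    def test_model_exceeding_box_rejected(self):
        m = sd.build_filament_model(n_tetramers=10)
        with pytest.raises(ValueError, match="fit"):
            sd.render_density_map(m, voxel_size=3.44, box=(16, 16, 16))


class TestMissingWedge:
    def test_full_range_is_identity(self):
        m = sd.build_filament_model(n_tetramers=3)
        dm = sd.render_density_map(m, voxel_size=4.0)
        out = sd.apply_missing_wedge(dm, (-90, 90))
        assert np.abs(out.grid - dm.grid).max() <= 1e-6 * np.abs(dm.grid).max()

    def test_idempotent(self):
        m = sd.build_filament_model(n_tetramers=3)
        dm = sd.render_density_map(m, voxel_size=4.0)
        once = sd.apply_missing_wedge(dm, (-60, 60))
        twice = sd.apply_missing_wedge(once, (-60, 60))
        assert np.allclose(once.grid, twice.grid,
                           atol=1e-9 * np.abs(once.grid).max())

    def test_wedge_region_is_zeroed(self):
        m = sd.build_filament_model(n_tetramers=3)
        dm = sd.render_density_map(m, voxel_size=4.0)
        out = sd.apply_missing_wedge(dm, (-60, 60))
        F = np.fft.fftn(out.grid)
        nz, ny, _ = out.grid.shape
        kz = np.fft.fftfreq(nz)[:, None]
        ky = np.fft.fftfreq(ny)[None, :]
        ang = np.degrees(np.arctan2(kz, ky))
        ang = ((ang + 90) % 180) - 90
        missing = (np.abs(ang) > 60.001)
        assert np.abs(F[missing[:, :, None] & np.ones(F.shape, bool)]).max() \
            <= 1e-6 * np.abs(F).max()

    def test_point_source_elongates_along_z(self):
        pt = _point_model(params_from_units(5.0, 42.5))
        dm = sd.render_density_map(pt, voxel_size=2.0, box=(48, 48, 48))
        out = sd.apply_missing_wedge(dm, (-60, 60))

        def extent(profile):
            p = np.abs(profile) / np.abs(profile).max()
            return int((p > 0.1).sum())

        z_ext = extent(out.grid.sum(axis=(1, 2)))
        x_ext = extent(out.grid.sum(axis=(0, 1)))
        assert z_ext / x_ext > 1.0

    def test_degenerate_range_rejected(self):
        m = sd.build_filament_model(n_tetramers=2)
        dm = sd.render_density_map(m, voxel_size=4.0)
        for rng in ((60, 60), (70, 60), (-100, 60), (-60, 95)):
            with pytest.raises(ValueError):
                sd.apply_missing_wedge(dm, rng)


class TestBendPath:
    def test_straight_path_is_identity(self, default_model):
        z0 = default_model.coords[:, 2].min()
        z = np.linspace(z0, default_model.coords[:, 2].max() + 10, 6)
        cps = np.stack([np.zeros_like(z), np.zeros_like(z), z], axis=1)
        bent = sd.bend_path(default_model, cps)
        assert np.abs(bent.coords - default_model.coords).max() < 1e-9

    def test_quarter_circle(self, default_model):
        """End-to-end shortens, contour length is preserved to 0.1%."""
        L = default_model.arc_length()
        R = 2 * (L + 100) / np.pi   # quarter circle slightly longer than the model
        th = np.linspace(0, np.pi / 2, 50)
        z0 = default_model.coords[:, 2].min()
        cps = np.stack([R - R * np.cos(th), np.zeros_like(th),
                        z0 + R * np.sin(th)], axis=1)
        bent = sd.bend_path(default_model, cps)
        # independent arc-length oracle: integrate the bent centerline
        pts = np.stack([bent.centerline_point(s)
                        for s in np.linspace(0, L, 400)])
        contour = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        e2e = np.linalg.norm(pts[-1] - pts[0])
        assert e2e < contour
        assert contour == pytest.approx(L, rel=1e-3)

    def test_excessive_curvature_rejected(self, default_model):
        # tight sinusoid: curvature radius ~40 Å < 2 x filament radius
        z0 = default_model.coords[:, 2].min()
        z = np.linspace(z0, z0 + 3400, 400)
        cps = np.stack([100 * np.sin(2 * np.pi * (z - z0) / 400.0),
                        np.zeros_like(z), z], axis=1)
        with pytest.raises(ValueError, match="curvature"):
            sd.bend_path(default_model, cps)

    def test_short_path_rejected(self, default_model):
        cps = np.array([[0, 0, 0], [0, 0, 100.0]])
        with pytest.raises(ValueError, match="shorter"):
            sd.bend_path(default_model, cps)


class TestStackIO:
    def test_mrc_csv_round_trip(self, small_stack, tmp_path):
        mpath, cpath = small_stack.write(tmp_path / "stk")
        from vifhelix import mrc
        data, voxel, _ = mrc.read_mrc(mpath)
        assert data.shape == small_stack.images.shape
        assert voxel == pytest.approx(small_stack.imaging.pixel_size, rel=1e-6)
        assert np.allclose(data, small_stack.images, atol=1e-5)
        import pandas as pd
        rec = pd.read_csv(cpath)
        assert len(rec) == len(small_stack)
        assert {"segment_id", "filament_id", "psi_deg", "dx_px", "dy_px",
                "arc_A", "class_id"} <= set(rec.columns)
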