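"""Segment alignment, compositing, straightening, uniform boxing."""

import numpy as np
import pandas as pd
import pytest

from vifhelix import ca_assembly as ca
from vifhelix import layerline_spectra as lls
from vifhelix import synthetic_data as sd


def _single_record(**kw):
    rec = {"segment_id": 0, "filament_id": 0, "psi_deg": 0.0, "dx_px": 0.0,
           "dy_px": 0.0, "arc_A": 0.0, "class_id": 0, "cx_A": 0.0, "cz_A": 0.0}
    rec.update(kw)
    return pd.DataFrame([rec])


@pytest.fixture(scope="module")
def coherent_stack(default_model):
    """Segments of one filament with coherent orientations (shift jitter only)."""
    im = sd.ImagingParams(seed=21, noise_sigma=0.3)
    return sd.project_segments(default_model, im, 20, 60.0,
                               psi_range=0.0, max_shift_px=5.0)


class TestAlignSegments:
    def test_identity_alignment(self, default_model):
        im = sd.ImagingParams(seed=0, noise_sigma=0.0)
        ref = sd.render_projection(default_model, im, (0.0, 900.0))
        stack = sd.SegmentStack(images=ref[None], records=_single_record(),
                                imaging=im)
        out = ca.align_segments(stack, ref, psi_step=10.0, max_shift=6)
        rec = out.records.iloc[0]
        assert rec.psi_deg == 0.0 and rec.dx_px == 0.0 and rec.dy_px == 0.0
        assert rec.score == pytest.approx(1.0, abs=1e-9)

    def test_recovers_known_transforms(self, default_model):
        im = sd.ImagingParams(seed=7, noise_sigma=0.0)
        st = sd.project_segments(default_model, im, 3, 20.0,
                                 psi_range=30.0, max_shift_px=4.0)
        ref = sd.render_projection(default_model, im,
                                   (0.0, st.records.cz_A.iloc[1]))
        out = ca.align_segments(st, ref, psi_step=2.0, max_shift=10)
        rec_true = st.records.iloc[1]
        rec_est = out.records.iloc[1]
        dpsi = (rec_est.psi_deg - rec_true.psi_deg + 180) % 360 - 180
        assert abs(dpsi) <= 2.0                      # within the grid step
        # a psi-grid error of 2 deg displaces features near the box corner
        # by ~2 px, which couples into the best integer shift
        assert rec_est.dx_px == pytest.approx(rec_true.dx_px, abs=3.0)
        assert rec_est.dy_px == pytest.approx(rec_true.dy_px, abs=3.0)
        assert rec_est.score > 0.8

    def test_pure_noise_flagged(self, default_model):
        im = sd.ImagingParams(seed=3)
        ref = sd.render_projection(default_model, im, (0.0, 900.0))
        noise = np.random.default_rng(5).normal(size=(1, im.box, im.box))
        stack = sd.SegmentStack(images=noise, records=_single_record(),
                                imaging=im)
        out = ca.align_segments(stack, ref, psi_step=30.0, max_shift=6)
        assert not out.records.iloc[0].reliable

    def test_empty_references_rejected(self, small_stack):
        with pytest.raises(ValueError):
            ca.align_segments(small_stack, np.empty((0, 8, 8)))


class TestComposite:
    def test_single_identity_paste_equals_class_average(self):
        rng = np.random.default_rng(0)
        avg = rng.random((32, 32))
        caf = ca.composite_ca_filament(avg, _single_record(), pixel_size=2.0)
        filled = caf.image[caf.support > 0]
        assert filled.size == avg.size
        assert np.allclose(np.sort(filled.ravel()), np.sort(avg.ravel()))

    def test_overlap_of_identical_pastes_is_idempotent(self):
        avg = np.random.default_rng(1).random((32, 32))
        recs = pd.concat([_single_record(), _single_record(segment_id=1)],
                         ignore_index=True)
        caf = ca.composite_ca_filament(avg, recs, pixel_size=2.0)
        one = ca.composite_ca_filament(avg, _single_record(), pixel_size=2.0)
        assert np.allclose(caf.image[caf.support > 0],
                           one.image[one.support > 0])

    def test_ground_truth_composite_matches_projection(self, default_model,
                                                       coherent_stack):
        """Inverse-transform compositing reproduces the noiseless filament."""
        st = coherent_stack
        im = st.imaging
        canon = np.stack([sd.render_projection(default_model, im,
                                               (r.cx_A, r.cz_A))
                          for r in st.records.itertuples()])
        recs = st.records.assign(class_id=np.arange(len(st)))
        caf = ca.composite_ca_filament(canon, recs, im.pixel_size)
        H, W = caf.image.shape
        big_box = H + (H % 2) + 16
        ctr_z = 0.5 * (st.records.cz_A.min() + st.records.cz_A.max())
        big = sd.render_projection(
            default_model,
            sd.ImagingParams(seed=0, box=big_box, pixel_size=im.pixel_size),
            (0.0, ctr_z))
        mask = caf.support > 0
        # the canvas frame is defined up to a ~1 px rounding offset;
        # compare at the best small integer registration
        r0 = (big_box - H) // 2
        c0 = (big_box - W) // 2
        ncc = max(
            np.corrcoef(caf.image[mask],
                        big[r0 + dr:r0 + dr + H, c0 + dc:c0 + dc + W][mask])[0, 1]
            for dr in range(-3, 4) for dc in range(-3, 4))
        assert ncc >= 0.9

    def test_no_records_rejected(self):
        with pytest.raises(ValueError):
            ca.composite_ca_filament(np.zeros((8, 8)),
                                     pd.DataFrame(), pixel_size=2.0)


class TestStraighten:
    def test_vertical_path_is_identity(self, default_model):
        im = sd.ImagingParams(seed=1)
        img = sd.render_projection(default_model, im, (0.0, 900.0))
        path = np.stack([np.full(5, 54.5), np.linspace(0, 109, 5)], axis=1)
        out = ca.straighten_filament(img, path, width=40)
        crop = img[:, 35:75]
        n = min(len(out), len(crop))
        assert np.abs(out[:n] - crop[:n]).max() < 1e-9
        # interpolation conserves total intensity
        assert out[:n].sum() == pytest.approx(crop[:n].sum(), rel=0.01)

    def test_arc_length_sets_output_height(self):
        img = np.zeros((200, 200))
        th = np.linspace(0, np.pi / 2, 12)
        R = 120.0
        path = np.stack([10 + R * np.sin(th), 10 + R * (1 - np.cos(th))],
                        axis=1)
        out = ca.straighten_filament(img, path, width=10)
        assert out.shape[0] == pytest.approx(R * np.pi / 2, abs=1.5)

    def test_path_outside_image_names_point(self):
        img = np.zeros((50, 50))
        path = np.array([[10.0, 10.0], [25.0, 30.0], [80.0, 45.0]])
        with pytest.raises(ValueError, match="point 2"):
            ca.straighten_filament(img, path, width=8)

    def test_sinusoid_recovers_repeat(self, default_model):
        """Straightening a bent filament restores the straight repeat."""
        m = default_model
        L = m.arc_length()
        z0 = m.coords[:, 2].min()
        zz = np.linspace(z0 - 60, z0 + L + 60, 60)
        cps = np.stack([100.0 * np.sin(2 * np.pi * (zz - z0) / 2200.0),
                        np.zeros_like(zz), zz], axis=1)
        bent = sd.bend_path(m, cps)
        px = 3.44
        xlo, xhi = bent.coords[:, 0].min(), bent.coords[:, 0].max()
        zlo, zhi = bent.coords[:, 2].min(), bent.coords[:, 2].max()
        box = int(np.ceil(max(xhi - xlo, zhi - zlo) / px)) + 60
        box += box % 2
        imb = sd.ImagingParams(seed=0, box=box, pixel_size=px,
                               projection_thickness=1e9)
        ctr = (0.5 * (xlo + xhi), 0.5 * (zlo + zhi))
        micro = sd.render_projection(bent, imb, ctr)
        ss = np.linspace(0, L, 80)
        pts = np.stack([bent.centerline_point(s) for s in ss])
        path = np.stack([(pts[:, 0] - ctr[0]) / px + box / 2 - 0.5,
                         (pts[:, 2] - ctr[1]) / px + box / 2 - 0.5], axis=1)
        straightened = ca.straighten_filament(micro, path, width=44)
        # dominant-peak repeat after removing the slow axial background the
        # resampling leaves behind
        kw = dict(peak_fraction=0.9, detrend_sigma_px=20.0)
        rep_bent, _ = lls.autocorrelation_repeat(straightened, px, **kw)
        st0 = sd.project_segments(m, sd.ImagingParams(seed=0, box=512,
                                                      pixel_size=px),
                                  1, 10.0, psi_range=0.0, max_shift_px=0.0)
        rep_straight, _ = lls.autocorrelation_repeat(st0.images[0], px, **kw)
        assert rep_bent == pytest.approx(rep_straight, rel=0.05)


class TestBoxUniformLength:
    def _fake_ca(self, length_A, pixel=3.44, width=30):
        rows = int(round(length_A / pixel))
        img = np.random.default_rng(int(length_A)).random((rows, width))
        return ca.CaFilament(image=img, support=np.ones_like(img),
                             pixel_size=pixel, length=length_A)

    def test_counts_and_shapes(self):
        cas = [self._fake_ca(L) for L in (3000.0, 3530.0, 4000.0)]
        stack, excluded = ca.box_uniform_length(cas, 3530.0)
        assert excluded == 1
        assert stack.shape[0] == 2
        assert len({s.shape for s in stack}) == 1
        assert stack.shape[1] == int(round(3530.0 / 3.44))

    def test_empty_output_allowed(self):
        stack, excluded = ca.box_uniform_length([self._fake_ca(500.0)], 3530.0)
        assert stack is None and excluded == 1

    def test_longer_boxes_sharpen_layer_lines(self, default_model):
        """Fourier line width shrinks as the analyzed length grows."""
        im = sd.ImagingParams(seed=2, box=512)
        st = sd.project_segments(default_model, im, 1, 10.0,
                                 psi_range=0.0, max_shift_px=0.0)
        img = st.images[0]

        def peak_width_q(image):
            x = image - image.mean()
            mer = np.abs(np.fft.rfft(x.sum(axis=1))) ** 2
            q = np.arange(len(mer)) / (image.shape[0] * im.pixel_size)
            band = (q > 1 / 69) & (q < 1 / 30)
            sub = mer[band]
            half = sub.max() / 2
            return (sub > half).sum() / (image.shape[0] * im.pixel_size)

        assert peak_width_q(img) < peak_width_q(img[:128])
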