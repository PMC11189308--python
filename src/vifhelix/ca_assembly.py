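"""Computational filament assembly (ca-VIFs).

Filament segments are aligned to reference images; the per-segment 2D
transform (in-plane rotation and xy shift) is then inverted and the
matched class average is pasted back at the segment's position, which
reconstitutes an extended, low-noise image of the whole filament.  Bent
filaments are straightened by resampling along a spline centerline, and
straightened filaments are boxed to a uniform length for long-range
spectral analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import CubicSpline, UnivariateSpline

from .synthetic_data import SegmentStack

__all__ = [
    "CaFilament",
    "align_segments",
    "composite_ca_filament",
    "straighten_filament",
    "box_uniform_length",
    "estimate_centerline",
]


@dataclass
class CaFilament:
    """A computationally assembled filament image.

    ``support`` counts the class-average pastes contributing to each pixel;
    pixels with support 0 are empty and excluded from statistics.  ``path``
    is the centerline estimate in pixel coordinates (columns x, rows z) and
    ``length`` the arc length in Å.
    """

    image: np.ndarray
    support: np.ndarray
    pixel_size: float
    path: np.ndarray | None = None
    length: float = 0.0

    @property
    def mask(self) -> np.ndarray:
        return self.support > 0


def _rotate_about_center(image: np.ndarray, psi: float,
                         dx: float = 0.0, dy: float = 0.0,
                         order: int = 1) -> np.ndarray:
    """Apply the forward segment transform R(psi) then shift, bilinear."""
    box = image.shape[0]
    c = box / 2 - 0.5
    phi = np.deg2rad(psi)
    R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    vv, uu = np.meshgrid(np.arange(box) - c, np.arange(box) - c, indexing="ij")
    # output p_obs -> input p_canon = R^-1 (p_obs - t)
    uin = R[0, 0] * (uu - dx) + R[1, 0] * (vv - dy) + c
    vin = R[0, 1] * (uu - dx) + R[1, 1] * (vv - dy) + c
    return ndimage.map_coordinates(image, [vin, uin], order=order,
                                   mode="constant", cval=0.0)


def align_segments(segments: SegmentStack, references: np.ndarray,
                   psi_step: float = 2.0,
                   max_shift: int | None = None,
                   score_threshold: float = 0.2) -> SegmentStack:
    """Assign each segment a reference, in-plane rotation and shift.

    Exhaustive search over a discretized psi grid; for each rotation the
    integer shift maximizing the FFT cross-correlation with the normalized
    reference is taken.  Updated records carry ``psi_deg, dx_px, dy_px,
    class_id, score``; scores below ``score_threshold`` are flagged in the
    ``reliable`` column.
    """
    references = np.asarray(references, dtype=float)
    if references.ndim == 2:
        references = references[None]
    if len(references) == 0:
        raise ValueError("empty references")
    box = segments.images.shape[1]
    if max_shift is None:
        max_shift = box // 3
    psis = np.arange(0.0, 360.0, psi_step)
    # pre-rotate references once per grid angle
    rot_refs = np.empty((len(references), len(psis), box, box))
    for r, ref in enumerate(references):
        ref = (ref - ref.mean()) / (ref.std() + 1e-30)
        for i, psi in enumerate(psis):
            rot_refs[r, i] = _rotate_about_center(ref, psi)
    recs = []
    n_pix = box * box
    for idx, img in enumerate(segments.images):
        x = (img - img.mean()) / (img.std() + 1e-30)
        Fx = np.fft.fft2(x)
        best = (-np.inf, 0.0, 0.0, 0.0, 0)
        for r in range(len(references)):
            for i, psi in enumerate(psis):
                cc = np.real(np.fft.ifft2(Fx * np.conj(np.fft.fft2(rot_refs[r, i]))))
                cc = np.fft.fftshift(cc) / n_pix
                mid = box // 2
                win = cc[mid - max_shift: mid + max_shift + 1,
                         mid - max_shift: mid + max_shift + 1]
                j = np.unravel_index(np.argmax(win), win.shape)
                score = float(win[j])
                if score > best[0]:
                    # cc peak at offset (dv, du) means the image equals the
                    # rotated reference shifted by that amount
                    best = (score, psi, float(j[1] - max_shift),
                            float(j[0] - max_shift), r)
        rec = segments.records.iloc[idx].to_dict()
        rec.update({"psi_deg": best[1], "dx_px": best[2], "dy_px": best[3],
                    "class_id": best[4], "score": best[0],
                    "reliable": best[0] >= score_threshold})
        recs.append(rec)
    return SegmentStack(images=segments.images, records=pd.DataFrame(recs),
                        imaging=segments.imaging, truth=segments.truth,
                        noiseless=segments.noiseless)


def composite_ca_filament(class_averages: np.ndarray,
                          records: pd.DataFrame,
                          pixel_size: float,
                          pad_px: int | None = None) -> CaFilament:
    """Paste inverse-transformed class averages into the filament frame.

    Each record's class average is carried through the forward transform
    (rotation psi then shift) -- the inverse of the alignment that produced
    the canonical class average -- and placed at the segment's position
    ``(cx_A, cz_A)``; overlapping pastes are averaged with equal weight
    and a support map is returned.
    """
    class_averages = np.asarray(class_averages, dtype=float)
    if class_averages.ndim == 2:
        class_averages = class_averages[None]
    if len(records) == 0:
        raise ValueError("no records to composite")
    box = class_averages.shape[1]
    if pad_px is None:
        pad_px = box // 2 + 2
    # the segment crop is centered at the recorded point minus the shift
    # jitter; pasting the forward-transformed class average there puts the
    # canonical content back at the recorded filament coordinate
    cx = records["cx_A"].to_numpy() / pixel_size - records["dx_px"].to_numpy()
    cz = records["cz_A"].to_numpy() / pixel_size - records["dy_px"].to_numpy()
    x0, x1 = cx.min() - pad_px, cx.max() + pad_px
    z0, z1 = cz.min() - pad_px, cz.max() + pad_px
    W = int(np.ceil(x1 - x0)) + box
    H = int(np.ceil(z1 - z0)) + box
    canvas = np.zeros((H, W))
    support = np.zeros((H, W))
    for i, rec in enumerate(records.itertuples()):
        ca = class_averages[int(rec.class_id)]
        patch = _rotate_about_center(ca, rec.psi_deg, rec.dx_px, rec.dy_px)
        mask = _rotate_about_center(np.ones_like(ca), rec.psi_deg,
                                    rec.dx_px, rec.dy_px) > 0.5
        r0 = int(round(cz[i] - z0))
        c0 = int(round(cx[i] - x0))
        canvas[r0:r0 + box, c0:c0 + box][mask] += patch[mask]
        support[r0:r0 + box, c0:c0 + box][mask] += 1
    out = np.zeros_like(canvas)
    nz = support > 0
    out[nz] = canvas[nz] / support[nz]
    length = float((records["arc_A"].max() - records["arc_A"].min()) + box * pixel_size)
    return CaFilament(image=out, support=support, pixel_size=pixel_size,
                      length=length)


def straighten_filament(image: np.ndarray, path: np.ndarray,
                        width: int) -> np.ndarray:
    """Resample an image along a spline centerline.

    ``path`` is an (M, 2) array of (col, row) control points in pixels.
    The output has one row per unit of arc length; each row is the
    bilinear profile perpendicular to the unit-speed path, ``width``
    pixels wide.  Raises if the path (or its perpendicular band) leaves
    the image, naming the offending control point.
    """
    image = np.asarray(image, dtype=float)
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or path.shape[1] != 2 or len(path) < 2:
        raise ValueError("path must be (M>=2, 2) of (col, row) points")
    H, W = image.shape
    for i, (c, r) in enumerate(path):
        if not (0 <= c < W and 0 <= r < H):
            raise ValueError(f"path control point {i} at ({c:.1f}, {r:.1f}) "
                             f"is outside the {W}x{H} image")
    t = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(path, axis=0), axis=1))])
    spl = CubicSpline(t, path, axis=0)
    tt = np.linspace(t[0], t[-1], max(2000, 10 * len(path)))
    pts = spl(tt)
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    n_rows = int(np.floor(arc[-1])) + 1
    s = np.arange(n_rows)
    cx = np.interp(s, arc, pts[:, 0])
    cy = np.interp(s, arc, pts[:, 1])
    d1 = spl(np.interp(s, arc, tt), 1)
    tang = d1 / np.linalg.norm(d1, axis=1, keepdims=True)
    # right-handed perpendicular: for a path running down the rows the
    # profile reads left to right
    normal = np.stack([tang[:, 1], -tang[:, 0]], axis=1)
    offs = np.arange(width) - (width - 1) / 2
    cols = cx[:, None] + offs[None, :] * normal[:, 0:1]
    rows = cy[:, None] + offs[None, :] * normal[:, 1:2]
    return ndimage.map_coordinates(image, [rows, cols], order=1,
                                   mode="constant", cval=0.0)


def estimate_centerline(image: np.ndarray, smooth: float | None = None,
                        threshold_frac: float = 0.1) -> np.ndarray:
    """Centerline of a roughly vertical filament image.

    Intensity-weighted column centroid per row, smoothed by a spline;
    rows with total intensity below ``threshold_frac`` of the maximum row
    are interpolated through.  Returns (M, 2) of (col, row) samples.
    """
    image = np.asarray(image, dtype=float)
    img = np.clip(image - image.mean(), 0, None)
    rowsum = img.sum(axis=1)
    good = rowsum > threshold_frac * rowsum.max()
    rows = np.arange(image.shape[0])
    cols = np.where(good, (img * np.arange(image.shape[1])[None, :]).sum(axis=1)
                    / np.maximum(rowsum, 1e-30), np.nan)
    valid = ~np.isnan(cols)
    if valid.sum() < 4:
        raise ValueError("not enough filament signal to estimate a centerline")
    if smooth is None:
        smooth = 2.0 * valid.sum()
    spl = UnivariateSpline(rows[valid], cols[valid], s=smooth)
    return np.stack([spl(rows[valid]), rows[valid]], axis=1)


def box_uniform_length(ca_filaments: list[CaFilament],
                       length: float) -> tuple[np.ndarray | None, int]:
    """Center-crop assembled filaments to a uniform axial length.

    Filaments shorter than ``length`` (Å) are excluded; the survivors are
    center-cropped along the axial (row) direction to exactly
    ``length / pixel_size`` rows and stacked.  Returns (stack, n_excluded);
    the stack is None when nothing survives.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    crops = []
    n_excluded = 0
    for ca in ca_filaments:
        n_rows = int(round(length / ca.pixel_size))
        if ca.image.shape[0] < n_rows or ca.length < length:
            n_excluded += 1
            continue
        r0 = (ca.image.shape[0] - n_rows) // 2
        crops.append(ca.image[r0:r0 + n_rows])
    if not crops:
        return None, n_excluded
    w = min(c.shape[1] for c in crops)
    crops = [c[:, (c.shape[1] - w) // 2:(c.shape[1] - w) // 2 + w] for c in crops]
    return np.stack(crops), n_excluded
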