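"""Transverse cross-section extraction and protofibril counting.

Cross-sections of a filament oriented along the z grid axis are thin slabs
integrated over a stated thickness.  Counting protofibrils reads the
intensity around an annulus at the protofibril-center radius as a function
of polar angle and counts prominent peaks of the circularly continuous
profile.  Under full Fourier sampling the five-protofibril architecture
shows five peaks ~72 degrees apart; a +-60 degree missing wedge smears the
annulus anisotropically and lowers the angular contrast -- the artifact
this module demonstrates (learned missing-wedge restoration is out of
scope; only the forward corruption is modelled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import find_peaks

from .synthetic_data import DensityMap

__all__ = [
    "CrossSectionStack",
    "extract_cross_sections",
    "average_fixed_alignment",
    "count_protofibrils",
    "angular_profile",
    "angular_contrast",
]


@dataclass
class CrossSectionStack:
    """Stack of square transverse sections sharing geometry."""

    sections: np.ndarray              # (n, size, size)
    thickness: float                  # Å per section
    pixel_size: float                 # Å
    z_positions: np.ndarray           # (n,) Å, section centers
    source_wedge: tuple[float, float] | None = None
    alignment: np.ndarray | None = None   # per-section rotation, degrees
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")

    def __len__(self) -> int:
        return len(self.sections)


def extract_cross_sections(density: DensityMap, axis_points: np.ndarray,
                           thickness: float, size: float) -> CrossSectionStack:
    """Integrate slabs perpendicular to the (z-aligned) filament axis.

    ``axis_points`` are (M, 3) centerline samples in Å (map frame); each
    yields one section of ``size`` x ``size`` Å centered on the axis,
    integrated over ``thickness`` along z.  Points whose slab or lateral
    window leaves the map are skipped with a warning.
    """
    axis_points = np.atleast_2d(np.asarray(axis_points, dtype=float))
    if thickness <= 0 or size <= 0:
        raise ValueError("thickness and size must be positive")
    v = density.voxel_size
    nz, ny, nx = density.grid.shape
    npx = int(round(size / v))
    half = (npx - 1) / 2.0
    sections, zs = [], []
    skipped = 0
    for pt in axis_points:
        # map frame -> voxel coordinates
        xv, yv, zv = (pt - np.asarray(density.origin)) / v
        # the slab is clamped to the grid; the point itself and the full
        # lateral window must lie inside
        z0 = max(0, int(np.floor(zv - thickness / (2 * v))))
        z1 = min(nz, int(np.ceil(zv + thickness / (2 * v))))
        if (not (0 <= zv <= nz - 1) or z1 <= z0
                or xv - half < 0 or xv + half > nx - 1
                or yv - half < 0 or yv + half > ny - 1):
            skipped += 1
            continue
        slab = density.grid[z0:z1].sum(axis=0) * v     # integrate along z
        offs = np.arange(npx) - half
        cols = xv + offs
        rows = yv + offs
        cc, rr = np.meshgrid(cols, rows)
        sections.append(ndimage.map_coordinates(slab, [rr, cc], order=1))
        zs.append(pt[2])
    if skipped:
        warnings.warn(f"{skipped} of {len(axis_points)} sections skipped "
                      "(too close to the map edge)")
    sections = np.asarray(sections) if sections else np.empty((0, npx, npx))
    return CrossSectionStack(sections=sections, thickness=thickness,
                             pixel_size=v, z_positions=np.asarray(zs),
                             source_wedge=density.wedge, n_skipped=skipped)


def average_fixed_alignment(stack: CrossSectionStack,
                            transforms_deg: np.ndarray) -> np.ndarray:
    """Rotate each section by its supplied angle and average.

    The transforms are given, never searched (fixed-alignment averaging):
    e.g. ``-k * twist`` per section undoes the helical rotation between
    sections spaced one rise apart, making the protofibril pattern add
    coherently instead of smearing into an annulus.
    """
    transforms_deg = np.asarray(transforms_deg, dtype=float)
    if len(transforms_deg) != len(stack):
        raise ValueError("one transform per section required")
    acc = np.zeros_like(stack.sections[0])
    for sec, ang in zip(stack.sections, transforms_deg):
        acc += ndimage.rotate(sec, ang, reshape=False, order=1)
    return acc / len(stack)


def angular_profile(image: np.ndarray, pixel_size: float,
                    annulus_radius: float, annulus_width: float,
                    angle_step_deg: float = 2.0,
                    n_radial: int = 7) -> tuple[np.ndarray, np.ndarray]:
    """Mean intensity around an annulus as a function of polar angle."""
    image = np.asarray(image, dtype=float)
    n = image.shape[0]
    c = (n - 1) / 2.0
    rmax_px = (annulus_radius + annulus_width / 2) / pixel_size
    if rmax_px > c:
        raise ValueError("annulus does not fit inside the image")
    angles = np.deg2rad(np.arange(0.0, 360.0, angle_step_deg))
    radii = np.linspace(annulus_radius - annulus_width / 2,
                        annulus_radius + annulus_width / 2, n_radial) / pixel_size
    aa, rr = np.meshgrid(angles, radii)
    cols = c + rr * np.cos(aa)
    rows = c + rr * np.sin(aa)
    vals = ndimage.map_coordinates(image, [rows, cols], order=1)
    return np.rad2deg(angles), vals.mean(axis=0)


def count_protofibrils(image: np.ndarray, pixel_size: float,
                       annulus_radius: float = 38.0,
                       annulus_width: float = 20.0,
                       angle_step_deg: float = 2.0,
                       prominence_frac: float = 0.2,
                       smooth_sigma_deg: float = 8.0
                       ) -> tuple[int, pd.DataFrame]:
    """Count protofibrils from the annular intensity profile.

    The circularly continuous angular profile is smoothed with a wrapped
    Gaussian of ``smooth_sigma_deg`` (a protofibril is a bundle of chains
    ~15-20 degrees wide at the annulus radius; smoothing merges its
    sub-peaks into one), then peaks with prominence of at least
    ``prominence_frac`` times (max - median) are counted; a flat
    (uniform) annulus yields zero.  Returns the count and the profile as
    a DataFrame (angle_deg, intensity).
    """
    ang, prof = angular_profile(image, pixel_size, annulus_radius,
                                annulus_width, angle_step_deg)
    if smooth_sigma_deg > 0:
        prof = ndimage.gaussian_filter1d(prof, smooth_sigma_deg / angle_step_deg,
                                         mode="wrap")
    df = pd.DataFrame({"angle_deg": ang, "intensity": prof})
    scale = prof.max() - np.median(prof)
    if scale <= 0 or not np.isfinite(scale):
        return 0, df
    n = len(prof)
    tiled = np.concatenate([prof, prof, prof])
    peaks, _ = find_peaks(tiled, prominence=prominence_frac * scale)
    count = int(np.sum((peaks >= n) & (peaks < 2 * n)))
    return count, df


def angular_contrast(image: np.ndarray, pixel_size: float,
                     annulus_radius: float = 38.0,
                     annulus_width: float = 20.0,
                     smooth_sigma_deg: float = 8.0) -> float:
    """Angular modulation contrast of the annular profile.

    Defined as the coefficient of variation (std/mean) of the smoothed
    angular profile: it measures how strongly the annulus intensity is
    modulated by discrete protofibrils.  Missing-wedge corruption smears
    the protofibril pattern and lowers it (clearly in the population mean
    over sections; individual sections fluctuate).
    """
    ang, prof = angular_profile(image, pixel_size, annulus_radius, annulus_width)
    if smooth_sigma_deg > 0:
        step = ang[1] - ang[0]
        prof = ndimage.gaussian_filter1d(prof, smooth_sigma_deg / step, mode="wrap")
    m = prof.mean()
    if m == 0:
        return 0.0
    return float(prof.std() / m)
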