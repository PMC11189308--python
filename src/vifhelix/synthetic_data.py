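"""Synthetic cryo-EM data generator for filament analysis.

Stands in for the microscopy pipeline that is out of scope here: it produces
ground-truth bead models of vimentin-like filaments, noisy 2D projection
segments with known per-segment transforms, 3D density maps, missing-wedge
corrupted volumes and bent filaments with known centerlines.  Everything is
deterministic given the seed recorded in :class:`ImagingParams`.

Image conventions
-----------------
Projection is a line integral along +y (the beam). Segment images are
``(box, box)`` arrays with the filament axis along axis 0 (rows = axial
coordinate v, columns = lateral coordinate u).  A segment record
``(psi, dx, dy)`` means the observed image is the canonical (axis-vertical)
view rotated by ``psi`` degrees and shifted by ``(dx, dy)`` pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from . import mrc
from .helix_core import HelicalParams
from .lattice_model import (
    LatticeModel,
    TetramerGeometry,
    assemble_filament,
    default_params,
)

__all__ = [
    "FilamentModel",
    "ImagingParams",
    "SegmentStack",
    "DensityMap",
    "build_filament_model",
    "project_segments",
    "render_density_map",
    "apply_missing_wedge",
    "bend_path",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FilamentModel:
    """Bead-cloud filament with ground-truth annotations.

    ``coords`` are in Å.  For a straight model the centerline is the z axis;
    a bent model carries its centerline as ``path`` (dense arc-length
    parametrized samples) together with the transported frames used to map
    the straight model onto it.
    """

    coords: np.ndarray            # (N, 3)
    mass: np.ndarray              # (N,) kDa
    chain_id: np.ndarray          # (N,) int (4*tetramer + chain)
    domain: np.ndarray            # (N,) str
    tetramer_index: np.ndarray    # (N,) int
    protofibril_index: np.ndarray  # (N,) int
    params: HelicalParams
    radius: float
    bead_sigma: float = 4.0
    n_protofibrils: int = 5
    path: np.ndarray | None = None        # (M, 3) centerline samples, arc-length spaced
    path_arc: np.ndarray | None = None    # (M,) arc coordinate of each sample
    frames: np.ndarray | None = None      # (M, 3, 3) rows = (n1, n2, tangent)
    straight_z: np.ndarray | None = None  # (N,) original axial coordinate if bent

    @classmethod
    def from_lattice(cls, lattice: LatticeModel) -> "FilamentModel":
        return cls(
            coords=lattice.coords.copy(),
            mass=lattice.mass.copy(),
            chain_id=4 * lattice.tetramer_index + lattice.chain,
            domain=lattice.domain.copy(),
            tetramer_index=lattice.tetramer_index.copy(),
            protofibril_index=lattice.protofibril_index.copy(),
            params=lattice.params,
            radius=lattice.geometry.filament_radius,
            bead_sigma=lattice.geometry.bead_sigma,
            n_protofibrils=lattice.n_protofibrils,
        )

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    @property
    def is_bent(self) -> bool:
        return self.path is not None

    def arc_length(self) -> float:
        """Contour length of the centerline spanned by the model."""
        if self.is_bent:
            return float(self.path_arc[-1] - self.path_arc[0])
        return float(np.ptp(self.coords[:, 2]))

    def centerline_point(self, s: float) -> np.ndarray:
        """Centerline position at arc coordinate ``s`` (s = 0 at the start)."""
        if not self.is_bent:
            z0 = self.coords[:, 2].min()
            return np.array([0.0, 0.0, z0 + s])
        return np.array([np.interp(s, self.path_arc, self.path[:, i])
                         for i in range(3)])

    def tangent_angle_deg(self, s: float) -> float:
        """In-plane (x-z) angle of the tangent relative to +z, degrees."""
        if not self.is_bent:
            return 0.0
        t = np.array([np.interp(s, self.path_arc, self.frames[:, 2, i])
                      for i in range(3)])
        return float(np.degrees(np.arctan2(t[0], t[2])))


@dataclass(frozen=True)
class ImagingParams:
    """Parameters of the synthetic projection imaging.

    ``noise_sigma`` is the additive white Gaussian noise level relative to
    the RMS of the noiseless signal.  No CTF is simulated.
    """

    pixel_size: float = 3.44      # Å / px
    box: int = 110                # px, even
    noise_sigma: float = 0.0
    projection_thickness: float = 220.0  # Å
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.box % 2 != 0 or self.box <= 0:
            raise ValueError("box must be a positive even integer")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class SegmentStack:
    """Stack of 2D segment images plus per-segment ground-truth records."""

    images: np.ndarray            # (n, box, box)
    records: pd.DataFrame
    imaging: ImagingParams
    truth: FilamentModel | None = None
    noiseless: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.images) != len(self.records):
            raise ValueError("records and images must have equal length")

    def __len__(self) -> int:
        return len(self.images)

    def write(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write images as an MRC stack and records as CSV."""
        prefix = Path(prefix)
        mpath = prefix.with_suffix(".mrc")
        cpath = prefix.with_suffix(".csv")
        mrc.write_mrc(mpath, self.images, voxel_size=self.imaging.pixel_size,
                      is_stack=True)
        self.records.to_csv(cpath, index=False)
        return mpath, cpath


@dataclass
class DensityMap:
    """3D density grid (z, y, x order) with voxel calibration."""

    grid: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    wedge: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    def write_mrc(self, path: str | Path) -> None:
        mrc.write_mrc(path, self.grid, voxel_size=self.voxel_size,
                      origin=self.origin)

    def transposed(self, axes: tuple[int, int, int]) -> "DensityMap":
        """Permute the grid axes (given in (z, y, x) order).

        Useful to bring a filament lying along y onto the z axis before
        cross-section extraction.  The wedge flag is dropped because the
        wedge orientation is defined in the original frame.
        """
        grid = np.transpose(self.grid, axes)
        # origin is stored (x, y, z); grid axes are (z, y, x)
        o_zyx = self.origin[::-1]
        new_o = tuple(o_zyx[a] for a in axes)[::-1]
        return DensityMap(grid=grid, voxel_size=self.voxel_size,
                          origin=new_o, wedge=None)

    @classmethod
    def read_mrc(cls, path: str | Path) -> "DensityMap":
        grid, voxel, origin = mrc.read_mrc(path)
        return cls(grid=grid, voxel_size=voxel, origin=origin)


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def build_filament_model(geometry: TetramerGeometry | None = None,
                         params: HelicalParams | None = None,
                         n_tetramers: int = 30,
                         n_protofibrils: int = 5,
                         include_tails: bool = True) -> FilamentModel:
    """Ground-truth filament bead model (straight, centerline = z axis)."""
    lattice = assemble_filament(n_tetramers, params or default_params(),
                                geometry, n_protofibrils=n_protofibrils,
                                include_tails=include_tails)
    return FilamentModel.from_lattice(lattice)


# ---------------------------------------------------------------------------
# 2D projection
# ---------------------------------------------------------------------------

def _splat2d(img: np.ndarray, u: np.ndarray, v: np.ndarray, mass: np.ndarray,
             sigma_px: float) -> None:
    """Accumulate normalized Gaussian blobs (in-place)."""
    if len(u) == 0:
        return
    w = max(2, int(np.ceil(4 * sigma_px)))
    offs = np.arange(-w, w + 1)
    iu = np.rint(u).astype(int)
    iv = np.rint(v).astype(int)
    gu = np.exp(-0.5 * ((iu[:, None] + offs[None, :] - u[:, None]) / sigma_px) ** 2)
    gv = np.exp(-0.5 * ((iv[:, None] + offs[None, :] - v[:, None]) / sigma_px) ** 2)
    norm = mass / (2 * np.pi * sigma_px ** 2)
    blob = norm[:, None, None] * gv[:, :, None] * gu[:, None, :]
    shape = blob.shape
    rows = np.broadcast_to(iv[:, None, None] + offs[None, :, None], shape)
    cols = np.broadcast_to(iu[:, None, None] + offs[None, None, :], shape)
    ok = (rows >= 0) & (rows < img.shape[0]) & (cols >= 0) & (cols < img.shape[1])
    np.add.at(img, (rows[ok], cols[ok]), blob[ok])


def render_projection(model: FilamentModel, imaging: ImagingParams,
                      center: tuple[float, float], psi: float = 0.0,
                      dx: float = 0.0, dy: float = 0.0) -> np.ndarray:
    """Analytic noiseless projection image of the model.

    ``center`` is the (x, z) position (Å) of the box center in the
    projection plane; the image is the canonical view rotated by ``psi``
    degrees and shifted by ``(dx, dy)`` pixels.  Beads outside the
    projection thickness (|y| > thickness/2) are excluded.
    """
    box, px = imaging.box, imaging.pixel_size
    half = box * px / 2
    cx, cz = center
    sel = np.abs(model.coords[:, 1]) <= imaging.projection_thickness / 2
    # generous axial pre-selection (rotation safe)
    sel &= (np.abs(model.coords[:, 2] - cz) <= half * 1.5 + 6 * model.bead_sigma)
    pts = model.coords[sel]
    mass = model.mass[sel]
    xu = pts[:, 0] - cx
    zv = pts[:, 2] - cz
    phi = np.deg2rad(psi)
    c, s = np.cos(phi), np.sin(phi)
    u = (c * xu - s * zv) / px + dx + box / 2 - 0.5
    v = (s * xu + c * zv) / px + dy + box / 2 - 0.5
    img = np.zeros((box, box))
    inside = (u > -4) & (u < box + 3) & (v > -4) & (v < box + 3)
    _splat2d(img, u[inside], v[inside], mass[inside], model.bead_sigma / px)
    return img


def project_segments(model: FilamentModel, imaging: ImagingParams,
                     n_segments: int, spacing: float,
                     psi_range: float = 360.0,
                     max_shift_px: float | None = None,
                     filament_id: int = 0) -> SegmentStack:
    """Sample overlapping segment images along the filament path.

    Segments are spaced ``spacing`` Å apart in arc length; each is the
    analytic projection of the beads, rotated by a random in-plane angle
    psi (plus the local tangent angle for bent filaments), shifted by
    random sub-box offsets and degraded with white Gaussian noise of
    standard deviation ``noise_sigma`` times the noiseless signal RMS.
    All randomness derives from ``imaging.seed``.
    """
    if model.n_beads == 0:
        raise ValueError("model is empty")
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    box, px = imaging.box, imaging.pixel_size
    margin = box * px / 2
    length = model.arc_length()
    run = (n_segments - 1) * spacing
    if run + 2 * margin > length:
        raise ValueError(
            f"{n_segments} segments at {spacing} Å spacing need "
            f"{run + 2 * margin:.0f} Å of filament; model has {length:.0f} Å")
    s0 = (length - run) / 2
    if max_shift_px is None:
        max_shift_px = box / 10

    rng = np.random.default_rng(imaging.seed)
    images = np.empty((n_segments, box, box))
    recs = []
    for i in range(n_segments):
        s = s0 + i * spacing
        cpt = model.centerline_point(s)
        tangent = model.tangent_angle_deg(s)
        psi = tangent + rng.uniform(-psi_range / 2, psi_range / 2)
        dx, dy = rng.uniform(-max_shift_px, max_shift_px, size=2)
        images[i] = render_projection(model, imaging, (cpt[0], cpt[2]),
                                      psi=psi, dx=dx, dy=dy)
        recs.append({"segment_id": i, "filament_id": filament_id,
                     "psi_deg": psi, "dx_px": dx, "dy_px": dy,
                     "arc_A": s, "class_id": 0,
                     "cx_A": cpt[0], "cz_A": cpt[2]})
    noiseless = images.copy()
    rms = float(np.sqrt(np.mean(noiseless ** 2)))
    if imaging.noise_sigma > 0 and rms > 0:
        images = images + rng.normal(0.0, imaging.noise_sigma * rms,
                                     size=images.shape)
    return SegmentStack(images=images, records=pd.DataFrame(recs),
                        imaging=imaging, truth=model, noiseless=noiseless)


# ---------------------------------------------------------------------------
# 3D rendering and the missing wedge
# ---------------------------------------------------------------------------

def render_density_map(model: FilamentModel, voxel_size: float,
                       box: tuple[int, int, int] | None = None,
                       pad: float = 25.0) -> DensityMap:
    """Gaussian-blob rendering of the bead model on a 3D grid.

    The integral of the map (sum * voxel^3) equals the total bead mass to
    well within 0.5%.  Grid axes are (z, y, x); the filament axis is z.
    """
    if model.n_beads == 0:
        if box is None:
            raise ValueError("box required for an empty model")
        return DensityMap(grid=np.zeros(box[::-1] if len(box) == 3 else box),
                          voxel_size=voxel_size)
    lo = model.coords.min(axis=0) - pad
    hi = model.coords.max(axis=0) + pad
    if box is None:
        nx, ny, nz = (int(np.ceil((hi[i] - lo[i]) / voxel_size)) for i in range(3))
    else:
        nx, ny, nz = box if len(box) == 3 else (box, box, box)
        need = hi - lo
        if need[0] > nx * voxel_size or need[1] > ny * voxel_size or need[2] > nz * voxel_size:
            raise ValueError("model does not fit in the requested box")
    center = 0.5 * (lo + hi)
    origin = center - 0.5 * np.array([nx, ny, nz]) * voxel_size
    grid = np.zeros((nz, ny, nx))
    sig = model.bead_sigma / voxel_size
    w = max(2, int(np.ceil(4 * sig)))
    offs = np.arange(-w, w + 1)
    pos = (model.coords - origin) / voxel_size - 0.5
    ip = np.rint(pos).astype(int)
    g = [np.exp(-0.5 * ((ip[:, i, None] + offs[None, :] - pos[:, i, None]) / sig) ** 2)
         for i in range(3)]
    norm = model.mass / ((2 * np.pi) ** 1.5 * (model.bead_sigma ** 3)) * voxel_size ** 3
    blob = (norm[:, None, None, None]
            * g[2][:, :, None, None] * g[1][:, None, :, None] * g[0][:, None, None, :])
    shape = blob.shape
    zz = np.broadcast_to(ip[:, 2, None, None, None] + offs[None, :, None, None], shape)
    yy = np.broadcast_to(ip[:, 1, None, None, None] + offs[None, None, :, None], shape)
    xx = np.broadcast_to(ip[:, 0, None, None, None] + offs[None, None, None, :], shape)
    ok = ((zz >= 0) & (zz < nz) & (yy >= 0) & (yy < ny) & (xx >= 0) & (xx < nx))
    np.add.at(grid, (zz[ok], yy[ok], xx[ok]), blob[ok])
    # convert to density per voxel so that sum * voxel^3 = mass
    grid /= voxel_size ** 3
    return DensityMap(grid=grid, voxel_size=voxel_size,
                      origin=tuple(origin))


def apply_missing_wedge(density: DensityMap,
                        tilt_range: tuple[float, float] = (-60.0, 60.0)) -> DensityMap:
    """Zero Fourier coefficients outside the sampled tilt range.

    Single-axis tomography convention: tilt axis x, beam along z at zero
    tilt.  A frequency (kx, ky, kz) is sampled iff the tilt angle
    ``atan2(kz, ky)`` (folded into (-90, 90]) lies within the tilt range;
    the unsampled double wedge in the ky-kz plane is set to zero.
    Idempotent; a (-90, 90) range leaves the map unchanged.
    """
    tmin, tmax = tilt_range
    if not (-90 <= tmin < tmax <= 90):
        raise ValueError("tilt range must satisfy -90 <= tmin < tmax <= 90")
    nz, ny, nx = density.grid.shape
    kz = np.fft.fftfreq(nz)[:, None]
    ky = np.fft.fftfreq(ny)[None, :]
    ang = np.degrees(np.arctan2(kz, ky))
    ang = ((ang + 90.0) % 180.0) - 90.0          # fold Friedel mates together
    eps = 1e-9
    sampled = (ang >= tmin - eps) & (ang <= tmax + eps)
    if tmax >= 90 - eps:
        sampled |= ang <= -90 + eps
    F = np.fft.fftn(density.grid)
    F *= sampled[:, :, None]
    out = np.real(np.fft.ifftn(F))
    return DensityMap(grid=out, voxel_size=density.voxel_size,
                      origin=density.origin, wedge=(float(tmin), float(tmax)))


# ---------------------------------------------------------------------------
# bent filaments
# ---------------------------------------------------------------------------

def bend_path(model: FilamentModel, path_control_points: np.ndarray,
              n_samples: int = 2000) -> FilamentModel:
    """Map a straight model onto a smooth 3D path.

    The path is an arc-length parametrized cubic spline through the control
    points; beads are carried by a parallel-transported orthonormal frame,
    so the bead cloud is rigid in each cross-section and the centerline arc
    length is preserved.  Raises if the path is shorter than the model or
    if the curvature radius drops below twice the filament radius.
    """
    if model.is_bent:
        raise ValueError("model is already bent")
    cps = np.asarray(path_control_points, dtype=float)
    if cps.ndim != 2 or cps.shape[1] != 3 or len(cps) < 2:
        raise ValueError("path_control_points must be (M>=2, 3)")
    t = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(cps, axis=0), axis=1))])
    spl = CubicSpline(t, cps, axis=0)
    # arc-length reparametrization on a dense grid
    tt = np.linspace(t[0], t[-1], max(n_samples, 20 * len(cps)))
    pts = spl(tt)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    length = arc[-1]
    model_len = float(np.ptp(model.coords[:, 2]))
    if length < model_len:
        raise ValueError(
            f"path length {length:.0f} Å shorter than model span {model_len:.0f} Å")

    d1 = spl(tt, 1)
    d2 = spl(tt, 2)
    speed = np.linalg.norm(d1, axis=1)
    kappa = np.linalg.norm(np.cross(d1, d2), axis=1) / np.maximum(speed, 1e-12) ** 3
    min_radius = 1.0 / max(kappa.max(), 1e-12)
    if min_radius < 2 * model.radius:
        i = int(np.argmax(kappa))
        raise ValueError(
            f"curvature radius {min_radius:.0f} Å at arc {arc[i]:.0f} Å is below "
            f"2 x filament radius ({2 * model.radius:.0f} Å)")

    # parallel-transported frames (n1, n2, tangent)
    T = d1 / speed[:, None]
    frames = np.empty((len(tt), 3, 3))
    n1 = np.array([1.0, 0.0, 0.0])
    n1 = n1 - np.dot(n1, T[0]) * T[0]
    if np.linalg.norm(n1) < 1e-6:
        n1 = np.array([0.0, 1.0, 0.0]) - np.dot([0.0, 1.0, 0.0], T[0]) * T[0]
    n1 /= np.linalg.norm(n1)
    for i in range(len(tt)):
        if i:
            n1 = n1 - np.dot(n1, T[i]) * T[i]
            n1 /= np.linalg.norm(n1)
        n2 = np.cross(T[i], n1)
        frames[i] = np.stack([n1, n2, T[i]])

    z0 = model.coords[:, 2].min()
    s = model.coords[:, 2] - z0
    C = np.stack([np.interp(s, arc, pts[:, i]) for i in range(3)], axis=1)
    N1 = np.stack([np.interp(s, arc, frames[:, 0, i]) for i in range(3)], axis=1)
    N2 = np.stack([np.interp(s, arc, frames[:, 1, i]) for i in range(3)], axis=1)
    new_coords = C + model.coords[:, 0:1] * N1 + model.coords[:, 1:2] * N2
    return replace(model, coords=new_coords, path=pts, path_arc=arc,
                   frames=frames, straight_z=model.coords[:, 2].copy())
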