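"""Modular tetramer -> protofibril -> filament lattice model.

The vimentin filament is modelled as a helical lattice of A11 tetramers
(two antiparallel, half-staggered dimers with aligned 1B domains).  Each
tetramer is a coarse-grained bead cloud with per-bead domain annotations and
masses; tetramer ``k`` is tetramer 0 under the k-th power of the helical
screw operator.  Protofibril membership is ``k mod n_protofibrils``.

Geometry calibration
--------------------
The in-wall rod span of every dimer is ``2 * n_protofibrils * rise``
(425 Å for the default 5-start / 42.5 Å lattice), so that each rod covers
exactly two protofibril repeats and the cross-section chain count is an
exact lattice consequence: 4 chains for a lone tetramer, 6 for two
overlapping tetramers of one protofibril, 8 for the full protofibril
repeat, and 8 per protofibril (40 total) for the mature filament.  The
1A-side N-terminal end of the rod continues beyond the wall span to
``(cte_span + nte_pair_separation) / 2`` = 470 Å, which puts the paired
1A-1B NTEs 290 Å apart and makes the A_CN overlap between consecutive
tetramers of a protofibril ~32.5 Å.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .helix_core import (
    HelicalParams,
    apply_operator,
    mass_per_length,
    monomer_mass_kda,
    params_from_units,
    tetramer_mass_kda,
)

__all__ = [
    "DomainMap",
    "TetramerGeometry",
    "TetramerTemplate",
    "LatticeModel",
    "default_params",
    "build_tetramer",
    "assemble_filament",
    "assemble_protofibril",
    "cross_section_chain_count",
    "minimal_tetramer_count",
    "geometry_report",
    "export_model",
]

N_RESIDUES = 466


def default_params() -> HelicalParams:
    """The measured filament symmetry: rise 42.5 Å, twist 73.7 deg."""
    return params_from_units(360.0 / 73.7, 42.5)


@dataclass(frozen=True)
class DomainMap:
    """Residue intervals (1-based, inclusive) of the vimentin domains."""

    head: tuple[int, int] = (1, 85)
    coil1_1A1B: tuple[int, int] = (86, 253)
    linker_L12: tuple[int, int] = (254, 264)
    coil2_2A2B: tuple[int, int] = (265, 411)
    tail: tuple[int, int] = (412, 466)
    conserved_1A: tuple[int, int] = (100, 125)
    conserved_2B: tuple[int, int] = (380, 411)

    def __post_init__(self) -> None:
        parts = [self.head, self.coil1_1A1B, self.linker_L12,
                 self.coil2_2A2B, self.tail]
        for (a, b) in parts + [self.conserved_1A, self.conserved_2B]:
            if a > b:
                raise ValueError(f"empty residue interval {a}-{b}")
        # contiguous, non-overlapping cover of 1..466
        if parts[0][0] != 1 or parts[-1][1] != N_RESIDUES:
            raise ValueError("domains must cover residues 1-466")
        for (a, b), (c, d) in zip(parts, parts[1:]):
            if c != b + 1:
                raise ValueError("domains must be contiguous and non-overlapping")
        if not (self.coil1_1A1B[0] <= self.conserved_1A[0]
                and self.conserved_1A[1] <= self.coil1_1A1B[1]):
            raise ValueError("conserved 1A must nest inside 1A-1B")
        if not (self.coil2_2A2B[0] <= self.conserved_2B[0]
                and self.conserved_2B[1] <= self.coil2_2A2B[1]):
            raise ValueError("conserved 2B must nest inside 2A-2B")

    @property
    def rod(self) -> tuple[int, int]:
        return (self.coil1_1A1B[0], self.coil2_2A2B[1])


@dataclass(frozen=True)
class TetramerGeometry:
    """Axial and radial calibration of the coarse-grained tetramer.

    All lengths in Å.  Defaults follow the measured filament: the tetramer
    extends ~65 nm between the CTEs of the flanking 2A-2B dimers, the paired
    1A-1B NTEs sit ~29 nm apart, each 2A-2B bundle spans ~21 nm, and the
    bead envelope reaches the 55 Å filament radius.
    """

    cte_span: float = 650.0
    nte_pair_separation: float = 290.0
    coil2_length: float = 210.0
    protofibril_center_radius: float = 38.0
    filament_radius: float = 55.0
    beads_per_chain: int = 48
    chain_offset: float = 8.0       # half-spacing of the 2x2 chain bundle
    lumen_radius: float = 8.0       # radius of the head-domain (luminal) strings
    bead_sigma: float = 4.0         # Gaussian bead sigma used when rendering

    def __post_init__(self) -> None:
        for name in ("cte_span", "nte_pair_separation", "coil2_length",
                     "protofibril_center_radius", "filament_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cte_span <= self.nte_pair_separation:
            raise ValueError("cte_span must exceed nte_pair_separation")
        if self.coil2_length >= self.rod_length:
            raise ValueError("coil2_length exceeds the dimer rod span")
        if self.beads_per_chain < 8:
            raise ValueError("beads_per_chain must be >= 8")

    @property
    def rod_length(self) -> float:
        """Axial span of one dimer rod (CTE to 1A NTE tip)."""
        return 0.5 * (self.cte_span + self.nte_pair_separation)


@dataclass
class TetramerTemplate:
    """Bead cloud of one tetramer placed at protofibril angle 0.

    Arrays are parallel over beads.  ``chain`` is 0..3 (chains 0,1 form the
    dimer whose 2A-2B CTE sits at z = 0 and points +z; chains 2,3 the
    antiparallel dimer with its CTE at z = cte_span).  ``domain`` holds one
    of head/coil1_1A1B/linker_L12/coil2_2A2B/tail.
    """

    coords: np.ndarray          # (N, 3) Å
    chain: np.ndarray           # (N,) int
    domain: np.ndarray          # (N,) str
    res_center: np.ndarray      # (N,) float, representative residue number
    mass: np.ndarray            # (N,) kDa
    chain_cte_z: np.ndarray     # (4,) Å
    chain_direction: np.ndarray  # (4,) +1 if NTE above CTE else -1
    geometry: TetramerGeometry = field(default=None)
    domains: DomainMap = field(default=None)

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    def rod_z_of_residue(self, res: float, chain: int) -> float:
        """Axial position of a rod residue on a given chain."""
        lo, hi = self.domains.rod
        frac = (hi - res) / (hi - lo)
        z_local = self.geometry.rod_length * frac
        if self.chain_direction[chain] > 0:
            return z_local
        return self.geometry.cte_span - z_local


def build_tetramer(geometry: TetramerGeometry | None = None,
                   domains: DomainMap | None = None,
                   include_tails: bool = True) -> TetramerTemplate:
    """Build the coarse-grained A11 tetramer bead template.

    Two antiparallel dimers, half-staggered so their 1A-1B sections overlap
    in the middle of the tetramer; flanking 2A-2B bundles at the CTE ends;
    head beads as an axial string near the lumen; tail beads at the 2A-2B
    CTEs, displaced toward the neighbouring protofibril.
    """
    geometry = geometry or TetramerGeometry()
    domains = domains or DomainMap()
    res_mass = monomer_mass_kda() / N_RESIDUES
    R = geometry.protofibril_center_radius
    du = geometry.chain_offset

    coords, chain_ids, dom_labels, res_centers, masses = [], [], [], [], []

    rod_lo, rod_hi = domains.rod
    n_rod_res = rod_hi - rod_lo + 1
    nb = geometry.beads_per_chain
    edges = np.linspace(rod_lo - 0.5, rod_hi + 0.5, nb + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    res_per_bead = n_rod_res / nb

    def domain_of(res: float) -> str:
        for name in ("head", "coil1_1A1B", "linker_L12", "coil2_2A2B", "tail"):
            a, b = getattr(domains, name)
            if a - 0.5 <= res <= b + 0.5:
                return name
        return "tail"

    chain_cte_z = np.empty(4)
    chain_dir = np.empty(4, dtype=int)
    # chain -> (dimer, lateral side): dimer A = chains 0,1 ; dimer B = 2,3
    for c in range(4):
        dimer = c // 2
        side = 1 if c % 2 == 0 else -1
        direction = 1 if dimer == 0 else -1
        cte_z = 0.0 if dimer == 0 else geometry.cte_span
        chain_cte_z[c] = cte_z
        chain_dir[c] = direction
        # perpendicular offsets: dimers side by side tangentially, the two
        # chains of a dimer split radially
        u = side * du                            # radial
        v = (-du if dimer == 0 else du)          # tangential
        x0, y0 = R + u, v

        # rod beads: linear residue -> z map from the CTE (z = cte_z) to the
        # 1A NTE tip (rod_length away, along `direction`)
        frac = (rod_hi - centers) / (rod_hi - rod_lo)
        z = cte_z + direction * geometry.rod_length * frac
        for zi, ri in zip(z, centers):
            coords.append((x0, y0, zi))
            chain_ids.append(c)
            dom_labels.append(domain_of(ri))
            res_centers.append(ri)
            masses.append(res_per_bead * res_mass)

        # head beads: luminal axial string beyond the 1A NTE tip
        n_head = 6
        h_lo, h_hi = domains.head
        head_res = np.linspace(h_hi, h_lo, n_head)
        nte_tip = cte_z + direction * geometry.rod_length
        head_z = nte_tip + direction * np.linspace(5.0, 60.0, n_head)
        # small per-chain angular offset so the four strings do not coincide
        ang = np.deg2rad(25.0 * (c - 1.5))
        hx = geometry.lumen_radius * np.cos(ang)
        hy = geometry.lumen_radius * np.sin(ang)
        head_mass = (h_hi - h_lo + 1) * res_mass / n_head
        for zi, ri in zip(head_z, head_res):
            coords.append((hx, hy, zi))
            chain_ids.append(c)
            dom_labels.append("head")
            res_centers.append(ri)
            masses.append(head_mass)

        # tail beads: annotation beads at the CTE z, displaced half-way
        # toward the adjacent protofibril (lateral contact sites)
        if include_tails:
            n_tail = 3
            t_lo, t_hi = domains.tail
            tail_res = np.linspace(t_lo, t_hi, n_tail)
            tail_ang = np.deg2rad(36.0 * side)
            tr = R + geometry.chain_offset
            tx, ty = tr * np.cos(tail_ang), tr * np.sin(tail_ang)
            tail_z = cte_z - direction * np.linspace(0.0, 20.0, n_tail)
            tail_mass = (t_hi - t_lo + 1) * res_mass / n_tail
            for zi, ri in zip(tail_z, tail_res):
                coords.append((tx, ty, zi))
                chain_ids.append(c)
                dom_labels.append("tail")
                res_centers.append(ri)
                masses.append(tail_mass)

    return TetramerTemplate(
        coords=np.asarray(coords, dtype=float),
        chain=np.asarray(chain_ids, dtype=int),
        domain=np.asarray(dom_labels, dtype=object),
        res_center=np.asarray(res_centers, dtype=float),
        mass=np.asarray(masses, dtype=float),
        chain_cte_z=chain_cte_z,
        chain_direction=chain_dir,
        geometry=geometry,
        domains=domains,
    )


@dataclass
class LatticeModel:
    """A placed multi-tetramer filament (or single-protofibril) model."""

    template: TetramerTemplate
    params: HelicalParams
    symmetry_indices: np.ndarray        # (T,) operator power of each tetramer
    n_protofibrils: int
    coords: np.ndarray                  # (T*N, 3)
    tetramer_index: np.ndarray          # (T*N,)
    protofibril_index: np.ndarray       # (T*N,)
    chain: np.ndarray                   # (T*N,) 0..3 within tetramer
    domain: np.ndarray
    res_center: np.ndarray
    mass: np.ndarray
    include_tails: bool = True

    @property
    def geometry(self) -> TetramerGeometry:
        return self.template.geometry

    @property
    def domains(self) -> DomainMap:
        return self.template.domains

    @property
    def n_tetramers(self) -> int:
        return len(self.symmetry_indices)

    @property
    def protofibril_spacing(self) -> float:
        """Axial offset between successive tetramers of one protofibril."""
        return self.n_protofibrils * self.params.rise

    @property
    def wall_span(self) -> float:
        """In-wall rod span of each dimer, used for chain counting."""
        return 2.0 * self.protofibril_spacing

    def z_extent(self) -> tuple[float, float]:
        return float(self.coords[:, 2].min()), float(self.coords[:, 2].max())

    def cte_extent(self) -> float:
        """CTE-to-CTE axial extent of the model."""
        ctes = []
        for k in self.symmetry_indices:
            ctes.extend(self.template.chain_cte_z + k * self.params.rise)
        ctes = np.asarray(ctes)
        return float(ctes.max() - ctes.min())

    def chain_wall_intervals(self) -> np.ndarray:
        """(T*4, 4) rows of (zmin, zmax, protofibril, global_chain_id).

        The interval is the in-wall rod span of the chain; head/tail beads
        and the luminal NTE extension beyond the wall span are excluded
        (they are annotations, not rod chains crossing the section).
        """
        rows = []
        L = self.wall_span
        for t, k in enumerate(self.symmetry_indices):
            dz = k * self.params.rise
            pf = int(k) % self.n_protofibrils
            for c in range(4):
                z0 = self.template.chain_cte_z[c] + dz
                z1 = z0 + self.template.chain_direction[c] * L
                rows.append((min(z0, z1), max(z0, z1), pf, 4 * t + c))
        return np.asarray(rows, dtype=float)


def assemble_filament(n_tetramers: int,
                      params: HelicalParams | None = None,
                      geometry: TetramerGeometry | None = None,
                      domains: DomainMap | None = None,
                      n_protofibrils: int = 5,
                      stride: int = 1,
                      include_tails: bool = True) -> LatticeModel:
    """Replicate the tetramer template by helical symmetry powers.

    Tetramer ``j`` is the template under operator power ``k = j * stride``;
    ``stride = 1`` builds the filament, ``stride = n_protofibrils`` a single
    protofibril (see :func:`assemble_protofibril`).
    """
    if n_tetramers < 1:
        raise ValueError("n_tetramers must be >= 1")
    if n_protofibrils < 1:
        raise ValueError("n_protofibrils must be >= 1")
    params = params or default_params()
    template = build_tetramer(geometry, domains, include_tails=include_tails)
    geom = template.geometry
    spacing = n_protofibrils * params.rise
    wall = 2.0 * spacing
    if wall > geom.rod_length:
        raise ValueError(
            f"wall span 2*n_protofibrils*rise = {wall:.1f} Å exceeds the dimer "
            f"rod length {geom.rod_length:.1f} Å; geometry and symmetry are "
            "inconsistent")
    if wall <= geom.cte_span / 2:
        raise ValueError("wall span too short: antiparallel dimers would not overlap")

    ks = np.arange(n_tetramers) * stride
    coords, tet_idx = [], []
    for j, k in enumerate(ks):
        coords.append(apply_operator(template.coords, params, int(k)))
        tet_idx.append(np.full(template.n_beads, j))
    coords = np.concatenate(coords)
    tet_idx = np.concatenate(tet_idx)
    pf_idx = (ks[tet_idx] % n_protofibrils).astype(int)
    tile = lambda a: np.concatenate([a] * n_tetramers)
    return LatticeModel(
        template=template,
        params=params,
        symmetry_indices=ks,
        n_protofibrils=n_protofibrils,
        coords=coords,
        tetramer_index=tet_idx,
        protofibril_index=pf_idx,
        chain=tile(template.chain),
        domain=tile(template.domain),
        res_center=tile(template.res_center),
        mass=tile(template.mass),
        include_tails=include_tails,
    )


def assemble_protofibril(n_tetramers: int,
                         params: HelicalParams | None = None,
                         geometry: TetramerGeometry | None = None,
                         domains: DomainMap | None = None,
                         n_starts: int = 5) -> LatticeModel:
    """A single protofibril of an ``n_starts``-protofibril lattice.

    Successive tetramers are related by operator power ``n_starts``
    (axial spacing ``n_starts * rise`` = the ~21 nm protofibril repeat).
    """
    return assemble_filament(n_tetramers, params, geometry, domains,
                             n_protofibrils=n_starts, stride=n_starts)


def cross_section_chain_count(model: LatticeModel, z: float) -> tuple[int, dict[int, int]]:
    """Rod chains whose in-wall axial span contains ``z``.

    Returns the total count and a per-protofibril breakdown.  Head and tail
    beads never contribute; intervals are half-open ``[zmin, zmax)``.
    """
    zmin, zmax = model.z_extent()
    if not (zmin <= z <= zmax):
        raise ValueError(f"z = {z} outside model extent [{zmin}, {zmax}]")
    rows = model.chain_wall_intervals()
    inside = (rows[:, 0] <= z) & (z < rows[:, 1])
    breakdown = {p: 0 for p in range(model.n_protofibrils)}
    for pf in rows[inside, 2].astype(int):
        breakdown[pf] += 1
    return int(inside.sum()), breakdown


def _z_grid(model: LatticeModel, n: int = 400) -> np.ndarray:
    zmin, zmax = model.z_extent()
    # irrational-ish offset keeps the grid off exact lattice boundaries
    off = 0.1234567 * model.params.rise
    return np.linspace(zmin + off, zmax - off, n)


def minimal_tetramer_count(target: str,
                           params: HelicalParams | None = None,
                           geometry: TetramerGeometry | None = None,
                           domains: DomainMap | None = None,
                           n_protofibrils: int = 5,
                           max_tetramers: int = 40) -> int:
    """Smallest tetramer count achieving a named occupancy target.

    Targets
    -------
    ``"full_filament"``
        Some transverse plane crosses 8 rod chains in each protofibril
        (40 chains for the 5-start lattice).
    ``"protofibril_repeat"``
        Some plane of a lone protofibril crosses 8 chains.
    ``"unit_length"``
        Every protofibril holds at least one tetramer and some common plane
        crosses all of them (one tetramer per protofibril).
    """
    if target not in ("full_filament", "protofibril_repeat", "unit_length"):
        raise ValueError(f"unknown target {target!r}")
    for n in range(1, max_tetramers + 1):
        if target == "protofibril_repeat":
            model = assemble_protofibril(n, params, geometry, domains,
                                         n_starts=n_protofibrils)
        else:
            model = assemble_filament(n, params, geometry, domains,
                                      n_protofibrils=n_protofibrils)
        rows = model.chain_wall_intervals()
        zs = _z_grid(model)
        inside = (rows[:, 0][None, :] <= zs[:, None]) & (zs[:, None] < rows[:, 1][None, :])
        if target == "protofibril_repeat":
            if (inside.sum(axis=1) >= 8).any():
                return n
        elif target == "full_filament":
            per_pf = np.stack([
                inside[:, rows[:, 2] == p].sum(axis=1)
                for p in range(n_protofibrils)], axis=1)
            if (per_pf >= 8).all(axis=1).any():
                return n
        else:  # unit_length
            occupied = {int(k) % n_protofibrils for k in model.symmetry_indices}
            if len(occupied) < n_protofibrils:
                continue
            per_pf = np.stack([
                inside[:, rows[:, 2] == p].sum(axis=1)
                for p in range(n_protofibrils)], axis=1)
            if (per_pf >= 4).all(axis=1).any():
                return n
    raise RuntimeError(f"target {target!r} not reached within {max_tetramers} tetramers")


def _interlock_sites(model: LatticeModel) -> np.ndarray:
    """z positions of conserved-1A / conserved-2B coincidence sites.

    Along one protofibril, the conserved 1A stretch near the NTE of a
    tetramer's forward dimer meets the conserved 2B stretch at the CTE of
    its predecessor's backward dimer; the site is the midpoint of the
    overlap of the two residue stretches' axial intervals.
    """
    t = model.template
    dom = model.domains
    rise = model.params.rise
    pf0 = [int(k) for k in model.symmetry_indices
           if int(k) % model.n_protofibrils == int(model.symmetry_indices[0]) % model.n_protofibrils]
    pf0.sort()
    sites = []
    for k_prev, k_next in zip(pf0, pf0[1:]):
        # conserved 2B on the predecessor's +z-pointing CTE (dimer B, chain 2)
        z2b = sorted(t.rod_z_of_residue(r, 2) + k_prev * rise
                     for r in dom.conserved_2B)
        # conserved 1A near the successor's dimer-A NTE (chain 0)
        z1a = sorted(t.rod_z_of_residue(r, 0) + k_next * rise
                     for r in dom.conserved_1A)
        lo, hi = max(z2b[0], z1a[0]), min(z2b[1], z1a[1])
        if hi > lo:
            sites.append(0.5 * (lo + hi))
    return np.asarray(sites)


def geometry_report(model: LatticeModel) -> dict:
    """Geometric and stoichiometric summary of an assembled model.

    Fields that need at least three tetramers in one protofibril
    (interlock spacing) are reported as None when unavailable.
    """
    geom = model.geometry
    zc = 0.5 * sum(model.z_extent())
    total, breakdown = cross_section_chain_count(model, zc)
    sites = _interlock_sites(model)
    interlock = float(np.diff(sites).mean()) if len(sites) >= 2 else None
    a_cn = model.protofibril_spacing + geom.nte_pair_separation / 2 - geom.cte_span / 2
    radial = np.hypot(model.coords[:, 0], model.coords[:, 1])
    outer_d = 2.0 * (float(radial.max()) + 2.0 * geom.bead_sigma)
    return {
        "n_tetramers": model.n_tetramers,
        "n_protofibrils": model.n_protofibrils,
        "rise_A": model.params.rise,
        "twist_deg": model.params.twist,
        "pitch_A": model.params.pitch,
        "interlock_spacing_A": interlock,
        "a_cn_overlap_A": float(a_cn),
        "axial_extent_A": float(np.ptp(model.coords[:, 2])),
        "cte_extent_A": model.cte_extent(),
        "outer_diameter_A": outer_d,
        "mass_per_length_kDa_nm": mass_per_length(tetramer_mass_kda(),
                                                  model.params.rise / 10.0),
        "chains_in_cross_section": total,
        "chains_per_protofibril": breakdown,
    }


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

_CHAIN_ALPHABET = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
                   "abcdefghijklmnopqrstuvwxyz0123456789")


def export_model(model: LatticeModel, path: str | Path, fmt: str | None = None,
                 voxel_size: float = 3.44) -> list[Path]:
    """Export the bead model as pseudo-atom PDB file(s) or an MRC map.

    PDB: one CA pseudo-atom per bead, residue number from the bead's
    representative residue, chain id encoding (tetramer, chain).  Models
    with more than 62 distinct chains are split into several files plus a
    JSON manifest.  Returns the list of files written.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "mrc":
        from .synthetic_data import FilamentModel, render_density_map
        fm = FilamentModel.from_lattice(model)
        dm = render_density_map(fm, voxel_size=voxel_size)
        dm.write_mrc(path)
        return [path]
    if fmt != "pdb":
        raise ValueError(f"unknown export format {fmt!r}")

    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    global_chain = 4 * model.tetramer_index + model.chain
    uniq = np.unique(global_chain)
    n_files = int(np.ceil(len(uniq) / len(_CHAIN_ALPHABET)))
    files: list[Path] = []
    manifest = []
    for i in range(n_files):
        sel_chains = uniq[i * 62:(i + 1) * 62]
        mask = np.isin(global_chain, sel_chains)
        n = int(mask.sum())
        arr = struc.AtomArray(n)
        arr.coord = model.coords[mask].astype(np.float32)
        arr.atom_name = np.full(n, "CA")
        arr.res_name = np.full(n, "ALA")
        arr.element = np.full(n, "C")
        arr.hetero = np.zeros(n, dtype=bool)
        arr.res_id = np.rint(model.res_center[mask]).astype(int)
        local = {g: _CHAIN_ALPHABET[j] for j, g in enumerate(sel_chains)}
        arr.chain_id = np.array([local[g] for g in global_chain[mask]])
        arr.set_annotation("b_factor", model.mass[mask].astype(np.float32))
        out = path if n_files == 1 else path.with_name(
            f"{path.stem}_part{i + 1}{path.suffix}")
        f = pdb.PDBFile()
        f.set_structure(arr)
        f.write(str(out))
        files.append(out)
        manifest.append({"file": out.name,
                         "chains": {local[g]: int(g) for g in sel_chains}})
    if n_files > 1:
        mpath = path.with_suffix(".manifest.json")
        mpath.write_text(json.dumps(manifest, indent=1))
        files.append(mpath)
    return files
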