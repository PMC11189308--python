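"""Helical-symmetry arithmetic shared by every other module.

A helical assembly is described by the axial translation (rise, ``h_r``) and
rotation (twist) relating consecutive asymmetric units.  The number of units
per helical pitch ``n = P / h_r`` is real-valued in general; for vimentin
intermediate filaments the asymmetric unit is the tetramer and ``n`` is close
to, but not exactly, the protofibril count of 5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "HelicalParams",
    "SymmetryOperator",
    "params_from_units",
    "initial_symmetry_estimate",
    "mass_per_length",
    "apply_operator",
    "VIMENTIN_SEQUENCE",
    "monomer_mass_kda",
    "tetramer_mass_kda",
]

# Human vimentin (UniProt P08670), 466 residues.  The monomer mass derived
# from this sequence (~53.65 kDa) fixes the tetramer mass used for the
# mass-per-length bookkeeping.
VIMENTIN_SEQUENCE = (
    "MSTRSVSSSSYRRMFGGPGTASRPSSSRSYVTTSTRTYSLGSALRPSTSRSLYASSPGGVYATRSSAVRL"
    "RSSVPGVRLLQDSVDFSLADAINTEFKNTRTNEKVELQELNDRFANYIDKVRFLEQQNKILLAELEQLKG"
    "QGKSRLGDLYEEEMRELRRQVDQLTNDKARVEVERDNLAEDIMRLREKLQEEMLQREEAENTLQSFRQDV"
    "DNASLARLDLERKVESLQEEIAFLKKLHEEEIQELQAQIQEQHVQIDVDVSKPDLTAALRDVRQQYESVA"
    "AKNLQEAEEWYKSKFADLSEAANRNNDALRQAKQESTEYRRQVQSLTCEVDALKGTNESLERQMREMEEN"
    "FAVEAANYQDTIGRLQDEIQNMKEEMARHLREYQDLLNVKMALDIEIATYRKLLEGEESRISLPLPNFSS"
    "LNLRETNLDSLPLVDTHSKRTLLIKTVETRDGQVINETSQHHDDLE"
)


def monomer_mass_kda(sequence: str = VIMENTIN_SEQUENCE) -> float:
    """Average molecular weight of one monomer in kDa."""
    from Bio.SeqUtils import molecular_weight

    return molecular_weight(sequence, seq_type="protein") / 1000.0


def tetramer_mass_kda(sequence: str = VIMENTIN_SEQUENCE) -> float:
    """Mass of the A11 tetramer (four monomers) in kDa."""
    return 4.0 * monomer_mass_kda(sequence)


_REL_TOL = 1e-9


@dataclass(frozen=True)
class HelicalParams:
    """Rise / twist / pitch / units-per-pitch description of a helix.

    Parameters
    ----------
    rise : float
        Axial translation per asymmetric unit, in Å.
    twist : float
        Rotation per asymmetric unit, in degrees (0 < twist <= 360).
    pitch : float
        Axial length of one helical pitch, in Å.
    units_per_pitch : float
        Number of asymmetric units per pitch (``n``); real-valued.
    handedness : int
        +1 for a right-handed helix (default, arbitrary: the data do not
        determine the hand), -1 for left-handed.
    """

    rise: float
    twist: float
    pitch: float
    units_per_pitch: float
    handedness: int = 1

    def __post_init__(self) -> None:
        if not (self.rise > 0 and self.pitch > 0):
            raise ValueError("rise and pitch must be positive")
        if not (0 < self.twist <= 360):
            raise ValueError("twist must satisfy 0 < twist <= 360 degrees")
        if self.handedness not in (-1, 1):
            raise ValueError("handedness must be +1 or -1")
        if not np.isclose(self.pitch, self.units_per_pitch * self.rise, rtol=1e-9, atol=0):
            raise ValueError("pitch != units_per_pitch * rise")
        if not np.isclose(self.twist, 360.0 / self.units_per_pitch, rtol=1e-9, atol=0):
            raise ValueError("twist != 360 / units_per_pitch")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "rise_A": self.rise,
            "twist_deg": self.twist,
            "pitch_A": self.pitch,
            "n": self.units_per_pitch,
            "handedness": self.handedness,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HelicalParams":
        return cls(
            rise=d["rise_A"],
            twist=d["twist_deg"],
            pitch=d["pitch_A"],
            units_per_pitch=d["n"],
            handedness=d.get("handedness", 1),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "HelicalParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def params_from_units(units_per_pitch: float, rise: float, handedness: int = 1) -> HelicalParams:
    """Build :class:`HelicalParams` from ``n`` and the rise.

    ``twist = 360 / n`` and ``pitch = n * rise``.  ``n`` may be non-integral
    (e.g. 4.8824 for vimentin filaments); no rounding is applied.
    """
    if units_per_pitch <= 0:
        raise ValueError("units_per_pitch must be positive")
    if rise <= 0:
        raise ValueError("rise must be positive")
    return HelicalParams(
        rise=rise,
        twist=360.0 / units_per_pitch,
        pitch=units_per_pitch * rise,
        units_per_pitch=units_per_pitch,
        handedness=handedness,
    )


def initial_symmetry_estimate(n_protofibrils: int, axial_period: float) -> HelicalParams:
    """First-guess symmetry from a protofibril count and an axial period.

    An N-protofibril architecture translates directly to a twist of 360/N
    degrees, and an axial period of ``d`` Å to a rise of d/N: e.g. five
    protofibrils and the classic ~210 Å intermediate-filament periodicity
    give 72° / 42 Å.
    """
    if int(n_protofibrils) != n_protofibrils or n_protofibrils < 1:
        raise ValueError("n_protofibrils must be a positive integer")
    if axial_period <= 0:
        raise ValueError("axial_period must be positive")
    return params_from_units(float(n_protofibrils), axial_period / n_protofibrils)


def mass_per_length(asymmetric_unit_mass: float, rise_nm: float) -> float:
    """Linear mass density in kDa/nm.

    The mass per length of a helical filament is the asymmetric-unit mass
    divided by the helical rise (one unit is added per rise step).

    Parameters
    ----------
    asymmetric_unit_mass : float
        Mass of one asymmetric unit in kDa (for vimentin, the ~214.6 kDa
        tetramer).
    rise_nm : float
        Helical rise in nm.
    """
    if asymmetric_unit_mass <= 0:
        raise ValueError("asymmetric_unit_mass must be positive")
    if rise_nm <= 0:
        raise ValueError("rise must be positive")
    return asymmetric_unit_mass / rise_nm


@dataclass(frozen=True)
class SymmetryOperator:
    """The k-th power of the helical screw operator.

    rotation is in degrees about z (sign includes handedness), translation
    in Å along z.
    """

    rotation: float
    translation: float
    repeat_index: int = 1

    @classmethod
    def from_params(cls, params: HelicalParams, k: int) -> "SymmetryOperator":
        return cls(
            rotation=(k * params.twist * params.handedness),
            translation=k * params.rise,
            repeat_index=k,
        )

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        if points.ndim == 1:
            points = points[None, :]
        if points.shape[-1] != 3 or not np.all(np.isfinite(points)):
            raise ValueError("points must be finite (N, 3) coordinates")
        phi = np.deg2rad(self.rotation)
        c, s = np.cos(phi), np.sin(phi)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        out = points @ rot.T
        out[:, 2] += self.translation
        return out

    def compose(self, other: "SymmetryOperator") -> "SymmetryOperator":
        return SymmetryOperator(
            rotation=self.rotation + other.rotation,
            translation=self.translation + other.translation,
            repeat_index=self.repeat_index + other.repeat_index,
        )


def apply_operator(points: np.ndarray, params: HelicalParams, k: int) -> np.ndarray:
    """Rotate points by k*twist about z and translate by k*rise along z."""
    return SymmetryOperator.from_params(params, k)(points)
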