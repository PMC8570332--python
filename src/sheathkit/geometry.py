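"""Geometry of an n-start helical tail sheath.

A contractile phage tail sheath is a lattice of identical protein subunits
arranged on ``n_start`` interleaved helical strands around the tail tube.
Within one strand, consecutive subunits are related by a screw operation:
a rotation by ``twist_deg`` about the tail axis and a translation by
``rise_ang`` along it.  The ``n_start`` strands are related by the C_n point
group.  For phage G the sheath is a six-start, right-handed helix with C6
symmetry; the two physiological states are

* non-contracted: twist 20.57 deg, rise 41.53 A, outer/inner diameter 240/60 A
* contracted:     twist 27.13 deg, rise 18.89 A, outer/inner diameter 320/120 A

on a 4500 A tail.  This module provides the exact lattice model and every
scalar derived from it (pitches, subunit counts, contracted length,
contraction deltas and ratios).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from typing import List, Tuple

import pandas as pd

from .errors import DegenerateHelixError, IncompatibleStatesError

__all__ = [
    "HelicalSymmetry",
    "SheathGeometry",
    "SubunitPose",
    "phage_g_geometry",
    "pitch_continuous",
    "pitch_integer_turn",
    "subunits_per_strand",
    "total_subunits",
    "contracted_length",
    "contraction_delta",
    "apply_contraction",
    "contraction_ratio",
    "build_lattice",
]

_HAND_SIGN = {"right": +1, "left": -1}


@dataclass(frozen=True)
class HelicalSymmetry:
    """Helical symmetry of one strand plus the axial point group.

    Parameters
    ----------
    twist_deg : rotation per subunit along one strand, in (0, 360) degrees.
    rise_ang : axial translation per subunit along one strand, in Angstrom.
    n_start : number of interleaved strands.
    handedness : ``"right"`` if azimuth increases with +z (baseplate-to-head),
        else ``"left"``.
    point_group_order : order of the rotational symmetry C_n about the axis.
    """

    twist_deg: float
    rise_ang: float
    n_start: int = 1
    handedness: str = "right"
    point_group_order: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.twist_deg < 360.0:
            raise DegenerateHelixError(
                f"twist must be in (0, 360) deg, got {self.twist_deg}"
            )
        if self.rise_ang <= 0:
            raise DegenerateHelixError(f"rise must be > 0 A, got {self.rise_ang}")
        if self.n_start < 1 or self.point_group_order < 1:
            raise ValueError("n_start and point_group_order must be >= 1")
        if self.handedness not in _HAND_SIGN:
            raise ValueError(f"handedness must be 'right' or 'left', got {self.handedness!r}")

    @property
    def hand_sign(self) -> int:
        """+1 for right-handed (azimuth grows with +z), -1 for left-handed."""
        return _HAND_SIGN[self.handedness]


@dataclass(frozen=True)
class SheathGeometry:
    """A sheath state: diameters, tail length and strand symmetry."""

    state: str
    outer_diameter_ang: float
    inner_diameter_ang: float
    tail_length_ang: float
    symmetry: HelicalSymmetry

    def __post_init__(self) -> None:
        if not self.outer_diameter_ang > self.inner_diameter_ang > 0:
            raise ValueError("need outer_diameter > inner_diameter > 0")
        if self.tail_length_ang <= 0:
            raise ValueError("tail_length_ang must be > 0")

    @property
    def mid_radius_ang(self) -> float:
        """Radial position of subunit centers: mid-point of inner/outer radius."""
        return (self.outer_diameter_ang + self.inner_diameter_ang) / 4.0


@dataclass(frozen=True)
class SubunitPose:
    """Cylindrical position of one sheath subunit in the lattice."""

    strand_index: int
    layer_index: int
    z_ang: float
    azimuth_deg: float
    radius_ang: float


def phage_g_geometry(state: str = "non_contracted") -> SheathGeometry:
    """Return the packaged phage G sheath geometry for one state.

    ``state`` is ``"non_contracted"`` or ``"contracted"``; values come from the
    packaged ``phage_g_states.csv`` fixture.
    """
    with resources.files("sheathkit.data").joinpath("phage_g_states.csv").open() as fh:
        df = pd.read_csv(fh)
    row = df[df["state"] == state]
    if row.empty:
        raise KeyError(f"unknown phage G state {state!r}; choose from {list(df['state'])}")
    r = row.iloc[0]
    sym = HelicalSymmetry(
        twist_deg=float(r["twist_deg"]),
        rise_ang=float(r["rise_ang"]),
        n_start=int(r["n_start"]),
        handedness=str(r["handedness"]),
        point_group_order=int(r["point_group_order"]),
    )
    return SheathGeometry(
        state=state,
        outer_diameter_ang=float(r["outer_diameter_ang"]),
        inner_diameter_ang=float(r["inner_diameter_ang"]),
        tail_length_ang=float(r["tail_length_ang"]),
        symmetry=sym,
    )


def pitch_continuous(sym: HelicalSymmetry) -> float:
    """Axial distance for one full 360 deg turn of a strand: rise * 360 / twist."""
    return sym.rise_ang * 360.0 / sym.twist_deg


def pitch_integer_turn(sym: HelicalSymmetry) -> float:
    """Strand pitch under the completed-turns convention: rise * floor(360/twist).

    Reported helical pitches for contractile sheaths are often quoted as the
    rise times the whole number of subunits completed per turn rather than the
    continuous 360/twist (phage G: 41.53 A x 17 = 706.01 A non-contracted,
    18.89 A x 13 = 245.57 A contracted).  ``pitch_continuous`` gives the
    standard continuous value.
    """
    turns = math.floor(360.0 / sym.twist_deg)
    if turns < 1:
        raise DegenerateHelixError(
            f"twist {sym.twist_deg} deg completes no full subunit turn"
        )
    return sym.rise_ang * turns


def subunits_per_strand(tail_length_ang: float, rise_ang: float) -> int:
    """Number of whole subunits fitting on one strand: floor(length / rise)."""
    if tail_length_ang <= 0 or rise_ang <= 0:
        raise ValueError("tail length and rise must be > 0")
    return int(math.floor(tail_length_ang / rise_ang))


def total_subunits(geometry: SheathGeometry) -> int:
    """Total sheath subunits: subunits per strand times the number of strands."""
    per_strand = subunits_per_strand(geometry.tail_length_ang, geometry.symmetry.rise_ang)
    return per_strand * geometry.symmetry.n_start


def contracted_length(n_per_strand: int, contracted_rise_ang: float) -> float:
    """Axial length of a fully contracted sheath of ``n_per_strand`` subunits."""
    if n_per_strand <= 0 or contracted_rise_ang <= 0:
        raise ValueError("subunit count and rise must be > 0")
    return n_per_strand * contracted_rise_ang


def contraction_delta(
    a: HelicalSymmetry, b: HelicalSymmetry
) -> Tuple[float, float]:
    """(rise compression, twist increase) from state ``a`` to state ``b``.

    ``a`` is the non-contracted and ``b`` the contracted state; returns
    ``(a.rise - b.rise, b.twist - a.twist)`` so both numbers are positive for a
    physical contraction.  For phage G's states this reproduces the classical
    22.6 A / 6.6 deg per-subunit change (after rounding to one decimal; see
    :func:`round_delta`).
    """
    if a.n_start != b.n_start or a.handedness != b.handedness:
        raise IncompatibleStatesError(
            "contraction delta requires equal n_start and handedness: "
            f"{a.n_start}/{a.handedness} vs {b.n_start}/{b.handedness}"
        )
    return (a.rise_ang - b.rise_ang, b.twist_deg - a.twist_deg)


def round_delta(delta: Tuple[float, float], ndigits: int = 1) -> Tuple[float, float]:
    """Round a (rise, twist) delta to ``ndigits`` decimals (reporting helper)."""
    return (round(delta[0], ndigits), round(delta[1], ndigits))


def apply_contraction(a: HelicalSymmetry, delta: Tuple[float, float]) -> HelicalSymmetry:
    """Apply a (rise compression, twist increase) delta to symmetry ``a``."""
    drise, dtwist = delta
    return replace(a, rise_ang=a.rise_ang - drise, twist_deg=a.twist_deg + dtwist)


def contraction_ratio(contracted_len: float, extended_len: float) -> float:
    """Length ratio contracted/extended; warns (not raises) if ratio > 1."""
    if contracted_len <= 0 or extended_len <= 0:
        raise ValueError("lengths must be > 0")
    if contracted_len > extended_len:
        warnings.warn(
            f"contracted length {contracted_len} exceeds extended {extended_len}; "
            "ratio > 1 (noisy atlas entry?)",
            stacklevel=2,
        )
    return contracted_len / extended_len


def build_lattice(
    geometry: SheathGeometry, azimuth0_deg: float = 0.0
) -> List[SubunitPose]:
    """Enumerate every subunit pose of the sheath lattice.

    Strand ``s`` contributes one subunit per layer ``k``:

    * ``z = k * rise``
    * ``azimuth = azimuth0 + s * 360/n_start + h * k * twist`` (mod 360),
      with ``h = +1`` for a right-handed helix (azimuth grows with +z),
    * ``radius`` at the sheath mid-radius ``(outer + inner) / 4``.
    """
    sym = geometry.symmetry
    n_layers = subunits_per_strand(geometry.tail_length_ang, sym.rise_ang)
    h = sym.hand_sign
    radius = geometry.mid_radius_ang
    poses: List[SubunitPose] = []
    for s in range(sym.n_start):
        strand_phase = azimuth0_deg + s * 360.0 / sym.n_start
        for k in range(n_layers):
            poses.append(
                SubunitPose(
                    strand_index=s,
                    layer_index=k,
                    z_ang=k * sym.rise_ang,
                    azimuth_deg=(strand_phase + h * k * sym.twist_deg) % 360.0,
                    radius_ang=radius,
                )
            )
    return poses
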