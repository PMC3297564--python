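"""Helical-wheel arithmetic for transmembrane-helix insertions/deletions.

An alpha helix has ~3.5 residues per turn, so each residue spans
360/3.5 ~= 103 degrees of the helical wheel.  Deleting a residue in the
transmembrane helix rotates everything C-terminal of it — in particular the
intracellular box-1 region and its associated JAK2 kinase — counterclockwise
by one step in top view; inserting a residue rotates it clockwise by the
same amount.  Seven residues are exactly two full turns, so indel effects
repeat with period 7.

Each receptor's JAK2 is modeled by a single top-view azimuth measured from
the direction facing the partner receptor: 0 means the kinase points
straight at its partner.  In the loosely bound pre-activation state the two
JAK2s are oriented away from mutual facing; the default baseline offset
places each one half a wheel step (180/3.5 ~= 51.4 deg) counterclockwise of
facing.  Under that baseline a three-residue deletion and a four-residue
insertion — which produce the same net rotation modulo 360 — both land the
kinases exactly face to face, while zero indels leaves them outside the
facing tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sampling import wrap_angle

DEGREES_PER_RESIDUE = 360.0 / 3.5
DEFAULT_OFFSET = 180.0 / 3.5        # half a wheel step from facing
DEFAULT_TOLERANCE = 30.0


def indel_rotation(n: int, degrees_per_residue: float = DEGREES_PER_RESIDUE) -> float:
    """Top-view rotation (counterclockwise positive) caused by ``n`` indels.

    ``n`` < 0 means deletions (counterclockwise, positive rotation);
    ``n`` > 0 insertions (clockwise).  Reduced into (-180, 180].
    """
    if abs(int(n)) > 10:
        raise ValueError("|n| <= 10 expected for an indel count")
    return float(wrap_angle(-int(n) * degrees_per_residue))


@dataclass(frozen=True)
class HelicalWheelState:
    """Indel state of one receptor's transmembrane helix."""

    indels: int = 0
    degrees_per_residue: float = DEGREES_PER_RESIDUE
    initial_offset: float = DEFAULT_OFFSET

    @property
    def rotation(self) -> float:
        return indel_rotation(self.indels, self.degrees_per_residue)

    @property
    def azimuth(self) -> float:
        """JAK2 azimuth from facing the partner receptor, in (-180, 180]."""
        return float(wrap_angle(self.initial_offset + self.rotation))


@dataclass(frozen=True)
class ProximityResult:
    in_proximity: bool
    relative_angle: float        # worst deviation from mutual facing, deg
    azimuth_1: float
    azimuth_2: float


def jak2_proximity(
    state1: HelicalWheelState,
    state2: HelicalWheelState,
    tolerance: float = DEFAULT_TOLERANCE,
) -> ProximityResult:
    """Are the two JAK2s oriented face to face within ``tolerance`` degrees?

    The relative facing angle reported is the larger of the two kinases'
    deviations from pointing straight at the partner; both must be inside
    the tolerance for transphosphorylation-ready proximity.
    """
    if abs(state1.degrees_per_residue - state2.degrees_per_residue) > 1e-9:
        raise ValueError("states must share degrees_per_residue")
    a1, a2 = state1.azimuth, state2.azimuth
    rel = max(abs(a1), abs(a2))
    return ProximityResult(
        in_proximity=bool(rel <= tolerance),
        relative_angle=float(rel),
        azimuth_1=a1,
        azimuth_2=a2,
    )


def wheel_table(
    n_min: int = -6,
    n_max: int = 6,
    initial_offset: float = DEFAULT_OFFSET,
    tolerance: float = DEFAULT_TOLERANCE,
    symmetric: bool = True,
) -> pd.DataFrame:
    """Rotation and proximity for each indel count (symmetric on both TMHs)."""
    rows = []
    for n in range(n_min, n_max + 1):
        s = HelicalWheelState(indels=n, initial_offset=initial_offset)
        partner = s if symmetric else HelicalWheelState(indels=0, initial_offset=initial_offset)
        prox = jak2_proximity(s, partner, tolerance=tolerance)
        rows.append({
            "indels": n,
            "rotation_deg": s.rotation,
            "jak2_azimuth_deg": s.azimuth,
            "in_proximity": prox.in_proximity,
        })
    return pd.DataFrame(rows)
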