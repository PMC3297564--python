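"""Synthetic two-subunit complexes with known geometry and contact structure.

The toy complex stands in for a deposited 1:2 cytokine-receptor structure:
a *fixed* subunit (a cytokine-like disk carrying an irregular field of
contact studs, plus an R1 receptor with N1/C1 rod subdomains) and a
*mobile* subunit (an R2 receptor with N2/C2 rods, a central knob, and studs
mirroring the fixed field).  Design constraints, in the order they drove
the geometry:

* Lock-and-key: each fixed stud faces its mobile partner across a 3.0-3.8 A
  gap.  The stud field is aperiodic (golden-angle azimuths, ruggedly varied
  radii and depths), so no rotation or translation can re-form the contact
  set away from the native registration — spinning the mobile subunit by
  chi both breaks contacts (the outer studs sweep out of their partners'
  contact range) and eventually clashes (deep studs of one side hit studs
  of the other).  As the subunits separate along the interface normal the
  clash lock releases before the contacts fully decay, which is exactly
  the sharp rotational-freedom transition the transient-complex analysis
  detects.
* Subdomain axes: C1 and C2 run along +z ("up", away from the
  membrane-proximal C-terminal end), N2 along -x, and the N1 direction is
  set from the requested native gamma; the requested native phi tilts C2
  in the y-z plane.  The interface normal is ~ -x, so the native body axis
  e, the dimer frame, and the ground-truth angles are all known by
  construction.
* Obstruction: a flat arc of fixed-side atoms flanking the C2 rod on its
  low-phi side (the side a scissor rotation below the native phi swings
  into), spanning the pull-out range, so the transient ensemble is biased
  toward phi above native — the loop-induced asymmetry mechanism of real
  interfaces.  A matching polar sector is kept free of studs so the arc
  and the C2 swing path stay clear of the contact field.

All pseudo-atoms are carbons with ~1.9 A spacing along rods, one residue
per atom, numbered from the N-terminal end of each rod so the
terminal-residue rule used for axis signs applies unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, EmptyInterfaceError, NativeClashError
from .structure import ComplexModel, RigidSubunit, SubdomainAssignment

ATOM_SPACING = 1.9

# polar sector (deg, in the lab y-z plane) kept free of studs: the C2 rod
# hangs at 270 and the obstruction arc lives beside it
_RESERVED_SECTOR = (235.0, 345.0)
_GOLDEN_ANGLE = 137.508


@dataclass
class ToyComplexSpec:
    """Construction parameters of the toy complex."""

    atoms_per_subdomain: int = 30
    rod_length: float = 24.0
    rod_radius: float = 1.2
    gamma_native: float = 160.0     # target native self-rotation angle, deg
    phi_native: float = 0.0         # target native scissor angle, deg
    interface_studs: int = 12       # stud sites = native interface depth
    stud_spacing: float = 7.0       # min lateral separation of stud sites, A
    stud_radius_range: tuple = (5.0, 24.0)
    stud_depth_range: tuple = (0.0, 9.0)
    contact_gap_range: tuple = (3.0, 3.8)
    obstruction: bool = False
    separation: float = 0.0         # extra rigid shift of the mobile subunit (-x)
    jitter: float = 0.04            # coordinate noise, A
    seed: int = 0
    clash_distance: float = 2.8     # used only for the native sanity check
    interface_cutoff: float = 5.0

    def __post_init__(self):
        if self.rod_length <= 0:
            raise ConfigurationError("rod_length must be positive")
        if self.atoms_per_subdomain < 10:
            raise ConfigurationError("need >= 10 atoms per subdomain")
        if self.interface_studs < 4:
            raise ConfigurationError("need >= 4 interface studs")
        lo, hi = self.contact_gap_range
        if lo < self.clash_distance + 0.1:
            raise ConfigurationError(
                "contact gaps must clear the clash distance with margin"
            )
        if hi >= self.interface_cutoff:
            raise ConfigurationError("contact gaps must be inside the interface cutoff")


@dataclass
class ToyGroundTruth:
    """What the generator knows exactly about its own complex."""

    native_gamma: float
    native_phi: float
    native_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    obstruction: bool = False


def _perpendicular(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    return u, np.cross(axis, u)


def make_rod_subdomain(
    n_atoms: int,
    length: float,
    radius: float,
    axis: np.ndarray,
    base: np.ndarray,
    start_residue: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Helix-like tube of pseudo-atoms along ``axis``.

    The rod occupies ``base`` to ``base + length * axis``; residue numbering
    starts at the far (N-terminal) end, so the C-to-N terminal-centroid rule
    recovers ``axis`` as the signed long axis.  Returns (coords,
    residue_index); consecutive atoms are ~1.9 A apart.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    base = np.asarray(base, dtype=float)
    u, v = _perpendicular(axis)
    ds = length / (n_atoms - 1)
    lateral = np.sqrt(max(ATOM_SPACING ** 2 - ds ** 2, 0.0))
    omega = 2.0 * np.arcsin(min(lateral / (2.0 * radius), 1.0)) if radius > 0 else 0.0
    i = np.arange(n_atoms)
    s = length * (1.0 - i / (n_atoms - 1))        # N-term (residue start) at s=length
    coords = (
        base[None, :]
        + s[:, None] * axis[None, :]
        + radius * (np.cos(omega * i)[:, None] * u[None, :]
                    + np.sin(omega * i)[:, None] * v[None, :])
    )
    return coords, start_residue + i


def _ring(radius: float, count: int, phase: float, x: float) -> np.ndarray:
    a = np.deg2rad(phase + 360.0 * np.arange(count) / count)
    return np.column_stack([np.full(count, x), radius * np.cos(a), radius * np.sin(a)])


def _polar(x: float, radius: float, ang_deg: float) -> np.ndarray:
    a = np.deg2rad(ang_deg)
    return np.array([x, radius * np.cos(a), radius * np.sin(a)])


def _stud_pattern(spec: ToyComplexSpec):
    """Aperiodic stud sites: (y-z position, depth, contact gap) per stud.

    Low-discrepancy sequences (golden-angle azimuth, irrational-multiplier
    radius/depth/gap) give a frozen, irregular, reproducible pattern;
    candidates inside the reserved polar sector or too close to an accepted
    site are skipped.
    """
    rlo, rhi = spec.stud_radius_range
    dlo, dhi = spec.stud_depth_range
    glo, ghi = spec.contact_gap_range
    pts, depth, gap = [], [], []
    k = 0
    while len(pts) < spec.interface_studs and k < 10000:
        theta = (k * _GOLDEN_ANGLE) % 360.0
        r = rlo + (rhi - rlo) * np.sqrt(((k * 0.6180339887) + 0.13) % 1.0)
        d = dlo + (dhi - dlo) * (((k * 0.7548776662) + 0.41) % 1.0)
        g = glo + (ghi - glo) * (((k * 0.3247179572) + 0.77) % 1.0)
        k += 1
        if _RESERVED_SECTOR[0] < theta < _RESERVED_SECTOR[1]:
            continue
        p = np.array([r * np.cos(np.deg2rad(theta)), r * np.sin(np.deg2rad(theta))])
        if all(np.linalg.norm(p - q) >= spec.stud_spacing for q in pts):
            pts.append(p)
            depth.append(d)
            gap.append(g)
    return np.array(pts), np.array(depth), np.array(gap)


def _native_pairs_bruteforce(fixed: np.ndarray, mobile: np.ndarray,
                             cutoff: float) -> list[tuple[int, int, float]]:
    """Literal double-loop interface listing (independent ground truth)."""
    pairs = []
    for i in range(len(fixed)):
        d = np.sqrt(((mobile - fixed[i]) ** 2).sum(axis=1))
        for j in np.flatnonzero(d < cutoff):
            pairs.append((i, int(j), float(d[j])))
    pairs.sort(key=lambda p: (p[2], p[0], p[1]))
    return pairs


def make_toy_complex(spec: ToyComplexSpec) -> tuple[ComplexModel, ToyGroundTruth]:
    """Build the toy 1:2 complex and its exact ground truth.

    Raises :class:`NativeClashError` if the requested parameters put the
    native placement inside the clash distance and
    :class:`EmptyInterfaceError` if they leave no interface pairs.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.atoms_per_subdomain
    L = spec.rod_length
    rr = spec.rod_radius
    g_ang = np.deg2rad(spec.gamma_native)
    p_ang = np.deg2rad(spec.phi_native)

    # ---- fixed subunit -----------------------------------------------------
    body = np.vstack([
        np.array([[0.0, 0.0, 0.0]]),
        _ring(3.0, 8, 0.0, 0.0), _ring(6.0, 12, 15.0, 0.0),
        _ring(9.5, 15, 7.0, 0.0), _ring(13.0, 20, 3.0, 0.0),
        _ring(16.5, 24, 11.0, 0.0), _ring(20.0, 28, 5.0, 0.0),
        np.array([[-2.0, 0.0, 0.0]]),
        _ring(6.0, 12, 0.0, -2.0), _ring(13.0, 20, 9.0, -2.0),
        _ring(20.0, 28, 0.0, -2.0),
    ])
    pts, depth, gap = _stud_pattern(spec)
    fx_tip = np.column_stack([-4.0 - depth, pts])
    fstuds = np.vstack([fx_tip, fx_tip + [1.8, 0, 0], fx_tip + [3.6, 0, 0]])

    fence = np.zeros((0, 3))
    if spec.obstruction:
        # arc beside C2 on the low-phi side, spanning the pull-out range
        fence = np.array([
            _polar(x, 13.5, ang)
            for ang in (250.0, 238.0, 226.0, 214.0, 202.0)
            for x in (-19.5, -21.4, -23.3, -25.2, -27.1)
        ])

    c1, c1_res = make_rod_subdomain(n, L, rr, [0, 0, 1.0], [13.0, 0.0, -2.0 - L],
                                    start_residue=101)
    d_n1 = np.array([-np.cos(g_ang), np.sin(g_ang), 0.0])
    n1, n1_res = make_rod_subdomain(n, L, rr, d_n1, [14.0, 0.0, 2.0], start_residue=1)

    fixed_coords = np.vstack([body, fstuds, fence, n1, c1])
    n_nonrod = len(body) + len(fstuds) + len(fence)
    fixed_res = np.concatenate([np.arange(1, n_nonrod + 1), n1_res, c1_res])
    fixed_chain = np.array(
        ["A"] * (len(body) + len(fstuds)) + ["B"] * len(fence)
        + ["B"] * n + ["B"] * n, dtype=object)

    # ---- mobile subunit ----------------------------------------------------
    mb_tip = np.column_stack([fx_tip[:, 0] - gap, pts])
    mstuds = np.vstack([mb_tip, mb_tip - [1.8, 0, 0], mb_tip - [3.6, 0, 0]])
    knob = np.array([[-5.2, 0.0, 0.0], [-6.8, 0.0, 0.0], [-8.4, 0.0, 0.0]])
    d_c2 = np.array([0.0, -np.sin(p_ang), np.cos(p_ang)])
    c2_top = np.array([-20.0, 0.0, -2.0])
    c2, c2_res = make_rod_subdomain(n, L, rr, d_c2, c2_top - L * d_c2, start_residue=101)
    n2, n2_res = make_rod_subdomain(n, L, rr, [-1.0, 0.0, 0.0], [-17.0, 0.0, 2.5],
                                    start_residue=1)

    mobile_coords = np.vstack([n2, c2, knob, mstuds])
    mobile_res = np.concatenate([n2_res, c2_res,
                                 np.arange(301, 301 + len(knob) + len(mstuds))])
    mobile_chain = np.array(["C"] * len(mobile_coords), dtype=object)

    fixed_coords = fixed_coords + rng.normal(0.0, spec.jitter, fixed_coords.shape)
    mobile_coords = mobile_coords + rng.normal(0.0, spec.jitter, mobile_coords.shape)
    mobile_coords[:, 0] -= spec.separation

    fixed = RigidSubunit(
        name="fixed", role="fixed", coords=fixed_coords,
        atom_id=np.arange(1, len(fixed_coords) + 1), residue_index=fixed_res,
        residue_name=["TOY"] * len(fixed_coords), atom_name=["C"] * len(fixed_coords),
        element=["C"] * len(fixed_coords), chain_tag=fixed_chain)
    mobile = RigidSubunit(
        name="mobile", role="mobile", coords=mobile_coords,
        atom_id=np.arange(1, len(mobile_coords) + 1), residue_index=mobile_res,
        residue_name=["TOY"] * len(mobile_coords), atom_name=["C"] * len(mobile_coords),
        element=["C"] * len(mobile_coords), chain_tag=mobile_chain)

    subdomains = {
        "N1": SubdomainAssignment("N1", "B", 1, n),
        "C1": SubdomainAssignment("C1", "B", 101, 100 + n),
        "N2": SubdomainAssignment("N2", "C", 1, n),
        "C2": SubdomainAssignment("C2", "C", 101, 100 + n),
    }
    model = ComplexModel(fixed=fixed, mobile=mobile, subdomains=subdomains)

    dmin = np.inf
    for i in range(0, len(fixed_coords), 64):
        chunk = fixed_coords[i:i + 64]
        d = np.linalg.norm(chunk[:, None, :] - mobile.coords[None, :, :], axis=2)
        dmin = min(dmin, float(d.min()))
    if dmin < spec.clash_distance:
        raise NativeClashError(
            f"toy spec produces a native clash (min cross distance {dmin:.2f} A)"
        )

    pairs = _native_pairs_bruteforce(fixed.coords, mobile.coords, spec.interface_cutoff)
    if not pairs:
        raise EmptyInterfaceError("toy spec produces no interface pairs")
    if spec.separation == 0.0 and len(pairs) < 8:
        raise ConfigurationError(
            f"toy native interface has only {len(pairs)} pairs (need >= 8); "
            "add studs or deepen the contact gaps"
        )

    truth = ToyGroundTruth(
        native_gamma=float(spec.gamma_native % 360.0),
        native_phi=float(spec.phi_native),
        native_pairs=pairs,
        obstruction=spec.obstruction,
    )
    return model, truth
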