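"""Dimer activation geometry: the C1-anchored frame and the gamma/phi angles.

The relative orientation of the two receptors is measured in a frame built
from the native complex: z is the long axis of the C1 subdomain pointing
"up" (away from the membrane-proximal, C-terminal end), x is the component
of the N2 long axis perpendicular to z (so x is roughly parallel to N2),
and y = z cross x completes a right-handed triad.  Two angles follow:

* gamma — the angle between the x-y-plane projections of the N1 and N2
  long axes, reported in [0, 360).  The self-rotation of R2 (clockwise in
  top view) on the way to the native complex decreases gamma.
* phi — the signed angle between the y-z-plane projections of the C1 and
  C2 long axes, in (-180, 180].  The scissor-like rotation that closes the
  membrane-proximal ends of C1 and C2 decreases phi.

Subdomain long axes are the largest-eigenvalue axis of the (unit-mass)
gyration tensor — the direction of greatest spatial extent — with the sign
fixed to point from the subdomain's C-terminal residue toward its
N-terminal residue.  An option selects the axis of largest inertia moment
instead (which is the SHORT axis of an elongated body; kept for comparison
with descriptions phrased in inertia language).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ComputationError, DegenerateStructureError
from .sampling import BindingGeometry, EnsembleStore, compose_transform, wrap_angle
from .structure import ComplexModel
from .transition import TransientEnsemble

_PROJECTION_TOL = 1e-8


def long_axis(
    coords: np.ndarray,
    residue_index: np.ndarray,
    method: str = "gyration",
    anisotropy_min: float = 1.2,
) -> np.ndarray:
    """Unit long axis of a subdomain's heavy-atom cloud.

    ``method='gyration'`` (default) returns the largest-eigenvalue
    eigenvector of the positional covariance; ``'inertia'`` the axis of the
    largest moment of inertia.  The sign points from the C-terminal-residue
    centroid toward the N-terminal-residue centroid.
    """
    coords = np.asarray(coords, dtype=float)
    residue_index = np.asarray(residue_index, dtype=int)
    if len(coords) < 10:
        raise DegenerateStructureError(
            f"need >= 10 heavy atoms for a long axis, got {len(coords)}"
        )
    centered = coords - coords.mean(axis=0)
    gyration = centered.T @ centered / len(coords)
    w, v = np.linalg.eigh(gyration)
    if w[2] < anisotropy_min * max(w[1], 1e-12):
        raise DegenerateStructureError(
            f"atom cloud too isotropic for a long axis "
            f"(eigenvalue ratio {w[2] / max(w[1], 1e-12):.3f} < {anisotropy_min})"
        )
    if method == "gyration":
        axis = v[:, 2]
    elif method == "inertia":
        # inertia tensor for unit masses: I = tr(G) * 1 - G (up to n); its
        # largest moment belongs to the smallest gyration eigenvalue axis
        axis = v[:, 0]
    else:
        raise ComputationError(f"unknown long-axis method {method!r}")

    n_cent = coords[residue_index == residue_index.min()].mean(axis=0)
    c_cent = coords[residue_index == residue_index.max()].mean(axis=0)
    direction = n_cent - c_cent
    if np.linalg.norm(direction) > 1e-9 and axis @ direction < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


@dataclass(frozen=True)
class DimerFrame:
    """Right-handed orthonormal frame anchored on the C1 subdomain."""

    origin: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        for v in (self.x, self.y, self.z):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ComputationError("frame axes must be unit vectors")
        if max(abs(self.x @ self.y), abs(self.y @ self.z), abs(self.z @ self.x)) > 1e-9:
            raise ComputationError("frame axes must be orthogonal")
        if abs(np.cross(self.x, self.y) @ self.z - 1.0) > 1e-9:
            raise ComputationError("frame must be right-handed")


@dataclass(frozen=True)
class AngleObservation:
    """(gamma, phi) of one configuration in the native dimer frame."""

    gamma: float      # [0, 360)
    phi: float        # (-180, 180]
    n_c: int | None = None


def build_frame(
    model: ComplexModel,
    axis_method: str = "gyration",
    min_axis_angle: float = 5.0,
) -> DimerFrame:
    """Construct the dimer frame from the NATIVE configuration.

    The frame is computed once from the native N2 placement and then held
    fixed when scoring transient configurations (rotations of R2 are
    reported relative to R1, whose C1 anchors the frame).
    """
    z = long_axis(model.subdomain_coords("C1"), model.subdomain_residue_index("C1"),
                  method=axis_method)
    n2 = long_axis(model.subdomain_coords("N2"), model.subdomain_residue_index("N2"),
                   method=axis_method)
    cosang = np.clip(abs(n2 @ z), 0.0, 1.0)
    if np.rad2deg(np.arccos(cosang)) < min_axis_angle:
        raise DegenerateStructureError(
            "C1 and N2 long axes are within "
            f"{min_axis_angle} deg of parallel; frame undefined"
        )
    x = n2 - (n2 @ z) * z
    x = x / np.linalg.norm(x)
    # sign is positive along N2 by construction (x is N2 minus its z part)
    y = np.cross(z, x)
    origin = model.subdomain_coords("C1").mean(axis=0)
    return DimerFrame(origin=origin, x=x, y=y / np.linalg.norm(y), z=z)


def _project_angle(v: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Azimuth of v's projection onto the (a, b) plane, atan2(v.b, v.a)."""
    pa, pb = v @ a, v @ b
    if pa * pa + pb * pb < _PROJECTION_TOL ** 2:
        raise ComputationError("axis is perpendicular to the projection plane")
    return float(np.rad2deg(np.arctan2(pb, pa)))


def compute_angles(
    frame: DimerFrame,
    model: ComplexModel,
    mobile_coords: np.ndarray | None = None,
    axis_method: str = "gyration",
    n_c: int | None = None,
) -> AngleObservation:
    """(gamma, phi) for one placement of the mobile subunit.

    ``mobile_coords`` are the placed coordinates of the whole mobile
    subunit; None scores the native placement.
    """
    n1 = long_axis(model.subdomain_coords("N1"), model.subdomain_residue_index("N1"),
                   method=axis_method)
    c1 = long_axis(model.subdomain_coords("C1"), model.subdomain_residue_index("C1"),
                   method=axis_method)
    n2 = long_axis(model.subdomain_coords("N2", mobile_coords),
                   model.subdomain_residue_index("N2"), method=axis_method)
    c2 = long_axis(model.subdomain_coords("C2", mobile_coords),
                   model.subdomain_residue_index("C2"), method=axis_method)

    # top view: azimuth about z, measured from x toward y
    az_n1 = _project_angle(n1, frame.x, frame.y)
    az_n2 = _project_angle(n2, frame.x, frame.y)
    gamma = float(np.mod(az_n2 - az_n1, 360.0))

    # side view: angle in the y-z plane, measured from z toward y
    b_c1 = _project_angle(c1, frame.z, frame.y)
    b_c2 = _project_angle(c2, frame.z, frame.y)
    phi = float(wrap_angle(b_c2 - b_c1))
    return AngleObservation(gamma=gamma, phi=phi, n_c=n_c)


def compute_ensemble_angles(
    store: EnsembleStore,
    model: ComplexModel,
    geometry: BindingGeometry,
    frame: DimerFrame | None = None,
    axis_method: str = "gyration",
) -> pd.DataFrame:
    """Angle table (config id, gamma, phi, N_c) for every stored member."""
    if frame is None:
        frame = build_frame(model, axis_method=axis_method)
    rows = []
    native_mobile = model.mobile.coords
    for i in range(len(store)):
        tf = compose_transform(store.r[i], store.e[i], float(store.chi[i]), geometry)
        obs = compute_angles(frame, model, tf.apply(native_mobile),
                             axis_method=axis_method, n_c=int(store.n_c[i]))
        rows.append({"config": i, "gamma": obs.gamma, "phi": obs.phi, "n_c": obs.n_c})
    return pd.DataFrame(rows)


@dataclass
class AngleHistograms:
    """Binned gamma/phi distributions with the native-asymmetry summary."""

    gamma_hist: pd.DataFrame
    phi_hist: pd.DataFrame
    native: AngleObservation
    gamma_median: float
    phi_median: float
    frac_gamma_above_native: float
    frac_phi_above_native: float
    n_members: int

    def summary(self) -> dict:
        return {
            "n_members": self.n_members,
            "native_gamma": self.native.gamma,
            "native_phi": self.native.phi,
            "gamma_median": self.gamma_median,
            "phi_median": self.phi_median,
            "frac_gamma_above_native": self.frac_gamma_above_native,
            "frac_phi_above_native": self.frac_phi_above_native,
        }


def angle_histograms(
    ensemble: TransientEnsemble,
    model: ComplexModel,
    geometry: BindingGeometry,
    frame: DimerFrame | None = None,
    bin_width: float = 5.0,
    axis_method: str = "gyration",
    angles: pd.DataFrame | None = None,
) -> AngleHistograms:
    """Histograms of gamma and phi over the transient ensemble.

    "Above native" is measured on the wrapped difference to the native
    value, so a distribution straddling 0/360 is handled consistently.
    Precomputed ``angles`` (from :func:`compute_ensemble_angles`) may be
    passed to avoid recomputation.
    """
    if ensemble.member_count == 0:
        raise ComputationError("transient ensemble is empty")
    if frame is None:
        frame = build_frame(model, axis_method=axis_method)
    native = compute_angles(frame, model, axis_method=axis_method)
    if angles is None:
        angles = compute_ensemble_angles(ensemble.members, model, geometry,
                                         frame=frame, axis_method=axis_method)

    def hist(values, lo, hi):
        edges = np.arange(lo, hi + bin_width, bin_width)
        counts, edges = np.histogram(values, bins=edges)
        return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                             "count": counts})

    dgamma = wrap_angle(angles["gamma"].to_numpy() - native.gamma)
    dphi = wrap_angle(angles["phi"].to_numpy() - native.phi)
    return AngleHistograms(
        gamma_hist=hist(angles["gamma"], 0.0, 360.0),
        phi_hist=hist(angles["phi"], -180.0, 180.0),
        native=native,
        gamma_median=float(np.median(angles["gamma"])),
        phi_median=float(np.median(angles["phi"])),
        frac_gamma_above_native=float(np.mean(dgamma > 0)),
        frac_phi_above_native=float(np.mean(dphi > 0)),
        n_members=int(len(angles)),
    )
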