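"""Rigid-body configuration sampling in the (r, e, chi) coordinates.

While the 1:1 complex stays fixed in space, the second receptor R2 is
translated and rotated around its native placement.  The three translational
degrees of freedom are the displacement vector r between the centers of the
two binding surfaces (the per-side centroids of the native interface heavy
atoms); the rotational degrees of freedom are a body-fixed unit vector e
(the unit normal of the least-squares plane of the interface atoms, pointing
from the fixed side toward the mobile side in the native placement) plus a
spin angle chi about e, with chi = 0 at native.

Sampling is uniform: r uniform in the ball |r| <= r_cut, e uniform on the
unit sphere, chi uniform in (-180, 180].  Because e is the image of the
native body axis and chi a uniform spin about it, the composed rotations are
Haar-uniform on SO(3).  Configurations with any cross-subunit heavy-atom
pair closer than the clash distance are rejected; the clash test is
exhaustive over all inter-subunit atom pairs.  r_cut is auto-determined as
the smallest grid value whose clash-free fraction reaches a floor (1e-4 by
default), so the sampled shell always straddles the native well and the
onset of the unbound state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

import numpy as np
from scipy.spatial.transform import Rotation

from . import _kernels
from .contacts import InteractionLocusSet, InterfacePair, find_interface
from .errors import (
    ComputationError,
    ConfigurationError,
    DegenerateStructureError,
    NativeClashError,
    SamplingError,
)
from .structure import ComplexModel


def wrap_angle(deg):
    """Reduce an angle (degrees) into (-180, 180]."""
    return deg - 360.0 * np.ceil((deg - 180.0) / 360.0)


# ---------------------------------------------------------------------------
# binding-surface geometry
# ---------------------------------------------------------------------------

def binding_surface_centers(
    model: ComplexModel, pairs: list[InterfacePair]
) -> tuple[np.ndarray, np.ndarray]:
    """Centroids of the unique interface heavy atoms on each side."""
    if not pairs:
        raise ComputationError("empty interface pair list")
    fidx = np.unique([p.fixed_index for p in pairs])
    midx = np.unique([p.mobile_index for p in pairs])
    return model.fixed.coords[fidx].mean(axis=0), model.mobile.coords[midx].mean(axis=0)


def native_body_axis(model: ComplexModel, pairs: list[InterfacePair]) -> np.ndarray:
    """Unit normal of the least-squares plane of all interface heavy atoms.

    Uses both sides' unique interface atoms in the native placement; the sign
    points from the fixed-side binding-surface center toward the mobile-side
    center.
    """
    fidx = np.unique([p.fixed_index for p in pairs])
    midx = np.unique([p.mobile_index for p in pairs])
    pts = np.vstack([model.fixed.coords[fidx], model.mobile.coords[midx]])
    if len(pts) < 3:
        raise DegenerateStructureError("need >= 3 interface atoms to fit a plane")
    centered = pts - pts.mean(axis=0)
    w, v = np.linalg.eigh(centered.T @ centered)
    if w[1] < 1e-9 * max(w[2], 1.0):
        raise DegenerateStructureError("interface atoms are collinear; plane undefined")
    normal = v[:, 0]
    cf, cm = binding_surface_centers(model, pairs)
    if normal @ (cm - cf) < 0:
        normal = -normal
    return normal / np.linalg.norm(normal)


@dataclass(frozen=True)
class BindingGeometry:
    """Native reference quantities the (r, e, chi) parameterization needs."""

    fixed_center: np.ndarray
    mobile_center: np.ndarray
    native_e: np.ndarray

    @property
    def native_r(self) -> np.ndarray:
        return self.mobile_center - self.fixed_center

    @classmethod
    def from_model(
        cls, model: ComplexModel, pairs: list[InterfacePair] | None = None
    ) -> "BindingGeometry":
        if pairs is None:
            pairs = find_interface(model)
        cf, cm = binding_surface_centers(model, pairs)
        return cls(fixed_center=cf, mobile_center=cm,
                   native_e=native_body_axis(model, pairs))


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion y = R x + t applied to native mobile coordinates."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _align_rotvecs(native_e: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Batched rotation vectors of the minimal rotation carrying native_e to e."""
    e = np.atleast_2d(e)
    axis = np.cross(np.broadcast_to(native_e, e.shape), e)
    s = np.linalg.norm(axis, axis=1)
    c = e @ native_e
    ang = np.arctan2(s, c)
    rv = np.zeros_like(e)
    ok = s > 1e-12
    rv[ok] = axis[ok] / s[ok, None] * ang[ok, None]
    anti = (~ok) & (c < 0)
    if anti.any():
        # antiparallel: rotate by pi about any axis perpendicular to native_e
        perp = np.cross(native_e, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(native_e, [0.0, 1.0, 0.0])
        perp = perp / np.linalg.norm(perp)
        rv[anti] = perp * np.pi
    return rv


def _rotations(native_e: np.ndarray, e: np.ndarray, chi_deg) -> Rotation:
    """R = spin(chi about e) o align(native_e -> e), batched."""
    e = np.atleast_2d(e)
    chi = np.atleast_1d(np.asarray(chi_deg, dtype=float))
    r_align = Rotation.from_rotvec(_align_rotvecs(native_e, e))
    r_spin = Rotation.from_rotvec(e * np.deg2rad(chi)[:, None])
    return r_spin * r_align


def compose_transform(
    r: np.ndarray, e: np.ndarray, chi_deg: float, geometry: BindingGeometry
) -> RigidTransform:
    """Realize (r, e, chi) as a rigid motion of the mobile subunit.

    The rotation (axis alignment followed by spin) acts about the mobile
    binding-surface center; the translation then places that center at
    fixed_center + r.  (native r, native e, chi=0) maps to the identity.
    """
    e = np.asarray(e, dtype=float)
    if abs(np.linalg.norm(e) - 1.0) > 1e-6:
        raise ComputationError("e must be a unit vector")
    R = _rotations(geometry.native_e, e, chi_deg).as_matrix()[0]
    t = geometry.fixed_center + np.asarray(r, dtype=float) - R @ geometry.mobile_center
    return RigidTransform(rotation=R, translation=t)


def decompose_transform(
    transform: RigidTransform, geometry: BindingGeometry
) -> tuple[np.ndarray, np.ndarray, float]:
    """Recover (r, e, chi) from a rigid motion (inverse of compose)."""
    R, t = transform.rotation, transform.translation
    e = R @ geometry.native_e
    r = (R @ geometry.mobile_center + t) - geometry.fixed_center
    r_align = Rotation.from_rotvec(_align_rotvecs(geometry.native_e, e))
    r_spin = Rotation.from_matrix(R) * r_align.inv()
    rv = r_spin.as_rotvec()[0] if r_spin.as_rotvec().ndim == 2 else r_spin.as_rotvec()
    ang = np.rad2deg(np.linalg.norm(rv))
    if ang > 1e-12 and rv @ e < 0:
        ang = -ang
    return r, e, float(wrap_angle(ang))


# ---------------------------------------------------------------------------
# sampling spec / configuration
# ---------------------------------------------------------------------------

@dataclass
class SamplingSpec:
    """Sampling conditions for one run.

    ``r_cut`` of ``None`` means auto-determine.  ``target_clashfree``
    defaults to the full production scale; toy runs pass smaller values.
    """

    r_cut: float | None = None
    clash_distance: float = 2.8
    target_clashfree: int = 8_000_000
    min_clashfree_fraction: float = 1e-4
    seed: int = 0
    batch_size: int = 8192
    rcut_pilot: int = 1_000_000
    rcut_grid_start: float = 2.0
    rcut_grid_step: float = 1.0
    rcut_ceiling: float = 30.0

    def __post_init__(self):
        if self.r_cut is not None and self.r_cut <= 0:
            raise ConfigurationError("r_cut must be positive")
        if not (0.0 < self.min_clashfree_fraction < 1.0):
            raise ConfigurationError("min_clashfree_fraction must be in (0, 1)")
        if self.target_clashfree < 1 or self.batch_size < 1:
            raise ConfigurationError("target_clashfree and batch_size must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Configuration:
    """One rigid-body placement of the mobile subunit."""

    r: np.ndarray
    e: np.ndarray
    chi: float
    clash_free: bool = True
    n_c: int | None = None

    def transform(self, geometry: BindingGeometry) -> RigidTransform:
        return compose_transform(self.r, self.e, self.chi, geometry)

    def mobile_coords(self, model: ComplexModel, geometry: BindingGeometry) -> np.ndarray:
        return self.transform(geometry).apply(model.mobile.coords)


# ---------------------------------------------------------------------------
# ensemble store
# ---------------------------------------------------------------------------

class EnsembleStore:
    """Columnar store of sampled clash-free configurations.

    Holds (r, e, chi, N_c) per configuration; transforms are recomputed on
    demand from the geometry rather than stored.  Serializes to TSV with a
    JSON header block; floats are written with 17 significant digits so a
    save/load round trip is bit exact.
    """

    COLUMNS = ("r_x", "r_y", "r_z", "e_x", "e_y", "e_z", "chi_deg", "n_c")

    def __init__(self, r: np.ndarray, e: np.ndarray, chi: np.ndarray,
                 n_c: np.ndarray, meta: dict | None = None):
        n = len(chi)
        if not (len(r) == len(e) == len(n_c) == n):
            raise ValueError("column length mismatch")
        self.r = np.asarray(r, dtype=float).reshape(n, 3)
        self.e = np.asarray(e, dtype=float).reshape(n, 3)
        self.chi = np.asarray(chi, dtype=float)
        self.n_c = np.asarray(n_c, dtype=int)
        self.meta = dict(meta or {})

    def __len__(self) -> int:
        return len(self.chi)

    def select(self, mask: np.ndarray) -> "EnsembleStore":
        return EnsembleStore(self.r[mask], self.e[mask], self.chi[mask],
                             self.n_c[mask], self.meta)

    def configuration(self, i: int) -> Configuration:
        return Configuration(r=self.r[i], e=self.e[i], chi=float(self.chi[i]),
                             n_c=int(self.n_c[i]))

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# tcomplex-ensemble v1\n")
            fh.write("# meta: " + json.dumps(self.meta, sort_keys=True) + "\n")
            fh.write("\t".join(self.COLUMNS) + "\n")
            for i in range(len(self)):
                vals = [*self.r[i], *self.e[i], self.chi[i]]
                fh.write("\t".join(f"{v:.17g}" for v in vals) + f"\t{self.n_c[i]}\n")

    @classmethod
    def load(cls, path: str | Path) -> "EnsembleStore":
        meta = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("# meta:"):
                    meta = json.loads(line.split(":", 1)[1])
                elif line.startswith("#") or line.startswith(cls.COLUMNS[0]):
                    continue
                elif line.strip():
                    rows.append(line.split())
        arr = np.array(rows, dtype=float) if rows else np.zeros((0, 8))
        return cls(arr[:, 0:3], arr[:, 3:6], arr[:, 6], arr[:, 7].astype(int), meta)


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

def _draw_batch(rng: np.random.Generator, n: int, r_cut: float):
    radii = r_cut * np.cbrt(rng.random(n))
    rdir = rng.normal(size=(n, 3))
    rdir /= np.linalg.norm(rdir, axis=1, keepdims=True)
    r = radii[:, None] * rdir
    e = rng.normal(size=(n, 3))
    e /= np.linalg.norm(e, axis=1, keepdims=True)
    chi = wrap_angle(rng.uniform(0.0, 360.0, size=n))
    return r, e, chi


def _batch_transforms(geometry: BindingGeometry, r, e, chi):
    rots = _rotations(geometry.native_e, e, chi).as_matrix()
    trans = geometry.fixed_center[None] + r - np.einsum("bij,j->bi", rots, geometry.mobile_center)
    return rots, trans


def iter_clashfree_batches(
    model: ComplexModel,
    loci: InteractionLocusSet | None,
    spec: SamplingSpec,
    geometry: BindingGeometry | None = None,
) -> Iterator[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Yield (r, e, chi, n_c) arrays of clash-free configurations.

    The low-level batched engine behind :func:`sample_configurations` and
    :func:`run_sampling`; N_c is -1 throughout when ``loci`` is None.
    Aborts with :class:`SamplingError` when the running clash-free fraction
    drops below ``spec.min_clashfree_fraction`` after a warm-up of
    ``10 / min_clashfree_fraction`` generated configurations.
    """
    if geometry is None:
        geometry = BindingGeometry.from_model(model)
    if spec.r_cut is None:
        raise ConfigurationError("spec.r_cut is unset; call determine_rcut first")
    fixed = model.fixed.coords
    mobile = model.mobile.coords

    if spec.clash_distance > 0 and _kernels.has_clash(fixed, mobile, spec.clash_distance):
        raise NativeClashError(
            "native configuration fails the sampler's own clash test"
        )

    rng = np.random.default_rng(spec.seed)
    warmup = int(np.ceil(10.0 / spec.min_clashfree_fraction))
    generated = 0
    accepted = 0
    while accepted < spec.target_clashfree:
        n = min(spec.batch_size, 4 * (spec.target_clashfree - accepted) + 64)
        r, e, chi = _draw_batch(rng, n, spec.r_cut)
        rots, trans = _batch_transforms(geometry, r, e, chi)
        clash = _kernels.clash_mask(fixed, mobile, rots, trans, spec.clash_distance)
        ok = ~clash
        generated += n
        keep = np.flatnonzero(ok)[: spec.target_clashfree - accepted]
        if len(keep):
            accepted += len(keep)
            if loci is not None:
                placed = np.einsum("bij,nj->bni", rots[keep], mobile) + trans[keep][:, None, :]
                nc = loci.count_contacts_many(placed, fixed)
            else:
                nc = np.full(len(keep), -1, dtype=int)
            yield r[keep], e[keep], chi[keep], nc
        if generated >= warmup and accepted / generated < spec.min_clashfree_fraction:
            raise SamplingError(
                f"clash-free fraction {accepted / generated:.2e} fell below "
                f"{spec.min_clashfree_fraction:.2e} after {generated} configurations; "
                "increase r_cut or relax the clash distance"
            )


def sample_configurations(
    model: ComplexModel,
    loci: InteractionLocusSet | None,
    spec: SamplingSpec,
    geometry: BindingGeometry | None = None,
) -> Iterator[Configuration]:
    """Stream clash-free :class:`Configuration` objects (lazily, seeded)."""
    for r, e, chi, nc in iter_clashfree_batches(model, loci, spec, geometry):
        for i in range(len(chi)):
            yield Configuration(
                r=r[i], e=e[i], chi=float(chi[i]),
                n_c=None if nc[i] < 0 else int(nc[i]),
            )


def run_sampling(
    model: ComplexModel,
    loci: InteractionLocusSet,
    spec: SamplingSpec,
    geometry: BindingGeometry | None = None,
) -> EnsembleStore:
    """Collect the full clash-free sample into an :class:`EnsembleStore`."""
    parts = list(iter_clashfree_batches(model, loci, spec, geometry))
    r = np.vstack([p[0] for p in parts])
    e = np.vstack([p[1] for p in parts])
    chi = np.concatenate([p[2] for p in parts])
    nc = np.concatenate([p[3] for p in parts])
    meta = {"spec": spec.to_dict(), "seed": spec.seed}
    return EnsembleStore(r, e, chi, nc, meta)


def estimate_clashfree_fraction(
    model: ComplexModel,
    spec: SamplingSpec,
    r_cut: float,
    n_pilot: int,
    seed,
    geometry: BindingGeometry | None = None,
) -> float:
    """Monte-Carlo estimate of the clash-free fraction at a given r_cut."""
    if geometry is None:
        geometry = BindingGeometry.from_model(model)
    rng = np.random.default_rng(seed)
    fixed = model.fixed.coords
    mobile = model.mobile.coords
    ok = 0
    done = 0
    while done < n_pilot:
        n = min(spec.batch_size, n_pilot - done)
        r, e, chi = _draw_batch(rng, n, r_cut)
        rots, trans = _batch_transforms(geometry, r, e, chi)
        clash = _kernels.clash_mask(fixed, mobile, rots, trans, spec.clash_distance)
        ok += int((~clash).sum())
        done += n
    return ok / n_pilot


def determine_rcut(
    model: ComplexModel,
    spec: SamplingSpec,
    geometry: BindingGeometry | None = None,
) -> float:
    """Smallest grid r_cut whose clash-free fraction reaches the floor.

    Walks a grid (default 2 A upward in 1 A steps) and returns the first
    value whose pilot-estimated clash-free fraction is at least
    ``spec.min_clashfree_fraction``.
    """
    if geometry is None:
        geometry = BindingGeometry.from_model(model)
    r = spec.rcut_grid_start
    k = 0
    while r <= spec.rcut_ceiling + 1e-9:
        frac = estimate_clashfree_fraction(
            model, spec, r, spec.rcut_pilot, seed=[spec.seed, 7919 + k],
            geometry=geometry,
        )
        if frac >= spec.min_clashfree_fraction:
            return float(r)
        r += spec.rcut_grid_step
        k += 1
    raise SamplingError(
        f"no r_cut up to {spec.rcut_ceiling:.0f} A reaches a clash-free "
        f"fraction of {spec.min_clashfree_fraction:.1e}"
    )
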