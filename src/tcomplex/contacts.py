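"""Native interface detection, interaction-locus selection, contact counting.

The short-range interaction surrogate N_c for a rigid-body placement of the
mobile subunit is the number of contacts, native or nonnative, formed by a
thinned set of "interaction-locus" atoms:

* the native interface is every cross-subunit heavy-atom pair closer than
  5 A in the native complex (plus pairs involving configured tail-contact
  residues, under a separate cutoff);
* pairs are scanned in ascending native distance and greedily thinned — a
  pair is dropped if either of its atoms lies within 3.5 A of the same-side
  atom of an already retained pair — leaving well-separated loci;
* a retained native pair counts as a contact when its current distance is at
  most its native distance + 3.5 A;
* every other fixed-locus/mobile-locus atom pair counts as a nonnative
  contact when its current distance is under the sum of the two atoms'
  contact radii (half their retained-pair native distance each) + 2.5 A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import EmptyInterfaceError
from .structure import ComplexModel

INTERFACE_CUTOFF = 5.0
ELIMINATION_RADIUS = 3.5
NATIVE_TOLERANCE = 3.5
NONNATIVE_MARGIN = 2.5


@dataclass(frozen=True)
class InterfacePair:
    """One native cross-interface heavy-atom pair (indices into the subunits)."""

    fixed_index: int
    mobile_index: int
    native_distance: float
    is_tail: bool = False


def find_interface(
    model: ComplexModel,
    cutoff: float = INTERFACE_CUTOFF,
    tail_cutoff: float = 8.0,
) -> list[InterfacePair]:
    """All cross-subunit heavy-atom pairs with native distance < ``cutoff``.

    Pairs involving fixed-subunit atoms in ``model.tail_contact_residues``
    are admitted up to ``tail_cutoff`` instead and flagged ``is_tail``
    (mirrors counting flexible-tail residues that touch the mobile receptor
    only in the final complex).  The result is sorted by ascending native
    distance, ties broken by (fixed_index, mobile_index) for determinism.
    """
    ftree = cKDTree(model.fixed.coords)
    mtree = cKDTree(model.mobile.coords)
    tail = model.tail_mask()
    radius = max(cutoff, tail_cutoff if tail.any() else cutoff)
    dist = ftree.sparse_distance_matrix(mtree, max_distance=radius, output_type="coo_matrix")

    pairs: list[InterfacePair] = []
    for fi, mi, d in zip(dist.row, dist.col, dist.data):
        if d < cutoff:
            pairs.append(InterfacePair(int(fi), int(mi), float(d), bool(tail[fi])))
        elif tail[fi] and d < tail_cutoff:
            pairs.append(InterfacePair(int(fi), int(mi), float(d), True))
    if not pairs:
        raise EmptyInterfaceError(
            f"no cross-subunit heavy-atom pairs within {cutoff:.1f} A"
        )
    pairs.sort(key=lambda p: (p.native_distance, p.fixed_index, p.mobile_index))
    return pairs


class InteractionLocusSet:
    """Retained native pairs plus per-atom contact radii.

    ``fixed_loci`` / ``mobile_loci`` are the unique atom indices appearing in
    retained pairs; ``contact_radius_fixed`` / ``..._mobile`` map those atoms
    to half their retained-pair native distance (the smaller one if an atom
    appears in two retained pairs).
    """

    def __init__(self, retained: list[InterfacePair]):
        self.retained_pairs = list(retained)
        self.native_count = len(retained)

        rf: dict[int, float] = {}
        rm: dict[int, float] = {}
        for p in retained:
            half = 0.5 * p.native_distance
            rf[p.fixed_index] = min(half, rf.get(p.fixed_index, np.inf))
            rm[p.mobile_index] = min(half, rm.get(p.mobile_index, np.inf))
        self.fixed_loci = np.array(sorted(rf), dtype=int)
        self.mobile_loci = np.array(sorted(rm), dtype=int)
        self.contact_radius_fixed = {k: float(v) for k, v in rf.items()}
        self.contact_radius_mobile = {k: float(v) for k, v in rm.items()}

        # dense counting tables ------------------------------------------------
        fpos = {a: i for i, a in enumerate(self.fixed_loci)}
        mpos = {a: i for i, a in enumerate(self.mobile_loci)}
        nf, nm = len(self.fixed_loci), len(self.mobile_loci)
        rsum = (
            np.array([rf[a] for a in self.fixed_loci])[:, None]
            + np.array([rm[a] for a in self.mobile_loci])[None, :]
        )
        self._nonnative_threshold = rsum + NONNATIVE_MARGIN
        self._native_mask = np.zeros((nf, nm), dtype=bool)
        self._native_threshold = np.zeros((nf, nm))
        for p in retained:
            i, j = fpos[p.fixed_index], mpos[p.mobile_index]
            self._native_mask[i, j] = True
            self._native_threshold[i, j] = p.native_distance + NATIVE_TOLERANCE

    def count_contacts(
        self, mobile_coords: np.ndarray, fixed_coords: np.ndarray
    ) -> int:
        """N_c for one placement of the mobile subunit.

        ``mobile_coords`` are full mobile-subunit coordinates in the placed
        configuration; ``fixed_coords`` the (static) fixed-subunit
        coordinates the loci were built from.
        """
        fc = fixed_coords[self.fixed_loci]
        mc = mobile_coords[self.mobile_loci]
        d = np.linalg.norm(fc[:, None, :] - mc[None, :, :], axis=2)
        native = self._native_mask & (d <= self._native_threshold)
        nonnative = ~self._native_mask & (d < self._nonnative_threshold)
        return int(native.sum() + nonnative.sum())

    def count_contacts_many(
        self, mobile_coords_batch: np.ndarray, fixed_coords: np.ndarray
    ) -> np.ndarray:
        """Vectorized N_c over a (B, n_mobile, 3) batch of placements."""
        fc = fixed_coords[self.fixed_loci]
        mc = mobile_coords_batch[:, self.mobile_loci, :]
        d = np.linalg.norm(fc[None, :, None, :] - mc[:, None, :, :], axis=3)
        native = self._native_mask[None] & (d <= self._native_threshold[None])
        nonnative = ~self._native_mask[None] & (d < self._nonnative_threshold[None])
        return (native.sum(axis=(1, 2)) + nonnative.sum(axis=(1, 2))).astype(int)

    def to_table(self, model: ComplexModel) -> pd.DataFrame:
        """Retained pairs as an inspectable table (one row per pair)."""
        rows = []
        for p in self.retained_pairs:
            fa = model.fixed.atom(p.fixed_index)
            ma = model.mobile.atom(p.mobile_index)
            rows.append({
                "fixed_chain": fa.chain_tag, "fixed_res": fa.residue_index,
                "fixed_resname": fa.residue_name, "fixed_atom": fa.atom_name,
                "mobile_chain": ma.chain_tag, "mobile_res": ma.residue_index,
                "mobile_resname": ma.residue_name, "mobile_atom": ma.atom_name,
                "native_distance": p.native_distance,
                "radius_fixed": self.contact_radius_fixed[p.fixed_index],
                "radius_mobile": self.contact_radius_mobile[p.mobile_index],
                "is_tail": p.is_tail,
            })
        return pd.DataFrame(rows)


def select_interaction_loci(
    pairs: list[InterfacePair],
    elimination_radius: float = ELIMINATION_RADIUS,
    model: ComplexModel | None = None,
    fixed_coords: np.ndarray | None = None,
    mobile_coords: np.ndarray | None = None,
) -> InteractionLocusSet:
    """Greedy thinning of native pairs into well-separated interaction loci.

    Pairs are visited in ascending native distance; a pair is retained unless
    its fixed-side atom is within ``elimination_radius`` of a previously
    retained pair's fixed-side atom, or its mobile-side atom is within the
    radius of a previously retained pair's mobile-side atom.
    """
    if model is not None:
        fixed_coords = model.fixed.coords
        mobile_coords = model.mobile.coords
    if fixed_coords is None or mobile_coords is None:
        raise ValueError("provide either model or both coordinate arrays")

    order = sorted(pairs, key=lambda p: (p.native_distance, p.fixed_index, p.mobile_index))
    kept: list[InterfacePair] = []
    kept_f = np.empty((0, 3))
    kept_m = np.empty((0, 3))
    for p in order:
        fxyz = fixed_coords[p.fixed_index]
        mxyz = mobile_coords[p.mobile_index]
        if len(kept):
            if (np.linalg.norm(kept_f - fxyz, axis=1) < elimination_radius).any():
                continue
            if (np.linalg.norm(kept_m - mxyz, axis=1) < elimination_radius).any():
                continue
        kept.append(p)
        kept_f = np.vstack([kept_f, fxyz])
        kept_m = np.vstack([kept_m, mxyz])
    return InteractionLocusSet(kept)


def count_contacts(
    loci: InteractionLocusSet,
    mobile_coords: np.ndarray,
    fixed_coords: np.ndarray,
) -> int:
    """Functional wrapper around :meth:`InteractionLocusSet.count_contacts`."""
    return loci.count_contacts(mobile_coords, fixed_coords)
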