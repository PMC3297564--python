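"""Structure loading and subunit/subdomain assignment.

A 1:2 cytokine-receptor complex is split into two rigid bodies: the *fixed*
subunit (cytokine + first receptor, the 1:1 complex) and the *mobile* subunit
(the second receptor, R2).  Four beta-sandwich subdomains — N1/C1 on the fixed
side's receptor chain, N2/C2 on the mobile receptor — carry the long axes used
by the dimer-geometry analysis.  All downstream computation uses heavy atoms
only; hydrogens (and deuteriums) are dropped at load time and alternate
locations are resolved to the highest-occupancy conformer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import (
    ConfigurationError,
    DegenerateStructureError,
    EmptyInterfaceError,
    NativeClashError,
)

SUBDOMAIN_LABELS = ("N1", "C1", "N2", "C2")
_HYDROGENS = {"H", "D"}


@dataclass(frozen=True)
class AtomSite:
    """One heavy atom: identity plus Cartesian coordinates in angstroms."""

    atom_id: int
    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    coords: np.ndarray
    chain_tag: str

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HYDROGENS


class RigidSubunit:
    """An ordered collection of heavy atoms treated as one rigid body.

    Atom records are stored as parallel numpy arrays for speed; ``atom(i)``
    materializes an :class:`AtomSite` view of row ``i``.
    """

    def __init__(
        self,
        name: str,
        role: str,
        coords: np.ndarray,
        atom_id: np.ndarray,
        residue_index: np.ndarray,
        residue_name: Sequence[str],
        atom_name: Sequence[str],
        element: Sequence[str],
        chain_tag: Sequence[str],
    ):
        if role not in ("fixed", "mobile"):
            raise ConfigurationError(f"subunit role must be fixed|mobile, got {role!r}")
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ConfigurationError("coords must be (n, 3)")
        if not np.all(np.isfinite(coords)):
            raise DegenerateStructureError(f"subunit {name!r} has non-finite coordinates")
        self.name = name
        self.role = role
        self.coords = coords
        self.atom_id = np.asarray(atom_id, dtype=int)
        self.residue_index = np.asarray(residue_index, dtype=int)
        self.residue_name = np.asarray(residue_name, dtype=object)
        self.atom_name = np.asarray(atom_name, dtype=object)
        self.element = np.asarray(element, dtype=object)
        self.chain_tag = np.asarray(chain_tag, dtype=object)
        self._validate()

    def _validate(self) -> None:
        n = len(self.coords)
        if n < 4:
            raise DegenerateStructureError(
                f"subunit {self.name!r} has only {n} heavy atoms (need >= 4)"
            )
        if len(np.unique(self.atom_id)) != n:
            raise DegenerateStructureError(f"subunit {self.name!r} has duplicate atom_ids")
        # non-collinearity: centered coordinates must span at least a plane
        centered = self.coords - self.coords.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        if sv[1] < 1e-6 * max(sv[0], 1.0):
            raise DegenerateStructureError(f"subunit {self.name!r} atoms are collinear")

    def __len__(self) -> int:
        return len(self.coords)

    def atom(self, i: int) -> AtomSite:
        return AtomSite(
            atom_id=int(self.atom_id[i]),
            residue_index=int(self.residue_index[i]),
            residue_name=str(self.residue_name[i]),
            atom_name=str(self.atom_name[i]),
            element=str(self.element[i]),
            coords=self.coords[i].copy(),
            chain_tag=str(self.chain_tag[i]),
        )

    def mask_residues(self, chain: str, start: int, end: int) -> np.ndarray:
        """Boolean mask for atoms of ``chain`` with start <= resseq <= end."""
        return (
            (self.chain_tag == chain)
            & (self.residue_index >= start)
            & (self.residue_index <= end)
        )


@dataclass(frozen=True)
class SubdomainAssignment:
    """Inclusive author-numbered residue range of one receptor subdomain."""

    label: str
    chain_tag: str
    start: int
    end: int

    def __post_init__(self):
        if self.label not in SUBDOMAIN_LABELS:
            raise ConfigurationError(f"unknown subdomain label {self.label!r}")
        if self.end < self.start:
            raise ConfigurationError(
                f"subdomain {self.label}: empty range {self.start}-{self.end}"
            )

    @property
    def on_mobile(self) -> bool:
        return self.label in ("N2", "C2")


@dataclass
class ComplexModel:
    """The native 1:2 complex split into fixed and mobile rigid bodies."""

    fixed: RigidSubunit
    mobile: RigidSubunit
    subdomains: dict[str, SubdomainAssignment]
    tail_contact_residues: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        missing = [lb for lb in SUBDOMAIN_LABELS if lb not in self.subdomains]
        if missing:
            raise ConfigurationError(f"missing subdomain assignments: {missing}")
        for lb, sd in self.subdomains.items():
            if lb != sd.label:
                raise ConfigurationError(f"subdomain key {lb!r} != label {sd.label!r}")
            sub = self.mobile if sd.on_mobile else self.fixed
            n = int(self.subdomain_mask(lb).sum())
            if n == 0:
                raise ConfigurationError(
                    f"subdomain {lb}: chain {sd.chain_tag!r} range "
                    f"{sd.start}-{sd.end} matches no atoms in the {sub.role} subunit"
                )
            if n < 10:
                raise DegenerateStructureError(
                    f"subdomain {lb} resolves to only {n} heavy atoms (need >= 10)"
                )
        self._check_range_overlap()

    def _check_range_overlap(self) -> None:
        by_chain: dict[str, list[SubdomainAssignment]] = {}
        for sd in self.subdomains.values():
            by_chain.setdefault(sd.chain_tag, []).append(sd)
        for chain, sds in by_chain.items():
            sds = sorted(sds, key=lambda s: s.start)
            for a, b in zip(sds, sds[1:]):
                if b.start <= a.end:
                    raise ConfigurationError(
                        f"subdomains {a.label} and {b.label} overlap on chain {chain}"
                    )

    def subunit_of(self, label: str) -> RigidSubunit:
        return self.mobile if self.subdomains[label].on_mobile else self.fixed

    def subdomain_mask(self, label: str) -> np.ndarray:
        sd = self.subdomains[label]
        return self.subunit_of(label).mask_residues(sd.chain_tag, sd.start, sd.end)

    def subdomain_coords(self, label: str, mobile_coords: np.ndarray | None = None) -> np.ndarray:
        """Coordinates of a subdomain; for N2/C2 optionally from a placement."""
        mask = self.subdomain_mask(label)
        sub = self.subunit_of(label)
        coords = sub.coords
        if mobile_coords is not None and sub is self.mobile:
            coords = mobile_coords
        return coords[mask]

    def subdomain_residue_index(self, label: str) -> np.ndarray:
        return self.subunit_of(label).residue_index[self.subdomain_mask(label)]

    def tail_mask(self) -> np.ndarray:
        """Mask of fixed-subunit atoms in the configured tail-contact residues."""
        mask = np.zeros(len(self.fixed), dtype=bool)
        for chain, res in self.tail_contact_residues:
            mask |= (self.fixed.chain_tag == chain) & (self.fixed.residue_index == res)
        return mask


# ---------------------------------------------------------------------------
# assignment spec
# ---------------------------------------------------------------------------

def _parse_assignment(config: Mapping | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise ConfigurationError("assignment spec must be a mapping or a YAML file path")
    for key in ("fixed_chains", "mobile_chains", "subdomains"):
        if key not in config:
            raise ConfigurationError(f"assignment spec missing key {key!r}")
    sds = config["subdomains"]
    for lb in SUBDOMAIN_LABELS:
        if lb not in sds:
            raise ConfigurationError(f"assignment spec missing subdomain {lb!r}")
        for k in ("chain", "start", "end"):
            if k not in sds[lb]:
                raise ConfigurationError(f"subdomain {lb} missing field {k!r}")
    return dict(config)


def _resolve_altlocs(chain) -> None:
    """Keep only the highest-occupancy altloc per (residue, atom name).

    Ties resolve to the first conformer encountered, matching the usual
    deposition order (altloc 'A' first).
    """
    for residue in chain:
        best: dict[str, object] = {}
        for atom in residue:
            key = atom.name
            if key not in best or atom.occ > best[key].occ + 1e-9:
                best[key] = atom
        keep_serial = {a.serial for a in best.values()}
        for i in range(len(residue) - 1, -1, -1):
            if residue[i].serial not in keep_serial:
                del residue[i]


def _collect_chain_atoms(structure, chain_names: Iterable[str], path: str):
    import gemmi

    model = structure[0]
    present = {ch.name for ch in model}
    rows = {k: [] for k in (
        "coords", "atom_id", "residue_index", "residue_name",
        "atom_name", "element", "chain_tag",
    )}
    for cname in chain_names:
        if cname not in present:
            raise ConfigurationError(
                f"chain {cname!r} not found in {path} (available: {sorted(present)})"
            )
        chain = model[cname]
        _resolve_altlocs(chain)
        for residue in chain:
            for atom in residue:
                elem = atom.element.name.upper()
                if elem in _HYDROGENS:
                    continue
                rows["coords"].append([atom.pos.x, atom.pos.y, atom.pos.z])
                rows["atom_id"].append(atom.serial)
                rows["residue_index"].append(residue.seqid.num)
                rows["residue_name"].append(residue.name)
                rows["atom_name"].append(atom.name)
                rows["element"].append(elem)
                rows["chain_tag"].append(cname)
    return rows


def load_complex(structure_file: str | Path, config: Mapping | str | Path) -> ComplexModel:
    """Read a PDB file and partition it into a validated :class:`ComplexModel`.

    ``config`` assigns chains to the fixed (cytokine + R1) and mobile (R2)
    subunits, gives the four subdomain residue ranges, and may list
    ``tail_contact_residues`` on the fixed subunit that are counted as
    interface even when farther than the interface cutoff in the prepared
    coordinates (the treatment used for flexible cytokine N-terminal tails).
    """
    import gemmi

    spec = _parse_assignment(config)
    path = str(structure_file)
    try:
        structure = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, OSError) as exc:
        raise ConfigurationError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(structure) == 0:
        raise ConfigurationError(f"{path} contains no models")

    def build(chains, name, role):
        rows = _collect_chain_atoms(structure, chains, path)
        if not rows["coords"]:
            raise DegenerateStructureError(f"no heavy atoms in chains {chains}")
        # re-number atom ids to be unique within the subunit even if the file
        # restarts serials per chain
        n = len(rows["coords"])
        return RigidSubunit(
            name=name, role=role,
            coords=np.array(rows["coords"], dtype=float),
            atom_id=np.arange(1, n + 1),
            residue_index=np.array(rows["residue_index"], dtype=int),
            residue_name=rows["residue_name"],
            atom_name=rows["atom_name"],
            element=rows["element"],
            chain_tag=rows["chain_tag"],
        )

    fixed = build(spec["fixed_chains"], "fixed", "fixed")
    mobile = build(spec["mobile_chains"], "mobile", "mobile")

    subdomains = {}
    for lb in SUBDOMAIN_LABELS:
        sd = spec["subdomains"][lb]
        subdomains[lb] = SubdomainAssignment(
            label=lb, chain_tag=str(sd["chain"]), start=int(sd["start"]), end=int(sd["end"])
        )
        sub = mobile if subdomains[lb].on_mobile else fixed
        if not sub.mask_residues(subdomains[lb].chain_tag, subdomains[lb].start,
                                 subdomains[lb].end).any():
            raise ConfigurationError(
                f"subdomain {lb}: chain {sd['chain']!r} residues "
                f"{sd['start']}-{sd['end']} not present in the {sub.role} subunit"
            )

    tails = []
    tail_spec = spec.get("tail_contact_residues")
    if tail_spec:
        chain = str(tail_spec["chain"])
        for res in tail_spec["residues"]:
            tails.append((chain, int(res)))

    return ComplexModel(fixed=fixed, mobile=mobile, subdomains=subdomains,
                        tail_contact_residues=tails)


def write_complex(model: ComplexModel, path: str | Path, remark: str | None = None) -> None:
    """Write the normalized complex (heavy atoms, native placement) as PDB."""
    import gemmi

    st = gemmi.Structure()
    st.name = "tcomplex"
    md = gemmi.Model("1")
    serial = 0
    for sub in (model.fixed, model.mobile):
        for cname in dict.fromkeys(sub.chain_tag):  # preserve order, unique
            chain = gemmi.Chain(str(cname))
            sel = np.flatnonzero(sub.chain_tag == cname)
            residue = None
            last_key = None
            for i in sel:
                key = (int(sub.residue_index[i]), str(sub.residue_name[i]))
                if key != last_key:
                    residue = gemmi.Residue()
                    residue.seqid = gemmi.SeqId(key[0], " ")
                    residue.name = key[1]
                    chain.add_residue(residue)
                    last_key = key
                atom = gemmi.Atom()
                atom.name = str(sub.atom_name[i])
                atom.element = gemmi.Element(str(sub.element[i]))
                atom.pos = gemmi.Position(*sub.coords[i])
                atom.occ = 1.0
                serial += 1
                atom.serial = serial
                chain[-1].add_atom(atom)
            md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    if remark:
        st.raw_remarks = [f"REMARK 999 {line}" for line in remark.splitlines()]
    st.write_pdb(str(path))


@dataclass(frozen=True)
class ValidationReport:
    """Native-configuration sanity check."""

    min_cross_distance: float
    interface_pairs: int
    clash_distance: float
    interface_cutoff: float

    @property
    def clash_free(self) -> bool:
        return self.min_cross_distance >= self.clash_distance


def validate_native(
    model: ComplexModel,
    clash_distance: float = 2.8,
    interface_cutoff: float = 5.0,
) -> ValidationReport:
    """Confirm the native placement is clash-free with a non-empty interface.

    Raises :class:`NativeClashError` if any cross-subunit heavy-atom pair is
    closer than ``clash_distance`` (the sampler would then reject the native
    well itself) and :class:`EmptyInterfaceError` if no pair is within the
    interface cutoff.
    """
    from scipy.spatial import cKDTree

    tree = cKDTree(model.fixed.coords)
    dmin = tree.query(model.mobile.coords, k=1)[0].min()
    npairs = int(tree.count_neighbors(cKDTree(model.mobile.coords), interface_cutoff))
    # count_neighbors uses <=; the interface rule is strict <, but for the
    # validation report only the emptiness matters and ties are measure-zero
    report = ValidationReport(
        min_cross_distance=float(dmin),
        interface_pairs=npairs,
        clash_distance=clash_distance,
        interface_cutoff=interface_cutoff,
    )
    if dmin < clash_distance:
        raise NativeClashError(
            f"native configuration has a cross-subunit distance of {dmin:.2f} A "
            f"< clash distance {clash_distance:.2f} A"
        )
    if npairs == 0:
        raise EmptyInterfaceError(
            f"no cross-subunit pairs within {interface_cutoff:.1f} A "
            f"(min distance {dmin:.1f} A)"
        )
    return report
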