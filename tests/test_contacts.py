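"""Interface detection, locus thinning, and contact counting vs oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import tcomplex as tc
from tcomplex.contacts import (
    NATIVE_TOLERANCE,
    NONNATIVE_MARGIN,
    InterfacePair,
    InteractionLocusSet,
)
from tcomplex.errors import EmptyInterfaceError


# ---------------------------------------------------------------------------
# independent oracles (literal re-implementations of the stated rules)
# ---------------------------------------------------------------------------

def oracle_interface(fixed, mobile, cutoff=5.0):
    pairs = []
    for i, f in enumerate(fixed):
        for j, m in enumerate(mobile):
            d = float(np.linalg.norm(f - m))
            if d < cutoff:
                pairs.append((i, j, d))
    pairs.sort(key=lambda p: (p[2], p[0], p[1]))
    return pairs


def oracle_thinning(pairs, fixed, mobile, radius=3.5):
    kept = []
    for i, j, d in sorted(pairs, key=lambda p: (p[2], p[0], p[1])):
        conflict = False
        for ki, kj, _ in kept:
            if np.linalg.norm(fixed[i] - fixed[ki]) < radius:
                conflict = True
                break
            if np.linalg.norm(mobile[j] - mobile[kj]) < radius:
                conflict = True
                break
        if not conflict:
            kept.append((i, j, d))
    return kept


def oracle_count(loci: InteractionLocusSet, mobile_coords, fixed_coords):
    radius_f = loci.contact_radius_fixed
    radius_m = loci.contact_radius_mobile
    native_set = {(p.fixed_index, p.mobile_index) for p in loci.retained_pairs}
    n = 0
    for p in loci.retained_pairs:
        d = np.linalg.norm(fixed_coords[p.fixed_index] - mobile_coords[p.mobile_index])
        if d <= p.native_distance + NATIVE_TOLERANCE:
            n += 1
    for fi in loci.fixed_loci:
        for mi in loci.mobile_loci:
            if (fi, mi) in native_set:
                continue
            d = np.linalg.norm(fixed_coords[fi] - mobile_coords[mi])
            if d < radius_f[fi] + radius_m[mi] + NONNATIVE_MARGIN:
                n += 1
    return n


# ---------------------------------------------------------------------------
# find_interface
# ---------------------------------------------------------------------------

def test_interface_cutoff_is_strict():
    class M:
        pass

    def subunit(coords, role, chain):
        n = len(coords)
        return tc.RigidSubunit(
            name=role, role=role, coords=np.asarray(coords, float),
            atom_id=np.arange(1, n + 1), residue_index=np.arange(1, n + 1),
            residue_name=["X"] * n, atom_name=["C"] * n,
            element=["C"] * n, chain_tag=[chain] * n)

    base = [[0.0, 0, 0], [0, 3, 0], [0, 0, 3], [3, 0, 0]]
    m = M()
    m.fixed = subunit(base, "fixed", "A")
    m.tail_mask = lambda: np.zeros(4, dtype=bool)

    m.mobile = subunit([[4.9, 0, 0], [30, 0, 0], [30, 3, 0], [30, 0, 3]], "mobile", "B")
    pairs = tc.find_interface(m)
    assert any(p.fixed_index == 3 and p.mobile_index == 0 for p in pairs)
    assert min(p.native_distance for p in pairs) == pytest.approx(1.9)

    m.mobile = subunit([[8.0, 0, 0], [30, 0, 0], [30, 3, 0], [30, 0, 3]], "mobile", "B")
    # closest cross pair now exactly 5.0 -> excluded (strict <)
    with pytest.raises(EmptyInterfaceError):
        tc.find_interface(m)


def test_interface_matches_brute_force_on_toy(toy_model, toy_pairs):
    expected = oracle_interface(toy_model.fixed.coords, toy_model.mobile.coords)
    got = [(p.fixed_index, p.mobile_index, p.native_distance) for p in toy_pairs]
    assert len(got) == len(expected)
    for (gi, gj, gd), (ei, ej, ed) in zip(got, expected):
        assert (gi, gj) == (ei, ej)
        assert gd == pytest.approx(ed, abs=1e-12)


# ---------------------------------------------------------------------------
# select_interaction_loci
# ---------------------------------------------------------------------------

def test_thinning_keeps_well_separated_and_drops_duplicates():
    fixed = np.array([[0.0, 0, 0], [10, 0, 0]])
    mobile = np.array([[0.0, 4, 0], [10, 4, 0]])
    pairs = [InterfacePair(0, 0, 4.0), InterfacePair(1, 1, 4.0),
             InterfacePair(0, 0, 4.0)]  # exact duplicate must be eliminated
    loci = tc.select_interaction_loci(pairs, fixed_coords=fixed, mobile_coords=mobile)
    assert loci.native_count == 2
    assert loci.contact_radius_fixed[0] == pytest.approx(2.0)


def test_thinning_matches_independent_oracle_on_random_pairs():
    rng = np.random.default_rng(42)
    fixed = rng.uniform(-10, 10, size=(30, 3))
    mobile = rng.uniform(-10, 10, size=(30, 3))
    pairs = [InterfacePair(int(i), int(j), float(rng.uniform(2.0, 4.9)))
             for i, j in zip(rng.integers(0, 30, 50), rng.integers(0, 30, 50))]
    loci = tc.select_interaction_loci(pairs, fixed_coords=fixed, mobile_coords=mobile)
    kept = oracle_thinning([(p.fixed_index, p.mobile_index, p.native_distance)
                            for p in pairs], fixed, mobile)
    assert [(p.fixed_index, p.mobile_index) for p in loci.retained_pairs] == \
        [(i, j) for i, j, _ in kept]


def test_thinning_is_maximal(toy_model, toy_pairs, toy_loci):
    """Every eliminated pair conflicts with some retained pair."""
    kept_f = toy_model.fixed.coords[[p.fixed_index for p in toy_loci.retained_pairs]]
    kept_m = toy_model.mobile.coords[[p.mobile_index for p in toy_loci.retained_pairs]]
    retained = {(p.fixed_index, p.mobile_index) for p in toy_loci.retained_pairs}
    for p in toy_pairs:
        if (p.fixed_index, p.mobile_index) in retained:
            continue
        df = np.linalg.norm(kept_f - toy_model.fixed.coords[p.fixed_index], axis=1)
        dm = np.linalg.norm(kept_m - toy_model.mobile.coords[p.mobile_index], axis=1)
        assert (df < 3.5).any() or (dm < 3.5).any()


def test_contact_radii_are_half_native_distance(toy_loci):
    for p in toy_loci.retained_pairs:
        assert toy_loci.contact_radius_fixed[p.fixed_index] <= 0.5 * p.native_distance + 1e-12
        assert toy_loci.contact_radius_mobile[p.mobile_index] <= 0.5 * p.native_distance + 1e-12


# ---------------------------------------------------------------------------
# count_contacts
# ---------------------------------------------------------------------------

def test_native_count_and_distant_zero(toy_model, toy_loci):
    nc = toy_loci.count_contacts(toy_model.mobile.coords, toy_model.fixed.coords)
    assert nc >= toy_loci.native_count
    far = toy_model.mobile.coords + np.array([100.0, 0.0, 0.0])
    assert toy_loci.count_contacts(far, toy_model.fixed.coords) == 0


def test_count_matches_brute_force_on_random_configurations(toy_model, toy_loci, toy_geometry):
    rng = np.random.default_rng(7)
    for _ in range(200):
        r = rng.normal(scale=4.0, size=3) + toy_geometry.native_r
        e = rng.normal(size=3)
        e /= np.linalg.norm(e)
        chi = rng.uniform(-180.0, 180.0)
        placed = tc.compose_transform(r, e, chi, toy_geometry).apply(toy_model.mobile.coords)
        assert toy_loci.count_contacts(placed, toy_model.fixed.coords) == \
            oracle_count(toy_loci, placed, toy_model.fixed.coords)


def test_count_invariant_under_joint_rigid_motion(toy_model, toy_loci):
    rng = np.random.default_rng(3)
    nc0 = toy_loci.count_contacts(toy_model.mobile.coords, toy_model.fixed.coords)
    for _ in range(5):
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-20, 20, 3)
        fixed = toy_model.fixed.coords @ R.T + t
        mobile = toy_model.mobile.coords @ R.T + t
        assert toy_loci.count_contacts(mobile, fixed) == nc0


def test_monotone_in_tolerances(toy_model, toy_loci, toy_geometry):
    """Widening native tolerance or nonnative margin never lowers N_c."""
    rng = np.random.default_rng(11)
    placed = tc.compose_transform(
        toy_geometry.native_r + [1.5, 0.5, -0.5],
        toy_geometry.native_e, 8.0, toy_geometry).apply(toy_model.mobile.coords)

    def count_with(native_tol, nonnative_margin):
        native_set = {(p.fixed_index, p.mobile_index) for p in toy_loci.retained_pairs}
        n = 0
        for p in toy_loci.retained_pairs:
            d = np.linalg.norm(toy_model.fixed.coords[p.fixed_index] - placed[p.mobile_index])
            if d <= p.native_distance + native_tol:
                n += 1
        for fi in toy_loci.fixed_loci:
            for mi in toy_loci.mobile_loci:
                if (fi, mi) in native_set:
                    continue
                d = np.linalg.norm(toy_model.fixed.coords[fi] - placed[mi])
                if d < (toy_loci.contact_radius_fixed[fi]
                        + toy_loci.contact_radius_mobile[mi] + nonnative_margin):
                    n += 1
        return n

    base = count_with(3.5, 2.5)
    assert count_with(4.5, 2.5) >= base
    assert count_with(3.5, 3.5) >= base
    assert base == toy_loci.count_contacts(placed, toy_model.fixed.coords)


def test_batched_counting_agrees_with_scalar(toy_model, toy_loci, toy_geometry):
    rng = np.random.default_rng(5)
    batch = []
    for _ in range(16):
        r = rng.normal(scale=3.0, size=3) + toy_geometry.native_r
        e = rng.normal(size=3)
        e /= np.linalg.norm(e)
        batch.append(tc.compose_transform(r, e, rng.uniform(-180, 180), toy_geometry)
                     .apply(toy_model.mobile.coords))
    batch = np.stack(batch)
    many = toy_loci.count_contacts_many(batch, toy_model.fixed.coords)
    each = [toy_loci.count_contacts(b, toy_model.fixed.coords) for b in batch]
    assert list(many) == each


def test_locus_table_exports_one_row_per_pair(toy_model, toy_loci):
    table = toy_loci.to_table(toy_model)
    assert len(table) == toy_loci.native_count
    assert (table["native_distance"] < 5.0).all()
    assert (table["radius_fixed"] * 2 <= table["native_distance"] + 1e-9).all()
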