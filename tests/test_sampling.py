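"""Rigid-body (r, e, chi) parameterization and uniform sampling laws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation
from scipy.stats import kstest

import tcomplex as tc
from tcomplex.errors import DegenerateStructureError, SamplingError
from tcomplex.sampling import iter_clashfree_batches, wrap_angle


def test_wrap_angle_range_and_periodicity():
    xs = np.array([-540.0, -360.0, -180.0, -1e-9, 0.0, 179.999, 180.0, 181.0, 359.0, 720.0])
    w = wrap_angle(xs)
    assert (w > -180.0).all() and (w <= 180.0).all()
    assert wrap_angle(180.0) == 180.0
    assert wrap_angle(-180.0) == 180.0
    assert np.allclose(np.cos(np.deg2rad(w)), np.cos(np.deg2rad(xs)))
    assert np.allclose(np.sin(np.deg2rad(w)), np.sin(np.deg2rad(xs)))


# ---------------------------------------------------------------------------
# binding-surface geometry
# ---------------------------------------------------------------------------

def test_binding_surface_centers_single_pair_and_average(toy_model, toy_pairs):
    cf, cm = tc.binding_surface_centers(toy_model, toy_pairs)
    fidx = np.unique([p.fixed_index for p in toy_pairs])
    midx = np.unique([p.mobile_index for p in toy_pairs])
    assert np.allclose(cf, toy_model.fixed.coords[fidx].mean(axis=0))
    assert np.allclose(cm, toy_model.mobile.coords[midx].mean(axis=0))
    one = [toy_pairs[0]]
    cf1, cm1 = tc.binding_surface_centers(toy_model, one)
    assert np.allclose(cf1, toy_model.fixed.coords[one[0].fixed_index])
    assert np.allclose(cm1, toy_model.mobile.coords[one[0].mobile_index])


def test_native_axis_matches_eigensolver(toy_model, toy_pairs):
    e = tc.native_body_axis(toy_model, toy_pairs)
    fidx = np.unique([p.fixed_index for p in toy_pairs])
    midx = np.unique([p.mobile_index for p in toy_pairs])
    pts = np.vstack([toy_model.fixed.coords[fidx], toy_model.mobile.coords[midx]])
    centered = pts - pts.mean(axis=0)
    w, v = np.linalg.eigh(np.cov(centered.T))
    expected = v[:, 0]
    assert abs(abs(e @ expected) - 1.0) < 1e-9
    cf, cm = tc.binding_surface_centers(toy_model, toy_pairs)
    assert e @ (cm - cf) > 0  # sign points toward the mobile side


def test_native_axis_planar_and_degenerate_cases(toy_model):
    from tcomplex.contacts import InterfacePair

    class M:
        pass

    def planar_model(zjitter):
        m = M()
        rng = np.random.default_rng(0)
        f = np.column_stack([rng.uniform(-5, 5, 10), rng.uniform(-5, 5, 10),
                             np.zeros(10) + zjitter * rng.normal(size=10)])
        mob = f + [0.0, 0.0, 3.0]

        class S:
            pass

        m.fixed = S()
        m.fixed.coords = f
        m.mobile = S()
        m.mobile.coords = mob
        return m

    m = planar_model(0.0)
    pairs = [InterfacePair(i, i, 3.0) for i in range(10)]
    e = tc.native_body_axis(m, pairs)
    # interface atoms straddle two parallel z planes; normal is +/- z, resolved to mobile
    assert np.allclose(np.abs(e), [0, 0, 1], atol=1e-9)
    assert e[2] > 0

    # collinear atoms -> degenerate plane
    m.fixed.coords = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
    m.mobile.coords = m.fixed.coords.copy()
    with pytest.raises(DegenerateStructureError):
        tc.native_body_axis(m, pairs)


# ---------------------------------------------------------------------------
# compose / decompose transforms
# ---------------------------------------------------------------------------

def test_native_coordinates_give_identity(toy_geometry):
    tf = tc.compose_transform(toy_geometry.native_r, toy_geometry.native_e, 0.0,
                              toy_geometry)
    assert np.allclose(tf.rotation, np.eye(3), atol=1e-12)
    assert np.allclose(tf.translation, 0.0, atol=1e-9)


def test_chi_periodicity(toy_geometry, toy_model):
    e = toy_geometry.native_e
    a = tc.compose_transform(toy_geometry.native_r, e, 0.0, toy_geometry)
    b = tc.compose_transform(toy_geometry.native_r, e, 360.0, toy_geometry)
    pa = a.apply(toy_model.mobile.coords)
    pb = b.apply(toy_model.mobile.coords)
    assert np.abs(pa - pb).max() < 1e-6


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_compose_decompose_round_trip(toy_geometry, seed):
    rng = np.random.default_rng(seed)
    r = rng.normal(scale=4.0, size=3)
    e = rng.normal(size=3)
    e /= np.linalg.norm(e)
    chi = float(rng.uniform(-179.9, 179.9))
    tf = tc.compose_transform(r, e, chi, toy_geometry)
    assert abs(np.linalg.det(tf.rotation) - 1.0) < 1e-9
    assert np.allclose(tf.rotation @ tf.rotation.T, np.eye(3), atol=1e-9)
    r2, e2, chi2 = tc.decompose_transform(tf, toy_geometry)
    assert np.allclose(r2, r, atol=1e-6)
    assert np.allclose(e2, e, atol=1e-9)
    assert chi2 == pytest.approx(chi, abs=1e-6)


# ---------------------------------------------------------------------------
# sampling laws (point subunits, no clashes possible)
# ---------------------------------------------------------------------------

def _collect(model, geometry, n, seed, r_cut=10.0):
    spec = tc.SamplingSpec(r_cut=r_cut, clash_distance=0.0, target_clashfree=n,
                           seed=seed, batch_size=16384)
    rs, es, chis = [], [], []
    for r, e, chi, _ in iter_clashfree_batches(model, None, spec, geometry):
        rs.append(r)
        es.append(e)
        chis.append(chi)
    return np.vstack(rs), np.vstack(es), np.concatenate(chis)


def test_displacement_and_spin_distributions(point_model):
    model, geometry = point_model
    r, e, chi = _collect(model, geometry, 100_000, seed=123)
    # |r| has CDF (x / r_cut)^3
    ks_r = kstest(np.linalg.norm(r, axis=1), lambda x: (x / 10.0) ** 3)
    assert ks_r.pvalue > 0.01
    # chi uniform on (-180, 180]
    ks_chi = kstest(chi, "uniform", args=(-180.0, 360.0))
    assert ks_chi.pvalue > 0.01
    # e uniform on the sphere: z-component uniform on [-1, 1]
    ks_e = kstest(e[:, 2], "uniform", args=(-1.0, 2.0))
    assert ks_e.pvalue > 0.01


def test_composed_rotations_are_haar_uniform(point_model):
    """Rotation angle of the composed rotation follows (1-cos t)/pi."""
    model, geometry = point_model
    _, e, chi = _collect(model, geometry, 20_000, seed=5)
    from tcomplex.sampling import _rotations

    rots = _rotations(geometry.native_e, e, chi)
    angles = rots.magnitude()  # in [0, pi]
    ks = kstest(angles, lambda t: (t - np.sin(t)) / np.pi)
    assert ks.pvalue > 0.01


def test_seeded_streams_are_bit_reproducible(point_model):
    model, geometry = point_model
    a = _collect(model, geometry, 5_000, seed=99)
    b = _collect(model, geometry, 5_000, seed=99)
    for x, y in zip(a, b):
        assert np.array_equal(x, y)
    c = _collect(model, geometry, 5_000, seed=100)
    assert not np.array_equal(a[2], c[2])


def test_configuration_stream_attaches_nc(toy_model, toy_loci, toy_geometry):
    spec = tc.SamplingSpec(r_cut=8.0, target_clashfree=200, seed=1, batch_size=4096)
    configs = list(tc.sample_configurations(toy_model, toy_loci, spec, toy_geometry))
    assert len(configs) == 200
    assert all(c.clash_free for c in configs)
    for c in configs[:20]:
        placed = c.mobile_coords(toy_model, toy_geometry)
        assert c.n_c == toy_loci.count_contacts(placed, toy_model.fixed.coords)


def test_clash_test_matches_all_pairs_oracle(toy_model, toy_geometry):
    from tcomplex._kernels import clash_mask

    rng = np.random.default_rng(17)
    rots, trans, expected = [], [], []
    for _ in range(64):
        r = rng.normal(scale=4.0, size=3) + toy_geometry.native_r
        e = rng.normal(size=3)
        e /= np.linalg.norm(e)
        tf = tc.compose_transform(r, e, rng.uniform(-180, 180), toy_geometry)
        rots.append(tf.rotation)
        trans.append(tf.translation)
        placed = tf.apply(toy_model.mobile.coords)
        d = np.linalg.norm(placed[:, None, :] - toy_model.fixed.coords[None], axis=2)
        expected.append(bool((d < 2.8).any()))
    got = clash_mask(toy_model.fixed.coords, toy_model.mobile.coords,
                     np.stack(rots), np.stack(trans), 2.8)
    assert list(got) == expected


def test_native_configuration_accepted_by_sampler(toy_model, toy_loci, toy_geometry):
    from tcomplex._kernels import has_clash

    assert not has_clash(toy_model.fixed.coords, toy_model.mobile.coords, 2.8)


def test_sampler_aborts_when_fraction_collapses(toy_model, toy_loci, toy_geometry):
    # the toy's clash-free fraction at this shell is far below 90%
    spec = tc.SamplingSpec(r_cut=8.0, target_clashfree=1_000_000,
                           min_clashfree_fraction=0.9, seed=0, batch_size=2048)
    with pytest.raises(SamplingError):
        list(iter_clashfree_batches(toy_model, toy_loci, spec, toy_geometry))


# ---------------------------------------------------------------------------
# r_cut determination
# ---------------------------------------------------------------------------

def test_rcut_grid_floor_for_point_subunits(point_model):
    model, geometry = point_model
    spec = tc.SamplingSpec(clash_distance=0.0, seed=1, rcut_pilot=2000)
    assert tc.determine_rcut(model, spec, geometry) == 2.0


def test_rcut_matches_hard_sphere_analytics(point_model):
    """Two point-like subunits with clash distance d: clash-free fraction is
    1 - (d / r_cut)^3, so the smallest grid value reaching fraction f is
    ceil(d / (1 - f)^(1/3))."""
    model, geometry = point_model
    d = 10.0
    f = 0.5
    spec = tc.SamplingSpec(clash_distance=d, min_clashfree_fraction=f,
                           seed=2, rcut_pilot=20000)
    expected = d / (1.0 - f) ** (1.0 / 3.0)  # 12.6 A
    got = tc.determine_rcut(model, spec, geometry)
    assert abs(got - np.ceil(expected)) <= 1.0


def test_ensemble_store_round_trip(tmp_path, toy_model, toy_loci, toy_geometry):
    spec = tc.SamplingSpec(r_cut=8.0, target_clashfree=500, seed=4, batch_size=4096)
    store = tc.run_sampling(toy_model, toy_loci, spec, toy_geometry)
    path = tmp_path / "ens.tsv"
    store.save(path)
    loaded = tc.EnsembleStore.load(path)
    assert np.array_equal(store.r, loaded.r)
    assert np.array_equal(store.e, loaded.e)
    assert np.array_equal(store.chi, loaded.chi)
    assert np.array_equal(store.n_c, loaded.n_c)
    assert loaded.meta["seed"] == 4
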