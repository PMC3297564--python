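import numpy as np
import pytest

import tcomplex as tc


@pytest.fixture(scope="session")
def toy():
    """Standard toy complex (no obstruction) with its ground truth."""
    return tc.make_toy_complex(tc.ToyComplexSpec(seed=0))


@pytest.fixture(scope="session")
def toy_obstructed():
    return tc.make_toy_complex(tc.ToyComplexSpec(seed=0, obstruction=True))


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_pairs(toy_model):
    return tc.find_interface(toy_model)


@pytest.fixture(scope="session")
def toy_loci(toy_model, toy_pairs):
    return tc.select_interaction_loci(toy_pairs, model=toy_model)


@pytest.fixture(scope="session")
def toy_geometry(toy_model, toy_pairs):
    return tc.BindingGeometry.from_model(toy_model, toy_pairs)


@pytest.fixture(scope="session")
def toy_assignment():
    """Assignment spec matching the toy complex written to PDB."""
    n = tc.ToyComplexSpec().atoms_per_subdomain
    return {
        "fixed_chains": ["A", "B"],
        "mobile_chains": ["C"],
        "subdomains": {
            "N1": {"chain": "B", "start": 1, "end": n},
            "C1": {"chain": "B", "start": 101, "end": 100 + n},
            "N2": {"chain": "C", "start": 1, "end": n},
            "C2": {"chain": "C", "start": 101, "end": 100 + n},
        },
    }


@pytest.fixture(scope="session")
def point_subunits():
    """Two tight 4-atom clusters acting as near-point subunits.

    Used for sampling-law checks where clashes are impossible
    (clash_distance = 0) and the binding geometry is supplied explicitly.
    """
    def cluster(center, name, role):
        offsets = np.array([
            [0.0, 0.0, 0.0], [0.05, 0.0, 0.0], [0.0, 0.05, 0.0], [0.0, 0.0, 0.05],
        ])
        coords = np.asarray(center) + offsets
        return tc.RigidSubunit(
            name=name, role=role, coords=coords,
            atom_id=np.arange(1, 5), residue_index=np.arange(1, 5),
            residue_name=["PNT"] * 4, atom_name=["C"] * 4,
            element=["C"] * 4, chain_tag=[name[0].upper()] * 4,
        )

    fixed = cluster([0.0, 0.0, 0.0], "fixed", "fixed")
    mobile = cluster([8.0, 0.0, 0.0], "mobile", "mobile")
    geometry = tc.BindingGeometry(
        fixed_center=fixed.coords.mean(axis=0),
        mobile_center=mobile.coords.mean(axis=0),
        native_e=np.array([1.0, 0.0, 0.0]),
    )
    return fixed, mobile, geometry


class _BareModel:
    """Duck-typed stand-in for ComplexModel in sampler-level tests."""

    def __init__(self, fixed, mobile):
        self.fixed = fixed
        self.mobile = mobile


@pytest.fixture(scope="session")
def point_model(point_subunits):
    fixed, mobile, geometry = point_subunits
    return _BareModel(fixed, mobile), geometry
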