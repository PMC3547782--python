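import json

import pytest
from hypothesis import settings, HealthCheck
from rdkit import Chem

from screenlib import MoleculeStore, import_sdf
from screenlib.chem import mol_from_smiles, mol_to_molblock
from screenlib.fixtures import FixtureSpec, generate_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def mb(smiles: str) -> str:
    """Molblock from SMILES (test helper)."""
    return mol_to_molblock(mol_from_smiles(smiles))


#: Standard mixed fixture: 4 scaffold families of uneven size, acyclics,
#: one or two molecules per liability class, duplicates, a stereo pair and
#: corrupt records.
STD_SPEC = dict(
    n_scaffold_families=4,
    members_per_family=[6, 4, 3, 2],
    n_acyclic=3,
    n_flagged={
        "Reactive": 2,
        "Warhead": 2,
        "PAINS_lt15": 1,
        "PAINS_lt150": 2,
        "PAINS_gt150": 1,
    },
    n_duplicates=3,
    n_stereo_pairs=2,
    n_corrupt=2,
    seed=42,
)


@pytest.fixture(scope="session")
def std_fixture(tmp_path_factory):
    """(sdf path, manifest) for the standard mixed fixture."""
    d = tmp_path_factory.mktemp("fixture")
    sdf = d / "std.sdf"
    manifest = generate_fixture(FixtureSpec(**STD_SPEC), sdf, d / "std.json")
    return sdf, manifest


@pytest.fixture()
def store(std_fixture):
    """Fresh in-memory store populated from the standard fixture."""
    sdf, _ = std_fixture
    s = MoleculeStore(":memory:")
    import_sdf(s, sdf, "vendorA")
    yield s
    s.close()


@pytest.fixture()
def empty_store():
    s = MoleculeStore(":memory:")
    yield s
    s.close()
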