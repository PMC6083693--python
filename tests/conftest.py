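import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from rdkit import Chem

from ligopharm import GenerationConfig, Molecule, generate_conformers
from ligopharm.core import Conformer
from ligopharm.features import FeaturePoint, FeatureType
from ligopharm.synthetic import BenchmarkSpec, plant_pharmacophore

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def embed(smiles: str, name: str, seed: int = 7, max_conformers: int = 10) -> Molecule:
    m = Molecule(name, Chem.MolFromSmiles(smiles))
    return generate_conformers(
        m, GenerationConfig(max_conformers=max_conformers, seed=seed)
    )


@pytest.fixture(scope="session")
def benzene():
    return embed("c1ccccc1", "benzene")


@pytest.fixture(scope="session")
def phenol():
    return embed("Oc1ccccc1", "phenol")


@pytest.fixture(scope="session")
def butane():
    return embed("CCCC", "butane")


def make_cloud(points: list[tuple[FeatureType, tuple]], mol_id: str = "cloud") -> Molecule:
    """A feature-cloud molecule from (type, xyz) tuples."""
    feats = [FeaturePoint(t, np.asarray(p, dtype=float), (k,)) for k, (t, p) in enumerate(points)]
    coords = (
        np.array([f.position for f in feats]).reshape(-1, 3)
        if feats
        else np.zeros((0, 3))
    )
    return Molecule(
        id=mol_id, mol=None, conformers=[Conformer(coords, 0.0)], feature_sets=[feats]
    )


@pytest.fixture(scope="session")
def planted_exact():
    """A planted benchmark with zero jitter and no distractors: every
    training cloud is a rigid copy of the template."""
    spec = BenchmarkSpec(
        n_training=4, jitter_sd=0.0, extra_features_per_mol=0, seed=5
    )
    template, training = plant_pharmacophore(spec)
    return spec, template, training
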