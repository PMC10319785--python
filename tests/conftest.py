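"""Shared fixtures: small parsed molecules and the session-scoped
synthetic dataset + trained scaled model used by the heavier tests."""

import numpy as np
import pytest

import graphccs as g
from graphccs.synthetic import OracleConfig, SyntheticDatasetSpec, make_dataset


def _with_conformer(smiles: str, seed: int = 7) -> g.Molecule:
    mol = g.parse_molecule(smiles)
    g.generate_conformer(mol, seed=seed)
    return mol


@pytest.fixture(scope="session")
def methane():
    return _with_conformer("C")


@pytest.fixture(scope="session")
def benzene():
    return _with_conformer("c1ccccc1")


@pytest.fixture(scope="session")
def ethanol():
    return _with_conformer("CCO")


@pytest.fixture(scope="session")
def synthetic_records():
    """Default-condition synthetic dataset: 500 molecules x 3 adducts."""
    spec = SyntheticDatasetSpec(n_molecules=500, seed=0)
    return make_dataset(spec, OracleConfig(seed=0))


@pytest.fixture(scope="session")
def synthetic_split(synthetic_records):
    """Molecule-level 400 train / 100 test partition of the session dataset."""
    by_mol = {}
    for rec in synthetic_records:
        by_mol.setdefault(rec.identifier, []).append(rec)
    ids = sorted(by_mol)
    rng = np.random.default_rng(0)
    rng.shuffle(ids)
    train = [r for i in ids[:400] for r in by_mol[i]]
    test = [r for i in ids[400:] for r in by_mol[i]]
    return train, test


@pytest.fixture(scope="session")
def trained_model(synthetic_split):
    """Scaled network (2 ECC x 8 channels, 3 FC layers) fit on the
    400-molecule synthetic training set."""
    train, _ = synthetic_split
    tr, va = g.split(train, (0.9, 0.1), seed=0)
    model, _ = g.fit(tr, va, g.ModelConfig.scaled(seed=0))
    return model
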