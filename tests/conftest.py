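"""Shared fixtures: hand-written bonded molecules and the planted-signal
synthetic dataset used by the modeling and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Geometry import Point3D

import dipolegrid as dg
from dipolegrid.structures import Atom, Molecule3D

# Canonical conditions for the planted-signal study: 500 molecules,
# label = |point-charge DM, scheme N| + N(0, 0.3 D), one-third test split.
PLANTED_N = 500
PLANTED_NOISE_SD = 0.3
PLANTED_SEED = 0
TEST_FRACTION = 1.0 / 3.0


def bonded_molecule(name, atoms, bonds, formal_charges=None):
    """Build a Molecule3D with RDKit connectivity from literal geometry.

    ``atoms`` is a list of (element, x, y, z); ``bonds`` of
    (i, j, order) with 0-based indices.
    """
    rw = Chem.RWMol()
    for k, (el, *_xyz) in enumerate(atoms):
        a = Chem.Atom(el)
        if formal_charges:
            a.SetFormalCharge(formal_charges[k])
        rw.AddAtom(a)
    for i, j, order in bonds:
        rw.AddBond(i, j, Chem.BondType.values[order])
    conf = Chem.Conformer(len(atoms))
    for k, (_el, x, y, z) in enumerate(atoms):
        conf.SetAtomPosition(k, Point3D(x, y, z))
    rw.AddConformer(conf)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    mol.SetProp("_Name", name)
    m3d = Molecule3D(
        name,
        [Atom(el, np.array([x, y, z])) for el, x, y, z in atoms],
        Chem.GetFormalCharge(mol),
        rdkit_mol=mol,
    )
    return m3d


@pytest.fixture
def methane():
    d = 0.6289
    return bonded_molecule(
        "methane",
        [("C", 0, 0, 0), ("H", d, d, d), ("H", -d, -d, d),
         ("H", -d, d, -d), ("H", d, -d, -d)],
        [(0, 1, 1), (0, 2, 1), (0, 3, 1), (0, 4, 1)],
    )


@pytest.fixture
def water():
    return bonded_molecule(
        "water",
        [("O", 0, 0, 0.1173), ("H", 0, 0.7572, -0.4692), ("H", 0, -0.7572, -0.4692)],
        [(0, 1, 1), (0, 2, 1)],
    )


@pytest.fixture
def acetonitrile():
    return bonded_molecule(
        "acetonitrile",
        [("C", 0, 0, -1.180), ("C", 0, 0, 0.278), ("N", 0, 0, 1.436),
         ("H", 0.507, 0.886, -1.561), ("H", 0.507, -0.886, -1.561),
         ("H", -1.026, 0, -1.561)],
        [(0, 1, 1), (1, 2, 3), (0, 3, 1), (0, 4, 1), (0, 5, 1)],
    )


@pytest.fixture
def chloromethane():
    return bonded_molecule(
        "chloromethane",
        [("C", 0, 0, 0), ("Cl", 0, 0, 1.785), ("H", 1.037, 0, -0.366),
         ("H", -0.518, 0.898, -0.366), ("H", -0.518, -0.898, -0.366)],
        [(0, 1, 1), (0, 2, 1), (0, 3, 1), (0, 4, 1)],
    )


@pytest.fixture(scope="session")
def planted_data():
    """500-molecule planted-signal dataset featurized under MACCS_DM."""
    records = dg.generate_labeled_dataset(
        PLANTED_N, noise_sd=PLANTED_NOISE_SD, seed=PLANTED_SEED
    )
    mols = [r.molecule for r in records]
    y = np.array([r.dm_label for r in records])
    X = dg.MoleculeFeaturizer("MACCS_DM").fit(mols).transform(mols)
    train_idx, test_idx = dg.random_split(
        list(range(PLANTED_N)), TEST_FRACTION, seed=PLANTED_SEED
    )
    return {
        "records": records,
        "X": X,
        "y": y,
        "train_idx": np.array(train_idx),
        "test_idx": np.array(test_idx),
    }


@pytest.fixture(scope="session")
def planted_bundle(planted_data):
    """Forest trained on the planted training rows (OOB-tuned mtry)."""
    d = planted_data
    return dg.train_rf(
        d["X"].iloc[d["train_idx"]], d["y"][d["train_idx"]], seed=PLANTED_SEED
    )
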