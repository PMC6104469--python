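"""RDF, PchmDM, MACCS and feature-assembly behavior."""

import numpy as np
import pytest

import dipolegrid as dg
from dipolegrid.descriptors import (
    PAIR_CLASSES,
    PchmConfig,
    RDFConfig,
    dm_axis,
    maccs_block,
    pchm_block,
)
from dipolegrid.structures import Atom, Molecule3D

NITRILE_MACCS_KEY = 41  # C#N substructure key


def _pair(q1=1.0, q2=-1.0, d=1.0):
    return Molecule3D(
        "pair",
        [Atom("H", [0, 0, 0], {"N": q1}), Atom("H", [d, 0, 0], {"N": q2})],
    )


class TestRDF:
    def test_single_opposite_pair_at_exact_grid_distance(self):
        mol = _pair(1.0, -1.0, d=1.0)
        blk = dg.rdf_pair_block(mol, "N", "mixed")
        grid = RDFConfig().grid
        k = int(np.flatnonzero(np.isclose(grid, 1.0))[0])
        assert blk.values[k] == pytest.approx(-1.0)  # exponent 0, product -1
        for pc in ("both_positive", "both_negative"):
            np.testing.assert_array_equal(
                dg.rdf_pair_block(mol, "N", pc).values, 0.0
            )

    def test_gaussian_decay_one_angstrom_off(self):
        mol = _pair(1.0, -1.0, d=1.0)
        blk = dg.rdf_pair_block(mol, "N", "mixed")
        grid = RDFConfig().grid
        k = int(np.flatnonzero(np.isclose(grid, 2.0))[0])
        assert abs(blk.values[k]) < 1e-40  # exp(-100)

    def test_single_atom_all_blocks_zero(self):
        mol = Molecule3D("one", [Atom("C", [0, 0, 0], {"N": 0.3})])
        full = dg.rdf_full(mol, "N")
        np.testing.assert_array_equal(full.values, 0.0)
        assert len(full) == 384

    def test_all_positive_charges_only_middle_third_nonzero(self):
        mol = Molecule3D(
            "pos",
            [Atom("H", [0, 0, 0], {"N": 0.2}), Atom("H", [1, 0, 0], {"N": 0.3})],
        )
        v = dg.rdf_full(mol, "N").values
        np.testing.assert_array_equal(v[:128], 0.0)  # mixed
        assert v[128:256].max() > 0  # both_positive
        np.testing.assert_array_equal(v[256:], 0.0)  # both_negative

    def test_mixed_block_nonpositive_like_blocks_nonnegative(self):
        mol = dg.generate_molecule(dg.SynthConfig(seed=11))
        assert dg.rdf_pair_block(mol, "N", "mixed").values.max() <= 0
        assert dg.rdf_pair_block(mol, "N", "both_positive").values.min() >= 0
        assert dg.rdf_pair_block(mol, "N", "both_negative").values.min() >= 0

    def test_zero_charge_atoms_belong_to_no_class(self):
        mol = Molecule3D(
            "z",
            [
                Atom("H", [0, 0, 0], {"N": 0.0}),
                Atom("H", [1, 0, 0], {"N": 0.5}),
                Atom("H", [2, 0, 0], {"N": -0.5}),
            ],
        )
        # only the (+0.5, -0.5) pair exists, in the mixed class
        mixed = dg.rdf_pair_block(mol, "N", "mixed")
        both_pos = dg.rdf_pair_block(mol, "N", "both_positive")
        assert mixed.values.min() < 0
        np.testing.assert_array_equal(both_pos.values, 0.0)

    def test_missing_scheme_errors(self):
        mol = _pair()
        with pytest.raises(KeyError):
            dg.rdf_pair_block(mol, "P", "mixed")


class TestDmAxis:
    def test_axis_along_dipole(self):
        mol = _pair()
        dm = dg.point_charge_dipole(mol, "N")
        dm.vector = np.array([0.0, 0.0, 2.4])
        np.testing.assert_allclose(dm_axis(dm, mol), [0, 0, 1])

    def test_zero_dipole_linear_molecule_falls_back_to_principal_axis(self):
        mol = Molecule3D(
            "lin",
            [
                Atom("C", [-1.5, 0, 0], {"N": 0.0}),
                Atom("C", [0, 0, 0], {"N": 0.0}),
                Atom("C", [1.5, 0, 0], {"N": 0.0}),
            ],
        )
        dm = dg.point_charge_dipole(mol, "N")
        np.testing.assert_allclose(dm_axis(dm, mol), [1, 0, 0], atol=1e-12)

    def test_single_atom_degenerate_convention(self):
        mol = Molecule3D("one", [Atom("C", [0, 0, 0], {"N": 0.0})])
        dm = dg.point_charge_dipole(mol, "N")
        np.testing.assert_array_equal(dm_axis(dm, mol), [1, 0, 0])
        blk = pchm_block(mol, "N")
        charge_series = blk.values[:300]
        np.testing.assert_array_equal(charge_series, 0.0)


class TestPchm:
    def test_single_carbon_mass_lands_in_center_bin(self):
        mol = Molecule3D("c", [Atom("C", [0, 0, 0], {"N": 0.0})])
        blk = pchm_block(mol, "N")
        mass = blk.values[300:360]
        assert mass[30] == pytest.approx(12.011)  # bin [0, 0.5)
        assert mass.sum() == pytest.approx(12.011)

    @pytest.mark.parametrize("seed", [0, 5, 9])
    def test_partition_and_conservation_identities(self, seed):
        mol = dg.generate_molecule(dg.SynthConfig(seed=seed))
        v = pchm_block(mol, "N").values.reshape(6, 60)
        desc, plus, minus, noh, h, mass = v
        np.testing.assert_allclose(desc, plus + minus, atol=1e-9)
        np.testing.assert_allclose(desc, noh + h, atol=1e-9)
        assert desc.sum() == pytest.approx(
            mol.charge_array("N").sum(), abs=1e-9
        )
        assert mass.sum() == pytest.approx(mol.masses.sum())

    def test_out_of_range_projection_clamped_with_warning(self, caplog):
        cfg = PchmConfig(n_bins=4, bin_width=0.5, range_min=-1.0, range_max=1.0)
        mol = _pair(0.5, -0.5, d=6.0)
        with caplog.at_level("WARNING", logger="dipolegrid.descriptors"):
            blk = pchm_block(mol, "N", cfg)
        assert any("clamped" in m for m in caplog.messages)
        mass = blk.values[5 * 4:]
        assert mass.sum() == pytest.approx(mol.masses.sum())  # conserved

    def test_bin_tiling_validated(self):
        with pytest.raises(ValueError, match="span"):
            PchmConfig(n_bins=59, bin_width=0.5)


class TestMaccs:
    def test_exactly_166_binary_values(self, water):
        blk = maccs_block(water)
        assert len(blk) == 166
        assert set(np.unique(blk.values)) <= {0.0, 1.0}

    def test_nitrile_key(self, methane, acetonitrile):
        assert maccs_block(acetonitrile).values[NITRILE_MACCS_KEY - 1] == 1.0
        assert maccs_block(methane).values[NITRILE_MACCS_KEY - 1] == 0.0


class TestAssembly:
    @pytest.mark.parametrize(
        "recipe,length", [("C", 746), ("F", 912), ("MACCS_DM", 168)]
    )
    def test_recipe_lengths(self, recipe, length):
        mol = dg.generate_molecule(dg.SynthConfig(seed=2))
        block = dg.assemble_features(mol, recipe)
        assert len(block) == length
        assert block.labels[-2:] == ["DM_N", "DM_P"]
        assert len(set(block.labels)) == length

    def test_missing_scheme_listed_in_error(self):
        mol = Molecule3D("m", [Atom("C", [0, 0, 0], {"N": 0.0})])
        with pytest.raises(ValueError, match=r"\['P'\]"):
            dg.assemble_features(mol, "C")

    def test_featurizer_matches_assemble_and_orders_columns(self):
        mols = [dg.generate_molecule(dg.SynthConfig(seed=s), f"m{s}") for s in (1, 2)]
        feat = dg.MoleculeFeaturizer("MACCS_DM").fit(mols)
        X = feat.transform(mols)
        assert X.shape == (2, 168)
        assert list(X.columns) == feat.feature_names_
        block = dg.assemble_features(mols[0], "MACCS_DM")
        np.testing.assert_array_equal(X.iloc[0].to_numpy(), block.values)

    def test_featurizer_sklearn_clone_compatible(self):
        from sklearn.base import clone

        feat = dg.MoleculeFeaturizer("F")
        assert clone(feat).get_params()["recipe"] == "F"


class TestInvariance:
    """Rigid-motion invariance of every descriptor family."""

    @pytest.mark.parametrize("seed", [0, 1])
    def test_rotation_translation_invariance(self, seed):
        from scipy.stats import special_ortho_group

        mol = dg.generate_molecule(dg.SynthConfig(seed=seed))
        R = special_ortho_group.rvs(3, random_state=seed)
        shift = np.array([3.0, -2.0, 5.0])
        moved = Molecule3D(
            mol.id,
            [
                Atom(a.element, R @ a.coords + shift, dict(a.charges), a.mass)
                for a in mol.atoms
            ],
            mol.formal_charge,
        )
        for fn in (
            lambda m: dg.rdf_full(m, "N").values,
            lambda m: pchm_block(m, "N").values,
            lambda m: dg.assemble_features(m, "C").values,
        ):
            np.testing.assert_allclose(fn(moved), fn(mol), atol=1e-8)

    def test_atom_order_invariance(self):
        mol = dg.generate_molecule(dg.SynthConfig(seed=4))
        perm = np.random.default_rng(4).permutation(mol.n_atoms)
        permuted = Molecule3D(
            mol.id,
            [mol.atoms[i].copy() for i in perm],
            mol.formal_charge,
        )
        np.testing.assert_allclose(
            dg.assemble_features(permuted, "C").values,
            dg.assemble_features(mol, "C").values,
            atol=1e-10,
        )
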