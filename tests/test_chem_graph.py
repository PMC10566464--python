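"""Featurization: vertex features, adjacency stacks, conformer ensembles,
Boltzmann weights and geometric pair features."""

import numpy as np
import pytest
from rdkit import Chem

from spinsys.chem import (
    ELEMENTS,
    R_KCAL,
    ConformerEnsemble,
    FeatureConfig,
    MoleculeTooLargeError,
    UnsupportedElementError,
    boltzmann_weights,
    build_adjacency,
    build_pair_features,
    build_vertex_features,
    featurize,
    generate_conformers,
    mol_from_smiles,
    permute_graph,
)


class TestVertexFeatures:
    def test_methane_total_valence(self):
        mol = mol_from_smiles("C")
        x = build_vertex_features(mol)
        assert mol.GetNumAtoms() == 5
        carbon_row = x[[a.GetSymbol() == "C" for a in mol.GetAtoms()].index(True)]
        # total valence feature is scaled by 1/4
        assert carbon_row[len(ELEMENTS) + 2] == pytest.approx(1.0)

    def test_benzene_aromatic_and_ring_flags(self):
        mol = mol_from_smiles("c1ccccc1")
        x = build_vertex_features(mol)
        carbons = [i for i, a in enumerate(mol.GetAtoms()) if a.GetSymbol() == "C"]
        aromatic_col = len(ELEMENTS) + 5
        ring6_col = len(ELEMENTS) + 6 + 3  # ring sizes 3..8 -> size 6 at offset 3
        assert np.all(x[carbons, aromatic_col] == 1.0)
        assert np.all(x[carbons, ring6_col] == 1.0)

    def test_ammonium_formal_charge(self):
        mol = mol_from_smiles("[NH4+]")
        x = build_vertex_features(mol)
        n_idx = [a.GetSymbol() for a in mol.GetAtoms()].index("N")
        assert x[n_idx, len(ELEMENTS) + 3] == 1.0

    def test_element_whitelist_rejection(self):
        with pytest.raises(UnsupportedElementError):
            mol_from_smiles("CBr")

    def test_max_atoms_rejection(self):
        with pytest.raises(MoleculeTooLargeError):
            mol_from_smiles("C" * 50)  # 50 C + 102 H > 128


class TestAdjacency:
    def test_ethane_any_bond_count(self):
        adj = build_adjacency(mol_from_smiles("CC"))
        assert adj[..., 0].sum() == 14  # 7 bonds, symmetric

    def test_benzene_aromatic_slice(self):
        mol = mol_from_smiles("c1ccccc1")
        adj = build_adjacency(mol)
        assert adj[..., 4].sum() == 12  # 6 ring bonds
        # C-H bonds are single
        assert adj[..., 1].sum() == 12

    def test_bond_class_partition(self):
        # single-order molecule: class slices sum exactly to the any slice
        adj = build_adjacency(mol_from_smiles("CC(C)CO"))
        assert np.array_equal(adj[..., 1:].sum(axis=-1), adj[..., 0])

    def test_slices_symmetric_zero_diagonal(self):
        adj = build_adjacency(mol_from_smiles("C#CC=CC1CC1"))
        for s in range(5):
            assert np.array_equal(adj[..., s], adj[..., s].T)
            assert np.all(np.diag(adj[..., s]) == 0)
        assert np.array_equal(adj[..., 1:].max(axis=-1), adj[..., 0])


class TestConformers:
    def test_rigid_molecule_uniform_weights(self):
        ens = generate_conformers(mol_from_smiles("C"), 5, seed=3, mmff_iters=200)
        assert ens.n_conformers == 5
        assert np.allclose(ens.weights, 0.2, atol=1e-3)

    def test_determinism_bit_identical(self):
        mol = mol_from_smiles("CCCO")
        a = generate_conformers(mol, 3, seed=9)
        b = generate_conformers(mol, 3, seed=9)
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.energies, b.energies)

    def test_butane_torsional_modes(self):
        # anti vs gauche minima produce a multimodal terminal C-C distance
        mol = mol_from_smiles("CCCC")
        ens = generate_conformers(mol, 50, seed=1, mmff_iters=200)
        carbons = [i for i, a in enumerate(
            Chem.AddHs(Chem.MolFromSmiles("CCCC")).GetAtoms()) if a.GetSymbol() == "C"]
        d14 = np.linalg.norm(
            ens.coords[:, carbons[0]] - ens.coords[:, carbons[3]], axis=1
        )
        hist, _ = np.histogram(d14, bins=np.arange(2.0, 5.0, 0.5))
        occupied = hist > 0
        # at least two distinct occupied bins separated by structure
        assert occupied.sum() >= 2


class TestBoltzmann:
    def test_single_and_equal_energies(self):
        assert boltzmann_weights([3.0]) == pytest.approx([1.0])
        assert boltzmann_weights([1.0, 1.0]) == pytest.approx([0.5, 0.5])

    def test_rt_ln2_gives_two_thirds(self):
        t = 298.15
        de = R_KCAL * t * np.log(2.0)
        w = boltzmann_weights([0.0, de], t)
        assert w == pytest.approx([2.0 / 3.0, 1.0 / 3.0], abs=1e-12)

    def test_invariant_to_constant_shift(self):
        e = np.array([0.3, 1.7, 2.2])
        assert np.allclose(
            boltzmann_weights(e), boltzmann_weights(e + 123.4), atol=1e-12
        )

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            boltzmann_weights([])


def _diatomic_ensemble(d_values, weights):
    coords = np.array([[[0, 0, 0], [d, 0, 0]] for d in d_values], float)
    return ConformerEnsemble(
        coords=coords, energies=np.zeros(len(d_values)), weights=np.array(weights)
    )


class TestPairFeatures:
    def test_mean_distance_of_two_conformers(self):
        mol = Chem.AddHs(Chem.MolFromSmiles("[H][H]"))
        ens = _diatomic_ensemble([1.0, 3.0], [0.5, 0.5])
        feats = build_pair_features(mol, ens)
        assert feats[0, 1, 0] == pytest.approx(2.0)

    def test_gaussian_basis_matches_direct_evaluation(self):
        mol = Chem.AddHs(Chem.MolFromSmiles("[H][H]"))
        ens = _diatomic_ensemble([2.0], [1.0])
        cfg = FeatureConfig(gaussian_centers=(1.0, 2.0, 3.0), gaussian_sigma=0.5)
        feats = build_pair_features(mol, ens, cfg)
        expected = np.exp(-((2.0 - np.array([1.0, 2.0, 3.0])) ** 2) / (2 * 0.25))
        assert feats[0, 1, 1:4] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx([np.exp(-2), 1.0, np.exp(-2)])

    def test_linear_triatomic_terminal_angle_is_pi(self):
        mol = Chem.AddHs(Chem.MolFromSmiles("O=C=O"))  # O=C=O linear
        # order from RDKit: O, C, O
        coords = np.array([[[-1.16, 0, 0], [0, 0, 0], [1.16, 0, 0]]])
        ens = ConformerEnsemble(coords, np.zeros(1), np.ones(1))
        cfg = FeatureConfig()
        feats = build_pair_features(mol, ens, cfg)
        a_slice = 1 + len(cfg.gaussian_centers)
        assert feats[0, 2, a_slice] == pytest.approx(np.pi, abs=1e-6)
        assert feats[0, 2, a_slice + 1] == 1.0

    def test_all_slices_symmetric_and_distance_nonnegative(self):
        g = featurize(mol_from_smiles("CC(F)CO"), FeatureConfig(n_conformers=3), seed=2)
        for s in range(g.g_feat.shape[2]):
            assert np.allclose(g.g_feat[..., s], g.g_feat[..., s].T, atol=0)
        assert np.all(g.g_feat[..., 0] >= 0)
        assert np.all(np.diag(g.g_feat[..., 0]) == 0)


def test_pair_features_invariant_to_conformer_ordering(rng):
    mol = mol_from_smiles("CCCO")
    ens = generate_conformers(mol, 6, seed=2)
    perm = rng.permutation(ens.n_conformers)
    shuffled = ConformerEnsemble(
        ens.coords[perm], ens.energies[perm], ens.weights[perm]
    )
    a = build_pair_features(mol, ens)
    b = build_pair_features(mol, shuffled)
    assert np.allclose(a, b, atol=1e-12)


class TestPermutationCovariance:
    @pytest.mark.parametrize("smiles", ["CCO", "C1CC1CF", "CC(N)C(=O)O"])
    def test_feature_blocks_permute_exactly(self, smiles, rng):
        g = featurize(mol_from_smiles(smiles), FeatureConfig(n_conformers=2), seed=4)
        perm = rng.permutation(g.n_atoms)
        gp = permute_graph(g, perm)
        assert np.array_equal(gp.x, g.x[perm])
        assert np.array_equal(gp.g_adj, g.g_adj[np.ix_(perm, perm)])
        assert np.array_equal(gp.g_feat, g.g_feat[np.ix_(perm, perm)])


def test_rigid_features_independent_of_conformer_count():
    cfg5 = FeatureConfig(n_conformers=5, mmff_iters=2000, mmff_force_tol=1e-8)
    cfg50 = FeatureConfig(n_conformers=50, mmff_iters=2000, mmff_force_tol=1e-8)
    a = featurize(mol_from_smiles("C"), cfg5, seed=1)
    b = featurize(mol_from_smiles("C"), cfg50, seed=2)
    assert np.allclose(a.g_feat, b.g_feat, atol=1e-6)
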