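"""Network layers: message passing, decode, readouts, coupling masks."""

import networkx as nx
import numpy as np
import pytest
from rdkit import Chem

from spinsys._autodiff import Tensor
from spinsys.chem import FeatureConfig, featurize, mol_from_smiles, permute_graph
from spinsys.model import (
    COUPLING_CLASSES,
    DecodeLayer,
    MessagePassingLayer,
    ModelConfig,
    SpinSystemNetwork,
    coupling_class_masks,
)


def _net(graph, **kw):
    defaults = dict(
        hidden_dim=16,
        n_message_layers=2,
        n_decode_layers=2,
        n_bootstraps=2,
        dtype="float64",
        seed=7,
    )
    defaults.update(kw)
    cfg = ModelConfig(**defaults)
    return SpinSystemNetwork(cfg, graph.x.shape[1], graph.g_feat.shape[2]), cfg


@pytest.fixture(scope="module")
def ethanol_graph():
    return featurize(mol_from_smiles("CCO"), FeatureConfig(n_conformers=3), seed=5)


class TestMessagePassing:
    def test_single_step_moves_features_along_path(self):
        # path A-B-C with identity lifts: B receives A's feature, C nothing
        adj = np.zeros((1, 3, 3, 1))
        adj[0, 0, 1, 0] = adj[0, 1, 0, 0] = 1
        adj[0, 1, 2, 0] = adj[0, 2, 1, 0] = 1
        x = np.zeros((1, 3, 1))
        x[0, 0, 0] = 1.0  # one-hot on A
        out = adj[0, ..., 0] @ x[0]
        assert out[1, 0] == 1.0 and out[2, 0] == 0.0

    def test_power_two_connects_second_neighbors(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = 1
        a2 = a @ a
        assert a2[0, 2] == 1.0  # A and C connected via B

    def test_augmented_adjacency_includes_powers_and_identity(self, ethanol_graph):
        net, cfg = _net(ethanol_graph, adjacency_powers=(2, 3), include_self_loops=True)
        slices = net.augmented_adjacency(ethanol_graph.g_adj[None])
        assert len(slices) == cfg.n_adj_slices == 8
        any_bond = ethanol_graph.g_adj[..., 0]
        assert np.allclose(slices[5].data[0], any_bond @ any_bond)
        assert np.allclose(slices[7].data[0], np.eye(ethanol_graph.n_atoms))

    def test_zero_input_gives_zero_before_normalization(self, rng):
        layer = MessagePassingLayer(rng, 4, 8, 2, np.float64)
        x = Tensor(np.zeros((1, 3, 4)))
        adj = [Tensor(np.eye(3)[None]), Tensor(np.eye(3)[None])]
        acc = None
        for a, lift, coll in zip(adj, layer.lifts, layer.collects):
            term = coll(a @ lift(x))
            acc = term if acc is None else acc + term
        # biases are zero-initialized, so the pre-normalization signal is 0
        assert np.allclose(acc.data, 0.0)


class TestDecodeLayer:
    def test_output_shapes(self, rng):
        layer = DecodeLayer(rng, 16, "mean", np.float64)
        x = Tensor(rng.normal(size=(1, 4, 16)))
        g = Tensor(rng.normal(size=(1, 4, 4, 16)))
        g = (g + g.swapaxes(1, 2)) * 0.5
        vmask = Tensor(np.ones((1, 4, 1)))
        pmask = Tensor(np.ones((1, 4, 4, 1)))
        counts = Tensor(np.full((1, 1, 1), 0.25))
        x2, g2 = layer(x, g, vmask, pmask, counts)
        assert x2.shape == (1, 4, 16)
        assert g2.shape == (1, 4, 4, 16)

    def test_edge_state_symmetric_after_update(self, rng):
        layer = DecodeLayer(rng, 8, "mean", np.float64)
        x = Tensor(rng.normal(size=(1, 5, 8)))
        g = Tensor(rng.normal(size=(1, 5, 5, 8)))
        g = (g + g.swapaxes(1, 2)) * 0.5
        vmask = Tensor(np.ones((1, 5, 1)))
        pmask = Tensor(np.ones((1, 5, 5, 1)))
        counts = Tensor(np.full((1, 1, 1), 0.2))
        _, g2 = layer(x, g, vmask, pmask, counts)
        assert np.array_equal(g2.data, np.swapaxes(g2.data, 1, 2))


class TestForward:
    def test_deterministic_repeat(self, ethanol_graph):
        net, _ = _net(ethanol_graph)
        args = (
            ethanol_graph.x[None],
            ethanol_graph.g_adj[None],
            ethanol_graph.g_feat[None],
            ethanol_graph.atom_mask[None],
        )
        s1, c1 = net.forward(*args)
        s2, c2 = net.forward(*args)
        assert np.array_equal(s1.data, s2.data)
        assert np.array_equal(c1.data, c2.data)

    def test_coupling_output_symmetric_exactly(self, ethanol_graph):
        net, _ = _net(ethanol_graph)
        _, c = net.forward(
            ethanol_graph.x[None],
            ethanol_graph.g_adj[None],
            ethanol_graph.g_feat[None],
            ethanol_graph.atom_mask[None],
        )
        assert np.array_equal(c.data, np.swapaxes(c.data, 2, 3))

    def test_permutation_equivariance(self, ethanol_graph, rng):
        net, _ = _net(ethanol_graph)
        perm = rng.permutation(ethanol_graph.n_atoms)
        gp = permute_graph(ethanol_graph, perm)
        s, c = net.forward(
            ethanol_graph.x[None],
            ethanol_graph.g_adj[None],
            ethanol_graph.g_feat[None],
            ethanol_graph.atom_mask[None],
        )
        sp, cp = net.forward(gp.x[None], gp.g_adj[None], gp.g_feat[None],
                             gp.atom_mask[None])
        assert np.allclose(sp.data, s.data[:, :, perm], atol=1e-9)
        assert np.allclose(
            cp.data, c.data[:, :, perm][:, :, :, perm], atol=1e-9
        )

    def test_stereoisomers_differ_only_through_geometry(self):
        cfg = FeatureConfig(n_conformers=8)
        cis = featurize(mol_from_smiles("C/C=C\\C"), cfg, seed=3)
        trans = featurize(mol_from_smiles("C/C=C/C"), cfg, seed=3)
        assert np.array_equal(cis.g_adj, trans.g_adj)
        net, _ = _net(cis)
        s_cis, _ = net.forward(cis.x[None], cis.g_adj[None], cis.g_feat[None],
                               cis.atom_mask[None])
        s_trans, _ = net.forward(trans.x[None], trans.g_adj[None],
                                 trans.g_feat[None], trans.atom_mask[None])
        assert np.abs(s_cis.data - s_trans.data).max() > 0

    def test_single_atom_molecule(self):
        # degenerate N=1 input: slice a single atom out of a small molecule
        g = featurize(mol_from_smiles("O"), FeatureConfig(n_conformers=1), seed=0)
        net, _ = _net(g)
        s, c = net.forward(g.x[:1][None], g.g_adj[:1, :1][None],
                           g.g_feat[:1, :1][None], np.ones((1, 1), bool))
        assert s.shape[2] == 1 and np.all(np.isfinite(s.data))

    @pytest.mark.parametrize("agg", ["mean", "sum", "max"])
    def test_aggregation_variants_run(self, ethanol_graph, agg):
        net, _ = _net(ethanol_graph, aggregation=agg, n_decode_layers=1)
        s, c = net.forward(
            ethanol_graph.x[None],
            ethanol_graph.g_adj[None],
            ethanol_graph.g_feat[None],
            ethanol_graph.atom_mask[None],
        )
        assert np.all(np.isfinite(s.data)) and np.all(np.isfinite(c.data))

    def test_padding_does_not_change_outputs(self, ethanol_graph):
        net, _ = _net(ethanol_graph)
        n = ethanol_graph.n_atoms
        s, c = net.forward(
            ethanol_graph.x[None],
            ethanol_graph.g_adj[None],
            ethanol_graph.g_feat[None],
            ethanol_graph.atom_mask[None],
        )
        pad = 4
        xp = np.zeros((1, n + pad, ethanol_graph.x.shape[1]))
        xp[0, :n] = ethanol_graph.x
        adjp = np.zeros((1, n + pad, n + pad, 5))
        adjp[0, :n, :n] = ethanol_graph.g_adj
        gfp = np.zeros((1, n + pad, n + pad, ethanol_graph.g_feat.shape[2]))
        gfp[0, :n, :n] = ethanol_graph.g_feat
        maskp = np.zeros((1, n + pad), bool)
        maskp[0, :n] = True
        sp, cp = net.forward(xp, adjp, gfp, maskp)
        assert np.allclose(sp.data[:, :, :n], s.data, atol=1e-10)
        assert np.allclose(cp.data[:, :, :n, :n], c.data, atol=1e-10)


def test_decode_layers_improve_coupling_error_over_mp_only():
    """Couplings need edge states: a message-passing-only model cannot see
    geometry, so adding decode layers must lower held-out 3JHH error."""
    from spinsys.fixtures import FixtureSpec, generate_fixtures
    from spinsys.training import TrainConfig, collect_errors, mae, train_model

    examples = generate_fixtures(FixtureSpec(n_molecules=140, seed=61))
    train, test = examples[:110], examples[110:]
    tc = TrainConfig(epochs=8, val_fraction=0.0, seed=0)
    maes = {}
    for name, n_dec in (("mp_only", 0), ("with_decode", 2)):
        cfg = ModelConfig(hidden_dim=32, n_message_layers=2,
                          n_decode_layers=n_dec, n_bootstraps=2, seed=0)
        fitted = train_model(train, cfg, tc)
        errs, _ = collect_errors(fitted, test)["3JHH"]
        maes[name] = mae(errs)
    assert maes["with_decode"] < maes["mp_only"], maes


def _brute_force_masks(mol):
    g = nx.Graph()
    g.add_nodes_from(range(mol.GetNumAtoms()))
    for b in mol.GetBonds():
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
    sym = [a.GetSymbol() for a in mol.GetAtoms()]
    lengths = dict(nx.all_pairs_shortest_path_length(g))
    n = mol.GetNumAtoms()
    masks = {c: np.zeros((n, n), bool) for c in COUPLING_CLASSES}
    for i in range(n):
        for j in range(n):
            if i == j or j not in lengths[i]:
                continue
            d = lengths[i][j]
            pair = {sym[i], sym[j]}
            if d == 1 and pair == {"C", "H"}:
                masks["1JCH"][i, j] = True
            if sym[i] == sym[j] == "H" and d in (2, 3, 4):
                masks[f"{d}JHH"][i, j] = True
    return masks


class TestCouplingMasks:
    def test_ethane_counts(self):
        mol = mol_from_smiles("CC")
        masks = coupling_class_masks(mol)
        assert np.triu(masks["1JCH"]).sum() == 6
        assert np.triu(masks["2JHH"]).sum() == 6  # 3 per methyl
        assert np.triu(masks["3JHH"]).sum() == 9
        assert np.triu(masks["4JHH"]).sum() == 0

    def test_methane_geminal_only(self):
        masks = coupling_class_masks(mol_from_smiles("C"))
        assert np.triu(masks["2JHH"]).sum() == 6
        assert np.triu(masks["3JHH"]).sum() == 0

    def test_benzene_ortho_vicinal(self):
        masks = coupling_class_masks(mol_from_smiles("c1ccccc1"))
        assert np.triu(masks["3JHH"]).sum() == 6

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_bfs(self, seed, small_fixture_set):
        ex = small_fixture_set[seed * 5 % len(small_fixture_set)]
        masks = coupling_class_masks(ex.mol)
        brute = _brute_force_masks(ex.mol)
        for cls in COUPLING_CLASSES:
            assert np.array_equal(masks[cls], brute[cls])

    def test_masks_mutually_exclusive_and_symmetric(self, small_fixture_set):
        for ex in small_fixture_set[:8]:
            masks = coupling_class_masks(ex.mol)
            total = np.zeros_like(masks["1JCH"], dtype=int)
            for cls in COUPLING_CLASSES:
                assert np.array_equal(masks[cls], masks[cls].T)
                total += masks[cls].astype(int)
            assert total.max() <= 1
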