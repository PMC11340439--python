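"""Equivariant network components and symmetry properties."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from geqshift import autodiff as ad
from geqshift import build_graph, parse_smiles
from geqshift.irreps import Irreps
from geqshift.model import (EquivariantLayerNorm, GeqShiftNet, MLP,
                            ModelConfig)

from conftest import TINY_CONFIG, transformed_sample


class TestEmbeddings:
    def test_default_node_embedding_dimension_is_128(self, gal_sample):
        net = GeqShiftNet(ModelConfig(n_layers=1), seed=0)
        x = net.embed_nodes(gal_sample.node_element_idx,
                            gal_sample.node_hcount_idx)
        assert x.shape == (gal_sample.n_nodes, 128)

    def test_default_edge_embedding_dimension_is_32(self, gal_sample):
        net = GeqShiftNet(ModelConfig(n_layers=1), seed=0)
        e = net.embed_edges(gal_sample.edge_bond_idx,
                            gal_sample.edge_distance)
        assert e.shape == (gal_sample.n_edges, 32)

    def test_identical_atoms_get_identical_embeddings(self, tiny_net):
        x = tiny_net.embed_nodes(np.array([0, 0, 2]), np.array([2, 2, 1]))
        np.testing.assert_array_equal(x.data[0], x.data[1])
        assert np.any(x.data[0] != x.data[2])

    def test_hcount_changes_embedding(self, tiny_net):
        x = tiny_net.embed_nodes(np.array([0, 0]), np.array([1, 2]))
        assert np.any(x.data[0] != x.data[1])

    def test_out_of_vocabulary_rejected(self, tiny_net):
        with pytest.raises(ValueError, match="element"):
            tiny_net.embed_nodes(np.array([99]), np.array([0]))
        with pytest.raises(ValueError, match="hcount"):
            tiny_net.embed_nodes(np.array([0]), np.array([9]))

    def test_edge_features_differ_only_in_distance_slot(self, tiny_net):
        e = tiny_net.embed_edges(np.array([1, 1]), np.array([1.5, 2.5]))
        diff = e.data[0] != e.data[1]
        assert diff.sum() == 1 and diff[-1]

    def test_reverse_edge_features_identical(self, gal_sample, tiny_net):
        s = gal_sample
        e = tiny_net.embed_edges(s.edge_bond_idx, s.edge_distance).data
        pairs = {(i, j): k for k, (i, j) in enumerate(zip(s.edge_src,
                                                          s.edge_dst))}
        for (i, j), k in pairs.items():
            np.testing.assert_allclose(e[k], e[pairs[(j, i)]], atol=1e-12)


class TestAttention:
    def _attention(self, net, sample):
        layer = net.layers[0]
        x = net.embed_nodes(sample.node_element_idx, sample.node_hcount_idx)
        e = net.embed_edges(sample.edge_bond_idx, sample.edge_distance)
        sh = net._edge_sh(sample.edge_unit_vec)
        return layer.attention_weights(x, e, sh, sample.edge_src,
                                       sample.edge_dst).data

    def test_weights_form_distribution(self, gal_sample, tiny_net):
        alpha = self._attention(tiny_net, gal_sample)
        assert np.all(alpha >= 0)
        sums = np.zeros(gal_sample.n_nodes)
        np.add.at(sums, gal_sample.edge_dst, alpha)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_single_neighbor_gets_weight_one(self, tiny_net):
        mol = parse_smiles("CO", molecule_id="m")
        from geqshift import Conformer
        s = build_graph(mol, Conformer("m", np.array([[0.0, 0, 0],
                                                      [1.4, 0, 0]]), 0.0))
        alpha = self._attention(tiny_net, s)
        np.testing.assert_allclose(alpha, 1.0, atol=1e-12)

    def test_symmetric_neighbors_split_evenly(self, tiny_net):
        # central C with two O neighbors mirrored through the origin:
        # identical elements, distances and edge categories
        mol = parse_smiles("O=C=O", molecule_id="co2")
        from geqshift import Conformer
        order = [el for _, el, _ in mol.atoms]
        coords = np.zeros((3, 3))
        o_idx = [i for i, el in enumerate(order) if el == "O"]
        c_idx = order.index("C")
        coords[o_idx[0]] = [1.2, 0, 0]
        coords[o_idx[1]] = [-1.2, 0, 0]
        s = build_graph(mol, Conformer("co2", coords, 0.0))
        alpha = self._attention(tiny_net, s)
        into_c = alpha[s.edge_dst == c_idx]
        np.testing.assert_allclose(into_c, 0.5, atol=1e-10)

    def test_softmax_matches_dense_oracle(self, tiny_net, rng):
        mol = parse_smiles("OCC", molecule_id="m3")
        from geqshift import Conformer
        coords = rng.normal(scale=1.5, size=(3, 3))
        s = build_graph(mol, Conformer("m3", coords, 0.0))
        layer = tiny_net.layers[0]
        x = tiny_net.embed_nodes(s.node_element_idx, s.node_hcount_idx)
        e = tiny_net.embed_edges(s.edge_bond_idx, s.edge_distance)
        sh = tiny_net._edge_sh(s.edge_unit_vec)
        alpha = layer.attention_weights(x, e, sh, s.edge_src, s.edge_dst).data
        # independent dense-softmax oracle from the raw logits
        q = layer.lin_q(x)
        k = layer.tp_k(ad.gather(x, s.edge_src), sh, layer.nn_k(e))
        qk_ir = layer.tp_k.irreps_out
        logits = np.zeros(s.n_edges)
        for sl, (m, l, _), W in zip(qk_ir.slices(), qk_ir.blocks,
                                    layer.dot_w):
            d = 2 * l + 1
            qb = q.data[s.edge_dst][:, sl].reshape(-1, m, d)
            kb = k.data[:, sl].reshape(-1, m, d)
            logits += np.einsum("uv,num,nvm->n", W.data, qb, kb)
        logits /= np.sqrt(qk_ir.dim)
        for node in range(3):
            sel = s.edge_dst == node
            if not sel.any():
                continue
            z = np.exp(logits[sel] - logits[sel].max())
            np.testing.assert_allclose(alpha[sel], z / z.sum(), atol=1e-6)


class TestLayerNorm:
    def test_scalar_block_standardized(self):
        ir = Irreps.parse("2x0e")
        ln = EquivariantLayerNorm(ir)
        out = ln(ad.constant(np.array([[2.0, 4.0]])))
        np.testing.assert_allclose(out.data, [[-1.0, 1.0]], atol=1e-5)

    def test_zero_l1_block_stays_zero(self):
        ir = Irreps.parse("2x0e+1x1o")
        ln = EquivariantLayerNorm(ir)
        x = np.array([[1.0, 3.0, 0.0, 0.0, 0.0]])
        out = ln(ad.constant(x)).data
        np.testing.assert_allclose(out[0, 2:], 0.0)
        assert np.all(np.isfinite(out))

    def test_direction_preserved_up_to_scale(self, rng):
        ir = Irreps.parse("1x0e+2x1o")
        ln = EquivariantLayerNorm(ir)
        x = rng.normal(size=(4, 7))
        out = ln(ad.constant(x)).data
        for u in range(2):
            sl = slice(1 + 3 * u, 4 + 3 * u)
            cos = np.sum(out[:, sl] * x[:, sl], axis=1) / (
                np.linalg.norm(out[:, sl], axis=1)
                * np.linalg.norm(x[:, sl], axis=1))
            np.testing.assert_allclose(cos, 1.0, atol=1e-10)

    def test_rotation_equivariance(self, rng):
        ir = Irreps.parse("3x0e+2x1o+1x2e")
        ln = EquivariantLayerNorm(ir)
        x = rng.normal(size=(5, ir.dim))
        R = Rotation.random(random_state=2).as_matrix()
        D = ir.rep(R)
        out_rot = ln(ad.constant(x @ D.T)).data
        rot_out = ln(ad.constant(x)).data @ D.T
        np.testing.assert_allclose(out_rot, rot_out, atol=1e-5)


class TestReadout:
    def test_hand_set_silu_mlp(self):
        # 1 -> 1 -> 1 MLP with unit weights, zero biases: silu(1) * 1
        mlp = MLP([1, 1, 1], np.random.default_rng(0))
        mlp.W[0].data[:] = 1.0
        mlp.W[1].data[:] = 1.0
        mlp.b[0].data[:] = 0.0
        mlp.b[1].data[:] = 0.0
        out = mlp(ad.constant(np.array([[1.0]])))
        silu1 = 1.0 / (1.0 + np.exp(-1.0))
        assert out.data[0, 0] == pytest.approx(silu1, abs=1e-7)

    def test_zero_head_weights_give_zero_output(self, gal_sample):
        net = GeqShiftNet(ModelConfig(**TINY_CONFIG), seed=0)
        for mlp in (net.head_c13, net.head_h1):
            for t in mlp.parameters():
                t.data[:] = 0.0
        c13, h1 = net.forward(gal_sample)
        np.testing.assert_allclose(c13.data, 0.0)
        np.testing.assert_allclose(h1.data, 0.0)

    def test_identical_scalar_features_identical_outputs(self, tiny_net):
        scalars = np.tile(np.linspace(-1, 1, 16), (2, 1))
        out = tiny_net.head_c13(ad.constant(scalars)).data
        assert out[0, 0] == pytest.approx(out[1, 0], abs=1e-12)


class TestForwardSymmetries:
    @pytest.mark.parametrize("transform", ["translation", "rotation",
                                           "reflection"])
    def test_e3_invariance_of_predictions(self, gal_record, gal_ensemble,
                                          tiny_net, transform, rng):
        conf = gal_ensemble.conformers[0]
        base_c, base_h = tiny_net.forward(build_graph(gal_record, conf))
        if transform == "translation":
            s = transformed_sample(gal_record, conf,
                                   translation=np.array([10.0, -3.0, 7.0]))
            tol = 1e-5
        elif transform == "rotation":
            R = Rotation.random(random_state=8).as_matrix()
            s = transformed_sample(gal_record, conf, R=R)
            tol = 1e-4
        else:
            R = np.diag([-1.0, 1.0, 1.0])
            s = transformed_sample(gal_record, conf, R=R)
            tol = 1e-4
        c, h = tiny_net.forward(s)
        assert np.abs(c.data - base_c.data).max() <= tol
        assert np.abs(h.data - base_h.data).max() <= tol

    def test_hidden_features_rotate_by_wigner_matrices(self, gal_record,
                                                       gal_ensemble,
                                                       tiny_net):
        conf = gal_ensemble.conformers[0]
        R = Rotation.random(random_state=13).as_matrix()
        s0 = build_graph(gal_record, conf)
        s1 = transformed_sample(gal_record, conf, R=R)
        feats0 = tiny_net.hidden_features(s0)
        feats1 = tiny_net.hidden_features(s1)
        D = tiny_net.config.hidden_irreps().rep(R)
        for f0, f1 in zip(feats0, feats1):
            expected = f0.data @ D.T
            err = np.abs(f1.data - expected).max()
            scale = max(np.abs(expected).max(), 1e-12)
            assert err / scale <= 1e-4

    def test_permutation_consistency(self, rng):
        # same molecule written from a different root atom: atom order is
        # canonical, so graphs and outputs must coincide
        from rdkit import Chem
        smi = "OC[C@H](O)CO"
        mol1 = parse_smiles(smi, molecule_id="m")
        alt = Chem.MolToSmiles(Chem.MolFromSmiles(smi), rootedAtAtom=2)
        mol2 = parse_smiles(alt, molecule_id="m")
        assert mol1.atoms == mol2.atoms
        from geqshift import Conformer
        coords = rng.normal(scale=2.0, size=(mol1.n_atoms, 3))
        net = GeqShiftNet(ModelConfig(**TINY_CONFIG), seed=1)
        c1, _ = net.forward(build_graph(mol1, Conformer("m", coords, 0.0)))
        c2, _ = net.forward(build_graph(mol2, Conformer("m", coords, 0.0)))
        np.testing.assert_allclose(c1.data, c2.data, atol=1e-10)

    def test_scalars_only_model_ignores_directions(self, gal_sample):
        # the invariant ablation sees geometry only through distances:
        # scrambling edge directions (keeping distances) changes nothing
        cfg = dict(TINY_CONFIG)
        cfg.update(hidden="8x0e", l_max_sh=0)
        inv_net = GeqShiftNet(ModelConfig(**cfg), seed=0)
        full_net = GeqShiftNet(ModelConfig(**TINY_CONFIG), seed=0)
        import copy
        scrambled = copy.copy(gal_sample)
        rng = np.random.default_rng(0)
        u = rng.normal(size=gal_sample.edge_unit_vec.shape)
        scrambled.edge_unit_vec = u / np.linalg.norm(u, axis=1,
                                                     keepdims=True)
        inv_a, _ = inv_net.forward(gal_sample)
        inv_b, _ = inv_net.forward(scrambled)
        np.testing.assert_allclose(inv_a.data, inv_b.data, atol=1e-12)
        full_a, _ = full_net.forward(gal_sample)
        full_b, _ = full_net.forward(scrambled)
        assert np.abs(full_a.data - full_b.data).max() > 1e-6

    def test_forward_deterministic(self, gal_sample, tiny_net):
        c1, h1 = tiny_net.forward(gal_sample)
        c2, h2 = tiny_net.forward(gal_sample)
        np.testing.assert_array_equal(c1.data, c2.data)
        np.testing.assert_array_equal(h1.data, h2.data)


class TestIsolatedNodes:
    def test_isolated_node_aggregate_is_zero_not_nan(self):
        # disconnected atoms beyond cutoff: outputs must stay finite
        mol = parse_smiles("C.C", molecule_id="iso")
        from geqshift import Conformer
        conf = Conformer("iso", np.array([[0.0, 0, 0], [50.0, 0, 0]]), 0.0)
        s = build_graph(mol, conf, r_cut=6.0)
        assert s.n_edges == 0
        net = GeqShiftNet(ModelConfig(**TINY_CONFIG), seed=0)
        c, h = net.forward(s)
        assert np.all(np.isfinite(c.data)) and np.all(np.isfinite(h.data))
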