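import numpy as np
import pytest
from autograd import value_and_grad
from autograd.misc import flatten
from scipy.spatial.transform import Rotation

from ffinet.errors import AlignmentError
from ffinet.model import (
    AttentionRecord,
    FFiNet,
    ModelConfig,
    atom_contributions,
    attention_map,
    axial_combine,
    batch_graphs,
    build_graph,
    forward,
    init_params,
    khop_attention,
    node_similarity,
    positional_encoding,
    readout,
    segment_softmax,
)
from ffinet.molio import embed_conformer
from ffinet.synthdata import SMILES_VOCABULARY
from oracles import dense_attention_oracle


class TestModelConfig:
    def test_divisibility_check(self):
        with pytest.raises(ValueError):
            ModelConfig(hidden_dim=30, n_heads=4)

    def test_empty_hops_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(use_hops=())

    def test_dropout_range(self):
        with pytest.raises(ValueError):
            ModelConfig(dropout=1.0)

    def test_round_trip_dict(self):
        cfg = ModelConfig(hidden_dim=32, use_hops=(1, 3), use_axial=False)
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg


class TestPositionalEncoding:
    def test_first_entry_closed_form(self):
        pe = positional_encoding(1, 8)
        assert abs(pe[0] - np.sin(1.0)) < 1e-12
        assert abs(pe[1] - np.cos(1.0)) < 1e-12

    def test_dim4_k2_closed_form(self):
        pe = positional_encoding(2, 4)
        expected = [np.sin(2), np.cos(2), np.sin(2 / 100), np.cos(2 / 100)]
        np.testing.assert_allclose(pe, expected, atol=1e-12)

    def test_pairwise_distinct(self):
        vecs = [positional_encoding(k, 16) for k in (1, 2, 3)]
        assert not np.allclose(vecs[0], vecs[1])
        assert not np.allclose(vecs[1], vecs[2])
        assert not np.allclose(vecs[0], vecs[2])

    def test_invalid_hop(self):
        with pytest.raises(ValueError):
            positional_encoding(4, 8)


class TestKhopAttention:
    def _setup(self, smiles, cfg, seed=0):
        rec = embed_conformer(smiles, seed=seed)
        graph = build_graph(rec)
        rng = np.random.default_rng(seed)
        params = init_params(cfg, rec.atom_features.shape[1], rng)
        h = rng.normal(size=(rec.n_atoms, cfg.hidden_dim))
        return graph, params, h

    def test_singleton_softmax_and_output(self):
        cfg = ModelConfig(hidden_dim=8, n_heads=2, n_layers=1)
        graph, params, h = self._setup("CCC", cfg)
        hop = params["layers"][0]["hops"][2]
        e, alpha, o = khop_attention(
            hop, h, graph.paths[2], graph.basis[2], 2, cfg, n_atoms=graph.n_atoms
        )
        # propane: atom 0 has exactly one 2-hop path (0,1,2)
        row = np.nonzero(graph.paths[2][:, 0] == 0)[0]
        assert row.shape == (1,)
        np.testing.assert_allclose(alpha[row[0]], 1.0)
        # output equals W_src h'_j for the singleton
        pe = positional_encoding(2, cfg.hidden_dim)
        hp = (h * pe).reshape(graph.n_atoms, cfg.n_heads, -1)
        j = graph.paths[2][row[0], -1]
        expected = np.concatenate(
            [hp[j, head] @ hop["W_r"][2, head] for head in range(cfg.n_heads)]
        )
        np.testing.assert_allclose(o[0], expected, atol=1e-10)

    def test_alpha_sums_to_one_per_target(self):
        cfg = ModelConfig(hidden_dim=16, n_heads=4, n_layers=1)
        graph, params, h = self._setup("c1ccccc1CC", cfg)
        for k in (1, 2, 3):
            _, alpha, _ = khop_attention(
                params["layers"][0]["hops"][k], h, graph.paths[k], graph.basis[k],
                k, cfg, edge_type=graph.edge_type if k == 1 else None,
                n_atoms=graph.n_atoms,
            )
            targets = graph.paths[k][:, 0]
            for t in np.unique(targets):
                np.testing.assert_allclose(
                    alpha[targets == t].sum(axis=0), 1.0, atol=1e-6
                )

    @pytest.mark.parametrize("smiles", ["CCC", "CCCC", "c1ccccc1", "CC(C)CO"])
    def test_dense_loop_oracle(self, smiles):
        cfg = ModelConfig(hidden_dim=12, n_heads=3, n_layers=1)
        graph, params, h = self._setup(smiles, cfg, seed=9)
        for k in (1, 2, 3):
            if graph.paths[k].shape[0] == 0:
                continue
            hop = params["layers"][0]["hops"][k]
            e, alpha, o = khop_attention(
                hop, h, graph.paths[k], graph.basis[k], k, cfg,
                edge_type=graph.edge_type if k == 1 else None, n_atoms=graph.n_atoms,
            )
            e2, alpha2, o2 = dense_attention_oracle(
                hop, h, [tuple(p) for p in graph.paths[k]], graph.basis[k], k, cfg,
                edge_type=graph.edge_type if k == 1 else None,
            )
            np.testing.assert_allclose(e, e2, atol=1e-6)
            np.testing.assert_allclose(alpha, alpha2, atol=1e-6)
            np.testing.assert_allclose(o, o2, atol=1e-6)

    def test_misaligned_basis_raises(self):
        cfg = ModelConfig(hidden_dim=8, n_heads=2, n_layers=1)
        graph, params, h = self._setup("CCC", cfg)
        with pytest.raises(AlignmentError):
            khop_attention(
                params["layers"][0]["hops"][2], h, graph.paths[2],
                graph.basis[2][:1], 2, cfg, n_atoms=graph.n_atoms,
            )


class TestAxialCombine:
    def test_single_hop_passthrough(self, rng):
        u = rng.normal(size=(5, 8))
        h = rng.normal(size=(5, 8))
        out, beta = axial_combine(h, {1: u}, {1: np.ones(5, dtype=bool)}, True, 8)
        np.testing.assert_allclose(out, u, atol=1e-12)
        np.testing.assert_allclose(beta[:, 0], 1.0)

    def test_identical_outputs_uniform_beta(self, rng):
        u = rng.normal(size=(4, 6))
        h = rng.normal(size=(4, 6))
        masks = {k: np.ones(4, dtype=bool) for k in (1, 2, 3)}
        out, beta = axial_combine(h, {1: u, 2: u, 3: u}, masks, True, 6)
        np.testing.assert_allclose(out, u, atol=1e-10)
        np.testing.assert_allclose(beta, 1.0 / 3.0, atol=1e-10)

    def test_no_axial_is_exact_sum(self, rng):
        u, v, w = (rng.normal(size=(5, 8)) for _ in range(3))
        h = rng.normal(size=(5, 8))
        masks = {k: np.ones(5, dtype=bool) for k in (1, 2, 3)}
        out, _ = axial_combine(h, {1: u, 2: v, 3: w}, masks, False, 8)
        assert np.array_equal(out, u + v + w)

    def test_masked_hop_gets_zero_beta(self, rng):
        u, v = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
        masks = {1: np.ones(3, dtype=bool), 2: np.zeros(3, dtype=bool)}
        _, beta = axial_combine(rng.normal(size=(3, 4)), {1: u, 2: v}, masks, True, 4)
        np.testing.assert_allclose(beta[:, 1], 0.0)
        np.testing.assert_allclose(beta[:, 0], 1.0)


class TestForward:
    def test_deterministic_eval(self, small_model, butane):
        m = small_model()
        g = build_graph(butane)
        out1, _ = m.forward_graph(g)
        out2, _ = m.forward_graph(g)
        assert np.array_equal(out1, out2)

    def test_rotation_translation_invariance(self, small_model):
        m = small_model()
        rng = np.random.default_rng(0)
        for i, smi in enumerate(SMILES_VOCABULARY[:20]):
            rec = embed_conformer(smi, seed=i)
            base, _ = m.forward_graph(build_graph(rec))
            rot = Rotation.random(random_state=i).as_matrix()
            rec.positions = rec.positions @ rot.T + rng.normal(size=3) * 5
            moved, _ = m.forward_graph(build_graph(rec))
            np.testing.assert_allclose(moved, base, rtol=1e-4, atol=1e-7)

    def test_atom_permutation_invariance(self, small_model, rng):
        m = small_model()
        rec = embed_conformer("CC(C)Oc1ccccc1", seed=1)
        base, _ = m.forward_graph(build_graph(rec))
        perm = rng.permutation(rec.n_atoms)
        inv = np.argsort(perm)
        rec.positions = rec.positions[perm]
        rec.atom_features = rec.atom_features[perm]
        rec.bonds = [(int(inv[i]), int(inv[j])) for i, j in rec.bonds]
        permuted, _ = m.forward_graph(build_graph(rec))
        np.testing.assert_allclose(permuted, base, rtol=1e-5, atol=1e-8)

    def test_ablation_changes_function(self, feat_dim, butane):
        g = build_graph(butane)
        full = FFiNet(ModelConfig(hidden_dim=16, n_heads=2, seed=3), feat_dim)
        one = FFiNet(ModelConfig(hidden_dim=16, n_heads=2, use_hops=(1,), seed=3), feat_dim)
        out_full, _ = full.forward_graph(g)
        out_one, _ = one.forward_graph(g)
        assert not np.allclose(out_full, out_one)

    def test_classification_shape(self, feat_dim, butane):
        m = FFiNet(
            ModelConfig(hidden_dim=16, n_heads=2, task="classification", n_tasks=12),
            feat_dim,
        )
        out, _ = m.forward_graph(build_graph(butane))
        assert out.shape == (1, 12)

    def test_gradients_finite_everywhere(self, small_model, butane, benzene):
        m = small_model()
        batch = batch_graphs([build_graph(butane), build_graph(benzene)])

        def loss(params):
            return np.sum(forward(params, batch, m.config) ** 2)

        val, grads = value_and_grad(loss)(m.params)
        flat, _ = flatten(grads)
        assert np.all(np.isfinite(flat))
        assert np.any(flat != 0)

    def test_unused_hop_params_get_zero_grads(self, feat_dim, butane):
        # params built for all hops, forward restricted to hop 1
        from dataclasses import replace

        m = FFiNet(ModelConfig(hidden_dim=16, n_heads=2, n_layers=1), feat_dim)
        cfg1 = replace(m.config, use_hops=(1,))
        g = build_graph(butane)

        def loss(params):
            return np.sum(forward(params, g, cfg1) ** 2)

        _, grads = value_and_grad(loss)(m.params)
        for k in (2, 3):
            flat, _ = flatten(grads["layers"][0]["hops"][k])
            assert np.all(flat == 0)
            assert np.all(flatten(grads["layers"][0]["mix"][k])[0] == 0)

    def test_finite_difference_gradient(self, small_model, butane):
        m = small_model(hidden_dim=8, n_heads=2, n_layers=1)
        g = build_graph(butane)

        def loss(params):
            return np.sum(forward(params, g, m.config) ** 2)

        _, grads = value_and_grad(loss)(m.params)
        flat, unflatten = flatten(m.params)
        gflat, _ = flatten(grads)
        rng = np.random.default_rng(0)
        for idx in rng.choice(len(flat), size=10, replace=False):
            eps = 1e-6
            up, down = flat.copy(), flat.copy()
            up[idx] += eps
            down[idx] -= eps
            fd = (loss(unflatten(up)) - loss(unflatten(down))) / (2 * eps)
            assert abs(fd - gflat[idx]) < 1e-4 * max(1.0, abs(fd))


class TestReadout:
    def test_single_atom_graph(self, rng):
        h = rng.normal(size=(1, 6))
        params = {"w": rng.normal(size=6), "b": 0.1}
        rec = AttentionRecord()
        out = readout(params, h, np.zeros(1, dtype=np.int64), 1, record=rec)
        gate = 1 / (1 + np.exp(-(h[0] @ params["w"] + 0.1)))
        np.testing.assert_allclose(out[0, :6], gate * h[0], atol=1e-12)
        np.testing.assert_allclose(out[0, 6:], h[0], atol=1e-12)

    def test_duplicated_node_max_half(self, rng):
        h1 = rng.normal(size=(1, 4))
        h2 = np.vstack([h1, h1])
        params = {"w": rng.normal(size=4), "b": 0.0}
        single = readout(params, h1, np.zeros(1, dtype=np.int64), 1)
        double = readout(params, h2, np.zeros(2, dtype=np.int64), 1)
        np.testing.assert_allclose(double[0, 4:], single[0, 4:], atol=1e-12)

    def test_permutation_invariant(self, rng):
        h = rng.normal(size=(5, 4))
        params = {"w": rng.normal(size=4), "b": 0.0}
        base = readout(params, h, np.zeros(5, dtype=np.int64), 1)
        perm = rng.permutation(5)
        out = readout(params, h[perm], np.zeros(5, dtype=np.int64), 1)
        np.testing.assert_allclose(out, base, atol=1e-12)

    def test_empty_graph_raises(self, rng):
        params = {"w": rng.normal(size=4), "b": 0.0}
        with pytest.raises(ValueError):
            readout(params, np.zeros((0, 4)), np.zeros(0, dtype=np.int64), 0)


class TestInterpretation:
    def test_atom_contributions_normalised(self, small_model, benzene):
        m = small_model()
        w = atom_contributions(m, benzene)
        assert w.shape == (6,)
        assert np.all(w >= 0)
        np.testing.assert_allclose(w.sum(), 1.0, atol=1e-10)

    def test_symmetric_atoms_equal_weights(self, small_model):
        m = small_model()
        rec = embed_conformer("CC", seed=4)
        w = atom_contributions(m, rec)
        np.testing.assert_allclose(w[0], w[1], atol=1e-4)

    def test_attention_map_sums_to_beta(self, small_model, butane):
        m = small_model()
        g = m.graph_for(butane)
        _, rec = m.forward_graph(g, record_attention=True)
        target, layer, head = 1, 0, 0
        amap = attention_map(m, butane, target, layer, head)
        beta = rec.beta[layer][target]
        total = 0.0
        for k, entries in amap.items():
            hop_sum = sum(wt for _, wt in entries)
            if entries:
                np.testing.assert_allclose(hop_sum, beta[k - 1], atol=1e-8)
            total += hop_sum
        np.testing.assert_allclose(total, beta.sum(), atol=1e-8)
        np.testing.assert_allclose(total, 1.0, atol=1e-6)

    def test_node_similarity_properties(self, small_model, benzene):
        m = small_model()
        sim = node_similarity(m, benzene)
        assert sim.shape == (6, 6)
        np.testing.assert_allclose(np.diag(sim), 1.0)
        np.testing.assert_allclose(sim, sim.T, atol=1e-10)
        assert np.all(sim >= -1.0) and np.all(sim <= 1.0)


class TestCheckpoint:
    def test_save_load_round_trip(self, small_model, butane, tmp_path):
        m = small_model()
        g = build_graph(butane)
        base, _ = m.forward_graph(g)
        path = str(tmp_path / "model.npz")
        m.save(path)
        m2 = FFiNet.load(path)
        out, _ = m2.forward_graph(g)
        np.testing.assert_array_equal(out, base)
        assert m2.config == m.config


class TestSegmentOps:
    def test_segment_softmax_normalises(self, rng):
        e = rng.normal(size=(7, 3))
        seg = np.array([0, 0, 1, 1, 1, 2, 2])
        sm = segment_softmax(e, seg, 3)
        for s in range(3):
            np.testing.assert_allclose(np.asarray(sm)[seg == s].sum(axis=0), 1.0, atol=1e-12)
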