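"""Network math: ECC layers, pooling, adduct fusion, forward pass, checkpoints.

The reference implementations here are deliberate brute-force double loops
over nodes and edges, independent of the vectorized code paths they check.
"""

import numpy as np
import pytest

import graphccs as g
from graphccs.errors import (
    ChecksumError,
    EmptyGraphError,
    ShapeError,
    VersionError,
)
from graphccs.gnn import CCSModel, ECCLayerParams, ModelConfig


# ---------------------------------------------------------------------------
# Brute-force references
# ---------------------------------------------------------------------------

def mlp_reference(params: ECCLayerParams, e: np.ndarray) -> np.ndarray:
    """Edge filter MLP for one edge attribute vector, as an Fin x Fout matrix."""
    hidden = np.maximum(e @ params.mlp_W1 + params.mlp_b1, 0.0)
    fin, fout = params.W.shape
    return (hidden @ params.mlp_W2 + params.mlp_b2).reshape(fin, fout)


def ecc_reference(X, E, edge_index, params, activation="relu"):
    """Per-node double loop over all directed edges."""
    n = X.shape[0]
    out = np.zeros((n, params.W.shape[1]))
    for i in range(n):
        acc = X[i] @ params.W + params.b
        for (s, d), e in zip(edge_index, E):
            if d == i:
                acc = acc + X[s] @ mlp_reference(params, e)
        out[i] = acc
    if activation == "relu":
        out = np.maximum(out, 0.0)
    return out


def forward_reference(model: CCSModel, graph, adduct: str) -> float:
    """Straight-line reimplementation of the whole forward pass."""
    std = np.where(model.params.feature_std > 0, model.params.feature_std, 1.0)
    X = (graph.X - model.params.feature_mean) / std
    for layer in model.params.ecc:
        X = ecc_reference(X, graph.E, graph.edge_index, layer)
    p = X.sum(axis=0)
    h = np.concatenate([p, g.get_adduct(adduct).onehot])
    for layer in model.params.fc:
        h = h @ layer.W + layer.b
        if layer.activation == "relu":
            h = np.maximum(h, 0.0)
    return float(h[0])


def random_graph(rng, n_max=10, fin=5):
    """A random undirected graph with one-hot edge attributes."""
    n = int(rng.integers(2, n_max + 1))
    X = rng.normal(size=(n, fin))
    bonds = []
    for i in range(1, n):           # spanning tree keeps it connected
        bonds.append((int(rng.integers(i)), i))
    extra = rng.integers(0, n)
    for _ in range(extra):
        i, j = rng.integers(n), rng.integers(n)
        if i != j and (min(i, j), max(i, j)) not in bonds:
            bonds.append((min(int(i), int(j)), max(int(i), int(j))))
    edge_index, E = [], []
    for (i, j) in bonds:
        order = rng.integers(4)
        for a, b in ((i, j), (j, i)):
            edge_index.append((a, b))
            onehot = np.zeros(4)
            onehot[order] = 1.0
            E.append(onehot)
    return X, np.array(E), np.array(edge_index, dtype=int)


def random_layer(rng, fin, fout, hidden=6) -> ECCLayerParams:
    return ECCLayerParams(
        W=rng.normal(size=(fin, fout)),
        b=rng.normal(size=fout),
        mlp_W1=rng.normal(size=(4, hidden)),
        mlp_b1=rng.normal(size=hidden),
        mlp_W2=rng.normal(size=(hidden, fin * fout)),
        mlp_b2=rng.normal(size=fin * fout),
    )


# ---------------------------------------------------------------------------
# ECC layer
# ---------------------------------------------------------------------------

class TestECCForward:
    def test_identity_case(self):
        """Zero edge filters + identity root weight pass features through."""
        fin = 4
        params = ECCLayerParams(
            W=np.eye(fin), b=np.zeros(fin),
            mlp_W1=np.zeros((4, 3)), mlp_b1=np.zeros(3),
            mlp_W2=np.zeros((3, fin * fin)), mlp_b2=np.zeros(fin * fin),
        )
        X = np.arange(12.0).reshape(3, 4)
        E = np.tile([1.0, 0, 0, 0], (4, 1))
        edge_index = np.array([[0, 1], [1, 0], [1, 2], [2, 1]])
        out = g.ecc_forward(X, E, edge_index, params, activation="linear")
        np.testing.assert_allclose(out, X)

    def test_path_graph_hand_case(self):
        """Path 1-2-3, scalar features [1,2,3], unit edge filter: [2,4,2]."""
        params = ECCLayerParams(
            W=np.zeros((1, 1)), b=np.zeros(1),
            mlp_W1=np.zeros((4, 2)), mlp_b1=np.zeros(2),
            mlp_W2=np.zeros((2, 1)), mlp_b2=np.ones(1),
        )
        X = np.array([[1.0], [2.0], [3.0]])
        E = np.tile([1.0, 0, 0, 0], (4, 1))
        edge_index = np.array([[0, 1], [1, 0], [1, 2], [2, 1]])
        out = g.ecc_forward(X, E, edge_index, params, activation="linear")
        np.testing.assert_allclose(out.ravel(), [2.0, 4.0, 2.0])

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            X, E, edge_index = random_graph(rng, n_max=8)
            params = random_layer(rng, X.shape[1], int(rng.integers(1, 6)))
            fast = g.ecc_forward(X, E, edge_index, params)
            slow = ecc_reference(X, E, edge_index, params)
            np.testing.assert_allclose(fast, slow, atol=1e-6)

    def test_shape_error(self):
        rng = np.random.default_rng(0)
        params = random_layer(rng, 5, 3)
        with pytest.raises(ShapeError):
            g.ecc_forward(np.zeros((4, 7)), np.zeros((0, 4)),
                          np.zeros((0, 2), dtype=int), params)


class TestPoolingAndFusion:
    def test_sum_pool_examples(self):
        np.testing.assert_allclose(
            g.global_sum_pool(np.array([[1.0, 2], [3, 4]])), [4, 6])
        np.testing.assert_allclose(
            g.global_sum_pool(np.array([[5.0, 7]])), [5, 7])

    def test_sum_pool_permutation_invariant(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(9, 4))
        perm = rng.permutation(9)
        np.testing.assert_allclose(
            g.global_sum_pool(X), g.global_sum_pool(X[perm]), atol=1e-12)

    def test_empty_graph_raises(self):
        with pytest.raises(EmptyGraphError):
            g.global_sum_pool(np.zeros((0, 3)))

    def test_fuse_adduct_codes(self):
        p = np.arange(1.0, 17.0)
        m = g.fuse_adduct(p, "[M+H]+")
        assert len(m) == 19
        np.testing.assert_array_equal(m[-3:], [1, 0, 0])
        np.testing.assert_array_equal(
            g.fuse_adduct(p, "[M+Na]+")[-3:], [0, 1, 0])
        np.testing.assert_array_equal(
            g.fuse_adduct(p, "[M-H]-")[-3:], [0, 0, 1])


# ---------------------------------------------------------------------------
# Full forward pass
# ---------------------------------------------------------------------------

class TestPredict:
    def _model(self, seed=0):
        cfg = ModelConfig.scaled(seed=seed)
        return CCSModel(cfg)

    def test_all_zero_weights_predict_zero(self, ethanol):
        model = self._model()
        for arr in model.params.arrays():
            arr[:] = 0.0
        graph = g.build_graph(ethanol)
        assert model.predict_ccs(graph, "[M+H]+") == 0.0

    def test_deterministic(self, ethanol):
        model = self._model(seed=3)
        graph = g.build_graph(ethanol)
        a = model.predict_ccs(graph, "[M+Na]+")
        b = model.predict_ccs(graph, "[M+Na]+")
        assert a == b

    def test_matches_straight_line_reference(self, methane, ethanol):
        model = self._model(seed=5)
        # make the untrained output informative: lift biases off zero
        rng = np.random.default_rng(9)
        for layer in model.params.fc:
            layer.b[:] = rng.normal(size=layer.b.shape)
        for mol in (methane, ethanol):
            graph = g.build_graph(mol)
            for adduct in g.SUPPORTED_ADDUCTS:
                fast = model.predict_ccs(graph, adduct)
                slow = forward_reference(model, graph, adduct)
                assert abs(fast - slow) < 1e-5

    def test_batched_equals_per_graph(self, methane, ethanol, benzene):
        model = self._model(seed=7)
        rng = np.random.default_rng(2)
        for layer in model.params.fc:
            layer.b[:] = np.abs(rng.normal(size=layer.b.shape))
        graphs = [g.build_graph(m) for m in (methane, ethanol, benzene)]
        adducts = ["[M+H]+", "[M+Na]+", "[M-H]-"]
        batched = model.predict_batch(graphs, adducts, warn_ceiling=False)
        single = [model.predict_ccs(gr, a) for gr, a in zip(graphs, adducts)]
        np.testing.assert_allclose(batched, single, atol=1e-9)

    def test_prediction_is_smooth_in_coordinates(self, ethanol):
        """Tiny coordinate perturbations barely move the output."""
        model = self._model(seed=1)
        rng = np.random.default_rng(4)
        for layer in model.params.fc:
            layer.b[:] = np.abs(rng.normal(size=layer.b.shape))
        graph = g.build_graph(ethanol)
        base = model.predict_ccs(graph, "[M+H]+")
        coords = ethanol.conformer.coords + 1e-6
        from graphccs.chem_io import Conformer

        wiggled = g.build_graph(
            ethanol, conf=Conformer(coords, True))
        assert abs(model.predict_ccs(wiggled, "[M+H]+") - base) <= 1e-3

    def test_ceiling_warning(self, ethanol):
        model = self._model(seed=1)
        for arr in model.params.arrays():
            arr[:] = 0.0
        model.params.fc[-1].b[:] = 500.0   # force an out-of-domain output
        graph = g.build_graph(ethanol)
        with pytest.warns(UserWarning, match="ceiling"):
            model.predict_batch([graph], ["[M+H]+"])


class TestPermutationEquivariance:
    def test_pooled_invariant_and_nodes_equivariant(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            X, E, edge_index = random_graph(rng, n_max=10)
            params = random_layer(rng, X.shape[1], 6)
            out = g.ecc_forward(X, E, edge_index, params)
            perm = rng.permutation(X.shape[0])
            inv = np.argsort(perm)
            out_p = g.ecc_forward(X[perm], E, inv[edge_index], params)
            np.testing.assert_allclose(out_p, out[perm], atol=1e-9)
            np.testing.assert_allclose(out_p.sum(axis=0), out.sum(axis=0),
                                       atol=1e-9)

    def test_pooled_invariant_to_edge_ordering(self):
        rng = np.random.default_rng(22)
        X, E, edge_index = random_graph(rng, n_max=8)
        params = random_layer(rng, X.shape[1], 4)
        out = g.ecc_forward(X, E, edge_index, params)
        shuffle = rng.permutation(len(E))
        out_s = g.ecc_forward(X, E[shuffle], edge_index[shuffle], params)
        np.testing.assert_allclose(out_s, out, atol=1e-9)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

class TestCheckpoints:
    def test_save_load_roundtrip(self, tmp_path, ethanol):
        model = CCSModel(ModelConfig.scaled(seed=13))
        rng = np.random.default_rng(5)
        for layer in model.params.fc:
            layer.b[:] = np.abs(rng.normal(size=layer.b.shape))
        graph = g.build_graph(ethanol)
        before = model.predict_ccs(graph, "[M+H]+")
        model.save(tmp_path / "ckpt")
        loaded = g.load_model(tmp_path / "ckpt")
        after = loaded.predict_ccs(graph, "[M+H]+")
        assert abs(before - after) < 1e-7

    def test_config_roundtrips_exactly(self, tmp_path):
        cfg = ModelConfig.scaled(seed=99, learning_rate=0.007, epochs=123)
        model = CCSModel(cfg)
        model.save(tmp_path / "ckpt")
        loaded = g.load_model(tmp_path / "ckpt")
        assert loaded.config.to_dict() == cfg.to_dict()

    def test_missing_weights_raises_checksum_error(self, tmp_path):
        model = CCSModel(ModelConfig.scaled(seed=1))
        model.save(tmp_path / "ckpt")
        (tmp_path / "ckpt" / "weights.npz").unlink()
        with pytest.raises(ChecksumError):
            g.load_model(tmp_path / "ckpt")

    def test_corrupted_weights_raises_checksum_error(self, tmp_path):
        model = CCSModel(ModelConfig.scaled(seed=1))
        model.save(tmp_path / "ckpt")
        f = tmp_path / "ckpt" / "weights.npz"
        f.write_bytes(f.read_bytes()[:-7] + b"garbage")
        with pytest.raises(ChecksumError):
            g.load_model(tmp_path / "ckpt")

    def test_schema_mismatch_raises_version_error(self, tmp_path):
        import json

        model = CCSModel(ModelConfig.scaled(seed=1))
        model.save(tmp_path / "ckpt")
        cfg_file = tmp_path / "ckpt" / "config.json"
        doc = json.loads(cfg_file.read_text())
        doc["schema_version"] = 999
        cfg_file.write_text(json.dumps(doc))
        with pytest.raises(VersionError):
            g.load_model(tmp_path / "ckpt")
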