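"""The network: edge-conditioned convolutions, pooling, adduct fusion, dense head.

The model maps a molecular graph plus an adduct one-hot code to a CCS
value in Å².  Each edge-conditioned convolution (ECC) layer computes, for
atom i,

    out_i = x_i W + sum_{j in N(i)} x_j MLP(e_ij) + b

where the filter network ``MLP`` maps the 4-dim bond-type one-hot e_ij to
an Fin x Fout weight matrix, so message weights are conditioned on the
bond order.  Global sum pooling collapses the node dimension into the
pooled representation ``p`` (16-dim by default); the adduct one-hot ``a``
is concatenated to give the molecular vector ``m = [p, a]``, which a stack
of ReLU fully connected layers maps to the CCS scalar (output layer also
ReLU, unregularized).

Everything — forward pass, backpropagation, and the Adam optimizer — is
implemented directly on NumPy arrays, which keeps the model dependency-
light and bit-deterministic on a single thread.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .adducts import AdductType, get_adduct
from .errors import ChecksumError, EmptyGraphError, ShapeError, VersionError
from .graphs import MolecularGraph, NodeFeaturizerConfig

SCHEMA_VERSION = 1

#: CCS values above this (Å²) are outside the training domain of typical
#: small-molecule CCS collections; predictions beyond it trigger a warning.
DOMAIN_CEILING = 380.0


# ---------------------------------------------------------------------------
# Configuration and parameters
# ---------------------------------------------------------------------------

def _geometric_taper(start: int, n: int) -> list[int]:
    """n layer widths decaying geometrically from `start` towards 1."""
    if n == 1:
        return [start]
    ratio = (1.0 / start) ** (1.0 / n)
    return [max(1, int(round(start * ratio ** k))) for k in range(n)]


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults follow the full-size architecture: three ECC layers with a
    16-dim pooled representation and an eight-layer fully connected head.
    The scaled configuration used for desk-size experiments is available
    via :meth:`scaled`.
    """

    n_ecc_layers: int = 3
    ecc_widths: tuple[int, ...] = (16, 16, 16)
    edge_mlp_hidden: int = 32
    n_fc_layers: int = 8
    fc_widths: tuple[int, ...] = tuple(_geometric_taper(384, 8))
    adduct_dim: int = 3
    seed: int = 0
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 300
    l2_coefficient: float = 1e-6
    patience: int = 50
    standardize: bool = True
    domain_ceiling: float = DOMAIN_CEILING

    def __post_init__(self):
        self.ecc_widths = tuple(int(w) for w in self.ecc_widths)
        self.fc_widths = tuple(int(w) for w in self.fc_widths)
        if len(self.ecc_widths) != self.n_ecc_layers:
            raise ShapeError("ecc_widths length must equal n_ecc_layers")
        if len(self.fc_widths) != self.n_fc_layers:
            raise ShapeError("fc_widths length must equal n_fc_layers")

    @property
    def pooled_dim(self) -> int:
        return self.ecc_widths[-1]

    @classmethod
    def scaled(cls, seed: int = 0, **overrides) -> "ModelConfig":
        """Small configuration (2 ECC x 8 channels, 3 FC layers) for
        CPU-scale experiments on synthetic data."""
        base = dict(
            n_ecc_layers=2,
            ecc_widths=(8, 8),
            edge_mlp_hidden=32,
            n_fc_layers=3,
            fc_widths=(64, 32, 16),
            epochs=400,
            batch_size=40,
            learning_rate=3e-3,
            patience=80,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return {
            "n_ecc_layers": self.n_ecc_layers,
            "ecc_widths": list(self.ecc_widths),
            "edge_mlp_hidden": self.edge_mlp_hidden,
            "n_fc_layers": self.n_fc_layers,
            "fc_widths": list(self.fc_widths),
            "adduct_dim": self.adduct_dim,
            "seed": self.seed,
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "epochs": self.epochs,
            "l2_coefficient": self.l2_coefficient,
            "patience": self.patience,
            "standardize": self.standardize,
            "domain_ceiling": self.domain_ceiling,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["ecc_widths"] = tuple(d["ecc_widths"])
        d["fc_widths"] = tuple(d["fc_widths"])
        return cls(**d)


@dataclass
class ECCLayerParams:
    W: np.ndarray        # Fin x Fout root weight
    b: np.ndarray        # Fout bias
    mlp_W1: np.ndarray   # 4 x hidden
    mlp_b1: np.ndarray   # hidden
    mlp_W2: np.ndarray   # hidden x (Fin * Fout)
    mlp_b2: np.ndarray   # Fin * Fout

    def arrays(self) -> list[np.ndarray]:
        return [self.W, self.b, self.mlp_W1, self.mlp_b1,
                self.mlp_W2, self.mlp_b2]


@dataclass
class DenseLayerParams:
    W: np.ndarray
    b: np.ndarray
    activation: str = "relu"   # "relu" or "linear"
    l2: float = 0.0

    def arrays(self) -> list[np.ndarray]:
        return [self.W, self.b]


@dataclass
class ModelParams:
    ecc: list[ECCLayerParams]
    fc: list[DenseLayerParams]      # hidden layers + output layer (last)
    feature_mean: np.ndarray        # Fn, zeros for non-standardized columns
    feature_std: np.ndarray         # Fn, ones  for non-standardized columns

    def arrays(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self.ecc:
            out.extend(layer.arrays())
        for layer in self.fc:
            out.extend(layer.arrays())
        return out

    def copy(self) -> "ModelParams":
        return ModelParams(
            ecc=[ECCLayerParams(*[a.copy() for a in l.arrays()])
                 for l in self.ecc],
            fc=[DenseLayerParams(l.W.copy(), l.b.copy(), l.activation, l.l2)
                for l in self.fc],
            feature_mean=self.feature_mean.copy(),
            feature_std=self.feature_std.copy(),
        )


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(config: ModelConfig, n_features: int,
                rng: np.random.Generator | None = None) -> ModelParams:
    """Glorot-uniform initialization seeded from the config."""
    rng = rng or np.random.default_rng(config.seed)
    ecc = []
    fin = n_features
    for fout in config.ecc_widths:
        h = config.edge_mlp_hidden
        ecc.append(ECCLayerParams(
            W=_glorot(rng, fin, fout),
            b=np.zeros(fout),
            mlp_W1=_glorot(rng, 4, h),
            mlp_b1=np.zeros(h),
            mlp_W2=_glorot(rng, h, fin * fout),
            mlp_b2=np.zeros(fin * fout),
        ))
        fin = fout
    fc = []
    width_in = config.pooled_dim + config.adduct_dim
    for width in config.fc_widths:
        fc.append(DenseLayerParams(
            W=_glorot(rng, width_in, width), b=np.zeros(width),
            activation="relu", l2=config.l2_coefficient,
        ))
        width_in = width
    # output layer: ReLU, no regularization
    fc.append(DenseLayerParams(
        W=_glorot(rng, width_in, 1), b=np.zeros(1),
        activation="relu", l2=0.0,
    ))
    return ModelParams(
        ecc=ecc, fc=fc,
        feature_mean=np.zeros(n_features),
        feature_std=np.ones(n_features),
    )


# ---------------------------------------------------------------------------
# Layer math (public ops)
# ---------------------------------------------------------------------------

def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def edge_filter_weights(params: ECCLayerParams, E: np.ndarray):
    """MLP(e_ij) for every directed edge: M x Fin x Fout filter tensor."""
    pre = E @ params.mlp_W1 + params.mlp_b1
    hidden = _relu(pre)
    theta = hidden @ params.mlp_W2 + params.mlp_b2
    fin, fout = params.W.shape
    return theta.reshape(-1, fin, fout), pre, hidden


def ecc_forward(X: np.ndarray, E: np.ndarray, edge_index: np.ndarray,
                params: ECCLayerParams, activation: str = "relu") -> np.ndarray:
    """One edge-conditioned convolution over the node matrix.

    ``edge_index`` must contain both directions of every bond; the
    neighbour sum excludes the node itself (the root term x_i W is
    separate).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != params.W.shape[0]:
        raise ShapeError(
            f"node matrix has {X.shape} but layer expects Fin={params.W.shape[0]}"
        )
    if len(edge_index) != len(E):
        raise ShapeError("edge_index and E row counts differ")
    theta, _, _ = edge_filter_weights(params, np.asarray(E, dtype=float))
    out = X @ params.W + params.b
    if len(edge_index):
        src = edge_index[:, 0]
        dst = edge_index[:, 1]
        msg = np.einsum("mf,mfo->mo", X[src], theta)
        np.add.at(out, dst, msg)
    if activation == "relu":
        out = _relu(out)
    return out


def global_sum_pool(X_last: np.ndarray) -> np.ndarray:
    """Pool a graph by summing node features across the node dimension."""
    X_last = np.asarray(X_last, dtype=float)
    if X_last.ndim != 2 or X_last.shape[0] == 0:
        raise EmptyGraphError("cannot pool an empty node matrix")
    return X_last.sum(axis=0)


def fuse_adduct(p: np.ndarray, adduct: AdductType | str) -> np.ndarray:
    """Concatenate the pooled representation with the adduct one-hot."""
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    return np.concatenate([np.asarray(p, dtype=float), adduct.onehot])


# ---------------------------------------------------------------------------
# Batched forward / backward over disjoint unions of graphs
# ---------------------------------------------------------------------------

@dataclass
class GraphBatch:
    """Disjoint union of molecular graphs with a graph-membership index."""

    X: np.ndarray            # total_nodes x Fn
    E: np.ndarray            # total_edges x 4
    edge_index: np.ndarray   # total_edges x 2 (offset node ids)
    graph_id: np.ndarray     # total_nodes, which graph each node belongs to
    adduct_codes: np.ndarray  # B x 3
    n_graphs: int

    @classmethod
    def from_graphs(cls, graphs: list[MolecularGraph],
                    adducts: list[AdductType | str]) -> "GraphBatch":
        if len(graphs) != len(adducts):
            raise ShapeError("one adduct per graph required")
        if not graphs:
            raise EmptyGraphError("empty batch")
        xs, es, eis, gids = [], [], [], []
        offset = 0
        for k, g in enumerate(graphs):
            xs.append(g.X)
            es.append(g.E)
            eis.append(g.edge_index + offset)
            gids.append(np.full(g.n_nodes, k, dtype=int))
            offset += g.n_nodes
        codes = np.stack([
            (get_adduct(a).onehot if isinstance(a, str) else a.onehot)
            for a in adducts
        ])
        return cls(
            X=np.vstack(xs),
            E=np.vstack(es) if any(len(e) for e in es) else np.zeros((0, 4)),
            edge_index=(np.vstack(eis) if any(len(e) for e in eis)
                        else np.zeros((0, 2), dtype=int)),
            graph_id=np.concatenate(gids),
            adduct_codes=codes,
            n_graphs=len(graphs),
        )


def _segment_sum(values: np.ndarray, segment_id: np.ndarray,
                 n_segments: int) -> np.ndarray:
    out = np.zeros((n_segments, values.shape[1]))
    np.add.at(out, segment_id, values)
    return out


def _forward(params: ModelParams, batch: GraphBatch,
             mask_columns: np.ndarray | None = None):
    """Full forward pass; returns (predictions B, pooled B x F, caches)."""
    std = np.where(params.feature_std > 0, params.feature_std, 1.0)
    X = (batch.X - params.feature_mean) / std
    if mask_columns is not None and len(mask_columns):
        X = X.copy()
        X[:, mask_columns] = 0.0

    src = batch.edge_index[:, 0] if len(batch.edge_index) else None
    dst = batch.edge_index[:, 1] if len(batch.edge_index) else None

    ecc_caches = []
    for layer in params.ecc:
        theta, mlp_pre, mlp_hidden = edge_filter_weights(layer, batch.E)
        Z = X @ layer.W + layer.b
        if src is not None:
            msg = np.einsum("mf,mfo->mo", X[src], theta)
            np.add.at(Z, dst, msg)
        out = _relu(Z)
        ecc_caches.append((X, theta, mlp_pre, mlp_hidden, Z))
        X = out

    pooled = _segment_sum(X, batch.graph_id, batch.n_graphs)
    m = np.hstack([pooled, batch.adduct_codes])

    fc_caches = []
    h = m
    for layer in params.fc:
        Z = h @ layer.W + layer.b
        out = _relu(Z) if layer.activation == "relu" else Z
        fc_caches.append((h, Z))
        h = out
    preds = h[:, 0]
    return preds, pooled, (ecc_caches, fc_caches, m)


def _loss_and_grads(params: ModelParams, batch: GraphBatch,
                    targets: np.ndarray, l2_ecc: float):
    """MSE + L2 loss and its gradients w.r.t. every parameter array.

    Gradient layout matches ``ModelParams.arrays()``.
    """
    preds, _, (ecc_caches, fc_caches, m) = _forward(params, batch)
    n = len(targets)
    resid = preds - targets
    loss = float(np.mean(resid ** 2))

    grads: dict[int, np.ndarray] = {}

    # ---- dense head backward
    dh = np.zeros((n, 1))
    dh[:, 0] = 2.0 * resid / n
    fc_grads = []
    for layer, (h_in, Z) in zip(reversed(params.fc), reversed(fc_caches)):
        if layer.activation == "relu":
            dZ = dh * (Z > 0)
        else:
            dZ = dh
        dW = h_in.T @ dZ
        db = dZ.sum(axis=0)
        if layer.l2 > 0:
            loss += layer.l2 * float(np.sum(layer.W ** 2))
            dW = dW + 2.0 * layer.l2 * layer.W
        fc_grads.append((dW, db))
        dh = dZ @ layer.W.T
    fc_grads.reverse()

    # split molecular-vector gradient: pooled part only (adduct is input)
    pooled_dim = params.fc[0].W.shape[0] - batch.adduct_codes.shape[1]
    d_pooled = dh[:, :pooled_dim]

    # ---- pooling backward: broadcast each graph's gradient to its nodes
    dX = d_pooled[batch.graph_id]

    # ---- ECC layers backward
    src = batch.edge_index[:, 0] if len(batch.edge_index) else None
    dst = batch.edge_index[:, 1] if len(batch.edge_index) else None
    ecc_grads = []
    for layer, (X_in, theta, mlp_pre, mlp_hidden, Z) in zip(
            reversed(params.ecc), reversed(ecc_caches)):
        dZ = dX * (Z > 0)
        dW = X_in.T @ dZ
        db = dZ.sum(axis=0)
        dX_in = dZ @ layer.W.T
        if src is not None:
            dmsg = dZ[dst]                                  # M x Fout
            np.add.at(dX_in, src,
                      np.einsum("mo,mfo->mf", dmsg, theta))
            dtheta = np.einsum("mf,mo->mfo", X_in[src], dmsg)
            dtheta_flat = dtheta.reshape(len(dmsg), -1)
            dW2 = mlp_hidden.T @ dtheta_flat
            db2 = dtheta_flat.sum(axis=0)
            dhid = (dtheta_flat @ layer.mlp_W2.T) * (mlp_pre > 0)
            dW1 = batch.E.T @ dhid
            db1 = dhid.sum(axis=0)
        else:
            dW1 = np.zeros_like(layer.mlp_W1)
            db1 = np.zeros_like(layer.mlp_b1)
            dW2 = np.zeros_like(layer.mlp_W2)
            db2 = np.zeros_like(layer.mlp_b2)
        if l2_ecc > 0:
            for Wmat, dWmat in ((layer.W, dW), (layer.mlp_W1, dW1),
                                (layer.mlp_W2, dW2)):
                loss += l2_ecc * float(np.sum(Wmat ** 2))
                dWmat += 2.0 * l2_ecc * Wmat
        ecc_grads.append((dW, db, dW1, db1, dW2, db2))
        dX = dX_in
    ecc_grads.reverse()

    flat: list[np.ndarray] = []
    for g in ecc_grads:
        flat.extend(g)
    for g in fc_grads:
        flat.extend(g)
    return loss, flat


class Adam:
    """Standard Adam optimizer over a list of parameter arrays."""

    def __init__(self, arrays: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.arrays = arrays
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for a, g, m, v in zip(self.arrays, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            a -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Model wrapper
# ---------------------------------------------------------------------------

class CCSModel:
    """A configured (and possibly trained) CCS prediction network."""

    def __init__(self, config: ModelConfig,
                 featurizer: NodeFeaturizerConfig | None = None,
                 params: ModelParams | None = None):
        self.config = config
        self.featurizer = featurizer or NodeFeaturizerConfig()
        self.params = params or init_params(config, self.featurizer.n_features)

    # -- inference ---------------------------------------------------------

    def _mask_columns(self, mask_blocks) -> np.ndarray | None:
        if not mask_blocks:
            return None
        slices = self.featurizer.block_slices()
        cols: list[int] = []
        for name in mask_blocks:
            if name not in slices:
                from .errors import UnknownAttributeError

                raise UnknownAttributeError(f"unknown attribute {name!r}")
            cols.extend(range(slices[name].start, slices[name].stop))
        return np.asarray(cols, dtype=int)

    def predict_batch(self, graphs: list[MolecularGraph],
                      adducts: list[AdductType | str],
                      mask_blocks: tuple[str, ...] = (),
                      warn_ceiling: bool = True) -> np.ndarray:
        batch = GraphBatch.from_graphs(graphs, adducts)
        preds, _, _ = _forward(self.params, batch,
                               self._mask_columns(mask_blocks))
        if warn_ceiling and np.any(preds >= self.config.domain_ceiling):
            warnings.warn(
                f"{int(np.sum(preds >= self.config.domain_ceiling))} "
                f"prediction(s) at or above the training-domain ceiling "
                f"({self.config.domain_ceiling:.0f} Å²); treat with caution",
                stacklevel=2,
            )
        return preds

    def predict_ccs(self, graph: MolecularGraph,
                    adduct: AdductType | str,
                    mask_blocks: tuple[str, ...] = ()) -> float:
        """Deterministic forward pass for one molecule; nonnegative Å²."""
        return float(self.predict_batch([graph], [adduct], mask_blocks)[0])

    def pooled_representations(self, graphs: list[MolecularGraph],
                               adducts: list[AdductType | str] | None = None
                               ) -> np.ndarray:
        """The learned per-molecule representation p (B x pooled_dim)."""
        if adducts is None:
            adducts = ["[M+H]+"] * len(graphs)
        batch = GraphBatch.from_graphs(graphs, adducts)
        _, pooled, _ = _forward(self.params, batch)
        return pooled

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        save_model(self, path)

    @classmethod
    def load(cls, path) -> "CCSModel":
        return load_model(path)


def _weight_dict(params: ModelParams) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for k, layer in enumerate(params.ecc):
        for name, arr in zip(("W", "b", "mlp_W1", "mlp_b1", "mlp_W2", "mlp_b2"),
                             layer.arrays()):
            out[f"ecc{k}_{name}"] = arr
    for k, layer in enumerate(params.fc):
        out[f"fc{k}_W"] = layer.W
        out[f"fc{k}_b"] = layer.b
    out["feature_mean"] = params.feature_mean
    out["feature_std"] = params.feature_std
    return out


def save_model(model: CCSModel, path) -> None:
    """Write a checkpoint directory: config JSON + weights + checksums."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    config_doc = {
        "schema_version": SCHEMA_VERSION,
        "model": model.config.to_dict(),
        "featurizer": model.featurizer.to_dict(),
        "fc_activations": [l.activation for l in model.params.fc],
        "fc_l2": [l.l2 for l in model.params.fc],
    }
    (path / "config.json").write_text(json.dumps(config_doc, indent=2))
    np.savez(path / "weights.npz", **_weight_dict(model.params))
    digest = hashlib.sha256((path / "weights.npz").read_bytes()).hexdigest()
    (path / "manifest.json").write_text(json.dumps({
        "files": {"weights.npz": digest},
    }, indent=2))


def load_model(path) -> CCSModel:
    path = Path(path)
    config_file = path / "config.json"
    if not config_file.exists():
        raise ChecksumError(f"missing config.json in {path}")
    config_doc = json.loads(config_file.read_text())
    if config_doc.get("schema_version") != SCHEMA_VERSION:
        raise VersionError(
            f"checkpoint schema {config_doc.get('schema_version')} != "
            f"{SCHEMA_VERSION}"
        )
    manifest = json.loads((path / "manifest.json").read_text())
    for fname, digest in manifest["files"].items():
        f = path / fname
        if not f.exists():
            raise ChecksumError(f"missing checkpoint file {fname}")
        if hashlib.sha256(f.read_bytes()).hexdigest() != digest:
            raise ChecksumError(f"checksum mismatch for {fname}")
    weights = np.load(path / "weights.npz")
    config = ModelConfig.from_dict(config_doc["model"])
    featurizer = NodeFeaturizerConfig.from_dict(config_doc["featurizer"])
    ecc = [
        ECCLayerParams(*[weights[f"ecc{k}_{n}"] for n in
                         ("W", "b", "mlp_W1", "mlp_b1", "mlp_W2", "mlp_b2")])
        for k in range(config.n_ecc_layers)
    ]
    fc = [
        DenseLayerParams(
            weights[f"fc{k}_W"], weights[f"fc{k}_b"],
            config_doc["fc_activations"][k], config_doc["fc_l2"][k],
        )
        for k in range(config.n_fc_layers + 1)
    ]
    params = ModelParams(
        ecc=ecc, fc=fc,
        feature_mean=weights["feature_mean"],
        feature_std=weights["feature_std"],
    )
    return CCSModel(config, featurizer, params)
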