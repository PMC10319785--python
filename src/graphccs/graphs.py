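"""Molecular graph construction for the network.

A molecule with a 3D conformer becomes three matrices: the node attribute
matrix ``X`` (one row per atom: element one-hot, degree, radius, mass,
ring flag, centred Cartesian coordinates), the edge attribute matrix ``E``
(one row per *directed* edge, one-hot over the four bond orders), and the
binary adjacency matrix ``A``.  ``edge_index`` aligns rows of ``E`` with
(i, j) atom pairs; both directions of every bond are present.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .chem_io import BOND_ORDERS, Conformer, Molecule, SUPPORTED_ELEMENTS
from .errors import (
    InconsistentInputError,
    NotARotationError,
    UnknownAttributeError,
)

#: Ordered attribute blocks of the node matrix.
ATTRIBUTE_BLOCKS = ("symbol", "degree", "radius", "mass", "in_ring", "coords")


@dataclass(frozen=True)
class NodeFeaturizerConfig:
    """Layout of the node attribute matrix.

    ``Fn = |vocabulary| + 1 + 1 + 1 + 1 + 3`` when all blocks are enabled.
    Block order is fixed (symbol | degree | radius | mass | in_ring | coords)
    so checkpoints stay reproducible and mask column ranges are stable.
    """

    element_vocabulary: tuple[str, ...] = SUPPORTED_ELEMENTS
    include: tuple[str, ...] = ATTRIBUTE_BLOCKS
    coord_centering: bool = True

    def __post_init__(self):
        unknown = set(self.include) - set(ATTRIBUTE_BLOCKS)
        if unknown:
            raise UnknownAttributeError(f"unknown attribute blocks {unknown}")

    @property
    def n_features(self) -> int:
        return sum(w for _, w in self.block_widths())

    def block_widths(self) -> list[tuple[str, int]]:
        widths = {
            "symbol": len(self.element_vocabulary),
            "degree": 1,
            "radius": 1,
            "mass": 1,
            "in_ring": 1,
            "coords": 3,
        }
        return [(name, widths[name]) for name in ATTRIBUTE_BLOCKS
                if name in self.include]

    def block_slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for name, width in self.block_widths():
            out[name] = slice(start, start + width)
            start += width
        return out

    def continuous_columns(self) -> np.ndarray:
        """Indices of columns standardized with training-set statistics."""
        cols: list[int] = []
        slices = self.block_slices()
        for name in ("radius", "mass", "coords"):
            if name in slices:
                cols.extend(range(slices[name].start, slices[name].stop))
        return np.asarray(cols, dtype=int)

    def to_dict(self) -> dict:
        return {
            "element_vocabulary": list(self.element_vocabulary),
            "include": list(self.include),
            "coord_centering": self.coord_centering,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NodeFeaturizerConfig":
        return cls(
            element_vocabulary=tuple(d["element_vocabulary"]),
            include=tuple(d["include"]),
            coord_centering=bool(d["coord_centering"]),
        )


@dataclass
class MolecularGraph:
    X: np.ndarray            # N x Fn node attributes
    E: np.ndarray            # M x 4 one-hot bond orders, M = 2 * n_bonds
    A: np.ndarray            # N x N symmetric binary adjacency
    edge_index: np.ndarray   # M x 2 (i, j) pairs aligned with rows of E
    config: NodeFeaturizerConfig = field(default_factory=NodeFeaturizerConfig)

    @property
    def n_nodes(self) -> int:
        return self.X.shape[0]

    @property
    def n_edges(self) -> int:
        return self.E.shape[0]


def build_graph(
    mol: Molecule,
    conf: Conformer | None = None,
    cfg: NodeFeaturizerConfig | None = None,
) -> MolecularGraph:
    """Assemble the node/edge/adjacency matrices for one molecule.

    Coordinates are taken from ``conf`` (default: the molecule's own
    conformer) and centred at the centroid when the config says so.
    """
    cfg = cfg or NodeFeaturizerConfig()
    conf = conf or mol.conformer
    if "coords" in cfg.include and conf is None:
        raise InconsistentInputError(f"{mol.smiles!r} has no conformer")
    n = mol.n_atoms
    if conf is not None and conf.coords.shape[0] != n:
        raise InconsistentInputError(
            f"conformer has {conf.coords.shape[0]} rows for {n} atoms"
        )

    slices = cfg.block_slices()
    X = np.zeros((n, cfg.n_features))
    if "symbol" in slices:
        vocab = {el: k for k, el in enumerate(cfg.element_vocabulary)}
        base = slices["symbol"].start
        for i, atom in enumerate(mol.atoms):
            if atom.element in vocab:
                X[i, base + vocab[atom.element]] = 1.0
    if "degree" in slices:
        X[:, slices["degree"]] = [[a.degree] for a in mol.atoms]
    if "radius" in slices:
        X[:, slices["radius"]] = [[a.radius] for a in mol.atoms]
    if "mass" in slices:
        X[:, slices["mass"]] = [[a.mass] for a in mol.atoms]
    if "in_ring" in slices:
        X[:, slices["in_ring"]] = [[float(a.in_ring)] for a in mol.atoms]
    if "coords" in slices:
        coords = conf.coords
        if cfg.coord_centering:
            coords = coords - coords.mean(axis=0, keepdims=True)
        X[:, slices["coords"]] = coords

    A = np.zeros((n, n), dtype=np.int8)
    m = 2 * len(mol.bonds)
    E = np.zeros((m, len(BOND_ORDERS)))
    edge_index = np.zeros((m, 2), dtype=int)
    order_idx = {o: k for k, o in enumerate(BOND_ORDERS)}
    row = 0
    for bond in mol.bonds:
        A[bond.i, bond.j] = 1
        A[bond.j, bond.i] = 1
        for i, j in ((bond.i, bond.j), (bond.j, bond.i)):
            E[row, order_idx[bond.order]] = 1.0
            edge_index[row] = (i, j)
            row += 1
    return MolecularGraph(X=X, E=E, A=A, edge_index=edge_index, config=cfg)


def mask_attribute(graph: MolecularGraph, attribute: str) -> MolecularGraph:
    """Return a copy of the graph with one attribute block zeroed out.

    Used by masking-based feature importance; idempotent.
    """
    slices = graph.config.block_slices()
    if attribute not in slices:
        raise UnknownAttributeError(
            f"unknown attribute {attribute!r}; have {sorted(slices)}"
        )
    X = graph.X.copy()
    X[:, slices[attribute]] = 0.0
    return replace(graph, X=X)


def rotate_conformer(conf: Conformer, rotation: np.ndarray) -> Conformer:
    """Rigidly rotate a conformer about its centroid.

    ``rotation`` must be a proper rotation matrix (orthonormal, det +1,
    checked to 1e-8); all pairwise distances are preserved.
    """
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise NotARotationError(f"expected 3x3 matrix, got {rotation.shape}")
    if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-8):
        raise NotARotationError("matrix is not orthonormal")
    if not np.isclose(np.linalg.det(rotation), 1.0, atol=1e-8):
        raise NotARotationError("determinant is not +1 (improper rotation)")
    centroid = conf.coords.mean(axis=0, keepdims=True)
    coords = (conf.coords - centroid) @ rotation.T + centroid
    return Conformer(coords=coords, energy_minimized=conf.energy_minimized)
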