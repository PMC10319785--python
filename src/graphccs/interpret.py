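"""Model interpretation: masking feature importance, rotation robustness,
and export of the learned pooled representations.

Feature importance follows the mask-and-compare recipe: one atom-attribute
block at a time is zeroed (after standardization) at inference, the
evaluation error of the masked model is compared against the unmasked
baseline, negative drops are clipped at zero, and the clipped drops are
normalized to percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .chem_io import CCSRecord, Molecule
from .gnn import CCSModel
from .graphs import ATTRIBUTE_BLOCKS, build_graph, rotate_conformer
from .training import _graphs_for, evaluate


@dataclass
class FeatureImportanceResult:
    baseline_error: float
    raw_drops: dict          # block -> masked_error - baseline_error
    relative_importance: dict  # block -> % (clipped drops, normalized to 100)

    def to_dict(self) -> dict:
        return {
            "baseline_error": self.baseline_error,
            "raw_drops": dict(self.raw_drops),
            "relative_importance": dict(self.relative_importance),
        }


def feature_importance(model: CCSModel, records: list[CCSRecord],
                       metric: str = "median_re",
                       seed: int = 42) -> FeatureImportanceResult:
    """Masking-based importance of each of the six atom-attribute blocks.

    The trained model is reused; masking happens at inference only (no
    retraining per mask).  ``metric`` selects which evaluation error is
    compared: "median_re" (default), "rmse", or "neg_r2".
    """
    def err(mask_blocks: tuple[str, ...]) -> float:
        m = evaluate(records, model, seed=seed, mask_blocks=mask_blocks)
        if metric == "neg_r2":
            return -m["r2"]
        return m[metric]

    baseline = err(())
    raw = {}
    blocks = [b for b in ATTRIBUTE_BLOCKS if b in model.featurizer.include]
    for block in blocks:
        raw[block] = err((block,)) - baseline
    clipped = {b: max(d, 0.0) for b, d in raw.items()}
    total = sum(clipped.values())
    if total > 0:
        rel = {b: 100.0 * v / total for b, v in clipped.items()}
    else:
        # degenerate model (e.g. untrained): no block matters
        rel = {b: 0.0 for b in clipped}
    return FeatureImportanceResult(
        baseline_error=baseline, raw_drops=raw, relative_importance=rel,
    )


def rotation_robustness(model: CCSModel, mol: Molecule,
                        adduct: str = "[M+H]+",
                        n_rotations: int = 100, seed: int = 0,
                        mask_blocks: tuple[str, ...] = ()) -> dict:
    """Spread of predictions under uniformly random rigid rotations.

    Rotations are sampled uniformly over SO(3) (random unit quaternions);
    the summary reports mean, standard deviation and coefficient of
    variation of the predicted CCS.
    """
    rng = np.random.default_rng(seed)
    rotations = Rotation.random(n_rotations, random_state=rng).as_matrix()
    preds = []
    for R in rotations:
        conf = rotate_conformer(mol.conformer, R)
        graph = build_graph(mol, conf=conf, cfg=model.featurizer)
        preds.append(model.predict_ccs(graph, adduct, mask_blocks=mask_blocks))
    preds = np.asarray(preds)
    mean = float(preds.mean())
    # shift by the first value before taking the spread: exact zero for
    # constant predictions, better conditioned in general
    std = float(np.std(preds - preds[0]))
    return {
        "mean": mean,
        "std": std,
        "cv": std / mean if mean else float("nan"),
        "n_rotations": n_rotations,
    }


def export_representations(model: CCSModel, records: list[CCSRecord],
                           seed: int = 42,
                           labels: list[str] | None = None):
    """Pooled representation table: one row per record.

    Columns: identifier, smiles, adduct, ring_count, optional label, and
    the pooled vector p (p0..p{F-1}).  Suitable input for any external
    2-D embedding tool (e.g. UMAP).
    """
    import pandas as pd

    graphs = _graphs_for(records, model.featurizer, seed)
    pooled = model.pooled_representations(graphs, [r.adduct for r in records])
    data = {
        "identifier": [r.identifier for r in records],
        "smiles": [r.smiles for r in records],
        "adduct": [r.adduct for r in records],
        "ring_count": [r.molecule.ring_count for r in records],
    }
    if labels is not None:
        data["label"] = list(labels)
    frame = pd.DataFrame(data)
    for j in range(pooled.shape[1]):
        frame[f"p{j}"] = pooled[:, j]
    return frame
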