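"""Dataset curation, splitting, model fitting, and evaluation metrics.

Curation applies five steps in order: (1) drop unparsable SMILES,
(2) keep only the three supported adducts, (3) collapse duplicate
(smiles, adduct) groups to the median CCS, (4) drop molecules whose 3D
conformer cannot be generated or minimized, (5) remove records deviating
from a robust per-adduct CCS ~ m/z trend by more than k scaled-MAD.
Counts after every step land in a :class:`CurationReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .adducts import adduct_mz, normalize_adduct
from .chem_io import CCSRecord, generate_conformer, parse_molecule
from .errors import (
    DivergenceError,
    EmptyEvaluationError,
    GraphCCSError,
)
from .gnn import (
    Adam,
    CCSModel,
    GraphBatch,
    ModelConfig,
    _forward,
    _loss_and_grads,
    init_params,
)
from .graphs import MolecularGraph, NodeFeaturizerConfig, build_graph

CURATION_STEPS = (
    "smiles_verification",
    "adduct_selection",
    "median_collapse",
    "conformer_generation",
    "outlier_removal",
)


@dataclass
class CurationReport:
    initial: int = 0
    surviving: dict = field(default_factory=dict)   # step name -> count
    dropped: list = field(default_factory=list)     # (identifier, reason)

    def counts(self) -> list[int]:
        return [self.initial] + [self.surviving[s] for s in CURATION_STEPS]

    def to_dict(self) -> dict:
        return {
            "initial": self.initial,
            "surviving": dict(self.surviving),
            "dropped": [list(d) for d in self.dropped],
        }


def curate(records: list[CCSRecord], seed: int = 42,
           outlier_k: float = 5.0,
           min_group_for_outliers: int = 8) -> tuple[list[CCSRecord], CurationReport]:
    """Run the five-step curation pipeline; every problem is a reason-coded drop.

    Idempotent: curating an already-curated set changes nothing.
    """
    report = CurationReport(initial=len(records))

    # step 1: SMILES verification (canonicalize; cache per input string)
    step1: list[CCSRecord] = []
    cache: dict[str, object] = {}
    for rec in records:
        if rec.smiles not in cache:
            try:
                cache[rec.smiles] = parse_molecule(rec.smiles)
            except GraphCCSError:
                cache[rec.smiles] = None
        mol = cache[rec.smiles]
        if mol is None:
            report.dropped.append((rec.identifier, "invalid_smiles"))
            continue
        rec.molecule = mol
        rec.smiles = mol.smiles
        step1.append(rec)
    report.surviving["smiles_verification"] = len(step1)

    # step 2: adduct type selection
    step2: list[CCSRecord] = []
    for rec in step1:
        canonical = normalize_adduct(rec.adduct)
        if canonical is None:
            report.dropped.append((rec.identifier, "unsupported_adduct"))
            continue
        rec.adduct = canonical
        step2.append(rec)
    report.surviving["adduct_selection"] = len(step2)

    # step 3: collapse duplicate (smiles, adduct) to the median CCS
    groups: dict[tuple[str, str], list[CCSRecord]] = {}
    order: list[tuple[str, str]] = []
    step3: list[CCSRecord] = []
    for rec in step2:
        if rec.ccs is None:
            report.dropped.append((rec.identifier, "missing_ccs"))
            continue
        key = (rec.smiles, rec.adduct)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)
    for key in order:
        grp = groups[key]
        keep = grp[0]
        keep.ccs = float(np.median([r.ccs for r in grp]))
        for extra in grp[1:]:
            report.dropped.append((extra.identifier, "duplicate_entry"))
        step3.append(keep)
    report.surviving["median_collapse"] = len(step3)

    # step 4: conformer generation (once per unique molecule)
    conf_ok: dict[str, bool] = {}
    step4: list[CCSRecord] = []
    for rec in step3:
        if rec.smiles not in conf_ok:
            if rec.molecule.conformer is not None:
                conf_ok[rec.smiles] = True
            else:
                try:
                    generate_conformer(rec.molecule, seed=seed)
                    conf_ok[rec.smiles] = True
                except GraphCCSError:
                    conf_ok[rec.smiles] = False
        if conf_ok[rec.smiles]:
            step4.append(rec)
        else:
            report.dropped.append((rec.identifier, "conformer_failed"))
    report.surviving["conformer_generation"] = len(step4)

    # step 5: outlier removal against a robust per-adduct CCS ~ m/z trend
    step5 = _remove_outliers(step4, report, outlier_k, min_group_for_outliers)
    report.surviving["outlier_removal"] = len(step5)
    return step5, report


def _remove_outliers(records, report, k, min_group):
    """Drop records > k scaled-MAD from a Theil-Sen CCS ~ m/z line per adduct.

    Iterated to a fixed point so curation is idempotent: the robust line
    is refit after each removal pass until no record is flagged.
    """
    for rec in records:
        if rec.mz is None:
            rec.mz = float(adduct_mz(rec.molecule.neutral_mass(), rec.adduct))
    current = list(records)
    while True:
        by_adduct: dict[str, list[CCSRecord]] = {}
        for rec in current:
            by_adduct.setdefault(rec.adduct, []).append(rec)
        flagged: set[int] = set()
        for group in by_adduct.values():
            if len(group) < min_group:
                continue
            mz = np.array([r.mz for r in group])
            ccs = np.array([r.ccs for r in group])
            slope, intercept, _, _ = stats.theilslopes(ccs, mz)
            resid = ccs - (intercept + slope * mz)
            mad = stats.median_abs_deviation(resid, scale="normal")
            if mad == 0:
                mad = np.finfo(float).eps
            for rec, r in zip(group, resid):
                if abs(r) > k * mad:
                    flagged.add(id(rec))
        if not flagged:
            return current
        kept = []
        for rec in current:
            if id(rec) in flagged:
                report.dropped.append((rec.identifier, "ccs_outlier"))
            else:
                kept.append(rec)
        current = kept


def split(records: list[CCSRecord], fractions: tuple[float, ...] = (0.9, 0.1),
          seed: int = 0, level: str = "entry") -> tuple[list[CCSRecord], ...]:
    """Random partition of records into len(fractions) disjoint sets.

    ``level="entry"`` (default) shuffles records; ``level="molecule"``
    keeps all entries of one canonical SMILES in the same partition.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    if level == "entry":
        units: list[list[CCSRecord]] = [[r] for r in records]
    elif level == "molecule":
        by_smiles: dict[str, list[CCSRecord]] = {}
        for r in records:
            by_smiles.setdefault(r.smiles, []).append(r)
        units = list(by_smiles.values())
    else:
        raise ValueError(f"unknown split level {level!r}")
    perm = rng.permutation(len(units))
    boundaries = np.floor(np.cumsum(fractions) * len(units)).astype(int)
    parts: list[list[CCSRecord]] = []
    start = 0
    for stop in boundaries:
        parts.append([rec for u in perm[start:stop] for rec in units[u]])
        start = stop
    return tuple(parts)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _graphs_for(records: list[CCSRecord], featurizer: NodeFeaturizerConfig,
                seed: int) -> list[MolecularGraph]:
    graphs = []
    for rec in records:
        if rec.molecule is None:
            rec.molecule = parse_molecule(rec.smiles)
        if rec.molecule.conformer is None:
            generate_conformer(rec.molecule, seed=seed)
        graphs.append(build_graph(rec.molecule, cfg=featurizer))
    return graphs


def fit(train: list[CCSRecord], validation: list[CCSRecord],
        config: ModelConfig,
        featurizer: NodeFeaturizerConfig | None = None,
        verbose: bool = False) -> tuple[CCSModel, list[dict]]:
    """Train the network with Adam on the MSE loss (plus L2 weight penalty).

    Returns the model at the best validation loss together with the
    per-epoch training log.  All randomness (init, shuffling) funnels
    through ``config.seed``.
    """
    featurizer = featurizer or NodeFeaturizerConfig()
    rng = np.random.default_rng(config.seed)
    train_graphs = _graphs_for(train, featurizer, config.seed)
    val_graphs = _graphs_for(validation, featurizer, config.seed)
    y_train = np.array([r.ccs for r in train], dtype=float)
    y_val = np.array([r.ccs for r in validation], dtype=float)
    adducts_train = [r.adduct for r in train]
    adducts_val = [r.adduct for r in validation]

    params = init_params(config, featurizer.n_features, rng)

    # standardize continuous node attributes with training-set statistics
    if config.standardize:
        all_X = np.vstack([g.X for g in train_graphs])
        cols = featurizer.continuous_columns()
        mean = np.zeros(featurizer.n_features)
        std = np.ones(featurizer.n_features)
        mean[cols] = all_X[:, cols].mean(axis=0)
        std[cols] = all_X[:, cols].std(axis=0)
        std[std == 0] = 1.0
        params.feature_mean, params.feature_std = mean, std

    # regression-head bias starts at the mean target so the ReLU output
    # is alive from step one
    params.fc[-1].b[:] = y_train.mean()

    opt = Adam(params.arrays(), lr=config.learning_rate)
    val_batch = GraphBatch.from_graphs(val_graphs, adducts_val) if validation else None

    best_val = np.inf
    best_params = params.copy()
    best_epoch = 0
    log: list[dict] = []
    n = len(train)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = GraphBatch.from_graphs(
                [train_graphs[i] for i in idx],
                [adducts_train[i] for i in idx],
            )
            loss, grads = _loss_and_grads(
                params, batch, y_train[idx], config.l2_coefficient
            )
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite training loss at epoch {epoch}"
                )
            opt.step(grads)
            epoch_loss += loss * len(idx)
        epoch_loss /= n
        if val_batch is not None:
            preds, _, _ = _forward(params, val_batch)
            val_loss = float(np.mean((preds - y_val) ** 2))
        else:
            val_loss = epoch_loss
        log.append({"epoch": epoch, "train_loss": epoch_loss,
                    "val_loss": val_loss})
        if verbose and epoch % 20 == 0:
            print(f"epoch {epoch:4d}  train {epoch_loss:10.3f}  "
                  f"val {val_loss:10.3f}")
        if val_loss < best_val:
            best_val = val_loss
            best_params = params.copy()
            best_epoch = epoch
        elif epoch - best_epoch >= config.patience:
            break
    model = CCSModel(config, featurizer, best_params)
    return model, log


def predict_records(records: list[CCSRecord], model: CCSModel,
                    seed: int = 42) -> np.ndarray:
    """Predicted CCS (Å²) for each record, in order; fills ``ccs_pred``."""
    graphs = _graphs_for(records, model.featurizer, seed)
    preds = model.predict_batch(graphs, [r.adduct for r in records],
                                warn_ceiling=False)
    for rec, p in zip(records, preds):
        rec.ccs_pred = float(p)
    return preds


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    ss_res = np.sum((observed - predicted) ** 2)
    ss_tot = np.sum((observed - observed.mean()) ** 2)
    if ss_tot == 0:
        # constant observations: R^2 undefined
        return float("nan")
    return float(1.0 - ss_res / ss_tot)


def median_relative_error(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Median of |pred - obs| / obs, as a percentage."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    return float(np.median(np.abs(predicted - observed) / observed) * 100.0)


def rmse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Root mean squared error in Å²."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


def evaluate(records: list[CCSRecord], model: CCSModel,
             seed: int = 42,
             mask_blocks: tuple[str, ...] = ()) -> dict:
    """R², median relative error (%) and RMSE (Å²) on records with known CCS."""
    records = [r for r in records if r.ccs is not None]
    if not records:
        raise EmptyEvaluationError("no records with experimental CCS")
    graphs = _graphs_for(records, model.featurizer, seed)
    preds = model.predict_batch(graphs, [r.adduct for r in records],
                                mask_blocks=mask_blocks, warn_ceiling=False)
    obs = np.array([r.ccs for r in records], dtype=float)
    return {
        "r2": r_squared(obs, preds),
        "median_re": median_relative_error(obs, preds),
        "rmse": rmse(obs, preds),
        "n": len(records),
    }
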