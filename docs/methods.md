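# Methods

This note documents the models and procedures implemented in `graphccs`,
the parameters that matter, the numerical choices behind them, and what
the synthetic benchmark does and does not demonstrate.

## The prediction model

A molecule's collision cross section (CCS) is, to a good approximation,
the orientation-averaged effective area the ion presents to buffer gas.
It therefore depends on the 3D shape of the molecule and on the adduct
that ionized it. The model consumes:

1. **One 3D conformer per molecule**, generated by distance-geometry
   embedding with experimental torsion preferences (ETKDG, as implemented
   in RDKit) and minimized with MMFF94. Explicit hydrogens are kept:
   they contribute to the projected area, and MMFF94 needs them. A
   conformer ensemble is deliberately not used; the conformational spread
   is small relative to the target accuracy for drug-like molecules, and
   one conformer keeps featurization deterministic per seed.
2. **A molecular graph.** Node attributes, in fixed block order:
   element one-hot over a 13-element vocabulary (C, H, O, N, P, S, F, Cl,
   Br, I, Co, As, Se), explicit degree, per-element radius (Å), atomic
   mass (Da), ring-membership flag, and centroid-centred Cartesian
   coordinates (Å). Edge attributes are a one-hot over the four bond
   orders (single, double, triple, aromatic), one row per directed edge.
   The fixed block order makes checkpoints reproducible and lets the
   masking machinery address columns by name.
3. **An adduct code.** [M+H]+ → [1,0,0], [M+Na]+ → [0,1,0],
   [M−H]− → [0,0,1]. These are the three most common electrospray
   adducts; the code vector width is a config field, so further adducts
   can be added by retraining with a wider one-hot.

Each edge-conditioned convolution (ECC) layer computes, per atom i,

    out_i = x_i W + Σ_{j ∈ N(i)} x_j · MLP(e_ij) + b,    then ReLU

The filter network MLP (one hidden layer, 32 ReLU units by default) maps
the 4-dim bond one-hot to an Fin×Fout weight matrix, so the message a
neighbour sends is conditioned on the bond order joining it. The
neighbour sum excludes the atom itself — the root term `x_i W` is
separate. Global sum pooling collapses node features to the pooled
vector **p**; sum (rather than mean) pooling preserves extensivity: a
bigger molecule yields a larger-norm representation, which suits an
extensive target like an area. The adduct code is concatenated and an
all-ReLU fully connected stack produces the CCS. The output layer is
also ReLU (CCS is nonnegative) and carries no L2 penalty.

Two architectures are configured:

| | full | scaled |
|---|---|---|
| ECC layers × width | 3 × 16 | 2 × 8 |
| FC layers | 8 (geometric taper from 384) | 3 (64, 32, 16) |
| pooled dim | 16 | 8 |

The full architecture is the default for real-data training; the scaled
one is used throughout the test suite and the acceptance run, where the
problem (500 synthetic molecules of 3–10 heavy atoms) is small enough
that the full stack would only slow things down without changing the
conclusions. Every layer, the backpropagation, and the Adam optimizer
are implemented directly on NumPy arrays; on a single thread the whole
training run is bit-reproducible from the config seed.

### Training details

- Loss: mean squared error in Å² (no log transform — the target spans
  less than one order of magnitude), plus L2 on all layer weights except
  the output layer (coefficient 1e-6 by default).
- Optimizer: Adam, learning rate 1e-3 (3e-3 for the scaled config,
  which has far fewer parameters), batches of disjoint graph unions with
  a membership index; batched forward equals per-graph forward.
- Continuous node attributes (radius, mass, coordinates) are
  standardized with training-set statistics stored in the checkpoint;
  one-hot and small-integer columns are left raw.
- The output bias is initialized to the mean training target so the
  ReLU output starts in its active region; the rest is Glorot-uniform.
- Early stopping on validation MSE with a patience window; the
  returned parameters are those of the best validation epoch.
- `DivergenceError` is raised if the loss goes non-finite rather than
  silently returning garbage.

Predictions at or above 380 Å² trigger a warning: typical experimental
small-molecule CCS collections contain almost nothing beyond that, so a
model trained on them extrapolates there.

## Curation

Five ordered steps, each recording reason-coded drops:

1. **SMILES verification** — unparsable strings are dropped; survivors
   are canonicalized.
2. **Adduct selection** — only the three supported adducts pass.
3. **Median collapse** — duplicate (canonical SMILES, adduct) entries
   become one record at the median CCS, which is robust to a single bad
   replicate.
4. **Conformer generation** — molecules for which embedding or
   force-field setup fails are dropped (in prediction mode they are kept
   with a warning instead; a slightly unconverged geometry is better
   than no prediction).
5. **Outlier removal** — CCS and m/z are strongly correlated, so per
   adduct a Theil–Sen line of CCS on m/z is fit and records deviating by
   more than k·(scaled MAD) are dropped (k = 5 by default; groups
   smaller than 8 are left untouched). The pass is iterated to a fixed
   point, which makes curation idempotent. This rule is this package's
   own declared statistic: transparent, robust, and configurable.

Splitting is random at the entry level by default (records of one
molecule may land in different partitions); a molecule-level mode keeps
all adducts of a canonical SMILES together, which is the stricter
generalization test and is what the synthetic benchmark uses.

## The synthetic benchmark

Real CCS training collections are external downloads, so the test suite
fabricates its own data with known ground truth.

**Molecules.** Random bonded trees over 3–10 heavy atoms drawn from a
C/N/O/S/F palette (carbon-weighted), with an optional ring closure and
occasional double-bond upgrades, sanitized by RDKit and embedded like any
other molecule. Assembly failures are resampled; generation is
deterministic per seed.

**Labels.** A projection-approximation-style oracle: the CCS is the mean
over orientations of the area of the union of the projected atomic disks
(van der Waals radius + 1.0 Å probe addition). Orientations come from a
scrambled Sobol sequence mapped to uniform rotations (Shoemake's method),
64 per molecule for labelling; areas are estimated by jittered stratified
Monte-Carlo on a 48×48 grid per orientation. A fixed per-adduct offset
(+H: 0, +Na: +4, −H: −2 Å²; arbitrary but learnable) and Gaussian noise
(σ = 1 Å², roughly 1.5% of a typical label, mimicking inter-lab spread)
complete the label. m/z is computed from the molecular mass and the
adduct mass shift (+1.00728, +22.98922, −1.00728 Da), and a linear
mass–RT trend with noise supplies retention times for the identification
benchmark.

The oracle is *not* a trajectory-method calculation — it has no
long-range potential, no temperature, no gas model. What it shares with
the physical quantity is exactly what the tests need: rotation
invariance (up to quantified Monte-Carlo error), monotonicity in
molecular bulk, a strong mass–CCS correlation (Pearson r ≈ 0.92 under
the default conditions), and an additive adduct effect. Passing the
end-to-end benchmark therefore shows that the architecture, featurization
and training loop can learn a shape-determined, adduct-shifted area from
3D molecular graphs — it does not certify accuracy on experimental CCS
values, which requires training on a real collection.

**Benchmark conditions.** 500 molecules × 3 adducts; 400 molecules for
training (90/10 train/validation at entry level), 100 held out at the
molecule level; scaled architecture. Under these conditions the model
reaches R² ≈ 0.96–0.98 and median relative error ≈ 2% on the held-out
molecules (the acceptance gates are R² ≥ 0.8 and ≤ 10%).

## Interpretation machinery

**Feature importance.** One attribute block at a time is zeroed at
inference — after standardization, so "masked" means "uninformative",
not "extreme value" — and the evaluation error (median relative error by
default) is compared with the unmasked baseline. Negative drops are
clipped to zero and the rest normalized to percentages. Masking is done
at inference on the trained model, not by retraining per mask; this
measures what the model actually uses. On the synthetic benchmark the
coordinate block dominates (the labels are literally projected areas)
and mass is nearly irrelevant (the labels never see it, and it is
redundant with the element one-hot) — the same qualitative ordering
reported for experimental CCS models. Importances are computed on the
held-out partition.

**Rotation robustness.** Coordinates enter raw (centred but not
rotation-normalized), so the model is not rotation-invariant by
construction; it must learn approximate invariance from data. The
robustness probe predicts under n uniformly random rotations (unit
quaternions) and reports mean, standard deviation and coefficient of
variation. The oracle's own rotational spread (< 1% at 256 orientations)
is the reference scale. The spread is computed after shifting by the
first prediction so a constant series yields exactly zero.

**Representations.** The pooled vector **p** is exported per record with
the molecule's SSSR ring count and optional labels, ready for any 2-D
embedding tool; the embedding itself is intentionally out of the core
dependency set.

## Identification filtering

Candidates are filtered in stages: |Δm/z| ≤ tolerance (ppm) gives the
MList, the RT window narrows it to the RList, and the CCS window (% of
the observed value) to the CList. Stages whose dimension is absent from
the query or library pass through, so stage counts never increase. The
CList is ranked by a fused score

    score = 1 − mean_d( w_d · |error_d| / tolerance_d )

over the available dimensions (equal weights by default, configurable),
which is monotone non-increasing in each error; ties break on smaller
m/z error, then identifier, for determinism. recall@k is the percentage
of queries whose true identifier ranks in the top k. Defaults (10 ppm,
1 min, 3%) reflect common practice and are all configurable. The
synthetic identification benchmark plants isomeric decoys (identical
m/z, in-window RT, CCS displaced by ≥ 5%) so that only the CCS stage can
separate truth from decoys; adding the CCS filter raises recall@1 from
~10% to ~100% under those conditions.

## Degenerate inputs and numerical conventions

- R² is returned as NaN for constant observations (undefined) instead
  of dividing by zero.
- A zero feature standard deviation falls back to 1 to avoid division
  by zero on constant columns.
- Empty graphs, empty libraries, and empty evaluation sets raise typed
  errors rather than returning empty results.
- Rotation matrices are validated (orthonormal, det +1, tolerance 1e-8);
  reflections are rejected.
- All randomness — initialization, shuffling, molecule generation,
  oracle orientations, noise — funnels through explicit integer seeds.

## Known limitations

- The synthetic generator produces small (3–10 heavy atoms), mostly
  saturated molecules; it does not emulate lipids, peptides, aromatic
  ring systems beyond single closures, stereochemistry, or instrument-
  specific biases. Conclusions about those regimes require real data.
- One conformer per molecule; strongly flexible molecules are
  represented by a single ETKDG/MMFF94 minimum.
- The outlier rule and the fused identification score are this
  package's own declared formulations (robust-trend MAD cut; weighted
  normalized-error sum) — transparent substitutes for procedures that
  vary between laboratories.
- Whether the node radius should be covalent or van der Waals is not
  settled; it is a config choice (`radius_table`), covalent by default,
  with the table swappable.
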