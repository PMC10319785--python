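# graphccs

Collision cross section (CCS) prediction for small molecules from 3D
molecular graphs, with an edge-conditioned graph convolutional network.

CCS values measured by ion mobility spectrometry are an orthogonal
physicochemical property for compound identification in LC-IMS-MS
metabolomics and lipidomics: a candidate whose predicted CCS disagrees
with the observed one can be filtered out even when its *m/z* matches.
`graphccs` provides the full workflow around that idea:

- **Conformers.** SMILES → RDKit molecule with explicit hydrogens → one
  3D conformer via experimental-torsion distance geometry (ETKDG),
  minimized with MMFF94.
- **Molecular graphs.** Node attribute matrix **X** (element one-hot,
  degree, radius, mass, ring flag, centred x/y/z), edge attribute matrix
  **E** (one-hot over single/double/triple/aromatic, one row per directed
  edge), adjacency matrix **A**.
- **Network.** Edge-conditioned convolution (ECC) layers

  &nbsp;&nbsp;&nbsp;&nbsp;**x**ᵢᵒ = **x**ᵢ**W** + Σ_{j∈N(i)} **x**ⱼ·MLP(**e**ᵢⱼ) + **b**

  where the filter network MLP maps the bond-type one-hot to a weight
  matrix; global sum pooling **p**ⱼ = Σᵢ **X**ᵢⱼ gives a fixed-length
  molecular representation (16-dim by default); the adduct one-hot
  **a** ∈ {[M+H]⁺→[1,0,0], [M+Na]⁺→[0,1,0], [M−H]⁻→[0,0,1]} is
  concatenated into **m** = [**p**, **a**]; a stack of ReLU fully
  connected layers maps **m** to the CCS scalar in Å². Training
  minimizes MSE with Adam, with L2 regularization on layer weights.
  The network, backpropagation and optimizer are implemented in NumPy.
- **Curation.** Five steps: SMILES verification, adduct selection,
  median collapse of duplicate (SMILES, adduct) entries, removal of
  molecules whose conformer generation fails, and robust outlier removal
  against a per-adduct CCS ~ m/z trend.
- **Interpretation.** Masking-based feature importance over the six
  atom-attribute blocks, rotation-robustness analysis, and export of the
  pooled representations for 2-D embedding.
- **Identification.** Staged m/z → RT → CCS candidate filtering with
  fused-score ranking and recall@k scoring.
- **Synthetic data.** A generator of random small organic molecules
  labelled by a deterministic orientation-averaged projected-area CCS
  oracle, so the entire pipeline runs and is tested without any external
  download. Training on a real CCS collection (e.g. a curated
  experimental database CSV with `smiles,adduct,ccs` columns) uses the
  exact same commands.

## Worked example

```bash
# 1. make a synthetic dataset: 100 molecules x 3 adducts, oracle-labelled
graphccs simulate --n-molecules 100 --seed 3 --out raw.csv

# 2. curate it (five steps; counts go to the report)
graphccs curate raw.csv --out curated.csv --report report.json

# 3. train the scaled network and save a checkpoint
graphccs train curated.csv --checkpoint ckpt --seed 3

# 4. predict all three adducts for new molecules
printf 'smiles,adduct\nCCO,[M+H]+\n' > todo.csv
graphccs predict todo.csv --checkpoint ckpt --out pred.csv
cat pred.csv
```

A run of steps 1–4 prints, among others:

```
curation counts: [300, 300, 300, 300, 300, 300]
saved checkpoint to ckpt; best val MSE 1.8688
predicted 3 rows (0 failures, 0 above the 380 Å² domain ceiling) -> pred.csv
identifier,smiles,adduct,ccs_pred
row2,CCO,[M+H]+,36.6833
row2,CCO,[M+Na]+,41.0675
row2,CCO,[M-H]-,35.4225
```

The curation counts list the records surviving each of the five steps
(here the synthetic input is already clean, so nothing is dropped). The
prediction rows give the modelled CCS in Å² for each adduct of ethanol;
the sodiated ion is largest and the deprotonated one smallest, matching
the adduct offsets built into the training labels.

In Python the same pipeline is:

```python
import graphccs as g

mol = g.parse_molecule("CCO")
g.generate_conformer(mol, seed=3)
graph = g.build_graph(mol)
model = g.load_model("ckpt")
print(model.predict_ccs(graph, "[M+H]+"))   # CCS in Å²
```

## Checkpoint layout

A checkpoint is a directory of three text/array files: `config.json`
(schema version, architecture, featurizer layout), `weights.npz` (all
parameter arrays plus feature-standardization statistics), and
`manifest.json` (SHA-256 checksums; loading verifies them).
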