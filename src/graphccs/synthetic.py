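"""Download-free synthetic CCS data.

Real CCS training collections are external downloads, so this module
fabricates a statistically similar stand-in: random small organic
molecules (random bonded trees with occasional ring closures and double
bonds, assembled from a C/N/O/S/F palette), embedded to 3D conformers,
and labelled by a deterministic physics-inspired oracle.

The oracle is a projection-approximation-style CCS: the orientation-
averaged area of the union of the projected atomic spheres (van der Waals
radius plus a probe addition), estimated per orientation by stratified
Monte-Carlo over the bounding square, with orientations drawn from a
seeded low-discrepancy sequence on SO(3).  A fixed per-adduct offset and
optional Gaussian noise complete the label.  It is NOT a trajectory-method
calculation — it is cheap, deterministic, rotation-invariant up to
Monte-Carlo error, and monotone in molecular bulk, which is what the
learnability and invariance tests need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from scipy.stats import qmc

from .adducts import SUPPORTED_ADDUCTS, adduct_mz, get_adduct
from .chem_io import (
    CCSRecord,
    Conformer,
    Molecule,
    VDW_RADII,
    generate_conformer,
    parse_molecule,
)
from .errors import GenerationExhaustedError, GraphCCSError

_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1}


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Study conditions for the synthetic dataset."""

    n_molecules: int = 500
    element_palette: tuple[str, ...] = ("C", "C", "C", "C", "N", "O", "O", "S", "F")
    heavy_atom_range: tuple[int, int] = (3, 10)
    #: fixed CCS offsets per adduct, Å² (arbitrary but learnable effect)
    adduct_offsets: dict = field(default_factory=lambda: {
        "[M+H]+": 0.0, "[M+Na]+": 4.0, "[M-H]-": -2.0,
    })
    noise_sd: float = 1.0      # Å² Gaussian noise on labels
    #: simple linear retention-time model rt = a + b * mass + noise (minutes)
    rt_slope: float = 0.05
    rt_intercept: float = 1.0
    rt_noise_sd: float = 0.3
    seed: int = 0
    max_retries: int = 50

    def __post_init__(self):
        if self.n_molecules <= 0:
            raise ValueError("n_molecules must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class OracleConfig:
    """Settings of the projected-area CCS oracle."""

    probe_addition: float = 1.0   # Å added to every atomic radius
    n_rotations: int = 64         # orientations averaged per molecule
    grid_resolution: int = 48     # stratified samples per axis per orientation
    seed: int = 0

    def __post_init__(self):
        if self.n_rotations < 1:
            raise ValueError("n_rotations must be >= 1")


# ---------------------------------------------------------------------------
# Random molecule generation
# ---------------------------------------------------------------------------

def _random_smiles(rng: np.random.Generator, spec: SyntheticDatasetSpec) -> str | None:
    """One random connected molecule as SMILES, or None if assembly failed.

    Grammar: a random bonded tree over heavy atoms drawn from the palette,
    an optional ring closure between atoms with free valence, and
    occasional single->double bond upgrades.
    """
    lo, hi = spec.heavy_atom_range
    n_heavy = int(rng.integers(lo, hi + 1))
    rw = Chem.RWMol()
    free = []  # free valence per atom
    symbols = []
    for k in range(n_heavy):
        el = str(rng.choice(spec.element_palette))
        if k > 0:
            parents = [i for i, f in enumerate(free) if f >= 1]
            if not parents:
                return None
            parent = int(rng.choice(parents))
        rw.AddAtom(Chem.Atom(el))
        symbols.append(el)
        free.append(_VALENCE[el])
        if k > 0:
            rw.AddBond(parent, k, Chem.BondType.SINGLE)
            free[parent] -= 1
            free[k] -= 1
    # optional ring closure (ring size >= 3 needs graph distance >= 2)
    if n_heavy >= 3 and rng.random() < 0.5:
        candidates = [
            (i, j)
            for i in range(n_heavy)
            for j in range(i + 1, n_heavy)
            if free[i] >= 1 and free[j] >= 1
            and rw.GetBondBetweenAtoms(i, j) is None
        ]
        if candidates:
            i, j = candidates[int(rng.integers(len(candidates)))]
            path = Chem.GetShortestPath(rw.GetMol(), i, j)
            if len(path) >= 3:
                rw.AddBond(i, j, Chem.BondType.SINGLE)
                free[i] -= 1
                free[j] -= 1
    # occasional double bonds where both ends still have valence
    for bond in rw.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if free[i] >= 1 and free[j] >= 1 and rng.random() < 0.2:
            bond.SetBondType(Chem.BondType.DOUBLE)
            free[i] -= 1
            free[j] -= 1
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return Chem.MolToSmiles(mol)


def generate_molecules(spec: SyntheticDatasetSpec) -> list[Molecule]:
    """Generate ``spec.n_molecules`` random molecules with 3D conformers.

    Deterministic for a fixed seed; molecules that fail assembly,
    parsing, embedding or minimization are resampled.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[Molecule] = []
    seen: set[str] = set()
    attempts_left = spec.n_molecules * spec.max_retries
    while len(out) < spec.n_molecules:
        if attempts_left <= 0:
            raise GenerationExhaustedError(
                f"could not generate {spec.n_molecules} molecules within "
                f"{spec.n_molecules * spec.max_retries} attempts"
            )
        attempts_left -= 1
        smiles = _random_smiles(rng, spec)
        if smiles is None or smiles in seen:
            continue
        try:
            mol = parse_molecule(smiles)
            generate_conformer(mol, seed=int(rng.integers(2 ** 31)))
        except (GraphCCSError, ValueError):
            continue
        seen.add(smiles)
        out.append(mol)
    return out


# ---------------------------------------------------------------------------
# Projected-area CCS oracle
# ---------------------------------------------------------------------------

def _so3_rotations(n: int, seed: int) -> np.ndarray:
    """n rotation matrices from a scrambled-Sobol sequence on SO(3).

    Uses Shoemake's map from the unit cube to uniform quaternions, so the
    low-discrepancy structure of the Sobol points carries over to SO(3).
    """
    sampler = qmc.Sobol(d=3, scramble=True, rng=np.random.default_rng(seed))
    u = sampler.random(n)
    u1, u2, u3 = u[:, 0], u[:, 1], u[:, 2]
    q = np.stack([
        np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
        np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
        np.sqrt(u1) * np.sin(2 * np.pi * u3),
        np.sqrt(u1) * np.cos(2 * np.pi * u3),
    ], axis=1)
    w, x, y, z = q[:, 3], q[:, 0], q[:, 1], q[:, 2]
    R = np.empty((n, 3, 3))
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (x * y - z * w)
    R[:, 0, 2] = 2 * (x * z + y * w)
    R[:, 1, 0] = 2 * (x * y + z * w)
    R[:, 1, 1] = 1 - 2 * (x * x + z * z)
    R[:, 1, 2] = 2 * (y * z - x * w)
    R[:, 2, 0] = 2 * (x * z - y * w)
    R[:, 2, 1] = 2 * (y * z + x * w)
    R[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return R


def _projected_union_area(xy: np.ndarray, radii: np.ndarray,
                          resolution: int, rng: np.random.Generator) -> float:
    """Area of the union of disks by jittered stratified Monte-Carlo."""
    rmax = radii.max()
    lo = xy.min(axis=0) - rmax
    hi = xy.max(axis=0) + rmax
    span = hi - lo
    k = resolution
    # jittered grid: one uniform sample per cell
    jitter = rng.random((k, k, 2))
    cell = span / k
    gx, gy = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    pts = np.stack([gx, gy], axis=-1) + jitter
    pts = lo + pts * cell
    pts = pts.reshape(-1, 2)
    d2 = ((pts[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    inside = (d2 <= (radii[None, :] ** 2)).any(axis=1)
    return float(inside.mean() * span[0] * span[1])


def oracle_ccs(conf: Conformer, radii: np.ndarray,
               adduct: str | None = None,
               cfg: OracleConfig | None = None) -> float:
    """Deterministic orientation-averaged projected area in Å².

    ``radii`` are per-atom sphere radii (Å); the probe addition from the
    config is added to each.  When ``adduct`` is given, its fixed offset
    from :data:`DEFAULT_ADDUCT_OFFSETS` is applied.
    """
    cfg = cfg or OracleConfig()
    radii = np.asarray(radii, dtype=float) + cfg.probe_addition
    coords = conf.coords - conf.coords.mean(axis=0, keepdims=True)
    rotations = _so3_rotations(cfg.n_rotations, cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    areas = [
        _projected_union_area((coords @ R.T)[:, :2], radii,
                              cfg.grid_resolution, rng)
        for R in rotations
    ]
    area = float(np.mean(areas))
    if adduct is not None:
        area += DEFAULT_ADDUCT_OFFSETS[get_adduct(adduct).label]
    return area


DEFAULT_ADDUCT_OFFSETS = {"[M+H]+": 0.0, "[M+Na]+": 4.0, "[M-H]-": -2.0}


def vdw_radii_for(mol: Molecule) -> np.ndarray:
    """Per-atom van der Waals radii used by the oracle."""
    return np.array([VDW_RADII[a.element] for a in mol.atoms])


# ---------------------------------------------------------------------------
# Full dataset assembly
# ---------------------------------------------------------------------------

def make_dataset(spec: SyntheticDatasetSpec,
                 oracle_cfg: OracleConfig | None = None,
                 molecules: list[Molecule] | None = None) -> list[CCSRecord]:
    """Oracle-labelled records: one per (molecule, adduct) over all three adducts.

    Each record carries ccs = oracle + adduct offset + Gaussian noise, an
    m/z computed from the molecular mass and adduct mass shift, and a
    retention time from a simple linear mass trend (so the identification
    benchmark has a plausible third dimension).
    """
    oracle_cfg = oracle_cfg or OracleConfig(seed=spec.seed)
    if molecules is None:
        molecules = generate_molecules(spec)
    rng = np.random.default_rng(spec.seed + 1)
    records: list[CCSRecord] = []
    for k, mol in enumerate(molecules):
        radii = vdw_radii_for(mol)
        base_ccs = oracle_ccs(mol.conformer, radii, adduct=None, cfg=oracle_cfg)
        mass = mol.neutral_mass()
        rt = (spec.rt_intercept + spec.rt_slope * mass
              + rng.normal(0.0, spec.rt_noise_sd))
        for adduct in SUPPORTED_ADDUCTS:
            ccs = (base_ccs + spec.adduct_offsets[adduct]
                   + rng.normal(0.0, spec.noise_sd))
            records.append(CCSRecord(
                identifier=f"SYN-{k:05d}",
                smiles=mol.smiles,
                adduct=adduct,
                ccs=float(ccs),
                mz=float(adduct_mz(mass, adduct)),
                rt=float(rt),
                instrument="synthetic",
                molecule=mol,
            ))
    return records
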