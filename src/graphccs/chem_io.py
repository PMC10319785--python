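"""Molecule parsing, 3D conformer generation, and tabular I/O.

Molecules enter as SMILES strings (or SDF), are parsed with RDKit, get
explicit hydrogens, and receive a single 3D conformer from experimental-
torsion distance geometry (ETKDG) followed by MMFF94 force-field
minimization.  Atom attributes (element, degree, radius, mass, ring
membership) and the conformer coordinates feed the molecular graph
downstream.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .adducts import normalize_adduct
from .errors import (
    EmbeddingFailedError,
    FormatError,
    InvalidSmilesError,
    MinimizationFailedError,
    UnknownAdductError,
    UnsupportedElementError,
)

#: Elements covered by the default model; anything else is rejected (or
#: warned about when ``on_unsupported_element="warn"``).
SUPPORTED_ELEMENTS: tuple[str, ...] = (
    "C", "H", "O", "N", "P", "S", "F", "Cl", "Br", "I", "Co", "As", "Se",
)

# Cordero covalent radii, Å
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
    "Co": 1.26, "As": 1.19, "Se": 1.20,
}

# Bondi / Alvarez van der Waals radii, Å (used by the projected-area oracle
# and available as an alternative node-attribute radius source)
VDW_RADII: dict[str, float] = {
    "H": 1.10, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
    "Co": 2.00, "As": 1.85, "Se": 1.90,
}

RADIUS_TABLES = {"covalent": COVALENT_RADII, "vdw": VDW_RADII}

BOND_ORDERS = ("single", "double", "triple", "aromatic")

_RDKIT_BOND_ORDER = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


@dataclass(frozen=True)
class AtomRecord:
    element: str
    degree: int          # explicit bonded neighbours, hydrogens included
    radius: float        # Å, from the configured radius table
    mass: float          # Da
    in_ring: bool


@dataclass(frozen=True)
class BondRecord:
    i: int
    j: int
    order: str           # one of BOND_ORDERS


@dataclass(frozen=True)
class Conformer:
    coords: np.ndarray   # N x 3 Cartesian coordinates, Å
    energy_minimized: bool


@dataclass
class Molecule:
    smiles: str
    atoms: list[AtomRecord]
    bonds: list[BondRecord]
    conformer: Conformer | None = None
    rdmol: Chem.Mol = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def ring_count(self) -> int:
        """Number of smallest rings (SSSR) in the molecule."""
        return self.rdmol.GetRingInfo().NumRings()

    def neutral_mass(self) -> float:
        return float(sum(a.mass for a in self.atoms))


def parse_molecule(
    smiles: str,
    radius_table: str = "covalent",
    on_unsupported_element: str = "raise",
) -> Molecule:
    """Parse a SMILES string into a Molecule with explicit hydrogens.

    Parameters
    ----------
    smiles:
        Input SMILES. The canonical form is stored on the result.
    radius_table:
        ``"covalent"`` (default) or ``"vdw"``: which per-element radius
        populates the atom records.
    on_unsupported_element:
        ``"raise"`` (default) or ``"warn"`` for elements outside the 13
        supported ones.

    Raises
    ------
    InvalidSmilesError
        If RDKit cannot parse the string.
    UnsupportedElementError
        If an element is outside the supported set and the policy is "raise".
    """
    if not smiles or not smiles.strip():
        raise InvalidSmilesError("empty SMILES string")
    rd = Chem.MolFromSmiles(smiles)
    if rd is None:
        raise InvalidSmilesError(f"could not parse SMILES {smiles!r}")
    bad = sorted({a.GetSymbol() for a in rd.GetAtoms()} - set(SUPPORTED_ELEMENTS))
    if bad:
        msg = f"unsupported element(s) {bad} in {smiles!r}"
        if on_unsupported_element == "raise":
            raise UnsupportedElementError(msg)
        import warnings

        warnings.warn(msg, stacklevel=2)
    canonical = Chem.MolToSmiles(rd)
    rd = Chem.AddHs(rd)
    radii = RADIUS_TABLES[radius_table]
    atoms = [
        AtomRecord(
            element=a.GetSymbol(),
            degree=a.GetDegree(),
            radius=radii.get(a.GetSymbol(), 1.5),
            mass=a.GetMass(),
            in_ring=a.IsInRing(),
        )
        for a in rd.GetAtoms()
    ]
    bonds = []
    for b in rd.GetBonds():
        order = _RDKIT_BOND_ORDER.get(b.GetBondType())
        if order is None:
            raise InvalidSmilesError(
                f"bond type {b.GetBondType()} in {smiles!r} is not one of "
                f"{BOND_ORDERS}"
            )
        bonds.append(BondRecord(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    return Molecule(smiles=canonical, atoms=atoms, bonds=bonds, rdmol=rd)


def generate_conformer(mol: Molecule, seed: int = 42) -> Conformer:
    """Embed one 3D conformer (ETKDG) and minimize it with MMFF94.

    Deterministic for a fixed seed.  ``energy_minimized`` on the returned
    conformer records whether the force-field optimization converged.

    Raises
    ------
    EmbeddingFailedError
        If distance geometry yields no conformer.
    MinimizationFailedError
        If MMFF94 cannot be set up for the molecule.
    """
    rd = Chem.Mol(mol.rdmol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    params.useRandomCoords = False
    conf_id = AllChem.EmbedMolecule(rd, params)
    if conf_id < 0:
        # retry with random starting coordinates before declaring failure
        params.useRandomCoords = True
        conf_id = AllChem.EmbedMolecule(rd, params)
    if conf_id < 0:
        raise EmbeddingFailedError(f"ETKDG embedding failed for {mol.smiles!r}")
    if not AllChem.MMFFHasAllMoleculeParams(rd):
        raise MinimizationFailedError(
            f"MMFF94 parameters unavailable for {mol.smiles!r}"
        )
    status = AllChem.MMFFOptimizeMolecule(rd, maxIters=2000)
    if status < 0:
        raise MinimizationFailedError(
            f"MMFF94 setup failed for {mol.smiles!r}"
        )
    coords = rd.GetConformer(conf_id).GetPositions().astype(float)
    conformer = Conformer(coords=coords, energy_minimized=(status == 0))
    mol.conformer = conformer
    mol.rdmol = rd  # keep the embedded coordinates for SDF export
    return conformer


# ---------------------------------------------------------------------------
# Records and tabular I/O
# ---------------------------------------------------------------------------

@dataclass
class CCSRecord:
    """One (molecule, adduct, CCS) entry: the unit of curation and training.

    ``ccs`` is optional (prediction mode); ``(smiles, adduct)`` is the
    deduplication key during curation.
    """

    identifier: str
    smiles: str
    adduct: str
    ccs: float | None = None
    mz: float | None = None
    rt: float | None = None
    instrument: str = "unknown"
    ccs_pred: float | None = None
    molecule: Molecule | None = field(default=None, repr=False, compare=False)


_COLUMN_ALIASES = {
    "smiles": "smiles",
    "canonical_smiles": "smiles",
    "adduct": "adduct",
    "adducts": "adduct",
    "ccs": "ccs",
    "ccs_pred": "ccs_pred",
    "predicted_ccs": "ccs_pred",
    "mz": "mz",
    "m/z": "mz",
    "rt": "rt",
    "retention_time": "rt",
    "id": "identifier",
    "identifier": "identifier",
    "name": "identifier",
    "instrument": "instrument",
}


def _parse_float(value: str, column: str, line: int) -> float | None:
    value = value.strip()
    if not value:
        return None
    try:
        out = float(value)
    except ValueError as exc:
        raise FormatError(f"line {line}: bad {column} value {value!r}") from exc
    if not math.isfinite(out):
        raise FormatError(f"line {line}: non-finite {column} value")
    return out


def read_records(path, format: str = "csv", strict_adducts: bool = True) -> list[CCSRecord]:
    """Read CCS records from a CSV or SDF file, in file order.

    CSV needs header columns for SMILES and adduct; ccs/mz/rt/identifier
    are optional.  With ``strict_adducts`` (default) an adduct outside the
    supported three raises :class:`UnknownAdductError`; curation mode
    passes ``strict_adducts=False`` and drops them instead.
    """
    if format == "csv":
        return _read_csv(path, strict_adducts)
    if format == "sdf":
        return _read_sdf(path, strict_adducts)
    raise ValueError(f"unknown format {format!r}")


def _read_csv(path, strict_adducts: bool) -> list[CCSRecord]:
    records: list[CCSRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        colmap: dict[int, str] = {}
        for idx, name in enumerate(header):
            canon = _COLUMN_ALIASES.get(name.strip().lower())
            if canon:
                colmap[idx] = canon
        if "smiles" not in colmap.values():
            raise FormatError(f"{path}: no SMILES column in header {header}")
        if "adduct" not in colmap.values():
            raise FormatError(f"{path}: no adduct column in header {header}")
        for line_no, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(header):
                raise FormatError(f"line {line_no}: expected {len(header)} "
                                  f"fields, got {len(row)}")
            fields = {colmap[i]: row[i] for i in colmap if i < len(row)}
            adduct = fields.get("adduct", "").strip()
            if strict_adducts and normalize_adduct(adduct) is None:
                raise UnknownAdductError(
                    f"line {line_no}: unsupported adduct {adduct!r}"
                )
            canonical = normalize_adduct(adduct)
            records.append(
                CCSRecord(
                    identifier=fields.get("identifier", "").strip()
                    or f"row{line_no}",
                    smiles=fields.get("smiles", "").strip(),
                    adduct=canonical if canonical else adduct,
                    ccs=_parse_float(fields.get("ccs", ""), "ccs", line_no),
                    mz=_parse_float(fields.get("mz", ""), "mz", line_no),
                    rt=_parse_float(fields.get("rt", ""), "rt", line_no),
                    instrument=fields.get("instrument", "unknown").strip()
                    or "unknown",
                )
            )
    return records


def _read_sdf(path, strict_adducts: bool) -> list[CCSRecord]:
    records: list[CCSRecord] = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    for idx, rd in enumerate(supplier):
        if rd is None:
            raise FormatError(f"{path}: molecule #{idx + 1} unreadable")
        props = {k.lower(): rd.GetProp(k) for k in rd.GetPropNames()}
        adduct = props.get("adduct", "[M+H]+").strip()
        if strict_adducts and normalize_adduct(adduct) is None:
            raise UnknownAdductError(
                f"{path}: molecule #{idx + 1} has unsupported adduct {adduct!r}"
            )
        canonical = normalize_adduct(adduct)
        ccs = props.get("ccs")
        records.append(
            CCSRecord(
                identifier=(rd.GetProp("_Name") if rd.HasProp("_Name") else "")
                or f"sdf{idx + 1}",
                smiles=Chem.MolToSmiles(Chem.RemoveHs(rd)),
                adduct=canonical if canonical else adduct,
                ccs=float(ccs) if ccs not in (None, "") else None,
            )
        )
    return records


def write_predictions(records: list[CCSRecord], path) -> None:
    """Write one CSV row per (molecule, adduct) with the predicted CCS in Å²."""
    try:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["identifier", "smiles", "adduct", "ccs_pred"])
            for rec in records:
                writer.writerow([
                    rec.identifier,
                    rec.smiles,
                    rec.adduct,
                    "" if rec.ccs_pred is None else f"{rec.ccs_pred:.4f}",
                ])
    except OSError as exc:
        raise OSError(f"cannot write predictions to {path}: {exc}") from exc


def read_predictions(path) -> list[CCSRecord]:
    """Read back a prediction CSV written by :func:`write_predictions`."""
    records: list[CCSRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for line_no, row in enumerate(reader, start=2):
            records.append(
                CCSRecord(
                    identifier=row["identifier"],
                    smiles=row["smiles"],
                    adduct=row["adduct"],
                    ccs_pred=float(row["ccs_pred"]) if row["ccs_pred"] else None,
                )
            )
    return records


def write_conformer_sdf(molecules: list[Molecule], path) -> None:
    """Export molecules with their 3D coordinates as an SDF file."""
    writer = Chem.SDWriter(str(path))
    try:
        for mol in molecules:
            if mol.conformer is None:
                raise ValueError(f"{mol.smiles!r} has no conformer to export")
            writer.write(mol.rdmol)
    finally:
        writer.close()
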