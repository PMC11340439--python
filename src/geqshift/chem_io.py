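"""Molecule and chemical-shift table I/O.

Molecules are represented over heavy atoms only: hydrogens are folded into a
per-atom attached-hydrogen count, which is itself an input feature of the
model.  Shift tables are flat CSV/JSON records keyed by
(molecule_id, atom_index, nucleus) in the frozen canonical atom order of the
parser.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

__all__ = [
    "MoleculeRecord",
    "ShiftRecord",
    "ShiftDataset",
    "parse_smiles",
    "iupac_to_smiles",
    "load_shift_dataset",
    "write_shift_dataset",
    "write_predictions",
    "read_predictions",
]

BOND_CATEGORIES = ("single", "double", "other")
NUCLEI = ("C13", "H1")
SACCHARIDE_CLASSES = ("mono", "di", "tri", "other")

_SHIFT_COLUMNS = ["molecule_id", "smiles", "saccharide_class",
                  "atom_index", "nucleus", "shift_ppm"]


@dataclass
class MoleculeRecord:
    """Heavy-atom topology of one molecule.

    ``atoms`` is an ordered list of ``(index, element, attached_h_count)``
    in the parser's canonical order; ``bonds`` holds
    ``(i, j, category)`` with category in {single, double, other}.
    """

    molecule_id: str
    smiles: str
    atoms: list[tuple[int, str, int]]
    bonds: list[tuple[int, int, str]]
    saccharide_class: str = "other"

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a[1] for a in self.atoms]

    @property
    def h_counts(self) -> list[int]:
        return [a[2] for a in self.atoms]

    def validate(self) -> None:
        n = len(self.atoms)
        for k, (idx, _el, hc) in enumerate(self.atoms):
            if idx != k:
                raise ValueError(
                    f"{self.molecule_id}: atom indices must be contiguous "
                    f"0..{n - 1}, got {idx} at position {k}")
            if hc < 0:
                raise ValueError(f"{self.molecule_id}: negative H count")
        for i, j, cat in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(
                    f"{self.molecule_id}: bond ({i}, {j}) out of range")
            if cat not in BOND_CATEGORIES:
                raise ValueError(f"{self.molecule_id}: bad bond category {cat!r}")
        if self.saccharide_class not in SACCHARIDE_CLASSES:
            raise ValueError(
                f"{self.molecule_id}: bad class {self.saccharide_class!r}")


@dataclass(frozen=True)
class ShiftRecord:
    """One experimental chemical shift assigned to a heavy atom."""

    molecule_id: str
    atom_index: int
    nucleus: str  # "C13" or "H1"
    shift_ppm: float


@dataclass
class ShiftDataset:
    """Molecules plus their assigned experimental shifts."""

    molecules: list[MoleculeRecord]
    shifts: list[ShiftRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        self._by_id = {m.molecule_id: m for m in self.molecules}

    def molecule(self, molecule_id: str) -> MoleculeRecord:
        return self._by_id[molecule_id]

    @property
    def molecule_ids(self) -> list[str]:
        return [m.molecule_id for m in self.molecules]

    def shifts_for(self, molecule_id: str) -> list[ShiftRecord]:
        return [s for s in self.shifts if s.molecule_id == molecule_id]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.molecules:
            counts[m.saccharide_class] = counts.get(m.saccharide_class, 0) + 1
        return counts

    def validate(self) -> None:
        if len(self._by_id) != len(self.molecules):
            raise ValueError("duplicate molecule_id in dataset")
        for m in self.molecules:
            m.validate()
        seen: set[tuple[str, int, str]] = set()
        for s in self.shifts:
            key = (s.molecule_id, s.atom_index, s.nucleus)
            if key in seen:
                raise ValueError(f"duplicate shift record {key}")
            seen.add(key)
            mol = self._by_id.get(s.molecule_id)
            if mol is None:
                raise ValueError(f"shift references unknown molecule "
                                 f"{s.molecule_id!r}")
            if not 0 <= s.atom_index < mol.n_atoms:
                raise ValueError(f"shift references atom {s.atom_index} "
                                 f"outside {s.molecule_id!r}")
            if s.nucleus not in NUCLEI:
                raise ValueError(f"bad nucleus {s.nucleus!r}")
            _, el, hc = mol.atoms[s.atom_index]
            if s.nucleus == "C13" and el != "C":
                raise ValueError(
                    f"{key}: C13 shift assigned to non-carbon atom ({el})")
            if s.nucleus == "H1" and hc < 1:
                raise ValueError(
                    f"{key}: H1 shift assigned to atom with no attached H")
            if not 0.0 <= s.shift_ppm <= 250.0:
                raise ValueError(f"{key}: shift {s.shift_ppm} ppm out of range")


def _bond_category(bond: Chem.Bond) -> str:
    t = bond.GetBondType()
    if t == Chem.BondType.SINGLE:
        return "single"
    if t == Chem.BondType.DOUBLE:
        return "double"
    return "other"  # aromatic, triple, dative, ...


def _canonical_mol(smiles: str) -> Chem.Mol:
    """Parse and renumber atoms into RDKit's canonical rank order.

    Canonical ranks depend only on the structure, so every SMILES spelling
    of a molecule yields the same frozen heavy-atom indexing.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    order = Chem.CanonicalRankAtoms(mol, breakTies=True)
    perm = sorted(range(mol.GetNumAtoms()), key=lambda a: order[a])
    return Chem.RenumberAtoms(mol, [int(i) for i in perm])


def mol_from_record(record: MoleculeRecord) -> Chem.Mol:
    """Re-parse the record's SMILES with the record's atom ordering."""
    mol = _canonical_mol(record.smiles)
    if mol.GetNumAtoms() != record.n_atoms:
        raise ValueError(f"{record.molecule_id!r}: SMILES heavy-atom count "
                         "disagrees with record")
    for atom, (_, el, _) in zip(mol.GetAtoms(), record.atoms):
        if atom.GetSymbol() != el:
            raise ValueError(f"{record.molecule_id!r}: atom order mismatch "
                             "between record and re-parsed SMILES")
    return mol


def parse_smiles(smiles: str, molecule_id: str = "",
                 saccharide_class: str = "other") -> MoleculeRecord:
    """Parse a SMILES string into a heavy-atom :class:`MoleculeRecord`.

    Hydrogens are folded into per-atom counts; atoms are indexed in RDKit's
    canonical order for the parsed structure, and that order is the one all
    shift tables reference.
    """
    mol = _canonical_mol(smiles)
    atoms = [(a.GetIdx(), a.GetSymbol(), a.GetTotalNumHs())
             for a in mol.GetAtoms()]
    bonds = sorted((min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                    max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                    _bond_category(b)) for b in mol.GetBonds())
    rec = MoleculeRecord(molecule_id=molecule_id or Chem.MolToSmiles(mol),
                         smiles=Chem.MolToSmiles(mol),
                         atoms=atoms, bonds=bonds,
                         saccharide_class=saccharide_class)
    rec.validate()
    return rec


def iupac_to_smiles(name: str) -> str:
    """Optional adapter: convert an IUPAC glycan name to SMILES.

    Requires the ``glyles`` converter; the core pipeline consumes SMILES and
    never calls this.
    """
    try:
        from glyles import convert  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "IUPAC glycan name conversion requires the optional 'glyles' "
            "package; supply SMILES directly instead") from exc
    out = convert(name)  # pragma: no cover
    return out[0][1]  # pragma: no cover


def _dataset_from_frame(df: pd.DataFrame, provenance: str) -> ShiftDataset:
    missing = [c for c in _SHIFT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"shift table missing columns: {missing}")
    molecules: list[MoleculeRecord] = []
    for mol_id, grp in df.groupby("molecule_id", sort=False):
        smiles = grp["smiles"].iloc[0]
        klass = grp["saccharide_class"].iloc[0]
        molecules.append(parse_smiles(str(smiles), molecule_id=str(mol_id),
                                      saccharide_class=str(klass)))
    raw: dict[tuple[str, int, str], list[float]] = {}
    order: list[tuple[str, int, str]] = []
    for r in df.itertuples(index=False):
        if pd.isna(r.atom_index):
            continue
        key = (str(r.molecule_id), int(r.atom_index), str(r.nucleus))
        if key not in raw:
            raw[key] = []
            order.append(key)
        raw[key].append(float(r.shift_ppm))
    shifts = []
    for key in order:
        vals = raw[key]
        if len(vals) > 1:
            # one value per heavy atom: inequivalent protons on one carbon
            # (e.g. H6a/H6b of a CH2) are stored as their average
            if key[2] != "H1":
                raise ValueError(f"duplicate shift record {key}")
            warnings.warn(f"{key}: {len(vals)} proton values on one heavy "
                          f"atom averaged to {np.mean(vals):.4f} ppm",
                          stacklevel=3)
        shifts.append(ShiftRecord(key[0], key[1], key[2],
                                  float(np.mean(vals))))
    ds = ShiftDataset(molecules=molecules, shifts=shifts,
                      provenance=provenance)
    ds.validate()
    return ds


def load_shift_dataset(path: str | Path, format: str | None = None) -> ShiftDataset:
    """Load a shift dataset from CSV or JSON records.

    Each row/record carries molecule_id, smiles, saccharide_class,
    atom_index, nucleus and shift_ppm; a row with an empty atom_index
    declares a molecule without contributing a shift.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        df = pd.read_csv(path)
    elif format == "json":
        with open(path) as fh:
            df = pd.DataFrame(json.load(fh))
    else:
        raise ValueError(f"unknown format {format!r}")
    return _dataset_from_frame(df, provenance=str(path))


def write_shift_dataset(dataset: ShiftDataset, path: str | Path,
                        format: str | None = None) -> None:
    """Write a dataset in the flat schema that :func:`load_shift_dataset` reads."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    rows = []
    covered = set()
    for s in dataset.shifts:
        mol = dataset.molecule(s.molecule_id)
        covered.add(s.molecule_id)
        rows.append(dict(molecule_id=s.molecule_id, smiles=mol.smiles,
                         saccharide_class=mol.saccharide_class,
                         atom_index=s.atom_index, nucleus=s.nucleus,
                         shift_ppm=s.shift_ppm))
    for mol in dataset.molecules:  # molecules without shifts still round-trip
        if mol.molecule_id not in covered:
            rows.append(dict(molecule_id=mol.molecule_id, smiles=mol.smiles,
                             saccharide_class=mol.saccharide_class,
                             atom_index=None, nucleus=None, shift_ppm=None))
    df = pd.DataFrame(rows, columns=_SHIFT_COLUMNS)
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1)
    else:
        raise ValueError(f"unknown format {format!r}")


_PRED_COLUMNS = ["molecule_id", "atom_index", "nucleus",
                 "pred_mean_ppm", "pred_std_ppm", "n_conformers"]


def write_predictions(preds, path: str | Path) -> None:
    """Write per-atom ensemble predictions to CSV (6-decimal round trip)."""
    rows = [dict(molecule_id=p.molecule_id, atom_index=p.atom_index,
                 nucleus=p.nucleus,
                 pred_mean_ppm=f"{p.mean_ppm:.6f}",
                 pred_std_ppm=f"{p.std_ppm:.6f}",
                 n_conformers=len(p.per_conformer_ppm))
            for p in preds]
    pd.DataFrame(rows, columns=_PRED_COLUMNS).to_csv(path, index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _PRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"prediction table missing columns: {missing}")
    return df
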