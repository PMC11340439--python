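"""Conformer-ensemble generation: embed, diversity-filter, energy-rank.

Molecules in solution populate many conformations; the model is trained and
evaluated on an ensemble per molecule.  The pipeline here generates
``n_generate`` distance-geometry candidates (ETKDGv3), computes MMFF94
potential energies with explicit hydrogens, drops near-duplicates whose
aligned heavy-atom RMSD falls below a threshold, and keeps the
``n_keep`` lowest-energy survivors.  Hydrogens are stripped from the stored
coordinates: the graph model never sees them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem_io import MoleculeRecord, mol_from_record

__all__ = [
    "Conformer",
    "ConformerEnsemble",
    "EnsembleParams",
    "generate_ensemble",
    "rmsd_heavy",
    "read_sdf",
    "write_sdf",
]


@dataclass
class Conformer:
    """One heavy-atom coordinate set (Å) with its MMFF94 energy (kcal/mol)."""

    molecule_id: str
    coords: np.ndarray  # (n_heavy, 3)
    energy_kcal_mol: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")


@dataclass
class EnsembleParams:
    n_generate: int = 200
    n_keep: int = 100
    rmsd_min_angstrom: float = 0.01
    seed: int = 0


@dataclass
class ConformerEnsemble:
    molecule_id: str
    conformers: list[Conformer]
    params: EnsembleParams = field(default_factory=EnsembleParams)

    def __len__(self) -> int:
        return len(self.conformers)

    def energies(self) -> np.ndarray:
        return np.array([c.energy_kcal_mol for c in self.conformers])


def _kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimal RMSD over proper rotations (Kabsch; reflections excluded)."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    u, _, vt = np.linalg.svd(b.T @ a)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    # explicit residual avoids the cancellation of the singular-value form
    resid = a - b @ rot
    return float(np.sqrt((resid * resid).sum() / len(a)))


def rmsd_heavy(a: Conformer | np.ndarray, b: Conformer | np.ndarray,
               align: bool = True) -> float:
    """Heavy-atom RMSD between two conformers of the same molecule.

    With ``align`` the structures are optimally superposed by a proper
    rotation (Kabsch) first, so the value is frame-independent; enantiomeric
    conformers are *not* collapsed because reflections are excluded.
    """
    ca = a.coords if isinstance(a, Conformer) else np.asarray(a, dtype=float)
    cb = b.coords if isinstance(b, Conformer) else np.asarray(b, dtype=float)
    if ca.shape != cb.shape:
        raise ValueError(f"conformer shape mismatch: {ca.shape} vs {cb.shape}")
    if align:
        return _kabsch_rmsd(ca, cb)
    return float(np.sqrt(((ca - cb) ** 2).sum() / len(ca)))


def diversity_filter(candidates: list[Conformer],
                     rmsd_min: float) -> list[Conformer]:
    """Greedy pruning in energy-ascending order.

    A candidate survives only if its aligned RMSD to every already-kept
    conformer exceeds ``rmsd_min``; processing low-energy candidates first
    biases retention toward low-energy basins.
    """
    ordered = sorted(candidates, key=lambda c: c.energy_kcal_mol)
    kept: list[Conformer] = []
    for cand in ordered:
        if all(rmsd_heavy(cand, k, align=True) > rmsd_min for k in kept):
            kept.append(cand)
    return kept


def generate_ensemble(mol: MoleculeRecord,
                      n_generate: int = 200,
                      n_keep: int = 100,
                      rmsd_min: float = 0.01,
                      seed: int = 0) -> ConformerEnsemble:
    """Generate a diverse, low-energy conformer ensemble.

    ETKDGv3 distance-geometry embedding of ``n_generate`` candidates with
    the given seed; MMFF94 single-point energies (with hydrogens present);
    greedy diversity filter at ``rmsd_min`` Å on heavy atoms; the lowest
    ``min(n_keep, survivors)`` energies are retained.
    """
    if mol.n_atoms < 2:
        raise ValueError(f"{mol.molecule_id!r}: need >= 2 heavy atoms to embed")
    rdmol = Chem.AddHs(mol_from_record(mol))
    params = AllChem.ETKDGv3()
    # the embedder needs a strictly positive seed: 0 degenerately re-seeds
    # every conformer identically and -1 means non-deterministic
    params.randomSeed = int(seed) % (2 ** 31 - 2) + 1
    conf_ids = AllChem.EmbedMultipleConfs(rdmol, numConfs=int(n_generate),
                                          params=params)
    if len(conf_ids) == 0:
        raise RuntimeError(f"{mol.molecule_id!r}: 3D embedding failed for "
                           "all candidates")
    props = AllChem.MMFFGetMoleculeProperties(rdmol)
    if props is None:
        raise RuntimeError(f"{mol.molecule_id!r}: MMFF94 setup failed")
    heavy = [a.GetIdx() for a in rdmol.GetAtoms() if a.GetAtomicNum() > 1]
    candidates = []
    for cid in conf_ids:
        ff = AllChem.MMFFGetMoleculeForceField(rdmol, props, confId=cid)
        if ff is None:
            raise RuntimeError(f"{mol.molecule_id!r}: MMFF94 setup failed")
        energy = ff.CalcEnergy()
        coords = rdmol.GetConformer(cid).GetPositions()[heavy]
        candidates.append(Conformer(mol.molecule_id, coords, float(energy)))
    survivors = diversity_filter(candidates, rmsd_min)
    kept = sorted(survivors, key=lambda c: c.energy_kcal_mol)[:int(n_keep)]
    if len(kept) < n_keep:
        warnings.warn(f"{mol.molecule_id!r}: only {len(kept)} of the "
                      f"requested {n_keep} conformers survived the "
                      "diversity filter", stacklevel=2)
    return ConformerEnsemble(
        molecule_id=mol.molecule_id, conformers=kept,
        params=EnsembleParams(int(n_generate), int(n_keep),
                              float(rmsd_min), int(seed)))


def check_ensemble(ensemble: ConformerEnsemble,
                   candidates: list[Conformer] | None = None) -> None:
    """Post-hoc verification of the ensemble invariants.

    All pairwise aligned RMSDs exceed the threshold, and (when the original
    candidate list is supplied) the maximum retained energy does not exceed
    the minimum energy among discarded diversity survivors.
    """
    confs = ensemble.conformers
    thr = ensemble.params.rmsd_min_angstrom
    for i in range(len(confs)):
        for j in range(i + 1, len(confs)):
            r = rmsd_heavy(confs[i], confs[j], align=True)
            if r <= thr:
                raise AssertionError(
                    f"pairwise RMSD {r:.4g} Å <= {thr} between kept "
                    f"conformers {i}, {j}")
    if candidates is not None:
        survivors = diversity_filter(candidates, thr)
        kept_e = ensemble.energies()
        discarded = sorted(c.energy_kcal_mol for c in survivors)[len(confs):]
        if len(kept_e) and discarded and kept_e.max() > min(discarded) + 1e-9:
            raise AssertionError("energy ranking violated: a kept conformer "
                                 "is higher in energy than a discarded one")


# ---------------------------------------------------------------------------
# SDF round trip (V2000, one record per conformer, energy as an SD tag)

ENERGY_TAG = "MMFF94_energy_kcal_mol"
ID_TAG = "molecule_id"


def write_sdf(ensemble: ConformerEnsemble, mol: MoleculeRecord,
              path) -> None:
    """Write the ensemble as a multi-record V2000 SDF."""
    rdmol = mol_from_record(mol)
    writer = Chem.SDWriter(str(path))
    writer.SetForceV3000(False)
    for conf in ensemble.conformers:
        m = Chem.Mol(rdmol)
        c = Chem.Conformer(m.GetNumAtoms())
        for i, xyz in enumerate(conf.coords):
            c.SetAtomPosition(i, [float(x) for x in xyz])
        m.RemoveAllConformers()
        m.AddConformer(c, assignId=True)
        m.SetProp(ID_TAG, ensemble.molecule_id)
        m.SetProp(ENERGY_TAG, f"{conf.energy_kcal_mol:.6g}")
        writer.write(m)
    writer.close()


def read_sdf(path, molecule_id: str | None = None) -> ConformerEnsemble:
    """Read a multi-record SDF written by :func:`write_sdf`."""
    if Path(str(path)).stat().st_size == 0:  # zero-record file
        return ConformerEnsemble(molecule_id=molecule_id or "",
                                 conformers=[])
    supplier = Chem.SDMolSupplier(str(path), removeHs=True, sanitize=True)
    conformers: list[Conformer] = []
    mol_id = molecule_id
    for idx, m in enumerate(supplier):
        if m is None:
            raise ValueError(f"malformed SDF record at index {idx}")
        rec_id = m.GetProp(ID_TAG) if m.HasProp(ID_TAG) else (mol_id or "")
        if mol_id is None:
            mol_id = rec_id
        energy = float(m.GetProp(ENERGY_TAG)) if m.HasProp(ENERGY_TAG) else float("nan")
        coords = m.GetConformer().GetPositions()
        heavy = [a.GetIdx() for a in m.GetAtoms() if a.GetAtomicNum() > 1]
        conformers.append(Conformer(rec_id, coords[heavy], energy))
    return ConformerEnsemble(molecule_id=mol_id or "", conformers=conformers)
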