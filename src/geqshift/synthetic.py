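"""Synthetic molecules and an E(3)-invariant shift oracle.

Real shift data requires curated experimental tables; for fully
self-contained testing this module generates small stereochemistry-rich
polyol/ether/acetyl molecules and assigns them synthetic "shifts" from a
closed-form, rotation/translation/reflection-invariant function of the
conformer geometry:

    delta(i) = a(element_i)
             + b * sum_{j != i, d_ij < r_cut} exp(-d_ij^2 / sigma^2)
             + c * sum_{j < k bonded to i} cos(theta_jik)
             + eps_i,   eps_i ~ Normal(0, noise_sd)

The noise is drawn once per (molecule, atom, nucleus) — not per conformer —
so the oracle behaves like a single experimental observation seen across
many geometries, matching the ensemble-training premise.  The dataset's
per-molecule target is the ensemble average of the deterministic part plus
that fixed noise.  The proton mimic divides the same functional form by 10
to land in the 0-10 ppm window.  This is *not* a physical shift model.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .chem_io import MoleculeRecord, ShiftDataset, ShiftRecord, parse_smiles
from .conformers import Conformer, ConformerEnsemble, generate_ensemble

__all__ = ["SyntheticOracleConfig", "make_toy_molecules", "oracle_shift",
           "make_synthetic_dataset", "CATALOGUE"]


# Small polyols, cyclic ethers and acetylated sugars with defined
# stereocenters, 5-20 heavy atoms; pseudo-classes assigned by size in
# proportions echoing the real mono/di/tri distribution (107/153/115).
CATALOGUE: dict[str, list[str]] = {
    "mono": [  # 5-8 heavy atoms
        "OC[C@@H](O)CO",                      # glycerol-like triol
        "C[C@@H](O)[C@H](O)CO",               # butanetriol
        "OC[C@H](O)[C@@H](O)CO",              # threitol
        "CO[C@@H](C)CO",                      # methoxy propanediol
        "C[C@H]1CCO[C@@H]1O",                 # tetrahydrofuranol
        "CC(=O)OC[C@H](C)O",                  # acetylated diol
    ],
    "di": [  # 9-14 heavy atoms
        "OC[C@H](O)[C@@H](O)[C@H](O)CO",      # xylitol
        "OC[C@H](O)[C@@H](O)[C@H](O)[C@H](O)CO",  # hexitol
        "CO[C@H]1O[C@H](CO)[C@H](O)[C@H](O)[C@H]1O",  # methyl hexopyranoside
        "OC[C@H]1O[C@@H](O)[C@H](O)[C@@H](O)[C@@H]1O",  # hexopyranose
        "CC(=O)OC[C@H](O)[C@@H](O)CO",        # acetylated tetritol
        "O[C@H]1CO[C@H](CO)[C@H]1O",          # anhydro sugar
    ],
    "tri": [  # 15-20 heavy atoms
        "OC[C@H]1O[C@@H](OC[C@H](O)[C@@H](O)CO)[C@H](O)[C@@H](O)[C@@H]1O",
        "CC(=O)O[C@H]1[C@H](O)O[C@H](CO)[C@H](O)[C@H]1O",
        "CO[C@H]1O[C@H](COC(C)=O)[C@H](O)[C@H](O)[C@H]1O",
        "OC[C@H](O)[C@@H](O)[C@H](O)[C@H](O)[C@@H](O)[C@H](O)CO",  # octitol
        "CC(=O)OC[C@H]1O[C@@H](OC)[C@H](O)[C@@H](O)[C@@H]1O",
    ],
}

# class sampling probabilities ~ the real 107/153/115 split
_CLASS_P = {"mono": 107 / 375, "di": 153 / 375, "tri": 115 / 375}


@dataclass
class SyntheticOracleConfig:
    """Constants of the synthetic shift function.

    Element offsets are chosen so carbon targets sit in a plausible window
    and the /10 proton mimic stays within 0-10 ppm; ``pair_scale`` of 1.8 Å
    makes bonded and 1,3-neighbor contacts dominate the pair term.
    """

    element_offsets: dict[str, float] = field(
        default_factory=lambda: {"C": 50.0, "O": 30.0, "N": 20.0})
    default_offset: float = 15.0
    pair_weight: float = 20.0     # b
    pair_scale: float = 1.8       # sigma, Å
    angle_weight: float = 8.0     # c
    noise_sd: float = 0.1         # ppm, on the carbon scale
    r_cut: float = 6.0
    seed: int = 0


def make_toy_molecules(n: int, seed: int = 0) -> list[MoleculeRecord]:
    """Deterministic sample of ``n`` catalogue molecules with class tags."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    classes = list(_CLASS_P.keys())
    probs = np.array([_CLASS_P[c] for c in classes])
    out = []
    for i in range(n):
        klass = classes[int(rng.choice(len(classes), p=probs))]
        smiles = CATALOGUE[klass][int(rng.integers(len(CATALOGUE[klass])))]
        out.append(parse_smiles(smiles, molecule_id=f"syn-{i:04d}",
                                saccharide_class=klass))
    return out


def _atom_noise(cfg: SyntheticOracleConfig, molecule_id: str,
                atom_index: int, nucleus: str) -> float:
    """Noise drawn once per (molecule, atom, nucleus), stable across
    conformers, calls and processes."""
    if cfg.noise_sd == 0:
        return 0.0
    key = f"{cfg.seed}:{molecule_id}:{atom_index}:{nucleus}".encode()
    sub = np.random.default_rng(zlib.crc32(key))
    return float(sub.normal(0.0, cfg.noise_sd))


def _deterministic_shift(mol: MoleculeRecord, coords: np.ndarray,
                         atom_index: int, cfg: SyntheticOracleConfig) -> float:
    el = mol.atoms[atom_index][1]
    a = cfg.element_offsets.get(el, cfg.default_offset)
    d = np.linalg.norm(coords - coords[atom_index], axis=1)
    within = (d > 0) & (d < cfg.r_cut)
    pair = cfg.pair_weight * float(
        np.exp(-d[within] ** 2 / cfg.pair_scale ** 2).sum())
    nbrs = sorted({j for i, j, _ in mol.bonds if i == atom_index} |
                  {i for i, j, _ in mol.bonds if j == atom_index})
    angle = 0.0
    for ai in range(len(nbrs)):
        for bi in range(ai + 1, len(nbrs)):
            u = coords[nbrs[ai]] - coords[atom_index]
            w = coords[nbrs[bi]] - coords[atom_index]
            angle += float(np.dot(u, w) /
                           (np.linalg.norm(u) * np.linalg.norm(w)))
    return a + pair + cfg.angle_weight * angle


def oracle_shift(mol: MoleculeRecord, conformer: Conformer, atom_index: int,
                 cfg: SyntheticOracleConfig, nucleus: str = "C13") -> float:
    """Synthetic shift of one atom in one conformer (carbon scale; the H1
    mimic is this value divided by 10).  E(3)-invariant by construction."""
    coords = np.asarray(conformer.coords, dtype=float)
    if coords.shape[0] != mol.n_atoms:
        raise ValueError("conformer does not match molecule")
    val = (_deterministic_shift(mol, coords, atom_index, cfg)
           + _atom_noise(cfg, mol.molecule_id, atom_index, nucleus))
    return val / 10.0 if nucleus == "H1" else val


def make_synthetic_dataset(
        n_mol: int, n_conf: int,
        cfg: SyntheticOracleConfig | None = None,
        ) -> tuple[ShiftDataset, dict[str, ConformerEnsemble]]:
    """Molecules, conformer ensembles and oracle targets, fully seeded.

    Targets: every carbon receives a C13 record; every heavy atom with at
    least one attached hydrogen receives an H1 record (the /10 mimic).  The
    stored value is the ensemble mean of the per-conformer oracle (the
    per-atom noise is constant across conformers, so it rides along).
    """
    cfg = cfg or SyntheticOracleConfig()
    mols = make_toy_molecules(n_mol, seed=cfg.seed)
    ensembles: dict[str, ConformerEnsemble] = {}
    shifts: list[ShiftRecord] = []
    for k, mol in enumerate(mols):
        ens = generate_ensemble(mol, n_generate=2 * n_conf, n_keep=n_conf,
                                seed=cfg.seed * 100003 + k)
        ensembles[mol.molecule_id] = ens
        for idx, el, hc in mol.atoms:
            for nucleus, eligible in (("C13", el == "C"), ("H1", hc >= 1)):
                if not eligible:
                    continue
                vals = [oracle_shift(mol, conf, idx, cfg, nucleus)
                        for conf in ens.conformers]
                shifts.append(ShiftRecord(mol.molecule_id, idx, nucleus,
                                          float(np.mean(vals))))
    ds = ShiftDataset(molecules=mols, shifts=shifts,
                      provenance=f"synthetic oracle (seed={cfg.seed})")
    ds.validate()
    return ds, ensembles
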