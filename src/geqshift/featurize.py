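"""Graph featurization: molecules + conformers -> model inputs.

A :class:`GraphSample` is a directed graph over heavy atoms.  Edges connect
every bonded pair and every pair closer than the cutoff radius (default
6 Å); both directions are always present.  Each edge carries its bond
category (``none`` for through-space contacts), the Euclidean distance and
the unit direction vector; each node carries its element-vocabulary index
and capped attached-hydrogen count, plus masked shift targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .chem_io import MoleculeRecord, ShiftRecord
from .conformers import Conformer
from .irreps import sph_harm

__all__ = ["GraphSample", "build_graph", "spherical_harmonic_features",
           "assemble_batch", "unbatch", "ELEMENT_VOCAB", "BOND_VOCAB"]

# embedding table keyed by atomic number; everything else shares one bucket
ELEMENT_VOCAB: dict[int, int] = {6: 0, 7: 1, 8: 2, 16: 3, 15: 4, 9: 5, 17: 6}
OTHER_ELEMENT_IDX = 7
BOND_VOCAB = {"none": 0, "single": 1, "double": 2, "other": 3}

_SYMBOL_TO_Z = {"C": 6, "N": 7, "O": 8, "S": 16, "P": 15, "F": 9, "Cl": 17}


def element_index(symbol: str) -> int:
    z = _SYMBOL_TO_Z.get(symbol)
    return ELEMENT_VOCAB.get(z, OTHER_ELEMENT_IDX) if z else OTHER_ELEMENT_IDX


@dataclass
class GraphSample:
    """Featurized directed graph for one (molecule, conformer) pair."""

    molecule_id: str
    node_element_idx: np.ndarray   # (n,)
    node_hcount_idx: np.ndarray    # (n,)
    edge_src: np.ndarray           # (E,) sender j
    edge_dst: np.ndarray           # (E,) receiver i
    edge_bond_idx: np.ndarray      # (E,)
    edge_distance: np.ndarray      # (E,) Å
    edge_unit_vec: np.ndarray      # (E, 3), (r_i - r_j) / d_ij
    target_c13: np.ndarray         # (n,) ppm, 0 where unobserved
    mask_c13: np.ndarray           # (n,) bool
    target_h1: np.ndarray          # (n,)
    mask_h1: np.ndarray            # (n,) bool
    node_mol: np.ndarray = field(default=None)  # per-node sample index

    def __post_init__(self):
        if self.node_mol is None:
            self.node_mol = np.zeros(self.n_nodes, dtype=int)

    @property
    def n_nodes(self) -> int:
        return len(self.node_element_idx)

    @property
    def n_edges(self) -> int:
        return len(self.edge_src)


def build_graph(mol: MoleculeRecord, conf: Conformer,
                targets: list[ShiftRecord] | None = None,
                r_cut: float = 6.0, hcount_cap: int = 4) -> GraphSample:
    """Build the model's graph sample from a molecule and one conformer.

    Edge set: all bonded pairs (keeping their bond category even beyond the
    cutoff) plus all non-bonded pairs with d_ij < ``r_cut`` (category
    ``none``), in both directions.
    """
    n = mol.n_atoms
    coords = np.asarray(conf.coords, dtype=float)
    if coords.shape[0] != n:
        raise ValueError(f"{mol.molecule_id!r}: conformer has "
                         f"{coords.shape[0]} atoms, molecule has {n}")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    bond_cat = np.full((n, n), -1, dtype=int)
    for i, j, cat in mol.bonds:
        bond_cat[i, j] = bond_cat[j, i] = BOND_VOCAB[cat]
    adjacency = (dist < r_cut) | (bond_cat >= 0)
    np.fill_diagonal(adjacency, False)
    dst, src = np.nonzero(adjacency)  # receiver i, sender j
    d = dist[dst, src]
    if np.any(d <= 0):
        raise ValueError(f"{mol.molecule_id!r}: coincident atoms in conformer")
    unit = diff[dst, src] / d[:, None]
    bonds = bond_cat[dst, src]
    bonds[bonds < 0] = BOND_VOCAB["none"]

    element_idx = np.array([element_index(el) for el in mol.elements])
    hcount_idx = np.minimum(np.array(mol.h_counts, dtype=int), hcount_cap)

    target_c13 = np.zeros(n)
    mask_c13 = np.zeros(n, dtype=bool)
    target_h1 = np.zeros(n)
    mask_h1 = np.zeros(n, dtype=bool)
    for rec in targets or []:
        if rec.molecule_id != mol.molecule_id:
            raise ValueError(f"target for {rec.molecule_id!r} attached to "
                             f"{mol.molecule_id!r}")
        if rec.nucleus == "C13":
            target_c13[rec.atom_index] = rec.shift_ppm
            mask_c13[rec.atom_index] = True
        else:
            target_h1[rec.atom_index] = rec.shift_ppm
            mask_h1[rec.atom_index] = True

    return GraphSample(
        molecule_id=mol.molecule_id,
        node_element_idx=element_idx, node_hcount_idx=hcount_idx,
        edge_src=src, edge_dst=dst, edge_bond_idx=bonds,
        edge_distance=d, edge_unit_vec=unit,
        target_c13=target_c13, mask_c13=mask_c13,
        target_h1=target_h1, mask_h1=mask_h1)


def spherical_harmonic_features(unit_vec: np.ndarray,
                                l_max: int = 2) -> np.ndarray:
    """Real spherical harmonics of unit directions, orders 0..l_max.

    Each l-block has unit L2 norm for unit input and parity (-1)^l; l=1
    components are ordered (y, z, x).
    """
    v = np.asarray(unit_vec, dtype=float)
    norms = np.linalg.norm(v, axis=-1)
    if np.any(norms < 1e-12):
        raise ValueError("zero vector has no direction")
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("input must be unit-norm")
    return np.concatenate([sph_harm(l, v) for l in range(l_max + 1)], axis=-1)


def assemble_batch(samples: list[GraphSample]) -> GraphSample:
    """Concatenate graph samples into one disjoint-union graph.

    Edge indices of sample k are offset by the number of nodes in samples
    0..k-1; ``node_mol`` records each node's sample of origin so
    :func:`unbatch` is an exact inverse.
    """
    if not samples:
        raise ValueError("cannot batch an empty list of samples")
    offsets = np.cumsum([0] + [s.n_nodes for s in samples[:-1]])
    return GraphSample(
        molecule_id="|".join(s.molecule_id for s in samples),
        node_element_idx=np.concatenate([s.node_element_idx for s in samples]),
        node_hcount_idx=np.concatenate([s.node_hcount_idx for s in samples]),
        edge_src=np.concatenate([s.edge_src + o
                                 for s, o in zip(samples, offsets)]),
        edge_dst=np.concatenate([s.edge_dst + o
                                 for s, o in zip(samples, offsets)]),
        edge_bond_idx=np.concatenate([s.edge_bond_idx for s in samples]),
        edge_distance=np.concatenate([s.edge_distance for s in samples]),
        edge_unit_vec=np.concatenate([s.edge_unit_vec for s in samples]),
        target_c13=np.concatenate([s.target_c13 for s in samples]),
        mask_c13=np.concatenate([s.mask_c13 for s in samples]),
        target_h1=np.concatenate([s.target_h1 for s in samples]),
        mask_h1=np.concatenate([s.mask_h1 for s in samples]),
        node_mol=np.concatenate([np.full(s.n_nodes, k)
                                 for k, s in enumerate(samples)]))


def unbatch(batch: GraphSample) -> list[GraphSample]:
    """Split a batched sample back into its constituents."""
    ids = batch.molecule_id.split("|")
    out = []
    edge_mol = batch.node_mol[batch.edge_dst]
    for k, mol_id in enumerate(ids):
        nmask = batch.node_mol == k
        emask = edge_mol == k
        offset = int(np.nonzero(nmask)[0][0]) if nmask.any() else 0
        out.append(GraphSample(
            molecule_id=mol_id,
            node_element_idx=batch.node_element_idx[nmask],
            node_hcount_idx=batch.node_hcount_idx[nmask],
            edge_src=batch.edge_src[emask] - offset,
            edge_dst=batch.edge_dst[emask] - offset,
            edge_bond_idx=batch.edge_bond_idx[emask],
            edge_distance=batch.edge_distance[emask],
            edge_unit_vec=batch.edge_unit_vec[emask],
            target_c13=batch.target_c13[nmask],
            mask_c13=batch.mask_c13[nmask],
            target_h1=batch.target_h1[nmask],
            mask_h1=batch.mask_h1[nmask]))
    return out
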