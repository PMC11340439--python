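"""Ensemble prediction with uncertainty and stratified evaluation.

The final prediction for a nucleus is the arithmetic mean of the per-
conformer predictions over the molecule's ensemble; the spread (population
standard deviation) is reported as an uncertainty estimate.  Metrics are
MAE and RMSE in ppm, stratified by nucleus and saccharide class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_io import MoleculeRecord, ShiftDataset
from .conformers import ConformerEnsemble
from .featurize import build_graph, assemble_batch

__all__ = ["ShiftPrediction", "MetricsReport", "predict_ensemble",
           "evaluate", "compare_runs", "ensemble_mae_inequality"]

_CLASS_ORDER = ("mono", "di", "tri", "other")
_NUC_ORDER = ("C13", "H1")


@dataclass
class ShiftPrediction:
    """Per-(atom, nucleus) ensemble of predicted shifts.

    ``mean_ppm`` is the arithmetic mean of ``per_conformer_ppm``;
    ``std_ppm`` the population (1/N) standard deviation of the same list.
    """

    molecule_id: str
    atom_index: int
    nucleus: str
    per_conformer_ppm: list[float]
    mean_ppm: float = field(init=False)
    std_ppm: float = field(init=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.per_conformer_ppm, dtype=float)
        if vals.size == 0:
            raise ValueError("empty prediction ensemble")
        self.mean_ppm = float(vals.mean())
        self.std_ppm = float(vals.std())  # population convention


@dataclass
class MetricsReport:
    """MAE/RMSE per (nucleus, saccharide class) plus the pooled errors."""

    cells: dict[tuple[str, str], dict[str, float]]
    pooled_errors: np.ndarray

    @property
    def error_std(self) -> float:
        return float(self.pooled_errors.std())

    def n_total(self) -> int:
        return int(sum(c["n_shifts"] for c in self.cells.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (nuc, klass), cell in sorted(
                self.cells.items(),
                key=lambda kv: (_NUC_ORDER.index(kv[0][0]),
                                _CLASS_ORDER.index(kv[0][1]))):
            rows.append(dict(nucleus=nuc, saccharide_class=klass, **cell))
        return pd.DataFrame(rows)


def predict_ensemble(model, mol: MoleculeRecord,
                     ensemble: ConformerEnsemble,
                     r_cut: float = 6.0) -> list[ShiftPrediction]:
    """One forward pass per conformer; group per (atom, nucleus).

    ``model`` is a fitted estimator exposing ``predict_nodes``.  Emitted
    predictions: every carbon for C13; every heavy atom with at least one
    attached hydrogen for H1 (regardless of element, covering OMe/NAc and
    hydroxyl protons).
    """
    if len(ensemble) == 0:
        raise ValueError(f"{mol.molecule_id!r}: empty conformer ensemble")
    per_conf_c, per_conf_h = [], []
    samples = [build_graph(mol, conf, r_cut=r_cut)
               for conf in ensemble.conformers]
    batch = assemble_batch(samples)
    c13, h1 = model.predict_nodes(batch)
    n = mol.n_atoms
    for k in range(len(samples)):
        per_conf_c.append(c13[k * n:(k + 1) * n])
        per_conf_h.append(h1[k * n:(k + 1) * n])
    c_mat = np.stack(per_conf_c, axis=1)   # (n_atoms, n_conf)
    h_mat = np.stack(per_conf_h, axis=1)
    preds: list[ShiftPrediction] = []
    for idx, el, hc in mol.atoms:
        if el == "C":
            preds.append(ShiftPrediction(mol.molecule_id, idx, "C13",
                                         c_mat[idx].tolist()))
        if hc >= 1:
            preds.append(ShiftPrediction(mol.molecule_id, idx, "H1",
                                         h_mat[idx].tolist()))
    return preds


def evaluate(preds: list[ShiftPrediction],
             truth: ShiftDataset) -> MetricsReport:
    """MAE/RMSE per (nucleus, class); predictions must cover every truth key.

    Predictions for atoms without experimental data are ignored.
    """
    by_key = {(p.molecule_id, p.atom_index, p.nucleus): p for p in preds}
    missing = [(s.molecule_id, s.atom_index, s.nucleus)
               for s in truth.shifts
               if (s.molecule_id, s.atom_index, s.nucleus) not in by_key]
    if missing:
        raise ValueError(f"missing predictions for truth keys: "
                         f"{missing[:10]}{'...' if len(missing) > 10 else ''}")
    errors: dict[tuple[str, str], list[float]] = {}
    pooled = []
    for s in truth.shifts:
        p = by_key[(s.molecule_id, s.atom_index, s.nucleus)]
        delta = p.mean_ppm - s.shift_ppm
        klass = truth.molecule(s.molecule_id).saccharide_class
        errors.setdefault((s.nucleus, klass), []).append(delta)
        pooled.append(delta)
    cells = {}
    for key, deltas in errors.items():
        d = np.asarray(deltas)
        cells[key] = dict(mae_ppm=float(np.abs(d).mean()),
                          rmse_ppm=float(np.sqrt((d ** 2).mean())),
                          n_shifts=int(d.size))
    return MetricsReport(cells=cells, pooled_errors=np.asarray(pooled))


def compare_runs(reports: list[MetricsReport]) -> pd.DataFrame:
    """Fold-aggregated table: per-cell "mean (std)" across runs.

    Population-std convention; rows ordered (C13, H1) x (mono, di, tri,
    other) deterministically.
    """
    if not reports:
        raise ValueError("no reports to compare")
    keys = set(reports[0].cells.keys())
    for r in reports[1:]:
        if set(r.cells.keys()) != keys:
            raise ValueError("reports have inconsistent cell sets")
    rows = []
    for nuc, klass in sorted(keys, key=lambda k: (_NUC_ORDER.index(k[0]),
                                                  _CLASS_ORDER.index(k[1]))):
        row = dict(nucleus=nuc, saccharide_class=klass)
        for metric in ("mae_ppm", "rmse_ppm"):
            vals = np.array([r.cells[(nuc, klass)][metric] for r in reports])
            row[metric] = f"{vals.mean():.2f} ({vals.std():.2f})"
        row["n_shifts"] = int(reports[0].cells[(nuc, klass)]["n_shifts"])
        rows.append(row)
    return pd.DataFrame(rows)


def ensemble_mae_inequality(preds: list[ShiftPrediction],
                            truth: ShiftDataset) -> tuple[float, float]:
    """(ensemble-mean MAE, mean per-conformer MAE) over the truth keys.

    By the triangle inequality the first never exceeds the second; asserted
    on every evaluation run.
    """
    by_key = {(p.molecule_id, p.atom_index, p.nucleus): p for p in preds}
    mean_err, conf_err = [], []
    for s in truth.shifts:
        p = by_key.get((s.molecule_id, s.atom_index, s.nucleus))
        if p is None:
            raise ValueError("predictions do not cover truth")
        mean_err.append(abs(p.mean_ppm - s.shift_ppm))
        conf_err.append(float(np.mean([abs(v - s.shift_ppm)
                                       for v in p.per_conformer_ppm])))
    lhs = float(np.mean(mean_err))
    rhs = float(np.mean(conf_err))
    if lhs > rhs + 1e-9:
        raise AssertionError(
            f"ensemble-mean MAE {lhs} exceeds mean per-conformer MAE {rhs}")
    return lhs, rhs
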