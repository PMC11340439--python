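"""Training: masked-MAE objective, conformer expansion, CV and splits.

The training set is expanded so that every (molecule, conformer) pair is an
independent sample carrying the molecule's full shift targets; by the
triangle inequality, driving the per-conformer error down bounds the error of
the ensemble-mean prediction, so the expanded set is trained like any flat
dataset.  Optimization is Adam on the masked mean-absolute-error summed
over both nuclei in normalized (z-scored) units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .chem_io import ShiftDataset
from .conformers import ConformerEnsemble
from .featurize import GraphSample, assemble_batch, build_graph
from .model import GeqShiftNet, ModelConfig

__all__ = ["TrainConfig", "FoldPlan", "mae_loss", "expand_with_conformers",
           "make_cv_folds", "make_exclusion_split", "train", "TrainResult"]


@dataclass
class TrainConfig:
    """Optimization settings.

    ``mode`` selects the schedule: ``single_conformer`` uses a
    reduce-on-plateau scheduler (patience 20 epochs, factor 0.1) watched on
    a 5% molecule-level validation split; ``ensemble`` trains a fixed number
    of epochs (default 3) with the learning rate decaying by 0.1 each new
    epoch and no validation split.
    """

    lr: float = 3e-4
    batch_size: int = 32
    mode: str = "single_conformer"  # or "ensemble"
    epochs: int = 3
    plateau_patience: int = 20
    plateau_factor: float = 0.1
    val_fraction: float = 0.05
    n_conf_train: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not 0.0 < self.val_fraction < 0.5:
            raise ValueError("val_fraction must be in (0, 0.5)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.mode not in ("single_conformer", "ensemble"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class FoldPlan:
    """Stratified k-fold assignment of molecules to test folds."""

    k: int
    assignments: dict[str, int]
    strata: dict[str, str]

    def fold_ids(self, fold: int) -> list[str]:
        return [m for m, f in self.assignments.items() if f == fold]

    def split(self, fold: int) -> tuple[list[str], list[str]]:
        test = self.fold_ids(fold)
        train = [m for m, f in self.assignments.items() if f != fold]
        return train, test


def mae_loss(pred, target, mask):
    """Masked mean absolute error, (1/N) sum |x - x_hat| over masked entries.

    Accepts autodiff tensors (for training) or plain arrays.  N is the
    number of masked-true entries; an all-false mask is an error.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("mask selects no supervised entries")
    if isinstance(pred, Tensor):
        t = np.where(mask, np.asarray(target, dtype=float), 0.0)
        diff = (pred - ad.constant(t)) * ad.constant(mask.astype(float))
        return diff.abs().sum() * (1.0 / n)
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    return float(np.abs(pred[mask] - target[mask]).mean())


def expand_with_conformers(dataset: ShiftDataset,
                           ensembles: dict[str, ConformerEnsemble],
                           r_cut: float = 6.0,
                           hcount_cap: int = 4) -> list[GraphSample]:
    """One :class:`GraphSample` per (molecule, conformer), all sharing the
    molecule's shift targets."""
    samples: list[GraphSample] = []
    for mol in dataset.molecules:
        ens = ensembles.get(mol.molecule_id)
        if ens is None:
            raise ValueError(f"no conformer ensemble for {mol.molecule_id!r}")
        targets = dataset.shifts_for(mol.molecule_id)
        for conf in ens.conformers:
            samples.append(build_graph(mol, conf, targets,
                                       r_cut=r_cut, hcount_cap=hcount_cap))
    return samples


def make_cv_folds(dataset: ShiftDataset, k: int = 10,
                  seed: int = 0) -> FoldPlan:
    """Stratified-by-saccharide-class k-fold partition of the molecules.

    Folds are disjoint and exhaustive; per-fold class proportions are within
    one molecule of the global proportions (sklearn stratification).
    """
    if k < 2:
        raise ValueError("k must be >= 2 (k=1 leaves no held-out data)")
    ids = dataset.molecule_ids
    classes = [m.saccharide_class for m in dataset.molecules]
    counts: dict[str, int] = {}
    for c in classes:
        counts[c] = counts.get(c, 0) + 1
    small = {c: n for c, n in counts.items() if n < k}
    if small:
        raise ValueError(f"classes smaller than k={k}: {small}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(ids, classes)):
        for i in test_idx:
            assignments[ids[i]] = fold
    return FoldPlan(k=k, assignments=assignments,
                    strata=dict(zip(ids, classes)))


def make_exclusion_split(dataset: ShiftDataset,
                         predicate) -> tuple[ShiftDataset, ShiftDataset]:
    """Structure-exclusion split: test = molecules flagged by ``predicate``.

    Used to probe out-of-distribution generalization by deliberately
    removing a structural family from training.
    """
    test_ids = {m.molecule_id for m in dataset.molecules if predicate(m)}
    train_ids = {m.molecule_id for m in dataset.molecules} - test_ids
    if not test_ids or not train_ids:
        raise ValueError("exclusion predicate must flag a non-empty strict "
                         "subset of molecules")
    def subset(keep: set) -> ShiftDataset:
        return ShiftDataset(
            molecules=[m for m in dataset.molecules if m.molecule_id in keep],
            shifts=[s for s in dataset.shifts if s.molecule_id in keep],
            provenance=dataset.provenance)
    return subset(train_ids), subset(test_ids)


# ---------------------------------------------------------------------------


@dataclass
class TrainResult:
    net: GeqShiftNet
    norm_stats: dict[str, tuple[float, float]]
    loss_trace: list[float]
    lr_trace: list[float]
    val_trace: list[float] = field(default_factory=list)


def normalization_stats(samples: list[GraphSample]) -> dict[str, tuple[float, float]]:
    """Per-nucleus mean and population std of the observed shifts."""
    stats = {}
    for nuc, t_attr, m_attr in (("C13", "target_c13", "mask_c13"),
                                ("H1", "target_h1", "mask_h1")):
        vals = np.concatenate([getattr(s, t_attr)[getattr(s, m_attr)]
                               for s in samples])
        if vals.size == 0:
            stats[nuc] = (0.0, 1.0)
        else:
            sd = float(vals.std())
            stats[nuc] = (float(vals.mean()), sd if sd > 1e-12 else 1.0)
    return stats


def _batch_loss(net: GeqShiftNet, batch: GraphSample,
                stats: dict[str, tuple[float, float]]):
    """Masked MAE in normalized units, summed over nuclei with data."""
    pred_c, pred_h = net.forward(batch)
    total = None
    for pred, nuc, t_attr, m_attr in ((pred_c, "C13", "target_c13", "mask_c13"),
                                      (pred_h, "H1", "target_h1", "mask_h1")):
        mask = getattr(batch, m_attr)
        if not mask.any():
            continue
        mu, sd = stats[nuc]
        tgt = (getattr(batch, t_attr) - mu) / sd
        term = mae_loss(pred, tgt, mask)
        total = term if total is None else total + term
    if total is None:
        raise ValueError("batch contains no supervised nuclei")
    return total


def _eval_loss(net: GeqShiftNet, samples: list[GraphSample],
               stats, batch_size: int) -> float:
    tot, nb = 0.0, 0
    for i in range(0, len(samples), batch_size):
        batch = assemble_batch(samples[i:i + batch_size])
        tot += float(_batch_loss(net, batch, stats).data)
        nb += 1
    return tot / max(nb, 1)


def train(model_config: ModelConfig, train_config: TrainConfig,
          samples: list[GraphSample]) -> TrainResult:
    """Train a network on featurized samples.

    Fully seeded: parameter initialization, the validation split and epoch
    shuffling all derive from ``train_config.seed``.  Raises on divergence
    (non-finite loss), reporting the last finite epoch.
    """
    train_config.validate()
    if not samples:
        raise ValueError("no training samples")
    rng = np.random.default_rng(train_config.seed)
    net = GeqShiftNet(model_config, seed=train_config.seed)

    val_samples: list[GraphSample] = []
    fit_samples = list(samples)
    if train_config.mode == "single_conformer":
        # molecule-level split prevents conformers of one molecule from
        # leaking between train and validation
        mol_ids = sorted({s.molecule_id for s in samples})
        n_val = max(1, int(round(train_config.val_fraction * len(mol_ids))))
        val_ids = set(rng.choice(mol_ids, size=n_val, replace=False))
        val_samples = [s for s in samples if s.molecule_id in val_ids]
        fit_samples = [s for s in samples if s.molecule_id not in val_ids]
        if not fit_samples:
            raise ValueError("validation split consumed all samples")

    stats = normalization_stats(fit_samples)
    opt = Adam(net.parameters(), lr=train_config.lr)
    loss_trace: list[float] = []
    lr_trace: list[float] = []
    val_trace: list[float] = []
    best_val = np.inf
    since_best = 0
    bs = train_config.batch_size

    for epoch in range(train_config.epochs):
        if train_config.mode == "ensemble" and epoch > 0:
            opt.lr *= 0.1  # fixed schedule: x0.1 every new epoch
        order = rng.permutation(len(fit_samples))
        epoch_losses = []
        for i in range(0, len(order), bs):
            batch = assemble_batch([fit_samples[j] for j in order[i:i + bs]])
            loss = _batch_loss(net, batch, stats)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}; last finite "
                    f"epoch losses: {loss_trace[-3:]}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        loss_trace.append(float(np.mean(epoch_losses)))
        lr_trace.append(opt.lr)
        if train_config.mode == "single_conformer" and val_samples:
            val = _eval_loss(net, val_samples, stats, bs)
            val_trace.append(val)
            if val < best_val - 1e-12:
                best_val = val
                since_best = 0
            else:
                since_best += 1
                if since_best >= train_config.plateau_patience:
                    opt.lr *= train_config.plateau_factor
                    since_best = 0
    return TrainResult(net=net, norm_stats=stats, loss_trace=loss_trace,
                       lr_trace=lr_trace, val_trace=val_trace)
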