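"""Scikit-learn style estimator facade over the equivariant network.

``GeqShiftRegressor`` bundles architecture and optimization hyperparameters
as constructor arguments (so it composes with ``sklearn`` model selection),
trains on featurized graph samples via :func:`geqshift.training.train`, and
predicts de-normalized chemical shifts in ppm.
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import NotFittedError

from .featurize import GraphSample, assemble_batch
from .model import GeqShiftNet, ModelConfig
from .training import TrainConfig, mae_loss, train

__all__ = ["GeqShiftRegressor"]


class GeqShiftRegressor(BaseEstimator, RegressorMixin):
    """E(3)-invariant chemical-shift regressor.

    Parameters mirror the network defaults (seven equivariant attention
    layers, hidden layout ``64x0e+32x1o+8x2e``) and the optimizer settings
    (Adam, learning rate 3e-4, batch size 32).  ``mode`` selects the
    schedule: ``"single_conformer"`` (reduce-on-plateau, 5% molecule-level
    validation split) or ``"ensemble"`` (fixed epochs, x0.1 lr decay per
    epoch).  Setting ``hidden`` to a scalars-only layout (e.g. ``"104x0e"``)
    with ``l_max_sh=0`` gives the invariant ablation that sees geometry only
    through pairwise distances.

    Fitted attributes: ``net_`` (the network), ``norm_stats_`` (per-nucleus
    z-scoring statistics), ``loss_trace_``, ``lr_trace_``, ``val_trace_``.
    """

    def __init__(self, n_layers: int = 7, node_emb_dim: int = 128,
                 edge_emb_dim: int = 32, hidden: str = "64x0e+32x1o+8x2e",
                 l_max_sh: int = 2, readout_scalars: int = 128,
                 readout_hidden: int = 384, weight_hidden: int = 64,
                 use_rbf: bool = False, hcount_cap: int = 4,
                 lr: float = 3e-4, batch_size: int = 32,
                 mode: str = "single_conformer", epochs: int = 3,
                 val_fraction: float = 0.05, plateau_patience: int = 20,
                 plateau_factor: float = 0.1, seed: int = 0):
        self.n_layers = n_layers
        self.node_emb_dim = node_emb_dim
        self.edge_emb_dim = edge_emb_dim
        self.hidden = hidden
        self.l_max_sh = l_max_sh
        self.readout_scalars = readout_scalars
        self.readout_hidden = readout_hidden
        self.weight_hidden = weight_hidden
        self.use_rbf = use_rbf
        self.hcount_cap = hcount_cap
        self.lr = lr
        self.batch_size = batch_size
        self.mode = mode
        self.epochs = epochs
        self.val_fraction = val_fraction
        self.plateau_patience = plateau_patience
        self.plateau_factor = plateau_factor
        self.seed = seed

    # -- config assembly -----------------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            n_layers=self.n_layers, node_emb_dim=self.node_emb_dim,
            edge_emb_dim=self.edge_emb_dim, hidden=self.hidden,
            l_max_sh=self.l_max_sh, readout_scalars=self.readout_scalars,
            readout_hidden=self.readout_hidden,
            weight_hidden=self.weight_hidden, use_rbf=self.use_rbf,
            hcount_cap=self.hcount_cap)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            lr=self.lr, batch_size=self.batch_size, mode=self.mode,
            epochs=self.epochs, val_fraction=self.val_fraction,
            plateau_patience=self.plateau_patience,
            plateau_factor=self.plateau_factor, seed=self.seed)

    # -- sklearn API ---------------------------------------------------------
    def fit(self, X: list[GraphSample], y=None) -> "GeqShiftRegressor":
        """Fit on a list of featurized graph samples (targets are node-level
        fields of the samples; ``y`` is ignored)."""
        if not isinstance(X, (list, tuple)) or not X:
            raise ValueError("X must be a non-empty list of GraphSample")
        for s in X:
            if not isinstance(s, GraphSample):
                raise TypeError(f"expected GraphSample, got {type(s)}")
        result = train(self._model_config(), self._train_config(), list(X))
        self.net_ = result.net
        self.norm_stats_ = result.norm_stats
        self.loss_trace_ = result.loss_trace
        self.lr_trace_ = result.lr_trace
        self.val_trace_ = result.val_trace
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise NotFittedError("this GeqShiftRegressor is not fitted yet")

    def predict_nodes(self, sample: GraphSample) -> tuple[np.ndarray, np.ndarray]:
        """Per-node (c13_ppm, h1_ppm) predictions for one (possibly batched)
        graph sample, de-normalized with the training statistics."""
        self._check_fitted()
        c13, h1 = self.net_.forward(sample)
        mu_c, sd_c = self.norm_stats_["C13"]
        mu_h, sd_h = self.norm_stats_["H1"]
        return c13.data * sd_c + mu_c, h1.data * sd_h + mu_h

    def predict(self, X: list[GraphSample]) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per-sample list of (c13_ppm, h1_ppm) node arrays."""
        self._check_fitted()
        return [self.predict_nodes(s) for s in X]

    def score(self, X: list[GraphSample], y=None) -> float:
        """Negative masked MAE in normalized units (higher is better)."""
        self._check_fitted()
        losses = []
        for i in range(0, len(X), self.batch_size):
            batch = assemble_batch(X[i:i + self.batch_size])
            c13, h1 = self.net_.forward(batch)
            for pred, nuc, t, m in ((c13, "C13", batch.target_c13, batch.mask_c13),
                                    (h1, "H1", batch.target_h1, batch.mask_h1)):
                if m.any():
                    mu, sd = self.norm_stats_[nuc]
                    losses.append(mae_loss(pred.data, (t - mu) / sd, m))
        return -float(np.mean(losses))

    # -- persistence ---------------------------------------------------------
    def save(self, path, dataset_hash: str | None = None) -> None:
        """Single-file artifact: config JSON + parameter blob + statistics
        + provenance (seed, package version, optional dataset hash)."""
        from . import __version__
        self._check_fitted()
        meta = dict(estimator_params=self.get_params(),
                    model_config=json.loads(self.net_.config.to_json()),
                    norm_stats=self.norm_stats_,
                    provenance=dict(seed=self.seed, version=__version__,
                                    dataset_hash=dataset_hash,
                                    loss_trace=self.loss_trace_))
        arrays = {f"param_{i}": a
                  for i, a in enumerate(self.net_.state_arrays())}
        np.savez_compressed(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "GeqShiftRegressor":
        with np.load(path, allow_pickle=False) as blob:
            meta = json.loads(str(blob["meta"]))
            arrays = [blob[f"param_{i}"]
                      for i in range(len(blob.files) - 1)]
        est = cls(**meta["estimator_params"])
        cfg = ModelConfig(**meta["model_config"])
        if cfg != est._model_config():
            raise ValueError("stored model config disagrees with estimator "
                             "parameters; artifact is inconsistent")
        est.net_ = GeqShiftNet(cfg, seed=meta["provenance"]["seed"])
        est.net_.load_state_arrays(arrays)
        est.norm_stats_ = {k: tuple(v)
                           for k, v in meta["norm_stats"].items()}
        est.loss_trace_ = meta["provenance"]["loss_trace"]
        est.lr_trace_ = []
        est.val_trace_ = []
        return est
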