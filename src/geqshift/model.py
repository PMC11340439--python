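"""E(3)-equivariant graph self-attention network for chemical shifts.

Architecture: invariant node embeddings (element, attached-H count) and edge
scalars (bond category, distance) feed K equivariant self-attention layers.
Each layer derives queries by an irreps-wise linear map, and keys/values by
tensor products of neighbor features with the spherical harmonics of the
edge direction, with path weights generated per edge by small MLPs of the
edge scalars.  Attention logits are the scalar channel of q (x) k; messages
are the attention-weighted sum of values; the update is an equivariant
feed-forward (gate nonlinearity) plus residual, followed by equivariant
layer normalization.  The final layer's scalar block passes through a
two-head MLP producing one shift per nucleus per node, in normalized units.

Predictions are invariant under rotation, translation and reflection of the
input coordinates by construction: every operation is equivariant and the
readout consumes only scalar channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .irreps import Irreps, allowed_paths, coupling, sh_irreps, sph_harm

__all__ = ["ModelConfig", "GeqShiftNet"]


@dataclass
class ModelConfig:
    """Hyperparameters of the network.

    Defaults are the full-size model: seven layers; hidden geometric tensors
    of 64 scalars, 32 l=1 odd vectors and 8 l=2 even tensors; 128-dim node
    embedding; 32-dim edge scalars; readout MLP with hidden width 384.
    """

    n_layers: int = 7
    node_emb_dim: int = 128
    edge_emb_dim: int = 32
    hidden: str = "64x0e+32x1o+8x2e"
    l_max_sh: int = 2
    readout_scalars: int = 128
    readout_hidden: int = 384
    weight_hidden: int = 64
    ff_mult: int = 1
    n_elements: int = 8      # {C, N, O, S, P, F, Cl} + other bucket
    hcount_cap: int = 4
    n_bond_categories: int = 4  # none, single, double, other
    use_rbf: bool = False
    n_rbf: int = 16
    rbf_max: float = 6.0

    def hidden_irreps(self) -> Irreps:
        return Irreps.parse(self.hidden)

    def edge_scalar_dim(self) -> int:
        base = self.edge_emb_dim - 1
        return base + (self.n_rbf if self.use_rbf else 1)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @staticmethod
    def from_json(s: str) -> "ModelConfig":
        return ModelConfig(**json.loads(s))


# ---------------------------------------------------------------------------
# building blocks


class Linear:
    """Irreps-wise linear map: mixes multiplicities within each (l, parity)."""

    def __init__(self, irreps_in: Irreps, irreps_out: Irreps,
                 rng: np.random.Generator):
        self.irreps_in = irreps_in
        self.irreps_out = irreps_out
        self.weights: dict[tuple[int, int], Tensor] = {}
        in_slices = irreps_in.slices()
        for b_out, (m_out, l_out, p_out) in enumerate(irreps_out.blocks):
            for b_in, (m_in, l_in, p_in) in enumerate(irreps_in.blocks):
                if (l_in, p_in) == (l_out, p_out):
                    w = ad.parameter((m_out, m_in), rng,
                                     scale=1.0 / np.sqrt(m_in))
                    self.weights[(b_in, b_out)] = w
        self._in_slices = in_slices

    def parameters(self) -> list[Tensor]:
        return list(self.weights.values())

    def __call__(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        pieces = []
        for b_out, (m_out, l_out, _) in enumerate(self.irreps_out.blocks):
            d = 2 * l_out + 1
            acc = None
            for b_in, (m_in, l_in, _) in enumerate(self.irreps_in.blocks):
                w = self.weights.get((b_in, b_out))
                if w is None:
                    continue
                xb = x[:, self._in_slices[b_in]].reshape(n, m_in, d)
                y = ad.einsum("oi,nim->nom", w, xb)
                acc = y if acc is None else acc + y
            if acc is None:
                pieces.append(ad.constant(np.zeros((n, m_out * d))))
            else:
                pieces.append(acc.reshape(n, m_out * d))
        return ad.concatenate(pieces, axis=1)


class TensorProduct:
    """Weighted tensor product x (x)_w Y with per-edge path weights.

    'uvu'-style: each allowed (in-block, sh-block, output order) path keeps
    the input multiplicity and carries one scalar weight per multiplet per
    edge, generated by an external network; multiplicities are mixed by the
    irreps-wise Linear that follows the product.  Output orders are capped
    at ``l_out_max`` (the hidden layout's maximum).
    """

    def __init__(self, irreps_in: Irreps, l_max_sh: int, l_out_max: int):
        self.irreps_in = irreps_in
        self.irreps_sh = sh_irreps(l_max_sh)
        self._in_slices = irreps_in.slices()
        self._sh_slices = self.irreps_sh.slices()
        self.paths: list[tuple[int, int, int, int]] = []  # (a, b, l3, p3)
        out_blocks = []
        for a, (m1, l1, p1) in enumerate(irreps_in.blocks):
            for b, (_, l2, p2) in enumerate(self.irreps_sh.blocks):
                for l3 in range(abs(l1 - l2), min(l1 + l2, l_out_max) + 1):
                    self.paths.append((a, b, l3, p1 * p2))
                    out_blocks.append((m1, l3, p1 * p2))
        if not self.paths:
            raise ValueError("no allowed tensor-product paths; check irreps")
        self.irreps_out = Irreps.parse(out_blocks)
        self.weight_numel = sum(irreps_in.blocks[a][0]
                                for a, _, _, _ in self.paths)
        self._norm = 1.0 / np.sqrt(len(self.paths) /
                                   max(len(irreps_in.blocks), 1))

    def __call__(self, x: Tensor, sh: np.ndarray, weights: Tensor) -> Tensor:
        n = x.shape[0]
        pieces = []
        woff = 0
        by_in: dict[int, list[tuple[int, int]]] = {}
        for a, b, l3, _ in self.paths:  # paths are ordered by (a, b, l3)
            by_in.setdefault(a, []).append((b, l3))
        for a, sub in by_in.items():
            m1, l1, _ = self.irreps_in.blocks[a]
            # constant edge basis: coupling contracted with the harmonics,
            # stacked over this block's paths along the output axis
            S = np.concatenate(
                [np.einsum("kab,nb->nka",
                           coupling(l1, self.irreps_sh.blocks[b][1], l3)
                           * self._norm,
                           sh[:, self._sh_slices[b]]) for b, l3 in sub],
                axis=1)
            xb = x[:, self._in_slices[a]].reshape(n, m1, 2 * l1 + 1)
            y = ad.einsum("nka,nua->nuk", ad.constant(S), xb)
            koff = 0
            for b, l3 in sub:
                d3 = 2 * l3 + 1
                w = weights[:, woff:woff + m1].reshape(n, m1, 1)
                woff += m1
                piece = y[:, :, koff:koff + d3] * w
                koff += d3
                pieces.append(piece.reshape(n, m1 * d3))
        return ad.concatenate(pieces, axis=1)


class MLP:
    """Ordinary scalar MLP with SiLU hidden activations and biases."""

    def __init__(self, dims: list[int], rng: np.random.Generator):
        self.W, self.b = [], []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            self.W.append(ad.parameter((d_in, d_out), rng,
                                       scale=1.0 / np.sqrt(d_in)))
            self.b.append(ad.parameter(np.zeros(d_out)))

    def parameters(self) -> list[Tensor]:
        return self.W + self.b

    def __call__(self, x: Tensor) -> Tensor:
        for k, (W, b) in enumerate(zip(self.W, self.b)):
            x = x @ W + b
            if k < len(self.W) - 1:
                x = x.silu()
        return x


class Gate:
    """Equivariant nonlinearity.

    Input irreps: [scalars | gate scalars (one per l>0 multiplet) | l>0
    blocks].  Scalars pass through SiLU; each l>0 multiplet is multiplied by
    the sigmoid of its gate scalar.
    """

    def __init__(self, irreps_out: Irreps):
        self.irreps_out = irreps_out
        self.n_scalars = irreps_out.num_scalars
        self.n_gates = sum(m for m, l, _ in irreps_out.blocks if l > 0)
        gated = [(m, l, p) for m, l, p in irreps_out.blocks if l > 0]
        self.irreps_pre = Irreps.parse(
            [(self.n_scalars, 0, 1), (self.n_gates, 0, 1)] + gated
            if self.n_gates else [(self.n_scalars, 0, 1)])

    def __call__(self, x: Tensor) -> Tensor:
        s = x[:, :self.n_scalars].silu()
        if self.n_gates == 0:
            return s
        gates = x[:, self.n_scalars:self.n_scalars + self.n_gates].sigmoid()
        pieces = [s]
        off = self.n_scalars + self.n_gates
        goff = 0
        n = x.shape[0]
        for m, l, _ in self.irreps_out.blocks:
            if l == 0:
                continue
            d = 2 * l + 1
            xb = x[:, off:off + m * d].reshape(n, m, d)
            gb = gates[:, goff:goff + m].reshape(n, m, 1)
            pieces.append((xb * gb).reshape(n, m * d))
            off += m * d
            goff += m
        return ad.concatenate(pieces, axis=1)


class EquivariantLayerNorm:
    """Per-irrep normalization preserving directions.

    Scalar channels are standardized (population variance over the scalar
    block); each l>0 block is rescaled by the root-mean-square of its
    multiplet norms.  Learnable per-channel/per-multiplet gains.
    """

    EPS = 1e-12

    def __init__(self, irreps: Irreps):
        self.irreps = irreps
        self.gains: list[Tensor] = [ad.parameter(np.ones(m))
                                    for m, _, _ in irreps.blocks]

    def parameters(self) -> list[Tensor]:
        return self.gains

    def __call__(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        pieces = []
        for sl, (m, l, _), gain in zip(self.irreps.slices(),
                                       self.irreps.blocks, self.gains):
            xb = x[:, sl]
            if l == 0:
                mu = xb.mean(axis=1, keepdims=True)
                centered = xb - mu
                var = (centered * centered).mean(axis=1, keepdims=True)
                out = centered / (var + self.EPS).sqrt() * gain
                pieces.append(out)
            else:
                d = 2 * l + 1
                xb = xb.reshape(n, m, d)
                sq = (xb * xb).sum(axis=2, keepdims=True)  # (n, m, 1)
                rms = (sq.mean(axis=1, keepdims=True) + self.EPS).sqrt()
                out = xb / rms * gain.reshape(1, m, 1)
                pieces.append(out.reshape(n, m * d))
        return ad.concatenate(pieces, axis=1)


class AttentionLayer:
    """One equivariant self-attention layer (query/key/value + update)."""

    def __init__(self, irreps_in: Irreps, irreps_out: Irreps,
                 edge_dim: int, l_max_sh: int, weight_hidden: int,
                 ff_mult: int, rng: np.random.Generator):
        self.irreps_in = irreps_in
        self.irreps_out = irreps_out
        l_out_max = irreps_out.lmax()
        self.tp_k = TensorProduct(irreps_in, l_max_sh, l_out_max)
        self.tp_v = TensorProduct(irreps_in, l_max_sh, l_out_max)
        self.lin_q = Linear(irreps_in, self.tp_k.irreps_out, rng)
        self.lin_v = Linear(self.tp_v.irreps_out, irreps_out, rng)
        self.nn_k = MLP([edge_dim, weight_hidden, self.tp_k.weight_numel], rng)
        self.nn_v = MLP([edge_dim, weight_hidden, self.tp_v.weight_numel], rng)
        # learned weights of the q (x) k -> scalar product, one per
        # (block, u, u') pair of matching irreps
        qk_ir = self.tp_k.irreps_out
        self.dot_w = [ad.parameter((m, m), rng, scale=1.0 / m)
                      for m, _, _ in qk_ir.blocks]
        self._qk_slices = qk_ir.slices()
        self.gate = Gate(_mul_irreps(irreps_out, ff_mult))
        self.lin_ff1 = Linear(irreps_out, self.gate.irreps_pre, rng)
        self.lin_ff2 = Linear(_mul_irreps(irreps_out, ff_mult),
                              irreps_out, rng)
        self.skip = (None if irreps_in == irreps_out
                     else Linear(irreps_in, irreps_out, rng))
        self.norm = EquivariantLayerNorm(irreps_out)

    def parameters(self) -> list[Tensor]:
        mods = [self.lin_q, self.lin_v, self.nn_k, self.nn_v,
                self.lin_ff1, self.lin_ff2, self.norm]
        if self.skip is not None:
            mods.append(self.skip)
        return [p for m in mods for p in m.parameters()] + self.dot_w

    def attention_weights(self, x: Tensor, edge_scalars: Tensor,
                          sh: np.ndarray, edge_src: np.ndarray,
                          edge_dst: np.ndarray) -> Tensor:
        """Softmax attention coefficients alpha_ij over each node's neighbors."""
        q = self.lin_q(x)
        x_src = ad.gather(x, edge_src)
        w_k = self.nn_k(edge_scalars)
        k = self.tp_k(x_src, sh, w_k)
        q_dst = ad.gather(q, edge_dst)
        # summed scalar channel of the weighted product q (x) k: per block,
        # learned mixing over multiplicities of the irrep-wise dot product
        logits = None
        qk_ir = self.tp_k.irreps_out
        scale = 1.0 / np.sqrt(qk_ir.dim)
        for sl, (m, l, _), W in zip(self._qk_slices, qk_ir.blocks,
                                    self.dot_w):
            d = 2 * l + 1
            n_e = k.shape[0]
            qb = q_dst[:, sl].reshape(n_e, m, d)
            kb = k[:, sl].reshape(n_e, m, d)
            term = ad.einsum("uv,num,nvm->n", W, qb, kb) * scale
            logits = term if logits is None else logits + term
        n = x.shape[0]
        # max-subtracted softmax per destination node (max is a constant)
        seg_max = np.full(n, -np.inf)
        np.maximum.at(seg_max, edge_dst, logits.data)
        z = (logits - ad.constant(seg_max[edge_dst])).exp()
        denom = ad.segment_sum(z.reshape(-1, 1), edge_dst, n)
        return z / ad.gather(denom, edge_dst).reshape(-1)

    def __call__(self, x: Tensor, edge_scalars: Tensor, sh: np.ndarray,
                 edge_src: np.ndarray, edge_dst: np.ndarray) -> Tensor:
        n = x.shape[0]
        alpha = self.attention_weights(x, edge_scalars, sh, edge_src, edge_dst)
        x_src = ad.gather(x, edge_src)
        w_v = self.nn_v(edge_scalars)
        v = self.tp_v(x_src, sh, w_v)
        msg = v * alpha.reshape(-1, 1)
        agg = ad.segment_sum(msg, edge_dst, n)  # zero tensor for isolated nodes
        agg = self.lin_v(agg)
        h = self.lin_ff2(self.gate(self.lin_ff1(agg)))
        res = x if self.skip is None else self.skip(x)
        return self.norm(h + res)


def _mul_irreps(irreps: Irreps, mult: int) -> Irreps:
    return Irreps.parse([(m * mult, l, p) for m, l, p in irreps.blocks])


# ---------------------------------------------------------------------------
# full network


class GeqShiftNet:
    """The full network: embeddings, K attention layers, invariant readout."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        half = c.node_emb_dim // 2
        self.emb_z = ad.parameter((c.n_elements, half), rng, scale=1.0)
        self.emb_h = ad.parameter((c.hcount_cap + 1, c.node_emb_dim - half),
                                  rng, scale=1.0)
        self.emb_e = ad.parameter((c.n_bond_categories, c.edge_emb_dim - 1),
                                  rng, scale=1.0)
        hidden = c.hidden_irreps()
        node_irreps = Irreps.parse([(c.node_emb_dim, 0, 1)])
        edge_dim = c.edge_scalar_dim()
        self.layers = []
        irreps_in = node_irreps
        for _ in range(c.n_layers):
            self.layers.append(AttentionLayer(
                irreps_in, hidden, edge_dim, c.l_max_sh,
                c.weight_hidden, c.ff_mult, rng))
            irreps_in = hidden
        self.lin_out = Linear(hidden,
                              Irreps.parse([(c.readout_scalars, 0, 1)]), rng)
        self.head_c13 = MLP([c.readout_scalars, c.readout_hidden, 1], rng)
        self.head_h1 = MLP([c.readout_scalars, c.readout_hidden, 1], rng)

    def parameters(self) -> list[Tensor]:
        params = [self.emb_z, self.emb_h, self.emb_e]
        for layer in self.layers:
            params.extend(layer.parameters())
        params.extend(self.lin_out.parameters())
        params.extend(self.head_c13.parameters())
        params.extend(self.head_h1.parameters())
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- pieces, exposed for tests -----------------------------------------
    def embed_nodes(self, element_idx: np.ndarray,
                    hcount_idx: np.ndarray) -> Tensor:
        c = self.config
        if np.any(element_idx >= c.n_elements) or np.any(element_idx < 0):
            raise ValueError("element index out of vocabulary")
        if np.any(hcount_idx > c.hcount_cap) or np.any(hcount_idx < 0):
            raise ValueError("hcount index out of vocabulary")
        return ad.concatenate([ad.gather(self.emb_z, element_idx),
                               ad.gather(self.emb_h, hcount_idx)], axis=1)

    def embed_edges(self, bond_idx: np.ndarray,
                    distance: np.ndarray) -> Tensor:
        c = self.config
        if np.any(distance <= 0):
            raise ValueError("edge distances must be positive")
        emb = ad.gather(self.emb_e, bond_idx)
        if c.use_rbf:
            centers = np.linspace(0.0, c.rbf_max, c.n_rbf)
            width = c.rbf_max / c.n_rbf
            rbf = np.exp(-((distance[:, None] - centers) / width) ** 2)
            return ad.concatenate([emb, ad.constant(rbf)], axis=1)
        return ad.concatenate([emb, ad.constant(distance[:, None])], axis=1)

    def _edge_sh(self, unit_vec: np.ndarray) -> np.ndarray:
        return np.concatenate([sph_harm(l, unit_vec)
                               for l in range(self.config.l_max_sh + 1)],
                              axis=1)

    def hidden_features(self, sample) -> list[Tensor]:
        """Per-layer node features (for equivariance diagnostics)."""
        x = self.embed_nodes(sample.node_element_idx, sample.node_hcount_idx)
        e = self.embed_edges(sample.edge_bond_idx, sample.edge_distance)
        sh = self._edge_sh(sample.edge_unit_vec)
        feats = []
        for layer in self.layers:
            x = layer(x, e, sh, sample.edge_src, sample.edge_dst)
            feats.append(x)
        return feats

    def forward(self, sample) -> tuple[Tensor, Tensor]:
        """Predict normalized (c13, h1) per node."""
        x = self.embed_nodes(sample.node_element_idx, sample.node_hcount_idx)
        e = self.embed_edges(sample.edge_bond_idx, sample.edge_distance)
        sh = self._edge_sh(sample.edge_unit_vec)
        for layer in self.layers:
            x = layer(x, e, sh, sample.edge_src, sample.edge_dst)
        scalars = self.lin_out(x)
        c13 = self.head_c13(scalars).reshape(-1)
        h1 = self.head_h1(scalars).reshape(-1)
        return c13, h1

    # -- serialization -------------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch when loading state")
        for p, a in zip(params, arrays):
            a = np.asarray(a, dtype=float)
            if a.shape != p.data.shape:
                raise ValueError("parameter shape mismatch when loading state")
            p.data = a.copy()
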