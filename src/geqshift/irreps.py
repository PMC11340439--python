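"""Irreducible-representation algebra for O(3), orders l <= 2.

Features carried by the network are *geometric tensors*: concatenations of
blocks, each block ``mul`` copies of an irrep (l, parity).  This module fixes
the conventions used throughout the package:

* real spherical harmonics with unit L2 norm per l-block on unit input;
* l = 1 components ordered (y, z, x), so that Y1(v) is the permuted vector;
* parity of Y_l is (-1)^l;
* real coupling (Clebsch-Gordan) coefficients normalized to
  ||C||_F = sqrt(2*l3 + 1), constructed numerically as the one-dimensional
  solution space of the rotation-equivariance constraint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["Irreps", "sph_harm", "wigner_d", "rep_matrix", "coupling",
           "allowed_paths"]

_SQRT3 = np.sqrt(3.0)


def sph_harm(l: int, vec: np.ndarray) -> np.ndarray:
    """Real spherical harmonics of unit vectors, one l at a time.

    ``vec`` is (..., 3); output is (..., 2l+1) with unit norm per row for
    unit input.  Conventions: l=1 is (y, z, x); l=2 is
    (sqrt3*xy, sqrt3*yz, (3z^2-1)/2, sqrt3*zx, sqrt3*(x^2-y^2)/2).
    """
    v = np.asarray(vec, dtype=float)
    x, y, z = v[..., 0], v[..., 1], v[..., 2]
    if l == 0:
        return np.ones(v.shape[:-1] + (1,))
    if l == 1:
        return np.stack([y, z, x], axis=-1)
    if l == 2:
        return np.stack([
            _SQRT3 * x * y,
            _SQRT3 * y * z,
            0.5 * (3.0 * z * z - 1.0),
            _SQRT3 * z * x,
            0.5 * _SQRT3 * (x * x - y * y),
        ], axis=-1)
    raise NotImplementedError(f"l={l} not supported (l <= 2)")


# Fixed probe directions for fitting representation matrices; any spanning
# set works, these are well-spread and never degenerate.
_PROBES = np.array([
    [1, 0, 0], [0, 1, 0], [0, 0, 1],
    [1, 1, 0], [0, 1, 1], [1, 0, 1],
    [1, 1, 1], [1, -1, 2], [2, 1, -1],
], dtype=float)
_PROBES /= np.linalg.norm(_PROBES, axis=1, keepdims=True)


def wigner_d(l: int, R: np.ndarray) -> np.ndarray:
    """Representation matrix of an orthogonal R carried by Y_l.

    Satisfies Y_l(R v) = D @ Y_l(v) for all v.  For improper R the parity
    (-1)^l of the harmonics is built in.
    """
    R = np.asarray(R, dtype=float)
    if l == 0:
        return np.ones((1, 1))
    A = sph_harm(l, _PROBES).T            # (2l+1, n_probes)
    B = sph_harm(l, _PROBES @ R.T).T
    D, *_ = np.linalg.lstsq(A.T, B.T, rcond=None)
    return D.T


def rep_matrix(l: int, parity: int, R: np.ndarray) -> np.ndarray:
    """Representation of orthogonal R on an irrep (l, parity).

    ``parity`` is +1 (even) or -1 (odd).  For proper rotations this is the
    Wigner matrix; for improper ones an extra sign parity*(-1)^l corrects
    the harmonic parity baked into :func:`wigner_d`.
    """
    D = wigner_d(l, R)
    if np.linalg.det(R) < 0 and parity * (-1) ** l < 0:
        D = -D
    return D


_coupling_cache: dict[tuple[int, int, int], np.ndarray] = {}


def coupling(l1: int, l2: int, l3: int) -> np.ndarray:
    """Real coupling coefficients C[m3, m1, m2] for l1 x l2 -> l3.

    Unique (up to sign, fixed deterministically) solution of
    D3 C = C (D1 kron D2) over rotations; normalized to
    ||C||_F = sqrt(2*l3+1), so (l, 0) -> l couples with the identity.
    """
    key = (l1, l2, l3)
    if key in _coupling_cache:
        return _coupling_cache[key]
    if not abs(l1 - l2) <= l3 <= l1 + l2:
        raise ValueError(f"triangle rule violated: {key}")
    d1, d2, d3 = 2 * l1 + 1, 2 * l2 + 1, 2 * l3 + 1
    rots = Rotation.random(4, random_state=12345).as_matrix()
    rows = []
    for R in rots:
        D1, D2, D3 = wigner_d(l1, R), wigner_d(l2, R), wigner_d(l3, R)
        E = np.kron(D1, D2)
        # row-major vec of the (d3, d1*d2) matrix C: D3 C - C E = 0
        rows.append(np.kron(D3, np.eye(d1 * d2)) - np.kron(np.eye(d3), E.T))
    A = np.vstack(rows)
    _, s, vt = np.linalg.svd(A)
    if s[-1] > 1e-8:
        raise RuntimeError(f"no equivariant coupling found for {key}")
    if s.size > 1 and s[-2] < 1e-8:
        raise RuntimeError(f"coupling space for {key} is degenerate")
    C = vt[-1].reshape(d3, d1, d2)
    C *= np.sqrt(d3) / np.linalg.norm(C)
    # deterministic sign: first element of magnitude > 0.1 is positive
    flat = C.ravel()
    lead = flat[np.argmax(np.abs(flat) > 0.1)]
    if lead < 0:
        C = -C
    _coupling_cache[key] = C
    return C


@dataclass(frozen=True)
class Irreps:
    """An ordered list of (multiplicity, l, parity) blocks.

    ``parity`` is +1 for even, -1 for odd.  The flat feature dimension is
    sum(mul * (2l+1)).
    """

    blocks: tuple[tuple[int, int, int], ...]

    @staticmethod
    def parse(spec) -> "Irreps":
        """Accept ``"64x0e+32x1o+8x2e"`` or an iterable of triples."""
        if isinstance(spec, Irreps):
            return spec
        if isinstance(spec, str):
            blocks = []
            for part in spec.split("+"):
                mul_s, rest = part.strip().split("x")
                l = int(rest[:-1])
                p = {"e": 1, "o": -1}[rest[-1]]
                blocks.append((int(mul_s), l, p))
            return Irreps(tuple(blocks))
        return Irreps(tuple((int(m), int(l), int(p)) for m, l, p in spec))

    def __str__(self) -> str:
        return "+".join(f"{m}x{l}{'e' if p > 0 else 'o'}"
                        for m, l, p in self.blocks)

    @property
    def dim(self) -> int:
        return sum(m * (2 * l + 1) for m, l, _ in self.blocks)

    @property
    def num_scalars(self) -> int:
        return sum(m for m, l, p in self.blocks if l == 0 and p > 0)

    def slices(self) -> list[slice]:
        out, off = [], 0
        for m, l, _ in self.blocks:
            d = m * (2 * l + 1)
            out.append(slice(off, off + d))
            off += d
        return out

    def rep(self, R: np.ndarray) -> np.ndarray:
        """Block-diagonal representation matrix on the flat feature vector."""
        mats = []
        for m, l, p in self.blocks:
            D = rep_matrix(l, p, R)
            mats.append(np.kron(np.eye(m), D))
        dim = self.dim
        out = np.zeros((dim, dim))
        off = 0
        for M in mats:
            d = M.shape[0]
            out[off:off + d, off:off + d] = M
            off += d
        return out

    def lmax(self) -> int:
        return max(l for _, l, _ in self.blocks)


def sh_irreps(l_max: int) -> Irreps:
    """Irreps layout of the spherical-harmonic edge features, 0e+1o+2e+..."""
    return Irreps(tuple((1, l, (-1) ** l) for l in range(l_max + 1)))


def allowed_paths(irreps_in: Irreps, irreps_sh: Irreps,
                 irreps_out: Irreps) -> list[tuple[int, int, int]]:
    """Tensor-product paths (in-block, sh-block, out-block) allowed by the
    triangle rule and parity selection."""
    paths = []
    for a, (_, l1, p1) in enumerate(irreps_in.blocks):
        for b, (_, l2, p2) in enumerate(irreps_sh.blocks):
            for c, (_, l3, p3) in enumerate(irreps_out.blocks):
                if abs(l1 - l2) <= l3 <= l1 + l2 and p1 * p2 == p3:
                    paths.append((a, b, c))
    return paths
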