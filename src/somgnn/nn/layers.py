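"""The three graph convolutions used for SOM prediction.

All three operate on per-atom feature rows over the molecular graph:

* GIN:   x'_i = MLP((1 + eps) x_i + sum_{j in N(i)} x_j)
* MF:    x'_i = W(deg i) x_i + H(deg i) sum_{j in N(i)} x_j, with
         degree-specific weight matrices (degrees capped at 5 for organics)
* Cheb:  x' = sum_{k=1..K} Z(k) Theta_k with the Chebyshev recurrence
         Z(1) = x, Z(2) = L_bar x, Z(k) = 2 L_bar Z(k-1) - Z(k-2)

where L_bar is the rescaled symmetric normalized Laplacian
L_bar = 2 L_sym / lambda_max - I with lambda_max fixed at 2, i.e.
L_bar = L_sym - I, keeping the spectrum inside [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ..molgraph import FeatureMatrix, MoleculeGraph
from .autograd import (
    Tensor,
    mask_rows,
    neighbor_sum,
    scale_by_scalar,
    sparse_mm,
)

MAX_DEGREE = 5


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


@dataclass
class BatchedGraph:
    """Block-diagonal union of molecule graphs for batched message passing."""

    n_nodes: int
    src: np.ndarray
    dst: np.ndarray
    degrees: np.ndarray
    laplacian: sp.csr_matrix
    node_slices: list[tuple[int, int]]
    bond_endpoints: list[np.ndarray]  # per graph, (|E|, 2) global node ids

    @classmethod
    def from_graphs(cls, graphs: list[MoleculeGraph]) -> "BatchedGraph":
        offsets, n = [], 0
        for g in graphs:
            offsets.append(n)
            n += g.n_atoms
        src, dst = [], []
        bond_endpoints = []
        for g, off in zip(graphs, offsets):
            e = g.edge_index()
            src.append(e[0] + off)
            dst.append(e[1] + off)
            be = np.array([[b.i + off, b.j + off] for b in g.bonds],
                          dtype=np.int64).reshape(-1, 2)
            bond_endpoints.append(be)
        src = np.concatenate(src) if src else np.zeros(0, dtype=np.int64)
        dst = np.concatenate(dst) if dst else np.zeros(0, dtype=np.int64)
        degrees = np.zeros(n, dtype=np.int64)
        np.add.at(degrees, dst, 1)
        lap = scaled_laplacian_from_edges(n, src, dst, degrees)
        slices = [(off, off + g.n_atoms) for g, off in zip(graphs, offsets)]
        return cls(n, src, dst, degrees, lap, slices, bond_endpoints)


def scaled_laplacian_from_edges(
    n: int, src: np.ndarray, dst: np.ndarray, degrees: np.ndarray
) -> sp.csr_matrix:
    """L_bar = L_sym - I on the unweighted adjacency.

    Off-diagonal entries are -1/sqrt(d_i d_j); diagonal entries are 0 for
    connected nodes and -1 for isolated nodes (whose L_sym row is zero).
    """
    dinv = np.zeros(n)
    nz = degrees > 0
    dinv[nz] = 1.0 / np.sqrt(degrees[nz])
    vals = -dinv[src] * dinv[dst]
    A = sp.csr_matrix((vals, (dst, src)), shape=(n, n))
    diag = np.where(degrees > 0, 0.0, -1.0)
    return (A + sp.diags(diag)).tocsr()


def scaled_laplacian(graph: MoleculeGraph) -> sp.csr_matrix:
    """Single-molecule rescaled normalized Laplacian."""
    return BatchedGraph.from_graphs([graph]).laplacian


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass
class MLPParams:
    """Linear layers with ReLU between them (never after the last)."""

    layers: list[tuple[Tensor, Tensor]]  # (W of shape (in, out), b of shape (out,))

    @classmethod
    def create(cls, widths: list[int], rng: np.random.Generator) -> "MLPParams":
        layers = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            layers.append(
                (
                    Tensor(glorot(rng, fan_in, fan_out), requires_grad=True),
                    Tensor(np.zeros(fan_out), requires_grad=True),
                )
            )
        return cls(layers=layers)

    @classmethod
    def identity(cls, width: int) -> "MLPParams":
        return cls(layers=[(Tensor(np.eye(width), requires_grad=True),
                            Tensor(np.zeros(width), requires_grad=True))])

    def apply(self, x: Tensor) -> Tensor:
        for k, (W, b) in enumerate(self.layers):
            x = x @ W + b
            if k < len(self.layers) - 1:
                x = x.relu()
        return x

    @property
    def in_width(self) -> int:
        return self.layers[0][0].shape[0]

    @property
    def out_width(self) -> int:
        return self.layers[-1][0].shape[1]

    def tensors(self) -> list[Tensor]:
        return [t for pair in self.layers for t in pair]


@dataclass
class GINLayerParams:
    epsilon: Tensor
    mlp: MLPParams

    @classmethod
    def create(cls, in_width: int, out_width: int, rng: np.random.Generator,
               mlp_depth: int = 2) -> "GINLayerParams":
        widths = [in_width] + [out_width] * mlp_depth
        return cls(epsilon=Tensor(0.0, requires_grad=True),
                   mlp=MLPParams.create(widths, rng))

    @property
    def in_width(self) -> int:
        return self.mlp.in_width

    @property
    def out_width(self) -> int:
        return self.mlp.out_width

    def apply(self, x: Tensor, batch: BatchedGraph) -> Tensor:
        if x.shape[1] != self.in_width:
            raise ValueError(
                f"feature width {x.shape[1]} != GIN MLP input {self.in_width}")
        one_plus_eps = Tensor(1.0) + self.epsilon
        agg = scale_by_scalar(x, one_plus_eps) + neighbor_sum(x, batch.src, batch.dst)
        return self.mlp.apply(agg)

    def tensors(self) -> list[Tensor]:
        return [self.epsilon] + self.mlp.tensors()


@dataclass
class MFLayerParams:
    """Degree-specific weights; W[d-1]/H[d-1] serve nodes of degree d."""

    W: list[Tensor]
    H: list[Tensor]
    D_max: int

    @classmethod
    def create(cls, in_width: int, out_width: int, D_max: int,
               rng: np.random.Generator) -> "MFLayerParams":
        if not 1 <= D_max <= MAX_DEGREE:
            raise ValueError(f"D_max must be in 1..{MAX_DEGREE}")
        W = [Tensor(glorot(rng, in_width, out_width), requires_grad=True)
             for _ in range(D_max)]
        H = [Tensor(glorot(rng, in_width, out_width), requires_grad=True)
             for _ in range(D_max)]
        return cls(W=W, H=H, D_max=D_max)

    @property
    def in_width(self) -> int:
        return self.W[0].shape[0]

    @property
    def out_width(self) -> int:
        return self.W[0].shape[1]

    def apply(self, x: Tensor, batch: BatchedGraph) -> Tensor:
        if x.shape[1] != self.in_width:
            raise ValueError(
                f"feature width {x.shape[1]} != MF input {self.in_width}")
        too_big = np.nonzero(batch.degrees > self.D_max)[0]
        if len(too_big):
            raise ValueError(
                f"node {int(too_big[0])} has degree "
                f"{int(batch.degrees[too_big[0]])} > D_max={self.D_max}")
        nsum = neighbor_sum(x, batch.src, batch.dst)
        out = None
        # Degree-0 nodes reuse the degree-1 self-weights; their neighbor sum
        # is identically zero so H contributes nothing.
        for d in range(self.D_max + 1):
            mask = batch.degrees == d
            if not mask.any():
                continue
            Wd = self.W[max(d, 1) - 1]
            term = mask_rows(x @ Wd, mask)
            if d > 0:
                term = term + mask_rows(nsum @ self.H[d - 1], mask)
            out = term if out is None else out + term
        return out

    def tensors(self) -> list[Tensor]:
        return list(self.W) + list(self.H)


@dataclass
class ChebLayerParams:
    theta: list[Tensor]  # K matrices of shape (in, out)
    K: int
    laplacian_mode: str = "sym_rescaled_lmax2"

    @classmethod
    def create(cls, in_width: int, out_width: int, K: int,
               rng: np.random.Generator) -> "ChebLayerParams":
        if K < 1:
            raise ValueError("Chebyshev filter size K must be >= 1")
        theta = [Tensor(glorot(rng, in_width, out_width), requires_grad=True)
                 for _ in range(K)]
        return cls(theta=theta, K=K)

    @property
    def in_width(self) -> int:
        return self.theta[0].shape[0]

    @property
    def out_width(self) -> int:
        return self.theta[0].shape[1]

    def apply(self, x: Tensor, batch: BatchedGraph) -> Tensor:
        if x.shape[1] != self.in_width:
            raise ValueError(
                f"feature width {x.shape[1]} != Cheb input {self.in_width}")
        L = batch.laplacian
        Z_prev2 = x
        out = Z_prev2 @ self.theta[0]
        if self.K >= 2:
            Z_prev1 = sparse_mm(L, x)
            out = out + Z_prev1 @ self.theta[1]
            for k in range(2, self.K):
                # Z(k) = 2 L Z(k-1) - Z(k-2)
                Z = sparse_mm(L, Z_prev1) * Tensor(2.0) + Z_prev2 * Tensor(-1.0)
                out = out + Z @ self.theta[k]
                Z_prev2, Z_prev1 = Z_prev1, Z
        return out

    def tensors(self) -> list[Tensor]:
        return list(self.theta)


# ---------------------------------------------------------------------------
# Functional single-graph interfaces


def _prepare(features, graph: MoleculeGraph):
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    return Tensor(x), BatchedGraph.from_graphs([graph])


def gin_conv(params: GINLayerParams, features, graph: MoleculeGraph) -> FeatureMatrix:
    x, batch = _prepare(features, graph)
    return FeatureMatrix(params.apply(x, batch).data)


def mf_conv(params: MFLayerParams, features, graph: MoleculeGraph) -> FeatureMatrix:
    x, batch = _prepare(features, graph)
    return FeatureMatrix(params.apply(x, batch).data)


def cheb_conv(params: ChebLayerParams, features, graph: MoleculeGraph) -> FeatureMatrix:
    x, batch = _prepare(features, graph)
    return FeatureMatrix(params.apply(x, batch).data)
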