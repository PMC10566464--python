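"""Graph network for full spin-system prediction.

Two layer families operate on a featurized molecule:

* message-passing layers update per-vertex states by multiplication with an
  augmented adjacency stack (the five bond-class slices, optional matrix
  powers of the any-bond slice, and an optional identity slice for
  self-loops);
* decode layers alternate GRU updates of the per-vertex state and a dense
  N x N per-edge state (the stacked adjacency + geometric features),
  symmetrizing the edge state after every update.

The final vertex states of the two stacks are concatenated and fed to a set
of B bootstrap heads (one residual block + linear output each) producing
per-nucleus-class shift channels; the final edge state feeds the analogous
coupling heads.  Every shift and coupling output has two data channels
(experimental / ab initio) to support disagreement-regularized training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from ._autodiff import (
    Tensor,
    concat,
    layer_norm,
    relu,
    sigmoid,
    slice_last,
    tanh,
)

SHIFT_CLASSES = ("1H", "13C")
COUPLING_CLASSES = ("1JCH", "2JHH", "3JHH", "4JHH")
N_CHANNELS = 2  # experimental, ab initio


@dataclass
class ModelConfig:
    hidden_dim: int = 64
    n_message_layers: int = 2
    n_decode_layers: int = 2
    adjacency_powers: tuple = (2, 3)
    include_self_loops: bool = True
    aggregation: str = "mean"
    n_bootstraps: int = 10
    p_include: float = 0.5
    shift_classes: tuple = SHIFT_CLASSES
    coupling_classes: tuple = COUPLING_CLASSES
    seed: int = 0
    dtype: str = "float32"
    max_atoms: int = 128

    def __post_init__(self):
        if self.hidden_dim < 1 or self.n_message_layers < 0 or self.n_decode_layers < 0:
            raise ValueError("dimensions must be positive")
        if not set(self.adjacency_powers) <= {1, 2, 3, 4}:
            raise ValueError("adjacency powers must lie in {1, 2, 3, 4}")
        if self.aggregation not in ("mean", "sum", "max"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")

    @property
    def n_adj_slices(self) -> int:
        extra = len([p for p in self.adjacency_powers if p > 1])
        return 5 + extra + (1 if self.include_self_loops else 0)


# ---------------------------------------------------------------------------
# coupling class masks


def coupling_class_masks(mol: Chem.Mol) -> dict:
    """Boolean N x N masks per coupling class.

    1JCH marks bonded C-H pairs; kJHH (k = 2, 3, 4) marks H,H pairs whose
    shortest bond path has length k.  Masks are symmetric, zero-diagonal and
    mutually exclusive for a given pair.
    """
    n = mol.GetNumAtoms()
    dmat = Chem.GetDistanceMatrix(mol)
    sym = [a.GetSymbol() for a in mol.GetAtoms()]
    is_h = np.array([s == "H" for s in sym])
    is_c = np.array([s == "C" for s in sym])
    masks = {c: np.zeros((n, n), dtype=bool) for c in COUPLING_CLASSES}
    ch = (is_c[:, None] & is_h[None, :]) | (is_h[:, None] & is_c[None, :])
    masks["1JCH"] = ch & (dmat == 1)
    hh = is_h[:, None] & is_h[None, :]
    for k, name in ((2, "2JHH"), (3, "3JHH"), (4, "4JHH")):
        masks[name] = hh & (dmat == k)
    return masks


# ---------------------------------------------------------------------------
# parameterized building blocks


class _Module:
    def parameters(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, _Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, _Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out


def _init(rng, shape, fan_in, dtype):
    scale = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(
        rng.uniform(-scale, scale, size=shape).astype(dtype), requires_grad=True
    )


def _mm(x, w):
    """Matrix product with leading axes flattened to one big GEMM."""
    if x.ndim <= 2:
        return x @ w
    lead = x.shape[:-1]
    out = x.reshape(-1, x.shape[-1]) @ w
    return out.reshape(*lead, w.shape[-1])


class Linear(_Module):
    def __init__(self, rng, d_in, d_out, dtype):
        self.w = _init(rng, (d_in, d_out), d_in, dtype)
        self.b = Tensor(np.zeros(d_out, dtype=dtype), requires_grad=True)

    def __call__(self, x):
        return _mm(x, self.w) + self.b


class LayerNorm(_Module):
    def __init__(self, dim, dtype):
        self.gain = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)

    def __call__(self, x):
        return layer_norm(x, self.gain, self.bias)


class GRUCell(_Module):
    """Gated recurrent unit used for both vertex and edge updates.

    Gate projections are fused ([reset | update | candidate] along the last
    axis) so one input matmul and one hidden matmul feed the r/z gates.
    """

    def __init__(self, rng, d_in, d_hidden, dtype):
        self.h = d_hidden
        self.w_all = _init(rng, (d_in, 3 * d_hidden), d_in, dtype)
        self.u_rz = _init(rng, (d_hidden, 2 * d_hidden), d_hidden, dtype)
        self.u_n = _init(rng, (d_hidden, d_hidden), d_hidden, dtype)
        self.b_all = Tensor(np.zeros(3 * d_hidden, dtype=dtype), requires_grad=True)

    def __call__(self, hidden, inp):
        h = self.h
        xp = inp @ self.w_all + self.b_all
        hp = hidden @ self.u_rz
        r = sigmoid(slice_last(xp, 0, h) + slice_last(hp, 0, h))
        z = sigmoid(slice_last(xp, h, 2 * h) + slice_last(hp, h, 2 * h))
        n = tanh(slice_last(xp, 2 * h, 3 * h) + (r * hidden) @ self.u_n)
        return (1.0 - z) * n + z * hidden


class MessagePassingLayer(_Module):
    """Per-slice linear lift of x, multiplication by each augmented
    adjacency slice, linear collection, ReLU and layer normalization."""

    def __init__(self, rng, d_in, d_out, n_slices, dtype):
        self.lifts = [Linear(rng, d_in, d_out, dtype) for _ in range(n_slices)]
        self.collects = [Linear(rng, d_out, d_out, dtype) for _ in range(n_slices)]
        self.norm = LayerNorm(d_out, dtype)

    def __call__(self, x, adj_slices, vmask):
        acc = None
        for a, lift, coll in zip(adj_slices, self.lifts, self.collects):
            term = coll(a @ lift(x))
            acc = term if acc is None else acc + term
        out = self.norm(relu(acc)) * vmask
        return out


class DecodeLayer(_Module):
    """GRU vertex update from aggregated edge state, then GRU edge update
    from broadcast endpoint states, followed by symmetrization and a
    nonlinear + normalization stage on both outputs."""

    def __init__(self, rng, dim, aggregation, dtype):
        self.aggregation = aggregation
        self.vertex_gru = GRUCell(rng, dim, dim, dtype)
        # Edge GRU.  Its input is the linear map of the concatenated
        # endpoint states [x_i | x_j]; composed with the GRU's own (linear)
        # input projection this is one learned map per endpoint and gate,
        # parameterized directly as wi/wj and evaluated per vertex, then
        # broadcast-added over pairs -- the same function family at ~N x
        # less compute than materializing per-pair inputs.
        self.wi = _init(rng, (dim, 3 * dim), dim, dtype)
        self.wj = _init(rng, (dim, 3 * dim), dim, dtype)
        self.be = Tensor(np.zeros(3 * dim, dtype=dtype), requires_grad=True)
        self.u_r = _init(rng, (dim, dim), dim, dtype)
        self.u_z = _init(rng, (dim, dim), dim, dtype)
        self.u_n = _init(rng, (dim, dim), dim, dtype)
        self.vertex_out = Linear(rng, dim, dim, dtype)
        self.edge_out = Linear(rng, dim, dim, dtype)
        self.vertex_norm = LayerNorm(dim, dtype)
        self.edge_norm = LayerNorm(dim, dtype)

    def _aggregate(self, g, vmask, counts):
        # reduce the neighbor (third) axis of (B, N, N, d)
        if self.aggregation == "mean":
            return (g * vmask.reshape(vmask.shape[0], 1, -1, 1)).sum(axis=2) * counts
        if self.aggregation == "sum":
            return (g * vmask.reshape(vmask.shape[0], 1, -1, 1)).sum(axis=2)
        neg = (1.0 - vmask.data.reshape(vmask.shape[0], 1, -1, 1)) * 1e9
        return (g - neg).max(axis=2)

    def __call__(self, x, g, vmask, pmask, counts):
        agg = self._aggregate(g, vmask, counts)
        x_new = self.vertex_gru(x, agg)
        x_new = self.vertex_norm(relu(self.vertex_out(x_new))) * vmask

        b, n, d = x_new.shape
        pi = x_new @ self.wi + self.be  # (B, N, 3d): per-vertex, per-gate
        pj = x_new @ self.wj

        def gate(start):
            gi = slice_last(pi, start, start + d).reshape(b, n, 1, d)
            gj = slice_last(pj, start, start + d).reshape(b, 1, n, d)
            return gi + gj

        r = sigmoid(gate(0) + _mm(g, self.u_r))
        z = sigmoid(gate(d) + _mm(g, self.u_z))
        cand = tanh(gate(2 * d) + _mm(r * g, self.u_n))
        g_new = (1.0 - z) * cand + z * g
        g_new = (g_new + g_new.swapaxes(1, 2)) * 0.5
        g_new = self.edge_norm(relu(self.edge_out(g_new))) * pmask
        return x_new, g_new


class _HeadStack(_Module):
    """All B bootstrap heads evaluated jointly via batched matmuls.

    Each head is a residual block + linear output on the shared final
    representation; the head axis is the leading axis of the stacked
    weights so one batched GEMM evaluates every head.
    """

    def __init__(self, rng, n_heads, d_in, d_out, dtype):
        self.w1 = _init(rng, (n_heads, d_in, d_in), d_in, dtype)
        self.b1 = Tensor(np.zeros((n_heads, 1, d_in), dtype=dtype), requires_grad=True)
        self.w2 = _init(rng, (n_heads, d_in, d_in), d_in, dtype)
        self.b2 = Tensor(np.zeros((n_heads, 1, d_in), dtype=dtype), requires_grad=True)
        self.w_out = _init(rng, (n_heads, d_in, d_out), d_in, dtype)
        self.b_out = Tensor(
            np.zeros((n_heads, 1, d_out), dtype=dtype), requires_grad=True
        )

    def __call__(self, h_flat):
        """h_flat: (1, M, d_in) shared representation; returns (H, M, d_out)."""
        mid = relu(h_flat @ self.w1 + self.b1)
        res = h_flat + (mid @ self.w2 + self.b2)
        return res @ self.w_out + self.b_out


class SpinSystemNetwork(_Module):
    """The full trunk + bootstrap-head network (standardized output space)."""

    def __init__(self, config: ModelConfig, f_v: int, f_e: int):
        rng = np.random.default_rng(config.seed)
        dtype = np.dtype(config.dtype).type
        self.config = config
        d = config.hidden_dim
        s = config.n_adj_slices
        self.vertex_lift = Linear(rng, f_v, d, dtype)
        self.edge_lift = Linear(rng, 5 + f_e, d, dtype)
        self.edge_lift_norm = LayerNorm(d, dtype)
        self.mp_layers = [
            MessagePassingLayer(rng, f_v if i == 0 else d, d, s, dtype)
            for i in range(config.n_message_layers)
        ]
        self.decode_layers = [
            DecodeLayer(rng, d, config.aggregation, dtype)
            for _ in range(config.n_decode_layers)
        ]
        n_shift_out = len(config.shift_classes) * N_CHANNELS
        n_coup_out = len(config.coupling_classes) * N_CHANNELS
        self.shift_heads = _HeadStack(
            rng, config.n_bootstraps, 2 * d, n_shift_out, dtype
        )
        self.coupling_heads = _HeadStack(
            rng, config.n_bootstraps, d, n_coup_out, dtype
        )
        # learned per-class systematic experimental-vs-ab-initio offset
        self.shift_channel_offset = Tensor(
            np.zeros(len(config.shift_classes), dtype=dtype), requires_grad=True
        )
        self.coupling_channel_offset = Tensor(
            np.zeros(len(config.coupling_classes), dtype=dtype),
            requires_grad=True,
        )
        self._dtype = dtype

    # -- forward ------------------------------------------------------------

    def augmented_adjacency(self, g_adj: np.ndarray) -> list:
        """Build the augmented adjacency slice list (constants, no grad):
        the five bond-class slices, requested powers of the any-bond slice,
        and the identity if self-loops are enabled."""
        cfg = self.config
        dtype = self._dtype
        any_bond = g_adj[..., 0]
        slices = [np.ascontiguousarray(g_adj[..., s], dtype=dtype) for s in range(5)]
        power = any_bond
        for p in range(2, max(cfg.adjacency_powers, default=1) + 1):
            power = power @ any_bond
            if p in cfg.adjacency_powers:
                slices.append(power.astype(dtype))
        if cfg.include_self_loops:
            b, n = g_adj.shape[0], g_adj.shape[1]
            eye = np.broadcast_to(np.eye(n, dtype=dtype), (b, n, n)).copy()
            slices.append(eye)
        return [Tensor(s) for s in slices]

    def make_cache(self, x, g_adj, g_feat, atom_mask) -> dict:
        """Precompute the constant (gradient-free) forward inputs for a
        padded batch: dtype-cast feature tensors, masks, neighbor counts
        and the augmented adjacency slices.  Reusable across epochs."""
        cfg = self.config
        dtype = self._dtype
        atom_mask = np.asarray(atom_mask, dtype=bool)
        b, n = atom_mask.shape
        if n > cfg.max_atoms:
            raise ValueError(f"batch atom count {n} exceeds max_atoms")
        pmask_np = (atom_mask[:, :, None] & atom_mask[:, None, :]).astype(dtype)
        g0 = np.concatenate(
            [np.asarray(g_adj, dtype=dtype), np.asarray(g_feat, dtype=dtype)], axis=-1
        )
        return {
            "x": Tensor(np.ascontiguousarray(x, dtype=dtype)),
            "g0": Tensor(g0),
            "adj_slices": self.augmented_adjacency(np.asarray(g_adj)),
            "vmask": Tensor(atom_mask.astype(dtype)[..., None]),
            "pmask": Tensor(pmask_np[..., None]),
            "counts": Tensor(
                (1.0 / np.maximum(atom_mask.sum(axis=1), 1.0))
                .astype(dtype)
                .reshape(b, 1, 1)
            ),
            "shape": (b, n),
            "key": (cfg.dtype, tuple(cfg.adjacency_powers), cfg.include_self_loops),
        }

    def forward(self, x, g_adj, g_feat, atom_mask):
        """Run the trunk and all heads on a padded batch.

        Inputs are arrays: x (B, N, f_v), g_adj (B, N, N, 5),
        g_feat (B, N, N, f_e), atom_mask (B, N) boolean.  Returns Tensors
        shift_out (B_heads, B, N, n_shift_classes, 2) and coupling_out
        (B_heads, B, N, N, n_coupling_classes, 2), symmetric in (i, j).
        """
        return self.forward_cached(self.make_cache(x, g_adj, g_feat, atom_mask))

    def forward_cached(self, cache: dict):
        cfg = self.config
        b, n = cache["shape"]
        x_t, vmask, pmask = cache["x"], cache["vmask"], cache["pmask"]
        counts, adj_slices = cache["counts"], cache["adj_slices"]

        # message-passing stack
        x_mp = x_t
        for layer in self.mp_layers:
            x_mp = layer(x_mp, adj_slices, vmask)
        if not self.mp_layers:
            x_mp = self.vertex_lift(x_t) * vmask

        # decode stack
        g_state = self.edge_lift_norm(relu(self.edge_lift(cache["g0"]))) * pmask
        x_dec = self.vertex_lift(x_t) * vmask
        for layer in self.decode_layers:
            x_dec, g_state = layer(x_dec, g_state, vmask, pmask, counts)

        vertex_rep = concat([x_mp, x_dec], axis=-1)

        nsc, ncc = len(cfg.shift_classes), len(cfg.coupling_classes)
        nb = cfg.n_bootstraps
        d = cfg.hidden_dim
        shift_raw = self.shift_heads(vertex_rep.reshape(1, b * n, 2 * d)).reshape(
            nb, b, n, nsc, N_CHANNELS
        )
        coupling_raw = self.coupling_heads(
            g_state.reshape(1, b * n * n, d)
        ).reshape(nb, b, n, n, ncc, N_CHANNELS)
        return (
            self._compose_channels(shift_raw, self.shift_channel_offset),
            self._compose_channels(coupling_raw, self.coupling_channel_offset),
        )

    @staticmethod
    def _compose_channels(raw, class_offset):
        """Tie the two data channels at the output: the heads emit an
        ab initio level plus a damped per-atom correction, and the
        experimental channel is level + per-class offset + correction.
        Sharing everything but a (mostly systematic) correction is what
        lets the learned experimental/ab-initio difference transfer to
        regions with only ab initio supervision.  Requires the channels to
        share standardization constants (see Standardizer)."""
        delta = slice_last(raw, 0, 1)
        level = slice_last(raw, 1, 2)
        offset = class_offset.reshape(*([1] * (raw.ndim - 2)), -1, 1)
        exp = level + (offset + delta * 0.05)
        return concat([exp, level], axis=-1)  # (exp, ab)

    # -- serialization --------------------------------------------------------

    def state_arrays(self) -> list:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.data = np.asarray(a, dtype=p.data.dtype)
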