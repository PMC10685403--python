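"""Graph-coupled encoder-decoder network for residue-level quality.

The encoder couples three stages.  A graph-transformer attends over all
residue pairs with edge-conditioned multi-head attention and a sigmoid gate
blending the updated and original node embeddings.  An invariant-point-
attention (IPA) stage operates in per-residue rigid frames: attention logits
mix scalar dot products, an edge bias and distances between learned 3-D
points carried by the frames, so scalar outputs are invariant to global pose
while the predicted frames/coordinates move covariantly.  An E(3)-equivariant
GNN then refines coordinates over the K-nearest-neighbour graph, scaling
displacement vectors by rotation-invariant messages.

The decoder tiles node representations into an N x N pair map alongside
encoder edge representations and freshly projected raw features, runs a
residual trunk of dilated 2-D convolutions (dilations 1, 4, 9, 16 cycling;
inverted-bottleneck blocks with GELU), and emits two symmetrized heads: a
5-class distance-error distribution and a 15-A threshold probability per
pair.  Per-residue predicted lDDT aggregates the two heads over the four
lDDT tolerances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, concat, conv2d, layer_norm, log_softmax, softmax, stack
from .errors import ContractError, DegenerateInputError
from .features import FeatureBundle
from .embeddings import EmbeddingBundle

#: lDDT thresholds used by the scoring head.
SCORE_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)
#: (5, 4) cumulative matrix: bin b counts toward threshold s iff b <= s.
CUMULATIVE_BINS = np.triu(np.ones((5, 4)))


# ---------------------------------------------------------------------------
# module plumbing
# ---------------------------------------------------------------------------
class Module:
    """Lightweight parameter container with recursive collection."""

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out[key] = value
            elif isinstance(value, Module):
                out.update(value.parameters(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for k, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.parameters(f"{key}.{k}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out[f"{key}.{k}"] = item
        return out


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, zero: bool = False):
        if zero:
            self.w = Tensor(np.zeros((d_in, d_out)), requires_grad=True)
        else:
            self.w = ad.parameter((d_in, d_out), rng, fan_in=d_in)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, axis=-1)


class MLP(Module):
    def __init__(self, dims: list[int], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for k, layer in enumerate(self.layers):
            x = layer(x)
            if k < len(self.layers) - 1:
                x = x.gelu()
        return x


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
@dataclass
class NetworkConfig:
    """Architecture hyper-parameters (all layer sizes are configurable)."""

    d_node: int = 128
    d_edge: int = 64
    n_heads: int = 8
    head_dim: int = 16
    n_gt_layers: int = 3
    n_ipa_blocks: int = 2
    ipa_points: int = 4
    n_egnn_layers: int = 2
    egnn_hidden: int = 64
    fourier_bands: int = 8
    decoder_channels: int = 64
    decoder_blocks: int = 8
    decoder_expand: int = 4
    mode: str = "single"
    seed: int = 0

    @classmethod
    def toy(cls, seed: int = 0, mode: str = "single") -> "NetworkConfig":
        """Desk-scale configuration used by the training demonstrations."""
        return cls(
            d_node=24, d_edge=16, n_heads=4, head_dim=6,
            n_gt_layers=2, n_ipa_blocks=1, ipa_points=2,
            n_egnn_layers=1, egnn_hidden=24, fourier_bands=6,
            decoder_channels=8, decoder_blocks=3, decoder_expand=4,
            mode=mode, seed=seed,
        )


@dataclass
class EncoderState:
    node_repr: Tensor        # (N, d_node)
    edge_repr: Tensor        # (N, N, d_edge)
    coords: Tensor           # (N, 3) refined CA positions
    frames: Tensor           # (N, 3, 3)


@dataclass
class QAOutput:
    """Network predictions for one model structure."""

    error_probs: np.ndarray      # (N, N, 5), rows sum to 1
    threshold_probs: np.ndarray  # (N, N) in (0, 1)
    pred_local_lddt: np.ndarray  # (N,) in [0, 1]
    pred_global: float
    no_support: np.ndarray       # (N,) True where the threshold head had no mass
    # differentiable counterparts, kept for the loss
    tensors: dict = field(default_factory=dict, repr=False)


# ---------------------------------------------------------------------------
# encoder stages
# ---------------------------------------------------------------------------
class GraphTransformerLayer(Module):
    """Edge-conditioned multi-head attention over all residue pairs."""

    def __init__(self, d_node: int, d_edge: int, n_heads: int, head_dim: int,
                 rng: np.random.Generator):
        self.h, self.hd = n_heads, head_dim
        d_attn = n_heads * head_dim
        self.q = Linear(d_node, d_attn, rng)
        self.k = Linear(d_node, d_attn, rng)
        self.v = Linear(d_node, d_attn, rng)
        self.m = Linear(d_edge, d_attn, rng)   # head-specific edge bias
        self.out = Linear(d_attn, d_node, rng)
        self.gate = Linear(3 * d_node, 1, rng)
        self.norm = LayerNorm(d_node)

    def __call__(self, h: Tensor, e: Tensor, return_attention: bool = False):
        n = h.shape[0]
        H, hd = self.h, self.hd
        q = self.q(h).reshape(n, H, hd)
        k = self.k(h).reshape(n, H, hd)
        v = self.v(h).reshape(n, H, hd)
        m = self.m(e).reshape(n, n, H, hd)

        km = k.reshape(1, n, H, hd) + m
        logits = (q.reshape(n, 1, H, hd) * km).sum(axis=-1) * (1.0 / np.sqrt(hd))
        attn = softmax(logits, axis=1)  # (n, n, H), rows over j

        vals = v.reshape(1, n, H, hd) + m
        mixed = (attn.reshape(n, n, H, 1) * vals).sum(axis=1)  # (n, H, hd)
        h_bar = self.out(mixed.reshape(n, H * hd))

        gate_in = concat([h - h_bar, h, h_bar], axis=-1)
        c1 = self.gate(gate_in).sigmoid()     # (n, 1)
        h_update = c1 * h + (1.0 - c1) * h_bar
        h_update = self.norm(h_update)
        if return_attention:
            return h_update, attn
        return h_update


def _quat_to_rotation(bcd: Tensor) -> Tensor:
    """(N, 3) unconstrained vector -> (N, 3, 3) rotation via (1, b, c, d)."""
    n = bcd.shape[0]
    b, c, d = bcd[:, 0], bcd[:, 1], bcd[:, 2]
    one = Tensor(np.ones(n))
    norm2 = one + b * b + c * c + d * d
    a = one
    rows = [
        a * a + b * b - c * c - d * d, 2 * (b * c - a * d), 2 * (b * d + a * c),
        2 * (b * c + a * d), a * a - b * b + c * c - d * d, 2 * (c * d - a * b),
        2 * (b * d - a * c), 2 * (c * d + a * b), a * a - b * b - c * c + d * d,
    ]
    mat = stack([r / norm2 for r in rows], axis=-1)  # (N, 9)
    return mat.reshape(n, 3, 3)


class IPABlock(Module):
    """Invariant point attention plus a rigid frame update."""

    def __init__(self, d_node: int, d_edge: int, n_heads: int, head_dim: int,
                 n_points: int, rng: np.random.Generator):
        self.h, self.hd, self.p = n_heads, head_dim, n_points
        d_attn = n_heads * head_dim
        d_pt = n_heads * n_points * 3
        self.q = Linear(d_node, d_attn, rng)
        self.k = Linear(d_node, d_attn, rng)
        self.v = Linear(d_node, d_attn, rng)
        self.qp = Linear(d_node, d_pt, rng)
        self.kp = Linear(d_node, d_pt, rng)
        self.vp = Linear(d_node, d_pt, rng)
        self.bias = Linear(d_edge, n_heads, rng)
        self.ev = Linear(d_edge, d_attn, rng)
        self.gamma = Tensor(np.zeros(n_heads), requires_grad=True)
        d_cat = n_heads * (2 * head_dim + 4 * n_points)
        self.out = Linear(d_cat, d_node, rng)
        self.norm = LayerNorm(d_node)
        self.update = Linear(d_node, 6, rng, zero=True)  # translation + quaternion

    def _points_global(self, local: Tensor, rot: Tensor, trans: Tensor) -> Tensor:
        """Map (N, H*P, 3) local points through per-residue frames."""
        n = local.shape[0]
        pts = local.reshape(n, self.h * self.p, 3)
        return pts @ rot.transpose(0, 2, 1) + trans.reshape(n, 1, 3)

    def __call__(self, h: Tensor, e: Tensor, rot: Tensor, trans: Tensor):
        n = h.shape[0]
        H, hd, P = self.h, self.hd, self.p
        q = self.q(h).reshape(n, H, hd)
        k = self.k(h).reshape(n, H, hd)
        v = self.v(h).reshape(n, H, hd)
        gq = self._points_global(self.qp(h), rot, trans).reshape(n, H, P, 3)
        gk = self._points_global(self.kp(h), rot, trans).reshape(n, H, P, 3)
        gv = self._points_global(self.vp(h), rot, trans).reshape(n, H, P, 3)

        scalar = (q.reshape(n, 1, H, hd) * k.reshape(1, n, H, hd)).sum(-1)
        scalar = scalar * (1.0 / np.sqrt(hd))
        bias = self.bias(e)  # (n, n, H)
        diff = gq.reshape(n, 1, H, P, 3) - gk.reshape(1, n, H, P, 3)
        dist2 = (diff * diff).sum(-1).sum(-1)  # (n, n, H)
        head_w = self.gamma.softplus() * np.sqrt(2.0 / (9.0 * P)) * 0.5
        logits = scalar + bias - head_w.reshape(1, 1, H) * dist2
        attn = softmax(logits, axis=1)

        o_scalar = (attn.reshape(n, n, H, 1) * v.reshape(1, n, H, hd)).sum(axis=1)
        ev = self.ev(e).reshape(n, n, H, hd)
        o_edge = (attn.reshape(n, n, H, 1) * ev).sum(axis=1)
        o_pt = (attn.reshape(n, n, H, 1, 1) * gv.reshape(1, n, H, P, 3)).sum(axis=1)
        # back to the local frame of i -> invariant
        local = (o_pt.reshape(n, H * P, 3) - trans.reshape(n, 1, 3)) @ rot
        local = local.reshape(n, H, P, 3)
        norms = ((local * local).sum(-1) + 1e-8).sqrt()  # (n, H, P)

        cat = concat(
            [
                o_scalar.reshape(n, H * hd),
                o_edge.reshape(n, H * hd),
                local.reshape(n, H * P * 3),
                norms.reshape(n, H * P),
            ],
            axis=-1,
        )
        h_new = self.norm(h + self.out(cat))

        upd = self.update(h_new)          # (n, 6)
        u = upd[:, :3]
        rot_upd = _quat_to_rotation(upd[:, 3:])
        new_trans = trans + (u.reshape(n, 1, 3) @ rot.transpose(0, 2, 1)).reshape(n, 3)
        new_rot = rot @ rot_upd
        return h_new, new_rot, new_trans


class EGNNLayer(Module):
    """E(3)-equivariant message passing on the K-NN graph."""

    def __init__(self, d_node: int, d_edge: int, hidden: int, bands: int,
                 rng: np.random.Generator):
        self.bands = bands
        d_in = 2 * d_node + 2 * bands + d_edge
        self.msg = MLP([d_in, hidden, hidden], rng)
        self.coord_w = Linear(hidden, 1, rng, zero=True)
        self.node = MLP([hidden + d_node, hidden, d_node], rng)
        self.norm = LayerNorm(d_node)
        self.freqs = np.pi / 10.0 * (2.0 ** np.arange(bands))

    def __call__(self, v: Tensor, e_knn: Tensor, x: Tensor, knn: np.ndarray):
        n, k = knn.shape
        if n < 2:
            raise DegenerateInputError("EGNN needs at least 2 residues")
        rows = np.repeat(np.arange(n), k)
        cols = knn.ravel()
        xi = x[rows]
        xj = x[cols]
        diff = xi - xj                                  # (n*k, 3)
        dist = ((diff * diff).sum(-1) + 1e-12).sqrt()   # (n*k,)
        phases = dist.reshape(n * k, 1) * Tensor(self.freqs.reshape(1, -1))
        fourier = concat([phases.sin(), phases.cos()], axis=-1)

        vin = concat(
            [v[rows], v[cols], fourier, e_knn.reshape(n * k, -1)], axis=-1
        )
        m = self.msg(vin)                               # (n*k, hidden)
        w = self.coord_w(m)                             # (n*k, 1)
        beta = 1.0 / (n - 1)
        contrib = (diff * w).reshape(n, k, 3).sum(axis=1)
        x_new = x + beta * contrib

        agg = m.reshape(n, k, -1).sum(axis=1)
        v_new = self.norm(v + self.node(concat([agg, v], axis=-1)))
        return v_new, x_new


# ---------------------------------------------------------------------------
# decoder
# ---------------------------------------------------------------------------
class ChannelNorm(Module):
    """Layer norm across the channel axis of a (C, H, W) map."""

    def __init__(self, channels: int):
        self.gamma = Tensor(np.ones((channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((channels, 1, 1)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=0, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=0, keepdims=True)
        return self.gamma * (centered / (var + 1e-5).sqrt()) + self.beta


class DecoderBlock(Module):
    """Inverted-bottleneck residual block with one dilated 3x3 conv."""

    def __init__(self, channels: int, expand: int, dilation: int,
                 rng: np.random.Generator):
        self.dilation = dilation
        wide = channels * expand
        self.norm = ChannelNorm(channels)
        self.up = self._conv(channels, wide, 1, rng)
        self.mid = self._conv(wide, wide, 3, rng)
        self.down = self._conv(wide, channels, 1, rng)

    @staticmethod
    def _conv(ci, co, k, rng):
        w = ad.parameter((co, ci, k, k), rng, fan_in=ci * k * k)
        b = Tensor(np.zeros(co), requires_grad=True)
        return (w, b)

    def __call__(self, x: Tensor) -> Tensor:
        y = self.norm(x)
        y = conv2d(y, *self.up, dilation=1).gelu()
        y = conv2d(y, *self.mid, dilation=self.dilation).gelu()
        y = conv2d(y, *self.down, dilation=1)
        return x + y


class PairDecoder(Module):
    """Residual trunk plus symmetrized error / threshold branch heads."""

    DILATIONS = (1, 4, 9, 16)

    def __init__(self, d_in: int, channels: int, n_blocks: int, expand: int,
                 rng: np.random.Generator):
        self.inp = DecoderBlock._conv(d_in, channels, 1, rng)
        self.blocks = [
            DecoderBlock(channels, expand, self.DILATIONS[i % len(self.DILATIONS)], rng)
            for i in range(n_blocks)
        ]
        self.error_block = DecoderBlock(channels, expand, 1, rng)
        self.error_head = DecoderBlock._conv(channels, 5, 1, rng)
        self.cutoff_block = DecoderBlock(channels, expand, 1, rng)
        self.cutoff_head = DecoderBlock._conv(channels, 1, 1, rng)

    def __call__(self, pair_map: Tensor):
        # pair_map: (N, N, C) -> channel-first
        x = pair_map.transpose(2, 0, 1)
        x = conv2d(x, *self.inp, dilation=1)
        for block in self.blocks:
            x = block(x)
        err = conv2d(self.error_block(x), *self.error_head, dilation=1)
        cut = conv2d(self.cutoff_block(x), *self.cutoff_head, dilation=1)
        err = err.transpose(1, 2, 0)                  # (N, N, 5)
        cut = cut.transpose(1, 2, 0)[:, :, 0]         # (N, N)
        # symmetrize logits so P(i,j) == P(j,i) exactly
        err = 0.5 * (err + err.transpose(1, 0, 2))
        cut = 0.5 * (cut + cut.transpose(1, 0))
        return err, cut


def score_lddt(error_probs, threshold_probs):
    """Aggregate the two heads into per-residue predicted lDDT.

    For each pair and each lDDT tolerance s, the probability that the
    distance error is below s is the cumulative mass of the bins under s,
    weighted by the pair's probability of lying inside the 15-A radius.
    The per-residue score averages over the four tolerances and normalises
    by the threshold mass, giving exactly the lDDT value when fed one-hot
    ground truth.  Works on plain arrays (exact, used for labels and
    reporting) and on autodiff tensors (used in the loss).

    Returns ``(pred_local, no_support)`` where ``no_support`` flags residues
    with zero threshold mass (their score is defined as 0).
    """
    n_thresh = float(len(SCORE_THRESHOLDS))
    if isinstance(error_probs, Tensor) or isinstance(threshold_probs, Tensor):
        cum = error_probs @ Tensor(CUMULATIVE_BINS)          # (N, N, 4)
        t = threshold_probs
        num = (cum * t.reshape(t.shape[0], t.shape[1], 1)).sum(axis=-1).sum(axis=1)
        den = t.sum(axis=1) * n_thresh
        return num / den, np.zeros(error_probs.shape[0], dtype=bool)
    error_probs = np.asarray(error_probs, dtype=float)
    t = np.asarray(threshold_probs, dtype=float)
    cum = error_probs @ CUMULATIVE_BINS
    num = (cum * t[..., None]).sum(axis=(1, 2))
    den = t.sum(axis=1) * n_thresh
    no_support = den == 0
    local = np.zeros(len(den))
    local[~no_support] = num[~no_support] / den[~no_support]
    return np.clip(local, 0.0, 1.0), no_support


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------
class QualityModel(Module):
    """End-to-end model mapping (features, embeddings) to quality scores."""

    def __init__(self, config: NetworkConfig, d_raw_node: int, d_raw_edge: int,
                 d_seq: int, d_struct: int, d_pair: int = 0,
                 feature_layout_hash: str = ""):
        rng = np.random.default_rng(config.seed)
        cfg = config
        self.config = config
        self.feature_layout_hash = feature_layout_hash
        self.dims = {
            "d_raw_node": d_raw_node, "d_raw_edge": d_raw_edge,
            "d_seq": d_seq, "d_struct": d_struct, "d_pair": d_pair,
        }
        self.node_in = Linear(d_raw_node + d_seq + d_struct, cfg.d_node, rng)
        self.node_norm = LayerNorm(cfg.d_node)
        self.edge_in = Linear(d_raw_edge + d_pair, cfg.d_edge, rng)
        self.edge_norm = LayerNorm(cfg.d_edge)
        self.gt_layers = [
            GraphTransformerLayer(cfg.d_node, cfg.d_edge, cfg.n_heads, cfg.head_dim, rng)
            for _ in range(cfg.n_gt_layers)
        ]
        self.ipa_blocks = [
            IPABlock(cfg.d_node, cfg.d_edge, cfg.n_heads, cfg.head_dim,
                     cfg.ipa_points, rng)
            for _ in range(cfg.n_ipa_blocks)
        ]
        self.egnn_layers = [
            EGNNLayer(cfg.d_node, cfg.d_edge, cfg.egnn_hidden, cfg.fourier_bands, rng)
            for _ in range(cfg.n_egnn_layers)
        ]
        # fresh projections of the raw features for the decoder (Eq. 16 style)
        self.star_node = Linear(d_raw_node + d_seq + d_struct, cfg.d_node, rng)
        self.star_edge = Linear(d_raw_edge + d_pair, cfg.d_edge, rng)
        d_pair_map = 2 * cfg.d_node + 2 * cfg.d_edge
        self.decoder = PairDecoder(
            d_pair_map, cfg.decoder_channels, cfg.decoder_blocks,
            cfg.decoder_expand, rng,
        )

    # -- feature plumbing ---------------------------------------------------
    @staticmethod
    def _raw_inputs(bundle: FeatureBundle, emb: EmbeddingBundle):
        # constant leaf tensors; memoized because encoding and pair-map
        # assembly both need them, every optimization step
        cached = getattr(bundle, "_raw_cache", None)
        if cached is not None and cached[0] is emb:
            return cached[1], cached[2]
        node_parts = [bundle.node_features, emb.seq_embedding, emb.struct_embedding]
        raw_node = np.concatenate(node_parts, axis=1)
        if emb.pair_attention is not None:
            raw_edge = np.concatenate([bundle.edge_features, emb.pair_attention], axis=2)
        else:
            raw_edge = bundle.edge_features
        result = (Tensor(raw_node), Tensor(raw_edge))
        bundle._raw_cache = (emb, *result)
        return result

    def encode(self, bundle: FeatureBundle, emb: EmbeddingBundle) -> EncoderState:
        raw_node, raw_edge = self._raw_inputs(bundle, emb)
        h = self.node_norm(self.node_in(raw_node))
        e = self.edge_norm(self.edge_in(raw_edge))
        for layer in self.gt_layers:
            h = layer(h, e)
        rot = Tensor(bundle.frames)
        trans = Tensor(bundle.coords)
        for block in self.ipa_blocks:
            h, rot, trans = block(h, e, rot, trans)
        x = trans
        for layer in self.egnn_layers:
            rows = np.repeat(np.arange(len(bundle.knn_indices)),
                             bundle.knn_indices.shape[1])
            e_knn = e[rows, bundle.knn_indices.ravel()]
            h, x = layer(h, e_knn, x, bundle.knn_indices)
        return EncoderState(node_repr=h, edge_repr=e, coords=x, frames=rot)

    def assemble_pair_map(self, state: EncoderState, bundle: FeatureBundle,
                          emb: EmbeddingBundle) -> Tensor:
        raw_node, raw_edge = self._raw_inputs(bundle, emb)
        n = raw_node.shape[0]
        v_star = self.star_node(raw_node)
        e_star = self.star_edge(raw_edge)
        node_cat = concat([state.node_repr, v_star], axis=-1)      # (N, 2 d_node)
        tiled = node_cat.reshape(n, 1, node_cat.shape[1]) + Tensor(
            np.zeros((1, n, 1))
        )  # horizontal striping: row i carries node i
        return concat([tiled, state.edge_repr, e_star], axis=-1)

    def forward(self, bundle: FeatureBundle, emb: EmbeddingBundle) -> QAOutput:
        state = self.encode(bundle, emb)
        pair_map = self.assemble_pair_map(state, bundle, emb)
        err_logits, cut_logits = self.decoder(pair_map)
        error_probs = softmax(err_logits, axis=-1)
        threshold_probs = cut_logits.sigmoid()
        pred_local_t, _ = score_lddt(error_probs, threshold_probs)
        pred_local, no_support = score_lddt(error_probs.data, threshold_probs.data)
        return QAOutput(
            error_probs=error_probs.data,
            threshold_probs=threshold_probs.data,
            pred_local_lddt=pred_local,
            pred_global=float(pred_local.mean()),
            no_support=no_support,
            tensors={
                "error_logits": err_logits,
                "threshold_logits": cut_logits,
                "pred_local": pred_local_t,
                "coords": state.coords,
                "state": state,
            },
        )

    __call__ = forward

    # -- serialization ------------------------------------------------------
    def save(self, path, config_path) -> None:
        params = self.parameters()
        np.savez_compressed(path, **{k: v.data for k, v in params.items()})
        meta = {
            "network": asdict(self.config),
            "dims": self.dims,
            "feature_layout_hash": self.feature_layout_hash,
        }
        with open(config_path, "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, path, config_path, expected_layout_hash: str | None = None
             ) -> "QualityModel":
        with open(config_path) as fh:
            meta = json.load(fh)
        if expected_layout_hash is not None and (
            meta["feature_layout_hash"] != expected_layout_hash
        ):
            raise ContractError(
                "checkpoint feature layout hash "
                f"{meta['feature_layout_hash']!r} does not match expected "
                f"{expected_layout_hash!r}"
            )
        model = cls(NetworkConfig(**meta["network"]), **meta["dims"],
                    feature_layout_hash=meta["feature_layout_hash"])
        with np.load(path) as data:
            params = model.parameters()
            for key, tensor in params.items():
                tensor.data = np.array(data[key])
        return model

    def set_parameters(self, values: dict[str, np.ndarray]) -> None:
        for key, tensor in self.parameters().items():
            tensor.data = values[key].copy()

    def get_parameters(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}
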