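"""Composite loss and a desk-scale training loop.

The loss sums four terms: a geometric constraint on the encoder's refined
coordinates (coordinate MSE after optimal superposition plus an L1 penalty
on pairwise distances), categorical cross-entropy on the 5-class distance-
error head (masked to pairs within the reference 15-A radius), binary
cross-entropy on the threshold head, and an MSE between predicted and true
per-residue lDDT.  All weights default to 1.

Training follows the protocol of one model per batch with AdamW (lr 1e-3,
multiplicative 0.99 decay per epoch), a 4% validation split, per-epoch
validation Pearson tracking, and retention of the five best parameter sets.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor
from .decoys import DecoyEnsemble
from .embeddings import MockEmbeddingProvider
from .errors import ConfigError, ContractError
from .features import featurize
from .lddt import LDDTLabels
from .network import NetworkConfig, QAOutput, QualityModel, score_lddt
from .structure import BackboneStructure


@dataclass
class LossBreakdown:
    """One training example's loss components (floats) and total (tensor)."""

    l_geometric: float
    l_error_ce: float
    l_threshold_bce: float
    l_lddt_mse: float
    total: Tensor

    @property
    def total_value(self) -> float:
        return float(self.total.data)


@dataclass
class LossWeights:
    geometric: float = 1.0
    error_ce: float = 1.0
    threshold_bce: float = 1.0
    lddt_mse: float = 1.0


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation/translation superposing ``mobile`` onto ``target``."""
    mu_m = mobile.mean(axis=0)
    mu_t = target.mean(axis=0)
    h = (mobile - mu_m).T @ (target - mu_t)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = mu_t - rot @ mu_m
    return rot, trans


def compute_loss(
    qa: QAOutput,
    labels: LDDTLabels,
    reference: BackboneStructure,
    weights: LossWeights | None = None,
) -> LossBreakdown:
    """Differentiable composite loss for one (model, labels) pair.

    The rigid alignment of predicted coordinates is computed outside the
    graph (Kabsch on detached values), so the global pose of the encoder
    output carries no gradient.
    """
    weights = weights or LossWeights()
    n = len(reference)
    coords: Tensor = qa.tensors["coords"]
    if coords.shape != (n, 3):
        raise ContractError("coordinate shape mismatch between output and reference")
    ref_ca = reference.ca

    # geometric term: superposed coordinate MSE + pairwise-distance L1
    rot, trans = kabsch(coords.data, ref_ca)
    aligned = coords @ Tensor(rot.T) + Tensor(trans)
    l_coord = ((aligned - Tensor(ref_ca)) ** 2).mean()
    diff = coords.reshape(n, 1, 3) - coords.reshape(1, n, 3)
    d_pred = ((diff * diff).sum(axis=-1) + 1e-12).sqrt()
    d_ref = np.linalg.norm(ref_ca[:, None] - ref_ca[None, :], axis=-1)
    off = 1.0 - np.eye(n)
    l_dist = ((d_pred - Tensor(d_ref)).abs() * Tensor(off)).sum() * (
        1.0 / off.sum()
    )
    l_geo = l_coord + l_dist

    # error head: masked categorical cross-entropy
    from .autodiff import log_softmax

    err_logits: Tensor = qa.tensors["error_logits"]
    logp = log_softmax(err_logits, axis=-1)
    mask = labels.threshold_mask.astype(bool)
    rows, cols = np.nonzero(mask)
    bins = labels.error_bins[rows, cols]
    picked = logp[rows, cols, bins]
    l_ce = -picked.mean() if len(rows) else Tensor(0.0)

    # threshold head: binary cross-entropy over off-diagonal pairs
    cut_logits: Tensor = qa.tensors["threshold_logits"]
    off = ~np.eye(n, dtype=bool)
    z = cut_logits[off]
    y = labels.threshold_mask[off].astype(float)
    l_bce = (z.softplus() - Tensor(y) * z).mean()

    # predicted-lDDT MSE
    pred_local: Tensor = qa.tensors["pred_local"]
    l_mse = ((pred_local - Tensor(labels.local_lddt)) ** 2).mean()

    total = (
        weights.geometric * l_geo
        + weights.error_ce * l_ce
        + weights.threshold_bce * l_bce
        + weights.lddt_mse * l_mse
    )
    return LossBreakdown(
        l_geometric=float(l_geo.data),
        l_error_ce=float(l_ce.data),
        l_threshold_bce=float(l_bce.data),
        l_lddt_mse=float(l_mse.data),
        total=total,
    )


class AdamW:
    """Decoupled-weight-decay Adam on a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for key, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1**self.t)
            vhat = self.v[key] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data
            )


@dataclass
class TrainingConfig:
    epochs: int = 40
    lr: float = 1e-3
    lr_decay: float = 0.99
    weight_decay: float = 0.01
    val_fraction: float = 0.04
    loss_weights: LossWeights = field(default_factory=LossWeights)
    network: NetworkConfig = field(default_factory=NetworkConfig.toy)
    k_neighbors: int = 30
    seed: int = 0
    keep_best: int = 5

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainResult:
    model: QualityModel
    history: list            # per-epoch dicts
    best_checkpoints: list   # [(val_pearson, params dict)] best first
    val_indices: np.ndarray

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)


def _prepare_example(decoy, labels, provider, k):
    bundle = featurize(decoy, k=k)
    emb = provider.embed(decoy)
    return bundle, emb, labels, decoy


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() < 1e-12 or b.std() < 1e-12:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def train(
    ensembles: list[DecoyEnsemble] | DecoyEnsemble,
    config: TrainingConfig | None = None,
    provider: MockEmbeddingProvider | None = None,
    shuffle_labels: bool = False,
) -> TrainResult:
    """Train a quality model on decoy ensembles.

    ``shuffle_labels=True`` randomly reassigns the label sets across decoys
    (and permutes residues within each), a negative control that destroys
    the structure-quality relationship while preserving the label
    distribution.
    """
    config = config or TrainingConfig()
    if isinstance(ensembles, DecoyEnsemble):
        ensembles = [ensembles]
    items = [
        (decoy, labels, ens.reference)
        for ens in ensembles
        for decoy, labels in zip(ens.decoys, ens.labels)
    ]
    if not items:
        raise ConfigError("empty training dataset")
    rng = np.random.default_rng(config.seed)

    if shuffle_labels:
        order = rng.permutation(len(items))
        new_items = []
        for (decoy, _, ref), src in zip(items, order):
            labels = copy.deepcopy(items[src][1])
            perm = rng.permutation(len(labels.local_lddt))
            labels.local_lddt = labels.local_lddt[perm]
            labels.error_bins = labels.error_bins[np.ix_(perm, perm)]
            labels.threshold_mask = labels.threshold_mask[np.ix_(perm, perm)]
            labels.global_lddt = float(labels.local_lddt.mean())
            new_items.append((decoy, labels, ref))
        items = new_items

    provider = provider or MockEmbeddingProvider(
        mode=config.network.mode, seed=config.seed
    )

    n_total = len(items)
    n_val = max(1, int(round(config.val_fraction * n_total)))
    if n_total < 2:
        raise ConfigError("need at least 2 models for a train/val split")
    perm = rng.permutation(n_total)
    val_idx = np.sort(perm[:n_val])
    train_idx = np.sort(perm[n_val:])

    # featurize once; reused every epoch
    cache = {}
    for i in range(n_total):
        decoy, labels, ref = items[i]
        bundle = featurize(decoy, k=config.k_neighbors)
        emb = provider.embed(decoy)
        cache[i] = (bundle, emb, labels, ref)

    layout_hash = cache[0][0].layout_hash
    b0, e0 = cache[0][0], cache[0][1]
    model = QualityModel(
        config.network,
        d_raw_node=b0.node_features.shape[1],
        d_raw_edge=b0.edge_features.shape[2],
        d_seq=e0.seq_embedding.shape[1],
        d_struct=e0.struct_embedding.shape[1],
        d_pair=0 if e0.pair_attention is None else e0.pair_attention.shape[2],
        feature_layout_hash=layout_hash,
    )
    opt = AdamW(model.parameters(), lr=config.lr,
                weight_decay=config.weight_decay)

    history = []
    best: list[tuple[float, dict]] = []
    for epoch in range(config.epochs):
        opt.lr = config.lr * (config.lr_decay**epoch)
        order = rng.permutation(train_idx)
        sums = np.zeros(5)
        for i in order:
            bundle, emb, labels, ref = cache[i]
            qa = model(bundle, emb)
            loss = compute_loss(qa, labels, ref, config.loss_weights)
            opt.zero_grad()
            loss.total.backward()
            opt.step()
            sums += (
                loss.total_value, loss.l_geometric, loss.l_error_ce,
                loss.l_threshold_bce, loss.l_lddt_mse,
            )
        sums /= len(order)

        preds, truths = [], []
        for i in val_idx:
            bundle, emb, labels, ref = cache[i]
            qa = model(bundle, emb)
            preds.append(qa.pred_local_lddt)
            truths.append(labels.local_lddt)
        val_r = pearson(np.concatenate(preds), np.concatenate(truths))

        history.append({
            "epoch": epoch,
            "lr": opt.lr,
            "train_total": sums[0],
            "train_geometric": sums[1],
            "train_error_ce": sums[2],
            "train_threshold_bce": sums[3],
            "train_lddt_mse": sums[4],
            "val_pearson": val_r,
        })
        best.append((val_r, model.get_parameters()))
        best.sort(key=lambda kv: -kv[0])
        del best[config.keep_best:]

    if best:
        model.set_parameters(best[0][1])
    return TrainResult(
        model=model, history=history, best_checkpoints=best, val_indices=val_idx
    )


def evaluate(model: QualityModel, ensemble: DecoyEnsemble, indices=None,
             provider: MockEmbeddingProvider | None = None,
             k: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Predicted and true per-residue lDDT concatenated over decoys."""
    provider = provider or MockEmbeddingProvider(mode=model.config.mode,
                                                seed=model.config.seed)
    indices = range(len(ensemble)) if indices is None else indices
    preds, truths = [], []
    for i in indices:
        bundle = featurize(ensemble.decoys[i], k=k)
        qa = model(bundle, provider.embed(ensemble.decoys[i]))
        preds.append(qa.pred_local_lddt)
        truths.append(ensemble.labels[i].local_lddt)
    return np.concatenate(preds), np.concatenate(truths)
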