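"""Training loop: Adam with weight decay, per-epoch negative resampling,
fanout-limited subgraph mini-batches, and AUC-based early stopping.

Training negatives are redrawn every epoch from the zero cells of the
association matrix (never colliding with any known positive, including
validation/test positives); validation negatives stay frozen in the split
so the early-stopping signal is stable.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .autodiff import Tensor
from .containers import FeatureBlock, HeteroGraph
from .graph import EdgeSplit, message_adjacency
from .model import EncoderConfig, HybridEncoder, ModelState

__all__ = ["TrainConfig", "TrainReport", "Batch", "Adam", "make_subgraph_batches", "train", "predict_logits"]


@dataclass
class TrainConfig:
    learning_rate: float = 0.0076
    weight_decay: float = 1.75e-5
    max_epochs: int = 150
    patience: int = 20
    batch_size: int = 512
    neighbor_fanout: list[int] | None = None  # None: unlimited fanout
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.max_epochs < 1 or self.patience < 1 or self.batch_size < 1:
            raise ValueError("learning_rate, max_epochs, patience, batch_size must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


@dataclass
class TrainReport:
    train_loss: list[float] = field(default_factory=list)
    valid_auc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False
    n_epochs: int = 0


@dataclass
class Batch:
    nodes: np.ndarray  # sorted global node indices in the subgraph
    sub_adj: np.ndarray
    sub_degrees: np.ndarray  # full-graph degrees of the subgraph nodes
    pairs: np.ndarray  # (k, 2) (mirna_idx, disease_idx) supervision pairs
    labels: np.ndarray
    node_map: dict[int, int]


class Adam:
    """Adam with decoupled-from-nothing classic L2 weight decay on the gradient."""

    def __init__(self, params: dict[str, Tensor], lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.wd:
                g = g + self.wd * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _negative_candidates(split: EdgeSplit, m: int, n: int) -> np.ndarray:
    """Cells that are zero in the original A (complement of all positive sets)."""
    pos = np.zeros((m, n), dtype=bool)
    for arr in (split.train_msg_edges, split.train_sup_edges, split.valid_edges, split.test_edges):
        if len(arr):
            pos[arr[:, 0], arr[:, 1]] = True
    return np.argwhere(~pos)


def _expand_neighborhood(
    msg_adj: np.ndarray,
    seed_nodes: np.ndarray,
    n_hops: int,
    fanout: list[int] | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Seed nodes plus an n_hop neighborhood, fanout-limited per node per hop."""
    nodes = set(seed_nodes.tolist())
    frontier = set(seed_nodes.tolist())
    for hop in range(n_hops):
        nxt: set[int] = set()
        cap = None if fanout is None else fanout[hop]
        for u in sorted(frontier):
            nbrs = np.flatnonzero(msg_adj[u])
            if cap is not None and len(nbrs) > cap:
                nbrs = rng.choice(nbrs, size=cap, replace=False)
            nxt.update(int(v) for v in nbrs)
        frontier = nxt - nodes
        nodes |= nxt
        if not frontier:
            break
    return np.array(sorted(nodes), dtype=int)


def make_subgraph_batches(
    split: EdgeSplit,
    graph: HeteroGraph,
    batch_size: int = 512,
    neighbor_fanout: list[int] | None = None,
    seed: int = 0,
    n_layers: int = 2,
    include_similarity_edges: bool = False,
    msg_adj: np.ndarray | None = None,
) -> list[Batch]:
    """One epoch of supervision mini-batches with sampled neighborhoods.

    Every train supervision edge appears in exactly one batch; the epoch's
    training negatives (``split.n_train_negatives`` of them, redrawn under
    ``seed``) are spread proportionally across batches.  Each batch carries
    the fanout-limited ``n_layers``-hop subgraph needed to embed its
    endpoints, with full-graph degrees for exact GCN normalization.
    """
    if neighbor_fanout is not None and len(neighbor_fanout) != n_layers:
        raise ValueError(f"neighbor_fanout has {len(neighbor_fanout)} entries for {n_layers} layers")
    rng = np.random.default_rng(seed)
    m = graph.n_mirna
    if msg_adj is None:
        msg_adj = message_adjacency(graph, split.train_msg_edges, include_similarity_edges)
    cand = _negative_candidates(split, m, graph.n_disease)
    n_neg = min(split.n_train_negatives, len(cand))
    negs = cand[rng.choice(len(cand), size=n_neg, replace=False)]

    sup = split.train_sup_edges
    order = rng.permutation(len(sup))
    neg_order = rng.permutation(n_neg)
    n_batches = max(1, int(np.ceil(len(sup) / batch_size)))
    pos_chunks = np.array_split(order, n_batches)
    neg_chunks = np.array_split(neg_order, n_batches)

    batches: list[Batch] = []
    for pc, nc in zip(pos_chunks, neg_chunks):
        pairs = np.vstack([sup[pc], negs[nc]]) if len(nc) else sup[pc]
        labels = np.concatenate([np.ones(len(pc)), np.zeros(len(nc))])
        seeds = np.unique(np.concatenate([pairs[:, 0], pairs[:, 1] + m]))
        nodes = _expand_neighborhood(msg_adj, seeds, n_layers, neighbor_fanout, rng)
        node_map = {int(g): i for i, g in enumerate(nodes)}
        batches.append(
            Batch(
                nodes=nodes,
                sub_adj=msg_adj[np.ix_(nodes, nodes)],
                sub_degrees=msg_adj.sum(axis=1)[nodes],
                pairs=pairs,
                labels=labels,
                node_map=node_map,
            )
        )
    return batches


def _subset_features(
    feat_m: np.ndarray, feat_d: np.ndarray, f1: FeatureBlock | None, nodes: np.ndarray, m: int
):
    nm = nodes[nodes < m]
    nd = nodes[nodes >= m] - m
    f1_sub = None
    if f1 is not None:
        f1_sub = FeatureBlock(f1.mirna_features[nm], f1.disease_features[nd], f1.source, f1.d)
    return feat_m[nm], feat_d[nd], f1_sub


def predict_logits(
    encoder: HybridEncoder,
    feat_m: np.ndarray,
    feat_d: np.ndarray,
    adj: np.ndarray,
    f1: FeatureBlock | None,
    pairs: np.ndarray,
) -> np.ndarray:
    """Deterministic eval-mode logits over the full graph."""
    emb = encoder.node_embeddings(feat_m, feat_d, adj, f1, training=False)
    return encoder.pair_logits(emb, pairs, len(feat_m)).data


def train(
    graph: HeteroGraph,
    feat_m: np.ndarray,
    feat_d: np.ndarray,
    f1: FeatureBlock | None,
    split: EdgeSplit,
    enc_cfg: EncoderConfig,
    tr_cfg: TrainConfig,
) -> tuple[ModelState, TrainReport, HybridEncoder]:
    """Adam training with per-epoch batches and validation-AUC early stopping.

    Returns the best-validation-AUC weights, the per-epoch report, and the
    encoder (left loaded with the best weights) for downstream scoring.
    """
    if len(split.valid_edges) == 0:
        raise ValueError("validation set is empty; early stopping needs validation edges")
    m = graph.n_mirna
    mdmf_dim = f1.d if f1 is not None else 0
    encoder = HybridEncoder(enc_cfg, feat_m.shape[1], feat_d.shape[1], mdmf_dim, seed=tr_cfg.seed)
    opt = Adam(encoder.params, tr_cfg.learning_rate, tr_cfg.weight_decay)
    msg_adj = message_adjacency(graph, split.train_msg_edges, enc_cfg.use_similarity_edges)

    val_pairs = np.vstack([split.valid_edges, split.valid_neg_edges])
    val_labels = np.concatenate([np.ones(len(split.valid_edges)), np.zeros(len(split.valid_neg_edges))])

    report = TrainReport()
    best_auc, best_state, since_best = -np.inf, None, 0
    ss = np.random.SeedSequence(tr_cfg.seed)
    epoch_seeds = ss.generate_state(2 * tr_cfg.max_epochs, dtype=np.uint32).astype(np.int64)

    for epoch in range(tr_cfg.max_epochs):
        batches = make_subgraph_batches(
            split,
            graph,
            batch_size=tr_cfg.batch_size,
            neighbor_fanout=tr_cfg.neighbor_fanout,
            seed=int(epoch_seeds[2 * epoch]),
            n_layers=enc_cfg.n_layers,
            include_similarity_edges=enc_cfg.use_similarity_edges,
            msg_adj=msg_adj,
        )
        drop_rng = np.random.default_rng(int(epoch_seeds[2 * epoch + 1]))
        epoch_loss = 0.0
        for batch in batches:
            bm, bd, bf1 = _subset_features(feat_m, feat_d, f1, batch.nodes, m)
            emb = encoder.node_embeddings(
                bm, bd, batch.sub_adj, bf1, training=True, rng=drop_rng, degrees=batch.sub_degrees
            )
            logits = encoder.pair_logits(emb, batch.pairs, m, node_map=batch.node_map)
            loss = encoder.loss(logits, batch.labels)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"training loss diverged at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(batch.labels)
        epoch_loss /= sum(len(b.labels) for b in batches)

        val_logits = predict_logits(encoder, feat_m, feat_d, msg_adj, f1, val_pairs)
        val_auc = float(roc_auc_score(val_labels, val_logits))
        report.train_loss.append(epoch_loss)
        report.valid_auc.append(val_auc)

        if val_auc > best_auc:
            best_auc = val_auc
            best_state = encoder.get_state()
            report.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= tr_cfg.patience:
                report.stopped_early = True
                break

    report.n_epochs = len(report.train_loss)
    assert best_state is not None
    encoder.set_state(best_state)
    return best_state, report, encoder
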