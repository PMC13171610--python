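"""Hybrid graph encoder: GCN branch, GAT branch, residual connections,
weighted fusion of three feature blocks, and two interchangeable
pair classifiers.

The encoder treats miRNA and disease nodes heterogeneously only at the
input: each type gets its own linear projection into a shared hidden
space, after which message passing runs over the single block adjacency.
Three feature blocks are fused into the final node embeddings:

    F1  similarity-regularized matrix-factorization features (MDMF),
        linearly projected;
    F2  output of the GCN branch (symmetric-normalized averaging);
    F3  output of the GAT branch (softmax attention aggregation);

    F = (a1 F1 + a2 F2 + a3 F3) / (a1 + a2 + a3).

Every architectural switch (drop a branch, drop a feature block, drop
similarity edges, drop residuals) is a config field so ablation variants
are plain config edits.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Tensor, bce_with_logits, concat, gather_rows
from .containers import FeatureBlock

__all__ = [
    "EncoderConfig",
    "ModelState",
    "HybridEncoder",
    "gcn_norm",
    "gcn_layer",
    "gat_layer",
    "residual_combine",
    "fuse_features",
    "score_pairs",
    "bce_loss",
]

CLASSIFIERS = ("dot_product", "cosine", "fully_connected")


@dataclass
class EncoderConfig:
    """Architecture hyperparameters (defaults are the tuned configuration)."""

    hidden_dim: int = 117
    n_layers: int = 2
    n_heads: int = 12
    dropout: float = 0.4493
    use_gcn: bool = True
    use_gat: bool = True
    use_residual: bool = True
    use_mdmf_features: bool = True
    use_gip_features: bool = True
    use_similarity_edges: bool = True
    sim_edge_threshold: float = 0.4
    fusion_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    classifier: str = "cosine"
    out_channels: int = 22

    def __post_init__(self) -> None:
        if min(self.hidden_dim, self.n_layers, self.n_heads, self.out_channels) < 1:
            raise ValueError("hidden_dim, n_layers, n_heads, out_channels must be >= 1")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if not (self.use_gcn or self.use_gat):
            raise ValueError("at least one of use_gcn/use_gat must be enabled")
        if not (self.use_mdmf_features or self.use_gip_features):
            raise ValueError("at least one feature block must be enabled")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"classifier must be one of {CLASSIFIERS}")
        if sum(self.fusion_weights) == 0:
            raise ValueError("fusion weights must not all be zero")

    def variant(self, **kwargs) -> "EncoderConfig":
        return replace(self, **kwargs)


@dataclass
class ModelState:
    """All learnable weights plus the config and RNG seed that made them."""

    params: dict[str, np.ndarray]
    config: EncoderConfig
    seed: int
    mdmf_seed: int = 0
    extra: dict = field(default_factory=dict)

    def copy(self) -> "ModelState":
        return ModelState({k: v.copy() for k, v in self.params.items()}, self.config, self.seed, self.mdmf_seed, dict(self.extra))


# ---------------------------------------------------------------------------
# functional layer API (numpy in / numpy out)
# ---------------------------------------------------------------------------

def gcn_norm(adj: np.ndarray, degrees: np.ndarray | None = None) -> np.ndarray:
    """Symmetric GCN normalization D^-1/2 (A + I) D^-1/2.

    ``degrees`` optionally supplies full-graph degrees (before self-loops)
    so a sampled subgraph normalizes exactly like the full graph.
    """
    A_tilde = adj + np.eye(adj.shape[0])
    d = A_tilde.sum(axis=1) if degrees is None else np.asarray(degrees, dtype=float) + 1.0
    d_inv_sqrt = 1.0 / np.sqrt(np.maximum(d, 1e-12))
    return A_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def gcn_layer(H: np.ndarray, adj: np.ndarray, W: np.ndarray, activation: bool = True) -> np.ndarray:
    """One graph-convolution step: ReLU(D^-1/2 (A+I) D^-1/2 H W)."""
    if H.shape[0] != adj.shape[0]:
        raise ValueError("feature rows do not align with graph nodes")
    if H.shape[1] != W.shape[0]:
        raise ValueError("feature/weight dimension mismatch")
    out = gcn_norm(adj) @ H @ W
    return np.maximum(out, 0.0) if activation else out


def _attention_scores(Z: np.ndarray, a_src: np.ndarray, a_dst: np.ndarray, slope: float = 0.2) -> np.ndarray:
    s = Z @ a_src  # (N,)
    t = Z @ a_dst
    E = s[:, None] + t[None, :]
    return np.where(E > 0, E, slope * E)


def gat_layer(
    H: np.ndarray,
    adj: np.ndarray,
    head_params: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    concat_heads: bool = True,
    activation: bool = True,
    return_attention: bool = False,
):
    """One multi-head attention step over the graph (self-loops included).

    ``head_params`` holds (W, a_src, a_dst) per head.  Hidden layers
    concatenate head outputs; the final layer averages them.
    """
    if H.shape[0] != adj.shape[0]:
        raise ValueError("feature rows do not align with graph nodes")
    mask = (adj + np.eye(adj.shape[0])) > 0
    outs, att = [], []
    for W, a_src, a_dst in head_params:
        Z = H @ W
        E = _attention_scores(Z, a_src, a_dst)
        E = np.where(mask, E, -np.inf)
        E = E - E.max(axis=1, keepdims=True)
        ex = np.exp(E)
        alpha = ex / ex.sum(axis=1, keepdims=True)
        outs.append(alpha @ Z)
        att.append(alpha)
    out = np.concatenate(outs, axis=1) if concat_heads else np.mean(outs, axis=0)
    if activation:
        out = np.maximum(out, 0.0)
    return (out, att) if return_attention else out


def residual_combine(H_gcn: np.ndarray, H_in: np.ndarray, Wr: np.ndarray) -> np.ndarray:
    """H_out = H_gcn + H_in Wr (learnable projection of the layer input)."""
    return H_gcn + H_in @ Wr


def fuse_features(
    F1: FeatureBlock | None,
    F2: FeatureBlock | None,
    F3: FeatureBlock | None,
    alphas: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> FeatureBlock:
    """Weighted mean of the available feature blocks (same width required)."""
    blocks = [(a, f) for a, f in zip(alphas, (F1, F2, F3)) if f is not None]
    if not blocks:
        raise ValueError("no feature blocks to fuse")
    total = sum(a for a, _ in blocks)
    if total == 0:
        raise ValueError("fusion weights of available blocks sum to zero")
    d = blocks[0][1].d
    if any(f.d != d for _, f in blocks):
        raise ValueError("feature blocks must share a common width before fusion")
    fm = sum(a * f.mirna_features for a, f in blocks) / total
    fd = sum(a * f.disease_features for a, f in blocks) / total
    return FeatureBlock(fm, fd, "similarity", d)


def score_pairs(
    mirna_emb: np.ndarray,
    disease_emb: np.ndarray,
    pairs: np.ndarray,
    classifier: str = "dot_product",
    W: np.ndarray | None = None,
    b: float = 0.0,
) -> np.ndarray:
    """Logits for (mirna_index, disease_index) pairs."""
    pairs = np.asarray(pairs).reshape(-1, 2)
    zm = mirna_emb[pairs[:, 0]]
    zd = disease_emb[pairs[:, 1]]
    if classifier == "dot_product":
        return (zm * zd).sum(axis=1)
    if classifier == "fully_connected":
        if W is None:
            raise ValueError("fully_connected classifier needs weights")
        return np.concatenate([zm, zd], axis=1) @ W + b
    raise ValueError(f"unknown classifier {classifier!r}")


def bce_loss(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy on logits (stable form)."""
    x = np.asarray(logits, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.size == 0:
        raise ValueError("empty input to bce_loss")
    if x.shape != y.shape:
        raise ValueError("logits/labels length mismatch")
    return float(np.mean(np.maximum(x, 0) - x * y + np.log1p(np.exp(-np.abs(x)))))


# ---------------------------------------------------------------------------
# trainable encoder (autodiff)
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class HybridEncoder:
    """Dense-graph implementation of the hybrid GCN+GAT encoder.

    Built on the package's reverse-mode autodiff; suitable for the graph
    sizes this tool targets (hundreds to a few thousand nodes).
    """

    def __init__(self, cfg: EncoderConfig, in_dim_mirna: int, in_dim_disease: int, mdmf_dim: int, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        h, out = cfg.hidden_dim, cfg.out_channels
        p: dict[str, np.ndarray] = {
            "W_in_m": _glorot(rng, in_dim_mirna, h),
            "W_in_d": _glorot(rng, in_dim_disease, h),
        }
        if cfg.use_gcn:
            for l in range(cfg.n_layers):
                p[f"gcn.W{l}"] = _glorot(rng, h, h)
                if cfg.use_residual:
                    p[f"gcn.Wr{l}"] = _glorot(rng, h, h)
            p["gcn.Wout"] = _glorot(rng, h, out)
        if cfg.use_gat:
            dims = self._gat_dims()
            for l, (din, dh, _) in enumerate(dims):
                for hd in range(cfg.n_heads):
                    p[f"gat.W{l}.{hd}"] = _glorot(rng, din, dh)
                    p[f"gat.asrc{l}.{hd}"] = _glorot(rng, dh, 1)[:, 0]
                    p[f"gat.adst{l}.{hd}"] = _glorot(rng, dh, 1)[:, 0]
                if cfg.use_residual:
                    dout = dims[l][2]
                    p[f"gat.Wr{l}"] = _glorot(rng, din, dout)
            p["gat.Wout"] = _glorot(rng, h, out)
        if cfg.use_mdmf_features:
            p["f1.Wm"] = _glorot(rng, mdmf_dim, out)
            p["f1.Wd"] = _glorot(rng, mdmf_dim, out)
        if cfg.classifier == "fully_connected":
            p["clf.W"] = _glorot(rng, 2 * out, 1)
        if cfg.classifier == "cosine":
            # temperature turns the bounded cosine into a usable logit range
            p["clf.scale"] = np.array([4.0])
        # scalar bias absorbs the class prior so imbalance does not warp the embedding geometry
        p["clf.b"] = np.zeros(1)
        self.params: dict[str, Tensor] = {k: Tensor(v, requires_grad=True, name=k) for k, v in p.items()}

    def _gat_dims(self) -> list[tuple[int, int, int]]:
        """(in_dim, per_head_dim, out_dim) per GAT layer.

        Hidden layers concatenate heads at width hidden // heads; the final
        layer averages full-width heads back to hidden_dim.
        """
        cfg = self.cfg
        dims: list[tuple[int, int, int]] = []
        din = cfg.hidden_dim
        for l in range(cfg.n_layers):
            if l < cfg.n_layers - 1:
                dh = max(1, cfg.hidden_dim // cfg.n_heads)
                dout = dh * cfg.n_heads
            else:
                dh = cfg.hidden_dim
                dout = cfg.hidden_dim
            dims.append((din, dh, dout))
            din = dout
        return dims

    # -- state -----------------------------------------------------------
    def get_state(self) -> ModelState:
        return ModelState({k: t.data.copy() for k, t in self.params.items()}, self.cfg, self.seed)

    def set_state(self, state: ModelState) -> None:
        if set(state.params) != set(self.params):
            raise ValueError("checkpoint parameters do not match encoder architecture")
        for k, t in self.params.items():
            t.data = state.params[k].copy()

    # -- forward ---------------------------------------------------------
    def node_embeddings(
        self,
        feat_m: np.ndarray,
        feat_d: np.ndarray,
        adj: np.ndarray,
        f1: FeatureBlock | None,
        training: bool = False,
        rng: np.random.Generator | None = None,
        degrees: np.ndarray | None = None,
    ) -> Tensor:
        """Fused (N, out_channels) embeddings, miRNA rows first."""
        cfg = self.cfg
        if cfg.use_mdmf_features and f1 is None:
            raise ValueError("config requests MDMF features but none were provided")
        if rng is None:
            rng = np.random.default_rng(0)
        P = self.params
        Hm = Tensor(feat_m) @ P["W_in_m"]
        Hd = Tensor(feat_d) @ P["W_in_d"]
        H0 = concat([Hm, Hd], axis=0)
        H0 = H0.dropout(cfg.dropout, rng, training)
        blocks: list[tuple[float, Tensor]] = []
        a1, a2, a3 = cfg.fusion_weights

        if cfg.use_mdmf_features:
            F1m = Tensor(f1.mirna_features) @ P["f1.Wm"]
            F1d = Tensor(f1.disease_features) @ P["f1.Wd"]
            blocks.append((a1, concat([F1m, F1d], axis=0)))

        if cfg.use_gcn:
            S = Tensor(gcn_norm(adj, degrees))
            H = H0
            for l in range(cfg.n_layers):
                H_new = (S @ H @ P[f"gcn.W{l}"]).relu()
                if cfg.use_residual:
                    H_new = H_new + H @ P[f"gcn.Wr{l}"]
                H = H_new.dropout(cfg.dropout, rng, training)
            blocks.append((a2, H @ P["gcn.Wout"]))

        if cfg.use_gat:
            mask = (adj + np.eye(adj.shape[0])) > 0
            H = H0
            last = cfg.n_layers - 1
            for l in range(cfg.n_layers):
                heads: list[Tensor] = []
                for hd in range(cfg.n_heads):
                    Z = H @ P[f"gat.W{l}.{hd}"]
                    s = Z @ P[f"gat.asrc{l}.{hd}"].reshape_col()  # (N, 1): source term per row i
                    t = (Z @ P[f"gat.adst{l}.{hd}"].reshape_col()).T  # (1, N): target term per col j
                    E = (s + t).leaky_relu(0.2)  # e_ij = LeakyReLU(a_src.z_i + a_dst.z_j)
                    alpha = E.softmax_rows(mask)
                    alpha = alpha.dropout(cfg.dropout, rng, training)
                    heads.append(alpha @ Z)
                if l < last:
                    H_new = concat(heads, axis=1).relu()
                else:
                    acc = heads[0]
                    for extra in heads[1:]:
                        acc = acc + extra
                    H_new = acc / cfg.n_heads
                if cfg.use_residual:
                    H_new = H_new + H @ P[f"gat.Wr{l}"]
                H = H_new.dropout(cfg.dropout, rng, training)
            blocks.append((a3, H @ P["gat.Wout"]))

        total = sum(a for a, _ in blocks)
        fused = blocks[0][1] * (blocks[0][0] / total)
        for a, B in blocks[1:]:
            fused = fused + B * (a / total)
        return fused

    def pair_logits(self, embeddings: Tensor, pairs: np.ndarray, n_mirna: int, node_map: dict[int, int] | None = None) -> Tensor:
        """Score (mirna_idx, disease_idx) pairs from fused node embeddings.

        ``node_map`` remaps global node indices to embedding rows when the
        embeddings come from a subgraph.
        """
        pairs = np.asarray(pairs).reshape(-1, 2)
        gi = pairs[:, 0]
        gj = pairs[:, 1] + n_mirna
        if node_map is not None:
            gi = np.array([node_map[i] for i in gi])
            gj = np.array([node_map[j] for j in gj])
        zm = gather_rows(embeddings, gi)
        zd = gather_rows(embeddings, gj)
        if self.cfg.classifier == "dot_product":
            return (zm * zd).rowsum() + self.params["clf.b"]
        if self.cfg.classifier == "cosine":
            cos = (zm.rownormalize() * zd.rownormalize()).rowsum()
            return cos * self.params["clf.scale"] + self.params["clf.b"]
        cat = concat([zm, zd], axis=1)
        return (cat @ self.params["clf.W"].reshape_col()).rowsum() + self.params["clf.b"]

    def loss(self, logits: Tensor, labels: np.ndarray) -> Tensor:
        return bce_with_logits(logits, labels)
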