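"""End-to-end wiring: similarities -> MDMF -> graph -> training -> scoring.

Every interaction-derived input (GIPK, functional similarity, MDMF
factors) is rebuilt from the training positives of the current split only,
so validation/test edges can never leak into the features.  Sequence and
ontology similarities depend only on sequences and the disease DAG and are
association-independent.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as hio
from .containers import AssociationMatrix, FeatureBlock, HeteroGraph, SimilarityMatrix
from .graph import EdgeSplit, build_hetero_graph, message_adjacency
from .mdmf import FactorModel, fit_mdmf, gip_feature_block, mdmf_features
from .model import EncoderConfig, HybridEncoder, ModelState
from .similarity import (
    dag_semantic_matrix,
    functional_similarity,
    gipk_similarity,
    integrate_disease_similarity,
    integrate_mirna_similarity,
    sequence_similarity_matrix,
)
from .training import TrainConfig, TrainReport, predict_logits, train

log = logging.getLogger("hybridmda")

__all__ = ["RunResult", "train_only_matrix", "build_similarities", "run_split"]


@dataclass
class RunResult:
    """Everything needed to score pairs after one training run."""

    A: AssociationMatrix
    split: EdgeSplit
    graph: HeteroGraph
    feat_m: np.ndarray
    feat_d: np.ndarray
    f1: FeatureBlock | None
    encoder: HybridEncoder
    state: ModelState
    report: TrainReport
    msg_adj: np.ndarray
    factor_model: FactorModel | None

    def logits(self, pairs: np.ndarray) -> np.ndarray:
        return predict_logits(self.encoder, self.feat_m, self.feat_d, self.msg_adj, self.f1, pairs)

    def probabilities(self, pairs: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.logits(pairs)))


def train_only_matrix(A: AssociationMatrix, split: EdgeSplit) -> AssociationMatrix:
    """Copy of A keeping only training-split positives (message + supervision)."""
    values = np.zeros_like(A.values)
    tr = split.train_edges
    values[tr[:, 0], tr[:, 1]] = 1
    out = AssociationMatrix(values, list(A.mirna_ids), list(A.disease_ids))
    # leakage audit: no held-out positive may survive in the training matrix
    for arr in (split.valid_edges, split.test_edges):
        if len(arr) and out.values[arr[:, 0], arr[:, 1]].any():
            raise AssertionError("leakage audit failed: evaluation edge present in training matrix")
    return out


def _content_key(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def build_similarities(
    A_train: AssociationMatrix,
    sequences: dict[str, str] | None = None,
    dag=None,
    kmer_k: int = 4,
    functional_uses_integrated: bool = False,
    cache_dir: str | Path | None = None,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Integrated miRNA and disease similarities from a train-only matrix.

    Disease side: mean of DAG semantic similarity (when a DAG is given)
    and GIPK; GIPK alone otherwise.  miRNA side: mean of sequence
    similarity (when sequences are given), GIPK, and functional similarity
    over the train-associated disease sets; the functional measure scores
    disease pairs with the semantic matrix by default, or the integrated
    disease matrix when ``functional_uses_integrated`` is set.

    ``cache_dir`` enables a content-keyed .npz cache for the O(m^2)
    matrices.
    """
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)
        key = _content_key(A_train.values) + f"-k{kmer_k}-{int(functional_uses_integrated)}-{int(dag is not None)}-{int(sequences is not None)}"
        fm, fd = cache / f"sim-m-{key}.npz", cache / f"sim-d-{key}.npz"
        if fm.exists() and fd.exists():
            return hio.load_similarity_cache(fm), hio.load_similarity_cache(fd)

    d_gipk = gipk_similarity(A_train, "disease")
    if dag is not None:
        d_sem = dag_semantic_matrix(dag, A_train.disease_ids)
        disease_sim = integrate_disease_similarity(d_sem, d_gipk)
    else:
        d_sem = d_gipk
        disease_sim = SimilarityMatrix(d_gipk.values.copy(), list(A_train.disease_ids), "integrated")

    m_gipk = gipk_similarity(A_train, "mirna")
    fun_base = disease_sim if functional_uses_integrated else d_sem
    m_fun = functional_similarity(A_train.disease_sets(), fun_base, A_train.mirna_ids)
    if sequences is not None:
        m_seq = sequence_similarity_matrix(sequences, A_train.mirna_ids, k=kmer_k)
        mirna_sim = integrate_mirna_similarity(m_seq, m_gipk, m_fun)
    else:
        vals = (m_gipk.values + m_fun.values) / 2.0
        mirna_sim = SimilarityMatrix(vals, list(A_train.mirna_ids), "integrated")

    if cache is not None:
        hio.save_similarity_cache(mirna_sim, fm)
        hio.save_similarity_cache(disease_sim, fd)
    return mirna_sim, disease_sim


def run_split(
    A: AssociationMatrix,
    split: EdgeSplit,
    enc_cfg: EncoderConfig,
    tr_cfg: TrainConfig,
    sequences: dict[str, str] | None = None,
    dag=None,
    pca_dim: int = 32,
    latent_dim: int = 42,
    lambda_reg: float = 0.0121,
    mdmf_iters: int = 300,
    cache_dir: str | Path | None = None,
) -> RunResult:
    """Train one model on one split, with train-only feature construction."""
    A_train = train_only_matrix(A, split)
    Sm, Sd = build_similarities(A_train, sequences=sequences, dag=dag, cache_dir=cache_dir)

    f1 = None
    factor_model = None
    if enc_cfg.use_mdmf_features:
        factor_model = fit_mdmf(
            A_train, Sm, Sd, l=latent_dim, lambda_reg=lambda_reg, max_iters=mdmf_iters, seed=tr_cfg.seed
        )
        f1 = mdmf_features(factor_model, pca_dim=pca_dim)

    blocks_m, blocks_d = [], []
    if enc_cfg.use_gip_features:
        gip = gip_feature_block(Sm, Sd, pca_dim=pca_dim)
        blocks_m.append(gip.mirna_features)
        blocks_d.append(gip.disease_features)
    if enc_cfg.use_mdmf_features:
        blocks_m.append(f1.mirna_features)
        blocks_d.append(f1.disease_features)
    feat_m = np.concatenate(blocks_m, axis=1)
    feat_d = np.concatenate(blocks_d, axis=1)

    threshold = enc_cfg.sim_edge_threshold if enc_cfg.use_similarity_edges else None
    graph = build_hetero_graph(A_train, Sm, Sd, sim_edge_threshold=threshold)
    state, report, encoder = train(graph, feat_m, feat_d, f1, split, enc_cfg, tr_cfg)
    msg_adj = message_adjacency(graph, split.train_msg_edges, enc_cfg.use_similarity_edges)
    log.info(
        "run_split mode=%s epochs=%d best_epoch=%d best_val_auc=%.4f",
        split.mode, report.n_epochs, report.best_epoch,
        max(report.valid_auc) if report.valid_auc else float("nan"),
    )
    return RunResult(A, split, graph, feat_m, feat_d, f1, encoder, state, report, msg_adj, factor_model)
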