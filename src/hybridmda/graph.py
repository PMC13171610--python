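"""Heterogeneous graph assembly and leakage-controlled edge splits.

The graph couples the miRNA similarity block SS, the association matrix A
and the disease similarity block DS into one symmetric block adjacency
[[SS, A], [A^T, DS]].  Splits partition the positive association edges into
message-passing / supervision / validation / test sets with negative
sampling from the zero cells; cold modes hold out whole entities so their
edges never appear on the training side.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import AssociationMatrix, HeteroGraph, SimilarityMatrix

__all__ = [
    "EdgeSplit",
    "build_hetero_graph",
    "sample_negatives",
    "split_edges",
    "message_adjacency",
]

SPLIT_MODES = ("random", "cold_disease", "cold_mirna")
NEG_SEMANTICS = ("zero_cells", "positives")


@dataclass
class EdgeSplit:
    """Disjoint positive edge sets plus frozen evaluation negatives.

    All edges are (mirna_index, disease_index) pairs into the association
    matrix whose id registries are carried alongside.  Training negatives
    are *not* stored: they are resampled every epoch at ``neg_train_ratio``;
    validation/test negatives are frozen here so early stopping and the
    reported metrics are stable.
    """

    mode: str
    mirna_ids: list[str]
    disease_ids: list[str]
    train_msg_edges: np.ndarray  # (*, 2) message-passing-only positives
    train_sup_edges: np.ndarray  # (*, 2) supervision-only positives
    valid_edges: np.ndarray
    test_edges: np.ndarray
    valid_neg_edges: np.ndarray
    test_neg_edges: np.ndarray
    neg_train_ratio: float
    neg_eval_ratio: float
    neg_semantics: str
    n_train_negatives: int  # per-epoch training negative sample size
    seed: int
    disjoint_train_ratio: float = 0.3
    cold_fraction: float = 0.15
    held_out_entities: list[str] = field(default_factory=list)

    @property
    def train_edges(self) -> np.ndarray:
        """All training positives (message + supervision)."""
        return np.vstack([self.train_msg_edges, self.train_sup_edges])

    def positive_sets_disjoint(self) -> bool:
        seen: set[tuple[int, int]] = set()
        for arr in (self.train_msg_edges, self.train_sup_edges, self.valid_edges, self.test_edges):
            for e in map(tuple, arr.tolist()):
                if e in seen:
                    return False
                seen.add(e)
        return True

    def to_json(self, path: str | Path) -> None:
        def pairs(arr: np.ndarray) -> list[list[str]]:
            return [[self.mirna_ids[i], self.disease_ids[j]] for i, j in arr.tolist()]

        payload = {
            "mode": self.mode,
            "seed": self.seed,
            "neg_train_ratio": self.neg_train_ratio,
            "neg_eval_ratio": self.neg_eval_ratio,
            "neg_semantics": self.neg_semantics,
            "n_train_negatives": self.n_train_negatives,
            "disjoint_train_ratio": self.disjoint_train_ratio,
            "cold_fraction": self.cold_fraction,
            "held_out_entities": self.held_out_entities,
            "mirna_ids": self.mirna_ids,
            "disease_ids": self.disease_ids,
            "train_msg_edges": pairs(self.train_msg_edges),
            "train_sup_edges": pairs(self.train_sup_edges),
            "valid_edges": pairs(self.valid_edges),
            "test_edges": pairs(self.test_edges),
            "valid_neg_edges": pairs(self.valid_neg_edges),
            "test_neg_edges": pairs(self.test_neg_edges),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "EdgeSplit":
        payload = json.loads(Path(path).read_text())
        midx = {m: i for i, m in enumerate(payload["mirna_ids"])}
        didx = {d: j for j, d in enumerate(payload["disease_ids"])}

        def arr(key: str) -> np.ndarray:
            pairs = payload[key]
            if not pairs:
                return np.empty((0, 2), dtype=int)
            return np.array([[midx[m], didx[d]] for m, d in pairs], dtype=int)

        return cls(
            mode=payload["mode"],
            mirna_ids=payload["mirna_ids"],
            disease_ids=payload["disease_ids"],
            train_msg_edges=arr("train_msg_edges"),
            train_sup_edges=arr("train_sup_edges"),
            valid_edges=arr("valid_edges"),
            test_edges=arr("test_edges"),
            valid_neg_edges=arr("valid_neg_edges"),
            test_neg_edges=arr("test_neg_edges"),
            neg_train_ratio=payload["neg_train_ratio"],
            neg_eval_ratio=payload["neg_eval_ratio"],
            neg_semantics=payload["neg_semantics"],
            n_train_negatives=payload["n_train_negatives"],
            seed=payload["seed"],
            disjoint_train_ratio=payload["disjoint_train_ratio"],
            cold_fraction=payload["cold_fraction"],
            held_out_entities=payload["held_out_entities"],
        )


def build_hetero_graph(
    A: AssociationMatrix,
    mirna_sim: SimilarityMatrix,
    disease_sim: SimilarityMatrix,
    sim_edge_threshold: float | None = None,
) -> HeteroGraph:
    """Assemble the block adjacency [[SS, A], [A^T, DS]].

    When ``sim_edge_threshold`` is set, intra-type pairs whose similarity
    strictly exceeds it become similarity edges; otherwise the edge set
    holds association edges only (the similarity blocks still populate the
    block adjacency either way).
    """
    if mirna_sim.entity_ids != A.mirna_ids:
        raise ValueError("miRNA id registry mismatch between A and miRNA similarity")
    if disease_sim.entity_ids != A.disease_ids:
        raise ValueError("disease id registry mismatch between A and disease similarity")
    m, n = A.shape
    block = np.zeros((m + n, m + n))
    block[:m, :m] = mirna_sim.values
    block[m:, m:] = disease_sim.values
    block[:m, m:] = A.values
    block[m:, :m] = A.values.T
    assoc = A.positive_pairs()

    def thresholded(S: np.ndarray) -> np.ndarray:
        if sim_edge_threshold is None:
            return np.empty((0, 2), dtype=int)
        iu = np.triu_indices(S.shape[0], k=1)
        keep = S[iu] > sim_edge_threshold
        return np.column_stack([iu[0][keep], iu[1][keep]])

    return HeteroGraph(
        mirna_ids=list(A.mirna_ids),
        disease_ids=list(A.disease_ids),
        block_adjacency=block,
        assoc_edges=assoc,
        mirna_sim_edges=thresholded(mirna_sim.values),
        disease_sim_edges=thresholded(disease_sim.values),
    )


def sample_negatives(
    A: AssociationMatrix,
    n_samples: int,
    forbidden: np.ndarray | set | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Uniform sample without replacement from zero cells of A.

    ``forbidden`` removes extra cells (e.g. negatives already frozen for
    evaluation) from the candidate pool.
    """
    zero = np.argwhere(A.values == 0)
    if forbidden is not None:
        forb = {tuple(e) for e in np.asarray(list(forbidden)).reshape(-1, 2).tolist()} if not isinstance(forbidden, set) else forbidden
        if forb:
            mask = np.array([tuple(c) not in forb for c in zero.tolist()])
            zero = zero[mask]
    if n_samples > len(zero):
        raise ValueError(f"requested {n_samples} negatives but only {len(zero)} zero cells available")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(zero), size=n_samples, replace=False)
    return zero[np.sort(pick)]


def _round_sizes(total: int, ratios: tuple[float, float, float]) -> tuple[int, int, int]:
    n_test = int(round(ratios[2] * total))
    n_valid = int(round(ratios[1] * total))
    n_train = total - n_valid - n_test
    return n_train, n_valid, n_test


def split_edges(
    A: AssociationMatrix,
    mode: str = "random",
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    disjoint_train_ratio: float = 0.3,
    neg_train_ratio: float = 0.2,
    neg_eval_ratio: float = 0.1,
    neg_semantics: str = "zero_cells",
    cold_fraction: float = 0.15,
    seed: int = 0,
) -> EdgeSplit:
    """Partition positive edges into message/supervision/valid/test sets.

    random mode partitions edges by ``ratios``; cold modes hold out
    ``cold_fraction`` of diseases (or miRNAs) and send *all* their edges to
    test, carving validation from the remaining edges at the random-split
    proportion.  Within train, ``disjoint_train_ratio`` of edges become
    supervision-only labels and the rest message-passing-only structure.

    Negative counts follow ``neg_semantics``: "zero_cells" reads the ratios
    as fractions of the zero cells of A; "positives" reads them as
    negatives-per-positive multipliers.
    """
    if mode not in SPLIT_MODES:
        raise ValueError(f"mode must be one of {SPLIT_MODES}")
    if neg_semantics not in NEG_SEMANTICS:
        raise ValueError(f"neg_semantics must be one of {NEG_SEMANTICS}")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    pos = A.positive_pairs()
    P = len(pos)
    if P < 4:
        raise ValueError(f"need at least 4 positive edges, have {P}")

    held_out: list[str] = []
    if mode == "random":
        perm = rng.permutation(P)
        n_train, n_valid, n_test = _round_sizes(P, ratios)
        train = pos[perm[:n_train]]
        valid = pos[perm[n_train : n_train + n_valid]]
        test = pos[perm[n_train + n_valid :]]
    else:
        axis = 1 if mode == "cold_disease" else 0
        ids = A.disease_ids if mode == "cold_disease" else A.mirna_ids
        n_entities = len(ids)
        n_hold = max(1, int(round(cold_fraction * n_entities)))
        hold_idx = set(rng.choice(n_entities, size=n_hold, replace=False).tolist())
        held_out = sorted(ids[i] for i in hold_idx)
        in_hold = np.array([e[axis] in hold_idx for e in pos])
        test = pos[in_hold]
        rest = pos[~in_hold]
        if len(rest) < 2 or len(test) == 0:
            raise ValueError(
                f"infeasible {mode} holdout: {len(test)} test edges, {len(rest)} remaining "
                f"from {P} positives over {n_entities} entities"
            )
        valid_frac = ratios[1] / (ratios[0] + ratios[1])
        perm = rng.permutation(len(rest))
        n_valid = int(round(valid_frac * len(rest)))
        valid = rest[perm[:n_valid]]
        train = rest[perm[n_valid:]]

    if len(train) == 0:
        raise ValueError("split left zero training edges")

    n_sup = int(round(disjoint_train_ratio * len(train)))
    perm_t = rng.permutation(len(train))
    sup = train[perm_t[:n_sup]]
    msg = train[perm_t[n_sup:]]

    n_zero = A.n_zero_cells()
    if neg_semantics == "zero_cells":
        n_eval_neg = int(round(neg_eval_ratio * n_zero))
        n_train_neg = int(round(neg_train_ratio * n_zero))
    else:
        n_eval_neg = int(round(neg_eval_ratio * P))
        n_train_neg = int(round(neg_train_ratio * len(train)))
    n_eval_neg = max(1, n_eval_neg)
    n_train_neg = max(1, n_train_neg)
    # one draw, then split, so valid and test negatives never overlap
    eval_neg = sample_negatives(A, min(2 * n_eval_neg, n_zero), seed=int(rng.integers(2**31)))
    perm_n = rng.permutation(len(eval_neg))
    valid_neg = eval_neg[perm_n[: len(eval_neg) // 2]]
    test_neg = eval_neg[perm_n[len(eval_neg) // 2 :]]

    return EdgeSplit(
        mode=mode,
        mirna_ids=list(A.mirna_ids),
        disease_ids=list(A.disease_ids),
        train_msg_edges=msg,
        train_sup_edges=sup,
        valid_edges=valid,
        test_edges=test,
        valid_neg_edges=valid_neg,
        test_neg_edges=test_neg,
        neg_train_ratio=neg_train_ratio,
        neg_eval_ratio=neg_eval_ratio,
        neg_semantics=neg_semantics,
        n_train_negatives=n_train_neg,
        seed=seed,
        disjoint_train_ratio=disjoint_train_ratio,
        cold_fraction=cold_fraction,
        held_out_entities=held_out,
    )


def split_from_test_edges(
    A: AssociationMatrix,
    test_edges: np.ndarray,
    mode: str = "random",
    valid_frac: float = 0.125,
    disjoint_train_ratio: float = 0.3,
    neg_train_ratio: float = 0.2,
    neg_eval_ratio: float = 0.1,
    neg_semantics: str = "zero_cells",
    seed: int = 0,
    held_out_entities: list[str] | None = None,
) -> EdgeSplit:
    """Build an EdgeSplit around a predetermined test-edge set (CV folds).

    Validation takes ``valid_frac`` of the non-test positives; the rest is
    train, divided into supervision/message parts by
    ``disjoint_train_ratio``.  Negative handling matches ``split_edges``.
    """
    rng = np.random.default_rng(seed)
    test_set = {tuple(e) for e in np.asarray(test_edges).reshape(-1, 2).tolist()}
    pos = A.positive_pairs()
    rest = np.array([e for e in pos.tolist() if tuple(e) not in test_set], dtype=int)
    if len(rest) < 2:
        raise ValueError("fold leaves fewer than 2 non-test positives")
    perm = rng.permutation(len(rest))
    n_valid = max(1, int(round(valid_frac * len(rest))))
    valid = rest[perm[:n_valid]]
    train = rest[perm[n_valid:]]
    n_sup = int(round(disjoint_train_ratio * len(train)))
    perm_t = rng.permutation(len(train))
    sup = train[perm_t[:n_sup]]
    msg = train[perm_t[n_sup:]]

    n_zero = A.n_zero_cells()
    P = len(pos)
    if neg_semantics == "zero_cells":
        n_eval_neg = int(round(neg_eval_ratio * n_zero))
        n_train_neg = int(round(neg_train_ratio * n_zero))
    else:
        n_eval_neg = int(round(neg_eval_ratio * P))
        n_train_neg = int(round(neg_train_ratio * len(train)))
    n_eval_neg = max(1, n_eval_neg)
    eval_neg = sample_negatives(A, min(2 * n_eval_neg, n_zero), seed=int(rng.integers(2**31)))
    perm_n = rng.permutation(len(eval_neg))
    valid_neg = eval_neg[perm_n[: len(eval_neg) // 2]]
    test_neg = eval_neg[perm_n[len(eval_neg) // 2 :]]
    return EdgeSplit(
        mode=mode,
        mirna_ids=list(A.mirna_ids),
        disease_ids=list(A.disease_ids),
        train_msg_edges=msg,
        train_sup_edges=sup,
        valid_edges=valid,
        test_edges=np.asarray(test_edges).reshape(-1, 2),
        valid_neg_edges=valid_neg,
        test_neg_edges=test_neg,
        neg_train_ratio=neg_train_ratio,
        neg_eval_ratio=neg_eval_ratio,
        neg_semantics=neg_semantics,
        n_train_negatives=max(1, n_train_neg),
        seed=seed,
        disjoint_train_ratio=disjoint_train_ratio,
        held_out_entities=held_out_entities or [],
    )


def message_adjacency(
    graph: HeteroGraph,
    msg_edges: np.ndarray,
    include_similarity_edges: bool = False,
) -> np.ndarray:
    """Weighted symmetric (m+n) x (m+n) adjacency for message passing.

    Only the given association edges (weight 1) plus, optionally, the
    thresholded similarity edges (weighted by their similarity value, per
    the weighted heterogeneous block matrix) carry messages; supervision,
    validation and test edges stay invisible to the encoder.
    """
    m = graph.n_mirna
    N = graph.n_nodes
    adj = np.zeros((N, N))
    for i, j in np.asarray(msg_edges).reshape(-1, 2):
        adj[i, m + j] = adj[m + j, i] = 1.0
    if include_similarity_edges:
        SS = graph.block_adjacency[:m, :m]
        DS = graph.block_adjacency[m:, m:]
        for a, b in graph.mirna_sim_edges:
            adj[a, b] = adj[b, a] = SS[a, b]
        for a, b in graph.disease_sim_edges:
            adj[m + a, m + b] = adj[m + b, m + a] = DS[a, b]
    return adj
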