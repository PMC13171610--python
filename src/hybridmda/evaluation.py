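"""Metrics, k-fold cross-validation, ablation runner, per-category
stratification, and per-disease candidate ranking.

AUC-ROC is the Mann-Whitney rank statistic (ties averaged) and AUPRC the
step-integrated precision-recall area, both via scikit-learn; confusion
metrics use a probability threshold of 0.5 unless configured otherwise.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .containers import AssociationMatrix
from .graph import split_from_test_edges
from .model import EncoderConfig
from .pipeline import RunResult, run_split
from .training import TrainConfig

log = logging.getLogger("hybridmda")

__all__ = [
    "MetricSet",
    "CVResult",
    "compute_metrics",
    "evaluate_on_test",
    "cross_validate",
    "ablation_variants",
    "run_ablation",
    "stratified_eval",
    "rank_candidates",
]

METRIC_NAMES = ("acc", "pre", "rec", "f1", "auc_roc", "auprc")


@dataclass
class MetricSet:
    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    pre: float
    rec: float
    f1: float
    auc_roc: float
    auprc: float
    threshold: float = 0.5
    auc_defined: bool = True

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_NAMES}


@dataclass
class CVResult:
    folds: list[MetricSet]
    mode: str
    seeds: list[int]
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in METRIC_NAMES:
            vals = np.array([getattr(f, name) for f in self.folds], dtype=float)
            self.mean[name] = float(np.nanmean(vals))
            self.sd[name] = float(np.nanstd(vals))


def compute_metrics(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> MetricSet:
    """Confusion counts at ``threshold`` plus ranking metrics.

    ``scores`` may be probabilities or any monotone score; the threshold
    applies to the scores as given.  Single-class labels leave AUC/AUPRC
    undefined (NaN, flagged) while the threshold metrics are still
    returned.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores/labels length mismatch")
    pred = scores >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    tn = int(np.sum(~pred & ~pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    total = tp + tn + fp + fn
    acc = (tp + tn) / total if total else float("nan")
    pre = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * pre * rec / (pre + rec) if pre + rec else 0.0
    both = 0 < pos.sum() < len(labels)
    if both:
        auc = float(roc_auc_score(labels, scores))
        ap = float(average_precision_score(labels, scores))
    else:
        log.warning("compute_metrics single_class=true n=%d; AUC/AUPRC undefined", len(labels))
        auc = ap = float("nan")
    return MetricSet(tp, tn, fp, fn, acc, pre, rec, f1, auc, ap, threshold, auc_defined=both)


def evaluate_on_test(result: RunResult, threshold: float = 0.5) -> MetricSet:
    """Metrics on the split's test positives plus frozen test negatives."""
    split = result.split
    pairs = np.vstack([split.test_edges, split.test_neg_edges])
    labels = np.concatenate([np.ones(len(split.test_edges)), np.zeros(len(split.test_neg_edges))])
    probs = result.probabilities(pairs)
    return compute_metrics(probs, labels.astype(int), threshold)


def _fold_test_sets(A: AssociationMatrix, k: int, mode: str, rng: np.random.Generator) -> list[np.ndarray]:
    """k disjoint test-edge sets covering all positives (entity-level for cold)."""
    pos = A.positive_pairs()
    if mode == "random":
        perm = rng.permutation(len(pos))
        return [pos[idx] for idx in np.array_split(perm, k)]
    axis = 1 if mode == "cold_disease" else 0
    n_entities = A.shape[axis]
    perm = rng.permutation(n_entities)
    groups = np.array_split(perm, k)
    folds = []
    for g in groups:
        gset = set(g.tolist())
        folds.append(pos[np.array([e[axis] in gset for e in pos])])
    return folds


def cross_validate(
    A: AssociationMatrix,
    enc_cfg: EncoderConfig,
    tr_cfg: TrainConfig,
    k: int = 5,
    mode: str = "random",
    seed: int = 0,
    sequences: dict[str, str] | None = None,
    dag=None,
    max_retries: int = 5,
    **pipeline_kwargs,
) -> CVResult:
    """k-fold CV with per-fold rebuilding of interaction-derived features.

    Cold modes partition entities, so each disease's (or miRNA's) edges
    appear in exactly one test fold; a partition leaving an infeasible fold
    is redrawn up to ``max_retries`` times before rejection.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        folds = _fold_test_sets(A, k, mode, rng)
        if all(0 < len(f) < len(A.positive_pairs()) - 1 for f in folds):
            break
        log.warning("cross_validate redraw attempt=%d mode=%s", attempt + 1, mode)
    else:
        raise ValueError(f"could not draw a feasible {k}-fold {mode} partition in {max_retries} tries")

    results: list[MetricSet] = []
    fold_seeds: list[int] = []
    for fold_i, test_edges in enumerate(folds):
        fold_seed = int(rng.integers(2**31))
        fold_seeds.append(fold_seed)
        split = split_from_test_edges(A, test_edges, mode=mode, seed=fold_seed)
        fold_tr = TrainConfig(**{**tr_cfg.__dict__, "seed": fold_seed})
        res = run_split(A, split, enc_cfg, fold_tr, sequences=sequences, dag=dag, **pipeline_kwargs)
        ms = evaluate_on_test(res)
        log.info("cv fold=%d mode=%s auc=%.4f auprc=%.4f", fold_i, mode, ms.auc_roc, ms.auprc)
        results.append(ms)
    return CVResult(results, mode, fold_seeds)


def ablation_variants(base: EncoderConfig | None = None) -> dict[str, EncoderConfig]:
    """The seven standard architecture variants, as config edits of FULL."""
    full = base or EncoderConfig()
    return {
        "FULL": full,
        "GAT-Only": full.variant(use_gcn=False),
        "Only-MDMF": full.variant(use_gip_features=False),
        "GCN-Only": full.variant(use_gat=False),
        "No-MDMF": full.variant(use_mdmf_features=False),
        "Baseline-GCN": full.variant(use_gat=False, use_mdmf_features=False, use_similarity_edges=False),
        "Baseline-GAT": full.variant(use_gcn=False, use_mdmf_features=False, use_similarity_edges=False),
    }


def run_ablation(
    A: AssociationMatrix,
    variants: dict[str, EncoderConfig],
    tr_cfg: TrainConfig,
    split=None,
    seed: int = 0,
    sequences: dict[str, str] | None = None,
    dag=None,
    **pipeline_kwargs,
) -> dict[str, MetricSet]:
    """Run each variant on the identical split and seed; ranked output."""
    from .graph import split_edges

    if split is None:
        split = split_edges(A, mode="random", seed=seed)
    out: dict[str, MetricSet] = {}
    for name, cfg in variants.items():
        res = run_split(A, split, cfg, tr_cfg, sequences=sequences, dag=dag, **pipeline_kwargs)
        out[name] = evaluate_on_test(res)
        log.info("ablation variant=%s auc=%.4f", name, out[name].auc_roc)
    return dict(sorted(out.items(), key=lambda kv: -np.nan_to_num(kv[1].auc_roc)))


def stratified_eval(
    scores: np.ndarray,
    labels: np.ndarray,
    pair_diseases: list[str],
    category_map: dict[str, str],
) -> dict[str, float]:
    """Per-disease-category AUC over test pairs.

    Unmapped diseases fall into "Other"; a category whose labels are
    single-class is flagged and excluded from the table.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    cats = np.array([category_map.get(d, "Other") for d in pair_diseases])
    out: dict[str, float] = {}
    for cat in sorted(set(cats)):
        mask = cats == cat
        sub_l = labels[mask]
        if len(np.unique(sub_l)) < 2:
            log.warning("stratified_eval category=%s single_class=true excluded", cat)
            continue
        out[cat] = float(roc_auc_score(sub_l, scores[mask]))
    return out


def rank_candidates(
    result: RunResult,
    disease_id: str,
    k: int = 10,
    exclude_known: bool = True,
) -> list[tuple[str, float]]:
    """Top-k miRNAs for one disease by predicted probability.

    ``exclude_known`` masks miRNAs whose association with the disease is a
    training positive.  Ties break lexicographically by miRNA id so the
    ranking is deterministic.
    """
    didx = result.A.disease_index()
    if disease_id not in didx:
        raise KeyError(f"unknown disease id {disease_id!r}")
    j = didx[disease_id]
    m = len(result.A.mirna_ids)
    pairs = np.column_stack([np.arange(m), np.full(m, j)])
    probs = result.probabilities(pairs)
    known = set()
    if exclude_known:
        tr = result.split.train_edges
        known = {int(i) for i, jj in tr.tolist() if jj == j}
    scored = [
        (result.A.mirna_ids[i], float(probs[i]))
        for i in range(m)
        if i not in known
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[:k]
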