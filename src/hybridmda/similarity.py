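"""Multi-source similarity construction.

Three miRNA measures — k-mer sequence similarity, Gaussian interaction
profile kernel (GIPK) similarity, and functional similarity over shared
disease sets (best-match averaging) — and two disease measures — Wang-style
ontology semantic similarity and GIPK — plus their averaged integrations.

The GIPK between two entities compares their binary interaction profiles
(rows or columns of the association matrix) under an RBF kernel whose
bandwidth is set from the mean squared profile norm, so that densely
annotated datasets and sparse ones land on comparable similarity scales.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .containers import AssociationMatrix, DiseaseDAG, SimilarityMatrix

__all__ = [
    "SequenceFeatureVector",
    "GipkBandwidth",
    "kmer_profile",
    "sequence_similarity",
    "sequence_similarity_matrix",
    "gipk_bandwidth",
    "gipk_similarity",
    "dag_semantic_contribution",
    "dag_semantic_similarity",
    "dag_semantic_matrix",
    "functional_similarity",
    "integrate_mirna_similarity",
    "integrate_disease_similarity",
]

_BASES = "ACGT"


@dataclass
class SequenceFeatureVector:
    """k-mer count vector over the lexicographic {A,C,G,T} alphabet."""

    entity_id: str
    counts: np.ndarray
    k: int


@dataclass
class GipkBandwidth:
    axis: str  # {"mirna", "disease"}
    lambda_value: float


def _kmer_index(kmer: str) -> int:
    idx = 0
    for c in kmer:
        idx = idx * 4 + _BASES.index(c)
    return idx


def kmer_profile(sequence: str, k: int = 4, entity_id: str = "") -> SequenceFeatureVector:
    """Count the k-mers of a nucleotide sequence.

    U and T are treated as the same base so RNA and DNA inputs behave
    identically.  A sequence shorter than ``k`` yields an all-zero vector
    (with a warning); characters outside {A,C,G,T,U} are rejected with
    their position.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = sequence.upper().replace("U", "T")
    for pos, c in enumerate(seq):
        if c not in _BASES:
            raise ValueError(f"non-IUPAC nucleotide {sequence[pos]!r} at position {pos}")
    counts = np.zeros(4 ** k, dtype=np.int64)
    if len(seq) < k:
        warnings.warn(
            f"sequence {entity_id or sequence!r} shorter than k={k}; zero profile",
            stacklevel=2,
        )
        return SequenceFeatureVector(entity_id, counts, k)
    for i in range(len(seq) - k + 1):
        counts[_kmer_index(seq[i : i + k])] += 1
    return SequenceFeatureVector(entity_id, counts, k)


def sequence_similarity(si: SequenceFeatureVector, sj: SequenceFeatureVector) -> float:
    """Tanimoto-style similarity <si,sj> / (|si|^2 + |sj|^2 - <si,sj>).

    Equals 1 iff the count vectors are identical (and nonzero); two all-zero
    vectors are defined to have similarity 0 (no evidence of similarity).
    """
    if si.k != sj.k:
        raise ValueError("k-mer profiles computed with different k")
    a = si.counts.astype(float)
    b = sj.counts.astype(float)
    dot = float(a @ b)
    denom = float(a @ a) + float(b @ b) - dot
    if denom == 0.0:
        return 0.0
    return dot / denom


def sequence_similarity_matrix(
    sequences: dict[str, str], ids: list[str], k: int = 4
) -> SimilarityMatrix:
    """Pairwise sequence similarity over ``ids`` (diagonal forced to 1)."""
    profiles = [kmer_profile(sequences[i], k=k, entity_id=i) for i in ids]
    n = len(ids)
    vals = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = sequence_similarity(profiles[i], profiles[j])
    return SimilarityMatrix(vals, list(ids), "seq")


def _profiles(A: AssociationMatrix, axis: str) -> np.ndarray:
    if axis == "mirna":
        return A.values.astype(float)
    if axis == "disease":
        return A.values.T.astype(float)
    raise ValueError("axis must be 'mirna' or 'disease'")


def gipk_bandwidth(A: AssociationMatrix, axis: str) -> GipkBandwidth:
    """Kernel coefficient: reciprocal of the mean squared profile norm."""
    P = _profiles(A, axis)
    mean_sq = float((P * P).sum()) / P.shape[0]
    if mean_sq == 0.0:
        raise ValueError("empty interaction profile: all profiles are zero")
    return GipkBandwidth(axis, 1.0 / mean_sq)


def gipk_similarity(A: AssociationMatrix, axis: str) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel: exp(-lambda * ||p_i - p_j||^2)."""
    bw = gipk_bandwidth(A, axis)
    P = _profiles(A, axis)
    if P.shape[0] == 1:
        d2 = np.zeros((1, 1))
    else:
        d2 = squareform(pdist(P, metric="sqeuclidean"))
    vals = np.exp(-bw.lambda_value * d2)
    np.fill_diagonal(vals, 1.0)
    vals = (vals + vals.T) / 2.0  # kill 1-ulp asymmetry from pdist round-trip
    ids = A.mirna_ids if axis == "mirna" else A.disease_ids
    return SimilarityMatrix(vals, list(ids), "gipk")


def dag_semantic_contribution(dag: DiseaseDAG, disease: str) -> dict[str, float]:
    """Wang-style decayed contribution of each ancestor to ``disease``.

    The disease contributes 1 to itself; an ancestor t contributes
    ``decay * max(contribution of t's children that lie on a path to the
    disease)``, so contributions shrink geometrically with distance and a
    node reachable by several paths takes the best one.
    """
    anc = dag.ancestors_or_self(disease)  # raises on unknown id
    contrib: dict[str, float] = {disease: 1.0}

    def score(t: str) -> float:
        if t in contrib:
            return contrib[t]
        best = 0.0
        for c in dag.children(t):
            if c in anc:
                best = max(best, dag.decay * score(c))
        contrib[t] = best
        return best

    for t in anc:
        score(t)
    return contrib


def dag_semantic_similarity(dag: DiseaseDAG, di: str, dj: str) -> float:
    """Shared-ancestor similarity: joint contributions over total contributions."""
    ci = dag_semantic_contribution(dag, di)
    cj = dag_semantic_contribution(dag, dj)
    shared = set(ci) & set(cj)
    num = sum(ci[t] + cj[t] for t in shared)
    den = sum(ci.values()) + sum(cj.values())
    return num / den if den else 0.0


def dag_semantic_matrix(dag: DiseaseDAG, ids: list[str]) -> SimilarityMatrix:
    contribs = {d: dag_semantic_contribution(dag, d) for d in ids}
    totals = {d: sum(c.values()) for d, c in contribs.items()}
    n = len(ids)
    vals = np.eye(n)
    for a, b in itertools.combinations(range(n), 2):
        ca, cb = contribs[ids[a]], contribs[ids[b]]
        shared = set(ca) & set(cb)
        num = sum(ca[t] + cb[t] for t in shared)
        den = totals[ids[a]] + totals[ids[b]]
        vals[a, b] = vals[b, a] = num / den if den else 0.0
    return SimilarityMatrix(vals, list(ids), "semantic")


def functional_similarity(
    disease_sets: dict[str, frozenset | set],
    disease_sim: SimilarityMatrix,
    mirna_ids: list[str] | None = None,
) -> SimilarityMatrix:
    """miRNA functional similarity from the diseases each miRNA is linked to.

    For miRNAs n1, n2 with disease sets DE1 (size p) and DE2 (size q), each
    disease in one set is matched to its most similar disease in the other
    set and the 2-way best-match scores are averaged over p + q.  A miRNA
    with no known diseases gets 0 off-diagonal (the ratio is undefined) and
    1 on the diagonal.
    """
    ids = list(disease_sets) if mirna_ids is None else list(mirna_ids)
    didx = disease_sim.index()
    for mid in ids:
        missing = [d for d in disease_sets[mid] if d not in didx]
        if missing:
            raise ValueError(f"disease ids {missing[:5]} of {mid!r} absent from disease similarity")
    sets_idx = {mid: np.array(sorted(didx[d] for d in disease_sets[mid]), dtype=int) for mid in ids}
    n = len(ids)
    vals = np.eye(n)
    S = disease_sim.values
    for a in range(n):
        ia = sets_idx[ids[a]]
        for b in range(a + 1, n):
            ib = sets_idx[ids[b]]
            if ia.size == 0 or ib.size == 0:
                continue
            sub = S[np.ix_(ia, ib)]
            vals[a, b] = vals[b, a] = (sub.max(axis=1).sum() + sub.max(axis=0).sum()) / (
                ia.size + ib.size
            )
    return SimilarityMatrix(vals, ids, "functional")


def _check_same_ids(mats: list[SimilarityMatrix]) -> None:
    ref = mats[0].entity_ids
    for m in mats[1:]:
        if m.entity_ids != ref:
            diff = sorted(set(ref) ^ set(m.entity_ids))
            raise ValueError(f"entity id mismatch between similarity matrices: {diff[:10]}")


def integrate_mirna_similarity(
    seq: SimilarityMatrix, gipk: SimilarityMatrix, fun: SimilarityMatrix
) -> SimilarityMatrix:
    """Element-wise mean of the three miRNA measures."""
    _check_same_ids([seq, gipk, fun])
    vals = (seq.values + gipk.values + fun.values) / 3.0
    return SimilarityMatrix(vals, list(seq.entity_ids), "integrated")


def integrate_disease_similarity(sem: SimilarityMatrix, gipk: SimilarityMatrix) -> SimilarityMatrix:
    """Element-wise mean of semantic and GIPK disease measures."""
    _check_same_ids([sem, gipk])
    vals = (sem.values + gipk.values) / 2.0
    return SimilarityMatrix(vals, list(sem.entity_ids), "integrated")
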