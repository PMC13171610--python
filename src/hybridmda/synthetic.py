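"""Self-contained synthetic fixtures with planted co-cluster structure.

The generator partitions miRNAs and diseases into blocks and plants a
higher positive rate inside blocks than across them, so the low-rank
factorization, the neighborhood-aggregating encoders, and the
profile-correlation similarities can all detect the same signal.  Sequences
descend from per-block ancestors (so k-mer similarity correlates with the
co-clusters) and the disease ontology assigns block-mates to a shared
subtree (so semantic similarity does too).
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .containers import AssociationMatrix, DiseaseDAG

__all__ = [
    "SynthConfig",
    "planted_rate_matrix",
    "simulate_associations",
    "simulate_sequences",
    "simulate_dag",
    "block_assignments",
    "disease_categories",
    "write_fixture_set",
]

_RNA = np.array(list("ACGU"))


@dataclass
class SynthConfig:
    m: int = 150
    n: int = 40
    n_blocks: int = 4
    density: float = 0.08
    noise_rate: float = 0.02
    within_block_boost: float = 50.0  # within-block rate / cross-block rate
    propensity_sigma: float = 0.8  # lognormal sd of per-entity degree propensities
    seq_length_min: int = 18
    seq_length_max: int = 24
    mutation_rate: float = 0.10
    dag_depth: int = 3
    dag_branching: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.density < 1):
            raise ValueError("density must be in (0, 1)")
        if not (0 <= self.noise_rate < 0.5):
            raise ValueError("noise_rate must be in [0, 0.5)")
        if self.n_blocks > min(self.m, self.n):
            raise ValueError("n_blocks must not exceed min(m, n)")
        if self.density * self.m * self.n < 10:
            raise ValueError("expected fewer than 10 positives; increase density or size")
        if self.seq_length_min < 1 or self.seq_length_max < self.seq_length_min:
            raise ValueError("invalid sequence length range")


def block_assignments(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic round-robin block labels for miRNAs and diseases."""
    return np.arange(cfg.m) % cfg.n_blocks, np.arange(cfg.n) % cfg.n_blocks


def planted_rate_matrix(cfg: SynthConfig) -> np.ndarray:
    """Per-cell positive rates: degree-corrected planted co-clusters.

    q_ij is proportional to a_i * b_j (lognormal per-entity propensities,
    emulating the heavy-tailed degree distributions of curated association
    data) times ``within_block_boost`` when i and j share a block,
    calibrated so the mean rate equals the target density.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    mb, db = block_assignments(cfg)
    a = rng.lognormal(0.0, cfg.propensity_sigma, cfg.m)
    b = rng.lognormal(0.0, cfg.propensity_sigma, cfg.n)
    q = np.outer(a, b) * np.where(mb[:, None] == db[None, :], cfg.within_block_boost, 1.0)
    for _ in range(4):  # clip-and-rescale until mean sits on the target
        q *= cfg.density / q.mean()
        np.clip(q, 0.0, 0.9, out=q)
    return q


def simulate_associations(cfg: SynthConfig) -> AssociationMatrix:
    """Planted block-structured binary matrix at the configured density.

    Cells are Bernoulli draws from the degree-corrected planted rate
    matrix.  Label noise is class-conditional and density-preserving:
    a positive flips to 0 with probability ``noise_rate`` and a zero flips
    to 1 with probability ``noise_rate * d / (1 - d)``, so "2% noise"
    corrupts 2% of the curated labels rather than flooding the sparse
    positive class with spurious cells.  Every miRNA and disease is
    guaranteed at least one positive (a random within-block cell is forced
    on otherwise) so no interaction profile is degenerate.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 10]))
    mb, db = block_assignments(cfg)
    probs = planted_rate_matrix(cfg)
    A = (rng.random((cfg.m, cfg.n)) < probs).astype(np.int8)
    if cfg.noise_rate > 0:
        d = cfg.density
        flip_rate = np.where(A == 1, cfg.noise_rate, cfg.noise_rate * d / (1.0 - d))
        flip = rng.random((cfg.m, cfg.n)) < flip_rate
        A = np.where(flip, 1 - A, A)
    # minimum-degree guarantee: avoid all-zero GIPK profiles
    for i in np.flatnonzero(A.sum(axis=1) == 0):
        same = np.flatnonzero(db == mb[i])
        j = int(rng.choice(same if len(same) else cfg.n))
        A[i, j] = 1
    for j in np.flatnonzero(A.sum(axis=0) == 0):
        same = np.flatnonzero(mb == db[j])
        i = int(rng.choice(same if len(same) else cfg.m))
        A[i, j] = 1
    mirna_ids = [f"mir-{i:04d}" for i in range(cfg.m)]
    disease_ids = [f"D{j:03d}" for j in range(cfg.n)]
    return AssociationMatrix(A, mirna_ids, disease_ids)


def simulate_sequences(cfg: SynthConfig) -> dict[str, str]:
    """One RNA sequence per miRNA; block-mates share a mutated ancestor.

    Each block has an ancestor of the maximum length; a miRNA takes a
    prefix at its sampled length and substitutes each base independently at
    ``mutation_rate``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    mb, _ = block_assignments(cfg)
    ancestors = [rng.choice(_RNA, size=cfg.seq_length_max) for _ in range(cfg.n_blocks)]
    seqs: dict[str, str] = {}
    for i in range(cfg.m):
        length = int(rng.integers(cfg.seq_length_min, cfg.seq_length_max + 1))
        base = ancestors[mb[i]][:length].copy()
        mut = rng.random(length) < cfg.mutation_rate
        if mut.any():
            base[mut] = rng.choice(_RNA, size=int(mut.sum()))
        seqs[f"mir-{i:04d}"] = "".join(base)
    return seqs


def simulate_dag(cfg: SynthConfig) -> DiseaseDAG:
    """Rooted ontology tree; diseases attach under their block's subtree.

    Internal nodes form a ``dag_branching``-ary tree of ``dag_depth``
    levels under a single root; disease leaves of block b hang off internal
    nodes inside the b-th top-level subtree (cycling when there are more
    blocks than branches).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    _, db = block_assignments(cfg)
    nodes = ["ROOT"]
    edges: list[tuple[str, str]] = []
    levels: list[list[str]] = [["ROOT"]]
    for depth in range(1, cfg.dag_depth + 1):
        level = []
        for parent in levels[-1]:
            for b in range(cfg.dag_branching):
                child = f"{parent}.{b}" if parent != "ROOT" else f"T{b}"
                nodes.append(child)
                edges.append((child, parent))
                level.append(child)
        levels.append(level)
    # internal nodes living inside each top-level subtree
    subtree_nodes: list[list[str]] = []
    for b in range(cfg.dag_branching):
        top = f"T{b}"
        members = [top] + [x for lvl in levels[2:] for x in lvl if x.startswith(top + ".")]
        subtree_nodes.append(members)
    disease_ids = [f"D{j:03d}" for j in range(cfg.n)]
    for j, did in enumerate(disease_ids):
        members = subtree_nodes[db[j] % cfg.dag_branching]
        parent = members[int(rng.integers(len(members)))]
        nodes.append(did)
        edges.append((did, parent))
    return DiseaseDAG(nodes, edges, decay=0.5)


def disease_categories(cfg: SynthConfig) -> dict[str, str]:
    """Example disease -> category mapping (one category per planted block)."""
    _, db = block_assignments(cfg)
    return {f"D{j:03d}": f"category_{db[j]}" for j in range(cfg.n)}


def write_fixture_set(cfg: SynthConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write associations.tsv, sequences.fasta, dag.tsv, categories.tsv
    and a manifest.json capturing the config and seed."""
    from . import io as hio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    A = simulate_associations(cfg)
    seqs = simulate_sequences(cfg)
    dag = simulate_dag(cfg)
    cats = disease_categories(cfg)
    paths = {
        "associations": out / "associations.tsv",
        "sequences": out / "sequences.fasta",
        "dag": out / "dag.tsv",
        "categories": out / "categories.tsv",
        "manifest": out / "manifest.json",
    }
    hio.write_associations(A, paths["associations"])
    hio.write_fasta(seqs, paths["sequences"])
    hio.write_dag(dag, paths["dag"])
    hio.write_categories(cats, paths["categories"])
    paths["manifest"].write_text(json.dumps({"config": asdict(cfg), "seed": cfg.seed}, indent=1))
    return paths
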