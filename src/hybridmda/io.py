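"""File readers and writers.

Formats: association TSV (mirna_id, disease_id, optional label), FASTA
sequences, DAG edge-list TSV (child<TAB>parent, '#' comments), category
TSV, similarity-matrix TSV with id header row/column, and a compact .npz
cache for large matrices.  Identifiers are strings end to end; numeric
indices never leave the process.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import AssociationMatrix, DiseaseDAG, SimilarityMatrix

log = logging.getLogger("hybridmda")

__all__ = [
    "read_associations",
    "write_associations",
    "read_fasta",
    "write_fasta",
    "read_dag",
    "write_dag",
    "read_categories",
    "write_categories",
    "read_similarity",
    "write_similarity",
    "save_similarity_cache",
    "load_similarity_cache",
]


def read_associations(path: str | Path) -> AssociationMatrix:
    """Parse an association TSV into a binary matrix.

    Rows are ``mirna_id<TAB>disease_id[<TAB>label]``; a missing label
    column means positives-only.  Duplicate pairs are removed (count
    logged); id registries keep first-seen order.
    """
    path = Path(path)
    mirna_ids: list[str] = []
    disease_ids: list[str] = []
    midx: dict[str, int] = {}
    didx: dict[str, int] = {}
    pairs: list[tuple[int, int, int]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("mirna_id", "mirna"):
                continue
            if len(fields) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 tab-separated fields, got {len(fields)}")
            mid, did = fields[0].strip(), fields[1].strip()
            if not mid or not did:
                raise ValueError(f"{path}:{lineno}: empty identifier")
            label = 1
            if len(fields) == 3:
                try:
                    label = int(fields[2])
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: label must be 0 or 1, got {fields[2]!r}") from None
                if label not in (0, 1):
                    raise ValueError(f"{path}:{lineno}: label must be 0 or 1, got {label}")
            if (mid, did) in seen:
                n_dup += 1
                continue
            seen.add((mid, did))
            if mid not in midx:
                midx[mid] = len(mirna_ids)
                mirna_ids.append(mid)
            if did not in didx:
                didx[did] = len(disease_ids)
                disease_ids.append(did)
            pairs.append((midx[mid], didx[did], label))
    if not pairs:
        raise ValueError(f"{path}: no association records found")
    if n_dup:
        log.warning("read_associations path=%s deduplicated=%d", path, n_dup)
    values = np.zeros((len(mirna_ids), len(disease_ids)), dtype=np.int8)
    for i, j, label in pairs:
        values[i, j] = label
    return AssociationMatrix(values, mirna_ids, disease_ids)


def write_associations(A: AssociationMatrix, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("mirna_id\tdisease_id\tlabel\n")
        for i, j in A.positive_pairs():
            fh.write(f"{A.mirna_ids[i]}\t{A.disease_ids[j]}\t1\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA records as an id -> sequence map (ids kept verbatim)."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_dag(path: str | Path, decay: float = 0.5) -> DiseaseDAG:
    """Two-column child<TAB>parent edge list; '#' starts a comment line."""
    path = Path(path)
    edges: list[tuple[str, str]] = []
    nodes: list[str] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'child<TAB>parent'")
            c, p = fields[0].strip(), fields[1].strip()
            edges.append((c, p))
            for x in (c, p):
                if x not in seen:
                    seen.add(x)
                    nodes.append(x)
    if not edges:
        raise ValueError(f"{path}: no DAG edges found")
    return DiseaseDAG(nodes, edges, decay=decay)


def write_dag(dag: DiseaseDAG, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("# child\tparent\n")
        for c, p in dag.parent_edges:
            fh.write(f"{c}\t{p}\n")


def read_categories(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#", names=["disease_id", "category"], dtype=str)
    if df["disease_id"].iloc[0] == "disease_id":
        df = df.iloc[1:]
    return dict(zip(df["disease_id"], df["category"]))


def write_categories(categories: dict[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("disease_id\tcategory\n")
        for d, c in categories.items():
            fh.write(f"{d}\t{c}\n")


def read_similarity(path: str | Path, measure: str = "integrated") -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column identifiers differ")
    return SimilarityMatrix(df.to_numpy(dtype=float), [str(i) for i in df.index], measure)


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(sim.values, index=sim.entity_ids, columns=sim.entity_ids).to_csv(path, sep="\t")


def save_similarity_cache(sim: SimilarityMatrix, path: str | Path) -> None:
    np.savez_compressed(path, values=sim.values, ids=np.array(sim.entity_ids), measure=sim.measure)


def load_similarity_cache(path: str | Path) -> SimilarityMatrix:
    z = np.load(path, allow_pickle=False)
    return SimilarityMatrix(z["values"], [str(x) for x in z["ids"]], str(z["measure"]))
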