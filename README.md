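# hybridmda

Predicting miRNA–disease associations with a hybrid graph neural network
over a heterogeneous similarity network.

MicroRNAs (miRNAs) are ~18–24 nt non-coding RNAs whose dysregulation is
implicated in many human diseases; experimentally validating each
miRNA–disease association (MDA) is slow and expensive, so computational
ranking of candidate associations is a standard first screen.  `hybridmda`
is a library + CLI for this bipartite link-prediction problem, aimed at
computational biologists who have a curated positive-association list
(plus, optionally, miRNA sequences and a disease ontology) and want
leakage-controlled scores for the unobserved pairs.

## Method

Given a binary association matrix **A** (m miRNAs × n diseases), the
pipeline builds five similarity matrices and fuses three feature sources:

1. **Similarities.** miRNA side: 4-mer sequence similarity
   ⟨s_i,s_j⟩ / (‖s_i‖² + ‖s_j‖² − ⟨s_i,s_j⟩); Gaussian interaction-profile
   kernel (GIPK) exp(−λ‖A(i,·) − A(j,·)‖²) with λ the reciprocal mean
   squared profile norm; and functional similarity by best-match averaging
   of the semantic similarity between each miRNA's disease sets.  Disease
   side: Wang-style ontology semantic similarity (ancestor contributions
   decayed by ∂ = 0.5) and GIPK on columns.  Each side is averaged into an
   integrated matrix (SS for miRNAs, DS for diseases).
2. **Heterogeneous graph.** The weighted block matrix
   [[SS, A], [Aᵀ, DS]] defines an undirected message-passing graph:
   association edges plus intra-type similarity edges above a threshold,
   weighted by their similarity value.
3. **MDMF.** Similarity-regularized matrix factorization
   min ‖A − UVᵀ‖² + λ(‖U‖² + ‖V‖² + ‖UUᵀ − SS‖² + ‖VVᵀ − DS‖²)
   (λ = 0.0121, latent dim 42), PCA-reduced to 32 dims → feature block F1.
4. **Hybrid encoder.** A GCN branch (symmetric-normalized propagation,
   ReLU) and a multi-head GAT branch (softmax attention over neighbors),
   each with per-layer residual projections, produce F2 and F3; the fused
   embedding is F = (α₁F1 + α₂F2 + α₃F3)/Σα with equal weights.  Pairs are
   scored by a temperature-scaled cosine of the two embeddings (plain
   dot-product and fully-connected classifiers are also available).
5. **Protocol.** Edges split 80/10/10 (or cold-start: 15 % of diseases or
   miRNAs held out entirely); 30 % of training edges are supervision-only
   and invisible to message passing; training negatives are resampled every
   epoch from the zero cells (0.2 of them), evaluation negatives frozen
   (0.1); Adam (lr 0.0076, weight decay 1.75e−5) with binary cross-entropy
   on logits and early stopping on validation AUC (patience 20).  All
   interaction-derived inputs (GIPK, functional similarity, MDMF) are
   rebuilt per split from training positives only, so evaluation edges
   can never leak into the features.

A synthetic-data module generates a full test bed with no downloads:
a degree-corrected planted co-cluster association matrix, block-correlated
RNA sequences, and a tree-shaped disease ontology.

## Worked example

```python
from hybridmda import (
    SynthConfig, simulate_associations, simulate_sequences, simulate_dag,
    split_edges, run_split, EncoderConfig, TrainConfig,
)
from hybridmda.evaluation import evaluate_on_test, rank_candidates

cfg = SynthConfig(seed=7)                      # 150 miRNAs x 40 diseases, 4 planted co-clusters
A = simulate_associations(cfg)
sequences = simulate_sequences(cfg)
dag = simulate_dag(cfg)

split = split_edges(A, mode="random", seed=1)  # 80/10/10 with frozen eval negatives
result = run_split(A, split, EncoderConfig(), TrainConfig(seed=1),
                   sequences=sequences, dag=dag)
metrics = evaluate_on_test(result)
print(f"test AUC-ROC  {metrics.auc_roc:.4f}")
print(f"test AUPRC    {metrics.auprc:.4f}")
for mirna_id, score in rank_candidates(result, "D003", k=3):
    print(f"D003 candidate {mirna_id}  p={score:.3f}")
```

prints

```
test AUC-ROC  0.8720
test AUPRC    0.3442
D003 candidate mir-0047  p=0.952
D003 candidate mir-0055  p=0.951
D003 candidate mir-0095  p=0.951
```

The AUC of 0.87 says the model ranks held-out true associations well above
sampled non-associations on planted-structure data; AUPRC is lower because
the evaluation pool is heavily imbalanced (≈ 1 positive per 9 negatives).
The ranked candidates are the miRNAs most confidently predicted for
disease `D003` after masking its training-known partners.

The same chain is available from a shell:

```bash
hybridmda simulate --seed 7 --out data/
hybridmda split --associations data/associations.tsv --seed 1 --out split.json
hybridmda evaluate --associations data/associations.tsv \
    --sequences data/sequences.fasta --dag data/dag.tsv \
    --split split.json --seed 1 --out results/
hybridmda ablate --associations data/associations.tsv --seed 1 --out ablation.tsv
```

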