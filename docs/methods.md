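# Methods

## Problem and model

`hybridmda` scores unobserved miRNA–disease pairs given a curated list of
positive associations.  The observed matrix **A** ∈ {0,1}^{m×n} is treated
as positives-plus-unlabeled: zeros are unknown, not verified negatives.
The model assumes (i) miRNAs with similar sequences, interaction profiles,
or disease portfolios have similar association propensities; (ii) diseases
close in the ontology or with similar profiles likewise; and (iii) the
association structure is approximately low-rank.  These assumptions drive
the three feature sources (similarity profiles, matrix factors, message
passing) and justify averaging them.

### Similarity layer

- **Sequence**: 4-mer count vectors over {A,C,G,T} (U mapped to T so RNA
  and DNA FASTA behave identically), compared with the Tanimoto-style
  ratio dot/(‖a‖²+‖b‖²−dot).  Equals 1 iff profiles are identical; two
  empty profiles are defined as similarity 0 (no evidence).
- **GIPK**: RBF kernel on binary interaction profiles with bandwidth
  λ = N / Σ‖profile‖², so datasets of different density land on a
  comparable similarity scale.  Requires at least one nonzero profile.
- **Ontology semantic**: each disease contributes 1 to itself and each
  ancestor the maximum over its children-on-path of 0.5 × the child's
  contribution (decay ∂ = 0.5, dimensionless); similarity is shared
  contribution mass over total mass.  With several paths to an ancestor
  the strongest path wins.
- **Functional (miRNA)**: two-way best-match average of the disease-level
  semantic similarity between the diseases each miRNA is linked to; a
  miRNA with no training diseases gets 0 off-diagonal (the ratio is
  otherwise 0/0).  By default the matcher uses the pure semantic disease
  matrix; using the GIPK-augmented integrated matrix instead is a flag
  (`functional_uses_integrated`).

Integrated similarities are plain means (three miRNA measures, two
disease measures).  When sequences or an ontology are absent, the mean is
taken over the available measures.

### Heterogeneous graph

Message passing runs over the weighted block matrix [[SS, A], [Aᵀ, DS]]:
association (training message) edges carry weight 1; intra-type pairs with
integrated similarity above `sim_edge_threshold` carry their similarity
value as edge weight.  The default threshold 0.4 keeps the similarity
graph usefully dense at the few-hundred-node scale this package targets;
1.0 (or disabling the switch) recovers an association-only graph.  Edges
are undirected; both directions propagate.

### MDMF

Full-batch gradient descent on
‖A − UVᵀ‖²_F + λ(‖U‖²+‖V‖²+‖UUᵀ−SS‖²_F+‖VVᵀ−DS‖²_F), seeded N(0, 1/√l)
init, backtracking line search (halve on increase, regrow ×1.2 after
acceptance, cap 1.0) so the recorded loss trace is non-increasing.  Zeros
of A are reconstructed as weak negatives (the plain Frobenius objective);
an observed-only mask exists but is off by default.  The Gram-matrix
regularizers pull UUᵀ toward SS and VVᵀ toward DS, which is what makes the
factors informative for held-out cells rather than a memorization of the
training matrix.  Factors are PCA-reduced on the stacked [U; V] (shared
basis) to `pca_dim`.

### Encoder

miRNA and disease nodes get separate linear projections into a shared
hidden space; after that the graph is homogeneous.  The GCN branch is
ReLU(D̃^{-1/2}ÃD̃^{-1/2}HW) per layer with Ã the weighted adjacency plus
self-loops.  The GAT branch uses additive attention
e_ij = LeakyReLU₀.₂(a_src·Wh_i + a_dst·Wh_j), softmax-normalized over the
closed neighborhood; hidden layers concatenate `n_heads` heads at width
hidden//heads, the final layer averages full-width heads.  Each layer adds
a learned residual projection of its input (`use_residual`).  Dropout is
applied to hidden features and attention weights during training only.
The three blocks (projected MDMF features, GCN output, GAT output) are
averaged with configurable fusion weights (equal by default) into
`out_channels`-dim embeddings.

Pairs are scored by a temperature-scaled cosine: logit = s·cos(z_m, z_d) + b
with learnable s (init 4) and b.  The scale-invariant form was chosen over
the plain inner product because, with small supervision sets, raw
dot-product training can inflate embedding norms to memorize individual
pairs, which destroys the ranking; the cosine form caps that failure mode,
and the learnable bias absorbs the class prior so negative-heavy batches
do not warp the embedding geometry.  Plain `dot_product` and a linear
`fully_connected` head on concatenated embeddings remain available.

### Training and evaluation protocol

Edges split 80/10/10 (random) or by holding out 15 % of entities
(cold-start; all their edges go to test, validation carved from the rest).
Within train, 30 % of edges are supervision-only and the remaining 70 %
message-passing-only, so the model never passes messages along the edges
it is graded on.  Training negatives are resampled each epoch — 0.2 of the
zero cells, never colliding with any known positive; evaluation negatives
(0.1 of zero cells) are frozen per split so early stopping and reported
metrics are stable.  A "negatives per positive" semantics is available via
`neg_semantics="positives"`.  Optimization is Adam (lr 0.0076, weight
decay 1.75e−5 applied to the gradient), mini-batches over supervision
edges with fanout-limited neighborhood subgraphs; subgraphs normalize with
full-graph degrees, so with unlimited fanout batch embeddings equal
full-graph embeddings exactly.  Early stopping monitors validation AUC
with patience 20 and returns the best-AUC weights.

Every interaction-derived input — GIPK, functional similarity, MDMF — is
rebuilt from the current split's training positives only (enforced by an
internal audit that raises if an evaluation edge survives in the training
matrix).  Cross-validation repeats this per fold; cold-mode CV partitions
entities so each disease/miRNA is tested exactly once.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| hidden_dim | 117 | encoder hidden width |
| n_layers | 2 | GCN/GAT depth |
| n_heads | 12 | attention heads per GAT layer |
| dropout | 0.4493 | feature/attention dropout during training |
| out_channels | 22 | fused embedding width |
| latent_dim (l) | 42 | MDMF factor rank |
| lambda_reg (λ) | 0.0121 | MDMF similarity-regularization weight |
| pca_dim | 32 | feature width after PCA |
| learning_rate | 0.0076 | Adam step size |
| weight_decay | 1.75e−5 | L2 penalty on weights |
| patience | 20 | epochs without validation-AUC improvement |
| max_epochs | 150 | training-length cap |
| batch_size | 512 | supervision edges per mini-batch |
| neighbor_fanout | None | per-layer neighbor cap (None = exact) |
| sim_edge_threshold | 0.4 | min similarity for a similarity edge |
| decay (∂) | 0.5 | ontology ancestor-contribution decay |

The architecture defaults are a tuned configuration for full-scale curated
databases (hundreds of miRNAs/diseases, tens of thousands of positives).
They are kept as package defaults for fidelity; at the synthetic desk
scale the supervision set is two orders of magnitude smaller, so training
mostly calibrates the classifier around the similarity/factor features and
early stopping typically fires within a few epochs — see Limitations.

## Synthetic data: what it does and does not emulate

The generator plants `n_blocks` miRNA–disease co-clusters: cell (i,j) is
positive with rate ∝ a_i·b_j·boost^{[same block]}, with lognormal
propensities a, b (σ = 0.8) emulating the heavy-tailed degree
distributions of curated association data, and within-block boost 50,
calibrated so the mean rate equals `density`.  Label noise is
class-conditional and density-preserving: positives flip to 0 with
probability `noise_rate`, zeros flip to 1 with probability
`noise_rate·d/(1−d)`, so "2 % noise" corrupts about 2 % of the curated
labels instead of multiplying the sparse positive class.  (Uniform
symmetric flipping at the same nominal rate would make roughly a quarter
of all positives unrankable noise and put a Bayes-optimal ceiling near
0.84 on the recovery AUC — no model could then demonstrate recovery.)
Sequences descend from per-block ancestors with 10 % per-base
substitution; the ontology is a rooted tree whose subtrees host
block-mates; a categories table maps each disease to its block.  Every
entity is guaranteed one positive so no interaction profile is empty.

What passing the planted-signal tests shows: the pipeline detects joint
low-rank/similarity structure through every branch, with no leakage, at
chance level once the matrix is shuffled.  What it does not show: real
HMDD-scale performance — real data have richer ontology topology,
sequence families unaligned with disease structure, annotation biases,
and far more supervision.  Recovery AUC on the default conditions is
typically 0.84–0.88 depending on the generator draw (the Bayes ceiling of
the planted field at this size is ≈ 0.94; the remaining gap is estimation
error from ~480 positives).

## Numerical choices

- GIPK matrices are symmetrized after the pairwise-distance round trip and
  their diagonal forced to exactly 1.
- Softmax rows with no unmasked entries (isolated nodes before self-loops
  cannot occur — self-loops are always added) would yield zero rows rather
  than NaN.
- BCE is computed in the stable logits form max(x,0) − xy + log1p(e^{−|x|}).
- MDMF aborts with a diagnostic on non-finite loss; the line search keeps
  the trace monotone.
- Ranking ties in `rank_candidates` break lexicographically by miRNA id.
- Confusion-matrix metrics threshold probabilities at 0.5 (configurable);
  AUC uses the rank statistic with tie averaging, AUPRC step integration
  (scikit-learn implementations).
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; the simulate→train→evaluate chain is
  bit-reproducible under a fixed seed.

## Design choices on open points

- The ontology recursion is implemented as the standard decayed
  max-over-children form; the degenerate printed variants of this rule in
  the literature collapse to it.
- Matrix "decomposition" and "factorization" are realized as a single
  U,V factorization; the refinement step is the shared-basis PCA.
- Attention score parameterization (additive, LeakyReLU 0.2) follows the
  standard GAT formulation; similarity values enter through the
  message-graph weights, not the attention logits.
- Branch outputs are taken from the last layer (no layer concatenation).
- Similarity caching is opt-in (`cache_dir=` on the pipeline) keyed by a
  content hash of the training matrix; at package scale recomputation is
  cheap and implicit caches would complicate reproducibility audits.
- Ablation tables are produced on one shared split and seed per variant;
  cross-validated ablations are available by calling `cross_validate`
  per variant config.

## Limitations

- The dense-matrix encoder targets graphs up to a few thousand nodes;
  beyond that the O(N²) attention and adjacency storage dominate.
- At desk scale the tuned full-scale learning rate overfits the small
  supervision set within a few epochs; early stopping guards the result,
  but most of the discriminative power comes from the constructed
  features rather than long encoder training.  With realistically large
  supervision sets this reverses.
- Cold-start performance at desk scale is near chance: a held-out entity
  retains only its sequence/ontology similarity, and with ~40 diseases the
  remaining signal is thin.  The splits themselves are leakage-free (this
  is asserted over a thousand seeds); the limitation is statistical, not
  procedural.
- GPU execution, learning-rate schedules, and transformer/meta-path
  components are out of scope.
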