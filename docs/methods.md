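# Methods

This note documents the models, the training and evaluation protocol,
the synthetic data generators, and the numerical choices made in
`tripred`.  All quantitative statements here are computed by the test
suite (`tests/`) or by `scripts/acceptance.py`.

## Data model

Known associations arrive as three pairwise lists — drug–disease,
drug–gene, disease–gene.  `build_triple_tensor` closes triangles: cell
(i, j, k) of the binary tensor X is positive iff all three pairwise
edges (i,k), (i,j), (j,k) are present.  Entities are indexed per role by
`EntityIndex`; similarity matrices are symmetric with unit diagonal and
values in [0, 1] (inputs outside that range are min–max normalized,
asymmetric inputs are symmetrized by averaging).

## Feature fusion

Every role (drug, gene, disease) has a similarity matrix S.  The latent
vector of entity e is

    fuse(e) = ReLU(W [embed(e); S_e] + w0)  ∈ R^r

where `embed(e)` is a free r-dimensional embedding and `S_e` is the
entity's similarity row.  Cold-start entities still receive a trained
embedding row, but only the similarity part carries information that
generalizes to them (their embeddings receive no gradient from their own
triples, which are held out).  The fusion activation is configurable;
ReLU is the default.

## Models

**GTD** — score of cell (i, j, k):

    p = sigmoid( h · (a_i ⊙ b_j ⊙ c_k) )

with a_i, b_j, c_k the fused latents and h ∈ R^r a learned output
weight vector, no bias.  With identity activation and h = 1 this is
exactly CP decomposition; `scripts/acceptance.py` verifies the
equivalence to machine precision (`cp_equivalence_max_abs_error`).

**MLP** — each role's fused latent is passed through its own tower of
dense layers with widths [2r, r, max(1, r/2)] (ReLU on hidden layers,
linear output layer), then the element-wise product of the three tower
outputs is scored by a learned head of length max(1, r/2).

**Ensemble** — both paths run with separate fusion blocks and
parameters; the GTD interaction vector (length r) and the MLP
interaction vector (length max(1, r/2)) are concatenated in front of a
single learned head of length r + max(1, r/2).  Both paths therefore
receive gradients through their own interaction terms.

All parameters are initialized Glorot-uniform from a seeded
`numpy.random.default_rng`; runs are bit-reproducible for a fixed
configuration and seed.

## Training

- Binary cross-entropy on the sampled positives and negatives.
- Adam (lr 1e-3, β = (0.9, 0.999), ε = 1e-8), minibatches of 256,
  shuffled per epoch.
- Negative sampling: α negatives per positive (default α = 10), drawn
  uniformly **without replacement** from the non-positive cells of the
  full tensor.
- Early stopping on validation AUC with patience 10, with a
  **minimum-epoch warm-up (default 50)** before the patience rule may
  stop training: from random initialization, validation AUC routinely
  dips below its starting value for more than 10 epochs while the
  factors organize, and bare patience-10 would halt at an unfitted
  model.  The best-validation-AUC parameters are restored after
  stopping.

## Cold-start protocol

Folds are split by **entity** on one side (drug or disease).  Entities
are assigned to folds greedily in descending order of positive-triple
count, each to the currently lightest fold (seeded random tie-breaks),
which balances positives across folds to within the largest
single-entity count.  For fold t, entities of fold t are the test set,
entities of fold (t+1) mod n are validation (used only for early
stopping), and the rest train.  Both positives and negatives follow
their sided entity, so a test entity contributes nothing to training.

## Metrics

- **AUC** by the rank statistic (ties count ½), computed with
  `scipy.stats.rankdata`.
- **NDCG@n** with binary relevance, discount 1/log2(i+1), ideal DCG from
  the sorted relevance list; 0 when the ideal DCG is 0.  Score ties are
  broken by original index (stable sort).
- Default grouping is **per sided entity**: metrics are computed on each
  held-out entity's scored cells and averaged over entities, so
  high-degree entities do not dominate.  Global pooling is available.

## Pairwise prediction

A pair (e.g. drug i, disease k) is scored by the model's triple logit
averaged over all entities of the absent role.  Every model's logit is
linear in each role's latent (interaction product times the head h), so
this average equals

    score(i, k) = Σ_q h_q · m_q · lat_i,q · lat_k,q

with m the absent role's mean latent (mean tower output for MLP paths).
An unweighted inner product of latents is *not* used: dimensions with a
negative head weight, or with consistently negative absent-role tower
activations, would contribute with flipped sign and can invert the
ranking outright.  Note the marginalization averages the *logit*, not
the sigmoid probability; rankings are taken on this mean logit.
Cold-start pairwise evaluation reuses the triple fold assignment and
treats all unknown pairs of a held-out entity as negatives.

## Similarity kernels

**ATC** (drugs): a 7-character ATC code has cumulative prefixes of
length 1, 3, 4, 5, 7 at its five levels.  For two drugs' code sets the
per-level similarity is the Jaccard index of their level-k prefix sets,
and the kernel is the mean over the five levels.

**Ontology IC** (genes/diseases): annotations are propagated to all
ancestors (every term is its own ancestor); a term's information content
is −ln of the fraction of annotated entities carrying it.  Term–term
similarity is Σ IC over shared ancestors divided by Σ IC over the union
of ancestors; entity–entity similarity is the best-match average over
their annotation sets.  Loaders support OBO files (`is_a` edges only),
restriction to sub-ontology roots, and dropping IEA-evidence and NOT
annotations (both on by default).

## Synthetic generators (scope)

The package ships generators for self-contained experiments; they
emulate structure, not any particular dataset:

- **Planted tensor**: non-negative uniform factors with independent
  zeroing at rate `factor_sparsity`, positives = the top `n_positives`
  cells of the exact rank-R CP reconstruction (score ties resolved in
  lexicographic cell order via a stable sort), optional label noise that
  flips equal numbers of cells on and off, and per-role similarity
  matrices that are cosine similarities of the true factor rows
  (optionally replaced by random symmetric matrices).
- **Toy ontology**: a complete tree of given depth/branching plus a few
  random DAG edges to strictly shallower levels; entities annotated to
  random leaves.
- **Toy ATC**: valid 7-character codes in families that are disjoint at
  level 1 and share prefixes through a configurable level.

Generator scope limits: factor-**cosine** similarity discards row
magnitudes, and on very small instances (around 20 entities per mode at
rank 2) the cosine rows are nearly constant while the planted top-N
cells are driven by the discarded magnitudes — side information there is
uninformative or misleading for cold start.  The shipped defaults
(50×80×40 at rank 4, and 30×30×30 at rank 4 in tests) avoid that regime.

## Benchmark conditions

`run_planted_benchmark` is the package's reference experiment: a
50×80×40 tensor, rank 4, 300 positives, α = 10, no noise, informative
similarities, drug-side 10-fold cold-start splits with 2 folds evaluated
per seed, 5 seeds, against a permuted-label null with a paired one-sided
sign test.  These problem sizes are this package's choice, selected so
the full benchmark runs in about a minute on one CPU while staying in
the sparse regime (positives ≈ 0.2 % of cells); full 10-fold evaluation
is available through `training.cross_validate`.

## Limitations

- No real drug/gene/disease datasets are bundled; all shipped numbers
  are on planted synthetic data, and transfer to real data is untested
  here.
- Training is plain NumPy on one CPU; it is sized for thousands of
  sampled cells and ranks up to a few dozen, not for web-scale tensors.
- Per-fold cold-start AUC has high variance on small instances (few test
  entities); conclusions should be drawn across folds and seeds, as the
  benchmark does.
- Predicted probabilities are not calibrated; only rankings are
  evaluated.
- Hyperparameters (rank, α, learning rate, tower widths) are defaults,
  not tuned per dataset; `sweep` exists for that purpose.
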