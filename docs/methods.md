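# Methods

## Graph model

A prescription is modeled along three dimensions — its identity, its
disease information (diseases, symptoms, disease targets) and its herb
information (herbs; their pharmacopoeia attributes property, flavor,
meridian and category; their chemical ingredients; ingredient targets) —
as a typed graph with ten relation kinds (prescription–disease,
prescription–symptom, prescription–herb, disease–disease-target,
herb–{property, flavor, meridian, category, ingredient},
ingredient–ingredient-target). Edges are stored undirected and the
adjacency is symmetrized and binarized: the graph is unweighted, and the
symmetric GCN normalization assumes an undirected topology anyway.
Dosage and sovereign/minister/assistant/courier herb weighting are out of
scope: historical dosage units are not commensurable and no authoritative
weighting coefficients exist, so edges carry no weights. Node order is
input-file order and every matrix and embedding row follows it. Isolated
nodes are legal; after the self-loop they have degree one and a unit
diagonal entry in the normalized adjacency.

The node tables carry no numeric features, so features are initialized
synthetically: the default `identity` scheme gives each node a one-hot
indicator (the standard featureless transductive setting — the encoder
then learns from structure alone); `type-onehot-plus-identity` appends an
11-way node-type indicator for experiments where type information should
be shared across nodes.

## Encoder and objective

The encoder is a single graph-convolution layer by default (configurable
depth), with PReLU activation (learnable slope, initialized at 0.25;
ReLU/tanh/identity available). Sigmoids in the readout and discriminator
are fixed — the summary vector and the probability scores require them.
Corruption is a uniform permutation of the feature rows with the
topology kept, the canonical choice for this objective: it keeps the
node count (M = N) and the feature-row multiset unchanged, so positives
and negatives differ only in which structural position each feature row
occupies. One corruption draw is taken per epoch; the objective's
expectation is thereby estimated with a single sample, which is standard
and keeps epochs cheap.

Training is full-batch: per epoch the true and corrupted graphs are
encoded with shared weights, the summary is read out from the true
embeddings only, all 2N patch–summary scores are computed, and one Adam
step (learning rate 1e-3, β = 0.9/0.999, no weight decay) is taken on
the negated objective. Logits are evaluated through `log(1+exp(·))`
directly, so no probability ever reaches 0 or 1 in the loss; the
standalone `dgi_objective` additionally clamps its probability inputs at
1e-12. Weights are Glorot-uniform, drawn from a generator seeded by the
run seed; a run is bit-for-bit reproducible given the seed. Gradients
are hand-derived (the summary's dependence on every positive embedding
included) and verified against central finite differences in the test
suite. A non-finite objective aborts with the offending configuration in
the message.

Forward/backward passes keep the feature matrix and normalized adjacency
sparse, so one epoch is O(nnz(A)·d + N·d²); the default 1/10-scale graph
(~1,700 nodes) trains in well under a second, and the full reference
scale (15,210 nodes) remains a desktop-class problem.

## Similarity, summary, screening

Cosine similarity is computed between embedding vectors of every
target × candidate prescription pair — never candidate × candidate — so
20 targets × 67 candidates give exactly 1340 values per metric. The
Jaccard coefficient is computed on raw attribute sets (a prescription
viewed as the collection of its diseases, symptoms, herbs and its herbs'
attributes); molecular nodes are excluded by default because presence/
absence of thousands of shared targets swamps the macro-level signal,
but the type subset is a parameter. Degenerate inputs are defined, not
fatal: a zero vector has cosine 0 with a warning, two empty sets have
Jaccard 0.

Summary statistics use the sample SD (n−1), bias-corrected
(Fisher–Pearson G1) skewness, bias-corrected excess kurtosis (G2; normal
distribution → 0) and linear-interpolation percentiles. The estimators
behind the reference study's printed statistics are unstated, so
third-decimal disagreement on its data is possible; the replication test
therefore allows ±0.005 on moments while keeping counts exact.

Screening retains pairs with value ≥ threshold — inclusive, since pairs
printed exactly at the cosine cutoff of 0.77 count as findings. The two
curation rules are mechanized exactly as stated — drop pairs touching a
pediatric prescription, drop pairs touching a prescription that only
treats respiratory disease (cough/asthma) — and take the tags as an
input table; any further expert judgment in the original curation is
outside the rules and outside this implementation. A missing annotation
warns and retains the pair rather than silently deleting evidence.

## Stability-based hyperparameter selection

With unlabeled pair values, accuracy-style selection is impossible, so
configurations are compared by the dispersion of the similarity vector
a single trained model produces: SD and CV across the 1340 values of one
run (a cross-seed mode exists via the `seeds` argument). One axis is
varied at a time — hidden units over {32, 64, 128, 512}, epochs over
{9, 26, 47, 95, 97, 151} by default — while the other stays at its
default. `select_config` implements the objective rule: minimum CV, ties
to smaller SD, then to the smaller value for parsimony. The shipped
default (128 units, 26 epochs) is deliberately *not* wired to that rule:
picking 128 over a lower-CV 64 is an expressiveness/complexity judgment,
and the CLI prints both so the user sees the rule-based pick and the
default side by side. Distribution-shape inspection (the visual half of
the original selection) is not mechanized.

## Synthetic data

The generator emulates the reference dataset's shape: 87 prescriptions
(20 target, 67 candidate) and the other ten node types at one tenth of
the reference counts (~1,700 nodes in total), except the closed
attribute vocabularies (5 properties, 12 flavors, 12 meridians, 35
categories), which are kept at full size because a tenth of them would
be degenerate. `SyntheticParams.paper_scale()` restores the full 15,210
node counts. Each herb gets exactly one property and category and 1–3
flavors and meridians, mirroring pharmacopoeia structure; herbs link to
~7 ingredients, ingredients to 1–4 targets, diseases to ~30 targets.
Prescriptions draw 6 herbs, 3 diseases and 4 symptoms each — mid-range
for patent-drug formulations.

Ground truth is planted through 3 clusters: prescriptions are assigned
round-robin, each cluster owns disjoint herb/disease/symptom pools, and
a cluster member draws Binomial(k, overlap) of its k attribute links
from the pool, the rest uniformly from the whole universe. Pool sizes
are validated to be at least the per-prescription draw count so the
shared-draw count is never clipped and separation stays monotone in the
overlap parameter. Same-cluster target/candidate pairs are designated
similar; `recovery_metric` reports mean(similarity | designated) −
mean(similarity | rest).

What passing on this generator shows — and does not. The synthetic
attribute universes are ~10× denser per prescription than the real
ones, so absolute similarity levels are much higher than the reference
distribution (synthetic cosine means ≈ 0.86 vs 0.607); tests therefore
assert *relative* structure (cluster separation, monotonicity, counts,
estimator correctness), not the reference table's absolute values, which
require the original raw data. Node ids are opaque: no pharmacological
plausibility, name standardization or database curation is modeled.

## Problem sizes in the shipped checks

Unit and property tests run on graphs of ≤ 300 nodes; end-to-end and
stability checks use the default 1/10-scale graph (1,660 nodes, 1340
pairs) with 32–128 hidden units and up to 47 epochs. The acceptance
script uses the same 1/10-scale conditions with the default 128-unit /
26-epoch configuration. These sizes keep the whole suite in seconds
while exercising every code path at the same pair count (1340) as the
reference setting.

## Known limitations

- Transductive only: embeddings exist for nodes present at training
  time; no inductive encoder or neighbor sampling.
- Encoder depth, learning rate, optimizer, activation and initialization
  are this package's own defaults (single layer, 1e-3, Adam, PReLU,
  Glorot); the reference study does not report them, so its exact
  numerical outputs are not expected to be bit-reproducible even on its
  own data.
- The Jaccard route ignores multiplicity (an herb with two flavors
  contributes two flavor edges but each attribute node once).
- No alternative similarity measures (diffusion, proximity) and no
  recommendation system; both are natural extensions.
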