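# Methods

This note documents the models, parameter choices and numerical conventions
behind `mpm`, and what the synthetic benchmark does and does not show.

## Message passing on the directed PCG network

The PCG functional-interaction network is directed: `binding` rows produce
both ordered edges, while `inhibits`, `activates`, `regulates` and
`catalyzes` produce one. A miRNA's (disease's) PCG profile is a weight
vector over the PCG registry; entries that are nonzero on input are *known*
and are conserved exactly through propagation. Each iteration recomputes
every unknown node synchronously from the full previous state

    w_t(i) = d_in(i)^(-1/2) Σ_{j∈Par(i)} w_{t-1}(j) / √d_out(j),

so previously inferred values are overwritten, not frozen — a node whose
parents gain weight in iteration 1 changes again in iteration 2. Degrees are
structural properties of the graph, independent of the profile. Unknown
nodes with zero in-degree stay 0 (the empty sum), never NaN. Because the
update is linear in the weights, the matrix form `W @ P` with
`P = D_out^(-1/2) A D_in^(-1/2)` reproduces the per-node rule to machine
precision; the test suite checks this against a naive per-node evaluator at
1e-12. The default is **one** iteration: information then travels exactly
one hop from every known node, which adds neighbourhood context without
flooding the profile.

Whether profiles should be renormalised after propagation is genuinely open;
we conserve known values bit-identically and leave inferred values on the
natural scale of the update, since any renormalisation would break the
known-value conservation property that the downstream network construction
relies on.

## Disease categories and ReliefF

Category labels come from positional ontology codes (`C04.557` is a child
of `C04`): the label is the two-segment prefix when the top-level code is in
the infection branch (default `C01`), else the one-segment prefix. A disease
with several codes takes the label of its lexicographically smallest code —
an arbitrary but deterministic rule. Categories with fewer than
`min_category_size = 10` members collapse into `Others`; diseases without an
ontology record get `Others` directly.

ReliefF is the standard multiclass formulation: for each instance, the k
nearest same-class hits decrease a feature's weight and the k nearest
misses of every other class increase it, prior-weighted by
`P(C)/(1 − P(class(R)))`, under Manhattan distance on range-normalised
features. Defaults: `k_neighbors = 10`, all instances evaluated (no
subsampling), which makes the estimate deterministic; distance ties resolve
to the smaller sample index. Classes smaller than `k+1` contribute all their
members, normalised by the actual neighbour count, so small categories never
inflate weights. Constant features have zero diff by convention. Weights are
bounded in [−1, 1]; the implementation agrees with an O(n²p) reference to
1e-10 in the tests. Selection keeps the top `K = 100` features (weight
descending, index-ascending tie-break). The side task is fit on disease
profiles only; the selected PCG set is then applied to both miRNA and
disease profiles.

## Heterogeneous network and SDNE

`A_mdp` stacks [miRNAs | diseases | selected PCGs]. Training miRNA–disease
edges have weight 1; miRNA–PCG and disease–PCG edges carry the *enriched*
weights unthresholded; the PCG–PCG block is the undirected 0/1 projection
(edge if either direction exists) because the embedding model requires a
symmetric adjacency. Diagonal miRNA and disease blocks are zero. Building
the adjacency takes an explicit `forbidden_pairs` set and raises on any
overlap with the training edges, so split leakage is a hard error rather
than a silent bias.

SDNE minimises

    L = Σ_i ‖(x̂_i − s_i) ⊙ b_i‖²  +  α Σ_{i<j} s_ij ‖y_i − y_j‖²  +  ν Σ ‖W‖²

with `b_ij = β` where `s_ij > 0` and 1 elsewhere. The autoencoder has two
sigmoid encoder layers of sizes (1000, 128), one sigmoid decoder layer and
is trained with Adam on raw adjacency rows (no row normalisation). It is
implemented directly in numpy with hand-derived gradients, which keeps the
training bitwise reproducible for a fixed seed and dependency-light; the
networks involved are a few hundred nodes, for which this is fast on one
CPU. Defaults: `α = 0.05`, `β = 5`, `ν = 1e-4`, 200 epochs, batch size 256,
learning rate 1e-3. `β = 1` is permitted (it disables the observed-edge
penalty and reduces the second-order term to plain squared reconstruction,
which the tests exploit as a limit check); values below 1 are rejected.
Because the encoder is a deterministic function of the adjacency row, nodes
with identical rows receive identical codes. Entities absent from the
training network map to the zero vector. A NaN loss aborts with the epoch
number rather than returning garbage.

## Biological features

Disease semantic similarity is the Wang measure with contribution factor
`delta = 0.5` (the standard value): an ancestor k levels above a disease
contributes `0.5^k`, maximised over the disease's tree positions, and two
diseases are compared through their shared ancestors relative to their total
semantic values. A disease's feature vector is its similarity row over the
*training* disease set, so the feature length is fixed and a completely new
disease still gets features from its ontology position alone. miRNA family
features are one-hot over the training family vocabulary plus a reserved
`unknown` column for unmapped miRNAs.

## Classifier and evaluation

`X_md = [E_m, E_d, F_m, S_d]` feeds a 350-tree Random Forest (unlimited
depth, √p features per split, fixed seed). Training negatives are sampled
uniformly without replacement from unknown pairs within the training entity
universe at ratio 1:1, excluding *all* known positives so held-out true
associations are never mislabeled as training negatives. Test negatives are
drawn within the test entity universe at the configured ratio (1, 5 or 10),
excluding every known positive.

AUC is the rank-sum probability with half-credit for ties; AP is the
discrete precision–recall sum with tied scores entering as one group (not
the interpolated AUPR, which is optimistic when few distinct score values
exist). Thresholded metrics use 0.5; any 0/0 denominator (including the MCC
of a single-class predictor) is reported as 0. Top-N counts resolve
boundary ties by stable pair-id order. All metric implementations are
checked against exhaustive/naive oracles at 1e-12.

## Synthetic benchmark

The generator emulates the pipeline's statistical premise — miRNA–disease
relevance mediated by shared PCG neighbourhoods — with a planted mechanism:

* 200 PCGs in a directed random graph, Poisson(3) out-degree, uniform
  relation labels;
* 3 disease categories, each owning 10 disjoint signal PCGs;
* 30 diseases and 50 miRNAs assigned to categories round-robin (balanced,
  so every category clears the rare-category collapse threshold);
* disease profiles: Uniform(0.6, 1) scores on own-category signal PCGs plus
  5% background with Uniform(0, 0.4) scores; miRNA profiles binary with the
  same structure;
* a pair is truly associated iff the latent categories match, flipped with
  probability 0.05;
* a leaf-only ontology (one root code per category) and one family per
  latent miRNA category.

Every artifact draws from its own child stream of one seed, so outputs are
byte-identical across runs and independent of generation order.

What the benchmark does **not** emulate: the heavy-tailed degree
distributions, inter-category correlation, annotation bias and
false-positive structure of the real interaction and association databases,
nor their scale (tens of thousands of PCGs, thousands of diseases). Passing
the end-to-end checks therefore shows that the implementation wires the
stages together correctly, propagates information to genuinely new diseases
through PCG edges, and recovers a planted association mechanism — not that
any particular real-data performance level would be achieved.

One instructive interaction: ReliefF recovers essentially all planted
signal PCGs from the generated disease profiles, but after one
message-passing step the signal spreads onto the network neighbours of the
signal PCGs, which then legitimately compete for top ranks. On real,
incomplete association data this spreading is the point of the enrichment;
on the fully observed synthetic profiles it mainly adds redundancy, which is
why the measured gain of message passing over its ablation is small on this
benchmark.

## Problem sizes and determinism

The shipped defaults (200 PCGs / 50 miRNAs / 30 diseases, 10 benchmark
seeds, K = 100, 200 SDNE epochs) were chosen so a full multi-seed benchmark
with ablations completes in minutes on a single CPU while leaving all
qualitative conclusions stable across seeds. Every stochastic stage
(ReliefF subsampling, splits, negative sampling, SDNE initialisation and
batching, forest training) receives a sub-seed derived from the experiment
seed by hashing a stage tag, so a run is a pure function of inputs, settings
and seed; re-running a pipeline produces bit-identical score tables.

## Known limitations

* The SDNE hyperparameters are conventional defaults, not tuned values;
  very large networks would want mini-batch Laplacians on sparse storage
  and a GPU-backed implementation.
* Similarity rows span training diseases only; a model must be refit to
  extend the feature space to new reference diseases.
* The transductive split repairs candidate test pairs whose miRNA or
  disease would otherwise vanish from training by returning them to the
  training set, so the realised test fraction can be slightly below the
  requested one.
* Identifier handling is exact-string; no nomenclature normalisation
  (miRNA name variants, ontology cross-references) is attempted.
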