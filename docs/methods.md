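# Methods

## Model

The predictive model is a two-layer network whose first layer is masked by
a bipartite gene→complex membership graph. For an expression profile
x ∈ ℝ^k, complex activity i is f_ci(x) = σ(Σ_{g ∈ c_i} w_{g,i} x_g + b_i):
only member genes of c_i enter, because w_{g,i} is pinned to zero for
g ∉ c_i. Class scores are affine in the activities and trained with
multinomial softmax cross-entropy. The mask is enforced three ways —
masked initialization, masked gradients, and re-masking after each
optimizer step — so off-mask weights are exactly 0.0 (bitwise) at all
times; the masked model with a single complex is arithmetically identical
to a dense model on that complex's gene submatrix, which the test suite
verifies against an independent dense trainer.

The implementation is plain numpy behind a scikit-learn estimator surface
(`FactorGraphClassifier`): the model is small by construction (tens of
thousands of nonzero weights at cohort scale), so dense matrix products
with a boolean mask are simpler and fast enough, and the estimator
composes with sklearn model selection.

### Training protocol and defaults

| parameter | default | why |
|---|---|---|
| optimizer | Adam, lr 1e-4 | standard protocol for this model family |
| batch size | 32 | id. |
| max epochs | 500 | id. |
| validation fraction | 0.25 of the training split | held out, stratified, for early stopping |
| patience | 20 epochs, best-weights restore | the protocol specifies early stopping but no patience; 20 is conventional |
| initialization | Xavier uniform | limits from the dense (k, l) and (l, C) fan by default; a per-complex fan-in variant is behind `xavier_fan="per_complex"` |
| activation | ReLU (identity, tanh available) | the activity nonlinearity is a free choice; ReLU is the common default |
| biases | on, both layers | standard practice; excluded from parameter accounting (below) |
| class weighting | none | imbalance is handled in the metrics, not the loss |

Randomness: `random_state` feeds `SeedSequence(seed).spawn(3)` — child 0
initializes weights, child 1 seeds the stratified validation split, child 2
drives minibatch shuffling. Fixed seed + fixed data give an identical
training history.

Parameter accounting counts membership edges only: a clustered factor
graph has Σᵢ |c_i| first-layer parameters versus k × l fully connected.
Biases are excluded from these counts (which keeps the fully connected
figure exactly k × l) even though the model carries them; capacity and
accounting are reported separately.

## Complex discovery

All four algorithms are deterministic, allow overlapping clusters, and may
leave sparsely connected proteins unassigned (an implicit feature
selection). Ties are broken everywhere by (weight desc, degree desc,
identifier asc), so output is reproducible and equivariant under
order-preserving relabeling. Defaults follow the algorithms' original
publications:

- **MCODE** — vertex weight = k × density of the highest k-core of the
  closed neighbourhood; seeded BFS growth at weight ≥ (1 − vwp)·seed
  weight (vwp 0.2); haircut on, fluff off, min size 3. Post-processing
  order is haircut then fluff. Note that when all vertex weights in a
  region are equal (e.g. two equal cliques joined by a bridge), growth
  legitimately crosses the bridge and emits the union.
- **DPClus** — edge weight = common neighbours, node weight = incident edge
  weight sum; growth constrained by cluster density ≥ d_min (0.9) and
  cluster property cp(v) = edges(v, cluster)/(density·|cluster|) ≥ cp_min
  (0.5); min size 2. After emission the default "overlapping" update
  removes only the cluster's internal edges, which preserves the
  availability of members for later clusters while guaranteeing
  termination (the edge count strictly decreases); a "partition" mode
  removing member nodes is available.
- **IPCA** — DPClus weighting computed once; growth admits v when its
  interaction probability edges(v, cluster)/|cluster| ≥ t_in (0.5) and the
  extended cluster's diameter stays ≤ d_max (2); min size 2. Emitted
  members leave the seed queue but remain eligible to join later clusters,
  so overlapping near-duplicates around bridges are possible by design.
- **COACH** — preliminary core of v = v plus neighbours at ≥ average degree
  of the closed-neighbourhood subgraph; cores under density 0.7 dropped;
  redundant cores collapsed at neighbourhood affinity
  NA(A,B) = |A∩B|²/(|A||B|) ≥ 0.225 keeping the denser, then larger, then
  lexicographically first; vertices adjacent to more than half a core are
  attached; min size 3. The core of each emitted complex is kept in the
  clustering's metadata.

A 1-node subgraph has density 1.0 by convention (unreachable for emitted
clusters of size ≥ 2). Clusters are named `<algo>_<index>` in emission
order. Predicted-vs-reference matching uses NA with threshold ω (default
0.25; recovery tests in this package use the stricter ω = 0.5).

## Random-structure controls

`random_factor_graph_R` draws l uniformly from [30, 6000] (endpoints
inclusive) and u uniformly from [1, l·k], then places u *distinct*
membership edges uniformly at random — sampling without replacement, since
the connections form a simple bipartite graph and duplicates would
silently shrink u. `random_factor_graph_M` keeps a template's (l, u) and
re-draws the edges the same way; complexes that end up memberless are
permitted and produce constant activities.

## Evaluation

Five class-stratified 80:20 train/hold-out repetitions by default.
Balanced accuracy is the unweighted mean of per-class recall (×100); a
constant classifier scores exactly 100/C with C represented classes.
Weighted one-vs-rest AUC averages per-class ROC AUCs with prevalence
weights; ties count ½; a class without both positives and negatives is
skipped with a warning and the weights renormalized; the binary case uses
the same one-vs-rest weighting as multiclass rather than the single-class
convention, so one formula covers all tasks. Paired comparisons over
repeated splits use the correlated t-test
t = mean(d) / √(var(d)·(1/n + n_test/n_train)) with n − 1 degrees of
freedom (the Nadeau–Bengio correction for overlapping training sets);
zero-variance differences return t = 0, p = 1 when the mean difference is
zero and a flagged p → 0 otherwise.

## Attribution

Integrated gradients are computed at the complex layer along the straight
path from a baseline (default: the all-zeros profile; the training mean is
a supported alternative) with 128 steps by default. Attributions target
the class logit, not the softmax probability, because the affine
complex→class head then gives exact completeness: the per-complex sums
telescope to logit(x) − logit(baseline) for any step count. Per-complex
importance aggregates the mean absolute attribution over the supplied
samples (typically the samples of the target class), which is robust to
sign cancellation; ranking ties break by complex name.

## Synthetic benchmark

The generator plants n_complexes dense gene sets (sizes uniform in
`complex_size_range`; a fraction `overlap_fraction` of complexes reuses one
previously assigned gene) in an n_genes background: within-complex pairs
are connected with probability p_in, all other pairs with p_out.
Expression follows a Gaussian linear-activity model: per sample of class y,
latent activity z_i ~ N(μ_{y,i}, 1) with class means drawn once at scale
`class_effect_scale`; member genes read Σ_i loading · z_i plus
N(0, noise_sd) noise with a constant loading (`activity_loading_scale`,
default 1 — unit loadings keep the activity interpretable as the shared
component of its members); unassigned genes are pure noise; labels are
balanced. One seed drives four spawned streams (membership, topology,
latents, noise), so each sub-generator is independently reproducible.

Defaults — 300 genes, 12 complexes of 6–15 members, p_in 0.9 against
p_out 0.01, overlap 0.25, 400 samples, 3 classes, effect scale 2, noise SD
0.5 — define the study conditions for the end-to-end checks. What passing
tests on this generator show is that the pipeline recovers planted dense
modules and exploits complex-level signal; what they do not show is
robustness to the marginal distributions, batch effects or measurement
noise of real microarray/RNA-seq cohorts, which the generator deliberately
does not imitate.

A measured property of these conditions worth stating plainly: the
class signal is strong enough that both the discovered-structure model and
the matched random control reach 100% held-out balanced accuracy, so the
qualitative ordering "knowledge-derived structure beats matched random
structure" — which holds on the harder real-cohort tasks this design is
aimed at — ties at the ceiling here. The end-to-end acceptance check
asserts the strict ordering and therefore fails under these conditions;
the conditions were kept as stated rather than re-tuned to manufacture a
separation.

## Problem sizes and numerical choices

Tests run on graphs of ≤ 10 nodes (where exhaustive connected-subgraph
enumeration serves as the oracle), planted-clique graphs of ~120–300
genes, and training sets of tens to hundreds of samples; the end-to-end
benchmark uses the default 300-gene/400-sample conditions with 10
repetitions. Cross-entropy adds 1e-12 inside the log; softmax subtracts
the row maximum; non-finite losses raise with the offending epoch; the
validation split refuses classes absent from the training portion.

## Known limitations

- Table-scale reproductions on the public breast-cancer and head–neck
  cohorts against the STRING network require external downloads and are an
  integration path (same code, different inputs), not part of the offline
  test surface; the exact clustering-algorithm settings that reproduce the
  published cluster statistics are not fully determined by their default
  parameterizations.
- Enrichment of exported gene sets (GMT) is delegated to external services
  by design.
- Single bipartite layer only: no pathway hierarchies or multi-omic
  integration.
- Edge weights and directions in the input network are ignored beyond the
  optional confidence threshold at parse time.
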