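# Methods

## The model

`scboolnet` treats a gene-regulatory circuit as a synchronous Boolean
network: every gene is ON (1) or OFF (0), and all genes update
simultaneously, each through its own transition function over its
regulators. The modeling chain makes three assumptions worth keeping in
view:

* **Bimodality.** Single-cell qPCR expression is approximately bimodal
  per gene, so a two-state abstraction loses little. Genes whose
  distributions are not bimodal are still forced into two clusters; their
  binarization is the least trustworthy part of the chain.
* **Steady-state snapshots.** Each profiled cell is assumed to sit at a
  stable state of the network, so the same cell provides both the input
  (parent states) and the output (target state) of every transition
  function. Transient or oscillating cells violate this.
* **mRNA ≈ activity.** A gene and its product are merged into one node;
  post-transcriptional and post-translational regulation are invisible.

## Network assembly

An edge TF → gene requires physical binding evidence (ChIP) *and*
functional evidence (LOF/GOF perturbation followed by expression
profiling). The sign is the sign of `w_LOF·ΣL + w_GOF·ΣG`, with
`w_LOF = 2 > w_GOF = 1` by default — loss-of-function evidence is the more
direct causal probe, and 2:1 is the smallest integer ratio realizing the
ordering. A weighted sum of exactly zero is a genuine conflict: the edge
is dropped and logged rather than defaulted, and curated overrides
(citable, versioned as data) settle such cases. Overrides on pairs with
no evidence at all must carry an explicit add flag; silent edge invention
is an error.

Feedback loops are simple directed cycles; a loop's sign is the product
of its edge signs, auto-regulatory (length-1) loops are counted separately
from longer ones, and cycles are canonicalized by rotating to the
lexicographically smallest start node. Enumeration is unbounded by default
(tractable at the 30-node scale) with an optional length cap for stress
inputs.

## Preprocessing

Ct values above 35 cycles are non-detectable and recorded as 35; such
cells are kept (they populate the OFF cluster), not dropped. Normalization
is −ΔCt against the housekeeping gene per cell, i.e. log2-expression-like
units; binarization operates on −ΔCt directly rather than its exponential,
which is numerically more convenient and order-equivalent.

Per-gene two-means clustering uses a deterministic 1-D Lloyd iteration
seeded at the gene's 10th/90th percentiles — for a one-dimensional K = 2
problem this removes all seed sensitivity. The higher-centroid cluster is
always mapped to 1. A pooled mode (one split fitted to all genes' values)
is provided for sensitivity analysis; per-gene is the default because each
gene's bimodality lives on its own dynamic range. All-constant genes
binarize to all-0 or all-1 relative to the matrix-wide mean, with a logged
warning.

Heterogeneity is compared through the index of dispersion —
variance/mean of linear-scale expression `2^(−ΔCt)` per gene — with a
one-tailed paired t-test across genes (pairing by gene) for the hypothesis
that one condition is less dispersed. Identical inputs yield the p = 0.5
boundary by convention. Gene association uses 1 − Pearson correlation;
zero-variance genes get the maximum distance 2 and are flagged; display
orderings come from average-linkage Euclidean hierarchical clustering.

## Logic learning

Candidate update rules are *read-once* formulas: binary AND/OR trees whose
leaves are the parents, each appearing exactly once, optionally negated
(negations elsewhere can always be pushed to the leaves by De Morgan, so
leaf negation loses no generality). XOR and threshold functions are
excluded by construction — a deliberate simplification that can miss real
regulatory logic. Enumeration is bottom-up over leaf subsets with
deduplication by truth table at every level; the distinct-function counts
are 2, 8, 64, 832, 15 104 and 352 256 for 1–6 parents, which is why
`max_parents` defaults to 6 and the cap is explicit.

Fit is the agreement: the fraction of cells where the formula applied to
the cell's parent states equals the cell's target state. The threshold
θ defaults to 0.85 — strict enough that genuinely mis-wired nodes fail and
trigger refinement, loose enough to tolerate the ~10 % effective
disagreement that 5 % independent bit-flip noise induces on parent and
target rows. All reported results carry their θ.

The staged search: (1) score every read-once function over the prior
parent set and all subsets reachable by recursive one-by-one parent
removal (auto-regulatory edges are dropped first — self-inputs are
excluded from dynamic rules); (2) only if nothing reaches θ, scan single
replacement parents from the refinement pool (the core pluripotency
factors), then pairs from that pool. The ensemble returned holds *every*
function at the maximal attained agreement; among equals, functions whose
literal polarities match more prior edge signs are ranked first (a
tie-break, not a filter — learning may legitimately flip signs). If no
stage reaches θ the best ensemble is returned flagged `unresolved`, never
silently empty.

Consensus edges require one polarity in more than 90 % of ensemble
members; mixed polarity blocks the link. High-in-degree nodes carry large
equally-fitted ensembles, so their consensus edges are sensitive to exact
ties — replicate datasets can produce visibly different consensus
neighborhoods for such nodes even when the underlying ensembles overlap
heavily. This is expected behavior, quantified by the cross-replicate
connectivity-stability number the acceptance script reports.

AND-gate analysis: for every AND node in a member formula, all cross
pairs of leaves between its two subtrees count as AND-joined regulator
pairs; pairs are ranked by the number of member functions containing
them, and a one-tailed Fisher exact test (against all unordered pairs of
a declared regulator universe) checks enrichment of a reference
protein-interaction pair set.

## Dynamics

Updates are synchronous; a trajectory is fully determined by (model,
initial state, perturbation). Attractors are detected by trajectory
memory on the first revisited state: fixed points or limit cycles. The
fixed-point notion of "steady state" is extended to any recurrent set —
limit cycles contribute their per-gene cycle mean — because synchronous
updating can produce cycles that a fixed-point-only account would have to
discard. Non-convergence within `max_steps` (default 30, reached within
3–9 steps in practice here) is a flagged outcome.

Knockdowns clamp genes to 0 at every step including t = 0. Per condition,
`n_init = 100` uniform random initial states (clamped genes fixed at 0)
estimate basin weights; per-gene activity is the basin-weighted attractor
mean, averaged over 10 networks sampled from the ensembles (uniformly and
independently per gene, seeded). Sampled models are held fixed across all
conditions of one screen so conditions are compared like-for-like. Genes
with empty/unresolved ensembles or no inputs get constant rules frozen at
their majority binarized value, keeping the state space closed. The
three-level change call is `ΔS = sign(g − g_baseline)` with |difference|
≤ 0.1 (on the [0,1] activity scale) mapped to "no change"; the three-level
coding implies some tolerance and 0.1 is the documented default.

## Concordance and robustness

Experimental log2 fold-changes are oriented in Ct space (positive =
down-regulation); conventionally signed input must be declared and is
flipped on ingest. Discordance is

    d = |ΔS + tanh(ΔE/c)|,   D = σ(k·(d − d₀)),

defaults k = 4, d₀ = 1, c = 2, giving D ≤ 0.05 at perfect agreement and
D ≥ 0.95 at maximal disagreement; the exact parameterization is a
module-level choice — any strictly increasing logistic of a disagreement
magnitude honoring the sign conventions would serve — and because the
logistic never saturates, a "percent concordance" display 100·(1 − D)
never reaches 100 even on ideal data. The objective O is the plain mean of
D over all gene × condition entries.

The benchmark predictor draws each entry i.i.d. uniformly from
{−1, 0, +1}; its expected objective has a closed form (three-point
mixture averaged over the fixed ΔE table) against which the Monte-Carlo
mean (500 draws) is checked, and a one-sample t-test compares the random
objectives with the model's.

Robustness curves rerun the whole learn → screen → compare pipeline on
progressively randomized inputs. Data mode selects ⌈p%⌉ of matrix entries
and re-draws each uniformly from {0, 1} — a deliberate choice over
deterministic inversion, because inverting *all* bits is the complement
map, which the read-once function class (closed under De Morgan duality)
learns straight back into an equivalent model; only uniform redraw makes
p = 100 genuinely information-free so that relative accuracy,
`(O_random − O(p)) / (O_random − O(0))`, is anchored at 1 for p = 0 and
at ≈ 0 for p = 100. Topology mode reassigns ⌈p%⌉ of edges to uniform new
ordered endpoint pairs, preserving edge count and signs and forbidding
duplicates. The robustness pipeline learns with an *empty* refinement
pool: reassignment from a pool covering the roster would simply repair a
rewired topology, masking exactly the contribution the randomization is
meant to probe. Residual accuracy slightly above 0 at p = 100 is
systematic, not noise: models learned from pure noise predict "no change"
more often than the uniform three-point predictor does, and ΔS = 0 is the
right call for the many near-zero fold-change entries.

## Lineage prediction

Marker signatures map genes to trophectoderm, (primitive) endoderm,
mesoderm, or ectoderm; the shipped signature covers the 15 in-network
markers and is an editable TSV so larger marker sets can anchor through
curated upstream links (sign-weighted mean change of their in-network
regulators) without enlarging the dynamical model. The simulation route
scores a lineage as the mean change signal of its markers after a
knockdown; the direct-target route is dynamics-free — each knocked-down
TF contributes −sign(TF → marker) per curated link, additively across the
knockdown set. Contrast between routes uses top-lineage agreement plus a
Spearman rank correlation over the four lineages (chosen for robustness
at tiny list length; reported as undefined when scores are constant).

## Synthetic data

The generator emulates a 96 × 96 microfluidic qPCR experiment from a known
ground truth: per cell, the true network relaxes from a random initial
state to an attractor; one attractor state is the cell's latent snapshot;
each bit flips with probability `flip_noise` (default 0.05); ON bits emit
Ct ~ N(20, 1.5) and OFF bits Ct ~ N(33, 1.5) capped at 35, with the
housekeeping gene fixed at Ct 15 — clearly bimodal −ΔCt histograms that
still leave the binarizer a realistic job. By default only fixed points
are sampled (limit-cycle hits are re-drawn, bounded retries): real cells
occupy stable expression states, and phase-mismatch limit cycles of the
synchronous scheme (half of all random starts for a mutual-activation
pair) would violate the steady-state snapshot assumption the learner
rests on. Cycle sampling remains available as an option.

The 8-gene preset is engineered for identifiability: two independent
bistable mutual-activation pairs act as heritable "cell states", and every
two-input readout draws its parents from *different* pairs — at fixed
points, within-module parents expose only two clean input patterns, which
cannot distinguish AND from OR from a single literal, whereas cross-module
parents expose all four. The 30-node preset equips the vendored seed
network with canonical rules — ON iff any activator is ON and no repressor
is ON — truncated to six parents, with input-free upstream signals held
ON.

Evidence generation emits one ChIP row per true edge plus configurable
numbers of LOF/GOF sign reports with independent sign-error probability;
fold-change panels simulate the true network under each clamp set and set
`ΔE = −scale·Δg + N(0, σ)` in Ct orientation (scale 4, σ 0.25 by
default). All generators are seed-deterministic: identical parameters and
seed give byte-identical outputs.

What passing synthetic tests does *not* show: robustness to doublets,
amplification-efficiency variation, dropout structure beyond the
detection cap, batch effects between chips, or non-bimodal genes — none
of which the generator emulates.

## Problem sizes and numerics

The shipped experiments use the study-scale defaults throughout: 96 cells,
5 % flip noise, θ = 0.85, 10 sampled networks × 100 initial conditions,
500 random-predictor draws, 10 robustness repeats. The robustness and
recovery experiments run on the 8-gene truth, where one full
learn/screen/compare pass is sub-second, so 10-repeat curves stay cheap;
the 30-node analyses (screens, dispersion, four-model consensus) run once
each in the acceptance script. Agreement comparisons use an absolute
tolerance of 1e−12 when collecting equal-agreement ensembles; exact
integer truth tables avoid floating-point ambiguity everywhere else.

## Known limitations

* The read-once restriction excludes XOR/threshold logic; canalizing
  functions outside this class are approximated or missed.
* Consensus networks at high in-degree are tie-sensitive (see above).
* Basin weights from 100 random starts carry binomial error (~5 % SE at
  w = 0.5); exact enumeration is provided only for small models.
* Clamp-ON (over-expression) conditions and asynchronous/probabilistic
  update schemes are out of scope.
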