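# Methods

This note documents the models and procedures implemented in `deepsubtype`,
the parameter choices that matter, what the synthetic cohorts do and do not
emulate, and the numerical decisions a maintainer should know about. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Aberration calling

For each gene g and tissue t, a Gaussian is fitted by maximum likelihood to
the expression of *control* samples of tissue t only (SD with the unbiased
n−1 divisor by default; `ddof` is configurable). A tumor value x is called

* +1 if x > μ + zσ, −1 if x < μ − zσ, where z = Φ⁻¹(1 − tail) with
  `tail = 0.001` per side (z ≈ 3.0902). The phrase "outside the 0.001
  percentile on either side" is read as two one-sided tails of mass 0.001
  each; a caller wanting a *total* two-sided mass of 0.001 passes
  `tail = 0.0005`. The parameter is exposed precisely because the reading
  is ambiguous.
* Under the low-variance rule (σ < `low_sd = 0.2`): +1 if x ≥ 3μ, −1 if
  x ≤ μ/3. The down-regulation threshold is the fold change's symmetric
  counterpart on the ratio scale. σ exactly equal to 0.2 uses the Gaussian
  branch ("smaller than" is strict). A nonpositive control mean under this
  rule is an error — fold change is undefined there — which the synthetic
  generator precludes by bounding control means ≥ 5 SD above zero.

Signed calls are kept internally so that copy-number masking can match
directions: +1 calls with amplification (+1, or +2 treated as +1) and −1
calls with deletion are zeroed; everything else contributes |call|. Controls
are never scored. A masking audit table (sample, gene, call, cnv, masked) is
emitted alongside the binary matrix.

## Feature filters

The Bernoulli-variance filter removes a gene when its fraction of 1s is
≥ p or ≤ 1−p (default p = 0.90; 0.95 and the high-variance 0.70 variant are
the same operation at another p). Boundary rates exactly at p are removed.
The tissue filter removes genes whose absolute Pearson correlation with any
tissue's one-hot indicator exceeds 0.85 — absolute, because an
anti-correlated tissue marker is just as confounding. Constant genes are
removed with reason "constant"; a single-tissue cohort makes the filter a
logged no-op. Both filters are stable (kept genes preserve input order),
idempotent, and monotone in their thresholds; the test suite checks these
properties against brute-force reimplementations.

## Deep belief network

The representation learner is a stack of Bernoulli RBMs with energy
E(v,h) = −hᵀWv − cᵀv − bᵀh and joint P(v,h) = e^{−E}/Z. All units are
logistic/Bernoulli — the data are binary, so no Gaussian visible units are
needed. Pre-training is greedy CD-k (default k = 1): the data-driven Gibbs
step samples binary hidden states, while the sufficient statistics on both
phases use mean-field probabilities; upper RBMs consume the hidden
*probabilities* of the layer below. Weights initialize from N(0, 0.01²),
offsets at zero; batch order is reshuffled every epoch from the run seed.

The pre-trained stack is unfolded into an encoder/decoder pair (decoder
weights start as transposes, then untie) and fine-tuned by plain minibatch
SGD on binary cross-entropy via backpropagation, with deterministic logistic
probabilities throughout. Momentum and weight decay exist as configuration
but default to zero. The training log records per-epoch cross-entropy
(reported per unit) and MSE reconstruction error; fine-tuning aborts when
cross-entropy becomes non-finite or exceeds 10× max(initial, ln 2) — the
ln 2 floor (the trivial p = 0.5 predictor) prevents a well pre-trained model
from being aborted over a transient SGD spike.

For RBMs with ≤ 20 total units the exact joint distribution, partition
function, log-likelihood, and likelihood gradient are available by full
state enumeration; these are the correctness oracles for the sampled
learner (probabilities agree to 1e−10; CD-1 raises the exact training-set
log-likelihood on ≥ 95% of seeded tiny runs).

Front end: `DeepBeliefNetwork(data, layer_sizes).fit()` returns a
`DbnResults` holding the trained autoencoder, the pre-trained stack, the
training log, `encode()`, error measures, HDF5 serialization (bit-exact
round trip), and a `summary()` table.

## Model selection

`make_folds` builds k near-equal disjoint folds (default 8) and marks
`n_eval` of them (default 4, seeded order) for evaluation — which four are
evaluated is a seeded choice. `evaluate_config` trains on each evaluated
fold's complement and records held-out MSE per fine-tuning epoch; a
configuration is flagged as overfitting when its final mean held-out error
exceeds the curve's own minimum by more than 5% (relative, configurable).
Random search draws learning rates log-uniformly and integer parameters
uniformly, rejecting draws that violate the structural constraints
(strictly decreasing layer sizes, optional unit cap). Grid search over
architectures produces the table used for elbow inspection; `elbow` reports
the maximum of the discrete second derivative on the (possibly non-uniform)
size grid and is never auto-applied. Early stopping is deliberately absent:
models train for their configured epochs.

## Consensus clustering and PAC

One trial: subsample ⌊0.8·n⌋ samples without replacement, cluster with
average-linkage agglomeration on Euclidean distances (scipy), cut at k.
Over 100 trials the consensus entry for a pair is its co-clustering count
divided by its co-sampling count; never co-sampled pairs are imputed 0 and
counted in a log field. The final assignment clusters 1 − consensus as a
distance with the same linkage. PAC is the fraction of off-diagonal pairs
with consensus *strictly* between 0.2 and 0.8 (boundary values count as
unambiguous; both bounds configurable). `select_k` returns the candidate k
with minimal PAC, ties toward smaller k, with the full PAC-vs-k table.

The ensemble vote ("consensus of consensus") pools per-model consensus
matrices by elementwise mean; pooling the final co-assignment indicators is
available as an option. The pooling rule for the original protocol is not
recoverable, so the equal-vote mean was adopted.

## Survival and correlates

Kaplan–Meier curves and the g-sample log-rank test delegate to lifelines
(chi-square with g−1 degrees of freedom, standard aggregated risk-set
handling of ties); the test suite verifies both against hand-computed
product-limit and observed/expected oracles. Cluster correlates are Pearson
correlations between each binary feature and the cluster's one-vs-rest
indicator — one-vs-rest because a multi-class label has no single
correlation. Top-k lists rank positive correlations only; the full signed
table is also exported, along with n, so users can compute significance or
corrections themselves (none are applied). Word-cloud weights rescale r
within each cluster only (max → 1.0); sizes are intentionally not
comparable across clusters.

## Synthetic cohorts

The generator emulates exactly the structure the analysis assumes:

* Per (tissue, gene) control Gaussians with means from U(4, 10) and SDs
  from U(0.25, 0.6); means sit ≥ 5 SD above zero so fold-change rules are
  well defined, and the default SD range keeps all genes on the Gaussian
  branch of the caller.
* A fixed hierarchy: processes → pathways → TFs → genes. Each subtype
  activates a deterministic set of processes (a binary code, distinct per
  subtype; the first min(n_subtypes, n_processes) subtypes get singleton,
  pairwise non-nested codes so planted clusters are mutually equidistant).
  Every active TF shifts its target genes by ± `effect_size` control SDs,
  direction fixed per TF (Bernoulli 0.5). The default `effect_size` is 6:
  a planted activation then lies well past the z ≈ 3.09 calling threshold
  (per-gene call probability ≈ 0.998), so subtype identity is effectively
  deterministic at the binary level and planted clusters are as symmetric
  as the hierarchy says. Shifts near the threshold (e.g. 4 SD, call
  probability ≈ 0.82) leak per-gene realization noise into the cluster
  geometry and make two subtypes systematically closer — a soft planting
  that defeats stability-based k selection.
* The coverage invariant (every gene targeted by ≥ 1 TF) is satisfied for
  non-signal genes by an inert background TF that no cascade ever
  activates.
* CNV events at rate 0.02 per (tumor, gene) with random sign shift
  expression by 3 control SDs with matching sign.
* Driver mutations: 5 genes per subtype at enrichment 0.6 over a 0.05
  background rate (background mutations only in tumors).
* Survival: exponential with hazard `baseline_hazard ×` a per-subtype
  ratio (default geometric 1…3); censoring is independent exponential with
  rate (3/7) × mean hazard, giving ~30% censoring.

What it does *not* emulate: RNA-seq count distributions, batch effects,
library-size effects, within-subtype pathway heterogeneity (a tumor's
active TFs are fully determined by its subtype), or methylation. Passing
tests therefore demonstrate correctness of the machinery under the model's
own assumptions, not robustness to real-data artifacts.

## Pipeline

`run_pipeline` chains cohort → aberration → filter → train (ensemble of 6
DBNs by default, desk-scale architectures around 55–70 / 25–50 / 8–12
units, 30 pre-training and 150 fine-tuning epochs) → consensus → survival →
correlates, writing every artifact with a SHA-256 checksum into
`manifest.json`. Stage seeds derive deterministically from the global seed,
so interrupted runs resumed with `--resume` finish byte-identical to
uninterrupted ones. Before pooling, the ensemble is screened: a model whose
final training cross-entropy exceeds 2× the ensemble's best is excluded
(at least the two best are kept). This mirrors the protocol of selecting
well-converged models before the ensemble vote; a badly converged
autoencoder can map two distinct subtypes to the same saturated top-layer
code and would cast a systematically wrong vote.

## Known limitations

* PAC-based k selection degenerates when several candidate cuts are all
  perfectly stable (PAC = 0): with tight, well-separated groups the 2-way
  cut is often exactly as stable as the true k, and the tie rule (smaller
  k) then under-partitions. On default synthetic cohorts this occurs in
  roughly one seed in six; the PAC-vs-k table and consensus heatmap are
  exported so the choice can be inspected, which is how the original
  protocol resolved it.
* Plain SGD fine-tuning can land in a local optimum that merges two input
  prototypes (visible as ~8× higher final cross-entropy); longer
  pre-training makes this rare and the ensemble screen removes the
  remainder.
* CD-1 is a biased gradient; the tests assert likelihood improvement on
  tiny enumerable instances, not convergence to the maximum-likelihood
  solution.
* The desk-scale problem sizes (hundreds of samples, hundreds of genes,
  tens of hidden units) were chosen so the full pipeline and test suite
  run in minutes on one CPU; all algorithms are size-agnostic.
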