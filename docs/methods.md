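# Methods

## Model

`dc3` jointly analyzes three assays measured on *separate* cells of one
heterogeneous population: a gene × cell expression matrix **E** (scRNA-seq),
an enhancer × cell accessibility matrix **O** (scATAC-seq), and an
enhancer–promoter loop table **C** (bulk HiChIP counts, or a loop-pair × cell
matrix for single-cell contact data). The standard input combination
("setting 2": single-cell RNA + single-cell ATAC + bulk loops) minimizes

```
  ½‖C − αD⊙(W₁ΛW₂ᵀ)‖²_F + (μ₁/2)‖E − W₁H₁‖²_F + (μ₂/2)‖O − W₂H₂‖²_F
  s.t.  columns of H₁, H₂ on the simplex,  Σₖ λₖ = 1,  all factors ≥ 0
```

Each NMF term clusters one single-cell modality: columns of **W** are
subpopulation archetypes, columns of **H** soft cluster-assignment weights.
The coupling term models each observed loop count as proportional to the
λ-weighted product of promoter expression and enhancer openness within each
subpopulation; **D** is the 0/1 indicator restricting the model to pairs
with count ≥ 1, and α a single free scale. The coupling forces the cluster
identities of the two modalities to correspond, which is what makes joint
("coupled") clustering and the decomposition of bulk loops into
subpopulation-specific loop profiles possible.

Three further input combinations are supported: all-single-cell input
(setting 1; the loop matrix gets its own NMF term, no coupling scale), and
one bulk profile vector replacing either the ATAC (setting 3) or the RNA
(setting 4) matrix, in which case the bulk vector is tied to the λ-weighted
mixture of the corresponding archetype columns, `‖v − Wλ‖²`. At least one
modality must be single cell; bulk-only input is unidentifiable and
rejected.

## Optimization

Multiplicative updates with closed-form refreshes for α (the trace ratio
`tr(ĈᵀC)/tr(ĈᵀĈ)` with `Ĉ = D⊙(W₁ΛW₂ᵀ)`, its exact minimizer) and λ (the
average assignment weight per cluster across both H matrices). Three facts
shape the implementation:

* **Per-substep verification.** Column renormalization of H and the λ
  re-estimate are not descent operations, so every substep (W₁, H₁, W₂, H₂,
  α, λ) is verified against the total objective and exponent-damped
  (`x ← x·ratio^γ`, γ halved) or rejected if it would increase it. The
  objective trajectory is therefore non-increasing by construction; the
  trace records it and a convergence flag (relative change < 1e-4 by
  default, the quantity we use as "relative error").
* **Symmetric α in the W₂ rule.** The gradient split of the coupling term
  puts α in the numerator and α² in the denominator of both W rules. An
  asymmetric variant that drops α from the W₂ rule is available
  (`symmetric_alpha=False`) but stalls at poor stationary points when
  α deviates from 1 (observed on noiseless recovery: W₂ column PCC 0.86 vs
  0.9998), so the symmetric rule is the default.
* **Column alignment at initialization.** E and O are initialized by
  independent non-negativity-projected ALS (Monte-Carlo restarts, best
  residual kept), which fixes an arbitrary cluster order per modality.
  Multiplicative updates cannot permute columns afterwards, so a mismatched
  order strands the fit: W₂/H₂ columns are permuted once, at
  initialization, by Hungarian assignment on the correlation between the
  observed loop counts and each candidate rank-one coupling component.

Denominators are floored at 1e-12. ALS zero entries are floored at 1e-10 of
the factor maximum so multiplicative updates stay alive. Degenerate H
columns (e.g. a cell zeroed entirely by dropout) are reset to uniform.
Hard labels are per-column argmax of H, ties to the smallest cluster index.

**Hyper-parameters.** μ₁ and μ₂ default to the ratio `‖C‖²/‖X‖²` of squared
norms, which balances the coupling and NMF terms at the data scale. The
grid search `select_hyperparameters` follows the residual-ratio base values
(coupling residual over each NMF residual at the ALS initialization) times
`10^{0..4}`, scored by the summed subpopulation-specific subnetwork
connectivity: per cluster, the top 5% cluster-specific genes and enhancers
(one-tailed Welch t-tests, ties by |t|) span a subnetwork whose edges are
the model's predicted per-cluster loop strengths α·d·λₖ·w¹ᵢₖ·w²ⱼₖ.

**Choosing K.** For each candidate K, repeated fits from random starts give
a co-clustering consensus over scRNA cells; average-linkage cophenetic
correlation of the consensus dissimilarity is computed and the K before the
largest drop is returned. Drops below 0.01 count as no drop, in which case
the smallest K wins. Limitation: on strongly separated desk-scale fixtures
the optimizer is stable enough that surplus clusters die identically across
runs and the coefficient barely falls — the rule then conservatively
returns the smallest K of the range rather than detecting K > 2 reliably.

## Subpopulation profiles

Cluster means of the single-cell matrices give the expression and
accessibility profiles P₁, P₂ (empty clusters yield zero columns with a
warning). The bulk loop table is deconvolved by the plug-in expression
`p³ᵢⱼₖ = α·dᵢⱼ·λₖ·p¹ᵢₖ·p²ⱼₖ` (the default, cheap), or by a Poisson MAP
model: the observed count Cᵢⱼ splits into latent per-cluster counts whose
prior is multinomial with probabilities ρᵢⱼₖ ∝ √(Oᵢₖ·Oⱼₖ), while
cluster-level gene expression is Poisson with rate β·Σ_q Cᵢqₖ, tying the
allocations of all loops of a gene together. Iterated conditional modes
visit pairs in descending-count order; each conditional maximization is
exact (composition enumeration) up to 1e5 compositions and greedy
unit-transfer ascent above. Counts are conserved exactly. β is unspecified
upstream; it is initialized at 1 and re-estimated each sweep by moment
matching (ΣE / Σ allocated counts), which keeps the expression likelihood
on the observed scale. The Poisson rate carries a smoothing constant
τ = 1e-8 (`rate_smoothing`) so that a cluster holding no reads of an
expressed gene has a very unfavorable but finite posterior; without it the
log posterior is −∞ whenever expression is observed where no reads are
allocated, which both breaks the ascent diagnostics and over-constrains
low-count genes. Promoter openness constants default to gene-level
expression or accessibility profiles supplied by the caller; the mapping
from genes to promoter peaks is data-dependent and not fixed by the method.

Which profile basis deconvolves bulk loops better depends on the
hyper-parameter regime: with large μ (the regime the connectivity grid
search favors) the W columns are driven by the noisy single cells and
cluster means win; with balanced μ the coupling informs W directly and
W-based profiles can win instead. The regression test pins the former,
NMF-dominated regime.

## Synthetic data

`generate_mixture` emulates an in-silico mixture of K cell types measured
by the three assays on disjoint cells. Defaults follow the two-cell-line
design: 146 scRNA cells, 746 scATAC cells, 200 single-cell loop cells,
split evenly (any λ is supported; cells are allocated proportionally and
deterministically). Feature counts (genes m, enhancers n) are free; the
acceptance analyses use m = 300, n = 500 for single-fit checks and
m = 60, n = 80 for repeated-fit benchmarks — sizes at which one fit takes
seconds to a couple of minutes on one core while every qualitative
phenomenon of interest is expressed.

Archetypes contain a `separation` fraction of cluster-exclusive marker
features (high in one cluster, near zero elsewhere); the remaining features
are shared. Cells are Poisson draws around their cluster archetype
(`noise="none"` gives exact archetype copies). Loop support pairs are
sampled uniformly at random; bulk counts are Poisson around
α·Σₖλₖw¹ᵢₖw²ⱼₖ with α set so the mean count hits `mean_loop_count`.
Single-cell loop matrices thin the bulk reads: each read picks a cluster
with probability proportional to its per-cluster intensity λₖw¹ᵢₖw²ⱼₖ —
the generative decomposition of the bulk count — then a uniform cell
within that cluster.

Dropout is entrywise Bernoulli zeroing at the stated rate (grid 0, 0.5,
0.8, 0.9). Drop-seq-style down-sampling replaces each entry by a Poisson
draw with mean P/100 and zeroes it with probability
`1 − 1/(1 + (P/100)^(−0.1))` — the keep probability rises with expression,
matching shallow droplet data; the alternative literal precedence
`1/(1 + P·100^0.1)` is available behind `literal=True`.

What the generator does *not* emulate: batch effects, doublets, ambient
contamination, UMI saturation, distance-dependent loop background, or any
genomic coordinate structure. Passing tests therefore show internal
consistency of the method under its own generative assumptions plus
robustness to entrywise dropout — not performance on real sequencing data.
Two empirical sensitivities are worth knowing: the coupling's clustering
benefit under heavy dropout requires a loop table dense enough to inform
the factors (the benchmark fixture uses ~17 loops per gene; at ~4 loops per
gene the benefit disappears), and it grows with loop sequencing depth.

## Evaluation

Deconvolution PCC compares true and predicted per-cluster profiles as
n-dimensional vectors after Hungarian matching of predicted to true
clusters by maximum PCC (both the per-cluster mean and the
concatenated-vector variant are available). Clustering error is the
minimum misclassification fraction over cluster relabelings (exhaustive to
K = 6, Hungarian beyond). The benchmark harness runs the coupled model, a
no-coupling comparator (identical optimizer on an empty loop table —
isolating the loop contribution), and plain per-modality sklearn NMF, over
a dropout grid with repeated restarts, reporting mean ± sd.

The random-deconvolution null permutes the cell-to-cluster labels of both
modalities, recomputes cluster means and plug-in loop profiles, and scores
them against the truth — the distribution a label-free deconvolution would
produce.

## Regulatory networks

Subpopulation-specific genes combine two one-tailed p-values by Fisher's
method (χ² with 4 df): a Welch t-test on expression (cluster vs rest) and a
binomial test on loop evidence — each interaction's per-cluster loop
strengths are rescaled to a total of N = 10, the (rounded) count in the
cluster is tested against Binomial(N, 1/K) upper tail, and a gene takes its
most significant interaction (p = 1 with no interaction). Motif enrichment
is scored as √(−log₁₀(p)·fold-change). Key regulators require FPKM > 10,
motif score > 2 (both strict) and a BH-adjusted two-sided differential
expression p < 0.01 against at least one other cluster; they are ranked by
log₂(FPKM) × expression specificity (max fold change vs the other
clusters) × motif score. TF→gene edge weights sum motif-score × loop-count
over TF–enhancer–gene triples with loop count ≥ 2, significant motif match
and significant TF–gene correlation, restricted to key-TF nodes.

Dense subnetworks maximize Σ WᵢⱼxᵢyⱼÂ over the product of simplices (the
β = 1, L1 constraint) by alternating replicator updates from the uniform
start; support is weights > 1e-6, partitioned into upstream (x only), core
(both) and downstream (y only). The exact optimum of the β = 1 program is a
single max-weight edge; the replicator is the operational definition and
concentrates accordingly on heterogeneous-weight graphs, while near-tied
dense blocks (e.g. a constant-weight complete sub-digraph, self-loops
included) retain multi-node support — the planted-recovery fixture uses
that form. Significance comes from degree-preserving edge switching (pick
two edges (a→b), (c→d), rewire to (a→d), (c→b); reject duplicates and —
configurably — self-loops; weights travel with their source slot), 1000
accepted switches per null network, 1000 nulls, and the add-one estimator
`p = (#null ≥ observed + 1)/(n + 1)`.

Surface-marker selection ranks candidate surface-protein genes by t-test,
keeps the top 20, and requires mean TPM > 10 in the target cluster, < 2
(strict) in every other cluster, and the target mean highest. GO-term
filtering keeps externally computed per-cluster terms with score above
threshold and removes terms significant in all clusters; the enrichment
computation itself is out of scope and the filter operates on whatever
score the external tool reports.

## Numerical conventions and degenerate inputs

Genomic coordinates are 0-based half-open throughout; TSS is strand-aware
(start on +, end − 1 on −) and the promoter window defaults to ±2000 bp
(configurable — upstream loop-calling pipelines differ here). "Peak present
in a cell" means count > 0. Replicate QC passes with ≥ 500 loops of count
> 5 (strict). Loop tables with non-integer counts are rounded (with a
warning) for the Poisson MAP model only. All randomness flows from one
user-supplied seed through spawned `SeedSequence` streams; fits are
bitwise reproducible given (data, parameters, seed).
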