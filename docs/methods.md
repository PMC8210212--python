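# Methods

`cellcircuit` estimates the activity of signaling circuits — the
sub-networks that carry signal from receptor proteins to one effector
protein inside a pathway — in individual cells, from single-cell RNA-seq
expression, and uses those activities to compare cell populations and to
simulate targeted drug interventions per cell.

## Signal propagation model

A pathway is a signed directed graph; a node may carry several genes (a
family of proteins sharing the transducer role).  For a circuit, each node
*n* holds a normalized expression value `v_n ∈ [0, 1]` and transmits

    S_n = v_n · (1 − ∏_{s_a ∈ A} (1 − s_a)) · ∏_{s_i ∈ I} (1 − s_i)

where `A` and `I` are the signals arriving on activating and inhibiting
edges.  The effector's `S` is the circuit activity.  Conventions the
formula itself leaves open:

- **Receptor seeding.** Receptor nodes receive one implicit activation of
  1, so `S_receptor = v_receptor`: incoming signal at the top of a pathway
  is assumed present, and the receptor's own expression gates it.  Without
  this convention every source node would transmit zero.
- **Inhibitor-only nodes.** A node with inhibiting inputs but no activating
  edge uses an activation factor of 1, so inhibition alone can gate it.
- **Multi-gene nodes.** Summarized by the mean of the member genes' values
  (configurable: `min`, `percentile90`).  Genes absent from the matrix
  contribute a neutral 0.5 by default (configurable; `None` turns absence
  into an error).  Distinguishing "not measured" (0.5) from "measured zero"
  (0) matters because a zero anywhere on the only route to the effector
  switches the circuit off.
- **Evaluation.** Acyclic circuits are evaluated exactly in topological
  order.  Circuits with feedback loops are iterated synchronously from
  all-zero signals to a fixed point (tol 1e-6 on the max-abs change, max
  100 sweeps; non-convergence is an error carrying the last residual).  On
  acyclic circuits the two strategies agree to numerical precision, which
  is tested.

Circuit extraction is reachability-based: a node belongs to the circuit of
effector *e* if it is reachable from some receptor and *e* is reachable
from it.  For acyclic graphs this equals the union of all simple
receptor→effector paths (tested against exhaustive path enumeration); for
cyclic graphs it is the standard generalization.  Receptors and effectors
default to sources and sinks of the graph, overridable by boolean columns
in the node table or by explicit lists, because curated pathway resources
annotate these roles explicitly.

## Preprocessing

The model needs per-gene values in [0, 1] and true zeros distinguished from
dropout.  The pipeline is:

1. **Dropout imputation** (counts stage).  Cells are clustered once per
   combination of k ∈ {2, …, 8} and two cell–cell geometries — Euclidean
   distance on log1p counts, and a Spearman-style geometry (Euclidean on
   per-cell standardized gene ranks).  A zero entry is replaced by the
   average, over the 14 clusterings, of the gene's within-cluster mean
   (zeros included in the mean).  Nonzero entries are never altered, and an
   all-zero gene stays zero.  Averaging over many clusterings is what makes
   the estimate robust to any single bad partition; the within-cluster mean
   including zeros is a deliberately conservative estimate (a gene that is
   off in most of a cluster is imputed low).
2. **log(1+x) transform.**
3. **Quantile truncation** at each gene's 0.99 quantile (linear
   interpolation, the sort-based type-7 convention), so a single outlier
   cell cannot own a gene's whole dynamic range.
4. **Per-gene min–max scaling** to [0, 1]; constant genes map to zero.
   Truncation and scaling are per-gene by default so every gene's dynamic
   range is usable by the model; a matrix-global mode is available.

Clustering for population structure runs k-means on a 2-D embedding of the
cells.  The default embedding is the first two principal components,
because it is deterministic; a precomputed cells×2 table (e.g. a t-SNE
layout from any implementation) is accepted instead.  Agreement between
partitions is scored with the plain Rand index (fraction of concordant cell
pairs) and the chance-corrected adjusted Rand index.

## Differential circuit activity

Circuit activities of two cell groups are compared with a moderated t
statistic.  Per-circuit pooled variances are modeled as draws from a scaled
inverse-chi-squared prior whose parameters (d0, s0²) are fitted across all
circuits by method of moments on log variances; each circuit's posterior
variance is `s̃² = (d0·s0² + d_g·s_g²)/(d0 + d_g)` and the t statistic
gains d0 degrees of freedom.  With d0 = 0 the statistic reduces exactly to
the ordinary pooled two-sample t (tested on 10⁴ random instances); in the
non-degenerate case the fit and the resulting t and p values match the
Bioconductor reference implementation of this shrinkage estimator to
rtol 1e-8 (live cross-check in the test suite).  Two deliberate
simplifications: no intensity-dependent trend in the prior (simple
moments), and a two-group contrast only (no covariates or blocking).
Degenerate inputs: variances are floored at 1e-12, a circuit constant in
both groups gets t = 0, p = 1 by convention, and a set of exactly equal
variances yields d0 = ∞ with s0² equal to that common variance.
Multiplicity is controlled by Benjamini–Hochberg FDR (two-sided p, α
default 0.05).

## Hallmark aggregation

A circuit inherits the union of the cancer-hallmark annotations (GMT
input) of the genes in its *effector* node — the effector is what triggers
the cell function, so annotation through any member gene would conflate
transduction with outcome.  Across groups, "common" circuits are those
significant in every group; each group's "extra" set is its significant
circuits minus the common core, so common + extras partitions each group's
significant set exactly (asserted on random tables).  Two percentage views
are reported: share of the group's significant circuits, and share of all
circuits annotated to the hallmark.  UP/DOWN directions are retained per
circuit and group.

## Drug perturbation

A drug is a set of (gene, action) targets.  Inhibitors and antagonists set
the target's normalized expression to 0.0, agonists to 1.0 (both
configurable; a fractional mode multiplies by 1 − efficacy).  Activities
are recomputed on the edited profile and compared as
`LFC = log2((S' + ε)/(S + ε))` with ε = 1e-3, which caps |LFC| near 10 for
a total shutdown on the [0, 1] activity scale.  A cell's impact is the
mean |LFC| over the circuits in which a target gene participates (sum and
max modes available); circuits containing no target gene have identically
zero LFC.  Responders and low-responders are separated by 1-D 2-means on
the impact scores (higher-mean component = responders; threshold = midpoint
of component means), because no fixed cutoff generalizes across drugs; a
silhouette score flags weak bimodality.  The low-responder mechanism the
model exposes: a cell that already expresses the target weakly while
another ligand in the same node is high keeps the node — and every circuit
it feeds — active, so the knockdown barely moves its activities.

## Synthetic cohort

The generator provides full ground truth so every stage is testable without
external downloads.  Defaults (all in `SimulationConfig`):

- **Topology.** 5 random DAG pathways of 10 nodes, edge probability 0.3
  between ordered node pairs, 15% of edges inhibitory, 1–3 genes per node;
  regenerated until at least one source and sink exist and all sinks are
  reachable.  Pathway 1 is the drug pathway: one receptor node carries both
  the drug target and a compensator ligand.
- **Cells.** 3 types × 60 cells.  Gene base means are log-normal (median
  ≈ e, i.e. a few counts per cell, typical of non-UMI droplet depth after
  gene-level aggregation).  Each type is assigned one non-drug pathway and
  all genes of that pathway's circuits are shifted by 2.0 log2 units in
  that type — fold changes are injected on gene means, not on activities,
  so the propagation model is genuinely exercised, and the disjoint gene
  sets across types make the planted programs identifiable.
- **Counts.** Negative binomial (dispersion 2.0) with log-normal library
  factors (σ = 0.3).
- **Dropout.** A count is zeroed with probability exp(−λ·log1p(μ)²) —
  abundant transcripts drop out rarely, matching the empirical double-
  exponential decay of single-cell capture failure.  λ = 0.2 places the
  matrix at 64–68% zeros, the sparse regime imputation is meant for.
  λ = 0 disables dropout entirely (the parameter is an on/off intensity;
  note that among positive values, smaller λ means more dropout).  The
  pre-dropout matrix is kept for scoring imputation against truth.
- **Resistance.** 15% of type-0 cells get the target mean ×0.1 and the
  compensator mean ×5 (target base mean 20, compensator 2), reproducing
  the low-target/high-compensator structure.

What the generator does **not** emulate: UMI/read-level noise, ambient
RNA, batch effects, doublets, or realistic pathway topology sizes.
Passing the recovery tests therefore shows the pipeline is correct and
well-calibrated under its own assumptions — clean NB noise and cleanly
separated planted programs — not that it would reach the same accuracy on
real tissue data.

## Problem sizes used in tests and the acceptance script

Recovery statistics are computed on cohorts of 180 cells × ~100 genes ×
~16 circuits, averaged over 10–20 generator seeds; the differential
power/FDR study uses 20 shifted + 200 null circuits at 100 cells per group
over 10–12 seeds; oracle agreement uses 200 random DAG circuits (≤ 12
nodes) and 10⁴ randomized monotonicity perturbations.  These sizes give
stable averages (SE of the reported means well under the margins asserted)
while keeping the whole suite fast.

## Known limitations

- The receptor-seeding convention (implicit activation of 1) is a
  documented choice; published implementations of this model family do not
  all state theirs, and no equivalence is claimed.
- The consensus imputer pools a dropout cell with its cluster: expression
  structure confined to very few genes (smaller than what clustering can
  see) is partially averaged away.  In the resistance analysis the planted
  signal survives because the compensator — not only the low target —
  carries the discriminating information.
- Fixed-point iteration on cyclic circuits is a contraction in practice
  but no convergence proof is supplied; the error contract reports the
  residual.
- The two-group moderated t does not support covariates, patient blocking
  or more than two groups.
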