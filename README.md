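# cellcircuit

Mechanistic signaling-circuit analysis for single-cell expression data.

Single-cell RNA-seq shows *what* genes each cell expresses; `cellcircuit`
estimates *what the cell can do with them*.  It propagates normalized
expression through signed pathway topologies to score, per cell, the
activity of every signaling circuit — the sub-network connecting receptor
proteins to one effector protein — then uses those activities to compare
cell populations, summarize differences by cancer hallmark, and simulate
targeted drug interventions cell by cell.  The drug simulation exposes a
clinically interesting pattern: cells that already express the drugged
ligand weakly while a second ligand in the same node carries the signal are
nearly insensitive to the knockdown (*low responders*), a mechanistic
explanation for innate resistance to targeted therapy.

It is written for computational biologists who have a genes×cells matrix,
pathway topologies in a plain-text signed edge list, hallmark annotations
in GMT, and a drug→target table — and who want a tested, deterministic
pipeline rather than a web service.

## The model

Each pathway node *n* (one or more genes) carries a normalized expression
value `v_n ∈ [0, 1]` and emits a signal computed recursively from its
incoming activating signals `A` and inhibiting signals `I`:

```
S_n = v_n · (1 − ∏_{s_a ∈ A} (1 − s_a)) · ∏_{s_i ∈ I} (1 − s_i)
```

Receptor nodes receive an implicit activation of 1 (so `S_receptor =
v_receptor`); the effector's signal is the circuit activity.  Around this
core the package provides:

- consensus-cluster dropout imputation, log/quantile-0.99/min-max
  normalization (raw counts → model-ready values);
- 2-D embedding + k-means clustering with Rand / adjusted-Rand comparison
  against reference partitions;
- empirical-Bayes moderated-t differential circuit activity with BH FDR
  (matches the Bioconductor reference shrinkage to 1e-8, see tests);
- effector-gene → cancer-hallmark aggregation (common vs group-specific);
- per-cell drug perturbation (inhibitor/antagonist/agonist), log2
  fold-change impact scores and responder / low-responder classification;
- a fully ground-truthed synthetic-data generator so the entire pipeline is
  testable offline.

See `docs/methods.md` for conventions, parameter defaults and limitations.

## Worked example

```python
import cellcircuit as cc

cfg = cc.SimulationConfig(seed=1)          # 3 cell types, planted structure
graphs = cc.generate_pathways(cfg)
expr, truth = cc.generate_cells(cfg, graphs)

imputed = cc.impute_dropouts(expr, seed=1)
norm    = cc.normalize_expression(imputed)
acts    = cc.activity_matrix(norm, truth.circuits, graphs)
labels  = cc.cluster_cells(acts, k=3, seed=1)

drug = cc.DrugSpec("TargetInhibitor", (("VEGFA", "inhibitor"),))
res  = cc.simulate_drug(norm, drug, truth.circuits, graphs, seed=1)
```

With a few `print` statements around these calls, the run reports:

```
cohort: 104 genes x 180 cells, 16 circuits, 66% zeros
adjusted Rand vs true cell types: 0.966
differential circuits (type 0 vs rest): 13 significant; planted recovered: 5/5
VEGFA knockdown: 2 target circuits; median impact 0.76; 117 low-responders
planted resistant cells labeled low-responder: 89% (rank-sum p = 1.4e-06)
```

Reading: two thirds of the raw counts are zeros, yet after imputation the
circuit-activity clustering recovers the three planted cell types almost
perfectly (adjusted Rand 0.966 vs ~0.4 without imputation); all five
circuits planted in type 0 are called differentially active; and the
simulated VEGFA knockdown leaves the planted resistant cells (low VEGFA,
high co-node compensator) with impact scores far below the responders.

The same stages are available on the command line
(`cellcircuit simulate | impute | normalize | activity | cluster | diff |
hallmarks | perturb | run`); `cellcircuit run` executes the whole pipeline
and writes a JSON manifest alongside the outputs.

## File formats

| Input | Format |
|---|---|
| expression | TSV (genes × cells) or MatrixMarket MTX + name sidecars |
| pathways | TSV edge list `pathway_id source sign target` + node table `pathway_id node_id genes [label] [is_receptor] [is_effector]` |
| hallmark annotations | GMT (set name, description, gene symbols) |
| drugs | TSV `drug gene action` with action ∈ inhibitor / antagonist / agonist |

All outputs are TSV/JSON and re-readable by the package's own readers.
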