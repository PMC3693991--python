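# paretomi

Pareto-optimality based identification of the most reliable QSAR model for a
query chemical compound, from a collection of pre-existing models.

## The problem

QSAR (quantitative structure–activity relationship) models predict an
activity endpoint — e.g. `log(1/IGC50)`, the toxicity of a chemical to
*Tetrahymena pyriformis* — from molecular structure.  In practice many
models exist for the same endpoint, each reliable only inside its own
applicability domain, and the practical question is *which* model to trust
for a new compound.  `paretomi` automates that choice.

For a query compound *q* and a reference table of chemicals with known
activities and per-model predictions, every (chemical *i*, model *m*) pair
becomes a 2D point

&nbsp;&nbsp;&nbsp;&nbsp;(dᵢ, eᵢₘ) = (1 − Tanimoto(q, i),  |yᵢ − y′ᵢₘ|),

i.e. the structural distance of *i* to the query and the absolute error of
model *m* on *i*.  Minimising both criteria at once is a bi-criteria
problem: its solution set is the **Pareto front** Γ — the points no other
point beats on both coordinates.  The *n-Pareto neighbourhood* keeps at
most *n* front points with distance below a threshold τ, and one model is
then selected by:

* **n-APMI** — average each model's errors over the distinct neighbourhood
  chemicals; pick the smallest average;
* **n-CPMI** — pick the model tagged to the front point closest (Euclidean)
  to the neighbourhood centroid c = (mean d, mean e);
* **DMS** — baseline: the best model of the single nearest neighbour.

Every query receives exactly one model, so each rule realises a
*partitioning model* M̂ that splits chemical space into disjoint per-model
regions.  Selection quality is scored against the **oracle** (the model
with minimal error for each chemical — an upper bound) and by the
regression statistics R², RSE, Q², MAE, RMSE of the resulting predictions.

The package ships the two printed narcosis models for the IGC50 endpoint —
NPN: `log(1/IGC50) = 0.83·logP − 2.07` and PN: `log(1/IGC50) = 0.62·logP −
1.00` — plus a synthetic clustered dataset generator, so every stage is
testable without external data.

## Worked example

`python examples/identify_query.py` reruns the two worked neighbourhood
examples:

```
query: 3-Phenyl-1-propanol
  Pareto neighbourhood (distance, error, model):
    4-Chloro-3-methylphenol: d=0.30 e=0.610 [PN]
    Methylbenzene: d=0.33 e=0.280 [NPN]
    4-Dimethylbenzene: d=0.36 e=0.080 [NPN]
  mean PN error over neighbours: 0.5067
  mean NPN error over neighbours: 0.5000
  selected: NPN (expected NPN)
```

The three front points are the query's 3-Pareto neighbourhood (all closer
than τ = 0.4); NPN's mean error over those chemicals (0.5000) beats PN's
(0.5067), so the NPN model is identified for this query.  The second query
(Benzylamine) resolves to PN (0.1705 vs 0.4850).

Other examples: `pareto_front.py` (raw 2D front + initial set),
`loo_evaluation.py` (leave-one-out method comparison on clustered data),
`similarity_analysis.py` (pairwise similarity-vs-activity counts).

A thin CLI wraps the same library:

```
paretomi generate --n 500 --bits 256 --clusters 4 --models 4 --seed 42 --out t.csv
paretomi evaluate --table t.csv --method 3-apmi --out report.json
paretomi identify --table t.csv --query-id C0007 --method 3-cpmi --out res.json
paretomi pareto   --points pts.csv
paretomi simtable --table t.csv --out sim.csv
```

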