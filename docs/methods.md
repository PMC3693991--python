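# Methods

## Model and procedure

The package treats QSAR model selection as a bi-criteria minimisation.  For
a query chemical *q*, each (reference chemical *i*, model *m*) pair yields a
point (dᵢ, eᵢₘ): the Tanimoto distance of *i*'s binary fingerprint to *q*'s,
and model *m*'s absolute prediction error on *i*.  The vector set is built
*jointly* over all models (one front for all candidates), since a candidate
is only interesting relative to every alternative, not just alternatives
from the same model.  A reference row whose id equals the query's is always
excluded, which makes leave-one-out evaluation a plain loop over queries.

The Pareto front of the point set is computed by divide and conquer: a
minimal point γ is found by random descent (start at a random candidate,
repeatedly move to any point coordinate-wise no larger and different),
every point sharing γ's exact coordinates is emitted, the region dominated
by γ is discarded, and the two open rectangles strictly left-above and
right-below γ are processed in turn.  An explicit work stack replaces
recursion because the front can be as large as the input (an anti-chain),
which would otherwise exceed interpreter recursion limits.  The output is
seed-invariant; only the internal search order is randomised.  An O(n²)
all-pairs implementation of the same definition is kept solely as an
independent test oracle.

Selection then uses the *n-Pareto neighbourhood*: front points with d
strictly below τ, sorted by ascending d (ties: ascending e, compound id,
model id), truncated to the *n* nearest.  APMI averages each model's full
error column over the distinct chemicals represented (a chemical reached
through two tags counts once); CPMI takes the model of the point nearest
the neighbourhood centroid; DMS ignores the front and takes the best model
of the single nearest chemical.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| n | max neighbourhood size | 3 | the named 3-APMI/3-CPMI variants |
| τ | distance threshold (Tanimoto units, strict `<`) | 0.4 for n=3; 0.7 for n=5; 1.0 for n=10 | the experimentally tuned pairings exposed in the method registry |
| positive class | model counted for FP/FN | first model of the collection | the convention is dataset-specific, so it is configurable |

Named variants: `3-apmi`, `5-apmi`, `3-cpmi`, `5-cpmi`, `10-cpmi`, `dms`.

## Numerical choices and tie-breaks

* Coordinate comparisons are exact — no floating tolerance.  Inputs are
  short decimals and ratios of integer bit counts; a tolerance would merge
  distinct front points silently.  Points with exactly equal coordinates
  but different (compound, model) tags are all retained on the front.
* Tie-breaks (all deterministic, all logged in results): APMI — equal
  average errors take the model listed first; CPMI — equal centroid
  distances take the lower-error, then lower-distance point, then model
  order; DMS — equidistant chemicals take the smaller best-error, then id
  order.
* When no front point has d < τ, the nearest front point is used and
  flagged (`fallback_used`) rather than refusing: the partitioning model
  must be total over chemical space.
* All-zero fingerprints are rejected at construction (Tanimoto is 0/0
  for them); Tanimoto is the standard |a∧b|/|a∨b|.
* R² is the squared Pearson correlation of observed and predicted values
  and RSE the residual standard error of regressing observed on predicted
  (√(SSE/(n−2))).  Both are affine-invariant in the predictions — the
  property that makes two affinely-related one-descriptor models share
  them exactly.  Q² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)² with ȳ over the evaluated set.
  Predictions constant across chemicals get R² = 0 by convention.
  Regression statistics require ≥ 3 points and are omitted (None) for
  smaller tables.
* Error matrices are always recomputed as |activity − prediction| on table
  construction and on CSV load, never trusted from file.

## Synthetic data generator

`generate_dataset` emulates the structure the method assumes of real
chemical space: *k* structural clusters (fingerprints are cluster
prototypes with independent per-bit flips at `flip_prob`), a latent
logP-like descriptor uniform on [0, 5], cluster-specific affine activity
laws (slope ∈ [0.5, 1.5], intercept ∈ [−2, 0]) with Gaussian noise
(`local_noise_sd`), and one specialist model per cluster that applies its
cluster's true law everywhere but incurs an additive `foreign_bias` off
cluster.  Defaults: 500 chemicals, 256 bits, 4 clusters/models, flip 0.05,
noise 0.1, bias 1.0, seed 42.  Ground-truth cluster labels are returned
separately (and written only to a side file by the CLI) so identification
never sees them.

What the generator does *not* emulate: real fingerprint bit correlations
(fragment co-occurrence), activity cliffs, heterogeneous cluster sizes and
densities, or models whose error grows smoothly with distance from their
training domain.  Passing tests on generated data therefore demonstrate
that the machinery recovers planted structure under the stated noise, not
that any particular accuracy transfers to a real endpoint dataset.

The two printed worked-example neighbourhoods are materialised as small
model tables with synthetic stand-in fingerprints engineered to reproduce
the printed Tanimoto distances (subsets of a 100-on-bit query fingerprint),
with predictions back-computed so the recomputed errors equal the printed
PN/NPN errors.

## Evaluation protocol

Leave-one-out: each chemical in turn is the query; the identification runs
on the remaining rows; the selected label is scored against the oracle
(row-wise error argmin, ties to the first model) and the selected model's
stored prediction for the query enters the partitioning model's prediction
vector, scored with the regression statistics above.  The pseudo-method
`"oracle"` evaluates the oracle selector itself and upper-bounds every
method on accuracy, Q², MAE and RMSE.

The pairwise similarity-activity table counts, over all unordered chemical
pairs, those with Tanimoto distance ≤ row threshold and |activity
difference| ≤ column threshold.  Thresholds are inclusive so the (0, 0)
cell counts identical-fingerprint, identical-activity pairs.

## Problem sizes

The test suite verifies front/oracle agreement on 1000 random instances of
up to 500 points and runs the leave-one-out protocol at 500 chemicals ×
4 models in the low-noise (flip 0.02, noise 0.05) and moderate-noise
(generator defaults) regimes; the acceptance script uses 500 random front
instances of up to 300 points and the same two 500-chemical LOO runs.

## Known limitations

* The front algorithm and the initial-set bounds are 2D-specific; K > 2
  criteria are out of scope.
* Fingerprints are consumed precomputed; the bundled SMILES adapter
  (RDKit) produces toolkit-version-dependent bits and is not used by the
  core or its tests.
* The bundled PN/NPN models reproduce external predictions only given the
  same logP values; logP is an input column, not computed here.
* Missing predictions make a (chemical, model) pair ineligible as a Pareto
  vector; no imputation is attempted.
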