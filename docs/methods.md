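# Methods

## Model

`repowalk` scores candidate drug-disease associations by diffusion on a
heterogeneous network with two node types. The network couples three layers:

* **Associations** `A` (n drugs x m diseases, binary): curated known
  indications.
* **Drug-drug similarity** `w^(c)`: the probability disjunction
  `w = 1 - (1 - w1)(1 - w2)` of (1) the Jaccard similarity of binary chemical
  fingerprint vectors and (2) the bipartite resource-allocation projection of
  `A` onto drugs, `w2[i,j] = (1/k(c_i)) Σ_l a_il a_jl / k(d_l)`. The
  projection is deliberately asymmetric (each row of a connected node sums to
  1 — one unit of resource redistributed); the fused matrix inherits that
  asymmetry and is never symmetrised, which is well-defined because transition
  construction normalises row-wise.
* **Disease-disease similarity** `w^(d)`: the same disjunction of the cosine
  similarity of nonnegative concept-weight vectors (MeSH-style term weights)
  and the dual projection of `A` onto diseases.

From these the row-stochastic transition matrix is assembled blockwise. For a
drug with at least one association, a fraction `λ` of its mass crosses to its
associated diseases (equally split) and `1 − λ` stays on the drug side,
distributed proportionally to its (row-normalised) similarities; a drug with
no associations keeps all its mass on the drug side. Disease rows are dual.

A candidate pair (drug i, disease j) is scored by two restart walks
`P(t+1) = (1 − α) Tᵀ P(t) + α P₀`:

* the **drug-centric** pass seeds `η` on drug i and `1 − η` spread equally on
  its known diseases, and reads out the steady-state probability at disease j;
* the **disease-centric** pass is the mirror image, read out at drug i.

The confidence score is the mean of the two steady-state probabilities. `Tᵀ`
is the transpose of the row-stochastic transition matrix — the standard
column-action form, so probability mass flows along transitions.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `lambda_jump` (λ) | cross-network jump probability | 0.8 | 0 confines the walk to one node type |
| `alpha_restart` (α) | restart probability per step | 0.3 | contraction ratio of the iteration is 1 − α |
| `eta_tradeoff` (η) | seed-mass split | 0.4 | 1 puts all initial mass on the query node |
| `epsilon` (ε) | L1 convergence tolerance | 1e-10 | |
| `max_iter` | iteration cap | 10000 | the geometric bound needs ≤ ~67 at α = 0.3 |

The defaults are the reference setting of the method; all ranges are enforced
at construction.

## Numerical choices and degenerate inputs

* **Uniqueness and initialisation.** For α > 0 the iteration is an affine
  contraction with a unique fixed point; we start from `P₀` itself, which
  affects only the iteration count. The iterative solution agrees with the
  closed form `α (I − (1 − α) Tᵀ)⁻¹ P₀` to sup-norm < 1e-8 (tested on random
  fixtures up to 200 nodes).
* **Similarity self-loops** are removed before row normalisation
  (`zero_diagonal=True`, switchable): a self-loop would siphon transition
  mass without moving the walker between distinct nodes.
* **All-zero feature vectors** have similarity 0 to everything, themselves
  included (no evidence rather than NaN). **Isolated nodes** get a zero
  projection row.
* **A node with associations but zero similarity mass** cannot place its
  `1 − λ` intra-type share; its whole transition mass is moved to the cross
  block (logged). With λ = 0 crossing is forbidden, so such a row is left
  zero instead — preserving exact cross-network isolation at λ = 0.
* **Fully disconnected nodes** (no associations, no similarity) get a zero
  row; the walk then leaks mass, which the restart term continually
  replenishes, so `Σ P* ≤ 1` with equality iff no zero rows exist.
* **Degenerate seeds.** A query drug with no known diseases gets full unit
  seed mass (η effectively 1), so never-annotated drugs remain scorable;
  dually for diseases.
* **Ties** in ranking break on (drug_id, disease_id) lexicographically,
  deterministic across platforms.
* **Storage.** The transition matrix is dense up to 3000 nodes and CSR
  beyond, with values identical to 1e-12 either way.

## Evaluation protocol

Known associations are split by association (not by node) into k folds of
near-equal size. Per fold, the association-derived similarities and the
transition matrix are rebuilt **from training edges only** — held-out edges
contribute nothing to the model and merely become candidates. All candidate
pairs of the training network are scored; candidates from all folds are
pooled for the headline ROC/AUC (per-fold AUCs and their mean are reported
alongside — the pooled variant matches ranking *all* candidate associations,
which is how predictions would be consumed). AUC is the rank (Mann-Whitney)
statistic with midrank tie handling, identical to the trapezoidal area under
the ROC curve. The negative class is every unknown candidate pair; negatives
are not subsampled.

Top-rank hit counts use per-disease rankings of candidate drugs (matching how
predictions for a disease of interest are read); a held-out association is a
hit at threshold t if its drug ranks in the top t for its disease,
*inclusive* at the boundary. A per-drug ranking mode would be symmetric; the
per-disease view is the default because queries are disease-centred in
practice.

The two-pass score is compared with each single pass on identical folds and
identical walks (only the ranking column differs), so the comparison has no
extra sampling noise.

## Synthetic data

`simulate_fixture` emulates the statistical structure the method assumes —
similar drugs treat similar diseases — as planted block structure: drugs and
diseases are partitioned into matching blocks; associations are drawn
independently with density `within_density` (default study condition 0.5)
inside matching blocks and `between_density` (0.02) elsewhere. Each drug
block has a prototype fingerprint copied with independent per-bit flip
probability `fp_flip_rate` (0.05); each disease block has a prototype
nonnegative concept vector and members are the convex mixture
`(1 − r)·prototype + r·Uniform(0,1)` with `r = fp_flip_rate`, which keeps
entries nonnegative and makes within-block cosine similarity exceed
between-block similarity in expectation. The 40 x 30, 3-block study fixture
is small enough that the full cross-validation suite runs in seconds while
leaving ~1100 candidate pairs per fold.

Setting `fingerprint_signal=False` or `concept_signal=False` replaces the
corresponding feature matrix with structureless noise; the latter is used to
study the regime where the two passes carry complementary information.

What the generator does **not** emulate: the heavy-tailed degree
distributions of curated association sets, correlated missingness
(well-studied drugs have more recorded indications), fingerprint bit
correlations from shared substructures, and hub diseases. Passing the
planted-signal tests therefore demonstrates correct mechanics and genuine
signal recovery, not performance on real pharmacopoeias; published benchmark
AUCs on curated datasets require those external datasets as inputs.

Randomness: each generator component draws from its own sub-stream keyed by
(seed, fixed offset), so changing one component never perturbs another's
draws, and identical seeds give bitwise-identical fixtures.

## Design notes

* The package is organised around a scikit-learn style estimator
  (`TwoPassRandomWalk`, with `fit`/`predict`, `get_params`/`set_params` and
  trailing-underscore fitted attributes) because the method is naturally
  fit/predict shaped; the netio/similarity/heterograph/walker/evaluation
  modules remain a complete functional API underneath it.
* Identifier order is first-appearance order in the association file, making
  all matrices reproducible from the same input; feature matrices supplied
  with extra or differently-ordered rows are re-aligned to the network's ids.
* Duplicate association lines collapse silently to one edge (the adjacency is
  binary) with a logged count.
* One walk per drug and one per disease are executed regardless of how many
  candidate pairs are scored; steady states are cached and reused.

## Known limitations

* Associations are qualitative (binary); weighted association strengths are
  out of scope.
* Feature ingestion starts from a fingerprint matrix and a concept-weight
  matrix (or precomputed similarity matrices); generating fingerprints from
  SMILES or mining concept vectors from text is out of scope.
* Dense similarity matrices bound the practical size to a few thousand nodes
  per type.
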