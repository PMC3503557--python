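# Methods

## Model and inference

`ebvs` performs Bayesian variable selection for a continuous response with a
linear model that may include products of all orders among included
predictors. Writing γ for the inclusion indicator and X̄_γ for the
interaction-expanded design (one column per non-empty subset of the included
predictors, q = 2^|γ| − 1 columns; q = |γ| when interactions are disabled),
the hierarchy is

* Y | γ, β̄, σ² ~ N(X̄_γ β̄, σ²I)
* β̄ | γ, σ²    ~ N(0, n σ² (X̄_γᵀX̄_γ)⁻¹)   (g-prior with g = n)
* p(σ²) ∝ σ⁻²

All expanded columns are standardised to zero mean and unit variance using
the unbiased (n−1) standard deviation of the *training* data; test-time
designs reuse training statistics so prediction never leaks held-out data.
The response is centred by its training mean, which is added back at
prediction time; because the design columns are mean zero, this is
equivalent to an intercept handled outside the selection problem.

Marginalising (β̄, σ²) gives, up to a constant shared by all models on the
same data,

log p(Y | γ) = −(q/2)·log(1+n) − (n/2)·log(YᵀY − n/(n+1)·YᵀX̄_γ(X̄_γᵀX̄_γ)⁻¹X̄_γᵀY).

Derivation note: marginally Y | σ² ~ N(0, σ²(I + nH)) with H the hat
projection, |I + nH| = (1+n)^q and (I + nH)⁻¹ = I − n/(n+1)H; the remaining
σ² integral is an inverse-gamma kernel. The test suite verifies the result
against direct numerical integration (a projection-plus-quadrature oracle
and a full 2-D quadrature over (β, σ²)) and asserts the two invariances the
form is chosen for: rescaling Y shifts every model's log evidence equally,
and adding a constant to Y changes nothing.

The model space is restricted to |γ| ≤ d_max (default 4, per the sparsity
argument that only a few predictors drive the response); the restricted
space is enumerated lazily in a fixed order (by model size, then
lexicographically), and the posterior, inclusion probabilities, MAP model
and model-averaged predictions are computed exactly over it, in log space,
with one log-sum-exp normalisation. MAP ties break to the first model in
enumeration order (the smaller model).

### Numerical choices

* Per-model linear algebra uses a Cholesky solve of the expanded Gram
  matrix with a pseudo-inverse fallback (relative eigenvalue tolerance
  1e−10). The fallback arises by construction: products of correlated
  predictors can be collinear, and saturated models (q ≥ n) are
  rank-deficient. The pseudo-inverse yields the projection onto the column
  space, which keeps the evidence finite; the (1+n) exponent keeps the
  *column count* q, extending the closed form to rank-deficient designs
  (proper priors do not exist there, so no integral is contradicted).
* The fitted term is floored at residual ≥ 1e−12·YᵀY before logs.
* Expanded columns that are constant on training data are retained (q is
  unchanged) but zeroed, so they contribute nothing to the fit.
* A constant response (YᵀY = 0 after centring) is scored by the complexity
  penalty alone, making the empty model MAP and predictions exact.
* Evidence for a whole space is computed by a column cache: the expanded
  column for subset S is shared by every model containing S, so each of the
  Σ_k C(p,k) columns is built and standardised once and each model solves a
  small q×q system. At p = 11, d_max = 4 (562 models) a full evidence pass
  takes ~30 ms.

## Pathway priors and empirical Bayes

Model priors take the form P(γ | m, λ) ∝ exp(λ f_m(γ)), normalised exactly
over the restricted space by log-sum-exp (normalisers cached per source and
space).

* f₁ counts pathways via an exact minimum set cover of the model's
  annotated members by the pathways intersecting the model (brute force over
  pathway subsets — K is small), then subtracts 1, flooring at 0. Shared
  (hub) proteins are therefore never double counted, and including
  predictors with no annotation changes nothing.
* f₂ averages shortest-path distances between included proteins that share
  a pathway. Distances are computed on each pathway's induced subgraph
  (pathways are validated to induce a single connected component, which is
  what makes these distances well defined); a pair sharing several pathways
  contributes once, at its minimum distance across the shared pathways.
  Singleton-only and empty models score D_γ = 0, so after the −1 offset the
  prior is indifferent between singletons and maximally compact models.
* The MRF prior uses the energy γᵀAγ on the symmetrised adjacency matrix;
  unlike f₂ it is not agnostic to model size, which is why it is offered as
  a comparison source rather than a default.
* λ may take either sign for every source (a negative distance strength
  prefers compact models; positive prefers spread-out ones).

Empirical Bayes maximises log Σ_γ p(Y | γ) P(γ | m, λ) over a grid of
(m, λ). The default grid is λ ∈ [−5, 5] in steps of 0.5 for the two pathway
sources; model evidences are computed once and reused across the entire
grid, so the grid sweep costs only prior passes. Ties (which occur exactly
at λ = 0, where every source collapses to the flat prior) break toward the
weakest prior — smallest |λ| — then toward the smaller source index. The
grid always contains λ = 0, so the procedure can always fall back to no
prior information.

## Synthetic worlds

The generator exists so that every stage is testable without external data.
Predictors are drawn from a zero-mean Gaussian graphical model whose
precision matrix is I − ρA (ρ = 0.4 nominal edge partial correlation; the
diagonal is lifted if needed to keep the matrix positive definite, then the
covariance is rescaled to a correlation matrix). Adjacent proteins are
therefore more correlated than distant ones — verified empirically in the
tests.

The default world is a fixed, hand-curated 11-protein signalling network
(16 undirected edges) divided into four pathways, with two hub kinases (PKC,
PKA) belonging to all four. On this network the trio {PIP3, ERK, P38} spans
two pathways with mean shared-pathway distance 3.5 (f₁ = 1, f₂ = 2.5) and
the trio {RAF, MEK, PKA} is a triangle inside one pathway (f₁ = f₂ = 0);
these worked values anchor the prior implementations.

Three scenarios place a known three-variable truth (A, B, C in the order
listed above) and generate the response:

1. Y = A + B·C + ε with the distant trio — favoured by the distance prior
   with λ > 0;
2. Y = A + B·C + ε with the compact trio — favoured by either pathway prior
   with λ < 0;
3. Y = A + 2B + 3C + ε with the compact trio, analysed *without*
   interaction terms.

The noise level is set per realisation so that var(signal)/var(ε) = 4 — a
regime in which selection at n = 35 is possible but imperfect, which is the
regime of interest. For sizes other than (p = 11, K = 4) a random topology
is built: two hub nodes shared by all pathways, a random spanning tree per
pathway plus one triangle-closing edge, and deterministic truth placement
(scenario 1 maximises the intra-pathway distance among two-pathway trios and
fails loudly if none is distant enough, e.g. on a complete graph). All
randomness flows from one integer seed; replicate r of an experiment uses
seed + r, and identical seeds give byte-identical serialised worlds.

What the generator does **not** emulate: the heavy tails, zero inflation and
heterogeneous pair correlations of real single-cell phospho-proteomic data,
interventional conditions, or measurement error in the network itself.
Passing tests therefore demonstrate correctness of the machinery and
qualitative behaviour of the priors under network-structured Gaussian data,
not performance claims about any real assay. One concrete consequence
observed at desk scale: in the linear scenario 3 the empirical-Bayes choice
between the two pathway sources is nearly tied in evidence, tends to the
pathway-count prior, and then trails the flat prior slightly in ranking
accuracy (mean AUC ≈ −0.02 to −0.04), while the fixed distance prior would
lead it by ≈ +0.11 — a sensitivity of prior *selection* to the predictor
distribution that the Gaussian idealisation makes visible.

## Evaluation protocol

ROC curves threshold the inclusion probabilities at every level τ, plotting
true positives |γ* ∩ γ_τ| against false positives |γ_τ \ γ*|; the AUC is the
tie-averaged Mann–Whitney rank statistic (0.5 for uninformative scores).
Replicate curves are averaged as mean TP at each integer FP count; AUC is
averaged per replicate. The subsample experiment draws n = 35 training
samples without replacement per seeded replicate, runs the *entire* pipeline
(empirical Bayes included) on training data only, and scores selection
against the known truth and mean absolute prediction error on the held-out
remainder (with an all-predictor OLS baseline recorded for optional
normalisation). LOOCV re-runs empirical Bayes inside every fold and reports
model-averaged and MAP errors. Desk-scale default is 200 replicates
(configurable); the d_max sensitivity check selects hyperparameters once at
the reporting d_max and applies the same (m, λ) to the enlarged space, so
that it measures the restriction itself rather than grid jitter.

## Known limitations

* Cost grows as (2^d_max − 1)·p^d_max with interactions; p in the hundreds
  requires d_max ≤ 3, and the column cache assumes the expanded column set
  fits in memory.
* The priors assume the pathway annotation is correct and connected on the
  network; there is no model of annotation uncertainty.
* Empirical Bayes selects a single (m, λ) rather than averaging over them,
  and with near-tied sources the choice can be unstable (see the scenario-3
  note above).
* The g-prior's n/(n+1) shrinkage is mild; at q close to n, fitted models
  approach interpolation and the evidence differences among large models
  are driven mainly by the (1+n)^(−q/2) penalty.
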