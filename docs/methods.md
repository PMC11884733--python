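# Methods

## Network construction and cluster properties

Clonotypes are uppercase CDR3 amino-acid strings; duplicate sequences in an
input table are collapsed at read time with summed counts. The similarity
graph connects two sequences when their Levenshtein distance is ≤ `max_dist`
(default 1). The implementation prunes pairs whose lengths differ by more
than `max_dist` before running the DP, which cannot change the edge set.
Clusters are connected components with ≥ `min_size` (default 2) nodes,
ordered by descending size with ties broken by the lexicographically
smallest member sequence, so tables are stable under input row permutation.

Per cluster the package computes, on the induced subgraph:

| property | definition | undefined (NA) when |
|---|---|---|
| count_baseline / count_post | sum of member clone counts | never |
| node_count | cluster size n | never |
| diameter_length | longest geodesic, **in edges** | never |
| assortativity | Pearson degree–degree correlation over edges | degrees constant (includes n = 2) |
| transitivity | 3·triangles / connected triples | no connected triple (includes n = 2) |
| density | \|E\| / C(n,2) | never |
| degree_centralization | Freeman Σ(d_max − d_i) / ((n−1)(n−2)) | never — defined as 0 at n = 2 since the numerator is exactly 0 |
| closeness_centralization | Freeman on normalized closeness, max (n−1)(n−2)/(2n−3) | n = 2 (zero normalizer) |
| eigen_centrality_value | leading eigenvalue of the adjacency matrix | never |
| central_eigen | Freeman on max-1-normalized eigenvector scores, star-graph maximum (n−1)(1 − 1/√(n−1)) | n = 2 (zero normalizer) |

NA is therefore not a special case rule but the statement "this property's
definitional normalizer is zero/undefined for this shape", which reproduces
the observed behaviour that exactly four properties are NA on 2-node
clusters. Two conventions deserve note: "eigenvector centrality" is the
scalar leading eigenvalue (a per-cluster spectral size measure), distinct
from the *centralization* of the eigenvector scores (central_eigen); and the
diameter is counted in edges (a 2-node cluster has diameter 1). All graph
properties are unweighted; clone abundance enters only through the two count
sums.

## Feature extraction

Each property contributes min, Q1, median, mean, Q3, max of its per-cluster
values; the four NA-prone properties additionally contribute prob(NA),
always emitted even when no NA occurs (schema stability over
data-dependence). This gives 70 columns in 11 groups of sizes
(6,6,6,6,7,7,6,6,7,6,7), independent of cluster counts. Quantiles use
linear interpolation of order statistics (numpy default). A patient whose
clusters are all 2-node has no finite value for an NA-prone property; the
six location statistics are then imputed with the column median across
patients (and flagged), keeping the design complete. Standardization is a
column z-score with the n−1 standard deviation; constant columns (e.g.
`node_count__min`, which is 2 for every patient with any 2-node cluster)
become all-zero with a logged warning and are thereby inert in the penalized
fits. The z-scoring parameters are retained for scoring new patients.

## Logistic group Lasso

Objective: negative Bernoulli log-likelihood plus λ Σ_g s_{v_g} ‖β_g‖₂,
intercept unpenalized. The default penalty weights are s_{v_g} = √v_g, the
standard logistic group-Lasso weighting; the literal "weight = v_g"
convention is available as `penalty_convention="linear_size"`. The solver is
block coordinate gradient descent with a quadratic majorization of the
logistic loss: each block step uses the Lipschitz bound
h_g = 0.25·‖X_g‖₂², giving a closed-form group soft-threshold and exact
block zeros (support is read off stored zeros, no epsilon). Convergence is
declared when one full sweep decreases the objective by less than
`tol·max(1, |L|)` (default tol 1e-7, max_iter 10000); non-convergence is
flagged on the result, not raised. Between periodic full sweeps the solver
cycles only over active blocks.

λ_max = max_g ‖X_gᵀ(y − ȳ1)‖₂ / s_{v_g} is the KKT threshold at the
null model (intercept = logit ȳ, closed form), so the path's first grid
point is exactly the all-zero solution. The grid is log-spaced,
`grid_length=100` points down to `grid_ratio=0.001`·λ_max by default, warm
started downward. Benchmark-scale runs in the tests and the acceptance
script use a reduced grid (60 points to 0.01·λ_max) purely for runtime; the
tie-break slack 1+1e-12 in the threshold comparison resolves exact-equality
cases to the zero block.

## Pseudo-variable selection

One uniform row permutation π shuffles a copy of the whole standardized
matrix (preserving inter-feature correlation; an independent-per-group
shuffle mode exists but is off by default), doubling the groups. The
augmented path is fit on its own λ_max-anchored grid shared by all 2G
groups; the importance score W_g is the largest grid λ at which block g is
nonzero (0 if never; re-entering groups get their supremum). A round selects
S_π = {g ≤ G : W_g > C_π} with C_π the best pseudo score; strict
inequality means grid ties go to "not selected". Over K rounds (default 50;
20 in the scaled tests) a group is reported when its selection frequency
exceeds τ (default 0.5).

Implementation note: the path in one round is truncated at the first grid
point where any pseudo block becomes nonzero. Every group already in the
model entered at a strictly larger λ than C_π and no later entrant can
beat C_π, so the truncation is *exactly* equivalent to the full-grid
definition (verified against the literal computation in the tests) and is
the main reason a K=20 selection takes ~1 s rather than minutes.

CV baselines use stratified 10-fold splits; λ* minimizes the mean held-out
binomial deviance (not the 1-SE rule), and the selected groups are the
nonzero blocks of the full-data fit at λ*. Plain Lasso variants reuse the
same machinery with every column its own group (all penalty weights 1); for
cross-method comparison a property counts as recovered when any of its
singleton features is selected.

### Behaviour under the global null

The permutation filter controls, per round, the chance that a noise group
beats the best of G pseudo noise groups (≈ 1/(G+1) per group by
exchangeability). It does **not** drive the K-round selection probability to
zero: W_g of the *original* groups barely changes across rounds (only the
pseudo block is redrawn), so the frequency of the luckiest noise group is
roughly the indicator of whether its fixed W exceeds the median of the
C_π distribution. Empirically, with y independent of X (n = 200, 70
columns, 11 groups, K = 20, τ = 0.5), the mean number of selected groups is
~0.3–0.6 — but the probability of selecting *at least one* group is ~1/3,
so the per-dataset false-discovery indicator is far from 0.1. The null-
control acceptance test asserts the stricter bound and fails on that clause;
we regard this as a property of the method as defined, verified robust to
grid geometry and to the early-stopping shortcut. Users wanting stricter
null control should raise τ (τ = 0.75 roughly halves the null selection
rate) or increase K.

## Simulator

The generator emulates the pipeline's *output* rather than sequences: per
patient a cluster count is drawn (log-normal, median 271, σ = 0.8 —
matching the scale of a bulk-TCR cohort), then per cluster an
11-dimensional property vector through a Gaussian copula with exchangeable
correlation ρ = 0.3 and per-property marginals: log-normal for cluster
size (median 3, σ = 0.8, ceiled with floor 2, so ≈⅓ of clusters are
2-node), counts (median 30) and the leading eigenvalue; scaled Beta for the
bounded statistics (assortativity on [−1,1], transitivity, density,
centralizations on [0,1]); diameters ceiled with floor 1. The four NA-prone
properties are set NA on 2-node clusters, exercising the prob(NA)/imputation
machinery exactly as real data does.

Four latent causal variables Z₁…Z₄ correspond to the causal properties
(baseline count, diameter, eigen-centrality value, central eigenvector):
each is the equal-weight combination of that property's per-patient
{10,25,50,75,90}-th percentiles. The response is Bernoulli with logit
α₀ + αᵀZ̃ (Z̃ column-standardized), α = (1.1, 1.0, −0.9, 0.9); the
nonlinear mode adds 0.8·(Z̃₁Z̃₂ + Z̃₃Z̃₄). α₀ is solved by Brent's method
so the mean event probability hits 0.5 (balanced) or 0.3 (imbalanced).
These constants were chosen once to give an oracle logistic AUC ≈ 0.85 at
large n and are not tuned further. Twelve named scenarios vary
n ∈ {200,300}, the presence of 200 extra Uniform(0,1) nuisance columns
(modelled as 200 singleton groups), balance and linearity.

What the simulator does *not* reproduce: between-patient heterogeneity of
the property distributions (all patients share one cluster-level law, so
patient differences are finite-sample), any dependence of graph properties
on each other through actual graph constraints (density and centralization
are copula-coupled, not structurally coupled), and sequencing noise. A green
benchmark therefore establishes that the selection machinery ranks
percentile-coupled signal groups correctly, not that the effect sizes match
any particular cohort.

## Evaluation conventions

Sensitivity = |S∩T|/|T| against the 25 causal columns (or the 4 causal
groups in group-level mode; group selections are expanded to their columns
in feature-level mode). FDR of an empty selection is 0; F1 of an empty
selection against a nonempty truth is 0; Jaccard of two empty lists is 1.
Stability is the mean Jaccard over all C(N,2) pairs of replicate selection
lists. Benchmark child seeds are spawned deterministically from the master
seed per (scenario, method, replicate), so serial and parallel execution
agree; per-replicate failures become flagged rows rather than aborting the
sweep.

Per-patient composite scores are Σ coefficient × standardized feature over
the selected columns (intercept excluded). The CV methods supply the
penalized coefficients at λ*; the permutation methods select a set but no
single λ, so their composite scores use an unpenalized logistic refit on
the selected columns.

## Known limitations

- The n²-pairwise network build is exact but not indexed; repertoires of
  ~10⁴ sequences take minutes. Length-difference pruning is the only
  shortcut.
- The solver is first-order; at tiny λ on near-separable data convergence
  slows and the fit is flagged rather than polished by a Newton step.
- The null behaviour of the K-round frequency rule is documented above;
  the method bounds, but does not nullify, per-dataset false discoveries.
- Time-to-event and quantitative responses, nucleotide-level clonotypes,
  V/J annotation and network visualization are out of scope.
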