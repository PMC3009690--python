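# Methods

## Model and assumptions

The factorization treats an expression matrix **X** ∈ ℝ^(m×l) (m
experiments as rows, l genes as columns, each row mean-centered) as a
linear mixture X = AS + ε of n ≤ m sources.  ε is stationary white noise
with variance σ².  The identifying assumption is second-order and
network-based: the sources' *graph-delayed* cross-correlations vanish —
C̄_S^G(τ) is diagonal — where the delay operator is multiplication by the
weight matrix **W** of a user-supplied directed, weighted regulatory
network (self-loops and negative weights allowed).  Shifting along the
unit-weight line graph recovers the classic lag operator, so the framework
strictly generalizes time-delayed decorrelation to data with only a
partial, graph-induced ordering.

The scale indeterminacy is fixed by unit-variance sources
(C̄_S^G(0) = I under the unbiased 1/(l−1) estimator), which makes **A**
orthogonal after whitening; the procedure is then: center rows → whiten →
eigendecompose the symmetrized graph-delayed correlation of the whitened
data at a single shift τ → rotate back.  Symmetrization makes the
eigendecomposition well defined for the asymmetric graphs typical of
regulation and stabilizes estimation.  Identifiability holds up to
permutation and sign when the eigenvalues are pairwise distinct; the code
resolves both canonically (sort by decreasing |eigenvalue|; flip each
source so the dominant entry of its mixing column is positive) and flags
near-ties (relative gap < 1e−6) with a warning rather than an error, since
only the sources inside a tied block lose identifiability.

Everything is deterministic: no randomized initialization exists anywhere
in the factorization path, so identical inputs give bit-identical outputs.

## Parameters that matter

- **τ (graph shift, default 1).**  τ = 0 is rejected — after whitening the
  lag-0 correlation is the identity and carries no separation information.
  τ = 1 is the minimal informative shift and the default; any nonzero
  integer (including negative, i.e. shifting against edge direction) is
  accepted.  Joint diagonalization over several shifts is deliberately out
  of scope: the method diagonalizes a single matrix.
- **n_sources (default: full numerical rank).**  Eigenvalues of C̄(0) below
  1e−10 × the largest are treated as null space and refused for whitening.
  When the caller explicitly reduces the dimension, σ² is estimated as the
  mean of the discarded eigenvalues and subtracted from the retained ones
  before inversion; with no explicit reduction σ² = 0 (dimension reduction,
  and with it noise estimation, is impossible when m already equals the
  source count).
- **Replicates.**  Replicate observations of the same condition are
  averaged into one row before factorization (labels `condition.replicate`
  or an explicit design file); the robustness protocol instead resamples
  them.
- **Submode threshold (default 2).**  Sources have unit variance, so the
  ±2 cutoff is in standard-deviation units; the boundary is inclusive.
- **Network weights.**  Curated-interaction keywords map to ±1
  (activating +1, repressing −1) — the minimal signed encoding, since no
  canonical numeric scale exists for qualitative interaction records.
  Genes absent from the network keep all-zero rows/columns and contribute
  through lag-0 statistics only.  W^τ is never materialized; X is
  multiplied τ times by the sparse propagator.

## Statistical components

- **Moderated t.**  Per-gene residual variances from a one-way group-means
  fit are shrunk toward an ensemble prior with the closed-form
  empirical-Bayes moment matching on log variances (prior df from the
  trigamma inverse; infinite prior df falls back to the pooled-variance
  MLE).  Contrasts are each condition against the baseline; the reference
  t distribution uses residual + prior df, capped at the ensemble total.
  The implementation is verified against Bioconductor limma to machine
  precision in the test suite.
- **Enrichment.**  One-sided hypergeometric upper tail per gene set
  (`scipy.stats.hypergeom`), BH adjustment (`statsmodels`), minimum two
  genes of a set in the universe to avoid degenerate tests.  The PEI
  denominator is the number of testable sets under that rule — the natural
  reading of "fraction of significant pathways" — and BH is applied within
  each submode's table (a joint-correction flag exists).  Parent–child
  structure of ontologies is not modeled; annotations are generic GMT.
- **Amari index.**  For P = pinv(Â)·A_ref, the sum over rows and columns
  of (ℓ1 mass / largest |entry| − 1); zero iff P is a scaled permutation.
  The unnormalized form is the default because its scale matches the
  magnitudes this kind of analysis reports for n = 4 (≈ 3–10 for damaged
  networks); a 1/(2n(n−1)) normalized variant is available.
- **Robustness protocol.**  Degree-preserving rewiring swaps edge pairs
  (a→b, c→d) ⇒ (a→d, c→b) on the bipartite regulator/target view,
  rejecting duplicate-creating swaps, with weights traveling with their
  regulator; edge addition samples absent regulator→target pairs and draws
  weights from the empirical weight multiset; replicate subsampling picks
  1..R replicates per condition and averages.  Each fraction's 95% Amari
  quantile is compared against a null of i.i.d. standard-normal separating
  matrices applied to the reference mixing matrix; the empirical p-value
  uses the add-one rule (1 + #{null ≤ q}) / (1 + N).  Defaults: repetition
  count 1000 per fraction and fraction grid
  {0.001, 0.01, 0.03, 0.05, 0.1, 0.2, 0.5, 1.0}, both configurable; the
  acceptance script runs 30 repeats per fraction on a 150-gene synthetic
  benchmark, a desk-scale problem size that leaves the directional
  conclusions unchanged.  A master seed spawns one substream per repeat so
  individual repeats reproduce in isolation.

## Synthetic data and toy models

`synthetic_mixture` realizes the model class exactly: random centered rows
are whitened, the realized symmetrized graph-delayed correlation at τ is
eigendecomposed, and its eigenbasis rotates the whitened rows — giving
sources with exactly diagonal C̄_S^G(τ), exactly unit variance, mixed by a
random orthonormal-column **A**.  This is the ground truth for recovery
tests; it emulates network-consistent mixtures plus optional white noise.
It does *not* emulate real microarray features — probe-level error
structure, intensity-dependent variance, annotation bias of curated
networks, or model misspecification (real sources are at best
approximately graph-decorrelated).  Passing recovery tests therefore
demonstrates correctness of the algorithm, not performance guarantees on
real data; the robustness protocol probes the latter direction by
injecting controlled network errors.

The ODE fixtures use the regulation model
dx_i/dt = −γ_i x_i + Σ_j f_ji(x_j) + u_i(t) with Hill interactions
(activation β x^h/(K^h + x^h), inhibition β K^h/(K^h + x^h)).  The exact
parameters behind the published illustration are not available, so the
fixtures use uniform defaults γ = β = K = 1, h = 2 and target qualitative
behavior: in the bifan, regulator x1 (driven until t = 10) activates x3
and inhibits x4, regulator x2 (driven from t = 10) does the reverse, and
two reporters bring the observed species to six.  x3 then peaks at the
switch and x4 activates early while its inhibitor is still low; the
factorization concentrates ~94% of |eigenvalue| mass in three sources.
The funnel reads three steady-state conditions of a cascade converging on
one gene.  Integration uses LSODA at rtol 1e−8/atol 1e−10 with the maximum
step bounded below the input-switch spacing so step inputs are not
skipped; halving tolerances moves sampled trajectories by < 1e−4 relative.

## Numerical choices and degenerate inputs

- Centering contract: row means must be below 1e−8 × row SD, else an
  error (or auto-centering where the caller opts in); constant rows pass.
- Whitening refuses components at or below the rank tolerance or the
  noise floor, naming the offending component.
- Duplicate network edges with conflicting weights are an error; exact
  duplicates are silently deduplicated.  Gene matching is case-sensitive
  exact, with an opt-in upper-casing flag.
- A zero weight matrix is rejected by the mixture generator (no delayed
  structure to separate on) and annihilates any shifted data by
  construction.
- TSV output uses 10 significant digits; reruns are byte-identical.

## Known limitations

- A single shift τ is used; information at other shifts is ignored.
- Sources within an eigenvalue tie are recovered only up to rotation.
- The moderated-t screen assumes a common residual-variance model across
  conditions (one-way layout), not arbitrary design matrices.
- Enrichment treats gene sets as flat; ontology structure and
  annotation bias are the caller's concern.
- The expression filter's probe-collapsing strategy (`max_mean` default)
  can change downstream gene counts; it is exposed as a flag.
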