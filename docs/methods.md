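# Methods

## Problem and model

`mkbmc` predicts a binary case–control status from 16S-style microbiome
profiles: a samples × OTUs table of counts, a rooted phylogenetic tree over
the OTUs, and optionally numeric covariates.  The working hypothesis is
that several *forms* of microbiome–outcome association can coexist —
abundance versus presence/absence signals, carried by phylogenetically
clustered versus scattered taxa — and that each form is best captured by a
different distance metric.  The classifier therefore combines four
metric-specific similarity kernels (plus one per covariate) with learned
weights, instead of committing to a single metric.

### Boosted distances

Counts are row-normalized to relative abundances `p_i`.  For the tree
metrics, each branch `r` (identified by its child node; the root carries no
branch) gets a profile `p_ir` = summed relative abundance of its descendant
leaves, computed in one postorder pass.  The four distances are

- weighted UniFrac `d_w(i,j) = Σ_r b_r a_r |p_ir − p_jr| / Σ_r b_r a_r (p_ir + p_jr)`
- unweighted UniFrac — the same ratio on presence indicators `I(p_ir > 0)`,
  with denominator `Σ_r b_r a_r I(p_ir + p_jr > 0)`
- Bray–Curtis `d_BC(i,j) = Σ_r a_r |p_ir − p_jr| / 2` (on rows summing to 1
  the classical denominator is the constant 2)
- Hamming `d_H(i,j) = Σ_r a_r |I(p_ir>0) − I(p_jr>0)|`

with `b_r` the branch lengths and `a_r ≥ 0` the *boosting weights*.  With
`a_r ≡ 1` each reduces exactly to its textbook form (tested against
scikit-bio and explicit formulas).  Boosting weights are
`a_r ∝ −log10(p_r)` from a per-feature association test on the training
labels: Welch's two-sample t-test on abundances for the abundance metrics,
and a presence × label 2×2 test for the presence metrics (Pearson χ²
without continuity correction, falling back to Fisher's exact test when an
expected cell is below 5 or an observed cell is empty — the regime where
the χ² approximation is worst).  Degenerate features (no variance, constant
presence) get p = 1 and hence weight 0 before normalization.

Two choices here were genuinely open:

- **Normalization of a_r.**  Only relative weights can matter: the UniFrac
  ratios cancel any global scale exactly, and for Bray–Curtis/Hamming a
  global scale multiplies both the distances and the bandwidth σ (the mean
  pairwise distance), leaving the Gaussian kernel unchanged.  We normalize
  to mean 1 as a reproducible convention and test the invariance explicitly
  (c ∈ {0.1, 10} leaves every kernel unchanged to 1e-12).
- **Feature level for tree-metric boosting.**  The boosted UniFrac formulas
  index `a_r` by branch, so the default tests each *branch profile*
  directly (abundance test for weighted, presence test for unweighted
  UniFrac).  An alternative OTU-level mode (`boost_level="otu"`) tests OTUs
  and assigns each branch the strongest (minimum) descendant p-value.

p-values are floored at 1e-300 before the log; if every p equals 1 the
weights fall back to uniform with a warning.

### Kernels

Every distance matrix becomes a similarity kernel
`K(i,j) = exp(−d(i,j)² / 2σ²)` with σ the mean of the strict upper triangle
of the training distances (self-distances excluded so they cannot bias σ
downward).  Covariates are z-scored with training statistics, use
`|x_i − x_j|` as the distance, and get their own kernel; the z-scoring
makes the kernel invariant to affine rescaling of the raw covariate.
Test-versus-train kernels reuse the stored training σ, boosting weights and
covariate statistics unchanged — nothing at prediction time is computed
from test samples.  Kernels are used purely as similarities; positive
semidefiniteness is neither assumed nor needed (nothing downstream inverts
or factorizes K).

### Kernel weights

With `CC(i,j) ∈ {0, ±1}` the class-agreement matrix (+1 same class, −1
different, 0 diagonal), the weights minimize

    −Σ_l w_l S_l + ρ Σ_l w_l log w_l,   S_l = Σ_{i,j} K_l(i,j) CC(i,j),

over the simplex.  Stationarity gives the closed form
`w = softmax(S / ρ)` (computed with max-subtraction); at ρ = 0 all mass
goes to the best-aligned kernel, exact ties splitting equally.  The softmax
is order-preserving, so the *ranking* of kernels is the ranking of the
alignment scores at every ρ > 0.

ρ is tuned on the grid `{0, ρ_max/10, …, ρ_max}` by stratified 5-fold
cross-validated AUC of the full downstream classifier, ties going to the
largest ρ (flatter weights are the more conservative choice out of sample).
Exact maximum entropy is reached only as ρ → ∞, so ρ_max is defined
operationally: the smallest ρ in a doubling search (1, 2, 4, …, capped at
2^60) whose solution has entropy ≥ (1 − 1e-3)·log L.  Inside each CV fold
the boosting p-values, distances, bandwidths and alignment scores are all
recomputed from the fold's training split only; reusing full-training-set
boosting weights would leak label information into the held-out fold and
bias the tuning AUC upward.

### Classifier

Each training sample's combined similarity row `Σ_l w_l K_l(i,·)` is
summarized as a *similarity t-score*: the Welch two-sample t-statistic
comparing its similarities to the remaining cases versus the remaining
controls (leave-self-out).  A univariate logistic model
`logit P(y=1) = β0 + β1 t` is fitted by damped Newton iteration (step
halving on the log-likelihood, max 100 iterations, tolerance 1e-8).
Complete separation — disjoint t-score ranges between the classes — makes
the maximum-likelihood slope infinite; it is detected exactly and |β1| is
clamped at 30 (already saturating on any realistic t-scale), after which β0
is re-optimized with the slope fixed.  Test samples get t-scores from their
cross-kernel similarities to training cases/controls (no self to remove)
and probabilities from the fitted logistic.

## Synthetic data generator

The generator emulates a targeted-sequencing case–control study built on a
real upper-respiratory-tract parameter set (856 OTUs): per-sample total
counts `N_i ~ NegBin(mean 1000, size 25)` (variance μ + μ²/size), and OTU
counts from a Dirichlet-multinomial with baseline proportions π and
dispersion θ, using the standard concentration `α = π(1−θ)/θ`.  The real
estimated parameters are not redistributable here, so the shipped default
is an explicitly synthetic stand-in: a random Kingman-coalescent tree over
q leaves and i.i.d. log-normal proportions (σ_log = 2, giving the
heavy-tailed rank-abundance curve typical of 16S surveys), with θ = 0.02.
An externally estimated trio (Newick tree, proportions TSV, θ) can be
supplied through `SimConfig.tree_file` / `pi_file` for exact replication of
published summary tables.

Signal OTUs are chosen by phylogenetic structure: the tree's leaves are
partitioned into k = 20 clusters by PAM (classic BUILD + SWAP k-medoids,
deterministic tie-breaks) on the cophenetic distance matrix.  Scenario I
takes every OTU of the cluster at a requested total-abundance rank (default
rank 2 for abundance outcomes, rank 8 for presence outcomes, mirroring the
emulated study's settings); scenario II takes the top-abundance OTU from
each of 9 distinct clusters, scanning by descending abundance; scenario III
combines a related set G1 with a disjoint unrelated set G2.  Outcomes
follow `logit P(y=1) = β · scale(Σ_{ℓ∈G} p_iℓ)` (Model A, abundance) or the
same with presence indicators `I(p_iℓ > 0)` (Model B), `scale(·)`
standardizing over the generated pool; scenario III uses two-term
combinations with effects β1, β2.  Exact class balance is achieved
retrospectively: a pool of `pool_factor × 2n` samples is generated, labels
drawn once, and the first n/2 cases and n/2 controls (in pool order) form
the training set, the next n/2 + n/2 the testing set — so train and test
are disjoint draws from one population.

What the generator does *not* emulate: phylogenetic correlation of
abundances (π is i.i.d. across leaves, whereas related taxa in real
communities have correlated abundances), taxonomic block structure,
sequencing-run batch effects, and zero-inflation beyond what the
Dirichlet-multinomial produces.  Consequently, passing simulation tests
demonstrates correct behavior of the machinery under the stated generative
model, not field performance on real gut data.  One practical consequence
of the i.i.d. π is that small signal clusters are sometimes dominated by a
single abundant OTU, which genuinely weakens the advantage of tree-aware
metrics over Bray–Curtis in small-q runs; at the emulated study's q = 856
the clusters are large (tens of OTUs, individually rare) and the expected
attribution pattern holds.

## Problem sizes used by the test suite

Simulation-backed checks run at sizes chosen to keep the whole suite fast
while preserving the relevant structure: the oracle-AUC benchmark uses
1000 balanced testing sets of 500 (250 cases/controls); the null check runs
50 replicates at n = 200, q = 60 with full ρ tuning; the kernel-weight
attribution check runs 50 replicates per outcome model at n = 500 and the
full q = 856, with ρ fixed at 1 — legitimate because the argmax weight is
invariant to ρ (softmax order preservation), and verified to coincide with
tuned fits on spot checks.  Unit-level oracles (brute-force simplex
minimization, per-branch UniFrac enumeration, permutation tests,
scikit-bio cross-checks) run at 8–50 samples and 20–40 features.

## Numerical choices and edge cases

- Pairs of samples that are both empty under a metric get distance 0.
- A bandwidth computed as 0 (all training distances zero) is an error, not
  a silent fallback — the input is degenerate under that metric.
- Softmax uses max-subtraction; alignment scores grow as O(N²) and would
  otherwise overflow at small ρ.
- Zero-length branches are kept in the UniFrac sums (they contribute 0);
  a missing Newick branch length is read as 0 with a warning.
- All-zero count rows stay all-zero after normalization, with a warning.
- Similarity t-scores with zero variance in both groups are set to 0 with
  a warning; fewer than two training cases or controls is an error.
- Stratified folds are deterministic given the seed; every source of
  randomness in the package flows from explicit seeds.

## Known limitations

- The entropy-regularized weights have a closed form only because the
  alignment term is linear in w; replacing it (e.g. by centered kernel
  alignment) would require a numeric solver.
- The boosting tests are marginal (one feature at a time); correlated
  signal OTUs share their association strength across many branches, which
  is intended, but purely epistatic signals would be missed.
- Prediction requires the test OTU set to be mapped onto the training
  feature space; OTUs unseen in training are dropped (with re-normalization)
  rather than placed on the tree.
- PAM's swap phase is O(k · n²) per pass; fine at n = 856 leaves, not
  intended for tens of thousands.
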