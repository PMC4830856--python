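# Methods

## Model

Ordinal item responses are modelled as discretisations of a latent
multivariate Gaussian.  Item *j* with *K_j* categories has strictly
increasing thresholds τ_{j,1} < … < τ_{j,K_j−1} on the standard-normal
scale; the observed code is the number of thresholds below the latent
value.  Conditional-independence structure among the latent variables is
encoded by the precision matrix Θ: a zero θ_ij means items *i* and *j* are
independent given all other items, and the partial correlation
w_ij = −θ_ij/√(θ_ii θ_jj) is the network's edge weight.

## Estimation pipeline

**Thresholds** are estimated from marginal category proportions,
τ_k = Φ⁻¹(cumulative proportion through category k).  Empty categories are
collapsed away before inversion (logged); an item with all mass in one
category is an error because its latent scale is unidentified.

**Polychoric correlations** use two-step ML: with thresholds fixed, each
pairwise correlation maximises the multinomial log-likelihood of the
contingency table over bivariate-normal rectangle probabilities.  The
maximiser is found by root-finding on the score function, which is
available in closed form through Plackett's identity
∂Φ₂(h,k,ρ)/∂ρ = φ₂(h,k,ρ).  The estimate is clamped to ±0.999 and cell
probabilities floored at 1e−12, so perfect-association tables return the
clamp instead of diverging.  Rectangle probabilities use Genz's algorithm
for the bivariate normal CDF (absolute accuracy ≈ 1e−14), implemented as a
numba kernel: the permutation test below re-estimates everything hundreds
of thousands of times, and this throughput requirement is why the
numerical core is compiled rather than composed from per-call library
routines.  The pairwise-assembled matrix need not be positive definite; it
is repaired by iterated eigenvalue clipping (floor 1e−6) with rescaling to
unit diagonal, a no-op on matrices that are already PD.

**Graphical lasso.**  The penalised problem
max log det Θ − tr(RΘ) − λ Σ_{i≠j}|θ_ij| is solved by blockwise coordinate
descent on the covariance side, warm-started along the path.  The diagonal
is unpenalised, which preserves the partial-correlation reading of the
off-diagonals and gives two exact identities used as tests: λ ≥ max|r_ij|
yields the empty graph with θ_ii = 1/r_ii, and λ = 0 returns R⁻¹.
Convergence: maximum elementwise change of the working covariance below
1e−6, sweep cap 10 000 (an error, not a silent truncation).  Exact zeros
are produced by the soft-threshold update and survive symmetrisation, so
"edge present" downstream simply means w_ij ≠ 0.

**Model selection.**  λ runs over a log-spaced path of m = 100 values from
λ_max = max|r_ij| down to 0.01·λ_max (endpoints pinned exactly, because an
exp/log round trip can lose an ulp at λ_max and spuriously admit the
strongest edge — with the consequence that the empty model would never be
scored).  EBIC = −2ℓ + E log n + 4Eγ log p is evaluated on the penalised
estimate without refitting; γ defaults to 0.5, the conventional value in
psychometric network analysis; ties resolve toward the sparser model.

**Domain level.**  Domain scores (sum of item codes with reverse-coded
items flipped, rescaled to 0–100) are quasi-continuous, so the domain
network uses Pearson correlations; in the combined sample the binary group
indicator enters the Pearson matrix as a point-biserial column.  This is a
documented choice — with 2–10 categories per sum the Gaussian
approximation at the domain level is mild, and the method tag on the
correlation matrix records which input was used.

**Centrality.**  Edge distances are 1/|w_ij| — a strong association,
positive or negative, is a short path.  Closeness is 1/Σd(i,j) with the
sum over the node's connected component (Dijkstra via scipy.sparse.csgraph);
isolated nodes get closeness 0 and their own component id, which is
exported so disconnectedness is visible rather than fatal.  The
normalisation omits the (n−1) factor; it cancels in the z-standardisation
(sample SD, n−1 denominator) used for reporting.  Strength and betweenness
exist behind the API but are unvalidated extras.

**Comparison test.**  For two groups, the weighted statistic is
T = |S_A − S_B| with global strength S = Σ_{i<j}|w_ij|; the unweighted
statistic is the absolute edge-count difference (a Hamming-distance
variant is available).  Each of B permutations (default 1000) pools the
respondents, reshuffles labels preserving group sizes, and re-runs the
full pipeline — polychoric matrix, path, EBIC selection — per
pseudo-group, so the null distribution reflects estimation noise.  The
p-value is the add-one estimate (1 + #{T* ≥ T_obs})/(1 + B), valid in
finite samples and bounded below by 1/(B+1).  Permutations draw from RNG
streams spawned per permutation index from the master seed, so results are
bit-reproducible and independent of worker count.  A permutation that
produces a zero-variance item in a pseudo-group is redrawn, up to 10
times, with the count logged.

## Synthetic data

The generator inverts the model: a sparse Θ is built (chain, random
density, or clustered), Σ = Θ⁻¹ is rescaled to a correlation matrix,
latent draws are thresholded into categories.  Edge magnitudes are uniform
on [0.2, 0.4] — detectable at study-like sample sizes (hundreds to ~2000
respondents) without being trivial — and the diagonal is set to 1 plus the
row-wise absolute sum, so positive definiteness holds by diagonal
dominance for any structure and any rescaling.  The clustered default has
8 fully connected blocks of sizes (10, 4, 2, 5, 4, 2, 3, 5) plus one free
item (36 items total, mirroring an instrument in which one item belongs to
no domain); within-block weights are positive, emulating the positive
manifold of questionnaire domains, while sparse between-block edges
(density 0.05) carry random signs.  Category counts default to an
SF-36-like mixed profile (2/3/5/6) per block; thresholds are equiprobable
by default, with a skewed option (probabilities ∝ α^k) for right-shifted
health-item distributions.  A two-group design multiplies group B's edge
weights by δ: Θ's off-diagonals are scaled with the diagonal kept, so the
partial correlations obey w_B = δ·w_A exactly (the diagonal is lifted only
in the rare case positive definiteness would fail, which attenuates the
multiplier and is the reason the lift is not applied unconditionally).
δ = 1 gives an exactly exchangeable null.

What the generator does *not* emulate: item missingness, response styles,
local dependence beyond the Gaussian copula, and floor/ceiling effects
stronger than the threshold scheme produces.  Passing tests therefore
demonstrate correctness of the estimators under the assumed latent-normal
model, not robustness to its violations.

## Data handling choices

Missing responses are removed listwise with a logged count (a
pairwise-complete polychoric mode exists behind a flag); no imputation.
CSV category codes are normalised to 0-based consecutive integers; when the
coding origin is ambiguous (neither 0 nor the top category observed) the
1-based questionnaire convention is assumed.  Reverse coding follows the
standard SF-36 convention by default and is configurable per item.
Component-summary scores (PCS/MCS) are out of scope: their scoring
coefficients are proprietary, so only user-supplied weights could support
them.

## Problem sizes in the validation suite

The acceptance-style tests run at deliberately chosen sizes: brute-force
optimiser oracles at p = 3–4 (where a generic optimiser is trustworthy),
polychoric consistency at n = 5000, support recovery at n = 2000 (p = 10
chain) and n = 1742 (36-item clustered instrument), and the permutation
test at B = 200 with 200 null replicates (type-I error) and 100
alternative replicates (power) — B = 200 rather than the analysis default
B = 1000 keeps the calibration study's ~160 000 full re-estimations
tractable while leaving the add-one p-value resolution (1/201) well below
the 0.05 test level.

## Known limitations

* Two-step polychoric ML (not joint ML over thresholds and ρ); the
  difference is negligible at questionnaire sample sizes but the
  thresholds' sampling error is ignored in the pairwise likelihood.
* EBIC is evaluated on the penalised estimate without refitting the
  selected support; selected networks are therefore conservative in edge
  strength.
* The unweighted comparison statistic is the edge-count difference; two
  networks with equal counts but disjoint supports score T = 0 (the
  Hamming option addresses this).
* Closeness on disconnected graphs is a within-component quantity;
  z-scores mix components, which is flagged via the exported component id.
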