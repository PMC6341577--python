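# Methods

This note documents the models, numerical choices and defaults behind
`phyloseed`, what the synthetic-data generators do and do not emulate, and
the package's known limitations.

## Trees

A `Chronogram` is a rooted tree whose branch lengths are durations in Mya;
node ages are depths from the tips (tips at age 0).  Ultrametricity is
enforced with relative tolerance 1e-6 of the root age; inputs failing it are
rejected unless `force_ultrametric=True`, which adjusts each terminal edge so
every tip sits exactly at age 0.  Multifurcations are resolved into an
arbitrary binary shape with zero-length internal edges at construction; every
likelihood computed here (BM-family trait models, DEC pruning, the threshold
model) is invariant to the resolution chosen, which the tests check
explicitly.  Newick I/O and pruning are delegated to dendropy; the
Brownian-motion covariance matrix C (entries: shared root-to-MRCA path
length) is computed in one postorder sweep.

## Seed morphometrics

Per-seed volumes use the ellipsoid formula with **semi-axes** equal to half
the measured length, width and thickness: v = (π/6)·L·W·T.  This convention
is fixed because it reproduces the printed per-species volume summaries
exactly at integer rounding (e.g. 27 × 25 × 20 mm → 7069 mm³); treating the
full dimensions as axes would be 8× larger.  Reported volumes are rounded
half-up to integer mm³.  Species means are arithmetic means of per-seed
volumes (not volumes of mean dimensions), and the species-level trait used in
all comparative analyses is the mean of per-seed log₁₀ volumes.

Size classes are discovered by UPGMA (average linkage, Euclidean distance) on
(log₁₀L, log₁₀W, log₁₀T), cut at height 0.35 (the published analysis says
"~0.35"; the value is a config knob).  PCA is an eigen-decomposition of the
covariance matrix of the log dimensions — covariance rather than correlation
because the three variables share units after the log transform.  Canonical
category bounds (mm³): S [25, 100), M [100, 500), L [500, 3000),
XL [3000, 13000), Max [26000, 38000]; volumes in the XL–Max gap or outside
the overall range are assigned to the nearest interval and flagged
`extrapolated`.

## Continuous trait models

All three models give multivariate-normal tip distributions with mean z₀·1
and covariance σ²·V₀(θ), a transform of C with T = root age and s_ij = C_ij:

* BM: V₀ = C.
* OU (root-conditioned, non-stationary form on an ultrametric tree):
  V₀ᵢⱼ = (1 − e^{−2αs_ij}) e^{−2α(T−s_ij)} / (2α).  α → 0 recovers BM.
* EB: rate σ²(t) = σ²·e^{rt} with r ≤ 0, so V₀ᵢⱼ = (e^{r·s_ij} − 1)/r;
  r = 0 is BM.  r is bounded in [−10/T, 0].

For fixed shape parameter, z₀ and σ² have closed-form GLS/ML solutions via a
Cholesky solve; the single shape parameter is optimized by bounded Brent
(tolerance 1e-8) with α ∈ [1e-9, 50/T].  Since OU and EB nest BM at their
boundary, a fit is never reported below the BM likelihood; fits that settle
at a box bound are flagged `at_bound_`.  Model choice uses AIC (k = 2 for
BM, 3 for OU/EB), ΔAIC and Akaike weights wᵢ = exp(−ΔAICᵢ/2)/Σexp(−ΔAICⱼ/2).

Blomberg's K is (MSE₀/MSE)_obs / (MSE₀/MSE)_expected with the GLS mean,
MSE₀ the ordinary and MSE the C⁻¹-weighted mean squared deviation, and the
expectation term (tr C − n/(1ᵀC⁻¹1))/(n−1).  Significance uses 999 tip
permutations by default with the add-one rule p = (1 + hits)/(n_perm + 1),
counting permutations whose weighted MSE is ≤ the observed (more signal).
Pagel's λ scales the off-diagonal of C; λ̂ maximizes the profiled likelihood
on [0, 1] and p comes from a likelihood-ratio test against λ = 0 on χ²(1).
Whether the original analysis tested against λ = 0 is not stated; testing
the no-signal null is the natural default.  A cross-check test recomputes
both statistics with R's phytools on a small dataset and requires agreement.

## Ancestral states

Internal-node states under BM are computed by exact Gaussian belief
propagation: a postorder pass combines tip observations into downward
messages, a preorder pass sends the complementary messages, and each node's
marginal combines all neighbours, with a flat prior on the root.  This equals
the conditional expectation of the joint MVN given the tips (the test oracle
computes that dense conditioning directly) and runs in linear time.  Means
are independent of σ²; variances are scaled by the BM ML rate.  Edge
profiles interpolate the BM bridge mean (linear in time) between the parent
and child estimates at a default step of root_age/500; traitgram coordinates
are the per-lineage (age, state) polylines.  Ancestor size-class labels can
be read off the estimates with the category table, but on the approximate
fixture tree they are indicative only.

## Ancestral range estimation

Ranges are non-empty subsets of the area set with |range| ≤ 2 by default
(state space: 21 of 6 areas, plus an internal absorbing null range).
Anagenesis is a CTMC with expansion rate d·Σ_{b∈R} m(b,a) into area a
(m = dispersal multipliers in [0,1]) and contraction rate e per occupied
area; singletons contract to the null range.  Cladogenesis distributes the
parent range over daughters via single-area sympatry, subset sympatry and
vicariance (one daughter a singleton, the Lagrange convention), each event
weighted (3−j)/3, plus founder events into each area outside the parent with
total weight j (split over targets), normalized per parent; j = 0 is plain
DEC with all events equally weighted.  The likelihood is Felsenstein pruning
with matrix exponentials along edges (one eigendecomposition per rate matrix
when well-conditioned, scaling-and-squaring otherwise; per-length caching)
and a flat root prior over non-null states.  Fitting is Nelder–Mead on
(log d, log e[, logit-scaled j]) with d, e ∈ [1e-12, 10], j ∈ [0, 3), and 5
multistarts by default.  Node and corner marginals come from the standard
down-pass/up-pass combination and exclude the null range.

Default multipliers are distance-tiered (adjacent/continental 1.0, short
crossings such as Amazon–Atlantic Forest or Africa–Madagascar 0.5,
trans-oceanic 0.1) and fully overrideable by CSV; the published analysis
specified its matrix in a supplement that prints no values in the main text.

**Limitation — identifiability of e.**  On range data simulated forward and
conditioned on no lineage dying to the null range (the generator restarts
such histories, logging the count), the profile likelihood in e is typically
maximized at 0: ML fits return the boundary value for the range-loss rate in
almost every replicate even when d and j are recovered within ~25%.  This is
inherent to survival-conditioned range data, not an optimizer artifact (the
likelihood is monotone in e with d, j held at truth), and mirrors the
boundary estimates (d = e = 1e-5) the original analysis reports.  The
package's recovery test asserts factor-3 recovery of all three rates and
therefore fails on e by design; treat fitted e values near the lower bound
as "no evidence for range loss", not as estimates.

## Threshold regression

The binary trait is thresholded from a latent liability; (x, liability)
follow bivariate BM on the tree with covariance Σ⊗C,
Σ = [[σ_x², rσ_x], [rσ_x, 1]] — the liability rate is fixed at 1 and the
threshold at 0 for identifiability.  The sampler is Metropolis-within-Gibbs:
per-species liability proposals constrained to the observed sign, random-walk
updates of the two ancestral means, a log-scale walk on σ_x² (flat prior on
the rate), and a Fisher-z walk on r (flat prior on (−1, 1)).  Proposal
scales adapt toward ~30% acceptance during the first fifth of the chain and
freeze afterwards, so the post-burnin chain is a valid fixed-kernel sampler.
All quadratic forms are updated in O(1)–O(n) per proposal and the core loop
is numba-compiled; chains are bit-reproducible for a fixed seed.  Defaults
mirror the published schedule (3M generations, thin 1000, 20% burnin of the
thinned chain); tests and the bundled pipeline use 200k generations, which
reach ESS in the hundreds on 20–30-tip trees.  HPD intervals are the
shortest window containing ⌈0.95·n⌉ sorted samples (leftmost tie); ESS uses
the AR-fit spectral density at frequency 0 with Yule–Walker AIC order
selection (iid chains ≈ n, AR(1) chains match n(1−ρ)/(1+ρ)), capped at the
retained sample count.  Fixing the liabilities at observed continuous values
(supported via `observed_liability`) reduces the model to plain phylogenetic
correlation and reproduces the GLS estimate.

## Marker screening

Longest-ORF detection scans all six frames for ATG-initiated, stop-terminated
codon runs (ties: plus strand, then lowest start); open-ended 3′ ORFs are
admitted only with `allow_unterminated`.  Copy-number screening filters hit
tables at e ≤ 1e-6, classifies loci with < 4 retained sequences as
`insufficient`, loci with two hits in one assembly as `multi-copy-suspect`,
and the rest `candidate-low-copy`.  Amplifiable windows require every
sequence's ungapped span in [400, 750] bp and flanking blocks of 25 columns
with mean pairwise identity ≥ 0.9 (both knobs exposed; the source pipeline
states no flank thresholds), ranked by internal variable-site count.
External BLAST/aligner/tree tools are consumed as files, never executed.

## Synthetic data and the fixture

Simulators draw from the exact generative models above (Yule with
Exp(k·birth_rate) waits plus a final Exp(n·birth_rate) extension so tip edges
are never zero; MVN traits via Cholesky; bivariate liabilities; Gillespie
anagenesis with cladogenetic draws), threading a single numpy Generator
through all draws.  Calibration constants for calibrated tree heights are
root 36.43 Mya (SD 4.0) and focal-crown 15.21 Mya (SD 4.0).  The seed-class
generator draws, per class, a shared log₁₀ size factor (SD 0.008) plus
per-dimension shape noise (SD 0.010) around the geometric midpoint of each
published volume category; that keeps >99% of a class's volumes inside its
category interval and makes the five classes cleanly recoverable (Rand index
≥ 0.95 at cut 0.35).  Real measurement tables are messier — species straddle
category boundaries (e.g. S–M and M–L species exist) — so passing recovery
tests demonstrate correctness of the clustering machinery, not that real
data always yield five clusters.

The 21-tip Plukenetiinae fixture encodes the published topology (two
outgroup genera; pinnately- and palmately-veined clades; the Old World
lineage; the Madagascar polytomy) with the six printed node ages
(31.94, 28.71, 19.1, 17.39, 9.4, 4.5 Mya) honoured and all other ages
placed proportionally between their nearest constrained ancestor and
descendant (a node h unconstrained steps above its deepest chain gets
m + (A − m)(h+1)/(h+2)).  Two variant terminals are omitted to keep one tip
per species.  Trait values are log₁₀ of the printed mean volumes; binary
trait codings and single-area ranges are transcribed from the printed trait
and distribution tables.  The per-seed measurement table is reconstructed
deterministically from the per-species summaries (n seeds per species,
dimensions jointly log-interpolated between the printed minima and maxima);
it matches the summary counts and ranges but its individual seeds are
synthetic.  One summary row (the *Haematostemon* outgroup) is typographically
garbled in the source and is parsed as 1 seed of 4 × 4 × 4.5 mm (38 mm³,
class S), the only reading consistent with its printed category; it is
excluded from validation.

## Problem sizes used by the test suite

Simulation-based checks run at: 50-tip trees for trait-model and signal
properties (200 reps for K, 100 for λ), 8-tip trees for dense-oracle
comparisons, 50 reps of 50-tip forward DEC+J simulations for rate recovery,
and 100 reps of 200k-generation threshold chains on a 30-tip tree for HPD
coverage.  These sizes give stable medians/means for every assertion while
keeping the default suite in the minutes range.
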