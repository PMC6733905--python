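# Methods

This note documents the models implemented in climevol, the assumptions they
make, the numerical choices behind them, and what the synthetic-data
generators do and do not emulate.

## Trait estimation

**T_pref.** The preferred-temperature protocol assumes a photothermal
gradient (20–55 °C) on which body temperature rises from room temperature
during an acclimation phase and then fluctuates around the animal's
preferendum. The estimator is the arithmetic mean of all measurements at
minutes strictly greater than the acclimation window (default 15 min,
configurable). It is invariant to anything recorded inside the window.

**IWL.** Hourly weight loss is the mean of per-interval loss rates
(Δweight/Δtime), so unevenly spaced weighings are handled correctly;
intervals showing weight gain are kept (they are measurement noise, not
biology) and logged. Size correction regresses individual loss on estimated
surface area, `ln(SA) = 2.36 + 0.69 ln(mass)`, and keeps residual + grand
mean. This preserves the between-individual ordering at a common size scale
and makes the corrected values exactly uncorrelated with surface area. The
correction algebra is not uniquely determined by the verbal description
"corrected by regression"; the residual form is the standard choice and a
`method="ratio"` (loss per unit area) alternative is provided. The
regression is fitted across the whole dataset, not per species, because a
single allometry is assumed; species values are medians over individuals.
Units: grams and the allometry's own surface-area units — only relative
comparisons are used downstream.

## Niche metrics

Hour-count layers count qualifying hours on one representative day per
month and weight by calendar month lengths (non-leap year, 365 days), the
structure of gridded hourly microclimate products. Criteria use strict
inequalities (">30 °C" excludes exactly 30.0). The layers are monotone in
their thresholds and bounded by 8760 h.

The thermal safety margin excludes months with T_min strictly below 5 °C
(too cold for activity), averages T_max over the remaining months, and
subtracts from T_pref. If every month is excluded the TSM is undefined
(NaN), never zero. TSM is computed per occurrence record and summarised per
species by the median; the at-risk flag defaults to TSM < 12 °C, a
configurable empirical extirpation threshold. TSM is
translation-equivariant in T_pref.

## Comparative statistics

All methods assume a rooted, dated (ultrametric within 1e-6 relative
tolerance) tree and put a Brownian-motion (BM) or Ornstein–Uhlenbeck (OU)
process on branch time.

**Phylogenetic regression.** GLS with the fixed-root OU covariance
`V_ij = σ²/(2α) · exp(−α d_ij) · (1 − exp(−2α t_ij))`, where `t_ij` is the
shared root-to-MRCA time and `d_ij` the patristic distance; α → 0 recovers
BM. σ² is concentrated out of the likelihood; α is profiled on a 40-point
log grid spanning [1e-8, 50] per unit tree depth and refined by bounded
scalar minimization. Coefficient SEs use the unbiased GLS variance with
t-tests on n − p degrees of freedom; AIC counts the regression coefficients
plus σ² (plus α for OU). On a star tree, or as α grows large, estimates
converge to OLS (tested at 1e-8 and 1e-4). Polynomial terms of degree 2 and
family-wise Bonferroni adjustment are supported. Predictors spanning orders
of magnitude (body size, range size, activity hours) are log-transformed in
the pipeline before regression.

**Blomberg's K** uses the standard ratio-of-ratios with the GLS grand mean,
so K = 1 exactly on a star tree with equal depths and centres on 1 under BM
(Monte-Carlo checked). The randomization P permutes tip values by default,
counting the observed statistic in both numerator and denominator
(P ≥ 1/(n_perm+1)); a BM-simulation null (`method="bm"`) is available since
the verbal description "P-values by 1000 simulations" admits both readings.

**Contrasts.** Felsenstein's pruning with branch-length extension;
contrasts are standardized by their expected SD. Polytomies are rejected
with instructions to resolve; `resolve_polytomies` inserts seeded random
zero-length resolutions. The |contrast|-versus-node-age regression is OLS
with a two-sided t-test; its type-I error under BM is calibrated in tests.

**Ancestral states** are the BM maximum-likelihood (GLS conditional-mean)
states; the root equals the GLS grand mean used inside K (an internal
consistency the tests assert). Lineage trends set each branch's value to
the mean of its endpoint states and average over all branches alive at a
query time, using the half-open convention: at a speciation event the
parent branch is excluded and both daughters included; terminal branches
also count at the present.

**Phylogenetic PCA** eigen-decomposes the GLS-estimated evolutionary
covariance (n − 1 denominator); scores are phylogenetically centred
projections. On a star tree it reproduces ordinary PCA.

**Disparity through time.** Subclade disparity is the mean squared pairwise
Euclidean distance among tip values. The curve starts at 1 at the root
(whole-tree normalization); at each later node height it averages the
relative disparities of the clades of all branches crossing that height.
The null envelope (default 2.5–97.5%) comes from BM simulations
rate-matched to the data via the GLS evolutionary covariance; because
relative disparity is scale-free, the envelope is invariant to the overall
rate. Zero whole-tree disparity is an error, not a zero curve.

## Substitution-rate scan

Root-to-tip path sums on substitution-scaled gene trees proxy
lineage-specific rates: every extant tip spans the same time, so path
differences are rate differences. Per gene the scan reroots on the
outgroup, drops it, and fits OLS of ingroup path sums on the environmental
covariate using only the tips present in that gene (no imputation); genes
lacking the outgroup or with fewer than three usable tips are skipped and
logged. Tallies partition retained genes into positive/negative/zero slopes
with significance at P < 0.05 (configurable); exactly-zero slopes are
tallied separately rather than folded into a sign. Because tips of a
non-star species tree share ancestral branches, per-gene OLS residuals are
phylogenetically correlated and the per-gene test is conservative there;
the type-I calibration in the acceptance suite therefore uses a star
species tree, where the nominal OLS calibration applies.

The codon Z test implements Nei–Gojobori (1986): per-codon synonymous site
fractions from the standard code, difference counts averaged over all
mutational pathways avoiding stop codons, averages over all sequence pairs,
Jukes–Cantor correction, and Z = (dN − dS)/SE with the SE from a seeded
bootstrap over codons (1000 replicates) — deterministic per seed and robust
for short alignments, where the analytic variance approximation is poor.
Identical sequences are flagged untestable with P = 1. Proportions ≥ 3/4
(saturation) are an explicit error.

## Diversification models

The 15-model grid crosses speciation forms {constant; linear in time;
exponential in time; linear in T(t); exponential in T(t)} with extinction
forms {zero; constant; linear in the same driver (time for constant
speciation)}. Time t is measured backwards from the present; the
paleotemperature curve T(t) is linearly interpolated with endpoint
clamping.

With r(t) = λ(t) − μ(t), R(t) = ∫₀ᵗ r and I(t) = ∫₀ᵗ λ e^R, the
crown-conditioned log-likelihood of branching ages x_i (crown age T) is

    Σ_i [ln λ(x_i) + ln g(x_i)] + 2 ln g(T) − 2 ln(e^{R(T)}/(1 + I(T))),
    g(t) = e^{R(t)} / (1 + I(t))².

The integrals are evaluated by composite Simpson quadrature on a 513-point
age grid augmented with the exact branching ages, so no interpolation
occurs at evaluation points; agreement with the pure-birth and
constant-rate closed forms is tested at 1e-6 (observed ~1e-10). Rates are
kept in bounds by rejection (−∞ likelihood), not post-hoc truncation.
Fitting uses Nelder–Mead from 5 seeded starts; the first start is the
always-feasible constant-rate submodel (Yule MLE for λ₀, zero slopes), and
infeasible jittered starts are repaired by shrinking slope terms toward it.
AIC = 2k − 2logL; ranks, ΔAIC and Akaike weights are reported per grid.
A single global sampling fraction is assumed complete (ρ = 1).

## Synthetic data: what it does and does not emulate

The generators are pure functions of their seeds. Default study conditions:
a 40-species clade (λ₀ = 0.15, μ₀ = 0.05 per lineage per Ma — a crown age
of a few tens of Ma with moderate turnover), thermal niche evolving by BM
with σ² = 1 per Ma, 200 genes with rate coupling b = 0.02 per environment
unit and lognormal branch noise sd 0.1, physiology truths T_pref = 33 °C
(+0.8 °C per environment unit across species), loss 0.02 g/h (−0.002 per
environment unit), 5 g mean mass, 12 individuals per species, and a 65-Ma
cooling curve from 26 to 14 °C with bounded wiggles.

Birth–death trees are simulated forward from two crown lineages,
conditioned on the extant count first reaching n; the present is placed a
uniform fraction of the next inter-event waiting time later (so 2-tip trees
have positive depth), and extinct lineages are pruned. The mean crown age
of this scheme has the closed form Σ_{k=2}^{n−1} 1/(kλ) + 1/(2nλ) for pure
birth, which the tests verify by Monte Carlo.

Gene trees share the species topology: coalescent discordance is
deliberately absent because rate variation, not discordance, is the object
of study. Branch environments are midpoints of BM (GLS) ancestral states —
a heritable-niche interpolation; consequently a tip with the largest
environment value does not necessarily have the largest root-to-tip path in
noise-free genes (its ancestors may have been cold), and monotonicity is
only exact on symmetric configurations. Microclimate grids have a
west-to-east annual-mean gradient, a seasonal cosine, a daylight-sine
diurnal cycle and Gaussian noise — no topography, no cloud cover, no
spatial autocorrelation of noise. Occurrences are uniform discs, not range
polygons. Passing recovery tests on these generators demonstrates estimator
correctness under the assumed statistical structure, not robustness to the
messiness of real occurrence databases or microclimate products.

## Problem sizes in the test suite

The suite favours many small, seeded Monte-Carlo checks: Blomberg K
centring uses 500 BM simulations on 20 tips; permutation-test and
contrast-regression calibrations use 500 replicates; gene-scan calibration
pools 3000 genes; DTT coverage compares 400 BM curves against a 500-curve
envelope on 16 tips; Yule rate recovery uses 100 trees of 100 tips; the
model-selection check fits the full 15-model grid on ten 30-tip trees. All
seeds are fixed, so runs are bit-reproducible.

## Known limitations

- The OU regression treats α as fixed when computing coefficient SEs
  (profile-likelihood practice); uncertainty in α is not propagated.
- The diversification likelihood assumes complete sampling and no rate
  shifts across subclades; clade-specific or fossilized models are out of
  scope.
- The Z test uses the simple Nei–Gojobori counting (no
  transition/transversion weighting) and the standard genetic code only.
- `gjp_support` counts bipartition presence in each replicate tree
  directly; whether published jackknife supports counted strict or
  majority-rule summaries is ambiguous, and this is the simplest
  well-defined reading.
- Polytomies are accepted in the container and most operations but must be
  resolved (randomly, seeded) before independent contrasts.
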