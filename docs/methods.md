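# Methods

This note documents the models, numerical choices and known limitations
of `genomeflux`. It describes what the code computes; every number cited
here is produced by the test suite or by `scripts/acceptance.py`.

## The birth-death-gain process

Family size *n* on a tree branch follows a continuous-time Markov chain
with down-rate *nμ* and up-rate *κ + nλ*: μ is the per-copy loss rate, λ
the per-copy duplication rate, and κ the gain (immigration) rate of the
family as a whole. Rates are per unit branch length, so their absolute
scale is tied to the units of the input tree.

**Transition probabilities.** The chain is truncated to states {0..M}
and the transition matrix computed as the dense matrix exponential of
the tridiagonal generator (`scipy.linalg.expm`). The diagonal keeps the
full exit rate, including the upward flow out of state M, so rows are
sub-stochastic and the row-sum deficit is an upper bound on the
probability of ever leaving the truncated space — a direct, per-row
measure of truncation error. The default bound is
M = max(3 × max observed count, 20); when the deficit on the rows the
data can occupy exceeds 1e-9, M is doubled automatically (up to three
times). Explicitly requested bounds are honored without the strict
check, so that small-M results remain exactly comparable with
enumeration oracles.

Two independent oracles validate the matrices in the tests: a
uniformized power-series evaluation of the same generator (agreement to
1e-8 at M = 60) and frequencies from 10⁶ exact stochastic simulations
(agreement within 3 Monte-Carlo standard errors).

**Root prior.** The stationary distribution of the chain: negative
binomial with size κ/λ and success parameter λ/μ for λ > 0 (requires
λ < μ), Poisson with mean κ/μ for λ = 0, truncated and renormalized.
κ = 0 degenerates to a point mass at zero. This choice matches the
model's long-run behavior; a free-mean Poisson alternative was
considered and rejected to keep the parameter space identifiable at
desk scale.

**Likelihood.** Pruning over size states, vectorized across families,
with per-family rescaling at every internal node to avoid underflow.
Likelihoods are conditioned on the family being observed (non-all-zero
profile) by default, because families absent from every genome never
enter an orthology table; all-zero rows are dropped with a warning when
conditioning is on. Rate heterogeneity across families uses K ≤ 4
equal-probability discrete-gamma categories (mean-of-slice values,
renormalized to mean exactly 1). A category multiplier scales κ, λ and
μ jointly — equivalent to scaling elapsed time — which preserves λ < μ
within every category and lets transition matrices be cached by
effective branch length.

**Fitting.** Staged maximization with `scipy.optimize` (L-BFGS-B on
transformed parameters): round 1 fits uniform rates from three seeded
starts; later rounds warm-start and add optional per-edge multipliers
(geometric mean fixed to 1 to remove the scale redundancy with branch
lengths; OFF by default) and K = 2, 3, 4 categories. The optimizer
works on (log κ, log μ, logit λ/μ), so the stationary-prior constraint
λ < μ holds by construction. Convergence is declared at relative
log-likelihood change below 1e-6; a round that fails to improve keeps
the best-so-far model, making the fitting trace non-decreasing. On 2000
simulated families over 8 genomes, all three rates are recovered within
15% (most runs within 6%).

**Event decoding.** For each family and edge, an inside–outside pass
computes the joint posterior of the (parent, child) states given all
leaf counts; the four event probabilities are sums over state patterns:
gain = P(0 → ≥1), loss = P(≥1 → 0), expansion = P(child > parent ≥ 1),
reduction = P(parent > child ≥ 1). Expansion and reduction deliberately
generalize single-step copy-number changes to any jump, mirroring the
presence/absence logic of gain and loss: a multi-copy jump on one edge
counts as one event. Posteriors are defined on parent→child state pairs,
not path-integrated event counts — two events that cancel within one
edge are invisible, which is the same convention the event definitions
imply. Category mixing uses per-family posterior category weights.
Expected totals (sums of posteriors over families and edges) agree with
logged simulation truth within 10% for gains and losses at 2000
families.

## Flux statistics

Event totals are normalized to events per COG per genome:
rate = total / (N families × N genomes). Defense-vs-all relative rates
divide the defense-set rate by the all-family rate per event type; an
undefined ratio (zero denominator) propagates as missing, never as 0 or
infinity. Flux classes rank clusters by the total-GDE ratio: the top
⌊N/4⌋ are high, the bottom ⌊N/4⌋ low, ties broken by cluster ID
ascending so the assignment is deterministic and order-invariant.

The composition test builds a 2 × 4 table of expected event counts
(defense vs all-minus-defense × four event types), rounded to integers
— posterior totals are expected counts and the test treats them as
counts — and applies the chi-square test of homogeneity without
continuity correction (df = 3), flagging expected cells below 1. The
rate-excess test is a Welch two-sample t-test on log-transformed
per-cluster rates (defense vs all), two-sided, with non-positive pairs
dropped; log rates are compared because normalized rates are ratio-scale
and right-skewed.

## PCA of relative rates

Inputs are the four per-event-type ratio columns; the total-GDE column
is excluded as a derived quantity. The default is PCA of the
**standardized** ratios (eigendecomposition of the correlation matrix),
which on the packaged 36-cluster table gives PC1 = 54.2% and
PC2 = 25.2% of the variance. Covariance-matrix PCA and a natural-log
transform are available as options; covariance PCA of the log ratios
yields 54.5%/28.0% on the same table, so the scaling choice is
material and the default was chosen because it reproduces the published
variance shares of this analysis. Loadings are orientated so the
largest-magnitude entry of each component is positive, making reported
signs deterministic.

## Chromosomal clustering tests

Distances are measured in gene-index units — the randomization samples
genes, so index units make the null exchangeable regardless of
intergenic spacing — with minimum-arc distance on circular replicons.
The statistic is the median over defense units of the distance to the
closest other defense unit (even counts: mean of the two central order
statistics). The null resamples equally many units uniformly without
replacement from all units of the replicon (from the defense units
only, for the gain/loss-event variant), and the one-sided p-value uses
the add-one correction p = (1 + #{null ≤ observed})/(1 + reps), so p is
never 0 and p ∈ (0, 1]. Directons are maximal runs of co-directed
genes, with the first and last run merged on circular replicons when
co-directed; a directon is defense-flagged if any member gene is
defense. Results record the seed and replication count; identical
inputs and seeds reproduce p-values bit for bit. Under a uniform null
the empirical type-I error at α = 0.05 stays within the binomial 95%
interval across 200 replicate chromosomes.

## Synthetic data generator

The generator is the package's ground-truth instrument, not a fixture:
trees are seeded pure-birth (Yule) trees rescaled to a target depth;
family counts evolve by exact event-driven (Gillespie) simulation of
the birth-death-gain chain, so empirical transition frequencies are an
unbiased oracle for the analytic matrices; chromosome maps place
defense genes next to an existing defense gene with probability equal
to the island concentration and assign strands by a persistence-p
Markov chain.

Defaults describe a realistic mid-sized tight genome cluster: 10
genomes, 2000 families, 5% defense (class mix ≈ 30% TA, 20% RM, 15%
CRISPR-Cas, 5% Abi, 30% other predicted defense), base rates
(κ, λ, μ) = (0.4, 0.2, 1.0), a 1.5-fold defense multiplier applied to
all three rates (elevated turnover), island concentration 0.5 and
strand persistence 0.6. The default tree depth of 0.2 was calibrated so
the reconstructed event density matches the ≈0.16 events per COG per
genome typical of real tight clusters (the acceptance script reports
≈0.15 at these settings). Root counts are drawn from each family set's
own stationary distribution; under the default joint multiplier the
defense and background stationary laws coincide, because scaling all
three rates leaves κ/λ and λ/μ unchanged.

**A note on depth and rate contrasts.** Per-edge event indicators
saturate on deep trees: over a long branch nearly every family that can
lose a gene does, and losses telescope against gains and presence, so
the defense-vs-all ratio of *indicator* events collapses toward 1 even
when the underlying defense loss rate is genuinely 1.5-fold higher.
Shallow, tight clusters — the regime this pipeline targets — preserve
the contrast: at the calibrated depth, a μ-only 1.5× defense multiplier
yields fitted defense-vs-all loss ratios averaging ≈1.4 and bracketing
1.5 across replicate clusters. Equivalently: the relative-rate
statistic measures realized flux, not instantaneous rates, and the two
agree only when branches are short. This is also why a multiplier on μ
alone, at stationarity and large depth, leaves the per-family loss
count nearly unchanged — higher per-copy loss is offset by lower
occupancy.

What the generator does **not** emulate: sequence evolution, realistic
intergenic spacing, donor-structured horizontal transfer (gain is a
memoryless immigration process), multi-replicon genomes by default, and
family-specific rate variation beyond the defense/background split plus
gamma categories. Passing tests therefore demonstrate correctness of
the inference machinery under the model, not robustness to the many
ways real genome histories violate it.

## Degenerate inputs and tie-breaks

Trees with all-zero branch lengths have no midpoint and are rejected;
zero-length edges elsewhere are legal (identity transition). Families
with counts above M raise rather than silently truncating. A
co-localization test where defense units are all units is reported as
degenerate with p = 1. Undefined relative-rate cells are excluded from
column means with a logged count. All tie-breaks (flux classes, loading
signs, even-count medians) are deterministic and documented above.

## Problem sizes used in validation

The validation suite runs at desk scale: enumeration oracles on 2- and
3-leaf trees with M ≤ 6; matrix-oracle comparisons at M ≤ 60; 10⁶
stochastic simulations per transition-matrix row; parameter recovery
and event-total checks at 2000 families × 8 genomes; calibration over
200 replicate chromosomes at 999 randomizations and island detection at
10,000; end-to-end ratio recovery over 10 replicate clusters at the
generator defaults. A full 36-cluster reanalysis from raw genomes is
out of scope — it requires the upstream genome-cluster database — so
printed-table statistics are validated against the packaged
relative-rate table instead.
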