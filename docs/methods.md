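# Methods

## Trait evolution model

A binary character (eyespot presence, or focal expression of one gene) evolves
along a rooted chronogram under a continuous-time two-state Markov chain with
gain rate `q01` and loss rate `q10`, both in events per million years (MY).
The model is deliberately asymmetric: gains of a complex trait and losses of
it are different processes and there is no reason to force one rate. The
2×2 transition matrix over a branch of length `t` is evaluated in closed form
(no matrix exponentiation at run time), and the likelihood of the observed tip
states is computed by pruning from tips to root with per-node rescaling, so
trees of many hundreds of tips pose no underflow problem. Missing tip data
(species without expression data for a gene) enter as partial likelihoods
`(1, 1)`, i.e. they are marginalized, not dropped: the tree shape still
informs the reconstruction.

**Root prior.** The default prior on the root state is the stationary
distribution `(q10/s, q01/s)` of the fitted rate matrix; `equal` (½, ½) and a
fixed root state are available. Published analyses of this kind rarely state
the choice their software made, and the prior is the main source of small
log-likelihood differences between implementations, so it is exposed rather
than hidden. Under the stationary prior the chain is time-reversible and the
likelihood is invariant to root placement; the test suite checks this by
rerooting.

**Rate estimation.** Rates are optimized in log space with L-BFGS-B inside
`[1e-8, 1e3]` per MY, from 5 starts by default (one heuristic start at one
event per tree height, the rest log-uniform random, reproducible from the
seed). Likelihood surfaces for rare events are flat near the boundary: when
every tip shares one state, the gain estimate wanders on the plateau near the
lower bound rather than pinning exactly to it, and the fit is reported with
`converged` reflecting the optimizer's own status.

**Constraints.** An origin hypothesis fixes internal nodes to states. This is
implemented as conditioning — the disallowed state's partial likelihood is
zeroed at that node — not as a soft prior. Consequently constrained
likelihoods can never exceed the unconstrained one, and the two single-node
restricted likelihoods sum exactly to the full likelihood; both identities are
tested. Competing models are compared on raw log-likelihood differences with
the two-log-unit rejection rule. A χ² LRT would be inappropriate because the
models differ by constraints, not by free-parameter count.

**Ancestral states and origin counting.** Marginal posteriors come from the
up–down algorithm and equal node-fixed likelihood ratios to 1e-9 (tested).
A node is called state 1 when `p1 ≥ 0.5 + 1e-9`; exact ties are reported as
ambiguous, and the implied number of 0→1 edges is then an interval over all
resolutions (enumerated when ≤ 12 ambiguous nodes, bounded conservatively
otherwise). A root reconstructed in state 1 is reported as an origin on the
root stem, since such an origin predates the tree and cannot be placed on any
edge.

## Onset timing (δ) test

Expression of a gene across wing discs is modelled as
`P(expressed | stage x) = expit(a + bx)`, fitted by maximum likelihood with
Newton iterations. Developmental stage is an ordered continuous covariate in
arbitrary units. Perfect separation — a stage threshold splitting 0s from 1s
exactly, common at realistic sample sizes — sends the ML slope to infinity;
the slope is capped at `|b| ≤ 50` per stage-unit and the intercept is then
profiled at the cap. The area under the curve is insensitive to the slope
once the curve saturates inside the integration range, so capping stabilizes
δ without biasing it. One-sided samples (all 0 or all 1) return a flagged
boundary curve saturated at the observed outcome.

δ is the *absolute* difference of the two genes' AUCs (it is used as a
distance, and absoluteness makes the bootstrap test one-sided), integrated
analytically over the pooled min–max of the two genes' observed stages —
pooling matches the pooled resampling of the null. The null distribution is
built by the mixed bootstrap: pseudo-gene A\* takes `⌊nA/2⌋` rows from A and
the remainder from B, pseudo-gene B\* takes `⌊nB/2⌋` rows from A and the
remainder from B, each half drawn independently with replacement; both curves
are refitted and δ\* recorded, for 10,000 replicates by default. The p-value
uses the `(r+1)/(B+1)` estimator, so p ∈ (0, 1] and a self-comparison gives
exactly p = 1. Star annotations follow the usual convention
(\*\*\* p<0.0001, \*\* p<0.01, \* p<0.05, ns).

**Calibration.** With dissection-style data — each disc at its own
continuous stage, 60 discs per gene — the empirical size of the test at
α = 0.05 is ≈ 0.03–0.05 (slightly conservative, as the +1 estimator implies),
and power at a two-stage-unit midpoint separation exceeds 90%. A known
limitation: when stages are sampled on a coarse grid and the true curve is
steep enough that almost every dataset is perfectly separated between two
adjacent grid points, the fitted midpoint can only jump between separation
boundaries and the test becomes anticonservative (size ≈ 0.09 measured at a
6-point grid with the midpoint centered between grid points). Designs whose
stage resolution is fine relative to the logistic transition width calibrate
correctly; analyses of coarse-grid data should interpret p-values near the
threshold with caution.

## Molecular-clock dating

Divergence between aligned COI barcodes is the uncorrected p-distance over
comparable sites (both sequences A/C/G/T; gaps and IUPAC ambiguity codes are
excluded from numerator and denominator), expressed in percent, averaged with
equal weight over all between-species pairs when species have several
sequences. Conversion to time divides by a strict clock rate, 2.3% per MY by
default for butterfly COI, and reports two decimals (the exact value is
retained). The distance is deliberately uncorrected: the linear rule is what
reproduces standard published COI dating arithmetic; model-corrected
distances (JC, K2P) would require a correspondingly corrected rate. Distances
from fewer than 100 comparable sites are refused.

## Complexity regression

Ring count is regressed on expressed-gene count by OLS (via statsmodels) and
the slope tested with `F = MSR/MSE` on `(1, n−2)` df. Plain regression, not
PGLS, is used by design for parity with the analysis this mirrors.
Collinear data are reported as `R² = 1, F = inf` rather than an error.

## Synthetic data

Chronograms are pure-birth trees grown to the requested tip count and
rescaled to a target root depth (default 110 MY, the scale of a family-level
butterfly tree); a death rate is unnecessary for likelihood testing.
Characters evolve by drawing each branch's endpoint state from the closed-form
transition matrix; origin counts from this mode are endpoint counts (events
hidden within a branch cancel), so an exact mode that simulates waiting-time
paths and counts every individual event is provided and flagged. Forced
single-origin histories plant one gain on a chosen edge and run loss-only
dynamics below it, emulating a single trait origin followed by scattered
losses. Onset generators draw Bernoulli outcomes from logistic curves either
on a fixed stage grid (`simulate_onset`) or with one continuous stage per
observation (`simulate_onset_sampled`), the latter being the realistic
emulation of staged dissections. Sequence pairs plant
`round(length·d/100)` substitutions at distinct sites, so the realized
p-distance is the nearest achievable to the target (36 sites, 5.47%, for the
658-bp barcode at 5.45%).

What the generators do *not* emulate: staining noise and scoring error,
phylogenetic error in the input tree, among-site rate variation or multiple
hits in sequences, and compartment-specific onset differences (compartments
are cosmetic labels; the analyses pool across them). Passing tests therefore
demonstrate correctness of the estimators under their own model assumptions,
not robustness to these real-data complications.

## Problem sizes in the test suite

The stochastic suites use 50 replicates of 400-tip trees for rate recovery,
30 replicates of 200-tip trees for origin-model selection, 500 null tests
(n = 60 per gene, 500 bootstrap replicates each) for the δ test's size and
100 for its power, and 200 small-tree enumerations for likelihood exactness —
sizes chosen so the full suite gives stable verdicts in minutes on one core.
The acceptance script reports the same quantities at modestly reduced
replicate counts (20, 15, 100/50 respectively).
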