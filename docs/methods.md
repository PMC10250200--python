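# Methods

## Model and sampler

The estimation target is a generalized linear mixed model with
covariance-structured random effects. For a response vector `y` (Gaussian)
or count pairs `(successes, failures)` (binomial with logit link):

    l = X b + Σ_k Z_k u_k + e,   u_k ~ N(0, σ²_k A_k),   e ~ N(0, σ²_e I)

For the Gaussian family `l = y`; for the binomial family `l` is a latent
liability per observation and `successes_i ~ Binomial(n_i, logistic(l_i))`.
Each `A_k` is either the identity or a phylogenetic correlation matrix.

Priors: independent `N(0, 10^10)` on each fixed effect; inverse-gamma with
shape ν/2 and scale νV/2 (V = 1, ν = 0.002; equivalently
scaled-inverse-χ²(ν, V)) on every variance component including the residual.
These are the conventional weakly-informative defaults for animal-model
MCMC, and the variance prior is proper but close to flat on the scale of
the data simulated here.

Updates are blocked Gibbs steps: `b` and each `u_k` from their conjugate
multivariate-normal conditionals (Cholesky solves of p×p and q_k×q_k
systems), variances from scaled-inverse-χ² conditionals. Binomial
liabilities use one random-walk Metropolis proposal per observation per
iteration, with a single global step size adapted by Robbins–Monro toward
0.44 acceptance during burn-in and frozen afterwards. In chained ensemble
runs the proposal scale is adapted only under the first tree and carried
onward, keeping later per-tree segments a fixed-kernel Markov chain.

The residual ("units") variance of binomial models is estimated by default:
the responses here are counts of ~400 trials, which identify it. For binary
(single-trial) responses it is not identifiable and `fix_residual=True`
fixes it at 1; the test suite exercises this degeneration.

Numerical notes: design matrices are validated for full column rank (QR
with pivoting names the aliased columns); phylogenetic covariances are
checked positive-definite (the error reports the minimum eigenvalue);
variance draws are strictly positive by construction.

## Fixed-effect coding and transforms

The global intercept is removed: the first factor term contributes one
column per level (absolute level estimates, enabling arbitrary level
contrasts from posterior draws), later factors drop their first
(alphabetically sorted) level, and interaction terms always use drop-first
coding so lower-order terms remain estimable alongside them. Continuous
covariates are z-scored using the analysis dataset's mean and SD.
Proportion covariates are logit-transformed after the shrink
`(p(n−1)+0.5)/n`, which keeps 0 and 1 finite; `n` is the per-row
classified-particle total. Conditional ("at level") covariates multiply the
covariate by the indicator of one factor level, so a slope can apply only
where, e.g., multicellular groups are present.

## Trees, covariance, and repeated measures

`phylo_covariance` fills entry (i, j) with the root depth of the MRCA of
tips i and j (Brownian-motion expectation); `as_correlation=True` divides
by tree depth (ultrametric trees only). Repeated measurements are bound to
the tree before covariance construction: strain nodes as polytomous
children of their species tip, observation tips as children of strains.
Added branches default to `1e-6 ×` tree depth — long enough to keep the
matrix strictly positive-definite for GLS and Cholesky factorisation, short
enough to be biologically negligible; the length is configurable because no
canonical value exists. Trees are stored rooted; explicitly unrooted input
is rejected rather than auto-rooted. Polytomies are represented natively.

## Ensemble chaining

`run_over_trees` integrates over phylogenetic uncertainty: for tree *i* the
covariance is rebuilt (after optional replicate augmentation), the sampler
runs from the final state of tree *i − 1* (fixed effects, random effects,
variances, and — for binomial models — the liability vector and proposal
scale), and retained draws are tagged with the tree index. Draws from the
first `tree_burn_in` trees are discarded; the pooled draw count is exactly
`(ensemble size − tree_burn_in) × retained per tree`. The classic schedules
retain one draw per tree (1,000 iterations/999 burn-in for experiment-scale
data, 10,000/9,999 for the slower-converging lake models) over 1,500 trees
with a 500-tree burn-in, giving 1,000 pooled draws; the per-tree retention
is generalized so shorter ensembles can still pool a useful posterior.
Convergence can be checked by re-running the full ensemble under different
seeds and comparing chains with the classic Gelman–Rubin PSRF (< 1.1); for
identical chains the statistic is √((n−1)/n), i.e. 1 up to O(1/n).

## Posterior summaries

Point estimates are posterior modes: the argmax of a Gaussian KDE
(Silverman bandwidth) evaluated at the sample points, which is
deterministic and scale-free. Note the KDE argmax over a flat posterior
summit carries sampling noise of order 0.1 SD at ~10⁴ draws; means are also
reported. Intervals are 95% HPD (shortest contiguous window of sorted
draws). pMCMC is the two-sided convention `2·max(0.5/N, min(#>0, #<0)/N)`
capped at 1, with draws exactly at zero split between the sides; a literal
one-sided variant is exposed as `pmcmc_one_sided`. I² divides each variance
component by the total random variance plus the link distribution variance
(0 Gaussian, π²/3 binomial-logit) and is reported in percent.

## Path analysis

`dsep_basis` builds one independence claim per non-adjacent pair, ordered
along a topological sort so the regressed variable is never an ancestor of
the regressor, conditioning on the union of both variables' parents. Claims
are tested by GLS (statsmodels) under the augmented phylogenetic
correlation; with the identity covariance the pipeline reduces exactly to
ordinary path analysis. C = −2Σ ln p; CICc = C + 2qn/(n − 1 − q) with
q = #edges + #nodes (each node contributes an intercept/variance; within a
fixed variable set the node count is a constant offset, so rankings and
weights are unaffected by the convention). `n` defaults to the number of
observation rows after augmentation, overridable (e.g. to the strain count)
because no canonical choice exists for repeated-measures d-separation.
Markov-equivalent DAGs have analytically identical C; CICc is rounded to 8
decimals before sorting so ties resolve by fewer parameters, then input
order. The default nine-model set over {ECM, palmelloid fraction, group
fraction} spans the plausible orderings, single-edge and independence
structures, and includes the empirically supported chain
ECM → palmelloid → group and its palmelloid → ECM variant. The saturated
three-edge DAG is deliberately excluded: its basis set is empty, so C ≡ 0
and the d-separation test is vacuous for it. The binary ECM variable enters
the GLS as 0/1; a logistic-GLS variant is out of scope.

## Growth metrics

SGR defaults to `log2(N_t1 / N_t0) / (t1 − t0)` (doublings per day): zero
at no growth and invariant to concentration units. The difference-based
variant `log2(N_t1 − N_t0) / (t1 − t0)` is retained behind
`mode="as_printed"` for auditability; it depends on the concentration units
and is undefined without net growth, and the ratio form is therefore the
default. RelSGR divides each record by its strain's mean SGR across
environments, making the per-strain mean exactly 1. Census columns are
configurable since growth can be measured over either the 48-hour or the
14-day interval.

## Synthetic data

`simulate_yule_tree` draws pure-birth trees by the exponential waiting-time
construction (expected depth Σ_{k=2..n} 1/(kλ)); `jitter_tree_ensemble`
emulates a posterior tree sample by lognormal branch-length noise followed
by re-ultrametrization (terminal branches extended to the deepest tip, so
no branch can go negative).

`simulate_experiment` draws, per strain × treatment row: phylogenetic
effects MVN(0, V_phylo·C) at species level, independent lake and strain
effects, and a residual per row, on the logit scale for three responses
(group membership, palmelloid membership, ECM) and on the doublings/day
scale for growth. Counts are one multinomial of 400 classified particles
per row (single / palmelloid / group; an optional fourth "other" class sits
behind a flag since the classification scheme names four categories but
three are analysed); ECM is binomial over 10 inspected images; growth rate
is Gaussian with its own, much smaller variance components, and
concentrations are back-derived from it. Default scale is 19 species, 35
strains, 10 lakes, a 2×2×2 factorial (280 rows). Default treatment effects
are the reported posterior contrasts (group: predation 2.73, nitrate 6.73,
turbulence 3.81; palmelloid: −0.89, 0.67, 0.35 with an ECM coupling of
0.71; ECM: nitrate 0.84; growth: predation and turbulence −0.04) with
intercepts chosen to give realistic baseline prevalences (rare groups,
uncommon palmelloids, ~50% ECM). Default variance components are
V_phylo = 1, V_strain = 0.5, V_lake = 0.15, V_residual = 1 on the logit
scale.

`simulate_lake_data` draws genus-level chemistry (Gaussian logs), ECM
presence, and multicellular-vs-unicellular species counts from logit-linear
models with phylogenetic effects. Slopes are moderate values with the
empirically observed signs (ammonium raises ECM probability; ECM raises
multicellularity with a negative ECM × ammonium interaction): published
genus-level estimates of these effects come from near-separation posteriors
whose magnitudes would generate degenerate all-or-nothing data, so they are
not usable as generative parameters.

What the generators do not emulate: predator–prey population dynamics,
measurement error in particle classification, missing rows (the generators
produce complete factorials), non-ultrametric gene-tree discordance, and
any mechanistic link between growth rate and group formation beyond the
specified couplings. Passing recovery tests therefore demonstrates that the
estimation machinery is correct under its own assumptions, not that those
assumptions hold in any particular real dataset.

## Problem sizes used in tests

The test suite and the acceptance script run at sizes chosen to keep a full
run on one CPU within a few minutes while leaving the statistical checks
sharp: 10 random GLS-agreement instances at n = 30 with 20,000 retained
draws; 20 parameter-recovery replicates at full study scale over 100-tree
ensembles (250 iterations per tree, burn-in 150, thinning 10, 20-tree
burn-in → 800 pooled draws); 500 pMCMC-calibration posteriors; 1,000
C-statistic null replicates at n = 100; 100 path-recovery replicates at 200
tips; and the full 1,500-tree bookkeeping schedule at toy model size.

## Known limitations

- Single-response models only; no multi-trait covariance estimation.
- The liability update is one global-step random walk; very heterogeneous
  trial counts within one model would mix better with per-row scales.
- DIC is Gaussian-only (marginalising random effects analytically is
  problematic for non-Gaussian responses); binomial model comparison relies
  on R².
- The prediction R² uses the inverse-logit of the posterior-mean linear
  predictor for binomial models (no Jensen correction); a fixed-effects-only
  prediction variant is available via the stored posterior means.
- GLS d-separation tests treat the binary ECM indicator as Gaussian, as in
  standard phylogenetic path analysis.
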