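# Methods

## The observation model

A bisulfite-sequencing readout at a cytosine is "C" or "T". Three
library-level parameters distort the mapping from methylation state to
readout: the bisulfite conversion efficiency `bs_eff` (probability an
unmethylated C is converted, so read as "T"), the incorrect conversion
rate `bs_star_eff` (probability a methylated C is converted anyway) and
the sequencing error rate `seq_err`. The conditional readout
probabilities are bilinear in these parameters
(`methrep.model_core`), and the marginal probability of "C" at a site
with methylation level θ is the θ-mixture of the two conditionals. With a
perfect instrument (1, 0, 0) the "C" fraction equals θ; a low `bs_eff`
inflates it, which is exactly why poorly converted libraries overestimate
methylation when analysed naively.

The methylation state space is the two-state simplex (unmethylated,
5mC). Hydroxymethylation (5hmC) would enter as a third simplex component
with its own conditional readout probability; the mixture code is written
over component axes so this is an extension point, but it is not
implemented.

`bs_star_eff` is never estimated: experiments rarely include fully
methylated spike-ins. It is a single constant applied to every replicate,
default 0.001 (0.1%), configurable.

## Stage 1: experimental parameters from spike-in controls

Per technical replicate j: `logit(bs_eff_j) = mu + sigma * r_j` with
`r_j ~ N(0,1)`, `mu ~ N(4, 1.29)`, `ln sigma ~ N(0.4, 0.5)`; analogously
for `seq_err` with `mu ~ N(-8, 1.29)`. The hyper level (mu, sigma) is
shared across replicates in the default joint fit — the replicate plate
encloses only the r auxiliaries — and an independent per-replicate mode
exists for embarrassingly parallel runs (the two agree closely on typical
control data). Each control cytosine k carries a latent methylation
fraction with a Dirichlet(999, 1) prior over (unmethylated, methylated) —
spike-in DNA is unmethylated up to trace carryover — and the counts are
binomial through the observation model. The same (999, 1) concentration is
used for generation and inference; it is exposed in
`ControlModelConfig`.

Numerically, the per-cytosine latent is marginalised rather than sampled:
its Beta marginal is integrated by 32-node Gauss–Legendre quadrature after
the quantile-function substitution `t = F^{-1}(u)`, which maps the prior
integral onto the unit interval. Two consequences:

- the marginal likelihood of a cytosine depends only on its (total, "C")
  pair, so the 444-cytosine likelihood collapses to the ~10 distinct count
  pairs with multiplicities — a large constant-factor speedup;
- the free latent space shrinks to 4 + 2R dimensions for R replicates,
  which both backends handle easily.

This is a reparameterisation, not an approximation of the model (up to
quadrature error, which is negligible at these concentrations): the
posterior over `bs_eff`/`seq_err` is unchanged. Per-cytosine theta draws
can be reconstructed exactly from fitted draws by sampling the discretised
conditional on the quadrature grid (`ControlModel.sample_theta`).

Stage-1 posteriors are summarised by arithmetic means of the draws
(medians optional) and passed to stage 2 as fixed
`ExperimentalParams`.

## Stage 2: the general linear model

Per cytosine: `Y = D B + E` with Y ∈ R^{N×2}; sample i's methylation
level is the methylated component of `softmax(row_i(Y))`, computed
stably as `expit(y_i1 - y_i2)`. Priors are the diagonal matrix-normal
cases `vec(B) ~ N(0, sigma_B^2 I)` with `sigma_B^2 = 5` and
`vec(E) ~ N(0, sigma_E^2 I)` with a single `sigma_E^2 ~ InvGamma(1, 1)`
shared by both columns. E is kept as an explicit latent (non-centred
construction) rather than marginalised; the marginal covariance form is
used only in a test oracle. The softmax leaves one redundant degree of
freedom per row; identifiability comes solely from the proper priors and
no sum-to-zero constraint is imposed.

Each technical replicate contributes an independent binomial likelihood
with its own fixed experimental parameters; a zero-coverage replicate
contributes a constant and is harmless. The *reduced* model — the
traditional workflow — is the same code with parameters forced to
(1, 0, 0), applied by the caller to the well-converted libraries only.

Cytosine coordinates are 1-based and strand-collapsed (CpG level).
Per-cytosine fits are independent; the runner derives a per-cytosine seed
from (master seed, cytosine index), so results are reproducible and
order-independent.

## Differential methylation

For intercept + group-indicator designs, the tested scalar is the
coefficient contrast `delta = b_{2,1} - b_{2,2}` (only column differences
of B move theta under the softmax); its prior is N(0, 2 sigma_B^2). The
Bayes factor is the Savage–Dickey ratio of prior to posterior density at
zero; large values indicate differential methylation. Ranking, not
calibration, is the intended use (evaluation is by AUROC), and note that
for null-consistent data the ratio drops *below* one — the posterior
piles up at zero — rather than hovering at one.

The posterior density at zero is estimated two ways:

- **Conditional-Gaussian averaging (default for GLM fits).** Given the
  row differences `w_i = y_i1 - y_i2` and `sigma_E^2`, the contrast
  vector `beta = B[:,1] - B[:,2]` has an exact Gaussian posterior (a
  linear-Gaussian regression step), so the density of delta at zero is the
  posterior average of an explicit normal pdf. This Rao-Blackwellised
  estimator has no bandwidth, extends into tails, and — crucially — does
  not depend on the joint geometry of (b_{2,1}, b_{2,2}), whose
  near-perfect posterior correlation along the softmax-redundant direction
  a mean-field variational fit cannot represent. With a factorised
  approximation, a KDE over delta draws overstates Bayes factors by orders
  of magnitude; the conditional estimator agrees with MCMC to ~0.1 decades.
- **Gaussian KDE with Silverman bandwidth** (`savage_dickey_bf`), the
  generic estimator for arbitrary draw vectors. It falls back to a
  moment-matched normal density when there are fewer than 500 draws or
  when zero lies more than three standard deviations outside the draw
  bulk, where a kernel estimate at a point is dominated by the single
  nearest draw and unusable.

A joint bivariate Savage–Dickey at (b_{2,1}, b_{2,2}) = (0, 0) is
available behind a flag as an alternative estimator. Reported alongside
each Bayes factor is a Monte-Carlo standard error of its log, from the
asymptotic variance of the density estimate.

AUROC is the rank-based area (ties half-weighted; `sklearn` backed) over
positive (Δθ ≠ 0) and negative (Δθ = 0) cytosines; true positive rate uses
either a fixed Bayes-factor cutoff (default 3) or a quantile of the null
scores.

## Inference backends

Both backends consume the same model objects: batched closed-form log
posterior and gradient in an unconstrained space, derived by hand for the
two models (all transforms are compositions of expit, exp and affine
maps). A uniform `InferenceConfig` fixes the backend, the retrieved draw
count S (the same for both backends so downstream summaries are
comparable; defaults follow S = 1600 for MCMC and S = 1000 for ADVI in
the differential pipeline), and the seed, which is mandatory.

**MCMC** uses the affine-invariant ensemble sampler (`emcee`) with
max(2d+2, 8) walkers, initialised from a diagonal Laplace approximation at
the posterior mode (found by L-BFGS on the exact gradient); the first half
of the iterations is discarded as warmup and the remainder thinned to S.
Acceptance fraction is attached as a diagnostic.

**ADVI** fits a diagonal Gaussian in the unconstrained space by stochastic
gradient ascent on the ELBO with the reparameterisation trick: N_G
gradient samples per step (default 1), Adam with step size 0.08,
convergence declared when the relative change of the ELBO estimate (N_E =
100 samples) stays below 0.01. Two numerical details matter in practice:

- *Warm start.* The optimiser starts at the posterior mode with Laplace
  scales. The mode search itself starts from the hyperprior locations, not
  from zero: zero puts every probability at 0.5, a saddle of the readout
  likelihood from which the optimiser can slide into the mirrored mode
  (`bs_eff` and `seq_err` jointly flipped — the observation probability is
  invariant under that flip) that the priors all but exclude.
- *Tail averaging.* With few gradient samples the Adam iterates
  random-walk around the optimum at the learning-rate scale. After the
  stopping rule fires, the step size is cut 5× and the final 200 iterates
  of (mu, omega) are averaged (Polyak averaging). Without this the
  posterior means carry optimisation noise comparable to their Monte-Carlo
  error.

Mean-field ADVI underestimates variances along correlated posterior
directions (the softmax-redundant ridge above is the extreme case); point
estimates of theta and of experimental parameters agree with MCMC to
within a few hundredths, which the test suite checks, and Bayes factors
go through the conditional estimator for exactly this reason.

`sweep_advi_params` grids N_E × N_G against an MCMC reference and reports
mean absolute log10 Bayes-factor deviation, for choosing speed/precision
trade-offs.

## Synthetic data

Three generators (`methrep.simulate`) produce count tables plus full
latent ground truth, byte-reproducible from their seed:

- **Control study**: 444 spike-in cytosines per replicate, trace
  methylation Dir(999, 1), fixed `bs_eff` ∈ {0.995, 0.9}, `seq_err` =
  `bs_star_eff` = 0.001, coverage either uniform on {1, 2, 3} (the "a few
  reads" regime; a range in the design is read as per-cytosine uniform) or
  constant 10.
- **Level-estimation study**: one biological sample, three technical
  replicates of mixed quality — 'GGB' (two good, one bad) or 'GBB' — with
  `bs_eff` drawn from beta(99.5, 0.5) (good) or beta(90, 10) (bad) and
  `seq_err`, `bs_star_eff` from beta(0.1, 99.9); four cytosines at
  theta ~ beta(100,900), (300,700), (700,300), (900,100); coverage
  ∈ {6, 12, 24}; paired control blocks (100 cytosines, coverage 20) share
  the replicate parameters.
- **Differential study**: two groups × four biological replicates × three
  technical replicates; per biological replicate theta ~ Beta(α, β) from a
  mean-level grid 0.2 … 0.8 with concentration α + β = 1000; coverage 10
  ('GBB') / 6 ('GGB'); positives pair level 0.2 against 0.3/0.4/0.5,
  negatives reuse 0.2 vs 0.2. Replicate parameters are drawn once per
  dataset; paired control blocks (same settings as above, a choice made
  here since the differential design does not pin them down) let the full
  two-stage pipeline run on each dataset.

What the generators emulate is the count-level statistical structure:
binomial sampling through the observation model, replicate-specific
instrument quality, biological spread of methylation levels. What they do
not emulate: read-level artefacts (mapping, duplicates, M-bias), spatial
correlation along the genome, coverage heterogeneity beyond the stated
rules, or overdispersion beyond the modelled sources. Passing tests
therefore demonstrate correctness of the inference machinery under the
model's own assumptions and realistic misspecification of library quality
— not robustness to alignment artefacts.

## Study runners and problem sizes

`methrep.benchmark` re-runs the three studies end to end (stage 1 on the
paired controls, then full and reduced stage-2 fits) with dataset seeds
spawned from a master seed, never reused. Default desk-scale sizes, chosen
to make the comparisons statistically meaningful while staying pleasant to
run interactively: 20 replicates per control condition; 100 datasets per
scenario for level estimation; 50 positive + 50 negative cytosines per
contrast (generated in 10 datasets of 5 cytosines, so stage-1 fits are
shared within a dataset) for the power study. Everything accepts explicit
sizes.

## Known limitations

- 5hmC (and oxidative sequencing designs that resolve it) is out of scope.
- No spatial smoothing or region calling; every cytosine is independent.
- Mean-field ADVI credible intervals are too narrow along correlated
  directions; use the MCMC backend when interval calibration matters.
- The Bayes factor's absolute scale depends on the design coding through
  the implied prior on the group contrast (ranking of well-separated
  cytosines does not).
- The control model assumes the spike-in is homogeneous; gross
  contamination of the control DNA would bias `bs_eff` downward.
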