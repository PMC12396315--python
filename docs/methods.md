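# Methods

This note documents the models and procedures implemented in `lingcontact`,
the choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## The inference chain

The package estimates how much more likely two unrelated languages are to
share a structural feature state when their speaker populations show genetic
evidence of contact. The chain has five stages:

1. **Admixture screening** over per-K ancestry-proportion tables (ADMIXTURE
   `.Q` layout). A population is an admixture candidate at one K if its two
   largest ancestry components together reach at least `top2_min` (default
   0.70) and the smaller of the two contributes at least `minor_min`
   (default 0.05; smaller contributions are treated as noise). A candidate
   is retained only if this holds at `min_k_levels` (default 5) distinct K.
   Source proxies are populations carrying the relevant component at
   `source_purity_min` (default 0.80) or more. Triplets (target, source 1,
   source 2) are filtered to keep exactly one source inside the target's
   language family; the unrelated source's family supplies the source-clade
   languages of the resulting contact pair, and pairs sharing a source
   family collapse under one broad pair id.
2. **F3 confirmation.** Patterson's F3(T; A, B) averages
   `(p_T - p_A)(p_T - p_B)` over SNPs, with the per-site bias correction
   `p_T(1 - p_T)/(n_T - 1)` (the unbiased estimator of the sampling variance
   of the target frequency under binomial sampling of `n_T` chromosomes).
   Standard errors come from a weighted delete-one block jackknife over
   contiguous blocks of 500 SNPs by default (block weights proportional to
   usable SNPs per block). A pair is confirmed when F3 < 0 and z < -3.
3. **Statewise pair dataset.** Multistate features are binarized one state
   at a time (state vs. not-state); binary features contribute a single
   variable because the two binarizations carry identical agreement
   information. Contact rows pair the target language with every
   source-clade language that has data; baseline rows are 300 (configurable)
   uniformly sampled unordered cross-family pairs per feature, reused across
   the feature's states. Every row records agreement (the response), the
   genetic-contact indicator G, the same-area indicator A, the unordered
   area-combination label, and — for contact rows — the pair id nested in
   its broad pair id.
4. **Hierarchical logistic models** m1–m5 (below).
5. **Measurement-error meta-analyses** over the first-stage effects (below).

## The contact models

All models are Bernoulli-logit regressions of statewise agreement. The full
model (m1) uses the linear predictor

```
eta_i = alpha + alpha_STATE[i] + alpha_AA[i]
      + (beta_1 + betaA_STATE[i]) * A_i
      + (beta_2 + betaG_STATE[i] + beta_AA[i] + beta_BROAD/PAIR[i]) * G_i
```

with correlated varying effects: the per-state triple (intercept, area
slope, genetic slope) is multivariate normal with covariance
`diag(sigma_STATE) R_STATE diag(sigma_STATE)`, the per-area-combination pair
(intercept, genetic slope) likewise, and the nested broad/pair genetic
slopes are univariate normal. m2 keeps only the areal terms; m3–m5 keep
only the genetic terms and are fitted on all rows, same-area contact rows
only, and different-area contact rows only (baseline rows are always
retained). An intercept-only reference model m0 (global intercept plus
per-state intercepts) is provided for model comparison.

Priors: intercept `N(0.75, 0.5)` — with statewise binarization the baseline
agreement probability of a random pair is `q^2 + (1-q)^2 >= 1/2` for any
marginal q, so the intercept's prior mean is positive on the logit scale;
fixed effects `N(0, 1.5)`; group SDs half-normal(0, 2) (an SD is
non-negative, so the nominal `N(0, 2)` prior on a scale parameter is folded
onto the half line, matching what standard multilevel software does);
correlation matrices LKJ(2).

### Posterior computation

No probabilistic-programming framework is used: the package ships its own
No-U-Turn sampler (multinomial NUTS with dual-averaging step-size
adaptation, windowed diagonal mass-matrix estimation, divergence detection
at an energy error of 1000) driven by hand-derived analytic gradients of
the log posterior. All varying effects are non-centered (standard-normal
innovations scaled by `diag(sigma) L`), group SDs live on the log scale,
and correlation Cholesky factors are parameterized by canonical partial
correlations (tanh of unconstrained values) with the LKJ density and
transform Jacobian included. The gradient implementation is verified
against finite differences in the test suite; the unconstrained LKJ density
is verified by comparing NUTS samples of the transform against direct
onion-method draws (marginal correlation `2 Beta(2.5, 2.5) - 1` for d = 3,
eta = 2); and the full fit was cross-validated against an independent
mixed-model implementation (lme4) on one dataset during development, with
matching point estimates.

Default sampling: 4 chains of 1000 post-warmup draws after 500 warmup
iterations, sequential, seeded. A fit is flagged non-converged when any
reported parameter has rank-normalized split R-hat ≥ 1.01 or bulk ESS
< 400, or when post-warmup divergences occurred; summaries then refuse to
run unless forced.

### Summaries

Effects are reported as probability differences (delta-P). The global
delta-P toggles the condition's fixed effect at the population mean of all
varying effects: `invlogit(alpha + beta) - invlogit(alpha)`. Per-state
delta-P adds that state's varying intercept to both arms and its varying
slope to the toggled arm. Group levels unseen at fit time predict at the
population mean (zero offset) — deterministic and conservative. Intervals
are highest-posterior-density intervals computed as the shortest
contiguous window over sorted draws containing `ceil(mass * n)` samples
(ties leftmost), and the direction probability is the fraction of draws
strictly above zero. Model comparison uses PSIS-LOO via arviz on pointwise
Bernoulli log-likelihoods, with pairwise elpd differences and their
pointwise SEs; prior and posterior predictive checks compare per-condition
sharing rates with replicated datasets.

## The meta-analyses

First-stage effects enter as (posterior mean, posterior SD) pairs on the
probability-difference scale. The main-effect model regresses the effect on
categorical covariates (model, sensitivity status, parameter, dataset;
treatment coding with references m1/main/genetic/GBI) with a global
intercept; the feature-state model uses group-indexed means with no
intercept, fitted separately per contact type and per domain-group
classification. Both fix the observation SDs at their first-stage values
and put `N(0, 1.5)` priors on all coefficients, with no residual
heterogeneity term — the model is a pure measurement-error model as
specified (a random-effects tau can be added via a config flag by users who
want one). Because the likelihood is Gaussian with known variances and the
priors are Gaussian, the posterior is multivariate normal in closed form;
the implementation samples it exactly instead of running MCMC.

Average marginal effects are computed per categorical level against its
reference by switching every observed row's level and averaging the
difference in the linear predictor per posterior draw (for an additive
model this equals the coefficient; the averaging route is kept because it
generalizes and is cross-checked against the coefficient in tests).
Pairwise domain-group differences are reported as posterior medians with an
"89% HPDI includes zero" flag.

Domain-group vocabularies default to six top-level feature classes
(lexical semantics, lexical classes, grammatical categories, linear order,
other grammar, phonology) and a phonology-internal classification
(prosody, vocalic, consonantal); both are user-overridable.

## The synthetic-data generator

The generator produces every pipeline input with known ground truth:

* **Ancestry profiles.** Every population owns a home component per K
  (index mod K); top shares are drawn from `U(purity, purity + 0.05)`
  (capped at 0.98, default purity 0.9) and residual mass is spread
  uniformly over the remaining components. A planted admixture event splits
  the target's top share between the two sources' home components, with the
  minor source receiving exactly `min(alpha, 1 - alpha)` of the profile
  (capped at half the top share). This makes planted events exactly
  recoverable by the screen whenever `min(alpha, 1 - alpha) >= minor_min`
  and the event is visible at `min_k_levels` values of K — the generator's
  recovery contract.
* **Allele counts.** Ancestral frequencies are `U(0.05, 0.95)` (avoiding
  near-fixed sites that destabilize F3); sources drift by Balding–Nichols
  Beta rescaling with per-branch F; an admixed target's true frequency is
  the alpha-mixture of the source frequencies (optional post-admixture
  drift); observed counts are binomial in 2 x (diploid sample size)
  chromosomes. Without an event the target is a pure drift descendant of
  source 1 — the negative control whose expected F3 is non-negative.
* **Pair observations** are drawn exactly under the m1 generative model:
  varying effects from multivariate normals whose covariances share a
  single off-diagonal correlation rho (the simplest generator consistent
  with the model's two correlation matrices), contact pairs nested in broad
  pairs (default three pairs per broad pair, mirroring the ratio of curated
  pairs to broad pairs in real applications), and areas drawn from a
  ten-label inventory (a six-label alternative mirrors macroarea-scale
  coding for sensitivity runs).
* **Feature tables** are independent draws per language and feature with
  configurable state marginals; families are assigned so both related and
  unrelated pairs exist.

What the generator does **not** emulate: linkage disequilibrium and
genotype error (F3 block sizes are therefore a convention, not an LD
estimate), phylogenetic autocorrelation of features within families,
geographic diffusion, missing-data structure, and curation noise. Passing
tests therefore demonstrate correctness of the inference machinery under
the model's own assumptions, not robustness to real-data violations of
them.

## Numerical and scaling choices

* Ties for the second-largest ancestry component break toward the lowest
  component index; component identity is matched within each K only (no
  cross-K alignment), with cross-K support counted per population.
* F3 sites missing any of the three populations are skipped and counted;
  a site set with constant per-site values yields SE = 0 and is flagged
  degenerate rather than assigned an infinite z.
* Baseline pairs are sampled once per feature and reused across its states;
  multiple source-clade languages with identical states are kept (the
  pair-level varying slope absorbs the pseudo-replication).
* Test and demonstration runs use deliberately small problem sizes (tens of
  states, tens of contact pairs, a few hundred baseline pairs per state,
  thousands of SNPs) so the whole chain, including MCMC, runs on a laptop
  in minutes. One consequence worth knowing: at small group counts the
  half-normal SD hyperpriors keep substantial posterior mass at large
  values, so credible intervals for the genetic fixed effect are
  conservative — in repeated null simulations at 18 contact pairs in 9
  broad groups the 89% interval was roughly 2.3 times wider than the
  sampling spread of the posterior mean and covered zero in every run.
  This is a property of the model at that scale, not of the sampler
  (prior-draw coverage checks and an independent mixed-model cross-fit
  agree); near-nominal frequentist calibration of these intervals requires
  on the order of thirty groups in each varying-slope classification.
* Known limitation: for nested multilevel models compared by PSIS-LOO on
  data with no true effect, the expected elpd difference equals the extra
  effective-parameter count, so "no difference" cannot be certified by an
  elpd-within-2-SE rule when the complexity gap is large; the comparison
  table exposes `p_loo` so users can see the penalty directly.
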