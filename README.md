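# lingcontact

From genetic admixture evidence of population contact to Bayesian estimates
of linguistic feature-state borrowing.

When two speaker populations mix genetically, did their languages also
exchange structure? `lingcontact` implements a reusable inference chain for
that question, aimed at population geneticists and typologists who have (a)
model-based ancestry decompositions (ADMIXTURE-style Q tables) plus allele
counts for their populations and (b) structural feature tables for the
associated languages:

1. **Screen** ancestry profiles for admixed populations: the two largest
   components must jointly reach 70% of ancestry with the smaller at least
   5%, consistently across at least five values of K; source proxies carry
   the relevant component at ≥80%. Triplets with exactly one same-family
   source yield cross-family contact pairs, grouped by shared admixture
   source.
2. **Confirm** admixture with Patterson's F3: for sample frequencies the
   per-site statistic is `(p_T − p_A)(p_T − p_B) − p_T(1 − p_T)/(n_T − 1)`,
   averaged over SNPs, with a weighted block-jackknife z-score; F3 < 0 with
   z < −3 confirms.
3. **Assemble** a statewise dataset: every feature state becomes a binary
   sharing outcome for contact pairs and for 300 random cross-family
   baseline pairs per feature, annotated with areal colocation.
4. **Model** sharing with hierarchical Bayesian logistic regressions
   (m1–m5): fixed effects for genetic contact (G) and areal colocation (A),
   correlated varying intercepts and slopes by feature state and by area
   combination, and genetic slopes nested by contact pair within broad
   pair. For the full model,

   ```
   same_state_i ~ Bernoulli(logit⁻¹(η_i))
   η_i = α + α_STATE[i] + α_AA[i] + (β₁ + βA_STATE[i])·A_i
       + (β₂ + βG_STATE[i] + β_AA[i] + β_BROAD/PAIR[i])·G_i
   ```

   with priors α ~ N(0.75, 0.5), β ~ N(0, 1.5), group SDs half-N(0, 2),
   correlations LKJ(2). Effects are summarized as probability differences
   (ΔP) with 89% highest-density intervals, direction probabilities, and
   PSIS-LOO model comparisons. Fitting uses the package's own NUTS sampler
   with analytic gradients (see `docs/methods.md`).
5. **Meta-analyze** first-stage effects across models, datasets and domain
   groups with exact conjugate measurement-error regressions.

A synthetic-data module generates every input with known ground truth
(planted admixture events, known F3 signs, known contact effect sizes), so
the whole chain is testable end to end without any external data.

## Worked example

Simulate a statewise pair dataset with a known genetic borrowing effect
(β_G = 0.8 log-odds) and recover it with the full model:

```python
from lingcontact import (ContactEffectTruth, ModelSpec, build_design,
                         delta_p, fit_model, simulate_pair_observations)

truth = ContactEffectTruth(beta_G_true=0.8, beta_A_true=0.3,
                           sigma_state=0.2, sigma_AA=0.1,
                           sigma_pair=0.15, sigma_broad=0.15)
obs, _ = simulate_pair_observations(truth, n_states=16, n_contact_pairs=16,
                                    n_baseline=150, seed=7)
spec = ModelSpec.for_id("m1")
fit = fit_model(spec, build_design(obs, spec), chains=2, draws=500,
                warmup=400, seed=1)
for condition in ("genetic", "area"):
    es = delta_p(fit, scope="global", condition=condition, force=True)
    print(f"{condition:>7}: dP = {100*es.delta_p_mean:+.1f}% "
          f"[89% HPDI {100*es.hpdi89_low:+.1f}%, {100*es.hpdi89_high:+.1f}%] "
          f"P(>0) = {es.p_direction:.2f}")
```

prints (about a minute on one CPU core):

```
genetic: dP = +7.5% [89% HPDI -1.4%, +17.3%] P(>0) = 0.90
   area: dP = +6.3% [89% HPDI +0.5%, +11.9%] P(>0) = 0.96
```

Read: under genetic contact a language pair is an estimated 7.5 percentage
points more likely to share a feature state than a random cross-family
baseline pair (the planted +0.8 log-odds corresponds to ≈ +13 points at
this baseline; at 16 contact pairs the interval is honest about how little
a small pair sample constrains the effect). `state_effect_table(fit)` gives
the same contrast per feature state, and `loo_compare` ranks models.

The full chain — simulate → screen → f3 → pairs → fit → meta → report —
runs from the shell:

```sh
lingcontact run-all --outdir demo_run --seed 1
cat demo_run/report.txt
```

## Layout

| Module | Role |
| --- | --- |
| `lingcontact.synthetic` | ground-truth generators for all inputs |
| `lingcontact.screen` | per-K admixture screen, proxies, contact pairs |
| `lingcontact.f3` | Patterson F3 with weighted block jackknife |
| `lingcontact.pairs` | statewise binarization, baselines, assembly |
| `lingcontact.models` | m0–m5 fitting (NUTS), ΔP/HPDI/LOO/predictive checks |
| `lingcontact.meta` | conjugate measurement-error meta-analyses |
| `lingcontact.pipeline` / `lingcontact.cli` | orchestration and CLI |

`docs/methods.md` documents the models, priors, numerical choices and
limitations in detail.
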