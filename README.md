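# crashmix

Mixed (random-parameters) multinomial logit with **heterogeneity in means
and variances** for crash injury-severity analysis, plus the surrounding
apparatus of a severity study: KABCO recoding, descriptive tables, a
ground-truth synthetic crash-data generator, Halton-draw simulated maximum
likelihood, marginal effects, and the likelihood-ratio transferability
test.

## Who this is for

Traffic-safety and injury-epidemiology analysts who model police-reported
crash severity (the KABCO scale, collapsed to severe / minor / no injury)
as an unordered three-alternative outcome, and who need random
coefficients whose heterogeneity is itself explained by observed
attributes — for example comparing crashes of in-state vs out-of-state
large-truck drivers.

## The model

Each crash *n* has a severity function per alternative *k*:

    S_kn = β_k′ X_kn + ε_kn,        ε_kn ~ i.i.d. extreme value type I

which gives multinomial-logit probabilities conditional on β.  Selected
coefficients are random across crashes with both moments structured:

    β_kn = β + δ_k′ z_n + σ_k · exp(ω_k′ w_n) · v_n,     v_n ~ N(0,1)

so the mean shifts linearly with attributes *z* and the standard deviation
scales multiplicatively with attributes *w*.  Unconditional probabilities
integrate over the mixing density,

    P_n(k) = ∫ [exp(β_k′ X_kn) / Σ_j exp(β_j′ X_jn)] f(β|φ) dβ,

and the integral is approximated by averaging over Halton draws
(quasi-random radical-inverse sequences mapped through the inverse normal
CDF).  Estimation maximises the simulated log-likelihood with an analytic
gradient; fit quality is summarised by McFadden pseudo-ρ² =
1 − LL(convergence)/LL(zero).

Post-estimation: average discrete-change marginal effects for indicator
covariates (rows sum to zero across the three alternatives), sign shares
Φ(±mean/sd) of a normal random coefficient, and the transferability test
LR = −2[LL(pooled) − LL(group₁) − LL(group₂)] ~ χ²(df).

## Worked example

`examples/03_fit_mixed_logit.py` simulates 4000 crashes from a scenario
with one normally distributed random coefficient — `rural` in the
severe-injury utility, its mean shifted by an `interstate` indicator and
its standard deviation scaled by a `tree_collision` indicator — and
refits it with 200 Halton draws:

```
N=4000, draws=200, LL=-2992.39, LL0=-4394.45, pseudo-rho2=0.319, converged=True
                      parameter alternative  estimate  std_error  t_stat  significant  truth
                 beta:const[NI]          NI     1.949      0.048  40.416         True    2.0
              beta:rollover[SI]          SI     1.207      0.125   9.627         True    1.3
              beta:fatigue[MIN]         MIN     0.129      0.344   0.375        False    0.5
              beta:rear_end[NI]          NI    -0.740      0.094  -7.908         True   -0.7
                 beta:rural[SI]          SI    -0.929      0.588  -1.582        False   -1.0
    delta:rural[SI]<-interstate          SI    -0.646      0.286  -2.262         True   -0.6
                sigma:rural[SI]          SI     1.954      0.734   2.661         True    2.2
omega:rural[SI]<-tree_collision          SI     0.429      0.415   1.033        False    0.6

estimated rural coefficient ~ N(-0.929, 1.954^2): positive for 31.7% of crashes
```

The estimates sit near the generating truth (right-hand column); the
sign share says the rural effect *raises* severe-injury risk for about a
third of crashes and lowers it for the rest — exactly the kind of
heterogeneity a fixed-coefficient logit would average away.  The other
examples cover descriptive tables (`01`), Halton draws (`02`), marginal
effects (`04`) and the transferability test (`05`).

A thin CLI mirrors the library for shell pipelines:

```bash
crashmix simulate scenario.yaml out/         # dataset + truth from a recipe
crashmix describe crashes.csv --dictionary dict.yaml --out tables/
crashmix fit data.csv --spec model.yaml --out fit/
crashmix report --group in a.csv --group out b.csv --spec model.yaml --out rpt/
```

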