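# abnma — arm-based and contrast-based Bayesian network meta-analysis

Network meta-analysis (NMA) jointly synthesizes randomized trials that
compare several treatments for the same condition, combining direct
comparisons (within a trial) with indirect ones (through a common
comparator). A long-running methodological debate concerns *contrast-based*
(CB) models, which place distributions on relative effects, versus
*arm-based* (AB) models, which place them on arm-level means. `abnma`
implements the four structural models that bracket this debate for a binary
outcome under the exact binomial arm-level likelihood
`y_ik ~ Binomial(n_ik, expit(θ_ik))`:

| Model | Structure | Study intercepts |
|---|---|---|
| 1 | CB, observed arms only (Lu–Ades): `θ_ik = α_i + δ_ik`, `δ_ik ~ N(μ_k − μ_b, σ_c²)` | fixed |
| 2 | CB, all possible arms: `δ_i ~ MVN(μ^c, Σ^c)` (equivalent AB form available) | fixed |
| 3 | model 2 plus `α_i ~ N(μ_1^a, σ_a²)` | random |
| 4 | AB (Hong): `θ_i ~ MVN(μ^a, Σ^a)`, intercepts correlated with effects | random |

Heterogeneity is *common* (CH — every pairwise contrast shares one
heterogeneity variance `σ_c²`, via compound-symmetry structures such as
`Σ^a = σ_a² P_K(ρ^a)` with implied `σ_c² = 2σ_a²(1−ρ^a)`) or *non-common*
(NCH — unstructured covariance with an inverse-Wishart prior).

The key scientific distinction is that random study intercepts (models 3–4)
use *between-study information*: outcome levels are compared across trials,
which can bias treatment contrasts when trial design is associated with
underlying risk. The package ships machinery to demonstrate this
end-to-end: a deterministic generator of ten hypothetical three-treatment
datasets with known truth, estimand computation (conditional odds ratios,
marginal treatment means `π_k = E[expit(θ_ik)]`, marginal contrasts,
external-risk-targeted risk differences), and an 18-trial inhaled
corticosteroids network (seven steroids vs placebo, outcome = elimination
of oral corticosteroid use) as a packaged fixture.

## Worked example

Fit model 3 (random intercepts) and model 1 (fixed intercepts) to the
corticosteroids network and compare the mometasone (treatment 7) vs
placebo log odds ratio:

```python
import abnma

net = abnma.load_corticosteroids()
chains = abnma.ChainConfig(burn_in=10_000, post_burn_updates=40_000,
                           thin=4, seed=2)
m1 = abnma.fit(abnma.ModelSpec(1), net, chains)
m3 = abnma.fit(abnma.ModelSpec(3), net, chains)
print(abnma.summarize(m1, "mu_c[7]"))
print(abnma.summarize(m3, "mu_c[7]"))
print(abnma.summarize(m3, "sigma_a"))
```

```
ParamSummary(median=4.229506712368099, ci_low=1.5160124788776326, ci_high=8.505260917620136)
ParamSummary(median=2.664011192914057, ci_low=0.6821437957951109, ci_high=4.756067384519179)
ParamSummary(median=0.8482199235628558, ci_low=0.5077037045818571, ci_high=1.4196779704430376)
```

Model 1 estimates a 7-vs-1 log odds ratio around 4.2; model 3's random
intercepts (arm heterogeneity SD ≈ 0.85) shrink the very low placebo risks
of the mometasone trials toward the network mean, cutting the estimate by
roughly 2 log-odds units — odds ratios several times smaller from the same
data, purely through the use of between-study information. (Medians are
Monte Carlo quantities; reruns with other seeds move them by a few
hundredths.)

The same analyses run from the shell:

```bash
nma data corticosteroids --out ics.csv
nma fit --data corticosteroids --model 3 --het CH --seed 2 --out run_m3
nma compare --data corticosteroids --models 1,2,3,4 --contrast 7,1 \
    --seed 2 --out forest.csv
nma generate --scenario 3 --subtype b --out data3b.csv
nma prior-sample --model 4 -n 10000 --seed 1 --out prior.csv
```

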