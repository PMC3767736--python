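# spotnmix

Hierarchical Bayesian estimation of predator–prey numerical responses from
repeated spotlight counts.

Spotlight counts are cheap and cover the large areas that matter for
wide-ranging predators, but they confound abundance with detection: the
same transect can yield very different counts on consecutive nights.
`spotnmix` is built for robust-design count data — each transect surveyed
on repeated nights within a season (population closed), across many
seasons (population open) — of a predator and its primary prey, the
motivating system being feral cats and European rabbits in the pastoral
South Island of New Zealand. The package is aimed at quantitative
ecologists who want explicit abundance (not index) estimates and a
measurement of the predator's numerical response from this kind of data.

## The model

For each species, counts are binomial thinnings of latent abundances with
logit-linear, season- and length-dependent detection:

    y_ijk ~ Binomial(N_ik, p_ijk)
    logit(p_ijk) = α_k + β₁·TL_i + β₂·TL_i² + δ_ijk,   δ_ijk ~ N(0, γ)

Latent log abundances follow seasonal Gompertz dynamics, and the
predator's dynamics include a lagged numerical-response term on prey log
abundance:

    prey:      x_ik ~ N(a_s(k) + b·x_i,k−1, σ²)
    predator:  x_ik ~ N(a_s(k) + b·x_i,k−1 + c_s(k)·r_i,k−1, σ²)

with x = log N, seasons alternating breeding/non-breeding, `b = 1` meaning
no density dependence and `0 < b < 1` negative density dependence. The
joint posterior is sampled by an adaptive Metropolis-within-Gibbs scheme
(see `docs/methods.md` for the sampler and its convergence-critical
translation and interweaving moves). A synthetic-data generator with known
parameters makes every stage testable end to end.

## Worked example

```python
import spotnmix as sx

# a survey like the motivating one: 66 transects, lengths ~N(23.1, 5.9) km,
# 12 alternating 6-month seasons, two nights per season, 10% missingness
design = sx.make_survey_design(66, 12, 23.1, 5.9, 0.1, seed=31)
config = sx.default_config(design, seed=31)      # known "true" parameters
counts, truth = sx.simulate_dataset(design, config)

model = sx.NumericalResponseModel(counts)         # rabbit prey, cat predator
result = model.fit(n_chains=3, n_iter=20_000, burn_in=10_000, thin=5, seed=1031)

for name in ("rabbit.a_b", "rabbit.a_nb", "rabbit.b", "cat.c_b", "cat.c_nb"):
    lo, hi = result.credible_interval(name)
    print(f"{name:12s} {result.posterior_median(name):6.2f} ({lo:.2f}, {hi:.2f})"
          f"  sig={result.is_significant(name)}")
print("rabbit detection %.2f   cat detection %.2f"
      % (result.mean_detection('rabbit')[0], result.mean_detection('cat')[0]))
print("Bayesian p: rabbit %.2f  cat %.2f"
      % (result.bayesian_p_value('rabbit'), result.bayesian_p_value('cat')))
```

Output from this exact run:

```
rabbit.a_b     1.38 (1.09, 1.69)  sig=True
rabbit.a_nb    2.17 (1.89, 2.48)  sig=True
rabbit.b       0.56 (0.50, 0.63)  sig=True
cat.c_b        0.03 (-0.20, 0.27)  sig=False
cat.c_nb       0.64 (0.39, 0.91)  sig=True
rabbit detection 0.63   cat detection 0.27
Bayesian p: rabbit 0.48  cat 0.40
```

Read: both rabbit seasonal growth intercepts are positive with CIs
excluding zero (generating values 1.19 and 1.98); density dependence is
negative (b below 1 — check the b ≠ 1 question with
`is_significant("rabbit.b", null_value=1)`); the cat's numerical response
to last season's rabbits is significant into its non-breeding season
(`c_nb`, CI covering the generating 0.5) but not into its breeding season
(`c_b`, generating 0), exactly the generating structure. Rabbit detection
lands near the generating 0.69; the rare cat's detection (generating 0.20)
is the most weakly identified quantity at two surveys per season and sits
a little high — see `docs/methods.md` for why. Bayesian p-values near 0.5
say the fitted binomial model reproduces its own data comfortably.

`result.summary()` collates medians, 95% CIs, Gelman–Rubin statistics,
CI-rule significance flags, detection summaries, Bayesian p-values and
per-km density indices; `result.summary().write(outdir)` emits the CSV
tables. A thin CLI wraps the same pipeline:

    spotnmix simulate --config sim.yaml --out data/ --seed 1
    spotnmix fit --data data/counts.csv --config fit.yaml --out posterior.npz
    spotnmix report --posterior posterior.npz --data data/counts.csv --out report/

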