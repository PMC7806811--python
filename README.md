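# mscure

Multi-state cure modelling of cancer recurrence and death after
curative resection.

After a tumour is resected, some patients are *apparently cured* — the
tumour was eliminated and they will never relapse — while others carry
residual disease and remain at risk of recurrence and of death. Neither
group is directly observable at surgery. `mscure` is for
biostatisticians and cancer epidemiologists who want to model this
structure jointly rather than run separate survival analyses for
recurrence and death: it estimates how covariates (age, sex, stage,
metastasis, chemotherapy) affect **the probability of being cured** and
**every transition between disease states**, simultaneously.

## The model

Four states — 1 apparently cured, 2 not cured (event-free),
3 recurrence, 4 death — with latent membership in {1, 2} at baseline:

* incidence: `logit P(NotCured | x) = α + γ′x`
* transitions 1→4, 2→4, 2→3 on the study clock and 3→4 on the gap-time
  clock (semi-Markov clock reset at recurrence), each proportional
  hazards `λ_jk(t|x) = λ0_jk(t) exp(β_jk′x)` with an unrestricted
  (nonparametric, Breslow) baseline; state-2 survival uses the sum of
  the two cause-specific cumulative hazards, and the 3→4 submodel takes
  the realised time-to-recurrence as a covariate.

Estimation is by EM over the latent cure status: subjects with observed
recurrence are known not cured; subjects still at risk beyond 50 months
are labelled apparently cured; everyone else gets a posterior weight.
M-steps are weighted logistic and weighted Cox (Breslow) fits with
Firth stabilisation; standard errors come from a nonparametric
bootstrap. See `docs/methods.md` for the estimation details, the
synthetic-cohort generator, and known limitations.

## Worked example

```python
import numpy as np
from mscure import (FitConfig, fit, generate_cohort, kaplan_meier,
                    mean_profile, state_occupancy)

# a synthetic cohort with the study's structure (n=283, known truth)
cohort, latent = generate_cohort(283, seed=1)
df = cohort.frame
print(f"observed recurrence: {100*df.d_rec.mean():.1f}%")
km = kaplan_meier(df.t_rec, df.d_rec)
print(f"KM recurrence plateau: {km.values[-1]:.3f} (flag: {km.plateau})")

fitted = fit(cohort, FitConfig(n_boot=0, center_age=55.58))
print(f"EM converged in {fitted.n_iter} iterations,"
      f" log-likelihood {fitted.trace[-1]:.1f}")
print(f"posterior not-cured fraction: {fitted.weights.mean():.3f}")
g = dict(zip(fitted.incidence.names, fitted.incidence.gamma))
print(f"metastasis odds ratio (incidence): {np.exp(g['metastasis']):.2f}")

profile = mean_profile(cohort, center_age=fitted.age_center)
curves = state_occupancy(fitted, profile, grid=np.array([0.0, 60.0]))
print(f"mean-profile OS(60m) = {curves.os[1]:.3f}, EFS(60m) = {curves.efs[1]:.3f}")
```

prints

```
observed recurrence: 15.5%
KM recurrence plateau: 0.817 (flag: True)
EM converged in 65 iterations, log-likelihood -938.3
posterior not-cured fraction: 0.351
metastasis odds ratio (incidence): 14.94
mean-profile OS(60m) = 0.511, EFS(60m) = 0.509
```

Reading: 15.5% of subjects relapse during follow-up, and the
recurrence Kaplan–Meier curve plateaus at 0.82 with many late censored
subjects — the classic sign that a cured fraction exists and a cure
model is warranted. The EM attributes ~35% of the cohort to the
not-cured class. Metastatic patients have ~15-fold higher odds of not
being cured in this particular draw (single-cohort estimates at n=283
are noisy — the bootstrap CIs from `bootstrap_ci` are wide). For the
"mean" covariate profile, about half the probability mass has reached
the death state by 60 months, almost all of it without an intervening
recurrence (OS ≈ EFS).

The same pipeline runs from the shell:

```sh
mscure simulate --n 283 --seed 1 --out cohort.csv
mscure fit --cohort cohort.csv --out fit.json --table table.csv
mscure predict --fit fit.json --cohort cohort.csv --out curves.csv
mscure describe --cohort cohort.csv --out-dir desc/
mscure run --config pipeline.yaml --out-dir results/
```

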