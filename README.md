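# iiwbias

Quantifying the bias of inverse-intensity-weighted GEEs when patients with
no follow-up assessments are excluded from longitudinal analyses.

## The problem

In many longitudinal studies — chart reviews, registries, cohorts followed
through routine care — outcomes are measured at irregular, patient-specific
times, and the *timing* of assessments often depends on how sick the patient
is. Plain generalized estimating equations (GEEs) are then biased, and the
standard remedy is inverse-intensity weighting (IIW): model the assessment
intensity

λ(t | Z_i(t)) = λ₀(t) exp(Z_i(t) γ₀)

with an Andersen–Gill (recurrent-event Cox) model, and weight each observed
outcome by exp(−Z_i(t) γ̂) in the working-independence GEE

Σᵢ ∫₀^τ X_i(t)ᵀ (Y_i(t) − X_i(t)β) exp(−Z_i(t)γ) dN_i(t) = 0.

A side effect of irregular assessment is that some patients have **no
follow-up at all**, and common practice drops them. For a fixed γ the
weighted estimating function has no terms from these patients, so dropping
them cannot move β̂ directly — but it changes the *risk sets* of the
intensity fit and therefore biases γ̂, which propagates into β̂ and into any
derived estimand such as the area under the mean trajectory (AUC), the
average disease burden ∫₀^τ μ(t) dt.

This package provides, as a library plus a small CLI:

* **`iiwbias.simulate`** — a cohort simulator in which the assessment
  intensity depends on the last observed outcome
  (λᵢ(t) = λ₀ exp(γ₀ log(1+Y at last visit))), with latent random
  intercept/slope and an exponentially correlated residual process;
  zero-follow-up subjects are first-class citizens of the output.
* **`iiwbias.intensity`** — counting-process construction and an
  Andersen–Gill partial-likelihood fitter (`AndersenGillIntensity`,
  sklearn-style) under two inclusion schemes: `EV` (everyone) and `FU`
  (drop subjects with no events), plus inverse-intensity weights.
* **`iiwbias.iiw_gee`** — the weighted GEE solver (`IIWGEE`, an sklearn
  regressor) with cluster-robust sandwich covariance, and the AUC estimand
  with a delta-method standard error.
* **`iiwbias.bias_theory`** — closed-form large-sample bias of γ̂ under the
  `FU` scheme for time-invariant covariates (Bernoulli, Normal, Gamma),
  built from the weighted moments s_k(γ) = E(Z^k e^{γZ}) and their
  analogues conditional on N(τ)>0; the first-order transfer of that bias
  into β̂; and bias curves along λ₀, τ, fixed λ₀τ, and
  γ-with-fixed-visit-rate axes.
* **`iiwbias.experiments`** — Monte-Carlo scenario runner comparing the two
  schemes end to end, with calibration helpers (hold P(N(τ)=0) or the
  expected visit count fixed while other parameters move).

## Worked example

```python
import numpy as np
from iiwbias import (OutcomeModelSpec, VisitModelSpec, simulate_cohort,
                     build_counting_process, fit_intensity, compute_weights,
                     solve_iiw_gee, auc_from_beta, design_matrix,
                     gamma_bias_closed_form)

outcome = OutcomeModelSpec(mechanism=1)          # declining mean trajectory
visit = VisitModelSpec(lambda0=0.5, gamma0=0.5, tau=2.0)
cohort = simulate_cohort(500, outcome, visit, seed=7)
print("zero-visit subjects:", sum(p.n_visits == 0 for p in cohort))

rows = build_counting_process(cohort, visit)
for scheme in ("EV", "FU"):
    fit = fit_intensity(rows, scheme=scheme)
    events = rows[rows["event"] == 1]
    w = compute_weights(fit, events)
    gee = solve_iiw_gee(events["subject_id"], design_matrix(events["stop"]),
                        np.concatenate([p.visit_outcomes for p in cohort if p.n_visits]),
                        weights=w, scheme=scheme)
    auc = auc_from_beta(gee.beta_hat, visit.tau, cov=gee.cov_sandwich)
    print(f"{scheme}: gamma_hat = {fit.gamma_hat[0]:.3f}, "
          f"AUC = {auc.value:.2f} (SE {auc.se:.2f})")

print("analytic omission bias, Bernoulli(0.5), gamma0=0.5, Lambda0=1:",
      round(gamma_bias_closed_form(("bernoulli", 0.5), 0.5, 0.5, 2.0), 4))
```

prints

```
zero-visit subjects: 38
EV: gamma_hat = 0.439, AUC = 12.47 (SE 0.16)
FU: gamma_hat = 0.441, AUC = 12.47 (SE 0.16)
analytic omission bias, Bernoulli(0.5), gamma0=0.5, Lambda0=1: -0.2451
```

On a single cohort the two schemes differ little; the systematic difference
emerges across replicates (`iiwbias.experiments.run_scenario`), where the
`FU` scheme's γ̂ is attenuated and the AUC acquires a bias whose sign
depends on the shape of the mean trajectory. The true AUC here is 12.42,
and the analytic value −0.2451 is the large-sample γ̂ bias in the
time-invariant special case where it has a closed form: dropping zero-count
subjects inflates the low-rate group's conditional event count relatively
more, pulling γ̂ toward zero. The bias depends on λ₀ and τ only through
Λ₀ = λ₀τ and vanishes as follow-up becomes certain.

The same steps are available from the shell:

```bash
iiwbias simulate --config config.yml --out out/
iiwbias fit-intensity --visits out/visits.csv --scheme FU --tau 2 --out gamma.csv
iiwbias bias-theory --dist bernoulli --gamma 0.5 --axis lambda0 --out curve.csv
iiwbias experiment --grid lambda0 --reps 500 --out grid.csv
```

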