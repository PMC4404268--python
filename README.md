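# jointpredict

Dynamic prediction of death after cancer relapses, for biostatisticians
working with recurrent-event survival data (e.g. breast-cancer registry
series).  Relapses — loco-regional recurrences or distant metastases —
and death are semi-competing risks: a patient's relapse history carries
prognostic information about death, but relapses cannot enter a survival
model as an ordinary time-dependent covariate.  This package implements
the two standard answers and the machinery to compare them:

* a **joint frailty model**: relapse intensity u·λ_R0(t)·exp(β₁'Z) and
  death hazard u^α·λ_D0(t)·exp(β₂'Z) share a gamma frailty u (mean 1,
  variance θ); the power link α quantifies the relapse–death association.
  Fitted once by penalized maximum likelihood with M-spline baselines,
  it yields *dynamic* predictions P(death in (s, s+w] | alive at s,
  history at s) that update with every new relapse, with (`predict_rec`)
  or without (`predict_ign`) the relapse history;
* a **landmark Cox model** refitted at each prediction time s on the
  patients still alive, with the relapse count before s ({0, 1, ≥2}) as
  a baseline covariate (`predict_lm`);
* an **external-validation layer**: IPCW Brier prediction-error curves,
  explained variation R² = 1 − Err/Err_KM against the Kaplan–Meier
  prediction, and decile calibration tables;
* a **synthetic-cohort generator** with the published structure of the
  French development series and the UK/Dutch validation registries
  (covariate mix, ~66% relapse-free, ~89% five-year survival,
  administrative censoring, optional 5-year relapse-recording rule),
  since the original data are confidential.

## Worked example

```python
import numpy as np
from jointpredict import (
    FitConfig, LandmarkConfig, SimulationConfig, build_landmark_dataset,
    fit_joint_model, fit_landmark_cox, french_like, predict_lm, predict_rec,
    request_from_subject, simulate_cohort,
)

from jointpredict import predict_ign

truth = french_like()                      # theta=1.07, registry-like HRs
cohort = simulate_cohort(truth, SimulationConfig(n_subjects=1000, seed=3))
fit = fit_joint_model(cohort, FitConfig())
print(f"theta={fit.theta:.2f}  alpha={fit.alpha:.2f}  "
      f"HR(nodal, death)={np.exp(fit.beta_death[4]):.2f}")

# a grade-III, node-positive patient with three relapses before year 5
subject = next(s for s in cohort
               if s.followup_time > 10.0 and s.relapses_before(5.0)
               and s.covariates["nodal"] == 1 and s.covariates["grade"] == "III")
req = request_from_subject(subject, s=5.0, w=5.0)
print(f"P_rec = {predict_rec(req, fit).probability:.3f}")
print(f"P_ign = {predict_ign(req, fit).probability:.3f}")

lm = fit_landmark_cox(build_landmark_dataset(cohort, 5.0), 5.0,
                      LandmarkConfig())
print(f"P_lm  = {predict_lm(req, lm).probability:.3f}")
```

prints

```
theta=1.15  alpha=1.57  HR(nodal, death)=5.87
P_rec = 0.668
P_ign = 0.217
P_lm  = 0.263
```

The fitted frailty variance and power link recover the generative values
(θ = 1.07, α = 1.5) within sampling error, and the nodal-involvement
death hazard ratio 5.87 estimates the generative 4.89.  For this patient
the covariates alone put the risk of dying between years 5 and 10 at
22% (`P_ign`); the three relapses observed by year 5 raise the
joint-model prediction to 67% (`P_rec`), while the landmark model —
which only sees the pooled "≥2 relapses" category — gives 26% (`P_lm`).

A full study replica (develop on a French-like cohort, validate on
case-mix-shifted cohorts, write Brier/R² curves, calibration tables and
plots) runs from the shell:

```sh
jointpredict run --seed 1 --out-dir study_out
jointpredict simulate --seed 1 --n-subjects 500 --out-prefix demo
jointpredict fit-joint --subjects demo_subjects.csv \
    --recurrences demo_recurrences.csv --out model.json
```

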