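# qlcox — quasi-linear Cox proportional hazards models

Cox regression assumes one linear risk score for everyone. When a cohort
mixes subpopulations whose hazards respond differently to the same
covariates — a common situation in oncology, where molecularly distinct
patient groups react differently to the same treatment — a single linear
predictor can mask the signal. `qlcox` fits a **quasi-linear Cox model**:
the linear predictor is replaced by a log-sum-exp average of K linear
predictors,

    f_Q(x) = log( Σ_k π_k exp(β_k′ x) ),      π on the K-simplex,

so the hazard h(t|x) = h0(t) exp(f_Q(x)) = Σ_k π_k h0(t) exp(β_k′ x) is a
mixture of proportional-hazards components sharing one baseline. K = 1
recovers ordinary Cox regression.

The package provides, for right-censored survival data:

- **Maximum partial-likelihood estimation** by an MM
  (minorization–maximization) fixed-point algorithm with guaranteed
  likelihood ascent, random restarts, and observed-information standard
  errors;
- the **CLASSO estimator** — estimation under an adaptive *cross-L1*
  penalty `P_c(β) = n λ_c Σ_{ℓ≠m} Σ_j |β_ℓj β_mj| / |β̂_ℓj β̂_mj|` that
  drives each covariate's effect into at most one component (a
  *cross-sparse* fit), solved by a sign-restricted full-gradient method
  that produces exact zeros;
- a **restricted model** where a known covariate partition fixes which
  component each covariate may act in;
- **BIC selection** of the component count K and penalty strength λ_c;
- **time-dependent ROC/AUC** evaluation (cumulative cases / dynamic
  controls with IPCW) with bootstrap intervals;
- a **simulation engine** with six built-in scenarios (multivariate-normal
  covariates, exponential baseline and censoring, inverse-transform event
  times) and a replication harness that tabulates per-parameter Mean and
  MSE × 100 after resolving label switching.

## Worked example

Fit the penalized two-component model to a simulated dataset whose true
coefficients are cross-sparse (β = ((1, 0), (0, 1.5)), π = (0.3, 0.7)):

```python
from qlcox import QuasiLinearCoxModel, FitControl, generate_dataset, scenario_catalog

data = generate_dataset(scenario_catalog()["1-IS"], seed=3)
model = QuasiLinearCoxModel(data, K=2)
result = model.fit_regularized(lambda_c=0.5, control=FitControl(seed=0))
print(result.summary())
print("AUC at t=50:", round(result.auc(50.0), 3))
```

```
Quasi-linear Cox proportional hazards model
===========================================================
subjects: 400    events: 352    components: 2
log partial likelihood: -1540.4707    BIC: 3098.5322
converged: True in 31 sweeps
-----------------------------------------------------------
parameter         estimate     std err
pi_1                0.7029      0.0857
pi_2                0.2971      0.0857
beta_1[x1]          0.0000      0.0495  (zero)
beta_1[x2]          1.4255      0.0838
beta_2[x1]          0.9839      0.0812
beta_2[x2]          0.0000      0.0922  (zero)
===========================================================
AUC at t=50: 0.936
```

The penalty recovered the generating structure exactly: each covariate
acts in one component only (the `(zero)` rows are exact zeros, not
thresholded values), the mixing proportions estimate (0.70, 0.30) against
a truth of (0.7, 0.3) up to component labeling, and the nonzero
coefficients (1.43, 0.98) estimate (1.5, 1.0). The AUC is the
discrimination at day 50 between subjects who had the event by then and
those still at risk.

Model selection and data handling run the same way from the shell:

```sh
qlcox simulate --scenario 1-IS --outdir out --seed 3
qlcox fit      --input out/scenario_1-IS_seed3.csv --outdir out --k 2 --lambda-c 0.5
qlcox select   --input out/scenario_1-IS_seed3.csv --outdir out --k-grid 1,2,3
qlcox evaluate --input out/scenario_1-IS_seed3.csv --fit-json out/fit.json \
               --outdir out --eval-times 25,50,100 --bootstrap 200
```

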