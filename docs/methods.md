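# Methods

## Model

For a subject with covariate vector x ∈ R^p, the quasi-linear Cox model
sets

    h(t | x) = h0(t) exp(f_Q(x)),
    f_Q(x)   = log( Σ_{k=1..K} π_k exp(β_k′ x) ),

with mixing proportions π_k > 0, Σ π_k = 1, and component coefficient
vectors β_k. Because exp(f_Q) = Σ_k π_k exp(β_k′ x), this is a mixture
hazards model — the population hazard is a π-weighted sum of K
proportional-hazards terms sharing a single baseline h0(t). It is *not* a
mixture of densities: the survival function is the geometric mean
S(t) = Π_k S_k(t)^{π_k}. Assumptions: time-fixed covariates, independent
right-censoring, a common baseline hazard across components. K = 1 is
ordinary Cox regression.

The model is invariant to permuting component labels, and a constant
added to every β_k′ x shifts f_Q by that constant (the baseline absorbs
it), so only contrasts of the component predictors are interpretable.

### Partial likelihood

With data (x_i, t_i, δ_i), risk sets R(t_i) = {ℓ : t_ℓ ≥ t_i} and
η_i(θ_k) = π_k exp(β_k′ x_i), the partial log-likelihood is

    l(θ) = Σ_i δ_i [ log Σ_k η_i(θ_k) − log Σ_{ℓ∈R(t_i)} Σ_k η_ℓ(θ_k) ].

Ties are handled Breslow-style: tied subjects all belong to each other's
risk sets and each event keeps its own term; with distinct times this is
exactly the formula above. The score involves two posterior-weight
matrices: p_mi (component membership of subject i's hazard) and p*_mi
(component share of subject i's risk-set mass); both are columnwise
probability vectors over components.

All mixture and risk-set sums are computed as max-shifted log-sum-exp
over time-sorted suffix cumulative sums. This matters: the simulation
scenarios use coefficients up to 1.5 with covariate SD 2, and for p = 5
unshifted exponents overflow double precision.

## Maximum partial-likelihood estimation (MM)

The fitter maximizes the tangent surrogate G(θ, θ^(s)) — equal to l at
the anchor, with matching gradient, and minorizing l elsewhere — so each
sweep cannot decrease l. One sweep:

1. **Coefficients.** For each component k, solve the weighted Cox-type
   estimating equation
   Σ_i δ_i p_ki x_i = Σ_i δ_i p*_ki [Σ_{R_i} exp(b′x_ℓ) x_ℓ / Σ_{R_i} exp(β_k′x_ℓ)]
   for b by damped Newton iterations (default cap 25, step halving on the
   residual norm, gradient fallback if the inner Hessian is singular),
   warm-started at the current β_k. Masked coordinates (restricted model)
   stay at zero; the solve runs on the free submatrix.
2. **Mixing vector.** Closed-form rescaling of π using the posterior
   weights and the risk-sum ratio at the *new* coefficients, normalized
   to the simplex. The update order — β first, then π using the updated β
   inside the normalizer — follows the literal form of the update rule.
   π is floored at 1e-10 to keep the score defined.

Outer convergence: relative log-likelihood change
|l_{s+1} − l_s| / (|l_s| + 1) < `tol` (default 1e-8), cap 500 sweeps. The
likelihood need not be unimodal, so the fitter runs `n_restarts`
(default 5) initializations and keeps the best final likelihood.
Initialization: π_k = 1/K and β_k from a Cox fit on the k-th part of a
random disjoint K-way split of the subjects (a light ridge keeps these
tiny-subsample pilot fits finite under separation); deterministic given
the seed.

For K = 1 the model *is* Cox regression, and the MM fixed point is
polished by a full Newton solve of the exact partial likelihood, so the
K = 1 fit agrees with a standard Cox solver to ~1e-7 per coefficient
rather than at the (linear-rate) MM stopping accuracy.

The MM iteration converges linearly, so at the default tolerance the
residual score norm is of order 1e-2 on an N = 400 dataset and shrinks
proportionally as `tol` is tightened — a property the test suite checks
rather than hides.

Standard errors come from the observed information: the negative Hessian
of l on unconstrained coordinates (π log-ratio transformed with the last
component as reference, free β entries), obtained by central differences
of the analytic score (step 1e-5), inverted (pseudo-inverse with a
warning if singular), with π standard errors delta-method back-transformed
through the softmax.

## Cross-L1 (CLASSO) penalized estimation

The penalized objective is l(θ) − P_2(β) − P_c(β) with

    P_c(β) = n λ_c Σ_{ℓ≠m} Σ_j |β_ℓj β_mj| / (w_ℓj w_mj),
    P_2(β) = n λ β′β   (off by default; the unpenalized partial
                        likelihood is stable in practice),

where the adaptive weights w_kj = max(|β̂_kj|, 1e-3) come from a pilot
unpenalized fit. The ordered-pair sum counts (ℓ, m) and (m, ℓ) both. The
weight floor (1e-3) keeps the penalty finite when a pilot coordinate is
essentially zero while still penalizing such coordinates heavily. π is
never penalized. As λ_c → ∞ the solution becomes cross-sparse: each
covariate has a nonzero coefficient in at most one component, i.e. the
fit lands in the restricted-model class. The region
{β : P_c ≤ c, P_2 ≤ c} is convex, which the suite verifies empirically.

### Full-gradient inner solver

Within each MM sweep the coefficient update is replaced, component by
component, by repeated steps b ← b + t·d where d is the composite
("sign-restricted") gradient: for an active coordinate, the surrogate
gradient minus the penalty subgradient at sign(β_mj); for a zero
coordinate, zero unless the surrogate gradient exceeds the penalty's
subgradient bound, in which case the coordinate re-activates toward the
gradient's sign. The penalty factor is the exact subgradient bound of
P_c as defined above — 2 n λ_c Σ_{k≠m} |β_kj| / (w_mj w_kj) — so the
dead-zone condition and the objective are mutually consistent and the
inner iteration ascends the penalized surrogate.

Step size: t = min(t_opt, t_edge), where
t_edge = min_j(−β_mj/d_mj : sign(β_mj) = −sign(d_mj) ≠ 0) is the largest
step before any coordinate would cross zero (+∞ if none moves toward
zero), and t_opt = (d′d)/(d′Hd) maximizes the local quadratic model along
d, with H the negative surrogate Hessian block for component m (same
tangency as the likelihood Hessian, cheaper to form). A step that lands
on t_edge sets the limiting coordinates to exactly 0 — supports are
exact zeros by construction, never post-hoc thresholds. Each step is
safeguarded by backtracking halving on the penalized surrogate;
nonpositive curvature falls back to a backtracked unit-scale step. Inner
stopping: max coordinate update < 1e-8 or 200 steps. Outer stopping uses
the penalized objective with the same relative rule as the MLE loop.

The pilot fit supplies both the adaptive weights and (by default) the
starting point, freezing the component order along the penalty path;
`grid_search` warm-starts each λ_c from the previous solution.

## Selection and evaluation

**BIC** = −2 l(θ̂) + df · log(m), with df = #{exactly nonzero β_kj} +
(K − 1) and m the *event count* by default (the partial likelihood
accrues information per event, not per subject; `sample_size="n"`
switches to subjects). The grid search fits every (K, λ_c) pair, marks
failed fits without aborting, and breaks BIC ties toward smaller K, then
larger λ_c. The reference λ_c grid is {0, 0.1, …, 5.0}.

**Time-dependent AUC** at horizon t uses cumulative cases (event by t)
versus dynamic controls (still at risk after t), weighted concordance
with IPCW weights 1/Ĝ(t_i⁻) on the cases from a Kaplan–Meier fit of the
censoring distribution; score ties count 1/2. With no censoring this is
the plain pair-counting AUC. It agrees with scikit-survival's
`cumulative_dynamic_auc` to machine precision (checked in the tests).
Bootstrap intervals are percentile 2.5/97.5 over subject-level
resamples; degenerate resamples (no case or no control) are skipped and
counted. The AUC machinery is evaluation plumbing from the standard
survival-ROC literature, not a contribution of this package.

## Simulation engine

Per subject: x ~ N(0, Σ) with Σ = 2²I_p (independent) or
s_ij = 2²·0.7^|i−j| (dependent); censoring T1 ~ Exponential(mean 1000);
U ~ Uniform(0,1); event time by inverse transform

    T2 = −log(U) / (h0 · exp(f_Q(x; θ_true))),   h0 = 1/100,

so the baseline event time is Exponential(mean 100) and exp(f_Q) acts as
a hazard ratio (larger risk ⇒ stochastically earlier events). Observed
time = min(T1, T2), event indicator = 1{T2 ≤ T1}. With β ≡ 0 the event
probability is the competing-exponentials value 1000/1100 ≈ 0.9091, used
as a calibration check. Generation is bit-reproducible given the seed.

Six built-in scenarios at N = 400 (K, p, π, β as in the catalog;
scenarios 1/3/5 cross-sparse, 2/4/6 overlapped), each in IS and DS
covariance flavors.

The **recovery study** (`run_study`) fits, per replicate, the pilot MLE
at the true K and then the CLASSO path with λ_c chosen by BIC; estimates
are aligned to the truth by the component permutation minimizing
Σ_k ‖β̂_σ(k) − β_k‖² + (π̂_σ(k) − π_k)² (exhaustive over K! ≤ 120), then
averaged; MSE is the mean squared aligned error, reported ×100. Study
defaults are the package's own numerical choices: 2 restarts for the
pilot, outer tolerance 1e-7, and the coarse penalty grid
{0, 0.25, 0.5, 1, 2, 4}, whose top value reaches the cross-sparse form
in every scenario; replicate counts of 100 (Scenario 1) and 50
(Scenarios 3/5) give Monte-Carlo standard errors of roughly 0.005–0.02
per parameter. Failed replicates are dropped and counted; more than 10%
failures aborts the study.

What the generator does **not** emulate: ties in observed times (its
times are continuous), covariate measurement error, time-varying
effects, informative censoring, and unequal baseline hazards across
components. Passing recovery tests therefore show correctness of the
estimator under the model's own assumptions, not robustness to their
violation.

## Degenerate inputs and edge conventions

- Tied times are accepted (Breslow risk sets); tied *scores* in the AUC
  count 1/2.
- A dataset with no events has partial log-likelihood 0 and an undefined
  BIC (error).
- An empty restriction block is legal: that component contributes
  π_k · exp(0) to the mixture.
- sign(0) = 0 in the edge-step rule, so a coordinate sitting at zero
  never defines t_edge.
- Zero mixing proportions are rejected (the score divides by π_m); the
  π floor keeps the MM path interior.

## Limitations

- The MM fitter finds local optima; restarts mitigate but do not remove
  this, and the likelihood is provably well-behaved only under
  unimodality.
- Components are identified only up to label permutation; downstream
  summaries must align labels (the study harness does).
- Standard errors assume an interior, locally identified optimum; at a
  penalized solution with exact zeros the reported information-based
  errors for free coordinates are conditional on the selected support.
- No time-dependent covariates, left truncation, competing risks,
  stratified baselines, or per-component baseline hazards.
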