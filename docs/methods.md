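# Methods

This note documents the models, the numerical choices, and what the
synthetic data can and cannot show.

## Two-compartment PK engine

Vancomycin disposition is linear two-compartment with central elimination.
With micro-constants k10 = CL/V1, k12 = Q/V1, k21 = Q/V2, the hybrid rate
constants α > β > 0 solve α+β = k10+k12+k21, αβ = k10·k21 (the
implementation computes α by the quadratic formula and β = k10·k21/α, which
is stable when β ≪ α; both identities are property-tested to 1e−12).  The
unit-bolus central concentration is A·e^{−αt} + B·e^{−βt} with
A = (α−k21)/(V1(α−β)), B = (k21−β)/(V1(α−β)).  Constant-rate infusions use
the convolved closed forms (during/after branches agree algebraically at
the infusion end), arbitrary histories use superposition, and the
steady-state trough under a (dose D, duration T, interval τ) cycle applies
the geometric accumulation factor 1/(1−e^{−λτ}) per exponential:

    C_ss(τ) = (D/T) Σ_λ (coef_λ/λ)(1−e^{−λT}) e^{−λ(τ−T)} / (1−e^{−λτ}).

Units are hours, litres, mg; concentrations in mg/L ≡ μg/mL throughout.
CLcr (mL/min) enters only through the clearance covariate relation.

### Population model

Commercial TDM software does not publish its population parameterization,
so the shipped defaults are a documented stand-in in the range of published
adult vancomycin models, with clearance linear in CLcr and
weight-proportional volumes:

| parameter | default | units | role |
|---|---|---|---|
| `cl_slope` | 0.044 | L/h per mL/min | renal component of CL |
| `cl_intercept` | 0.32 | L/h | non-renal CL |
| `v1_per_kg` | 0.21 | L/kg | central volume |
| `v2_per_kg` | 0.44 | L/kg | peripheral volume |
| `q_per_kg` | 0.12 | L/h/kg | inter-compartmental clearance |
| `omega` | 0.30/0.25/0.30/0.30 | log-SD | inter-individual variability (cl/v1/q/v2) |
| `sigma_add`, `sigma_prop` | 1.0 μg/mL, 0.10 | | combined residual error |

Every constant is configurable (YAML `pop:` block); all engine tests are
oracle-based (stiff-ODE integration, superposition, closed-form limits), so
correctness does not hinge on these values.

### Bayesian individual estimation

MAP, not posterior mean: a single trough cannot support a meaningful full
posterior over four parameters, and MAP is what TDM practice computes.  By
default only (CL, V1) are estimated, with (Q, V2) fixed at population
values — one observation cannot identify four parameters; estimating all
four is supported but off by default.  Parameters are θ = θ_pop·e^η with
independent priors η ~ N(0, ω²): the population value is the prior mode, so
when the observed trough equals the population prediction the MAP is
exactly η = 0 (tested).  The residual SD in the objective is evaluated at
the *observed* concentration, not the predicted one; this keeps the SD
constant in η, which is what makes the identity above exact and the
one-parameter estimate provably shrink between the prior and data-only
fits.  CLcr is recomputed from the SCr contemporaneous with the trough.
Optimization is L-BFGS-B multistarted from η = 0 and ±1ω coordinate
perturbations; convergence is judged by the gradient norm at the best point
(< 1e−3), because the line-search status flag can report failure at an
exact optimum.  The trough is interpreted at the last scheduled dose time
at or before `trough_day`; BEPV always projects the *maintenance* cycle to
steady state at the MAP parameters, even when the observed history was
irregular.

## The mixed model and its sampler

All candidate models are normal linear models through the origin,

    y_i ~ N( Σ_k (β_k + u_{k,g(i)})·x_ik , σ² ),  u_{k,g} ~ N(0, τ_k²),

with u ≡ 0 outside the random-effect set.  No global intercept: the basic
model `BEPV = β₁·PMMPV` is the PMM itself re-expressed as a regression, and
an intercept would break that interpretation (one is available behind
`ModelSpec.intercept` for sensitivity analysis).  Priors are weakly
informative: β_k ~ N(0, (10·sd(y)/sd(x_k))²); σ and each τ_k get
half-Student-t(3) priors (scales sd(y) and 1.0 respectively) via the
Huang–Wand inverse-gamma mixture, which keeps every conditional conjugate.

Sampling is blocked Gibbs: all coefficients (β and u jointly) from their
conditional multivariate normal via Cholesky, then the variance parameters
from inverse-gamma conditionals.  Joint coefficient updates avoid the slow
mixing that alternating β/u updates would cause in the weakly identified
β_k + mean(u_k) direction.  σ² is floored at 1e−12 so exactly noiseless
test data cannot underflow.  Defaults: 3 chains, 3 000 kept draws per
chain, 1 000 warmup, doubled when a random effect is present (mirroring the
source software family's doubling of iterations for mixed models);
simulation-heavy tests and the acceptance pipeline scale these down
(typically 400–500 draws per chain), which the conjugate sampler's fast
mixing supports.  Per-chain RNG streams derive from the user seed plus a
CRC of the model label, so every fit in a report is independently
reproducible.

Convergence: split-R̂ on every sampled parameter, threshold 1.1.  A
non-converged fit is refit once with doubled draws; if still non-converged
it is excluded from selection and logged.  The report writer asserts the
winner's R̂ and that its WAIC is the minimum of the final stage.

### WAIC

Deviance scale: WAIC = −2·Σ_i(lppd_i − p_i) with lppd_i = log mean_s
exp(ll_si) and p_i = var_s(ll_si).  The variance uses the population form
(ddof = 0): it matches the arviz reference implementation (cross-checked in
a test to 1e−10) and is exactly invariant under draw duplication.  The
pointwise log-likelihood matrix is stored with every fit, so `waic()` is a
pure function checked against a brute-force loop to 1e−12.

### ICC

One-way random-effects ANOVA estimator,
icc = (MSB − MSW)/(MSB + (k̄−1)·MSW), with k̄ = (N − Σn_i²/N)/(k−1) for
unbalanced groups; negative estimates are legitimate and preserved (an
anti-clustered variable should rank below a null one).  95% bounds come
from the F distribution (Searle), which reproduces the characteristically
wide intervals of two-level groupings at small n.

### Selection details

- Spearman ρ uses mid-ranks with the t-approximation p-value; p-values are
  reported but only |ρ| ≥ 0.2 gates (threshold configurable).
- Near-duplicate covariates: declared pairs (default: BUN/adjusted-SCr vs
  BUN/SCr) plus an automatic trigger at pairwise |ρ| > 0.9 among kept
  candidates; the lower-WAIC member survives.  Without this rule the subset
  stage wastes its budget re-ranking interchangeable covariates.
- Subset search is exhaustive, capped at 1 024 subsets (tighten the screen
  past that); ties break toward fewer covariates, then lexicographic.
- Shapiro-Wilk on the response is computed and reported as a gate; failure
  warns but never aborts — the normal-family model is the procedure under
  study, and aborting would make the pipeline unrunnable on the skewed
  responses the misfit mechanism produces.
- "SCr adjustment amount" is defined as max(0, 0.6 − SCr), the increment
  the floor applied: it is zero for unadjusted patients, which is the only
  definition under which it can coexist with the separate discrete
  "adjusted or not" variable.

## Synthetic cohorts

The generator emulates the published cohort summary: truncated-normal
marginals (age 77.37 ± 8.79 y, height 157.66 ± 8.59 cm, weight
46.66 ± 9.91 kg, SCr 0.82 ± 0.35 mg/dL, BUN 19.15 ± 11.76 mg/dL, AST, ALT,
CRP, plus decoy labs with plausible elderly-inpatient values), with the
underlying normals moment-matched so truncation does not bias the targets,
joined by a Gaussian copula (height–weight 0.6, BUN–SCr 0.55, AST–ALT 0.7,
age–weight −0.2, TP–Alb 0.6 — the publication gives only marginals, so
these are documented choices).  Sex is Bernoulli at the published 14/46
female fraction.  Regimens are chosen per patient from a menu
(250–1000 mg, q12/q24/q48, 1 h infusions) by minimising the distance of the
population-predicted trough from 15 μg/mL — i.e. the generator *plans doses
the way the clinic does*, which is what makes planning misfit consequential.
The published work does not report its dosing menu; this one is an
assumption.

The misfit block distorts each patient's TRUE clearance, never the
observation:

    CL_true = CL_pop · (1 − γ·1[BUN/SCr > 20]) · m_sex · (1 − δ·SCrAdjAmt) · e^η

with defaults γ = 0.3, m = 1.05/0.95 (female/male), δ = 0.5 per mg/dL,
ω_cl = 0.20.  Measured troughs are simulated from the true parameters at a
day-3–5 trough time with the combined residual error.  Because BEPV sees
the measured trough, it partially corrects the misfit while PMMPV cannot —
so the BUN/adjusted-SCr signal in PMMPDQ *emerges* from the mechanism
rather than being pasted into the response.  With all misfit channels off,
PMMPDQ is centred on zero (tested), and the exposed-group deviation is
monotone in γ (tested at γ ∈ {0, 0.15, 0.3}).

For regression-recovery studies an explicit linear truth is provided
(`LinearTruth`: β₁ = 1.0, sex deviations ±0.05, β_bun = 0.10,
β_adj = −12, residual SD 2.0): the response is drawn directly from the
best-model-shaped predictor over the mechanistically generated PMMPV and
covariates.  This is the configuration under which coefficient recovery is
asserted (β_bun within ±0.03 at n = 500) and under which the corrected
predictor's held-out R² exceeds the population-mean predictor's.

What passing tests do **not** show about real data: the generator has no
longitudinal SCr drift (the mechanism behind the worst real-world outliers,
where renal function changes between planning and trough), no
hypoalbuminemia effect on creatinine secretion, no irregular dosing in the
default cohorts, and its misfit is a clean step function at BUN/SCr = 20
where reality is graded.  Selection results on synthetic cohorts validate
the *procedure*, not the transportability of any particular coefficient.

## Problem sizes and numerical defaults

Simulation tests run at n = 150–500 patients with 3 × 400–500 kept draws;
the acceptance pipeline uses n = 500 training / 200 held-out with 3 × 500
draws.  These sizes give Monte-Carlo error comfortably inside every
asserted tolerance while keeping full-suite runs to a few minutes.
Optimizer tolerances: L-BFGS-B gtol 1e−8, ftol 1e−10, multistart as above.
Degenerate inputs: zero dose → zero concentration (not an error); zero
predictor variance → correlation/regression flagged undefined; a single
group → ICC undefined; empty candidate sets fall back to the basic model.

## Known limitations

- The population PK defaults are a stand-in; conclusions about any real
  cohort require substituting a validated parameterization.
- MAP-based BEPV understates individual uncertainty; no credible interval
  is attached to BEPV.
- The staged WAIC search is greedy across stages (screen → singles →
  subsets → placement); it reproduces the intended procedure faithfully but
  is not a global search over the joint model space.
- WAIC at n ≈ 46 is noisy; stage decisions on cohorts that small are
  sensitive to the seed, which is why the recovery guarantees are stated at
  n = 500.
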