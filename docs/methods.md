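# Methods

`pulmodeconv` is a simulation–estimation framework for asking a deceptively
simple question: given plasma concentration–time data after oral inhalation
(plus an intravenous reference), how well can the *extent* and *duration* of
pulmonary drug exposure be inferred by model-based deconvolution — and when
does the inference silently fail?

## Models

### Structural models

The lung is represented as one or more well-stirred depot compartments
draining into the central compartment of a linear mammillary disposition
model with up to three peripheral compartments (parameters `CL`, `V1`,
`Q2/V2`, `Q3/V3`, `Q4/V4`; clearances in L/h, volumes in L). An inhaled dose
deposits the fraction `F_pul` (pulmonary bioavailability, the "designated
lung dose") into the depots; the remainder never enters the system (the
swallowed fraction is assumed charcoal-blocked and is out of scope). Six
absorption structures are supported:

| Variant | Structure | Pulmonary parameters |
|---|---|---|
| I | one first-order process | `k_fast` |
| II | two parallel processes | `f_fast/k_fast`, `f_slow/k_slow` |
| IIIa | three parallel processes | `f_i`, `k_i`, i ∈ {fast, med, slow} |
| IIIb | same structure, rate-ratio parameterisation | `k_fast`, `PF1 = k_med/k_fast`, `PF2 = k_slow/k_med` |
| Transit | chain of `n` transit compartments (default 3) | `k_trans` |
| NaL | one process plus parallel non-absorptive loss | `k_fast`, `k_nal` |

plus a simulation-only *semi-mechanistic* variant that adds first-order
back-flow (`k_back`) from the central compartment into the lung, used to
probe the one-directional-absorption assumption of all the empirical
models. It is never offered as an estimation model; it can also be supplied
as an arbitrary user-defined rate matrix.

The absorbed fractions of the parallel models live on a simplex
(`Σ f_i = 1`, enforced to 1e-9) and rate constants are canonically ordered
`k_fast > k_med > k_slow`, which removes label-switching: any permutation of
(fraction, rate) pairs maps to the same canonical parameter set.

All systems are linear with constant coefficients. Profiles are computed
from the matrix exponential, via eigendecomposition where it is numerically
trustworthy (checked by reconstructing the rate matrix; defective cases
such as the tied eigenvalues of a transit chain fall back to per-interval
`expm`). An adaptive stiff integrator is used only as an independent oracle
in the test-suite. Explicit sink states (systemic elimination and
non-absorptive loss) make mass balance checkable to 1e-8.

Lung concentration is defined as the total unabsorbed amount over **all**
pulmonary compartments (all parallel depots, all transit compartments; the
loss sink excluded, as lost drug is no longer in the lung) divided by a lung
volume `V_lung = 0.84 L` (literature lung weight). Closed forms:
`AUC_plasma = Dose·F/CL` and, for one-directional models,
`AUC_lung = Dose·F_pul·R/V_lung` with residence integral
`R = Σ f_i/(k_i + k_nal)` for parallel models and `n/k_trans` for the
transit chain. Back-flow models are integrated numerically.

### Exposure metrics

* **Extent**: `AUC(0–∞)` in plasma and lung.
* **Duration**: `t_C24h,lung` — the time at which a candidate model's lung
  profile declines to the *true* model's lung concentration at 24 h,
  preferred over a terminal half-life because it reflects all parallel
  processes at the clinically relevant dosing interval. Found by Brent
  root-finding to 1e-4 h on `[0, t_max]` with `t_max` = 10 slowest
  half-lives; non-crossing profiles are flagged rather than clipped.
* **Plasma equivalence**: geometric mean fold error,
  `GMFE = 10^(Σ|log10(pred/obs)|/N)`, symmetric in over/under-prediction;
  profiles are equivalent when `GMFE < 1.05`.
* **Accuracy bands**: 80–125 % (bioequivalence-style) for plasma AUC and
  for lung metrics in the identifiability screen; two-/three-/five-fold
  bands for the population studies. Bounds inclusive.
* **%Bias** `= 100·mean((pred−obs)/obs)` over replicates.

Each simulate/estimate pairing is classified: (1) plasma and lung adequate;
(2) plasma adequate, lung not — the dangerous, undetectable case; (3)
plasma misfit (lung not assessed); (4) parameters not identifiable.
Priority 4 → 3 → 2 → 1.

## Estimation

### Naive fits and structural identifiability

For the identifiability screen, rich noiseless profiles (every 0.01 h over
48 h) are simulated from each model and each candidate re-estimates its
pulmonary parameters from the plasma profile alone, with the systemic
disposition fixed. The loss is least squares on log concentrations (the
noiseless analogue of a proportional error model), minimised by
trust-region least squares in a transformed unconstrained space (log rates;
logit fractions; two log-ratios for the three-way simplex). Ten retries
with log-uniform ±10-fold perturbed initials guard against local minima.
Fits to the rich grid subsample it (default every 5th point); self-fit
recovery is unchanged at the 1e-6 level.

Identifiability is judged at the optimum from the Fisher information
`J^T J` of the log-scale residual sensitivities (central differences):
a fit is identifiable when the FIM condition number is below 1e10 and all
standard errors are finite; parameter pairs with |correlation| > 0.99 are
reported (a tiny ridge keeps the near-null direction visible in the
stabilised covariance). The thresholds are configurable.

### Population (FOCE) estimation

Trials are simulated with log-normal inter-individual variability
(`theta·exp(eta)`), optional log-normal inter-occasion variability, and
proportional residual error `y = f·(1+eps)`; at most four IIV/IOV terms are
allowed (a deliberate simplification so model comparison is not confounded
by stochastic-model size), draws producing non-positive observations are
redrawn, and occasions are treated as washed-out and independent. Datasets
use a NONMEM-style rectangular CSV (ID, TIME, AMT, DV, EVID, CMT, OCC,
ROUTE; DV "." on dose rows).

The estimator is FOCE with interaction implemented as a Laplace
approximation at the per-subject conditional mode: the inner problem is
solved by a damped Gauss–Newton iteration (finite-difference sensitivities,
trust-region step capped at 0.5 eta-units — the pure GN step overshoots
badly far from the mode on these exponential-in-eta models), and the
curvature for the Laplace log-determinant is rebuilt with a fresh Jacobian
at the mode so the objective does not depend on the optimisation history.
The interaction term enters through the residual-variance weights
`W = 1/V + (dV/df)²/(2V²)`. For a model linear in eta with additive error
the objective is exactly the Gaussian marginal likelihood (tested to 1e-6).
The outer problem (transformed population parameters, log-omegas,
log-sigma) is a Nelder–Mead search warm-starting each subject's mode, with
a soft quadratic box penalty on the packed vector (rates within
[1e-5, 1e4] /h, omegas within [0.005, 3], sigma within [0.001, 2]): the
likelihood is flat in directions like a variance component collapsing to
zero, and the penalty terminates the otherwise unbounded simplex crawl
without affecting interior optima. Convergence is declared either by the
simplex tolerance or by restart stability: when the budgeted search ends
without formally converging, a short fresh-simplex restart that improves
the objective by less than 1.0 (-2LL units) counts as converged — on flat
surfaces the simplex polishes an already-found optimum indefinitely. On
failure up to two retries draw log-uniform [0.1, 10] multiplicative
perturbations of the initials (retries at half budget). Population fits are initialised at the
simulation values, as in simulation–estimation practice where the published
model is the natural starting point.

An estimation is *successful* when the optimizer converged **and** the
finite-difference Hessian of the objective is positive definite with finite
implied standard errors (cov = 2·H⁻¹) — mirroring the covariance-step
failure mode of standard NLME software. Replicate summaries cover
successful estimations only. Model comparison uses
`AIC = -2LL + 2·(number of estimated parameters incl. variances)`.

Three data-combination strategies are provided: `PPP` (disposition
population parameters and variances fixed from an i.v.-stage fit;
individual disposition parameters still vary within the fixed IIV), `IPP`
(individual disposition parameters fixed at i.v.-stage empirical Bayes
estimates; requires cross-over data) and `ALL` (simultaneous fit of the
pooled data). Exposure metrics are computed from the population parameter
estimates, not averaged individual metrics.

### NCA deconvolution

The non-compartmental route computes AUC/AUMC by linear-up/log-down
trapezoids with terminal extrapolation (`lambda_z` from log-linear
regression over the last 3 points, or the best-adjusted-R² tail),
`MRT = AUMC/AUC`, `MAT = MRT_inh − MRT_iv`, `k_a = 1/MAT`, `F_pul` from the
dose-normalised AUC ratio and `AUC_lung = Dose·F_pul/(k_a·V_lung)`.
A non-positive MAT makes the result invalid ("negative MAT"), the
documented failure mode on noisy multi-process data. Per-subject results
are summarised by arithmetic means.

## Default study conditions

The packaged defaults are synthetic but chosen once to be realistic for
inhaled small molecules and to sit in the regimes the framework is meant to
expose. The published drug models this framework emulates are not
redistributed; any parameter set can be supplied via config.

* **Identifiability grid** — a shared three-compartment disposition
  (CL 30, V1 20, Q2 20/V2 100, Q3 5/V3 200) with, per variant: I
  (F 0.5, k 0.1); II (F 0.4, 98 % at 3/h plus a 2 % slow fraction at
  0.015/h — a minor slowly dissolving fraction invisible beneath the
  disposition tail yet carrying ~80 % of lung exposure); IIIa (F 0.5,
  fractions 0.25/0.40/0.35 at 15/0.7/0.023 per h); Transit (k 0.5, n=3);
  NaL (k 0.05 with k_nal 2.4 — loss-dominated, as for a slowly dissolving,
  mucociliary-cleared drug, where only ~2 % of the lung dose is absorbed);
  back-flow (k_back 0.1 with CL 150 L/h — high systemic clearance, the
  regime in which re-distribution barely touches the lung). Inhaled dose
  100 µg.
* **Two-process study** — cross-over i.v. (50 µg) / inhalation (400 µg) in
  13 subjects, rich 11-point sampling to 48 h, four-compartment disposition
  fully identified by the i.v. design; pulmonary II with F 0.4 and
  0.7 @ 1.5/h + 0.3 @ 0.1/h; IIV (ω 0.25–0.30) on F_pul, CL, V1, Q2; 15 %
  proportional error.
* **Three-process study** — separate cohorts (i.v. 20 µg sampled only to
  24 h; inhaled 30 µg sampled to 120 h), four-compartment disposition whose
  deep-tissue compartment (Q2 10, V2 400; ~30 h equilibration half-life) is
  weakly identified by the short i.v. design; pulmonary IIIa as in the
  grid; IIV on CL, V1, Q2 and IOV on F_pul; 15 % proportional error. This
  is the flip-flop-confusable design in which the slow absorption rate
  absorbs the unexplained terminal slope, inflating inferred lung exposure.

What the generator does *not* emulate: below-quantification-limit
censoring, covariate effects, non-proportional residual error, urine data,
dissolution/permeability separation and regional lung deposition. Passing
tests therefore demonstrate the behaviour of the estimators under the
stated stochastic model, not robustness to those real-data features.

## Problem sizes

The replicate experiments are scaled down from 500 replicates so the whole
suite runs on a laptop-class single core: the packaged acceptance run uses
2 replicates of the two-process study (13+13 subjects, as designed) and
2 replicates of the three-process study with cohorts scaled to 8 i.v. /
10 inhalation subjects and a single inhalation occasion; the test-suite
uses the same or smaller sizes. Replicate seeds derive deterministically
from a master seed (`master_seed + replicate`), so every estimation arm
sees identical datasets; quantiles use linear interpolation (type-7).
At these sizes the replicate summaries are indicative, not precise: medians
are stable but tail percentiles and rate estimates (convergence fractions,
adequacy fractions) carry large Monte-Carlo error.

## Known limitations

* The FOCE objective is a Laplace/Gauss–Newton approximation; its absolute
  value is not comparable to other implementations (AIC differences within
  a study are).
* Nelder–Mead outer optimisation with warm-started inner modes trades a
  little optimality for robustness; standard errors are classification
  devices (successful vs not), not inferential statements.
* The grid fixes each estimation model's disposition to the simulation
  model's values, isolating absorption-structure error; cross-drug
  disposition mismatch is a separate problem not studied here.
* Occasions are pharmacokinetically independent (complete washout).
* One parameter set per structure: conclusions about which scenarios occur
  where in the grid depend on the default parameters; the structural
  statements (identifiability, the NaL fold-error formula, back-flow
  negligibility under high clearance) do not.
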