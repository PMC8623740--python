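# Methods

`dtmdd` implements a population pharmacokinetic analysis of infliximab in
inflammatory bowel disease (IBD) built around a two-compartment model with
*double* target-mediated drug disposition (TMDD): the antibody binds TNF-α in
both the central (blood + well-perfused antigen mass) and the peripheral
(tissue) compartment, and elimination of the drug–target complex contributes
to drug clearance in each. This note records the model, its assumptions, the
numerical choices, and what the synthetic-data experiments do and do not
demonstrate.

## Structural model

States are total drug and total target concentration in each compartment,
all in nM: `CT`, `RTC` (central), `CPT`, `RTP` (peripheral). Under the
quasi-steady-state (QSS) approximation, free drug, free target and complex
equilibrate instantly with steady-state constant `KSS = (koff + kint)/kon`,
so the unbound concentration is the non-negative root of

```
C^2 + (RT + KSS - CT) C - KSS CT = 0
C   = [ (CT - RT - KSS) + sqrt((CT - RT - KSS)^2 + 4 KSS CT) ] / 2
```

(the positive sign under the radical is required for a real, non-negative
root). The ODEs:

```
dCT/dt  = In(t) - (CL/V1) C - (Q/V1) C + (Q/V2) CP - kintC (CT - C)
dRTC/dt = kinC - kout (RTC - (CT - C)) - kintC (CT - C)
dCPT/dt = (Q/V1) C - (Q/V2) CP - kintP (CPT - CP)
dRTP/dt = kinP - kout (RTP - (CPT - CP)) - kintP (CPT - CP)
```

with `kin = R0 * kout` in each compartment so that the undosed system rests
exactly at `(0, R0C, 0, R0P)`. Two conventions deserve emphasis:

* **Transfer terms are in the k12/k21 (micro-constant) concentration form**:
  `(Q/V1) C - (Q/V2) CP`. This conserves the *sum of concentration states*
  under pure transfer, not amounts scaled by volumes; `CPT` is therefore an
  apparent concentration. This is the estimated model and is implemented
  as-is — "repairing" mass balance would change the model that the published
  parameters belong to.
* **Units.** Data are mg/L; internals are nM. Conversion uses a configurable
  drug molar mass, default 149,000 g/mol (IgG1), applied exactly once at the
  data boundary. Binding is 1:1. With this mass, 5 mg/L = 33.6 nM and the
  closed-form central occupancy ratio at 5 mg/L is KSS/(KSS+C) =
  15.4/48.96 ≈ 31.4%.

Target occupancy is summarised by the unbound/total target ratio
`R/R_T = KSS/(KSS + C)`, an exact algebraic consequence of QSS that the code
also uses as an internal cross-check of every simulated trajectory.

Turning a TMDD arm off (`R0 = 0`) reduces that compartment exactly to linear
kinetics; ankylosing-spondylitis (AS) reference subjects are represented this
way and share the two-compartment backbone with IBD subjects.

Secondary parameters (`T1/2-alpha`, `T1/2-beta`) come from the eigen-rates of
the linear two-compartment system; at the base-model estimates (V1 2.8 L,
CL 0.20 L/day, V2 1.9 L, Q 1.5 L/day) the terminal half-life is 16.7 days.

## Population layer

Interindividual variability is exponential (log-normal) on V1, CL, V2, R0C
and R0P; variances of Q, KSS and kint are fixed to zero (they are not
identifiable from trough/peak-dominated designs). Covariates: body weight on
V1 as a power function centred at 66 kg (configurable; the published median
is not stated), sex on V1 and CL and ulcerative colitis on R0C as log-scale
shifts with females / Crohn's disease as references. Residual error is mixed
additive–proportional in the combined-1 form `y = f + (a + b f) eps`
(a = 1.8 mg/L, b = 0.20 at the final estimates); the
`sqrt(a^2 + b^2 f^2)` alternative is selectable but non-default.

## Synthetic data generator

No public dataset exists, so every downstream stage is exercised on
synthetic cohorts that emulate the two study designs:

* **AS reference** (`as_rich`): 25 subjects, 5 mg/kg at weeks 0/2/6/12/18,
  samples pre-dose, 2 h and 4 h after each infusion plus weeks
  1/3/4/5/8/10/14 (≈22 per subject; ≈490 observations after 10% random
  missingness, matching the reported ≈488). Body weight N(75, 15²) kg
  truncated to [41, 110]; 19/25 male.
* **IBD routine** (`ibd_sparse`): 5 mg/kg at weeks 0/2/6/14/22
  (induction + first maintenance cycles), peak (end of infusion + 1 h) at
  the first three infusions and troughs before infusions 2–5 (≈6.3 per
  subject after missingness; 133 subjects give ≈840 observations vs the
  reported 845). BW N(64, 12²); 80/133 male; CD:UC = 108:25. Exact routine
  sampling occasions are not published; this template is an emulation and is
  flagged as such in the dataset provenance.
* **IBD rich** (`ibd_rich`): the IBD regimen with trough + peak at every
  infusion, early-washout samples on days 1/3, 43/45 and 155/157, and
  twelve intermediate visits (28 per subject). This design exists for
  simulation studies of the estimator: trough/peak-only sampling leaves the
  V1/V2/Q split almost unidentified, and the recovery experiments need the
  distribution phase pinned.

Doses are weight-based and rounded half-up to 100 mg vials. Infusions last
2 h (not stated in the source; consistent with 2 h/4 h post-dose sampling).
Values below the 0.103 mg/L quantitation limit are flagged censored and
carry the limit as a bound; values above 15 mg/L are retained (dilution
assumed — peak concentrations in these regimens routinely exceed the upper
limit and were fitted). Age is generated as metadata only. Generation is
fully deterministic given (design, parameters, n, seed), and datasets
round-trip bit-identically through the NONMEM-style CSV.

The generator's defaults are the final published parameter estimates; they
reproduce the *assumed* study conditions. Passing recovery tests on these
cohorts shows the estimation machinery is consistent under the model's own
assumptions — it says nothing about model misspecification, ADA-positive
subjects, dropout-by-response or assay artefacts, none of which are
generated.

## Estimation

The marginal likelihood integrates the five random effects per subject. The
implementation uses a Laplace approximation with the Gauss–Newton (FOCE-type)
Hessian: per subject, the conditional mode is found by damped Gauss–Newton
with a finite-difference residual Jacobian, and

```
-2 log l_i = 2 U(eta_hat) - q log(2 pi) + log det(G' W G + Omega^-1).
```

With all omegas zero this reduces exactly to the Gaussian residual sum. An
importance-sampling refinement around the conditional modes (Gaussian
proposal from the same Hessian) is available and reports its Monte-Carlo
standard error; it serves as the internal accuracy cross-check against
brute-force Monte-Carlo integration on small fixtures. Censored records are
excluded from the likelihood (the simplest defensible treatment; a censored
likelihood is a flagged extension).

The outer problem (typical values, covariate coefficients, omegas, sigmas —
all simultaneously, `kout` always fixed) is solved by a damped Newton
(Levenberg–Marquardt) method whose Hessian is the BHHH outer product of
per-subject score vectors, with three provisions that the likelihood
geometry makes necessary:

* scores come from central differences around a snapshot of the conditional
  modes, frozen during the perturbed evaluations (by the envelope argument
  their first-order shift does not move the marginal likelihood at the
  mode);
* accepted steps are extended geometrically while the objective improves,
  under a per-iteration trust region — far from the optimum BHHH
  overestimates curvature and un-extended steps crawl;
* an EM-style recentering update runs each iteration: the mean conditional
  mode of each random effect is absorbed into its typical value and the
  omega is refreshed from the first/second EB moments, with the move kept
  only if it improves the objective. This jumps along the profile-flat
  ridges (typical value shifted, omega inflated, all subjects sharing a
  common eta displacement) on which gradient methods stall.

Likelihood predictions use a fixed-schedule Rosenbrock integrator (step
ramping from 0.01 to 0.5 days after each infusion boundary; relative
accuracy ~1e-4) whose error is a smooth function of the parameters — a
prerequisite for clean finite-difference scores. Reporting simulations use
an adaptive L-stable Rosenbrock 2(3) pair at rtol 1e-8 / atol 1e-10 nM with
hard event boundaries at infusion start/stop, cross-validated against
scipy's LSODA to 1e-6. Linear subjects (AS, or the two-compartment variant)
use the exact bi-exponential superposition instead of the ODE.

Standard errors (RSE%) come from the BHHH information estimate at the
optimum; log-scale standard errors are reported directly as relative errors.
Structural model building follows the four-variant ladder (two-compartment,
central TMDD, peripheral TMDD, double TMDD) compared by AIC
(= −2LL + 2·#estimated parameters; the counting rule reproduces the
published 9/13/13/17/21 parameter counts), `kout` is profiled over a fixed
grid with AIC argmin and ties broken toward the smaller value, and covariate
selection is the classical two-stage screen (univariate in at α = 0.05,
backward out at α = 0.02, fixed BW/SX/DIS ordering on ties, full decision
log). The univariate LRT guards against base-fit under-convergence by also
evaluating the base model at each candidate's non-covariate parameters and
using the better base likelihood.

Default starting values put the backbone at pooled-moment heuristics and the
TMDD arm at the published base-model magnitudes; all starts are configurable.
Starts that grossly *underestimate* the residual error put the optimiser on
a badly curved escape path and are not recommended; the defaults start the
error terms generously.

## Simulation study (target occupancy)

1000 virtual subjects (sex 50/50, CD:UC 5:1, BW N(66, 15²) kg truncated to
[41, 110]) receive 5 mg/kg (vial-rounded) at weeks 0, 2, 6, 14 and 22;
latent curves are simulated on a 0.1-day grid over 210 days without residual
error, and summarised as pointwise medians with 5th–95th percentile bands
(the 90% prediction interval). Metrics: the median central and peripheral
occupancy ratios pooled over all subject-time points with unbound serum
concentration within ±0.1 mg/L of 5 mg/L; pre-dose median ratios at each
trough (evaluated one grid step before the dose); and the maximum total
target / individual baseline fold, which cannot exceed `kout/kint`
analytically (≈118 centrally, and ≈25 is reached by the typical subject
under this regimen).

One documented interpretive choice: the source describes its regimen
inconsistently (five infusions at weeks 0/2/6/14/22 in the methods; four at
weeks 0/2/14/22 in the abstract), and its claim that the central ratio
re-increases above 30% "before the third and fourth infusions" is
quantitatively consistent only with the week-14 and week-22 troughs — the
3rd/4th infusions in the four-infusion numbering. The package simulates the
five-infusion protocol and reports the full per-trough table; the headline
"third/fourth infusion" metrics are taken at the week-14/22 pre-dose
instants. Similarly, the printed 26% central ratio at 5 mg/L is not
consistent with the closed form at a 149 kDa molar mass (which gives 31.4%,
and which the simulation reproduces); the conversion used by the original
analysis is unstated, and the package reports its own simulated value.

## Problem sizes and scaling

The bundled experiments are desk-scale by design: parameter recovery uses 25
AS + 125 rich-IBD subjects (~3,600 observations); the kout grid profiles
{10, 20, 40}/day on the *central*-TMDD model over the same dataset — the
double model's peripheral arm and its large baseline-target variability can
absorb a misspecified turnover rate, flattening the profile below its
sampling noise, whereas the central-model profile separates the candidates
by ~10 points of -2LL — with all grid fits started from a common two-round
reference solution for symmetric convergence effort (the double model is
then the verified final fit); estimator-consistency and
covariate-screen simulations run on the linear variant (closed-form
predictions) with 40–60 subjects per replicate, and diagnostics
self-consistency uses 35–40 subjects with 400–600 replicates. These sizes
give Monte-Carlo error comfortably inside the tolerances being checked while
keeping the whole suite reproducible on a single CPU.

## Known limitations

* Laplace/FOCE is an approximation; its error grows with sparse designs and
  large omegas (ω ≈ 1 on the baseline targets is large). The
  importance-sampling cross-check bounds this on small fixtures only.
* The likelihood treats negative-concentration support of the additive error
  component as Gaussian (no truncation), while the generator truncates
  simulated observations at zero — a deliberate, documented mismatch that is
  negligible at the fitted error magnitudes.
* Weakly identified directions (KSSC–R0C–kintC trade-offs; V2/Q under
  sparse sampling) remain: estimates on those axes scatter within a few
  tens of percent between replicates, consistent with the large reported
  RSEs for those parameters.
* No ADA kinetics, no inter-occasion variability, no covariance between
  random effects, no exposure–response linkage.
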