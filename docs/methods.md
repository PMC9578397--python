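# Methods

## Scientific setting

Bedaquiline (BDQ) is a diarylquinoline used in combination regimens for
multidrug-resistant tuberculosis (MDR-TB). Its licensed adult regimen is
400 mg daily for two weeks followed by 200 mg three times per week. This
package implements a population-pharmacokinetic analysis of BDQ plasma
concentrations in adult MDR-TB patients sampled sparsely at steady state
during the thrice-weekly maintenance phase, including the two covariates
found to matter for BDQ exposure in that population: the liver-function
marker gamma-glutamyl transferase (GGT) and the rs319952 polymorphism in
the *AGBL4* gene.

Because the underlying clinical dataset is not public, the package ships a
synthetic-data generator that reproduces the study's statistical design, so
every stage of the pipeline — estimation, covariate selection, bootstrap,
pcVPC, dosage simulation — runs end to end and can be checked for
parameter recovery against known generating values.

## Structural and statistical model

Disposition is a one-compartment model with first-order absorption,
parameterized in the apparent clearance CL/F (L/h), apparent central volume
Vc/F (L) and absorption rate constant Ka (1/h); bioavailability F is not
separable from oral data and is absorbed into the apparent parameters.
With ke = CL/V, the single-dose concentration is the Bateman function

    C(t) = D·Ka / (V·(Ka − ke)) · (e^(−ke·t) − e^(−Ka·t)),

and the steady-state profile under a dose D every τ hours is the
geometric-series superposition

    C_ss(t) = D·Ka / (V·(Ka − ke)) · [ e^(−ke·t)/(1 − e^(−ke·τ)) −
                                       e^(−Ka·t)/(1 − e^(−Ka·τ)) ],  0 ≤ t ≤ τ.

The thrice-weekly regimen is represented as evenly spaced doses with
τ = 56 h (168/3); the closed forms at τ = 56 h were verified against
Runge-Kutta integration of the two-state ODE system over 90 consecutive
doses (agreement < 0.1%). The degenerate case Ka ≈ ke raises by default;
an explicit equal-rates limit form can be enabled. The 400-mg daily
lead-in can be expressed with the regimen builder but does not affect the
steady state of the maintenance phase and plays no role in the analyses.

Interindividual variability (IIV) enters exponentially, P_i = P_typ·exp(η_i),
with independent normal η on CL/F and Vc/F (diagonal Ω; reported as
CV% = 100·√ω²). Residual error supports additive, proportional and
combined forms; the reference model is proportional. The final covariate
model on clearance is

    CL/F = 4.54 · (GGT / 28.9)^(−0.476)            for rs319952 AA or AG,
    CL/F = 4.54 · (GGT / 28.9)^(−0.476) − 1.4      for rs319952 GG,

i.e. a power model on GGT normalized at the population median with an
additive −1.4 L/h shift for GG homozygotes (the contrast pools AA with AG).
Multiplicative covariate terms are applied before additive shifts; a
non-positive resulting parameter raises. The reference ("final-model")
parameter set is Ka 0.447 1/h, CL/F 4.54 L/h, Vc/F 227 L, IIV 38.7% (CL/F)
and 83.5% (Vc/F), proportional residual SD 32.2%.

Units are hours, milligrams, litres, mg/L throughout; mg/L is numerically
identical to the assay's µg/mL.

## Estimation (FOCE-I)

The marginal likelihood of each subject's data is approximated by a
Laplacian expansion at the subject's conditional η mode with residual
variance evaluated at the individual prediction (first-order conditional
estimation with interaction). Writing q_i(η) for the joint −2·log density
of subject i's observations and η,

    OFV_i = q_i(η̂_i) − k·log 2π + log det(H_i / 2),

with H_i the Hessian of q_i at the mode and k the number of η's; the total
OFV approximates −2·log L and is the quantity used in likelihood-ratio
tests. On constructed sparse subjects with observations about one residual
SD from their predictions, this objective agrees with exact adaptive
Gauss–Hermite quadrature within 0.1 (additive error, 1 observation) and
0.5 (proportional error, 1–2 observations) OFV units; for rare subjects
whose single observation lies far in the tails the Laplace error can
exceed this (a known property of the approximation, not of the
implementation, which matches an independently computed Laplace value to
1e-5).

Numerics of the inner problem: all subjects are advanced in one vectorized
batch; gradients of q use complex-step differentiation (exact to machine
precision, enabling the 1e-8 gradient-norm convergence tolerance) and
Hessians central differences of q with a constant 1e-3 step; steps are
damped Newton with batched backtracking and a step-norm cap. Two
evaluation paths coexist. During outer optimization the inner search
warm-starts from the previous iteration's modes (with a fall-back to η = 0
where the warm point is worse), which is several-fold cheaper; because the
conditional density is occasionally bimodal this path is history-dependent
by up to ~1 OFV unit. Every REPORTED objective value — fit results and all
likelihood-ratio comparisons — is instead recomputed from a fixed start
set (η = 0 plus ±1.5 on each η axis, lowest mode per subject), so reported
OFVs are exactly reproducible functions of (parameters, data) and SCM
decisions never depend on optimizer history.

The outer search runs over log-transformed thetas and variance components
(covariate-effect coefficients unconstrained) with a Nelder–Mead simplex
followed by a Powell polish. Direct search is used on purpose: the
objective has small kinks where a subject's conditional mode switches
basins as parameters move, which break Wolfe line searches in quasi-Newton
methods. Optional restarts perturb Ka ×3 and /3 (the sparse design leaves
Ka with local optima). A fit is reported converged when the optimizer
terminates successfully or when the polish stage improves the objective by
less than 0.2 units (an explicit stationarity criterion). Refits inside
the bootstrap and stepwise loops start at the previous optimum and use a
Powell-only search whose termination tolerances are sized to the fast
path's evaluation noise.

Standard errors are computed on request from a central finite-difference
Hessian of the OFV in the transformed parameterization (covariance
2·H⁻¹), which directly yields relative standard errors on the natural
scale and, by the delta method, RSEs of the IIV CV% and residual
percentages. Empirical Bayes estimates (EBEs) are the conditional modes;
η-shrinkage is 100·(1 − SD(EBE)/ω) and ε-shrinkage 100·(1 − SD(IWRES)).
Diagnostics report PRED (η = 0), IPRED (at the EBE), IWRES, and CWRES from
the FOCE linearization (residuals decorrelated by the Cholesky factor of
F·Ω·Fᵀ + diag g).

## Covariate selection

Candidates are screened on base-model EBEs: continuous covariates by the
slope t-test of η against the log covariate, categorical ones by one-way
ANOVA across groups, retaining p < 0.05. Genotype levels observed in
fewer than two subjects are pooled into the modal level before the 0/1
indicator is formed. Missing continuous covariates are imputed with the
median, categorical ones with the mode.

Stepwise search then adds, per round, the candidate with the largest drop
in OFV strictly exceeding χ²₁(0.99) = 6.635 (forward, α = 0.01), and
afterwards removes effects whose removal raises the OFV by at most
χ²₁(0.995) = 7.879 (backward, α = 0.005; retention requires a strictly
larger rise). Ties break by larger ΔOFV, then candidate order.
Continuous effects use the power form normalized at the covariate median;
categorical effects use a shift form (the reference preset uses the
additive L/h shift, matching the final clearance model). Candidate fits
that fail to converge are skipped and logged in the trace.

## Bootstrap and pcVPC

The nonparametric bootstrap resamples subjects (not observations) with
replacement to the original subject count, refits each resample starting
from the original estimates, and summarizes converged fits only (medians,
5th–95th percentiles, convergence success rate). The prediction-corrected
VPC bins observations by time after dose (default 8 equal-count bins; bins
with fewer than 2 observations merge into their neighbour), rescales each
observed and simulated value by bin-median PRED / own PRED, and compares
observed 5th/50th/95th percentiles with 90% confidence bands from model
simulations of the original design (default 1000 replicates; the analysis
scripts use 400). Simulated values below the assay LOD are substituted by
it, mirroring the handling of the observed data.

## Synthetic-data generator

The generator defines the study conditions: 99 subjects contributing 246
samples with the reported per-subject distribution (38×1, 24×2, 12×3,
11×4, 7×5, 5×6, 1×7, 1×8); sampling times uniform within one 56-h
steady-state interval; concentrations from the reference model with
proportional error (negative draws resampled); values below the 0.024 mg/L
LOD substituted and flagged (about 0–3 per dataset, versus 1/246 in the
study). Baseline labs are truncated normals within the reported ranges
with (loc, scale) moment-matched so the truncated mean and SD equal the
reported summaries; for the right-skewed enzymes (ALT, AST, GGT) no
truncated normal attains the reported SD at the reported mean, so the mean
is matched exactly with the scale fixed at the reported SD (the generated
GGT SD is then ≈20 vs the reported 31 U/L — the real lab is more skewed
than a truncated normal). SNP genotypes are drawn per the reported
genotype counts including the missing ("NA") fractions, which exercises
the imputation path. Covariates are drawn independently; no joint
structure was reported. Weeks-on-therapy does not affect the steady state
and is not generated.

What passing tests on these data do not show: the generator has no
covariate correlations, no time-varying labs, no dropout or dosing-history
irregularities, and its uniform sampling-time rule is an interpretation of
"random within a dosing interval" — real sampling may cluster at clinic
visits, which changes how well the absorption phase is informed (see
limitations).

## Problem sizes and numerical settings

Default test/analysis scales, chosen for a single-CPU workflow: parameter
recovery uses 10 replicate datasets of the full design; stepwise-selection
operating characteristics 10 replicates (3 effect-free replicates for the
false-inclusion log); the bootstrap 40 resamples (medians are stable well
before that); VPC bands 150–400 simulation replicates. Outer-search
budgets: ~1600 simplex + 800 Powell evaluations for fresh fits, ~500 total
for warm refits inside bootstrap/SCM loops. The LRT thresholds use exact
chi-square quantiles, not their rounded textbook values.

## Known limitations

* Ka is weakly identified by sparse uniform steady-state sampling: only
  ~11% of samples fall in the absorption phase. The maximum-likelihood
  estimator of Ka is strongly right-skewed at this design — over 20
  replicate synthetic studies the median Ka estimate runs ~20–45% above
  the generating value, and spot checks with exact Gauss–Hermite marginal
  likelihoods confirm the likelihood genuinely prefers those estimates
  (this is not an optimizer or approximation artifact). CL/F (and hence
  all exposure metrics), the covariate effects, the residual SD and the
  CL/F IIV are recovered with median bias within a few percent; Vc/F
  within ~10% and its IIV within ~20%.
* The likelihood-ratio test for the rs319952-GG clearance shift has only
  ~40–60% power at alpha = 0.01 under these conditions (about 13 carriers,
  a −31% clearance shift against 38.7% IIV, sparse sampling, and
  mode-imputation diluting the 16% missing genotype calls); the GGT effect
  is detected essentially always.
* The Laplace (FOCE-I) objective deviates from the exact marginal
  likelihood by >0.5 OFV units for roughly one in ten single-observation
  subjects under 83.5% volume IIV; model comparisons rest on OFV
  differences, which are less affected.
* Exposure peaks are reported from the exact stationary point of the
  steady-state profile; peak values read off a discretized simulated curve
  are up to ~0.1% lower, which can flip the last printed digit of derived
  ratios.
* Only diagonal Ω, no inter-occasion variability, no metabolite kinetics,
  and one- (not multi-) compartment disposition are supported, matching
  the scope of the analysis.
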