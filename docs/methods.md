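# Methods

## Scope and model

`voripk` implements a population pharmacokinetic (PopPK) analysis of
voriconazole in critically ill adults: a two-compartment disposition model
with linear elimination, zero-order intravenous infusion and first-order
enteral absorption, lognormal inter-individual variability (IIV), a
combined residual-error model, a multiplicative covariate model on
clearance, FOCE estimation with empirical-Bayes (EB) random effects,
stepwise covariate selection, standard model-validation machinery (CWRES,
nonparametric bootstrap, prediction-corrected VPC), and a Monte Carlo
probability-of-target-attainment (PTA) simulation for dose selection.

### Structural model

Micro constants are `k10 = CL/Vc`, `k12 = Q/Vc`, `k21 = Q/Vp`; the hybrid
rate constants `alpha >= beta > 0` are the roots of
`s^2 - (k10+k12+k21) s + k10 k21` (beta computed as the root product over
alpha for accuracy). Central concentrations are closed-form biexponentials
(triexponential for enteral doses, absorption rate constant Ka fixed at
1.2 /h from literature; one shared bioavailability F for oral and
nasogastric routes). Arbitrary regimens superpose; a steady-state dose
event (NONMEM `SS=1` semantics: an infinite q`tau` train ending at the
event, superseding prior history) uses geometric accumulation factors
`1/(1-exp(-lambda tau))` instead of an explicit train. Closed forms are
verified against stiff ODE integration to ~1e-11 relative in the tests.

### Statistical model

Random effects act multiplicatively, `P_i = P_pop exp(eta_i)`, with
diagonal IIV on CL, Vc and Vp (none on Q). Residual error is combined:
`y = f (1 + eps_p) + eps_a` with proportional SD `sigma_prop` and additive
SD `sigma_add` (mg/L), so `Var(y|f) = (sigma_prop f)^2 + sigma_add^2`.
Reported %CV for IIV is `100 x omega` directly; the lognormal-exact
transform is available via `cv_to_omega(..., exact=True)` for callers who
prefer it.

### Covariate model on clearance

`CL = CL_TV x (qCRP/73.6)^-0.142 x (CLcr/71.8)^0.218 x 1.46^CRRT x
(PLT/144)^0.166 x (PT/15)^-0.875 x exp(eta_CL)`

Exponents are stored signed; the normalisation constants are the printed
equation values (not cohort medians, which differ slightly). During
covariate *search*, continuous candidates are normalised to the dataset
median; the published model overrides with the printed constants.
Creatinine clearance is Cockcroft-Gault from age, weight and serum
creatinine (umol/L, converted internally by 88.4), x0.85 for women.

## Estimation

The marginal likelihood over each subject's etas is approximated by a
Laplace expansion at the EB mode with interaction (residual variance at
conditional predictions). The curvature term defaults to the Gauss-Newton
FOCE-I linearisation `sum(g g'/v) + Omega^-1`; `hessian="exact"` substitutes
finite-difference second derivatives (full Laplace), which agrees with
adaptive quadrature to <1e-3 on toy subjects — the GN default trades
~0.01-0.05 OFV units of approximation error for speed. The whole dataset is
evaluated vectorised: observations are compiled once into
(observation, dose)-pair arrays and EB modes for all subjects are found by
a batched damped Newton iteration (central-difference gradients, step
1e-4).

The outer problem is unconstrained: log transforms for positive
parameters, logit for F, raw scale for signed power exponents, log for the
categorical CRRT factor. Default optimiser is finite-difference L-BFGS-B
(step 1e-4); Powell and Nelder-Mead are available. Ka is always fixed; an
IV-only dataset fixes F automatically (not identifiable) with a warning.
Omega/sigma components that start at zero stay fixed at zero. Standard
errors come from a central-difference Hessian of the OFV at the optimum
(`Cov = 2 H^-1`), delta-method-mapped to the natural scale;
RSE% = 100 SE/|estimate|. BLQ observations (< 0.097 mg/L, the assay LLOQ)
are excluded from estimation (M1) and counted in the log.

Inter-occasion variability is not modelled (subject-level IIV only), and
the omega matrix is diagonal.

## Covariate selection

Forward inclusion: one candidate per cycle, largest OFV drop, accepted if
drop > 3.84 (chi-square 1 df, p<0.05); ties break alphabetically. Backward
elimination: remove the covariate with the smallest OFV increase while that
increase is < 7.88 (p<0.005). Candidate fits that fail count as "no
improvement". A separate reporting rule flags retained effects with
RSE > 50% (configurable) for explicit removal, and an eta-screening table
(correlations for continuous, group shifts for categorical covariates) is
provided for inspection only, not as a gate.

## Validation machinery

- **CWRES** use the FOCE-I linearisation around the EB mode: marginal mean
  `f(eta_hat) - G eta_hat`, covariance `G Omega G' + diag(v)`, residuals
  whitened by the Cholesky factor. With omega = 0 and additive error this
  reduces exactly to `(DV - PRED)/sigma_add`.
- **Bootstrap**: subjects resampled with replacement to the original count;
  each resample refit from the point estimates (speed); failed or
  non-converged fits are excluded and counted, with a warning above 20%.
  Resample indices are a pure function of the seed.
- **pcVPC**: observations binned on time after the most recent dose
  (quantile bins, default 8; bins under 5 observations merge into a
  neighbour), each observed/simulated value scaled by
  (bin-median PRED / own PRED) without a lower-bound adjustment (BLQ
  excluded from the corrected set); observed 5/50/95th percentiles are
  overlaid on 95% CIs of the same percentiles across simulated replicates.

## PTA simulation

Target: fAUC24/MIC > 25 with fu = 0.42. Default exposure metric is the
steady-state identity `AUC24 = daily dose / CL` (steady state is the
monitoring condition of the underlying study), so only eta_CL is sampled;
a `day1` mode integrates the first-day profile numerically and samples all
three etas. Remaining covariates take the model's reference constants
("standardized values"): CLcr 71.8, PLT 144, PT 15. Residual error is
excluded — attainment is a true-exposure construct. The grid engine
(3 doses x 3 qCRP strata x CRRT yes/no x 8 MICs = 144 cells, n=1000,
PTA to one decimal) shares one standard-normal draw across all cells
(common random numbers), which makes monotonicity in MIC and dose exact
within a table. A closed lognormal form
`PTA = Phi([ln CL* - ln CL_typ]/omega_CL)`, `CL* = fu x daily/(25 MIC)`,
cross-checks the Monte Carlo estimate.

Note: the saturated cells (very low/high MIC) and the directional effects
of CRRT/qCRP/dose are robust to the exposure-metric choice; mid-range cells
are sensitive to it, and the original analysis does not pin the
configuration down, so they are validated by bounds and monotonicity, not
cell-exactly.

## Synthetic study generator

The generator emulates the source design: default 408 subjects on q12h
maintenance dosing (83.8% on 200 mg; remainder 150/100/250/300 mg),
routes ~68.1% IV infusion / 11% oral / 20.9% nasogastric, 1-h infusions.
10% of subjects contribute a steady-state intensive profile (pre-dose, end
of infusion, 2, 4, 6, 8, 12 h — seven samples, as in the clinical sampling
schedule); the rest contribute steady-state troughs 30 min before the next
dose, with 1 + Poisson(0.25) monitoring occasions per subject (matching the
cohort's ~1.25 troughs/patient), occasions one week apart. Expected total
observations ~745, mirroring the cohort's 746.

Covariates are independent lognormals matched by median and IQR to the
cohort table, truncated to physiologic ranges by inverse-CDF sampling with
the location re-calibrated so the truncated median still hits the target
(heavy-tailed qCRP would otherwise drift ~8% low). PT is not summarised in
the cohort table; median 15 s with IQR (13, 18) is a documented stand-in.
CRRT (prevalence 0.24) and ECMO (0.22) are redrawn per occasion; continuous
covariates are held within subject. Decoy covariates (AST, ALT, bilirubin,
albumin, SOFA, APACHE II, sex, co-medication, ECMO) are generated
independent of clearance to test selection specificity. Combined residual
noise is applied with resampling of negative values (avoiding a point mass
at zero); values below 0.097 mg/L are flagged BLQ. True parameters and
etas are stored in the dataset provenance.

What the generator does *not* emulate: covariate correlations (real renal,
hepatic and inflammatory markers co-vary), loading doses and TDM-driven
dose adjustments, inter-occasion variability, time-varying continuous
covariates, and assay-level artefacts. A green recovery test therefore
establishes internal consistency of estimator and generator under the
stated design, not robustness to those features.

## Numerical choices

- EB inner Newton: GN Hessian, per-subject backtracking (halving, max 8),
  convergence when the step max-norm < 1e-9, cap 60 iterations.
- Outer convergence: L-BFGS-B defaults with ftol 1e-10, gtol 1e-5,
  FD step 1e-4 on the transformed scale; the best iterate is kept even if
  the optimiser's own line search ends poorly.
- RSE Hessian step: 1e-3 (transformed scale), central differences;
  non-positive-definite Hessians fall back to a pseudo-inverse with a
  warning.
- Coincident rate constants (ka ~ alpha or beta) are nudged by 1e-7
  relative; Q = 0 (beta -> 0) is rejected as degenerate.
- Ties in forward selection break by larger drop, then alphabetically.
- All stochastic components (generator, bootstrap, VPC, PTA) take explicit
  integer seeds; per-component streams derive from `numpy` Generators.

## Known limitations

- FOCE/Laplace shares the usual small-sample biases of linearised
  mixed-effects estimators; sparse trough-heavy designs leave Vc/Vp/their
  IIV weakly identified (their omegas may collapse toward zero on small
  datasets — visible in reduced-size tests).
- The real clinical dataset is unavailable, so real-data OFVs are not
  reproducible; estimation targets are exercised against the synthetic
  twin.
- No SAEM/importance sampling, no off-diagonal omega, no
  Michaelis-Menten elimination, no lag time, no metabolite model, no
  CFR/MIC-distribution summaries.
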