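# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `intronkit`.

## Two-step splicing kinetics

The splicing scheme is modeled as two irreversible sequential
first-order reactions with unit initial precursor,

    5e-I-3e  --k1-->  I-3e  --k2-->  I,

whose closed-form solution (the Bateman equations) gives the species
fractions at any time.  Assumptions: no reverse reactions, no branched
or lariat pathway (appropriate for the hydrolytic group IIC pathway,
which produces linear intron), and each gel species treated as a single
pool — the documented double bands caused by cryptic cleavage are
expected to be aggregated by the user during densitometry before the
fractions enter the package.  Times are minutes, rates min⁻¹.

Numerics: when |k1 − k2| < 1e−6·max(k1, k2) the two-exponential
difference suffers catastrophic cancellation, so the continuous limit
`k1·t·e^(−k1·t)` is used instead; the switchover is continuous to well
below 1e−6 in the fractions.  The intermediate peak time uses the
matching limit 1/k.

### Rate-constant fitting

`fit_rate_constants` performs unweighted nonlinear least squares with
`scipy.optimize.least_squares` under positivity bounds.  Two modes are
provided because the original gel analysis does not state whether the
species were fitted jointly: `joint` (default) fits all three species
simultaneously with equal weight, `sequential` fits k1 to the precursor
decay and then k2 to the intermediate with k1 fixed.  Initialization
takes k1 from the log-linear slope of the early precursor decay and k2
from the post-peak intermediate decay; a 5×5 logarithmic grid multistart
over [1e−4, 1] min⁻¹ runs only if the solver fails or terminates on a
bound.  Uncertainties are reported two ways: standard errors from the
fit covariance (residual-variance-scaled Gauss–Newton approximation),
and, when ≥2 replicates are supplied, the across-replicate s.e.m. of
per-replicate fits — the s.e.m. is the headline number for triplicate
experiments.  A fit driven to the lower bound (k ≤ 1e−6, e.g. a
constant-precursor course) is flagged non-identifiable.

### K_i and IC50

K_i comes from the hyperbolic competitive model
`k_obs = k_max/(1 + [I]/K_i)` by (optionally weighted) least squares.
When per-point k_obs standard errors are available they should be
supplied: k_obs errors are strongly heteroscedastic (roughly
proportional to k_obs), and the weighted fit with `absolute_sigma` gives
a correctly scaled covariance.  Confidence intervals use the t
distribution with n−2 degrees of freedom; in simulation at the assay's
design (triplicate time courses, σ = 0.02 band noise, six doses) this
interval covers the true K_i in ~96% of experiments at nominal 95%.

IC50 fits the printed one-parameter hyperbola `% = 100/(1 + [I]/IC50)`
but parametrizes it internally as log(IC50) — the standard dose-response
convention — because a positive concentration parameter uncertain over
orders of magnitude has a far better calibrated Wald interval on the log
scale.  The reported standard error is delta-method transformed back to
concentration units.  Responses that rise with dose by more than 10
percentage points set a non-monotonicity warning rather than an error.

The percent-reacted-precursor normalization maps the 15-min precursor
fraction affinely so the DMSO control is 100% and the saturating dose
0%; FRET %activity is the ratio of initial slopes (linear fit over the
first 20% of time points by default, configurable) to the DMSO slope.

Fold-changes are reported from unrounded fitted constants.  Note that
recomputing the second-step fold from the rounded published constants
(0.031/0.001) gives 31, whereas the original analysis reports 34-fold
from unrounded values; the package makes no attempt to force agreement.

## Binding thermodynamics

Conventions: R = 1.9872042586e−3 kcal·mol⁻¹·K⁻¹, standard state
c° = 1 M, natural logarithms, temperature default 298.15 K.  The
experimental ΔΔG values derived from K_i pairs are reproduced at
298.15 K (and not at 310 K), fixing the temperature convention.
ΔΔG uses the delta method for errors; this propagation of the published
K_i s.e.m. values gives somewhat larger uncertainties than the published
ΔΔG error bars (whose propagation method is unstated) — the package
reports its own propagation and never back-fits published error bars.
ΔΔG is computed as RT·(ln K_B − ln K_A) so label-swap antisymmetry is
exact in floating point.

### ITC

The forward model is the single-site isotherm with perfusion-cell
bookkeeping: the calorimetric cell is constant-volume, so injecting a
cumulative volume ΔV scales cell-borne totals by exp(−ΔV/V0) while the
titrant accumulates as Xs·(1 − exp(−ΔV/V0)).  Bound ligand follows from
the mass-action quadratic, and the heat of injection i is ΔH times the
moles of complex formed by reaction, with a trapezoidal term for complex
carried out with the displaced volume:

    q_i = ΔH·[V0·(B_i − B_{i−1}) + v_i·(B_i + B_{i−1})/2] / (Xs·v_i) + offset.

This analytic model is validated in the test suite against an
independent micro-injection oracle (each injection split into 2000
discrete mixing steps).  The fit estimates (N, K_D, ΔH, offset), the
offset absorbing the blank control as a constant per-injection heat of
dilution; K_D is fitted in log space and its standard error transformed
back.  A Wiseman c-value N·[cell]/K_D outside [1, 1000] sets a warning;
a flat heat profile is flagged non-identifiable.  ΔG and −TΔS are
derived from the fitted K_D via the Gibbs relation, so the
decomposition ΔG = ΔH + (−TΔS) holds by construction.

### BLI

The instrument software's "2:1 heterogeneous" model is implemented as
two independent 1:1 Langmuir surface-site classes (the standard
interpretation; vendor equations are not public): per phase,
association follows `R_eq·(1 − e^(−(k_on·C + k_off)·t))` and
dissociation decays single-exponentially from the association endpoint.
The global fit shares the four rate constants and two saturating
amplitudes across all analyte concentrations, optimizes rates in log
space with a small multistart over phase-separation factors, and
reports phases ordered by increasing k_off.  If one amplitude collapses
below 1% of the total the result carries a single-phase warning (the
collapsed phase's rates are unconstrained).  Mass-transport limitation
and baseline drift are out of scope.

## Thermodynamic integration

The λ-schedule is generated, not hard-coded: the order-n Gauss–Legendre
nodes/weights on [−1, 1] (computed by Legendre-polynomial root finding
via `numpy.polynomial.legendre.leggauss`) are mapped affinely to [0, 1]
with weights rescaled to sum to 1.  The 12-point rule reproduces the
published 12 λ values and 6 symmetry-reduced weights at five decimals;
the published list's implicit mirror symmetry is thereby made explicit.

Toy alchemical systems interpolate end-state potentials linearly,
U(x; λ) = (1−λ)U_A + λU_B, so ∂U/∂λ = U_B − U_A.  Three families with
closed-form ΔG oracles are provided (d ≤ 3, isotropic):
harmonic stiffness morph (ΔG = d·kT/2·ln(k_B/k_A)), shifted well
(ΔG = 0 exactly, with nonzero window means — a stringent cancellation
test), and linear field (ΔG = −(b_B² − b_A²)/2k).  Softcore potentials,
replica exchange, and charge-correction schemes that matter for
explicit-solvent simulations are deliberately out of scope; independent
windows with burn-in stand in for equilibration.

Sampling is Metropolis random walk with Gaussian proposals; the step
size starts at 2.4·sqrt(kT/k_max) and is retuned every 50 burn-in steps
toward 40% acceptance (default burn-in: first 20% of the requested
steps, discarded).  A final acceptance rate outside [0.1, 0.9] sets a
warning flag.  The window estimate carries the sample variance and an
effective sample size from the initial-positive-sequence
autocorrelation estimator; the leg standard error is
sqrt(Σ wᵢ²·varᵢ/essᵢ) treating windows as independent, and cycle errors
add in quadrature.  `run_ti` derives per-leg, per-window child seeds
deterministically from one root seed, so identical configurations and
seeds give bit-identical results.

## Synthetic data

The generators define the study conditions the estimators are validated
under: gel time courses on the grid {0, 1, 2, 5, 10, 15, 30, 60, 120}
min (the exact experimental grid is unpublished; this is a realistic
densitometry schedule and is configurable) with triplicates and
σ = 0.02 Gaussian noise applied to band intensities *before*
normalization — truncated at zero and renormalized to sum to 1, as in
densitometry.  The truncation makes the noise slightly biased where a
species fraction is near zero (≈ E[max(0, N(0, σ))] ≈ 0.008 per pinned
species at σ = 0.02); interior points are unbiased to < 0.005.  k_obs
series use multiplicative log-normal noise, the natural model for
rate constants estimated from exponential fits.  ITC and BLI generators
add Gaussian noise to the exact forward models.  All generators are
pure functions of (parameters, design, seed), with per-stream child
seeds spawned from the root seed.

What passing these simulations does **not** show about real data: gel
densitometry has correlated lane backgrounds and saturation effects,
ITC baselines drift, BLI suffers nonspecific binding and transport
limitation — none of which the noise models emulate.  Recovery rates
quoted here are therefore best-case calibrations of the estimators, not
guarantees for raw instrument output.

## Problem sizes

Simulation-based checks use: 100-seed ensembles for rate-constant
recovery, 200 simulated experiments for K_i interval coverage, 400
dose-response fits for the IC50 recovery rate, 100 noisy titrations for
ITC, and 5,000 Monte-Carlo samples per λ-window (12 windows, 2 legs)
for the TI oracle — sizes chosen so each check's Monte-Carlo noise is
small relative to the margin it tests.

## Known limitations

* The kinetic model excludes reversible steps and lariat branches; it
  should not be applied to transesterification pathways where the
  lariat intermediate re-opens.
* Which step's k_obs feeds the K_i fit is the caller's choice; the
  package fits per-step series side by side rather than assuming one.
* The ITC model has no competitive-binding or baseline-drift terms.
* The TI sampler is a desk-scale estimator for analytically tractable
  potentials; it is not an MD engine and makes no claim about
  explicit-solvent convergence behavior.
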