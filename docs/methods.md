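# Methods

## Model

The C16 sphingolipid branch is modelled as a mass-action reaction network of
9 dynamic metabolites, 25 reactions and 29 nonnegative rate constants
(`src/sphingokin/data/c16_network.yaml`). The governing assumptions:

- **Linear (mass-action) kinetics.** Substrate concentrations are assumed far
  below the enzymes' Michaelis constants, so every flux is a rate constant
  times the product of its reactant concentrations, with the enzyme entering
  as one more multiplicative factor. Because each flux contains at most one
  *dynamic* species, the ODE system is linear in the state at frozen inputs —
  the package exploits this for exact Jacobians (`ReactionNetwork.linearize`)
  and closed-form steady-state cross-checks — and linear in the rate
  constants, which is what the matrix estimation step uses.
- **Gene folds as enzyme proxies.** Protein activity is represented by the
  mRNA fold-change shifted by 3 h, p(t) = g(t − 3) (a generic translation
  delay); for t < 3 h the earliest measured fold is held. The control
  condition uses fold 1 for every gene. Two reactions (2 and 16) are written
  without an enzyme factor because their enzymes (CerS5, Degs2) show no
  differential regulation.
- **Leaf-node absorption.** Unmeasured galactosylceramide branches are folded
  into the default degradation constants of their precursors (kf3, kf23);
  no GalCer species exists in the model.
- **Units.** Time in hours, concentrations in pmol/µg-DNA, gene folds
  dimensionless; rate constants carry whatever reciprocal units make each
  flux pmol/µg-DNA/hr. `convert_rate_units` maps fluxes to
  pmol/min/mg-protein via ~3 µg DNA and ~0.25 mg protein per 10^6 cells.

The network is loaded from a versioned YAML file rather than hard-coded, so
the same code can later be instantiated for other N-acyl chain lengths.

## Data model and preprocessing

Measurements live on the 8-point grid {0, 0.5, 1, 2, 4, 8, 12, 24} h under
two conditions, with 3 biological × 3 technical replicates. Preprocessing is
(1) per-time-point outlier removal and (2) averaging into mean ± SEM
(sd/√n, ddof = 1; SEM of a single replicate is defined as 0). The outlier
test is an iterative two-sided Grubbs (studentized extreme deviation) test at
α = 0.05, capped at ⌊n/3⌋ removals per time point and skipped below three
replicates; the exact test variant and level are a package choice, since only
"a t-test" is prescribed by the protocol being emulated. Inputs are
interpolated piecewise-linearly between samples and held constant outside the
measured range (the constant tail is what the 1000-h steady-state run uses).

## Estimation

**Step 1 — discretized linear system.** Backward differences
(x_k − x_{k−1})/(t_k − t_{k−1}) are assigned to the right endpoint t_k, and
the design row for interval k is evaluated at t_k with the measured
metabolite values and delayed gene folds, keeping Y and X time-aligned (the
endpoint convention is a package choice). Both conditions stack into a
126 × 29 system. The bound-constrained problem min‖Y − Xb‖², b ≥ 0 is solved
by `scipy.optimize.lsq_linear` after scaling columns to unit norm; singular
directions below 1e-7 of the leading singular value are reported as
confounded parameter groups (e.g. kf4/kf5 when the two sphingosine-kinase
fold profiles are proportional).

**Step 2 — weighted nonlinear refinement.** The objective is

    Σ_cond Σ_i Σ_j w_j² (ŷ_ij − y_ij)² / M_i²

with M_i the maximum measured value of species i over *all* fitted conditions
(one scale per species; concentrations span ~5 orders of magnitude) and
w_j = Δt_j^(1/4) (the t = 0 point reuses the first interval's weight). The
29 constants (bounds [0, 100]; the largest reference constant is 13) and the
9 initial concentrations per condition are optimised together; the
initial-condition window is ±2 SEM around the measured t = 0 value, falling
back to ±20 % when the SEM is 0. The optimiser is deterministic
bound-constrained least squares (scipy TRF, fixed start from step 1, no
random restarts), so a fit is exactly reproducible.

**Refinement integrator.** Objective evaluations use a fixed-step classical
Runge–Kutta integrator whose step grid contains every kink of the
piecewise-linear inputs (sampling times, and their 3-h-delayed images for the
treatment genes), subdivided to ≤ 0.05 h. Inside each step the right-hand
side is smooth, so the scheme keeps full fourth order, and — unlike an
adaptive solver, whose step-selection noise pollutes finite-difference
gradients — it makes the objective exactly smooth in the parameters. The
kernel is numba-compiled when numba is importable and runs as plain Python
otherwise (identical arithmetic, just slower). Its agreement with scipy's
adaptive reference solvers is enforced in the test suite (< 1e-7 relative).
The public `simulate()` keeps scipy's adaptive solvers (explicit Runge–Kutta
by default with an automatic stiff LSODA fallback, rtol 1e-6 / atol 1e-9);
nonnegativity is checked after the fact (tolerance-scaled), never clipped
during integration.

**Shared-parameter variant.** The dihydro-/desaturated-substrate reactions
of Ugcg, Cerk, Sms1 and Sms2 may be tied pairwise to a common constant; the
tied problem is nested in the untied one, and the tied fit starts from the
mean of the two untied values.

## Uncertainty

Replicate noise is propagated by resampling: each measured course is
perturbed as mean + SEM·z with i.i.d. standard-normal z per point (negative
candidates floored at 0 — a small bias source for points within ~2 SEM of
zero), the full two-step fit is rerun on each of k = 10 candidates, and the
spread of each constant across the k estimates is reported. "Spread" is the
standard deviation of the re-estimates, with sd/√k also available; the sd is
the headline number because it measures how much the estimate moves under
measurement noise. Metabolite, input-lipid and gene courses are all
perturbed; the conventional control gene folds (exactly 1, SEM 0) are not.
Resampling refits use a capped iteration budget (max_nfev 40, tolerances
1e-8): the quantity of interest is the spread, which is dominated by the data
perturbation rather than by the last digits of optimiser convergence.

## Sensitivity and time scales

Sensitivity scans scale one constant over {0.5, 0.667, 1, 1.5, 2} (two-fold
up and down), re-simulate the treatment condition on a dense grid (241
points) and record each metabolite's maximum relative to the unperturbed
maximum; the scalar slope is a central difference at ratio 1 with a ±10 %
step. The differencing scheme and dense-grid resolution are package choices;
slope values therefore carry a (small) method dependence, and their numeric
values also depend on the input time courses used.

Time-scale classification: the control system is integrated for 1000 h with
inputs frozen at their t = 0 values (a package choice; control inputs are
near-constant by construction) and convergence is verified as
‖rhs‖∞ < 1e-8·max(1, ‖x‖∞) — flagged, never silently ignored. The Jacobian
is computed by central differences (exact here, since the rhs is linear in
the state; the analytic linearisation is the cross-check). A metabolite
contributes to an eigenvector when its component is ≥ 0.3 of that vector's
∞-norm; each metabolite takes the slowest (smallest |Re λ|) eigenvalue among
the eigenvectors it contributes to, because the slow manifold governs its
approach to steady state. Buckets: fast < 3 h, medium 3–30 h, slow > 30 h —
boundaries placed symmetrically on a log scale between the ~1/~10/~100 h
clusters the model produces.

## Synthetic data

The generator emulates the experimental design: both conditions simulated
from the packaged reference constants, sampled on the 8-point grid, 3 × 3
replicates, fractional SEM defaulting to 0.25 (the middle of the observed
20–30 % range). Default input shapes encode the measured qualitative
behaviour — treatment sphinganine doubles by 4 h and returns to baseline by
24 h, palmitoyl-CoA rises monotonically, gene folds start at 1 and diverge
after 2–4 h with pairwise non-proportional, per-gene piecewise-linear shapes
(a deterministic identifiability guard). Control inputs are constant and the
default initial state is the exact control steady state, so control courses
are flat. Replicate noise is multiplicative lognormal (concentrations are
positive and dispersion is roughly a constant CV), mean-preserving, with
per-replicate CV = fractional-SEM × √n; additive-normal perturbation remains
available through the uncertainty module's resampler.

What passing recovery tests therefore show — and do not show: with exact
model structure, exactly known inputs, and noise-free data, the two-step
estimator returns the generating constants essentially exactly, i.e. the
pipeline is correct and the default conditions identify all 29 constants.
They do not show robustness to model misspecification, to mRNA–protein
discrepancies, to declining (non-steady) control baselines, or to the real
(unpublished) input trajectories; weakly leveraged constants (kf4, kf21,
kf23) remain poorly determined once realistic noise is added, mirroring the
large published ± values for those same constants.

## Problem sizes and numerical defaults

Recovery runs use the full design (8 time points × 9 species × 2 conditions
= 144 observations, 47 decision variables) and finish in well under a minute;
resampling uses k = 10 refits. Generation integrates at rtol 1e-10 so the
"measurements" are tighter than any fitting tolerance. Optimiser defaults:
ftol = xtol = gtol = 1e-12, relative FD step 1e-6, x_scale from the starting
point.

## Known limitations

- DHSph1P is dynamically decoupled (its eigenvalue is exactly −kf6,
  τ ≈ 1.9 h) and classifies as *fast* under the 3-h boundary, whereas the
  published grouping places it in the medium cluster; the discrepancy is a
  property of the bucket boundaries, not of the eigenvalue.
- Published sensitivity slopes depend on the real input time courses; with
  the package's synthetic inputs the kf16 slopes are −0.75 (C16 DHCer) and
  +0.19 (C16 Cer) — same signs and comparable magnitudes, different numbers.
- The resampler perturbs mean courses with independent noise per point,
  ignoring any temporal or cross-species correlation in the replicates.
- The 1000-h steady-state check legitimately fails for systems with
  characteristic times ≳ 200 h started far from equilibrium; the flag is the
  intended behaviour.
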