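# sphingokin

Kinetic modelling of the **C16 branch of sphingolipid metabolism** — the
ceramides, sphingomyelins and glucosylceramides carrying a palmitoyl (C16)
N-acyl chain — from paired lipidomics and transcriptomics time courses, as
measured in endotoxin-stimulated RAW264.7 macrophages.

The package is for systems biologists who want to turn dual-condition
(control vs. stimulus) metabolite and mRNA time series into a quantitative
mass-action model: estimate the rate constants, attach resampling-based
uncertainties, and interrogate the fitted network through parametric
sensitivity and eigenvalue time-scale analysis. A built-in synthetic-data
generator reproduces the experimental design (8 samples over 24 h, two
conditions, 3 × 3 replicates, ~20–30 % fractional SEM), so the entire
pipeline is validated by parameter recovery against a known ground truth.

## The model

Nine dynamic metabolites x (pmol/µg-DNA) — C16 DHCer, DHSph1P, C16 DHGlcCer,
C16 DHSM, C16 DHCerP, C16 Cer, C16 CerP, C16 SM, C16 GlcCer — evolve as

    dx/dt = S v(x, u(t), p(t); k)

with 25 mass-action fluxes v, stoichiometry S, four measured input lipids
u(t) (sphinganine DHSph, palmitoyl-CoA, C16 DG, C16 GPCho) and nine enzyme
activities p(t) proxied by mRNA fold-changes with a 3-hour translation delay,
p(t) = g(t − 3); the control condition uses fold 1 for every gene. Each flux
is linear in its rate constant, e.g.

    v1  = kf1 [DHSph][CoA16][CerS6]
    v9  = kf9 [C16 DHCer][Sms1][C16 GPCho] − kb9 [C16 DHSM][Sms1][C16 DG]
    v16 = kf16 [C16 DHCer]

(valid when substrate concentrations are far below the enzymes' K_m). Four
sphingomyelin-synthase reactions are reversible, giving 29 nonnegative rate
constants k.

Estimation is two-step:

1. **Matrix step** — backward-difference derivatives of the measured species
   form Y, the mass-action regressors evaluated at the measured
   concentrations form X, and min‖Y − Xb‖² s.t. b ≥ 0 gives a fast initial
   guess (with an identifiability report from the SVD of X).
2. **Refinement** — the constants and the initial concentrations (within a
   narrow window around the measured t = 0 values) minimise the weighted fit
   error Σ w_j² (ŷ_ij − y_ij)²/M_i² over both conditions jointly, with
   per-species maximum normalisation M_i and interval weights
   w_j = Δt_j^(1/4), predictions coming from full ODE integration.

Downstream: SEM-resampling of the data propagates replicate noise into
per-constant spreads; one-at-a-time two-fold parameter scans give
fold-change-of-maximum sensitivities; the eigen-decomposition of the
steady-state Jacobian classifies each metabolite as fast (< 3 h), medium
(3–30 h) or slow (> 30 h).

## Worked example

```python
import sphingokin as sk

net = sk.load_default_network()                      # packaged C16 network
truth = sk.SyntheticTruth.default(net, noise_frac_sem=0.0, n_bio=1, n_tech=1)
data = sk.generate_dataset(net, truth)               # noise-free synthetic data

model = sk.SphingolipidKinetics(data, network=net)
res = model.fit()
print(res.summary())
```

which prints (abridged)

```
C16 sphingolipid kinetics — two-step mass-action fit
====================================================
network: c16-sphingolipid  (9 species, 25 reactions, 29 rate constants)
conditions fitted: control, treatment
observations: 144   objective: 4.36451e-16
converged: True   (`xtol` termination condition is satisfied.)

parameter       estimate
------------------------
kf1           1.3000e+01
kf2           5.6198e-02
...
kf16          8.0300e-01
...
kb20          1.3343e+00
```

The generator's ground truth is the packaged reference constant set, so the
estimates above *are* the recovered truth: every constant comes back to
within a fraction of a percent, and the objective ~4e-16 says the refined
model reproduces the synthetic measurements to solver precision. Analyses
hang off the results object:

```python
res.timescales().assignment      # C16SM -> slow (tau ~95 h), C16DHCer -> fast (~0.3 h)
res.sensitivity("kf16").slope    # C16DHCer -0.75, C16Cer +0.19: raising the
                                 # desaturation rate drains DHCer into Cer
res.resample(k=10, seed=0)       # SEM-resampling uncertainties -> res.bse
```

A thin CLI mirrors the library: `sphingokin synth | fit | resample |
sensitivity | timescale` (see `--help`).

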