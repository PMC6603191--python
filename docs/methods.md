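# Methods

## Model structure and assumptions

Survival is the product of a targeted-effect (TE) and a non-targeted-effect
(NTE) factor, S = exp(−w_T)·exp(−w_NT). The TE term follows
microdosimetric-kinetic theory: potentially lethal lesions are produced in
micron-scale domains in proportion to specific energy, convert to lethal
lesions directly (linear term) or pairwise (quadratic term), and are
repaired at first-order rate (a+c). Interaction between TE and NTE lesion
pathways is neglected (their interaction probability is assumed small), which
is what makes the two survival factors exactly multiplicative.

The NTE term assumes (i) signals released by "hit" cells (cells with at
least one activated micron-scale signal-emitting target) reach the whole
flask, for both half-field and uniform geometry; (ii) the hit probability
f_h depends on cumulative dose only — never on delivery timing or
fractionation; (iii) lethal lesions in signal recipients are proportional
to an empirical coefficient δ, so w_NT = δ·f_h(D_IF)·f_b(D_*) ≤ δ. Setting
δ = 0 represents chemical inhibition of the signalling pathway.

The angled-bracket average over inter-fraction decay in the fractionated
lesion sum is evaluated as a plain exponential in the elapsed sub-section
count: with a fixed ΔT grid the expectation collapses and no stochastic
averaging is performed.

Out-of-field cells receive direct dose `scatter_fraction × D_IF`, default
0: transmission through the shielding is treated as negligible for direct
killing, so out-of-field killing is purely signal-mediated. Out-of-field
survival curves are parameterized against the *delivered in-field* dose.

## Dose-delivery representation

All exposures are piecewise-constant dose-rate timelines. "Acute"
exposures are segments of finite duration 1e-6 h (so every code path goes
through one schedule representation); their residual protraction error is
of order (a+c)·1e-6 relative. Discretization into N equal sub-sections
integrates the dose-rate profile exactly (total dose conserved to < 1e-9
relative at any N). The evaluation cost of the double sum is linear in N:
the exponentially-decayed dose history is carried by a first-order
recursive filter.

N is chosen adaptively: powers of two, stopping when successive values of
w_T agree to 1e-6 relative (capped at 2^20). The noiseless recovery-curve
generator tightens this to 1e-9 because the fine-step slope estimator
differences survivals across a 1e-4 h gap and needs w_T resolved well
below that signal. Zero-dose-rate segments at either end of a schedule are
trimmed before discretization — beam-off time outside the delivery window
cannot change the lesion count, and trimming makes results exactly
invariant to zero-dose padding.

The four pulsed dose-rate regimens (0.59/0.2/0.1/0.05 Gy/min average for
4 Gy) are presets: the source is on at 0.59 Gy/min and the lower averages
interleave equal beam-off gaps between 8 equal pulses. The true pulse
pattern of the experimental rig is not published, so the presets are
labelled approximations and are plain data that callers can override.

## Numerical choices

* Lea-Catcheside factor: for x = (a+c)T < 1e-3 a cubic Taylor series
  replaces the direct expression. At the switch point both branches agree
  to < 1e-12; the direct branch uses expm1 to limit cancellation.
* Exponents are clipped at ±700 before exponentiation; survival is
  returned as exp(−w) without flooring.
* Reflection at zero in the Metropolis proposal keeps draws non-negative
  while preserving detailed balance; the truncated-normal prior
  contributes only its Gaussian kernel (the truncation constant is
  parameter-independent).
* Proposal widths are tuned every 200 burn-in sweeps by ×0.7 / ×1.4
  factors towards a 20–50% acceptance window, then frozen.

## Estimators and their conventions

The plateau S(∞) is the mean survival over tau in the half-open window
(6, 48] h; with the standard tau grid {0, 0.25, 0.5, 1, 2, 4, 24, 48} h
this averages the 24 h and 48 h points and deliberately excludes 4 h,
following the published convention literally. The initial specific slope
is a forward finite difference (S(step) − S(0))/(step·S(0)) with
step = 0.25 h by convention. A finite step biases the rate estimate low by
the computable factor expm1(x)/(step·2β₀D₁D₂) with
x = 2β₀D₁D₂(1 − e^{−(a+c)·step}); the tests assert this bias exactly. The
fine-step mode (step ≈ 1e-4 h on noiseless model curves) recovers the true
limit to ≲0.1%. Negative β₀ (inverse recovery, seen in flat out-of-field
curves) is reported with a warning rather than clamped.

Both estimators are invariant to a common rescaling of all survivals, so
plating-efficiency normalization cancels.

## Inference design

β₀ and (a+c) are fixed at their split-dose estimates during MCMC; only
θ = (α₀, α_b, β_b, δ) is sampled (the staged procedure of the original
analysis). Dose-response records are treated as acute exposures, for which
the fixed (a+c) drops out (F = 1). In-field, out-of-field and uniform
records are fitted jointly with a single shared α₀ and shared NTE
parameters; fitting two field conditions with their own TE sets means
running two fits. Priors default to normals with mean = initial guess and
sd = 10× that guess, truncated at zero — weakly informative; the defaults
are implementation choices, overridable per parameter. Default chain
length is 20,000 sweeps with 5,000 burn-in.

The error model is Gaussian on −ln S. When records carry replicate-based
standard errors, they are mapped to the −lnS scale as sd/S (delta method);
a global σ can be configured instead (required for noiseless data). R² is
computed on the survival scale by default (configurable to −lnS); χ² is
the mean squared standardized residual on the survival scale, with zero-sd
points excluded and n adjusted. The migration-vs-damage-yield model
comparison is expressed as two model variants (`MigrationModel`,
`DamageScaling`) scored with the same χ².

## Synthetic data

The generator emulates three experiment families — acute dose-response
({0, 0.5, 1, 2, 4, 6, 8, 10} Gy), split-dose recovery (2 Gy + 2 Gy over
the standard tau grid) and the four pulsed regimens — for two cell lines
and both geometries, with the shipped parameter sets as generating truth.
The `idealized` variant sets the AGO1522 half-field SLDR rate to exactly 0
(the fitted value is statistically indistinguishable from zero), making
schedule-independence checks exact; the literal fitted numbers remain
available.

Noise is replicate-level additive Gaussian on −ln S (default sd 0.1,
3 replicates), chosen to be conjugate to the fitted likelihood; the true
replicate scatter of the real assays is only visible as figure error bars,
so this magnitude is a stand-in, not a measured value. Replicate −lnS
draws are clipped at 0 (negligible for doses ≥ 0.5 Gy at the default sd)
and the zero-dose control is recorded as exactly 1, keeping all survivals
in (0, 1]. Each record stores exp(−mean replicate −lnS) and the standard
error of the replicate survivals; with this convention the reduced χ² of
correctly-modelled data is ≈ 1. An optional colony-count mode draws
Poisson colony numbers instead. The generator does not simulate plating
efficiency drift, spatial signal gradients, cell-cycle structure or
flask-to-flask variation — passing tests demonstrate estimator and sampler
correctness under the model's own assumptions, not robustness to every
feature of real assay data.

## Problem sizes

The shipped test and reproduction runs use desk-scale problems chosen as
representative: dose grids of 21–41 points over 0–10 Gy, 9-point tau
grids, chains of 5,000–20,000 sweeps, and 20-dataset replications for
band-coverage checks.

## Known limitations

* Eq.-level coefficients a, b, c of the lesion kinetics are not
  individually identifiable from survival data; only (a+c) and the
  damage-yield ratio k'/k enter the implementation.
* The pulse fine-structure of the sub-maximal dose-rate regimens is an
  approximation (see above).
* No track-structure simulation: y_D values (4.393 keV/µm in-field,
  4.769 keV/µm out-of-field for the 225 kVp beam) are consumed as
  constants.
* No cell-cycle, tissue-level or spatial diffusion modelling.
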