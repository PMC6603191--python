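# imk — microdosimetric-kinetic survival modelling for modulated radiation fields

`imk` implements the integrated microdosimetric-kinetic (IMK) model of
clonogenic cell survival for intensity-modulated radiation exposures, where
irradiated (in-field) and shielded (out-of-field) cell populations coexist
in one flask. It is aimed at radiobiologists and medical physicists who
want to analyse dose-rate effects, split-dose recovery and bystander
(signal-mediated) cell killing within a single quantitative framework:
forward survival prediction for arbitrary dose-delivery timelines,
closed-form estimation of the sub-lethal damage repair (SLDR) rate from
split-dose experiments, and MCMC inference of the remaining dose-response
parameters with 95.4% credible bands.

## The model

Cell killing is described by two independent Poisson lethal-lesion loads,
so the surviving fraction is S = exp(−w_T − w_NT).

**Targeted effects (TE).** For a delivery timeline chopped into N
sub-sections of width ΔT with sub-section doses d_n,

    w_T = Σₙ [(α₀ + γβ₀) d_n + β₀ d_n²]
          + 2β₀ Σ_{n<m} d_n d_m e^{−(m−n)(a+c)ΔT}

where α₀ (Gy⁻¹) and β₀ (Gy⁻²) are cell-specific coefficients, (a+c)
(h⁻¹) is the SLDR rate, and γ = y_D/(ρπr_d²) (Gy) converts the dose-mean
lineal energy y_D of the beam into the dose-mean specific energy of a
0.5 µm domain. For constant-rate delivery of dose D over time T this
collapses to the linear-quadratic form with the Lea-Catcheside
protraction factor,

    w_T = (α₀ + γβ₀) D + F β₀ D²,
    F   = 2[(a+c)T + e^{−(a+c)T} − 1] / ((a+c)T)².

**Non-targeted effects (NTE).** Hit cells (those with at least one
activated signal-emitting target, probability
f_h(D) = 1 − e^{−(α_b+γβ_b)D − β_bD²}, a function of cumulative dose
only) release signals that can kill non-hit cells anywhere in the flask:

    w_NT = δ · f_h(D_IF) · f_b(D_*),   f_b = 1 − f_h,

bounded by δ. Out-of-field cells receive no direct dose by default
(configurable scatter fraction), so their killing is purely
signal-mediated.

**Split-dose estimators.** For two equal fractions separated by τ,
S(τ) rises from S(0) to a plateau S(∞), and

    (a+c) = [lim_{τ→0} (1/S) dS/dτ] / ln(S(∞)/S(0)),
    β₀    = ln(S(∞)/S(0)) / (2 D₁D₂).

**Inference.** With γ, β₀ and (a+c) fixed, θ = (α₀, α_b, β_b, δ) is
sampled by component-wise random-walk Metropolis (reflection at zero,
truncated-normal priors, Gaussian error on −ln S), yielding posterior
moments and pointwise 2.3%/97.7% (95.4%) predictive bands.

Reference parameter sets for a normal fibroblast line (AGO1522) and a
prostate tumour line (DU145), under half-field and uniform-field
exposure, ship with the package (`imk.presets`, `imk/data/parameters.yaml`).

## Worked example

Predict survival at 4 Gy acute exposure for AGO1522 under half-field
geometry (in-field cells are killed by direct dose plus signals;
out-of-field cells by signals alone):

```
$ imk simulate --preset ago1522-half --dose 4 --schedule acute
in_field        0.177209
out_of_field    0.579389
```

Slowing the same uniform-field dose to 0.05 Gy/min average lets repair
act during delivery and raises survival relative to the acute 0.0407:

```
$ imk simulate --preset ago1522-uniform --dose 4 --schedule 0.05
uniform 0.0768218
```

Recover the SLDR rate from a noiseless synthetic split-dose experiment
(2 Gy + 2 Gy, uniform field):

```python
from imk import GeneratorConfig, estimate_a_plus_c, generate_recovery_curve

curves = generate_recovery_curve(GeneratorConfig(
    seed=7, cell_line="AGO1522", a_if=1.0, noise_sd=0.0,
    taus=(0.0, 1e-4, 0.25, 0.5, 1, 2, 4, 24, 48),
))
est = estimate_a_plus_c(curves["uniform"], step=1e-4)
print(f"a+c = {est.a_plus_c:.4f} /h, beta0 = {est.beta0:.4f} /Gy^2")
# a+c = 1.6840 /h, beta0 = 0.0810 /Gy^2
```

The estimate returns the generating preset values (a+c = 1.684 h⁻¹,
β₀ = 0.081 Gy⁻²): survival recovers from S(0) = 0.0407 at zero gap to
the plateau 0.0778 once all sub-lethal damage from the first fraction
has been repaired.

The CLI also provides `generate` (synthetic datasets), `estimate-sldr`,
`fit` (MCMC), `predict` (credible bands) and `gof` (R², χ²); every
artifact-producing command writes a `manifest.json` recording seed and
configuration.

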