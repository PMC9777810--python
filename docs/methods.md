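# Methods

## Scope and model structure

hydrokin implements a two-level empirical description of enzymatic protein
hydrolysis monitored by pH-stat titration.

Level 1 treats each experiment (fixed temperature T and protease dose E) as
one curve of released α-amino concentration P(t) and summarizes it by the
logarithmic model P = (1/b)·ln(a·b·t + 1), the closed form of the rate law
dP/dt = a·e^(−bP) with P(0) = 0. The model is deliberately empirical: `a`
is an operational initial rate (dP/dt at t = 0), `b` an attenuation scale
(1/b is roughly where the curve bends over). No mechanistic
(Michaelis–Menten, substrate-depletion or product-inhibition) structure is
claimed, and enzyme inactivation is *not* part of the fitted model — an
inactivating protease shows up as lack of fit, which is informative and is
exactly how the simulator's inactivation variant is used in tests.

Level 2 treats the fitted constants as responses over a two-factor central
composite circumscribed design in coded units x = (natural − center)/step,
fitting the full quadratic y = β₀ + β₁x₁ + β₂x₂ + β₁₁x₁² + β₂₂x₂² + β₁₂x₁x₂
by OLS and removing non-significant terms.

## Titration conversions

P = V·N/(α·V_T) and DH = P·V_T/(h_T·M_P). Default assay constants are those
of the bundled milk study: N = 0.5 eq/L, α = 0.2, h_T = 10.7 meq/g,
M_P = 1.24 g, V_T = 0.040 L. V_T is not measured independently; 40 g of
reaction mixture at unit density gives 0.040 L, and this value reproduces
the bundled study's DH numbers to better than 1%. All constants are
user-overridable; none is hard-coded outside `datasets.default_assay`.
The added titrant volume is treated as non-diluting (constant V_T), matching
the conversion formulas above; at the ~2 mL of titrant typical for these
experiments this is a ≲5% volume effect absorbed into the empirical
constants. α is held fixed at 0.2 with no temperature correction — a known
simplification of pH-stat practice at a fixed working pH.

Time is minutes everywhere internally; second-resolution traces are
accepted with an explicit unit flag. A cumulative titrant volume that
decreases is treated as an input error unless the caller opts into
running-maximum correction, because silent monotonization biases the curve
upward (see "Known limitations").

## Level-1 fitting

Nonlinear least squares (`scipy.optimize.least_squares`, bounds a, b >
1e−12, analytic Jacobian, ftol 1e−10). Starting values: a₀ = OLS slope of
the first 10% of points (a is the initial slope), b₀ = 1/max(P) (1/b is
the saturation scale); on failure the fit restarts from b₀×{0.1, 10}.
σ̂² = SSE/(n−2) (two parameters; the standard NLS convention), C = (JᵀJ)⁻¹
at the optimum, se_j = √(σ̂²·C_jj); R² is the coefficient of determination
about the mean. If b collapses to its bound the linear limit P = a·t is
reported with a warning rather than a spurious tiny-b fit.

## Level-2 regression and reduction

OLS and coefficient inference (se, t, two-sided p with df = n − k) are
delegated to statsmodels. Two elimination rules are provided:

- `backward` (default): repeatedly drop the non-intercept term with the
  largest p-value above α and refit, until all remaining terms are
  significant.
- `single_pass`: drop every non-significant term of the full model at once.

Both are idempotent and α defaults to 0.05. They can genuinely disagree: on
the bundled Alcalase a-response, x₂² has p = 0.097 in the full model (so a
single pass discards it) but becomes significant once x₁² is removed (so
backward elimination keeps it). The bundled study's published supports are
reproduced by `single_pass` for the Alcalase/Protamex rate models and by
`backward` for the Neutrase rate model — evidence that published RSM tables
of this kind are not always the output of one mechanical rule. Users should
pick one rule and report it.

A caution encoded in the tests rather than the API: with five candidate
non-intercept terms, per-term α = 0.05 elimination retains *some* spurious
term in roughly 1 − 0.95⁵ ≈ 23% of pure-noise datasets, and recovers an
exact true support at best ~(1−α)^m for m null terms. Exact-support
recovery claims stronger than that ceiling cannot be met by this class of
procedures.

ANOVA reports SS_reg = Σ(ŷ−ȳ)², SS_err = Σ(y−ŷ)², SS_tot = Σ(y−ȳ)² under
two df conventions: `standard` (df_reg = k−1, df_err = n−k) and `paper`
(df_reg = k, df_err = n−k−1), the bookkeeping printed in some
food-engineering RSM reports. The sums of squares are identical; only
df/MS/F/p differ. Coefficient t-tests always use df = n−k, which is the
convention consistent with the bundled study's printed per-coefficient
p-values even where its ANOVA block uses the other one.

## Prediction

At a coded x₀ the response prediction is ŷ = x₀ᵀβ with
se = √(σ̂²·x₀ᵀ(XᵀX)⁻¹x₀) and a Student-t interval; the `convention` flag
selects σ̂² and df as SSE/(n−k), n−k (standard) or SSE/(n−k−1), n−k−1
(paper). This is a *mean-response* (confidence) interval, not a
new-observation (prediction) interval — there is no "+1" in the leverage —
matching the interval definition the tool is built around. Conditions
outside the axial radius warn about extrapolation but proceed.

Curve prediction fixes b at the reduced b-surface's design-center value
(its intercept) — justified because b correlates poorly with T and E when
the substrate load is constant — and propagates only the uncertainty in a.
Because P(t) is strictly increasing in a at every t > 0, evaluating the
model at the interval endpoints of a gives the exact pointwise band; no
delta-method linearization is used. A negative lower endpoint (possible at
high confidence with a weak model) is clamped to zero with a warning. DH
bands follow by the linear DH–P relation. Validation scoring offers
100·|pred−exp|/exp per condition and the squared Pearson correlation across
conditions; the latter is sign-blind and measures association, not
agreement, which the API documents.

## Synthetic data generator

`simulate_product` integrates dP/dt = a·e^(−bP)·e^(−k_d·t) by fixed-step
RK4 (step ≤ 0.01 min; the rate law is smooth, and the integrator matches
the k_d = 0 closed form to ~1e−13 relative, far below any tolerance used).
k_d is a first-order enzyme-inactivation constant; ln(2)/10 min⁻¹
reproduces the ~10-minute half-life typical of a thermolabile neutral
metalloprotease near 60 °C. k_d is scenario-specified per run; no Arrhenius
law is fitted or assumed.

`simulate_titration` inverts the titration relation (V = P·α·V_T/N), adds
iid Gaussian noise on the cumulative volume — the quantity the instrument
records — anchors V(0) = 0, restores monotonicity with a running maximum,
and quantizes to the dispensing resolution. One integer seed drives one
`numpy.random.Generator` stream per run, so fixtures are bit-reproducible.

Scenario defaults mirror the bundled study's conditions: a true a-surface
equal to the study's Alcalase reduced model (β₀ 9.69, β₁ 4.56, β₂ 4.88,
β₁₂ 2.82 mM/min in coded units), b = 0.0410 mM⁻¹ shared across runs, 60-min
duration, 1-s sampling, no inactivation, no noise. `noise_for_target_r2`
sizes the volume noise so the product-level signal-to-noise corresponds to
a chosen curve R², so simulations are pitched at a stated fit quality
rather than an arbitrary sd.

What the generator does **not** emulate: model lack-of-fit. Real hydrolysis
curves with R² ≈ 0.99 deviate from the logarithmic form systematically
(inactivation, substrate depletion), not through ~1.8 mM of white
measurement noise; a pH-stat burette's actual noise is of order 5 µL
(~0.3 mM). Passing pipeline tests on synthetic data therefore demonstrate
estimator correctness under the assumed error model, not robustness to
misspecification — except for the inactivation variant, which probes
exactly that.

## Known limitations and numerical choices

- **Running-maximum monotonization is upward biased.** The running max of
  signal plus iid noise sits above the signal (an extreme-value effect), so
  monotonized noisy traces systematically inflate P and hence â. Measured
  on the default surface at center: noise sized for curve R² ≈ 0.99 gives
  mean â ≈ 10.6 (true 9.69) at 5-s sampling and ≈ 11.5 at 1-s sampling,
  while the same noise *without* monotonization is unbiased. At
  instrument-realistic noise (0.005 mL) the bias is under 3%. Consequence:
  end-to-end surface recovery from heavily noisy monotonized traces carries
  a positive intercept bias of the same order; this is a property of the
  measurement emulation, not of the fitter. Tests cover both regimes and
  the corresponding acceptance check documents the large-noise behaviour.
- Problem sizes in the test suite are scaled for a single CPU: simulated
  studies sample every 5–30 s instead of every second and the recovery
  study uses 50 seeded replicates; the statistical conclusions are
  unchanged at 1-s sampling except where noted above.
- Coefficient reproduction tolerances against the bundled tables are 2%
  because the bundled per-run constants are printed to three significant
  figures.
- Axial distance is exactly √2 (the printed "±1.4" is display rounding:
  the natural levels 48/62 °C and 19/231 mAU decode from ±√2, not ±1.40).
- Degenerate inputs: all-zero curves raise a degenerate-data error; < 4
  points are rejected (2 parameters + 2 residual df); duplicate time
  stamps are rejected rather than averaged.
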