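# hydrokin

Two-level modeling of the enzymatic hydrolysis of milk proteins from
pH-stat data: per-curve kinetic fitting, response-surface correlation of the
kinetic constants with operating conditions, and prediction of hydrolysis
curves and degree of hydrolysis (DH) with confidence bands at new
conditions.

## Who this is for

Food-process and bioprocess engineers characterizing protease performance
(e.g. Alcalase, Neutrase, Protamex on milk proteins) who need to answer:
*what DH will I reach after t minutes at temperature T and protease dose E,
and how confident am I in that number?* Partially hydrolyzed milk proteins
are of direct interest for hypoallergenic formulas, where DH is the control
parameter linking process conditions to allergenicity reduction.

## The model

**First level — one curve.** A pH-stat experiment holds pH constant and
titrates the protons released by peptide-bond cleavage, so the cumulative
NaOH volume V tracks the released α-amino concentration

    P [mM] = V·N / (α·V_T),          DH = P·V_T / (h_T·M_P),

with N the titrant normality, α the average dissociation of the α-amino
groups, V_T the reaction volume, h_T the total α-amino content per gram of
protein and M_P the protein mass. Each curve is summarized by the
logarithmic kinetic model

    P(t) = (1/b) · ln(a·b·t + 1),

the closed form of dP/dt = a·e^(−bP): `a` (mM/min) is the initial
hydrolysis rate dP/dt at t = 0 and `b` (mM⁻¹) the extension constant
governing how the rate attenuates as product accumulates. Constants are
estimated by nonlinear least squares with standard errors from the
linearized dispersion matrix, se_j = √(σ̂²·C_jj), C = (JᵀJ)⁻¹.

**Second level — across conditions.** Temperature and protease dose are
coded as x₁, x₂ on a two-factor central composite circumscribed design
(factorial corners ±1, axial points ±√2, replicated center), and each
kinetic constant is regressed on

    y = β₀ + β₁x₁ + β₂x₂ + β₁₁x₁² + β₂₂x₂² + β₁₂x₁x₂

with t-test-based elimination of non-significant terms and an ANOVA block.
Predictions at a new condition x₀ carry the confidence interval

    ŷ(x₀) ± t_{α/2,df} · √(σ̂² · x₀ᵀ(XᵀX)⁻¹x₀),

and a predicted hydrolysis curve pushes that interval through the
(monotone-in-a) logarithmic model with `b` fixed at its design-center
value.

A synthetic-data module simulates complete pH-stat studies — including a
first-order enzyme-inactivation variant (thermolabile-protease behaviour)
and instrument noise on the titrant volume — so the entire pipeline is
testable without raw lab data.

## Worked example

Refit the bundled milk-study constants for Alcalase, then predict the
60-minute DH at the coded condition (x₁, x₂) = (0, −1), i.e. 55 °C and
50 mAU:

```python
import numpy as np
from hydrokin import fit_polynomial, fixed_b, predict_a, predict_curve
from hydrokin.datasets import (default_assay, load_kinetic_constants,
                               reduced_model_terms, study_design)

x = study_design().coded
tab = load_kinetic_constants("alcalase")
res_a = fit_polynomial(x, tab["a"], reduced_model_terms("alcalase", "a"))
print(res_a.summary(convention="paper"))

b_fix = fixed_b(fit_polynomial(x, tab["b"], reduced_model_terms("alcalase", "b")))
pred = predict_a(res_a, (0.0, -1.0))
curve = predict_curve(pred, b_fix, np.linspace(0, 60, 61), default_assay())
print(f"fixed b: {b_fix:.4f}")
print(f"a at (0,-1): {pred}")
print(f"DH(60 min): {curve.dh_at(60):.1f}% band [{curve.dh_low[-1]:.1f}, {curve.dh_high[-1]:.1f}]")
```

Output:

```
Response-surface regression (coded factors x1, x2)
  terms : 1 + x1 + x2 + x1*x2
  n = 10,  R^2 = 0.9818,  adj R^2 = 0.9728

  term      coefficient          se           t            p
  1         9.698      0.3461       28.02      1.366e-07
  x1        4.5552      0.3869       11.77      2.268e-05
  x2        4.8832      0.3869       12.62      1.516e-05
  x1*x2     2.8175      0.5472       5.149      2.117e-03
  ...
fixed b: 0.0411
a at (0,-1): 4.815 +/- 0.519 [3.545, 6.085] at 95%
DH(60 min): 18.8% band [16.7, 20.4]
```

Reading: halving the protease dose from the center (x₂ = −1) drops the
initial rate from ~9.7 to ~4.8 mM/min, but because the logarithmic curve
saturates, the 60-minute DH only falls to ≈18.8%, with a 95% band of about
±2 DH points inherited from the uncertainty in `a`.

The same workflow is available from the shell (`hydrokin fit | rsm |
predict | validate | simulate | study`); `hydrokin study study.yaml
--report report.txt` runs the full two-level pipeline from a directory of
trace CSVs.

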