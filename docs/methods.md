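# Methods

This note documents the models implemented in `ilextract`, their
assumptions, the default parameters and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
choices that matter.

## Spectrophotometric quantification

Heme and hemoglobin are quantified from the Soret absorption band at
410 nm.  Quantification assumes Beer–Lambert linearity at the analytical
wavelength: `c = A / slope`, with the default slope 1/0.15 ≈ 6.667
absorbance units per (mg/mL) — i.e., 0.15 mg/mL hemoglobin gives an
absorbance of ~1 at 410 nm on the reference instrument.  The molar
absorptivity and path length are never separated; the slope is a single
empirical constant and is user-overridable.

Extraction efficiency is computed on absorbances,
`100·(1 − A_after/A_before)`, which under Beer–Lambert linearity equals
the efficiency on concentrations (asserted by a test).  Values outside
[0, 100] raise instead of being clipped: an after-measurement exceeding
the before-measurement signals a measurement problem, not a negative
efficiency.  Spectra are assumed blank-subtracted upstream; no baseline,
scattering, or multi-component correction is attempted.  Interpolation
between grid points is linear (the analysis only ever uses the 410 nm
gridpoint).

## Extraction kinetics

The aqueous-phase concentration during shaking follows the reversible
first-order rate law

    dC_aq/dt = −k1·C_aq + k2·C_IL,      C_IL = (q − C_aq·V_aq)/V_IL,

with boundary condition `C_aq(0) = q/V_aq`.  Influx into each phase is
proportional to the concentration in the other phase — the standard
assumption for liquid–liquid extraction far from interfacial-area or
diffusion limitation.  The ODE is linear with the closed form

    C_aq(t) = C∞ + (C0 − C∞)·exp(−a·t),
    a = k1 + k2·V_aq/V_IL,   C∞ = (k2·q/V_IL)/a.

At equilibrium `k1·C_aq = k2·C_IL`, so the model reduces to a constant
separation ratio `S = C_IL/C_aq = k1/k2`, which is the bridge to the
partition module.  Rate constants are in 1/min, matching shaking-time
axes of 0–20 min.  The ionic-liquid volume is derived from its mass via
the density 1.12 g/mL (OMIM BF4); overridable.

Fitting is unweighted nonlinear least squares of the closed form (no
error model is assumed for the measurements), with non-negativity bounds
on `(k1, k2)` and, absent a user-supplied start, a multi-start over a
5×5 log-spaced grid (10⁻²–10 per constant) to avoid local minima.
Standard errors come from the Gauss–Newton covariance at the optimum.
Optimizer tolerances are 10⁻¹⁴ so that noiseless data are recovered to
~10⁻⁶ relative.  A flat trace is scale-unidentifiable — any `(k1, k2)`
with `k1/a ≈ 0` fits it — so the fit reports a near-zero equilibrium
depletion with very large standard errors rather than failing.

## Equilibrium partitioning

Two equilibrium models relate the phase concentrations:

- **linear**: `C_IL = S0·C_aq` (constant separation ratio), valid at low
  solute concentration;
- **hyperbolic**: `C_IL = S0·C_aq/(1 + C_aq/K)`, the simplest hyperbola
  in the separation factor that decreases with aqueous concentration and
  saturates (`C_IL → S0·K`), reflecting the limited solubility of
  heme/hemoglobin in the ionic-liquid phase.

The hyperbolic form is an empirical stand-in — no uniform, physically
meaningful isotherm is claimed — and is isolated behind the
`PartitionModel` interface so alternative saturation laws can be added.
Fitting is least squares on the `(C_aq, C_IL)` pairs, not on the ratio,
to avoid noise amplification at small `C_aq`.  Model selection under
`kind="auto"` prefers the hyperbola only when it reduces the residual
sum of squares by more than 20% relative to the linear fit; the
threshold is this package's own convention for what the original
two-regime treatment did by hand.

`predict_depletion` solves the mass balance
`q = C_aq·V_aq + C_IL(C_aq)·V_IL`.  For the hyperbolic model this is a
quadratic with exactly one non-negative root (the root product is
negative); the numerically stable quadratic formula avoids cancellation,
and mass conservation holds to 10⁻¹⁰ relative.  Under the hyperbolic
model the predicted efficiency decreases with initial concentration, as
observed for saturating extractions.

## Competitive ELISA

The dose–response is the four-parameter logistic

    A(c) = A_bot + (A_top − A_bot)/(1 + (c/IC50)^h),

decreasing in concentration.  A strictly "inversely proportional" curve
cannot pass through the 0 ng/mL standard; the 4PL is the standard
competitive-immunoassay model and its flat extremes explain why
determinations far from the midpoint are error-prone.  The inverse is
analytic, `c = IC50·((A_top − A)/(A − A_bot))^(1/h)`, and round-trips to
10⁻⁹ relative; absorbances at or beyond the plateaus raise a range error
naming the violated bound (below-range vs above-range sample).
Calibration needs ≥4 standards (the zero standard anchors `A_top`), and
standards whose absorbance rises with concentration are rejected as
non-competitive.

Replicate statistics follow assay convention: arithmetic mean, sample SD
(n−1 denominator — this, not the population SD, reproduces the reference
table), CV% = 100·SD/mean, and the signed relative error
100·(mean − nominal)/nominal.  Relative error stays signed internally;
rendered reports also expose its magnitude, since published assay tables
sometimes print |RE|.  Rounding for display is half-up at the table's
printed precision and is applied only at render time, never internally.
The reference dataset in `ilextract.datasets` stores the triplicate
back-calculated concentrations per condition; its calibration-standard
absorbances were never published, so sample absorbances cannot be
independently re-inverted and all table checks start from the printed
concentrations.  The published narrative for the 0.1 and 0.2 mg/mL
hemoglobin levels is internally garbled (the text pairs "did not change"
and the 32.27-point improvement ambiguously); this package follows the
table columns and leaves the narrative inconsistency unresolved.

## Free energies

BAR estimates ΔG from forward (A→B) and reverse (B→A) work samples by
solving, in reduced units `u = βw` and with `M = ln(n_F/n_R)`,

    Σ_F 1/(1 + exp(M + u_F − βΔG)) = Σ_R 1/(1 + exp(−M + u_R + βΔG)).

The left side increases and the right side decreases in ΔG, so the root
is unique; it is found by bracket expansion around the midpoint of the
two exponential-averaging (Jarzynski) estimates followed by Brent's
method at ~machine precision.  The uncertainty is the asymptotic
maximum-likelihood variance

    var(βΔG) = [Σ_i 1/(2 + 2·cosh(M + βw_i − βΔG))]⁻¹ − 1/n_F − 1/n_R,

summed over all works in the forward frame.  This estimator mildly
underestimates the sampling spread at moderate dissipation (Monte-Carlo
check: empirical SD 0.026 vs mean reported SE 0.020 kJ/mol at n = 5000,
σ = 2 kJ/mol), which is the known behavior of the asymptotic formula.
When the mean Fermi overlap of the two work distributions falls below
10⁻¹², the variance is meaningless and an overlap error is raised
instead.  `kB = 8.3145×10⁻³ kJ/(mol·K)`, default temperature 298 K.

BAR lies between the forward and reverse Jarzynski estimates whenever
those are statistically resolved (interval wider than 4 SE); when they
nearly coincide, BAR can sit marginally (within 3 SE) outside the
interval, so the property tests assert exactly those two statistical
forms rather than a strict sandwich.

The transfer cycle combines two alchemical decoupling legs:
`ΔG_transfer(water→IL) = ΔG_decouple(water) − ΔG_decouple(IL)`, with
uncertainties added in quadrature.  Negative values mean the solute
prefers the ionic liquid.  Preference classification uses a 2σ
convention by default (IL-preferring below −2σ, water-preferring above
+2σ, indeterminate otherwise): with the reported transfer values, heme
(−127.3 ± 5.1 kJ/mol) and cotinine (+5.0 ± 1.1 kJ/mol) classify at any
reasonable threshold, while hemoglobin (−38.6 ± 15.1 kJ/mol) is
IL-preferring at 2σ but indeterminate at 3σ.  Producing the work samples
themselves (MD, λ-windows, soft-core potentials) is out of scope; this
module is the estimator/cycle layer that normally sits downstream of the
MD engine.

## Synthetic-data generator

`ScenarioConfig` fixes one ground truth per stage; its defaults are the
reference study conditions:

| parameter | default | rationale |
|---|---|---|
| V_aq, IL mass, density | 3 mL, 0.7 g, 1.12 g/mL | reference extraction composition (V_IL = 0.625 mL) |
| c0 = q/V_aq | 0.125 mg/mL | reference kinetic experiment |
| k1, k2 | 0.9489, 0.010646 min⁻¹ | equilibrium depletion 94.89% and 95% relaxation within 5 min (a = 1.0 min⁻¹) |
| S0, K | 89.14, 0.15 mg/mL | S0 = k1/k2 (kinetics↔partition consistency); K places saturation just above the reference concentration range |
| 4PL | A_top 1.2, A_bot 0.05, IC50 25 ng/mL, h 1 | midpoint near the 20 ng/mL smoker/non-smoker cut-off, 0–100 ng/mL range |
| replicate CV | 5% | consistent with the 3–7% CVs of the reference table |
| Hb bias | +32 ng/mL per (mg/mL Hb) | reproduces the +32% relative error at 0.2 mg/mL hemoglobin before extraction |
| work samples | ΔG 10, σ 2 kJ/mol, n 10⁵ | overlapping Gaussians with ~0.8 kT dissipation |

Plates carry standards in duplicate wells (the usual kit protocol) and
samples in triplicate (matching the reference assay).  Hemoglobin
interference is modeled as nonspecific binding that adds
`bias·Hb` ng/mL of apparent cotinine; "after extraction" samples keep
only the residual bias `(1 − efficiency/100)` with the efficiency taken
from the partition truth, so the ELISA arm is coupled to the extraction
arm.  Replicate noise on absorbances is multiplicative lognormal with
unit mean; kinetic noise is additive Gaussian truncated at zero;
isotherm noise is multiplicative lognormal on C_IL.  Work samples are
Crooks-consistent Gaussians (forward N(ΔG + βσ²/2, σ²), reverse
N(−ΔG + βσ²/2, σ²)).

What the generator does **not** emulate: instrument drift and baseline
structure in spectra, plate edge effects and heteroscedasticity beyond a
constant CV, matrix effects other than the single additive hemoglobin
bias, multi-solute competition in the IL phase, and the time course of
the assay itself.  Passing recovery tests therefore demonstrate
estimator correctness under the stated noise model, not robustness to
real-instrument artifacts.

## Problem sizes and numerical choices

Recovery suites use 200 replicates per stage (2% kinetic noise, 3%
isotherm noise, 5% plate CV) and report median absolute relative errors;
medians are robust to the occasional ill-conditioned replicate.  The
closed-form-vs-ODE check uses 100 random parameter sets against DOP853
at rtol 10⁻¹², agreeing to 10⁻⁸ relative.  The BAR ground-truth check
uses 10⁵ samples per direction.  CSV readers parse floats in round-trip
mode and writers emit 17 significant digits, so file round-trips are
bit-exact.  CLI JSON floats are rendered at 6 significant digits; the
run manifest (which carries a timestamp) goes to stderr so stdout is
byte-reproducible.  For this package the library functions and the
`ilextract` console script are the interface; there is no GUI or
instrument driver.

## Known limitations

- The hyperbolic saturation law is empirical; its parameters have no
  thermodynamic interpretation beyond the low-concentration limit S0.
- The 4PL fit at 5% CV with six duplicate standards sits near its
  information limit for IC50 (~10% median error); designs needing tighter
  calibration should add standard replicates or narrow the range.
- The BAR asymptotic SE is slightly anticonservative at moderate
  dissipation (see above).
- Experimental endpoints that require wet-lab or MD inputs (measured
  extraction efficiencies, per-leg decoupling free energies, QM
  complexation energies) are out of scope; they enter only as reference
  inputs to downstream arithmetic.
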