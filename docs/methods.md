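# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `nirglucose`. The package analyzes data from a reflectance
near-infrared (940 nm) blood-glucose sensor read out as voltage frames, and
validates its calibration against invasive reference measurements.

## Forward model of the synthetic generator

The study population the analysis was designed for (101 volunteers, two
sensor sites, three skin tones, reference glucose 80–488 mg/dL) is not
publicly available, so all pipeline stages are exercised on synthetic data
with the statistical structure the analysis assumes.

Reflected intensity follows the Beer–Lambert law for a diffusely scattering
medium:

    R = R0 · exp(−μ_eff · l),
    μ_eff = sqrt(3 γa (γa + γs′)),   γa = 2.303 ε C,   γs′ = γs (1 − a),

where `C` is the chromophore (glucose) concentration in mol/L, converted
from mg/dL by `C = g / (180.156 · 100)` (molar mass of glucose, mg/dL →
g/L → mol/L). The detector voltage for one acquisition is

    V = G_site · m_tone · R0 · exp(−μ_eff l) + DC,

with a per-site gain `G_site`, a skin-tone transmission multiplier
`m_tone`, and the dark-current offset `DC`. Voltage is strictly decreasing
in glucose: higher concentration absorbs more and the reflected signal is
low.

### Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| incident intensity R0 | 1.0 | V-equivalent | scale absorbed into gains |
| path length l | 0.09 | cm | shallow capillary sampling depth; sets a mild (~25 % in log) attenuation span over 80–488 mg/dL |
| molar extinction ε | 30 | L mol⁻¹ cm⁻¹ | weak NIR overtone absorption of glucose |
| scatter coefficient γs | 10 | cm⁻¹ | tissue-like scattering; with a = 0.99, γs′ = 0.1 cm⁻¹ |
| anisotropy a | 0.99 | – | strongly forward-scattering tissue |
| site gains | finger 0.21, wrist 0.19 | V | put noise-free voltages in the 0.13–0.19 V band the wrist sensor reports |
| tone multipliers | dark 0.98, wheatish 0.99, fair 1.00 | – | melanin attenuation at 940 nm is small; ~1 % transmission differences reproduce a constant tone offset at equal glucose |
| dark current | 0.002 | V | detector offset removed by normalization |
| ambient offset | 0.005 (off by default) | V | additive stray-light term, toggleable |
| frame noise SD | 1e-4 | V | low-noise photodiode/amplifier chain with a 16-bit DAQ; 100-frame averaging reduces it another 10× |
| frames per sample | 100 | – | the device's acquisition protocol |

The tone multipliers are deliberately *not* taken from the pilot table's
single-reading spread (~7 % of the voltage), which mixes tone with glucose
and visit-to-visit variation; the generator attributes to tone only a small
constant transmission factor, consistent with the premise that melanin
absorbs weakly at 940 nm.

### Acquisition designs

* `interval` (default): a calibration sweep — for every 5 mg/dL interval of
  the configured range, one volunteer of each skin tone is measured at a
  matched reference value. This scales the study's three-volunteer pilot
  protocol over the full range and is exactly the condition the
  interval-adjustment algorithm assumes ("the variance of the three skin
  tones falling within the same interval"). It yields 83 intervals × 3
  tones × 2 sites = 498 acquisitions at the defaults.
* `random`: a survey design — each volunteer contributes
  `visits_per_volunteer` readings with glucose drawn from a meal-state ×
  diabetic-status mixture, clipped to the configured range.

The cohort reproduces the study marginals exactly at n = 101 (57 M / 44 F;
age groups 20–35: 4, 35–50: 22, 50–65: 61, 65–90: 14; 97 diabetic) and
proportionally otherwise. Covariates (BMI, SpO₂, sleep, stress, wrist hair)
are drawn independently of glucose and tone; they act as nuisance features.

### What the generator does not emulate

Layered skin optics, wavelength-resolved spectra, PPG waveform morphology,
motion artifacts, drift, and any physiological coupling between covariates
and the optical signal. Passing tests therefore demonstrate the internal
consistency of the analysis pipeline under its own assumptions, not
device-level accuracy on real skin.

## Preprocessing branches

Three alternative branches mirror the study's dataset variants; the
framework branch does not additionally apply the normalization.

1. **raw** — the aggregated (frame-mean) voltage as measured.
2. **normalized** — dark-current normalization against the bare-LED value:
   `N = 100 (HV − DC) / (LV − DC)`, defined only for `LV > DC`.
3. **framework** — the interval-based data analytic framework:
   * *Adjustment model.* Records are grouped into inclusive integer
     intervals of 5 mg/dL ([81, 85], [86, 90], …, extended by the same width
     below 81 and above 500 to cover the observed range; non-integer
     references are assigned by floor). Within each interval the voltages
     of all skin tones are pooled and the sample variance
     `X_var = Σ(C_i − μ)² / (n − 1)` is computed. As printed in the source
     material the numerator lacks the square and is identically zero; the
     standard squared-deviation sample variance is the only usable reading.
     `C_i` are member *voltages* (a configurable choice; the narrative
     computes voltage spreads across tones). The correction factor is
     `F = 1/√X_var` and the adjustment factor `A = X_var · F ≡ √X_var`.
     Degenerate intervals (n < 2 or zero variance) carry the identity
     factor A = 1, leaving their data untouched.
   * *Application.* Each record's voltage is multiplied by its interval's
     adjustment factor. Multiplying voltages (not reference levels) is the
     only reading that does not leak labels into the regression targets.
   * *Target integration.* Reference values are converted to mmol/L
     (factor 18.0 — the study's own tables round-trip at 18.0 rather than
     the exact 18.0156; configurable) and every record's target is replaced
     by the mean reference of its interval.

The adjustment model is fitted on the full processed dataset before the
train/test split, matching the study's procedure of building the adjustment
model first and feeding the adjusted dataset to the learners. This is a
deliberate reproduction of the method as described, and it leaks label
information twice: interval membership is defined by the reference value,
and both the adjustment factor and the integrated target are functions of
that membership. The framework's accuracy advantage over the raw branch
(typical held-out r² ≈ 0.992–0.994 vs ≈ 0.985 at the defaults) should be
read in that light; `fit_adjustment_model` accepts any subset, so
training-split-only fitting is available to callers who want a
leakage-free protocol.

## Regression

The ridge core is the in-repo closed form of the penalized least squares
objective `Σ(y_i − Σ x_ik β_k)² + λ Σ β_k²`:

    β = (XᵀX + λI)⁻¹ Xᵀ y

computed on z-scored features (the penalty is scale-sensitive) with an
unpenalized intercept handled by centering `y`. λ defaults to 1.0 (the
source states no value); λ = 0 reduces to ordinary least squares and a
singular system at λ = 0 raises with advice to use λ > 0. Constant columns
get unit scale (they carry no signal and receive ~0 coefficient).

The model roster (LR, PR degree 2, Lasso CV, RF, k-NN, k-NN bagging,
k-NN boosting, DT, DT bagging, DT boosting, NN) delegates to scikit-learn
with pinned seeds; they are comparators. The comparison harness uses a
shuffled 80/20 split, seed 42 by default; the best model per branch
maximizes r², ties breaking toward lower MAE.

Ten inputs enter the feature matrix: the branch's voltage plus nine
covariates, with the three-level meal state one-hot encoded and binary
fields as single 0/1 columns (12 numeric columns in total, in a fixed
documented order).

## Validation statistics

* **Metrics.** MAE, MSE, and `r² = 1 − SS_res/SS_tot` with `SS_tot` about
  the mean of the *reference* series (the standard convention; the source's
  symbol for that mean is a prediction symbol but its definition sums
  references).
* **Error table.** Signed error `pred − ref` in mg/dL alongside both unit
  systems; values are kept at full precision and rounded only at rendering.
* **Bland–Altman.** Bias = mean of differences, SD with n−1 divisor,
  LOA = bias ± 1.96 SD, and the share of differences inside the LOA
  (≈95 % for Gaussian errors). Computed in mg/dL by default, configurable.
* **Clarke Error Grid.** The canonical 1987 piecewise boundaries, applied
  in the order A, E, C, D, else B so boundary ties resolve deterministically:
  A if (ref ≤ 70 and pred ≤ 70) or |pred − ref| ≤ 0.2 ref; E if
  (ref ≥ 180, pred ≤ 70) or (ref ≤ 70, pred ≥ 180); C if
  (70 ≤ ref ≤ 290, pred ≥ ref + 110) or (130 ≤ ref ≤ 180,
  pred ≤ 1.4 ref − 182); D if (ref ≥ 240, 70 ≤ pred ≤ 180) or
  (ref ≤ 175/3, 70 ≤ pred ≤ 180) or (175/3 ≤ ref ≤ 70, pred ≥ 1.2 ref).
* **Paired t-test.** `t = mean(d) / (sd(d)/√n)`, df = n − 1, p and the
  critical value from the t distribution (scipy). Two-tailed at α = 0.05 by
  default; the one-tailed critical value at df = 100 is 1.660. Zero-variance
  differences with nonzero mean are reported as a rejection with an
  infinite-t flag. The computed p-value and the t-vs-critical decision are
  reported separately and never reconciled for each other.

## Problem sizes and numerical choices

The default campaign (498 acquisitions) runs the full twelve-model,
three-branch, two-site comparison in ~10 s on one CPU; tests use the same
or smaller sizes (property simulations use 10⁵ draws). Variance and r² are
validated against independent two-pass and scikit-learn oracles to 1e-12;
the ridge closed form against a gradient-descent minimizer of the objective
to 1e-6. Glucose unit conversion is bijective to 1e-12 relative error.

## Known limitations

* The interval adjustment and target integration both condition on the
  reference value; the framework branch's metrics are calibration-set
  diagnostics, not prospective accuracy (see above).
* The tissue optics are deliberately minimal; no claim is made about
  absolute voltages on real skin.
* The pilot table's printed interval variance (0.000375) is not recoverable
  from its printed voltages under any variance convention (pooled voltages
  give 1.1505e-4); the package computes the chain from whichever variance it
  is given and does not guess the original arithmetic.
* mmol/mg-dL column pairs in the study's validation tables are not mutually
  consistent to two decimals under any single conversion factor; the
  package keeps full precision internally and treats 18.0 as the canonical
  factor.
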