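# Methods

## Viability normalization

A resazurin (alamarBlue) readout quantifies metabolic activity as the
absorbance difference A570 − A600. For each treated well the background
(medium + dye, no cells) is removed at both wavelengths and the result is
scaled by the mean background-corrected signal of the solvent-control
wells on the same plate:

    viability = [(A570_t − A570_b) − (A600_t − A600_b)]
                / mean_controls[(A570_c − A570_b) − (A600_c − A600_b)] × 100.

Choices and their reasons:

* **Blank averaging.** The blank terms are the per-plate means over all
  blank wells at each wavelength, symmetric with the control averaging;
  with a single blank well this reduces to simple subtraction. Averaging
  is more robust to a single misread blank.
* **Per-plate matching.** Blanks and controls are never pooled across
  plates, because each plate carries its own solvent control and dye
  batch. A plate without both well types is rejected up front.
* **No clipping.** Individual-well viabilities may be negative or exceed
  100; they are retained so that downstream statistics (curve fits,
  t-tests) see unbiased noise. Display layers may clip.
* **Replicates.** Each treated well is one replicate (5–7 wells per
  condition in the emulated design).

Two identities follow from the formula and are enforced by tests: adding
a constant to every reading of a plate, or scaling all readings by a
positive factor, leaves viabilities unchanged; and the control wells
average to exactly 100 by construction.

## Four-parameter logistic fitting

Viability against dose d (mM) is modelled as

    V(d) = bottom + (top − bottom) / (1 + (d / IC50)^hill),

with hill > 0 so that response decreases with dose, and with V(IC50) =
(top + bottom)/2 exactly (midpoint parameterization). At d = 0 the power
term is defined as 0, so V(0) = top; zero-dose control points therefore
anchor the upper asymptote without any log transform of doses.

* **Optimization.** Trust-region least squares over replicate-level
  points (replicates are not dose-averaged; this preserves the residual
  degrees of freedom). The midpoint is fitted as log10(IC50). Soft sanity
  bounds: bottom ∈ [−10, 50], top ∈ [50, 150], hill ∈ [0.05, 10],
  log10(IC50) within the dose range widened by a factor 50 each way.
  Either asymptote can be fixed (e.g. bottom = 0, top = 100).
* **Initialization.** top/bottom from the extreme dose-averaged
  viabilities, IC50 from the dose whose mean response is nearest the
  half-way level, hill = 1; three seeded jittered restarts are tried only
  if the first start fails, and the best solution is kept. A fit that
  stalls is returned with `converged=False` rather than raising.
* **Identifiability guards.** At least 5 distinct non-zero doses are
  required; all-identical responses or dose vectors without positive
  entries are rejected as degenerate.
* **Goodness of fit.** R² = 1 − SSres/SStot on the replicate-level
  points.

### IC50 confidence intervals

* `asymptotic_log` (default): a Wald interval on the log10(IC50)
  coordinate, using the curvature of the residual surface
  (covariance (JᵀJ)⁻¹·s² from the final Jacobian) and a t quantile at
  N − p degrees of freedom (p = 4 free parameters by default). The
  interval is exponentiated back, so it is asymmetric in IC50 and
  collapses to a point for noise-free data. If the curvature is not
  invertible the code falls back to the bootstrap with a warning.
* `bootstrap`: replicates are resampled with replacement **within each
  dose**, the curve refit (warm-started at the full-data solution), and
  the 2.5/97.5 percentiles of the refitted IC50s taken; seeded and
  reproducible bit for bit. 999 resamples by default.

In a seeded Monte-Carlo study at the default scenario (8 log-spaced doses
spanning 0.1×–4× the true IC50, 6 replicates, 5 pp Gaussian noise, 200
seeds) the acceptance suite verifies median relative IC50 error below 5%
and asymptotic-CI coverage between 90% and 99%.

## Mixture reference models

Let V_i be the measured single-exposure viability (percent) of component
i at the concentration it has in the mixture.

* **Effect summation** (the model used for the bundled study tables,
  where it is labelled "Concentration Addition"): inhibitions add,
  `V_mix = 100 − Σ_i (100 − V_i)`. The package keeps the name
  `effect_summation` because the equation sums effects, not
  concentrations, and records on every report row which model produced
  the prediction; true Loewe concentration addition is provided
  separately. Predictions below 0 are possible and are returned
  unclamped with a flag — clamping before the t-test would bias it.
* **Bliss independence**: survival fractions multiply,
  `V_mix = 100 · Π_i V_i/100`; inputs outside [0, 100] are clipped with
  a warning. For a binary mixture with inhibitions I₁, I₂ (pp), Bliss
  and summation differ by exactly I₁·I₂/100 pp, so they agree to first
  order for small inhibitions; the gap grows with the number of
  component pairs (Σ over pairs of products, minus higher-order terms),
  which the tests assert exactly.
* **Loewe concentration addition**: the predicted effect level y solves
  `Σ_i c_i / EC_{y,i} = 1`, with EC_{y,i} the 4PL inverse
  `IC50_i · ((top_i − y)/(y − bottom_i))^(1/hill_i)`. The root is
  bracketed inside the shared response range (max bottom, min top) and
  found by Brent's method to a condition tolerance of 1e−8. The
  sham-combination axiom (a compound combined with itself at any dose
  split predicts its own curve) holds identically and is property-tested.

## Interaction classification

Observed replicate viabilities are compared to the model prediction with
a two-sided one-sample t-test on the per-replicate differences, treating
the prediction as a known constant (no error propagated from the
single-agent measurements — an optional refinement deliberately left
out, since the emulated protocol computes the prediction once from
measured singles). At α = 0.05:

* observed mean significantly **below** the prediction → *synergistic*
  (stronger-than-additive loss of viability),
* significantly **above** → *antagonistic*,
* otherwise → *additive*.

No multiple-testing correction is applied across mixtures; raw p-values
are reported. Zero-variance replicates are handled as an exact-equality
check (additive if the mean difference is 0, otherwise an indeterminate-
variance error). Calibration is verified by simulation: truly additive
mixtures at the study design (n = 6, σ = 5 pp, 1000 seeds) produce
non-additive calls at 3–7%, and a twofold-inhibition synergy is detected
in > 95% of runs.

## Consistency reconstruction of published predictions

Under effect summation every binary prediction equals
100 − (I_i + I_j), so a set of pairwise predictions defines the linear
system I_i + I_j = 100 − predicted_ij. With six pairs over four
compounds the system is overdetermined (6 equations, rank 4); its
least-squares solution yields the implied single-agent inhibitions and a
residual norm that measures internal consistency. Applied to the bundled
24 h table the residual is ~6e−4 and re-summing the implied inhibitions
reproduces the four published ternary predictions to within 0.01 pp; the
implied quaternary (≈ 42.96) however disagrees with the published 54.000,
and the 48 h block as a whole is inconsistent (residual ≈ 1.06),
consistent with single-exposure measurements taken in separate batches.
The package reports these residuals; it does not guess which measurement
set produced which published value.

## Synthetic generator

The generator emulates the study design so that every stage can be
tested against known truth:

* **Curves.** Four compounds with bottom = 0, top = 100, the bundled
  published IC50s as true midpoints, and per-compound hill slopes between
  1.8 and 2.6 — steep sigmoids typical of acute cytotoxicity assays,
  chosen once as the default scenario.
* **Design.** 8 log-spaced doses from 0.1× to 4× each IC50, 6 replicate
  wells (the emulated protocol used 5–7); fixed-ratio mixtures with each
  component at 0.5 × IC50, in all 6 binary, 4 ternary and 1 quaternary
  combinations.
* **Noise.** Gaussian on viability (default σ = 5 pp, matching the
  replicate spread implied by the published CIs). In `absorbance_mode`
  the noise is instead placed on simulated A570/A600 readings of a
  96-well plate (blanks and controls included) and viability noise
  emerges through the normalization formula; treated-well signals are
  scaled so the noise-free plate reproduces the true viabilities
  exactly, which makes plate round-trip tests exact to 1e−9.
* **Mixture truth.** Per-mixture interaction modes: summed inhibitions
  scaled by a synergy factor (1 = additive, 2 = strong synergy, 0.5 =
  antagonism) or a Bliss survival product.
* **Seeds.** Explicit arguments everywhere (numpy `default_rng`); the
  same seed reproduces a dataset bit for bit. A JSON manifest records
  truth and seed for every generated dataset.

What the generator does **not** emulate: plate-position (edge) effects,
heteroscedastic or time-dependent noise, pipetting serial-dilution error
correlation, and compound interactions beyond the three stated modes.
Passing tests therefore demonstrate correctness of the computations and
calibration of the statistics under a well-behaved error model, not
robustness to real-world plate artifacts.

## Pipeline and reports

`run_single_analysis` fits one curve per compound × exposure time and
emits the IC50 report (`compound, exposure_h, ic50_mM, ci_low_mM,
ci_high_mM, r2, converged, n_points`); compounds whose fit fails are
listed in a failures section and the run continues.
`run_mixture_analysis` predicts each mixture (measured singles matched on
compound and concentration by default; curve-interpolated V_i behind a
flag, and always for Loewe), classifies it, and emits the interaction
report (`exposure_h, mixture, observed_pct, predicted_pct, interaction,
p_value, model`); when at least six binary predictions are present it
appends the consistency reconstruction. Reports are written with 3
decimals (display parity with the published tables); in-memory frames
keep full precision. Runs are deterministic given the config seed, and
logs record package version, config hash and seed.

## Known limitations

* The asymptotic CI is a local (Wald) approximation; for very shallow
  curves or few doses the bootstrap is the safer choice.
* Effect summation is used as the study's additivity reference for
  fidelity to the emulated protocol, although it is not a
  thermodynamically consistent additivity model (it can predict negative
  viability); Loewe addition is the principled alternative provided.
* The t-test ignores uncertainty in the predicted value; when the
  single-agent means are themselves noisy, the test is anti-conservative
  in proportion to that extra variance.
* Five-parameter logistic curves, response-surface synergy maps
  (ZIP/HSA), isobolograms and ratio optimization are out of scope.
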