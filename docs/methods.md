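# Methods

## Scope and data model

The pipeline analyses active-dynamic-thermography scans of skin-accessible
masses. A scan is 60 s of surface temperature at 10 Hz for every pixel of
two clinician-marked 5×5 grids, each covering 1.5×1.5 mm²: *site* (over the
mass) and *control* (adjacent normal tissue). Heating runs for the first
10 s and is calibrated to raise the surface by 7 °C; the remaining 50 s are
free relaxation. Each mass carries a pathology label (benign/malignant), a
dog identifier (dogs contribute 1–3 masses), and optionally a tumor-type
name. No public recordings of this kind exist, so the simulator is a
first-class, tested component: every downstream stage is exercised against
cohorts whose generating truth is known.

## Lumped bioheat model

Tissue heat transport is commonly written as the Pennes balance
(conduction + perfusion exchange with arterial blood + metabolic heat).
Only per-pixel surface-temperature curves are observed here, so the model
is reduced to one compartment per pixel:

    dT/dt = −λ_p (T − T_eq) + g·u(t),   T(0) = T_eq,

* λ_p = (ω_b ρ_b c_b)/(ρ c) + κ_geom — the perfusion rate constant of the
  Pennes equation plus a lumped conduction-loss term κ_geom (default
  0.02 s⁻¹) that keeps relaxation finite when perfusion is small;
* T_eq — resting surface temperature: control baseline (default 34.0 °C,
  a typical clipped-skin value) plus the region's elevation δ_base;
* g — constant volumetric drive during the heating window, solved in
  closed form so that T(10 s) − T(0) equals the protocol's 7 °C exactly.
  Heating is *not* modelled radiatively: only the trajectory matters
  downstream, and the device calibrates its stimulus per scan, which is
  why g is recomputed whenever λ_p changes.

The closed-form solution is piecewise exponential; an RK4 integrator
(`simulate_signal_ode`, with sub-steps split at the heating switch-off so
the discontinuous drive does not degrade the integration order) exists
solely as a cross-check and agrees to <1e-12 °C.

Default tissue parameters (k = 0.5 W m⁻¹K⁻¹, ρ = 1050 kg m⁻³,
c = 3600 J kg⁻¹K⁻¹, ω_b = 5e-4 s⁻¹, ρ_b = 1060, c_b = 3800, T_a = 38.5 °C)
are textbook soft-tissue values; they give λ_p ≈ 0.0205 s⁻¹, i.e. roughly
one relaxation time constant within the recorded 50 s tail.

## Synthetic cohorts

Cohort structure mirrors the pilot study: 45 dogs, 24/18/3 with one/two/
three masses (69 total), 27 malignant. Counts and labels are drawn
(categorical / Bernoulli) by default; `exact_counts` / `exact_prevalence`
switch to quota assignment so every replicate matches that composition
exactly — the study-shaped factory `reference_cohort_config()` sets both.

Hierarchy of effects, all configurable:

| effect | default | applied to |
|---|---|---|
| malignant resting elevation δ_base | N(1.0, 0.3) °C, truncated ≥0 | site T_eq |
| malignant rate ratio | 1.3, log-sd 0.1 | site λ_p |
| dog level | log-sd 0.10 on λ_p; sd 0.3 °C on baseline | both grids |
| mass level | log-sd 0.05 on λ_p; sd 0.05 °C on baseline | site grid |
| pixel noise | sd 0.05 °C i.i.d. per sample | every sample |

Dog- and mass-level effects perturb the lumped (λ_p, T_eq) directly rather
than the underlying physiological parameters — the lumped pair is the
simulator's working state, and any λ_p perturbation is followed by drive
recalibration. All pixels of a grid share their grid's draw; only
measurement noise is pixel-independent. Randomness is split counter-style
from one root seed (numpy `SeedSequence` keyed by dog/mass/stream), so a
mass's content does not depend on generation order and serialized cohorts
are byte-reproducible.

What the generator deliberately does **not** emulate: radiometric camera
effects, emissivity and pigmentation optics, 3-D anatomy (notably lymph
nodes, a known failure mode of the real device), motion, and spatial
correlation of noise across pixels. Passing tests therefore demonstrate
the pipeline's statistical machinery, not clinical performance.

## Features

Per pixel, 44 features by default:

* **Fourier coefficients** (2 windows × (2H+1) values, H = 8): the window's
  duration is taken as one fundamental period; a linear trend is removed
  first (relaxation curves are aperiodic) while preserving the mean, so a0
  remains the window's average temperature. Detrending is switchable.
  Windows: relaxation-only and full recording.
* **Relaxation decay fit** (3): least squares of T_eq + A·e^(−λt) on the
  post-heating segment.
* **Lumped bioheat fit** (3): least squares of the piecewise
  heating+relaxation solution for (λ_p, g, T_eq) on the full curve.
* **Summaries** (4): baseline (the t = 0 sample — a window mean would be
  contaminated by the heating ramp), peak, rise, time to half relaxation.

Both fits exploit that their model is linear in two parameters once λ is
fixed: the profiled residual sum of squares is scanned on a 40-point log
grid over λ ∈ [1e-4, 10] s⁻¹ (seeded additionally with a log-linear
regression estimate), then refined by bounded scalar minimization
(xatol 1e-12). This is exact to optimizer tolerance on noiseless
model-class data, immune to local minima, and fast enough to run
per pixel at cohort scale. A flat segment leaves λ unidentifiable; the
decay fit then flags `converged=False` instead of raising.

**Control integration** replaces every site value by (site − mean over the
mass's 25 control pixels) per feature, then drops control rows. Subtraction
(not ratio; ratio is available by config) cancels additive patient/ambient
offsets exactly — verified as an equivariance property test. **Normalization**
is a per-feature z-score with sample (n−1) s.d.; statistics are always
computed on training rows only and applied to held-out rows, never refit on
them. Zero-variance features are zeroed with a warning. Feature extraction
contains no randomness.

## Classification and validation

Feature selection is filter-style: absolute standardized mean difference
between classes computed on *mass-level* feature means (25 pixels of one
mass are one biological unit, not 25 observations), ties broken
lexicographically; top k = 4 by default. The classifier is a linear-kernel
SVM (C = 1) on pixel rows — with 4 features and ~1,700 rows a margin
classifier is appropriate and deterministic.

Grouped leave-one-out CV runs one fold per mass: the held-out mass's 25
pixels are the test set; z-scoring statistics, the feature ranking and the
SVM are all refit on the training masses only. Because the standardized
mean difference is invariant to per-feature affine rescaling, the ranking
is computed on control-integrated values directly and only the selected
columns are z-scored — identical output, far less per-fold work. A fold
whose training masses collapse to one class predicts that class and logs a
warning. Pixel votes aggregate to a mass call: high-risk iff the malignant
fraction ≥ τ (default 0.5), with exact ties going high-risk — the protocol
prefers a false alarm over a missed malignancy. A fixed-selection mode
(single ranking on the full table) mirrors a published final feature set;
the per-fold refit is the leakage-free default.

## Metrics

Accuracy, sensitivity, specificity, PPV and NPV from the 2×2 matrix with
malignant/high-risk as the positive class. Integer percents round half-up
(89.86 → 90). Zero-denominator metrics are reported as null with a flag,
never as silent zeros. The packaged study tables (per-tumor-type diagnosis
modality and classifier calls for the 69-mass pilot cohort) are
checksum-validated at load; the headline 90/93/88/83/95% are a
deterministic function of the classification table.

## Problem sizes and numerical choices

* Sampling rate 10 Hz (600 samples/scan) — the camera's true rate is not
  public; configurable.
* Power study: 20 study-shaped cohorts per arm (signal at default effect
  sizes, null with all effect sizes zero), chosen as the smallest replicate
  count giving stable Monte-Carlo means for the accuracy comparison.
* λ bounds [1e-4, 10] s⁻¹ span relaxation times from ~0.1 s to ~3 h —
  far beyond anything the protocol can produce, so the bounds never bind
  for realistic data.
* Degenerate inputs: constant signals (unidentifiable decay) flag rather
  than fail; empty relaxation segments, non-finite temperatures, single-
  class training sets and unwritable outputs raise with explicit messages.

## Known limitations

The feature inventory is a configurable family of the three stated kinds
plus summaries (44 by default), not a reconstruction of any proprietary
~1,000-feature set; the classifier trains on 4 features regardless. The
simulator's effect sizes are plausibility-chosen knobs, not estimates from
clinical data, so synthetic accuracies characterize the pipeline under its
own assumptions only. Pixel-to-mass aggregation is vote-based; score-based
aggregation would need calibrated decision values the model does not
currently expose.
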