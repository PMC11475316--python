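# Methods

## Scope and data model

The package analyzes two acquisition products of a multimodal OCT
instrument operating at a 1.3 µm center wavelength with 256 depth pixels
over ~1.7 mm in air and 512 lateral pixels over 2.4 mm: a two-channel
(co/cross polarization) intensity B-scan, and an ordered series of
complex phase-sensitive B-scans acquired under stepwise uniaxial
compression with a pre-calibrated, linearly elastic silicone layer on
the sample surface. Tissue masks are inputs, not outputs: boundary
*detection* beyond the single-interface localization helper is out of
scope.

Depth is converted from air to tissue with a refractive index
`n_tissue` (default 1.4, typical soft tissue; configurable because
instrument scan depths are specified in air and the conversion affects
the mm⁻¹ scale of every attenuation value).

## Synthetic phantoms

The phantom module is the package's ground-truth source.

**Intensity stacks.** Per channel and layer, the noiseless ensemble-mean
intensity follows Beer–Lambert decay in tissue depth,
`I(z) ∝ sens(z)·exp(−2∫μ dz)`, discretized so pixel *i* of a uniform
column carries exactly `exp(−2μΔi)`. Speckle is fully developed: each
pixel is the squared magnitude of an independent circular complex
Gaussian (unit mean, unit contrast, exponential distribution). There is
no lateral point-spread correlation — the simplest model sufficient for
estimator testing; correlated-PSF speckle is a known omission, so
passing tests bound estimator behavior under *independent* speckle only.
Additive noise is exponential with mean `noise_floor` (default 1e-3 of
the surface signal, ≈ −30 dB); the sensitivity roll-off is flat by
default with an optional exponential decay to exercise the compensation
path. The deepest named layer extends to the bottom of the scan.

**Compression series.** Frame *m* is the *same* base speckle field
phase-modulated by `exp(−i·4π·n·u_m/λ)`, where `u_m(z)` is the path
shortening between probe and depth z accumulated from per-layer strain
under stress σ_m. The sign convention is the common-path one:
compression shortens the optical path, phase decreases, and compressive
strain is reported positive. No lateral/axial speckle motion is
simulated (valid for the small per-step strains the generator enforces;
real acquisitions add decorrelation this phantom does not model).
Stress–strain laws are linear (ε = σ/E) or exponential,
σ(ε) = (E∞/k)(e^{kε}−1), whose tangent modulus grows linearly with
stress (E(σ) = E∞ + kσ) and whose inverse is closed-form. The generator
rejects any load program whose per-step strain increment would move the
interframe phase across the processing lag beyond π (unwrap-free limit:
Δε < λ/(4·q·pitch_air), ≈ 1.2% per step at q = 4).

## Depth-resolved attenuation

The estimator is the single-scattering depth-resolved ratio

    μ̂[i] = I[i] / (2Δ · Σ_{j>i} I[j]),   Δ = pitch_air / n_tissue.

On an infinite noiseless exponential column this equals
`(e^{2μΔ}−1)/(2Δ)` — μ with a first-order discretization bias of
μΔ (≈ 1–3% at this instrument's pitch), which the package reports as-is.

Three practical choices, each configurable:

* **Noise/sensitivity compensation** (`compensate_signal`): subtract the
  additive floor (explicit value, or "auto" = per-column median of the
  deepest 5% of pixels), clip at zero, divide by the per-depth gain.
  Clipping keeps tail sums nonnegative but leaves a small positive
  residual where the signal falls near the floor; this residual is the
  dominant error source for strongly attenuating, deeply imaged media
  (≈ −4% on map medians at μ ≈ 5.4 mm⁻¹ with a −30 dB floor).
* **Tail extension** (default `tail="extend"`): the in-scan tail sum is
  augmented with the analytic geometric remainder beyond the deepest
  pixel, using a decay rate fitted to the deepest still-signal-bearing
  stretch of the lateral-mean log profile. Without it the truncated sum
  biases μ̂ upward by `1/(1−e^{−2μΔm})` (up to +14% at mid-depth for the
  weakest clinically relevant attenuation, ~1.7 mm⁻¹, which does not
  decay out within the scan); with it the estimator is exact on
  noiseless exponentials at every pixel, and the correction vanishes
  when decay completes in-scan.
* **Speckle averaging** (default lateral-only boxcar, 21 px ≈ 0.1 mm):
  the per-pixel ratio of exponentially distributed intensities has a
  median of ln 2 ≈ 0.69 of its mean, so raw per-pixel medians are
  uninterpretable; averaging ~21 independent speckles moves the map
  median to within ~2% of μ. The axial window stays 1 px so layer
  steps remain sharp. `smooth=None` gives the raw estimator.

A validity guard marks pixels whose (extended) tail energy falls below
a fraction (default 1%) of the column total — bounding the usable
optical depth at ~ln(100)/2 ≈ 2.3 round-trip extinction lengths — and
the deepest pixel is always invalid. Invalid pixels are NaN in the map
and excluded by the mask, never zeroed.

**Layer boundaries.** Near an interface the ratio estimator smoothly
approaches the *deeper* layer's value over one extinction length
1/(2μ₁), because the tail sum integrates what lies below. Consequences
adopted as protocol: per-layer statistics are computed over layer
interiors (excluding one extinction length above an interface), and
`locate_layer_boundary` finds the interface as the deep edge of the
gradient peak of the lateral-mean profile (the gradient grows
monotonically toward the interface and drops to zero past it; the deep
edge undoes the leftward smear of profile smoothing). At the default
analysis conditions (μ 4 over 6 mm⁻¹, 2048 A-scans) localization is
accurate to ≤3 px.

## Compression elastography

Per frame pair, the interframe phasor `b = f_{m+1}·conj(f_m)` carries
the phase change; the vector method forms lagged products
`c(z) = b(z+q)·conj(b(z))` (lag q = 4 px), averages them *as complex
numbers* over an 8×8 window, and reads strain from the argument:

    ε̂ = −arg⟨c⟩ · λ / (4π · q · pitch_air)

(the tissue index cancels between the phase term and the tissue-depth
pitch). Averaging before the argument is what avoids phase unwrapping;
pixels whose averaged argument approaches ±π (98% by default) are
flagged, and if more than 1% of checked pixels are flagged the
transition errors out with advice to reduce the load step. Quality is
`|⟨c⟩|/⟨|c|⟩` ∈ [0, 1]: exactly 1 for noiseless data, decreasing with
complex noise; it propagates through accumulation as the running
minimum. The default lag trades strain sensitivity (larger q amplifies
phase per unit strain) against wrap risk; both lag and window are
parameters.

Cumulative strain is the running sum of interframe strains (small-strain
additivity). Applied stress per frame is E_ref times the cumulative
strain averaged over the interior of the silicone rows (8-px margins
against window/lag cross-talk at the interfaces); stress is taken
depth-uniform in the column under the uniaxial-loading contract, and a
nonmonotone stress sequence under monotone loading warns. The silicone
modulus (default 100 kPa) and the number of load steps are free
parameters — the defaults (8 increments to 2 kPa) put five stress
samples inside the tangent window.

Stiffness is the tangent Young's modulus at 1 kPa applied stress:
the least-squares slope of σ on ε over the curve points with σ within
±0.5 kPa of the operating point (windowed regression rather than a
two-point difference, for noise robustness). A curve that never reaches
1.5 kPa raises "insufficient compression range". The per-pixel map
variant runs the same regression vectorized over pixels; positivity and
frame-validity define its mask.

## ROI statistics

Measurement regions are axis-aligned, non-overlapping (to avoid double
counting pixels in pooled statistics), fully inside the tissue mask,
placed uniformly at random; "10 × 10 speckles" is read as 10 × 10 image
pixels. Region means ignore invalid pixels. Descriptives are
`Me [Q1; Q3]` with linear-interpolation quartiles (one convention,
pinned for reproducibility); attenuation formats with two decimals,
stiffness as integers.

The Mann–Whitney U test is exact by full enumeration of labelings when
both groups have ≤8 values (a permutation test, hence valid under
ties, with the two-sided p defined by deviation of U from its null mean
n₁n₂/2), and otherwise uses the normal approximation with tie and
continuity correction (scipy). The Bonferroni family is all class pairs
within one modality — the family is a convention, documented rather
than inferred. Region means from the same sample are pooled as
independent observations; patient-level clustering is deliberately not
modeled, so reported p-values are anti-conservative in the presence of
strong within-sample correlation.

## Diagnostics

ROC curves sweep every distinct observed value as a candidate threshold
(boundary value counts as a positive call); AUC is the trapezoidal
integral of the sweep, which equals P(pos ranked above neg) with ties
counted half. Threshold selection is the Youden index (max TPR − FPR)
by default, ties broken toward higher specificity; a
closest-to-(0, 1)-corner policy is provided. The cancer-vs-non-tumorous
contrast places EIN among the negatives (hyperplasia), configurable
because it materially affects specificity.

Synthetic cohorts draw each class/modality from a log-normal matched to
the published `Me [Q1; Q3]`: median exactly, spread via
σ = (ln Q3 − ln Q1)/(2·z₀.₇₅). The published quartiles are not exactly
log-symmetric, so individual quartiles are matched in interquartile
log-width rather than pointwise — adequate for ordering and threshold
behavior, not a distributional claim.

## Pipeline, determinism, problem sizes

`run_pipeline` chains phantom generation → compensation → attenuation
maps → compression elastography → ROI sampling → descriptives →
comparison matrix → ROC per contrast, writing CSV/JSON/PNG outputs plus
a provenance record (config hash, version, seed). Per-sample phantom
parameters are drawn from the class log-normals so within-class spread
exists; sampled tangent moduli are clipped to [15, 700] kPa and the
load program adapts its step count so the softest layer stays inside
the wrap limit. All randomness flows from the single config seed
through `numpy.random.SeedSequence`; identical configs produce
byte-identical CSV/JSON outputs.

Default problem sizes (512 A-scans × 256 px maps; 64–128-px-wide
compression phantoms with 9 frames; cohorts of 10 regions × 1–2 samples
per class; 200 measurements per ROC side) were chosen so every
estimator operates well inside its asymptotic regime while a full run
completes in seconds; all are configurable upward.

## Known limitations

* Independent-pixel speckle and pure phase modulation under compression:
  no PSF correlation, no interframe decorrelation, no birefringence
  model for the cross channel (it is an independent attenuation profile).
* Subtract-then-clip noise compensation leaves a positive residual in
  noise-dominated tails (few-percent negative bias on medians of
  strongly attenuating media).
* Single-scattering attenuation model; no confocal-function or
  multiple-scattering corrections.
* Tangent modulus at a single stress level; no nonlinearity mapping
  across stress levels, no 3D elastography, no probe contact mechanics.
* Pooled-region statistics without patient-level random effects.
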