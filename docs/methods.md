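# Methods

This note documents the models, numerical choices and known limits of
`liverfcm`. Formulas use TE in milliseconds, R2\* in s⁻¹ and LIC in mg iron
per g dry liver tissue.

## Signal model and fitting

Magnitude signal in iron-loaded liver is modelled as
S(TE) = S0·exp(−TE·R2\*/1000) + C. The constant offset C represents the
magnitude-image noise floor, which is why no late-echo truncation is
applied even for fast decays. Fitting is bounded trust-region nonlinear
least squares (`scipy.optimize.least_squares`) with an analytic Jacobian,
tolerances 1e-8 and at most 500 function evaluations, initialised from the
data: S0 = max − min, C = min, and R2\* from a log-linear fit of the first
half of the echo train. Both R2\* ≥ 0 and C ≥ 0 are enforced. The C ≥ 0
bound matters: for slow decays (blood, R2\* ≈ 30 s⁻¹ over a 16 ms train)
the model is nearly linear in TE and (S0, C) become collinear, so an
unbounded fit drifts along the S0 ↑ / C ↓ valley without converging; the
physical non-negativity of the noise-floor offset removes that direction.
A pixel is marked invalid when its signal carries no decay information
(all samples equal) or the optimizer fails; invalid pixels are excluded
from every downstream statistic (median/IQR included) and, in 2D
clustering, from the feature matrix.

Noiseless round trips over R2\* ∈ [20, 1000] s⁻¹ recover parameters to
≪ 0.1 %; the test suite asserts 0.5 % per pixel through the full phantom →
fit path.

## Calibration and grading

LIC = slope·R2\* + intercept with the biopsy-calibrated defaults
slope = 0.0254 mg·g⁻¹·s, intercept = 0.202 mg/g dw. The coefficients are a
configurable convention — every report echoes the pair actually used.
Grading uses left-closed intervals (< 3 normal, [3, 7) mild, [7, 15)
moderate, ≥ 15 severe) so that boundary values classify deterministically.

## Fuzzy c-means

Standard Bezdek alternating optimisation with C = 2, m = 2 (configurable
but only m = 2 is exercised): memberships from inverse squared Euclidean
distances with exponent 2/(m−1), centroids as uᵐ-weighted means.
Numerical choices:

* **Features** are min-max normalised to [0, 1] per feature over the ROI,
  so intensity and LIC carry equal weight in the 2D distance. A constant
  feature is a degenerate-feature error.
* **Initialisation** is deterministic — centroids at the 10th and 90th
  percentile of each feature — so a run is exactly reproducible without a
  RNG.
* **Convergence**: maximum centroid displacement < 1e-6, at most 300
  iterations; memberships are recomputed once from the final centroids so
  the returned (u, v) pair is self-consistent.
* **Zero distance**: a point coinciding with a centroid receives crisp
  membership there.
* **Vessel identification**: in 2D mode the vessel cluster is the one with
  the lower LIC centroid (blood carries little iron); in 1D mode the
  brighter one (blood outlasts iron-loaded parenchyma). Equal centroids
  raise a degenerate-clustering error.
* **Defuzzification**: pixel → vessel iff its vessel membership ≥ u₀, ties
  to vessel, applied uniformly for u₀ ∈ [0, 0.98]; u₀ = 0 labels the whole
  ROI vessel. ROI pixels excluded from clustering (invalid LIC) default to
  parenchyma so vessel ∪ parenchyma always partitions the ROI.

## Selection schemes

The OP scheme enumerates every (TE, u₀) pair — 20 × 50 = 1000 candidates
per mode by default — scores each by D_TSA against the reference and keeps
the minimum; ties break toward lower TE, then lower u₀, by scanning in
that order with strict improvement. Degenerate TEs contribute unscored
rows (so the enumeration count is auditable) and cannot win. OP without a
reference is refused: it is defined only relative to manual segmentation.
MIX takes the component with the lower D_TSA (tie → 1D).

The SA scheme estimates per-echo noise SD from the four 8×8 corner patches
of each echo image (assumed air background; a user-supplied per-echo SD or
callable is accepted instead), picks the RNR-maximising echo (earliest on
ties) and exposes the 50-threshold gallery per mode. User interaction is
file-based (indexed PNG gallery + `--choose MODE:INDEX`); `reference-auto`
picks the gallery minimum to make SA testable. Because SA's 100 candidates
are a subset of OP's 2000, SA D_TSA ≥ OP-MIX D_TSA holds study-wise by
construction.

## Metrics

TSA is the Dice coefficient × 100 per class; two empty masks score 100
(agreement on absence — a logged convention, since the Dice ratio is 0/0).
D_TSA = √((100−TSA_par)² + (100−TSA_ves)²). Quartiles use linear
interpolation between order statistics (NumPy default); nIQR =
(Q3−Q1)·100/median and is undefined (error) at zero median. The agreement
CV is 1.96·SD(paired differences, n−1 denominator)/grand mean·100, with
the bias (mean difference) reported alongside so both readings of the
"mean ± 1.96 SD over mean" convention are recoverable.

## Synthetic phantom

The generator emulates a mid-hepatic slice of a 20-echo breath-hold GRE
acquisition (TE = 1.07 + 0.8·k ms, k = 0..19). Geometry: an elliptical
liver (~30/38 % of the image per axis, jittered), 5 circular vessels with
radii 2–4 px plus one branching dilated polyline, all strictly interior;
an optional population of 1-px "microvessel" twigs (default off).
Parenchyma R2\* is drawn so the calibrated LIC median lands inside the
requested band with a safety margin (mild 3.6–6.5, moderate 7.8–14,
severe 16.5–30 mg/g dw); vessels get blood R2\* = 30 s⁻¹.

On top of the ideal decay the generator models, with defaults chosen to
emulate a realistic 1.5 T body-array acquisition:

* **Bias field** — sum of two low-frequency cosine modes rescaled to
  ±20 %, multiplicative on intensities only (rates are immune to shading,
  which is exactly why the LIC feature helps 2D clustering).
* **Noise** — additive Gaussian, SD 55 a.u. against parenchyma S0 = 1000
  (early-echo SNR ≈ 18), clipped at zero; magnitude-Rician optional.
* **Point-spread blur** — Gaussian, FWHM 1.5 px, applied to the clean
  signal: partial-volume mixtures at vessel and liver edges while the
  ground-truth masks stay crisp.
* **Granular iron** — pixel-wise log-normal R2\* dispersion (unit mean,
  12 %) plus a ±5 % smooth texture; this is the source of the parenchymal
  LIC spread (nIQR), matching the scale seen in patient reports.
* **Vessel inflow** — per-structure S0 factor uniform in [0.7, 1.6]
  (through-plane flow refreshes spins and brightens a vessel; in-plane
  flow saturates it) around a bright-blood base S0 of 1300.
* **Flow dispersion** — pixel-wise log-normal spread (log-SD 0.3) of the
  blood decay rate.
* **Pulsation** — 10 % per-echo multiplicative flutter of vessel signal:
  it barely perturbs any single echo image but substantially corrupts the
  per-pixel decay fit, i.e. the LIC feature inside vessels.
* **Perivascular blooming** — above a parenchyma R2\* onset of 300 s⁻¹,
  vessels acquire an extra decay rate of 0.3·(R2\*_par − 300) and an
  amplitude attenuation exp(−rate·4 ms/1000) from intravoxel dephasing by
  the surrounding iron. This is what closes the late-echo intensity
  window at severe overload.

These imperfections were designed and their defaults fixed so the phantom
reproduces the contrast regimes that drive the method comparison:
intensity-only (1D) clustering is the weaker method at severe overload
(blooming + bias kill its contrast window; the LIC feature, being a rate,
survives) while 2D clustering is the weaker method at mild overload
(vessel-vs-parenchyma LIC differences of ~3 mg/g dw are comparable to the
granularity + pulsation-corrupted fit spread, while the multiplicative
intensity contrast of slowly decaying bright blood stays large). What the
phantom does **not** model: anatomy beyond an ellipse, respiratory motion
and ghosting, fat–water chemical shift, multi-slice effects, and spatially
correlated noise — so passing tests demonstrate correct algorithmic
behaviour under these regimes, not clinical performance.

Determinism: one `numpy` Generator seeded from the config; cohorts derive
per-study child seeds via `SeedSequence.spawn`, so every study and cohort
is bit-reproducible.

## Scaled-down study sizes

The cohort experiment uses 30 studies (10 per overload band) at 64×64 —
the full 169-study cohort behind the published tables is patient data and
out of reach, and 64×64 keeps a desk-scale run at a few minutes while
leaving ≈ 1400 ROI pixels per study. The full-grid OP demonstration runs
at the native 128×128. The vessel-exclusion (nIQR) experiment uses
severe-band phantoms with low-LIC vessels — blooming off, SNR ≈ 33 — so
that the parenchymal spread is dominated by granular iron rather than
severe-range fit scatter, mirroring the variability scale of clinical LIC
reports; at the default SNR the per-pixel fit noise at R2\* ≈ 1000 s⁻¹
widens the parenchyma distribution enough that even the median shifts
by > 5 % when vessels are included.

## Known limitations

* The C-EXP fit is per-pixel maximum likelihood under Gaussian noise; at
  very low SNR the magnitude (Rician) bias is only absorbed, not modelled.
* FCM with Euclidean distance assumes roughly spherical clusters in
  feature space; elongated joint (intensity, LIC) distributions — which
  the phantom produces at moderate overload — are a documented failure
  mode of the 2D variant, not a bug.
* Only C = 2 clusters and a single slice are supported; gain-field
  corrected FCM variants are deliberately out of scope.
* `u0` applies to the vessel cluster's membership; with C = 2 the
  parenchyma assignment is its complement.
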