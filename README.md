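# liverfcm

Fuzzy-c-means vessel/parenchyma segmentation for liver R2\* relaxometry,
built for MRI-based liver iron concentration (LIC) assessment in
transfusion-dependent patients (e.g. thalassemia major).

Pixel-wise R2\* mapping of a multi-echo gradient-echo slice is the standard
non-invasive way to grade hepatic iron overload. The measurement ROI is the
whole liver cross-section, but blood vessels inside it carry almost no iron:
their pixels contaminate the LIC distribution and inflate its reported
variability, worst at severe overload where vessel and parenchyma R2\*
differ the most. `liverfcm` segments vessels from parenchyma *a posteriori*
with unsupervised fuzzy clustering so the LIC report can be restricted to
true parenchyma — and ships a seedable synthetic phantom generator so the
whole pipeline is testable without patient data.

## The method

**Relaxometry.** Each pixel's echo train is fitted with the constant-offset
mono-exponential (C-EXP) model

    S(TE) = S0 · exp(−TE · R2*/1000) + C,      TE in ms, R2* in s⁻¹,

by bounded nonlinear least squares (R2\* ≥ 0, C ≥ 0; the offset absorbs the
magnitude noise floor, so no echo truncation is needed). R2\* converts to
LIC through a linear biopsy calibration (default slope 0.0254 mg·g⁻¹·s,
intercept 0.202 mg/g dw), and LIC grades as normal (< 3), mild ([3, 7)),
moderate ([7, 15)) or severe (≥ 15 mg/g dw).

**Clustering.** Standard fuzzy c-means with C = 2 clusters and fuzzifier
m = 2 minimises

    J_m(u, v) = Σᵢ Σⱼ uᵢⱼ² ‖xⱼ − vᵢ‖²,   subject to Σᵢ uᵢⱼ = 1,

where the feature vector xⱼ is either the min-max-normalised intensity of
one echo image (**1D-FCM**) or that intensity paired with the pixel's LIC
value (**2D-FCM**). Hard labels come from a defuzzification threshold u₀ on
the vessel-cluster membership.

**Selection schemes.** Clustering quality depends on the echo (TE) chosen
and on u₀:

* **OP** (optimal): exhaustive search over all 20 TEs × 50 thresholds
  {0, 0.02, …, 0.98} — 1000 candidates per mode — scored against a manual
  reference; the accuracy ceiling.
* **SA** (semi-automatic): the TE is picked automatically as the echo
  maximising the signal-range-to-noise ratio RNR = (max − min in ROI) /
  noise SD; the user only picks a threshold from a 50-image gallery per
  mode (a `reference-auto` mode emulates the user for unattended runs).
* **MIX**: the better of the 1D and 2D results. Intensity-only clustering
  fails under bias fields and severe-overload dephasing, 2D clustering
  fails when the LIC contrast is low — MIX covers both regimes.

**Metrics.** Segmentations are scored per class by the Dice coefficient in
percent (TSA) and combined into D_TSA = √((100−TSA_par)² + (100−TSA_ves)²),
0 = perfect. LIC distributions are reported as median/IQR with
nIQR(%) = (Q3 − Q1)·100/median; method agreement uses a CV of paired
differences (1.96·SD/grand mean).

## Worked example

`examples/op_vs_sa_segmentation.py` builds one severe-overload phantom,
fits its LIC map and runs every scheme against the ground truth:

```
candidates scored per mode: {'1D-FCM': 1000, '2D-FCM': 1000}
OP 1D-FCM : D_TSA   5.46 %  (TE  2.67 ms, u0 0.30)
OP 2D-FCM : D_TSA   5.29 %  (TE  2.67 ms, u0 0.38)
OP MIX-FCM: D_TSA   5.29 %  (TE  2.67 ms, u0 0.38)
SA MIX-FCM: D_TSA  15.35 %  (TE  1.07 ms from RNR_max, u0 0.36)
```

The OP scheme finds the best reachable segmentation (here 5.3 % error,
with 2D narrowly beating 1D as expected at severe overload); the practical
SA scheme, restricted to one automatically chosen echo, lands at 15 % —
never better than OP, since it searches a subset of OP's grid.
`examples/vessel_exclusion_niqr.py` then shows the clinical payoff:
excluding vessels cuts the LIC nIQR by ~10 % on that study while moving
the median by only 1.8 %, and `examples/fit_lic_map.py` prints the basic
relaxometry report (median LIC, quartiles, overload grade).

## Command line

A thin CLI wraps the same library calls:

```bash
liverfcm phantom --level severe --seed 1 -o study/      # synthetic study
liverfcm fit --stack study/stack.nii --tes study/tes.yaml --roi study/roi.nii -o maps/
liverfcm op  --stack ... --roi ... --ref study/truth.nii -o op_out/
liverfcm sa  --stack ... --roi ... -o sa_out/ --choose 2D:31
liverfcm metrics --lic maps/lic.nii --labels op_out/labels_op_mix.nii -o report.json
```

Outputs are NIfTI label maps (0 outside / 1 parenchyma / 2 vessel),
deterministic JSON reports, per-candidate CSV tables and PNG galleries.
Exit codes: 0 success, 2 input error, 3 degenerate computation.

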