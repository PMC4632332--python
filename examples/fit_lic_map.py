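"""Fit a pixel-wise R2* map on a synthetic study and summarise its LIC.

Builds a moderate-overload phantom, fits the constant-offset
mono-exponential decay in every liver pixel, converts R2* to liver iron
concentration (mg Fe / g dry weight) and prints the robust summary a
reading session would report.
"""

import numpy as np

from liverfcm import (
    PhantomConfig,
    classify_lic_level,
    fit_r2star_map,
    generate_phantom,
    lic_summary,
    r2star_to_lic,
)

study = generate_phantom(PhantomConfig(shape=(64, 64), lic_level="moderate", seed=42))
r2 = fit_r2star_map(study.stack, study.roi)
lic = r2star_to_lic(r2, study.config.calibration)
summary = lic_summary(lic, study.roi, klass="parenchyma")

print(f"liver ROI: {int(study.roi.sum())} pixels, "
      f"{int(r2.valid_mask.sum())} valid fits")
print(f"median R2*: {np.nanmedian(r2.values[study.roi]):.0f} s^-1")
print(f"median LIC: {summary.median:.2f} mg/g dw "
      f"(Q1 {summary.q1:.2f}, Q3 {summary.q3:.2f})")
print(f"nIQR: {summary.niqr_pct:.1f} %  ->  overload level: "
      f"{classify_lic_level(summary.median).value}")
# The median LIC grades the patient's iron burden; nIQR is the
# within-liver variability that vessel exclusion is meant to shrink.
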