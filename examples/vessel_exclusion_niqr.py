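"""Show why vessel exclusion matters for LIC reporting.

On a severe-overload liver the vessels carry near-zero iron, so leaving
them inside the ROI inflates the spread (nIQR) of the reported LIC
distribution while the median barely moves.
"""

from liverfcm import (
    PhantomConfig,
    fit_r2star_map,
    generate_phantom,
    lic_summary,
    r2star_to_lic,
)

cfg = PhantomConfig(shape=(64, 64), lic_level="severe", seed=11,
                    vessel_blooming=0.0, noise_sd=30.0)
study = generate_phantom(cfg)
lic = r2star_to_lic(fit_r2star_map(study.stack, study.roi), cfg.calibration)

whole = lic_summary(lic, study.truth, klass="roi-all")
par = lic_summary(lic, study.truth, klass="parenchyma")

print(f"whole ROI   : median {whole.median:6.2f} mg/g dw, nIQR {whole.niqr_pct:5.1f} %")
print(f"parenchyma  : median {par.median:6.2f} mg/g dw, nIQR {par.niqr_pct:5.1f} %")
print(f"median shift: {100 * abs(par.median - whole.median) / whole.median:.1f} % "
      f"(robust), nIQR reduction: {100 * (1 - par.niqr_pct / whole.niqr_pct):.0f} %")
# The median is robust to the low-LIC vessel outliers; the variability
# measure is not - excluding vessels tightens it considerably.
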