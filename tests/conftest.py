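import numpy as np
import pytest

from liverfcm import (
    PhantomConfig,
    fit_r2star_map,
    generate_phantom,
    r2star_to_lic,
)

TE20 = 1.07 + 0.8 * np.arange(20)


@pytest.fixture(scope="session")
def severe_study():
    """One 64x64 severe-overload phantom with fitted R2*/LIC maps, shared
    across tests (the fit is the slow step)."""
    study = generate_phantom(PhantomConfig(shape=(64, 64), lic_level="severe", seed=7))
    r2 = fit_r2star_map(study.stack, study.roi)
    lic = r2star_to_lic(r2)
    return study, r2, lic


@pytest.fixture(scope="session")
def mild_study():
    study = generate_phantom(PhantomConfig(shape=(64, 64), lic_level="mild", seed=7))
    r2 = fit_r2star_map(study.stack, study.roi)
    lic = r2star_to_lic(r2)
    return study, r2, lic


@pytest.fixture(scope="session")
def clean_study():
    """Noise-free, bias-free, artifact-free phantom for round-trip checks."""
    cfg = PhantomConfig(
        shape=(48, 48), lic_level="severe", seed=3, noise_sd=0.0,
        bias_field="none", psf_fwhm_px=0.0, vessel_pulsation=0.0,
    )
    return generate_phantom(cfg)
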