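"""Built-in photosensitizers, light schedules, optics tables and reference values.

The in vitro entries (extinction coefficients, irradiances, exposures) are
the experimental conditions of the RG-2 rat glioma comparison the package
models.  The per-tissue optical properties are literature-typical
PLACEHOLDERS constructed to be consistent with the penetration depths
quoted for gray/white matter at 635 and 808 nm (the study's own per-tissue
tables are not published); treat them as defaults to be overridden with
measured values, not as ground truth.  The same applies to the in vivo
tissue-concentration and 808 nm extinction placeholders.
"""

from __future__ import annotations

from .light_transport import TissueOptics
from .photonics import LightSource, Photosensitizer

# ---------------------------------------------------------------------------
# Photosensitizers
# ---------------------------------------------------------------------------

RUTHERRIN = Photosensitizer(
    name="rutherrin",
    epsilon=8427.4,          # M^-1 cm^-1 at 530 nm
    wavelength_nm=530.0,
    molecular_weight=1007.0,  # TLD1433
    precursor_ratio=1.0,
)

ALA_PPIX = Photosensitizer(
    name="ala_ppix",
    epsilon=5121.0,          # M^-1 cm^-1, PpIX Q-band near 630-635 nm
    wavelength_nm=635.0,
    molecular_weight=562.66,  # PpIX
    precursor_ratio=8.0,     # 8 ALA molecules per PpIX, complete conversion
)

# PLACEHOLDER: TLD1433's NIR tail extinction at the 808 nm treatment
# wavelength is not published at this precision.
RUTHERRIN_808 = Photosensitizer(
    name="rutherrin_808",
    epsilon=50.0,
    wavelength_nm=808.0,
    molecular_weight=1007.0,
    precursor_ratio=1.0,
)

# ---------------------------------------------------------------------------
# Light sources
# ---------------------------------------------------------------------------

# Flat-field well irradiators (in vitro): 360 mW/cm2 at 530 nm delivering
# 20 J/cm2; 75 mW/cm2 at 635 nm delivering 10 J/cm2.
WELL_530 = LightSource(
    name="well_530", power=0.360, wavelength_nm=530.0,
    duration_s=20.0 / 0.360, geometry="flat_field", mode="irradiance",
)
WELL_635 = LightSource(
    name="well_635", power=0.075, wavelength_nm=635.0,
    duration_s=10.0 / 0.075, geometry="flat_field", mode="irradiance",
)

# Interstitial isotropic emitters (in vivo): 200 mW x 50 min = 600 J at
# 808 nm; 18 mW x 22 min 13 s = 24 J at 635 nm.
INTERSTITIAL_808 = LightSource(
    name="interstitial_808", power=0.200, wavelength_nm=808.0,
    duration_s=3000.0, geometry="isotropic_point", mode="power",
)
INTERSTITIAL_635 = LightSource(
    name="interstitial_635", power=0.018, wavelength_nm=635.0,
    duration_s=1333.0, geometry="isotropic_point", mode="power",
)

# ---------------------------------------------------------------------------
# Tissue optics (PLACEHOLDERS — see module docstring).  Chosen so the
# effective penetration depths 1/mu_eff match the quoted values:
# gray 808 ~ 1.0 cm, white 808 ~ 0.54 cm, gray 635 ~ 0.84 cm,
# white 635 ~ 0.36 cm.
# ---------------------------------------------------------------------------

GRAY_808 = TissueOptics(mu_a=0.02, mu_s_prime=16.62, g=0.9, label="gray")
WHITE_808 = TissueOptics(mu_a=0.029, mu_s_prime=40.0, g=0.85, label="white")
GRAY_635 = TissueOptics(mu_a=0.03, mu_s_prime=15.70, g=0.9, label="gray")
WHITE_635 = TissueOptics(mu_a=0.0626, mu_s_prime=40.0, g=0.85, label="white")
# Tumor optics default to gray matter at each wavelength (placeholder).
TUMOR_808 = TissueOptics(mu_a=0.02, mu_s_prime=16.62, g=0.9, label="tumor")
TUMOR_635 = TissueOptics(mu_a=0.03, mu_s_prime=15.70, g=0.9, label="tumor")

# ---------------------------------------------------------------------------
# Reference quantities of the modeled study, used as inputs when
# parameterizing synthetic scenarios.
# ---------------------------------------------------------------------------

# In vitro LD50 in absorbed photons per cm^3 (published figures).
LD50_RUTHERRIN_HV_CM3 = 2.388e16
LD50_ALA_HV_CM3 = 1.539e19

# In vivo photodynamic thresholds (mean, sd) [hv cm^-3].
THRESHOLD_RUTHERRIN_TUMOR = (8.86e18, 1.46e18)
THRESHOLD_ALA_TUMOR = (1.25e19, 3.51e19)
THRESHOLD_RUTHERRIN_NORMAL = (3.09e18, 2.96e17)
THRESHOLD_ALA_NORMAL = (1.07e17, 2.32e16)

# Specific uptake ratios (tumor vs normal brain).
SUR_RUTHERRIN = 20.0
SUR_ALA_PPIX = 10.6

# In vivo tissue-concentration placeholders [ug drug per g tissue].
TUMOR_TLD1433_UG_PER_G = 5.0
TUMOR_PPIX_UG_PER_G = 1.0

PHOTOSENSITIZERS = {
    p.name: p for p in (RUTHERRIN, ALA_PPIX, RUTHERRIN_808)
}
LIGHT_SOURCES = {
    s.name: s for s in (WELL_530, WELL_635, INTERSTITIAL_808, INTERSTITIAL_635)
}
TISSUE_OPTICS = {
    "gray_808": GRAY_808,
    "white_808": WHITE_808,
    "gray_635": GRAY_635,
    "white_635": WHITE_635,
    "tumor_808": TUMOR_808,
    "tumor_635": TUMOR_635,
}
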