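"""Photonic and radiometric unit conversions.

Every downstream dose quantity in the package — LD50 in absorbed photons,
photodynamic thresholds at the necrosis boundary, selectivity distances —
rests on four conversions implemented here:

* photon energy ``E = h c / lambda``;
* radiant exposure [J cm^-2] to areal photon density [hv cm^-2];
* exposure/irradiance/time arithmetic;
* the photosensitizer absorption coefficient
  ``mu_a,ps = ln(10) * epsilon * C`` (Beer–Lambert, with the decadic molar
  extinction coefficient ``epsilon`` [M^-1 cm^-1] and concentration ``C``
  [M]), whose product with the areal photon density gives the volumetric
  absorbed photon density [hv cm^-3] — the common dose currency that lets
  photosensitizers with different extinction coefficients and tissue
  concentrations be compared on one axis.

The ``natural_log`` switch on :func:`ps_absorption_coefficient` drops the
ln(10) factor; published absorbed-photon figures do not always state which
convention they used, and both lead to in-range implied concentrations for
the assays handled here, so the choice is surfaced rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._constants import LN10, C_M_S, PLANCK_J_S

__all__ = [
    "Photosensitizer",
    "LightSource",
    "photon_energy",
    "radiant_exposure_to_photon_density",
    "photon_density_to_radiant_exposure",
    "exposure_time",
    "total_energy",
    "ps_absorption_coefficient",
    "absorbed_photon_density",
]


@dataclass(frozen=True)
class Photosensitizer:
    """Optical/chemical identity of a photosensitizer.

    Parameters
    ----------
    name : str
        Label, e.g. ``"rutherrin"``.
    epsilon : float
        Decadic molar extinction coefficient [M^-1 cm^-1] at ``wavelength_nm``.
    wavelength_nm : float
        Activation wavelength [nm] at which ``epsilon`` holds.
    molecular_weight : float
        [g/mol] of the active (light-absorbing) species.
    precursor_ratio : float, default 1
        Precursor molecules consumed per active photosensitizer molecule
        (8 for ALA -> PpIX under complete conversion; 1 for directly
        administered agents).
    """

    name: str
    epsilon: float
    wavelength_nm: float
    molecular_weight: float
    precursor_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if not 300.0 < self.wavelength_nm < 1100.0:
            raise ValueError(
                f"activation wavelength must lie in (300, 1100) nm, got "
                f"{self.wavelength_nm}"
            )
        if not self.molecular_weight > 0:
            raise ValueError("molecular_weight must be > 0")
        if not self.precursor_ratio >= 1:
            raise ValueError(
                f"precursor_ratio must be >= 1, got {self.precursor_ratio}"
            )


_GEOMETRIES = ("flat_field", "isotropic_point")
_MODES = ("irradiance", "power")


@dataclass(frozen=True)
class LightSource:
    """A treatment light source.

    ``mode`` declares the unit of ``power``: ``"irradiance"`` means
    W cm^-2 (flat-field well irradiator), ``"power"`` means emitted W
    (interstitial isotropic emitter).  Operations check the mode and
    geometry they require and refuse mismatches rather than silently
    converting.
    """

    name: str
    power: float
    wavelength_nm: float
    duration_s: float
    geometry: str = "flat_field"
    mode: str = "irradiance"

    def __post_init__(self) -> None:
        if not self.power > 0:
            raise ValueError("power must be > 0")
        if not self.duration_s > 0:
            raise ValueError("duration must be > 0")
        if self.geometry not in _GEOMETRIES:
            raise ValueError(
                f"geometry must be one of {_GEOMETRIES}, got {self.geometry!r}"
            )
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")

    # -- unit-audited accessors ------------------------------------------
    @property
    def irradiance_w_cm2(self) -> float:
        """Irradiance [W cm^-2]; only meaningful for flat-field sources."""
        if self.mode != "irradiance":
            raise ValueError(
                f"source {self.name!r} declares emitted power [W], not "
                "irradiance [W cm^-2]; refusing to reinterpret units"
            )
        return self.power

    @property
    def emitted_power_w(self) -> float:
        """Emitted power [W]; only meaningful for interstitial sources."""
        if self.mode != "power":
            raise ValueError(
                f"source {self.name!r} declares irradiance [W cm^-2], not "
                "emitted power [W]; refusing to reinterpret units"
            )
        return self.power

    @property
    def radiant_exposure_j_cm2(self) -> float:
        """Delivered radiant exposure [J cm^-2] for a flat-field source."""
        return self.irradiance_w_cm2 * self.duration_s

    @property
    def total_energy_j(self) -> float:
        """Total delivered energy [J] for a power-mode source."""
        return self.emitted_power_w * self.duration_s

    @property
    def photon_energy_j(self) -> float:
        return photon_energy(self.wavelength_nm)


def photon_energy(wavelength_nm: float) -> float:
    """Energy of one photon [J] at the given vacuum wavelength [nm]."""
    if not wavelength_nm > 0:
        raise ValueError(f"wavelength must be > 0, got {wavelength_nm}")
    return PLANCK_J_S * C_M_S / (wavelength_nm * 1e-9)


def radiant_exposure_to_photon_density(
    exposure_j_cm2: float, wavelength_nm: float
) -> float:
    """Areal photon density [hv cm^-2] delivered by a radiant exposure."""
    if exposure_j_cm2 < 0:
        raise ValueError(f"exposure must be >= 0, got {exposure_j_cm2}")
    return exposure_j_cm2 / photon_energy(wavelength_nm)


def photon_density_to_radiant_exposure(
    photon_density_cm2: float, wavelength_nm: float
) -> float:
    """Inverse of :func:`radiant_exposure_to_photon_density`."""
    if photon_density_cm2 < 0:
        raise ValueError("photon density must be >= 0")
    return photon_density_cm2 * photon_energy(wavelength_nm)


def exposure_time(target_exposure_j_cm2: float, irradiance_w_cm2: float) -> float:
    """Seconds of irradiation needed to deliver a target radiant exposure.

    Full-precision value; round only for display.
    """
    if not irradiance_w_cm2 > 0:
        raise ValueError(f"irradiance must be > 0, got {irradiance_w_cm2}")
    if target_exposure_j_cm2 < 0:
        raise ValueError("target exposure must be >= 0")
    return target_exposure_j_cm2 / irradiance_w_cm2


def total_energy(power_w: float, duration_s: float) -> float:
    """Total emitted energy [J] = power [W] x duration [s]."""
    if power_w < 0 or duration_s < 0:
        raise ValueError("power and duration must be >= 0")
    return power_w * duration_s


def ps_absorption_coefficient(
    ps: Photosensitizer, concentration_m: float, natural_log: bool = True
) -> float:
    """Photosensitizer absorption coefficient mu_a,ps [cm^-1].

    Beer–Lambert with a decadic extinction coefficient gives
    ``mu_a = ln(10) * epsilon * C``.  With ``natural_log=False`` the ln(10)
    factor is dropped (i.e. epsilon is treated as already base-e), a
    convention ambiguity sensitivity switch.
    """
    if concentration_m < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration_m}")
    factor = LN10 if natural_log else 1.0
    return factor * ps.epsilon * concentration_m


def absorbed_photon_density(
    areal_photon_density_cm2: float, mu_a_ps_cm1: float
) -> float:
    """Volumetric absorbed photon density [hv cm^-3].

    The areal photon density traversing a voxel times the photosensitizer
    absorption coefficient gives photons absorbed by the photosensitizer
    per unit tissue volume.
    """
    if areal_photon_density_cm2 < 0:
        raise ValueError("areal photon density must be >= 0")
    if mu_a_ps_cm1 < 0:
        raise ValueError("absorption coefficient must be >= 0")
    return areal_photon_density_cm2 * mu_a_ps_cm1
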