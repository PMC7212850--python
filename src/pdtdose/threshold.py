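"""Photodynamic threshold estimation and inversion at the necrosis boundary.

The photodynamic threshold model states that tissue necroses wherever the
absorbed photon density (photons absorbed by the photosensitizer per cm^3
of tissue) exceeds a tissue-specific threshold.  Given the boundary radius
of the treatment effect observed on post-treatment imaging, the threshold
is the absorbed photon density the light delivery produced at that radius:

    T = phi(r_b) * t / E_photon * mu_a,ps(C_tissue)

with ``phi`` the fluence rate from the transport model, ``t`` the
irradiation time, ``E_photon`` the photon energy and ``mu_a,ps`` the
photosensitizer absorption coefficient at the measured tissue
concentration.  Inverting the monotone radial profile predicts the
treatable (necrosis) radius for a known threshold.

Also here: the specific-uptake-ratio selectivity heuristic (each factor of
3 in SUR buys one effective penetration depth of selective treatment
margin) and a small edema fold-change helper for mask volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

from ._constants import TISSUE_DENSITY_G_PER_ML
from .light_transport import (
    Phantom,
    TissueOptics,
    diffusion_fluence,
    effective_penetration_depth,
    mc_fluence,
    radial_average,
)
from .photonics import (
    LightSource,
    Photosensitizer,
    photon_energy,
    ps_absorption_coefficient,
)

__all__ = [
    "BoundaryObservation",
    "ThresholdEstimate",
    "absorbed_density_profile",
    "threshold_at_boundary",
    "predict_necrosis_radius",
    "selectivity_depths",
    "edema_fold_change",
    "mask_volume_cm3",
    "two_sample_t",
    "ug_per_g_to_molar",
]


@dataclass(frozen=True)
class BoundaryObservation:
    """Per-animal minimum/maximum enhancement distance from the light source."""

    animal_id: str
    r_min_cm: float
    r_max_cm: float
    tissue: str = "tumor"

    def __post_init__(self) -> None:
        if not 0 < self.r_min_cm <= self.r_max_cm:
            raise ValueError(
                f"need 0 < r_min <= r_max, got ({self.r_min_cm}, {self.r_max_cm})"
            )


@dataclass
class ThresholdEstimate:
    """Cohort threshold (mean +/- sample sd) with its input snapshot."""

    threshold_hv_cm3: float
    sd_hv_cm3: float
    boundary_radius_cm: float
    per_animal: np.ndarray
    inputs: dict


def ug_per_g_to_molar(
    conc_ug_per_g: float,
    molecular_weight: float,
    density_g_per_ml: float = TISSUE_DENSITY_G_PER_ML,
) -> float:
    """Convert a tissue drug concentration [ug/g] to molar, assuming 1 g/mL."""
    if conc_ug_per_g < 0:
        raise ValueError("concentration must be >= 0")
    # ug/g -> g drug per L tissue -> mol/L
    return conc_ug_per_g * 1e-6 * density_g_per_ml * 1e3 / molecular_weight


def absorbed_density_profile(
    r_cm: float | np.ndarray,
    source: LightSource,
    optics: TissueOptics,
    ps: Photosensitizer,
    tissue_concentration_m: float,
    natural_log: bool = True,
) -> float | np.ndarray:
    """Absorbed photon density [hv cm^-3] at radius r (diffusion transport)."""
    phi = diffusion_fluence(r_cm, source.emitted_power_w, optics)
    areal = phi * source.duration_s / photon_energy(source.wavelength_nm)
    mu = ps_absorption_coefficient(ps, tissue_concentration_m, natural_log=natural_log)
    return areal * mu


def _mc_profile_interpolator(
    source: LightSource,
    optics: TissueOptics,
    ps: Photosensitizer,
    tissue_concentration_m: float,
    r_max_cm: float,
    packets: int,
    seed: int,
    natural_log: bool,
):
    """Radially averaged MC absorbed-density profile, log-interpolated.

    The grid extends three penetration depths beyond the largest boundary
    radius so the absorbing grid edge does not depress the fluence in the
    region of interest.
    """
    extent = 1.3 * max(r_max_cm, 0.3) + 3.0 / optics.mu_eff
    voxel = max(extent / 40.0, 0.02)
    n = int(2 * math.ceil(extent / voxel)) + 1
    phantom = Phantom.homogeneous(optics, shape=(n, n, n), voxel_cm=voxel)
    fld = mc_fluence(phantom, source, packets=packets, seed=seed)
    mu = ps_absorption_coefficient(ps, tissue_concentration_m, natural_log=natural_log)
    dens = fld.photon_density_cm2 * mu
    edges = np.linspace(2 * voxel, extent, 30)
    centers, means = radial_average(dens, phantom, edges)
    ok = np.isfinite(means) & (means > 0)
    lr, lm = centers[ok], np.log(means[ok])

    def profile(r):
        return np.exp(np.interp(r, lr, lm))

    return profile


def threshold_at_boundary(
    observations: Sequence[BoundaryObservation],
    source: LightSource,
    optics: TissueOptics,
    ps: Photosensitizer,
    tissue_concentration_m: float,
    transport: Literal["diffusion", "mc"] = "diffusion",
    boundary: Literal["min", "max"] = "min",
    natural_log: bool = True,
    mc_packets: int = 200_000,
    mc_seed: int = 0,
) -> ThresholdEstimate:
    """Estimate the photodynamic threshold from observed boundary radii.

    Per animal, the absorbed photon density is evaluated at the chosen
    boundary radius; the cohort estimate is the unweighted mean +/- sample
    sd.  ``boundary="min"`` (default) uses the minimum enhancement
    distance, the conservative *upper-bound* threshold appropriate when
    the whole target is necrosed; ``"max"`` gives the lower bound.
    """
    if not observations:
        raise ValueError("need at least one boundary observation")
    radii = np.array(
        [o.r_min_cm if boundary == "min" else o.r_max_cm for o in observations]
    )
    if transport == "diffusion":
        per_animal = absorbed_density_profile(
            radii, source, optics, ps, tissue_concentration_m, natural_log=natural_log
        )
    elif transport == "mc":
        prof = _mc_profile_interpolator(
            source, optics, ps, tissue_concentration_m,
            float(radii.max()), mc_packets, mc_seed, natural_log,
        )
        per_animal = prof(radii)
    else:
        raise ValueError(f"unknown transport {transport!r}")
    per_animal = np.atleast_1d(np.asarray(per_animal, dtype=float))
    sd = float(per_animal.std(ddof=1)) if per_animal.size > 1 else 0.0
    return ThresholdEstimate(
        threshold_hv_cm3=float(per_animal.mean()),
        sd_hv_cm3=sd,
        boundary_radius_cm=float(radii.mean()),
        per_animal=per_animal,
        inputs={
            "source": source,
            "optics": optics,
            "ps": ps,
            "tissue_concentration_m": tissue_concentration_m,
            "transport": transport,
            "boundary": boundary,
            "natural_log": natural_log,
        },
    )


def predict_necrosis_radius(
    threshold_hv_cm3: float,
    source: LightSource,
    optics: TissueOptics,
    ps: Photosensitizer,
    tissue_concentration_m: float,
    natural_log: bool = True,
    r_min_cm: float = 1e-4,
    xtol_cm: float = 1e-4,
) -> float:
    """Radius [cm] out to which the absorbed density exceeds the threshold.

    Inverse of :func:`threshold_at_boundary` on the diffusion profile; the
    profile is strictly decreasing, so the root is unique.  A threshold
    above the near-source maximum returns 0 (no necrosis), not an error.
    """
    if not threshold_hv_cm3 > 0:
        raise ValueError("threshold must be > 0")

    def f(r):
        return (
            absorbed_density_profile(
                r, source, optics, ps, tissue_concentration_m, natural_log=natural_log
            )
            - threshold_hv_cm3
        )

    if f(r_min_cm) <= 0:
        return 0.0
    r_hi = 1.0
    while f(r_hi) > 0:
        r_hi *= 2.0
        if r_hi > 1e3:  # pragma: no cover - absurd threshold/power combos
            raise RuntimeError("necrosis radius bracket exceeded 10 m")
    return float(optimize.brentq(f, r_min_cm, r_hi, xtol=xtol_cm))


def selectivity_depths(sur: float, optics: TissueOptics | None = None):
    """Selective-treatment margin bought by a specific uptake ratio.

    The heuristic: each factor of 3 in SUR provides selectivity over one
    effective penetration depth, i.e. ``depths = log3(SUR)``.  With an
    optics table the margin is also returned in cm
    (``depths / mu_eff``).  Returns ``depths`` alone when optics is None,
    else ``(depths, distance_cm)``.
    """
    if not sur >= 1:
        raise ValueError(f"SUR must be >= 1, got {sur}")
    depths = math.log(sur) / math.log(3.0)
    if optics is None:
        return depths
    return depths, depths * effective_penetration_depth(optics)


def mask_volume_cm3(
    n_voxels: int, voxel_dims_mm: tuple[float, float, float]
) -> float:
    """Volume [cm^3] of a binary imaging mask of N voxels."""
    if n_voxels < 0:
        raise ValueError("voxel count must be >= 0")
    vol_mm3 = n_voxels * float(np.prod(voxel_dims_mm))
    return vol_mm3 * 1e-3


def edema_fold_change(pre_volume_cm3: float, post_volume_cm3: float) -> float:
    """Post/pre ratio of enhancement-mask volumes."""
    if not pre_volume_cm3 > 0:
        raise ValueError("pre-treatment volume must be > 0")
    if post_volume_cm3 < 0:
        raise ValueError("post-treatment volume must be >= 0")
    return post_volume_cm3 / pre_volume_cm3


def two_sample_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Unpaired two-sample t statistic (pooled variance) and two-sided p.

    Textbook Student formula:
    t = (mean_x - mean_y) / (s_p sqrt(1/n_x + 1/n_y)) with the pooled
    variance s_p^2 on n_x + n_y - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each group needs >= 2 observations")
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    df = nx + ny - 2
    if sp2 == 0:
        t = 0.0 if x.mean() == y.mean() else math.inf
    else:
        t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)
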