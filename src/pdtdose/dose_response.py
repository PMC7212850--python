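"""Sigmoidal cell-kill fitting and LD50 in concentration and photon units.

In vitro PDT plates report viability per well relative to a solvent control
and a kill control.  This module normalizes viability to percent kill,
fits a four-parameter logistic (4PL) on log10 concentration, and converts
the fitted LD50 into the absorbed-photon-density dose axis using the light
schedule and the photosensitizer's extinction coefficient.  For pro-drugs
(ALA -> PpIX) the administered concentration is divided by the precursor
stoichiometry before the photon conversion, assuming complete conversion.

The 4PL is

    kill(c) = bottom + (top - bottom) / (1 + 10**(hill * (log10(LD50) - log10(c))))

with free asymptotes (assay floors and ceilings drift); LD50 is the
concentration at the midpoint of the fitted asymptotes.  Uncertainty on
LD50 is propagated to photon units by the first-order delta method; a
bootstrap is available for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .photonics import (
    LightSource,
    Photosensitizer,
    absorbed_photon_density,
    ps_absorption_coefficient,
    radiant_exposure_to_photon_density,
)

__all__ = [
    "PlateError",
    "FitError",
    "normalize_plate",
    "effective_ps_concentration",
    "four_param_logistic",
    "fit_sigmoid",
    "DoseResponseFit",
    "ld50_in_photons",
    "implied_ld50_concentration",
]


class PlateError(ValueError):
    """Raised for missing/contradictory plate controls."""


class FitError(RuntimeError):
    """Raised when the sigmoid fit cannot converge or data are degenerate."""


def normalize_plate(records: pd.DataFrame) -> pd.DataFrame:
    """Convert raw viability to percent kill using on-plate controls.

    Parameters
    ----------
    records : DataFrame
        Columns ``concentration_M``, ``viability``, ``control_flag``
        (values ``solvent``, ``kill``, ``treated``).

    Returns
    -------
    DataFrame with columns ``concentration_M`` and ``kill_pct`` for treated
    wells only.  kill% = 100 * (1 - (v - mean_kill)/(mean_solvent - mean_kill)),
    clipped to [0, 100].
    """
    required = {"concentration_M", "viability", "control_flag"}
    missing = required - set(records.columns)
    if missing:
        raise PlateError(f"plate table missing columns: {sorted(missing)}")
    solvent = records.loc[records["control_flag"] == "solvent", "viability"]
    kill = records.loc[records["control_flag"] == "kill", "viability"]
    if solvent.empty or kill.empty:
        raise PlateError("plate must contain at least one solvent and one kill control")
    mean_solvent = float(solvent.mean())
    mean_kill = float(kill.mean())
    if mean_solvent <= mean_kill:
        raise PlateError(
            f"solvent-control mean ({mean_solvent:.3g}) must exceed kill-control "
            f"mean ({mean_kill:.3g}); check plate orientation"
        )
    treated = records.loc[records["control_flag"] == "treated"]
    kill_pct = 100.0 * (
        1.0 - (treated["viability"] - mean_kill) / (mean_solvent - mean_kill)
    )
    out = pd.DataFrame(
        {
            "concentration_M": treated["concentration_M"].to_numpy(float),
            "kill_pct": np.clip(kill_pct.to_numpy(float), 0.0, 100.0),
        }
    )
    return out


def effective_ps_concentration(
    administered_m: float | np.ndarray, ps: Photosensitizer
) -> float | np.ndarray:
    """Active photosensitizer concentration from an administered dose.

    Divides by the precursor stoichiometry (8 ALA per PpIX), assuming
    complete conversion of precursor to active agent.
    """
    administered = np.asarray(administered_m, dtype=float)
    if np.any(administered < 0):
        raise ValueError("administered concentration must be >= 0")
    result = administered / ps.precursor_ratio
    return float(result) if np.isscalar(administered_m) else result


def four_param_logistic(
    log10_c: np.ndarray, bottom: float, top: float, log10_ld50: float, hill: float
) -> np.ndarray:
    """4PL response at log10 concentration."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log10_ld50 - log10_c)))


@dataclass
class DoseResponseFit:
    """Fitted 4PL parameters with covariance and optional photon-unit LD50."""

    ld50_concentration: float          # [M], administered units
    hill_slope: float
    top: float                         # kill% upper asymptote
    bottom: float                      # kill% lower asymptote
    covariance: np.ndarray             # order: bottom, top, log10_ld50, hill
    ld50_log10_sd: float
    n_points: int
    ld50_photon_density: float | None = None   # [hv cm^-3]
    ld50_photon_density_sd: float | None = None

    @property
    def ld50_concentration_sd(self) -> float:
        """Delta-method sd of LD50 on the concentration scale [M]."""
        return self.ld50_concentration * np.log(10.0) * self.ld50_log10_sd

    def predict(self, concentration_m: np.ndarray) -> np.ndarray:
        c = np.asarray(concentration_m, dtype=float)
        return four_param_logistic(
            np.log10(c),
            self.bottom,
            self.top,
            np.log10(self.ld50_concentration),
            self.hill_slope,
        )


def fit_sigmoid(
    concentration_m: Sequence[float],
    kill_pct: Sequence[float],
    p0: Sequence[float] | None = None,
) -> DoseResponseFit:
    """Fit the 4PL on log10 concentration.

    Zero-concentration points are excluded (log of zero); at least four
    distinct non-zero concentrations are required so the transition is
    identifiable.
    """
    c = np.asarray(concentration_m, dtype=float)
    y = np.asarray(kill_pct, dtype=float)
    if c.shape != y.shape:
        raise ValueError("concentration and kill% must have equal length")
    keep = c > 0
    c, y = c[keep], y[keep]
    if np.unique(c).size < 4:
        raise FitError("need >= 4 distinct non-zero concentrations to fit a 4PL")
    if np.ptp(y) < 1e-9:
        raise FitError("flat response: no dose-dependent kill to fit")
    x = np.log10(c)

    if p0 is None:
        # midpoint guess: concentration where response crosses half-range
        half = y.min() + 0.5 * np.ptp(y)
        x0 = float(np.interp(half, y[np.argsort(x)], np.sort(x)))
        p0 = (float(y.min()), float(y.max()), x0, 1.0)

    try:
        popt, pcov = curve_fit(
            four_param_logistic, x, y, p0=p0, maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise FitError(f"4PL fit did not converge: {exc}") from exc
    bottom, top, log10_ld50, hill = popt
    if not np.all(np.isfinite(pcov)):
        pcov = np.full((4, 4), np.nan)
    if bottom > top:
        # re-express the same curve with bottom < top (flips hill sign)
        bottom, top, hill = top, bottom, -hill
        perm = np.array([1, 0, 2, 3])
        pcov = pcov[np.ix_(perm, perm)]
    return DoseResponseFit(
        ld50_concentration=float(10.0 ** log10_ld50),
        hill_slope=float(hill),
        top=float(top),
        bottom=float(bottom),
        covariance=pcov,
        ld50_log10_sd=float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.nan,
        n_points=int(c.size),
    )


def ld50_in_photons(
    fit: DoseResponseFit,
    source: LightSource,
    ps: Photosensitizer,
    natural_log: bool = True,
) -> DoseResponseFit:
    """Attach the absorbed-photon-density LD50 [hv cm^-3] to a fit.

    The flat-field schedule's areal photon density is multiplied by the
    photosensitizer absorption coefficient at the *effective* LD50
    concentration (administered LD50 / precursor ratio).  Returns the same
    fit object with ``ld50_photon_density`` (and its delta-method sd) set.
    """
    if source.geometry != "flat_field":
        raise ValueError(
            "LD50 photon conversion requires a flat_field source; got "
            f"geometry {source.geometry!r}"
        )
    areal = radiant_exposure_to_photon_density(
        source.radiant_exposure_j_cm2, source.wavelength_nm
    )
    c_eff = effective_ps_concentration(fit.ld50_concentration, ps)
    mu = ps_absorption_coefficient(ps, c_eff, natural_log=natural_log)
    fit.ld50_photon_density = absorbed_photon_density(areal, mu)
    # photon-density LD50 is linear in concentration -> relative sd carries over
    if np.isfinite(fit.ld50_log10_sd):
        rel_sd = np.log(10.0) * fit.ld50_log10_sd
        fit.ld50_photon_density_sd = fit.ld50_photon_density * rel_sd
    return fit


def implied_ld50_concentration(
    ld50_photon_density_cm3: float,
    source: LightSource,
    ps: Photosensitizer,
    natural_log: bool = True,
) -> float:
    """Invert a published photon-unit LD50 to the administered concentration [M].

    Solves  ld50_hv = areal_density * factor * epsilon * C_eff  for the
    administered concentration ``C_eff * precursor_ratio``.  Used to recover
    plausible assay concentrations from printed absorbed-photon LD50s.
    """
    if not ld50_photon_density_cm3 > 0:
        raise ValueError("photon-unit LD50 must be > 0")
    areal = radiant_exposure_to_photon_density(
        source.radiant_exposure_j_cm2, source.wavelength_nm
    )
    mu_per_molar = ps_absorption_coefficient(ps, 1.0, natural_log=natural_log)
    c_eff = ld50_photon_density_cm3 / (areal * mu_per_molar)
    return c_eff * ps.precursor_ratio
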