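"""ICP-MS biodistribution: ruthenium readouts to drug concentrations and SUR.

Tissue samples (tumor, contralateral brain, cerebellum) digested in 2 mL
of nitric acid are quantified for ruthenium by ICP-MS in ppb (ug/L of
digest).  The ruthenium mass converts to drug (TLD1433) mass through the
molecular-weight ratio, then to a tissue concentration via the fresh
tissue mass.  The specific uptake ratio (SUR) is the ratio of group-mean
tumor concentration to a reference normal tissue; because it is a ratio
of concentrations of the same compound, SUR is invariant to the unit
(ug/g vs molar) and to any common calibration scale factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from ._constants import (
    RU101_ISOTOPE_MASS,
    RU_ATOMIC_WEIGHT,
    TISSUE_DENSITY_G_PER_ML,
    TLD1433_MW,
)

__all__ = [
    "ru_to_tld1433_mass",
    "tissue_concentration",
    "add_concentrations",
    "compute_sur",
    "SurResult",
    "UPTAKE_COLUMNS",
]

UPTAKE_COLUMNS = [
    "animal",
    "tissue",
    "timepoint_h",
    "dose_mg_per_kg",
    "ru_ppb",
    "tissue_mass_g",
]

DEFAULT_DIGEST_VOLUME_L = 0.002  # 2 mL nitric acid digest


def ru_to_tld1433_mass(
    ru_ppb: float | np.ndarray,
    digest_volume_l: float = DEFAULT_DIGEST_VOLUME_L,
    ru_atomic_mass: float = RU_ATOMIC_WEIGHT,
) -> float | np.ndarray:
    """Drug mass [ug] in a digest from its ICP-MS ruthenium reading.

    ppb is ug Ru per L of digest; Ru mass [ug] = ppb * digest volume [L];
    drug mass = Ru mass * MW_TLD1433 / AM_Ru.  One ruthenium atom per
    TLD1433 molecule.  ``ru_atomic_mass`` defaults to the standard atomic
    weight; pass :data:`pdtdose._constants.RU101_ISOTOPE_MASS` to use the
    101Ru isotope mass instead (0.16% difference).
    """
    ppb = np.asarray(ru_ppb, dtype=float)
    if np.any(ppb < 0) or digest_volume_l < 0:
        raise ValueError("ppb and digest volume must be >= 0")
    mass = ppb * digest_volume_l * (TLD1433_MW / ru_atomic_mass)
    return float(mass) if np.isscalar(ru_ppb) else mass


def tissue_concentration(
    mass_ug: float | np.ndarray,
    tissue_mass_g: float | np.ndarray,
    molecular_weight: float = TLD1433_MW,
) -> tuple:
    """Tissue concentration as (ug/g, molar), assuming density 1 g/mL."""
    m = np.asarray(mass_ug, dtype=float)
    tm = np.asarray(tissue_mass_g, dtype=float)
    if np.any(m < 0):
        raise ValueError("drug mass must be >= 0")
    if np.any(tm <= 0):
        raise ValueError("tissue mass must be > 0")
    ug_per_g = m / tm
    molar = ug_per_g * 1e-6 * TISSUE_DENSITY_G_PER_ML * 1e3 / molecular_weight
    if np.isscalar(mass_ug) and np.isscalar(tissue_mass_g):
        return float(ug_per_g), float(molar)
    return ug_per_g, molar


def add_concentrations(
    samples: pd.DataFrame,
    digest_volume_l: float = DEFAULT_DIGEST_VOLUME_L,
    ru_atomic_mass: float = RU_ATOMIC_WEIGHT,
) -> pd.DataFrame:
    """Append drug mass and concentration columns to an uptake table."""
    missing = set(UPTAKE_COLUMNS) - set(samples.columns)
    if missing:
        raise ValueError(f"uptake table missing columns: {sorted(missing)}")
    out = samples.copy()
    mass = ru_to_tld1433_mass(
        out["ru_ppb"].to_numpy(float), digest_volume_l, ru_atomic_mass
    )
    ug_per_g, molar = tissue_concentration(mass, out["tissue_mass_g"].to_numpy(float))
    out["tld1433_ug"] = mass
    out["conc_ug_per_g"] = ug_per_g
    out["conc_m"] = molar
    return out


@dataclass
class SurResult:
    """Specific uptake ratio between a target and a reference tissue group."""

    ratio: float | None
    status: Literal["ok", "absent", "undefined"]
    target: str
    reference: str
    target_mean_ug_per_g: float
    reference_mean_ug_per_g: float | None
    n_target: int
    n_reference: int
    low_n: bool                    # fewer than 3 animals in either group
    ci95: tuple[float, float] | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.status == "ok":
            return (
                f"SUR {self.target}/{self.reference} = {self.ratio:.2f} "
                f"(n={self.n_target}/{self.n_reference})"
            )
        return f"SUR {self.target}/{self.reference}: {self.status}"


def compute_sur(
    samples: pd.DataFrame,
    target: str = "tumor",
    reference: str = "contralateral_brain",
    timepoint_h: float | None = None,
    dose_mg_per_kg: float | None = None,
) -> SurResult:
    """Specific uptake ratio of group-mean concentrations.

    Filters the uptake table to the requested timepoint/dose group, takes
    the unweighted mean concentration per tissue, and returns their ratio.
    A reference group with zero mean concentration returns the ``absent``
    sentinel (complete absence of drug in normal tissue — very high
    selectivity, not a number); an empty reference group returns
    ``undefined``.  An empty target group is a data error.
    """
    if "conc_ug_per_g" not in samples.columns:
        samples = add_concentrations(samples)
    sel = samples
    if timepoint_h is not None:
        sel = sel[sel["timepoint_h"] == timepoint_h]
    if dose_mg_per_kg is not None:
        sel = sel[sel["dose_mg_per_kg"] == dose_mg_per_kg]
    tgt = sel.loc[sel["tissue"] == target, "conc_ug_per_g"].to_numpy(float)
    ref = sel.loc[sel["tissue"] == reference, "conc_ug_per_g"].to_numpy(float)
    if tgt.size == 0:
        raise ValueError(
            f"no {target!r} samples at timepoint={timepoint_h}, dose={dose_mg_per_kg}"
        )
    low_n = tgt.size < 3 or ref.size < 3
    tmean = float(tgt.mean())
    if ref.size == 0:
        return SurResult(None, "undefined", target, reference, tmean, None,
                         tgt.size, 0, low_n)
    rmean = float(ref.mean())
    if rmean == 0.0:
        return SurResult(None, "absent", target, reference, tmean, rmean,
                         tgt.size, ref.size, low_n)
    ratio = tmean / rmean
    ci = None
    if tgt.size > 1 and ref.size > 1 and tmean > 0:
        # first-order delta method on the ratio of independent means
        rel_var = tgt.var(ddof=1) / tgt.size / tmean**2 + ref.var(ddof=1) / ref.size / rmean**2
        se = ratio * np.sqrt(rel_var)
        ci = (float(ratio - 1.96 * se), float(ratio + 1.96 * se))
    return SurResult(float(ratio), "ok", target, reference, tmean, rmean,
                     tgt.size, ref.size, low_n, ci)
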