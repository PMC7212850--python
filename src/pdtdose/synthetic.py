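"""Seeded generators for every input the analysis pipeline consumes.

Each generator is a pure function of (design, seed): the same arguments
always reproduce the same table bit for bit.  Defaults emulate the
modeled study's conditions — plate concentration ranges (0–500 nM
Rutherrin, 0–6000 uM ALA) with Gaussian assay noise, lognormal tissue
concentrations with tumor-selective uptake (SUR ~ 20 early, > 10 at 48 h),
necrosis boundary radii produced by the forward threshold model plus
multiplicative jitter, and survival arms with medians near 4.5 / 8.5 /
12.5 days.

Noise families: Gaussian for viability (assay read noise), lognormal for
concentrations (positive, right-skewed biological variability), Weibull
(shape 3, roughly 36% CV) for survival times — rodent glioma survival
clusters far more tightly around its median than an exponential would;
an exponential family is selectable where memoryless arms are wanted.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import presets
from .dose_response import four_param_logistic, implied_ld50_concentration
from .light_transport import TissueOptics
from .photonics import LightSource, Photosensitizer
from .threshold import BoundaryObservation, predict_necrosis_radius, ug_per_g_to_molar
from ._constants import RU_ATOMIC_WEIGHT, TLD1433_MW

__all__ = [
    "PlateDesign",
    "UptakeDesign",
    "ThresholdDesign",
    "SurvivalDesign",
    "ScenarioConfig",
    "gen_plate",
    "gen_uptake",
    "gen_boundaries",
    "gen_survival",
    "default_scenario",
    "config_hash",
]


# ---------------------------------------------------------------------------
# Designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlateDesign:
    """True 4PL parameters and layout of a synthetic viability plate."""

    agent: str
    concentrations_m: tuple[float, ...]
    ld50_m: float
    hill: float = 1.5
    bottom: float = 0.0            # true kill% asymptotes
    top: float = 100.0
    replicates: int = 6
    noise_sd: float = 0.05         # viability-fraction scale (5% assay noise)
    solvent_level: float = 1.0
    kill_level: float = 0.03
    n_controls: int = 6


@dataclass(frozen=True)
class UptakeDesign:
    """Tissue-uptake study layout with target SUR per timepoint."""

    timepoints_h: tuple[float, ...] = (4.0, 24.0, 48.0)
    doses_mg_per_kg: tuple[float, ...] = (5.0, 10.0)
    n_per_group: int = 3
    tumor_conc_ug_per_g: float = 20.0
    sur_by_timepoint: tuple[tuple[float, float], ...] = ((4.0, 20.0), (24.0, 20.0), (48.0, 12.0))
    cv: float = 0.15
    tissue_mass_g: float = 0.1
    tissue_mass_cv: float = 0.2
    reference_tissues: tuple[str, ...] = ("contralateral_brain", "cerebellum")
    absent_probability: float = 0.0


@dataclass(frozen=True)
class ThresholdDesign:
    """Forward threshold-model configuration for one treatment condition."""

    name: str
    true_threshold_hv_cm3: float
    source: LightSource
    optics: TissueOptics
    ps: Photosensitizer
    tissue_concentration_m: float
    tissue: str = "tumor"
    n_animals: int = 6
    radius_jitter_cv: float = 0.05
    max_spread: float = 1.2        # r_max up to this factor beyond r_min


@dataclass(frozen=True)
class SurvivalDesign:
    """Survival arms by median; Weibull shape sets the dispersion."""

    arm_medians_days: tuple[tuple[str, float], ...] = (
        ("control", 4.5),
        ("ala_pdt", 8.5),
        ("rutherrin_pdt_5mg_4h", 12.5),
    )
    n_per_arm: int = 8
    family: str = "weibull"        # or "exponential"
    shape: float = 3.0
    censor_time_days: float | None = None


@dataclass(frozen=True)
class ScenarioConfig:
    """Every synthetic input of the end-to-end comparison."""

    rutherrin_plate: PlateDesign
    ala_plate: PlateDesign
    uptake: UptakeDesign
    thresholds: tuple[ThresholdDesign, ...]
    survival: SurvivalDesign


def _geometric_grid(top: float, n: int, factor: float = 2.0) -> tuple[float, ...]:
    return tuple(top / factor**i for i in reversed(range(n)))


def default_scenario(natural_log: bool = True) -> ScenarioConfig:
    """The study-conditions scenario.

    Plate LD50 truths are the concentrations implied by inverting the
    published absorbed-photon LD50s under the given light schedules;
    threshold truths are the published in vivo values with placeholder
    tissue concentrations chosen once to put necrosis radii at rat-brain
    (mm) scale.
    """
    ld50_ruth = implied_ld50_concentration(
        presets.LD50_RUTHERRIN_HV_CM3, presets.WELL_530, presets.RUTHERRIN,
        natural_log=natural_log,
    )
    ld50_ala = implied_ld50_concentration(
        presets.LD50_ALA_HV_CM3, presets.WELL_635, presets.ALA_PPIX,
        natural_log=natural_log,
    )
    ruth_plate = PlateDesign(
        agent="rutherrin",
        concentrations_m=_geometric_grid(500e-9, 10),
        ld50_m=ld50_ruth,
    )
    ala_plate = PlateDesign(
        agent="ala",
        concentrations_m=_geometric_grid(6000e-6, 10),
        ld50_m=ld50_ala,
    )
    c_tumor_ruth = ug_per_g_to_molar(presets.TUMOR_TLD1433_UG_PER_G, TLD1433_MW)
    c_tumor_ala = ug_per_g_to_molar(presets.TUMOR_PPIX_UG_PER_G, presets.ALA_PPIX.molecular_weight)
    thresholds = (
        ThresholdDesign(
            name="rutherrin_tumor",
            true_threshold_hv_cm3=presets.THRESHOLD_RUTHERRIN_TUMOR[0],
            source=presets.INTERSTITIAL_808,
            optics=presets.TUMOR_808,
            ps=presets.RUTHERRIN_808,
            tissue_concentration_m=c_tumor_ruth,
            tissue="tumor",
        ),
        ThresholdDesign(
            name="rutherrin_normal",
            true_threshold_hv_cm3=presets.THRESHOLD_RUTHERRIN_NORMAL[0],
            source=presets.INTERSTITIAL_808,
            optics=presets.GRAY_808,
            ps=presets.RUTHERRIN_808,
            tissue_concentration_m=c_tumor_ruth / presets.SUR_RUTHERRIN,
            tissue="normal_brain",
        ),
        ThresholdDesign(
            name="ala_tumor",
            true_threshold_hv_cm3=presets.THRESHOLD_ALA_TUMOR[0],
            source=presets.INTERSTITIAL_635,
            optics=presets.TUMOR_635,
            ps=presets.ALA_PPIX,
            tissue_concentration_m=c_tumor_ala,
            tissue="tumor",
        ),
        ThresholdDesign(
            name="ala_normal",
            true_threshold_hv_cm3=presets.THRESHOLD_ALA_NORMAL[0],
            source=presets.INTERSTITIAL_635,
            optics=presets.GRAY_635,
            ps=presets.ALA_PPIX,
            tissue_concentration_m=c_tumor_ala / presets.SUR_ALA_PPIX,
            tissue="normal_brain",
        ),
    )
    return ScenarioConfig(
        rutherrin_plate=ruth_plate,
        ala_plate=ala_plate,
        uptake=UptakeDesign(),
        thresholds=thresholds,
        survival=SurvivalDesign(),
    )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_plate(design: PlateDesign, seed: int) -> pd.DataFrame:
    """Synthetic viability plate: 4PL truth + Gaussian noise, clipped at 0."""
    rng = np.random.default_rng(seed)
    rows = []
    span = design.solvent_level - design.kill_level
    for flag, level in (("solvent", design.solvent_level), ("kill", design.kill_level)):
        v = level + rng.normal(0.0, design.noise_sd, design.n_controls)
        for i, vi in enumerate(v):
            rows.append((f"{flag[0].upper()}{i+1}", design.agent, 0.0,
                         max(0.0, vi), flag))
    for ci, conc in enumerate(design.concentrations_m):
        if conc > 0:
            kill = four_param_logistic(
                np.log10(conc), design.bottom, design.top,
                np.log10(design.ld50_m), design.hill,
            )
        else:
            kill = design.bottom
        true_v = design.kill_level + (1.0 - kill / 100.0) * span
        v = true_v + rng.normal(0.0, design.noise_sd, design.replicates)
        for ri, vi in enumerate(v):
            rows.append((f"C{ci+1}R{ri+1}", design.agent, conc,
                         max(0.0, vi), "treated"))
    return pd.DataFrame(
        rows, columns=["well_id", "agent", "concentration_M", "viability", "control_flag"]
    )


def _lognormal_mean(rng, mean: float, cv: float, size) -> np.ndarray:
    """Lognormal draws with the requested arithmetic mean and CV."""
    if mean == 0:
        return np.zeros(size)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def gen_uptake(design: UptakeDesign, seed: int) -> pd.DataFrame:
    """Synthetic ICP-MS uptake table (ru_ppb + tissue masses)."""
    rng = np.random.default_rng(seed)
    sur = dict(design.sur_by_timepoint)
    rows = []
    animal = 0
    for tp in design.timepoints_h:
        for dose in design.doses_mg_per_kg:
            for _ in range(design.n_per_group):
                animal += 1
                aid = f"A{animal:03d}"
                for tissue in ("tumor", *design.reference_tissues):
                    target = (
                        design.tumor_conc_ug_per_g
                        if tissue == "tumor"
                        else design.tumor_conc_ug_per_g / sur[tp]
                    )
                    conc = float(_lognormal_mean(rng, target, design.cv, ()))
                    if tissue != "tumor" and rng.random() < design.absent_probability:
                        conc = 0.0
                    mass = float(_lognormal_mean(rng, design.tissue_mass_g,
                                                 design.tissue_mass_cv, ()))
                    tld_ug = conc * mass
                    ru_ug = tld_ug / (TLD1433_MW / RU_ATOMIC_WEIGHT)
                    ppb = ru_ug / 0.002
                    rows.append((aid, tissue, tp, dose, ppb, mass))
    return pd.DataFrame(rows, columns=[
        "animal", "tissue", "timepoint_h", "dose_mg_per_kg", "ru_ppb", "tissue_mass_g",
    ])


def gen_boundaries(
    design: ThresholdDesign, seed: int, natural_log: bool = True
) -> list[BoundaryObservation]:
    """Forward threshold model + multiplicative radius jitter."""
    rng = np.random.default_rng(seed)
    r_fwd = predict_necrosis_radius(
        design.true_threshold_hv_cm3, design.source, design.optics,
        design.ps, design.tissue_concentration_m, natural_log=natural_log,
        xtol_cm=1e-6,
    )
    if r_fwd <= 0:
        raise ValueError(
            f"threshold design {design.name!r} yields no necrosis; check inputs"
        )
    obs = []
    for i in range(design.n_animals):
        jit = 1.0 + design.radius_jitter_cv * rng.standard_normal()
        r_min = max(0.2 * r_fwd, r_fwd * jit)
        r_max = r_min * rng.uniform(1.0, design.max_spread)
        obs.append(BoundaryObservation(
            animal_id=f"{design.name}_{i+1}", r_min_cm=float(r_min),
            r_max_cm=float(r_max), tissue=design.tissue,
        ))
    return obs


def boundaries_to_frame(obs: list[BoundaryObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        [(o.animal_id, o.r_min_cm, o.r_max_cm, o.tissue) for o in obs],
        columns=["animal_id", "r_min_cm", "r_max_cm", "tissue"],
    )


def gen_survival(design: SurvivalDesign, seed: int) -> pd.DataFrame:
    """Synthetic survival records per arm (times in days, event flag)."""
    rng = np.random.default_rng(seed)
    ln2 = np.log(2.0)
    rows = []
    sid = 0
    for arm, median in design.arm_medians_days:
        if design.family == "exponential":
            t = rng.exponential(median / ln2, design.n_per_arm)
        elif design.family == "weibull":
            scale = median / ln2 ** (1.0 / design.shape)
            t = scale * rng.weibull(design.shape, design.n_per_arm)
        else:
            raise ValueError(f"unknown survival family {design.family!r}")
        t = np.maximum(t, 1e-3)
        for ti in t:
            sid += 1
            if design.censor_time_days is not None and ti > design.censor_time_days:
                rows.append((f"S{sid:03d}", arm, design.censor_time_days, 0))
            else:
                rows.append((f"S{sid:03d}", arm, float(ti), 1))
    return pd.DataFrame(rows, columns=["subject", "arm", "time_days", "event"])


# ---------------------------------------------------------------------------
# Manifest support
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_hash(config: ScenarioConfig) -> str:
    """Stable sha256 of a scenario's JSON form (first 16 hex chars)."""
    payload = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
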