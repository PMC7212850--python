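"""Tabular and config file I/O.

All tables are plain CSV; the structured config is YAML with explicit
units in the field names.  A minimal text phantom format (JSON header
line + ASCII label planes) keeps voxel grids diff-able and
platform-independent.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .biodistribution import UPTAKE_COLUMNS
from .light_transport import Phantom, TissueOptics
from .photonics import LightSource, Photosensitizer
from .threshold import BoundaryObservation

__all__ = [
    "read_plate_csv", "write_plate_csv",
    "read_uptake_csv", "write_uptake_csv",
    "read_boundaries_csv", "write_boundaries_csv",
    "read_survival_csv", "write_survival_csv",
    "load_config", "save_phantom", "load_phantom", "load_mask_nifti",
]

PLATE_COLUMNS = ["well_id", "agent", "concentration_M", "viability", "control_flag"]
SURVIVAL_COLUMNS = ["subject", "arm", "time_days", "event"]
BOUNDARY_COLUMNS = ["animal_id", "r_min_cm", "r_max_cm", "tissue"]


def _read_csv(path, required):
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_plate_csv(path) -> pd.DataFrame:
    df = _read_csv(path, PLATE_COLUMNS)
    return df.astype({"concentration_M": float, "viability": float})


def write_plate_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def read_uptake_csv(path) -> pd.DataFrame:
    df = _read_csv(path, UPTAKE_COLUMNS)
    floats = ["timepoint_h", "dose_mg_per_kg", "ru_ppb", "tissue_mass_g"]
    return df.astype({c: float for c in floats})


def write_uptake_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def read_boundaries_csv(path) -> list[BoundaryObservation]:
    df = _read_csv(path, BOUNDARY_COLUMNS)
    return [
        BoundaryObservation(str(r.animal_id), float(r.r_min_cm),
                            float(r.r_max_cm), str(r.tissue))
        for r in df.itertuples()
    ]


def write_boundaries_csv(obs, path) -> None:
    pd.DataFrame(
        [(o.animal_id, o.r_min_cm, o.r_max_cm, o.tissue) for o in obs],
        columns=BOUNDARY_COLUMNS,
    ).to_csv(path, index=False, float_format="%.17g")


def read_survival_csv(path) -> pd.DataFrame:
    df = _read_csv(path, SURVIVAL_COLUMNS)
    return df.astype({"time_days": float, "event": int})


def write_survival_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Structured config
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load photosensitizers, light sources and tissue optics from YAML.

    Expected shape::

        photosensitizers:
          rutherrin: {epsilon: 8427.4, wavelength_nm: 530, molecular_weight: 1007,
                      precursor_ratio: 1}
        light_sources:
          well_530: {power: 0.36, mode: irradiance, wavelength_nm: 530,
                     duration_s: 55.56, geometry: flat_field}
        tissues:
          gray_808: {mu_a: 0.02, mu_s_prime: 16.62, g: 0.9, label: gray}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {"photosensitizers": {}, "light_sources": {}, "tissues": {}}
    for name, kw in (raw.get("photosensitizers") or {}).items():
        out["photosensitizers"][name] = Photosensitizer(name=name, **kw)
    for name, kw in (raw.get("light_sources") or {}).items():
        out["light_sources"][name] = LightSource(name=name, **kw)
    for name, kw in (raw.get("tissues") or {}).items():
        out["tissues"][name] = TissueOptics(**kw)
    return out


# ---------------------------------------------------------------------------
# Phantom text format
# ---------------------------------------------------------------------------

def save_phantom(phantom: Phantom, path) -> None:
    """Write a phantom as a JSON header line plus ASCII label planes."""
    header = {
        "shape": list(phantom.labels.shape),
        "voxel_cm": phantom.voxel_cm,
        "source_cm": list(phantom.source_cm),
        "optics": {
            str(lbl): {
                "mu_a": o.mu_a, "mu_s_prime": o.mu_s_prime,
                "g": o.g, "label": o.label,
            }
            for lbl, o in phantom.optics.items()
        },
    }
    with open(path, "w") as fh:
        fh.write("#pdtphantom " + json.dumps(header) + "\n")
        flat = phantom.labels.reshape(phantom.labels.shape[0], -1)
        np.savetxt(fh, flat, fmt="%d")


def load_phantom(path) -> Phantom:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#pdtphantom "):
            raise ValueError(f"{path} is not a phantom file")
        header = json.loads(first[len("#pdtphantom "):])
        flat = np.loadtxt(fh, dtype=np.uint8, ndmin=2)
    shape = tuple(header["shape"])
    optics = {
        int(lbl): TissueOptics(**kw) for lbl, kw in header["optics"].items()
    }
    return Phantom(
        labels=flat.reshape(shape),
        voxel_cm=float(header["voxel_cm"]),
        optics=optics,
        source_cm=tuple(header["source_cm"]),
    )


def load_mask_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Load a binary mask volume from NIfTI; returns (mask, voxel dims mm).

    Requires the optional ``nibabel`` dependency.
    """
    try:
        import nibabel as nib
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading NIfTI masks requires nibabel (pip install nibabel)"
        ) from exc
    img = nib.load(str(path))
    mask = np.asarray(img.dataobj) > 0
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return mask, zooms
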