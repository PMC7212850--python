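"""Interstitial light transport in turbid tissue.

Two transport routes around an isotropic point emitter:

* a diffusion-approximation closed form for a homogeneous medium,
  ``phi(r) = P exp(-mu_eff r) / (4 pi D r)`` with
  ``D = 1/(3 (mu_a + mu_s'))`` and ``mu_eff = sqrt(3 mu_a (mu_a + mu_s'))``
  — valid in the high-albedo regime a few transport mean free paths from
  the source;

* a voxel photon-packet Monte Carlo simulator: exponential step lengths
  ``-ln(xi)/mu_t``, fractional absorption ``w mu_a/mu_t`` deposited at each
  interaction, Henyey–Greenstein scattering, Russian roulette below a
  weight threshold.  Fluence in a voxel is the deposited weight divided by
  ``mu_a * voxel volume`` (the absorption estimator).

The Monte Carlo runs on a regular isotropic voxel grid of tissue labels
(a "phantom"); each label maps to a :class:`TissueOptics` entry.  The
random stream is an explicitly seeded PCG32 generator implemented inside
the kernel, so identical seeds give bit-identical fields on any platform.

Dose–volume histograms summarize a fluence field as cumulative tissue
volume receiving at least a given photon density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from numba import njit

from .photonics import LightSource, photon_energy

__all__ = [
    "TissueOptics",
    "Phantom",
    "FluenceField",
    "diffusion_fluence",
    "effective_penetration_depth",
    "mc_fluence",
    "radial_average",
    "dose_volume_histogram",
]


@dataclass(frozen=True)
class TissueOptics:
    """Bulk optical properties of one tissue class at one wavelength.

    mu_a and mu_s_prime in cm^-1; g (anisotropy) is used by the Monte
    Carlo only — the diffusion closed form depends on the reduced
    scattering coefficient alone.
    """

    mu_a: float
    mu_s_prime: float
    g: float = 0.9
    label: str = "tumor"

    def __post_init__(self) -> None:
        if not self.mu_a > 0:
            raise ValueError("mu_a must be > 0")
        if not self.mu_s_prime > 0:
            raise ValueError("mu_s_prime must be > 0")
        if not -1.0 < self.g < 1.0:
            raise ValueError("anisotropy g must lie in (-1, 1)")

    @property
    def mu_s(self) -> float:
        """Scattering coefficient [cm^-1] recovered from mu_s' = mu_s (1-g)."""
        return self.mu_s_prime / (1.0 - self.g)

    @property
    def diffusion_constant(self) -> float:
        """D = 1 / (3 (mu_a + mu_s')) [cm]."""
        return 1.0 / (3.0 * (self.mu_a + self.mu_s_prime))

    @property
    def mu_eff(self) -> float:
        """Effective attenuation coefficient sqrt(3 mu_a (mu_a + mu_s')) [cm^-1]."""
        return math.sqrt(3.0 * self.mu_a * (self.mu_a + self.mu_s_prime))

    @property
    def albedo(self) -> float:
        return self.mu_s / (self.mu_a + self.mu_s)


def diffusion_fluence(
    r_cm: float | np.ndarray, power_w: float, optics: TissueOptics
) -> float | np.ndarray:
    """Fluence rate [W cm^-2] at radius r from an isotropic point source.

    Infinite homogeneous medium diffusion approximation.  Singular at
    r = 0; callers must stay strictly away from the source.
    """
    r = np.asarray(r_cm, dtype=float)
    if np.any(r <= 0):
        raise ValueError("diffusion fluence is singular at r <= 0")
    if power_w < 0:
        raise ValueError("power must be >= 0")
    phi = power_w * np.exp(-optics.mu_eff * r) / (4.0 * math.pi * optics.diffusion_constant * r)
    return float(phi) if np.isscalar(r_cm) else phi


def effective_penetration_depth(optics: TissueOptics) -> float:
    """1/mu_eff [cm]: the distance over which fluence falls by 1/e (diffusive regime)."""
    return 1.0 / optics.mu_eff


@dataclass
class Phantom:
    """Isotropic voxel grid of tissue labels with a source position.

    ``labels[i, j, k]`` indexes into ``optics``; the source sits at
    ``source_cm`` in grid coordinates (origin at the corner of voxel
    (0,0,0)).
    """

    labels: np.ndarray
    voxel_cm: float
    optics: Mapping[int, TissueOptics]
    source_cm: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if not self.voxel_cm > 0:
            raise ValueError("voxel edge length must be > 0")
        present = np.unique(self.labels)
        undefined = [int(v) for v in present if int(v) not in self.optics]
        if undefined:
            raise ValueError(f"labels {undefined} missing from the optics table")
        if self.source_cm is None:
            self.source_cm = tuple(
                0.5 * n * self.voxel_cm for n in self.labels.shape
            )
        lo = np.zeros(3)
        hi = np.asarray(self.labels.shape) * self.voxel_cm
        src = np.asarray(self.source_cm, dtype=float)
        if np.any(src <= lo) or np.any(src >= hi):
            raise ValueError(f"source {tuple(src)} lies outside the grid {tuple(hi)}")

    @classmethod
    def homogeneous(
        cls,
        optics: TissueOptics,
        shape: tuple[int, int, int] = (81, 81, 81),
        voxel_cm: float = 0.02,
    ) -> "Phantom":
        """Uniform single-tissue phantom with a centered source."""
        return cls(
            labels=np.zeros(shape, dtype=np.uint8),
            voxel_cm=voxel_cm,
            optics={0: optics},
        )

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_cm ** 3

    @property
    def total_volume_cm3(self) -> float:
        return self.labels.size * self.voxel_volume_cm3

    def voxel_radii_cm(self) -> np.ndarray:
        """Distance of every voxel center from the source [cm]."""
        nx, ny, nz = self.labels.shape
        ax = (np.arange(nx) + 0.5) * self.voxel_cm - self.source_cm[0]
        ay = (np.arange(ny) + 0.5) * self.voxel_cm - self.source_cm[1]
        az = (np.arange(nz) + 0.5) * self.voxel_cm - self.source_cm[2]
        return np.sqrt(
            ax[:, None, None] ** 2 + ay[None, :, None] ** 2 + az[None, None, :] ** 2
        )

    def _optics_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nlab = max(self.optics) + 1
        mua = np.zeros(nlab)
        mus = np.zeros(nlab)
        g = np.zeros(nlab)
        for lbl, opt in self.optics.items():
            mua[lbl] = opt.mu_a
            mus[lbl] = opt.mu_s
            g[lbl] = opt.g
        return mua, mus, g


@dataclass
class FluenceField:
    """Monte Carlo fluence result on a phantom grid.

    ``fluence_per_packet`` is in cm^-2 per launched packet; multiplying by
    emitted power gives the fluence rate [W cm^-2], and by total delivered
    photons gives the time-integrated areal photon density [hv cm^-2].
    """

    fluence_per_packet: np.ndarray
    packets: int
    seed: int
    source: LightSource
    phantom: Phantom
    absorbed_weight: float
    escaped_weight: float
    roulette_killed_weight: float
    roulette_gained_weight: float

    @property
    def weight_balance_error(self) -> float:
        """Relative weight-accounting error (should be ~machine epsilon)."""
        accounted = (
            self.absorbed_weight
            + self.escaped_weight
            + self.roulette_killed_weight
            - self.roulette_gained_weight
        )
        return abs(accounted - self.packets) / self.packets

    @property
    def fluence_rate_w_cm2(self) -> np.ndarray:
        return self.fluence_per_packet * self.source.emitted_power_w

    @property
    def photon_density_cm2(self) -> np.ndarray:
        """Time-integrated areal photon density [hv cm^-2] per voxel."""
        n_photons = self.source.total_energy_j / photon_energy(self.source.wavelength_nm)
        return self.fluence_per_packet * n_photons


# ----------------------------------------------------------------------
# Monte Carlo kernel (PCG32 random stream; all state explicit)
# ----------------------------------------------------------------------

_PCG_MULT = np.uint64(6364136223846793005)
_PCG_INC = np.uint64(1442695040888963407)
_INV_2_32 = 1.0 / 4294967296.0


@njit(cache=True, inline="always")
def _pcg_next(state):
    state = state * _PCG_MULT + _PCG_INC
    xorshifted = np.uint32(((state >> np.uint64(18)) ^ state) >> np.uint64(27))
    rot = np.uint32(state >> np.uint64(59))
    out = np.uint32(
        (xorshifted >> rot) | (xorshifted << ((np.uint32(32) - rot) & np.uint32(31)))
    )
    return state, (float(out) + 0.5) * _INV_2_32


@njit(cache=True)
def _mc_kernel(labels, mua, mus, g, voxel, sx, sy, sz, packets, seed, weight_min,
               survive_p, absorb):
    nx, ny, nz = labels.shape
    state = np.uint64(seed) * np.uint64(2) + np.uint64(1)
    for _ in range(4):  # mix the seed
        state, _u = _pcg_next(state)
    absorbed = 0.0
    escaped = 0.0
    r_killed = 0.0
    r_gained = 0.0
    for _p in range(packets):
        x, y, z = sx, sy, sz
        state, u = _pcg_next(state)
        ct = 2.0 * u - 1.0
        st = math.sqrt(max(0.0, 1.0 - ct * ct))
        state, u = _pcg_next(state)
        phi = 2.0 * math.pi * u
        ux = st * math.cos(phi)
        uy = st * math.sin(phi)
        uz = ct
        w = 1.0
        i = int(x / voxel)
        j = int(y / voxel)
        k = int(z / voxel)
        while True:
            lbl = labels[i, j, k]
            mut = mua[lbl] + mus[lbl]
            state, u = _pcg_next(state)
            s = -math.log(u) / mut
            x += ux * s
            y += uy * s
            z += uz * s
            if x < 0.0 or y < 0.0 or z < 0.0:
                escaped += w
                break
            i = int(x / voxel)
            j = int(y / voxel)
            k = int(z / voxel)
            if i >= nx or j >= ny or k >= nz:
                escaped += w
                break
            lbl = labels[i, j, k]
            mut = mua[lbl] + mus[lbl]
            dep = w * mua[lbl] / mut
            absorb[i, j, k] += dep
            absorbed += dep
            w -= dep
            if w < weight_min:
                state, u = _pcg_next(state)
                if u < survive_p:
                    r_gained += w * (1.0 / survive_p - 1.0)
                    w /= survive_p
                else:
                    r_killed += w
                    break
            gg = g[lbl]
            state, u = _pcg_next(state)
            if abs(gg) < 1e-8:
                cos_t = 2.0 * u - 1.0
            else:
                tmp = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * u)
                cos_t = (1.0 + gg * gg - tmp * tmp) / (2.0 * gg)
            sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
            state, u = _pcg_next(state)
            psi = 2.0 * math.pi * u
            cp = math.cos(psi)
            sp = math.sin(psi)
            if abs(uz) > 0.99999:
                ux = sin_t * cp
                uy = sin_t * sp
                uz = cos_t if uz >= 0.0 else -cos_t
            else:
                den = math.sqrt(1.0 - uz * uz)
                nux = sin_t * (ux * uz * cp - uy * sp) / den + ux * cos_t
                nuy = sin_t * (uy * uz * cp + ux * sp) / den + uy * cos_t
                nuz = -sin_t * cp * den + uz * cos_t
                norm = math.sqrt(nux * nux + nuy * nuy + nuz * nuz)
                ux = nux / norm
                uy = nuy / norm
                uz = nuz / norm
    return absorbed, escaped, r_killed, r_gained


def mc_fluence(
    phantom: Phantom,
    source: LightSource,
    packets: int = 10**6,
    seed: int = 0,
    weight_min: float = 1e-4,
    survive_p: float = 0.1,
) -> FluenceField:
    """Photon-packet Monte Carlo fluence around an interstitial emitter.

    The emitter is modeled as an ideal isotropic point at the phantom's
    source position.  Steps are sampled from the optics of the voxel the
    packet occupies; the absorbed fraction is deposited in the voxel where
    the interaction lands (exact for homogeneous media, first-order for
    heterogeneous ones).  A packet whose step leaves the grid escapes
    (matched refractive index, no Fresnel reflection).

    Returns a :class:`FluenceField`; rerunning with identical arguments is
    bit-identical.
    """
    if source.geometry != "isotropic_point":
        raise ValueError(
            "Monte Carlo transport requires an isotropic_point source; got "
            f"geometry {source.geometry!r}"
        )
    source.emitted_power_w  # unit audit: must be power mode
    if packets < 10**4:
        raise ValueError("use at least 1e4 packets for a meaningful field")
    mua, mus, g = phantom._optics_arrays()
    absorb = np.zeros(phantom.labels.shape, dtype=np.float64)
    sx, sy, sz = phantom.source_cm
    absorbed, escaped, r_killed, r_gained = _mc_kernel(
        phantom.labels, mua, mus, g, phantom.voxel_cm,
        float(sx), float(sy), float(sz), int(packets), int(seed),
        float(weight_min), float(survive_p), absorb,
    )
    accounted = absorbed + escaped + r_killed - r_gained
    if abs(accounted - packets) / packets > 1e-2:
        raise RuntimeError(
            f"weight accounting off by {abs(accounted - packets) / packets:.3g}; "
            "transport kernel invariant violated"
        )
    mua_grid = mua[phantom.labels]
    fluence = absorb / (mua_grid * phantom.voxel_volume_cm3 * packets)
    return FluenceField(
        fluence_per_packet=fluence,
        packets=packets,
        seed=seed,
        source=source,
        phantom=phantom,
        absorbed_weight=absorbed,
        escaped_weight=escaped,
        roulette_killed_weight=r_killed,
        roulette_gained_weight=r_gained,
    )


def radial_average(
    values: np.ndarray, phantom: Phantom, r_edges: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Average a per-voxel quantity over spherical shells around the source.

    Returns (bin centers, shell means); empty shells give NaN.
    """
    r = phantom.voxel_radii_cm().ravel()
    v = np.asarray(values, dtype=float).ravel()
    if v.size != r.size:
        raise ValueError("values grid does not match the phantom grid")
    idx = np.digitize(r, r_edges) - 1
    nbins = len(r_edges) - 1
    means = np.full(nbins, np.nan)
    for b in range(nbins):
        sel = idx == b
        if np.any(sel):
            means[b] = v[sel].mean()
    centers = 0.5 * (np.asarray(r_edges)[:-1] + np.asarray(r_edges)[1:])
    return centers, means


def dose_volume_histogram(
    field: FluenceField, phantom: Phantom, values: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative dose–volume histogram of a fluence field.

    Returns ``(dose, volume_cm3)`` where ``volume_cm3[i]`` is the tissue
    volume receiving at least ``dose[i]`` (photon density [hv cm^-2] by
    default).  The curve is non-increasing and starts at the total phantom
    volume for dose 0.
    """
    if field.phantom.labels.shape != phantom.labels.shape:
        raise ValueError("fluence field and phantom grids do not match")
    v = field.photon_density_cm2 if values is None else np.asarray(values)
    if v.shape != phantom.labels.shape:
        raise ValueError("values grid does not match the phantom grid")
    flat = np.sort(v.ravel())
    doses = np.concatenate([[0.0], np.unique(flat)])
    # voxels with value >= d, exact under ties
    n_at_least = flat.size - np.searchsorted(flat, doses, side="left")
    return doses, n_at_least * phantom.voxel_volume_cm3
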