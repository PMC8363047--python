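"""Synthetic data, analytic oracles, and preclinical dosing arithmetic.

Three groups of tools, all closed-form or seed-deterministic so every stage
of the pipeline is testable without external data:

* preclinical dosing — hemi-ellipsoid caliper volumes, volume-normalized
  iron doses, and the injected-volume -> iron-mass chain used for mouse
  xenograft treatments;
* synthetic cohorts — reproducible tables of tumor volumes drawn from the
  small (0.15 +/- 0.03 cm^3) and large (0.30 +/- 0.06 cm^3) group
  distributions, with back-derived caliper triples and dosing columns;
* solver verification — a method-of-manufactured-solutions case for the
  Pennes equation and the heated-sphere conduction oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable

import numpy as np
import pandas as pd

from .tissue import BloodProperties, TissueProperties, VoxelGrid

#: Hemi-ellipsoid prefactor: V = 0.5236 * L * w * h ~ (pi/6) * L * w * h.
HEMI_ELLIPSOID_FACTOR = 0.5236

#: Preclinical volume-normalized iron dose, mg Fe per cm^3 of tumor
#: (tissue density ~1 g/cm^3, so numerically equal to mg Fe/g).
PRECLINICAL_DOSE_MG_PER_CM3 = 5.5

#: Working MION suspension concentration for intratumor injection, mg Fe/ml.
STOCK_CONCENTRATION_MG_PER_ML = 23.6

#: Intratumor injections are unreliable below this tumor volume (cm^3).
MIN_RELIABLE_VOLUME_CM3 = 0.1

#: Caliper aspect ratio L:w:h used to back-derive triples from a volume.
CALIPER_ASPECT = (1.2, 1.0, 0.8)


# ---------------------------------------------------------------------------
# rounding helpers (presentation rule: round half away from zero)


def round_half_away(x: float, decimals: int) -> float:
    """Round to ``decimals`` places, halves away from zero (0.825 -> 0.83)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(f"{x:.12g}").quantize(q, rounding=ROUND_HALF_UP))


def round_sig_away(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures, halves away from zero."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round_half_away(x, sig - 1 - exponent)


# ---------------------------------------------------------------------------
# preclinical dosing arithmetic


def tumor_volume(length: float, width: float, height: float) -> float:
    """Hemi-ellipsoid tumor volume from caliper measurements (cm -> cm^3)."""
    if length < 0 or width < 0 or height < 0:
        raise ValueError("caliper dimensions must be >= 0")
    return HEMI_ELLIPSOID_FACTOR * length * width * height


def fe_dose(volume_cm3: float,
            dose_density: float = PRECLINICAL_DOSE_MG_PER_CM3) -> float:
    """Unrounded iron dose (mg Fe) for a tumor volume at a normalized dose."""
    if volume_cm3 < 0:
        raise ValueError("tumor volume must be >= 0")
    return dose_density * volume_cm3


def fe_dose_reported(volume_cm3: float,
                     dose_density: float = PRECLINICAL_DOSE_MG_PER_CM3
                     ) -> float:
    """Iron dose rounded to 2 significant figures for reporting
    (0.15 cm^3 -> 0.83 mg; 0.30 cm^3 -> 1.7 mg)."""
    return round_sig_away(fe_dose(volume_cm3, dose_density), 2)


def injection_volume_ul(fe_mg: float,
                        stock_concentration: float =
                        STOCK_CONCENTRATION_MG_PER_ML) -> float:
    """Injection volume (ul) delivering ``fe_mg`` of iron from the stock."""
    if fe_mg < 0:
        raise ValueError("fe_mg must be >= 0")
    return fe_mg / stock_concentration * 1000.0


def injected_fe(injection_ul: float,
                stock_concentration: float =
                STOCK_CONCENTRATION_MG_PER_ML) -> float:
    """Iron mass (mg) in an injected volume, reported to two decimals
    (37 ul -> 0.87 mg; 75 ul -> 1.77 mg)."""
    if injection_ul < 0:
        raise ValueError("injection volume must be >= 0")
    return round_half_away(injection_ul * stock_concentration / 1000.0, 2)


@dataclass(frozen=True)
class DosingRecord:
    """One animal's dosing chain: volume -> Fe dose -> injection volume."""

    tumor_volume_cm3: float
    dose_density: float = PRECLINICAL_DOSE_MG_PER_CM3
    stock_concentration: float = STOCK_CONCENTRATION_MG_PER_ML

    @property
    def fe_mg(self) -> float:
        return fe_dose(self.tumor_volume_cm3, self.dose_density)

    @property
    def fe_mg_reported(self) -> float:
        return round_sig_away(self.fe_mg, 2)

    @property
    def injection_ul(self) -> float:
        return injection_volume_ul(self.fe_mg, self.stock_concentration)


# ---------------------------------------------------------------------------
# synthetic cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic two-arm mouse cohort.

    Tumor volumes are normal within each arm — small: mean 0.15, sd 0.03;
    large: mean 0.30, sd 0.06 (cm^3) — truncated below ``min_volume_cm3``
    because intratumor injection is unreliable in smaller tumors.  An
    optional upper cutoff models a protocol inclusion window.
    """

    seed: int
    n_small: int = 4
    n_large: int = 5
    small_mean: float = 0.15
    small_sd: float = 0.03
    large_mean: float = 0.30
    large_sd: float = 0.06
    min_volume_cm3: float = MIN_RELIABLE_VOLUME_CM3
    max_volume_cm3: float | None = None

    def __post_init__(self) -> None:
        if self.n_small < 1 or self.n_large < 1:
            raise ValueError("group sizes must be >= 1")


def _truncated_normal(rng: np.random.Generator, n: int, mean: float,
                      sd: float, lo: float, hi: float | None) -> np.ndarray:
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        ok = draw > lo
        if hi is not None:
            ok &= draw < hi
        keep = draw[ok][: n - filled]
        out[filled:filled + keep.size] = keep
        filled += keep.size
    return out


def caliper_triple(volume_cm3: float,
                   aspect: tuple[float, float, float] = CALIPER_ASPECT
                   ) -> tuple[float, float, float]:
    """Caliper (L, w, h) in cm consistent with a hemi-ellipsoid volume.

    Uses a fixed aspect ratio, so :func:`tumor_volume` round-trips the
    volume to machine precision.
    """
    a, b, c = aspect
    s = (volume_cm3 / (HEMI_ELLIPSOID_FACTOR * a * b * c)) ** (1.0 / 3.0)
    return a * s, b * s, c * s


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Reproducible per-animal measurement and dosing table.

    Columns: animal_id, group, volume_cm3, L_cm, w_cm, h_cm, fe_mg,
    fe_mg_reported, injection_ul, injected_fe_mg.
    """
    rng = np.random.default_rng(spec.seed)
    vols = np.concatenate([
        _truncated_normal(rng, spec.n_small, spec.small_mean, spec.small_sd,
                          spec.min_volume_cm3, spec.max_volume_cm3),
        _truncated_normal(rng, spec.n_large, spec.large_mean, spec.large_sd,
                          spec.min_volume_cm3, spec.max_volume_cm3),
    ])
    groups = ["small"] * spec.n_small + ["large"] * spec.n_large
    rows = []
    for i, (group, v) in enumerate(zip(groups, vols), start=1):
        L, w, h = caliper_triple(v)
        record = DosingRecord(tumor_volume_cm3=v)
        rows.append({
            "animal_id": i,
            "group": group,
            "volume_cm3": v,
            "L_cm": L, "w_cm": w, "h_cm": h,
            "fe_mg": record.fe_mg,
            "fe_mg_reported": record.fe_mg_reported,
            "injection_ul": record.injection_ul,
            "injected_fe_mg": injected_fe(record.injection_ul),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# solver verification oracles


@dataclass(frozen=True)
class ManufacturedCase:
    """Manufactured solution of the Pennes equation on a homogeneous box.

    Prescribes ``T*(x, t) = T_b + A exp(-lambda t) prod_i cos(k_i x_i)`` and
    the source that forces the bioheat equation to admit it exactly:

        Q*(x, t) = (-lambda rho c + k |k|^2 + rho_b c_b w_b)
                   * A exp(-lambda t) prod_i cos(k_i x_i).

    With ``k_i = n_i pi / L_i`` the solution has zero normal derivative on
    the box faces, matching adiabatic boundaries.
    """

    wavenumbers: tuple[float, float, float]
    decay_rate: float
    amplitude: float
    props: TissueProperties
    blood: BloodProperties

    @property
    def source_coefficient(self) -> float:
        k2 = sum(k ** 2 for k in self.wavenumbers)
        return (-self.decay_rate * self.props.volumetric_heat_capacity
                + self.props.conductivity * k2
                + self.blood.perfusion_factor * self.props.perfusion)

    def _mode(self, x, y, z):
        kx, ky, kz = self.wavenumbers
        return np.cos(kx * np.asarray(x)) * np.cos(ky * np.asarray(y)) \
            * np.cos(kz * np.asarray(z))

    def temperature(self, x, y, z, t: float):
        """Exact solution T*(x, t) in C."""
        return (self.blood.arterial_temperature
                + self.amplitude * np.exp(-self.decay_rate * t)
                * self._mode(x, y, z))

    def source(self, x, y, z, t: float):
        """Forcing Q*(x, t) in W/m^3."""
        return (self.source_coefficient * self.amplitude
                * np.exp(-self.decay_rate * t) * self._mode(x, y, z))


def mms_case(wavenumbers: tuple[float, float, float], decay_rate: float,
             amplitude: float, props: TissueProperties,
             blood: BloodProperties) -> ManufacturedCase:
    """Build a manufactured verification case (homogeneous properties)."""
    return ManufacturedCase(wavenumbers=tuple(wavenumbers),
                            decay_rate=decay_rate, amplitude=amplitude,
                            props=props, blood=blood)


def heated_sphere_oracle(Q: float, R: float, k: float, T_inf: float
                         ) -> Callable[[np.ndarray], np.ndarray]:
    """Steady conduction around a uniformly heated sphere (no perfusion).

    Returns T(r) for a sphere of radius ``R`` heated at ``Q`` W/m^3 in an
    infinite medium of conductivity ``k`` with far-field temperature
    ``T_inf``:

        T(r <= R) = T_inf + Q (3 R^2 - r^2) / (6 k)
        T(r >  R) = T_inf + Q R^3 / (3 k r)

    Continuous at r = R; center excess Q R^2 / (2k) is exactly 3/2 the
    surface excess Q R^2 / (3k).
    """

    def profile(r):
        r = np.asarray(r, dtype=float)
        inside = T_inf + Q * (3 * R ** 2 - r ** 2) / (6.0 * k)
        with np.errstate(divide="ignore"):
            outside = T_inf + Q * R ** 3 / (3.0 * k * np.maximum(r, 1e-300))
        out = np.where(r <= R, inside, outside)
        return float(out) if out.ndim == 0 else out

    return profile


# ---------------------------------------------------------------------------
# test-bed grids


def uniform_box_grid(shape: tuple[int, int, int], spacing: float,
                     name: str = "medium",
                     origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
                     ) -> VoxelGrid:
    """A fully interior single-region box grid for verification studies."""
    labels = np.zeros(shape, dtype=np.int16)
    return VoxelGrid(spacing=spacing, origin=origin, labels=labels,
                     region_names=(name,))


def water_like(name: str = "medium", *, conductivity: float = 0.5,
               density: float = 1000.0, specific_heat: float = 4000.0,
               perfusion: float = 0.0, metabolic_rate: float = 0.0,
               electrical_conductivity: float = 0.0) -> TissueProperties:
    """Convenience homogeneous soft-tissue-like property set."""
    return TissueProperties(name=name, density=density,
                            specific_heat=specific_heat,
                            conductivity=conductivity, perfusion=perfusion,
                            metabolic_rate=metabolic_rate,
                            electrical_conductivity=electrical_conductivity)
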