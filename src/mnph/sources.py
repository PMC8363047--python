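"""Volumetric heat sources and AMF exposure schedules.

Two sources drive the bioheat model:

* nonspecific eddy-current (Joule) heating of conductive tissue,
  ``Q_eddy = (sigma_t / 2) * (pi * mu0 * r * f * H)**2`` with ``r`` the
  perpendicular distance from the coil axis — the physical cost of exposing
  a human-scale conductor to an alternating magnetic field; and
* nanoparticle heating ``Q_p``, a uniform volumetric rate over the
  MION-loaded region obtained from a volume-normalized iron dose
  (mg Fe per cm^3 of tumor) and a specific-loss-power model SLP(H) in W/g Fe.

Pulsed operation is described by a duty cycle,
``duty% = on / (on + off) * 100``; reducing the duty lets perfusion clear
nonspecific heat between pulses at the price of a longer elapsed treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .tissue import AXIS_INDEX, BodyModel, VoxelGrid

#: Vacuum permeability, T m / A.
MU0 = 4e-7 * np.pi

#: Clinically permissible H*f product for a 30 cm diameter tissue region,
#: A/(m s) (Atkinson-Brezovich-type limit); compliance is a strict inequality.
CLINICAL_HF_LIMIT = 4.85e8


@dataclass(frozen=True)
class AMFExposure:
    """Alternating magnetic field exposure.

    ``amplitude_peak`` is the PEAK field amplitude H in A/m.  Hardware specs
    quoted peak-to-peak must be halved at the boundary (a silent factor-of-4
    error in eddy heating otherwise); use :meth:`from_peak_to_peak`.
    """

    amplitude_peak: float
    frequency: float
    coil_axis: str = "y"

    def __post_init__(self) -> None:
        if self.amplitude_peak < 0:
            raise ValueError("amplitude_peak must be >= 0")
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if self.coil_axis not in AXIS_INDEX:
            raise ValueError("coil_axis must be one of x/y/z")

    @classmethod
    def from_peak_to_peak(cls, amplitude_pp: float, frequency: float,
                          coil_axis: str = "y") -> "AMFExposure":
        """Convert a peak-to-peak amplitude spec to the internal peak value."""
        return cls(amplitude_pp / 2.0, frequency, coil_axis)


@dataclass(frozen=True)
class PulseSchedule:
    """An on/off pulse train delivering a fixed cumulative AMF-on time.

    The train starts ON at t = 0 and repeats with period
    ``on_block_s + off_block_s`` until ``total_on_s`` of on-time has been
    delivered; the elapsed duration is ``total_on_s / (duty/100)``.
    """

    duty_percent: float
    on_block_s: float
    off_block_s: float
    total_on_s: float

    def __post_init__(self) -> None:
        if not 0 < self.duty_percent <= 100:
            raise ValueError("duty_percent must lie in (0, 100]")
        if self.on_block_s <= 0 or self.off_block_s < 0 or self.total_on_s <= 0:
            raise ValueError("block lengths must be positive")
        duty = 100.0 * self.on_block_s / (self.on_block_s + self.off_block_s)
        if abs(duty - self.duty_percent) > 1e-3 * self.duty_percent:
            raise ValueError(
                f"duty_percent {self.duty_percent} inconsistent with blocks "
                f"(implies {duty:.4f}%)")

    @property
    def period_s(self) -> float:
        return self.on_block_s + self.off_block_s

    @property
    def elapsed_s(self) -> float:
        """Total elapsed (wall-clock) duration of the treatment."""
        return self.total_on_s * 100.0 / self.duty_percent


def schedule_from_duty(duty_percent: float, on_block_s: float = 30.0,
                       total_on_s: float = 1200.0) -> PulseSchedule:
    """Build a pulse schedule from a duty cycle and an on-block length.

    ``total_on_s`` must be an integer multiple of ``on_block_s`` so every arm
    of a duty sweep delivers exactly the same cumulative on-time.
    """
    if not 0 < duty_percent <= 100:
        raise ValueError("duty_percent must lie in (0, 100]")
    if on_block_s <= 0 or total_on_s <= 0:
        raise ValueError("on_block_s and total_on_s must be > 0")
    n_blocks = total_on_s / on_block_s
    if abs(n_blocks - round(n_blocks)) > 1e-9 * n_blocks:
        raise ValueError("total_on_s must be an integer multiple of on_block_s")
    off = on_block_s * (100.0 / duty_percent - 1.0)
    return PulseSchedule(duty_percent=duty_percent, on_block_s=on_block_s,
                         off_block_s=off, total_on_s=total_on_s)


def power_factor(t, schedule: PulseSchedule):
    """AMF power modulation factor at time ``t`` (scalar or array): 1 during
    on-blocks, 0 during off-blocks.  Its time average over one period equals
    ``duty/100`` exactly."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    phase = np.mod(t, schedule.period_s)
    out = (phase < schedule.on_block_s).astype(float)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ComplianceResult:
    """Outcome of the clinical H*f exposure check (strict inequality)."""

    product: float
    limit: float
    passed: bool

    @property
    def margin(self) -> float:
        return self.limit - self.product


def compliance_check(H: float, f: float) -> ComplianceResult:
    """Check H*f against the 30 cm torso exposure limit (strict '<')."""
    if H < 0 or f < 0:
        raise ValueError("H and f must be >= 0")
    product = H * f
    return ComplianceResult(product=product, limit=CLINICAL_HF_LIMIT,
                            passed=product < CLINICAL_HF_LIMIT)


# ---------------------------------------------------------------------------
# eddy-current heating


def q_eddy(sigma, r, f, H):
    """Volumetric eddy-current heating rate, W/m^3.

    ``(sigma/2) * (pi * mu0 * r * f * H)**2``: quadratic in the radial
    distance ``r`` from the coil axis, the frequency ``f`` and the peak
    amplitude ``H``, linear in the tissue electrical conductivity ``sigma``.
    Accepts scalars or broadcastable arrays.
    """
    sigma, r, f, H = (np.asarray(a, dtype=float) for a in (sigma, r, f, H))
    if any(np.any(a < 0) for a in (sigma, r, f, H)):
        raise ValueError("q_eddy arguments must be >= 0")
    out = 0.5 * sigma * (np.pi * MU0 * r * f * H) ** 2
    return float(out) if out.ndim == 0 else out


def eddy_field(grid: VoxelGrid, body: BodyModel,
               exposure: AMFExposure) -> np.ndarray:
    """Per-voxel eddy-current heating field, W/m^3 (exterior voxels 0).

    Each voxel uses its tissue's electrical conductivity and its
    perpendicular distance from the coil axis (which passes through the
    torso center).  ``body`` must be the body the grid was voxelized from.
    """
    missing = set(grid.region_names) - set(body.region_names)
    if missing:
        raise ValueError(f"grid regions not in body: {sorted(missing)}")
    sigma_lut = np.array(
        [body.region(n).properties.electrical_conductivity
         for n in grid.region_names])
    labels = grid.labels
    sigma = np.where(labels >= 0, sigma_lut[np.clip(labels, 0, None)], 0.0)

    ax = AXIS_INDEX[exposure.coil_axis]
    perp = [i for i in range(3) if i != ax]
    coords = [grid.axis_centers(i) for i in range(3)]
    shape3 = [1, 1, 1]
    r2 = np.zeros(grid.shape)
    for i in perp:
        s = list(shape3)
        s[i] = -1
        r2 = r2 + (coords[i].reshape(s)) ** 2
    return q_eddy(sigma, np.sqrt(r2), exposure.frequency,
                  exposure.amplitude_peak)


# ---------------------------------------------------------------------------
# nanoparticle heating


@dataclass(frozen=True)
class SLPModel:
    """Polynomial specific-loss-power model SLP(H) in W/g Fe.

    ``coefficients`` are ascending polynomial coefficients in H (A/m); the
    constant term must be zero (no field, no heating) and the polynomial must
    be nonnegative and nondecreasing on ``valid_range``.  Evaluation outside
    the valid range raises (no extrapolation).
    """

    coefficients: tuple[float, ...]
    valid_range: tuple[float, float] = (0.0, 1.0e4)
    reference_frequency: float = 155e3

    def __post_init__(self) -> None:
        c = self.coefficients
        if not c or abs(c[0]) > 0:
            raise ValueError("SLP(0) must be 0: constant coefficient is zero")
        lo, hi = self.valid_range
        if not 0 <= lo < hi:
            raise ValueError("invalid valid_range")
        H = np.linspace(lo, hi, 513)
        vals = np.polynomial.polynomial.polyval(H, c)
        if np.any(vals < -1e-12) or np.any(np.diff(vals) < -1e-12):
            raise ValueError("SLP must be nonnegative and nondecreasing "
                             "on its valid range")

    def __call__(self, H) -> float:
        return self.evaluate(H)

    def evaluate(self, H):
        """SLP at peak amplitude H (A/m), W/g Fe."""
        H = np.asarray(H, dtype=float)
        lo, hi = self.valid_range
        if np.any(H < lo) or np.any(H > hi):
            raise ValueError(f"H outside SLP valid range [{lo}, {hi}] A/m")
        out = np.polynomial.polynomial.polyval(H, self.coefficients)
        return float(out) if out.ndim == 0 else out

    @classmethod
    def default(cls) -> "SLPModel":
        """Shipped placeholder SLP model (synthetic, not a measured curve).

        A monotone quadratic through the origin at 155 kHz,
        ``SLP(H) = 3.2e-7 * H**2`` W/g Fe, calibrated so that the standard
        scenario (5 mg Fe/cm^3 volume-normalized dose, H*f at the clinical
        limit, 2 cm tumor) reaches hyperthermic tumor temperatures
        (41-46 C).  Replace with a measured nanoparticle curve via config
        for quantitative work.
        """
        return cls(coefficients=(0.0, 0.0, 3.2e-7))


@dataclass(frozen=True)
class MIONLoading:
    """A volume-normalized iron dose deposited in a fill region.

    ``dose_density`` is mg Fe per cm^3 of *tumor*; the total iron mass is
    ``dose_density * tumor_volume_cm3`` and is deposited uniformly over
    ``fill_region`` (default: the MION core sphere).
    """

    dose_density: float
    tumor_volume_cm3: float
    fill_region: str = "mion"

    def __post_init__(self) -> None:
        if self.dose_density < 0:
            raise ValueError("dose_density must be >= 0")
        if self.tumor_volume_cm3 < 0:
            raise ValueError("tumor_volume_cm3 must be >= 0")

    @property
    def total_fe_mg(self) -> float:
        return self.dose_density * self.tumor_volume_cm3

    @classmethod
    def for_tumor_radius(cls, dose_density: float, tumor_radius_m: float,
                         fill_region: str = "mion") -> "MIONLoading":
        """Loading for a spherical tumor using the analytic volume."""
        volume_cm3 = 4.0 / 3.0 * np.pi * (100.0 * tumor_radius_m) ** 3
        return cls(dose_density=dose_density, tumor_volume_cm3=volume_cm3,
                   fill_region=fill_region)


def q_p_field(grid: VoxelGrid, loading: MIONLoading, slp: SLPModel,
              exposure: AMFExposure) -> np.ndarray:
    """Per-voxel nanoparticle heating field, W/m^3.

    ``Q_p = SLP(H) * m_Fe / V_fill`` uniformly over the fill region, zero
    elsewhere.  The fill volume is the voxelized region volume, so the total
    deposited power ``sum(Q_p * voxel_volume)`` equals ``SLP(H) * m_Fe``
    exactly at any spacing (power conservation).
    """
    mask = grid.region_mask(loading.fill_region)
    n_fill = int(mask.sum())
    if n_fill == 0:
        raise ValueError(f"fill region {loading.fill_region!r} is empty")
    slp_w_per_g = slp.evaluate(exposure.amplitude_peak)
    fe_g = loading.total_fe_mg / 1000.0
    fill_volume = n_fill * grid.voxel_volume
    q = np.zeros(grid.shape)
    q[mask] = slp_w_per_g * fe_g / fill_volume
    return q
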