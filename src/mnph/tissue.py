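"""Idealized torso geometry, tissue properties, and voxelization.

The planning geometry is a human-scale multilayer cylindrical torso:
concentric skin, fat and muscle cylinders along the long (Y) axis, a
pancreas cylinder along X, and a spherical pancreatic tumor at the torso
center whose concentric core (half the tumor radius by default) is loaded
with magnetic iron-oxide nanoparticles (MIONs).  Regions are painted onto a
regular isotropic voxel grid by precedence (innermost region wins), which is
the mesh the finite-difference bioheat solver runs on.

Default tissue properties ship in ``mnph/data/tissue_properties.yaml`` and
are representative IT'IS-database values; everything is overridable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

Axis = Literal["x", "y", "z"]
AXIS_INDEX: Mapping[str, int] = {"x": 0, "y": 1, "z": 2}

#: Validated range of tumor sphere radii for the default torso (m).
TUMOR_RADIUS_RANGE = (0.005, 0.03)

SKIN_OUTER_RADIUS = 0.126
FAT_OUTER_RADIUS = 0.1244
MUSCLE_OUTER_RADIUS = 0.109
TORSO_HEIGHT = 0.55
PANCREAS_RADIUS = 0.075
PANCREAS_HEIGHT = 0.10
MION_RADIUS_FRACTION = 0.5

#: Grids coarser than this cannot resolve the 1.6 mm skin shell; by default
#: the fat and skin shells are then merged into one ``fat_skin`` region.
SKIN_RESOLUTION_LIMIT = 1.5e-3

EXTERIOR_LABEL = -1


class GeometryError(ValueError):
    """Raised when a body's regions violate the required nesting."""


@dataclass(frozen=True)
class TissueProperties:
    """Thermal and electrical properties of one tissue.

    Parameters
    ----------
    name : str
        Tissue label.
    density : float
        rho, kg/m^3.
    specific_heat : float
        c, J/(kg K).
    conductivity : float
        Thermal conductivity k, W/(m K).
    perfusion : float
        Blood perfusion rate omega_b, 1/s (blood volume per tissue volume
        per second).
    metabolic_rate : float
        Volumetric metabolic heat Q_m, W/m^3.
    electrical_conductivity : float
        sigma_t, S/m, used for induced eddy-current heating.
    """

    name: str
    density: float
    specific_heat: float
    conductivity: float
    perfusion: float = 0.0
    metabolic_rate: float = 0.0
    electrical_conductivity: float = 0.0

    def __post_init__(self) -> None:
        for attr in ("density", "specific_heat", "conductivity"):
            if not getattr(self, attr) > 0:
                raise ValueError(f"{self.name}: {attr} must be > 0")
        for attr in ("perfusion", "metabolic_rate", "electrical_conductivity"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{self.name}: {attr} must be >= 0")

    @property
    def volumetric_heat_capacity(self) -> float:
        """rho * c, J/(m^3 K)."""
        return self.density * self.specific_heat

    def scaled(self, name: str, *, perfusion_ratio: float = 1.0,
               metabolic_ratio: float = 1.0) -> "TissueProperties":
        """Derived tissue with scaled perfusion and metabolic rate."""
        return replace(self, name=name,
                       perfusion=self.perfusion * perfusion_ratio,
                       metabolic_rate=self.metabolic_rate * metabolic_ratio)


@dataclass(frozen=True)
class BloodProperties:
    """Arterial blood entering the perfusion sink of the bioheat equation."""

    density: float = 1050.0
    specific_heat: float = 3617.0
    arterial_temperature: float = 37.0

    def __post_init__(self) -> None:
        if self.density <= 0 or self.specific_heat <= 0:
            raise ValueError("blood density and specific heat must be > 0")
        if not 30.0 <= self.arterial_temperature <= 40.0:
            raise ValueError("arterial temperature must lie in [30, 40] C")

    @property
    def perfusion_factor(self) -> float:
        """rho_b * c_b, multiplied by omega_b to give the sink strength."""
        return self.density * self.specific_heat


@dataclass(frozen=True)
class Region:
    """A labeled geometric region (axis-aligned cylinder or sphere).

    ``precedence`` resolves overlaps during voxelization: the region with the
    highest precedence containing a voxel center owns the voxel.
    """

    name: str
    shape: Literal["cylinder", "sphere"]
    outer_radius: float
    center: tuple[float, float, float]
    properties: TissueProperties
    precedence: int
    axis: Axis | None = None
    height: float | None = None

    def __post_init__(self) -> None:
        if self.outer_radius <= 0:
            raise ValueError(f"{self.name}: outer_radius must be > 0")
        if self.shape == "cylinder":
            if self.axis not in AXIS_INDEX:
                raise ValueError(f"{self.name}: cylinder needs axis x/y/z")
            if self.height is None or self.height <= 0:
                raise ValueError(f"{self.name}: cylinder height must be > 0")
        elif self.shape != "sphere":
            raise ValueError(f"{self.name}: unknown shape {self.shape!r}")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized membership test for an (N, 3) array of points."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d = points - np.asarray(self.center)
        if self.shape == "sphere":
            return (d ** 2).sum(axis=1) <= self.outer_radius ** 2
        ax = AXIS_INDEX[self.axis]  # type: ignore[index]
        perp = [i for i in range(3) if i != ax]
        radial = d[:, perp[0]] ** 2 + d[:, perp[1]] ** 2
        return (radial <= self.outer_radius ** 2) & \
            (np.abs(d[:, ax]) <= self.height / 2)  # type: ignore[operator]

    def contains_grid(self, xs: np.ndarray, ys: np.ndarray,
                      zs: np.ndarray) -> np.ndarray:
        """Membership on the tensor grid spanned by 1-D center coordinates."""
        cx, cy, cz = self.center
        X = (xs - cx)[:, None, None]
        Y = (ys - cy)[None, :, None]
        Z = (zs - cz)[None, None, :]
        if self.shape == "sphere":
            return X ** 2 + Y ** 2 + Z ** 2 <= self.outer_radius ** 2
        ax = AXIS_INDEX[self.axis]  # type: ignore[index]
        deltas = [X, Y, Z]
        axial = deltas[ax]
        perp = [deltas[i] for i in range(3) if i != ax]
        r2 = perp[0] ** 2 + perp[1] ** 2
        return (r2 <= self.outer_radius ** 2) & \
            (np.abs(axial) <= self.height / 2)  # type: ignore[operator]

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box (min corner, max corner)."""
        c = np.asarray(self.center)
        if self.shape == "sphere":
            half = np.full(3, self.outer_radius)
        else:
            ax = AXIS_INDEX[self.axis]  # type: ignore[index]
            half = np.full(3, self.outer_radius)
            half[ax] = self.height / 2  # type: ignore[operator]
        return c - half, c + half


@dataclass(frozen=True)
class BodyModel:
    """An ordered set of labeled regions plus blood properties."""

    regions: tuple[Region, ...]
    blood: BloodProperties = field(default_factory=BloodProperties)

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        precs = [r.precedence for r in self.regions]
        if len(set(precs)) != len(precs):
            raise ValueError("region precedences must be unique")

    @property
    def region_names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.regions)

    def region(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def properties(self) -> dict[str, TissueProperties]:
        return {r.name: r.properties for r in self.regions}


@dataclass(frozen=True)
class VoxelGrid:
    """A regular isotropic voxel grid with one region label per voxel.

    ``labels[i, j, k]`` indexes into ``region_names``; voxels outside every
    region carry :data:`EXTERIOR_LABEL`.  Ownership is decided at voxel
    centers (half-open cells); the grid origin is the minimum corner.
    """

    spacing: float
    origin: tuple[float, float, float]
    labels: np.ndarray
    region_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.labels.ndim != 3 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 3-D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return self.spacing ** 3

    def axis_centers(self, axis: int) -> np.ndarray:
        """1-D voxel-center coordinates along one axis (absolute, m)."""
        n = self.labels.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing

    def region_index(self, name: str) -> int:
        try:
            return self.region_names.index(name)
        except ValueError:
            raise KeyError(f"unknown region {name!r}") from None

    def region_mask(self, name: str) -> np.ndarray:
        return self.labels == self.region_index(name)

    def counts(self) -> dict[str, int]:
        """Voxel count per region (exterior under key ``'exterior'``)."""
        out = {name: int((self.labels == i).sum())
               for i, name in enumerate(self.region_names)}
        out["exterior"] = int((self.labels == EXTERIOR_LABEL).sum())
        return out


# ---------------------------------------------------------------------------
# default properties


def load_default_properties() -> tuple[dict[str, TissueProperties],
                                       BloodProperties, dict[str, float]]:
    """Load the shipped tissue-property table.

    Returns ``(tissues, blood, tumor_ratios)`` where ``tumor_ratios`` holds
    the tumor:pancreas perfusion and metabolic ratios.
    """
    text = resources.files("mnph").joinpath(
        "data/tissue_properties.yaml").read_text()
    raw = yaml.safe_load(text)
    tissues = {name: TissueProperties(name=name, **vals)
               for name, vals in raw["tissues"].items()}
    blood = BloodProperties(**raw["blood"])
    return tissues, blood, dict(raw["tumor"])


# ---------------------------------------------------------------------------
# default torso


def build_default_body(tumor_radius: float,
                       properties: Mapping[str, TissueProperties] | None = None,
                       blood: BloodProperties | None = None,
                       tumor_perfusion_ratio: float | None = None,
                       tumor_metabolic_ratio: float | None = None,
                       mion_radius_fraction: float = MION_RADIUS_FRACTION,
                       ) -> BodyModel:
    """Build the standard multilayer torso with an embedded tumor.

    Skin/fat/muscle are concentric cylinders along Y (outer radii 0.126,
    0.1244 and 0.109 m; height 0.55 m), the pancreas is a cylinder along X
    (radius 0.075 m, height 0.1 m), and the tumor is a sphere at the torso
    center with a concentric MION-loaded core of radius
    ``mion_radius_fraction * tumor_radius``.  Placing the tumor on the coil
    axis is the worst case for nanoparticle heating: the eddy-current
    contribution vanishes at the axis.

    Parameters
    ----------
    tumor_radius : float
        Tumor sphere radius in m, within :data:`TUMOR_RADIUS_RANGE`.
    properties, blood
        Overrides for the shipped property table.
    tumor_perfusion_ratio, tumor_metabolic_ratio : float, optional
        Tumor:pancreas ratios; defaults come from the property config.
    """
    lo, hi = TUMOR_RADIUS_RANGE
    if not lo <= tumor_radius <= hi:
        raise ValueError(
            f"tumor_radius {tumor_radius} m outside [{lo}, {hi}] m")
    defaults, default_blood, ratios = load_default_properties()
    props = dict(defaults)
    if properties is not None:
        props.update(properties)
    blood = blood or default_blood
    if tumor_perfusion_ratio is None:
        tumor_perfusion_ratio = ratios["perfusion_ratio"]
    if tumor_metabolic_ratio is None:
        tumor_metabolic_ratio = ratios["metabolic_ratio"]

    if tumor_radius > min(PANCREAS_RADIUS, PANCREAS_HEIGHT / 2):
        raise GeometryError("tumor sphere not contained in pancreas cylinder")

    tumor_props = props.get("tumor") or props["pancreas"].scaled(
        "tumor", perfusion_ratio=tumor_perfusion_ratio,
        metabolic_ratio=tumor_metabolic_ratio)
    mion_props = replace(tumor_props, name="mion")
    origin = (0.0, 0.0, 0.0)

    regions = (
        Region("skin", "cylinder", SKIN_OUTER_RADIUS, origin,
               props["skin"], precedence=0, axis="y", height=TORSO_HEIGHT),
        Region("fat", "cylinder", FAT_OUTER_RADIUS, origin,
               props["fat"], precedence=1, axis="y", height=TORSO_HEIGHT),
        Region("muscle", "cylinder", MUSCLE_OUTER_RADIUS, origin,
               props["muscle"], precedence=2, axis="y", height=TORSO_HEIGHT),
        Region("pancreas", "cylinder", PANCREAS_RADIUS, origin,
               props["pancreas"], precedence=3, axis="x",
               height=PANCREAS_HEIGHT),
        Region("tumor", "sphere", tumor_radius, origin,
               tumor_props, precedence=4),
        Region("mion", "sphere", mion_radius_fraction * tumor_radius, origin,
               mion_props, precedence=5),
    )
    return BodyModel(regions=regions, blood=blood)


def merge_superficial_shells(body: BodyModel) -> BodyModel:
    """Merge the thin fat and skin shells into one ``fat_skin`` region.

    The merged region spans out to the skin outer radius and carries
    shell-volume-weighted average properties (cylindrical shells, so weights
    are proportional to r_out^2 - r_in^2).  Used when the voxel spacing
    cannot resolve the 1.6 mm skin shell.
    """
    names = body.region_names
    if "fat" not in names or "skin" not in names:
        return body
    fat, skin, muscle = (body.region(n) for n in ("fat", "skin", "muscle"))
    w_fat = fat.outer_radius ** 2 - muscle.outer_radius ** 2
    w_skin = skin.outer_radius ** 2 - fat.outer_radius ** 2
    wt = w_fat + w_skin

    def avg(attr: str) -> float:
        return (w_fat * getattr(fat.properties, attr)
                + w_skin * getattr(skin.properties, attr)) / wt

    merged_props = TissueProperties(
        name="fat_skin",
        density=avg("density"),
        specific_heat=avg("specific_heat"),
        conductivity=avg("conductivity"),
        perfusion=avg("perfusion"),
        metabolic_rate=avg("metabolic_rate"),
        electrical_conductivity=avg("electrical_conductivity"),
    )
    merged = Region("fat_skin", "cylinder", skin.outer_radius, skin.center,
                    merged_props, precedence=skin.precedence,
                    axis=skin.axis, height=skin.height)
    regions = tuple(r for r in body.regions if r.name not in ("fat", "skin"))
    return BodyModel(regions=(merged,) + regions, blood=body.blood)


def effective_body(body: BodyModel, spacing: float,
                   merge_superficial: bool | str = "auto") -> BodyModel:
    """Body actually voxelized at ``spacing``.

    With ``merge_superficial='auto'`` the fat and skin shells are merged
    whenever ``spacing`` exceeds :data:`SKIN_RESOLUTION_LIMIT`.
    """
    if merge_superficial == "auto":
        merge_superficial = spacing > SKIN_RESOLUTION_LIMIT
    if merge_superficial and {"fat", "skin"} <= set(body.region_names):
        logger.info(
            "spacing %.4g m > %.4g m: merging fat and skin shells into "
            "'fat_skin'", spacing, SKIN_RESOLUTION_LIMIT)
        return merge_superficial_shells(body)
    return body


def voxelize(body: BodyModel, spacing: float,
             merge_superficial: bool | str = "auto") -> VoxelGrid:
    """Label a regular voxel grid covering the body's bounding box.

    Each voxel is owned by the highest-precedence region containing its
    center; voxels outside every region are exterior.  If the spacing is
    too coarse for the skin shell and merging is disabled, a warning is
    issued because the superficial-heating readout may be unresolved.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    body = effective_body(body, spacing, merge_superficial)
    if "skin" in body.region_names and spacing > 1.6e-3:
        warnings.warn(
            f"spacing {spacing} m exceeds the 1.6 mm skin shell thickness; "
            "the skin layer may be unresolved", stacklevel=2)

    lows, highs = zip(*(r.bounds() for r in body.regions))
    lo = np.min(lows, axis=0)
    hi = np.max(highs, axis=0)
    shape = np.maximum(np.ceil((hi - lo) / spacing - 1e-12).astype(int), 1)
    xs, ys, zs = (lo[i] + (np.arange(shape[i]) + 0.5) * spacing
                  for i in range(3))

    labels = np.full(tuple(shape), EXTERIOR_LABEL, dtype=np.int16)
    order = sorted(range(len(body.regions)),
                   key=lambda i: body.regions[i].precedence)
    for i in order:
        labels[body.regions[i].contains_grid(xs, ys, zs)] = i
    return VoxelGrid(spacing=spacing, origin=tuple(lo), labels=labels,
                     region_names=body.region_names)


def region_volume(grid: VoxelGrid, region: str) -> float:
    """Voxelized volume of a region in m^3 (voxel count x spacing^3)."""
    return int(grid.region_mask(region).sum()) * grid.voxel_volume
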